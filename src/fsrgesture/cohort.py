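"""Cohort experiment runner: the full study on a synthetic cohort.

Generates N synthetic subjects, runs per-subject 10-fold and leave-one-out
cross-validation for the requested classifiers, the sensor-subset ablation,
the combined-database evaluation and the two-session reproducibility test,
and writes the tables and averaged confusion matrices as CSV plus a
deterministic JSON report.

All randomness flows from the root seed: subject ``i`` uses seed
``seed + i`` for its placement variability and recordings, and
``seed + i + SECOND_SESSION_OFFSET`` for the re-donned second session.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig
from .classifiers import TRAINERS, train_knn, train_linear_svm
from .errors import GestureError
from .evaluation import (
    ablation_study,
    cross_validate,
    reproducibility_eval,
    summarize_ablation,
)
from .features import (
    GestureDatabase,
    combine_databases,
    extract_features,
    session_database,
)
from .labels import GestureLabel
from .segmentation import (
    SegmentationConfig,
    apply_normalization,
    compute_normalization,
    timeline_segments,
)
from .synth import (
    default_activation_profile,
    generate_gesture_sequence,
    random_active_sequence,
    simulate_session,
    subject_profile,
)

logger = logging.getLogger(__name__)

SECOND_SESSION_OFFSET = 100_000
N_REPRO_GESTURES = 50


@dataclass
class RunConfig:
    """Fully serializable description of one cohort run; a run is
    reproducible from this object alone."""

    seed: int = 0
    subjects: int = 10
    repetitions: int = 10
    classifiers: tuple[str, ...] = ("linear_svm", "lda", "qda", "knn")
    svm_C: float = 1.0
    knn_k: int = 1
    cv_folds: int = 10
    fold_seed: int = 42
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    run_ablation: bool = True
    run_reproducibility: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _trainer(cfg: RunConfig, name: str):
    if name == "linear_svm":
        return lambda db: train_linear_svm(db, C=cfg.svm_C)
    if name == "knn":
        return lambda db: train_knn(db, k=cfg.knn_k)
    return TRAINERS[name]


def build_subject_database(
    cfg: RunConfig, index: int
) -> tuple[GestureDatabase, "object"]:
    """Generate subject ``index`` (seed ``cfg.seed + index``) and run the
    batch pipeline; returns the database and the subject's profile."""
    seed = cfg.seed + index
    rng = np.random.default_rng(seed)
    profile = subject_profile(default_activation_profile(), rng)
    session = simulate_session(
        profile,
        repetitions=cfg.repetitions,
        acq=cfg.acquisition,
        seed=rng,
        subject_id=f"S{index:02d}",
    )
    return session_database(session, cfg.segmentation), profile


def second_session_database(
    cfg: RunConfig, index: int, profile
) -> GestureDatabase:
    """Re-donned second session: a fresh variability draw around the same
    base profile, a randomized active-gesture sequence (cue-aligned
    windows), plus rest windows from the inter-burst gaps' plateaus."""
    seed = cfg.seed + index + SECOND_SESSION_OFFSET
    rng = np.random.default_rng(seed)
    redonned = subject_profile(default_activation_profile(), rng)
    labels = random_active_sequence(N_REPRO_GESTURES, rng)
    rec = generate_gesture_sequence(
        redonned, labels, acq=cfg.acquisition, seed=rng, subject_id=f"S{index:02d}b"
    )
    norm = compute_normalization(rec)
    pre = apply_normalization(rec, norm)
    segs = timeline_segments(pre)
    return extract_features(pre, segs, subject_id=f"S{index:02d}b")


def run_cohort_experiment(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full cohort study; returns the report dict and, if ``outdir``
    is given, writes the table CSVs, confusion matrices and report.json."""
    report: dict = {
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "subjects": [],
    }
    dbs: list[GestureDatabase] = []
    profiles = []
    cv_rows = []
    per_class_rows = []
    confusions: dict[str, list[pd.DataFrame]] = {name: [] for name in cfg.classifiers}
    for i in range(cfg.subjects):
        try:
            db, profile = build_subject_database(cfg, i)
        except GestureError as exc:  # keep going on per-subject failures
            logger.error("subject %d failed: %s", i, exc)
            continue
        dbs.append(db)
        profiles.append((i, profile))
        report["subjects"].append({"subject_id": db.subject_id, "rows": db.n_rows})
        for name in cfg.classifiers:
            trainer = _trainer(cfg, name)
            res10 = cross_validate(db, trainer, "kfold", cfg.cv_folds, cfg.fold_seed)
            resloo = cross_validate(db, trainer, "loo")
            cv_rows.append(
                {
                    "subject_id": db.subject_id,
                    "classifier": name,
                    "kfold_accuracy": res10.accuracy,
                    "kfold_pooled_accuracy": res10.pooled_accuracy,
                    "loo_accuracy": resloo.accuracy,
                }
            )
            confusions[name].append(res10.confusion)
            for code, acc in res10.per_class_accuracy.items():
                per_class_rows.append(
                    {
                        "subject_id": db.subject_id,
                        "classifier": name,
                        "gesture": GestureLabel(code).name.lower(),
                        "accuracy": acc,
                    }
                )

    cv_table = pd.DataFrame(cv_rows)
    per_class_table = pd.DataFrame(per_class_rows)
    report["per_subject_cv"] = {
        name: {
            "kfold_mean": float(
                cv_table.query("classifier == @name")["kfold_accuracy"].mean()
            ),
            "kfold_sd": float(
                cv_table.query("classifier == @name")["kfold_accuracy"].std()
            ),
            "loo_mean": float(
                cv_table.query("classifier == @name")["loo_accuracy"].mean()
            ),
        }
        for name in cfg.classifiers
    }

    combined = combine_databases(dbs)
    report["combined"] = {}
    for name in cfg.classifiers:
        res = cross_validate(
            combined, _trainer(cfg, name), "kfold", cfg.cv_folds, cfg.fold_seed
        )
        report["combined"][name] = res.accuracy

    ablation_table = summary_table = None
    if cfg.run_ablation:
        trainers = {
            name: _trainer(cfg, name)
            for name in cfg.classifiers
            if name in ("linear_svm", "lda")
        }
        if trainers:
            ablation_table = ablation_study(
                dbs, trainers, k=cfg.cv_folds, seed=cfg.fold_seed
            )
            summary_table = summarize_ablation(ablation_table)
            report["ablation"] = {
                f"{row.sensors}/{row.classifier}": row.mean_accuracy
                for row in summary_table.itertuples()
            }

    repro_rows = []
    if cfg.run_reproducibility:
        for (i, profile), db in zip(profiles, dbs):
            second = second_session_database(cfg, i, profile)
            for name in cfg.classifiers:
                if name not in ("linear_svm", "lda"):
                    continue
                model = _trainer(cfg, name)(db)
                res = reproducibility_eval(model, second)
                repro_rows.append(
                    {
                        "subject_id": db.subject_id,
                        "classifier": name,
                        "accuracy": res.accuracy,
                    }
                )
        repro_table = pd.DataFrame(repro_rows)
        if not repro_table.empty:
            report["reproducibility"] = {
                name: float(
                    repro_table.query("classifier == @name")["accuracy"].mean()
                )
                for name in repro_table["classifier"].unique()
            }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cv_table.to_csv(outdir / "per_subject_cv.csv", index=False)
        per_class_table.to_csv(outdir / "per_class_accuracy.csv", index=False)
        if ablation_table is not None:
            ablation_table.to_csv(outdir / "ablation.csv", index=False)
            summary_table.to_csv(outdir / "ablation_summary.csv", index=False)
        if repro_rows:
            pd.DataFrame(repro_rows).to_csv(
                outdir / "reproducibility.csv", index=False
            )
        for name, mats in confusions.items():
            if mats:
                total = sum(m.to_numpy() for m in mats)
                pct = 100.0 * total / total.sum(axis=1, keepdims=True)
                pd.DataFrame(
                    pct, index=mats[0].index, columns=mats[0].columns
                ).to_csv(outdir / f"confusion_{name}.csv")
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )
    return report
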