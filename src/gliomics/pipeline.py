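"""End-to-end orchestration: phantoms -> features -> selection -> model -> report.

A single :class:`RunConfig` drives every stage; unknown keys are rejected so
stale configs fail loudly.  One root seed is fanned out deterministically to
per-stage seeds, making the whole report reproducible byte-for-byte
(timestamps aside).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gliomics import survival
from gliomics.features import (
    FeatureConfig,
    build_feature_table,
    euler_columns,
    extract_subject_features,
    schema_report,
)
from gliomics.phantom import CohortSpec, PhantomSpec, generate_cohort, generate_phantom_subject

log = logging.getLogger("gliomics")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "gliomics_run"
    # phantom / schema stage
    phantom_shape: tuple[int, int, int] = (64, 64, 64)
    run_schema_stage: bool = True
    # cohort stage
    n_subjects: int = 163
    n_features: int = 100
    n_informative: int = 5
    effect_size: float = 1.5
    class_mix: tuple[int, int, int] = (65, 42, 56)
    # selection / model stage
    selection_mode: str = "sp2"  # sp1 | sp2 | modified
    run_loocv: bool = True
    nested_selection: bool = False
    alpha: float = 0.05
    boost_params: dict = field(default_factory=lambda: dict(survival.DEFAULT_BOOST_PARAMS))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("phantom_shape", "class_mix"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        tag = zlib.crc32(stage.encode()) % (2**31)
        return int(np.random.SeedSequence([self.seed, tag]).generate_state(1)[0] % (2**31))


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            self.elapsed = time.perf_counter() - self.t0
            log.info("stage %s: done in %.1fs", name, self.elapsed)

    return _T()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write features.csv + report.json.

    The report contains the feature-schema counts from a phantom extraction,
    the survival selection summary, and (optionally) the LOOCV confusion
    statistics and per-class regression errors.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}

    if config.run_schema_stage:
        with _timed("schema") as t:
            spec = PhantomSpec(shape=config.phantom_shape, seed=config.stage_seed("phantom"))
            vol, lmap, brain, counts = generate_phantom_subject(spec)
            feats = extract_subject_features(vol, lmap, brain, FeatureConfig())
            realized = {}
            expected = schema_report(FeatureConfig())
            for fam, prefix in [
                ("volume", "vol_"), ("area", "area_"), ("location", "loc_"),
                ("histstat", "hstat_"), ("texture", "tex_"), ("texton", "txn_"),
                ("histgraph", "hg_"), ("euler", "euler_"),
            ]:
                realized[fam] = sum(1 for k in feats if k.startswith(prefix))
            realized["total"] = len(feats)
            report["schema"] = {"expected": expected, "realized": realized,
                                "phantom_region_voxels": counts}
            table = build_feature_table({"phantom_000": feats})
            table.to_csv(out / "features.csv")

    with _timed("cohort"):
        cspec = CohortSpec(
            n_subjects=config.n_subjects,
            n_features=config.n_features,
            n_informative=config.n_informative,
            effect_size=config.effect_size,
            class_mix=config.class_mix,
            seed=config.stage_seed("cohort"),
        )
        features, clinical, planted = generate_cohort(cspec)
        labels = survival.risk_classes(clinical["os_days"])
        report["cohort"] = {
            "n_subjects": len(features),
            "class_counts": {c: int((labels == c).sum()) for c in survival.RISK_CLASSES},
            "planted_features": planted,
        }

    with _timed("selection"):
        sel_seed = config.stage_seed("selection")
        if config.selection_mode == "sp1":
            selected = survival.sp1_select(features, clinical, alpha=config.alpha)
        else:
            euler_cols = euler_columns(features.columns)
            other_cols = [c for c in features.columns if c not in set(euler_cols)]
            selected = []
            if euler_cols:
                selected += survival.rfs_select(features[euler_cols], labels, seed=sel_seed)
            if other_cols:
                selected += survival.rfs_select(features[other_cols], labels, seed=sel_seed)
        if not selected:
            selected = list(features.columns)
        variant = "sp1" if config.selection_mode == "sp1" else "sp2"
        if config.selection_mode == "modified":
            clf = survival.train_risk_classifier(
                features[selected], labels, variant="sp2", seed=sel_seed,
                params=config.boost_params,
            )
            selected = survival.importance_prune(clf)
        report["selection"] = {
            "mode": config.selection_mode,
            "n_selected": len(selected),
            "selected": selected,
            "planted_recovered": sorted(set(selected) & set(planted)),
        }

    with _timed("model"):
        model_seed = config.stage_seed("model")
        clf = survival.train_risk_classifier(
            features[selected], labels, variant=variant, seed=model_seed,
            params=config.boost_params if variant == "sp2" else None,
        )
        regs = survival.train_class_regressors(
            features[selected], clinical, alpha=config.alpha, seed=model_seed,
            params=config.boost_params,
        )
        preds = survival.predict_survival_days(clf, regs, features[selected])
        preds.to_csv(out / "predictions.csv")

    if config.run_loocv:
        with _timed("loocv"):
            report["evaluation"] = survival.loocv_evaluate(
                features[selected],
                clinical,
                variant=variant,
                nested_selection=config.nested_selection,
                alpha=config.alpha,
                seed=model_seed,
                params=config.boost_params,
            )

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    features.to_csv(out / "cohort_features.csv")
    clinical.to_csv(out / "clinical.csv")
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
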