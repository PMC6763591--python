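"""Synthetic multimodal tumor phantoms and survival cohorts with known ground truth.

Phantoms emulate the structure the feature extractors rely on: a brain
ellipsoid containing nested tumor shells (necrosis core inside an enhancing
rim inside an edema halo) with modality-specific contrasts — FLAIR-bright
edema, T1Gd-bright enhancing rim, dark necrosis core — plus Gaussian noise.

Cohorts emulate the survival-analysis setting: per-subject feature vectors in
which a small planted subset drives the hazard through a log-linear Cox-type
model, with survival days calibrated so the realized short/medium/long class
mix matches a target (default 65/42/56 out of 163, the structure of a typical
training cohort).  The generator returns the planted-feature key so selection
procedures can be scored on recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gliomics.io import BrainMask, MultimodalVolume, TissueLabelMap

SHORT_DAYS = 300  # 10 months at 30 days/month
LONG_DAYS = 450  # 15 months


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    center: tuple[float, float, float] | None = None  # default: grid center
    brain_radii: tuple[float, float, float] = (28.0, 28.0, 28.0)
    necrosis_radius: float = 5.0
    enhancing_radius: float = 8.0
    edema_radius: float = 12.0
    tumor_center: tuple[float, float, float] | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sigma: float = 2.0
    seed: int = 0
    # per-modality intensity means: brain tissue, edema, enhancing, necrosis
    intensity_table: dict = field(
        default_factory=lambda: {
            "t1": (100.0, 80.0, 90.0, 40.0),
            "t1gd": (100.0, 85.0, 160.0, 45.0),
            "t2": (90.0, 140.0, 110.0, 120.0),
            "flair": (90.0, 150.0, 115.0, 70.0),
        }
    )

    def __post_init__(self) -> None:
        if not (self.necrosis_radius < self.enhancing_radius < self.edema_radius):
            raise ValueError("radii must be nested: necrosis < enhancing < edema")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def generate_phantom_subject(spec: PhantomSpec):
    """One phantom: volumes, label map, brain mask, and exact region counts."""
    shape = spec.shape
    center = spec.center or tuple((s - 1) / 2.0 for s in shape)
    tcenter = spec.tumor_center or tuple(c + r for c, r in zip(center, (6.0, -4.0, 0.0)))
    for r in (spec.edema_radius,):
        if any(tc + r > s or tc - r < 0 for tc, s in zip(tcenter, shape)):
            raise ValueError("tumor shells exceed the grid")
    brain = _ellipsoid(shape, center, spec.brain_radii)
    edema_all = _ellipsoid(shape, tcenter, (spec.edema_radius,) * 3) & brain
    enh_all = _ellipsoid(shape, tcenter, (spec.enhancing_radius,) * 3) & brain
    nec = _ellipsoid(shape, tcenter, (spec.necrosis_radius,) * 3) & brain
    labels = np.zeros(shape, np.int16)
    labels[edema_all] = 2
    labels[enh_all] = 4
    labels[nec] = 1
    counts = {
        "necrosis": int(nec.sum()),
        "ET": int((labels == 4).sum()),
        "edema": int((labels == 2).sum()),
        "brain": int(brain.sum()),
    }
    counts["WT"] = counts["necrosis"] + counts["ET"] + counts["edema"]

    rng = np.random.default_rng(spec.seed)
    mods = {}
    for mod, (m_brain, m_edema, m_enh, m_nec) in spec.intensity_table.items():
        img = np.zeros(shape)
        img[brain] = m_brain
        img[labels == 2] = m_edema
        img[labels == 4] = m_enh
        img[labels == 1] = m_nec
        if spec.noise_sigma > 0:
            img[brain] += rng.normal(0, spec.noise_sigma, size=int(brain.sum()))
        mods[mod] = img
    vol = MultimodalVolume(
        mods["t1"], mods["t1gd"], mods["t2"], mods["flair"], spacing=spec.spacing
    )
    lmap = TissueLabelMap(labels, spacing=spec.spacing)
    return vol, lmap, BrainMask(brain, spacing=spec.spacing), counts


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 163
    n_features: int = 100
    n_informative: int = 5
    effect_size: float = 1.5  # log-hazard coefficient per planted feature
    class_mix: tuple[int, int, int] = (65, 42, 56)  # short, medium, long
    censoring_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("more informative features than features")
        if abs(sum(self.class_mix)) == 0:
            raise ValueError("empty class mix")


def generate_cohort(spec: CohortSpec):
    """Feature table + survival records with a planted hazard structure.

    Features are iid standard normal; the first ``n_informative`` (returned
    as the recovery key) contribute +effect_size each to the log hazard.
    Survival days follow a Weibull-type model t = exp(a + b*(log U - r)) with
    U ~ Exp(1) and risk score r; a and b are calibrated so the empirical
    300/450-day cut-offs land at the target class-mix quantiles, which pins
    the realized short/medium/long proportions to the targets.

    Returns (features: DataFrame indexed by subject_id, clinical: DataFrame
    with age_years/os_days/event, planted: list of planted feature names).
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, spec.n_features
    X = rng.normal(size=(n, p))
    names = [f"f{j:03d}" for j in range(p)]
    planted = names[: spec.n_informative]
    r = X[:, : spec.n_informative].sum(axis=1) * spec.effect_size
    log_u = np.log(rng.exponential(size=n))
    w = log_u - r  # higher w -> longer survival
    mix = np.asarray(spec.class_mix, float)
    frac = mix / mix.sum()
    q1, q2 = np.quantile(w, [frac[0], frac[0] + frac[1]])
    if q2 <= q1:  # degenerate draw; fall back to a fixed slope
        b, a = 1.0, np.log(SHORT_DAYS) - q1
    else:
        b = np.log(LONG_DAYS / SHORT_DAYS) / (q2 - q1)
        a = np.log(SHORT_DAYS) - b * q1
    os_days = np.maximum(np.exp(a + b * w), 1.0)
    event = np.ones(n, bool)
    if spec.censoring_fraction > 0:
        cens = rng.random(n) < spec.censoring_fraction
        os_days = np.where(cens, os_days * rng.uniform(0.3, 1.0, size=n), os_days)
        event = ~cens
    subjects = [f"S{i:03d}" for i in range(n)]
    features = pd.DataFrame(X, index=pd.Index(subjects, name="subject_id"), columns=names)
    clinical = pd.DataFrame(
        {
            "age_years": rng.uniform(25, 80, size=n).round(1),
            "os_days": os_days,
            "event": event,
        },
        index=features.index,
    )
    return features, clinical, planted


def generate_phantom_cohort(n: int, seed: int = 0, shape=(48, 48, 48)):
    """Small cohort of phantom subjects with geometry-driven survival.

    Tumor radii vary across subjects; the log hazard depends on whole-tumor
    volume and z-extent, so geometric features are the recoverable drivers.
    Returns a list of (subject_id, volume, label_map, brain_mask) plus the
    clinical table.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    risk = np.empty(n)
    for i in range(n):
        nec = rng.uniform(2.5, 5.5)
        enh = nec + rng.uniform(1.5, 4.0)
        ede = enh + rng.uniform(2.0, 5.0)
        spec = PhantomSpec(
            shape=shape,
            brain_radii=(shape[0] * 0.42,) * 3,
            necrosis_radius=nec,
            enhancing_radius=enh,
            edema_radius=ede,
            tumor_center=tuple((s - 1) / 2.0 + d for s, d in zip(shape, (3.0, -2.0, 0.0))),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, lmap, brain, counts = generate_phantom_subject(spec)
        subjects.append((f"P{i:03d}", vol, lmap, brain))
        risk[i] = 2.5 * (counts["WT"] / counts["brain"]) * 100 / 8.0 + 0.15 * (2 * ede)
    risk = (risk - risk.mean()) / risk.std()
    log_u = np.log(rng.exponential(size=n))
    w = log_u - 2.0 * risk
    q1, q2 = np.quantile(w, [0.4, 0.66])
    b = np.log(LONG_DAYS / SHORT_DAYS) / max(q2 - q1, 1e-6)
    a = np.log(SHORT_DAYS) - b * q1
    clinical = pd.DataFrame(
        {
            "age_years": rng.uniform(25, 80, size=n).round(1),
            "os_days": np.maximum(np.exp(a + b * w), 1.0),
            "event": True,
        },
        index=pd.Index([s[0] for s in subjects], name="subject_id"),
    )
    return subjects, clinical


def fixture_masks() -> dict[str, tuple[np.ndarray, int]]:
    """Named 2D binary masks with known Euler characteristic chi."""
    disk = np.zeros((15, 15), bool)
    yy, xx = np.mgrid[0:15, 0:15]
    disk[(yy - 7) ** 2 + (xx - 7) ** 2 <= 25] = True
    annulus = disk & ~((yy - 7) ** 2 + (xx - 7) ** 2 <= 9)
    two = np.zeros((12, 12), bool)
    two[1:5, 1:5] = True
    two[7:11, 7:11] = True
    u_shape = np.zeros((10, 10), bool)
    u_shape[2:8, 2:4] = True
    u_shape[2:8, 6:8] = True
    u_shape[6:8, 2:8] = True
    return {
        "disk": (disk, 1),
        "annulus": (annulus, 0),
        "two_disks": (two, 2),
        "u_shape": (u_shape, 1),
    }
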