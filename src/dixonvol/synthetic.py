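"""Seeded paired two-arm synthetic liver cohorts.

Each phantom subject carries, at baseline and after 8 weeks of "diet", a
ground-truth voxel-wise fat-fraction field on a deformed-ellipsoid liver
mask, magnitude Dixon renderings (water/fat/in-phase/opposed-phase) of that
field, and single-voxel MRS amplitudes with realistic T1/T2 decay from a
20 mm VOI placed deep in the mask. Subject-level severity targets are drawn
per arm; the 8-week value is the baseline plus an independent change draw,
which is what induces the within-subject pairing.

Severity can be parameterised on two scales:

``lv_percent`` (default)
    The subject-level variable is LV%_TH — the percentage of liver volume
    with PDFF above a steatosis threshold (default 5.56%). The field is
    shifted so the masked exceedance fraction hits the target exactly (up to
    voxel-count quantisation). Defaults calibrate both arms to the study
    conditions this package emulates: MUFA 73.95 ± 21.95 at baseline with
    paired change −6.66 ± 11.06 %-points, multifactorial 73.64 ± 19.85 with
    change −17.61 ± 13.43.

``mean_pdff``
    The subject-level variable is the masked mean PDFF (%); a preset with
    MRS-scale arm distributions (MUFA 9.47 ± 8.89, change −1.4 ± 2.7;
    multifactorial 9.18 ± 7.78, change −4.0 ± 4.5) is provided by
    :func:`mean_pdff_effects`.

Because both scales live on [0, 100], drawing targets from unbounded
normals and clamping would bias the realized moments (the configured SDs
put appreciable mass beyond the bounds). The generator instead
moment-matches: baseline targets come from a truncated normal whose parent
parameters are solved so the *truncated* mean/SD equal the configured ones,
and the change distribution's parent parameters are solved (deterministic
quadrature + root finding) so the realized change after end-point clamping
has the configured mean/SD. Cohort-level recovery of the configured
distributions is therefore unbiased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.stats import norm, truncnorm

from .fatmap import place_voi
from .grid import GeometryError, PDFFMap, VOISpec, VolumeGrid
from .mrs import AcquisitionConstants, MRSMeasurement, decay_factor

__all__ = [
    "ARM_MUFA",
    "ARM_MULTIFACTORIAL",
    "EffectDistribution",
    "GeneratorConfig",
    "DixonImages",
    "TimepointTruth",
    "PhantomSubject",
    "mean_pdff_effects",
    "generate_liver_mask",
    "generate_pdff_field",
    "generate_pdff_field_lv",
    "render_dixon_images",
    "simulate_mrs_signals",
    "draw_subject_targets",
    "generate_cohort",
    "write_cohort",
]

ARM_MUFA = "MUFA"
ARM_MULTIFACTORIAL = "MULTIFACTORIAL"

BASELINE = "baseline"
WEEK8 = "week8"


@dataclass(frozen=True)
class EffectDistribution:
    """Per-arm subject-level distributions: baseline severity and paired change.

    ``baseline`` is (mean, sd) of the baseline value on the configured effect
    scale; ``change`` is (mean, sd) of the 8-week-minus-baseline change in
    the same units (%-points).
    """

    baseline: tuple[float, float]
    change: tuple[float, float]

    def __post_init__(self) -> None:
        if self.baseline[1] < 0 or self.change[1] < 0:
            raise ValueError("standard deviations must be >= 0")


def _default_arm_effects() -> dict[str, EffectDistribution]:
    # LV%_5.56 scale: baseline and paired-change distributions per arm.
    return {
        ARM_MUFA: EffectDistribution(baseline=(73.95, 21.95), change=(-6.66, 11.06)),
        ARM_MULTIFACTORIAL: EffectDistribution(baseline=(73.64, 19.85), change=(-17.61, 13.43)),
    }


def mean_pdff_effects() -> dict[str, EffectDistribution]:
    """Arm effects on the mean-PDFF scale (MRS-calibrated preset)."""
    return {
        ARM_MUFA: EffectDistribution(baseline=(9.47, 8.89), change=(-1.4, 2.7)),
        ARM_MULTIFACTORIAL: EffectDistribution(baseline=(9.18, 7.78), change=(-4.0, 4.5)),
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Units: spatial quantities in mm, PDFF and LV% in percent, change
    distributions in %-points, signal quantities in arbitrary units.
    """

    n_per_arm: dict[str, int] = field(
        default_factory=lambda: {ARM_MUFA: 21, ARM_MULTIFACTORIAL: 18}
    )
    grid_shape: tuple[int, int, int] = (24, 24, 16)
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 5.0)
    arm_effects: dict[str, EffectDistribution] = field(default_factory=_default_arm_effects)
    #: scale on which arm_effects are expressed: "lv_percent" or "mean_pdff"
    effect_scale: str = "lv_percent"
    #: steatosis threshold (%) defining LV% when effect_scale == "lv_percent"
    lv_threshold: float = 5.56
    #: voxel-level spread of PDFF within one liver (%-points)
    within_field_sd: float = 5.5
    #: spatial smoothing scale of the PDFF field (mm)
    correlation_length: float = 15.0
    #: additive MRI-minus-MRS bias (%-points); MRS reads lower by this much
    method_bias: float = 2.07
    #: SD of the MRI-vs-MRS disagreement beyond the bias (%-points)
    method_noise_sd: float = 2.56
    #: additive Gaussian noise on rendered water/fat channels (signal units)
    image_noise_sd: float = 5.0
    #: common signal scale of the rendered images
    proton_density: float = 1000.0
    voi_side: float = 20.0
    thresholds: tuple[float, ...] = (5.56, 7.97, 8.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_arm:
            raise ValueError("n_per_arm must name at least one arm")
        for arm, n in self.n_per_arm.items():
            if n < 2:
                raise ValueError(f"arm {arm!r}: need >= 2 subjects, got {n}")
            if arm not in self.arm_effects:
                raise ValueError(f"arm {arm!r} has no entry in arm_effects")
        if len(self.grid_shape) != 3 or any(a < 8 for a in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be > 0 per axis")
        if self.effect_scale not in ("lv_percent", "mean_pdff"):
            raise ValueError(f"unknown effect_scale {self.effect_scale!r}")
        for name in ("within_field_sd", "method_noise_sd", "image_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")
        if not 0 < self.lv_threshold < 100:
            raise ValueError("lv_threshold must lie in (0, 100)")
        if self.proton_density <= 0:
            raise ValueError("proton_density must be > 0")

    # -- JSON round trip --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["arm_effects"] = {
            arm: {"baseline": list(e.baseline), "change": list(e.change)}
            for arm, e in self.arm_effects.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "arm_effects" in d:
            d["arm_effects"] = {
                arm: EffectDistribution(tuple(e["baseline"]), tuple(e["change"]))
                for arm, e in d["arm_effects"].items()
            }
        for key in ("grid_shape", "voxel_size", "thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


class DixonImages(NamedTuple):
    water: VolumeGrid
    fat: VolumeGrid
    in_phase: VolumeGrid
    opposed_phase: VolumeGrid


@dataclass
class TimepointTruth:
    """Ground truth and rendered data for one subject-timepoint."""

    truth: PDFFMap
    true_mean: float
    #: brute-force true LV% per declared threshold
    true_lv: dict[float, float]
    dixon: DixonImages
    mrs: MRSMeasurement
    #: fat fraction (0-1) actually encoded in the MRS amplitudes (includes
    #: the between-method bias/noise perturbation)
    mrs_fat_fraction: float


@dataclass
class PhantomSubject:
    subject_id: str
    arm: str
    mask: VolumeGrid
    voi: VOISpec
    #: severity targets drawn on the configured effect scale
    target_baseline: float
    target_week8: float
    timepoints: dict[str, TimepointTruth]


# ---------------------------------------------------------------------------
# moment-matched target samplers


@lru_cache(maxsize=64)
def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a [lo, hi]-truncated normal with given moments."""
    if sd == 0:
        return mean, 0.0

    def resid(p):
        mu, logs = p
        s = np.exp(logs)
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success or max(abs(np.asarray(resid(sol.x)))) > 1e-6:
        raise RuntimeError(
            f"could not moment-match truncated normal to mean={mean}, sd={sd} on [{lo},{hi}]"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _clamped_change_moments(
    b_nodes: np.ndarray, b_weights: np.ndarray, mu: float, sigma: float, lo: float, hi: float
) -> tuple[float, float]:
    """Mean/SD of D = clamp(B + C, lo, hi) - B with C ~ N(mu, sigma),
    B discretised on quadrature nodes/weights."""
    h, hw = np.polynomial.hermite_e.hermegauss(96)  # probabilists' Hermite
    hw = hw / hw.sum()
    c = mu + sigma * h  # (nc,)
    x = b_nodes[:, None] + c[None, :]
    d = np.clip(x, lo, hi) - b_nodes[:, None]
    w = b_weights[:, None] * hw[None, :]
    m1 = float((w * d).sum())
    m2 = float((w * d * d).sum())
    var = max(m2 - m1 * m1, 0.0)
    return m1, np.sqrt(var)


@lru_cache(maxsize=64)
def _change_parent(
    b_mean: float, b_sd: float, mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) of the change draw so the clamped change matches."""
    if sd == 0:
        return mean, 0.0
    bmu, bsig = _truncnorm_parent(b_mean, b_sd, lo, hi)
    if bsig == 0:
        b_nodes = np.array([bmu])
        b_weights = np.array([1.0])
    else:
        a, b = (lo - bmu) / bsig, (hi - bmu) / bsig
        # quadrature on the truncated baseline density via its quantiles
        q = (np.arange(400) + 0.5) / 400
        b_nodes = truncnorm.ppf(q, a, b, loc=bmu, scale=bsig)
        b_weights = np.full(400, 1.0 / 400)

    # skip the solve when clamping is negligible for the nominal parameters
    m0, s0 = _clamped_change_moments(b_nodes, b_weights, mean, sd, lo, hi)
    if abs(m0 - mean) < 1e-9 and abs(s0 - sd) < 1e-9:
        return mean, sd

    def resid(p):
        m, s = _clamped_change_moments(b_nodes, b_weights, p[0], np.exp(p[1]), lo, hi)
        return [m - mean, s - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success or max(abs(np.asarray(resid(sol.x)))) > 1e-6:
        raise RuntimeError(
            f"could not calibrate change distribution to mean={mean}, sd={sd}"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def draw_subject_targets(
    effects: EffectDistribution,
    n: int,
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (baseline, week8) severity targets on [lo, hi].

    Baseline from the moment-matched truncated normal; week8 = baseline +
    calibrated change draw, clamped to the bounds. Realized baseline and
    change moments are unbiased for the configured ones.
    """
    b_mean, b_sd = effects.baseline
    c_mean, c_sd = effects.change
    if b_sd == 0:
        baseline = np.full(n, float(b_mean))
    else:
        bmu, bsig = _truncnorm_parent(b_mean, b_sd, lo, hi)
        a, b = (lo - bmu) / bsig, (hi - bmu) / bsig
        baseline = truncnorm.ppf(rng.uniform(size=n), a, b, loc=bmu, scale=bsig)
    if c_sd == 0:
        change = np.full(n, float(c_mean))
    else:
        cmu, csig = _change_parent(b_mean, b_sd, c_mean, c_sd, lo, hi)
        change = rng.normal(cmu, csig, size=n)
    week8 = np.clip(baseline + change, lo, hi)
    return baseline, week8


# ---------------------------------------------------------------------------
# phantom geometry and fields


def generate_liver_mask(
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    seed: int | np.random.Generator,
) -> VolumeGrid:
    """A connected, randomly deformed ellipsoid strictly inside the lattice.

    The one-voxel border slab is always empty; if the deformation
    disconnects the shape, the largest connected component is kept.
    """
    if len(grid_shape) != 3 or any(a < 8 for a in grid_shape):
        raise ValueError(f"grid_shape axes must all be >= 8, got {grid_shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = tuple(int(a) for a in grid_shape)
    coords = [np.arange(n, dtype=float) * s for n, s in zip(shape, voxel_size)]
    centre = [c[-1] / 2.0 for c in coords]
    # semi-axes as random fractions of the half-extent, kept inside border
    semi = [rng.uniform(0.55, 0.72) * c for c in centre]
    q = np.zeros(shape)
    for ax in range(3):
        rel = ((coords[ax] - centre[ax]) / semi[ax]) ** 2
        q = q + rel.reshape([-1 if i == ax else 1 for i in range(3)])
    mask = q < 1.0
    # smooth multiplicative deformation of the implicit surface
    noise = ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=[max(n / 6.0, 1.0) for n in shape], mode="nearest"
    )
    s = noise.std()
    if s > 0:
        mask = (q + 0.25 * noise / s) < 1.0
    # enforce an empty border slab
    border = np.zeros(shape, dtype=bool)
    border[1:-1, 1:-1, 1:-1] = True
    mask &= border
    if not mask.any():  # deformation ate the whole shape: fall back
        mask = (q < 1.0) & border
    labels, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, nlab + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return VolumeGrid(mask.astype(np.float64), voxel_size)


def _smooth_noise(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    correlation_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    w = rng.standard_normal(shape)
    if correlation_length > 0:
        sigma = [correlation_length / s for s in voxel_size]
        w = ndimage.gaussian_filter(w, sigma=sigma, mode="nearest")
    return w


def _scaled_field_noise(
    mask: VolumeGrid, within_field_sd: float, correlation_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Smoothed Gaussian field with masked mean 0 and masked SD = within_field_sd."""
    m = mask.values > 0.5
    w = _smooth_noise(mask.shape, mask.voxel_size, correlation_length, rng)
    s = w[m].std()
    if s > 0 and within_field_sd > 0:
        w = w * (within_field_sd / s)
    else:
        w = np.zeros_like(w)
    return w - w[m].mean()


def generate_pdff_field(
    mask: VolumeGrid,
    target_mean: float,
    within_field_sd: float,
    correlation_length: float,
    seed: int | np.random.Generator,
) -> PDFFMap:
    """Spatially correlated PDFF field with a prescribed masked mean (%).

    The smoothed Gaussian field is clipped to [0, 100] and iteratively
    recentred so the masked mean lands within 0.1 %-points of the target
    (machine precision in practice, except at the 0/100 saturation edges).
    """
    if not 0.0 <= target_mean <= 100.0:
        raise ValueError(f"target_mean must lie in [0, 100], got {target_mean}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = mask.values > 0.5
    noise = _scaled_field_noise(mask, within_field_sd, correlation_length, rng)
    if target_mean in (0.0, 100.0):  # fully saturated: clipping is exact
        return PDFFMap(mask.like(np.full(mask.shape, target_mean)), mask)
    base = target_mean + noise
    shift = 0.0
    fvals = np.clip(base, 0.0, 100.0)
    for _ in range(500):
        fvals = np.clip(base + shift, 0.0, 100.0)
        mu = fvals[m].mean()
        delta = target_mean - mu
        if abs(delta) < 1e-10:
            break
        shift += delta
    return PDFFMap(mask.like(fvals), mask)


def generate_pdff_field_lv(
    mask: VolumeGrid,
    target_lv: float,
    threshold: float,
    within_field_sd: float,
    correlation_length: float,
    seed: int | np.random.Generator,
) -> PDFFMap:
    """PDFF field whose masked LV%_threshold equals the target exactly.

    The smoothed field is shifted additively so that the number of masked
    voxels strictly above ``threshold`` equals round(target_lv/100 * n);
    realized LV% is the nearest value the voxel count can represent.
    """
    if not 0.0 <= target_lv <= 100.0:
        raise ValueError(f"target_lv must lie in [0, 100], got {target_lv}")
    if not 0.0 < threshold < 100.0:
        raise ValueError(f"threshold must lie in (0, 100), got {threshold}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = mask.values > 0.5
    n = int(m.sum())
    k = int(round(target_lv / 100.0 * n))
    if within_field_sd == 0:
        if k == 0:
            value = threshold / 2.0
        elif k == n:
            value = min(threshold * 1.5, (threshold + 100.0) / 2.0)
        else:
            raise ValueError(
                "within_field_sd = 0 yields a constant field, which can only "
                "realize LV% targets of 0 or 100"
            )
        return PDFFMap(mask.like(np.full(mask.shape, value)), mask)
    noise = _scaled_field_noise(mask, within_field_sd, correlation_length, rng)
    vals = threshold + noise  # arbitrary anchor; the shift does the work
    inside = np.sort(vals[m])  # ascending
    if k == 0:
        shift = threshold - inside[-1]  # max lands exactly on threshold (not >)
    elif k == n:
        shift = threshold - inside[0] + 1e-9 * (1.0 + threshold)
    else:
        shift = threshold - 0.5 * (inside[n - k - 1] + inside[n - k])
    fvals = np.clip(vals + shift, 0.0, 100.0)
    return PDFFMap(mask.like(fvals), mask)


def render_dixon_images(
    truth: PDFFMap,
    proton_density: float = 1000.0,
    image_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DixonImages:
    """Render magnitude Dixon images from a ground-truth PDFF field.

    Noiseless relation per voxel: fat = PD * t/100, water = PD * (1 - t/100),
    in-phase = water + fat, opposed-phase = |water - fat|. Gaussian noise is
    added to the water and fat channels independently (then floored at 0)
    before composing the in/opposed-phase images.
    """
    if proton_density < 0:
        raise ValueError(f"proton_density must be >= 0, got {proton_density}")
    t = truth.map.values / 100.0
    fat = proton_density * t
    water = proton_density * (1.0 - t)
    if image_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        water = water + rng.normal(0.0, image_noise_sd, size=water.shape)
        fat = fat + rng.normal(0.0, image_noise_sd, size=fat.shape)
        water = np.maximum(water, 0.0)
        fat = np.maximum(fat, 0.0)
    grid = truth.map
    return DixonImages(
        water=grid.like(water),
        fat=grid.like(fat),
        in_phase=grid.like(water + fat),
        opposed_phase=grid.like(np.abs(water - fat)),
    )


def simulate_mrs_signals(
    truth: PDFFMap,
    voi: VOISpec,
    acq: AcquisitionConstants = AcquisitionConstants(),
    scale: float = 1000.0,
    fat_fraction: float | None = None,
) -> MRSMeasurement:
    """Raw MRS peak amplitudes carrying forward T1/T2 decay.

    The encoded fat fraction defaults to the mean truth over VOI ∩ mask
    (divided by 100); ``fat_fraction`` overrides it (used by the cohort
    generator to inject a between-method bias/noise perturbation). Raw
    amplitudes are Sf = scale * f * decay_f and Sw = scale * (1-f) * decay_w,
    so the paired relaxation correction inverts the model exactly.
    """
    if fat_fraction is None:
        voi_mask = place_voi(truth, voi)
        sel = (voi_mask.values > 0.5) & truth.mask_bool
        if not sel.any():
            raise GeometryError("VOI does not intersect the liver mask")
        fat_fraction = float(truth.map.values[sel].mean()) / 100.0
    if not 0.0 <= fat_fraction <= 1.0:
        raise ValueError(f"fat fraction must lie in [0, 1], got {fat_fraction}")
    a = acq
    sf = scale * fat_fraction * decay_factor(a.TE, a.TR, a.T1f, a.T2f)
    sw = scale * (1.0 - fat_fraction) * decay_factor(a.TE, a.TR, a.T1w, a.T2w)
    return MRSMeasurement(sw_raw=sw, sf_raw=sf, acq=a)


# ---------------------------------------------------------------------------
# cohort assembly


def _voi_for_mask(mask: VolumeGrid, side: float) -> VOISpec:
    """Cube centred on the deepest mask voxel (max distance-to-boundary)."""
    dist = ndimage.distance_transform_edt(mask.values > 0.5, sampling=mask.voxel_size)
    idx = np.unravel_index(int(np.argmax(dist)), mask.shape)
    centre = tuple(mask.origin[ax] + mask.voxel_size[ax] * idx[ax] for ax in range(3))
    return VOISpec(center=centre, side=side)


def _brute_lv(truth: PDFFMap, thresholds: tuple[float, ...]) -> dict[float, float]:
    vals = truth.map.values[truth.mask_bool]
    n = vals.size
    return {float(th): 100.0 * float((vals > th).sum()) / n for th in thresholds}


def _make_timepoint(
    cfg: GeneratorConfig,
    mask: VolumeGrid,
    voi: VOISpec,
    target: float,
    acq: AcquisitionConstants,
    rng: np.random.Generator,
) -> TimepointTruth:
    if cfg.effect_scale == "lv_percent":
        truth = generate_pdff_field_lv(
            mask, target, cfg.lv_threshold, cfg.within_field_sd, cfg.correlation_length, rng
        )
    else:
        truth = generate_pdff_field(
            mask, target, cfg.within_field_sd, cfg.correlation_length, rng
        )
    dixon = render_dixon_images(truth, cfg.proton_density, cfg.image_noise_sd, rng)
    voi_mask = place_voi(truth, voi)
    sel = (voi_mask.values > 0.5) & truth.mask_bool
    f_true = float(truth.map.values[sel].mean()) / 100.0
    perturb = (rng.normal(0.0, cfg.method_noise_sd) if cfg.method_noise_sd > 0 else 0.0)
    f_mrs = float(np.clip(f_true + (perturb - cfg.method_bias) / 100.0, 0.0, 1.0))
    mrs = simulate_mrs_signals(truth, voi, acq, scale=cfg.proton_density, fat_fraction=f_mrs)
    return TimepointTruth(
        truth=truth,
        true_mean=float(truth.map.values[truth.mask_bool].mean()),
        true_lv=_brute_lv(truth, cfg.thresholds),
        dixon=dixon,
        mrs=mrs,
        mrs_fat_fraction=f_mrs,
    )


def generate_cohort(
    config: GeneratorConfig,
    acq: AcquisitionConstants = AcquisitionConstants(),
) -> list[PhantomSubject]:
    """Generate the full paired two-arm cohort of phantom subjects.

    Fully reproducible from ``config.seed``: a root seed sequence is forked
    once for the arm-level target draws and once per subject, so cohorts of
    different sizes share per-subject streams.
    """
    root = np.random.SeedSequence(config.seed)
    arms = list(config.n_per_arm.items())
    total = sum(n for _, n in arms)
    ss = root.spawn(1 + total)
    target_rng = np.random.default_rng(ss[0])

    subjects: list[PhantomSubject] = []
    child = 1
    for arm, n in arms:
        effects = config.arm_effects[arm]
        base_t, week8_t = draw_subject_targets(effects, n, target_rng)
        for i in range(n):
            rng = np.random.default_rng(ss[child])
            child += 1
            mask = generate_liver_mask(config.grid_shape, config.voxel_size, rng)
            voi = _voi_for_mask(mask, config.voi_side)
            tps = {
                BASELINE: _make_timepoint(config, mask, voi, float(base_t[i]), acq, rng),
                WEEK8: _make_timepoint(config, mask, voi, float(week8_t[i]), acq, rng),
            }
            subjects.append(
                PhantomSubject(
                    subject_id=f"{arm.lower()[:4]}-{i:04d}",
                    arm=arm,
                    mask=mask,
                    voi=voi,
                    target_baseline=float(base_t[i]),
                    target_week8=float(week8_t[i]),
                    timepoints=tps,
                )
            )
    return subjects


def write_cohort(
    subjects: list[PhantomSubject],
    out_dir: str | Path,
    config: GeneratorConfig | None = None,
) -> Path:
    """Write per-subject NIfTI volumes and the cohort manifest CSV.

    Layout: ``<out>/<subject>/<timepoint>_{water,fat,inphase,opposed,truth}.nii.gz``
    plus one ``mask.nii.gz`` per subject; ``manifest.csv`` lists one row per
    subject-timepoint with file paths, raw MRS amplitudes and the VOI.
    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        s.mask.to_nifti(sdir / "mask.nii.gz")
        for tp, data in s.timepoints.items():
            files = {
                "water": data.dixon.water,
                "fat": data.dixon.fat,
                "inphase": data.dixon.in_phase,
                "opposed": data.dixon.opposed_phase,
                "truth": data.truth.map,
            }
            for name, grid in files.items():
                grid.to_nifti(sdir / f"{tp}_{name}.nii.gz")
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "arm": s.arm,
                    "timepoint": tp,
                    "mask_path": str(sdir / "mask.nii.gz"),
                    **{f"{k}_path": str(sdir / f"{tp}_{k}.nii.gz") for k in files},
                    "sw_raw": data.mrs.sw_raw,
                    "sf_raw": data.mrs.sf_raw,
                    "voi_x": s.voi.center[0],
                    "voi_y": s.voi.center[1],
                    "voi_z": s.voi.center[2],
                    "voi_side": s.voi.side,
                }
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if config is not None:
        config.to_json(out / "generator_config.json")
    return manifest
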