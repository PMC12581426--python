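"""Synthetic inputs with known ground truth.

Three generators make every downstream stage testable without any scan data:

* a skull-base-like *phantom*: a bone plate carrying a half-ellipsoid fossa
  that opens cranially, with non-ossified lateral gaps carved as rectangular
  notches so that the lateral closure planes are functionally necessary. The
  cavity volume below the cranial closure plane is known in closed form,
  ``(2/3)·π·a·b·c``, and every landmark of the measurement vocabulary is
  placed by construction;
* a *cohort* table with the group structure of the clinical sample
  (three sagittal classes recruited by Wits appraisal, vertical and
  transverse groups, sex), class-specific anterior-volume shifts, and a
  calibrated rank correlation between the anterior volume and Wits;
* paired *rater measurements* with a controlled bias and noise, feeding the
  Bland–Altman agreement analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .stats import classify_sagittal, classify_transverse, classify_vertical
from .types import LandmarkSet, SizingError, VoxelVolume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_fossa_phantom",
    "analytic_fossa_volume",
    "expected_cavity_volume",
    "generate_cohort",
    "generate_rater_pairs",
]

# ---------------------------------------------------------------------------
# Phantom geometry constants (mm). The plate extends to the full grid
# footprint so the only non-bone space below the rim is the fossa itself and
# the lateral notches.
PLATE_MARGIN = 2.0      #: bone beyond the fossa rim in x and y
HEADROOM = 1.5          #: soft-tissue space above the plate top
NOTCH_HALF_WIDTH = 1.0  #: lateral notch half-width along y
NOTCH_DEPTH = 1.5       #: lateral notch depth below the rim
NOTCH_INSET = 0.5       #: notch starts this far inside the fossa equator


@dataclass(frozen=True)
class PhantomSpec:
    """Half-ellipsoid fossa phantom.

    ``a``, ``b``, ``c`` are the semi-axes (mm) along x (width), y (length)
    and z (depth); the fossa opens cranially (+z) at the plate top ``z = 0``.
    Defaults approximate the adult linear medians (width ~11, length ~10,
    height ~8 mm). Intensities are in GU; 1800/0 with 50 GU noise sits well
    inside the clinical grayscale window.
    """

    a: float = 5.5
    b: float = 5.0
    c: float = 8.0
    plate_thickness: float = 9.5
    bone_intensity: float = 1800.0
    soft_intensity: float = 0.0
    noise_sd: float = 50.0
    spacing: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.bone_intensity <= self.soft_intensity:
            raise ValueError("bone_intensity must exceed soft_intensity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.plate_thickness <= self.c:
            raise ValueError("plate_thickness must exceed the fossa depth c")

    @property
    def lateral_plane_offset(self) -> float:
        """|x| position of the lateral closure planes (at the notch mouths)."""
        return self.a - NOTCH_INSET


def analytic_fossa_volume(spec: PhantomSpec) -> float:
    """Closed-form cavity volume below the cranial closure plane: (2/3)·π·a·b·c."""
    return (2.0 / 3.0) * math.pi * spec.a * spec.b * spec.c


def expected_cavity_volume(spec: PhantomSpec, kerf: float = 0.0) -> float:
    """Exact volume of the cavity region the closure planes actually keep.

    The kept region is the half-ellipsoid truncated by the cranial plane at
    ``z = -kerf/2`` and by the lateral planes at ``|x| = x_L - kerf/2``; its
    volume is a one-dimensional integral of elliptic-segment cross sections,
    evaluated by adaptive quadrature to machine precision. With ``kerf = 0``
    and tangent lateral planes it reduces to :func:`analytic_fossa_volume`.
    """
    if kerf < 0:
        raise ValueError("kerf must be >= 0")
    a, b, c = spec.a, spec.b, spec.c
    h = kerf / 2.0
    x0 = spec.lateral_plane_offset - kerf / 2.0
    if h >= c or x0 <= 0:
        return 0.0
    x1 = min(x0, a * math.sqrt(max(0.0, 1.0 - (h / c) ** 2)))
    if x1 <= 0:
        return 0.0

    def segment_area(x: float) -> float:
        f = 1.0 - (x / a) ** 2
        if f <= 0:
            return 0.0
        big_b = b * math.sqrt(f)
        big_c = c * math.sqrt(f)
        if big_c <= h:
            return 0.0
        tau = h / big_c
        return big_b * big_c * (math.acos(tau) - tau * math.sqrt(1.0 - tau * tau))

    value, _ = integrate.quad(segment_area, -x1, x1, limit=200)
    return float(value)


def _phantom_landmarks(spec: PhantomSpec) -> LandmarkSet:
    a, b, c = spec.a, spec.b, spec.c
    x_l = spec.lateral_plane_offset
    points = {
        # orientation / measurement landmarks
        "sella_mid": (0.0, 0.0, -c / 2.0),
        "tuberculum": (0.0, b, 0.0),
        "dorsum_posterior_cranial": (0.0, -b - 1.0, 0.5),
        "interclinoid_left": (-a, 0.0, 0.0),
        "interclinoid_right": (a, 0.0, 0.0),
        "nasofrontal_suture": (0.0, b + 63.6, 0.0),
        "length_ant": (0.0, b, 0.0),
        "length_post": (0.0, -b, 0.0),
        "height_sup": (0.0, 0.0, 0.0),
        "height_inf": (0.0, 0.0, -c),
        # anterior/posterior split plane
        "pcp": (1.5, -2.0, 0.0),
        "dorsum": (-1.5, -2.0, 0.0),
        "floor_caudal": (0.0, -3.5, -c),
        # cranial closure plane (z = 0)
        "cranial_1": (x_l - 1.0, 0.0, 0.0),
        "cranial_2": (-x_l + 1.0, 1.5, 0.0),
        "cranial_3": (0.0, -1.5, 0.0),
        # lateral closure planes (x = ±x_L) over the notch mouths
        "lat_left_1": (-x_l, 0.0, -NOTCH_DEPTH),
        "lat_left_2": (-x_l, 1.2, 0.0),
        "lat_left_3": (-x_l, -1.2, 0.0),
        "lat_right_1": (x_l, 0.0, -NOTCH_DEPTH),
        "lat_right_2": (x_l, 1.2, 0.0),
        "lat_right_3": (x_l, -1.2, 0.0),
    }
    return LandmarkSet(points)


def generate_fossa_phantom(
    spec: PhantomSpec,
    grid_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[VoxelVolume, LandmarkSet, float]:
    """Build the phantom volume, its landmark set and the analytic cavity volume.

    ``grid_offset`` shifts the voxel grid by a sub-voxel amount relative to
    the geometry; convergence experiments average over such offsets so that
    lattice-alignment luck does not masquerade as accuracy.

    Returns ``(volume, landmarks, true_volume)`` where ``true_volume`` is the
    closed-form half-ellipsoid volume below the cranial closure plane.
    """
    s = spec.spacing
    if PLATE_MARGIN / s < 2 or (spec.plate_thickness - spec.c) / s < 2:
        raise SizingError(
            f"spacing {s} mm leaves fewer than 2 voxels of plate margin; "
            "use a finer grid or a thicker plate"
        )
    a, b, c = spec.a, spec.b, spec.c
    extent = {
        0: (-(a + PLATE_MARGIN), a + PLATE_MARGIN),
        1: (-(b + PLATE_MARGIN), b + PLATE_MARGIN),
        2: (-spec.plate_thickness, HEADROOM),
    }
    coords = []
    origin = []
    for ax in range(3):
        lo, hi = extent[ax]
        n = int(math.ceil((hi - lo) / s))
        start = lo + s / 2.0 + float(grid_offset[ax])
        coords.append(start + s * np.arange(n))
        origin.append(start)
    xs, ys, zs = coords
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    in_slab = (Z <= 0.0) & (Z >= -spec.plate_thickness)
    in_fossa = (Z <= 0.0) & ((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0)
    in_notch = (
        (np.abs(Y) <= NOTCH_HALF_WIDTH)
        & (Z <= 0.0)
        & (Z >= -NOTCH_DEPTH)
        & (np.abs(X) >= spec.lateral_plane_offset)
    )
    bone = in_slab & ~in_fossa & ~in_notch

    values = np.where(bone, spec.bone_intensity, spec.soft_intensity).astype(np.float32)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape).astype(np.float32)

    vol = VoxelVolume(values=values, spacing=(s, s, s), origin=tuple(origin))
    return vol, _phantom_landmarks(spec), analytic_fossa_volume(spec)


def phantom_sample_regions(vol: VoxelVolume, spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean sample regions (bone, soft tissue) for the adaptive threshold.

    Small boxes placed where the phantom is certainly bone (deep plate below
    the fossa floor) and certainly soft (headroom above the plate top), kept
    clear of interfaces so blurred scans still sample pure material.
    """
    xs, ys, zs = vol.axis_coordinates()
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    core = (np.abs(X) <= 1.5) & (np.abs(Y) <= 1.5)
    bone_box = core & (Z >= -spec.plate_thickness + 0.2) & (Z <= -spec.plate_thickness + 0.9)
    soft_box = core & (Z >= 0.6) & (Z <= HEADROOM - 0.2)
    bone_box = np.broadcast_to(bone_box, vol.shape).copy()
    soft_box = np.broadcast_to(soft_box, vol.shape).copy()
    if not bone_box.any() or not soft_box.any():
        raise SizingError("grid too coarse to place threshold sample regions")
    return bone_box, soft_box


# ---------------------------------------------------------------------------
# Cohort generation


def _apportion(n: int, weights) -> np.ndarray:
    """Largest-remainder apportionment of n subjects across groups."""
    w = np.asarray(weights, dtype=float)
    quota = n * w / w.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts


@lru_cache(maxsize=128)
def _calibrated_truncnorm(mean_target: float, sd: float, lower: float, upper: float):
    """Frozen truncated normal on [lower, upper] whose mean equals mean_target.

    Group means in the clinical table describe subjects *after* recruitment by
    the classification cut-offs, so the generative distribution is a truncated
    normal whose location is solved (not equal to the group mean).
    """
    if not lower < mean_target < upper:
        raise ValueError(
            f"target mean {mean_target} not interior to truncation interval "
            f"[{lower}, {upper}]"
        )

    def truncated_mean(loc: float) -> float:
        alpha = (lower - loc) / sd
        beta = (upper - loc) / sd
        return float(stats.truncnorm.mean(alpha, beta, loc=loc, scale=sd))

    loc = optimize.brentq(
        lambda m: truncated_mean(m) - mean_target,
        mean_target - 8 * sd,
        mean_target + 8 * sd,
        xtol=1e-9,
    )
    alpha = (lower - loc) / sd
    beta = (upper - loc) / sd
    return stats.truncnorm(alpha, beta, loc=loc, scale=sd)


_WITS_INTERVALS = {"I": (-2.0, 2.0), "II": (2.0, math.inf), "III": (-math.inf, -2.0)}
_MLNL_INTERVALS = {
    "hypodivergent": (-math.inf, 20.5),
    "neutral": (20.5, 26.5),
    "hyperdivergent": (26.5, math.inf),
}
_MEMSP_INTERVALS = {"symmetric": (0.0, 2.0), "asymmetric": (2.0, math.inf)}


def _default_wits():
    return {"I": (0.5, 1.3), "II": (5.4, 3.0), "III": (-8.9, 4.4)}


def _default_mlnl():
    return {"hypodivergent": (16.6, 2.3), "neutral": (23.4, 1.6), "hyperdivergent": (32.8, 5.1)}


def _default_memsp():
    return {"symmetric": (1.0, 0.6), "asymmetric": (4.2, 2.0)}


def _default_vol_a_shift():
    # anterior-volume medians by class: 719.6 / 784.9 / 646.4 mm³
    return {"I": 0.0, "II": 65.3, "III": -73.2}


def _default_linear():
    # pooled medians and IQR/1.349 spreads of the linear measures
    return {
        "st_length": (10.1, 1.8),
        "st_width": (11.1, 1.3),
        "st_height": (7.9, 1.0),
        "st_diameter": (12.1, 1.5),
        "cb": (69.0, 4.5),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Class-conditional covariates are truncated normals supported on their
    classification interval with means matching the clinical group summaries.
    The anterior volume carries class-specific mean shifts (mm³) relative to
    class I and a within-class coupling to the Wits percentile calibrated so
    the cohort-level Spearman correlation lands near ``spearman_target``.
    The posterior volume is class-independent and the total volume is their
    sum, so the anterior/posterior split is the only class-discriminative
    volumetric signal.
    """

    n_per_class: int = 30
    wits_params: dict = field(default_factory=_default_wits)
    mlnl_params: dict = field(default_factory=_default_mlnl)
    mlnl_weights: tuple = (30, 28, 32)  # hypodivergent, neutral, hyperdivergent
    memsp_params: dict = field(default_factory=_default_memsp)
    memsp_weights: tuple = (57, 33)  # symmetric, asymmetric
    male_fraction: float = 44.0 / 90.0
    vol_a_mean: float = 719.6
    vol_a_shift: dict = field(default_factory=_default_vol_a_shift)
    vol_a_sd: float = 150.0
    vol_p_mean: float = 195.0
    vol_p_sd: float = 75.0
    linear_params: dict = field(default_factory=_default_linear)
    spearman_target: float = 0.337
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if abs(self.spearman_target) > 1:
            raise ValueError("|spearman_target| must be <= 1")
        for params in (self.wits_params, self.mlnl_params, self.memsp_params):
            for mean, sd in params.values():
                if sd <= 0:
                    raise ValueError("all SDs must be positive")
        if self.vol_a_sd <= 0 or self.vol_p_sd <= 0:
            raise ValueError("volume SDs must be positive")

    def zero_effect(self) -> "CohortSpec":
        """Copy with no class shifts and no Wits coupling (null cohort)."""
        return replace(
            self,
            vol_a_shift={k: 0.0 for k in self.vol_a_shift},
            spearman_target=0.0,
        )


def _lambda_cache_key(spec: CohortSpec) -> tuple:
    return (
        tuple(sorted((k, v[0], v[1]) for k, v in spec.wits_params.items())),
        tuple(sorted(spec.vol_a_shift.items())),
        spec.vol_a_sd,
        spec.spearman_target,
    )


_LAMBDA_CACHE: dict[tuple, float] = {}


def _solve_coupling(spec: CohortSpec) -> float:
    """Within-class copula coefficient giving the requested cohort Spearman ρ.

    The class structure alone already induces a rank correlation (classes are
    ordered in both Wits and anterior volume), so the coefficient is found by
    a seeded internal simulation at large n and inverse interpolation.
    """
    if spec.spearman_target == 0:
        return 0.0
    key = _lambda_cache_key(spec)
    if key in _LAMBDA_CACHE:
        return _LAMBDA_CACHE[key]

    rng = np.random.default_rng(20240517)
    n_cal = 3000
    classes = list(spec.wits_params)
    z_w = []
    wits = []
    base = []
    for cls in classes:
        mean, sd = spec.wits_params[cls]
        lo, hi = _WITS_INTERVALS[cls]
        dist = _calibrated_truncnorm(mean, sd, lo, hi)
        u = rng.uniform(size=n_cal)
        wits.append(dist.ppf(u))
        z_w.append(stats.norm.ppf(u))
        base.append(np.full(n_cal, spec.vol_a_mean + spec.vol_a_shift[cls]))
    z_w = np.concatenate(z_w)
    wits = np.concatenate(wits)
    base = np.concatenate(base)
    eps = rng.standard_normal(z_w.size)

    lam_grid = np.linspace(-0.95, 0.95, 39)
    rho_grid = np.empty_like(lam_grid)
    for i, lam in enumerate(lam_grid):
        vol = base + spec.vol_a_sd * (lam * z_w + math.sqrt(1 - lam * lam) * eps)
        rho_grid[i] = stats.spearmanr(wits, vol).statistic
    order = np.argsort(rho_grid)
    lam = float(np.interp(spec.spearman_target, rho_grid[order], lam_grid[order]))
    lam = float(np.clip(lam, -0.95, 0.95))
    _LAMBDA_CACHE[key] = lam
    return lam


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort table (3 × n_per_class subjects).

    Columns: subject_id, sex, wits_mm, mlnl_deg, memsp_mm, the five linear
    measures, vol_t/vol_a/vol_p (mm³) and the derived class labels, which are
    consistent with the covariates by construction.
    """
    rng = np.random.default_rng(spec.seed)
    classes = [c for c in ("I", "II", "III") for _ in range(spec.n_per_class)]
    n = len(classes)
    lam = _solve_coupling(spec)

    wits = np.empty(n)
    z_w = np.empty(n)
    for cls in ("I", "II", "III"):
        sel = np.array([c == cls for c in classes])
        mean, sd = spec.wits_params[cls]
        lo, hi = _WITS_INTERVALS[cls]
        dist = _calibrated_truncnorm(mean, sd, lo, hi)
        u = rng.uniform(size=sel.sum())
        wits[sel] = dist.ppf(u)
        z_w[sel] = stats.norm.ppf(u)

    def grouped_values(intervals: dict, params: dict, weights) -> np.ndarray:
        names = list(params)
        counts = _apportion(n, weights)
        membership = np.repeat(np.arange(len(names)), counts)
        rng.shuffle(membership)
        out = np.empty(n)
        for gi, name in enumerate(names):
            sel = membership == gi
            mean, sd = params[name]
            lo, hi = intervals[name]
            dist = _calibrated_truncnorm(mean, sd, lo, hi)
            out[sel] = dist.ppf(rng.uniform(size=sel.sum()))
        return out

    mlnl = grouped_values(_MLNL_INTERVALS, spec.mlnl_params, spec.mlnl_weights)
    memsp = grouped_values(_MEMSP_INTERVALS, spec.memsp_params, spec.memsp_weights)

    n_male = int(round(spec.male_fraction * n))
    sex = np.array(["m"] * n_male + ["f"] * (n - n_male))
    rng.shuffle(sex)

    shifts = np.array([spec.vol_a_shift[c] for c in classes])
    eps = rng.standard_normal(n)
    vol_a = spec.vol_a_mean + shifts + spec.vol_a_sd * (
        lam * z_w + math.sqrt(1 - lam * lam) * eps
    )
    vol_a = np.maximum(vol_a, 0.0)
    vp_dist = _calibrated_truncnorm(
        spec.vol_p_mean, spec.vol_p_sd, 0.0, math.inf
    )
    vol_p = vp_dist.ppf(rng.uniform(size=n))
    vol_t = vol_a + vol_p

    data = {
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "sex": sex,
        "wits_mm": wits,
        "mlnl_deg": mlnl,
        "memsp_mm": memsp,
    }
    for name, (mean, sd) in spec.linear_params.items():
        data[name] = np.maximum(rng.normal(mean, sd, size=n), 0.0)
    data["vol_t"] = vol_t
    data["vol_a"] = vol_a
    data["vol_p"] = vol_p
    df = pd.DataFrame(data)
    df["sagittal_class"] = [classify_sagittal(w) for w in df["wits_mm"]]
    df["vertical_class"] = [classify_vertical(v) for v in df["mlnl_deg"]]
    df["transverse_class"] = [classify_transverse(v) for v in df["memsp_mm"]]
    return df


def generate_rater_pairs(
    n: int, bias: float, sd: float, seed: int = 0, base_mean: float = 10.0, base_sd: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Paired measurements ``(x, x + bias + ε)`` with ε ~ Normal(0, sd)."""
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.normal(base_mean, base_sd, size=n)
    y = x + bias + rng.normal(0.0, sd, size=n)
    return x, y
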