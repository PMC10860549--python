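"""Synthetic pelvic phantoms and cohorts with known ground truth.

Two levels of synthesis:

``make_phantom``
    A voxelized geometric phantom — an ellipsoidal bladder, a PTV
    primitive (box, ellipsoid or capped cylinder), and a dose field that
    falls off sigmoidally with signed distance from the PTV surface,
    ``dose = prescription * sigmoid(-d / falloff) + noise``.  The sigmoid
    is a deliberately simple stand-in for a planned dose distribution; it
    preserves the monotone dose-distance structure that the overlap
    features exploit.

``make_cohort``
    A feature/endpoint table for n plans.  In ``voxel`` mode each plan is
    a full phantom pushed through the geometry and dosimetry pipeline.  In
    ``fast`` mode feature vectors are sampled directly from distributions
    calibrated to the shipped cohort summaries (normal for the variables
    with published mean/SD, log-normal matched to median/IQR for the
    skewed volumes, and a Gaussian copula whose correlation decays with
    margin distance for the overlap percentages, isotonically projected so
    each plan's percentages are non-decreasing in margin).  Endpoints follow a
    configurable generative linear rule; by default the shipped cohort
    equations with residual SD calibrated as endpoint_SD * sqrt(1 - R^2).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .dosimetry import DoseGrid, endpoints as dose_endpoints, renormalize_d95
from .geometry import (
    DEFAULT_MARGINS_CM,
    MarginSchedule,
    StructureMask,
    extract_wall,
    margin_column,
    spatial_features,
)
from .prediction import cohort_summaries, registry

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "GenerativeRule",
    "make_phantom",
    "make_cohort",
]

# Normal quantile spacing between the quartiles: q3 - q1 = 2 * 0.6745 sigma.
_IQR_TO_SD = 1.3489795003921634


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, dose model, and seed for one voxel phantom.

    Grid index order is (z, y, x); the default 240 x 192 x 256 mm volume
    (48 x 96 x 128 voxels at 5 x 2 x 2 mm) holds a realistically sized
    bladder and PTV with 3 cm of clearance so the largest expansion is not
    clipped.  Positions are physical mm relative to the grid origin.
    """

    shape: tuple[int, int, int] = (48, 96, 128)
    spacing_mm: tuple[float, float, float] = (5.0, 2.0, 2.0)
    bladder_center_mm: tuple[float, float, float] = (120.0, 96.0, 72.0)
    bladder_semiaxes_mm: tuple[float, float, float] = (33.0, 40.0, 40.0)
    ptv_kind: str = "box"  # box | ellipsoid | cylinder
    ptv_center_mm: tuple[float, float, float] = (122.5, 96.0, 128.0)
    ptv_size_mm: tuple[float, float, float] = (80.0, 70.0, 50.0)
    prescription_gy: float = 50.0
    falloff_mm: float = 8.0
    noise_sd_gy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.falloff_mm <= 0:
            raise ValueError("falloff length must be positive")
        if self.noise_sd_gy < 0:
            raise ValueError("noise sd must be non-negative")
        if self.ptv_kind not in ("box", "ellipsoid", "cylinder"):
            raise ValueError(f"unknown PTV primitive {self.ptv_kind!r}")


def _grid_coords(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, semiaxes):
    zz, yy, xx = coords
    cz, cy, cx = center
    az, ay, ax = semiaxes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _box(coords, center, size):
    zz, yy, xx = coords
    out = np.ones(zz.shape, dtype=bool)
    for g, c, s in zip((zz, yy, xx), center, size):
        out &= np.abs(g - c) <= s / 2.0
    return out


def _cylinder(coords, center, size):
    """Capped cylinder along z: size = (length_z, diameter_y, diameter_x)."""
    zz, yy, xx = coords
    cz, cy, cx = center
    lz, dy, dx = size
    radial = ((yy - cy) / (dy / 2.0)) ** 2 + ((xx - cx) / (dx / 2.0)) ** 2 <= 1.0
    return radial & (np.abs(zz - cz) <= lz / 2.0)


def _check_bounds(mask_occ, extent_mm, spacing, label, clearance_mm=0.0):
    if not mask_occ.any():
        raise ValueError(f"{label} primitive lies outside the grid")
    idx = np.argwhere(mask_occ)
    lo = idx.min(axis=0) * np.asarray(spacing)
    hi = idx.max(axis=0) * np.asarray(spacing)
    ext = np.asarray(extent_mm)
    if (lo < clearance_mm).any() or (hi > ext - clearance_mm).any():
        raise ValueError(
            f"{label} primitive violates the {clearance_mm:g} mm grid clearance"
        )


def make_phantom(spec: PhantomSpec):
    """Build (bladder, ptv, dose, truth) for one phantom.

    ``truth`` records the analytic primitive volumes and the dose-model
    parameters.  The dose field is *not* renormalized; the pipeline's
    renormalization step owns that.
    """
    rng = np.random.default_rng(spec.seed)
    coords = _grid_coords(spec.shape, spec.spacing_mm)
    extent = tuple((n - 1) * s for n, s in zip(spec.shape, spec.spacing_mm))

    bladder_occ = _ellipsoid(coords, spec.bladder_center_mm, spec.bladder_semiaxes_mm)
    builder = {"box": _box, "ellipsoid": _ellipsoid, "cylinder": _cylinder}[spec.ptv_kind]
    ptv_arg = (
        tuple(s / 2.0 for s in spec.ptv_size_mm)
        if spec.ptv_kind == "ellipsoid"
        else spec.ptv_size_mm
    )
    ptv_occ = builder(coords, spec.ptv_center_mm, ptv_arg)

    _check_bounds(bladder_occ, extent, spec.spacing_mm, "bladder")
    _check_bounds(ptv_occ, extent, spec.spacing_mm, "PTV", clearance_mm=30.0)

    bladder = StructureMask(bladder_occ, spec.spacing_mm, label="bladder")
    ptv = StructureMask(ptv_occ, spec.spacing_mm, label="ptv")

    d_out = ndimage.distance_transform_edt(~ptv_occ, sampling=spec.spacing_mm)
    d_in = ndimage.distance_transform_edt(ptv_occ, sampling=spec.spacing_mm)
    signed = d_out - d_in  # negative inside the PTV
    dose_vals = spec.prescription_gy / (1.0 + np.exp(signed / spec.falloff_mm))
    if spec.noise_sd_gy > 0:
        dose_vals = dose_vals + rng.normal(0.0, spec.noise_sd_gy, size=dose_vals.shape)
    dose = DoseGrid(np.clip(dose_vals, 0.0, None), spec.spacing_mm)

    az, ay, ax = spec.bladder_semiaxes_mm
    truth = {
        "bladder_volume_mm3": 4.0 / 3.0 * np.pi * az * ay * ax,
        "ptv_kind": spec.ptv_kind,
        "prescription_gy": spec.prescription_gy,
        "falloff_mm": spec.falloff_mm,
        "seed": spec.seed,
    }
    return bladder, ptv, dose, truth


@dataclass(frozen=True)
class GenerativeRule:
    """A known linear feature -> endpoint relation for recovery tests."""

    response: str
    intercept: float
    betas: dict[str, float]
    sigma: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic cohort.

    ``calibration`` names which shipped cohort's predictor distributions
    the sampler targets.  ``rules`` overrides the default endpoint
    generation (shipped equations + calibrated residual noise).
    """

    n: int = 49
    calibration: str = "combined"
    mode: str = "fast"  # fast | voxel
    rules: tuple[GenerativeRule, ...] | None = None
    copula_rho: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if self.mode not in ("fast", "voxel"):
            raise ValueError(f"unknown cohort mode {self.mode!r}")
        if not 0 <= self.copula_rho < 1:
            raise ValueError("copula correlation must lie in [0, 1)")


def _lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    mu = np.log(median)
    sigma = np.log(iqr[1] / iqr[0]) / _IQR_TO_SD
    return mu, sigma


def _summary_moments(entry: dict) -> tuple[float, float]:
    """(mean, sd) for a summary row, approximating median/IQR rows by
    median and IQR-derived sd."""
    if "mean" in entry:
        return entry["mean"], entry["sd"]
    lo, hi = entry["iqr"]
    return entry["median"], (hi - lo) / _IQR_TO_SD


def _sample_overlap_block(rng, stats, prefix, margins, n, rho):
    """Overlap percentages across margins via a Gaussian copula whose
    correlation decays with margin distance (lag-1 correlation ``rho``,
    AR(1) structure), clipped to [0, 100] and projected onto the monotone
    cone (isotonic regression) per plan.

    Adjacent margins differ by small geometric increments, so their
    correlation must exceed that of distant margins; the AR structure also
    keeps monotonicity violations rare, so the isotonic projection barely
    perturbs the calibrated marginal means.
    """
    from scipy.optimize import isotonic_regression

    k = len(margins)
    corr = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, k)) @ chol.T
    means = np.empty(k)
    sds = np.empty(k)
    for j, x in enumerate(margins):
        means[j], sds[j] = _summary_moments(stats[margin_column(prefix, x)])
    vals = np.clip(means + sds * z, 0.0, 100.0)
    bad = np.flatnonzero((np.diff(vals, axis=1) < 0).any(axis=1))
    for i in bad:
        vals[i] = isotonic_regression(vals[i]).x
    return pd.DataFrame(vals, columns=[margin_column(prefix, x) for x in margins])


def _default_rules(calibration: str) -> list[GenerativeRule]:
    """Endpoint rules from the shipped cohort equations, residual noise
    calibrated as endpoint_SD * sqrt(1 - R^2)."""
    summ = cohort_summaries()[calibration]
    rules = []
    for m in registry():
        if m.cohort != calibration:
            continue
        sd = summ["endpoints"][m.endpoint]["sd"]
        rules.append(GenerativeRule(
            response=m.endpoint if m.endpoint == "Dmean" else m.endpoint,
            intercept=m.intercept,
            betas=dict(m.terms),
            sigma=sd * np.sqrt(max(0.0, 1.0 - m.r2)),
        ))
    return rules


def _endpoint_column(name: str) -> str:
    return "Dmean_gy" if name == "Dmean" else name.replace("Gy", "") + "_cc"


def _fast_cohort(spec: CohortSpec, rng) -> pd.DataFrame:
    stats = cohort_summaries()[spec.calibration]["predictors"]
    n = spec.n
    margins = DEFAULT_MARGINS_CM

    vbw_m, vbw_s = _summary_moments(stats["Vbw_cc"])
    vbw = np.clip(rng.normal(vbw_m, vbw_s, n), 10.0, None)
    mu, sg = _lognormal_params(stats["Vbladder_cc"]["median"],
                               tuple(stats["Vbladder_cc"]["iqr"]))
    vbladder = np.maximum(rng.lognormal(mu, sg, n), vbw + 1.0)
    mu, sg = _lognormal_params(stats["VPTV_cc"]["median"], tuple(stats["VPTV_cc"]["iqr"]))
    vptv = rng.lognormal(mu, sg, n)

    df = pd.DataFrame({"Vbw_cc": vbw, "Vbladder_cc": vbladder, "VPTV_cc": vptv})
    df = pd.concat([
        df,
        _sample_overlap_block(rng, stats, "Pbw", margins, n, spec.copula_rho),
        _sample_overlap_block(rng, stats, "Pb", margins, n, spec.copula_rho),
    ], axis=1)
    return df


def _voxel_cohort(spec: CohortSpec, rng) -> pd.DataFrame:
    """Full geometry+dosimetry pipeline on n randomized phantoms.

    Bladder size follows the calibrated log-normal volume distribution
    (within voxelization limits); PTV-to-bladder proximity varies to
    spread the overlap features.
    """
    stats = cohort_summaries()[spec.calibration]["predictors"]
    mu, sg = _lognormal_params(stats["Vbladder_cc"]["median"],
                               tuple(stats["Vbladder_cc"]["iqr"]))
    rows = []
    base = PhantomSpec()
    for i in range(spec.n):
        vol_cc = float(np.clip(rng.lognormal(mu, sg), 150.0, 550.0))
        # sphere-equivalent radius, mildly flattened in z
        r = (3.0 * vol_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        semi = (0.85 * r, 1.08 * r, 1.08 * r)
        gap = float(rng.uniform(-10.0, 25.0))  # PTV edge offset from bladder edge
        ptv_size = base.ptv_size_mm
        center_x = base.bladder_center_mm[2] + semi[2] + gap + ptv_size[2] / 2.0
        pspec = replace(
            base,
            bladder_semiaxes_mm=semi,
            ptv_center_mm=(base.ptv_center_mm[0], base.ptv_center_mm[1], center_x),
            noise_sd_gy=0.5,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bladder, ptv, dose, _ = make_phantom(pspec)
        wall = extract_wall(bladder)
        feats = spatial_features(bladder, ptv, MarginSchedule(), wall=wall)
        dose_n = renormalize_d95(dose, ptv, pspec.prescription_gy)
        ep = dose_endpoints(dose_n, wall)
        rows.append({**feats.as_columns(), **ep.as_columns()})
    return pd.DataFrame(rows)


def make_cohort(spec: CohortSpec):
    """Generate a cohort table plus its generative ground truth.

    Returns ``(CohortTable, truth)`` where ``truth`` maps each endpoint to
    its :class:`GenerativeRule` (fast mode) or is empty (voxel mode, where
    the endpoints come from the simulated dose, not a linear rule).
    """
    from .regression import CohortTable  # local import to avoid cycle

    rng = np.random.default_rng(spec.seed)
    if spec.mode == "voxel":
        df = _voxel_cohort(spec, rng)
        return CohortTable(df, cohort=spec.calibration), {}

    df = _fast_cohort(spec, rng)
    rules = list(spec.rules) if spec.rules is not None else _default_rules(spec.calibration)
    truth = {}
    for rule in rules:
        missing = [k for k in rule.betas if k not in df.columns]
        if missing:
            raise KeyError(f"generative rule {rule.response!r} needs columns {missing}")
        y = rule.intercept + sum(b * df[k] for k, b in rule.betas.items())
        if rule.sigma > 0:
            y = y + rng.normal(0.0, rule.sigma, spec.n)
        df[_endpoint_column(rule.response)] = y
        truth[rule.response] = rule
    return CohortTable(df, cohort=spec.calibration), truth
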