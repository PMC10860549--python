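"""Dose-grid endpoints for the bladder wall.

A plan's dose distribution is renormalized so that 95% of the PTV receives
the prescription (50 Gy by default), after which VxGy (absolute cm^3 of the
wall receiving at least x Gy, x = 10..45 in 5 Gy steps) and the mean wall
dose are read directly from the voxel dose values — no histogram binning.
D95 uses the no-interpolation order-statistic definition: the largest dose
d such that at least the requested fraction of structure voxels receive
>= d.  "Receiving x Gy" is implemented inclusively (dose >= x), the
standard cumulative-DVH convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import StructureMask, volume_cc

__all__ = [
    "DoseGrid",
    "DoseEndpoints",
    "OARCriterion",
    "CriterionResult",
    "DVH_THRESHOLDS_GY",
    "dose_percentile",
    "renormalize_d95",
    "vx_cc",
    "dmean",
    "endpoints",
    "check_criteria",
]

DVH_THRESHOLDS_GY = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0)


@dataclass
class DoseGrid:
    """3D absorbed-dose field (Gy) on the same grid as the structure masks."""

    dose_gy: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        if self.dose_gy.ndim != 3 or self.dose_gy.size == 0:
            raise ValueError("dose_gy must be a non-empty 3D array")
        if not np.isfinite(self.dose_gy).all() or (self.dose_gy < 0).any():
            raise ValueError("dose values must be finite and non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    # duck-typed against StructureMask.same_grid
    @property
    def occupancy(self) -> np.ndarray:
        return self.dose_gy

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.dose_gy * factor, self.spacing_mm, self.origin_mm)


def _mask_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if dose.dose_gy.shape != mask.occupancy.shape or dose.spacing_mm != mask.spacing_mm \
            or dose.origin_mm != mask.origin_mm:
        raise ValueError(
            f"dose grid and mask {mask.label!r} are not on the same grid; "
            "resampling is not supported"
        )
    return dose.dose_gy[mask.occupancy]


@dataclass
class DoseEndpoints:
    """Bladder-wall DVH endpoints: VxGy in cm^3 and Dmean in Gy."""

    v_gy_cc: dict[float, float]
    dmean_gy: float

    def as_columns(self) -> dict[str, float]:
        cols = {f"V{int(t)}_cc": self.v_gy_cc[t] for t in sorted(self.v_gy_cc)}
        cols["Dmean_gy"] = self.dmean_gy
        return cols

    @staticmethod
    def endpoint_names() -> list[str]:
        return [f"V{int(t)}Gy" for t in DVH_THRESHOLDS_GY] + ["Dmean"]


@dataclass(frozen=True)
class OARCriterion:
    """A dose-volume limit: V(threshold_gy) must be < limit (strictly).

    ``kind`` is "cc" for an absolute-volume limit or "percent" for a limit on
    the percentage of the structure volume.
    """

    structure: str
    threshold_gy: float
    limit: float
    kind: str = "cc"

    def __post_init__(self) -> None:
        if self.limit < 0:
            raise ValueError("criterion limit must be non-negative")
        if self.kind not in ("cc", "percent"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")


@dataclass
class CriterionResult:
    criterion: OARCriterion
    measured: float
    passed: bool


def dose_percentile(dose: DoseGrid, mask: StructureMask, volume_fraction: float) -> float:
    """Largest dose d such that at least ``volume_fraction`` of the mask's
    voxels receive >= d (order statistic, no interpolation)."""
    if not 0 < volume_fraction <= 1:
        raise ValueError("volume_fraction must lie in (0, 1]")
    doses = _mask_doses(dose, mask)
    if doses.size == 0:
        raise ValueError(f"mask {mask.label!r} is empty")
    k = int(np.ceil(volume_fraction * doses.size))  # k-th largest
    return float(np.partition(doses, doses.size - k)[doses.size - k])


def renormalize_d95(
    dose: DoseGrid, ptv: StructureMask, prescription_gy: float = 50.0
) -> DoseGrid:
    """Globally rescale the dose so D95 of the PTV equals the prescription."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    d95 = dose_percentile(dose, ptv, 0.95)
    if d95 <= 0:
        raise ValueError("PTV D95 is zero; cannot renormalize")
    return dose.scaled(prescription_gy / d95)


def vx_cc(dose: DoseGrid, mask: StructureMask, threshold_gy: float) -> float:
    """Absolute volume (cm^3) of mask voxels receiving >= threshold_gy."""
    if mask.is_empty():
        return 0.0
    doses = _mask_doses(dose, mask)
    return float((doses >= threshold_gy).sum()) * mask.voxel_volume_mm3 / 1000.0


def dmean(dose: DoseGrid, mask: StructureMask) -> float:
    """Mean dose (Gy) over the mask (uniform voxels => volume-weighted)."""
    doses = _mask_doses(dose, mask)
    if doses.size == 0:
        raise ValueError(f"mask {mask.label!r} is empty")
    return float(doses.mean())


def endpoints(dose: DoseGrid, wall: StructureMask) -> DoseEndpoints:
    """All eight VxGy endpoints plus Dmean for the bladder wall.

    The caller is responsible for renormalizing the dose first.
    """
    if wall.is_empty():
        raise ValueError("wall mask is empty")
    doses = _mask_doses(dose, wall)
    voxel_cc = wall.voxel_volume_mm3 / 1000.0
    v = {t: float((doses >= t).sum()) * voxel_cc for t in DVH_THRESHOLDS_GY}
    return DoseEndpoints(v_gy_cc=v, dmean_gy=float(doses.mean()))


def check_criteria(
    dose: DoseGrid,
    masks: dict[str, StructureMask],
    criteria: list[OARCriterion],
) -> list[CriterionResult]:
    """Evaluate dose-volume criteria against named structures.

    Comparisons are strict: a measured value exactly equal to the limit
    fails.  Percent criteria measure VxGy as a percentage of the structure
    volume.
    """
    results = []
    for crit in criteria:
        if crit.structure not in masks:
            raise KeyError(f"criterion references unknown structure {crit.structure!r}")
        mask = masks[crit.structure]
        measured = vx_cc(dose, mask, crit.threshold_gy)
        if crit.kind == "percent":
            total = volume_cc(mask)
            if total == 0:
                raise ValueError(f"structure {crit.structure!r} is empty")
            measured = 100.0 * measured / total
        results.append(CriterionResult(crit, measured, measured < crit.limit))
    return results
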