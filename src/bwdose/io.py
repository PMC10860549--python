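"""Reading and writing the package's on-disk formats.

Masks and dose grids are NIfTI volumes (spacing and origin from the
header; arrays stored in (x, y, z) file order and converted to the
package's (z, y, x) index order on read).  Feature and cohort tables are
CSV with the frozen column schema; fitted models round-trip through JSON
with their full sufficient statistics.  Text artifacts carry ``#``
provenance comment lines (tool version, seed) which pandas skips on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .dosimetry import DoseGrid
from .geometry import StructureMask
from .regression import CohortTable, FittedModel, ScreeningReport

__all__ = [
    "read_mask",
    "write_mask",
    "read_dose",
    "write_dose",
    "read_table",
    "write_table",
    "model_to_dict",
    "model_from_dict",
    "save_models",
    "load_models",
]


def _affine(spacing_zyx, origin_zyx) -> np.ndarray:
    sz, sy, sx = spacing_zyx
    oz, oy, ox = origin_zyx
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = (ox, oy, oz)
    return aff


def _grid_from_nifti(img) -> tuple[np.ndarray, tuple, tuple]:
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
    sx, sy, sz = np.abs(np.diag(aff[:3, :3]))
    ox, oy, oz = aff[:3, 3]
    # file order (x, y, z) -> package order (z, y, x)
    return data.transpose(2, 1, 0), (float(sz), float(sy), float(sx)), (
        float(oz), float(oy), float(ox))


def read_mask(path: str | Path, label: str = "") -> StructureMask:
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    return StructureMask(data > 0, spacing, origin, label=label or Path(path).stem)


def write_mask(mask: StructureMask, path: str | Path) -> None:
    arr = mask.occupancy.transpose(2, 1, 0).astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(mask.spacing_mm, mask.origin_mm)), str(path))


def read_dose(path: str | Path) -> DoseGrid:
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    return DoseGrid(data.astype(float), spacing, origin)


def write_dose(dose: DoseGrid, path: str | Path) -> None:
    arr = dose.dose_gy.transpose(2, 1, 0).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, _affine(dose.spacing_mm, dose.origin_mm)), str(path))


def _provenance_lines(seed=None) -> list[str]:
    lines = [f"# bwdose {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path, seed=None) -> None:
    with open(path, "w") as f:
        for line in _provenance_lines(seed):
            f.write(line + "\n")
        df.to_csv(f, index=False)


def read_table(path: str | Path, cohort: str = "combined") -> CohortTable:
    return CohortTable(pd.read_csv(path, comment="#"), cohort=cohort)


def model_to_dict(model: FittedModel) -> dict:
    d = {
        "response": model.response,
        "predictors": list(model.predictors),
        "coefficients": dict(model.coefficients),
        "intercept": model.intercept,
        "n": model.n,
        "p": model.p,
        "residual_ss": model.residual_ss,
        "s2": model.s2,
        "xtx_inverse": np.asarray(model.xtx_inverse).tolist(),
        "r2": model.r2,
        "adjusted_r2": model.adjusted_r2,
        "vif": dict(model.vif),
        "column_means": dict(model.column_means),
        "provenance": {k: v for k, v in model.provenance.items()},
    }
    if model.screening is not None:
        s = model.screening
        d["screening"] = {
            "f_pvalue": s.f_pvalue,
            "coef_pvalues": dict(s.coef_pvalues),
            "max_vif": s.max_vif,
            "normality_pvalue": s.normality_pvalue,
            "homoscedasticity_pvalue": s.homoscedasticity_pvalue,
            "passed": s.passed,
            "degenerate": s.degenerate,
            "notes": s.notes,
        }
    return d


def model_from_dict(d: dict) -> FittedModel:
    screening = None
    if "screening" in d:
        screening = ScreeningReport(**d["screening"])
    return FittedModel(
        response=d["response"],
        predictors=list(d["predictors"]),
        coefficients={k: float(v) for k, v in d["coefficients"].items()},
        intercept=float(d["intercept"]),
        n=int(d["n"]),
        p=int(d["p"]),
        residual_ss=float(d["residual_ss"]),
        s2=float(d["s2"]),
        xtx_inverse=np.asarray(d["xtx_inverse"], dtype=float),
        r2=float(d["r2"]),
        adjusted_r2=float(d["adjusted_r2"]),
        vif={k: float(v) for k, v in d["vif"].items()},
        column_means={k: float(v) for k, v in d.get("column_means", {}).items()},
        screening=screening,
        provenance=dict(d.get("provenance", {})),
    )


def save_models(models: dict[str, FittedModel], path: str | Path, seed=None) -> None:
    payload = {
        "tool": f"bwdose {__version__}",
        "seed": seed,
        "models": {name: model_to_dict(m) for name, m in models.items()},
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def load_models(path: str | Path) -> dict[str, FittedModel]:
    with open(path) as f:
        payload = json.load(f)
    return {name: model_from_dict(d) for name, d in payload["models"].items()}
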