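"""Normalization layers.

Three harmonisation steps keep array-style and sequencing-derived beta
values on one scale:

* standard curves — polynomial regression of observed on known methylation
  for calibration standards (0-100% methylated DNA), inverted numerically
  to undo assay bias;
* cross-dataset normalization — per-CpG mean-shift of each study to the
  pooled grand mean, removing constant batch offsets while preserving the
  within-study variation that carries the age signal;
* NGS-to-array harmonisation — the sequencing batch treated as one extra
  study and shifted toward the array reference means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import beta_columns

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "apply_standard_curve",
    "cross_dataset_normalize",
    "ngs_to_array_normalize",
    "CalibrationError",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    """observed = polynomial(known); inverted at apply time."""

    cpg_id: str
    degree: int
    coefficients: tuple[float, ...]  # intercept-first
    r_squared: float
    residual_sd: float
    monotone_ok: bool

    def evaluate(self, known):
        return np.polynomial.polynomial.polyval(
            np.asarray(known, dtype=float), np.asarray(self.coefficients)
        )

    def to_dict(self) -> dict:
        return {
            "cpg_id": self.cpg_id,
            "degree": self.degree,
            "coefficients": list(self.coefficients),
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "monotone_ok": self.monotone_ok,
        }


def _fit_poly(known, observed, degree):
    coefs = np.polynomial.polynomial.polyfit(known, observed, degree)
    fitted = np.polynomial.polynomial.polyval(known, coefs)
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(len(known) - (degree + 1), 1)
    return coefs, r2, float(np.sqrt(ss_res / dof))


def _is_monotone(coefs) -> bool:
    grid = np.arange(0.0, 1.0 + 1e-9, 0.001)
    values = np.polynomial.polynomial.polyval(grid, coefs)
    return bool(np.all(np.diff(values) >= -1e-12))


def fit_standard_curve(known, observed, degree: int | None = None, cpg_id: str = "") -> StandardCurve:
    """Least-squares polynomial of observed on known methylation.

    With ``degree=None`` a linear fit is tried first and replaced by a cubic
    only when the cubic improves residual SD by more than 20% (assays behave
    linearly or with mild cubic distortion; the simpler curve is preferred).
    Non-monotone fits fall back to linear.
    """
    known = np.asarray(known, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if known.shape != observed.shape:
        raise CalibrationError("known and observed must have equal length")
    if known.min() > 0.0 + 1e-9 or known.max() < 1.0 - 1e-9:
        raise CalibrationError("known standards must span [0, 1]")

    def build(deg):
        if len(known) < deg + 2:
            raise CalibrationError(
                f"need at least {deg + 2} standards for degree {deg}, got {len(known)}"
            )
        return _fit_poly(known, observed, deg)

    if degree is None:
        coefs, r2, rsd = build(1)
        deg = 1
        if len(known) >= 5:
            coefs3, r23, rsd3 = build(3)
            if rsd3 < 0.8 * rsd and _is_monotone(coefs3):
                coefs, r2, rsd, deg = coefs3, r23, rsd3, 3
    else:
        if not 1 <= degree <= 3:
            raise CalibrationError("degree must be 1, 2 or 3")
        coefs, r2, rsd = build(degree)
        deg = degree

    monotone = _is_monotone(coefs)
    if not monotone and deg > 1:
        coefs, r2, rsd = build(1)
        deg = 1
        monotone = _is_monotone(coefs)
    return StandardCurve(cpg_id, deg, tuple(float(c) for c in coefs), r2, rsd, monotone)


def apply_standard_curve(curve: StandardCurve, observed_beta: float) -> float:
    """Invert the curve: the known methylation whose fit matches ``observed_beta``.

    Bisection on [0, 1] to 1e-6; observations outside the curve's range
    clamp to the corresponding endpoint.
    """
    lo, hi = curve.evaluate(0.0), curve.evaluate(1.0)
    if observed_beta <= lo:
        return 0.0
    if observed_beta >= hi:
        return 1.0
    root = brentq(lambda x: curve.evaluate(x) - observed_beta, 0.0, 1.0, xtol=1e-6)
    return float(min(max(root, 0.0), 1.0))


def cross_dataset_normalize(
    matrix: pd.DataFrame,
    mode: str = "per-cpg",
    return_report: bool = False,
):
    """Mean-shift each dataset's betas to the pooled grand mean.

    ``per-cpg`` (default) shifts every CpG of every dataset by
    (grand mean − dataset mean) for that CpG; ``global`` applies one shift
    per dataset computed over all CpGs. Within-dataset variance — and hence
    the age trend inside each study — is untouched. Results are clamped to
    [0, 1]; clamping is counted in the report.
    """
    if mode not in ("per-cpg", "global"):
        raise CalibrationError(f"unknown normalization mode {mode!r}")
    out = matrix.copy()
    cpgs = beta_columns(matrix)
    values = out[cpgs].to_numpy(dtype=float)
    groups = out["dataset"].to_numpy()
    report_rows = []
    if len(np.unique(groups)) >= 1:
        grand = np.nanmean(values, axis=0)  # per CpG
        grand_all = float(np.nanmean(values))
        for label in pd.unique(groups):
            mask = groups == label
            if mode == "per-cpg":
                shift = grand - np.nanmean(values[mask], axis=0)
            else:
                shift = np.full(len(cpgs), grand_all - float(np.nanmean(values[mask])))
            shifted = values[mask] + shift[None, :]
            clamped = int(np.sum((shifted < 0) | (shifted > 1)))
            values[mask] = np.clip(shifted, 0.0, 1.0)
            for cpg, s in zip(cpgs, shift):
                report_rows.append(
                    {"dataset": label, "cpg": cpg, "shift": float(s), "clamped_n": clamped}
                )
    out[cpgs] = values
    if return_report:
        return out, pd.DataFrame(report_rows)
    return out


def ngs_to_array_normalize(
    ngs_betas: pd.DataFrame, reference_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Shift a sequencing batch onto the array reference scale.

    The batch is treated as one extra dataset: per CpG, add
    (reference mean − batch mean). Rows are samples, columns CpGs; every
    batch CpG must exist in the reference.
    """
    ref_cpgs = set(beta_columns(reference_matrix))
    cpgs = [c for c in ngs_betas.columns if c not in ("age", "sex", "dataset", "tissue")]
    missing = [c for c in cpgs if c not in ref_cpgs]
    if missing:
        raise CalibrationError(f"CpGs absent from reference matrix: {missing}")
    out = ngs_betas.copy()
    for cpg in cpgs:
        shift = float(reference_matrix[cpg].mean()) - float(ngs_betas[cpg].mean())
        out[cpg] = np.clip(ngs_betas[cpg].to_numpy(dtype=float) + shift, 0.0, 1.0)
    return out
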