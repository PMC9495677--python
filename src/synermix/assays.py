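"""Reduction of raw plate-reader data to activity units.

FRAP: endpoint absorbance is calibrated against an Fe2+ standard ladder and
reported as µM Fe2+. ORAC: fluorescein fluorescence decays under peroxyl
radical attack; each well's curve is normalized to its initial fluorescence,
integrated over the observation window (80 min in study-conformant runs), and
the blank-corrected ("net") area is calibrated against a Trolox ladder and
reported as µM Trolox equivalents.

The cited wet-lab protocols are not restated in the source study; these
reductions follow the community-standard formulations (endpoint FRAP
calibration, net-AUC ORAC) and are calibration plumbing, not study-specific
math.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "StandardCurve",
    "KineticCurve",
    "fit_standard_curve",
    "frap_to_fe2",
    "curve_auc",
    "net_auc",
    "orac_te",
    "reduce_frap_plate",
    "reduce_orac_plate",
]


class StandardCurve(RegressorMixin, BaseEstimator):
    """Ordinary least-squares calibration line: response = slope * conc + intercept.

    Parameters
    ----------
    through_origin : bool, default=False
        Force the intercept to zero. The default keeps a free intercept;
        blank-corrected instruments may still show offsets.

    Attributes
    ----------
    slope_, intercept_ : float
    r_squared_ : float
        Coefficient of determination on the fitted standards.
    """

    def __init__(self, through_origin: bool = False) -> None:
        self.through_origin = through_origin

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("concentration and response lengths differ")
        if x.size < 2:
            raise ValueError("need at least 2 standard points")
        if np.unique(x).size < 2:
            raise ValueError("all standard concentrations are identical; cannot fit a line")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("non-finite standard point")
        if self.through_origin:
            slope = float(np.dot(x, y) / np.dot(x, x))
            intercept = 0.0
        else:
            from scipy.stats import linregress

            fit = linregress(x, y)
            slope, intercept = float(fit.slope), float(fit.intercept)
        resid = y - (slope * x + intercept)
        ss_res = float(np.dot(resid, resid))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.slope_ = slope
        self.intercept_ = intercept
        # constant responses fit exactly (flat line): define r^2 = 1 then
        self.r_squared_ = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
        self.n_points_ = int(x.size)
        return self

    def predict(self, X):
        self._check_fitted()
        x = np.asarray(X, dtype=float)
        return self.slope_ * x + self.intercept_

    def concentration(self, response):
        """Invert the line: concentration producing the given response."""
        self._check_fitted()
        if self.slope_ == 0:
            raise ZeroDivisionError("calibration slope is zero; cannot invert")
        r = np.asarray(response, dtype=float)
        out = (r - self.intercept_) / self.slope_
        return float(out) if out.ndim == 0 else out

    def _check_fitted(self) -> None:
        if not hasattr(self, "slope_"):
            raise RuntimeError("StandardCurve is not fitted")


def fit_standard_curve(points: Sequence[tuple[float, float]], through_origin: bool = False) -> StandardCurve:
    """Fit a calibration line to (known concentration, instrument response) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, response) pairs")
    return StandardCurve(through_origin=through_origin).fit(pts[:, 0], pts[:, 1])


def frap_to_fe2(absorbance: float, curve: StandardCurve) -> float:
    """Convert a FRAP endpoint absorbance to µM Fe2+ via the Fe2+ ladder."""
    return curve.concentration(absorbance)


@dataclass(frozen=True)
class KineticCurve:
    """A timestamped fluorescence trace for one well.

    times are minutes ascending from 0; role is one of sample, blank or
    trolox_standard.
    """

    well: str
    times: tuple[float, ...]
    fluorescence: tuple[float, ...]
    role: str = "sample"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.size != f.size:
            raise ValueError(f"{self.well}: times and fluorescence lengths differ")
        if t.size and t[0] != 0:
            raise ValueError(f"{self.well}: times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.well}: times must be strictly increasing")
        if np.any(f < 0):
            raise ValueError(f"{self.well}: negative fluorescence")
        if self.role not in ("sample", "blank", "trolox_standard"):
            raise ValueError(f"{self.well}: unknown role {self.role!r}")


def curve_auc(curve: KineticCurve, normalize: bool = True) -> float:
    """Trapezoidal area under the (normalized) fluorescence decay.

    With ``normalize`` (default) the trace is divided by its initial
    fluorescence before integration, so a constant trace over 80 min has
    area 80 regardless of its absolute brightness.
    """
    t = np.asarray(curve.times, dtype=float)
    f = np.asarray(curve.fluorescence, dtype=float)
    if t.size < 2:
        raise ValueError(f"{curve.well}: need at least 2 time points")
    if normalize:
        if f[0] == 0:
            raise ValueError(f"{curve.well}: initial fluorescence is 0; cannot normalize")
        f = f / f[0]
    return float(np.trapezoid(f, t))


def net_auc(sample_auc: float, blank_auc: float) -> float:
    """Blank-corrected area: sample minus blank (same window, same normalization)."""
    return sample_auc - blank_auc


def orac_te(net_area: float, curve: StandardCurve) -> float:
    """Convert a net AUC to µM Trolox equivalents via the Trolox ladder."""
    return curve.concentration(net_area)


def reduce_frap_plate(plate: pd.DataFrame, standards: pd.DataFrame) -> pd.DataFrame:
    """Reduce FRAP endpoint absorbances to µM Fe2+ measurement rows.

    ``plate`` columns: analyte, concentration_um, replicate_index, absorbance.
    ``standards`` columns: concentration_um (known Fe2+), response.
    Returns a long-format measurement table (analyte, assay, concentration_um,
    replicate_index, value, units).
    """
    curve = StandardCurve().fit(standards["concentration_um"], standards["response"])
    out = plate.loc[:, ["analyte", "concentration_um", "replicate_index"]].copy()
    out.insert(1, "assay", "FRAP")
    out["value"] = curve.concentration(plate["absorbance"].to_numpy(dtype=float))
    out["units"] = "µM Fe2+"
    return out


def reduce_orac_plate(
    curves: Iterable[KineticCurve],
    wells: pd.DataFrame,
    through_origin: bool = False,
) -> tuple[pd.DataFrame, StandardCurve]:
    """Reduce an ORAC kinetic plate to µM TE measurement rows.

    Every trace is normalized to its initial fluorescence and integrated;
    the mean blank area is subtracted; the Trolox ladder (wells with role
    ``trolox_standard`` and a ``trolox_um`` value) calibrates net AUC against
    concentration; sample wells are inverted through that line.

    ``wells`` columns: well, role, analyte, concentration_um, replicate_index,
    trolox_um. Returns (measurement table, fitted Trolox StandardCurve).
    """
    curve_list = list(curves)
    aucs = {c.well: curve_auc(c) for c in curve_list}
    roles = {c.well: c.role for c in curve_list}
    blank_aucs = [a for w, a in aucs.items() if roles[w] == "blank"]
    if not blank_aucs:
        raise ValueError("plate has no blank wells")
    blank = float(np.mean(blank_aucs))

    ladder = wells[wells["role"] == "trolox_standard"]
    if len(ladder) < 2:
        raise ValueError("plate needs >= 2 Trolox standard wells")
    net_std = [net_auc(aucs[w], blank) for w in ladder["well"]]
    trolox = StandardCurve(through_origin=through_origin).fit(
        ladder["trolox_um"].to_numpy(dtype=float), net_std
    )

    samples = wells[wells["role"] == "sample"]
    rows = [
        {
            "analyte": t.analyte,
            "assay": "ORAC",
            "concentration_um": t.concentration_um,
            "replicate_index": t.replicate_index,
            "value": orac_te(net_auc(aucs[t.well], blank), trolox),
            "units": "µM TE",
        }
        for t in samples.itertuples()
    ]
    return pd.DataFrame(rows), trolox
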