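"""Structure-activity summaries for the phenolic panel.

Encodes the computable part of the structural story: counts of hydroxyl and
methoxy ring substituents, the catechol indicator and the acid class, plus
descriptive rank correlations between those features and measured activity,
and the linearity check of activity against concentration. Positional
electronic effects (ortho/para donation, intramolecular hydrogen bonding) are
deliberately not modelled — they are not computable from substituent counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PhenolicCompound

__all__ = ["feature_table", "feature_activity_correlation", "linearity_check", "LinearityResult"]

FEATURE_COLUMNS = ("n_oh", "n_och3", "has_catechol", "is_hydroxybenzoic", "is_hydroxycinnamic")


def feature_table(panel: Sequence[PhenolicCompound]) -> pd.DataFrame:
    """One numeric feature vector per compound, ordered by id.

    Columns: n_oh, n_och3, has_catechol (0/1) and one 0/1 indicator per acid
    class (the caffeic ester is the implicit third level).
    """
    rows = [
        {
            "id": c.id,
            "n_oh": c.n_oh,
            "n_och3": c.n_och3,
            "has_catechol": int(c.has_catechol),
            "is_hydroxybenzoic": int(c.compound_class == "hydroxybenzoic"),
            "is_hydroxycinnamic": int(c.compound_class == "hydroxycinnamic"),
        }
        for c in panel
    ]
    df = pd.DataFrame(rows, columns=["id", *FEATURE_COLUMNS])
    return df.sort_values("id", ignore_index=True)


def feature_activity_correlation(
    features: pd.DataFrame, activities: Mapping[str, float]
) -> dict[str, float]:
    """Spearman rank correlation of each feature with activity.

    ``activities`` maps compound id to mean activity at one assay and
    concentration; compounds missing from either side are dropped. Ties get
    average ranks (scipy's convention). Requires >= 3 matched pairs.
    """
    matched = features[features["id"].isin(activities)]
    if len(matched) < 3:
        raise ValueError(f"need >= 3 matched compounds, got {len(matched)}")
    y = np.array([activities[i] for i in matched["id"]], dtype=float)
    out: dict[str, float] = {}
    for col in FEATURE_COLUMNS:
        x = matched[col].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            out[col] = 0.0  # zero-variance: correlation undefined, report 0
        else:
            out[col] = float(stats.spearmanr(x, y).statistic)
    return out


@dataclass(frozen=True)
class LinearityResult:
    """Pearson correlation and OLS slope of activity against concentration."""

    r: float
    slope: float
    intercept: float
    degenerate: bool = False


def linearity_check(
    concentrations: Sequence[float], activities: Sequence[float]
) -> LinearityResult:
    """Check the linear concentration-response of one compound.

    Requires >= 3 (concentration, activity) pairs with non-constant
    concentrations. A constant activity vector makes Pearson's r undefined;
    it is reported as 0 with ``degenerate=True`` (slope 0), so panel-wide
    sweeps never abort.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(activities, dtype=float)
    if x.size != y.size:
        raise ValueError("concentrations and activities lengths differ")
    if x.size < 3:
        raise ValueError("need >= 3 points for a linearity check")
    if np.all(x == x[0]):
        raise ValueError("zero variance in concentration")
    if np.all(y == y[0]):
        return LinearityResult(r=0.0, slope=0.0, intercept=float(y[0]), degenerate=True)
    fit = stats.linregress(x, y)
    return LinearityResult(r=float(fit.rvalue), slope=float(fit.slope), intercept=float(fit.intercept))
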