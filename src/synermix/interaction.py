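"""Expected-additivity interaction analysis of equimolar antioxidant mixtures.

For an equimolar k-component mixture at total concentration C, the expected
additive ("theoretical") activity is the mean of the k individual activities
measured at C — each component contributes 1/k of its full-concentration
activity, which assumes the individual dose-response is linear. The
interaction index is the percent difference between the observed mixture
activity E and the additive expectation T::

    difference (%) = 100 * E / T - 100

Positive differences beyond the additive band indicate synergy, negative ones
antagonism; |difference| <= band (default 5 percentage points) counts as
additive, i.e. no interaction.

The scikit-learn style :class:`InteractionAnalyzer` holds the individual
activity table (``fit``), scores mixture measurements (``transform``) and
returns bare classifications (``predict``). Module-level functions are thin
wrappers for one-off computations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import Mixture

__all__ = [
    "InteractionConfig",
    "InteractionResult",
    "ConcentrationTrend",
    "InteractionAnalyzer",
    "theoretical_mixture_value",
    "difference_percent",
    "classify_interaction",
    "difference_uncertainty",
    "enumerate_equimolar_mixtures",
    "analyze_panel",
    "concentration_trend",
    "round_half_away",
    "round_difference",
    "format_difference",
]

CLASSIFICATIONS = ("synergistic", "additive", "antagonistic")


@dataclass(frozen=True)
class InteractionConfig:
    """Reporting configuration for the interaction index.

    additive_band_pct
        Half-width of the no-interaction band in percentage points. The band
        is inclusive: |difference| == band classifies as additive.
    """

    additive_band_pct: float = 5.0

    def __post_init__(self) -> None:
        if self.additive_band_pct < 0:
            raise ValueError("additive_band_pct must be >= 0")


@dataclass(frozen=True)
class InteractionResult:
    """Experimental vs expected-additive activity for one mixture/assay/conc."""

    mixture: Mixture
    assay: str
    experimental: float
    theoretical: float
    difference_pct: float
    classification: str
    difference_sd: float | None = None

    @property
    def concentration_um(self) -> float:
        return self.mixture.total_concentration_um


@dataclass(frozen=True)
class ConcentrationTrend:
    """Difference-(%) profile of one mixture across concentrations."""

    mixture_label: str
    assay: str
    points: tuple[tuple[float, float, str], ...]  # (conc, difference_pct, classification)
    monotone_decrease: bool


# ---------------------------------------------------------------------------
# elementary operations


def theoretical_mixture_value(individual_means: Sequence[float], k: int | None = None) -> float:
    """Expected additive activity: mean of the k individual activities.

    ``individual_means`` are the activities of each component measured alone
    at the mixture's *total* concentration.
    """
    means = list(individual_means)
    if k is None:
        k = len(means)
    if k != len(means):
        raise ValueError(f"k={k} but {len(means)} individual means given")
    if k < 2:
        raise ValueError("a mixture needs at least 2 components")
    if any(not math.isfinite(v) for v in means):
        raise ValueError("non-finite individual mean")
    return float(sum(means)) / k


def difference_percent(experimental: float, theoretical: float) -> float:
    """Interaction index: 100 * experimental / theoretical - 100."""
    if not math.isfinite(theoretical) or theoretical <= 0:
        raise ValueError(f"theoretical activity must be positive, got {theoretical}")
    if experimental < 0:
        raise ValueError(f"negative experimental activity {experimental}")
    return 100.0 * experimental / theoretical - 100.0


def classify_interaction(d: float, cfg: InteractionConfig | float = InteractionConfig()) -> str:
    """Classify a difference (%) against the additive band (inclusive)."""
    band = cfg.additive_band_pct if isinstance(cfg, InteractionConfig) else float(cfg)
    if not math.isfinite(d):
        raise ValueError("difference must be finite")
    if d > band:
        return "synergistic"
    if d < -band:
        return "antagonistic"
    return "additive"


def difference_uncertainty(
    experimental_mean: float,
    experimental_sd: float,
    n_exp: int,
    individual_means: Sequence[float],
    individual_sds: Sequence[float],
    n_ind: int | Sequence[int],
) -> float:
    """First-order (delta-method) SD of the difference (%) index.

    Treats the mixture mean E and the k individual means as independent with
    standard errors sd/sqrt(n). With T the additive expectation,

        Var(D) ~= (100/T)^2 * [ Var(E) + (E/T)^2 * Var(T) ],
        Var(T) = sum_i Var(mean_i) / k^2.
    """
    means = list(individual_means)
    sds = list(individual_sds)
    if len(means) != len(sds):
        raise ValueError("individual_means and individual_sds length mismatch")
    k = len(means)
    ns = [n_ind] * k if isinstance(n_ind, int) else list(n_ind)
    if len(ns) != k:
        raise ValueError("n_ind length mismatch")
    if experimental_sd < 0 or any(s < 0 for s in sds):
        raise ValueError("standard deviations must be >= 0")
    if n_exp < 1 or any(n < 1 for n in ns):
        raise ValueError("replicate counts must be >= 1")
    T = theoretical_mixture_value(means, k)
    if T <= 0:
        raise ValueError("theoretical activity must be positive")
    var_E = experimental_sd**2 / n_exp
    var_T = sum(s**2 / n for s, n in zip(sds, ns)) / k**2
    return 100.0 / T * math.sqrt(var_E + (experimental_mean / T) ** 2 * var_T)


def enumerate_equimolar_mixtures(
    panel_ids: Sequence[str],
    k_range: tuple[int, int] | range = (2, 5),
    total_concentration_um: float = 100.0,
) -> list[Mixture]:
    """All k-subsets of the panel for each k in the inclusive range.

    Ordered deterministically: k ascending, then lexicographic by sorted
    component ids within each k.
    """
    ids = list(panel_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("panel ids must be distinct")
    if isinstance(k_range, range):
        lo, hi = k_range.start, k_range.stop - 1 if k_range.step == 1 else max(k_range)
    else:
        lo, hi = k_range
    if lo < 2:
        raise ValueError("k must be >= 2")
    if hi > len(ids):
        raise ValueError(f"k={hi} exceeds panel size {len(ids)}")
    out: list[Mixture] = []
    for k in range(lo, hi + 1):
        for combo in combinations(sorted(ids), k):
            out.append(Mixture(combo, total_concentration_um, display_label="+".join(combo)))
    return out


# ---------------------------------------------------------------------------
# rounding / reporting conventions


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention used for reported values)."""
    q = 10.0**decimals
    v = x * q
    r = math.floor(v + 0.5) if v >= 0 else math.ceil(v - 0.5)
    return r / q


def round_difference(d: float) -> float:
    """Reporting convention: one decimal when |d| < 10, integer otherwise."""
    return round_half_away(d, 1 if abs(d) < 10 else 0)


def format_difference(d: float) -> str:
    r = round_difference(d)
    return f"{r:.1f}" if abs(d) < 10 else f"{r:.0f}"


# ---------------------------------------------------------------------------
# estimator


def _as_summary_frame(X: pd.DataFrame | Iterable) -> pd.DataFrame:
    """Coerce input to a summary frame with analyte/assay/concentration_um/mean."""
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        rows = []
        for m in X:  # ActivityMeasurement-like
            rows.append(
                {
                    "analyte": m.analyte_label,
                    "assay": m.assay,
                    "concentration_um": m.concentration_um,
                    "mean": m.mean,
                    "sd": m.sd,
                    "n": m.n_replicates or None,
                }
            )
        df = pd.DataFrame(rows)
    required = {"analyte", "assay", "concentration_um", "mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table is missing columns {sorted(missing)}")
    for opt in ("sd", "n"):
        if opt not in df.columns:
            df[opt] = np.nan
    return df


class InteractionAnalyzer(TransformerMixin, BaseEstimator):
    """Score mixture activities against the expected-additivity null.

    Parameters
    ----------
    additive_band_pct : float, default=5.0
        Inclusive half-width of the no-interaction band, in percentage points.
    propagate_uncertainty : bool, default=True
        Attach a delta-method SD to each difference when replicate SDs are
        available.
    default_n : int, default=3
        Replicate count assumed for summary-only measurements (assays are run
        in triplicate).

    ``fit`` takes the *individual* activity table (long format: analyte,
    assay, concentration_um, mean[, sd, n]); ``transform`` takes the mixture
    table in the same format, with analyte a '+'-joined component label, and
    returns one row per mixture/assay/concentration with the theoretical
    value, the difference (%) and its classification.

    Attributes
    ----------
    individual_means_ : dict
        (compound id, assay, concentration) -> mean activity.
    individual_sds_, individual_ns_ : dict
        Matching SDs and replicate counts (NaN-free; missing -> 0 / default_n).
    """

    def __init__(
        self,
        additive_band_pct: float = 5.0,
        propagate_uncertainty: bool = True,
        default_n: int = 3,
    ) -> None:
        self.additive_band_pct = additive_band_pct
        self.propagate_uncertainty = propagate_uncertainty
        self.default_n = default_n

    # sklearn API ----------------------------------------------------------
    def fit(self, X, y=None):
        df = _as_summary_frame(X)
        cfg = InteractionConfig(self.additive_band_pct)  # validates the band
        self._config_ = cfg
        means: dict[tuple[str, str, float], float] = {}
        sds: dict[tuple[str, str, float], float] = {}
        ns: dict[tuple[str, str, float], int] = {}
        grouped = df.groupby(["analyte", "assay", "concentration_um"], sort=False)
        for key, g in grouped:
            if len(g) > 1:
                warnings.warn(
                    f"duplicate individual measurements for {key}; averaging", stacklevel=2
                )
            means[key] = float(g["mean"].mean())
            sd = g["sd"].mean()
            sds[key] = 0.0 if pd.isna(sd) else float(sd)
            n = g["n"].mean()
            ns[key] = self.default_n if pd.isna(n) else int(n)
        self.individual_means_ = means
        self.individual_sds_ = sds
        self.individual_ns_ = ns
        return self

    def transform(self, X) -> pd.DataFrame:
        self._check_fitted()
        df = _as_summary_frame(X)
        rows = []
        for t in df.itertuples():
            mixture = Mixture.from_label(t.analyte, t.concentration_um)
            comps = sorted(mixture.component_ids)
            try:
                means = [self.individual_means_[(c, t.assay, t.concentration_um)] for c in comps]
            except KeyError:
                missing = [
                    c
                    for c in comps
                    if (c, t.assay, t.concentration_um) not in self.individual_means_
                ]
                raise KeyError(
                    f"no individual measurement for {missing} in assay {t.assay} "
                    f"at {t.concentration_um} µM (mixture {t.analyte})"
                ) from None
            theo = theoretical_mixture_value(means)
            d = difference_percent(float(t.mean), theo)
            d_sd = None
            if self.propagate_uncertainty and not pd.isna(t.sd):
                d_sd = difference_uncertainty(
                    float(t.mean),
                    float(t.sd),
                    self.default_n if pd.isna(t.n) else int(t.n),
                    means,
                    [self.individual_sds_[(c, t.assay, t.concentration_um)] for c in comps],
                    [self.individual_ns_[(c, t.assay, t.concentration_um)] for c in comps],
                )
            rows.append(
                {
                    "mixture": mixture.label,
                    "display_label": t.analyte,
                    "assay": t.assay,
                    "concentration_um": t.concentration_um,
                    "k": mixture.k,
                    "experimental": float(t.mean),
                    "theoretical": theo,
                    "difference_pct": d,
                    "difference_sd": d_sd,
                    "classification": classify_interaction(d, self._config_),
                }
            )
        columns = [
            "mixture", "display_label", "assay", "concentration_um", "k",
            "experimental", "theoretical", "difference_pct", "difference_sd",
            "classification",
        ]
        return pd.DataFrame(rows, columns=columns)

    def predict(self, X) -> np.ndarray:
        """Classification labels only, aligned with the rows of ``X``."""
        return self.transform(X)["classification"].to_numpy()

    def _check_fitted(self) -> None:
        if not hasattr(self, "individual_means_"):
            raise RuntimeError("InteractionAnalyzer is not fitted; call fit(individuals) first")


# ---------------------------------------------------------------------------
# wrappers


def analyze_panel(
    individual_measurements,
    mixture_measurements,
    cfg: InteractionConfig = InteractionConfig(),
) -> list[InteractionResult]:
    """One InteractionResult per mixture measurement.

    Thin wrapper over :class:`InteractionAnalyzer`; both arguments accept a
    long-format summary DataFrame or an iterable of ActivityMeasurement.
    """
    analyzer = InteractionAnalyzer(additive_band_pct=cfg.additive_band_pct)
    res = analyzer.fit(individual_measurements).transform(mixture_measurements)
    out = []
    for t in res.itertuples():
        out.append(
            InteractionResult(
                mixture=Mixture.from_label(t.display_label, t.concentration_um),
                assay=t.assay,
                experimental=t.experimental,
                theoretical=t.theoretical,
                difference_pct=t.difference_pct,
                difference_sd=None if t.difference_sd is None else float(t.difference_sd),
                classification=t.classification,
            )
        )
    return out


def concentration_trend(results: Sequence[InteractionResult]) -> ConcentrationTrend:
    """Order one mixture's results by concentration and flag a strict decrease."""
    if len(results) < 2:
        raise ValueError("need results at >= 2 concentrations")
    labels = {r.mixture.label for r in results}
    assays = {r.assay for r in results}
    if len(labels) > 1 or len(assays) > 1:
        raise ValueError("trend requires a single mixture and assay")
    ordered = sorted(results, key=lambda r: r.concentration_um)
    points = tuple((r.concentration_um, r.difference_pct, r.classification) for r in ordered)
    diffs = [p[1] for p in points]
    monotone = all(b < a for a, b in zip(diffs, diffs[1:]))
    return ConcentrationTrend(
        mixture_label=ordered[0].mixture.label,
        assay=ordered[0].assay,
        points=points,
        monotone_decrease=monotone,
    )
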