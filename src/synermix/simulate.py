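"""Synthetic assay data with known ground truth.

Emulates the study design end to end: individual activities linear in
concentration with multiplicative triplicate noise, mixture activities equal
to the additive expectation inflated or deflated by a known interaction
effect delta (in percent), and ORAC kinetic plates (fluorescein-like decay
curves plus a Trolox ladder) whose reduction recovers programmed Trolox-
equivalent values.

What it emulates / does not: replicate scatter is multiplicative Gaussian
(published SDs grow with the mean; CV defaults to 0.03, the relative error
scale of the published activities); the interaction is injected on the
mixture mean, not per replicate, so delta is exactly identifiable in the
noiseless limit. No plate spatial effects, drift, or mechanistic radical
kinetics are modelled.

Seeding contract: one master seed; each generator draws from
``numpy.random.default_rng([seed, stream])`` with a fixed per-generator
stream id (0 individuals, 1 mixtures, 2 ORAC plate), so modules regenerate
independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .assays import KineticCurve
from .panel import ASSAY_UNITS

__all__ = [
    "SimulationSpec",
    "OracPlate",
    "DEFAULT_FRAP_SLOPES",
    "DEFAULT_ORAC_SLOPES",
    "gen_individual_measurements",
    "gen_mixture_measurements",
    "gen_orac_plate",
]

# Activity per µM of compound, on the scale of the published panel
# (FRAP response at 1000 µM divided by 1000; ORAC response at 5 µM divided by 5).
DEFAULT_FRAP_SLOPES: Mapping[str, float] = {
    "P": 2.34, "Ge": 3.19, "G": 5.03, "V": 0.85, "Sy": 3.21,
    "pC": 0.113, "C": 2.13, "F": 1.71, "Si": 2.19, "R": 3.66,
}
DEFAULT_ORAC_SLOPES: Mapping[str, float] = {
    "P": 11.4, "Ge": 10.6, "G": 5.6, "V": 11.2, "Sy": 8.0,
    "pC": 6.6, "C": 12.0, "F": 9.0, "Si": 8.8, "R": 18.4,
}
_DEFAULT_CONCENTRATIONS = {"FRAP": (100.0, 500.0, 1000.0), "ORAC": (2.5, 5.0)}

_STREAM_INDIVIDUALS, _STREAM_MIXTURES, _STREAM_PLATE = 0, 1, 2


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for one simulated assay campaign.

    slopes
        Activity per µM for each compound (linear dose-response).
    interaction_map
        '+'-joined mixture label -> injected interaction effect delta in
        percent; the simulated mixture mean is the additive expectation times
        (1 + delta/100). delta must exceed -100.
    noise_cv
        Coefficient of variation of the multiplicative replicate noise.
    """

    seed: int
    assay: str = "FRAP"
    slopes: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FRAP_SLOPES))
    concentrations: Sequence[float] | None = None
    n_replicates: int = 3
    noise_cv: float = 0.03
    interaction_map: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_UNITS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(s <= 0 for s in self.slopes.values()):
            raise ValueError("slopes must be positive")
        if any(d <= -100 for d in self.interaction_map.values()):
            raise ValueError("interaction effects must exceed -100%")

    @property
    def concentration_grid(self) -> tuple[float, ...]:
        if self.concentrations is not None:
            return tuple(self.concentrations)
        return _DEFAULT_CONCENTRATIONS[self.assay]

    def individual_truth(self) -> dict[tuple[str, float], float]:
        """Noiseless individual activity for each (compound, concentration)."""
        return {
            (cid, c): s * c
            for cid, s in self.slopes.items()
            for c in self.concentration_grid
        }


def _replicate_rows(rng, analyte, assay, conc, mean, n, cv, units):
    eps = rng.normal(0.0, cv, size=n) if cv > 0 else np.zeros(n)
    return [
        {
            "analyte": analyte,
            "assay": assay,
            "concentration_um": conc,
            "replicate_index": i + 1,
            "value": mean * (1.0 + eps[i]),
            "units": units,
        }
        for i in range(n)
    ]


def gen_individual_measurements(spec: SimulationSpec) -> pd.DataFrame:
    """Long-format replicate table for every compound on the concentration grid."""
    rng = np.random.default_rng([spec.seed, _STREAM_INDIVIDUALS])
    units = ASSAY_UNITS[spec.assay]
    rows = []
    for cid in spec.slopes:
        for conc in spec.concentration_grid:
            mean = spec.slopes[cid] * conc
            rows.extend(
                _replicate_rows(rng, cid, spec.assay, conc, mean, spec.n_replicates, spec.noise_cv, units)
            )
    return pd.DataFrame(rows)


def gen_mixture_measurements(
    spec: SimulationSpec,
    individual_truth: Mapping[tuple[str, float], float] | None = None,
) -> pd.DataFrame:
    """Replicate table for every mixture in the interaction map.

    The mixture mean at total concentration C is the additive expectation
    (mean of the component truths at C) times (1 + delta/100); replicate
    noise is applied around that mean.
    """
    truth = dict(individual_truth) if individual_truth is not None else spec.individual_truth()
    rng = np.random.default_rng([spec.seed, _STREAM_MIXTURES])
    units = ASSAY_UNITS[spec.assay]
    rows = []
    for label, delta in spec.interaction_map.items():
        comps = label.split("+")
        for conc in spec.concentration_grid:
            missing = [c for c in comps if (c, conc) not in truth]
            if missing:
                raise KeyError(f"no individual truth for {missing} at {conc} µM")
            additive = sum(truth[(c, conc)] for c in comps) / len(comps)
            mean = additive * (1.0 + delta / 100.0)
            rows.extend(
                _replicate_rows(rng, label, spec.assay, conc, mean, spec.n_replicates, spec.noise_cv, units)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ORAC kinetic plates


@dataclass(frozen=True)
class OracPlate:
    """A synthetic ORAC run: kinetic traces plus their layout.

    wells columns: well, role, analyte, concentration_um, replicate_index,
    trolox_um (ladder wells), programmed_te (ground-truth µM TE for samples).
    """

    curves: tuple[KineticCurve, ...]
    wells: pd.DataFrame
    ladder_slope: float
    blank_auc: float


def _decay_lambda_for_auc(target_auc: float, times: np.ndarray) -> float:
    """Decay rate whose trapezoidal AUC over ``times`` equals ``target_auc``.

    The trapezoidal area of exp(-lam*t) is continuous and strictly decreasing
    in lam, from the full window length (lam -> 0) toward half the first time
    step, so the root is bracketed and unique.
    """
    span = float(times[-1])
    if not 0 < target_auc < span:
        raise ValueError(f"target AUC {target_auc} outside feasible range (0, {span})")

    def gap(lam: float) -> float:
        return float(np.trapezoid(np.exp(-lam * times), times)) - target_auc

    return float(brentq(gap, 1e-9, 200.0, xtol=1e-13, rtol=1e-15))


def gen_orac_plate(
    spec: SimulationSpec,
    ladder_um: Sequence[float] = (0.0, 12.5, 25.0, 50.0, 75.0),
    ladder_slope: float = 0.7,
    blank_auc: float = 5.0,
    duration_min: float = 80.0,
    step_min: float = 1.0,
) -> OracPlate:
    """Fluorescein-like decay curves for blanks, a Trolox ladder, and samples.

    Curves are f(t) = exp(-lam * t) sampled on a regular grid over the
    observation window; lam decreases with antioxidant dose. Each curve's lam
    is solved so its trapezoidal net AUC is *exactly* ``ladder_slope`` times
    its programmed Trolox-equivalent value, making the ladder response
    perfectly linear and the reduction an exact inverse (up to replicate
    noise on the programmed value).

    Sample wells cover every compound (and every mixture in the interaction
    map) on the spec's concentration grid with programmed TE = slope * C
    (times 1 + delta/100 for mixtures).
    """
    if spec.assay != "ORAC":
        raise ValueError("ORAC plates require an ORAC spec")
    rng = np.random.default_rng([spec.seed, _STREAM_PLATE])
    times = np.arange(0.0, duration_min + step_min / 2, step_min)
    truth = spec.individual_truth()

    curves: list[KineticCurve] = []
    wells: list[dict] = []

    def add_curve(well, role, target_auc, **info):
        lam = _decay_lambda_for_auc(target_auc, times)
        curves.append(
            KineticCurve(well=well, times=tuple(times), fluorescence=tuple(np.exp(-lam * times)), role=role)
        )
        wells.append({"well": well, "role": role, **info})

    add_curve("blank", "blank", blank_auc, analyte=None, concentration_um=None,
              replicate_index=None, trolox_um=None, programmed_te=None)
    for c in ladder_um:
        add_curve(f"trolox_{c:g}", "trolox_standard", blank_auc + ladder_slope * c,
                  analyte=None, concentration_um=None, replicate_index=None,
                  trolox_um=c, programmed_te=None)

    def add_samples(analyte: str, conc: float, te_mean: float):
        eps = rng.normal(0.0, spec.noise_cv, size=spec.n_replicates) if spec.noise_cv > 0 else np.zeros(spec.n_replicates)
        for i in range(spec.n_replicates):
            te = te_mean * (1.0 + eps[i])
            add_curve(f"{analyte}@{conc:g}#{i + 1}", "sample", blank_auc + ladder_slope * te,
                      analyte=analyte, concentration_um=conc, replicate_index=i + 1,
                      trolox_um=None, programmed_te=te)

    for cid in spec.slopes:
        for conc in spec.concentration_grid:
            add_samples(cid, conc, truth[(cid, conc)])
    for label, delta in spec.interaction_map.items():
        comps = label.split("+")
        for conc in spec.concentration_grid:
            additive = sum(truth[(c, conc)] for c in comps) / len(comps)
            add_samples(label, conc, additive * (1.0 + delta / 100.0))

    return OracPlate(curves=tuple(curves), wells=pd.DataFrame(wells),
                     ladder_slope=ladder_slope, blank_auc=blank_auc)
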