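"""Domain model for the phenolic-acid panel and its assay measurements.

The study panel consists of ten phenolic acids: five hydroxybenzoic acids
(protocatechuic, gentisic, gallic, vanillic, syringic), four hydroxycinnamic
acids (p-coumaric, caffeic, ferulic, sinapic) and rosmarinic acid, a caffeic
acid ester carrying two catechol rings. Antioxidant activity is measured by
two assays with fixed reporting units:

* FRAP (ferric reducing antioxidant power) -- electron transfer; activity in
  µM Fe2+ equivalents.
* ORAC (oxygen radical absorbance capacity) -- hydrogen atom transfer;
  activity in µM Trolox equivalents (TE).

Mixtures are equimolar: a k-component mixture at total concentration C
contains each component at C/k.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ASSAY_UNITS",
    "ASSAYS",
    "PhenolicCompound",
    "ActivityMeasurement",
    "Mixture",
    "build_study_panel",
    "validate_measurement",
]

#: Reporting units are a function of the assay, not a free choice.
ASSAY_UNITS: Mapping[str, str] = {"FRAP": "µM Fe2+", "ORAC": "µM TE"}
ASSAYS = tuple(ASSAY_UNITS)

COMPOUND_CLASSES = ("hydroxybenzoic", "hydroxycinnamic", "caffeic_ester")
RING_GROUPS = ("OH", "OCH3", "H")


@dataclass(frozen=True)
class PhenolicCompound:
    """One panel member with its ring-substituent features.

    ``substituents`` maps ring-position labels R1..R3 to the attached group
    (OH, OCH3 or H). Rosmarinic acid, being an ester of two phenolic rings,
    carries no single-ring substituent map; only molecule-level counts.

    ``has_catechol`` marks an adjacent (ortho) dihydroxy pattern. The
    2,5-dihydroxy arrangement of gentisic acid is *not* a catechol: the two
    hydroxyls sit para to each other.
    """

    id: str
    common_name: str
    iupac_name: str
    compound_class: str
    n_oh: int
    n_och3: int = 0
    has_catechol: bool = False
    substituents: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        if self.n_oh < 1:
            raise ValueError(f"{self.id}: every panel member has at least one OH group")
        if self.n_och3 < 0:
            raise ValueError(f"{self.id}: negative methoxy count")
        if self.substituents is not None:
            bad = set(self.substituents.values()) - set(RING_GROUPS)
            if bad:
                raise ValueError(f"{self.id}: unknown ring groups {bad}")
            n_och3 = sum(1 for g in self.substituents.values() if g == "OCH3")
            if self.compound_class != "caffeic_ester" and n_och3 != self.n_och3:
                raise ValueError(
                    f"{self.id}: n_och3={self.n_och3} disagrees with substituent map ({n_och3})"
                )


def _c(id, name, iupac, cls, subs, n_oh, n_och3, catechol):
    substituents = None if subs is None else dict(zip(("R1", "R2", "R3"), subs))
    return PhenolicCompound(
        id=id,
        common_name=name,
        iupac_name=iupac,
        compound_class=cls,
        substituents=substituents,
        n_oh=n_oh,
        n_och3=n_och3,
        has_catechol=catechol,
    )


_HB = "hydroxybenzoic"
_HC = "hydroxycinnamic"

_STUDY_PANEL: tuple[PhenolicCompound, ...] = (
    _c("P", "protocatechuic acid", "3,4-dihydroxybenzoic acid", _HB, ("OH", "OH", "H"), 2, 0, True),
    _c("Ge", "gentisic acid", "2,5-dihydroxybenzoic acid", _HB, ("OH", "H", "OH"), 2, 0, False),
    _c("G", "gallic acid", "3,4,5-trihydroxybenzoic acid", _HB, ("OH", "OH", "OH"), 3, 0, True),
    _c("V", "vanillic acid", "4-hydroxy-3-methoxybenzoic acid", _HB, ("OCH3", "OH", "H"), 1, 1, False),
    _c("Sy", "syringic acid", "4-hydroxy-3,5-dimethoxybenzoic acid", _HB, ("OCH3", "OH", "OCH3"), 1, 2, False),
    _c("pC", "p-coumaric acid", "4-hydroxycinnamic acid", _HC, ("H", "OH", "H"), 1, 0, False),
    _c("C", "caffeic acid", "3,4-dihydroxycinnamic acid", _HC, ("OH", "OH", "H"), 2, 0, True),
    _c("F", "ferulic acid", "4-hydroxy-3-methoxycinnamic acid", _HC, ("OCH3", "OH", "H"), 1, 1, False),
    _c("Si", "sinapic acid", "4-hydroxy-3,5-dimethoxycinnamic acid", _HC, ("OCH3", "OH", "OCH3"), 1, 2, False),
    _c(
        "R",
        "rosmarinic acid",
        "(R)-1-carboxy-2-(3,4-dihydroxyphenyl)ethyl 3,4-dihydroxycinnamate",
        "caffeic_ester",
        None,
        4,
        0,
        True,
    ),
)


def build_study_panel() -> list[PhenolicCompound]:
    """Return the ten-compound study panel with its structural features."""
    return list(_STUDY_PANEL)


@dataclass(frozen=True)
class Mixture:
    """An equimolar combination of >= 2 distinct panel compounds.

    Identity is order-independent: ``Mixture(("P", "Ge"), 100)`` equals
    ``Mixture(("Ge", "P"), 100)`` and they hash alike. The display order of a
    source table can be kept in :attr:`display_label`; joins always use the
    canonical sorted label.
    """

    component_ids: frozenset[str]
    total_concentration_um: float
    display_label: str | None = field(default=None, compare=False)

    def __init__(
        self,
        component_ids: Iterable[str],
        total_concentration_um: float,
        display_label: str | None = None,
    ) -> None:
        ids = list(component_ids)
        if len(ids) != len(set(ids)):
            raise ValueError(f"mixture components must be distinct: {ids}")
        if len(ids) < 2:
            raise ValueError("a mixture needs at least 2 components")
        if total_concentration_um <= 0:
            raise ValueError("total concentration must be positive")
        object.__setattr__(self, "component_ids", frozenset(ids))
        object.__setattr__(self, "total_concentration_um", float(total_concentration_um))
        object.__setattr__(self, "display_label", display_label)

    @property
    def k(self) -> int:
        """Number of components."""
        return len(self.component_ids)

    @property
    def label(self) -> str:
        """Canonical '+'-joined label with components sorted alphabetically."""
        return "+".join(sorted(self.component_ids))

    @property
    def component_concentration_um(self) -> float:
        """Per-component concentration (equimolar: total / k)."""
        return self.total_concentration_um / self.k

    @classmethod
    def from_label(cls, label: str, total_concentration_um: float) -> "Mixture":
        """Parse a '+'-joined label, preserving it for display."""
        ids = [p.strip() for p in label.split("+")]
        return cls(ids, total_concentration_um, display_label="+".join(ids))


@dataclass
class ActivityMeasurement:
    """Replicate activities of one analyte in one assay at one concentration.

    ``analyte`` is a compound id or a Mixture. When only a published mean and
    SD are available (no raw replicates), pass them directly and set
    ``summary_only=True``; otherwise mean and sd are derived from replicates.
    """

    analyte: str | Mixture
    assay: str
    concentration_um: float
    replicates: Sequence[float] = ()
    mean: float | None = None
    sd: float | None = None
    n: int | None = None
    units: str | None = None
    summary_only: bool = False

    def __post_init__(self) -> None:
        if self.units is None and self.assay in ASSAY_UNITS:
            self.units = ASSAY_UNITS[self.assay]

    @property
    def analyte_label(self) -> str:
        return self.analyte.label if isinstance(self.analyte, Mixture) else self.analyte

    @property
    def n_replicates(self) -> int:
        if self.replicates:
            return len(self.replicates)
        return self.n if self.n is not None else 0


def validate_measurement(m: ActivityMeasurement) -> ActivityMeasurement:
    """Validate a measurement and recompute mean/sd from its replicates.

    Summary-only measurements (published mean ± SD without replicates) are
    checked for consistency but their stated mean/sd are kept.

    Raises ``ValueError`` on: unknown assay, negative concentration, units
    inconsistent with the assay, empty data, or a stated mean that disagrees
    with the replicates.
    """
    if m.assay not in ASSAY_UNITS:
        raise ValueError(f"unknown assay {m.assay!r}; expected one of {ASSAYS}")
    if m.concentration_um < 0:
        raise ValueError(f"negative concentration {m.concentration_um}")
    expected_units = ASSAY_UNITS[m.assay]
    if m.units is not None and m.units != expected_units:
        raise ValueError(
            f"units {m.units!r} inconsistent with assay {m.assay} (expected {expected_units!r})"
        )
    if m.summary_only:
        if m.mean is None:
            raise ValueError("summary-only measurement needs a mean")
        if m.sd is not None and m.sd < 0:
            raise ValueError("negative standard deviation")
        return replace(m, units=expected_units)
    if not m.replicates:
        raise ValueError("empty replicate list (use summary_only=True for published summaries)")
    if any(not math.isfinite(v) for v in m.replicates):
        raise ValueError("non-finite replicate value")
    mean = statistics.fmean(m.replicates)
    sd = statistics.stdev(m.replicates) if len(m.replicates) > 1 else 0.0
    if m.mean is not None and not math.isclose(m.mean, mean, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(f"stated mean {m.mean} disagrees with replicates (mean {mean})")
    return replace(m, mean=mean, sd=sd, n=len(m.replicates), units=expected_units)
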