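"""Catalog comparisons and the small normalization arithmetics.

Venn region counts across 2-5 RIFT catalogs (tissues or strains), integer
percentage summaries as printed in count tables, the plasmid-contamination-
corrected reporter ratio, and relative retrotransposition frequency from
colony counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .models import RIFTCatalog


def venn_counts(catalogs: Sequence[RIFTCatalog],
                ) -> dict[tuple[str, ...], int]:
    """Exhaustive disjoint region counts over 2-5 labelled sets.

    Returns a map from region signature — the tuple of catalog labels (in
    input order) whose sets contain an item, and no others — to the number
    of items in that region, over all 2^k - 1 non-empty signatures.
    """
    if not 2 <= len(catalogs) <= 5:
        raise ValueError("venn_counts takes between 2 and 5 catalogs")
    labels = [c.label for c in catalogs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate catalog labels")
    sets = {c.label: set(c.keys) for c in catalogs}
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for inside in combinations(labels, r):
            members = set.intersection(*(sets[l] for l in inside))
            for l in labels:
                if l not in inside:
                    members -= sets[l]
            regions[inside] = len(members)
    return regions


def proportion_summary(numerator: int, denominator: int) -> int:
    """Integer percent, rounded half away from zero (e.g. 363/940 -> 39)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    return int(Fraction(100 * numerator, denominator) + Fraction(1, 2))


@dataclass(frozen=True)
class ReporterMeasurement:
    """Interpolated transcript concentrations for one reporter construct.

    ``tem1_rt_minus`` (the no-reverse-transcriptase control) measures
    contaminating plasmid/genomic DNA and is subtracted from the +RT
    signal before normalizing to beta-actin.
    """

    construct_id: str
    tem1_rt_plus: float
    tem1_rt_minus: float
    actin: float

    def __post_init__(self) -> None:
        if min(self.tem1_rt_plus, self.tem1_rt_minus) < 0:
            raise ValueError("concentrations must be >= 0")
        if self.actin <= 0:
            raise ValueError("actin concentration must be > 0")


def normalized_reporter_ratio(m: ReporterMeasurement) -> float:
    """Contamination-corrected reporter/actin ratio (negative clamped to 0)."""
    return max(m.tem1_rt_plus - m.tem1_rt_minus, 0.0) / m.actin


@dataclass(frozen=True)
class ColonyCount:
    """Retrotransposition colony yield for one donor construct."""

    donor_id: str
    colonies: int
    cells_plated: int

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.cells_plated <= 0:
            raise ValueError("cells_plated must be > 0")


def relative_frequency(test: ColonyCount, control: ColonyCount) -> float:
    """Colony density of ``test`` relative to ``control`` (fold)."""
    if control.colonies == 0:
        raise ZeroDivisionError(
            f"control {control.donor_id} yielded no colonies; fold undefined")
    return (test.colonies / test.cells_plated) \
        / (control.colonies / control.cells_plated)


def catalog_from_calls(label: str, keys: Iterable[str]) -> RIFTCatalog:
    return RIFTCatalog(label=label, keys=frozenset(keys))
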