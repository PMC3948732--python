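"""Follicle classification, density computation and per-ovary summaries.

Follicles annotated with granulosa attributes are classified into maturity
stages (primordial / primary / secondary, Lundy-style rule), per-section
densities are computed as count / outlined cortical area (follicles per mm²),
and densities are log10-transformed with a configurable offset so that
sections devoid of follicles remain usable.  Summaries mirror the standard
whole-ovary quantification layout: one row per (ewe, ovary) with the number
of analyzed sections and the primordial / primary totals, plus a totals row.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError, ParameterError

__all__ = [
    "MaturityClass",
    "GranulosaMorphology",
    "SectionObservation",
    "classify_follicle",
    "compute_density",
    "log_transform",
    "summarize_by_ovary",
    "totals_from_ovary_rows",
    "class_fraction",
    "observations_to_frame",
    "TOTAL_LABEL",
]

#: Label of the totals row appended by the summary builders.
TOTAL_LABEL = "Total"


class MaturityClass(str, enum.Enum):
    """Follicle maturation stage."""

    PRIMORDIAL = "primordial"
    PRIMARY = "primary"
    SECONDARY = "secondary"


class GranulosaMorphology(str, enum.Enum):
    """Shape of the granulosa cells in the (single) layer around the oocyte."""

    FLATTENED = "flattened"
    CUBOIDAL = "cuboidal"


@dataclass
class SectionObservation:
    """One analyzed histological section.

    ``counts`` maps maturity class to the number of follicles whose nucleus
    was visible in the section; ``density`` and ``y`` are derived lazily via
    :func:`compute_density` and :func:`log_transform` for the class of
    interest (primordial by default).
    """

    ewe_id: str
    ovary_id: str
    fragment_id: str
    section_index: int
    area_mm2: float
    counts: dict = field(default_factory=dict)
    group: str = "control"

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ParameterError(f"area_mm2 must be positive, got {self.area_mm2}")
        if self.section_index < 0:
            raise ParameterError("section_index must be >= 0")
        for cls, n in self.counts.items():
            if n < 0:
                raise ParameterError(f"negative count {n} for class {cls}")

    def count(self, maturity_class: MaturityClass | str = MaturityClass.PRIMORDIAL) -> int:
        return int(self.counts.get(MaturityClass(maturity_class), 0))

    def density(self, maturity_class: MaturityClass | str = MaturityClass.PRIMORDIAL) -> float:
        """Follicles of the given class per mm² of cortical surface."""
        return compute_density(self.count(maturity_class), self.area_mm2)

    def y(
        self,
        maturity_class: MaturityClass | str = MaturityClass.PRIMORDIAL,
        offset: float = 1.0,
    ) -> float:
        """log10-transformed density of the given class."""
        return log_transform(self.density(maturity_class), offset)


def classify_follicle(
    granulosa_layers: int,
    granulosa_morphology: GranulosaMorphology | str,
) -> MaturityClass:
    """Classify a follicle from its granulosa annotation.

    A single layer of flattened cells marks a primordial follicle, a single
    layer of cuboidal cells a primary follicle, and two or more layers a
    secondary follicle.  Zero layers is not a follicle.
    """
    if granulosa_layers < 0:
        raise ParameterError("granulosa_layers must be >= 0")
    if granulosa_layers == 0:
        raise DataError("a structure with no granulosa layer is not a follicle")
    if granulosa_layers >= 2:
        return MaturityClass.SECONDARY
    morphology = GranulosaMorphology(granulosa_morphology)
    if morphology is GranulosaMorphology.FLATTENED:
        return MaturityClass.PRIMORDIAL
    return MaturityClass.PRIMARY


def compute_density(count: int, area_mm2: float) -> float:
    """Follicular density: follicles per mm² of outlined cortical surface."""
    if area_mm2 <= 0:
        raise ParameterError(f"area_mm2 must be positive, got {area_mm2}")
    if count < 0:
        raise ParameterError(f"count must be >= 0, got {count}")
    return count / area_mm2


def log_transform(density: float, offset: float = 1.0) -> float:
    """Base-10 log transform ``y = log10(density + offset)``.

    The additive ``offset`` (same units as density, follicles/mm²) keeps
    zero-count sections in the analysis; it must be positive whenever such
    sections can occur.
    """
    if density < 0 or offset < 0:
        raise ParameterError("density and offset must be nonnegative")
    if density + offset == 0:
        raise ParameterError(
            "log10(0) is undefined: set offset > 0 when zero-count sections exist"
        )
    return math.log10(density + offset)


def observations_to_frame(observations: Iterable[SectionObservation]) -> pd.DataFrame:
    """Flatten SectionObservation records into the canonical observation table."""
    rows = []
    for obs in observations:
        rows.append(
            {
                "ewe_id": obs.ewe_id,
                "ovary_id": obs.ovary_id,
                "fragment_id": obs.fragment_id,
                "section_index": obs.section_index,
                "group": obs.group,
                "area_mm2": obs.area_mm2,
                "n_primordial": obs.count(MaturityClass.PRIMORDIAL),
                "n_primary": obs.count(MaturityClass.PRIMARY),
                "n_secondary": obs.count(MaturityClass.SECONDARY),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ewe_id",
            "ovary_id",
            "fragment_id",
            "section_index",
            "group",
            "area_mm2",
            "n_primordial",
            "n_primary",
            "n_secondary",
        ],
    )


def totals_from_ovary_rows(per_ovary: pd.DataFrame) -> pd.DataFrame:
    """Append a totals row to a per-ovary summary.

    ``per_ovary`` needs columns ``ewe_id, ovary_id, sections_analyzed,
    n_primordial, n_primary``; totals are the column sums.
    """
    required = {"ewe_id", "ovary_id", "sections_analyzed", "n_primordial", "n_primary"}
    missing = required - set(per_ovary.columns)
    if missing:
        raise DataError(f"per-ovary summary missing columns: {sorted(missing)}")
    if per_ovary.empty:
        raise DataError("empty per-ovary summary")
    totals = pd.DataFrame(
        [
            {
                "ewe_id": TOTAL_LABEL,
                "ovary_id": "",
                "sections_analyzed": int(per_ovary["sections_analyzed"].sum()),
                "n_primordial": int(per_ovary["n_primordial"].sum()),
                "n_primary": int(per_ovary["n_primary"].sum()),
            }
        ]
    )
    return pd.concat([per_ovary, totals], ignore_index=True)


def summarize_by_ovary(table: pd.DataFrame | Iterable[SectionObservation]) -> pd.DataFrame:
    """Whole-ovary quantification summary.

    One row per (ewe, ovary) with the number of distinct analyzed sections
    and the summed primordial and primary counts, plus a totals row whose
    entries are the column sums.
    """
    if not isinstance(table, pd.DataFrame):
        table = observations_to_frame(table)
    if table.empty:
        raise DataError("empty observation table")
    dup = table.duplicated(subset=["ewe_id", "ovary_id", "fragment_id", "section_index"])
    if dup.any():
        rows = table.index[dup].tolist()
        raise DataError(f"duplicate (fragment, section_index) rows at index {rows}")
    grouped = (
        table.groupby(["ewe_id", "ovary_id"], sort=True)
        .agg(
            sections_analyzed=("section_index", "size"),
            n_primordial=("n_primordial", "sum"),
            n_primary=("n_primary", "sum"),
        )
        .reset_index()
    )
    return totals_from_ovary_rows(grouped)


def class_fraction(
    counts: Mapping[MaturityClass | str, int] | pd.DataFrame,
    maturity_class: MaturityClass | str,
) -> float:
    """Fraction of all counted follicles belonging to one maturity class.

    ``counts`` is either a mapping class -> total count, or an observation
    table with ``n_primordial / n_primary / n_secondary`` columns.
    """
    if isinstance(counts, pd.DataFrame):
        counts = {
            MaturityClass.PRIMORDIAL: int(counts["n_primordial"].sum()),
            MaturityClass.PRIMARY: int(counts["n_primary"].sum()),
            MaturityClass.SECONDARY: int(counts["n_secondary"].sum()),
        }
    normalized = {MaturityClass(k): int(v) for k, v in counts.items()}
    total = sum(normalized.values())
    if total <= 0:
        raise ParameterError("total follicle count must be positive")
    return normalized.get(MaturityClass(maturity_class), 0) / total
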