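"""Synthetic ovarian-cortex data at two levels of realism.

*Geometric mode* places follicles uniformly in a 3D cortical fragment
(default 2.5 × 2.5 × 1 mm), cuts the fragment into 5-µm serial sections,
analyzes every sixth section (30 µm apart) and counts a follicle on a
section only when its nucleus intersects that section — the "visible
nucleus" counting rule that prevents a 20–30 µm follicle from being counted
twice when sampled sections are 30 µm apart.

*Direct mode* draws log10-transformed densities straight from the nested
hierarchical model

    y_ijkl = mu + ewe_i + ovary_j(i) + delta·[treated] + f_k + e_l(k)

with a fragment random effect f ~ N(0, sigma2_fragment) and a section
residual e ~ N(0, sigma2_section).  The direct mode is what the power
engine resamples; its variance defaults (0.116 and 0.993 in log10 units²)
are the components estimated from the eight-ovary sheep cortex dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .quantify import GranulosaMorphology, MaturityClass, SectionObservation

__all__ = [
    "FragmentGeometry",
    "FollicleRecord",
    "SectionSlab",
    "HierarchyParams",
    "DEFAULT_CLASS_MIX",
    "DEFAULT_DIAMETER_RANGES_UM",
    "generate_fragment_follicles",
    "slice_fragment",
    "nucleus_visible",
    "observe_sections",
    "generate_density_table",
]

#: Default maturity-class mixture: primordial follicles dominate the cortex,
#: secondary follicles are under 1% of the population.
DEFAULT_CLASS_MIX = {
    MaturityClass.PRIMORDIAL: 0.92,
    MaturityClass.PRIMARY: 0.07,
    MaturityClass.SECONDARY: 0.01,
}

#: Follicle diameter ranges in µm by maturity class.  Sheep primordial
#: follicles measure 20–30 µm; the larger stages use field-typical ranges.
DEFAULT_DIAMETER_RANGES_UM = {
    MaturityClass.PRIMORDIAL: (20.0, 30.0),
    MaturityClass.PRIMARY: (30.0, 60.0),
    MaturityClass.SECONDARY: (60.0, 120.0),
}

#: Default oocyte-nucleus diameter in µm.  Small relative to the follicle
#: and to the 25 µm gap between consecutive sampled sections, so the
#: every-sixth-section rule provably prevents double counting (see
#: :func:`nucleus_visible`).
DEFAULT_NUCLEUS_DIAMETER_UM = 10.0


@dataclass(frozen=True)
class FragmentGeometry:
    """Geometry of a cortical fragment and its serial sectioning."""

    width_um: float = 2500.0
    depth_um: float = 2500.0
    height_um: float = 1000.0
    section_thickness_um: float = 5.0
    sampling_interval: int = 6

    def __post_init__(self) -> None:
        if min(self.width_um, self.depth_um, self.height_um) <= 0:
            raise ParameterError("fragment dimensions must be positive")
        if self.section_thickness_um <= 0:
            raise ParameterError("section thickness must be positive")
        if self.height_um < self.section_thickness_um:
            raise ParameterError("fragment height yields no full section")
        if self.sampling_interval < 1:
            raise ParameterError("sampling_interval must be >= 1")

    @property
    def n_sections(self) -> int:
        """Number of complete serial sections tiling the fragment height."""
        return int(self.height_um // self.section_thickness_um)

    @property
    def volume_mm3(self) -> float:
        return self.width_um * self.depth_um * self.height_um * 1e-9

    @property
    def face_area_mm2(self) -> float:
        """Area of the sectioning plane (the default cortical area)."""
        return self.width_um * self.depth_um * 1e-6


@dataclass(frozen=True)
class SectionSlab:
    """One serial section as a z-interval ``[z_low, z_high)`` in µm."""

    index: int
    z_low_um: float
    z_high_um: float
    sampled: bool


@dataclass(frozen=True)
class FollicleRecord:
    """One simulated follicle in fragment-local µm coordinates."""

    follicle_id: int
    center_um: tuple[float, float, float]
    diameter_um: float
    nucleus_diameter_um: float
    maturity_class: MaturityClass
    granulosa_layers: int
    granulosa_morphology: GranulosaMorphology

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_diameter_um < self.diameter_um:
            raise ParameterError("need 0 < nucleus diameter < follicle diameter")
        if self.granulosa_layers < 0:
            raise ParameterError("granulosa_layers must be >= 0")


def _granulosa_for_class(cls: MaturityClass, rng: np.random.Generator):
    if cls is MaturityClass.PRIMORDIAL:
        return 1, GranulosaMorphology.FLATTENED
    if cls is MaturityClass.PRIMARY:
        return 1, GranulosaMorphology.CUBOIDAL
    return int(rng.integers(2, 5)), GranulosaMorphology.CUBOIDAL


def generate_fragment_follicles(
    geometry: FragmentGeometry,
    intensity_per_mm3: float,
    class_mix: dict | None = None,
    rng_seed: int | np.random.Generator = 0,
    diameter_ranges_um: dict | None = None,
    nucleus_diameter_um: float = DEFAULT_NUCLEUS_DIAMETER_UM,
) -> list[FollicleRecord]:
    """Draw a homogeneous Poisson field of follicles inside a fragment.

    The follicle count is Poisson with mean ``intensity_per_mm3 × volume``;
    centers are uniform in the fragment box, diameters uniform in the
    per-class range.  Deterministic for a fixed seed.
    """
    if intensity_per_mm3 < 0:
        raise ParameterError("intensity must be >= 0")
    mix = {MaturityClass(k): float(v) for k, v in (class_mix or DEFAULT_CLASS_MIX).items()}
    if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-8:
        raise ParameterError("class_mix must be nonnegative and sum to 1")
    ranges = dict(DEFAULT_DIAMETER_RANGES_UM)
    ranges.update(
        {MaturityClass(k): v for k, v in (diameter_ranges_um or {}).items()}
    )

    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = int(rng.poisson(intensity_per_mm3 * geometry.volume_mm3))
    classes = list(mix)
    drawn = rng.choice(len(classes), size=n, p=[mix[c] for c in classes])
    xs = rng.uniform(0.0, geometry.width_um, n)
    ys = rng.uniform(0.0, geometry.depth_um, n)
    zs = rng.uniform(0.0, geometry.height_um, n)

    follicles: list[FollicleRecord] = []
    for i in range(n):
        cls = classes[int(drawn[i])]
        lo, hi = ranges[cls]
        diameter = float(rng.uniform(lo, hi))
        layers, morphology = _granulosa_for_class(cls, rng)
        follicles.append(
            FollicleRecord(
                follicle_id=i,
                center_um=(float(xs[i]), float(ys[i]), float(zs[i])),
                diameter_um=diameter,
                nucleus_diameter_um=min(nucleus_diameter_um, 0.99 * diameter),
                maturity_class=cls,
                granulosa_layers=layers,
                granulosa_morphology=morphology,
            )
        )
    return follicles


def slice_fragment(geometry: FragmentGeometry) -> list[SectionSlab]:
    """Tile the fragment height into serial sections and mark sampled ones.

    Section ``i`` occupies ``[i·t, (i+1)·t)`` and is analyzed iff
    ``i % sampling_interval == 0``, so consecutive analyzed sections sit
    ``sampling_interval × thickness`` apart (30 µm at defaults).
    """
    t = geometry.section_thickness_um
    return [
        SectionSlab(
            index=i,
            z_low_um=i * t,
            z_high_um=(i + 1) * t,
            sampled=(i % geometry.sampling_interval == 0),
        )
        for i in range(geometry.n_sections)
    ]


def nucleus_visible(
    follicle: FollicleRecord | float,
    slab: SectionSlab | tuple[float, float],
    nucleus_diameter_um: float | None = None,
) -> bool:
    """Whether a follicle's nucleus is visible on a section.

    The nucleus is a sphere of ``nucleus_diameter_um`` centered at the
    follicle center; it is visible iff its z-extent overlaps the open slab
    interval.  Equivalently, |center_z − slab midpoint| must be strictly
    less than (nucleus diameter + slab thickness)/2 — half-open slabs make
    boundary ties deterministic.

    ``follicle`` may be a :class:`FollicleRecord` or a bare ``center_z``
    (then ``nucleus_diameter_um`` is required).
    """
    if isinstance(follicle, FollicleRecord):
        center_z = follicle.center_um[2]
        nd = follicle.nucleus_diameter_um
    else:
        if nucleus_diameter_um is None:
            raise ParameterError("nucleus_diameter_um required with a bare center_z")
        center_z = float(follicle)
        nd = nucleus_diameter_um
    if isinstance(slab, SectionSlab):
        z_low, z_high = slab.z_low_um, slab.z_high_um
    else:
        z_low, z_high = slab
    if not z_low < z_high:
        raise ParameterError(f"degenerate slab [{z_low}, {z_high})")
    return (center_z - nd / 2.0) < z_high and (center_z + nd / 2.0) > z_low


def observe_sections(
    follicles: Sequence[FollicleRecord],
    geometry: FragmentGeometry,
    ewe_id: str = "ewe1",
    ovary_id: str = "ov1",
    fragment_id: str = "frag1",
    group: str = "control",
    area_jitter: float = 0.0,
    rng_seed: int | np.random.Generator = 0,
) -> list[SectionObservation]:
    """Emulate the histological analysis of one fragment.

    One observation per sampled section, counting per maturity class the
    follicles whose nucleus is visible in that section.  The cortical area
    defaults to the constant fragment face area; ``area_jitter`` in (0, 1)
    perturbs each section's area uniformly by ±that relative amount,
    standing in for the manual outlining of an irregular cortical surface.
    """
    if not 0.0 <= area_jitter < 1.0:
        raise ParameterError("area_jitter must be in [0, 1)")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    slabs = [s for s in slice_fragment(geometry) if s.sampled]
    base_area = geometry.face_area_mm2
    observations = []
    for slab in slabs:
        counts = {cls: 0 for cls in MaturityClass}
        for fol in follicles:
            if nucleus_visible(fol, slab):
                counts[fol.maturity_class] += 1
        area = base_area
        if area_jitter > 0:
            area *= 1.0 + rng.uniform(-area_jitter, area_jitter)
        observations.append(
            SectionObservation(
                ewe_id=ewe_id,
                ovary_id=ovary_id,
                fragment_id=fragment_id,
                section_index=slab.index,
                area_mm2=area,
                counts={k: v for k, v in counts.items() if v},
                group=group,
            )
        )
    return observations


@dataclass(frozen=True)
class HierarchyParams:
    """Parameters of the direct-mode hierarchical density model.

    Defaults mirror the study structure: 4 ewes × 2 ovaries, 15 fragments
    per ovary, 34 analyzed sections per fragment, fragment and section
    variance components 0.116 and 0.993 (log10 units²).
    """

    n_ewes: int = 4
    ovaries_per_ewe: int = 2
    fragments_per_ovary: int = 15
    sections_per_fragment: int = 34
    mu: float = 0.56
    ewe_offsets: tuple[float, ...] | None = None
    ovary_offsets: tuple[tuple[float, ...], ...] | None = None
    sigma2_fragment: float = 0.116
    sigma2_section: float = 0.993
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ewes, self.ovaries_per_ewe, self.fragments_per_ovary) < 1:
            raise ParameterError("hierarchy counts must be >= 1")
        if self.sections_per_fragment < 1:
            raise ParameterError("sections_per_fragment must be >= 1")
        if self.sigma2_fragment < 0:
            raise ParameterError("sigma2_fragment must be >= 0")
        if self.sigma2_section < 0:
            raise ParameterError("sigma2_section must be >= 0")
        if self.ewe_offsets is not None and len(self.ewe_offsets) != self.n_ewes:
            raise ParameterError("ewe_offsets length must equal n_ewes")
        if self.ovary_offsets is not None:
            if len(self.ovary_offsets) != self.n_ewes or any(
                len(row) != self.ovaries_per_ewe for row in self.ovary_offsets
            ):
                raise ParameterError(
                    "ovary_offsets must be n_ewes rows of ovaries_per_ewe shifts"
                )

    def ewe_offset(self, i: int) -> float:
        return 0.0 if self.ewe_offsets is None else self.ewe_offsets[i]

    def ovary_offset(self, i: int, j: int) -> float:
        return 0.0 if self.ovary_offsets is None else self.ovary_offsets[i][j]


def generate_density_table(
    params: HierarchyParams,
    treatment_delta: float = 0.0,
    n_groups: int = 1,
    group_labels: Sequence[str] = ("control", "treated"),
) -> pd.DataFrame:
    """Simulate a table of log10 densities from the hierarchical model.

    With ``n_groups > 1`` the fragments within each ovary are split evenly
    into the first ``n_groups`` labels of ``group_labels`` and
    ``treatment_delta`` (log10 units) is added to every non-control group —
    the design the power engine resamples.  Deterministic for a fixed
    ``params.seed``; fragments draw from independently spawned substreams
    so any fragment can be regenerated on its own.
    """
    if n_groups < 1:
        raise ParameterError("n_groups must be >= 1")
    if n_groups > 1 and params.fragments_per_ovary % n_groups:
        raise ParameterError(
            f"fragments_per_ovary={params.fragments_per_ovary} not divisible "
            f"into {n_groups} groups"
        )
    if n_groups > len(group_labels):
        raise ParameterError("not enough group labels")

    n_fragments_total = params.n_ewes * params.ovaries_per_ewe * params.fragments_per_ovary
    streams = np.random.SeedSequence(params.seed).spawn(n_fragments_total)
    per_group = params.fragments_per_ovary // n_groups

    rows = []
    stream_idx = 0
    for i in range(params.n_ewes):
        for j in range(params.ovaries_per_ewe):
            for k in range(params.fragments_per_ovary):
                rng = np.random.default_rng(streams[stream_idx])
                stream_idx += 1
                group = group_labels[min(k // per_group, n_groups - 1)] if n_groups > 1 else group_labels[0]
                delta = treatment_delta if (n_groups > 1 and group != group_labels[0]) else 0.0
                f = rng.normal(0.0, math.sqrt(params.sigma2_fragment)) if params.sigma2_fragment > 0 else 0.0
                if params.sigma2_section > 0:
                    e = rng.normal(0.0, math.sqrt(params.sigma2_section), params.sections_per_fragment)
                else:
                    e = np.zeros(params.sections_per_fragment)
                base = params.mu + params.ewe_offset(i) + params.ovary_offset(i, j) + delta + f
                for s in range(params.sections_per_fragment):
                    rows.append(
                        (
                            f"ewe{i + 1}",
                            f"ov{j + 1}",
                            f"frag{k + 1}",
                            s,
                            group,
                            base + e[s],
                        )
                    )
    return pd.DataFrame(
        rows, columns=["ewe_id", "ovary_id", "fragment_id", "section_index", "group", "y"]
    )
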