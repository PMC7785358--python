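"""Declarative model of the multiplex PCR-RFLP/STR assay panel.

An :class:`AssayPanel` is the single source of truth for everything the
digestion engine, the electropherogram simulator and the genotype caller
need to know about the assay: the restriction enzymes and their recognition
patterns, the fluorescently labeled primer pairs, the two diagnostic RFLP
markers (C282Y on *HFE* exon 4, H63D on exon 2), the two identity STR loci
(FGA, SE33), the *FZD1* internal digestion-control fragment, and the
analytical thresholds (noise ceiling, cutoff, saturation, stutter rule).

Panels are hand-editable YAML documents (see ``data/hfe_panel.yaml`` for the
bundled default); :func:`load_panel` / :func:`dump_panel` round-trip them,
and every structural invariant is enforced at construction time through
pydantic validators, so a panel object in hand is always internally
consistent.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

#: Minimum separation (bp) between any two expected fragment sizes that share
#: a dye channel -- single-base CE resolution with margin.
SIZE_SEPARATION_BP = 1.0


class Enzyme(BaseModel):
    """A restriction endonuclease: IUPAC recognition pattern plus the cut
    offset from the 5' end of the pattern on the top strand (SexAI A/CCWGGT
    and BspHI T/CATGA both cut after the first base)."""

    model_config = ConfigDict(frozen=True)

    name: str
    recognition: str
    cut_offset: int

    @field_validator("recognition")
    @classmethod
    def _recognition_is_iupac(cls, v: str) -> str:
        v = v.upper()
        bad = set(v) - IUPAC_CODES
        if not v or bad:
            raise ValueError(f"recognition must be non-empty IUPAC (ACGTRYSWKMBDHVN); bad: {sorted(bad)}")
        return v

    @model_validator(mode="after")
    def _offset_within_pattern(self) -> "Enzyme":
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside pattern of length {len(self.recognition)}"
            )
        return self


class PrimerPair(BaseModel):
    """An upper/lower PCR primer pair; at least one primer must carry a dye
    (an unlabeled fragment is invisible on the electropherogram)."""

    model_config = ConfigDict(frozen=True)

    name: str
    upper_seq: str
    lower_seq: str
    upper_dye: Optional[str] = None
    lower_dye: Optional[str] = None

    @field_validator("upper_seq", "lower_seq")
    @classmethod
    def _acgt(cls, v: str) -> str:
        v = v.upper()
        if not v or set(v) - set("ACGT"):
            raise ValueError("primer sequences must be non-empty uppercase ACGT")
        return v

    @model_validator(mode="after")
    def _at_least_one_label(self) -> "PrimerPair":
        if self.upper_dye is None and self.lower_dye is None:
            raise ValueError(f"primer pair {self.name!r} carries no dye on either primer")
        return self


class RFLPMarker(BaseModel):
    """A diagnostic RFLP marker: one amplicon, one enzyme, one polymorphic
    recognition site whose presence/absence distinguishes the two alleles."""

    model_config = ConfigDict(frozen=True)

    name: str
    enzyme_name: str
    amplicon_length: int
    site_position: int  # 0-based offset of the recognition-site start
    variant_creates_site: bool = True
    labeled_end: Literal["five_prime", "three_prime"] = "five_prime"
    dye: str
    primer_pair: str

    @model_validator(mode="after")
    def _site_inside(self) -> "RFLPMarker":
        if not 0 < self.site_position < self.amplicon_length:
            raise ValueError(
                f"site_position {self.site_position} outside amplicon of {self.amplicon_length} bp"
            )
        return self

    def cut_size(self, enzyme: Enzyme) -> int:
        """Size (bp) of the labeled fragment when the site is cut."""
        cut = self.site_position + enzyme.cut_offset
        return cut if self.labeled_end == "five_prime" else self.amplicon_length - cut


class STRLocus(BaseModel):
    """A short tandem repeat locus.  Allele designations follow forensic
    nomenclature: repeat count with the microvariant remainder in bp as a
    decimal (26.2 = 26 repeats + 2 bp).  ``size_offset`` is the fragment size
    of a hypothetical 0-repeat allele, so size = offset + 4*reps + remainder.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    repeat_unit_length: int
    size_offset: float
    allele_min: float
    allele_max: float
    stutter_mean: float
    stutter_sd: float
    dye: str
    primer_pair: str

    @model_validator(mode="after")
    def _ranges(self) -> "STRLocus":
        if not self.allele_min < self.allele_max:
            raise ValueError(f"allele_min {self.allele_min} must be < allele_max {self.allele_max}")
        if not 0 < self.stutter_mean < 1:
            raise ValueError("stutter_mean must be in (0, 1)")
        if not self.stutter_sd > 0:
            raise ValueError("stutter_sd must be > 0")
        if self.repeat_unit_length <= 0:
            raise ValueError("repeat_unit_length must be positive")
        return self

    def size_of(self, designation: float) -> float:
        """Fragment size (bp) of an allele designation."""
        reps = int(designation)
        remainder = round((designation - reps) * 10)
        return self.size_offset + reps * self.repeat_unit_length + remainder

    def designation_of(self, size: float) -> float:
        """Inverse of :meth:`size_of` with rounding to the nearest integer bp."""
        total = round(size - self.size_offset)
        reps, remainder = divmod(int(total), self.repeat_unit_length)
        return round(reps + remainder / 10, 1)

    def contains(self, designation: float) -> bool:
        return self.allele_min - 1e-9 <= designation <= self.allele_max + 1e-9

    def ladder(self) -> list[float]:
        """All integer and x.2 microvariant designations within the range."""
        out = []
        for reps in range(int(self.allele_min), int(self.allele_max) + 1):
            for frac in (0.0, 0.2):
                d = round(reps + frac, 1)
                if self.contains(d):
                    out.append(d)
        return out


class ControlFragment(BaseModel):
    """The FZD1 internal digestion control: one amplicon labeled on *both*
    primers that carries one obligate SexAI site and one obligate BspHI site.
    A complete double digest leaves two labeled terminal fragments; each
    enzyme's failure shows a characteristic larger labeled fragment."""

    model_config = ConfigDict(frozen=True)

    name: str
    amplicon_length: int
    sexai_position: int
    bsphi_position: int
    expected_double_digest_sizes: tuple[float, float]
    expected_single_failure_sizes: dict[str, float]
    uncut_size: float
    dye: str
    primer_pair: str

    @model_validator(mode="after")
    def _sizes_within(self) -> "ControlFragment":
        sizes = [*self.expected_double_digest_sizes,
                 *self.expected_single_failure_sizes.values(), self.uncut_size]
        for s in sizes:
            if s > self.amplicon_length:
                raise ValueError(f"control size {s} exceeds amplicon length {self.amplicon_length}")
        return self


class Thresholds(BaseModel):
    """Analytical thresholds in RFU: the noise ceiling of blank runs, the
    interpretation cutoff (multiplier x noise ceiling), the camera saturation
    limit, and the SD multiplier of the stutter contamination rule."""

    model_config = ConfigDict(frozen=True)

    noise_ceiling: float
    cutoff_multiplier: float
    analytical_cutoff: float
    saturation: float
    stutter_sd_multiplier: float = 2.0

    @model_validator(mode="after")
    def _consistent(self) -> "Thresholds":
        expected = self.cutoff_multiplier * self.noise_ceiling
        if not math.isclose(self.analytical_cutoff, expected, rel_tol=1e-9):
            raise ValueError(
                f"analytical_cutoff {self.analytical_cutoff} != "
                f"cutoff_multiplier*noise_ceiling = {expected}"
            )
        if not self.saturation > self.analytical_cutoff:
            raise ValueError("saturation must exceed analytical_cutoff")
        return self


class AssayPanel(BaseModel):
    model_config = ConfigDict(frozen=True)

    schema_version: int = 1
    name: str = "panel"
    dyes: tuple[str, ...]
    enzymes: tuple[Enzyme, ...]
    primer_pairs: tuple[PrimerPair, ...]
    rflp_markers: tuple[RFLPMarker, ...]
    str_loci: tuple[STRLocus, ...]
    control: ControlFragment
    thresholds: Thresholds

    # -- lookups ---------------------------------------------------------
    def enzyme(self, name: str) -> Enzyme:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise KeyError(f"enzyme {name!r} not in panel")

    def primer_pair_by_name(self, name: str) -> PrimerPair:
        for p in self.primer_pairs:
            if p.name == name:
                return p
        raise KeyError(f"primer pair {name!r} not in panel")

    def marker(self, name: str) -> RFLPMarker:
        for m in self.rflp_markers:
            if m.name == name:
                return m
        raise KeyError(f"marker {name!r} not in panel")

    def locus(self, name: str) -> STRLocus:
        for s in self.str_loci:
            if s.name == name:
                return s
        raise KeyError(f"STR locus {name!r} not in panel")

    def marker_sizes(self, marker_name: str) -> dict[str, float]:
        """Expected labeled sizes for a marker: ``{"cut": ..., "uncut": ...}``."""
        m = self.marker(marker_name)
        return {"cut": float(m.cut_size(self.enzyme(m.enzyme_name))),
                "uncut": float(m.amplicon_length)}

    # -- validation ------------------------------------------------------
    @model_validator(mode="after")
    def _cross_references(self) -> "AssayPanel":
        errors: list[str] = []
        enzyme_names = {e.name for e in self.enzymes}
        pair_names = {p.name for p in self.primer_pairs}
        dye_names = set(self.dyes)

        for m in self.rflp_markers:
            if m.enzyme_name not in enzyme_names:
                errors.append(f"marker {m.name}: unknown enzyme {m.enzyme_name!r}")
            if m.primer_pair not in pair_names:
                errors.append(f"marker {m.name}: unknown primer pair {m.primer_pair!r}")
            if m.dye not in dye_names:
                errors.append(f"marker {m.name}: unknown dye {m.dye!r}")
        for s in self.str_loci:
            if s.primer_pair not in pair_names:
                errors.append(f"locus {s.name}: unknown primer pair {s.primer_pair!r}")
            if s.dye not in dye_names:
                errors.append(f"locus {s.name}: unknown dye {s.dye!r}")
        for enz in self.control.expected_single_failure_sizes:
            if enz not in enzyme_names:
                errors.append(f"control failure size references unknown enzyme {enz!r}")
        if self.control.dye not in dye_names:
            errors.append(f"control: unknown dye {self.control.dye!r}")
        if self.control.primer_pair in pair_names:
            pair = self.primer_pair_by_name(self.control.primer_pair)
            if pair.upper_dye != self.control.dye or pair.lower_dye != self.control.dye:
                errors.append("control fragment must be labeled with the same dye on both primers")
        else:
            errors.append(f"control: unknown primer pair {self.control.primer_pair!r}")
        for p in self.primer_pairs:
            for dye in (p.upper_dye, p.lower_dye):
                if dye is not None and dye not in dye_names:
                    errors.append(f"primer pair {p.name}: unknown dye {dye!r}")

        if not errors:
            errors.extend(channel_conflicts(self))
        if errors:
            raise ValueError("; ".join(errors))
        return self


def expected_size_entries(panel: AssayPanel) -> list[tuple[str, float, str, Optional[str]]]:
    """Every expected fragment size in the panel as
    ``(dye, size, label, exclusivity_group)``.

    Entries sharing a non-None group are alternative alleles of the same STR
    ladder and are exempt from the pairwise separation requirement (adjacent
    ladder steps are 1-2 bp apart by nomenclature, and within a locus allele
    identity is carried by the designation, not by peak isolation).
    """
    entries: list[tuple[str, float, str, Optional[str]]] = []
    for m in panel.rflp_markers:
        sizes = panel.marker_sizes(m.name)
        entries.append((m.dye, sizes["cut"], f"{m.name} cut", None))
        entries.append((m.dye, sizes["uncut"], f"{m.name} uncut", None))
    c = panel.control
    for i, s in enumerate(c.expected_double_digest_sizes):
        entries.append((c.dye, float(s), f"{c.name} double-digest {s}", None))
    for enz, s in sorted(c.expected_single_failure_sizes.items()):
        entries.append((c.dye, float(s), f"{c.name} {enz}-failure", None))
    entries.append((c.dye, float(c.uncut_size), f"{c.name} uncut", None))
    for loc in panel.str_loci:
        for d in loc.ladder():
            entries.append((loc.dye, loc.size_of(d), f"{loc.name} allele {d}", f"str:{loc.name}"))
    return entries


def channel_conflicts(panel: AssayPanel) -> list[str]:
    """Report every pair of expected fragment sizes that share a dye channel
    and lie within ``SIZE_SEPARATION_BP`` of each other.  Empty list means the
    caller can resolve every expected peak unambiguously."""
    entries = expected_size_entries(panel)
    conflicts = []
    by_dye: dict[str, list[tuple[float, str, Optional[str]]]] = {}
    for dye, size, label, group in entries:
        by_dye.setdefault(dye, []).append((size, label, group))
    for dye, items in by_dye.items():
        items.sort()
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                s1, l1, g1 = items[i]
                s2, l2, g2 = items[j]
                if s2 - s1 > SIZE_SEPARATION_BP:
                    break
                if g1 is not None and g1 == g2:
                    continue
                conflicts.append(
                    f"dye {dye}: {l1} ({s1:g} bp) and {l2} ({s2:g} bp) within "
                    f"{SIZE_SEPARATION_BP} bp"
                )
    return conflicts


# Backwards-friendly alias matching the operation name used in docs.
validate_channel_separability = channel_conflicts


def load_panel(source: str | Mapping | Path) -> AssayPanel:
    """Build a validated panel from YAML text, a mapping, or a file path."""
    if isinstance(source, Mapping):
        data = source
    elif isinstance(source, Path):
        data = yaml.safe_load(source.read_text())
    else:
        data = yaml.safe_load(source)
    if not isinstance(data, Mapping):
        raise ValueError("panel config did not parse to a mapping")
    return AssayPanel.model_validate(data)


def load_panel_file(path: str | Path) -> AssayPanel:
    return load_panel(Path(path))


def dump_panel(panel: AssayPanel) -> str:
    """Serialize a panel back to YAML; ``load_panel`` round-trips it."""
    return yaml.safe_dump(panel.model_dump(mode="json"), sort_keys=False)


def default_panel() -> AssayPanel:
    """The bundled HFE C282Y/H63D panel (SexAI + BspHI, FZD1 control,
    FGA + SE33 STRs)."""
    text = resources.files("hfetype").joinpath("data/hfe_panel.yaml").read_text()
    return load_panel(text)
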