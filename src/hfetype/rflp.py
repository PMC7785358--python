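"""Sequence-level in-silico PCR-RFLP engine.

IUPAC-aware restriction-site scanning on both strands, complete digestion of
amplicons into labeled/unlabeled fragments, prediction of the expected peak
sizes for a genotype, and a fixture-template generator that builds synthetic
amplicon sequences consistent with the panel layout (primer-flanked, with
the diagnostic sites placed exactly where the panel declares them and no
off-target sites anywhere).

Coordinate convention: 0-based, half-open; a cut position is the index of
the first base of the downstream fragment (site start + enzyme cut offset).
Fragment sizes are integers at this layer; sub-bp mobility is the
simulator's concern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values
from Bio.Seq import Seq

from .panel import AssayPanel, Enzyme
from .sample import SITE_ABSENT, SITE_PRESENT, SampleGenotype

_BASES = "ACGT"


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def pattern_reverse_complement(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (W->W, R->Y, ...)."""
    return "".join(ambiguous_dna_complement[c] for c in reversed(pattern))


def _iupac_regex(pattern: str) -> str:
    parts = []
    for c in pattern:
        expansion = ambiguous_dna_values[c]
        parts.append(c if len(expansion) == 1 else f"[{expansion}]")
    return "".join(parts)


def find_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut coordinates of an enzyme on a double-stranded sequence.

    A recognition-site *window* may be discovered on either strand (the
    pattern itself, or its reverse complement, matching the top strand); for
    the palindromic SexAI/BspHI patterns the bottom-strand scan is a no-op.
    Each window yields one cut at ``window_start + cut_offset``.  Returns
    sorted, deduplicated positions.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set(_BASES)
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return sorted({w + enzyme.cut_offset for w in _site_windows(sequence, enzyme)})


def _site_windows(sequence: str, enzyme: Enzyme) -> list[int]:
    """Start offsets of every recognition-site occurrence (either strand)."""
    pattern = enzyme.recognition
    starts = {m.start() for m in re.finditer(f"(?=({_iupac_regex(pattern)}))", sequence)}
    rc = pattern_reverse_complement(pattern)
    starts |= {m.start() for m in re.finditer(f"(?=({_iupac_regex(rc)}))", sequence)}
    return sorted(starts)


@dataclass(frozen=True)
class Amplicon:
    """A PCR product: sequence plus which ends carry a dye."""

    marker_name: str
    sequence: str
    labeled_ends: Mapping[str, str]  # {"five_prime": dye} and/or {"three_prime": dye}

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Fragment:
    """One digestion product.  ``dye`` is None iff neither bounding end
    retains a label; ``cut_by`` lists the enzymes bounding the fragment."""

    length: int
    dye: Optional[str]
    origin: str
    cut_by: tuple[str, ...]


def digest(amplicon: Amplicon, enzymes: Iterable[Enzyme]) -> list[Fragment]:
    """Complete simultaneous digestion by all enzymes; fragments partition
    the amplicon left to right (lengths sum to the amplicon length)."""
    cut_map: dict[int, set[str]] = {}
    for enzyme in enzymes:
        for cut in find_sites(amplicon.sequence, enzyme):
            cut_map.setdefault(cut, set()).add(enzyme.name)
    bounds = [0, *sorted(cut_map), len(amplicon.sequence)]
    fragments = []
    last = len(bounds) - 2
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        cut_by = sorted(cut_map.get(a, set()) | cut_map.get(b, set()))
        dye = None
        if i == 0 and "five_prime" in amplicon.labeled_ends:
            dye = amplicon.labeled_ends["five_prime"]
        if i == last and dye is None and "three_prime" in amplicon.labeled_ends:
            dye = amplicon.labeled_ends["three_prime"]
        fragments.append(Fragment(length=b - a, dye=dye, origin=amplicon.marker_name,
                                  cut_by=tuple(cut_by)))
    return fragments


def predict_peak_sizes(panel: AssayPanel, genotype: SampleGenotype) -> dict[str, set[float]]:
    """Expected true-peak sizes per dye channel for a genotype.

    RFLP markers contribute the labeled cut-fragment size for a site-bearing
    allele and the uncut amplicon size for a site-free allele (both for a
    heterozygote); STR loci one size per distinct allele; the control
    fragment always its two double-digest sizes.
    """
    out: dict[str, set[float]] = {}
    for m in panel.rflp_markers:
        sizes = panel.marker_sizes(m.name)
        for allele in set(genotype.rflp_alleles[m.name]):
            key = "cut" if allele == SITE_PRESENT else "uncut"
            out.setdefault(m.dye, set()).add(sizes[key])
    if genotype.str_alleles is not None:
        for locus in panel.str_loci:
            for d in set(genotype.str_alleles[locus.name]):
                if not locus.contains(d):
                    raise ValueError(
                        f"allele {d} outside {locus.name} range "
                        f"[{locus.allele_min}, {locus.allele_max}]"
                    )
                out.setdefault(locus.dye, set()).add(locus.size_of(d))
    control = panel.control
    out.setdefault(control.dye, set()).update(float(s) for s in control.expected_double_digest_sizes)
    return out


# ---------------------------------------------------------------------------
# Fixture template generation
# ---------------------------------------------------------------------------

class TemplateGenerationError(RuntimeError):
    pass


def _concrete_site(enzyme: Enzyme) -> str:
    """One concrete instance of the recognition pattern (first expansion of
    each ambiguity code, e.g. ACCWGGT -> ACCAGGT)."""
    return "".join(ambiguous_dna_values[c][0] for c in enzyme.recognition)


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return [_BASES[int(i)] for i in rng.integers(0, 4, size=n)]


def _repair_offtarget(
    seq: list[str],
    enzymes: Iterable[Enzyme],
    allowed: set[tuple[str, int]],
    mutable: set[int],
    rng: np.random.Generator,
    max_iterations: int = 500,
) -> None:
    """Mutate filler bases in place until no enzyme site exists outside the
    designed windows.  Raises if a site overlaps only immutable positions."""
    enzymes = list(enzymes)
    for _ in range(max_iterations):
        offending = []
        text = "".join(seq)
        for enzyme in enzymes:
            for start in _site_windows(text, enzyme):
                if (enzyme.name, start) not in allowed:
                    offending.append((start, len(enzyme.recognition)))
        if not offending:
            return
        start, length = offending[0]
        candidates = [p for p in range(start, start + length) if p in mutable]
        if not candidates:
            raise TemplateGenerationError(
                f"off-target site at {start} overlaps only immutable positions"
            )
        pos = candidates[int(rng.integers(0, len(candidates)))]
        current = seq[pos]
        seq[pos] = _BASES[(_BASES.index(current) + 1 + int(rng.integers(0, 3))) % 4]
    raise TemplateGenerationError("could not eliminate off-target sites")


def _labeled_ends(panel: AssayPanel, primer_pair_name: str) -> dict[str, str]:
    pair = panel.primer_pair_by_name(primer_pair_name)
    ends = {}
    if pair.upper_dye:
        ends["five_prime"] = pair.upper_dye
    if pair.lower_dye:
        ends["three_prime"] = pair.lower_dye
    return ends


def _assemble(
    panel: AssayPanel,
    rng: np.random.Generator,
    name: str,
    primer_pair_name: str,
    length: int,
    placements: list[tuple[int, str]],
) -> Amplicon:
    pair = panel.primer_pair_by_name(primer_pair_name)
    upper = pair.upper_seq
    lower_rc = reverse_complement(pair.lower_seq)
    filler_len = length - len(upper) - len(lower_rc)
    if filler_len < 0:
        raise TemplateGenerationError(f"{name}: primers longer than amplicon")
    seq = list(upper) + _random_bases(rng, filler_len) + list(lower_rc)
    protected: set[int] = set()
    allowed: set[tuple[str, int]] = set()
    for start, site in placements:
        if start < len(upper) or start + len(site) > length - len(lower_rc):
            raise TemplateGenerationError(f"{name}: designed site at {start} overlaps a primer")
        seq[start:start + len(site)] = list(site)
        protected.update(range(start, start + len(site)))
        for enzyme in panel.enzymes:
            if re.fullmatch(_iupac_regex(enzyme.recognition), site):
                allowed.add((enzyme.name, start))
    mutable = set(range(len(upper), length - len(lower_rc))) - protected
    _repair_offtarget(seq, panel.enzymes, allowed, mutable, rng)
    return Amplicon(marker_name=name, sequence="".join(seq),
                    labeled_ends=_labeled_ends(panel, primer_pair_name))


def _disrupt_site(panel: AssayPanel, amplicon: Amplicon, site_start: int,
                  enzyme: Enzyme) -> Amplicon:
    """Single-base change inside the recognition window that removes the
    site without creating a site for any panel enzyme."""
    seq = amplicon.sequence
    length = len(enzyme.recognition)
    for offset in range(length - 1, -1, -1):
        pos = site_start + offset
        for base in _BASES:
            if base == seq[pos]:
                continue
            candidate = seq[:pos] + base + seq[pos + 1:]
            if all(not _site_windows(candidate, e) for e in panel.enzymes):
                return Amplicon(amplicon.marker_name, candidate, amplicon.labeled_ends)
    raise TemplateGenerationError(f"{amplicon.marker_name}: could not disrupt site at {site_start}")


def _substitute_neutral(panel: AssayPanel, amplicon: Amplicon, pos: int,
                        expected_sites: dict[str, int]) -> Amplicon:
    """Change one base outside any recognition window such that every
    enzyme's site count is unchanged (models a nearby SNP like rs1800730)."""
    seq = amplicon.sequence
    for base in _BASES:
        if base == seq[pos]:
            continue
        candidate = seq[:pos] + base + seq[pos + 1:]
        counts = {e.name: len(_site_windows(candidate, e)) for e in panel.enzymes}
        if counts == expected_sites:
            return Amplicon(amplicon.marker_name, candidate, amplicon.labeled_ends)
    raise TemplateGenerationError(f"{amplicon.marker_name}: no neutral substitution at {pos}")


#: Offset (bp) of the stand-in rs1800730 (S65C) position downstream of the
#: H63D diagnostic site start -- strictly outside the BspHI hexamer.
S65C_OFFSET_FROM_SITE = 12


def build_fixture_templates(
    panel: AssayPanel, seed: int
) -> dict[str, dict[str, Amplicon]]:
    """Deterministic synthetic template amplicons consistent with the panel.

    For each RFLP marker, a ``site_present`` and a ``site_absent`` allele
    (single-base disrupted); the H63D (exon 2) amplicon additionally carries
    a mutable position standing in for rs1800730 (S65C) strictly outside the
    BspHI recognition hexamer, yielding ``*_s65c`` variants with identical
    digestion patterns.  The control entry carries exactly one SexAI and one
    BspHI site at the configured positions.  Filler sequence varies with the
    seed; fragment-size predictions do not.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, Amplicon]] = {}

    for marker in panel.rflp_markers:
        enzyme = panel.enzyme(marker.enzyme_name)
        site = _concrete_site(enzyme)
        present = _assemble(panel, rng, marker.name, marker.primer_pair,
                            marker.amplicon_length, [(marker.site_position, site)])
        absent = _disrupt_site(panel, present, marker.site_position, enzyme)
        alleles = {SITE_PRESENT: present, SITE_ABSENT: absent}
        if marker.name == "H63D":
            snp_pos = marker.site_position + S65C_OFFSET_FROM_SITE
            expected_present = {e.name: len(_site_windows(present.sequence, e))
                                for e in panel.enzymes}
            expected_absent = {e.name: len(_site_windows(absent.sequence, e))
                               for e in panel.enzymes}
            alleles[SITE_PRESENT + "_s65c"] = _substitute_neutral(
                panel, present, snp_pos, expected_present)
            alleles[SITE_ABSENT + "_s65c"] = _substitute_neutral(
                panel, absent, snp_pos, expected_absent)
        out[marker.name] = alleles

    control = panel.control
    sexai = panel.enzyme("SexAI")
    bsphi = panel.enzyme("BspHI")
    fzd1 = _assemble(
        panel, rng, control.name, control.primer_pair, control.amplicon_length,
        [(control.sexai_position, _concrete_site(sexai)),
         (control.bsphi_position, _concrete_site(bsphi))],
    )
    out[control.name] = {"control": fzd1}

    _verify_templates(panel, out)
    return out


def _verify_templates(panel: AssayPanel, templates: dict[str, dict[str, Amplicon]]) -> None:
    for marker in panel.rflp_markers:
        enzyme = panel.enzyme(marker.enzyme_name)
        for key, amp in templates[marker.name].items():
            n_sites = len(_site_windows(amp.sequence, enzyme))
            expected = 1 if key.startswith(SITE_PRESENT) else 0
            if n_sites != expected:
                raise TemplateGenerationError(
                    f"{marker.name}/{key}: {n_sites} {enzyme.name} sites, expected {expected}")
            for other in panel.enzymes:
                if other.name != enzyme.name and _site_windows(amp.sequence, other):
                    raise TemplateGenerationError(
                        f"{marker.name}/{key}: off-target {other.name} site")
    control = panel.control
    fzd1 = templates[control.name]["control"]
    fragments = digest(fzd1, panel.enzymes)
    labeled = sorted(f.length for f in fragments if f.dye is not None)
    expected = sorted(control.expected_double_digest_sizes)
    if [float(x) for x in labeled] != [float(x) for x in expected]:
        raise TemplateGenerationError(
            f"{control.name}: double-digest labeled sizes {labeled} != {expected}")


def templates_to_fasta(templates: dict[str, dict[str, Amplicon]]) -> str:
    """FASTA text, one record per marker-allele template."""
    from io import StringIO

    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for marker in sorted(templates):
        for allele in sorted(templates[marker]):
            amp = templates[marker][allele]
            records.append(SeqRecord(Seq(amp.sequence), id=f"{marker}|{allele}",
                                     description=f"{len(amp.sequence)} bp synthetic template"))
    buf = StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
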