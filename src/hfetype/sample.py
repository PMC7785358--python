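"""Ground-truth sample genotypes and cohort compositions.

A :class:`SampleGenotype` is what the simulator consumes: for each RFLP
marker an unordered pair of allele states (``site_present`` /
``site_absent``), for each STR locus an unordered pair of repeat
designations (``None`` means "draw uniformly from the ladder at simulation
time"), the S65C status (carried only so its non-interference with BspHI
digestion can be asserted), an optional whole-enzyme digestion failure, and
the DNA input in ng.

:func:`hfe60_composition` reproduces the 60-sample validation series of the
assay: eight genotype classes with counts 18/11/9/8/6/5/2/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .panel import AssayPanel

SITE_PRESENT = "site_present"
SITE_ABSENT = "site_absent"

S65C_REF_HOM = "ref_hom"
S65C_HET = "het"
S65C_VAR_HOM = "var_hom"


@dataclass(frozen=True)
class SampleGenotype:
    """Ground truth for one simulated sample."""

    rflp_alleles: dict[str, tuple[str, str]]
    str_alleles: Optional[dict[str, tuple[float, float]]] = None
    s65c_status: str = S65C_REF_HOM
    digestion_failure: Optional[str] = None
    dna_input: float = 25.0
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dna_input <= 0:
            raise ValueError("dna_input must be positive (ng)")
        for name, pair in self.rflp_alleles.items():
            for a in pair:
                if a not in (SITE_PRESENT, SITE_ABSENT):
                    raise ValueError(f"marker {name}: bad allele state {a!r}")
        if self.s65c_status not in (S65C_REF_HOM, S65C_HET, S65C_VAR_HOM):
            raise ValueError(f"bad s65c_status {self.s65c_status!r}")

    def describe(self) -> str:
        parts = []
        for name in sorted(self.rflp_alleles):
            pair = self.rflp_alleles[name]
            n_var = sum(a == SITE_PRESENT for a in pair)
            parts.append(f"{name}:{['-/-', '+/-', '+/+'][n_var]}")
        parts.append(f"S65C:{self.s65c_status}")
        if self.str_alleles:
            for name in sorted(self.str_alleles):
                a, b = sorted(self.str_alleles[name])
                parts.append(f"{name}:{a:g}/{b:g}")
        if self.digestion_failure:
            parts.append(f"failure:{self.digestion_failure}")
        return " ".join(parts)


def _pair(n_variant: int) -> tuple[str, str]:
    """Allele-state pair for a variant-allele count (variant allele carries
    the site in the default panel polarity)."""
    return {
        0: (SITE_ABSENT, SITE_ABSENT),
        1: (SITE_PRESENT, SITE_ABSENT),
        2: (SITE_PRESENT, SITE_PRESENT),
    }[n_variant]


def make_genotype(
    c282y: int = 0,
    h63d: int = 0,
    s65c: str = S65C_REF_HOM,
    str_alleles: Optional[dict[str, tuple[float, float]]] = None,
    dna_input: float = 25.0,
    digestion_failure: Optional[str] = None,
    label: Optional[str] = None,
) -> SampleGenotype:
    """Convenience constructor from variant-allele counts (0/1/2)."""
    return SampleGenotype(
        rflp_alleles={"C282Y": _pair(c282y), "H63D": _pair(h63d)},
        str_alleles=str_alleles,
        s65c_status=s65c,
        digestion_failure=digestion_failure,
        dna_input=dna_input,
        label=label,
    )


#: (C282Y variant count, H63D variant count, S65C status, n) for the
#: 60-sample validation series.
HFE60_CLASSES: tuple[tuple[int, int, str, int], ...] = (
    (0, 0, S65C_REF_HOM, 18),
    (0, 1, S65C_REF_HOM, 11),
    (1, 0, S65C_REF_HOM, 9),
    (1, 1, S65C_REF_HOM, 8),
    (2, 0, S65C_REF_HOM, 6),
    (0, 2, S65C_REF_HOM, 5),
    (0, 0, S65C_HET, 2),
    (0, 1, S65C_HET, 1),
)


def hfe60_composition(dna_input: float = 25.0) -> list[tuple[SampleGenotype, int]]:
    """The 60-sample cohort composition (class counts 18/11/9/8/6/5/2/1);
    STR genotypes are left unspecified and drawn at simulation time."""
    out = []
    zygosity = ["-/-", "+/-", "+/+"]
    s65c_sym = {S65C_REF_HOM: "-/-", S65C_HET: "+/-", S65C_VAR_HOM: "+/+"}
    for c282y, h63d, s65c, n in HFE60_CLASSES:
        label = f"C282Y{zygosity[c282y]} H63D{zygosity[h63d]} S65C{s65c_sym[s65c]}"
        out.append((make_genotype(c282y, h63d, s65c, dna_input=dna_input, label=label), n))
    return out


def adversarial_mixture_pair(dna_input: float = 25.0) -> tuple[SampleGenotype, SampleGenotype]:
    """The two-person mixture construction used to probe contamination
    detection: the minor contributor carries one FGA allele (19) exactly one
    repeat unit below a major allele (the major is FGA 20-homozygous, so
    allele 19 sits squarely in its stutter bin), two clear extra STR
    alleles, and a heterozygous H63D variant absent from the major."""
    major = make_genotype(0, 0,
                          str_alleles={"FGA": (20.0, 20.0), "SE33": (17.0, 25.0)},
                          dna_input=dna_input, label="major")
    minor = make_genotype(0, 1,
                          str_alleles={"FGA": (19.0, 30.0), "SE33": (13.0, 29.0)},
                          dna_input=dna_input, label="minor")
    return major, minor


def random_str_alleles(panel: AssayPanel, rng: np.random.Generator) -> dict[str, tuple[float, float]]:
    """Draw one genotype per locus uniformly from the allele ladder
    (with replacement, so homozygotes occur)."""
    out = {}
    for locus in panel.str_loci:
        ladder = locus.ladder()
        idx = rng.integers(0, len(ladder), size=2)
        out[locus.name] = (ladder[int(idx[0])], ladder[int(idx[1])])
    return out


def with_str_alleles(genotype: SampleGenotype, alleles: dict[str, tuple[float, float]]) -> SampleGenotype:
    return replace(genotype, str_alleles=alleles)
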