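"""Capillary-electrophoresis electropherogram simulator.

Turns a ground-truth :class:`~hfetype.sample.SampleGenotype` (or a
two-person mixture) into a realistic peak table implementing the assay's
signal model:

* expected true-peak height scales linearly with DNA input,
  ``H(d) = H_REF_RFU * d / REF_INPUT_NG`` per diploid genome-equivalent,
  with multiplicative lognormal amplification noise and hard clipping at
  the saturation ceiling;
* the FZD1 control digest peaks run at a lower relative amplitude
  (``CONTROL_PEAK_WEIGHT``) so that at 2 ng input they are visible but
  below the analytical cutoff while every true-allele peak at 10-200 ng
  stays inside the 250-32000 RFU window;
* each STR allele peak is accompanied by one stutter peak exactly one
  repeat unit shorter, with a height ratio drawn from the locus's normal
  stutter distribution truncated at zero;
* baseline noise peaks with heights uniform in (0, noise ceiling) are
  scattered across every dye channel;
* every structured peak gets a sub-bp size jitter (uniform, ±0.3 bp);
* a whole-enzyme digestion failure replaces that enzyme's control
  double-digest peak with the configured single-failure size and forces the
  uncut size on every marker using that enzyme, regardless of allele;
* mixtures weight each contributor's peaks by its template share
  (``r/(1+r)`` for the minor contributor of a "1 : r" mix); components that
  land at the same size -- e.g. a minor allele in a major allele's stutter
  bin -- sum.

All randomness flows from an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .panel import AssayPanel
from .peaks import Peak, PeakTable
from .sample import (SITE_ABSENT, SITE_PRESENT, SampleGenotype,
                     hfe60_composition, random_str_alleles)

#: Expected height (RFU) of a two-copy true-allele peak at the reference input.
H_REF_RFU = 8000.0
#: Reference DNA input (ng) at which H_REF_RFU is calibrated.
REF_INPUT_NG = 25.0
#: Sigma of the multiplicative lognormal amplification noise.
SIGMA_LOG = 0.15
#: Relative amplitude of each labeled FZD1 control digest peak.
CONTROL_PEAK_WEIGHT = 0.25
#: Baseline noise peaks per dye channel.
NOISE_PEAKS_PER_DYE = 8
NOISE_SIZE_RANGE = (60.0, 420.0)
#: Maximum sub-bp size jitter applied to structured peaks.
SIZE_JITTER_BP = 0.3


@dataclass(frozen=True)
class _Component:
    """One expected structured peak before noise realization.  ``weight`` is
    the expected height as a fraction of a full two-copy allele peak."""

    dye: str
    size: float
    weight: float
    locus: Optional[str] = None  # set for STR allele components (drives stutter)


def _genotype_components(panel: AssayPanel, genotype: SampleGenotype) -> list[_Component]:
    comps: list[_Component] = []
    failure = genotype.digestion_failure

    for marker in panel.rflp_markers:
        sizes = panel.marker_sizes(marker.name)
        if failure is not None and marker.enzyme_name == failure:
            comps.append(_Component(marker.dye, sizes["uncut"], 1.0))
            continue
        pair = genotype.rflp_alleles[marker.name]
        for state in sorted(set(pair)):
            copies = pair.count(state)
            key = "cut" if state == SITE_PRESENT else "uncut"
            comps.append(_Component(marker.dye, sizes[key], copies / 2.0))

    if genotype.str_alleles is None:
        raise ValueError("genotype has no STR alleles; draw them before simulating")
    for locus in panel.str_loci:
        pair = genotype.str_alleles[locus.name]
        for d in sorted(set(pair)):
            if not locus.contains(d):
                raise ValueError(f"allele {d} outside {locus.name} ladder")
            copies = pair.count(d)
            comps.append(_Component(locus.dye, locus.size_of(d), copies / 2.0, locus=locus.name))

    control = panel.control
    failure_sizes = control.expected_single_failure_sizes
    for enzyme, dd_size in zip(("SexAI", "BspHI"), control.expected_double_digest_sizes):
        if failure is not None and enzyme == failure:
            comps.append(_Component(control.dye, float(failure_sizes[enzyme]),
                                    CONTROL_PEAK_WEIGHT))
        else:
            comps.append(_Component(control.dye, float(dd_size), CONTROL_PEAK_WEIGHT))
    return comps


def _noise_peaks(panel: AssayPanel, rng: np.random.Generator) -> list[Peak]:
    peaks = []
    lo, hi = NOISE_SIZE_RANGE
    for dye in panel.dyes:
        sizes = rng.uniform(lo, hi, NOISE_PEAKS_PER_DYE)
        heights = rng.uniform(0.0, panel.thresholds.noise_ceiling, NOISE_PEAKS_PER_DYE)
        peaks.extend(Peak(dye=dye, size=float(s), height=float(h))
                     for s, h in zip(sizes, heights))
    return peaks


def _realize(
    panel: AssayPanel,
    components: Sequence[_Component],
    dna_input: float,
    rng: np.random.Generator,
) -> list[Peak]:
    """Draw heights, add stutter, merge coinciding components, jitter sizes."""
    scale = H_REF_RFU * dna_input / REF_INPUT_NG
    realized: list[tuple[str, float, float, Optional[str]]] = []
    for comp in components:
        height = comp.weight * scale * rng.lognormal(0.0, SIGMA_LOG)
        realized.append((comp.dye, comp.size, height, comp.locus))

    stutter: list[tuple[str, float, float]] = []
    for dye, size, height, locus_name in realized:
        if locus_name is None:
            continue
        locus = panel.locus(locus_name)
        ratio = max(0.0, rng.normal(locus.stutter_mean, locus.stutter_sd))
        stutter.append((dye, size - locus.repeat_unit_length, ratio * height))

    merged: dict[tuple[str, float], float] = {}
    for dye, size, height, _ in realized:
        merged[(dye, round(size, 4))] = merged.get((dye, round(size, 4)), 0.0) + height
    for dye, size, height in stutter:
        merged[(dye, round(size, 4))] = merged.get((dye, round(size, 4)), 0.0) + height

    saturation = panel.thresholds.saturation
    peaks = []
    for (dye, size), height in sorted(merged.items()):
        jitter = rng.uniform(-SIZE_JITTER_BP, SIZE_JITTER_BP)
        peaks.append(Peak(dye=dye, size=size + jitter, height=min(height, saturation)))
    return peaks


def simulate_sample(panel: AssayPanel, genotype: SampleGenotype, seed: int) -> PeakTable:
    """Simulate one single-source sample (deterministic given the seed)."""
    rng = np.random.default_rng(seed)
    comps = _genotype_components(panel, genotype)
    peaks = _realize(panel, comps, genotype.dna_input, rng)
    peaks.extend(_noise_peaks(panel, rng))
    return PeakTable(
        sample_id=f"sim-{seed}",
        peaks=peaks,
        metadata={"dna_input": genotype.dna_input, "seed": seed,
                  "genotype": genotype.describe(),
                  "class_label": genotype.label},
    )


def simulate_blank(panel: AssayPanel, seed: int) -> PeakTable:
    """A water blank: baseline noise only, everything below the noise ceiling."""
    rng = np.random.default_rng(seed)
    return PeakTable(sample_id=f"blank-{seed}", peaks=_noise_peaks(panel, rng),
                     metadata={"blank": True, "seed": seed})


def simulate_mixture(
    panel: AssayPanel,
    major: SampleGenotype,
    minor: SampleGenotype,
    ratio: float,
    seed: int,
) -> PeakTable:
    """Two-person mixture at minor:major proportion ``ratio`` (a "1 : r" mix
    has ratio 1/r): the minor contributor provides ``ratio/(1+ratio)`` of the
    template, the major the rest.  Shared sizes sum; a minor allele one
    repeat below a major allele adds to the major's stutter peak.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    minor_share = ratio / (1.0 + ratio)
    major_share = 1.0 - minor_share
    comps = [replace(c, weight=c.weight * major_share)
             for c in _genotype_components(panel, major)]
    comps += [replace(c, weight=c.weight * minor_share)
              for c in _genotype_components(panel, minor)]
    peaks = _realize(panel, comps, major.dna_input, rng)
    peaks.extend(_noise_peaks(panel, rng))
    return PeakTable(
        sample_id=f"mix-{seed}",
        peaks=peaks,
        metadata={"dna_input": major.dna_input, "seed": seed,
                  "mixture": f"minor:major = {ratio:g}:1",
                  "major": major.describe(), "minor": minor.describe()},
    )


def simulate_cohort(
    panel: AssayPanel,
    composition: Sequence[tuple[SampleGenotype, int]],
    seed: int,
) -> list[PeakTable]:
    """One table per sample.  Per-sample seeds derive deterministically from
    the master seed; genotypes with unspecified STR alleles get a uniform
    draw from each locus's ladder."""
    master = np.random.default_rng(seed)
    tables = []
    index = 0
    for genotype, count in composition:
        if count <= 0:
            raise ValueError("composition counts must be positive")
        for _ in range(count):
            index += 1
            g = genotype
            if g.str_alleles is None:
                g = replace(g, str_alleles=random_str_alleles(panel, master))
            sample_seed = int(master.integers(0, 2**31 - 1))
            table = simulate_sample(panel, g, sample_seed)
            table.sample_id = f"S{index:03d}"
            tables.append(table)
    return tables


def simulate_hfe60(panel: AssayPanel, seed: int, dna_input: float = 25.0) -> list[PeakTable]:
    """The 60-sample validation cohort (classes 18/11/9/8/6/5/2/1)."""
    return simulate_cohort(panel, hfe60_composition(dna_input=dna_input), seed)
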