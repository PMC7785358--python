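"""Stutter statistics, contamination detection and identity matching.

The contamination logic follows the assay's interpretive rules: stutter
ratios (stutter height / parent allele height) are characterized on a
series of clean single-source samples, and on ongoing assays any
stutter-position peak above mean + 2 SD of that distribution, any STR locus
with more than two allele-status designations, or a grossly imbalanced
extra RFLP allele peak is flagged as evidence of a second DNA contributor.

Identity matching compares the FGA/SE33 genotypes of two samples and, when
they agree, reports the random match probability as a product of
Hardy-Weinberg genotype frequencies over loci (2pq for heterozygotes, p^2
for homozygotes) using a user-supplied allele frequency table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from statistics import mean, stdev
from typing import Optional, Sequence

from .caller import (SIZE_TOLERANCE_BP, STRCall, SampleReport, call_str,
                     filter_peaks, match_peak)
from .panel import AssayPanel
from .peaks import Peak, PeakTable

EVIDENCE_EXTRA_STR = "extra_str_allele"
EVIDENCE_ELEVATED_STUTTER = "elevated_stutter"
EVIDENCE_EXTRA_RFLP = "extra_rflp_peak"

#: An apparent RFLP heterozygote whose minor/major peak-height ratio falls
#: below this value is treated as carrying a foreign (contaminating) allele.
RFLP_IMBALANCE_RATIO = 0.2


@dataclass
class StutterStats:
    locus_name: str
    mean_ratio: float
    sd_ratio: float
    n_alleles: int

    @property
    def usable(self) -> bool:
        return self.n_alleles >= 2


@dataclass
class Finding:
    kind: str
    locus: str
    size: float
    height: float
    detail: str = ""


@dataclass
class ContaminationReport:
    flagged: bool
    evidence: list[Finding] = field(default_factory=list)

    def kinds(self) -> set[str]:
        return {f.kind for f in self.evidence}

    def to_dict(self) -> dict:
        return {"flagged": self.flagged,
                "evidence": [{"kind": f.kind, "locus": f.locus, "size": f.size,
                              "height": f.height, "detail": f.detail}
                             for f in self.evidence]}


@dataclass
class IdentityResult:
    match: bool
    compared_loci: int
    match_probability: float


# ---------------------------------------------------------------------------
# Stutter statistics
# ---------------------------------------------------------------------------

def _measurable_parents(call: STRCall, unit: int) -> list[Peak]:
    """Called allele peaks whose stutter bin does not coincide with another
    called allele (those ratios would be confounded and are excluded)."""
    parents = []
    allele_sizes = [p.size for p in call.allele_peaks]
    for p in call.allele_peaks:
        bin_center = p.size - unit
        if any(abs(s - bin_center) <= SIZE_TOLERANCE_BP for s in allele_sizes if s != p.size):
            continue
        parents.append(p)
    return parents


def _stutter_bin_height(raw_table: PeakTable, dye: str, bin_center: float,
                        allele_peaks: Sequence[Peak]) -> float:
    """Total height in the stutter bin, read from the *unfiltered* table so
    sub-cutoff (or absent -> zero) stutter pulls the ratio down honestly."""
    allele_ids = {(p.size, p.height) for p in allele_peaks}
    total = 0.0
    for p in raw_table.channel(dye):
        if (p.size, p.height) in allele_ids:
            continue
        if abs(p.size - bin_center) <= SIZE_TOLERANCE_BP:
            total += p.height
    return total


def estimate_stutter_stats(
    tables: Sequence[PeakTable],
    panel: AssayPanel,
    cutoff: Optional[float] = None,
) -> dict[str, StutterStats]:
    """Per-locus stutter ratio mean/SD over presumed-uncontaminated samples.

    For each called allele with an isolated stutter bin, ratio = stutter
    height / allele height (zero when the bin is empty).  Loci with fewer
    than two usable ratios are returned with ``usable == False``.
    """
    if cutoff is None:
        cutoff = panel.thresholds.analytical_cutoff
    ratios: dict[str, list[float]] = {locus.name: [] for locus in panel.str_loci}
    for table in tables:
        filtered = filter_peaks(table, cutoff)
        for locus in panel.str_loci:
            call = call_str(filtered, locus, cutoff)
            for parent in _measurable_parents(call, locus.repeat_unit_length):
                stutter_h = _stutter_bin_height(
                    table, locus.dye, parent.size - locus.repeat_unit_length,
                    call.allele_peaks)
                ratios[locus.name].append(stutter_h / parent.height)
    out = {}
    for locus in panel.str_loci:
        r = ratios[locus.name]
        if len(r) >= 2:
            out[locus.name] = StutterStats(locus.name, mean(r), stdev(r), len(r))
        else:
            out[locus.name] = StutterStats(locus.name, float("nan"), float("nan"), len(r))
    return out


def stutter_threshold(stats: StutterStats, sd_multiplier: float) -> float:
    """The contamination threshold mean + k*SD for one locus."""
    if not stats.usable:
        raise ValueError(f"stutter stats for {stats.locus_name} are unusable "
                         f"(n={stats.n_alleles})")
    return stats.mean_ratio + sd_multiplier * stats.sd_ratio


# ---------------------------------------------------------------------------
# Contamination detection
# ---------------------------------------------------------------------------

def detect_contamination(
    report: SampleReport,
    table: PeakTable,
    stats: dict[str, StutterStats],
    panel: AssayPanel,
    cutoff: Optional[float] = None,
    min_evidence: int = 1,
    rflp_imbalance_ratio: float = RFLP_IMBALANCE_RATIO,
) -> ContaminationReport:
    """Flag a sample on any of three evidence kinds.

    (a) an STR locus with more than two allele-status designations above
    the cutoff (extra or off-ladder alleles); (b) a stutter-position peak
    whose ratio to its called parent exceeds the locus's mean + k*SD
    threshold; (c) an RFLP marker showing both allele peaks at a
    minor/major height ratio below ``rflp_imbalance_ratio`` (a foreign
    allele riding under an apparent heterozygote).
    """
    if cutoff is None:
        cutoff = panel.thresholds.analytical_cutoff
    sd_multiplier = panel.thresholds.stutter_sd_multiplier
    filtered = filter_peaks(table, cutoff)
    evidence: list[Finding] = []

    # (a) extra STR designations
    for call in report.str_calls:
        locus = panel.locus(call.locus_name)
        for d, h in zip(call.extra_alleles, call.extra_heights):
            evidence.append(Finding(EVIDENCE_EXTRA_STR, call.locus_name,
                                    locus.size_of(d), h,
                                    detail=f"designation {d:g} beyond two alleles"))
        for d in call.off_ladder:
            evidence.append(Finding(EVIDENCE_EXTRA_STR, call.locus_name,
                                    locus.size_of(d), 0.0,
                                    detail=f"off-ladder designation {d:g}"))

    # (b) elevated stutter
    for call in report.str_calls:
        locus = panel.locus(call.locus_name)
        locus_stats = stats.get(call.locus_name)
        if locus_stats is None or not locus_stats.usable:
            continue
        threshold = stutter_threshold(locus_stats, sd_multiplier)
        unit = locus.repeat_unit_length
        channel = filtered.channel(locus.dye)
        allele_sizes = [p.size for p in call.allele_peaks]
        for parent in call.allele_peaks:
            bin_center = parent.size - unit
            if any(abs(s - bin_center) <= SIZE_TOLERANCE_BP
                   for s in allele_sizes if s != parent.size):
                continue  # bin occupied by another true allele
            candidates = [p for p in channel
                          if abs(p.size - bin_center) <= SIZE_TOLERANCE_BP
                          and p not in call.allele_peaks]
            if not candidates:
                continue
            stutter_peak = max(candidates, key=lambda p: p.height)
            ratio = stutter_peak.height / parent.height
            if ratio > threshold:
                evidence.append(Finding(
                    EVIDENCE_ELEVATED_STUTTER, call.locus_name,
                    stutter_peak.size, stutter_peak.height,
                    detail=f"ratio {ratio:.3f} > threshold {threshold:.3f}"))

    # (c) imbalanced extra RFLP peak
    for marker in panel.rflp_markers:
        sizes = panel.marker_sizes(marker.name)
        channel = filtered.channel(marker.dye)
        cut_peak = match_peak(channel, sizes["cut"])
        uncut_peak = match_peak(channel, sizes["uncut"])
        if cut_peak is None or uncut_peak is None:
            continue
        minor, major = sorted((cut_peak, uncut_peak), key=lambda p: p.height)
        if minor.height < rflp_imbalance_ratio * major.height:
            evidence.append(Finding(
                EVIDENCE_EXTRA_RFLP, marker.name, minor.size, minor.height,
                detail=f"minor/major ratio {minor.height / major.height:.3f} "
                       f"< {rflp_imbalance_ratio}"))

    return ContaminationReport(flagged=len(evidence) >= min_evidence, evidence=evidence)


# ---------------------------------------------------------------------------
# Identity matching
# ---------------------------------------------------------------------------

def load_frequency_table(path: str | Path) -> dict[str, dict[float, float]]:
    """CSV ``locus,allele,freq`` -> nested mapping."""
    out: dict[str, dict[float, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != ["locus", "allele", "freq"]:
            raise ValueError(f"{path}: expected header locus,allele,freq")
        for row in reader:
            out.setdefault(row["locus"].strip(), {})[float(row["allele"])] = float(row["freq"])
    return out


def default_frequency_table() -> dict[str, dict[float, float]]:
    """The bundled synthetic FGA/SE33 allele frequency table (uniform over
    common alleles; for exercising the machinery, not population-calibrated)."""
    text = resources.files("hfetype").joinpath("data/str_freqs_synthetic.csv").read_text()
    out: dict[str, dict[float, float]] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        locus, allele, freq = line.split(",")
        out.setdefault(locus, {})[float(allele)] = float(freq)
    return out


def _genotype_frequency(locus: str, alleles: Sequence[float],
                        freqs: dict[str, dict[float, float]]) -> float:
    if locus not in freqs:
        raise ValueError(f"locus {locus!r} missing from frequency table")
    table = freqs[locus]
    alleles = sorted(alleles)
    try:
        if len(alleles) == 1 or alleles[0] == alleles[-1]:
            p = table[alleles[0]]
            return p * p
        p, q = table[alleles[0]], table[alleles[1]]
        return 2 * p * q
    except KeyError as exc:
        raise ValueError(f"allele {exc.args[0]} of locus {locus!r} missing "
                         f"from frequency table") from exc


def match_samples(a: SampleReport, b: SampleReport,
                  freqs: dict[str, dict[float, float]]) -> IdentityResult:
    """Compare STR genotypes of two samples at their shared loci.

    ``match`` is true iff every shared-locus genotype is identical;
    ``match_probability`` is the probability that a random individual
    carries sample *a*'s multi-locus genotype under Hardy-Weinberg,
    multiplicative across loci.
    """
    a_loci = {c.locus_name: c for c in a.str_calls if c.alleles}
    b_loci = {c.locus_name: c for c in b.str_calls if c.alleles}
    shared = sorted(set(a_loci) & set(b_loci))
    if not shared:
        raise ValueError("no shared STR loci with called alleles")
    is_match = True
    probability = 1.0
    for locus in shared:
        ga = sorted(a_loci[locus].alleles)
        gb = sorted(b_loci[locus].alleles)
        if ga != gb:
            is_match = False
        probability *= _genotype_frequency(locus, ga, freqs)
    return IdentityResult(match=is_match, compared_loci=len(shared),
                          match_probability=probability)
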