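"""Rule-based interpretation of peak tables.

The calling pipeline runs in a fixed order: threshold filtering, FZD1
digestion-control validation, per-marker RFLP calls, STR allele calls.

Conventions (stated once, used everywhere):

* peak-size matching tolerance is ±1.0 bp (single-base CE resolution);
* the height cutoff is inclusive (height >= cutoff survives);
* a genotype call is only issued when the marker's enzyme passed the
  digestion control -- an uncut peak with a failed control is reported as
  ``no_call``/``control_fail``, never as a homozygote (the assay's
  anti-dropout guarantee);
* a stutter-position peak (one repeat unit below a taller peak) is excluded
  from allele status only while its height ratio to the taller peak stays
  below ``STUTTER_ALLELE_CEILING``; a comparable-height peak one repeat
  below is a genuine adjacent-allele heterozygote, not stutter;
* no heterozygote peak-balance requirement is imposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .panel import AssayPanel, RFLPMarker, STRLocus
from .peaks import Peak, PeakTable

#: ±bp window for matching a peak to an expected size.
SIZE_TOLERANCE_BP = 1.0
#: A stutter-position peak at or above this fraction of its parent's height
#: is treated as a true allele rather than stutter.
STUTTER_ALLELE_CEILING = 0.5

GENOTYPE_REF_HOM = "ref_hom"
GENOTYPE_HET = "het"
GENOTYPE_VAR_HOM = "var_hom"
GENOTYPE_NO_CALL = "no_call"

REASON_CONTROL_FAIL = "control_fail"
REASON_AMPLIFICATION_FAIL = "amplification_fail"
REASON_NO_PEAKS = "no_peaks"


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclass
class ControlStatus:
    amplification_ok: bool
    enzyme_status: dict[str, str]  # enzyme -> pass | fail | indeterminate
    evidence: list[Peak] = field(default_factory=list)

    def passed(self, enzyme_name: str) -> bool:
        return self.enzyme_status.get(enzyme_name) == "pass"


@dataclass
class MarkerCall:
    marker_name: str
    genotype: str
    supporting_peaks: list[Peak] = field(default_factory=list)
    reason: Optional[str] = None


@dataclass
class STRCall:
    locus_name: str
    alleles: list[float]
    peak_heights: list[float]
    extra_alleles: list[float] = field(default_factory=list)
    extra_heights: list[float] = field(default_factory=list)
    off_ladder: list[float] = field(default_factory=list)
    allele_peaks: list[Peak] = field(default_factory=list)  # called alleles, tallest first
    stutter_peaks: list[Peak] = field(default_factory=list)


@dataclass
class SampleReport:
    sample_id: str
    control: ControlStatus
    marker_calls: list[MarkerCall]
    str_calls: list[STRCall]
    contamination: Optional[object] = None

    def marker_call(self, name: str) -> MarkerCall:
        for c in self.marker_calls:
            if c.marker_name == name:
                return c
        raise KeyError(name)

    def str_call(self, name: str) -> STRCall:
        for c in self.str_calls:
            if c.locus_name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "control": {
                "amplification_ok": self.control.amplification_ok,
                "enzyme_status": dict(self.control.enzyme_status),
                "evidence": [[p.dye, p.size, p.height] for p in self.control.evidence],
            },
            "marker_calls": [
                {"marker": c.marker_name, "genotype": c.genotype, "reason": c.reason,
                 "peaks": [[p.dye, p.size, p.height] for p in c.supporting_peaks]}
                for c in self.marker_calls
            ],
            "str_calls": [
                {"locus": c.locus_name, "alleles": c.alleles,
                 "peak_heights": c.peak_heights, "extra_alleles": c.extra_alleles,
                 "off_ladder": c.off_ladder}
                for c in self.str_calls
            ],
            "contamination": (self.contamination.to_dict()
                              if hasattr(self.contamination, "to_dict") else None),
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def derive_cutoff(blank_tables: Sequence[PeakTable], multiplier: float) -> float:
    """Analytical cutoff = multiplier x (highest blank peak, rounded up to
    the nearest 10 RFU)."""
    if not blank_tables:
        raise ValueError("at least one blank table is required")
    heights = [p.height for t in blank_tables for p in t.peaks]
    if not heights:
        raise ValueError("blank tables contain no peaks")
    noise = math.ceil(max(heights) / 10.0) * 10.0
    return multiplier * noise


def filter_peaks(table: PeakTable, cutoff: float) -> PeakTable:
    """Retain exactly the peaks with height >= cutoff (input unmodified)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return PeakTable(
        sample_id=table.sample_id,
        peaks=[p for p in table.peaks if p.height >= cutoff],
        metadata=dict(table.metadata),
    )


def match_peak(peaks: Sequence[Peak], size: float,
               tolerance: float = SIZE_TOLERANCE_BP) -> Optional[Peak]:
    """The tallest peak within ±tolerance bp of an expected size, if any."""
    hits = [p for p in peaks if abs(p.size - size) <= tolerance]
    return max(hits, key=lambda p: p.height) if hits else None


def check_digestion_controls(table: PeakTable, panel: AssayPanel,
                             cutoff: float) -> ControlStatus:
    """Validate the FZD1 control channel.

    An enzyme passes iff its double-digest control size is present above the
    cutoff; it fails iff its single-failure size or the uncut size is present
    instead; with no control peak at all, amplification failed and both
    enzymes are indeterminate.
    """
    control = panel.control
    channel = [p for p in table.channel(control.dye) if p.height >= cutoff]
    amplification_ok = bool(channel)
    status: dict[str, str] = {}
    evidence: list[Peak] = []
    uncut = match_peak(channel, float(control.uncut_size))
    for enzyme, dd_size in zip(("SexAI", "BspHI"), control.expected_double_digest_sizes):
        if not amplification_ok:
            status[enzyme] = "indeterminate"
            continue
        dd_peak = match_peak(channel, float(dd_size))
        if dd_peak is not None:
            status[enzyme] = "pass"
            evidence.append(dd_peak)
            continue
        failure_size = control.expected_single_failure_sizes.get(enzyme)
        failure_peak = (match_peak(channel, float(failure_size))
                        if failure_size is not None else None)
        if failure_peak is not None or uncut is not None:
            status[enzyme] = "fail"
            evidence.append(failure_peak or uncut)
        else:
            status[enzyme] = "indeterminate"
    return ControlStatus(amplification_ok=amplification_ok, enzyme_status=status,
                         evidence=evidence)


def call_marker(table: PeakTable, marker: RFLPMarker, control: ControlStatus,
                cutoff: float, panel: AssayPanel) -> MarkerCall:
    """Call one RFLP marker from its cut/uncut peak pattern, gated on the
    digestion control of the marker's enzyme."""
    if not control.amplification_ok:
        return MarkerCall(marker.name, GENOTYPE_NO_CALL, reason=REASON_AMPLIFICATION_FAIL)
    if not control.passed(marker.enzyme_name):
        return MarkerCall(marker.name, GENOTYPE_NO_CALL, reason=REASON_CONTROL_FAIL)
    sizes = panel.marker_sizes(marker.name)
    channel = [p for p in table.channel(marker.dye) if p.height >= cutoff]
    cut_peak = match_peak(channel, sizes["cut"])
    uncut_peak = match_peak(channel, sizes["uncut"])
    supporting = [p for p in (cut_peak, uncut_peak) if p is not None]
    if cut_peak is not None and uncut_peak is not None:
        genotype = GENOTYPE_HET
    elif cut_peak is not None:
        genotype = GENOTYPE_VAR_HOM if marker.variant_creates_site else GENOTYPE_REF_HOM
    elif uncut_peak is not None:
        genotype = GENOTYPE_REF_HOM if marker.variant_creates_site else GENOTYPE_VAR_HOM
    else:
        return MarkerCall(marker.name, GENOTYPE_NO_CALL, reason=REASON_NO_PEAKS)
    return MarkerCall(marker.name, genotype, supporting_peaks=supporting)


def classify_str_peaks(table: PeakTable, locus: STRLocus,
                       cutoff: float) -> tuple[list[Peak], list[Peak]]:
    """Split a locus channel into allele-status and stutter-status peaks.

    A peak is stutter iff a peak one repeat unit above it (±1 bp) is at
    least ``1/STUTTER_ALLELE_CEILING`` times taller.
    """
    channel = [p for p in table.channel(locus.dye) if p.height >= cutoff]
    unit = locus.repeat_unit_length
    alleles, stutters = [], []
    for p in channel:
        parent = match_peak(channel, p.size + unit)
        if parent is not None and p.height < STUTTER_ALLELE_CEILING * parent.height:
            stutters.append(p)
        else:
            alleles.append(p)
    return alleles, stutters


def call_str(table: PeakTable, locus: STRLocus, cutoff: float) -> STRCall:
    """Convert the locus channel into allele designations.

    The two tallest non-stutter designations are the call (one designation
    for a homozygote); further surviving designations are reported as
    ``extra_alleles``; designations outside the locus range are recorded as
    off-ladder, never raised.
    """
    allele_peaks, stutter_peaks = classify_str_peaks(table, locus, cutoff)
    in_range: list[tuple[Peak, float]] = []
    off_ladder: list[float] = []
    for p in allele_peaks:
        d = locus.designation_of(p.size)
        if locus.contains(d):
            in_range.append((p, d))
        else:
            off_ladder.append(d)
    in_range.sort(key=lambda item: -item[0].height)
    # collapse duplicate designations (jitter cannot split one, but raw user
    # tables may carry repeats)
    seen: dict[float, Peak] = {}
    ordered: list[tuple[Peak, float]] = []
    for p, d in in_range:
        if d not in seen:
            seen[d] = p
            ordered.append((p, d))
    called = ordered[:2]
    extras = ordered[2:]
    return STRCall(
        locus_name=locus.name,
        alleles=[d for _, d in called],
        peak_heights=[p.height for p, _ in called],
        extra_alleles=[d for _, d in extras],
        extra_heights=[p.height for p, _ in extras],
        off_ladder=off_ladder,
        allele_peaks=[p for p, _ in called],
        stutter_peaks=stutter_peaks,
    )


def genotype_sample(table: PeakTable, panel: AssayPanel,
                    cutoff: Optional[float] = None) -> SampleReport:
    """Full deterministic interpretation: filter, controls, markers, STRs."""
    if cutoff is None:
        cutoff = panel.thresholds.analytical_cutoff
    filtered = filter_peaks(table, cutoff)
    control = check_digestion_controls(filtered, panel, cutoff)
    marker_calls = [call_marker(filtered, m, control, cutoff, panel)
                    for m in panel.rflp_markers]
    str_calls = [call_str(filtered, locus, cutoff) for locus in panel.str_loci]
    return SampleReport(sample_id=table.sample_id, control=control,
                        marker_calls=marker_calls, str_calls=str_calls)
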