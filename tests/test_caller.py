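"""Genotype caller: cutoff derivation, filtering, control gating, RFLP rule
table, STR designation mapping, end-to-end cohort recovery."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hfetype as h
from hfetype.caller import (GENOTYPE_HET, GENOTYPE_NO_CALL, GENOTYPE_REF_HOM,
                            GENOTYPE_VAR_HOM, REASON_AMPLIFICATION_FAIL,
                            REASON_CONTROL_FAIL, call_marker, call_str,
                            check_digestion_controls, derive_cutoff,
                            filter_peaks, genotype_sample)
from hfetype.peaks import Peak, PeakTable


def _table(peaks, sample_id="t"):
    return PeakTable(sample_id=sample_id, peaks=peaks)


def _control_peaks(heights=(2000.0, 2000.0)):
    return [Peak("ATTO 550", 114.0, heights[0]), Peak("ATTO 550", 147.0, heights[1])]


# ---------------------------------------------------------------------------
# cutoff derivation and filtering
# ---------------------------------------------------------------------------

def test_derive_cutoff_published_rule():
    blanks = [_table([Peak("FAM", 100.0, 50.0)])]
    assert derive_cutoff(blanks, 5.0) == 250.0


def test_derive_cutoff_rounds_noise_up_to_ten():
    blanks = [_table([Peak("FAM", 100.0, 43.2)])]
    assert derive_cutoff(blanks, 5.0) == 250.0


def test_derive_cutoff_requires_peaks():
    with pytest.raises(ValueError):
        derive_cutoff([], 5.0)
    with pytest.raises(ValueError):
        derive_cutoff([_table([])], 5.0)


def test_filter_boundary_is_inclusive():
    table = _table([Peak("FAM", 100.0, 249.0), Peak("FAM", 110.0, 250.0),
                    Peak("FAM", 120.0, 251.0)])
    kept = filter_peaks(table, 250.0)
    assert [p.height for p in kept.peaks] == [250.0, 251.0]
    assert len(table.peaks) == 3  # input unmodified


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1.0, max_value=40000.0), max_size=30),
       st.floats(min_value=1.0, max_value=500.0),
       st.floats(min_value=1.0, max_value=500.0))
def test_raising_cutoff_never_retains_more(heights, c1, c2):
    table = _table([Peak("FAM", 60.0 + i, x) for i, x in enumerate(heights)])
    lo, hi = sorted((c1, c2))
    assert len(filter_peaks(table, hi).peaks) <= len(filter_peaks(table, lo).peaks)


# ---------------------------------------------------------------------------
# digestion controls
# ---------------------------------------------------------------------------

def test_controls_pass_on_double_digest_pattern(panel):
    status = check_digestion_controls(_table(_control_peaks()), panel, 250.0)
    assert status.amplification_ok
    assert status.enzyme_status == {"SexAI": "pass", "BspHI": "pass"}


def test_sexai_failure_pattern(panel):
    peaks = [Peak("ATTO 550", 147.0, 2000.0), Peak("ATTO 550", 171.0, 2000.0)]
    status = check_digestion_controls(_table(peaks), panel, 250.0)
    assert status.enzyme_status == {"SexAI": "fail", "BspHI": "pass"}


def test_uncut_control_fails_both(panel):
    peaks = [Peak("ATTO 550", 309.0, 2500.0)]
    status = check_digestion_controls(_table(peaks), panel, 250.0)
    assert status.enzyme_status == {"SexAI": "fail", "BspHI": "fail"}


def test_empty_control_channel_is_amplification_failure(panel):
    status = check_digestion_controls(_table([Peak("FAM", 200.0, 5000.0)]), panel, 250.0)
    assert not status.amplification_ok
    assert status.enzyme_status == {"SexAI": "indeterminate", "BspHI": "indeterminate"}


# ---------------------------------------------------------------------------
# marker calls
# ---------------------------------------------------------------------------

def _marker_case(panel, sizes_present):
    peaks = _control_peaks()
    m = panel.marker_sizes("C282Y")
    peaks += [Peak("ATTO 565", m[k], 4000.0) for k in sizes_present]
    table = _table(peaks)
    control = check_digestion_controls(table, panel, 250.0)
    return call_marker(table, panel.marker("C282Y"), control, 250.0, panel)


def test_marker_rule_table(panel):
    assert _marker_case(panel, ["cut", "uncut"]).genotype == GENOTYPE_HET
    assert _marker_case(panel, ["cut"]).genotype == GENOTYPE_VAR_HOM
    assert _marker_case(panel, ["uncut"]).genotype == GENOTYPE_REF_HOM
    no_peaks = _marker_case(panel, [])
    assert no_peaks.genotype == GENOTYPE_NO_CALL and no_peaks.reason == "no_peaks"


def test_marker_polarity_follows_variant_creates_site(panel):
    flipped = panel.marker("C282Y").model_copy(update={"variant_creates_site": False})
    peaks = _control_peaks() + [Peak("ATTO 565", panel.marker_sizes("C282Y")["cut"], 4000.0)]
    table = _table(peaks)
    control = check_digestion_controls(table, panel, 250.0)
    assert call_marker(table, flipped, control, 250.0, panel).genotype == GENOTYPE_REF_HOM


def test_uncut_peak_with_failed_control_is_no_call(panel):
    """The anti-dropout guarantee: an undigested pattern with a failed
    digestion control is never reported as a homozygote."""
    peaks = [Peak("ATTO 550", 114.0, 2000.0), Peak("ATTO 550", 204.0, 2000.0),
             Peak("ATTO 565", panel.marker_sizes("H63D")["uncut"], 4000.0)]
    table = _table(peaks)
    control = check_digestion_controls(table, panel, 250.0)
    call = call_marker(table, panel.marker("H63D"), control, 250.0, panel)
    assert call.genotype == GENOTYPE_NO_CALL and call.reason == REASON_CONTROL_FAIL
    # SexAI marker unaffected
    c282y = call_marker(table, panel.marker("C282Y"), control, 250.0, panel)
    assert c282y.reason != REASON_CONTROL_FAIL


# ---------------------------------------------------------------------------
# STR calls
# ---------------------------------------------------------------------------

def test_str_single_peak_is_homozygote(panel):
    fga = panel.locus("FGA")
    table = _table([Peak("FAM", fga.size_of(24.0), 8000.0)])
    call = call_str(table, fga, 250.0)
    assert call.alleles == [24.0]


def test_str_microvariant_designation(panel):
    fga = panel.locus("FGA")
    table = _table([Peak("FAM", fga.size_offset + 96, 8000.0),
                    Peak("FAM", fga.size_offset + 106, 7000.0)])
    call = call_str(table, fga, 250.0)
    assert sorted(call.alleles) == [24.0, 26.2]


def test_str_stutter_excluded_from_allele_status(panel):
    fga = panel.locus("FGA")
    table = _table([Peak("FAM", fga.size_of(24.0), 8000.0),
                    Peak("FAM", fga.size_of(23.0), 640.0)])  # 8% stutter
    call = call_str(table, fga, 250.0)
    assert call.alleles == [24.0]
    assert [p.size for p in call.stutter_peaks] == [fga.size_of(23.0)]


def test_str_adjacent_balanced_alleles_both_called(panel):
    """A genuine heterozygote with alleles one repeat apart is not mistaken
    for allele+stutter."""
    fga = panel.locus("FGA")
    table = _table([Peak("FAM", fga.size_of(24.0), 8000.0),
                    Peak("FAM", fga.size_of(23.0), 7200.0)])
    call = call_str(table, fga, 250.0)
    assert sorted(call.alleles) == [23.0, 24.0]


def test_str_three_peaks_two_tallest_called_one_extra(panel):
    fga = panel.locus("FGA")
    table = _table([Peak("FAM", fga.size_of(20.0), 8000.0),
                    Peak("FAM", fga.size_of(24.0), 7000.0),
                    Peak("FAM", fga.size_of(30.0), 3000.0)])
    call = call_str(table, fga, 250.0)
    assert sorted(call.alleles) == [20.0, 24.0]
    assert call.extra_alleles == [30.0]


def test_str_off_ladder_recorded_not_raised(panel):
    fga = panel.locus("FGA")
    table = _table([Peak("FAM", fga.size_of(24.0), 8000.0),
                    Peak("FAM", fga.size_offset + 240, 5000.0)])  # allele 60
    call = call_str(table, fga, 250.0)
    assert call.alleles == [24.0]
    assert call.off_ladder == [60.0]


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def test_simulated_compound_sample_recovered(panel):
    g = h.make_genotype(2, 1, str_alleles={"FGA": (20.0, 24.0), "SE33": (17.0, 25.0)})
    report = genotype_sample(h.simulate_sample(panel, g, 99), panel)
    assert report.marker_call("C282Y").genotype == GENOTYPE_VAR_HOM
    assert report.marker_call("H63D").genotype == GENOTYPE_HET
    assert sorted(report.str_call("FGA").alleles) == [20.0, 24.0]
    assert sorted(report.str_call("SE33").alleles) == [17.0, 25.0]


def test_blank_table_yields_no_calls(panel):
    report = genotype_sample(h.simulate_blank(panel, 4), panel)
    assert not report.control.amplification_ok
    for call in report.marker_calls:
        assert call.genotype == GENOTYPE_NO_CALL
        assert call.reason == REASON_AMPLIFICATION_FAIL
    for call in report.str_calls:
        assert call.alleles == []


_CLASS_TO_GENOTYPE = {"-/-": GENOTYPE_REF_HOM, "+/-": GENOTYPE_HET, "+/+": GENOTYPE_VAR_HOM}


def _expected_calls(label):
    c282y, h63d, _ = label.split()
    return _CLASS_TO_GENOTYPE[c282y[5:]], _CLASS_TO_GENOTYPE[h63d[4:]]


def test_cohort_recovery_all_sixty(panel):
    """Every marker call over the 60-sample cohort matches its generating
    class, including 6 C282Y variant homozygotes."""
    tables = h.simulate_hfe60(panel, seed=7)
    counts = {}
    for table in tables:
        report = genotype_sample(table, panel)
        want_c, want_h = _expected_calls(table.metadata["class_label"])
        assert report.marker_call("C282Y").genotype == want_c
        assert report.marker_call("H63D").genotype == want_h
        counts[table.metadata["class_label"]] = counts.get(table.metadata["class_label"], 0) + 1
    assert sorted(counts.values(), reverse=True) == [18, 11, 9, 8, 6, 5, 2, 1]


def test_s65c_status_never_changes_h63d_call(panel):
    """Toggling S65C leaves every H63D call unchanged (the variant does not
    interfere with BspHI cleavage)."""
    for h63d in (0, 1, 2):
        base = h.make_genotype(0, h63d,
                               str_alleles={"FGA": (20.0, 24.0), "SE33": (17.0, 25.0)})
        calls = set()
        for status in ("ref_hom", "het", "var_hom"):
            g = replace(base, s65c_status=status)
            report = genotype_sample(h.simulate_sample(panel, g, 55), panel)
            calls.add(report.marker_call("H63D").genotype)
        assert len(calls) == 1


@pytest.mark.parametrize("failed_enzyme,affected", [("SexAI", "C282Y"), ("BspHI", "H63D")])
def test_digestion_failure_gates_only_that_enzymes_markers(panel, failed_enzyme, affected):
    """With a whole-enzyme digestion failure, every marker using that enzyme
    is a no_call (never a wrong homozygote); the other marker still calls."""
    for c282y, h63d in ((0, 0), (1, 1), (2, 2), (2, 0)):
        g = h.make_genotype(c282y, h63d,
                            str_alleles={"FGA": (20.0, 24.0), "SE33": (17.0, 25.0)},
                            digestion_failure=failed_enzyme)
        for seed in (1, 2, 3):
            report = genotype_sample(h.simulate_sample(panel, g, seed), panel)
            gated = report.marker_call(affected)
            assert gated.genotype == GENOTYPE_NO_CALL
            assert gated.reason == REASON_CONTROL_FAIL
            other = next(c for c in report.marker_calls if c.marker_name != affected)
            assert other.genotype != GENOTYPE_NO_CALL


def test_raising_cutoff_moves_calls_toward_no_call(panel):
    """With control peaks below allele peaks (the assay's design), scanning
    the cutoff upward only ever degrades a call to no_call; it never flips
    het to a homozygote."""
    m = panel.marker_sizes("C282Y")
    table = _table([Peak("ATTO 550", 114.0, 1000.0), Peak("ATTO 550", 147.0, 1100.0),
                    Peak("ATTO 565", m["cut"], 3000.0), Peak("ATTO 565", m["uncut"], 3500.0)])
    seen = []
    for cutoff in (100.0, 500.0, 999.0, 1050.0, 1500.0, 3200.0, 4000.0):
        control = check_digestion_controls(filter_peaks(table, cutoff), panel, cutoff)
        call = call_marker(filter_peaks(table, cutoff), panel.marker("C282Y"),
                           control, cutoff, panel)
        seen.append(call.genotype)
    assert seen[0] == GENOTYPE_HET
    first_no_call = seen.index(GENOTYPE_NO_CALL)
    assert all(g == GENOTYPE_HET for g in seen[:first_no_call])
    assert all(g == GENOTYPE_NO_CALL for g in seen[first_no_call:])
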