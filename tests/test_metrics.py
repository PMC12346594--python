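"""Chromatographic metrics, screening aggregation, and EEO-reversal taxonomy."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from enantiosep.dataio import EEO, ValidationError
from enantiosep.metrics import (
    PeakPair,
    detect_eeo_reversals,
    directed_resolution,
    extraction_rate,
    resolution_from_peaks,
    retention_factor,
    screening_summary,
    selectivity,
)


class TestRetentionFactor:
    def test_unit_case(self):
        assert retention_factor(2.0, 1.0) == 1.0

    def test_unretained_peak(self):
        assert retention_factor(1.0, 1.0) == 0.0

    def test_peak_before_dead_time_rejected(self):
        with pytest.raises(ValueError, match="precedes dead time"):
            retention_factor(0.5, 1.0)


class TestSelectivity:
    def test_table_values(self):
        assert selectivity(1.77, 5.88) == pytest.approx(5.88 / 1.77)
        assert selectivity(0.88, 0.88) == 1.0
        assert selectivity(1.0, 1.0) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            selectivity(0.0, 1.0)
        with pytest.raises(ValidationError):
            selectivity(2.0, 1.0)


class TestResolutionFromPeaks:
    def test_arithmetic_case(self):
        assert resolution_from_peaks(PeakPair(4, 6, 1, 1, 1)) == 2.0

    def test_coelution_gives_zero(self):
        assert resolution_from_peaks(PeakPair(5, 5, 0.7, 1.3, 1)) == 0.0

    def test_plate_model_widths_match_formula(self):
        # widths from w = 4 tR / sqrt(N) reproduce Rs analytically
        N, t0, k1, k2 = 5000.0, 1.0, 1.0, 2.0
        t1, t2 = t0 * (1 + k1), t0 * (1 + k2)
        w1, w2 = 4 * t1 / math.sqrt(N), 4 * t2 / math.sqrt(N)
        rs = resolution_from_peaks(PeakPair(t1, t2, w1, w2, t0))
        expected = 2 * (t2 - t1) / (w1 + w2)
        assert rs == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            PeakPair(4, 6, 0.0, 1, 1)

    @given(
        gap=st.floats(0, 10, allow_nan=False),
        scale=st.floats(0.1, 5, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scales_linearly_with_peak_gap_at_fixed_widths(self, gap, scale):
        base = resolution_from_peaks(PeakPair(2, 2 + gap, 1, 1, 1))
        scaled = resolution_from_peaks(PeakPair(2, 2 + gap * scale, 1, 1, 1))
        assert scaled == pytest.approx(base * scale, abs=1e-9)
        assert base >= 0


class TestDirectedResolution:
    @pytest.mark.parametrize(
        "rs,eeo,expected",
        [
            (7.02, EEO.S_FIRST, -7.02),
            (2.83, EEO.R_FIRST, +2.83),
            (None, EEO.COELUTION, 0.0),
        ],
    )
    def test_sign_rule(self, rs, eeo, expected):
        assert directed_resolution(rs, eeo) == expected

    def test_unknown_eeo_with_resolution_is_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            directed_resolution(1.0, EEO.UNKNOWN)

    @given(rs=st.floats(0, 20, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_odd_under_eeo_swap(self, rs):
        plus = directed_resolution(rs, EEO.R_FIRST)
        minus = directed_resolution(rs, EEO.S_FIRST)
        assert plus == -minus and abs(plus) == rs


def test_extraction_rate_is_mass_over_half_injected():
    assert extraction_rate(13.2, 30.0) == pytest.approx(88.0)
    assert extraction_rate(7.4, 20.0) == pytest.approx(74.0)


class TestScreeningSummary:
    def test_counts_and_success_rate(self, table1):
        s = screening_summary(table1)
        assert s.n_total == 84
        assert s.n_separated == 59
        assert s.success_rate == pytest.approx(100 * 59 / 84)
        assert s.success_rate * s.n_total / 100 == pytest.approx(s.n_separated)

    def test_baseline_count_matches_brute_force(self, table1):
        s = screening_summary(table1, baseline_threshold=1.5)
        brute = sum(1 for r in table1 if r.rs is not None and r.rs > 1.5)
        assert s.n_baseline == brute == 38
        assert 0 <= s.n_baseline <= s.n_separated <= s.n_total

    def test_max_rs_reports_argmax_system(self, table1):
        s = screening_summary(table1)
        assert s.max_rs_by_analyte["omeprazole"] == (9.91, "AD", "MeOH")
        assert s.max_rs_by_analyte["rabeprazole"] == (6.16, "Cell4", "MeOH")
        assert s.max_rs_by_analyte["lansoprazole"] == (3.26, "Cell4", "MeOH")

    def test_sum_rs_treats_unresolved_as_zero(self, table1):
        s = screening_summary(table1)
        # OJ never resolved anything: its sums are exactly zero
        for eluent in ("MeOH", "EtOH", "1-PrOH", "2-PrOH"):
            assert s.sum_rs_by_csp_eluent[("OJ", eluent)] == 0.0

    def test_invariant_to_row_order(self, table1):
        from enantiosep.dataio import ScreeningTable

        reversed_table = ScreeningTable(list(reversed(table1.records)))
        a, b = screening_summary(table1), screening_summary(reversed_table)
        assert (a.n_separated, a.n_baseline, a.max_rs_by_analyte) == (
            b.n_separated, b.n_baseline, b.max_rs_by_analyte
        )

    def test_empty_table_rejected(self):
        from enantiosep.dataio import ScreeningTable

        with pytest.raises(ValueError):
            screening_summary(ScreeningTable([]))


class TestEEOReversals:
    def test_backbone_reversal_rabeprazole_etoh(self, table1):
        report = detect_eeo_reversals(table1, "backbone")
        hits = [
            e for e in report.events
            if e.analyte == "rabeprazole"
            and e.condition_a[1] == "EtOH"
            and {e.condition_a[0], e.condition_b[0]} == {"AD", "OD"}
        ]
        assert len(hits) == 1
        # and AD/OD disagree for rabeprazole only in EtOH
        ad_od = [
            e for e in report.events
            if e.analyte == "rabeprazole"
            and {e.condition_a[0], e.condition_b[0]} == {"AD", "OD"}
        ]
        assert [e.condition_a[1] for e in ad_od] == ["EtOH"]

    def test_backbone_omeprazole_2proh_not_assessable(self, table1):
        # OD/2-PrOH co-elutes omeprazole, so the AD/OD contrast there
        # cannot be scored as a reversal
        report = detect_eeo_reversals(table1, "backbone")
        na = [
            e for e in report.not_assessable
            if e["analyte"] == "omeprazole"
            and e["condition_a"][1] == "2-PrOH"
        ]
        assert na
        assert not any(
            ev.analyte == "omeprazole" and ev.condition_a[1] == "2-PrOH"
            for ev in report.events
        )

    def test_meoh_etoh_exchange_reverses_all_analytes_on_AS(self, table1):
        report = detect_eeo_reversals(table1, "mobile_phase")
        as_meoh_etoh = [
            e for e in report.events
            if e.condition_a[0] == "AS"
            and {e.condition_a[1], e.condition_b[1]} == {"MeOH", "EtOH"}
        ]
        assert sorted(e.analyte for e in as_meoh_etoh) == [
            "lansoprazole", "omeprazole", "rabeprazole",
        ]

    def test_no_mobile_phase_reversals_on_cellulose_csps(self, table1):
        from enantiosep.dataio import ScreeningTable, Backbone

        cellulose = ScreeningTable(
            [r for r in table1 if r.system.backbone is Backbone.CELLULOSE]
        )
        report = detect_eeo_reversals(cellulose, "mobile_phase")
        assert report.events == []

    def test_axis_without_contrasts_warns(self, table1):
        from enantiosep.dataio import ScreeningTable

        only_ad = ScreeningTable([r for r in table1 if r.system.csp_id == "AD"])
        report = detect_eeo_reversals(only_ad, "backbone")
        assert report.events == [] and report.warning is not None

    def test_agrees_with_brute_force_scan_on_synthetic_tables(self):
        from enantiosep.synthgen import SynthConfig, gen_screening_table

        for seed in (11, 12, 13):
            table, _ = gen_screening_table(
                SynthConfig(seed=seed, missing_rate=0.25, sigma_lnk=0.05)
            )
            by_key = {r.key: r for r in table}
            systems = {r.system.csp_id: r.system for r in table}
            for axis in ("backbone", "substituent", "mobile_phase"):
                report = detect_eeo_reversals(table, axis)
                expected = set()
                for a, b in itertools.combinations(by_key.values(), 2):
                    ca, ea, na = a.key
                    cb, eb, nb = b.key
                    if na != nb:
                        continue
                    sa, sb = systems[ca], systems[cb]
                    if axis == "mobile_phase":
                        ok = ca == cb and ea != eb
                    elif axis == "backbone":
                        ok = (
                            ea == eb
                            and sa.backbone is not sb.backbone
                            and sa.selector_substituent == sb.selector_substituent
                        )
                    else:
                        ok = (
                            ea == eb
                            and sa.backbone is sb.backbone
                            and sa.selector_substituent != sb.selector_substituent
                        )
                    if not ok:
                        continue
                    if EEO.COELUTION in (a.eeo, b.eeo):
                        continue
                    if a.eeo is not b.eeo:
                        expected.add(frozenset((a.key, b.key)))
                got = {
                    frozenset((
                        (e.condition_a[0], e.condition_a[1], e.analyte),
                        (e.condition_b[0], e.condition_b[1], e.analyte),
                    ))
                    for e in report.events
                }
                assert got == expected
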