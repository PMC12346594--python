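"""Hystereticity, ratio orientation, and case-A/case-B outcome inference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enantiosep.dataio import EEO
from enantiosep.hysteresis import (
    ForwardCase,
    HysteresisLoop,
    ReverseOutcome,
    classify_forward_case,
    detect_hysteresis,
    hystereticity,
    hystereticity_profile,
    hystereticity_ratio,
    infer_loop,
    infer_reverse_outcomes,
    realized_reverse_outcome,
)
from enantiosep.synthgen import SynthConfig, gen_hysteresis_loop


class TestHystereticity:
    def test_arithmetic(self):
        assert hystereticity(2.0, 1.0) == 2.0
        assert hystereticity(1.5, 1.5) == 1.0

    def test_zero_reverse_rejected_zero_forward_warns(self):
        with pytest.raises(ValueError):
            hystereticity(1.0, 0.0)
        with pytest.warns(UserWarning):
            assert hystereticity(0.0, 1.0) == 0.0

    @given(
        kf=st.floats(0.01, 10, allow_nan=False),
        kr=st.floats(0.01, 10, allow_nan=False),
        c=st.floats(0.01, 100, allow_nan=False),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_scale_invariance(self, kf, kr, c):
        assert hystereticity(c * kf, c * kr) == pytest.approx(
            hystereticity(kf, kr), rel=1e-12
        )

    def test_generator_offset_gives_exp_delta(self):
        loop, truth = gen_hysteresis_loop(
            SynthConfig(seed=5, hysteresis_amplitude=0.4)
        )
        prof = hystereticity_profile(loop).table.set_index("pct_meoh")
        for x, v in truth["true_hystereticity"].items():
            assert prof.loc[x, "v_R"] == pytest.approx(v["v_R"], abs=1e-9)
            assert prof.loc[x, "v_S"] == pytest.approx(v["v_S"], abs=1e-9)
        assert prof.loc[50.0, "v_R"] == pytest.approx(math.exp(0.1), abs=1e-9)


class TestHystereticityRatio:
    def test_symmetric_case(self):
        ratio, oriented = hystereticity_ratio(2.0, 3.0, 1.0, 1.5, EEO.R_FIRST)
        assert ratio == pytest.approx(2.0 / (3.0 / 1.5))
        assert oriented == ratio

    def test_s_first_uses_reciprocal(self):
        ratio, oriented = hystereticity_ratio(2.0, 1.0, 1.0, 1.0, EEO.S_FIRST)
        assert ratio == 2.0 and oriented == 0.5

    @given(
        kRf=st.floats(0.01, 10), kSf=st.floats(0.01, 10),
        kRr=st.floats(0.01, 10), kSr=st.floats(0.01, 10),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_algebraic_identity(self, kRf, kSf, kRr, kSr):
        # v_R/v_S = (k_Rf k_Sr)/(k_Rr k_Sf), and in R-first orientation
        # equals alpha_rev/alpha_fwd
        ratio, _ = hystereticity_ratio(kRf, kSf, kRr, kSr, EEO.R_FIRST)
        assert ratio == pytest.approx((kRf * kSr) / (kRr * kSf), rel=1e-12)
        alpha_fwd, alpha_rev = kSf / kRf, kSr / kRr
        assert ratio == pytest.approx(alpha_rev / alpha_fwd, rel=1e-9)


class TestClassifyForwardCase:
    @pytest.mark.parametrize(
        "kR,kS,expected_case,expected_eeo",
        [
            (1.77, 5.88, ForwardCase.A_SEPARATED, EEO.R_FIRST),
            (5.88, 1.77, ForwardCase.A_SEPARATED, EEO.S_FIRST),
            (0.88, 0.88, ForwardCase.B_COELUTION, EEO.COELUTION),
            (1.000, 1.0005, ForwardCase.B_COELUTION, EEO.COELUTION),
        ],
    )
    def test_cases(self, kR, kS, expected_case, expected_eeo):
        case, eeo = classify_forward_case(kR, kS, tol=1e-3)
        assert case is expected_case and eeo is expected_eeo


class TestInferReverseOutcomes:
    def test_case_a_three_ratio_classes(self):
        eq, _ = infer_reverse_outcomes(ForwardCase.A_SEPARATED, 1.0)
        gt, _ = infer_reverse_outcomes(ForwardCase.A_SEPARATED, 1.5)
        lt, _ = infer_reverse_outcomes(ForwardCase.A_SEPARATED, 0.7)
        assert eq == {ReverseOutcome.SELECTIVITY_EQUAL}
        assert gt == {ReverseOutcome.SELECTIVITY_INCREASED}
        assert lt == {
            ReverseOutcome.SELECTIVITY_DECREASED_EEO_PRESERVED,
            ReverseOutcome.COELUTION,
            ReverseOutcome.EEO_REVERSED,
        }

    def test_case_b_ratio_classes_are_a_bijection(self):
        eq, _ = infer_reverse_outcomes(ForwardCase.B_COELUTION, 1.0)
        gt, _ = infer_reverse_outcomes(ForwardCase.B_COELUTION, 2.0)
        lt, _ = infer_reverse_outcomes(ForwardCase.B_COELUTION, 0.5)
        assert eq == {ReverseOutcome.COELUTION}
        assert gt == {ReverseOutcome.EEO_A_FIRST}
        assert lt == {ReverseOutcome.EEO_B_FIRST}

    def test_missing_ratio_gives_empty_set_with_reason(self):
        outcomes, reason = infer_reverse_outcomes(ForwardCase.A_SEPARATED, None)
        assert outcomes == frozenset() and reason

    def test_counterexample_ratio_below_one_with_preserved_order(self):
        # k_Af=1, k_Bf=2, k_Ar=1, k_Br=1.5: ratio = 0.75 < 1 yet the
        # reverse branch keeps A first with merely reduced selectivity —
        # hence the three-member outcome set for case A / ratio < 1
        k_Af, k_Bf, k_Ar, k_Br = 1.0, 2.0, 1.0, 1.5
        ratio = (k_Af / k_Ar) / (k_Bf / k_Br)
        assert ratio == pytest.approx(0.75)
        outcomes, _ = infer_reverse_outcomes(ForwardCase.A_SEPARATED, ratio)
        realized = realized_reverse_outcome(
            ForwardCase.A_SEPARATED, k_Af, k_Bf, k_Ar, k_Br
        )
        assert realized is ReverseOutcome.SELECTIVITY_DECREASED_EEO_PRESERVED
        assert realized in outcomes

    def test_realized_outcome_always_in_inferred_set(self):
        # the core soundness property, on 10,000 random quadruples with
        # exact (zero-tolerance) classification
        rng = np.random.default_rng(123)
        quads = rng.uniform(0.05, 10.0, size=(10_000, 4))
        # make a fifth of them exact forward coelutions to exercise case B
        coel = rng.uniform(size=len(quads)) < 0.2
        quads[coel, 1] = quads[coel, 0]
        for kRf, kSf, kRr, kSr in quads:
            case, forward_eeo = classify_forward_case(kRf, kSf, tol=0.0)
            _, oriented = hystereticity_ratio(kRf, kSf, kRr, kSr, forward_eeo)
            outcomes, _ = infer_reverse_outcomes(case, oriented, tol=0.0)
            if forward_eeo is EEO.S_FIRST:
                args = (kSf, kRf, kSr, kRr)
            else:
                args = (kRf, kSf, kRr, kSr)
            realized = realized_reverse_outcome(case, *args, tol=0.0)
            assert realized in outcomes, (case, oriented, realized, (kRf, kSf, kRr, kSr))


class TestWorkedRatioCases:
    """The three narrated loop compositions, rebuilt from their descriptions."""

    def test_rabeprazole_ad_30pct_meoh_eeo_reversal(self):
        # forward S-first, v_R/v_S > 1 (oriented reciprocal < 1);
        # reverse branch flips the order to R-first
        kRf, kSf = 2.0, 1.5  # S first in forward
        kRr, kSr = 1.1, 1.4  # R first in reverse: EEO reversed
        case, eeo = classify_forward_case(kRf, kSf, tol=1e-3)
        assert case is ForwardCase.A_SEPARATED and eeo is EEO.S_FIRST
        ratio, oriented = hystereticity_ratio(kRf, kSf, kRr, kSr, eeo)
        assert ratio > 1 and oriented < 1
        outcomes, _ = infer_reverse_outcomes(case, oriented)
        realized = realized_reverse_outcome(case, kSf, kRf, kSr, kRr, tol=1e-3)
        assert realized is ReverseOutcome.EEO_REVERSED
        assert realized in outcomes

    def test_omeprazole_as_70pct_meoh_reverse_coelution(self):
        # forward S-first with v_R/v_S > 1; reverse branch co-elutes
        kRf, kSf = 1.8, 1.2
        kRr, kSr = 1.0, 1.0
        case, eeo = classify_forward_case(kRf, kSf, tol=1e-3)
        assert eeo is EEO.S_FIRST
        ratio, oriented = hystereticity_ratio(kRf, kSf, kRr, kSr, eeo)
        assert ratio > 1 and oriented < 1
        outcomes, _ = infer_reverse_outcomes(case, oriented)
        realized = realized_reverse_outcome(case, kSf, kRf, kSr, kRr, tol=1e-3)
        assert realized is ReverseOutcome.COELUTION
        assert realized in outcomes

    def test_omeprazole_ia_60pct_meoh_forward_coelution(self):
        # forward co-elutes; reverse branch elutes S first, which forces
        # the hystereticity ratio below 1
        kRf = kSf = 1.5
        kRr, kSr = 1.3, 1.1  # S first in reverse
        case, eeo = classify_forward_case(kRf, kSf, tol=1e-3)
        assert case is ForwardCase.B_COELUTION
        ratio, oriented = hystereticity_ratio(kRf, kSf, kRr, kSr, eeo)
        assert ratio < 1
        outcomes, _ = infer_reverse_outcomes(case, oriented)
        # A = R in case B, so S-first is "EEO_B_first"
        assert outcomes == {ReverseOutcome.EEO_B_FIRST}
        realized = realized_reverse_outcome(case, kRf, kSf, kRr, kSr, tol=1e-3)
        assert realized in outcomes


class TestLoops:
    def test_zero_divergence_loop_has_unit_hystereticity(self):
        loop, _ = gen_hysteresis_loop(SynthConfig(seed=1, hysteresis_amplitude=0.0))
        present, flags = detect_hysteresis(loop, threshold=0.05)
        assert not present
        prof = hystereticity_profile(loop).table
        assert np.allclose(prof["v_R"], 1.0) and np.allclose(prof["v_S"], 1.0)

    def test_threshold_sensitivity(self):
        # ln-k bump of 0.4 peaks at delta = 0.1: |v-1| ~ 0.105 at x = 50
        loop, _ = gen_hysteresis_loop(SynthConfig(seed=1, hysteresis_amplitude=0.4))
        assert detect_hysteresis(loop, threshold=0.05)[0]
        assert not detect_hysteresis(loop, threshold=0.2)[0]

    def test_single_composition_loop_rejected(self):
        df = pd.DataFrame(
            {"pct_meoh": [100.0, 100.0], "direction": ["forward", "reverse"],
             "k_R": [1.0, 1.0], "k_S": [1.2, 1.2]}
        )
        with pytest.raises(ValueError, match="composition"):
            detect_hysteresis(HysteresisLoop(data=df))

    def test_loop_endpoints_close(self):
        # delta vanishes at the pure solvents: v = 1 at both loop ends
        loop, _ = gen_hysteresis_loop(SynthConfig(seed=3, hysteresis_amplitude=0.4))
        prof = hystereticity_profile(loop).table.set_index("pct_meoh")
        assert prof.loc[100.0, "v_R"] == pytest.approx(1.0, abs=1e-12)
        assert prof.loc[0.0, "v_R"] == pytest.approx(1.0, abs=1e-12)

    def test_planted_eeo_reversal_recovered_along_loop(self):
        # enantiomer-specific amplitudes flip the reverse-branch order at
        # mid compositions; infer_loop should flag EEO_reversed there and
        # stay consistent with the realized branch everywhere
        cfg = SynthConfig(seed=7, hysteresis_amplitude=0.4,
                          hysteresis_amplitude_ratio=3.0)
        loop, _ = gen_hysteresis_loop(
            cfg,
            base_lnk_R=lambda x: 0.2 - 0.5 * (x / 100.0),
            base_lnk_S=lambda x: 0.3 - 0.5 * (x / 100.0),
        )
        inference = infer_loop(loop)
        assert inference.all_consistent
        reversed_rows = inference.table[
            inference.table["observed"] == "EEO_reversed"
        ]
        assert len(reversed_rows) > 0

    def test_inference_consistent_on_random_generated_loops(self):
        for seed in range(10):
            loop, _ = gen_hysteresis_loop(
                SynthConfig(seed=seed, hysteresis_amplitude=0.3,
                            hysteresis_amplitude_ratio=0.5)
            )
            assert infer_loop(loop).all_consistent
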