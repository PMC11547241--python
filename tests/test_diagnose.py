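"""Reaction planning, the replicate positivity rule, and the two-step caller."""

import pytest

from dropscreen.diagnose import call_detection_group, plan_reaction, run_two_step
from dropscreen.limits import estimate_limits
from dropscreen.quantify import SamplePrep
from dropscreen.simulate import ChamberConfig, simulate_chamber
from dropscreen.workflows import (
    default_gates,
    run_simulated_sample,
    simulate_patient_sample,
)


def _limits(lob, lod):
    lim = estimate_limits([0, 0, 0], "g")
    lim.lob95_droplets, lim.lod95_droplets = lob, lod
    return lim


class TestPlanReaction:
    def test_dilution_for_concentrated_sample(self):
        plan = plan_reaction(66 / 15)  # 66 ng in the 15 uL input
        assert plan.dilution_factor == pytest.approx(2.0)
        assert plan.input_ng_per_pcr == pytest.approx(33.0)
        assert plan.projected_copies_per_pcr == pytest.approx(10_000.0)

    def test_33ng_is_ten_thousand_copies(self):
        plan = plan_reaction(33 / 15)
        assert plan.dilution_factor == 1.0
        assert plan.projected_copies_per_pcr == pytest.approx(10_000.0)

    def test_low_input_triggers_three_replicates(self):
        plan = plan_reaction(4 / 15, available_ul=45.0)  # 4 ng per input
        assert plan.n_replicates == 3
        assert plan.n_replicates * plan.input_ng_per_pcr >= 10.0

    def test_material_exhaustion_caps_replicates(self):
        plan = plan_reaction(4 / 15, available_ul=20.0)  # volume for one rerun only
        assert plan.n_replicates == 1

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            plan_reaction(-1.0)


class TestPositivityRule:
    def test_two_replicates_at_lod_is_positive(self):
        gc = call_detection_group([6, 7, 2], _limits(lob=3, lod=5))
        assert gc.status == "positive"

    def test_all_at_or_below_lob_is_negative(self):
        assert call_detection_group([1, 0], _limits(3, 8)).status == "negative"

    def test_single_between_lob_and_lod_is_equivocal(self):
        gc = call_detection_group([4], _limits(3, 8))
        assert gc.status == "equivocal"
        assert gc.recommended_additional_replicates == 2

    def test_single_above_lod_is_positive(self):
        assert call_detection_group([9], _limits(3, 8)).status == "positive"

    def test_one_of_three_at_lod_stays_equivocal(self):
        assert call_detection_group([9, 1, 2], _limits(3, 8)).status == "equivocal"

    def test_empty_counts_raise(self):
        with pytest.raises(ValueError):
            call_detection_group([], _limits(3, 8))


class TestTwoStep:
    def test_blank_sample_all_negative(self):
        call = run_simulated_sample({}, seed=50)
        assert call.controls_ok and call.status == "ok"
        assert call.positive_groups == []
        assert call.identified == []

    def test_v777l_screen_and_identify(self):
        """High-MAF V777L: hotspot screen positive, duplex pins the variant."""
        call = run_simulated_sample({"V777L(G>C)": 8.7}, seed=51)
        assert call.positive_groups == ["776-779_MUT"]
        assert [m.protein_name for m, _ in call.identified] == ["V777L(G>C)"]
        _, q = call.identified[0]
        assert q.maf_pct == pytest.approx(8.7, rel=0.35)
        screen_q = next(g.quant for g in call.screen if g.status == "positive")
        assert 0.5 < screen_q.maf_pct / q.maf_pct < 2.0  # screen vs duplex agree

    def test_double_mutation_two_identifications(self):
        call = run_simulated_sample({"L755S": 1.2, "D769H": 0.8}, seed=52)
        names = sorted(m.protein_name for m, _ in call.identified)
        assert names == ["D769H", "L755S"]

    def test_failed_controls_suppress_calls(self, screening, screen_gates, screen_limits):
        blank = simulate_chamber(
            ChamberConfig(templates={}, fp_rate={}, seed=60), screening, "neg"
        )
        screen, dup = simulate_patient_sample({"L755S": 5.0}, seed=60)
        call = run_two_step(
            "s", screen, dup, screen_gates, {}, screen_limits,
            SamplePrep(plasma_volume_ml=4.0),
            positive_control=blank,  # a blank passed off as positive control
        )
        assert not call.controls_ok
        assert call.status == "invalid-controls"
        assert call.screen == [] and call.identified == []

    def test_positive_screen_without_duplex_is_incomplete(
        self, screening, screen_gates, screen_limits
    ):
        screen, _ = simulate_patient_sample({"L755S": 5.0}, seed=61)
        call = run_two_step(
            "s", screen, {}, screen_gates, {}, screen_limits,
            SamplePrep(plasma_volume_ml=4.0),
        )
        assert call.positive_groups
        assert call.status == "incomplete"

    def test_no_identification_without_positive_screen(self):
        # MAF far below LOD: screen negative, so no duplex identification at all
        call = run_simulated_sample({"L755S": 0.01}, seed=53)
        assert call.positive_groups == []
        assert call.identified == []


def test_sensitivity_and_specificity_at_one_percent_maf(
    screening, duplexes, screen_gates, screen_limits
):
    """200 simulated single-replicate samples at MAF >= 1%: every true positive
    is called with the right identity; false positive calls stay below 5%."""
    from dropscreen.workflows import default_gates

    duplex_gates = {d.name: default_gates(d, seed=0) for d in duplexes}
    prep = SamplePrep(plasma_volume_ml=4.0)
    variants = ["L755S", "S310F", "V777M", "L869R"]
    tp = fp = 0
    n_pos = n_neg = 100
    for i in range(n_pos):
        v = variants[i % len(variants)]
        screen, dup = simulate_patient_sample(
            {v: 1.0 + (i % 7)}, seed=1000 + i, sample_id=f"pos{i}"
        )
        call = run_two_step(
            f"pos{i}", screen, dup, screen_gates, duplex_gates, screen_limits, prep
        )
        if any(m.protein_name == v for m, _ in call.identified):
            tp += 1
    for i in range(n_neg):
        screen, dup = simulate_patient_sample({}, seed=5000 + i, sample_id=f"neg{i}")
        call = run_two_step(
            f"neg{i}", screen, dup, screen_gates, duplex_gates, screen_limits, prep
        )
        if call.positive_groups:
            fp += 1
    assert tp == n_pos                # sensitivity 100%
    assert fp / n_neg <= 0.05         # specificity >= 95%
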