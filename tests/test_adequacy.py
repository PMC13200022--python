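import pytest
from hypothesis import given, settings, strategies as st

from snpeval import (
    NUTRIENT_KEYS,
    StandardsConfig,
    ValidationError,
    classify,
    digestible_protein,
    evaluate_energy,
    evaluate_fat,
    evaluate_micronutrient,
    evaluate_protein,
    evaluate_provision,
    evaluate_state,
    state_summary,
)
from snpeval.engine import DailyProvision


class TestClassify:
    @pytest.mark.parametrize(
        "pct,expected",
        [(79.99, "red"), (80.0, "yellow"), (89.99, "yellow"), (90.0, "green"),
         (100.0, "green"), (110.0, "green"), (115.0, "green"), (0.0, "red")],
    )
    def test_bands_without_upper_rule(self, pct, expected):
        assert classify(pct) == expected

    @pytest.mark.parametrize(
        "pct,expected",
        [(110.0, "green"), (110.01, "red"), (115.0, "red"), (100.0, "green")],
    )
    def test_excess_rule(self, pct, expected):
        assert classify(pct, has_upper_rule=True) == expected

    @settings(deadline=None, derandomize=True)
    @given(pct=st.floats(0, 1e4), upper=st.booleans())
    def test_total_function(self, pct, upper):
        assert classify(pct, upper) in {"green", "yellow", "red"}


class TestDigestibleProtein:
    def test_factor_0_8_hits_2012_floor(self):
        assert digestible_protein(15.0, 0.8) == pytest.approx(12.0)

    def test_identity_at_d_1(self):
        assert digestible_protein(13.7, 1.0) == 13.7

    def test_zero_crude(self):
        assert digestible_protein(0.0, 0.8) == 0.0

    @pytest.mark.parametrize("d", [0.0, -0.1, 1.1])
    def test_invalid_factor_rejected(self, d):
        with pytest.raises(ValidationError):
            digestible_protein(10.0, d)


class TestEnergy:
    def test_90pct_boundary_met(self, snp2012):
        r = evaluate_energy(450.0, snp2012)
        assert r.pct_of_requirement == pytest.approx(90.0)
        assert r.met and r.status == "green"

    def test_zero_is_red(self, snp2012):
        r = evaluate_energy(0.0, snp2012)
        assert r.pct_of_requirement == 0.0 and r.status == "red" and not r.met

    def test_excess_is_red(self, snp2012):
        r = evaluate_energy(600.0, snp2012)
        assert r.pct_of_requirement == pytest.approx(120.0)
        assert r.status == "red"


class TestProtein:
    def test_crude_at_2012_floor_met(self, snp2012):
        r = evaluate_protein(12.0, snp2012)
        assert r.met and r.rule_applied == "protein_floor"

    def test_margin_decides_adjusted_14g(self, snp2012):
        # 14 g crude -> 11.2 g digestible; floor 12 with 10% margin is 10.8
        r = evaluate_protein(14.0, snp2012, apply_digestibility=True)
        assert r.provision == pytest.approx(11.2)
        assert r.met
        strict = StandardsConfig.snp2012(tolerance=0.0)
        assert not evaluate_protein(14.0, strict, apply_digestibility=True).met

    def test_zero_red(self, snp2012):
        r = evaluate_protein(0.0, snp2012)
        assert not r.met and r.status == "red"

    def test_digestibility_1_equals_crude(self):
        cfg = StandardsConfig.snp2012(digestibility_factor=1.0)
        a = evaluate_protein(13.0, cfg, apply_digestibility=True)
        b = evaluate_protein(13.0, cfg, apply_digestibility=False)
        assert a.provision == b.provision and a.met == b.met and a.status == b.status


class TestFat:
    def test_mid_band_met(self, snp2012):
        # 30% of energy from fat: energy 450, fat 15
        r = evaluate_fat(15.0, 450.0, snp2012)
        assert r.met and r.rule_applied == "fat_ratio_band"

    def test_relaxed_lower_edge(self, snp2012):
        # ratio = 22.5% exactly (0.9 x 25): fat = 22.5*E/900
        assert evaluate_fat(22.5 * 450 / 900, 450.0, snp2012).met
        assert not evaluate_fat(22.4 * 450 / 900, 450.0, snp2012).met

    def test_excess_red(self, snp2012):
        # ratio 40% > 38.5 = 1.1 x 35
        r = evaluate_fat(40 * 450 / 900, 450.0, snp2012)
        assert not r.met and r.status == "red"

    def test_one_sided_allowance_switch(self):
        cfg = StandardsConfig.snp2012(fat_allowance_two_sided=False)
        # 36% is inside 35*1.1 but above 35
        assert not evaluate_fat(36 * 450 / 900, 450.0, cfg).met

    def test_2023_absolute_band(self, snp2023):
        assert evaluate_fat(16.0, 400.0, snp2023).rule_applied == "fat_absolute_band"
        assert evaluate_fat(13.5, 400.0, snp2023).met  # 15*(1-0.1)
        assert not evaluate_fat(13.4, 400.0, snp2023).met
        assert not evaluate_fat(22.1, 400.0, snp2023).met  # > 20*1.1


class TestMicronutrient:
    def test_exact_third_ear_green(self, snp2012):
        req = snp2012.ear_per_day["iron_mg"] / 3
        r = evaluate_micronutrient(req, "iron_mg", snp2012)
        assert r.pct_of_requirement == pytest.approx(100.0)
        assert r.met and r.status == "green"

    def test_margin_keeps_90pct_met(self, snp2012):
        req = snp2012.ear_per_day["calcium_mg"] / 3
        r = evaluate_micronutrient(0.9 * req, "calcium_mg", snp2012)
        assert r.met and r.status == "green"

    def test_79pct_red(self, snp2012):
        req = snp2012.ear_per_day["zinc_mg"] / 3
        r = evaluate_micronutrient(0.79 * req, "zinc_mg", snp2012)
        assert not r.met and r.status == "red"

    def test_missing_ear_names_nutrient(self, snp2012):
        with pytest.raises(ValidationError, match="fat_g"):
            evaluate_micronutrient(1.0, "fat_g", snp2012)


class TestEvaluateState:
    def _summary(self, values):
        ps = [
            DailyProvision("s", "a", f"d{i}", dict(zip(NUTRIENT_KEYS, row)))
            for i, row in enumerate(values)
        ]
        return state_summary(ps, n_draws=200, seed=9)

    def test_all_zero_state_all_red(self):
        s = self._summary([[0.0] * len(NUTRIENT_KEYS)] * 2)
        results = evaluate_state(s, StandardsConfig.snp2012())
        assert all(r.status == "red" and not r.met for r in results)

    def test_protein_appears_twice(self, snp2012):
        s = self._summary([[500, 15, 16, 160, 3, 1.4, 40, 100, 0.3, 0.4]] * 2)
        results = evaluate_state(s, snp2012)
        rules = [r.rule_applied for r in results]
        assert rules.count("protein_floor") == 1
        assert rules.count("protein_digestible") == 1
        assert len(results) == 4 + len(snp2012.ear_per_day)

    def test_constructed_adequate_state_all_green(self, snp2012):
        ear = snp2012.ear_per_day
        row = [500.0, 15.0, 500 * 0.30 / 9]  # energy, protein, fat at 30% ratio
        row += [ear[k] / 3 for k in NUTRIENT_KEYS[3:]]
        results = evaluate_state(self._summary([row, row]), snp2012)
        assert all(r.status == "green" for r in results)

    def test_standards_switch_energy_flip(self, snp2012, snp2023):
        # 420 kcal: 84% of 500 (fails 2012) but 105% of 400 (meets 2023)
        r12 = evaluate_energy(420.0, snp2012)
        r23 = evaluate_energy(420.0, snp2023)
        assert r12.pct_of_requirement == pytest.approx(84.0) and not r12.met
        assert r23.pct_of_requirement == pytest.approx(105.0) and r23.met


def test_floor_rules_monotone_in_provision(snp2012):
    """More provision never worsens a floor-type status."""
    order = {"red": 0, "yellow": 1, "green": 2}
    for f in [evaluate_protein, lambda p, c: evaluate_micronutrient(p, "iron_mg", c)]:
        last = -1
        for p in [0.0, 0.5, 1.0, 2.0, 2.5, 3.0, 5.0, 10.0, 20.0]:
            r = f(p, snp2012)
            assert order[r.status] >= last or r.status == "green"
            last = order[r.status]


def test_band_rules_unimodal_in_provision(snp2012):
    """Energy status rises then falls as provision sweeps through the band."""
    order = {"red": 0, "yellow": 1, "green": 2}
    seq = [order[evaluate_energy(p, snp2012).status] for p in range(0, 800, 10)]
    peak = seq.index(max(seq))
    assert all(a <= b for a, b in zip(seq[:peak], seq[1:peak + 1]))
    assert all(a >= b for a, b in zip(seq[peak:], seq[peak + 1:]))


def test_version_consistency(snp2012, snp2023):
    """The two standards differ only in the documented target fields."""
    assert snp2012.meal_fraction == snp2023.meal_fraction
    assert snp2012.tolerance == snp2023.tolerance
    assert snp2012.digestibility_factor == snp2023.digestibility_factor
    assert snp2012.ear_per_day == snp2023.ear_per_day
    assert (snp2012.energy_target_kcal, snp2023.energy_target_kcal) == (500.0, 400.0)
    assert (snp2012.protein_min_g, snp2023.protein_min_g) == (12.0, 15.0)
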