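"""Unit and property tests for the fuzzy inference engine."""

import math

import numpy as np
import pytest
import yaml

from conftest import random_system
from oracles import fis_oracle, mf_oracle
from urbanhealth.fis import (
    FuzzyRule,
    FuzzySystem,
    FuzzyVariable,
    GaussianMF,
    NoRuleFiredError,
    SigmoidDiffMF,
    SigmoidMF,
    TriangularMF,
    defuzzify,
    evaluate_system,
    fire_rules,
    fuzzify,
    system_from_dict,
    system_to_dict,
)

RNG = np.random.default_rng(1357715)


class TestMembershipFunctions:
    def test_sigmoid_center_is_half(self):
        assert SigmoidMF(a=3.0, c=2.5)(3.0) == pytest.approx(0.5)

    def test_sigmoid_closed_form(self):
        # 1 / (1 + exp(-ln 3)) = 1 / (1 + 1/3) = 0.75
        assert SigmoidMF(a=0.0, c=1.0, b=1.0)(math.log(3)) == pytest.approx(0.75)

    def test_sigmoid_saturation_open_bounds(self):
        mf = SigmoidMF(a=0.0, c=5.0)
        assert mf(1e6) == pytest.approx(1.0) and mf(1e6) < 1.0
        assert mf(-1e6) == pytest.approx(0.0) and mf(-1e6) > 0.0

    def test_sigmoid_base_scales_steepness(self):
        assert SigmoidMF(a=0.0, c=2.0, b=2.0)(1.0) == pytest.approx(
            SigmoidMF(a=0.0, c=1.0)(1.0)
        )

    def test_gaussian_closed_forms(self):
        mf = GaussianMF(b=0.4, sigma=0.1)
        assert mf(0.4) == 1.0
        assert mf(0.5) == pytest.approx(math.exp(-0.5))
        assert mf(0.2) == pytest.approx(math.exp(-2.0))

    def test_triangular_shape(self):
        mf = TriangularMF(left=0.0, peak=0.25, right=1.0)
        assert mf(0.25) == 1.0
        assert mf(0.0) == 0.0 and mf(1.0) == 0.0
        assert mf(0.125) == pytest.approx(0.5)
        assert mf(0.625) == pytest.approx(0.5)

    def test_sigmoid_diff_partition_of_unity(self):
        lo, med, hi = (
            SigmoidMF(a=0.35, c=-8.0),
            SigmoidDiffMF(a_left=0.35, a_right=0.65, c=8.0),
            SigmoidMF(a=0.65, c=8.0),
        )
        for x in np.linspace(0, 1, 41):
            assert lo(x) + med(x) + hi(x) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SigmoidMF(a=0.0, c=1.0, b=0.0)
        with pytest.raises(ValueError):
            GaussianMF(b=0.0, sigma=0.0)
        with pytest.raises(ValueError):
            TriangularMF(left=1.0, peak=0.5, right=2.0)


class TestFuzzify:
    def _var(self):
        return FuzzyVariable(
            name="x",
            universe=(0.0, 1.0),
            terms={"low": SigmoidMF(a=0.3, c=-6.0), "high": SigmoidMF(a=0.7, c=6.0)},
        )

    def test_center_degree_is_half(self):
        assert fuzzify(0.3, self._var())["low"] == pytest.approx(0.5)

    def test_saturation_far_below_centers(self):
        var = FuzzyVariable(
            name="x",
            universe=(-100.0, 100.0),
            terms={
                "low": SigmoidMF(a=-50.0, c=-2.0),
                "mid": SigmoidDiffMF(a_left=-50.0, a_right=50.0, c=2.0),
                "high": SigmoidMF(a=50.0, c=2.0),
            },
        )
        deg = fuzzify(-100.0, var)
        assert deg["low"] == pytest.approx(1.0, abs=1e-6)
        assert deg["mid"] == pytest.approx(0.0, abs=1e-6)
        assert deg["high"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_per_term_oracle(self):
        var = self._var()
        for x in RNG.uniform(0, 1, 200):
            deg = fuzzify(float(x), var)
            for label, mf in var.terms.items():
                assert deg[label] == pytest.approx(mf_oracle(mf, x), abs=1e-12)

    def test_out_of_universe_clamped_or_strict(self, caplog):
        var = self._var()
        import logging

        with caplog.at_level(logging.WARNING, logger="urbanhealth.fis"):
            deg = fuzzify(2.0, var)
        assert deg == fuzzify(1.0, var)
        assert any("clamped" in m for m in caplog.messages)
        with pytest.raises(ValueError):
            fuzzify(2.0, var, clamp=False)


class TestFireDefuzzify:
    def _system(self, and_op="product", weights=(1.0, 1.0)):
        x = FuzzyVariable("x", (0, 1), {"a": SigmoidMF(0.5, 4.0)})
        y = FuzzyVariable("y", (0, 1), {"b": SigmoidMF(0.5, 4.0)})
        out = FuzzyVariable("z", (0, 1), {"lo": GaussianMF(0.1, 0.1), "hi": GaussianMF(0.9, 0.1)})
        rules = (
            FuzzyRule((("x", "a"), ("y", "b")), "hi", weight=weights[0]),
            FuzzyRule((("x", "a"),), "lo", weight=weights[1]),
        )
        return FuzzySystem((x, y), out, rules, and_operator=and_op)

    def test_single_conjunct_strength(self):
        sys = self._system()
        degrees = {"x": {"a": 0.7}, "y": {"b": 1.0}}
        fired = fire_rules(sys, degrees)
        assert fired[1][1] == pytest.approx(0.7)

    def test_and_operators(self):
        degrees = {"x": {"a": 0.4}, "y": {"b": 0.9}}
        assert fire_rules(self._system("min"), degrees)[0][1] == pytest.approx(0.4)
        assert fire_rules(self._system("product"), degrees)[0][1] == pytest.approx(0.36)

    def test_zero_weight_annihilates(self):
        fired = fire_rules(self._system(weights=(0.0, 1.0)), {"x": {"a": 0.9}, "y": {"b": 0.9}})
        assert fired[0][1] == 0.0

    def test_missing_variable_is_contract_violation(self):
        with pytest.raises(KeyError):
            fire_rules(self._system(), {"x": {"a": 0.5}})

    def test_defuzzify_identities(self):
        assert defuzzify([(0.37, 42.0)]) == 42.0
        assert defuzzify([(0.2, 0.0), (0.8, 1.0)]) == pytest.approx(0.8)
        assert defuzzify([(0.5, 10.0), (0.5, 20.0), (0.5, 30.0)]) == pytest.approx(20.0)

    def test_no_rule_fired(self):
        with pytest.raises(NoRuleFiredError):
            defuzzify([(0.0, 1.0), (0.0, 2.0)])


class TestEvaluateSystem:
    def test_constant_consequent_system(self):
        x = FuzzyVariable("x", (0, 1), {"a": SigmoidMF(0.5, 4.0), "b": SigmoidMF(0.5, -4.0)})
        out = FuzzyVariable("y", (0, 1), {"k": GaussianMF(0.37, 0.1)})
        rules = (FuzzyRule((("x", "a"),), "k"), FuzzyRule((("x", "b"),), "k"))
        sys = FuzzySystem((x,), out, rules)
        for v in (0.0, 0.21, 0.5, 0.93):
            assert evaluate_system(sys, {"x": v})[0] == pytest.approx(0.37)

    def test_monotone_system_saturates(self):
        x = FuzzyVariable(
            "x", (-100, 100),
            {"low": SigmoidMF(0.0, -1.0), "high": SigmoidMF(0.0, 1.0)},
        )
        out = FuzzyVariable("y", (0, 1), {"lo": GaussianMF(0.0, 0.1), "hi": GaussianMF(1.0, 0.1)})
        sys = FuzzySystem(
            (x,), out,
            (FuzzyRule((("x", "low"),), "lo"), FuzzyRule((("x", "high"),), "hi")),
        )
        assert evaluate_system(sys, {"x": -100.0})[0] == pytest.approx(0.0, abs=1e-6)
        assert evaluate_system(sys, {"x": 100.0})[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_oracle_on_random_systems(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            system, points = random_system(rng)
            for record in points:
                try:
                    got, _ = evaluate_system(system, record)
                except NoRuleFiredError:
                    with pytest.raises(ZeroDivisionError):
                        fis_oracle(system, record)
                    continue
                assert got == pytest.approx(fis_oracle(system, record), abs=1e-9)

    def test_output_in_convex_hull_of_consequents(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            system, points = random_system(rng)
            levels = [system.consequent_level(r.consequent) for r in system.rules]
            for record in points:
                try:
                    got, _ = evaluate_system(system, record)
                except NoRuleFiredError:
                    continue
                assert min(levels) - 1e-12 <= got <= max(levels) + 1e-12

    def test_rule_order_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            system, points = random_system(rng)
            perm = rng.permutation(len(system.rules))
            shuffled = FuzzySystem(
                system.inputs, system.output,
                tuple(system.rules[i] for i in perm),
                and_operator=system.and_operator,
                consequent_levels=system.consequent_levels,
            )
            for record in points:
                try:
                    expected = evaluate_system(system, record)[0]
                except NoRuleFiredError:
                    continue
                assert evaluate_system(shuffled, record)[0] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_weight_split_invariance_under_product(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            system, points = random_system(rng)
            if system.and_operator != "product":
                continue
            halves = []
            for r in system.rules:
                halves.append(FuzzyRule(r.antecedent, r.consequent, r.weight / 2))
                halves.append(FuzzyRule(r.antecedent, r.consequent, r.weight / 2))
            split = FuzzySystem(
                system.inputs, system.output, tuple(halves),
                and_operator="product", consequent_levels=system.consequent_levels,
            )
            for record in points:
                try:
                    expected = evaluate_system(system, record)[0]
                except NoRuleFiredError:
                    continue
                assert evaluate_system(split, record)[0] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_crisp_degrees_reduce_to_lookup_table(self):
        """Spike memberships (degrees in {0,1}) make the system a lookup table."""
        spikes = {f"v{k}": TriangularMF(k, k, k) for k in range(3)}
        x = FuzzyVariable("x", (0.0, 2.0), terms=spikes)
        out = FuzzyVariable("y", (0, 100), {"any": GaussianMF(0, 1)})
        lookup = {0: 10.0, 1: 50.0, 2: 90.0}
        rules = tuple(
            FuzzyRule((("x", f"v{k}"),), lookup[k]) for k in range(3)
        )
        sys = FuzzySystem((x,), out, rules)
        for k, expected in lookup.items():
            assert evaluate_system(sys, {"x": float(k)})[0] == expected

    def test_monotone_grid(self):
        """Same-sign sigmoid terms with ordered consequents give monotone output."""
        x = FuzzyVariable(
            "x", (0, 1),
            {"low": SigmoidMF(0.35, -8.0), "high": SigmoidMF(0.65, 8.0)},
        )
        out = FuzzyVariable("y", (0, 1), {"lo": GaussianMF(0.1, 0.1), "hi": GaussianMF(0.9, 0.1)})
        sys = FuzzySystem(
            (x,), out,
            (FuzzyRule((("x", "low"),), "lo"), FuzzyRule((("x", "high"),), "hi")),
        )
        vals = [evaluate_system(sys, {"x": v})[0] for v in np.linspace(0, 1, 21)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_validation_catches_bad_references(self):
        x = FuzzyVariable("x", (0, 1), {"a": SigmoidMF(0.5, 1.0)})
        out = FuzzyVariable("y", (0, 1), {"k": GaussianMF(0.5, 0.1)})
        with pytest.raises(ValueError):
            FuzzySystem((x,), out, (FuzzyRule((("z", "a"),), "k"),))
        with pytest.raises(ValueError):
            FuzzySystem((x,), out, (FuzzyRule((("x", "nope"),), "k"),))
        with pytest.raises(ValueError):
            FuzzySystem((x,), out, (FuzzyRule((("x", "a"),), "unknown"),))


def test_yaml_round_trip():
    rng = np.random.default_rng(3)
    system, points = random_system(rng)
    doc = yaml.safe_dump(system_to_dict(system))
    restored = system_from_dict(yaml.safe_load(doc))
    for record in points:
        assert evaluate_system(restored, record)[0] == pytest.approx(
            evaluate_system(system, record)[0], abs=1e-12
        )
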