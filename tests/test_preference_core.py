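"""Dominance, Pareto filtering, preferred-range classification, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from premio import (
    AlternativeSet,
    IdealNadir,
    PreferenceSet,
    PreferredRange,
    Status,
    TherapyRecord,
    ValidationError,
    aspiration_distance,
    classify,
    closeness_score,
    dominates,
    ideal_nadir,
    pareto_front,
    select,
    status,
)
from conftest import random_alternative_set


def brute_force_front(altset):
    """Independent all-pairs dominance scan (row-by-row numpy sweep)."""
    signs = np.array(
        [1.0 if s.direction == "minimize" else -1.0 for s in altset.specs]
    )
    a = np.array(
        [[r.objectives[s.key] for s in altset.specs] for r in altset.records]
    ) * signs
    dominated = np.zeros(len(altset), dtype=bool)
    for i in range(len(altset)):
        dom_by_i = (a[i] <= a).all(axis=1) & (a[i] < a).any(axis=1)
        dominated |= dom_by_i
    return [r.id for r, d in zip(altset.records, dominated) if not d]


def make_prefs(**bounds):
    defaults = {
        "cost_eur": (300, 600),
        "pain_net_change_pct": (15, 30),
        "function_net_change_pct": (15, 25),
        "supervised_sessions": (0, 15),
        "period_weeks": (8, 26),
    }
    defaults.update(bounds)
    return PreferenceSet(
        {k: PreferredRange(k, lo, hi) for k, (lo, hi) in defaults.items()}
    )


def vec_record(rec_id, cost, pain, func, sessions, weeks):
    return TherapyRecord(
        rec_id,
        "s",
        "t",
        {
            "cost_eur": float(cost),
            "pain_net_change_pct": float(pain),
            "function_net_change_pct": float(func),
            "supervised_sessions": float(sessions),
            "period_weeks": float(weeks),
        },
    )


objective_vectors = st.tuples(
    st.integers(0, 1500),
    st.integers(-5, 45),
    st.integers(-5, 45),
    st.integers(0, 36),
    st.integers(8, 48),
)


class TestDominance:
    def test_equal_records_do_not_dominate(self, specs):
        a = vec_record("a", 100, 10, 10, 5, 12)
        b = vec_record("b", 100, 10, 10, 5, 12)
        assert not dominates(a, b, specs) and not dominates(b, a, specs)

    def test_better_on_all_objectives_dominates(self, specs):
        a = vec_record("a", 100, 30, 30, 2, 10)
        b = vec_record("b", 500, 10, 10, 20, 20)
        assert dominates(a, b, specs) and not dominates(b, a, specs)

    def test_trade_off_is_incomparable(self, specs):
        cheap = vec_record("a", 100, 10, 10, 5, 12)
        effective = vec_record("b", 500, 30, 10, 5, 12)
        assert not dominates(cheap, effective, specs)
        assert not dominates(effective, cheap, specs)

    def test_mismatched_objectives_rejected(self, specs):
        a = vec_record("a", 100, 10, 10, 5, 12)
        b = TherapyRecord("b", "s", "t", {"cost_eur": 1.0})
        with pytest.raises(ValidationError):
            dominates(a, b, specs)

    @given(u=objective_vectors, v=objective_vectors, w=objective_vectors)
    @settings(max_examples=200, derandomize=True)
    def test_partial_order_axioms(self, specs, u, v, w):
        """Irreflexive, antisymmetric and transitive on generated triples."""
        a, b, c = (vec_record(n, *vec) for n, vec in zip("abc", (u, v, w)))
        assert not dominates(a, a, specs)
        if dominates(a, b, specs):
            assert not dominates(b, a, specs)
        if dominates(a, b, specs) and dominates(b, c, specs):
            assert dominates(a, c, specs)


class TestParetoFront:
    def test_singleton(self, specs):
        altset = AlternativeSet(specs, [vec_record("only", 100, 10, 10, 5, 12)])
        assert pareto_front(altset) == ["only"]

    def test_single_dominator_survives(self, specs):
        records = [
            vec_record("best", 100, 30, 30, 2, 10),
            vec_record("mid", 500, 20, 20, 10, 15),
            vec_record("worst", 900, 10, 10, 20, 20),
        ]
        assert pareto_front(AlternativeSet(specs, records)) == ["best"]

    def test_matches_brute_force_oracle_on_random_sets(self, specs, rng):
        for _ in range(30):
            n = int(rng.integers(2, 200))
            altset = random_alternative_set(rng, n, specs)
            assert pareto_front(altset) == brute_force_front(altset)

    def test_front_order_is_input_order(self, specs, rng):
        altset = random_alternative_set(rng, 50, specs)
        front = pareto_front(altset)
        positions = [altset.ids.index(i) for i in front]
        assert positions == sorted(positions)


class TestIdealNadir:
    def test_single_record_ideal_equals_nadir(self, specs):
        rec = vec_record("a", 100, 10, 10, 5, 12)
        inad = ideal_nadir(AlternativeSet(specs, [rec]))
        assert inad.ideal == inad.nadir == rec.objectives

    def test_direction_respected(self, specs):
        records = [
            vec_record("a", 100, 10, 10, 5, 12),
            vec_record("b", 500, 30, 20, 10, 15),
            vec_record("c", 900, 20, 15, 20, 20),
        ]
        inad = ideal_nadir(AlternativeSet(specs, records))
        assert (inad.ideal["cost_eur"], inad.nadir["cost_eur"]) == (100, 900)
        assert (
            inad.ideal["pain_net_change_pct"], inad.nadir["pain_net_change_pct"]
        ) == (30, 10)

    def test_extremes_attained_by_some_record(self, specs, rng):
        altset = random_alternative_set(rng, 40, specs)
        inad = ideal_nadir(altset)
        for spec in specs:
            values = {r.objectives[spec.key] for r in altset.records}
            assert inad.ideal[spec.key] in values
            assert inad.nadir[spec.key] in values


class TestStatus:
    @pytest.mark.parametrize(
        "value, lo, hi, direction, expected",
        [
            (450, 300, 600, "minimize", Status.WITHIN),
            (250, 300, 600, "minimize", Status.BETTER),
            (700, 300, 600, "minimize", Status.WORSE),
            (12, 15, 30, "maximize", Status.WORSE),
            (35, 15, 30, "maximize", Status.BETTER),
            (15, 15, 30, "maximize", Status.WITHIN),
            (600, 300, 600, "minimize", Status.WITHIN),
        ],
    )
    def test_range_classification(self, value, lo, hi, direction, expected):
        assert status(value, PreferredRange("x", lo, hi), direction) is expected


class TestClassifyAndCloseness:
    def nad(self):
        return IdealNadir(
            ideal={
                "cost_eur": 100,
                "pain_net_change_pct": 40,
                "function_net_change_pct": 40,
                "supervised_sessions": 0,
                "period_weeks": 8,
            },
            nadir={
                "cost_eur": 1500,
                "pain_net_change_pct": 0,
                "function_net_change_pct": 0,
                "supervised_sessions": 36,
                "period_weeks": 48,
            },
        )

    def test_all_within_is_group_i_with_zero_closeness(self, specs):
        rec = vec_record("a", 450, 20, 20, 10, 12)
        cls = classify(rec, make_prefs(), specs, self.nad())
        assert cls.group == "I" and cls.closeness == 0.0
        assert all(s is Status.WITHIN for s in cls.statuses.values())

    def test_better_than_every_good_bound_is_group_i(self, specs):
        rec = vec_record("a", 100, 40, 40, 0, 8)  # beyond every aspiration
        prefs = make_prefs(supervised_sessions=(2, 15), period_weeks=(10, 26))
        cls = classify(rec, prefs, specs, self.nad())
        assert cls.group == "I"
        assert all(s is Status.BETTER for s in cls.statuses.values())

    def test_single_violation_is_group_ii(self, specs):
        rec = vec_record("a", 700, 20, 20, 10, 12)
        cls = classify(rec, make_prefs(), specs, self.nad())
        assert cls.group == "II" and cls.closeness > 0

    def test_closeness_hand_oracle_single_violation(self, specs):
        # (700 - 600) / (1500 - 100) = 0.0714...
        rec = vec_record("a", 700, 20, 20, 10, 12)
        score = closeness_score(rec, make_prefs(), specs, self.nad())
        assert score == pytest.approx(100 / 1400)

    def test_closeness_hand_oracle_two_violations(self, specs):
        # cost: 100/1400; pain: (15 - 10) / 40
        rec = vec_record("a", 700, 10, 20, 10, 12)
        score = closeness_score(rec, make_prefs(), specs, self.nad())
        assert score == pytest.approx(100 / 1400 + 5 / 40)

    def test_chebyshev_aggregation_pluggable(self, specs):
        rec = vec_record("a", 700, 10, 20, 10, 12)
        score = closeness_score(rec, make_prefs(), specs, self.nad(), agg=max)
        assert score == pytest.approx(max(100 / 1400, 5 / 40))

    def test_degenerate_objective_normalizer_falls_back_to_one(self, specs):
        nad = self.nad()
        degenerate = IdealNadir(
            ideal={**nad.ideal, "cost_eur": 700},
            nadir={**nad.nadir, "cost_eur": 700},
        )
        rec = vec_record("a", 700, 20, 20, 10, 12)
        assert degenerate.span("cost_eur") == 1.0
        # violation 100 over the fallback normalizer 1; identical for every
        # record since all share the degenerate value
        assert closeness_score(rec, make_prefs(), specs, degenerate) == 100.0

    def test_closeness_zero_iff_group_i(self, specs, rng):
        altset = random_alternative_set(rng, 300, specs)
        nad = self.nad()
        for rec in altset.records:
            cls = classify(rec, make_prefs(), specs, nad)
            assert (cls.closeness == 0.0) == (cls.group == "I")

    def test_invariant_under_positive_affine_rescaling(self, specs, rng):
        """Statuses and closeness are unchanged when an objective's values,
        range and ideal/nadir are rescaled together by x -> a*x + b."""
        a, b, key = 3.7, 250.0, "cost_eur"
        nad = self.nad()
        prefs = make_prefs()
        scaled_prefs = make_prefs(
            **{key: (a * prefs.ranges[key].lower + b, a * prefs.ranges[key].upper + b)}
        )
        scaled_nad = IdealNadir(
            ideal={**nad.ideal, key: a * nad.ideal[key] + b},
            nadir={**nad.nadir, key: a * nad.nadir[key] + b},
        )
        for _ in range(50):
            cost = float(rng.uniform(0, 1500))
            rec = vec_record("r", cost, 20, 20, 10, 12)
            scaled = vec_record("r", a * cost + b, 20, 20, 10, 12)
            plain = classify(rec, prefs, specs, nad)
            other = classify(scaled, scaled_prefs, specs, scaled_nad)
            assert plain.statuses == other.statuses
            assert plain.group == other.group
            assert plain.closeness == pytest.approx(other.closeness)


class TestMonotonicity:
    def test_relaxing_reservation_bound_never_shrinks_group_i(self, specs, rng):
        """Raising the binding upper bound of a minimized objective (or
        lowering the lower bound of a maximized one) preserves every
        existing group I member."""
        for _ in range(60):
            altset = random_alternative_set(rng, int(rng.integers(5, 40)), specs)
            nad = ideal_nadir(altset)
            prefs = make_prefs()
            spec = specs[int(rng.integers(0, len(specs)))]
            old = prefs.ranges[spec.key]
            slack = float(rng.uniform(0, 200))
            if spec.direction == "minimize":
                relaxed_bounds = (old.lower, old.upper + slack)
            else:
                relaxed_bounds = (old.lower - slack, old.upper)
            relaxed = make_prefs(**{spec.key: relaxed_bounds})

            before = {
                r.id for r in altset.records
                if classify(r, prefs, specs, nad).group == "I"
            }
            after = {
                r.id for r in altset.records
                if classify(r, relaxed, specs, nad).group == "I"
            }
            assert before <= after


class TestSelect:
    def test_k_validated(self, scenario, prefs_pair):
        with pytest.raises(ValueError):
            select(scenario, prefs_pair[0], 0)

    def test_group_i_comes_first_then_closest_group_ii(self, scenario, prefs_pair):
        result = select(scenario, prefs_pair[0], 4)
        groups = [c.group for c in result.selection]
        assert groups == sorted(groups)  # "I" sorts before "II"
        closeness = [c.closeness for c in result.group_ii]
        assert closeness == sorted(closeness)

    def test_k_larger_than_pool_returns_entire_pool(self, scenario, prefs_pair):
        result = select(scenario, prefs_pair[0], 100)
        assert len(result.selection) == len(pareto_front(scenario))

    def test_selection_invariant_under_row_permutation(self, specs, rng):
        altset = random_alternative_set(rng, 60, specs)
        prefs = make_prefs()
        base = select(altset, prefs, 5)
        order = rng.permutation(len(altset))
        shuffled = AlternativeSet(specs, [altset.records[i] for i in order])
        again = select(shuffled, prefs, 5)
        assert [c.record.id for c in base.selection] == [
            c.record.id for c in again.selection
        ]

    def test_restrict_to_front_excludes_dominated(self, specs):
        records = [
            vec_record("best", 100, 30, 30, 2, 10),
            vec_record("dominated", 900, 10, 10, 20, 20),
        ]
        altset = AlternativeSet(specs, records)
        prefs = make_prefs()
        assert len(select(altset, prefs, 4).selection) == 1
        assert len(select(altset, prefs, 4, restrict_to_front=False).selection) == 2

    def test_each_selected_item_carries_classification(self, scenario, prefs_pair):
        result = select(scenario, prefs_pair[1], 4)
        for cls in result.selection:
            assert set(cls.statuses) == set(scenario.objective_keys)
            assert cls.closeness >= 0
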