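"""1:1 age/sex matching: invariants, determinism, and agreement with an
exhaustive assignment oracle on small instances."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from obesnp.matching import match_indices, match_pairs, split_cases_controls

from conftest import mk_subject


def brute_force(case_keys, control_keys, tolerance):
    """Exhaustive search over injective assignments: maximize the number of
    pairs, then minimize the total age gap.  Feasible only for tiny inputs."""
    n_cases, n_controls = len(case_keys), len(control_keys)
    best = (0, 0.0)
    indices = list(range(n_controls)) + [None] * n_cases
    seen = set()
    for perm in itertools.permutations(indices, n_cases):
        if perm in seen:
            continue
        seen.add(perm)
        count, gap = 0, 0.0
        ok = True
        for i, j in enumerate(perm):
            if j is None:
                continue
            cs, ca, _ = case_keys[i]
            ks, ka, _ = control_keys[j]
            if cs != ks or abs(ca - ka) > tolerance:
                ok = False
                break
            count += 1
            gap += abs(ca - ka)
        if ok and (count > best[0] or (count == best[0] and gap < best[1])):
            best = (count, gap)
    return best


def random_instance(rng, n_cases, n_controls):
    cases = [("male" if rng.random() < 0.5 else "female", int(rng.integers(20, 81)), f"c{i}")
             for i in range(n_cases)]
    controls = [("male" if rng.random() < 0.5 else "female", int(rng.integers(20, 81)), f"k{i}")
                for i in range(n_controls)]
    return cases, controls


class TestMatchIndices:
    def test_perfect_fixture_fully_matched_with_zero_gap(self):
        cases = [("male", 30, "c1"), ("female", 50, "c2"), ("male", 61, "c3")]
        controls = [("female", 50, "k2"), ("male", 61, "k3"), ("male", 30, "k1")]
        pairs = match_indices(cases, controls, tolerance=3)
        assert len(pairs) == 3
        for i, j in pairs:
            assert cases[i][0] == controls[j][0]
            assert cases[i][1] == controls[j][1]

    def test_tolerance_boundary(self):
        cases = [("male", 50, "c")]
        assert match_indices(cases, [("male", 46, "k1"), ("male", 54, "k2")], 3) == []
        assert len(match_indices(cases, [("male", 47, "k")], 3)) == 1

    def test_nearest_age_preferred_with_ties_to_lower_age_then_id(self):
        cases = [("male", 50, "c")]
        controls = [("male", 52, "k_far"), ("male", 51, "k_b"), ("male", 49, "k_a")]
        ((_, j),) = match_indices(cases, controls, 3)
        assert controls[j][2] == "k_a"  # gap 1 tie -> lower age wins
        controls = [("male", 50, "k_z"), ("male", 50, "k_a")]
        ((_, j),) = match_indices(cases, controls, 3)
        assert controls[j][2] == "k_a"  # same age -> lexicographic id

    def test_contested_controls_match_exhaustive_optimum(self):
        """A fixture where early greedy choices must be re-routed: the
        pairing still reaches the brute-force optimum count and gap."""
        cases = [
            ("male", 22, "c1"),
            ("male", 26, "c2"),
            ("male", 40, "c3"),
            ("female", 60, "c4"),
            ("female", 63, "c5"),
        ]
        controls = [
            ("male", 23, "k1"),
            ("male", 19, "k2"),
            ("male", 40, "k3"),
            ("female", 63, "k4"),
            ("female", 57, "k5"),
        ]
        pairs = match_indices(cases, controls, tolerance=3)
        count, gap = brute_force(cases, controls, 3)
        assert len(pairs) == count == 5
        total = sum(abs(cases[i][1] - controls[j][1]) for i, j in pairs)
        assert total == gap

    @pytest.mark.parametrize("trial", range(40))
    def test_random_small_instances_attain_optimum_count(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_cases = int(rng.integers(1, 7))
        n_controls = int(rng.integers(1, 7))
        cases, controls = random_instance(rng, n_cases, n_controls)
        pairs = match_indices(cases, controls, tolerance=3)
        count, _ = brute_force(cases, controls, 3)
        assert len(pairs) == count
        # invariants: valid pairs, each subject used once
        assert len({i for i, _ in pairs}) == len(pairs)
        assert len({j for _, j in pairs}) == len(pairs)
        for i, j in pairs:
            assert cases[i][0] == controls[j][0]
            assert abs(cases[i][1] - controls[j][1]) <= 3

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(77)
        cases, controls = random_instance(rng, 30, 40)
        assert match_indices(cases, controls, 3) == match_indices(cases, controls, 3)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_indices([], [], -1)


class TestMatchPairs:
    def test_pairs_satisfy_invariants(self):
        cases = [mk_subject(sex="male", age=a, bmi=30.0) for a in (30, 44, 58)]
        controls = [mk_subject(sex="male", age=a, bmi=21.0) for a in (31, 43, 60, 70)]
        pairs, unmatched = match_pairs(cases, controls)
        assert len(pairs) == 3 and not unmatched
        ids = set()
        for p in pairs:
            assert p.case.sex == p.control.sex
            assert p.age_gap <= 3
            ids |= {p.case.id, p.control.id}
        assert len(ids) == 6

    def test_case_below_obesity_threshold_rejected(self):
        with pytest.raises(ValueError, match="case"):
            match_pairs([mk_subject(bmi=27.0)], [])

    def test_control_band_enforced_and_relaxable(self):
        underweight = mk_subject(sex="male", age=40, bmi=17.0)
        case = mk_subject(sex="male", age=40, bmi=30.0)
        with pytest.raises(ValueError, match="control"):
            match_pairs([case], [underweight])
        pairs, _ = match_pairs([case], [underweight], allow_underweight_controls=True)
        assert len(pairs) == 1

    def test_split_cases_controls(self):
        subjects = [
            mk_subject(bmi=30.0),
            mk_subject(bmi=25.0),
            mk_subject(bmi=20.0),
            mk_subject(bmi=17.0),
        ]
        cases, controls = split_cases_controls(subjects)
        assert len(cases) == 1 and len(controls) == 1
        _, controls_relaxed = split_cases_controls(subjects, allow_underweight_controls=True)
        assert len(controls_relaxed) == 2
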