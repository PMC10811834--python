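"""1:1 case-control matching on sex and age.

Cases (obesity, BMI >= 28) are paired with eligible controls of the same
sex within an age tolerance (default +/- 3 years).  The algorithm is a
deterministic greedy pass — cases processed in (sex, age, id) order, each
taking the unused eligible control with the smallest age gap, ties broken
by smaller control age then id — followed by an augmenting-path repair step
that re-routes earlier assignments whenever that lets an otherwise
unmatched case be paired.  The repair guarantees the maximum attainable
number of pairs while preserving the nearest-age flavour of the greedy
pass; it does not guarantee a globally minimal total age gap.

Controls default to the normal-weight band (18.5 <= BMI < 24); a flag
admits underweight subjects to honor a plain "BMI < 24" eligibility rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .datamodel import BMI_OBESITY_LOWER, BMI_OVERWEIGHT_LOWER, BMI_UNDERWEIGHT_UPPER, Subject


@dataclass(frozen=True)
class MatchedPair:
    """One case paired with one control of the same sex and similar age."""

    pair_id: int
    case: Subject
    control: Subject

    def __post_init__(self) -> None:
        if self.case.sex != self.control.sex:
            raise ValueError(f"pair {self.pair_id}: case and control differ in sex")

    @property
    def age_gap(self) -> int:
        return abs(self.case.age - self.control.age)


def match_indices(
    case_keys: Sequence[tuple[str, int, str]],
    control_keys: Sequence[tuple[str, int, str]],
    tolerance: int,
) -> list[tuple[int, int]]:
    """Core matcher on (sex, age, id) keys; returns (case_idx, control_idx)
    pairs.  Deterministic: greedy nearest-age pass plus augmenting-path
    repair to maximum cardinality."""
    if tolerance < 0:
        raise ValueError("matching tolerance must be >= 0")

    case_order = sorted(range(len(case_keys)), key=lambda i: case_keys[i])
    # bucket controls by (sex, age); within a bucket, ids ascending
    buckets: dict[tuple[str, int], list[int]] = {}
    for j, (sex, age, cid) in enumerate(control_keys):
        buckets.setdefault((sex, int(age)), []).append(j)
    for b in buckets.values():
        b.sort(key=lambda j: control_keys[j][2], reverse=True)  # pop() yields smallest id

    assigned_control_of_case: dict[int, int] = {}
    case_of_control: dict[int, int] = {}

    def candidate_ages(age: int) -> list[int]:
        # gap ascending, lower age before higher at equal gap
        out = [age]
        for g in range(1, tolerance + 1):
            out.extend([age - g, age + g])
        return out

    unmatched: list[int] = []
    for i in case_order:
        sex, age, _ = case_keys[i]
        age = int(age)
        chosen = None
        for a in candidate_ages(age):
            bucket = buckets.get((sex, a))
            if bucket:
                chosen = bucket.pop()
                break
        if chosen is None:
            unmatched.append(i)
        else:
            assigned_control_of_case[i] = chosen
            case_of_control[chosen] = i

    # augmenting-path repair (Kuhn): controls explored gap-then-age-then-id
    if unmatched:
        by_sex_age: dict[tuple[str, int], list[int]] = {}
        for j, (sex, age, cid) in enumerate(control_keys):
            by_sex_age.setdefault((sex, int(age)), []).append(j)
        for b in by_sex_age.values():
            b.sort(key=lambda j: control_keys[j][2])

        def all_eligible(i: int) -> list[int]:
            sex, age, _ = case_keys[i]
            out = []
            for a in candidate_ages(int(age)):
                out.extend(by_sex_age.get((sex, a), []))
            return out

        def try_augment(root: int) -> bool:
            # BFS for an augmenting path; via[j] = case whose exploration
            # first reached control j (iterative: safe for large inputs)
            via: dict[int, int] = {}
            visited: set[int] = set()
            queue = [root]
            qi = 0
            while qi < len(queue):
                i = queue[qi]
                qi += 1
                for j in all_eligible(i):
                    if j in visited:
                        continue
                    visited.add(j)
                    via[j] = i
                    holder = case_of_control.get(j)
                    if holder is None:
                        while True:  # flip assignments back along the path
                            i2 = via[j]
                            prev = assigned_control_of_case.get(i2)
                            assigned_control_of_case[i2] = j
                            case_of_control[j] = i2
                            if i2 == root:
                                return True
                            j = prev
                    queue.append(holder)
            return False

        for i in list(unmatched):
            if try_augment(i):
                unmatched.remove(i)

    pairs = sorted(assigned_control_of_case.items(), key=lambda kv: case_keys[kv[0]])
    return [(i, j) for i, j in pairs]


def _control_eligible(s: Subject, allow_underweight: bool) -> bool:
    if allow_underweight:
        return s.bmi < BMI_OVERWEIGHT_LOWER
    return BMI_UNDERWEIGHT_UPPER <= s.bmi < BMI_OVERWEIGHT_LOWER


def match_pairs(
    cases: Sequence[Subject],
    controls: Sequence[Subject],
    tolerance: int = 3,
    seed: Optional[int] = None,
    allow_underweight_controls: bool = False,
) -> tuple[list[MatchedPair], list[Subject]]:
    """Pair each obesity case with a same-sex control within the age
    tolerance; unmatched cases are returned rather than raised.

    Each subject appears in at most one pair.  ``seed`` is accepted for
    interface stability but unused: the algorithm is fully deterministic,
    so identical inputs always yield the identical pairing.

    Raises
    ------
    ValueError
        If the tolerance is negative, a case is not in the obesity class,
        or a control is outside its eligible BMI band.
    """
    if tolerance < 0:
        raise ValueError("matching tolerance must be >= 0")
    for s in cases:
        if s.bmi < BMI_OBESITY_LOWER:
            raise ValueError(f"case {s.id} has BMI {s.bmi} < {BMI_OBESITY_LOWER}")
    for s in controls:
        if not _control_eligible(s, allow_underweight_controls):
            raise ValueError(f"control {s.id} has BMI {s.bmi} outside the eligible band")

    case_keys = [(s.sex.value, s.age, s.id) for s in cases]
    control_keys = [(s.sex.value, s.age, s.id) for s in controls]
    index_pairs = match_indices(case_keys, control_keys, tolerance)
    matched_cases = {i for i, _ in index_pairs}
    pairs = [
        MatchedPair(pair_id=k, case=cases[i], control=controls[j])
        for k, (i, j) in enumerate(index_pairs)
    ]
    unmatched = [cases[i] for i in range(len(cases)) if i not in matched_cases]
    return pairs, unmatched


def split_cases_controls(
    subjects: Sequence[Subject], allow_underweight_controls: bool = False
) -> tuple[list[Subject], list[Subject]]:
    """Partition a classified sample into obesity cases and eligible
    controls (subjects in neither group are ignored)."""
    cases = [s for s in subjects if s.bmi >= BMI_OBESITY_LOWER]
    controls = [s for s in subjects if _control_eligible(s, allow_underweight_controls)]
    return cases, controls
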