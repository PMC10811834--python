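"""Crude, stratified, and directly standardized prevalence, plus the Pearson
chi-square machinery used for all between-group categorical comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    DEFAULT_AGE_BANDS,
    BmiClass,
    Sex,
    StandardPopulation,
    Subject,
    age_band_label,
)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A proportion with its numerator, denominator, and stratum labels."""

    numerator: int
    denominator: int
    stratum: tuple[Hashable, ...] = ()

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError("numerator exceeds denominator")
        if self.numerator < 0 or self.denominator < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def proportion(self) -> float:
        """Point estimate; NaN for an empty stratum (flagged, not dropped)."""
        if self.denominator == 0:
            return float("nan")
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion


Condition = Callable[[Subject], bool]


def is_obese(s: Subject) -> bool:
    return s.bmi_class is BmiClass.OBESITY


def is_overweight(s: Subject) -> bool:
    return s.bmi_class is BmiClass.OVERWEIGHT


def crude_prevalence(subjects: Sequence[Subject], condition: Condition) -> PrevalenceEstimate:
    """Proportion of all subjects meeting ``condition`` (denominator = full
    sample)."""
    if len(subjects) == 0:
        raise ValueError("cannot compute prevalence of an empty sample")
    num = sum(1 for s in subjects if condition(s))
    return PrevalenceEstimate(numerator=num, denominator=len(subjects))


def stratified_prevalence(
    subjects: Sequence[Subject],
    condition: Condition,
    strata: Callable[[Subject], tuple[Hashable, ...]],
    stratum_labels: Optional[Sequence[tuple[Hashable, ...]]] = None,
) -> list[PrevalenceEstimate]:
    """One estimate per stratum of the partition induced by ``strata``.

    ``stratum_labels`` fixes the set and order of strata; a listed stratum
    with no subjects yields a zero-denominator estimate (flagged via its NaN
    proportion) rather than being dropped.
    """
    if len(subjects) == 0:
        raise ValueError("cannot compute prevalence of an empty sample")
    groups: dict[tuple[Hashable, ...], list[Subject]] = {}
    for s in subjects:
        groups.setdefault(strata(s), []).append(s)
    labels = list(stratum_labels) if stratum_labels is not None else sorted(groups)
    out = []
    for label in labels:
        members = groups.get(label, [])
        num = sum(1 for s in members if condition(s))
        out.append(PrevalenceEstimate(numerator=num, denominator=len(members), stratum=label))
    return out


def by_sex(s: Subject) -> tuple[Hashable, ...]:
    return (s.sex.value,)


def sex_age_strata(bands=DEFAULT_AGE_BANDS) -> Callable[[Subject], tuple[Hashable, ...]]:
    def key(s: Subject) -> tuple[Hashable, ...]:
        return (s.sex.value, age_band_label(s.age, bands))

    return key


def direct_standardize(
    stratum_estimates: Sequence[PrevalenceEstimate],
    standard: StandardPopulation,
) -> float:
    """Directly standardized prevalence: sum_a w_a p_a / sum_a w_a over the
    (sex, age-band) strata, with weights from an external standard
    population.

    Every estimate must carry a ``(sex, age_band)`` stratum label matching a
    standard-population stratum.  A stratum with zero denominator but
    positive standard weight is an error (its rate is undefined yet would
    receive weight).
    """
    total_w = 0.0
    acc = 0.0
    for est in stratum_estimates:
        if len(est.stratum) != 2:
            raise ValueError(f"stratum label {est.stratum!r} is not (sex, age_band)")
        sex, band = est.stratum
        w = standard.weight(Sex(sex), str(band))
        if est.denominator == 0:
            if w > 0:
                raise ValueError(
                    f"stratum ({sex}, {band}) has no subjects but positive standard weight"
                )
            continue
        acc += w * est.proportion
        total_w += w
    if total_w <= 0:
        raise ValueError("standard weights over the supplied strata sum to zero")
    return acc / total_w


def pearson_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Accepts any 2-D array-like of nonnegative counts (a DataFrame keeps its
    labels out of the computation).  Returns (statistic, df, p).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table cells must be nonnegative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin; expected counts undefined")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


def format_p(p: float, floor: float = 1e-4) -> str:
    """Render a p-value the way the report tables do: 4 decimals, values
    below the floor as ``"<0.0001"``.  Full precision is kept internally."""
    if p < floor:
        return "<0.0001"
    return f"{p:.4f}"


def prevalence_report(
    subjects: Sequence[Subject],
    standard: Optional[StandardPopulation] = None,
    bands=DEFAULT_AGE_BANDS,
) -> pd.DataFrame:
    """Crude, sex-specific, age-specific, sex-x-age, and (when a standard
    population is given) directly standardized prevalence of obesity and
    overweight, as one tidy table."""
    rows = []
    conditions = [("obesity", is_obese), ("overweight", is_overweight)]
    band_labels = [f"{lo}-{hi}" for lo, hi in bands]
    for name, cond in conditions:
        crude = crude_prevalence(subjects, cond)
        rows.append(
            {
                "outcome": name,
                "stratum": "overall",
                "numerator": crude.numerator,
                "denominator": crude.denominator,
                "percent": crude.percent,
            }
        )
        for est in stratified_prevalence(
            subjects, cond, by_sex, [(s.value,) for s in Sex]
        ):
            rows.append(
                {
                    "outcome": name,
                    "stratum": est.stratum[0],
                    "numerator": est.numerator,
                    "denominator": est.denominator,
                    "percent": est.percent,
                }
            )
        sexage = stratified_prevalence(
            subjects,
            cond,
            sex_age_strata(bands),
            [(s.value, b) for s in Sex for b in band_labels],
        )
        for est in sexage:
            rows.append(
                {
                    "outcome": name,
                    "stratum": f"{est.stratum[0]}:{est.stratum[1]}",
                    "numerator": est.numerator,
                    "denominator": est.denominator,
                    "percent": est.percent,
                }
            )
        if standard is not None:
            std = direct_standardize(sexage, standard)
            rows.append(
                {
                    "outcome": name,
                    "stratum": "standardized",
                    "numerator": np.nan,
                    "denominator": np.nan,
                    "percent": 100.0 * std,
                }
            )
    return pd.DataFrame(rows)
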