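"""Allele/genotype summaries, Hardy-Weinberg testing, case-control
contingency tests, and inheritance-model design coding.

All chi-square tests are asymptotic Pearson tests without continuity
correction.  The Hardy-Weinberg test compares observed genotype counts with
the (p^2, 2pq, q^2) expectation at the estimated allele frequency and uses
one degree of freedom (one frequency estimated from the data); it is
conventionally evaluated in the control group, where genotype frequencies
should reflect the source population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import Subject

INHERITANCE_MODELS = ("dominant", "recessive", "codominant", "additive")

#: Design values per effect-allele dosage (0, 1, 2) for single-column models.
_SINGLE_COLUMN_CODING = {
    "dominant": (0, 1, 1),
    "recessive": (0, 0, 1),
    "additive": (0, 1, 2),
}


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one SNP: hom-ref / het / hom-effect."""

    snp_id: str
    n_hom_ref: int
    n_het: int
    n_hom_effect: int

    def __post_init__(self) -> None:
        for n in (self.n_hom_ref, self.n_het, self.n_hom_effect):
            if n < 0:
                raise ValueError(f"{self.snp_id}: negative genotype count")
        if self.total == 0:
            raise ValueError(f"{self.snp_id}: empty genotype counts")

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_effect

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_hom_ref, self.n_het, self.n_hom_effect)

    @classmethod
    def from_subjects(cls, subjects: Iterable[Subject], snp_id: str) -> "GenotypeCounts":
        """Tally effect-allele dosages over subjects with a non-missing call."""
        tallies = [0, 0, 0]
        for s in subjects:
            c = s.genotype_count(snp_id)
            if c is not None:
                tallies[c] += 1
        return cls(snp_id, *tallies)


def allele_counts(gc: GenotypeCounts) -> tuple[int, int, float]:
    """Collapse genotype counts to allele counts.

    Returns ``(n_ref_alleles, n_effect_alleles, effect_allele_freq)``; the
    two counts always sum to twice the number of genotyped subjects.
    """
    n_effect = 2 * gc.n_hom_effect + gc.n_het
    n_ref = 2 * gc.n_hom_ref + gc.n_het
    return n_ref, n_effect, n_effect / (2 * gc.total)


def hwe_test(gc: GenotypeCounts) -> tuple[float, float]:
    """Asymptotic chi-square test of Hardy-Weinberg equilibrium (df = 1).

    Expected counts are n*(p^2, 2pq, q^2) at the allele frequency estimated
    from the same counts; one degree of freedom is spent on that estimate.

    Raises
    ------
    ValueError
        If the SNP is monomorphic (the test is undefined).
    """
    n_ref, n_effect, q = allele_counts(gc)
    if n_ref == 0 or n_effect == 0:
        raise ValueError(f"{gc.snp_id}: monomorphic genotype counts, HWE test undefined")
    p = 1.0 - q
    n = gc.total
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.asarray(gc.counts, dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def case_control_genotype_test(
    gc_case: GenotypeCounts, gc_control: GenotypeCounts
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2x3 genotype table (df = 2), no correction."""
    table = np.array([gc_case.counts, gc_control.counts], dtype=float)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def case_control_allele_test(
    gc_case: GenotypeCounts, gc_control: GenotypeCounts
) -> tuple[float, int, float, float]:
    """Pearson chi-square on the 2x2 allele table plus the allelic odds ratio.

    The odds ratio is the cross-product (case effect x control ref) /
    (case ref x control effect); a zero cell gets the Haldane-Anscombe 0.5
    correction for the OR only — the chi-square itself is uncorrected.
    """
    case_ref, case_eff, _ = allele_counts(gc_case)
    ctrl_ref, ctrl_eff, _ = allele_counts(gc_control)
    table = np.array([[case_ref, case_eff], [ctrl_ref, ctrl_eff]], dtype=float)
    if (case_ref + ctrl_ref) == 0 or (case_eff + ctrl_eff) == 0:
        raise ValueError(f"{gc_case.snp_id}: pooled sample monomorphic, allele test undefined")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    cells = [case_eff, ctrl_ref, case_ref, ctrl_eff]
    if any(c == 0 for c in cells):
        cells = [c + 0.5 for c in cells]
    allelic_or = (cells[0] * cells[1]) / (cells[2] * cells[3])
    return float(chi2), int(df), float(p), float(allelic_or)


def encode(genotype_count: int, model: str):
    """Map an effect-allele dosage to its design value under an inheritance
    model.

    Single-column models return a scalar: dominant (0,1,1), recessive
    (0,0,1), additive (0,1,2).  The codominant model returns two indicators
    (het, hom-effect) against the hom-ref reference.
    """
    if genotype_count not in (0, 1, 2):
        raise ValueError(f"genotype count must be 0, 1 or 2, got {genotype_count!r}")
    if model == "codominant":
        return (int(genotype_count == 1), int(genotype_count == 2))
    try:
        coding = _SINGLE_COLUMN_CODING[model]
    except KeyError:
        raise ValueError(f"unknown inheritance model {model!r}") from None
    return coding[genotype_count]


def encode_array(genotype_counts: Sequence[int] | np.ndarray, model: str) -> np.ndarray:
    """Vectorized :func:`encode`; returns an (n,) or (n, 2) array."""
    g = np.asarray(genotype_counts)
    if model == "codominant":
        return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
    coding = np.asarray(_SINGLE_COLUMN_CODING[model], dtype=float)
    return coding[g.astype(int)]


def model_column_names(snp_id: str, model: str) -> list[str]:
    if model == "codominant":
        return [f"{snp_id}_het", f"{snp_id}_hom"]
    return [f"{snp_id}_{model}"]


def snp_association_table(
    case_counts: dict[str, GenotypeCounts],
    control_counts: dict[str, GenotypeCounts],
    hwe_group: str = "control",
) -> "np.typing.NDArray | object":
    """Per-SNP summary table: genotype and allele counts/frequencies in both
    groups, case-control genotype and allele p-values, allelic OR, and the
    HWE p-value (evaluated in the control group by default)."""
    import pandas as pd

    rows = []
    for snp_id, gc_case in case_counts.items():
        gc_ctrl = control_counts[snp_id]
        _, _, freq_case = allele_counts(gc_case)
        _, _, freq_ctrl = allele_counts(gc_ctrl)
        chi2_g, df_g, p_g = case_control_genotype_test(gc_case, gc_ctrl)
        chi2_a, df_a, p_a, allelic_or = case_control_allele_test(gc_case, gc_ctrl)
        hwe_counts = gc_ctrl if hwe_group == "control" else gc_case
        _, p_hwe = hwe_test(hwe_counts)
        rows.append(
            {
                "snp": snp_id,
                "case_hom_ref": gc_case.n_hom_ref,
                "case_het": gc_case.n_het,
                "case_hom_eff": gc_case.n_hom_effect,
                "control_hom_ref": gc_ctrl.n_hom_ref,
                "control_het": gc_ctrl.n_het,
                "control_hom_eff": gc_ctrl.n_hom_effect,
                "case_effect_freq": freq_case,
                "control_effect_freq": freq_ctrl,
                "genotype_p": p_g,
                "allele_p": p_a,
                "allelic_or": allelic_or,
                "hwe_p": p_hwe,
            }
        )
    return pd.DataFrame(rows)
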