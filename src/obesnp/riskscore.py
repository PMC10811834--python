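"""Genetic risk scores and their tertile-based association with obesity.

The unweighted score (GRS) is the total number of risk (effect) alleles
over the SNP panel, 0-8 for four SNPs.  The weighted score (wGRS) replaces
each allele count by count x log(OR) with per-SNP odds-ratio weights; by
default the weights are the panel's own additive-model conditional-logistic
log-ORs estimated from the matched sample (external weights may be
supplied instead).  Scores are cut at the empirical tertiles of the pooled
case + control sample and the top two tertile indicators are entered into
an adjusted conditional logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import DEFAULT_SNP_IDS, Subject
from .matching import MatchedPair
from .regression import RegressionFit, fit_conditional_logistic, pair_design

TERTILE_LABELS = ("T1", "T2", "T3")


def compute_grs(subject: Subject, snp_ids: Sequence[str] = DEFAULT_SNP_IDS) -> int:
    """Unweighted risk score: sum of effect-allele counts over the panel.

    Raises
    ------
    ValueError
        If any panel genotype is missing (complete-case scoring; the caller
        excludes and logs such subjects).
    """
    total = 0
    for snp_id in snp_ids:
        c = subject.genotype_count(snp_id)
        if c is None:
            raise ValueError(f"subject {subject.id}: missing genotype at {snp_id}")
        total += c
    return total


def compute_wgrs(subject: Subject, weights: Mapping[str, float]) -> float:
    """Weighted risk score: sum of count_i * w_i with per-SNP log-OR weights
    (each weight must be positive, i.e. OR > 1)."""
    total = 0.0
    for snp_id, w in weights.items():
        if w <= 0:
            raise ValueError(f"weight for {snp_id} must be a positive log-OR, got {w}")
        c = subject.genotype_count(snp_id)
        if c is None:
            raise ValueError(f"subject {subject.id}: missing genotype at {snp_id}")
        total += c * w
    return total


@dataclass(frozen=True)
class TertileAssignment:
    labels: tuple[str, ...]
    cutpoints: tuple[float, float]


def tertile_groups(scores: Sequence[float]) -> TertileAssignment:
    """Cut scores at the empirical 1/3 and 2/3 quantiles of the pooled
    sample; a score tied with a cutpoint goes to the lower group.

    Raises
    ------
    ValueError
        If fewer than 3 distinct values are present (tertiles undefined).
    """
    arr = np.asarray(scores, dtype=float)
    if len(np.unique(arr)) < 3:
        raise ValueError("tertiles undefined: fewer than 3 distinct score values")
    q1, q2 = np.quantile(arr, [1 / 3, 2 / 3])
    labels = np.where(arr <= q1, "T1", np.where(arr <= q2, "T2", "T3"))
    return TertileAssignment(labels=tuple(labels), cutpoints=(float(q1), float(q2)))


def additive_logor_weights(
    pairs: Sequence[MatchedPair],
    covariates: Sequence[str] = (),
    snp_ids: Sequence[str] = DEFAULT_SNP_IDS,
) -> dict[str, float]:
    """Per-SNP additive-model conditional-logistic log-ORs from the matched
    sample itself, floored at a small positive value so they remain valid
    wGRS weights even for a SNP whose estimated OR dips below 1."""
    weights = {}
    for snp_id in snp_ids:
        extra_case = pd.DataFrame({f"{snp_id}_additive": [p.case.genotype_count(snp_id) for p in pairs]})
        extra_control = pd.DataFrame(
            {f"{snp_id}_additive": [p.control.genotype_count(snp_id) for p in pairs]}
        )
        design = pair_design(pairs, covariates, extra_case, extra_control)
        fit = fit_conditional_logistic(design)
        weights[snp_id] = max(fit.coef(f"{snp_id}_additive"), 1e-6)
    return weights


def score_pairs(
    pairs: Sequence[MatchedPair],
    weights: Optional[Mapping[str, float]] = None,
    snp_ids: Sequence[str] = DEFAULT_SNP_IDS,
) -> pd.DataFrame:
    """GRS (and wGRS when weights are given) for every member of every
    pair; pairs with a missing panel genotype on either side are excluded
    (complete-case) and reported in the ``excluded`` attribute."""
    rows = []
    excluded = []
    for p in pairs:
        try:
            rec = {
                "pair_id": p.pair_id,
                "case_grs": compute_grs(p.case, snp_ids),
                "control_grs": compute_grs(p.control, snp_ids),
            }
            if weights is not None:
                rec["case_wgrs"] = compute_wgrs(p.case, weights)
                rec["control_wgrs"] = compute_wgrs(p.control, weights)
            rows.append(rec)
        except ValueError:
            excluded.append(p.pair_id)
    df = pd.DataFrame(rows)
    df.attrs["excluded"] = excluded
    return df


def score_association(
    pairs: Sequence[MatchedPair],
    scores: pd.DataFrame,
    score_col: str = "grs",
    covariates: Sequence[str] = (),
) -> tuple[RegressionFit, TertileAssignment]:
    """Conditional logistic association between score tertiles and obesity.

    Tertiles are computed on the pooled case + control scores; indicators
    for T2 and T3 (vs T1) enter the model alongside the adjustment
    covariates.  Returns the fit together with the tertile cutpoints.
    """
    by_pair = {int(r["pair_id"]): r for _, r in scores.iterrows()}
    kept = [p for p in pairs if p.pair_id in by_pair]
    case_scores = [by_pair[p.pair_id][f"case_{score_col}"] for p in kept]
    control_scores = [by_pair[p.pair_id][f"control_{score_col}"] for p in kept]
    assignment = tertile_groups(list(case_scores) + list(control_scores))
    labels = np.asarray(assignment.labels)
    case_labels, control_labels = labels[: len(kept)], labels[len(kept):]

    def indicators(lbls) -> pd.DataFrame:
        return pd.DataFrame(
            {
                f"{score_col}_t2": (lbls == "T2").astype(float),
                f"{score_col}_t3": (lbls == "T3").astype(float),
            }
        )

    design = pair_design(kept, covariates, indicators(case_labels), indicators(control_labels))
    fit = fit_conditional_logistic(design)
    return fit, assignment
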