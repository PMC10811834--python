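"""Gene-environment interaction on the multiplicative and additive scales.

The genotype enters under dominant coding (carrier of at least one effect
allele) and the environmental exposure as a binary indicator.  Two
parameterizations of the joint effect are used:

* product:   logit = b_G * G + b_E * E + b_GE * G*E (+ covariates); the
  Wald test of ``b_GE`` is the multiplicative-interaction test;
* joint:     indicators for (G+E-), (G-E+), (G+E+) against the doubly
  unexposed reference; writing OR10, OR01, OR11 for the three exponentiated
  coefficients, the additive-interaction measures are

      RERI = OR11 - OR10 - OR01 + 1
      AP   = RERI / OR11
      SI   = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))

  with delta-method confidence intervals (SI via its logarithm).  An
  interaction is flagged "present" only when the RERI and AP intervals
  exclude 0 and the SI interval excludes 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matching import MatchedPair
from .regression import RegressionFit, fit_conditional_logistic, pair_design

JOINT_NAMES = ("g_only", "e_only", "g_and_e")


def joint_coding(dominant_genotype, binary_env) -> pd.DataFrame:
    """Three joint-exposure indicator columns (G+E-, G-E+, G+E+) against the
    G-E- baseline, from a binary genotype carrier indicator and a binary
    environmental indicator."""
    g = np.asarray(dominant_genotype, dtype=float)
    e = np.asarray(binary_env, dtype=float)
    for arr, label in ((g, "genotype"), (e, "environment")):
        if set(np.unique(arr)) - {0.0, 1.0}:
            raise ValueError(f"{label} indicator must be binary 0/1")
    return pd.DataFrame(
        {
            JOINT_NAMES[0]: g * (1 - e),
            JOINT_NAMES[1]: (1 - g) * e,
            JOINT_NAMES[2]: g * e,
        }
    )


@dataclass(frozen=True)
class InteractionEstimate:
    """Additive-interaction measures with delta-method CIs, plus the
    multiplicative Wald p-value."""

    reri: float
    reri_ci: tuple[float, float]
    ap: float
    ap_ci: tuple[float, float]
    si: Optional[float]
    si_ci: Optional[tuple[float, float]]
    multiplicative_p: Optional[float]
    present: bool

    @property
    def si_defined(self) -> bool:
        return self.si is not None


def additive_interaction(
    fit: RegressionFit,
    names: Sequence[str] = JOINT_NAMES,
    alpha: float = 0.05,
    multiplicative_p: Optional[float] = None,
) -> InteractionEstimate:
    """RERI / AP / SI with delta-method CIs from a converged joint-coding
    fit.

    Gradients are taken with respect to the three joint-coding coefficients
    (b10, b01, b11):

        RERI:  (-OR10, -OR01, OR11)
        AP:    quotient rule on RERI / OR11
        ln SI: (-OR10/d, -OR01/d, OR11/(OR11 - 1)),  d = OR10 + OR01 - 2

    When OR10 + OR01 <= 2 the SI denominator is non-positive and SI is
    reported as undefined (None); RERI and AP are still returned.
    """
    if not fit.converged:
        raise ValueError("additive interaction requires a converged fit")
    b10, b01, b11 = (fit.coef(n) for n in names)
    cov = fit.subcov(names)
    or10, or01, or11 = np.exp([b10, b01, b11])
    z = stats.norm.ppf(1 - alpha / 2)

    def delta_ci(value: float, grad: np.ndarray) -> tuple[float, float]:
        var = float(grad @ cov @ grad)
        half = z * np.sqrt(var)
        return (value - half, value + half)

    reri = or11 - or10 - or01 + 1
    reri_ci = delta_ci(reri, np.array([-or10, -or01, or11]))

    ap = reri / or11
    # AP = 1 - e^(b10-b11) - e^(b01-b11) + e^(-b11)
    g_ap = np.array(
        [
            -np.exp(b10 - b11),
            -np.exp(b01 - b11),
            np.exp(b10 - b11) + np.exp(b01 - b11) - np.exp(-b11),
        ]
    )
    ap_ci = delta_ci(ap, g_ap)

    si: Optional[float] = None
    si_ci: Optional[tuple[float, float]] = None
    denom = (or10 - 1) + (or01 - 1)
    if denom > 0 and or11 > 1:
        si = (or11 - 1) / denom
        g_lnsi = np.array([-or10 / denom, -or01 / denom, or11 / (or11 - 1)])
        lo, hi = delta_ci(float(np.log(si)), g_lnsi)
        si_ci = (float(np.exp(lo)), float(np.exp(hi)))

    present = (
        (reri_ci[0] > 0 or reri_ci[1] < 0)
        and (ap_ci[0] > 0 or ap_ci[1] < 0)
        and si_ci is not None
        and (si_ci[0] > 1 or si_ci[1] < 1)
    )
    return InteractionEstimate(
        reri=float(reri),
        reri_ci=(float(reri_ci[0]), float(reri_ci[1])),
        ap=float(ap),
        ap_ci=(float(ap_ci[0]), float(ap_ci[1])),
        si=si,
        si_ci=si_ci,
        multiplicative_p=multiplicative_p,
        present=bool(present),
    )


def multiplicative_interaction(fit: RegressionFit, term: str = "product") -> tuple[float, float]:
    """Wald z and two-sided p for the product-term coefficient."""
    if not fit.converged:
        raise ValueError("multiplicative interaction requires a converged fit")
    return fit.wald(term)


def _binary_columns(pairs: Sequence[MatchedPair], snp_id: str, env_attr: str, env_level: str):
    g_case = np.array([(p.case.genotype_count(snp_id) or 0) > 0 for p in pairs], dtype=float)
    g_ctrl = np.array([(p.control.genotype_count(snp_id) or 0) > 0 for p in pairs], dtype=float)
    e_case = np.array(
        [getattr(p.case, env_attr).value == env_level for p in pairs], dtype=float
    )
    e_ctrl = np.array(
        [getattr(p.control, env_attr).value == env_level for p in pairs], dtype=float
    )
    return g_case, g_ctrl, e_case, e_ctrl


#: Default dichotomizations of the behavioural exposures: the level whose
#: presence defines "exposed" for each covariate.
DEFAULT_EXPOSURES: dict[str, tuple[str, str]] = {
    "smoking_current": ("smoking", "current"),
    "drinking_current": ("drinking", "current"),
    "occupational_pa_heavy": ("occupational_pa", "heavy"),
    "leisure_exercise_heavy": ("leisure_exercise", "heavy"),
}


def gene_environment_analysis(
    pairs: Sequence[MatchedPair],
    snp_id: str,
    exposure: str,
    covariates: Sequence[str] = (),
    alpha: float = 0.05,
) -> InteractionEstimate:
    """Full additive + multiplicative interaction analysis for one SNP
    (dominant coding) and one binary behavioural exposure on matched pairs.

    ``exposure`` names an entry of :data:`DEFAULT_EXPOSURES` (e.g.
    ``"smoking_current"``).  Adjustment covariates enter both fits.  Pairs
    with a missing genotype at the SNP are excluded.
    """
    env_attr, env_level = DEFAULT_EXPOSURES[exposure]
    # the joint coding already encodes the exposure, so its parent covariate
    # must leave the adjustment set to keep the design full rank
    covariates = [c for c in covariates if c != env_attr]
    kept = [p for p in pairs if p.case.genotype_count(snp_id) is not None
            and p.control.genotype_count(snp_id) is not None]
    g_case, g_ctrl, e_case, e_ctrl = _binary_columns(kept, snp_id, env_attr, env_level)

    joint = pair_design(
        kept, covariates, joint_coding(g_case, e_case), joint_coding(g_ctrl, e_ctrl)
    )
    joint_fit = fit_conditional_logistic(joint)

    def product_cols(g, e) -> pd.DataFrame:
        return pd.DataFrame({"genotype": g, "environment": e, "product": g * e})

    product = pair_design(kept, covariates, product_cols(g_case, e_case), product_cols(g_ctrl, e_ctrl))
    product_fit = fit_conditional_logistic(product)
    _, mult_p = multiplicative_interaction(product_fit, "product")
    return additive_interaction(joint_fit, alpha=alpha, multiplicative_p=mult_p)
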