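"""Synthetic population generator.

Generates cross-sectional samples with the statistical structure the
analysis pipeline assumes: independent categorical covariates drawn from
specified marginal distributions, genotypes drawn per SNP as
Binomial(2, effect-allele frequency) — exact Hardy-Weinberg equilibrium in
expectation — and an obesity indicator drawn from a multiplicative
(logistic) risk model on the covariates and additive genotype dosages, with
optional gene-environment product terms.  BMI values are then drawn uniform
within the band implied by the assigned weight class, since only the class
matters downstream.

The default specification reproduces the marginal covariate distribution,
control-group allele frequencies, and reported covariate/genotype odds
ratios of a survey of 1741 Tibetan adults; odds ratios the survey did not
print (non-significant terms) default to values near 1.  Covariates are
generated independently — the real joint distribution is not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import refdata
from .datamodel import (
    DEFAULT_AGE_BANDS,
    DEFAULT_SNPS,
    BmiClass,
    GenotypeCall,
    SnpDef,
    Subject,
)
from .regression import CATEGORICAL_LEVELS, build_design

#: BMI sampling intervals per weight class (kg/m2, uniform draw).
_BMI_RANGES = {
    BmiClass.UNDERWEIGHT: (16.0, 18.5),
    BmiClass.NORMAL: (18.5, 24.0),
    BmiClass.OVERWEIGHT: (24.0, 28.0),
    BmiClass.OBESITY: (28.0, 35.0),
}

#: Intercept calibrated so the default model's marginal obesity prevalence
#: equals the survey's crude 19.47% under the default effect sizes.
DEFAULT_INTERCEPT = -4.13225


@dataclass
class GeneratorSpec:
    """Everything needed to generate a synthetic population."""

    n_subjects: int = 1741
    seed: int = 0
    #: P(sex = male).
    sex_male_prob: float = refdata.N_MALE / refdata.N_TOTAL
    #: Category probabilities per categorical covariate, in the level order
    #: of :data:`obesnp.regression.CATEGORICAL_LEVELS`.
    category_probs: dict[str, tuple[float, ...]] = field(default_factory=dict)
    #: Per-SNP effect-allele frequency (HWE assumed).
    effect_allele_freq: dict[str, float] = field(default_factory=dict)
    #: Obesity log-odds model: intercept plus coefficients keyed by design
    #: column name (e.g. ``"sex_male"``, ``"age_band_50_59"``,
    #: ``"smoking_current"``) or by SNP id for additive dosage effects.
    intercept: float = DEFAULT_INTERCEPT
    log_odds: dict[str, float] = field(default_factory=dict)
    #: Optional gene-environment product terms: (snp_id, env_column) ->
    #: log-OR applied to dominant(genotype) * env indicator.
    gxe_log_odds: dict[tuple[str, str], float] = field(default_factory=dict)
    #: Weight-class split among the non-obese (underweight, normal,
    #: overweight); obesity itself comes from the logistic model.
    nonobese_class_probs: tuple[float, float, float] = (0.04, 0.542, 0.418)
    snp_defs: tuple[SnpDef, ...] = DEFAULT_SNPS
    age_bands: tuple[tuple[int, int], ...] = DEFAULT_AGE_BANDS

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0 <= self.sex_male_prob <= 1:
            raise ValueError("sex_male_prob must lie in [0, 1]")
        for cov, probs in self.category_probs.items():
            p = np.asarray(probs, dtype=float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{cov}: category probabilities must lie in [0,1] and sum to 1")
        for snp, q in self.effect_allele_freq.items():
            if not 0 < q < 1:
                raise ValueError(f"{snp}: allele frequency must lie strictly in (0, 1)")
        if abs(sum(self.nonobese_class_probs) - 1.0) > 1e-9:
            raise ValueError("nonobese_class_probs must sum to 1")
        # a model term referencing a zero-probability category can never vary
        for name, beta in self.log_odds.items():
            if beta != 0.0 and self._term_probability(name) == 0.0:
                raise ValueError(f"model term {name!r} references a zero-probability category")

    def _term_probability(self, name: str) -> float:
        if name == "sex_male":
            return self.sex_male_prob
        if name in self.effect_allele_freq:
            return self.effect_allele_freq[name]
        for cov, levels in CATEGORICAL_LEVELS.items():
            for i, level in enumerate(levels):
                if name == f"{cov}_{level.replace('-', '_')}":
                    probs = self.category_probs.get(cov)
                    return 1.0 if probs is None else float(probs[i])
        return 1.0  # unknown names are validated later, at design time


def _survey_probs(covariate: str) -> tuple[float, ...]:
    counts = refdata.SURVEY_MARGINALS[covariate]
    total = sum(counts.values())
    return tuple(c / total for c in counts.values())


def default_spec(n_subjects: int = 1741, seed: int = 0) -> GeneratorSpec:
    """The reference generator specification.

    Marginals follow the survey's covariate distribution; effect-allele
    frequencies are the control-group minor-allele frequencies; the obesity
    model uses the survey's reported adjusted odds ratios (male sex 2.33,
    age 50-59 vs 20-29 12.22, current smoking 0.44, heavy occupational
    activity 0.79, heavy leisure-time exercise 1.55, MC4R additive 1.45 and
    1.42) with unreported terms set to modest defaults.
    """
    category_probs = {
        cov: _survey_probs(cov)
        for cov in (
            "age_band",
            "residence",
            "income",
            "education",
            "smoking",
            "drinking",
            "occupational_pa",
            "leisure_exercise",
        )
    }
    effect_allele_freq = {
        snp_id: 1.0 - _control_ref_freq(snp_id) for snp_id in refdata.CONTROL_GENOTYPES
    }
    log_odds = {
        "sex_male": np.log(2.33),
        "age_band_30_39": np.log(3.0),
        "age_band_40_49": np.log(7.0),
        "age_band_50_59": np.log(12.22),
        "age_band_60_80": np.log(11.0),
        "smoking_current": np.log(0.44),
        "occupational_pa_heavy": np.log(0.79),
        "leisure_exercise_heavy": np.log(1.55),
        "rs17782313": np.log(1.45),
        "rs12970134": np.log(1.42),
        "rs1121980": np.log(1.10),
        "rs17817449": np.log(1.05),
    }
    return GeneratorSpec(
        n_subjects=n_subjects,
        seed=seed,
        category_probs=category_probs,
        effect_allele_freq=effect_allele_freq,
        intercept=DEFAULT_INTERCEPT,
        log_odds=log_odds,
    )


def _control_ref_freq(snp_id: str) -> float:
    from .genetics import allele_counts

    _, _, eff = allele_counts(refdata.CONTROL_GENOTYPES[snp_id])
    return 1.0 - eff


def generate_frame(spec: GeneratorSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a population as an analysis DataFrame (vectorized).

    One numpy Generator seeded from ``seed`` (default ``spec.seed``) governs
    every draw, so a fixed seed gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    df = pd.DataFrame(index=range(n))
    df["id"] = [f"S{i:06d}" for i in range(n)]
    df["sex"] = np.where(rng.random(n) < spec.sex_male_prob, "male", "female")

    for cov in (
        "age_band",
        "residence",
        "income",
        "education",
        "smoking",
        "drinking",
        "occupational_pa",
        "leisure_exercise",
    ):
        levels = CATEGORICAL_LEVELS[cov]
        probs = spec.category_probs.get(cov)
        p = np.full(len(levels), 1.0 / len(levels)) if probs is None else np.asarray(probs)
        p = p / p.sum()
        idx = rng.choice(len(levels), size=n, p=p)
        df[cov] = np.asarray(levels, dtype=object)[idx]

    # integer age uniform within the drawn band
    band_edges = {f"{lo}-{hi}": (lo, hi) for lo, hi in spec.age_bands}
    lo = df["age_band"].map(lambda b: band_edges[b][0]).to_numpy()
    hi = df["age_band"].map(lambda b: band_edges[b][1]).to_numpy()
    df["age"] = rng.integers(lo, hi + 1)

    for snp in spec.snp_defs:
        q = spec.effect_allele_freq.get(snp.snp_id)
        if q is None:
            raise ValueError(f"no effect-allele frequency for {snp.snp_id}")
        df[snp.snp_id] = rng.binomial(2, q, size=n).astype(float)

    # linear predictor from the same design coding the fitting module uses
    lp = np.full(n, spec.intercept)
    model_covs = sorted(
        {name for name in spec.log_odds if name not in spec.effect_allele_freq}
    )
    if model_covs:
        # identify which categorical covariates are referenced and build
        # their full dummy expansion once
        referenced = []
        for cov in CATEGORICAL_LEVELS:
            prefix = f"{cov}_"
            if any(m.startswith(prefix) for m in model_covs):
                referenced.append(cov)
        design = build_design(df, referenced)
        for name in model_covs:
            if name not in design.columns:
                raise ValueError(f"unknown model term {name!r}")
            lp += spec.log_odds[name] * design[name].to_numpy()
    for snp_id, q in spec.effect_allele_freq.items():
        beta = spec.log_odds.get(snp_id, 0.0)
        if beta:
            lp += beta * df[snp_id].to_numpy()
    if spec.gxe_log_odds:
        env_design = build_design(df, list(CATEGORICAL_LEVELS))
        for (snp_id, env_col), beta in spec.gxe_log_odds.items():
            dominant = (df[snp_id].to_numpy() > 0).astype(float)
            lp += beta * dominant * env_design[env_col].to_numpy()

    prob = 1.0 / (1.0 + np.exp(-lp))
    obese = rng.random(n) < prob

    # weight class: obesity from the model, the rest split per spec
    classes = np.empty(n, dtype=object)
    classes[obese] = BmiClass.OBESITY.value
    n_rest = int((~obese).sum())
    rest_idx = rng.choice(3, size=n_rest, p=np.asarray(spec.nonobese_class_probs))
    rest_classes = np.asarray(
        [BmiClass.UNDERWEIGHT.value, BmiClass.NORMAL.value, BmiClass.OVERWEIGHT.value],
        dtype=object,
    )[rest_idx]
    classes[~obese] = rest_classes
    df["bmi_class"] = classes
    lo_bmi = np.array([_BMI_RANGES[BmiClass(c)][0] for c in classes])
    hi_bmi = np.array([_BMI_RANGES[BmiClass(c)][1] for c in classes])
    # round for realism, then clip so rounding can never cross a class boundary
    bmi = np.round(lo_bmi + rng.random(n) * (hi_bmi - lo_bmi), 2)
    df["bmi"] = np.clip(bmi, lo_bmi, hi_bmi - 0.01)
    df["obese"] = obese.astype(int)
    return df


def generate_population(spec: GeneratorSpec, seed: Optional[int] = None) -> list[Subject]:
    """Generate a population as validated :class:`Subject` objects."""
    df = generate_frame(spec, seed=seed)
    return frame_to_subjects(df, spec.snp_defs)


def frame_to_subjects(df: pd.DataFrame, snp_defs: Sequence[SnpDef] = DEFAULT_SNPS) -> list[Subject]:
    """Convert a generated frame into Subject objects (raw genotype strings
    are reconstructed as effect-allele-last, e.g. dosage 1 -> "T/C")."""
    from .datamodel import (
        ActivityLevel,
        DrinkingStatus,
        Education,
        Income,
        Residence,
        Sex,
        SmokingStatus,
    )

    subjects = []
    records = df.to_dict("records")
    for rec in records:
        genotypes = {}
        for snp in snp_defs:
            dosage = rec.get(snp.snp_id)
            if dosage is None or (isinstance(dosage, float) and np.isnan(dosage)):
                continue
            dosage = int(dosage)
            alleles = [snp.reference_allele] * (2 - dosage) + [snp.effect_allele] * dosage
            genotypes[snp.snp_id] = GenotypeCall(snp.snp_id, dosage, "/".join(alleles))
        subjects.append(
            Subject(
                id=str(rec["id"]),
                sex=Sex(rec["sex"]),
                age=int(rec["age"]),
                bmi=float(rec["bmi"]),
                residence=Residence(rec["residence"]),
                income=Income(rec["income"]),
                education=Education(rec["education"]),
                smoking=SmokingStatus(rec["smoking"]),
                drinking=DrinkingStatus(rec["drinking"]),
                occupational_pa=ActivityLevel(rec["occupational_pa"]),
                leisure_exercise=ActivityLevel(rec["leisure_exercise"]),
                genotypes=genotypes,
            )
        )
    return subjects
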