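"""End-to-end orchestration: classification -> prevalence -> matching ->
SNP statistics -> regression -> risk scores -> interaction, from a single
run configuration, with every output re-derivable from inputs + seed."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .datamodel import (
    BmiClass,
    RunConfig,
    StandardPopulation,
    Subject,
    read_standard_population,
    read_subjects,
    subjects_to_frame,
)
from .genetics import GenotypeCounts, model_column_names, snp_association_table
from .interaction import DEFAULT_EXPOSURES, gene_environment_analysis
from .matching import MatchedPair, match_pairs, split_cases_controls
from .prevalence import pearson_chisq, prevalence_report
from .regression import (
    build_design,
    fit_conditional_logistic,
    fit_logistic,
    model_report,
)
from .riskscore import additive_logor_weights, score_association, score_pairs
from .synth import default_spec, generate_population


class PipelineStageError(RuntimeError):
    """Wraps an error from one pipeline stage with the stage name and a
    remediation hint."""

    def __init__(self, stage: str, error: Exception, hint: str):
        self.stage = stage
        self.hint = hint
        super().__init__(f"stage {stage!r} failed: {error} (hint: {hint})")


@dataclass
class PipelineResult:
    descriptives: pd.DataFrame
    prevalence: pd.DataFrame
    pairs: pd.DataFrame
    case_control_descriptives: pd.DataFrame
    snp_table: pd.DataFrame
    covariate_fit: pd.DataFrame
    covariate_fit_sensitivity: pd.DataFrame
    inheritance_fits: pd.DataFrame
    risk_score_fits: pd.DataFrame
    interaction_table: pd.DataFrame
    log: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "descriptives",
            "prevalence",
            "pairs",
            "case_control_descriptives",
            "snp_table",
            "covariate_fit",
            "covariate_fit_sensitivity",
            "inheritance_fits",
            "risk_score_fits",
            "interaction_table",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(self.log, indent=2, sort_keys=True))


def _stage(name: str, hint: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc, hint) from exc

        return inner

    return wrap


def _descriptive_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Covariate counts by BMI class with chi-square comparisons of
    overweight vs normal-weight and obesity vs normal-weight."""
    rows = []
    covariates = (
        "sex",
        "residence",
        "income",
        "education",
        "smoking",
        "drinking",
        "occupational_pa",
        "leisure_exercise",
    )
    for cov in covariates:
        tab = pd.crosstab(frame[cov], frame["bmi_class"])
        for cls in (c.value for c in BmiClass):
            if cls not in tab.columns:
                tab[cls] = 0
        p_over = p_obese = float("nan")
        try:
            _, _, p_over = pearson_chisq(tab[["normal", "overweight"]])
            _, _, p_obese = pearson_chisq(tab[["normal", "obesity"]])
        except ValueError:
            pass
        for level, row in tab.iterrows():
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "normal": int(row["normal"]),
                    "overweight": int(row["overweight"]),
                    "obesity": int(row["obesity"]),
                    "underweight": int(row["underweight"]),
                    "p_overweight_vs_normal": p_over,
                    "p_obesity_vs_normal": p_obese,
                }
            )
    return pd.DataFrame(rows)


def _case_control_table(pairs: Sequence[MatchedPair]) -> pd.DataFrame:
    case_frame = subjects_to_frame([p.case for p in pairs])
    control_frame = subjects_to_frame([p.control for p in pairs])
    rows = []
    for cov in (
        "sex",
        "residence",
        "income",
        "education",
        "smoking",
        "drinking",
        "occupational_pa",
        "leisure_exercise",
    ):
        case_counts = case_frame[cov].value_counts()
        ctrl_counts = control_frame[cov].value_counts()
        levels = sorted(set(case_counts.index) | set(ctrl_counts.index))
        tab = pd.DataFrame(
            {
                "case": [case_counts.get(l, 0) for l in levels],
                "control": [ctrl_counts.get(l, 0) for l in levels],
            },
            index=levels,
        )
        try:
            _, _, p = pearson_chisq(tab)
        except ValueError:
            p = float("nan")
        for level in levels:
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "case": int(tab.loc[level, "case"]),
                    "control": int(tab.loc[level, "control"]),
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def _covariate_fit(frame: pd.DataFrame, outcome_col: str, alpha: float) -> pd.DataFrame:
    design = build_design(
        frame,
        (
            "sex",
            "age_band",
            "residence",
            "income",
            "education",
            "smoking",
            "drinking",
            "occupational_pa",
            "leisure_exercise",
        ),
    )
    fit = fit_logistic(design, frame[outcome_col].to_numpy())
    return model_report(fit, alpha=alpha)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; deterministic given the config seed."""
    log: dict = {"seed": config.seed, "version": __version__}

    load = _stage("load", "check subjects_path / synthetic_n in the config")(_load_subjects)
    subjects = load(config)
    log["n_subjects"] = len(subjects)

    standard: Optional[StandardPopulation] = None
    if config.standard_population_path is not None:
        standard = _stage(
            "standard_population", "check standard_population_path and its columns"
        )(read_standard_population)(config.standard_population_path)

    frame = subjects_to_frame(subjects)
    frame["age_band"] = [
        f"{lo}-{hi}"
        for lo, hi in (
            next(b for b in config.age_bands if b[0] <= a <= b[1]) for a in frame["age"]
        )
    ]

    descriptives = _stage("descriptives", "check covariate levels")(_descriptive_table)(frame)
    prev = _stage("prevalence", "check age bands cover all subjects")(prevalence_report)(
        subjects, standard, config.age_bands
    )

    covariate_fit = _stage("regression", "check for separation or collinearity")(
        _covariate_fit
    )(frame, "obese", config.alpha)
    sens_frame = frame[frame["bmi_class"] != BmiClass.UNDERWEIGHT.value]
    covariate_fit_sens = _stage("regression_sensitivity", "check for separation")(
        _covariate_fit
    )(sens_frame, "obese", config.alpha)
    log["n_underweight_dropped_in_sensitivity"] = int(len(frame) - len(sens_frame))

    cases, controls = split_cases_controls(subjects)
    pairs, unmatched = _stage("matching", "loosen the tolerance or check BMI classes")(
        match_pairs
    )(cases, controls, config.matching_tolerance, config.seed)
    log["n_pairs"] = len(pairs)
    log["n_unmatched_cases"] = len(unmatched)
    pairs_table = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "case_id": [p.case.id for p in pairs],
            "control_id": [p.control.id for p in pairs],
            "age_gap": [p.age_gap for p in pairs],
        }
    )

    cc_table = _stage("case_control_descriptives", "check pair construction")(
        _case_control_table
    )(pairs)

    case_counts = {}
    control_counts = {}
    for snp_id in [s.snp_id for s in config_snps(config)]:
        case_counts[snp_id] = GenotypeCounts.from_subjects([p.case for p in pairs], snp_id)
        control_counts[snp_id] = GenotypeCounts.from_subjects(
            [p.control for p in pairs], snp_id
        )
    snp_table = _stage("genetics", "check genotype completeness")(snp_association_table)(
        case_counts, control_counts
    )

    inh_rows = []
    for snp_id in case_counts:
        for model in config.inheritance_models:
            fit = _stage(
                "inheritance_fit", f"check discordance at {snp_id} under {model}"
            )(encode_pairs_design_and_fit)(pairs, snp_id, model, config.covariates)
            rep = model_report(fit, alpha=config.alpha)
            rep.insert(0, "snp", snp_id)
            rep.insert(1, "model", model)
            inh_rows.append(rep[rep["term"].str.startswith(snp_id)])
    inheritance_fits = pd.concat(inh_rows, ignore_index=True)

    weights = _stage("riskscore_weights", "check additive fits")(additive_logor_weights)(
        pairs, config.covariates
    )
    log["wgrs_weights"] = {k: float(v) for k, v in weights.items()}
    scores = score_pairs(pairs, weights)
    log["n_pairs_excluded_missing_genotype"] = len(scores.attrs["excluded"])
    rs_rows = []
    for score_col in ("grs", "wgrs"):
        fit, assignment = _stage("riskscore", "need >= 3 distinct scores")(
            score_association
        )(pairs, scores, score_col, config.covariates)
        rep = model_report(fit, alpha=config.alpha)
        rep.insert(0, "score", score_col)
        rep["cutpoints"] = f"{assignment.cutpoints[0]:.4g}/{assignment.cutpoints[1]:.4g}"
        rs_rows.append(rep[rep["term"].str.startswith(score_col)])
    risk_score_fits = pd.concat(rs_rows, ignore_index=True)

    int_rows = []
    for snp_id in case_counts:
        for exposure in DEFAULT_EXPOSURES:
            est = _stage("interaction", f"check discordance for {snp_id} x {exposure}")(
                gene_environment_analysis
            )(pairs, snp_id, exposure, config.covariates, config.alpha)
            int_rows.append(
                {
                    "snp": snp_id,
                    "exposure": exposure,
                    "reri": est.reri,
                    "reri_low": est.reri_ci[0],
                    "reri_high": est.reri_ci[1],
                    "ap": est.ap,
                    "ap_low": est.ap_ci[0],
                    "ap_high": est.ap_ci[1],
                    "si": est.si if est.si is not None else float("nan"),
                    "si_low": est.si_ci[0] if est.si_ci else float("nan"),
                    "si_high": est.si_ci[1] if est.si_ci else float("nan"),
                    "multiplicative_p": est.multiplicative_p,
                    "present": est.present,
                }
            )
    interaction_table = pd.DataFrame(int_rows)

    return PipelineResult(
        descriptives=descriptives,
        prevalence=prev,
        pairs=pairs_table,
        case_control_descriptives=cc_table,
        snp_table=snp_table,
        covariate_fit=covariate_fit,
        covariate_fit_sensitivity=covariate_fit_sens,
        inheritance_fits=inheritance_fits,
        risk_score_fits=risk_score_fits,
        interaction_table=interaction_table,
        log=log,
    )


def config_snps(config: RunConfig):
    from .datamodel import DEFAULT_SNPS

    return DEFAULT_SNPS


def _load_subjects(config: RunConfig) -> list[Subject]:
    if config.synthetic_n is not None:
        spec = default_spec(n_subjects=config.synthetic_n, seed=config.seed)
        return generate_population(spec)
    if config.subjects_path is None:
        raise ValueError("config must set either subjects_path or synthetic_n")
    return read_subjects(config.subjects_path)


def encode_pairs_design_and_fit(
    pairs: Sequence[MatchedPair],
    snp_id: str,
    model: str,
    covariates: Sequence[str],
):
    """Inheritance-model conditional-logistic fit for one SNP on matched
    pairs (pairs with a missing call at the SNP are excluded)."""
    from .genetics import encode_array
    from .regression import pair_design

    kept = [
        p
        for p in pairs
        if p.case.genotype_count(snp_id) is not None
        and p.control.genotype_count(snp_id) is not None
    ]
    names = model_column_names(snp_id, model)
    g_case = encode_array([p.case.genotype_count(snp_id) for p in kept], model)
    g_ctrl = encode_array([p.control.genotype_count(snp_id) for p in kept], model)
    if g_case.ndim == 1:
        g_case = g_case[:, None]
        g_ctrl = g_ctrl[:, None]
    extra_case = pd.DataFrame(g_case, columns=names)
    extra_control = pd.DataFrame(g_ctrl, columns=names)
    design = pair_design(kept, covariates, extra_case, extra_control)
    return fit_conditional_logistic(design)
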