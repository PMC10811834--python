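"""Domain types, input readers/validators, BMI classification, and run configuration.

The unit of analysis is a surveyed adult (20-80 years) with demographic and
lifestyle covariates, a measured BMI, and genotype calls at a small panel of
biallelic SNPs.  BMI classes follow the Working Group on Obesity in China
(WGOC) cut-offs for Chinese adults: obesity BMI >= 28 kg/m2, overweight
24 <= BMI < 28, normal weight 18.5 <= BMI < 24, underweight BMI < 18.5.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Residence(str, enum.Enum):
    URBAN = "urban"
    RURAL = "rural"


class Income(str, enum.Enum):
    """Personal annual income dichotomized at 10,000 CNY/year."""

    LOW = "low"
    HIGH = "high"


class Education(str, enum.Enum):
    PRIMARY_OR_BELOW = "primary_or_below"
    JUNIOR_OR_SENIOR_HIGH = "junior_or_senior_high"
    COLLEGE_OR_ABOVE = "college_or_above"


class SmokingStatus(str, enum.Enum):
    NEVER = "never"
    FORMER = "former"
    CURRENT = "current"


class DrinkingStatus(str, enum.Enum):
    NEVER = "never"
    FORMER = "former"
    CURRENT = "current"


class ActivityLevel(str, enum.Enum):
    """Three-level intensity grading shared by occupational physical activity
    and leisure-time exercise."""

    LIGHT = "light"
    MODERATE = "moderate"
    HEAVY = "heavy"


class BmiClass(str, enum.Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESITY = "obesity"


#: WGOC cut-offs (kg/m2); intervals are half-open, lower bound inclusive.
BMI_UNDERWEIGHT_UPPER = 18.5
BMI_OVERWEIGHT_LOWER = 24.0
BMI_OBESITY_LOWER = 28.0


def classify_bmi(bmi: float) -> BmiClass:
    """Map a BMI value (kg/m2) to its WGOC class.

    The mapping partitions (0, inf): underweight < 18.5 <= normal < 24 <=
    overweight < 28 <= obesity.

    Raises
    ------
    ValueError
        If ``bmi`` is not strictly positive.
    """
    if not bmi > 0:
        raise ValueError(f"BMI must be positive, got {bmi!r}")
    if bmi >= BMI_OBESITY_LOWER:
        return BmiClass.OBESITY
    if bmi >= BMI_OVERWEIGHT_LOWER:
        return BmiClass.OVERWEIGHT
    if bmi >= BMI_UNDERWEIGHT_UPPER:
        return BmiClass.NORMAL
    return BmiClass.UNDERWEIGHT


@dataclass(frozen=True)
class SnpDef:
    """A biallelic SNP with its reference and effect (risk) allele.

    The effect allele is the allele counted in inheritance-model coding and
    summed into risk scores; here it is the minor allele in the control
    group, i.e. the allele whose carriage raises the odds of obesity.
    """

    snp_id: str
    reference_allele: str
    effect_allele: str

    def __post_init__(self) -> None:
        for a in (self.reference_allele, self.effect_allele):
            if len(a) != 1 or not a.isalpha():
                raise ValueError(f"{self.snp_id}: allele must be a single letter, got {a!r}")
        if self.reference_allele == self.effect_allele:
            raise ValueError(f"{self.snp_id}: reference and effect allele must differ")


#: Default SNP panel: two MC4R variants and two FTO variants, effect alleles
#: being the minor alleles in the control group.
DEFAULT_SNPS: tuple[SnpDef, ...] = (
    SnpDef("rs17782313", "T", "C"),
    SnpDef("rs12970134", "G", "A"),
    SnpDef("rs1121980", "G", "A"),
    SnpDef("rs17817449", "T", "G"),
)

DEFAULT_SNP_IDS: tuple[str, ...] = tuple(s.snp_id for s in DEFAULT_SNPS)


@dataclass(frozen=True)
class GenotypeCall:
    """One subject's genotype at one SNP, stored both as the raw two-allele
    string and as the effect-allele dosage."""

    snp_id: str
    count_effect_allele: int
    raw: str

    def __post_init__(self) -> None:
        if self.count_effect_allele not in (0, 1, 2):
            raise ValueError(
                f"{self.snp_id}: effect-allele count must be 0, 1 or 2, "
                f"got {self.count_effect_allele}"
            )

    @classmethod
    def from_raw(cls, raw: str, snp: SnpDef) -> Optional["GenotypeCall"]:
        """Parse a two-allele string such as ``"T/C"`` (alleles in any order).

        ``"./."`` or an empty string denotes a missing call and returns None.
        An allele not matching the SNP definition is a hard error.
        """
        raw = raw.strip() if isinstance(raw, str) else ""
        if raw in ("", "./.", "."):
            return None
        parts = raw.split("/")
        if len(parts) != 2:
            raise ValueError(f"{snp.snp_id}: malformed genotype {raw!r}")
        count = 0
        for allele in parts:
            if allele == snp.effect_allele:
                count += 1
            elif allele != snp.reference_allele:
                raise ValueError(
                    f"{snp.snp_id}: unknown allele {allele!r} in genotype {raw!r} "
                    f"(expected {snp.reference_allele} or {snp.effect_allele})"
                )
        return cls(snp_id=snp.snp_id, count_effect_allele=count, raw=raw)


@dataclass
class Subject:
    """One surveyed individual."""

    id: str
    sex: Sex
    age: int
    bmi: float
    residence: Residence
    income: Income
    education: Education
    smoking: SmokingStatus
    drinking: DrinkingStatus
    occupational_pa: ActivityLevel
    leisure_exercise: ActivityLevel
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 20 <= self.age <= 80:
            raise ValueError(f"subject {self.id}: age {self.age} outside [20, 80]")
        if not self.bmi > 0:
            raise ValueError(f"subject {self.id}: BMI must be positive, got {self.bmi}")

    @property
    def bmi_class(self) -> BmiClass:
        return classify_bmi(self.bmi)

    def genotype_count(self, snp_id: str) -> Optional[int]:
        """Effect-allele dosage at ``snp_id``, or None if the call is missing."""
        call = self.genotypes.get(snp_id)
        return None if call is None else call.count_effect_allele


# --------------------------------------------------------------------------
# age bands

#: Decade bands used for age-specific rates and direct standardization.
DEFAULT_AGE_BANDS: tuple[tuple[int, int], ...] = (
    (20, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 80),
)


def age_band_label(age: int, bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS) -> str:
    for lo, hi in bands:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"age {age} falls in no configured band")


@dataclass(frozen=True)
class StandardPopulation:
    """External standard population as sex x age-band weights, used by the
    direct standardization method."""

    strata: tuple[tuple[Sex, str, float], ...]

    def __post_init__(self) -> None:
        seen = set()
        total = 0.0
        for sex, band, w in self.strata:
            if w < 0:
                raise ValueError(f"negative weight for stratum ({sex.value}, {band})")
            key = (sex, band)
            if key in seen:
                raise ValueError(f"duplicate stratum ({sex.value}, {band})")
            seen.add(key)
            total += w
        if not total > 0:
            raise ValueError("standard population weights must sum to a positive total")

    def weight(self, sex: Sex, band: str) -> float:
        for s, b, w in self.strata:
            if s == sex and b == band:
                return w
        raise KeyError(f"no standard weight for stratum ({sex.value}, {band})")


def read_standard_population(path: str | Path) -> StandardPopulation:
    """Read a standard-population table with columns sex, age_band, weight."""
    df = pd.read_csv(path)
    required = {"sex", "age_band", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"standard population file missing columns: {sorted(missing)}")
    strata = tuple(
        (Sex(row["sex"]), str(row["age_band"]), float(row["weight"]))
        for _, row in df.iterrows()
    )
    return StandardPopulation(strata=strata)


# --------------------------------------------------------------------------
# subject table I/O

_ENUM_COLUMNS: dict[str, type] = {
    "sex": Sex,
    "residence": Residence,
    "income": Income,
    "education": Education,
    "smoking": SmokingStatus,
    "drinking": DrinkingStatus,
    "occupational_pa": ActivityLevel,
    "leisure_exercise": ActivityLevel,
}

BASE_COLUMNS: tuple[str, ...] = (
    "id",
    "sex",
    "age",
    "bmi",
    "residence",
    "income",
    "education",
    "smoking",
    "drinking",
    "occupational_pa",
    "leisure_exercise",
)


class SubjectTableError(ValueError):
    """Raised when one or more rows of a subject table fail validation; the
    message lists every offending line."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid subject table:\n" + "\n".join(errors))


def _parse_row(row: Mapping[str, object], snp_defs: Sequence[SnpDef]) -> Subject:
    kwargs: dict = {"id": str(row["id"])}
    for col, enum_cls in _ENUM_COLUMNS.items():
        value = row[col]
        try:
            kwargs[col] = enum_cls(value)
        except ValueError:
            valid = [e.value for e in enum_cls]
            raise ValueError(f"column {col!r}: unknown level {value!r} (expected one of {valid})")
    try:
        kwargs["age"] = int(row["age"])
    except (TypeError, ValueError):
        raise ValueError(f"column 'age': not an integer: {row['age']!r}")
    try:
        kwargs["bmi"] = float(row["bmi"])
    except (TypeError, ValueError):
        raise ValueError(f"column 'bmi': not a number: {row['bmi']!r}")
    genotypes: dict[str, GenotypeCall] = {}
    for snp in snp_defs:
        raw = row.get(snp.snp_id)
        if raw is None or (isinstance(raw, float) and pd.isna(raw)):
            continue
        call = GenotypeCall.from_raw(str(raw), snp)
        if call is not None:
            genotypes[snp.snp_id] = call
    kwargs["genotypes"] = genotypes
    return Subject(**kwargs)


def read_subjects(
    path: str | Path, snp_defs: Sequence[SnpDef] = DEFAULT_SNPS
) -> list[Subject]:
    """Read and validate a comma-delimited subject table.

    Genotype columns (named by SNP id) hold two-allele strings like ``"T/C"``
    with alleles in either order; ``"./."`` marks a missing call.  Every
    invalid row is reported with its line number (header = line 1) in a
    single :class:`SubjectTableError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(BASE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    subjects: list[Subject] = []
    errors: list[str] = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # header occupies line 1
        try:
            subjects.append(_parse_row(row, snp_defs))
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SubjectTableError(errors)
    return subjects


def write_subjects(
    subjects: Iterable[Subject],
    path: str | Path,
    snp_defs: Sequence[SnpDef] = DEFAULT_SNPS,
) -> None:
    """Write subjects back to the same delimited schema read_subjects accepts."""
    records = []
    for s in subjects:
        rec: dict = {
            "id": s.id,
            "sex": s.sex.value,
            "age": s.age,
            "bmi": s.bmi,
            "residence": s.residence.value,
            "income": s.income.value,
            "education": s.education.value,
            "smoking": s.smoking.value,
            "drinking": s.drinking.value,
            "occupational_pa": s.occupational_pa.value,
            "leisure_exercise": s.leisure_exercise.value,
        }
        for snp in snp_defs:
            call = s.genotypes.get(snp.snp_id)
            rec[snp.snp_id] = call.raw if call is not None else "./."
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def subjects_to_frame(
    subjects: Sequence[Subject], snp_ids: Sequence[str] = DEFAULT_SNP_IDS
) -> pd.DataFrame:
    """Flatten subjects into an analysis DataFrame.

    Categorical columns hold the enum string values; each SNP column holds
    the effect-allele dosage (0/1/2) or NaN when the call is missing; the
    derived columns ``bmi_class`` and ``obese`` are appended.
    """
    data: dict[str, list] = {c: [] for c in BASE_COLUMNS}
    for c in snp_ids:
        data[c] = []
    for s in subjects:
        data["id"].append(s.id)
        data["sex"].append(s.sex.value)
        data["age"].append(s.age)
        data["bmi"].append(s.bmi)
        data["residence"].append(s.residence.value)
        data["income"].append(s.income.value)
        data["education"].append(s.education.value)
        data["smoking"].append(s.smoking.value)
        data["drinking"].append(s.drinking.value)
        data["occupational_pa"].append(s.occupational_pa.value)
        data["leisure_exercise"].append(s.leisure_exercise.value)
        for snp_id in snp_ids:
            count = s.genotype_count(snp_id)
            data[snp_id].append(float("nan") if count is None else count)
    df = pd.DataFrame(data)
    df["bmi_class"] = [s.bmi_class.value for s in subjects]
    df["obese"] = (df["bmi_class"] == BmiClass.OBESITY.value).astype(int)
    return df


# --------------------------------------------------------------------------
# run configuration

#: Covariates the adjusted models condition on, mirroring the matched-sample
#: adjustment set (sex and age are handled by the matching itself).
DEFAULT_ADJUSTMENT_COVARIATES: tuple[str, ...] = (
    "residence",
    "income",
    "education",
    "smoking",
    "drinking",
    "occupational_pa",
    "leisure_exercise",
)

INHERITANCE_MODELS: tuple[str, ...] = ("dominant", "recessive", "codominant", "additive")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (file paths + analysis knobs)."""

    subjects_path: Optional[str] = None
    standard_population_path: Optional[str] = None
    out_dir: str = "results"
    age_bands: tuple[tuple[int, int], ...] = DEFAULT_AGE_BANDS
    matching_tolerance: int = 3
    seed: int = 0
    alpha: float = 0.05
    inheritance_models: tuple[str, ...] = INHERITANCE_MODELS
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT_COVARIATES
    synthetic_n: Optional[int] = None  # generate instead of reading subjects

    def __post_init__(self) -> None:
        if self.matching_tolerance < 0:
            raise ValueError("matching_tolerance must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")
        unknown = set(self.inheritance_models) - set(INHERITANCE_MODELS)
        if unknown:
            raise ValueError(f"unknown inheritance models: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load configuration from a JSON or YAML key-value file."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} did not parse to a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "age_bands" in data:
            data["age_bands"] = tuple(tuple(b) for b in data["age_bands"])
        for key in ("inheritance_models", "covariates"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
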