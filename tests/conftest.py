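"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

from obesnp.datamodel import (
    ActivityLevel,
    DrinkingStatus,
    Education,
    Income,
    Residence,
    Sex,
    SmokingStatus,
    Subject,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

_counter = itertools.count()


def mk_subject(
    id: str | None = None,
    sex: str = "female",
    age: int = 40,
    bmi: float = 22.0,
    smoking: str = "never",
    drinking: str = "never",
    occupational_pa: str = "light",
    leisure_exercise: str = "light",
    residence: str = "urban",
    income: str = "low",
    education: str = "primary_or_below",
    genotypes: dict | None = None,
) -> Subject:
    """Build a valid Subject with sensible defaults for targeted tests."""
    return Subject(
        id=id if id is not None else f"T{next(_counter):05d}",
        sex=Sex(sex),
        age=age,
        bmi=bmi,
        residence=Residence(residence),
        income=Income(income),
        education=Education(education),
        smoking=SmokingStatus(smoking),
        drinking=DrinkingStatus(drinking),
        occupational_pa=ActivityLevel(occupational_pa),
        leisure_exercise=ActivityLevel(leisure_exercise),
        genotypes=genotypes or {},
    )


@pytest.fixture
def subject_builder():
    return mk_subject
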