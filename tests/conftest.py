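"""Shared fixtures: representative risk-factor profiles and small cohorts."""

from __future__ import annotations

import pytest
from hypothesis import settings

from lungrisk import Subject, SmokingHistory

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def heavy_current_smoker() -> Subject:
    """70-y-old white male, current smoker 30/day for 55 y, COPD, family
    history of lung cancer."""
    return Subject(
        id="p1", age=70, gender="male", race="white", education=2, bmi=28,
        copd=True, emphysema=False, personal_history_cancer=False,
        family_history_lc=True, history_pneumonia=False, asbestos=False,
        smoking=SmokingHistory(status="current", duration=55, intensity=30,
                               years_since_quit=0),
    )


@pytest.fixture
def moderate_former_smoker() -> Subject:
    """63-y-old black woman, former smoker (15/day for 40 y, quit 10 y ago),
    history of pneumonia."""
    return Subject(
        id="p2", age=63, gender="female", race="black", education=5, bmi=25,
        copd=False, emphysema=False, personal_history_cancer=False,
        family_history_lc=False, history_pneumonia=True, asbestos=False,
        smoking=SmokingHistory(status="former", duration=40, intensity=15,
                               years_since_quit=10),
    )


@pytest.fixture
def light_former_smoker() -> Subject:
    """65-y-old Asian male, former smoker (10/day for 30 y, quit 14 y ago),
    asbestos exposure."""
    return Subject(
        id="p3", age=65, gender="male", race="asian", education=4, bmi=24,
        copd=False, emphysema=False, personal_history_cancer=False,
        family_history_lc=False, history_pneumonia=False, asbestos=True,
        smoking=SmokingHistory(status="former", duration=30, intensity=10,
                               years_since_quit=14),
    )


@pytest.fixture
def reference_profile() -> Subject:
    """Every continuous covariate at the PLCOm2012 centering constant and
    every indicator at its reference level."""
    return Subject(
        id="ref", age=62, gender="male", race="white", education=4, bmi=27,
        copd=False, emphysema=False, personal_history_cancer=False,
        family_history_lc=False, history_pneumonia=False, asbestos=False,
        smoking=SmokingHistory(
            status="former",
            duration=27.6605081,
            intensity=10.0 / 0.4021541613,  # (cpd/10)^-1 equals its center
            years_since_quit=8.593417626,
        ),
    )
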