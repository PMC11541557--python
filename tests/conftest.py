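"""Shared fixtures and deterministic hypothesis configuration."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from reefheat.indices import SurveyObservation

settings.register_profile(
    "deterministic",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def survey_obs() -> SurveyObservation:
    """A small, warning-free survey (160 colonies, three species)."""
    return SurveyObservation(
        site_id="reefA",
        date="2016-10-12",
        latitude=16.2,
        longitude=-87.9,
        depth=8.0,
        colonies=[
            ("Acropora palmata", "normal", 40),
            ("Acropora palmata", "pale", 20),
            ("Orbicella annularis", "partially_bleached", 30),
            ("Orbicella annularis", "fully_bleached", 10),
            ("Porites astreoides", "normal", 60),
        ],
    )
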