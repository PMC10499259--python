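"""Shared fixtures: one subject, representative trials, and (for the
acceptance suite) full synthetic studies with extracted feature tables.

Expensive fixtures are session-scoped and lazy, so the cost is paid once and
only by the tests that request them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from emogait import features, synthcap

CLEAN_CONFIG = {"trial_jitter": 0.0, "marker_noise": 0.0, "step_cv": 0.0}


@pytest.fixture(scope="session")
def subject() -> synthcap.SubjectProfile:
    return synthcap.generate_subject(1, "S01", "female")


@pytest.fixture(scope="session")
def null_effects() -> synthcap.EmotionEffectSpec:
    return synthcap.EmotionEffectSpec.null()


@pytest.fixture(scope="session")
def trial_and_truth(subject, null_effects):
    """One default-noise neutral trial with its ground truth."""
    return synthcap.generate_trial(subject, "neutral", null_effects, seed=5)


@pytest.fixture(scope="session")
def clean_trial_and_truth(subject, null_effects):
    """Noise-free trial: no marker noise, no trial-to-trial jitter."""
    return synthcap.generate_trial(
        subject, "neutral", null_effects, seed=5, config=CLEAN_CONFIG
    )


@pytest.fixture(scope="session")
def standing_segment(subject, null_effects):
    return synthcap.generate_standing_segment(
        subject, "neutral", null_effects, duration=36.0, seed=3
    )


@pytest.fixture(scope="session")
def trial_features(trial_and_truth):
    trial, _ = trial_and_truth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return features.extract_trial_features(trial)


@pytest.fixture(scope="session")
def null_study_table():
    """Feature table of a full 24-subject study with no injected effects."""
    study = synthcap.generate_study(
        24, synthcap.EmotionEffectSpec.null(), seed=11
    )
    return features.extract_study_features(study)


@pytest.fixture(scope="session")
def effect_study_table():
    """Feature table of a 24-subject study with strong injected effects."""
    study = synthcap.generate_study(
        24, synthcap.EmotionEffectSpec.strong(), seed=12
    )
    return features.extract_study_features(study)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
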