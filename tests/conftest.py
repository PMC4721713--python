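"""Shared fixtures: rendered scene batches are expensive, so the 100-scene
batches used by the acceptance tests are session-scoped and computed once."""

from __future__ import annotations

import pytest

from pupilglint import pipeline, synthetic_eye


def _batch(difficulty: str, n: int, seed0: int = 0):
    truths, results = [], []
    for seed in range(seed0, seed0 + n):
        truth = synthetic_eye.sample_scene(seed, difficulty)
        truths.append(truth)
        results.append(pipeline.detect(synthetic_eye.render(truth)))
    return truths, results


@pytest.fixture(scope="session")
def clean_batch():
    """(truths, results) for 100 clean scenes, seeds 0..99."""
    return _batch("clean", 100)


@pytest.fixture(scope="session")
def contour_batch():
    """(truths, results) for 100 contour_glint scenes, seeds 0..99."""
    return _batch("contour_glint", 100)


@pytest.fixture()
def clean_scene():
    """One clean scene + rendered image (cheap enough per-test)."""
    truth = synthetic_eye.sample_scene(7, "clean")
    return truth, synthetic_eye.render(truth)
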