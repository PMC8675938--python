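"""Shared fixtures.

The two leave-one-subject-out experiments (strong class separation and
the zero-separation null) are expensive, so they run once per session
and are shared by every test that inspects them.
"""

from __future__ import annotations

from unittest import mock

import numpy as np
import pytest
from hypothesis import settings

from cardiomech import (
    RunConfig,
    SynthSpec,
    compute_metrics,
    generate_cohort,
    generate_subject,
    loso_run,
    preprocess_recording,
)
import cardiomech.evaluation as evaluation

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quiet_spec():
    """A noise-free, jitter-free, wander-free generator specification."""
    return SynthSpec(
        n_per_class=2, duration_s=30.0, hr_sd_bpm=0.0, noise_sd=0.0,
        wander_amp=0.0, amp_jitter=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def clean_subject(quiet_spec):
    """One preprocessed noise-free subject (250 Hz, normalised)."""
    rec = generate_subject(quiet_spec, "nonCAD", 42, "quiet_1")
    return rec, preprocess_recording(rec)


@pytest.fixture(scope="session")
def separable_loso():
    """Full LOSO on a strongly separated synthetic cohort.

    8 subjects per class, 30 s recordings (two 10-cycle series per
    subject), 10 training epochs.  ``train_calls`` records the channel
    of every classifier trained, in order, so fold bookkeeping can be
    audited.
    """
    spec = SynthSpec(n_per_class=8, duration_s=30.0, separation=1.0, seed=20)
    cohort = generate_cohort(spec)
    cfg = RunConfig(epochs=10, seed=7)
    train_calls = []
    original = evaluation.train_channel

    def counting(*args, **kwargs):
        train_calls.append(kwargs.get("channel", ""))
        return original(*args, **kwargs)

    with mock.patch.object(evaluation, "train_channel", counting):
        risks = loso_run(cohort, cfg)
    report = compute_metrics(risks, cfg.decision_threshold)
    return {
        "cohort": cohort,
        "cfg": cfg,
        "risks": risks,
        "report": report,
        "train_calls": train_calls,
    }


@pytest.fixture(scope="session")
def null_loso():
    """LOSO on a zero-separation cohort: classes identical in distribution."""
    spec = SynthSpec(n_per_class=6, duration_s=30.0, separation=0.0, seed=33)
    cohort = generate_cohort(spec)
    cfg = RunConfig(epochs=5, seed=9)
    risks = loso_run(cohort, cfg)
    return {"risks": risks, "report": compute_metrics(risks)}
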