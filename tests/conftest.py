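"""Shared fixtures: expensive simulated corpora and trained networks.

The corpora here are deliberately reduced-scale versions of the training
runs the package is designed for; session scope keeps each one simulated
and trained exactly once per test run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import gsrchoice as g
from gsrchoice.inference import (
    generate_training_set,
    split_training_set,
    train_classifier,
    train_estimator,
)


@pytest.fixture(scope="session")
def priors() -> g.PriorSpec:
    return g.PriorSpec()


@pytest.fixture(scope="session")
def classify_corpora(priors):
    """Single-condition classification corpora at N = 20, 40 and 100 trials."""
    out = {}
    for i, n_trials in enumerate((20, 40, 100)):
        rng = np.random.default_rng(1000 + i)
        out[n_trials] = generate_training_set(
            "classify", g.DesignSpec.single(n_trials), 4000, priors, rng
        )
    return out


@pytest.fixture(scope="session")
def classifier_n100(classify_corpora):
    rng = np.random.default_rng(2024)
    train, test = split_training_set(classify_corpora[100], 0.1, rng)
    model = train_classifier(train, rng=rng)
    return model, train, test


@pytest.fixture(scope="session")
def estimate_corpus(priors):
    """Reduced-scale gsr estimation corpus: 10,000 participants, 200 trials."""
    rng = np.random.default_rng(3000)
    return generate_training_set(
        "estimate", g.DesignSpec.single(200), 10_000, priors, rng
    )


@pytest.fixture(scope="session")
def estimator(estimate_corpus):
    rng = np.random.default_rng(3100)
    train, test = split_training_set(estimate_corpus, 0.15, rng)
    model = train_estimator(train, rng=rng)
    return model, train, test


@pytest.fixture(scope="session")
def gsr_participants(priors):
    """One hundred single-condition gsr participants with gamma in (pi/2, pi)."""
    rng = np.random.default_rng(4000)
    cfg = g.RunConfig(seed=4000, design="single", trials=200, n_participants=100, model="gsr")
    fs = g.generate_fixtures(cfg, rng)
    summaries = []
    for pid, sub in fs.trials.groupby("participant", sort=True):
        summaries.append(g.summarize_single_condition(sub).values)
    X = np.vstack(summaries)
    gamma_true = fs.manifest["gamma"].to_numpy(float)
    return X, gamma_true


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trial_table(rts, corrects, condition="c0m0d0", censored=None) -> pd.DataFrame:
    """Small hand-specified trial table for summary oracles."""
    n = len(rts)
    return pd.DataFrame(
        {
            "participant": 0,
            "condition": condition,
            "coherence": 0,
            "match": 0,
            "discriminability": 0,
            "choice": ["A"] * n,
            "rt": rts,
            "correct": corrects,
            "censored": censored if censored is not None else [False] * n,
        }
    )
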