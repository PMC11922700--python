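"""Shared fixtures: small synthetic cohorts and feature tables.

Everything is generated at test time from seeds; block durations are kept
short (10-20 s) so the full suite runs on one CPU in minutes. Band-power
statistics and classifier behaviour are duration-invariant apart from
Monte-Carlo noise, which the tolerances account for.
"""

from __future__ import annotations

import numpy as np
import pytest

import eegimpact as ei
from eegimpact.features import assemble_table
from eegimpact.simulate import (draw_subject_offsets, generate_block,
                                session_blocks)

QUIET = dict(blink_rate_per_min=0.0, saccade_rate_per_min=0.0,
             jumps_per_block=0.0)


def zero_offsets(config: ei.CohortConfig) -> dict:
    return {b: 0.0 for b in config.bands.names}


def cohort_tables(effect: ei.EffectSpec, n_subjects: int, seed: int,
                  post_lags=("post24h",), block_s: float = 20.0) -> dict:
    """Generate a cohort (no preprocessing; meant for artifact-free effect
    specs) and assemble pre-vs-post feature tables for the requested lags."""
    cfg = ei.CohortConfig(n_subjects=n_subjects, block_duration_s=block_s,
                          effect=effect, seed=seed)
    offs = {sid: draw_subject_offsets(cfg, i)
            for i, sid in enumerate(cfg.subject_ids())}
    vectors = []
    for sid in cfg.subject_ids():
        for lag in ("pre",) + tuple(post_lags):
            blocks = [generate_block(cfg, sid, s, offs[sid])[0]
                      for s in session_blocks(lag)]
            vectors.append(ei.session_features(blocks))
    return {lag: assemble_table(vectors, lags=("pre", lag))
            for lag in post_lags}


def gaussian_table(n_subjects: int, n_features: int, seed: int,
                   shift: float = 0.0) -> ei.FeatureTable:
    """A feature table drawn directly from Gaussians (fast classifier
    fixture): optional mean shift on the first feature for post rows."""
    rng = np.random.default_rng(seed)
    sids = np.repeat([f"S{i:02d}" for i in range(n_subjects)], 2)
    labels = np.tile([0, 1], n_subjects)
    X = rng.normal(size=(2 * n_subjects, n_features))
    X[labels == 1, 0] += shift
    groups = np.array(["kicking" if i % 4 < 2 else "non_kicking"
                       for i in range(2 * n_subjects)])
    lags = np.where(labels == 0, "pre", "post24h")
    return ei.FeatureTable(X=X, feature_names=[f"f{i}" for i in range(n_features)],
                           subject_ids=sids, labels=labels, groups=groups,
                           lags=lags)


@pytest.fixture(scope="session")
def tiny_config() -> ei.CohortConfig:
    return ei.CohortConfig(n_subjects=2, block_duration_s=10.0, seed=42)


@pytest.fixture(scope="session")
def quiet_config() -> ei.CohortConfig:
    """Two subjects, no artifacts, 10 s blocks."""
    return ei.CohortConfig(n_subjects=2, block_duration_s=10.0,
                           effect=ei.EffectSpec(**QUIET), seed=42)


@pytest.fixture(scope="session")
def quiet_block(quiet_config):
    off = zero_offsets(quiet_config)
    rec, art = generate_block(quiet_config, "S01",
                              session_blocks("pre")[0], off)
    return rec, art


@pytest.fixture(scope="session")
def separable_table() -> ei.FeatureTable:
    """Post rows shifted by ~100 SD on one feature: trivially separable."""
    return gaussian_table(12, 60, seed=7, shift=100.0)


@pytest.fixture(scope="session")
def null_table() -> ei.FeatureTable:
    return gaussian_table(18, 60, seed=8, shift=0.0)
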