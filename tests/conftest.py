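"""Shared fixtures: small synthetic cohorts generated at session start."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.preprocessing import StandardScaler

from smfkit.synthgen import SynthConfig, generate_cohort, cohort_feature_matrix
from smfkit.nn import NNArchitecture, fit_nn
from smfkit.panel import integrated_gradients


@pytest.fixture(scope="session")
def raw_cohort():
    """Small rendered cohort on the full 124k-point grid (12 vs 12, 3 reps)."""
    cfg = SynthConfig(n_case=12, n_control=12, n_replicates=3, n_batches=2, seed=7)
    spectra, metadata, truth = generate_cohort(cfg)
    return cfg, spectra, metadata, truth


@pytest.fixture(scope="session")
def preprocessed_matrix(raw_cohort):
    """Fingerprint matrix recovered from the rendered cohort by the full chain."""
    from smfkit.preprocess import PreprocessConfig, run_preprocessing
    cfg, spectra, _, truth = raw_cohort
    fm = run_preprocessing(spectra, PreprocessConfig(),
                           group_of_sample=truth.group_of_sample)
    return fm


@pytest.fixture(scope="session")
def separable_matrix():
    """Strongly separable fingerprint cohort (20 peaks at log2FC >= 3, n=60)."""
    cfg = SynthConfig(n_case=30, n_control=30, n_differential=20,
                      log2fc_range=(3.0, 3.5), seed=5)
    fm, truth = cohort_feature_matrix(cfg)
    return fm, truth


@pytest.fixture(scope="session")
def panel_cohort():
    """Cohort with 6 strong planted signals among 134 plus a trained network."""
    cfg = SynthConfig(n_case=40, n_control=40, n_differential=6,
                      log2fc_range=(2.5, 3.0), seed=9)
    fm, truth = cohort_feature_matrix(cfg)
    y = (np.asarray(fm.labels) == "case").astype(int)
    xz = StandardScaler().fit_transform(fm.values)
    clf = fit_nn(xz, y, NNArchitecture(seed=0))
    attr = integrated_gradients(clf, xz, n_steps=300)
    return fm, truth, clf, attr, xz, y


@pytest.fixture(scope="session")
def cluster_cohort():
    """Three well-separated metabolite-pattern clusters of case samples."""
    cfg = SynthConfig(n_case=90, n_control=0, n_case_clusters=3,
                      cluster_log2_sep=3.0, height_sigma_log=0.5,
                      n_differential=0, seed=4)
    fm, truth = cohort_feature_matrix(cfg)
    return fm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
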