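"""Shared fixtures: small toy datasets and the study-scale recovery batch."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from floa import FrameGrid
from floa.agreement import empirical_coverage, floa_band
from floa.basis import BasisSystem
from floa.datasets import DifferenceCurves
from floa.lmm import ErrorSpec, RandomLevelSpec, fit_reml
from floa.synthetic import (SimConfig, simulate_differences, truth_eigenbasis)

warnings.filterwarnings("ignore", category=UserWarning)

N_RECOVERY_SEEDS = 20


@pytest.fixture(scope="session")
def random_intercept_toy():
    """Balanced one-way layout: 20 groups x 5 observations, known truth."""
    rng = np.random.default_rng(5)
    n_groups, n_obs = 20, 5
    grid = FrameGrid(n_frames=n_obs, t_min=0.0, t_max=float(n_obs - 1))
    ones = BasisSystem(np.ones((n_obs, 1)), kind="bspline", grid=grid)
    curves = {}
    for g in range(n_groups):
        curves[(f"S{g:02d}", "ses1", "rep1")] = (
            3.0 + rng.normal(0.0, np.sqrt(2.0))
            + rng.normal(0.0, np.sqrt(1.5), n_obs))
    return DifferenceCurves(curves, grid), ones


@pytest.fixture(scope="session")
def study_fit():
    """One study-scale dataset with its well-specified REML fit."""
    cfg = SimConfig(seed=1)
    diffs, truth = simulate_differences(cfg)
    B = truth_eigenbasis(cfg)
    levels = [RandomLevelSpec(lv, B, "diagonal")
              for lv in ("subject", "session", "replicate")]
    model = fit_reml(diffs, truth["basis"], levels, ErrorSpec("arma", 2, 1),
                     n_starts=1)
    return cfg, diffs, truth, model


@pytest.fixture(scope="session")
def recovery_batch():
    """Study-scale recovery harness: the generating model (stated
    eigenbasis, diagonal covariance, ARMA(2,1) error) refitted on
    independent replicates of the study; per seed the error variance,
    bias-curve RMS error, and fresh-data band coverage."""
    rows = []
    for seed in range(1, N_RECOVERY_SEEDS + 1):
        cfg = SimConfig(seed=seed)
        diffs, truth = simulate_differences(cfg)
        B = truth_eigenbasis(cfg)
        levels = [RandomLevelSpec(lv, B, "diagonal")
                  for lv in ("subject", "session", "replicate")]
        model = fit_reml(diffs, truth["basis"], levels,
                         ErrorSpec("arma", 2, 1), n_starts=1)
        band = floa_band(model)
        bias_rms = float(np.sqrt(np.mean(
            (band.bias - truth["bias_curve"]) ** 2)))
        fresh, _ = simulate_differences(
            SimConfig(seed=seed + 500, n_subjects=400))
        rows.append({"sigma2": model.params.sigma2,
                     "bias_rms": bias_rms,
                     "coverage": empirical_coverage(band, fresh),
                     "truth_sigma2": cfg.sigma2,
                     "converged": model.converged})
    return rows
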