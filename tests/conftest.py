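"""Shared fixtures: render configurations and point-matching helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from neuropheno.imagegen import RenderConfig


@pytest.fixture(scope="session")
def clean_cfg() -> RenderConfig:
    """Noise- and blur-free rendering: exact forward model."""
    return RenderConfig(noise=False, psf_sigma=0.0, background_gradient=0.0)


@pytest.fixture(scope="session")
def blur_cfg() -> RenderConfig:
    """PSF blur without noise."""
    return RenderConfig(noise=False, background_gradient=0.0)


@pytest.fixture(scope="session")
def default_cfg() -> RenderConfig:
    return RenderConfig()


def match_points(truth: np.ndarray, detected: np.ndarray, tol: float):
    """Greedy one-to-one matching of detected points to ground truth.

    Returns (n_matched, n_truth, n_detected); recall = matched/truth,
    precision = matched/detected.
    """
    truth = np.asarray(truth, dtype=float)
    detected = np.asarray(detected, dtype=float)
    if len(truth) == 0 or len(detected) == 0:
        return 0, len(truth), len(detected)
    tree = cKDTree(detected)
    used: set[int] = set()
    matched = 0
    for p in truth:
        dists, idxs = tree.query(p, k=min(4, len(detected)))
        for d, i in zip(np.atleast_1d(dists), np.atleast_1d(idxs)):
            if d <= tol and int(i) not in used:
                used.add(int(i))
                matched += 1
                break
    return matched, len(truth), len(detected)
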