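"""Shared fixtures: small deterministic scenes and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240508)


def brute_force_metrics(coords: np.ndarray, threshold: float) -> dict:
    """O(N²) reference for the five mesh metrics, independent of the
    package's k-d tree implementation."""
    n = len(coords)
    edges, lengths = [], []
    degree = np.zeros(n, dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        d = float(np.sqrt(((coords[i] - coords[j]) ** 2).sum()))
        if d <= threshold:
            edges.append((i, j))
            lengths.append(d)
            degree[i] += 1
            degree[j] += 1
    return {
        "n_nodes": n,
        "edges": set(edges),
        "pct_connected": 100.0 * (degree > 0).sum() / n if n else 0.0,
        "mean_internode_dist": float(np.mean(lengths)) if lengths else np.nan,
        "mean_degree": 2.0 * len(edges) / n if n else 0.0,
    }


def brute_force_r95(coords: np.ndarray, start=0.7, step=0.05, max_t=3.0):
    """Exhaustive sweep oracle for R95 (no nearest-neighbour shortcut)."""
    t = start
    while t <= max_t + 1e-12:
        t = round(t, 9)
        m = brute_force_metrics(coords, t)
        if m["pct_connected"] >= 95.0:
            return t
        t += step
    return np.nan


@pytest.fixture
def random_cloud(rng):
    """50 uniform points in a 5 µm cube."""
    return rng.uniform(0, 5.0, size=(50, 3))
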