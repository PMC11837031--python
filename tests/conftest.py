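"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately use plain Python loops over voxels so
they stay independent of the vectorised implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clinidp.grids import VolumeGrid
from clinidp.synthetic import make_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """Phantom small enough for triple-loop voxel-count oracles."""
    return make_phantom(seed=7, shape=(20, 20, 20), voxel_size=(2.0, 2.0, 2.0),
                        wmh_burden=0.05, atrophy=0.1)


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(seed=3, shape=(32, 32, 32), wmh_burden=0.02, atrophy=0.1)


# ---------------------------------------------------------------------------
# Brute-force oracles (pure Python loops)
# ---------------------------------------------------------------------------


def loop_weighted_volume(weight: np.ndarray, mask: np.ndarray, voxvol: float) -> float:
    """Sum of weight inside mask times voxel volume, by explicit loops."""
    nx, ny, nz = weight.shape
    total = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask[i, j, k] > 0:
                    total += weight[i, j, k]
    return total * voxvol


def loop_overlap_volume(a: np.ndarray, b: np.ndarray, voxvol: float) -> float:
    """Count voxels where both binary masks are 1, times voxel volume."""
    nx, ny, nz = a.shape
    n = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if a[i, j, k] > 0 and b[i, j, k] > 0:
                    n += 1
    return n * voxvol


def loop_weighted_mean(metric: np.ndarray, weight: np.ndarray, mask: np.ndarray) -> float:
    nx, ny, nz = metric.shape
    num = den = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask[i, j, k] > 0:
                    w = weight[i, j, k]
                    num += metric[i, j, k] * w
                    den += w
    return num / den


def sort_interpolate_percentile(values: np.ndarray, pct: float) -> float:
    """Percentile by explicit sort + linear interpolation between closest ranks."""
    v = sorted(float(x) for x in values)
    n = len(v)
    pos = (pct / 100.0) * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def exhaustive_bh(pvals: np.ndarray, q: float) -> np.ndarray:
    """BH rejection set by exhaustive threshold search (for small m).

    The BH set rejects all p <= t*, where t* is the largest p_(i) with
    p_(i) <= i*q/m; searching all candidate thresholds reproduces it
    without the step-up shortcut.
    """
    m = len(pvals)
    order = np.argsort(pvals)
    best_k = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * q / m:
            best_k = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:best_k]] = True
    return reject


def grid(data: np.ndarray, voxel=(1.0, 1.0, 1.0)) -> VolumeGrid:
    return VolumeGrid(np.asarray(data, dtype=float), voxel)
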