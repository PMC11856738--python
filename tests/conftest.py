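"""Shared fixtures and independent brute-force oracles.

The surface-distance oracles here deliberately avoid the package's own
implementation path (KD-trees, morphological erosion): boundaries are found
by explicit 6-neighbourhood enumeration and distances by all-pairs
Euclidean computation.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_mask(rng, shape, p=0.3, ensure_nonempty=True):
    """A random binary mask; guaranteed nonempty foreground by default."""
    m = (rng.random(shape) < p).astype(np.uint8)
    if ensure_nonempty and m.sum() == 0:
        idx = tuple(rng.integers(0, s) for s in shape)
        m[idx] = 1
    return m


def brute_boundary(mask):
    """Boundary voxels by explicit 6-neighbourhood check (oracle)."""
    mask = np.asarray(mask).astype(bool)
    out = []
    shape = mask.shape
    for idx in np.argwhere(mask):
        x, y, z = idx
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nx, ny, nz = x + d[0], y + d[1], z + d[2]
            outside = not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2])
            if outside or not mask[nx, ny, nz]:
                out.append((x, y, z))
                break
    return np.array(sorted(out)).reshape(-1, 3)


def brute_directed_distances(a, b):
    """All-pairs nearest-boundary distances from S(a) to S(b) (oracle)."""
    sa = brute_boundary(a).astype(float)
    sb = brute_boundary(b).astype(float)
    return cdist(sa, sb).min(axis=1), cdist(sb, sa).min(axis=1)


def brute_assd(a, b):
    d_ab, d_ba = brute_directed_distances(a, b)
    return (d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba))


def brute_hd95(a, b):
    d_ab, d_ba = brute_directed_distances(a, b)
    return max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))


def brute_hausdorff(a, b):
    d_ab, d_ba = brute_directed_distances(a, b)
    return max(d_ab.max(), d_ba.max())


def numerical_gradient(f, x, eps=1e-6):
    """Central finite differences of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
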