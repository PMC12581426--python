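import numpy as np
import pytest

from sella3d import PhantomSpec, generate_fossa_phantom


@pytest.fixture(scope="session")
def coarse_spec() -> PhantomSpec:
    """Default phantom geometry on a fast 0.3 mm grid."""
    return PhantomSpec(spacing=0.3, seed=0)


@pytest.fixture(scope="session")
def coarse_phantom(coarse_spec):
    """(volume, landmarks, true_volume) of the default phantom at 0.3 mm."""
    return generate_fossa_phantom(coarse_spec)


def kruskal_h_bruteforce(groups) -> float:
    """Independent tie-corrected Kruskal–Wallis H from first principles.

    Mid-ranks are computed by their definition (count of smaller values plus
    half the ties), not by a library ranking routine.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = np.array([
        np.sum(pooled < v) + (1.0 + np.sum(pooled == v)) / 2.0 for v in pooled
    ])
    h = 0.0
    start = 0
    for g in groups:
        r_mean = ranks[start:start + g.size].mean()
        h += g.size * (r_mean - (n_total + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / correction


def spearman_bruteforce(x, y) -> float:
    """Pearson correlation of mid-ranks, written out longhand."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        return np.array([np.sum(v < w) + (1.0 + np.sum(v == w)) / 2.0 for w in v])

    rx, ry = midranks(x), midranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))
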