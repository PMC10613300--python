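import numpy as np
import pytest

from linkscan import Config, CurveSpec, make_pair


@pytest.fixture(scope="session")
def cfg_notrim():
    """Default hyperparameters but no terminal trimming.

    Synthetic curves have no flexible tails, so the 15-residue trim meant
    for real protein termini would eat into the constructed topology.
    """
    return Config(trim=0)


@pytest.fixture(scope="session")
def hopf_pair():
    return make_pair(CurveSpec(kind="hopf", seed=1))


@pytest.fixture(scope="session")
def cancellation_pair():
    return make_pair(CurveSpec(kind="cancellation", seed=1))


@pytest.fixture(scope="session")
def wrapped_pair():
    return make_pair(CurveSpec(kind="wrapped_unlinked", seed=1))


def random_segment_pairs(n, rng, min_separation=0.05, box=8.0):
    """Well-separated random segment pairs for oracle comparisons."""
    from linkscan.gauss import _segment_distance

    out = []
    while len(out) < n:
        pts = rng.uniform(-box, box, (4, 3))
        if _segment_distance(*pts) >= min_separation:
            out.append(pts)
    return out


def gauss_legendre_pair(p1, p2, q1, q2, order=24, panels=12):
    """Composite tensor Gauss-Legendre quadrature of the Gauss integrand.

    Panel subdivision keeps the rule accurate when the segments pass close
    to each other and the integrand is sharply peaked.
    """
    x, w = np.polynomial.legendre.leggauss(order)
    edges = np.linspace(0.0, 1.0, panels + 1)
    s = np.concatenate([lo + (hi - lo) * 0.5 * (x + 1.0) for lo, hi in zip(edges, edges[1:])])
    ws = np.concatenate([(hi - lo) * 0.5 * w for lo, hi in zip(edges, edges[1:])])
    u, v = p2 - p1, q2 - q1
    c = np.cross(u, v)
    r1 = p1[None, :] + s[:, None] * u[None, :]
    r2 = q1[None, :] + s[:, None] * v[None, :]
    diff = r1[:, None, :] - r2[None, :, :]
    norm = np.linalg.norm(diff, axis=-1)
    integrand = (diff @ c) / norm**3
    return float(ws @ integrand @ ws) / (4.0 * np.pi)
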