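import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_nucleolar_scene():
    """One 512x512 scene with three compliant nuclei, shared across tests."""
    from rdnalinks.simulate import make_nucleolar_scene

    return make_nucleolar_scene(n_nuclei=3, seed=7, shape=(512, 512))


def crofton_perimeter_oracle(mask: np.ndarray) -> float:
    """Independent 4-direction Crofton perimeter: count boundary crossings
    of the four line families directly and weight by line spacing."""
    m = np.pad(np.asarray(mask, bool), 1).astype(int)
    nh = np.abs(np.diff(m, axis=1)).sum()
    nv = np.abs(np.diff(m, axis=0)).sum()
    nd1 = np.abs(m[1:, 1:] - m[:-1, :-1]).sum()
    nd2 = np.abs(m[1:, :-1] - m[:-1, 1:]).sum()
    return float(np.pi / 4 * (nh / 2 + nv / 2 + (nd1 / 2 + nd2 / 2) / np.sqrt(2)))


def fisher_greater_oracle(table) -> float:
    """One-sided (more events in row 1) Fisher p by exact integer
    enumeration of the hypergeometric tail; independent of scipy."""
    import math
    from fractions import Fraction

    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = math.comb(n, c1)
    tail = sum(math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(a, hi + 1))
    return float(Fraction(tail, total))


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p: sum of all hypergeometric outcomes no more
    probable than the observed one (exact integer weights)."""
    import math

    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    total = math.comb(n, c1)
    obs = weights[a]
    tail = sum(w for w in weights.values() if w <= obs)
    return tail / total
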