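import numpy as np
import pytest

from slicequant.synth import (
    AstroSynthParams,
    FpspSynthParams,
    PunctaSynthParams,
    gen_eaat2_stack,
    gen_fpsp_sweeps,
    gen_gfap_stack,
)


@pytest.fixture(scope="session")
def gfap_default():
    """One default synthetic astrocyte arbor stack with its ground truth."""
    return gen_gfap_stack(AstroSynthParams(seed=0))


@pytest.fixture(scope="session")
def eaat2_default():
    """One default synthetic puncta stack (no chains) with ground truth."""
    return gen_eaat2_stack(PunctaSynthParams(seed=0))


@pytest.fixture(scope="session")
def eaat2_chains():
    """Puncta stack with 30% of the blob budget strung into ridge chains."""
    return gen_eaat2_stack(PunctaSynthParams(ridge_fraction=0.3, seed=3))


@pytest.fixture(scope="session")
def fpsp_noiseless():
    """Noiseless paired-pulse session, potentiation 1.5, PPR 1.42."""
    return gen_fpsp_sweeps(FpspSynthParams(noise_sd=0.0, seed=0))


def hysteresis_flood_oracle(data: np.ndarray, low: float, high: float) -> np.ndarray:
    """Reference hysteresis: breadth-first flood fill (26-conn) from seeds >= high."""
    from collections import deque

    low_m = data >= low
    high_m = data >= high
    out = np.zeros(data.shape, dtype=bool)
    dq = deque(map(tuple, np.argwhere(high_m & low_m)))
    seen = set(dq)
    while dq:
        p = dq.popleft()
        out[p] = True
        z, y, x = p
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    q = (z + dz, y + dy, x + dx)
                    if q == p or min(q) < 0:
                        continue
                    if q[0] >= data.shape[0] or q[1] >= data.shape[1] or q[2] >= data.shape[2]:
                        continue
                    if q not in seen and low_m[q]:
                        seen.add(q)
                        dq.append(q)
    return out


def brute_force_otsu3(counts: np.ndarray, centers: np.ndarray) -> tuple[int, int]:
    """Reference 3-class Otsu: plain double loop over all threshold pairs."""
    p = counts.astype(float) / counts.sum()
    nbins = counts.size
    best = None
    for i in range(1, nbins - 1):
        for j in range(i + 1, nbins):
            v = 0.0
            for sl in (slice(0, i), slice(i, j), slice(j, nbins)):
                w = p[sl].sum()
                if w > 0:
                    mu = (p[sl] * centers[sl]).sum() / w
                    v += w * mu * mu
            if best is None or v > best[0]:
                best = (v, i, j)
    return best[1], best[2]
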