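"""Shared fixtures and independent numerical oracles.

The oracles here are deliberately naive (explicit python loops, closed
forms) so they share no code path with the package implementation they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from acaunet.config import test_profile
from acaunet.network import build_network
from acaunet.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_pairs():
    """8 synthetic 64x64 image/mask pairs — the desk-scale training fixture."""
    return generate_dataset(SyntheticSpec(size=64, seed=7), 8)


@pytest.fixture(scope="session")
def test_net():
    """A freshly initialised reduced-profile network (read-only in tests)."""
    return build_network(test_profile(), seed=11)


# ----------------------------------------------------------------- oracles

def naive_conv2d(x, w, b=None, stride=1, padding=0, dilation=1):
    """Loop-based 2-D cross-correlation oracle for tiny inputs."""
    n, c, h, wdt = x.shape
    o, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    ho = (h + 2 * padding - eh) // stride + 1
    wo = (wdt + 2 * padding - ew) // stride + 1
    out = np.zeros((n, o, ho, wo), dtype=np.float64)
    for ni in range(n):
        for oi in range(o):
            for yi in range(ho):
                for xi in range(wo):
                    acc = 0.0
                    for ci in range(c):
                        for ky in range(kh):
                            for kx in range(kw):
                                acc += (
                                    w[oi, ci, ky, kx]
                                    * xp[ni, ci, yi * stride + ky * dilation,
                                         xi * stride + kx * dilation]
                                )
                    out[ni, oi, yi, xi] = acc + (b[oi] if b is not None else 0.0)
    return out


def numgrad(f, x, eps=1e-3):
    """Central finite differences of scalar-valued f with respect to x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = float(x[i])
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def mask_counts(pred, truth):
    """Enumerated confusion counts over every pixel (no vectorised tricks)."""
    tp = fp = fn = 0
    for a, b in zip(np.ravel(pred), np.ravel(truth)):
        if a == 1 and b == 1:
            tp += 1
        elif a == 1 and b == 0:
            fp += 1
        elif a == 0 and b == 1:
            fn += 1
    return tp, fp, fn
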