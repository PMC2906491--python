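"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.special import gammaln

from metamotif.model import DirichletParams, Metamotif
from metamotif.simulate import sample_background_motifs


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def background():
    return DirichletParams(np.full(4, 0.5))


@pytest.fixture
def small_motifs(rng, background):
    return sample_background_motifs(6, 8, background, rng)


def random_metamotif(rng, length, name="mm") -> Metamotif:
    return Metamotif(name, rng.uniform(0.1, 40.0, size=(length, 4)))


# -- exhaustive MUMM path-enumeration oracle -------------------------------
#
# Independent of the dynamic-programming implementation: every legal
# arrangement of background columns and non-overlapping metamotif matches
# is enumerated explicitly and its probability accumulated.

_RC = [3, 2, 1, 0]


def _column_log_density(logx_col, alpha):
    a = np.asarray(alpha, float)
    return float(-(gammaln(a).sum() - gammaln(a.sum())) + np.dot(a - 1.0, logx_col))


def _segment_log_density(logx, start, mm, revcomp, real, log_b):
    def one_orientation(a):
        total = 0.0
        for k in range(len(mm)):
            pos = start + k
            if real[pos]:
                total += _column_log_density(logx[pos], a[k])
            else:
                total += log_b[pos]
        return total

    value = one_orientation(mm.alpha)
    if revcomp:
        value = np.logaddexp(value, one_orientation(mm.alpha[::-1, _RC]))
    return value


def mumm_enumeration_oracle(padded_pwm, metamotifs, bg, revcomp, unpadded_length):
    """Sum over every explicit background/metamotif path of a padded motif.

    Padding columns always emit under the background; a metamotif match
    must cover at least one real column.  Matches carry the transition
    weight t = 1 / unpadded_length.
    """
    from metamotif.infer import INFERENCE_WEIGHT_FLOOR

    logx = np.log(padded_pwm.floored(INFERENCE_WEIGHT_FLOOR))
    C = logx.shape[0]
    l_pad = (C - unpadded_length) // 2
    real = [l_pad <= c < l_pad + unpadded_length for c in range(C)]
    log_b = [_column_log_density(logx[c], bg.alpha) for c in range(C)]
    log_t = -math.log(unpadded_length)

    total = -np.inf

    def recurse(c, acc):
        nonlocal total
        if c == C:
            total = np.logaddexp(total, acc)
            return
        recurse(c + 1, acc + log_b[c])
        for mm in metamotifs:
            l = len(mm)
            if c + l <= C and any(real[c : c + l]):
                recurse(
                    c + l,
                    acc + log_t + _segment_log_density(logx, c, mm, revcomp, real, log_b),
                )

    recurse(0, 0.0)
    return float(total)
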