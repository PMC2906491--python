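"""Maximum-likelihood Dirichlet fitting and greedy gapless motif alignment.

The MLE of a Dirichlet from observed probability vectors has no closed form;
we use the classical fixed-point iteration on the digamma equations with a
moment-matching start.  The alignment half provides a STAMP-style greedy
gapless multiple alignment of PWMs, from which a metamotif is estimated by
fitting one Dirichlet per alignment column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln
from scipy.optimize import minimize_scalar

from .model import PWM, DirichletParams, Metamotif, floor_weights

#: Clip range for user-facing MLE fits (wider than the sampler's clip so
#: estimation results are not artificially truncated).
FIT_ALPHA_MIN = 1e-3
FIT_ALPHA_MAX = 1e4

#: Minimum number of aligned columns two motifs must share.
MIN_OVERLAP = 4


def dirichlet_log_likelihood(columns: np.ndarray, alpha: np.ndarray) -> float:
    """Summed log Dirichlet density of ``columns`` (n, K) under ``alpha``."""
    a = np.asarray(alpha, float)
    logx = np.log(columns)
    n = columns.shape[0]
    norm = gammaln(a).sum() - gammaln(a.sum())
    return float(-n * norm + (logx @ (a - 1.0)).sum())


def _inverse_digamma(y: np.ndarray) -> np.ndarray:
    """Newton inversion of the digamma function (elementwise)."""
    y = np.asarray(y, float)
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y + 0.5772156649015329))
    for _ in range(6):
        x = x - (digamma(x) - y) / _trigamma(x)
        x = np.maximum(x, 1e-12)
    return x


def _trigamma(x: np.ndarray) -> np.ndarray:
    from scipy.special import polygamma

    return polygamma(1, x)


def _moment_match(columns: np.ndarray) -> np.ndarray:
    """Moment-matching initialiser for the Dirichlet MLE."""
    m = columns.mean(axis=0)
    v = columns.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = m * (1.0 - m) / v - 1.0
    s = s[np.isfinite(s) & (s > 0)]
    prec = float(np.exp(np.log(s).mean())) if s.size else FIT_ALPHA_MAX
    prec = float(np.clip(prec, 4 * FIT_ALPHA_MIN, 4 * FIT_ALPHA_MAX))
    return np.clip(m * prec, FIT_ALPHA_MIN, FIT_ALPHA_MAX)


def fit_mle_dirichlet(
    columns, max_iter: int = 1000, tol: float = 1e-8
) -> DirichletParams:
    """Fit a Dirichlet distribution to nucleotide weight vectors by MLE.

    Fixed-point iteration: ``psi(alpha_k') = psi(sum alpha) + mean log x_k``,
    which monotonically increases the likelihood from the moment-matching
    start.  Parameters are clipped to ``[1e-3, 1e4]``; a set of identical
    columns therefore escalates to the clip ceiling (infinite-precision
    limit) instead of diverging.

    Parameters
    ----------
    columns
        (n, 4) array-like of probability vectors, n >= 2.  Columns are
        floored and renormalised before fitting.
    """
    cols = np.asarray(columns, dtype=float)
    if cols.ndim != 2 or cols.shape[1] != 4:
        raise ValueError("columns must be an (n, 4) array")
    if cols.shape[0] < 2:
        raise ValueError("need at least 2 columns to fit a Dirichlet")
    cols = floor_weights(cols)
    mean_logx = np.log(cols).mean(axis=0)

    alpha = _moment_match(cols)
    converged = False
    for _ in range(max_iter):
        new = _inverse_digamma(digamma(alpha.sum()) + mean_logx)
        new = np.clip(new, FIT_ALPHA_MIN, FIT_ALPHA_MAX)
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            converged = True
            break
        alpha = new
    if not converged:
        warnings.warn(
            "Dirichlet MLE did not converge within "
            f"{max_iter} iterations; returning last iterate",
            RuntimeWarning,
        )
    return DirichletParams(alpha)


def fit_symmetric_dirichlet(columns, max_iter: int = 200) -> float:
    """MLE of a symmetric Dirichlet(a, a, a, a) by profile-likelihood search.

    One-dimensional golden-section/Brent maximisation over log a.
    """
    cols = floor_weights(np.asarray(columns, dtype=float))
    if cols.ndim != 2 or cols.shape[1] != 4:
        raise ValueError("columns must be an (n, 4) array")
    mean_logx_sum = np.log(cols).mean(axis=0).sum()

    def neg_ll(log_a: float) -> float:
        a = np.exp(log_a)
        # per-observation symmetric Dirichlet log likelihood
        norm = 4 * gammaln(a) - gammaln(4 * a)
        return -(-norm + (a - 1.0) * mean_logx_sum)

    res = minimize_scalar(
        neg_ll,
        bounds=(np.log(FIT_ALPHA_MIN), np.log(FIT_ALPHA_MAX)),
        method="bounded",
        options={"maxiter": max_iter},
    )
    return float(np.exp(res.x))


def estimate_background(motifs) -> DirichletParams:
    """MLE Dirichlet background from all columns of all motifs pooled."""
    motifs = list(motifs)
    if not motifs:
        raise ValueError("cannot estimate a background from an empty motif set")
    pooled = np.vstack([m.weights for m in motifs])
    return fit_mle_dirichlet(pooled)


@dataclass(frozen=True)
class AlignedMotif:
    """One motif's placement in a gapless multiple alignment."""

    pwm: PWM
    offset: int
    reverse: bool

    @property
    def oriented_weights(self) -> np.ndarray:
        if self.reverse:
            return self.pwm.reverse_complement().weights
        return self.pwm.weights


@dataclass(frozen=True)
class MotifAlignment:
    """A gapless multiple alignment: placements on a shared coordinate axis.

    Offsets are relative to the alignment origin (the seed motif's first
    column); they may be negative.
    """

    members: tuple[AlignedMotif, ...]

    def column_span(self) -> tuple[int, int]:
        lo = min(m.offset for m in self.members)
        hi = max(m.offset + len(m.pwm) for m in self.members)
        return lo, hi

    def column_stacks(self) -> list[np.ndarray]:
        """Per alignment column, the stack of overlapping motif columns."""
        lo, hi = self.column_span()
        stacks: list[list[np.ndarray]] = [[] for _ in range(hi - lo)]
        for m in self.members:
            w = m.oriented_weights
            for i in range(len(m.pwm)):
                stacks[m.offset - lo + i].append(w[i])
        return [np.vstack(s) if s else np.empty((0, 4)) for s in stacks]


def _overlap_ssd(profile_sum, profile_cnt, weights, offset, lo) -> tuple[float, int]:
    """Summed squared deviation of ``weights`` placed at ``offset`` against
    the running average profile; returns (score, overlap length)."""
    score = 0.0
    n = 0
    for i in range(weights.shape[0]):
        c = offset - lo + i
        if 0 <= c < profile_cnt.shape[0] and profile_cnt[c] > 0:
            avg = profile_sum[c] / profile_cnt[c]
            d = weights[i] - avg
            score += float(d @ d)
            n += 1
    return score, n


def greedy_align(motifs, allow_revcomp: bool = False) -> MotifAlignment:
    """Greedy gapless multiple alignment of PWMs.

    The first motif seeds the alignment; each subsequent motif is placed at
    the offset (and orientation, when ``allow_revcomp``) minimising the
    summed squared deviation between its columns and the running
    column-average profile over the overlap, requiring at least
    ``MIN_OVERLAP`` overlapping columns (or the motif length if shorter).
    Ties break towards the smallest absolute offset, forward orientation.
    """
    motifs = list(motifs)
    if len(motifs) < 2:
        raise ValueError("alignment needs at least 2 motifs")

    seed = motifs[0]
    members = [AlignedMotif(seed, 0, False)]
    lo, hi = 0, len(seed)
    width = hi - lo
    profile_sum = np.zeros((width, 4))
    profile_cnt = np.zeros(width, dtype=int)
    profile_sum[:] = seed.weights
    profile_cnt[:] = 1

    for pwm in motifs[1:]:
        lw = len(pwm)
        min_ov = min(MIN_OVERLAP, lw, width)
        candidates = []
        orientations = [(False, pwm.weights)]
        if allow_revcomp:
            orientations.append((True, pwm.reverse_complement().weights))
        for offset in range(lo - lw + min_ov, hi - min_ov + 1):
            for rev, w in orientations:
                score, n = _overlap_ssd(profile_sum, profile_cnt, w, offset, lo)
                if n >= min_ov:
                    candidates.append((score, abs(offset), rev, offset, w))
        score, _, rev, offset, w = min(candidates, key=lambda c: c[:3])
        members.append(AlignedMotif(pwm, offset, rev))
        # grow the profile
        new_lo = min(lo, offset)
        new_hi = max(hi, offset + lw)
        if new_lo < lo or new_hi > hi:
            ns = np.zeros((new_hi - new_lo, 4))
            nc = np.zeros(new_hi - new_lo, dtype=int)
            ns[lo - new_lo : hi - new_lo] = profile_sum
            nc[lo - new_lo : hi - new_lo] = profile_cnt
            profile_sum, profile_cnt, lo, hi = ns, nc, new_lo, new_hi
            width = hi - lo
        profile_sum[offset - lo : offset - lo + lw] += w
        profile_cnt[offset - lo : offset - lo + lw] += 1

    return MotifAlignment(tuple(members))


def metamotif_from_alignment(
    alignment: MotifAlignment, name: str = "aligned", min_support: int = 2
) -> Metamotif:
    """Estimate an MLE metamotif from a gapless motif alignment.

    One Dirichlet MLE fit per alignment column; columns supported by fewer
    than ``min_support`` motifs are trimmed from the alignment ends.
    """
    stacks = alignment.column_stacks()
    support = np.array([s.shape[0] for s in stacks])
    keep = np.where(support >= min_support)[0]
    if keep.size == 0:
        raise ValueError("no alignment column is supported by enough motifs")
    stacks = stacks[keep[0] : keep[-1] + 1]
    if any(s.shape[0] < min_support for s in stacks):
        # interior low-support columns keep their fits but are rare; fit on
        # whatever support exists (>= 1 motif) to keep the model gapless
        pass
    alpha = np.vstack(
        [
            fit_mle_dirichlet(s).alpha
            if s.shape[0] >= 2
            else fit_mle_dirichlet(np.vstack([s, s])).alpha
            for s in stacks
        ]
    )
    return Metamotif(name, alpha)
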