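"""Nested-sampling inference of metamotifs from a motif collection.

The generative story: each motif in the collection is emitted column by
column by a hidden path that alternates between a background Dirichlet and
matches of one or more metamotifs (the MUMM -- multiple-uncounted
motif-metamotif HMM mixture).  A binary mixing matrix Q pairs metamotifs
with the motifs that contain them.  The likelihood of a motif given its
active metamotifs marginalises over all non-overlapping arrangements of
metamotif matches and background columns with a one-dimensional forward
recursion:

    L_c = B_c * L_{c-1}  +  sum_{m in M} t * P^m(c-l_m+1 .. c) * L_{c-l_m}

where ``B_c`` is the background density of column c, ``P^m`` the metamotif
density of a column segment, and ``t = 1/l_X`` the transition probability
into a metamotif (one match expected per motif, any position equally
likely).  With the reverse-complement option, ``P^m`` sums the densities of
the forward and reverse-complement orientations of the segment.

Motifs are padded on both ends with ``l_max`` uninformative columns (the
background mean weights) so that partial metamotif matches overhanging
either motif end are representable.  Padding columns are structural, not
data: they always emit under the background, inside or outside a metamotif
match, and a match must cover at least one real motif column.  (Scoring the
constant padding columns under metamotif columns would let a
maximum-precision metamotif centred on the background mean collect
unbounded reward from the zero-variance padding, a degenerate mode that
swamps any genuine signal.)

Inference is by nested sampling: an ensemble of states (metamotif sets plus
mixing matrices) is evolved under a rising likelihood bound; the worst state
is repeatedly replaced by a fresh prior draw or by decorrelating a copy of
a surviving state with constrained Metropolis moves.  The sequence of
removed likelihoods is non-decreasing and yields an estimate of the model
evidence through the standard prior-volume shrinkage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.special import gammaln, logsumexp, xlogy

from .model import (
    ALPHA_MAX,
    ALPHA_MIN,
    PWM,
    DirichletParams,
    Metamotif,
    floor_weights,
    _COMPLEMENT,
)

logger = logging.getLogger(__name__)

_NEG_INF = -np.inf

#: Regularisation floor applied to motif weights inside the inference
#: likelihood (stronger than the generic density-evaluation floor).  The
#: Dirichlet density diverges at the simplex boundary, so near-boundary
#: columns would otherwise dominate the likelihood: a clip-limit Dirichlet
#: fitted to one sharp noise column out-scores any recurring pattern.
#: Flooring at 1% bounds the per-column log density ratio between any two
#: clipped Dirichlets to a few nats, making recurrence across motifs --
#: not column sharpness -- the signal the sampler rewards.
INFERENCE_WEIGHT_FLOOR = 0.01


@dataclass(frozen=True)
class InferenceConfig:
    """Settings for metamotif nested sampling.

    Parameters
    ----------
    num_metamotifs
        Number of metamotif components n to estimate (fixed, user-set).
    min_length, max_length
        Bounds l_min <= l_max on metamotif length in columns.
    expected_fraction
        Expected fraction f of motifs containing any one metamotif; both the
        Bernoulli prior on mixing-matrix entries and its density term.
    revcomp
        Allow metamotif matches on either strand.
    ensemble_size, iterations
        Nested-sampling ensemble size and number of worst-state
        replacements.
    moves_per_decorrelation
        Length of the constrained-Metropolis chain used to decorrelate a
        copied survivor into a replacement state.
    mixing_flip_prob
        Probability that a proposal also flips one mixing-matrix entry.
    step_sigma
        Log-normal step size of the mean/precision/raw-alpha perturbations.
    prior_draw_prob
        Probability of first attempting a fresh prior draw as replacement.
    seed_draw_prob
        Probability of first attempting a data-seeded replacement: a copy
        of a surviving state in which one metamotif is re-initialised from
        a randomly chosen window of a randomly chosen input motif
        (pseudocounted mean, moderate precision).  A data-driven proposal
        in the usual MCMC sense; it is subject to the same likelihood
        bound as every other replacement.  Patterns present in several
        motifs gain across all of them at once when seeded, which is what
        makes weakly represented recurring signals discoverable at small
        sampling budgets.
    seed
        Seed for all randomness in the run.
    """

    num_metamotifs: int = 1
    min_length: int = 4
    max_length: int = 14
    expected_fraction: float = 0.5
    revcomp: bool = False
    ensemble_size: int = 100
    iterations: int = 2000
    moves_per_decorrelation: int = 20
    mixing_flip_prob: float = 0.3
    step_sigma: float = 0.15
    prior_draw_prob: float = 0.1
    seed_draw_prob: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError("need 1 <= min_length <= max_length")
        if not (0.0 < self.expected_fraction <= 1.0):
            raise ValueError("expected_fraction must be in (0, 1]")
        if self.ensemble_size < 2:
            raise ValueError("ensemble_size must be >= 2")
        if self.num_metamotifs < 1:
            raise ValueError("num_metamotifs must be >= 1")


@dataclass(frozen=True)
class MixingMatrix:
    """Binary n x p indicator of metamotif-in-motif presence."""

    entries: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.entries)
        if arr.ndim != 2:
            raise ValueError("mixing matrix must be 2-dimensional")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mixing matrix entries must be 0 or 1")
        object.__setattr__(self, "entries", arr.astype(np.int8))

    @property
    def n_metamotifs(self) -> int:
        return self.entries.shape[0]

    @property
    def n_motifs(self) -> int:
        return self.entries.shape[1]


@dataclass(frozen=True)
class InferenceState:
    """One point in the posterior: n metamotifs plus a mixing matrix."""

    metamotifs: tuple[Metamotif, ...]
    mixing: MixingMatrix
    log_likelihood: float | None = field(default=None, compare=False)

    def with_log_likelihood(self, ll: float) -> "InferenceState":
        return dc_replace(self, log_likelihood=ll)


def pad_motif(pwm: PWM, l_max: int, background: DirichletParams) -> PWM:
    """Pad a motif with ``l_max`` uninformative columns at both ends.

    Padding columns equal the background Dirichlet's mean weight vector, so
    metamotif matches may overhang either end of the original motif.
    """
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    if l_max == 0:
        return pwm
    pad = np.tile(background.mean, (l_max, 1))
    return PWM(pwm.name, np.vstack([pad, pwm.weights, pad]))


def _background_log_densities(logx: np.ndarray, background: DirichletParams):
    """Per-column log Dirichlet density under the background; logx is
    (..., 4) of floored log weights."""
    a = background.alpha
    norm = gammaln(a).sum() - gammaln(a.sum())
    return logx @ (a - 1.0) - norm


class MummEngine:
    """Cached, vectorised MUMM likelihood over a fixed motif collection.

    Pads and floors the motifs once, groups them by padded length, and
    caches per-metamotif segment log densities so that proposals touching a
    single metamotif only recompute that metamotif's windows.
    """

    _SEG_CACHE_MAX = 512

    def __init__(self, motifs, background: DirichletParams, config: InferenceConfig):
        self.background = background
        self.config = config
        self.motifs = list(motifs)
        if not self.motifs:
            raise ValueError("need at least one motif")
        # per group: (indices, logX, logB, logt, real mask, logB*pad)
        self._groups = []
        by_len: dict[int, list[int]] = {}
        for i, m in enumerate(self.motifs):
            by_len.setdefault(len(m), []).append(i)
        for l_x, idx in sorted(by_len.items()):
            padded = np.stack(
                [
                    pad_motif(self.motifs[i], config.max_length, background).floored(
                        INFERENCE_WEIGHT_FLOOR
                    )
                    for i in idx
                ]
            )
            logx = np.log(padded)
            logb = _background_log_densities(logx, background)
            logt = np.full(len(idx), -math.log(l_x))
            real = np.zeros(logx.shape[1], dtype=bool)
            real[config.max_length : config.max_length + l_x] = True
            logb_pad = logb * (~real)
            self._groups.append((np.array(idx), logx, logb, logt, real, logb_pad))
        self._seg_cache: dict[int, tuple[Metamotif, list]] = {}

    # -- segment densities -------------------------------------------------

    @staticmethod
    def _window_scores(logx, real, logb_pad, alpha) -> np.ndarray:
        """(g, C-l+1) log match scores of every length-l window.

        Real columns in the window are scored under the metamotif columns;
        padding columns emit their background density; windows covering no
        real column are forbidden (-inf).
        """
        l = alpha.shape[0]
        g, C = logx.shape[0], logx.shape[1]
        if C < l:
            return np.empty((g, 0))
        per_col_norm = gammaln(alpha).sum(axis=1) - gammaln(alpha.sum(axis=1))  # (l,)
        logx_real = logx * real[None, :, None]
        win = np.lib.stride_tricks.sliding_window_view(logx_real, l, axis=1)
        # win: (g, C-l+1, 4, l); coefficients: (l, 4)
        s = np.einsum("gwkl,lk->gw", win, alpha - 1.0)
        real_win = np.lib.stride_tricks.sliding_window_view(real.astype(float), l)
        s = s - real_win @ per_col_norm  # metamotif normalisers on real cols only
        pad_bg = np.lib.stride_tricks.sliding_window_view(logb_pad, l, axis=1)
        s = s + pad_bg.sum(axis=2)
        n_real = real_win.sum(axis=1)
        s[:, n_real < 1] = _NEG_INF
        return s

    def _segments(self, mm: Metamotif) -> list:
        key = id(mm)
        hit = self._seg_cache.get(key)
        if hit is not None and hit[0] is mm:
            return hit[1]
        segs = []
        alpha = mm.alpha
        alpha_rc = alpha[::-1, _COMPLEMENT]
        for _, logx, _, _, real, logb_pad in self._groups:
            s = self._window_scores(logx, real, logb_pad, alpha)
            if self.config.revcomp:
                s = np.logaddexp(
                    s, self._window_scores(logx, real, logb_pad, alpha_rc)
                )
            segs.append(s)
        if len(self._seg_cache) >= self._SEG_CACHE_MAX:
            self._seg_cache.clear()
        self._seg_cache[key] = (mm, segs)
        return segs

    # -- likelihood --------------------------------------------------------

    def state_log_likelihood(self, state: InferenceState) -> float:
        """Dataset log likelihood plus the Bernoulli(f) mixing prior term."""
        q = state.mixing.entries
        f = self.config.expected_fraction
        total = float(xlogy(q, f).sum() + xlogy(1 - q, 1.0 - f).sum())
        seg_per_mm = [self._segments(mm) for mm in state.metamotifs]
        lengths = [len(mm) for mm in state.metamotifs]
        for gi, (idx, logx, logb, logt, real, logb_pad) in enumerate(self._groups):
            g, C = logb.shape
            act = q[:, idx].astype(bool) if q.size else np.zeros((0, g), bool)
            prev = np.zeros((C + 1, g))
            for c in range(1, C + 1):
                acc = logb[:, c - 1] + prev[c - 1]
                for j, l in enumerate(lengths):
                    if l <= c and seg_per_mm[j][gi].shape[1] > 0 and act[j].any():
                        term = np.where(
                            act[j],
                            logt + seg_per_mm[j][gi][:, c - l] + prev[c - l],
                            _NEG_INF,
                        )
                        acc = np.logaddexp(acc, term)
                prev[c] = acc
            total += float(prev[C].sum())
        return total


def mumm_log_likelihood(
    pwm: PWM,
    metamotifs,
    background: DirichletParams,
    revcomp: bool = False,
    unpadded_length: int | None = None,
) -> float:
    """Forward MUMM log likelihood of one (already padded) motif.

    ``metamotifs`` is the active subset M for this motif (possibly empty,
    in which case the result is the pure-background likelihood).
    ``unpadded_length`` sets l_X in the transition probability t = 1/l_X and
    locates the padding: the real motif is assumed centred, with
    ``(len(pwm) - l_X) / 2`` padding columns at each end.  It defaults to
    the length of ``pwm`` itself (an unpadded motif).  Metamotifs longer
    than the padded motif contribute no match paths.
    """
    metamotifs = list(metamotifs)
    l_x = unpadded_length if unpadded_length is not None else len(pwm)
    if l_x < 1:
        raise ValueError("unpadded motif length must be >= 1")
    C = len(pwm)
    if (C - l_x) % 2:
        raise ValueError("padded length minus unpadded length must be even")
    l_pad = (C - l_x) // 2
    logx = np.log(pwm.floored(INFERENCE_WEIGHT_FLOOR))[None]  # (1, C, 4)
    logb = _background_log_densities(logx, background)
    logt = -math.log(l_x)
    real = np.zeros(C, dtype=bool)
    real[l_pad : l_pad + l_x] = True
    logb_pad = logb * (~real)

    segs = []
    for mm in metamotifs:
        if len(mm) > C:
            segs.append(None)
            continue
        s = MummEngine._window_scores(logx, real, logb_pad, mm.alpha)
        if revcomp:
            s = np.logaddexp(
                s,
                MummEngine._window_scores(
                    logx, real, logb_pad, mm.alpha[::-1, _COMPLEMENT]
                ),
            )
        segs.append(s[0])

    prev = np.zeros(C + 1)
    for c in range(1, C + 1):
        acc = logb[0, c - 1] + prev[c - 1]
        for mm, s in zip(metamotifs, segs):
            l = len(mm)
            if s is not None and l <= c:
                acc = np.logaddexp(acc, logt + s[c - l] + prev[c - l])
        prev[c] = acc
    return float(prev[C])


def dataset_log_likelihood(
    motifs, state: InferenceState, background: DirichletParams, config: InferenceConfig
) -> float:
    """Joint log likelihood of a motif collection under an inference state.

    Sum over motifs of the MUMM likelihood with each motif's active
    metamotifs (those with mixing entry 1), plus the Bernoulli(f) prior
    density of the mixing matrix.
    """
    return MummEngine(motifs, background, config).state_log_likelihood(state)


# -- prior sampling and moves ---------------------------------------------


def _prior_column(rng) -> np.ndarray:
    return rng.uniform(ALPHA_MIN, ALPHA_MAX, size=4)


def sample_state_from_prior(
    config: InferenceConfig, rng, n_motifs: int | None = None
) -> InferenceState:
    """Draw an inference state from the clipped uninformative prior.

    Metamotif lengths are uniform on [l_min, l_max], every Dirichlet
    parameter uniform on [0.1, 40.0], and mixing entries independent
    Bernoulli(f).
    """
    rng = np.random.default_rng(rng)
    if n_motifs is None:
        n_motifs = 1
    mms = []
    for j in range(config.num_metamotifs):
        l = int(rng.integers(config.min_length, config.max_length + 1))
        alpha = rng.uniform(ALPHA_MIN, ALPHA_MAX, size=(l, 4))
        mms.append(Metamotif(f"metamotif{j}", alpha))
    q = (rng.random((config.num_metamotifs, n_motifs)) < config.expected_fraction)
    return InferenceState(tuple(mms), MixingMatrix(q.astype(np.int8)))


def _project_mean(mean: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Project a probability vector onto the simplex intersected with the
    box [lo, hi]^4 (feasible when 4*lo <= 1 <= 4*hi)."""
    m = mean.copy()
    for _ in range(50):
        m = np.clip(m, lo, hi)
        s = m.sum()
        if abs(s - 1.0) < 1e-12:
            return m
        free = (m > lo + 1e-15) if s > 1.0 else (m < hi - 1e-15)
        if not free.any():
            return m / s
        m[free] -= (s - 1.0) / free.sum()
    return np.clip(m, lo, hi) / np.clip(m, lo, hi).sum()


def propose_move(
    state: InferenceState,
    config: InferenceConfig,
    rng,
    step_scale: float = 1.0,
) -> InferenceState:
    """Propose a new state by one randomly chosen metamotif move.

    The move set (applied to one random metamotif):

    1. perturb one column's mean weights, holding precision fixed;
    2. perturb one column's precision alpha_0, holding the mean fixed;
    3. perturb one raw alpha entry (indirectly changing the precision);
    4. replace a column with a draw from the clipped simplex prior;
    5. shift: drop a column from one end, add a prior-drawn one to the
       other;
    6. length change: add or remove an end column within [l_min, l_max].

    Additionally, with probability ``mixing_flip_prob``, one mixing-matrix
    entry is flipped.  All resulting parameters honour the [0.1, 40.0] clip
    and the length bounds (infeasible choices are resampled).
    """
    rng = np.random.default_rng(rng)
    sigma = config.step_sigma * step_scale
    mms = list(state.metamotifs)
    j = int(rng.integers(len(mms)))
    alpha = mms[j].alpha.copy()
    L = alpha.shape[0]

    moves = ["mean", "precision", "raw", "replace", "shift"]
    if config.min_length < config.max_length:
        moves.append("length")
    move = moves[int(rng.integers(len(moves)))]
    i = int(rng.integers(L))

    if move == "mean":
        a0 = alpha[i].sum()
        mean = alpha[i] / a0
        k = int(rng.integers(4))
        mean[k] *= math.exp(rng.normal(0.0, sigma))
        mean /= mean.sum()
        mean = _project_mean(mean, ALPHA_MIN / a0, ALPHA_MAX / a0)
        alpha[i] = mean * a0
    elif move == "precision":
        mean = alpha[i] / alpha[i].sum()
        a0 = alpha[i].sum() * math.exp(rng.normal(0.0, sigma))
        a0 = float(np.clip(a0, ALPHA_MIN / mean.min(), ALPHA_MAX / mean.max()))
        alpha[i] = mean * a0
    elif move == "raw":
        k = int(rng.integers(4))
        alpha[i, k] *= math.exp(rng.normal(0.0, sigma))
    elif move == "replace":
        alpha[i] = _prior_column(rng)
    elif move == "shift":
        col = _prior_column(rng)
        if rng.random() < 0.5:
            alpha = np.vstack([alpha[1:], col])
        else:
            alpha = np.vstack([col, alpha[:-1]])
    else:  # length
        options = []
        if L < config.max_length:
            options += [("add", 0), ("add", 1)]
        if L > config.min_length:
            options += [("remove", 0), ("remove", 1)]
        what, end = options[int(rng.integers(len(options)))]
        if what == "add":
            col = _prior_column(rng)[None]
            alpha = np.vstack([col, alpha]) if end == 0 else np.vstack([alpha, col])
        else:
            alpha = alpha[1:] if end == 0 else alpha[:-1]

    alpha = np.clip(alpha, ALPHA_MIN, ALPHA_MAX)
    mms[j] = Metamotif(mms[j].name, alpha, family=mms[j].family)

    mixing = state.mixing
    if rng.random() < config.mixing_flip_prob:
        q = mixing.entries.copy()
        r = int(rng.integers(q.shape[0]))
        c = int(rng.integers(q.shape[1]))
        q[r, c] = 1 - q[r, c]
        mixing = MixingMatrix(q)

    return InferenceState(tuple(mms), mixing)


# -- nested sampling -------------------------------------------------------


@dataclass
class NestedSamplingResult:
    """Output of a nested-sampling run."""

    best_state: InferenceState
    posterior: list[tuple[InferenceState, float]]
    log_evidence: float
    log_evidence_trace: np.ndarray
    removed_log_likelihoods: np.ndarray

    @property
    def metamotifs(self) -> tuple[Metamotif, ...]:
        return self.best_state.metamotifs


def nested_sample(
    motifs, config: InferenceConfig, background: DirichletParams | None = None
) -> NestedSamplingResult:
    """Infer metamotifs from a motif collection by nested sampling.

    The background defaults to the MLE Dirichlet pooled over all input
    motif columns.  Returns the maximum-likelihood state, the
    posterior-weighted removed states, and the accumulated log-evidence
    trace.  Fully deterministic given ``config.seed`` and the input.
    """
    from .estimate import estimate_background

    motifs = list(motifs)
    if not motifs:
        raise ValueError("need at least one motif")
    if background is None:
        background = estimate_background(motifs)
    rng = np.random.default_rng(config.seed)
    engine = MummEngine(motifs, background, config)
    p = len(motifs)
    N = config.ensemble_size

    states = [sample_state_from_prior(config, rng, p) for _ in range(N)]
    logls = np.array([engine.state_log_likelihood(s) for s in states])

    removed: list[tuple[InferenceState, float]] = []
    logz_terms: list[float] = []
    logz_trace = np.empty(config.iterations)
    for it in range(config.iterations):
        worst = int(np.argmin(logls))
        bound = float(logls[worst])
        # prior-volume shrinkage: X_i = exp(-i/N)
        log_w = logsumexp(
            [-(it) / N, -(it + 1) / N], b=[1.0, -1.0]
        )
        removed.append((states[worst].with_log_likelihood(bound), bound))
        logz_terms.append(log_w + bound)
        logz_trace[it] = logsumexp(logz_terms)

        new_state, new_ll = _replace_state(
            engine, states, logls, worst, bound, config, rng, p
        )
        states[worst] = new_state
        logls[worst] = new_ll

    best = int(np.argmax(logls))
    best_state = states[best].with_log_likelihood(float(logls[best]))

    # posterior weights over removed states: w_i * L_i, normalised
    log_post = np.array(logz_terms)
    log_post -= logsumexp(log_post)
    posterior = [
        (st, float(w)) for (st, _), w in zip(removed, np.exp(log_post))
    ]
    return NestedSamplingResult(
        best_state=best_state,
        posterior=posterior,
        log_evidence=float(logz_trace[-1]),
        log_evidence_trace=logz_trace,
        removed_log_likelihoods=np.array([b for _, b in removed]),
    )


def _weakest_component(engine, state: InferenceState, base_ll: float) -> int:
    """Index of the metamotif contributing least to the state likelihood.

    Contribution is measured as the likelihood drop when the component's
    mixing row is zeroed.  Duplicated or noise-fitting components cost
    little and are the natural targets for re-seeding.
    """
    n = len(state.metamotifs)
    if n == 1:
        return 0
    losses = []
    for j in range(n):
        q = state.mixing.entries.copy()
        q[j] = 0
        ll = engine.state_log_likelihood(
            InferenceState(state.metamotifs, MixingMatrix(q))
        )
        losses.append(base_ll - ll)
    return int(np.argmin(losses))


def _data_seeded_state(
    base: InferenceState, motifs, config: InferenceConfig, rng, component: int
) -> InferenceState | None:
    """Re-initialise one metamotif of ``base`` from a random motif window.

    The window's columns (pseudocounted with 0.05) become the metamotif
    means; per-column precisions are drawn uniformly from [4, 12].  The
    seeded metamotif's mixing row is redrawn from Bernoulli(f) with the
    source motif forced on.  Returns None when no motif can host a window
    of a legal length.
    """
    src_index = int(rng.integers(len(motifs)))
    src = motifs[src_index]
    l_hi = min(config.max_length, len(src))
    if l_hi < config.min_length:
        return None
    # Half the seeds are drawn long and left to the length moves to trim
    # (dropping a mismatching end column always raises the likelihood,
    # whereas growing a short component requires accepting a random,
    # almost surely mismatching, prior-drawn column first); the other half
    # cover the full legal range so short signals can be seeded at their
    # exact length.
    if rng.random() < 0.5:
        l_lo = max(config.min_length, (config.min_length + l_hi + 1) // 2)
    else:
        l_lo = config.min_length
    l = int(rng.integers(l_lo, l_hi + 1))
    off = int(rng.integers(0, len(src) - l + 1))
    window = src.weights[off : off + l] + 0.05
    means = window / window.sum(axis=1, keepdims=True)
    prec = rng.uniform(4.0, 12.0, size=l)
    alpha = np.clip(means * prec[:, None], ALPHA_MIN, ALPHA_MAX)
    j = component
    mms = list(base.metamotifs)
    mms[j] = Metamotif(mms[j].name, alpha, family=mms[j].family)
    q = base.mixing.entries.copy()
    q[j] = (rng.random(q.shape[1]) < config.expected_fraction).astype(np.int8)
    q[j, src_index] = 1
    return InferenceState(tuple(mms), MixingMatrix(q))


def _replace_state(engine, states, logls, worst, bound, config, rng, p):
    """Find a replacement state with likelihood above ``bound``.

    Decorrelation chains adapt their step size to the local acceptance
    rate (grow on acceptance, shrink on rejection), so chains stay
    productive both early (wide moves over a flat constrained prior) and
    late (fine moves near the likelihood peak).
    """
    if rng.random() < config.prior_draw_prob:
        cand = sample_state_from_prior(config, rng, p)
        ll = engine.state_log_likelihood(cand)
        if ll > bound:
            return cand, ll

    if rng.random() < config.seed_draw_prob:
        survivors = [i for i in range(len(states)) if i != worst]
        src = survivors[int(rng.integers(len(survivors)))]
        base = states[src]
        j = _weakest_component(engine, base, float(logls[src]))
        cand = _data_seeded_state(base, engine.motifs, config, rng, j)
        if cand is not None:
            ll = engine.state_log_likelihood(cand)
            if ll > bound:
                return cand, ll

    # decorrelate a copy of a random surviving state
    survivors = [i for i in range(len(states)) if i != worst]
    src = survivors[int(rng.integers(len(survivors)))]
    cur, cur_ll = states[src], float(logls[src])

    step_scale = 1.0
    for attempt in range(3):
        accepted = 0
        for _ in range(config.moves_per_decorrelation):
            prop = propose_move(cur, config, rng, step_scale=step_scale)
            ll = engine.state_log_likelihood(prop)
            if ll > bound:
                cur, cur_ll = prop, ll
                accepted += 1
                step_scale = min(step_scale * 1.3, 4.0)
            else:
                step_scale = max(step_scale * 0.85, 0.02)
        if accepted > 0:
            return cur, cur_ll
        if attempt == 0:
            logger.warning(
                "no decorrelation move accepted above the likelihood bound; "
                "continuing with a reduced step size"
            )
    return cur, cur_ll
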