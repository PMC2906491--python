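"""Motif and metamotif comparison: distances, shuffle p-values, clustering.

Two distances are provided.  The Cartesian distance operates on mean-weight
matrices (PWM weights, or metamotif column means) and normalises by overlap
length, making it comparable across motif lengths.  The SSD distance is the
classical sum-of-squared-deviations motif metric used for hierarchical
clustering, with non-overlapping columns penalised against a background
column so that trivially short overlaps are not favoured.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import PWM, Metamotif, _COMPLEMENT

_UNIFORM = np.full(4, 0.25)


def _mean_matrix(obj) -> np.ndarray:
    if isinstance(obj, Metamotif):
        return obj.means
    if isinstance(obj, PWM):
        return obj.weights
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("expected a PWM, Metamotif, or (L, 4) matrix")
    return arr


def _revcomp_matrix(m: np.ndarray) -> np.ndarray:
    return m[::-1, _COMPLEMENT]


def _offset_range(la: int, lb: int, min_overlap: int):
    """Offsets of b relative to a with at least ``min_overlap`` columns."""
    return range(-(lb - min_overlap), la - min_overlap + 1)


def cartesian_distance(a, b, allow_revcomp: bool = False) -> float:
    """Cartesian-like distance between mean nucleotide weight matrices.

    The two matrices are slid against each other over every gapless offset
    at which the shorter matrix lies entirely within the longer one (both
    orientations when ``allow_revcomp``); at the best offset the distance
    is ``sqrt(sum of squared differences over the overlap) / overlap
    length``.  Requiring full containment keeps the distance (and the
    column-shuffle null built on it) about whole-pattern agreement: with
    partial overlaps allowed, a lucky alignment of a few boundary columns
    scores arbitrarily well.  Symmetric, non-negative, zero for identical
    inputs.
    """
    ma, mb = _mean_matrix(a), _mean_matrix(b)
    min_ov = min(ma.shape[0], mb.shape[0])
    best = np.inf
    variants = [mb]
    if allow_revcomp:
        variants.append(_revcomp_matrix(mb))
    for mbv in variants:
        for off in _offset_range(ma.shape[0], mbv.shape[0], min_ov):
            lo = max(0, off)
            hi = min(ma.shape[0], off + mbv.shape[0])
            da = ma[lo:hi] - mbv[lo - off : hi - off]
            n = hi - lo
            d = np.sqrt((da * da).sum()) / n
            if d < best:
                best = d
    return float(best)


def _ssd_at_offset(ma, mb, off, bg_col) -> float:
    """SSD of b placed at ``off`` against a, overhangs scored vs background."""
    la, lb = ma.shape[0], mb.shape[0]
    lo, hi = max(0, off), min(la, off + lb)
    d = ma[lo:hi] - mb[lo - off : hi - off]
    score = float((d * d).sum())
    # overhanging columns of either motif compared against the background
    for seg in (ma[:lo], ma[hi:]):
        if seg.size:
            dd = seg - bg_col
            score += float((dd * dd).sum())
    for seg in (mb[: lo - off], mb[hi - off :]):
        if seg.size:
            dd = seg - bg_col
            score += float((dd * dd).sum())
    return score


def ssd_distance(
    a,
    b,
    allow_revcomp: bool = False,
    background_column: np.ndarray | None = None,
    min_overlap: int = 1,
    normalise: bool = False,
) -> float:
    """Sum-of-squared-deviations distance between two PWMs.

    Minimum over offsets (and orientations when ``allow_revcomp``) of the
    summed squared column differences over the overlap, with every
    non-overlapping column of either motif penalised by its squared
    deviation from the background mean column (uniform by default).  Ties
    break deterministically to the smallest offset, forward orientation.
    ``normalise=True`` divides by the total number of scored columns.
    """
    ma, mb = _mean_matrix(a), _mean_matrix(b)
    bg = _UNIFORM if background_column is None else np.asarray(background_column, float)
    best = (np.inf, np.inf, 1)
    best_len = 1
    variants = [(0, mb)]
    if allow_revcomp:
        variants.append((1, _revcomp_matrix(mb)))
    for rev, mbv in variants:
        for off in _offset_range(ma.shape[0], mbv.shape[0], min_overlap):
            score = _ssd_at_offset(ma, mbv, off, bg)
            key = (score, abs(off), rev)
            if key < best:
                best = key
                lo, hi = max(0, off), min(ma.shape[0], off + mbv.shape[0])
                best_len = (hi - lo) + (ma.shape[0] - (hi - lo)) + (
                    mbv.shape[0] - (hi - lo)
                )
    score = best[0]
    if normalise:
        score = score / best_len
    return float(score)


def empirical_pvalue(
    query,
    target,
    n_shuffles: int = 10000,
    rng=None,
    allow_revcomp: bool = False,
) -> float:
    """Empirical p-value of the Cartesian distance under a column-shuffle null.

    The null distribution is built by permuting the columns of ``target``
    ``n_shuffles`` times and recomputing the best-offset distance to
    ``query``; the add-one estimator
    ``p = (1 + #{null <= observed}) / (n_shuffles + 1)`` avoids p = 0.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a meaningful p-value")
    rng = np.random.default_rng(rng)
    mq, mt = _mean_matrix(query), _mean_matrix(target)
    observed = _best_distance_matrices(mq, mt, allow_revcomp)

    lt = mt.shape[0]
    perms = np.argsort(rng.random((n_shuffles, lt)), axis=1)
    shuffled = mt[perms]  # (S, lt, 4)
    null = _best_distance_batch(mq, shuffled, allow_revcomp)
    return float((1 + int((null <= observed + 1e-12).sum())) / (n_shuffles + 1))


def _best_distance_matrices(ma, mb, allow_revcomp) -> float:
    return cartesian_distance(ma, mb, allow_revcomp=allow_revcomp)


def _best_distance_batch(ma: np.ndarray, mbs: np.ndarray, allow_revcomp: bool):
    """Vectorised best-offset Cartesian distance of ``ma`` to a batch of
    target matrices ``mbs`` (S, lb, 4); returns (S,) distances."""
    la, lb = ma.shape[0], mbs.shape[1]
    variants = [mbs]
    if allow_revcomp:
        variants.append(mbs[:, ::-1, :][:, :, _COMPLEMENT])
    best = np.full(mbs.shape[0], np.inf)
    min_ov = min(la, lb)
    for mv in variants:
        for off in _offset_range(la, lb, min_ov):
            lo, hi = max(0, off), min(la, off + lb)
            d = ma[None, lo:hi, :] - mv[:, lo - off : hi - off, :]
            n = hi - lo
            dist = np.sqrt((d * d).sum(axis=(1, 2))) / n
            np.minimum(best, dist, out=best)
    return best


def distance_matrix(motifs, allow_revcomp: bool = False, **kwargs) -> np.ndarray:
    """Symmetric pairwise SSD distance matrix over a motif list."""
    motifs = list(motifs)
    n = len(motifs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ssd_distance(motifs[i], motifs[j], allow_revcomp=allow_revcomp, **kwargs)
            dm[i, j] = dm[j, i] = d
    return dm


def cluster_motifs(
    motifs, cutoff: float = 6.0, allow_revcomp: bool = False
) -> np.ndarray:
    """Complete-linkage hierarchical clustering of motifs by SSD distance.

    The dendrogram is cut at height ``cutoff``; returned labels are 0-based
    and deterministically renumbered by the index of each cluster's first
    member, so clustering is invariant to input order up to renaming.
    """
    motifs = list(motifs)
    if not motifs:
        raise ValueError("cannot cluster an empty motif set")
    if len(motifs) == 1:
        return np.zeros(1, dtype=int)
    dm = distance_matrix(motifs, allow_revcomp=allow_revcomp)
    z = linkage(squareform(dm, checks=False), method="complete")
    raw = fcluster(z, t=cutoff, criterion="distance")
    # renumber clusters by first appearance
    mapping: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        labels[i] = mapping[r]
    return labels
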