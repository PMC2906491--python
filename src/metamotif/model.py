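"""Core domain types and closed-form metamotif mathematics.

A PWM column is a point on the 3-simplex (a multinomial over A, C, G, T); a
metamotif column is a Dirichlet distribution over such points.  The density
of a whole PWM under a metamotif factorises over columns, so everything here
reduces to Dirichlet column densities evaluated and combined in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

#: Fixed nucleotide alphabet; all matrices use this column order.
ALPHABET = ("A", "C", "G", "T")

#: Index permutation implementing the A<->T, C<->G complement map.
_COMPLEMENT = np.array([3, 2, 1, 0])

#: Weight floor applied before density evaluation so that PWMs with hard
#: zeros (simplex-boundary columns) yield finite log densities.
WEIGHT_FLOOR = 1e-4

#: Dirichlet parameter clip range used during nested-sampling inference.
ALPHA_MIN = 0.1
ALPHA_MAX = 40.0


def _as_matrix(columns, name: str) -> np.ndarray:
    arr = np.asarray(columns, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError(f"{name} must be an (L, 4) matrix, got shape {arr.shape}")
    if arr.shape[0] < 1:
        raise ValueError(f"{name} must have at least one column")
    return arr


@dataclass(frozen=True)
class PWM:
    """A named position weight matrix: ``weights[i, k]`` is the probability
    of base ``ALPHABET[k]`` at position ``i``.

    Every row must lie on the probability simplex (sum to 1 within 1e-9,
    all entries non-negative).
    """

    name: str
    weights: np.ndarray

    def __post_init__(self):
        arr = _as_matrix(self.weights, "PWM weights")
        if np.any(arr < -1e-12):
            raise ValueError(f"PWM {self.name!r} has negative weights")
        sums = arr.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"PWM {self.name!r}: column {bad[0]} sums to {sums[bad[0]]:.6g}, not 1"
            )
        object.__setattr__(self, "weights", arr)

    def __len__(self) -> int:
        return self.weights.shape[0]

    def floored(self, floor: float = WEIGHT_FLOOR) -> np.ndarray:
        """Weights floored at ``floor`` and renormalised row-wise."""
        return floor_weights(self.weights, floor)

    def reverse_complement(self, name: str | None = None) -> "PWM":
        return PWM(name or f"{self.name}_rc", self.weights[::-1, _COMPLEMENT])


@dataclass(frozen=True)
class Metamotif:
    """A named matrix of Dirichlet parameter columns: ``alpha[i, k]`` > 0.

    Column ``i`` defines Dirichlet(alpha[i]) over PWM columns.  The mean
    view is ``alpha[i] / alpha[i].sum()`` and the precision of column ``i``
    is ``alpha[i].sum()`` -- high precision means the family tolerates
    little variation at that position.
    """

    name: str
    alpha: np.ndarray
    family: str | None = field(default=None, compare=False)

    def __post_init__(self):
        arr = _as_matrix(self.alpha, "Metamotif alpha")
        if np.any(arr <= 0):
            raise ValueError(f"Metamotif {self.name!r} has non-positive alpha entries")
        object.__setattr__(self, "alpha", arr)

    def __len__(self) -> int:
        return self.alpha.shape[0]

    @property
    def means(self) -> np.ndarray:
        """(L, 4) mean nucleotide weights [X | alpha]."""
        return self.alpha / self.alpha.sum(axis=1, keepdims=True)

    @property
    def precisions(self) -> np.ndarray:
        """(L,) per-column precision alpha_0."""
        return self.alpha.sum(axis=1)

    def reverse_complement(self, name: str | None = None) -> "Metamotif":
        return Metamotif(
            name or f"{self.name}_rc", self.alpha[::-1, _COMPLEMENT], family=self.family
        )


@dataclass(frozen=True)
class DirichletParams:
    """A single Dirichlet parameter vector over (A, C, G, T)."""

    alpha: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.alpha, dtype=float).ravel()
        if arr.shape != (4,):
            raise ValueError(f"expected 4 Dirichlet parameters, got {arr.shape}")
        if np.any(arr <= 0):
            raise ValueError("Dirichlet parameters must be strictly positive")
        object.__setattr__(self, "alpha", arr)

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    @property
    def precision(self) -> float:
        return float(self.alpha.sum())


def floor_weights(weights: np.ndarray, floor: float = WEIGHT_FLOOR) -> np.ndarray:
    """Floor weights at ``floor`` and renormalise each row to sum to 1."""
    w = np.maximum(np.asarray(weights, dtype=float), floor)
    return w / w.sum(axis=-1, keepdims=True)


def multinomial_beta_log(alpha) -> float:
    """log of the multinomial beta function B(alpha).

    ``log B(alpha) = sum_k log Gamma(alpha_k) - log Gamma(sum_k alpha_k)``,
    the normalising constant of the Dirichlet density.
    """
    a = alpha.alpha if isinstance(alpha, DirichletParams) else np.asarray(alpha, float)
    if np.any(a <= 0):
        raise ValueError("multinomial beta requires strictly positive parameters")
    return float(gammaln(a).sum() - gammaln(a.sum()))


def log_column_density(x, alpha) -> float:
    """Log Dirichlet density of a nucleotide weight vector ``x`` under ``alpha``.

    ``x`` is floored at :data:`WEIGHT_FLOOR` and renormalised first, so
    boundary columns (hard zeros) evaluate to a finite value.
    """
    a = alpha.alpha if isinstance(alpha, DirichletParams) else np.asarray(alpha, float)
    xv = np.asarray(x, dtype=float).ravel()
    if xv.shape != (4,):
        raise ValueError(f"expected a 4-vector of weights, got shape {xv.shape}")
    s = xv.sum()
    if not np.isfinite(s) or s <= 0:
        raise ValueError("weight vector is not normalisable")
    xv = floor_weights(xv / s)
    return float(-multinomial_beta_log(a) + np.dot(a - 1.0, np.log(xv)))


def metamotif_log_density(pwm: PWM, mm: Metamotif) -> float:
    """Log probability density of observing PWM ``pwm`` under metamotif ``mm``.

    The columns are independent, so this is the sum over positions of the
    per-column Dirichlet log densities.
    """
    if len(pwm) != len(mm):
        raise ValueError(
            f"length mismatch: PWM has {len(pwm)} columns, metamotif has {len(mm)}"
        )
    logx = np.log(pwm.floored())
    a = mm.alpha
    norm = gammaln(a).sum() - gammaln(a.sum(axis=1)).sum()
    return float(-norm + ((a - 1.0) * logx).sum())


def mean_and_precision(mm: Metamotif) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a metamotif into (L, 4) column means and (L,) precisions."""
    return mm.means, mm.precisions


def from_mean_precision(means, precisions, name: str = "metamotif") -> Metamotif:
    """Build a metamotif from per-column mean weights and precisions.

    ``alpha[i, k] = means[i, k] * precisions[i]``; the exact inverse of
    :func:`mean_and_precision`.
    """
    m = _as_matrix(means, "means")
    p = np.asarray(precisions, dtype=float).ravel()
    if p.shape[0] != m.shape[0]:
        raise ValueError("means and precisions disagree on the number of columns")
    if np.any(p <= 0):
        raise ValueError("precisions must be strictly positive")
    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9) or np.any(m < 0):
        raise ValueError("means must lie on the probability simplex")
    return Metamotif(name, m * p[:, None])


def sample_pwm(mm: Metamotif, rng, name: str | None = None) -> PWM:
    """Draw one PWM from the metamotif: one Dirichlet draw per column."""
    rng = np.random.default_rng(rng)
    cols = np.vstack([rng.dirichlet(a) for a in mm.alpha])
    # Guard against exact zeros from extreme parameter draws.
    cols = cols / cols.sum(axis=1, keepdims=True)
    return PWM(name or f"{mm.name}_sample", cols)


def reverse_complement(obj):
    """Reverse-complement a PWM or metamotif.

    Column order is reversed and, within each column, the A and T entries
    and the C and G entries are swapped.
    """
    return obj.reverse_complement()


def information_content(weights: np.ndarray) -> np.ndarray:
    """Per-column information content in bits: 2 - Shannon entropy."""
    w = floor_weights(np.asarray(weights, dtype=float))
    ent = -(w * np.log2(w)).sum(axis=-1)
    return 2.0 - ent
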