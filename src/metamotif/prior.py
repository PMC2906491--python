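"""Metamotif-based Bayesian prior density over PWMs, and conversions from
PWMs / IUPAC consensus strings into metamotifs.

The prior density of a PWM under a collection of metamotifs is the sum,
over metamotifs and over every gapless window of the PWM of matching
length, of the metamotif density of that window.  Because it is a sum (not
an average) over windows it scales with PWM length; callers comparing PWMs
of different lengths should account for this.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import PWM, Metamotif, floor_weights

#: Log-density returned when no metamotif fits in the PWM at all;
#: effectively excludes the configuration.
FLOOR_LOG_DENSITY = -1e9

#: IUPAC degenerate nucleotide codes mapped to allowed bases (A,C,G,T order).
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def window_log_densities(pwm_or_weights, mm: Metamotif) -> np.ndarray:
    """Log metamotif density of every length-l window of a PWM.

    Returns a vector of length ``L - l + 1`` (empty when the metamotif is
    longer than the PWM).
    """
    if isinstance(pwm_or_weights, PWM):
        w = pwm_or_weights.floored()
    else:
        w = floor_weights(np.asarray(pwm_or_weights, dtype=float))
    logx = np.log(w)
    l = len(mm)
    L = logx.shape[0]
    if L < l:
        return np.empty(0)
    a = mm.alpha
    norm = gammaln(a).sum() - gammaln(a.sum(axis=1)).sum()
    coef = a - 1.0  # (l, 4)
    win = np.lib.stride_tricks.sliding_window_view(logx, l, axis=0)  # (L-l+1, 4, l)
    return np.einsum("wkl,lk->w", win, coef) - norm


def pwm_prior_log_density(
    pwm: PWM, metamotifs, allow_revcomp: bool = False
) -> float:
    """Log prior density of a PWM under a list of metamotifs.

    Sums ``exp(metamotif log density)`` over every gapless window of the
    PWM matching each metamotif's length (plus the reverse-complement
    orientation of each window when ``allow_revcomp``), across all
    metamotifs, returning the total in log space.  If no metamotif fits in
    the PWM the configured floor log-density is returned with a warning.
    """
    metamotifs = list(metamotifs)
    parts = []
    for mm in metamotifs:
        vals = window_log_densities(pwm, mm)
        if vals.size:
            parts.append(vals)
        if allow_revcomp:
            vals_rc = window_log_densities(pwm, mm.reverse_complement())
            if vals_rc.size:
                parts.append(vals_rc)
    if not parts:
        warnings.warn(
            f"no metamotif fits within PWM {pwm.name!r} "
            f"({len(pwm)} columns); returning floor log density",
            RuntimeWarning,
        )
        return FLOOR_LOG_DENSITY
    return float(logsumexp(np.concatenate(parts)))


def pwm_to_metamotif(
    pwm: PWM,
    pseudocount: float = 0.1,
    precision: float = 4.0,
    name: str | None = None,
) -> Metamotif:
    """Interpret a PWM as a metamotif with a constant column precision.

    Each column gets ``pseudocount`` added to every weight and is
    renormalised; the result is taken as the Dirichlet mean and multiplied
    by ``precision`` to give the parameters.  The defaults (0.1, 4.0) suit
    the hypothesis-testing use of known PWMs as motif-inference priors.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if precision <= 0:
        raise ValueError("precision must be strictly positive")
    w = pwm.weights + pseudocount
    means = w / w.sum(axis=1, keepdims=True)
    return Metamotif(name or pwm.name, means * precision)


def consensus_to_pwm(iupac: str, name: str | None = None) -> PWM:
    """Expand an IUPAC consensus string into a PWM with equal weights over
    each code's allowed bases and zeros elsewhere."""
    if not iupac:
        raise ValueError("empty consensus string")
    rows = []
    for pos, ch in enumerate(iupac.upper()):
        bases = IUPAC_CODES.get(ch)
        if bases is None:
            raise ValueError(
                f"unknown IUPAC code {ch!r} at position {pos} in {iupac!r}"
            )
        row = np.zeros(4)
        for b in bases:
            row[_BASE_INDEX[b]] = 1.0 / len(bases)
        rows.append(row)
    return PWM(name or iupac, np.vstack(rows))


def consensus_to_metamotif(
    iupac: str,
    pseudocount: float = 0.1,
    precision: float = 4.0,
    name: str | None = None,
) -> Metamotif:
    """Convert an IUPAC consensus string straight to a metamotif.

    The string is expanded to a PWM (equal weights over each code's allowed
    bases) and then converted with :func:`pwm_to_metamotif`.
    """
    return pwm_to_metamotif(
        consensus_to_pwm(iupac, name=name), pseudocount=pseudocount,
        precision=precision, name=name,
    )
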