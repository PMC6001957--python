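"""Dating germline invasions from the divergence among ERV copies.

All copies of a single germline invasion start identical (they derive from
one integrated provirus) and then decay independently at the host's neutral
rate mu.  The largest pairwise distance d among copies therefore brackets
the age of the invasion: t = d / (2 mu), the factor 2 because both copies of
a pair accumulated substitutions.  Distances are Kimura two-parameter (K2P),
which corrects separately for multiple transitions (proportion P) and
transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites with a gap or ambiguity in either sequence are excluded pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

__all__ = ["K2PResult", "DatingResult", "SaturationError", "k2p_distance",
           "max_pairwise_distance", "invasion_time", "MU_LOW", "MU_HIGH"]

# host neutral substitution rate bounds (substitutions/site/year)
MU_LOW = 1.9e-9
MU_HIGH = 2.4e-9

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_UNAMBIGUOUS = frozenset("ACGT")


class SaturationError(ValueError):
    """Raised when P, Q leave the domain of the K2P log corrections."""


@dataclass(frozen=True)
class K2PResult:
    P: float        # transition proportion
    Q: float        # transversion proportion
    d: float        # substitutions/site
    n_sites: int    # compared (unambiguous, ungapped) sites


@dataclass(frozen=True)
class DatingResult:
    d_max: float
    mu_low: float
    mu_high: float
    t_low: float    # years, at mu_high (faster clock -> younger bound)
    t_high: float   # years, at mu_low


def k2p_distance(seq_a: str, seq_b: str) -> K2PResult:
    """Kimura two-parameter distance between two aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}")
    n = transitions = transversions = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in _UNAMBIGUOUS or b not in _UNAMBIGUOUS:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"distance saturated (P={P:.3f}, Q={Q:.3f}); K2P undefined")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, d=d, n_sites=n)


def max_pairwise_distance(seqs: Sequence[str],
                          ids: Sequence[str] | None = None,
                          ) -> tuple[float, tuple[str, str]]:
    """Largest defined pairwise K2P distance; saturated pairs are skipped.

    Returns ``(d_max, (id_a, id_b))``.  Raises if fewer than two sequences
    are given or every pair is saturated.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if ids is None:
        ids = [str(i) for i in range(len(seqs))]
    best: tuple[float, tuple[str, str]] | None = None
    n_saturated = 0
    for i, j in combinations(range(len(seqs)), 2):
        try:
            res = k2p_distance(seqs[i], seqs[j])
        except SaturationError:
            n_saturated += 1
            continue
        if best is None or res.d > best[0]:
            best = (res.d, (ids[i], ids[j]))
    if best is None:
        raise SaturationError("all pairs saturated; no defined distance")
    if n_saturated:
        import logging
        logging.getLogger("ervpipe.dating").warning(
            "%d saturated pairs skipped", n_saturated)
    return best


def invasion_time(d: float,
                  mu_range: tuple[float, float] = (MU_LOW, MU_HIGH),
                  ) -> DatingResult:
    """Invasion-time window t = d/(2 mu) at both neutral-rate bounds."""
    mu_low, mu_high = mu_range
    if mu_low <= 0 or mu_high <= 0:
        raise ValueError("mu must be positive")
    if mu_low > mu_high:
        raise ValueError("mu_low must be <= mu_high")
    if d < 0:
        raise ValueError("distance must be >= 0")
    return DatingResult(
        d_max=d, mu_low=mu_low, mu_high=mu_high,
        t_low=d / (2.0 * mu_high), t_high=d / (2.0 * mu_low),
    )
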