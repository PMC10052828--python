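"""Permutation test for overlap between two gene sets within a universe.

The observed overlap |A ∩ B| is compared against the null obtained by
repeatedly drawing a uniform random subset of the universe of size |B| and
recording its overlap with A.  The add-one p-value estimator
``(1 + #{null >= observed}) / (n_perm + 1)`` avoids p = 0 from finite
permutations.  The null is hypergeometric, so the exact tail probability is
available as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass
class OverlapTest:
    universe_size: int
    set_a_size: int
    set_b_size: int
    observed_overlap: int
    null_overlaps: np.ndarray = field(repr=False)
    p_value: float = 1.0
    n_perm: int = 1000
    seed: int = 0


def overlap_permutation_test(
    set_a: Iterable,
    set_b: Iterable,
    universe: Iterable,
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapTest:
    """Permutation overlap enrichment of set_a within random size-|B| sets."""
    universe = list(dict.fromkeys(universe))
    a = set(set_a)
    b = set(set_b)
    uni = set(universe)
    if not a <= uni or not b <= uni:
        raise ValidationError("both sets must be contained in the universe")
    mask_a = np.array([g in a for g in universe])
    observed = len(a & b)
    rng = np.random.default_rng(seed)
    n_u = len(universe)
    k_b = len(b)
    nulls = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        idx = rng.choice(n_u, size=k_b, replace=False)
        nulls[i] = int(mask_a[idx].sum())
    p = (1 + int((nulls >= observed).sum())) / (n_perm + 1)
    return OverlapTest(
        universe_size=n_u,
        set_a_size=len(a),
        set_b_size=k_b,
        observed_overlap=observed,
        null_overlaps=nulls,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


def hypergeometric_tail(
    universe_size: int, k_a: int, k_b: int, observed: int
) -> float:
    """Exact upper-tail P(X >= observed), X ~ Hypergeom(universe, k_a, k_b)."""
    if not (0 <= k_a <= universe_size and 0 <= k_b <= universe_size):
        raise ValidationError("set sizes must lie within the universe")
    if observed < 0:
        raise ValidationError("observed overlap cannot be negative")
    if observed > min(k_a, k_b):
        return 0.0
    if observed == 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, universe_size, k_a, k_b))
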