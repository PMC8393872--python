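"""Overlap statistics on restricted gene universes.

All list comparisons in the pipeline go through this module: explicit
restriction of gene lists to a detection universe, one-sided hypergeometric
over-representation tests, three-way Venn region counts, and
Benjamini-Hochberg multiple-testing adjustment.

The over-representation p-value for an overlap of size ``k`` between lists of
sizes ``n1`` and ``n2`` drawn from a universe of size ``N`` is the upper tail
``P(X >= k)`` of ``X ~ Hypergeometric(N, n1, n2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetOverlap",
    "restrict_to_universe",
    "hypergeom_overlap",
    "hypergeom_tail",
    "triple_overlap",
    "bh_adjust",
]


@dataclass(frozen=True)
class GeneSetOverlap:
    """Result of a two-list over-representation test.

    Attributes
    ----------
    universe_size : int
        Size ``N`` of the restricted universe both lists live in.
    size_a, size_b : int
        List sizes after de-duplication.
    overlap : int
        ``|A ∩ B|``.
    p_value : float
        Upper-tail hypergeometric p-value, in ``(0, 1]``.
    """

    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    p_value: float


def _check_unique(genes: Sequence[str], label: str) -> None:
    seen: set[str] = set()
    dupes: set[str] = set()
    for g in genes:
        if g in seen:
            dupes.add(g)
        seen.add(g)
    if dupes:
        raise ValueError(
            f"duplicate identifiers in {label}: {sorted(dupes)[:10]}"
        )


def restrict_to_universe(genes: Iterable[str], universe: Iterable[str]) -> list[str]:
    """Intersect ``genes`` with ``universe``, preserving the order of ``genes``."""
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    return [g for g in genes if g in uni]


def hypergeom_tail(k: int, N: int, n1: int, n2: int) -> float:
    """Upper-tail ``P(X >= k)`` for ``X ~ Hypergeometric(N, n1, n2)``.

    Clipped into ``(0, 1]`` so a zero overlap always reports p = 1 and
    underflow never returns exactly 0.
    """
    p = float(hypergeom.sf(k - 1, N, n1, n2))
    return min(max(p, np.finfo(float).tiny), 1.0)


def hypergeom_overlap(
    list_a: Sequence[str], list_b: Sequence[str], universe: Sequence[str]
) -> GeneSetOverlap:
    """One-sided over-representation test of the overlap of two gene lists.

    Both lists must already be restricted to ``universe``; passing an
    unrestricted list raises, which forces the caller to state its universe
    explicitly (detection universes differ between experiments and silently
    mixing them inflates significance).
    """
    _check_unique(list_a, "list_a")
    _check_unique(list_b, "list_b")
    _check_unique(universe, "universe")
    uni = set(universe)
    a, b = set(list_a), set(list_b)
    for name, s in (("list_a", a), ("list_b", b)):
        stray = s - uni
        if stray:
            raise ValueError(
                f"{name} is not contained in the universe "
                f"(e.g. {sorted(stray)[:5]}); restrict_to_universe() first"
            )
    k = len(a & b)
    p = hypergeom_tail(k, len(uni), len(a), len(b))
    return GeneSetOverlap(len(uni), len(a), len(b), k, p)


def triple_overlap(
    lists: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    universe: Sequence[str],
) -> dict[str, int]:
    """Exclusive Venn region counts for three gene lists.

    Returns a dict with keys ``a``, ``b``, ``c`` (exclusive singles), ``ab``,
    ``ac``, ``bc`` (exclusive pairs) and ``abc`` (triple intersection), where
    a/b/c follow the input order.
    """
    if isinstance(lists, Mapping):
        seqs = list(lists.values())
    else:
        seqs = list(lists)
    if len(seqs) != 3:
        raise ValueError(f"triple_overlap needs exactly 3 lists, got {len(seqs)}")
    uni = set(universe)
    sets = []
    for i, s in enumerate(seqs):
        _check_unique(s, f"list {i}")
        ss = set(s)
        if ss - uni:
            raise ValueError(f"list {i} not restricted to the universe")
        sets.append(ss)
    a, b, c = sets
    return {
        "a": len(a - b - c),
        "b": len(b - a - c),
        "c": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(a & b & c),
    }


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    q(i) = min_{j >= i} p(j) * m / j over the ascending p ranking, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
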