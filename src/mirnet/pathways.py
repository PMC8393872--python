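"""Over-representation analysis against GMT gene-set collections.

Includes the leave-one-out list merging used to combine the three
experiments (every union that omits exactly one experiment, plus the full
union) and the top-N pathway-overlap comparison between two ORA result
tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import setstats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "merge_lists",
    "ora",
    "top_n_overlap",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (members de-duplicated, insertion order kept)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, "
                    f"description and at least one member)"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(m for m in fields[2:] if m))
    return GeneSetCollection(sets=sets, source=source or str(path))


def write_gmt(collection: GeneSetCollection, path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def merge_lists(
    lists: Mapping[str, Sequence[str]],
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Singles, leave-one-out unions and the full union of selected gene lists.

    Returns ``(merged, provenance)`` where ``merged`` maps a combination name
    (each input name; ``combined_minus_<name>`` for every union leaving that
    experiment out, when there are >= 3 inputs; and ``combined``) to its
    de-duplicated union in first-seen order, and ``provenance`` maps each gene
    to the sorted input names that contributed it.
    """
    names = list(lists)
    if len(names) < 2:
        raise ValueError("need at least 2 lists to merge")

    def union(keys: Sequence[str]) -> list[str]:
        out: dict[str, None] = {}
        for key in keys:
            for g in lists[key]:
                out.setdefault(g, None)
        return list(out)

    merged: dict[str, list[str]] = {n: list(dict.fromkeys(lists[n])) for n in names}
    if len(names) >= 3:
        for leave_out in names:
            merged[f"combined_minus_{leave_out}"] = union(
                [n for n in names if n != leave_out]
            )
    merged["combined"] = union(names)
    provenance: dict[str, list[str]] = {}
    for n in names:
        for g in lists[n]:
            provenance.setdefault(g, [])
            if n not in provenance[g]:
                provenance[g].append(n)
    provenance = {g: sorted(v) for g, v in provenance.items()}
    return merged, provenance


def ora(
    gene_list: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in every set.

    Sets are intersected with the universe before testing; the list must
    already live inside the universe.  Columns: set_name, hits, set_size,
    list_size, universe_size, p_value, q_value; sorted by p ascending, ties
    by set name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    lst = set(gene_list)
    if lst - uni:
        raise ValueError("gene list is not contained in the universe; restrict first")
    N, n = len(uni), len(lst)
    rows = []
    for name, members in collection.sets.items():
        m_set = set(members) & uni
        m = len(m_set)
        k = len(lst & m_set)
        p = setstats.hypergeom_tail(k, N, m, n) if m else 1.0
        rows.append((name, k, m, n, N, p))
    df = pd.DataFrame(
        rows, columns=["set_name", "hits", "set_size", "list_size", "universe_size", "p_value"]
    )
    df["q_value"] = setstats.bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return df


def top_n_overlap(
    result_a: pd.DataFrame, result_b: pd.DataFrame, n: int = 100
) -> setstats.GeneSetOverlap:
    """Overlap of the two results' top-n set names, tested hypergeometrically
    over the universe of all sets in the (shared) collection."""
    names_a = set(result_a["set_name"])
    names_b = set(result_b["set_name"])
    if names_a != names_b:
        raise ValueError("ORA results were not computed against the same collection")
    n_eff = min(n, len(result_a), len(result_b))
    if n_eff < n:
        warnings.warn(f"top_n truncated from {n} to {n_eff}", stacklevel=2)
    top_a = list(result_a["set_name"].iloc[:n_eff])
    top_b = list(result_b["set_name"].iloc[:n_eff])
    return setstats.hypergeom_overlap(top_a, top_b, sorted(names_a))
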