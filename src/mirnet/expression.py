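"""Transcriptome fold-change selection and SILAC peptide-to-protein rollup.

Transcript-level input is a finished log2 fold-change table (miRNA vs
control).  Proteome input is a peptide ratio table from a SILAC label-swap
design: per mix, log2 ratios are scale-normalized (median shifted to 0 to
absorb mixing errors), label-swap replicates are averaged per peptide, and
protein ratios are the geometric mean of their peptides (arithmetic mean in
log2 space).  Proteins quantified by fewer than 3 peptides are dropped.
Significance is a two-sided one-sample t-test of peptide log2 ratios against
0, BH-adjusted.
"""

from __future__ import annotations

import sys

import numpy as np
import pandas as pd
from scipy import stats

from .setstats import bh_adjust

__all__ = [
    "read_fold_changes",
    "read_peptides",
    "scale_normalize",
    "rollup_protein",
    "select_by_foldchange",
    "select_proteins",
]

#: p-value assigned when peptide ratios are identical but nonzero (t undefined)
P_DEGENERATE = sys.float_info.min


def read_fold_changes(path) -> pd.DataFrame:
    """Read a TSV with columns gene, log2fc (optional boolean column detected)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "log2fc"} <= set(df.columns):
        raise ValueError("fold-change table needs columns 'gene' and 'log2fc'")
    if "detected" not in df.columns:
        df["detected"] = True
    bad = df.loc[df["detected"] & ~np.isfinite(df["log2fc"])]
    if len(bad):
        raise ValueError(f"non-finite log2fc for detected genes: {list(bad['gene'])[:5]}")
    return df


def read_peptides(path) -> pd.DataFrame:
    """Read a peptide TSV with columns peptide, protein, mix, log2_ratio."""
    df = pd.read_csv(path, sep="\t")
    need = {"peptide", "protein", "log2_ratio"}
    if not need <= set(df.columns):
        raise ValueError(f"peptide table needs columns {sorted(need)}")
    if "mix" not in df.columns:
        df["mix"] = "mix1"
    return df


def scale_normalize(peptides: pd.DataFrame) -> pd.DataFrame:
    """Shift log2 ratios so every mix has median 0 (compensates mixing errors)."""
    if peptides.empty:
        raise ValueError("empty peptide table")
    out = peptides.copy()
    out["log2_ratio"] = peptides.groupby("mix")["log2_ratio"].transform(
        lambda x: x - x.median()
    )
    return out


def rollup_protein(peptides: pd.DataFrame, min_peptides: int = 3) -> pd.DataFrame:
    """Roll peptide log2 ratios up to protein-level calls.

    Label-swap replicates (rows sharing a peptide id across mixes) are averaged
    at the peptide level first; protein log2 ratio is then the mean of its
    peptide log2 ratios (geometric mean on the raw scale).  Proteins with fewer
    than ``min_peptides`` distinct quantified peptides are dropped.  The
    p-value is a two-sided one-sample t-test of the peptide log2 ratios
    against 0; a protein whose peptides are exactly identical but nonzero has
    no defined t statistic and receives the smallest representable p-value
    with ``degenerate=True``.
    """
    if min_peptides < 3:
        raise ValueError("min_peptides must be >= 3")
    pep = (
        peptides.groupby(["protein", "peptide"], sort=True)["log2_ratio"]
        .mean()
        .reset_index()
    )
    rows = []
    for protein, grp in pep.groupby("protein", sort=True):
        x = grp["log2_ratio"].to_numpy(dtype=float)
        if x.size < min_peptides:
            continue
        mean = float(x.mean())
        degenerate = False
        if np.all(x == x[0]):
            if mean == 0.0:
                p = 1.0
            else:
                p = P_DEGENERATE
                degenerate = True
        else:
            p = float(stats.ttest_1samp(x, 0.0).pvalue)
        rows.append((protein, mean, x.size, p, degenerate))
    if not rows:
        raise ValueError(f"no protein has >= {min_peptides} quantified peptides")
    out = pd.DataFrame(
        rows, columns=["protein", "log2_ratio", "n_peptides", "p_value", "degenerate"]
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def select_by_foldchange(
    table: pd.DataFrame, cutoff: float = 0.5, fc_column: str = "log2fc", id_column: str = "gene"
) -> tuple[list[str], list[str]]:
    """Split a fold-change table into (down, up) lists at a closed threshold.

    down: log2fc <= -cutoff (most down-regulated first);
    up:   log2fc >= +cutoff (most up-regulated first).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    t = table
    if "detected" in t.columns:
        t = t.loc[t["detected"]]
    fc = t.set_index(id_column)[fc_column]
    down = fc[fc <= -cutoff].sort_values(kind="stable")
    up = fc[fc >= cutoff].sort_values(ascending=False, kind="stable")
    key = lambda s, sign: [g for g, _ in sorted(s.items(), key=lambda kv: (sign * kv[1], kv[0]))]
    return key(down, +1), key(up, -1)


def select_proteins(
    protein_table: pd.DataFrame, cutoff: float = 0.5, fdr: float | None = None
) -> tuple[list[str], list[str]]:
    """Down/up protein lists by fold change, optionally also requiring q <= fdr."""
    t = protein_table
    if fdr is not None:
        t = t.loc[t["q_value"] <= fdr]
    return select_by_foldchange(t, cutoff=cutoff, fc_column="log2_ratio", id_column="protein")
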