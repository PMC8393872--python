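"""Seed-word derivation and hypergeometric k-mer enrichment scans over 3'UTRs.

Given a gene list ranked by some signal (pull-down enrichment ratio or
expression fold change), the scan asks, for every DNA word of length k,
whether the word is over- or under-represented in the leading window of the
ranking relative to the whole list.  Counting is occurrence-based: the balls
of the hypergeometric urn are k-mer occurrences, words drawn from nested
leading windows of growing size until the window covers every sequence.  For
a word with K occurrences among N total k-mers, observed k_obs times among
the n k-mers of the current window, the reported value is

    +(-log10 P(X >= k_obs))   if the over-representation tail is smaller,
    -(-log10 P(X <= k_obs))   otherwise,        X ~ Hypergeometric(N, K, n).

A genuine miRNA signature shows as a peak of the seed-complementary word near
the window cut that separates targets from the rest of the ranking.

Seed-match words follow the canonical site-type conventions: the 8mer site is
the reverse complement of miRNA positions 2-8 followed by an A opposite
position 1; 7mer-m8 drops the A, 7mer-A1 drops the position-8 match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "SeedWords",
    "RankedUtrList",
    "WordScanResult",
    "read_fasta",
    "read_transcript_map",
    "longest_utr_per_gene",
    "derive_seed_words",
    "reverse_complement",
    "count_words",
    "sylamer_scan",
    "scan_report",
]

#: -log10(p) values are floored here to avoid underflow in the report
LOG10_FLOOR = 320.0

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_DNA_FROM_RNA = {"A": "A", "U": "T", "G": "G", "C": "C"}


@dataclass(frozen=True)
class SeedWords:
    """DNA seed-match words derived from one mature miRNA sequence."""

    mirna: str
    match_words: dict[str, str]

    def matching_types(self, word: str) -> list[str]:
        w = word.upper()
        return sorted(t for t, mw in self.match_words.items() if mw == w)


@dataclass
class RankedUtrList:
    """Genes in ranked order, one 3'UTR sequence each, signal end first."""

    genes: list[str]
    sequences: list[str]
    ranking_key: str = ""
    direction: str = "signal_first"

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.sequences):
            raise ValueError("genes and sequences differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        for g, s in zip(self.genes, self.sequences):
            if not s:
                raise ValueError(f"empty UTR sequence for gene {g}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class WordScanResult:
    """Signed -log10 hypergeometric p per (word, window cut-point)."""

    k: int
    cutpoints: list[int]
    words: list[str]
    signed_log10p: np.ndarray  # shape (n_words, n_windows)
    total_counts: np.ndarray  # occurrences of each word over the whole list
    ranking_key: str = ""
    direction: str = "signal_first"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signed_log10p, index=self.words, columns=self.cutpoints)


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered id -> uppercase sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_transcript_map(path) -> dict[str, str]:
    """Read a transcript->gene TSV (columns transcript, gene)."""
    df = pd.read_csv(path, sep="\t")
    if not {"transcript", "gene"} <= set(df.columns):
        raise ValueError("transcript map needs columns 'transcript' and 'gene'")
    return dict(zip(df["transcript"], df["gene"]))


def longest_utr_per_gene(
    utrs: Mapping[str, str], transcript_to_gene: Mapping[str, str]
) -> tuple[dict[str, str], dict[str, str]]:
    """Keep one UTR per gene: the longest, ties to the smallest transcript id.

    Returns (gene -> sequence, gene -> chosen transcript id).  Transcripts
    without a gene mapping are an error listing the offending identifiers.
    """
    unmapped = [t for t in utrs if t not in transcript_to_gene]
    if unmapped:
        raise ValueError(f"transcripts with no gene mapping: {sorted(unmapped)[:10]}")
    best: dict[str, tuple[int, str]] = {}
    for tx in sorted(utrs):  # sorted => ties resolved to smallest transcript id
        gene = transcript_to_gene[tx]
        cand = (len(utrs[tx]), tx)
        if gene not in best or cand[0] > best[gene][0]:
            best[gene] = cand
    seqs = {g: utrs[tx] for g, (_, tx) in best.items()}
    chosen = {g: tx for g, (_, tx) in best.items()}
    return seqs, chosen


def reverse_complement(dna: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
    return "".join(comp[b] for b in reversed(dna.upper()))


def derive_seed_words(mirna: str) -> SeedWords:
    """Seed-match DNA words for a mature miRNA (5'->3', RNA alphabet).

    Positions are 1-based from the miRNA 5' end; rc() is the DNA reverse
    complement of the given positions:

    - 6mer      = rc(2-7)
    - 7mer-m8   = rc(2-8)
    - 7mer-A1   = rc(2-7) + A
    - 8mer      = rc(2-8) + A
    - 5mer-core = rc(2-6), the core five seed positions
    """
    seq = mirna.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters in miRNA sequence: {sorted(bad)}")
    dna = "".join(_DNA_FROM_RNA[b] for b in seq)

    def rc(start: int, end: int) -> str:  # 1-based inclusive
        return reverse_complement(dna[start - 1 : end])

    words = {
        "6mer": rc(2, 7),
        "7mer-m8": rc(2, 8),
        "7mer-A1": rc(2, 7) + "A",
        "8mer": rc(2, 8) + "A",
        "5mer-core": rc(2, 6),
    }
    return SeedWords(mirna=seq, match_words=words)


# ---------------------------------------------------------------------------
# k-mer counting

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """Occurrence counts of all 4^k words in one sequence (overlapping,
    forward strand; windows containing non-ACGT characters are skipped)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = arr.size - k + 1
    counts = np.zeros(4**k, dtype=np.int64)
    if n <= 0:
        return counts
    valid = arr >= 0
    codes = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        codes = codes * 4 + np.where(valid[j : j + n], arr[j : j + n], 0)
        ok &= valid[j : j + n]
    np.add.at(counts, codes[ok], 1)
    return counts


def _decode(code: int, k: int) -> str:
    letters = "ACGT"
    out = []
    for _ in range(k):
        out.append(letters[code % 4])
        code //= 4
    return "".join(reversed(out))


def count_words(sequence: str, k: int) -> dict[str, int]:
    """Overlapping occurrence counts of every k-mer present in ``sequence``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = _kmer_counts(sequence, k)
    nz = np.nonzero(counts)[0]
    return {_decode(int(c), k): int(counts[c]) for c in nz}


# ---------------------------------------------------------------------------
# scan


def sylamer_scan(
    ranked: RankedUtrList,
    k: int = 7,
    window_start: int = 500,
    window_step: int = 500,
) -> WordScanResult:
    """Hypergeometric word-enrichment landscape over nested leading windows.

    Window cut-points run from ``window_start`` in steps of ``window_step``;
    the final window always covers the whole list, where every word's p-value
    is 1 and the signed value is exactly 0.
    """
    if not 4 <= k <= 8:
        warnings.warn(f"k={k} is outside the usual 4..8 range", stacklevel=2)
    n_seq = len(ranked)
    if window_start > n_seq:
        raise ValueError("window_start exceeds the number of sequences")
    if window_step <= 0:
        raise ValueError("window_step must be positive")

    cutpoints = list(range(window_start, n_seq + 1, window_step))
    if cutpoints[-1] != n_seq:
        cutpoints.append(n_seq)

    n_words = 4**k
    running = np.zeros(n_words, dtype=np.int64)
    snapshots = np.empty((len(cutpoints), n_words), dtype=np.int64)
    ci = 0
    for i, seq in enumerate(ranked.sequences):
        running += _kmer_counts(seq, k)
        while ci < len(cutpoints) and cutpoints[ci] == i + 1:
            snapshots[ci] = running
            ci += 1
    total = running
    N = int(total.sum())
    if N == 0:
        raise ValueError("no valid k-mers in the ranked list")

    signed = np.zeros((n_words, len(cutpoints)), dtype=float)
    for w, cut in enumerate(cutpoints):
        kobs = snapshots[w]
        n_in = int(kobs.sum())
        # X ~ Hypergeom(N, K, n_in); over: P(X >= kobs), under: P(X <= kobs)
        p_over = hypergeom.sf(kobs - 1, N, total, n_in)
        p_under = hypergeom.cdf(kobs, N, total, n_in)
        lo = np.power(10.0, -LOG10_FLOOR)
        over = -np.log10(np.clip(p_over, lo, 1.0))
        under = np.log10(np.clip(p_under, lo, 1.0))
        signed[:, w] = np.where(p_over <= p_under, over, under)
    signed[:, -1] = 0.0  # whole list: complement empty, p = 1 by construction

    words = [_decode(c, k) for c in range(n_words)]
    return WordScanResult(
        k=k,
        cutpoints=cutpoints,
        words=words,
        signed_log10p=signed,
        total_counts=total,
        ranking_key=ranked.ranking_key,
        direction=ranked.direction,
    )


def scan_report(
    result: WordScanResult,
    seed_words: SeedWords | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-word summary of a scan: peak signed value, its window, seed flags.

    One row per word observed anywhere in the list, sorted by peak signed
    value descending (most over-represented first).  ``flagged`` marks words
    whose peak magnitude exceeds the Bonferroni-corrected ``alpha`` line over
    all (word, window) tests.
    """
    observed = np.nonzero(result.total_counts > 0)[0]
    n_tests = len(result.words) * len(result.cutpoints)
    line = -np.log10(alpha / n_tests)
    rows = []
    for idx in observed:
        vals = result.signed_log10p[idx]
        peak_i = int(np.argmax(np.abs(vals)))
        peak = float(vals[peak_i])
        word = result.words[idx]
        types = seed_words.matching_types(word) if seed_words else []
        rows.append(
            {
                "word": word,
                "peak_signed_log10p": peak,
                "peak_window": result.cutpoints[peak_i],
                "total_count": int(result.total_counts[idx]),
                "is_seed_match": bool(types),
                "seed_match_types": ",".join(types),
                "flagged": abs(peak) > line,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["peak_signed_log10p", "word"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
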