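"""Synthetic multi-omics inputs with planted, recoverable ground truth.

Emulates the full input surface of the pipeline for one miRNA transfection
experiment: a gene universe with random 3'UTRs, seed-match sites planted in
the UTRs of true target genes, a 4-library pull-down count matrix in which
targets are enriched, transcript and peptide-level expression shifts for the
same targets, a scale-free interaction network with planted high-degree hubs
among the targets, and GMT gene sets enriched for targets.

All randomness flows from ``SimulationConfig.seed``; each generator draws
from its own ``numpy`` Generator stream spawned from that seed, so a fixed
seed yields byte-identical output files while individual stages stay
independent of each other's draw counts.

Default condition: 5000 genes, 200 targets (8-fold pull-down enrichment,
1.0 log2 down-shift at transcript and protein level over 0.3 SD biological
noise), 15 hubs, half the universe undetected at the protein level.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .pathways import GeneSetCollection, write_gmt
from .seedscan import derive_seed_words

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticData",
    "generate_universe",
    "plant_seed_sites",
    "simulate_pulldown_counts",
    "simulate_expression",
    "simulate_network",
    "simulate_genesets",
    "simulate_all",
]

#: mature hsa-miR-491-5p; seed = positions 2-8 (GUGGGGA)
DEFAULT_MIRNA = "AGUGGGGAACCCUUCCAUGAGG"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment. Lengths in nt."""

    n_genes: int = 5000
    n_targets: int = 200
    mirna_sequence: str = DEFAULT_MIRNA
    utr_length_mean: int = 800
    utr_length_sd: int = 160
    gc_content: float = 0.45
    site_type: str = "8mer"  # which seed-match variant is planted
    sites_per_target: int = 1
    pulldown_enrichment_fold: float = 8.0
    input_depletion_log2: float = 0.0  # optional down-shift of targets in miR input
    baseline_log_mean: float = np.log(300.0)
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    library_factors: tuple[float, float, float, float] = (1.0, 1.3, 0.8, 1.1)
    transcript_effect: float = 1.0
    protein_effect: float = 1.0
    noise_sd: float = 0.3
    peptide_noise_sd: float = 0.2
    mix_error_sd: float = 0.2
    peptides_per_protein_mean: int = 5
    undetected_protein_fraction: float = 0.5
    n_hubs: int = 15
    hub_extra_degree: int = 400
    hub_target_bias: float = 0.0  # fraction of extra hub edges wired to targets
    network_attachment: int = 3
    decoy_edge_fraction: float = 0.25  # fraction of background edges scored < 400
    n_genesets: int = 200
    n_enriched_genesets: int = 10
    geneset_size_range: tuple[int, int] = (20, 200)
    geneset_target_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if not 0 <= self.n_targets < self.n_genes:
            raise ValueError("need 0 <= n_targets < n_genes")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.utr_length_mean < 50:
            raise ValueError("utr_length_mean must be >= 50")
        if self.pulldown_enrichment_fold <= 0:
            raise ValueError("pulldown_enrichment_fold must be > 0")
        if self.peptides_per_protein_mean < 3:
            raise ValueError("peptides_per_protein_mean must be >= 3 "
                             "(proteins need >= 3 quantified peptides)")
        if self.n_hubs > self.n_genes:
            raise ValueError("n_hubs cannot exceed n_genes")
        lo, hi = self.geneset_size_range
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError("geneset_size_range must fit inside the gene universe")
        for name in ("transcript_effect", "protein_effect", "noise_sd",
                     "input_depletion_log2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    target_genes: list[str] = field(default_factory=list)
    hub_genes: list[str] = field(default_factory=list)
    enriched_genesets: list[str] = field(default_factory=list)
    planted_site_counts: dict[str, int] = field(default_factory=dict)
    planted_word: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticData:
    """Bundle of every pipeline input plus the ground truth."""

    config: SimulationConfig
    genes: list[str]
    utrs: dict[str, str]
    counts: pd.DataFrame
    transcript_fc: pd.DataFrame
    peptides: pd.DataFrame
    network: pd.DataFrame
    genesets: GeneSetCollection
    truth: GroundTruth


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_universe(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    """Gene identifiers plus one i.i.d. random UTR per gene.

    Nucleotides are drawn at the configured GC content (G and C equiprobable,
    likewise A and T); lengths are normal around ``utr_length_mean`` with SD
    ``utr_length_sd``, floored at 50 nt.
    """
    rng = config.rng(1)
    genes = _gene_ids(config.n_genes)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    lengths = np.maximum(
        50, np.round(rng.normal(config.utr_length_mean, config.utr_length_sd, config.n_genes))
    ).astype(int)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    utrs = {
        g: rng.choice(alphabet, size=int(L), p=probs).tobytes().decode("ascii")
        for g, L in zip(genes, lengths)
    }
    return genes, utrs


def plant_seed_sites(
    utrs: dict[str, str], config: SimulationConfig
) -> tuple[dict[str, str], GroundTruth]:
    """Choose target genes and write seed-match sites into their UTRs.

    The planted word is the configured site type derived from the miRNA
    (default the 8mer); ``sites_per_target`` non-overlapping copies replace
    the UTR substring at random positions.  Non-target UTRs are untouched.
    """
    rng = config.rng(2)
    word = derive_seed_words(config.mirna_sequence).match_words[config.site_type]
    genes = list(utrs)
    targets = sorted(rng.choice(genes, size=config.n_targets, replace=False))
    out = dict(utrs)
    site_counts: dict[str, int] = {}
    for g in targets:
        seq = out[g]
        if len(seq) < len(word):
            raise ValueError(f"UTR of gene {g} is shorter than the seed site")
        placed: list[int] = []
        attempts = 0
        while len(placed) < config.sites_per_target:
            attempts += 1
            if attempts > 1000:
                raise ValueError(f"cannot place {config.sites_per_target} sites in gene {g}")
            pos = int(rng.integers(0, len(seq) - len(word) + 1))
            if all(abs(pos - q) >= len(word) for q in placed):
                seq = seq[:pos] + word + seq[pos + len(word):]
                placed.append(pos)
        out[g] = seq
        site_counts[g] = len(placed)
    truth = GroundTruth(
        target_genes=list(targets),
        planted_site_counts=site_counts,
        planted_word=word,
    )
    return out, truth


def simulate_pulldown_counts(
    genes: list[str], truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """4-library negative-binomial count matrix with target enrichment.

    Each gene has a log-normal baseline mean shared by the four libraries;
    counts are NB with fixed dispersion; sample columns are scaled by
    distinct library-size factors; the miR pull-down mean is multiplied by
    ``pulldown_enrichment_fold`` for targets, and the miR input mean is
    down-scaled by ``input_depletion_log2`` (modeling target degradation in
    the transfected lysate).
    """
    rng = config.rng(3)
    n = len(genes)
    is_target = np.isin(genes, truth.target_genes)
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    mu = np.tile(base[:, None], (1, 4))  # columns: mir_pd ctl_pd mir_in ctl_in
    mu[is_target, 0] *= config.pulldown_enrichment_fold
    mu[is_target, 2] *= 2.0 ** (-config.input_depletion_log2)
    mu *= np.asarray(config.library_factors)[None, :]
    disp = config.nb_dispersion
    if disp > 0:
        shape = 1.0 / disp
        counts = rng.negative_binomial(shape, shape / (shape + mu))
    else:
        counts = rng.poisson(mu)
    return pd.DataFrame(
        counts, index=pd.Index(genes, name="gene"),
        columns=["mir_pd", "ctl_pd", "mir_in", "ctl_in"],
    )


def simulate_expression(
    genes: list[str], truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcript log2 fold-change table and SILAC label-swap peptide table.

    Transcript: targets ~ Normal(-transcript_effect, noise_sd), others
    ~ Normal(0, noise_sd), all genes detected.  Protein: a random
    ``1 - undetected_protein_fraction`` subset of genes is detected; each
    detected protein gets >= 3 peptides whose log2 ratios are the protein
    value plus peptide noise plus a per-mix constant mixing error, reported
    for both label orientations (mixes) already sign-aligned to miR/control.
    """
    rng = config.rng(4)
    n = len(genes)
    is_target = np.isin(genes, truth.target_genes)
    fc = rng.normal(0.0, config.noise_sd, n) - np.where(is_target, config.transcript_effect, 0.0)
    transcript = pd.DataFrame({"gene": genes, "log2fc": fc, "detected": True})

    n_detected = int(round((1.0 - config.undetected_protein_fraction) * n))
    detected = sorted(rng.choice(genes, size=n_detected, replace=False))
    det_target = np.isin(detected, truth.target_genes)
    prot_true = rng.normal(0.0, config.noise_sd, n_detected) - np.where(
        det_target, config.protein_effect, 0.0
    )
    mix_errors = {m: rng.normal(0.0, config.mix_error_sd) for m in ("mix1", "mix2")}
    extra = config.peptides_per_protein_mean - 3
    n_pep = 3 + (rng.poisson(extra, n_detected) if extra > 0 else np.zeros(n_detected, int))
    rows = []
    for g, true_val, npep in zip(detected, prot_true, n_pep):
        for i in range(int(npep)):
            pep_id = f"{g}_pep{i + 1}"
            for mix in ("mix1", "mix2"):
                noise = rng.normal(0.0, config.peptide_noise_sd) if config.peptide_noise_sd > 0 else 0.0
                rows.append((pep_id, g, mix, true_val + noise + mix_errors[mix]))
    peptides = pd.DataFrame(rows, columns=["peptide", "protein", "mix", "log2_ratio"])
    return transcript, peptides


def simulate_network(
    genes: list[str], truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Scored scale-free interaction table with planted hubs.

    The backbone is a preferential-attachment graph over all genes.  Hubs are
    drawn from the target genes (so they survive the selection stages) and
    wired to ``hub_extra_degree`` extra random partners — far past the 99th
    degree percentile, and enough that a hub's degree inside any induced
    list subnetwork scales with list size and still dominates the natural
    scale-free tail (an optional ``hub_target_bias`` fraction of the extra
    partners can instead be drawn from the targets).  Background edges get integer scores in [150, 999] with a
    ``decoy_edge_fraction`` below the 400 confidence threshold; planted hub
    edges always score >= 400.
    """
    rng = config.rng(5)
    n = len(genes)
    if config.n_hubs > n:
        raise ValueError("n_hubs cannot exceed the number of genes")
    g = nx.barabasi_albert_graph(n, config.network_attachment,
                                 seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, dict(enumerate(genes)))
    background = set(map(tuple, (sorted(e) for e in g.edges())))

    hub_pool = truth.target_genes if len(truth.target_genes) >= config.n_hubs else genes
    hubs = sorted(rng.choice(list(hub_pool), size=config.n_hubs, replace=False))
    # a planted hub must beat the whole natural scale-free tail, not just the
    # 99th percentile, so pin the extra degree above the base graph's maximum
    max_base_degree = max((d for _, d in g.degree()), default=0)
    extra = min(max(config.hub_extra_degree, max_base_degree + 10), n - 1)
    n_target_partners = int(round(config.hub_target_bias * extra))
    planted: set[tuple[str, str]] = set()
    targets = [t for t in truth.target_genes]
    others = [x for x in genes]
    for h in hubs:
        t_pool = [t for t in targets if t != h]
        partners = list(rng.choice(t_pool, size=min(n_target_partners, len(t_pool)),
                                   replace=False))
        o_pool = [o for o in others if o != h and o not in set(partners)]
        n_rand = min(extra - len(partners), len(o_pool))
        partners += list(rng.choice(o_pool, size=n_rand, replace=False))
        for p in partners:
            planted.add(tuple(sorted((h, p))))
    background -= planted

    bg = sorted(background)
    decoy = rng.random(len(bg)) < config.decoy_edge_fraction
    bg_scores = np.where(
        decoy,
        rng.integers(150, 400, len(bg)),
        rng.integers(400, 1000, len(bg)),
    )
    pl = sorted(planted)
    pl_scores = rng.integers(400, 1000, len(pl))
    df = pd.DataFrame(
        [(a, b, int(s)) for (a, b), s in zip(bg, bg_scores)]
        + [(a, b, int(s)) for (a, b), s in zip(pl, pl_scores)],
        columns=["protein_a", "protein_b", "combined_score"],
    ).sort_values(["protein_a", "protein_b"], kind="stable").reset_index(drop=True)
    truth.hub_genes = list(hubs)
    return df


def simulate_genesets(
    genes: list[str], truth: GroundTruth, config: SimulationConfig
) -> GeneSetCollection:
    """GMT collection in which the first ``n_enriched_genesets`` sets draw a
    ``geneset_target_fraction`` of their members from the target genes."""
    rng = config.rng(6)
    lo, hi = config.geneset_size_range
    if hi > len(genes):
        raise ValueError("gene set size range exceeds the universe")
    targets = list(truth.target_genes)
    non_targets = [g for g in genes if g not in set(targets)]
    sets: dict[str, list[str]] = {}
    width = max(4, len(str(config.n_genesets)))
    for i in range(config.n_genesets):
        name = f"SET_{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if i < config.n_enriched_genesets and targets:
            n_t = min(int(round(config.geneset_target_fraction * size)), len(targets))
            members = list(rng.choice(targets, size=n_t, replace=False))
            members += list(rng.choice(non_targets, size=size - n_t, replace=False))
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        sets[name] = sorted(members)
    truth.enriched_genesets = [
        f"SET_{i + 1:0{width}d}" for i in range(min(config.n_enriched_genesets, config.n_genesets))
    ]
    return GeneSetCollection(sets=sets, source="synthetic")


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None) -> SyntheticData:
    """Run every generator and optionally write the standard file layout.

    Files written when ``outdir`` is given: utrs.fasta, pulldown_counts.tsv,
    transcriptome.tsv, peptides.tsv, network_edges.tsv, sets.gmt, truth.json,
    transcript_map.tsv (identity transcript->gene map, one UTR per gene).
    """
    genes, utrs = generate_universe(config)
    utrs, truth = plant_seed_sites(utrs, config)
    counts = simulate_pulldown_counts(genes, truth, config)
    transcript_fc, peptides = simulate_expression(genes, truth, config)
    network = simulate_network(genes, truth, config)
    genesets = simulate_genesets(genes, truth, config)
    data = SyntheticData(config, genes, utrs, counts, transcript_fc,
                         peptides, network, genesets, truth)
    if outdir is not None:
        write_files(data, outdir)
    return data


def write_fasta(utrs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in utrs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_files(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "utrs": out / "utrs.fasta",
        "transcript_map": out / "transcript_map.tsv",
        "counts": out / "pulldown_counts.tsv",
        "transcriptome": out / "transcriptome.tsv",
        "peptides": out / "peptides.tsv",
        "network": out / "network_edges.tsv",
        "genesets": out / "sets.gmt",
        "truth": out / "truth.json",
    }
    write_fasta(data.utrs, paths["utrs"])
    pd.DataFrame(
        {"transcript": list(data.utrs), "gene": list(data.utrs)}
    ).to_csv(paths["transcript_map"], sep="\t", index=False)
    data.counts.to_csv(paths["counts"], sep="\t")
    data.transcript_fc.to_csv(paths["transcriptome"], sep="\t", index=False)
    data.peptides.to_csv(paths["peptides"], sep="\t", index=False)
    data.network.to_csv(paths["network"], sep="\t", index=False)
    write_gmt(data.genesets, paths["genesets"])
    data.truth.to_json(paths["truth"])
    return paths
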