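"""Synthetic data generators for every stage of the screen.

Real inputs to this kind of analysis are whole genomes, curated PWM
collections and published expression/ChIP compendia.  The generators
here build small stand-ins with known ground truth: i.i.d. background
promoters with motif words planted at chosen gaps and orientations,
expression matrices where designated target sets share a latent
condition profile, and Poisson read counts with configurable IP
enrichment at bound promoters.  Every generator is deterministic under
a fixed seed, and planting records a truth table so precision/recall
of the screen can be computed exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chipseq import SampleCounts
from .motif_scan import BASES, PWM, Promoter, reverse_complement
from .orientation import ORIENTATION_CLASSES
from .rewiring import TargetPartition

#: approximate S. cerevisiae intergenic base composition (A, C, G, T)
YEAST_COMPOSITION = (0.31, 0.19, 0.19, 0.31)

#: default planted consensus words; deliberately NOT reverse-complement
#: palindromes, so strand information survives scanning
DEFAULT_WORD_A = "TGACTCAT"
DEFAULT_WORD_B = "GCCACGTT"

DEFAULT_PROMOTER_LEN = 600


@dataclass
class FixtureSpec:
    """Knobs for a complete synthetic dataset.

    Defaults mirror the study conditions the generators emulate:
    600 bp promoters, yeast-like AT-rich composition, planted pair
    gaps within the 25 bp interaction limit, expression latent loading
    0.8 with unit noise over 20 conditions, and 4-fold IP enrichment
    at bound promoters.
    """

    seed: int = 0
    n_promoters: int = 500
    promoter_len: int = DEFAULT_PROMOTER_LEN
    composition: tuple = YEAST_COMPOSITION
    planted_fraction: float = 0.05
    max_planted_gap: int = 25
    orientation_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    n_conditions: int = 20
    loading: float = 0.8
    noise_sd: float = 1.0
    chip_depth: int = 200_000
    chip_fold: float = 4.0


def consensus_pwm(name: str, consensus: str, specificity: float = 0.97) -> PWM:
    """PWM concentrated on a consensus word.

    ``specificity`` is the probability of the consensus base at each
    position; the remainder spreads evenly over the other three bases,
    so off-consensus windows score far below the 25-fold cutoff.
    """
    freq = np.full((len(consensus), 4), (1 - specificity) / 3)
    for i, b in enumerate(consensus.upper()):
        freq[i, BASES.index(b)] = specificity
    return PWM(name=name, freq=freq)


def simulate_promoters(
    n_promoters: int,
    promoter_len: int = DEFAULT_PROMOTER_LEN,
    composition=YEAST_COMPOSITION,
    species_id: str = "sp1",
    rng=None,
    gene_prefix: str = "g",
) -> list[Promoter]:
    """i.i.d. background promoters with the given base composition."""
    rng = np.random.default_rng(rng)
    comp = np.asarray(composition, dtype=float)
    comp = comp / comp.sum()
    out = []
    for k in range(n_promoters):
        codes = rng.choice(4, size=promoter_len, p=comp)
        seq = "".join(BASES[c] for c in codes)
        out.append(
            Promoter(gene_id=f"{gene_prefix}{k:05d}", species_id=species_id,
                     sequence=seq)
        )
    return out


def plant_pair_sites(
    promoters: list[Promoter],
    pwmA: PWM,
    pwmB: PWM,
    target_genes,
    gap_choices=None,
    gap_probs=None,
    orientation_probs=(0.25, 0.25, 0.25, 0.25),
    rng=None,
):
    """Embed consensus words for both motifs in the designated promoters.

    For each target gene one (A word, gap, B word) block is written at
    a uniformly chosen position, with the gap drawn from
    ``gap_choices`` (default 0..25) and the strand pattern of the
    (upstream, downstream) words drawn from ``orientation_probs`` over
    ``(tandem_plus, tandem_minus, convergent, divergent)``.  The A word
    is always the upstream one.  Returns ``(edited promoters, truth
    table)`` where the truth table records gene, gap, orientation and
    the two word starts.
    """
    rng = np.random.default_rng(rng)
    if gap_choices is None:
        gap_choices = np.arange(26)
    gap_choices = np.asarray(gap_choices)
    orientation_probs = np.asarray(orientation_probs, dtype=float)
    if not np.isclose(orientation_probs.sum(), 1.0):
        raise ValueError("orientation probabilities must sum to 1")
    targets = set(target_genes)
    wordA, wordB = pwmA.consensus, pwmB.consensus
    wA, wB = len(wordA), len(wordB)
    edited = []
    records = []
    for prom in promoters:
        if prom.gene_id not in targets:
            edited.append(prom)
            continue
        gap = int(rng.choice(gap_choices, p=gap_probs))
        span = wA + gap + wB
        if span > prom.length:
            raise ValueError(
                f"planted block ({span} bp) does not fit promoter "
                f"{prom.gene_id} ({prom.length} bp)"
            )
        start = int(rng.integers(0, prom.length - span + 1))
        cls = ORIENTATION_CLASSES[rng.choice(4, p=orientation_probs)]
        s_up, s_down = {
            "tandem_plus": ("+", "+"),
            "tandem_minus": ("-", "-"),
            "convergent": ("+", "-"),
            "divergent": ("-", "+"),
        }[cls]
        up_word = wordA if s_up == "+" else reverse_complement(wordA)
        down_word = wordB if s_down == "+" else reverse_complement(wordB)
        seq = list(prom.sequence)
        seq[start : start + wA] = up_word
        seq[start + wA + gap : start + span] = down_word
        edited.append(
            Promoter(prom.gene_id, prom.species_id, "".join(seq))
        )
        records.append(
            {
                "gene_id": prom.gene_id,
                "gap": gap,
                "orientation": cls,
                "startA": start,
                "startB": start + wA + gap,
            }
        )
    truth = pd.DataFrame(
        records, columns=["gene_id", "gap", "orientation", "startA", "startB"]
    )
    return edited, truth


def write_promoter_genome(promoters, fasta_path, gff_path, gene_len: int = 30):
    """One chromosome per promoter with the gene downstream of it.

    The chromosome holds the promoter followed by a poly-A stand-in for
    the coding region; the GFF gene record starts right after the
    promoter, so extracting 600 bp upstream recovers the promoter
    byte-for-byte.
    """
    with open(fasta_path, "w") as fa, open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for p in promoters:
            chrom = f"chr_{p.gene_id}"
            fa.write(f">{chrom}\n{p.sequence}{'A' * gene_len}\n")
            gff.write(
                f"{chrom}\tsim\tgene\t{p.length + 1}\t{p.length + gene_len}\t"
                f".\t+\t.\tID={p.gene_id}\n"
            )


def simulate_expression_matrix(
    genes,
    target_sets: dict[str, float] | list,
    n_conditions: int = 20,
    loading: float = 0.8,
    noise_sd: float = 1.0,
    rng=None,
    condition_prefix: str = "c",
) -> pd.DataFrame:
    """Expression matrix where each target set shares a latent profile.

    ``target_sets`` maps each coherent set (frozenset/tuple of gene
    ids) to its loading, or is a list of sets all using ``loading``.
    Members get ``loading * latent(condition) + N(0, noise_sd)``; every
    other gene is pure noise.  Latents are i.i.d. standard normal per
    condition and independent between sets.
    """
    if not 0 <= loading <= 1:
        raise ValueError("loading must be in [0, 1]")
    rng = np.random.default_rng(rng)
    genes = list(genes)
    if not isinstance(target_sets, dict):
        target_sets = {tuple(s): loading for s in target_sets}
    conditions = [f"{condition_prefix}{j:03d}" for j in range(n_conditions)]
    data = rng.normal(0.0, noise_sd, size=(len(genes), n_conditions))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for members, lam in target_sets.items():
        if not 0 <= lam <= 1:
            raise ValueError("loading must be in [0, 1]")
        latent = rng.normal(0.0, 1.0, size=n_conditions)
        for g in members:
            if g in gene_pos:
                data[gene_pos[g]] += lam * latent
    return pd.DataFrame(data, index=genes, columns=conditions)


def simulate_rewiring_scenario(
    n_A: int = 12,
    n_B: int = 15,
    n_C: int = 12,
    n_background: int = 150,
    n_conditions: int = 30,
    loading: float = 0.8,
    noise_sd: float = 1.0,
    rewired: bool = True,
    rng=None,
):
    """Two-species expression data for the A/B/C permutation test.

    In the rewired scenario, A and B share the species-1 latent while B
    and C share an independent species-2 latent — the pattern expected
    when the pair's targets genuinely differ between species.  With
    ``rewired=False``, A and C are exchangeable (only B is coherent in
    both species), the null of the permutation test.

    Returns ``(partition, expr_sp1, expr_sp2, orthologs)``; species-2
    gene ids are the species-1 ids prefixed with ``"b_"``.
    """
    rng = np.random.default_rng(rng)
    A = [f"ga{k:04d}" for k in range(n_A)]
    B = [f"gb{k:04d}" for k in range(n_B)]
    C = [f"gc{k:04d}" for k in range(n_C)]
    bg = [f"gx{k:04d}" for k in range(n_background)]
    genes = A + B + C + bg
    orthologs = {g: f"b_{g}" for g in genes}

    sp1_sets = {tuple(A + B): loading} if rewired else {tuple(B): loading}
    sp2_core = B + C if rewired else B
    expr1 = simulate_expression_matrix(
        genes, sp1_sets, n_conditions, loading, noise_sd, rng=rng
    )
    expr2 = simulate_expression_matrix(
        [orthologs[g] for g in genes],
        {tuple(orthologs[g] for g in sp2_core): loading},
        n_conditions,
        loading,
        noise_sd,
        rng=rng,
    )
    partition = TargetPartition(
        pair=("TFA", "TFB"), set_A=set(A), set_B=set(B), set_C=set(C)
    )
    return partition, expr1, expr2, orthologs


def simulate_chip_counts(
    genes,
    bound_sets: dict[str, float],
    depth_per_promoter: float = 50.0,
    n_replicates: int = 3,
    rng=None,
    sample_prefix: str = "s",
) -> tuple[list[SampleCounts], list[SampleCounts]]:
    """Poisson IP/INPUT promoter counts with planted enrichment.

    INPUT counts are Poisson(``depth_per_promoter``) everywhere; IP
    counts are Poisson(depth x fold) at promoters named in
    ``bound_sets`` (gene -> fold, folds >= 1) and Poisson(depth)
    elsewhere.  Returns matched (ip_replicates, input_replicates).
    """
    rng = np.random.default_rng(rng)
    genes = list(genes)
    if any(f < 1 for f in bound_sets.values()):
        raise ValueError("enrichment folds must be >= 1")
    if depth_per_promoter <= 0:
        raise ValueError("depth must be > 0")
    folds = np.array([bound_sets.get(g, 1.0) for g in genes])
    # library size is dominated by genome-wide background, not by the
    # handful of enriched promoters: keep totals fixed per sample so RPM
    # normalization does not couple unrelated promoters
    total = int(depth_per_promoter * len(genes) * 20)
    ips, inputs = [], []
    for r in range(n_replicates):
        ip_counts = rng.poisson(depth_per_promoter * folds)
        in_counts = rng.poisson(depth_per_promoter, size=len(genes))
        ips.append(
            SampleCounts(
                sample_id=f"{sample_prefix}_ip_{r + 1}",
                role="IP",
                replicate=r + 1,
                counts=dict(zip(genes, map(int, ip_counts))),
                total_mapped=total,
            )
        )
        inputs.append(
            SampleCounts(
                sample_id=f"{sample_prefix}_input_{r + 1}",
                role="INPUT",
                replicate=r + 1,
                counts=dict(zip(genes, map(int, in_counts))),
                total_mapped=total,
            )
        )
    return ips, inputs


def simulate_chip_reads(
    chrom_lengths: dict[str, int],
    bound_intervals: list[tuple[str, int, int]],
    n_background_reads: int = 20000,
    reads_per_bound_site: int = 60,
    read_len: int = 42,
    rng=None,
):
    """Aligned-read positions: uniform background plus piles at bound sites.

    Returns BED-style tuples ``(chrom, start, end, strand)``.  Used to
    exercise read counting and the window peak caller end to end.
    """
    rng = np.random.default_rng(rng)
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    reads = []
    picks = rng.choice(len(chroms), size=n_background_reads, p=lens / lens.sum())
    for k in picks:
        start = int(rng.integers(0, max(chrom_lengths[chroms[k]] - read_len, 1)))
        reads.append((chroms[k], start, start + read_len, "+"))
    for chrom, lo, hi in bound_intervals:
        for _ in range(reads_per_bound_site):
            start = int(rng.integers(lo, max(hi - read_len, lo + 1)))
            reads.append((chrom, start, start + read_len, "+"))
    return reads


def write_reads_bed(reads, path):
    with open(path, "w") as fh:
        for k, (chrom, start, end, strand) in enumerate(reads):
            fh.write(f"{chrom}\t{start}\t{end}\tread{k}\t0\t{strand}\n")


def write_expression_tsv(expr: pd.DataFrame, path):
    expr.to_csv(path, sep="\t", na_rep="NA")


def write_gmt(terms: dict[str, set[str]], path):
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")


def spec_to_json(spec: FixtureSpec, path):
    with open(path, "w") as fh:
        json.dump(spec.__dict__, fh, indent=2, default=list)


def spec_from_json(path) -> FixtureSpec:
    with open(path) as fh:
        d = json.load(fh)
    d["composition"] = tuple(d.get("composition", YEAST_COMPOSITION))
    d["orientation_probs"] = tuple(d.get("orientation_probs", (0.25,) * 4))
    return FixtureSpec(**d)
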