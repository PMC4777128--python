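"""Promoter-level ChIP occupancy quantification and differential tests.

Aligned read 5' positions are counted per promoter (the 600 bp upstream
of each translational start), normalized to reads per million mapped
(RPM), and expressed as IP/INPUT enrichment ratios.  Replicate peak
calls define, for a TF pair, three equal-size target gene sets (joint,
TF1-only, TF2-only); a paired test over genes then asks whether
occupancy in a cofactor-deletion strain differs from wild type within
each set.  A simple Poisson sliding-window peak caller against the
INPUT track is provided; externally produced peak BEDs work the same.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

DEFAULT_WINDOW = 300
DEFAULT_STEP = 50
DEFAULT_PEAK_ALPHA = 1e-5
PSEUDOCOUNT_READS = 0.5


@dataclass
class SampleCounts:
    """Per-promoter aligned-read counts for one sequencing sample."""

    sample_id: str
    role: str                      # "IP" or "INPUT"
    replicate: int
    counts: dict[str, int]
    total_mapped: int
    skipped_reads: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("IP", "INPUT"):
            raise ValueError("role must be 'IP' or 'INPUT'")
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be > 0")

    def rpm(self, pseudocount: float = 0.0) -> dict[str, float]:
        scale = 1e6 / self.total_mapped
        return {g: (c + pseudocount) * scale for g, c in self.counts.items()}


def read_reads_bed(path):
    """Aligned read records from BED6: (chrom, start, end, strand)."""
    reads = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) >= 6 else "+"
            reads.append((f[0], int(f[1]), int(f[2]), strand))
    return reads


def promoter_read_counts(
    reads,
    promoter_intervals: dict[str, tuple[str, int, int]],
    sample_id: str = "sample",
    role: str = "IP",
    replicate: int = 1,
) -> SampleCounts:
    """Count aligned reads per promoter by 5' position.

    ``promoter_intervals`` maps gene_id -> (chrom, start, end) in
    genomic 0-based half-open coordinates.  A read is assigned to every
    promoter whose interval contains its 5' end (the start for + reads,
    end-1 for - reads).  Reads on unknown chromosomes are skipped and
    counted.
    """
    if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
        reads = read_reads_bed(reads)
    trees: dict[str, IntervalTree] = {}
    for gene, (chrom, start, end) in promoter_intervals.items():
        if end <= start:
            raise ValueError(f"empty promoter interval for {gene}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end, gene)
    counts: Counter = Counter({g: 0 for g in promoter_intervals})
    skipped = 0
    total = 0
    for chrom, start, end, strand in reads:
        total += 1
        tree = trees.get(chrom)
        if tree is None:
            skipped += 1
            continue
        pos5 = start if strand != "-" else end - 1
        for iv in tree.at(pos5):
            counts[iv.data] += 1
    return SampleCounts(
        sample_id=sample_id,
        role=role,
        replicate=replicate,
        counts=dict(counts),
        total_mapped=total,
        skipped_reads=skipped,
    )


# ---------------------------------------------------------------------------
# simple Poisson sliding-window peak calling
# ---------------------------------------------------------------------------

def _window_counts(positions: np.ndarray, length: int, window: int, step: int):
    starts = np.arange(0, max(length - window, 0) + 1, step)
    pos = np.sort(positions)
    lo = np.searchsorted(pos, starts)
    hi = np.searchsorted(pos, starts + window)
    return starts, (hi - lo).astype(float)


def poisson_window_peaks(
    ip_reads,
    input_reads,
    chrom_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    alpha: float = DEFAULT_PEAK_ALPHA,
):
    """Call enriched intervals by comparing IP to INPUT per window.

    The IP count in each window is tested against a Poisson null whose
    mean is the depth-scaled INPUT count in the same window, floored at
    the genome-wide INPUT rate per window (so empty INPUT windows do
    not produce spurious calls).  Overlapping significant windows merge
    into peaks keeping the minimum p.

    Returns a list of ``(chrom, start, end, p)``.
    """
    if window < step:
        raise ValueError("window must be >= step")
    if isinstance(ip_reads, (str,)) or hasattr(ip_reads, "__fspath__"):
        ip_reads = read_reads_bed(ip_reads)
    if isinstance(input_reads, (str,)) or hasattr(input_reads, "__fspath__"):
        input_reads = read_reads_bed(input_reads)

    def by_chrom(reads):
        d: dict[str, list[int]] = {}
        for chrom, start, end, strand in reads:
            pos5 = start if strand != "-" else end - 1
            d.setdefault(chrom, []).append(pos5)
        return {c: np.array(v) for c, v in d.items()}

    ip_by = by_chrom(ip_reads)
    in_by = by_chrom(input_reads)
    ip_total = sum(len(v) for v in ip_by.values())
    in_total = sum(len(v) for v in in_by.values())
    if in_total == 0:
        raise ValueError("INPUT sample has no reads")
    scale = ip_total / in_total
    genome_len = sum(chrom_lengths.values())
    lambda_floor = in_total * scale * window / genome_len

    peaks = []
    for chrom, length in chrom_lengths.items():
        starts, ip_counts = _window_counts(
            ip_by.get(chrom, np.array([])), length, window, step
        )
        _, in_counts = _window_counts(
            in_by.get(chrom, np.array([])), length, window, step
        )
        lam = np.maximum(in_counts * scale, lambda_floor)
        p = stats.poisson.sf(ip_counts - 1, lam)
        sig = np.flatnonzero(p < alpha)
        cur = None
        for k in sig:
            s, e, pv = int(starts[k]), int(starts[k]) + window, float(p[k])
            if cur is not None and s <= cur[1]:
                cur = (cur[0], max(cur[1], e), min(cur[2], pv))
            else:
                if cur is not None:
                    peaks.append((chrom, *cur))
                cur = (s, e, pv)
        if cur is not None:
            peaks.append((chrom, *cur))
    return peaks


def read_peaks_bed(path):
    """Peak intervals from BED: (chrom, start, end, p) with p from the
    score column when present (interpreted as -log10 p), else 0."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            p = 10 ** (-float(f[4])) if len(f) >= 5 else 1.0
            peaks.append((f[0], int(f[1]), int(f[2]), p))
    return peaks


# ---------------------------------------------------------------------------
# replicate-consistent target sets
# ---------------------------------------------------------------------------

@dataclass
class TargetGeneSets:
    combination: list[str]
    tf1_only: list[str]
    tf2_only: list[str]


def _genes_per_replicate(peak_sets, promoter_intervals):
    """Per replicate: gene -> best (minimum) peak p overlapping its promoter."""
    trees: dict[str, IntervalTree] = {}
    for gene, (chrom, start, end) in promoter_intervals.items():
        trees.setdefault(chrom, IntervalTree()).addi(start, end, gene)
    out = []
    for peaks in peak_sets:
        best: dict[str, float] = {}
        for chrom, start, end, p in peaks:
            tree = trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                g = iv.data
                best[g] = min(best.get(g, 1.0), p)
        out.append(best)
    return out


def _consistent_targets(per_rep, min_support=2):
    """Genes supported in >= min_support replicates, with their best p."""
    support: Counter = Counter()
    best: dict[str, float] = {}
    for rep in per_rep:
        for g, p in rep.items():
            support[g] += 1
            best[g] = min(best.get(g, 1.0), p)
    return {g: best[g] for g, c in support.items() if c >= min_support}


def define_target_sets(
    peaks_tf1: list,
    peaks_tf2: list,
    promoter_intervals: dict[str, tuple[str, int, int]],
    min_support: int = 2,
) -> TargetGeneSets:
    """Three equal-size gene sets from replicate peak calls of two TFs.

    A gene is bound by a TF when a peak overlaps its promoter in at
    least ``min_support`` replicates.  Joint targets are genes bound by
    both TFs; each single-TF set keeps only its most significant genes
    (ascending best peak p, gene id as tie-break), truncated to the
    joint-set size.
    """
    if len(peaks_tf1) < min_support or len(peaks_tf2) < min_support:
        raise ValueError("need at least as many replicates as min_support")
    t1 = _consistent_targets(
        _genes_per_replicate(peaks_tf1, promoter_intervals), min_support
    )
    t2 = _consistent_targets(
        _genes_per_replicate(peaks_tf2, promoter_intervals), min_support
    )
    joint = sorted(set(t1) & set(t2))
    if not joint:
        raise ValueError("no joint targets")
    k = len(joint)

    def top(only: dict[str, float]) -> list[str]:
        ranked = sorted(only.items(), key=lambda kv: (kv[1], kv[0]))
        return [g for g, _ in ranked[:k]]

    tf1_only = top({g: p for g, p in t1.items() if g not in t2})
    tf2_only = top({g: p for g, p in t2.items() if g not in t1})
    return TargetGeneSets(combination=joint, tf1_only=tf1_only, tf2_only=tf2_only)


# ---------------------------------------------------------------------------
# enrichment ratios and differential occupancy
# ---------------------------------------------------------------------------

def promoter_enrichment_ratio(
    ip_replicates: list[SampleCounts],
    input_replicates: list[SampleCounts],
    pseudocount_reads: float = PSEUDOCOUNT_READS,
) -> pd.Series:
    """Per-gene mean IP/INPUT RPM ratio across replicates.

    The pseudocount (0.5 raw reads, scaled to RPM per sample) keeps
    ratios finite at zero-count promoters.
    """
    if not ip_replicates or len(ip_replicates) != len(input_replicates):
        raise ValueError("need matched, non-empty IP and INPUT replicate lists")
    ratios = []
    for ip, inp in zip(ip_replicates, input_replicates):
        ip_rpm = pd.Series(ip.rpm(pseudocount_reads))
        in_rpm = pd.Series(inp.rpm(pseudocount_reads))
        ratios.append(ip_rpm / in_rpm)
    return pd.concat(ratios, axis=1).mean(axis=1)


def differential_occupancy_test(
    wt_ratios: pd.Series,
    del_ratios: pd.Series,
    gene_set,
    method: str = "paired_t",
):
    """Two-sided paired test of WT vs deletion enrichment over a gene set.

    ``method`` is ``paired_t`` or ``signed_rank``.  All-zero paired
    differences return p = 1 by convention.
    """
    genes = [g for g in gene_set if g in wt_ratios.index and g in del_ratios.index]
    if len(genes) < len(list(gene_set)):
        missing = set(gene_set) - set(genes)
        raise ValueError(f"genes without both ratios: {sorted(missing)[:5]}")
    if len(genes) < 3:
        raise ValueError("need at least 3 genes")
    wt = wt_ratios.loc[genes].to_numpy()
    dl = del_ratios.loc[genes].to_numpy()
    diff = wt - dl
    mean_diff = float(diff.mean())
    if np.allclose(diff, 0.0):
        return {"p": 1.0, "mean_difference": 0.0, "n": len(genes),
                "direction": "none"}
    if method == "paired_t":
        p = float(stats.ttest_rel(wt, dl).pvalue)
    elif method == "signed_rank":
        # exact enumeration for small samples (handles tied magnitudes);
        # normal approximation with tie correction otherwise
        kw = {"method": "exact"} if len(genes) <= 25 and not np.any(diff == 0) else {}
        p = float(stats.wilcoxon(wt, dl, **kw).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "p": p,
        "mean_difference": mean_diff,
        "n": len(genes),
        "direction": "wt_higher" if mean_diff > 0 else "deletion_higher",
    }
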