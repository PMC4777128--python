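"""Cross-species rewiring of combinatorial regulation.

For a motif pair screened in two species, orthologous target genes
split into three sets: A (targets only in species 1), B (targets in
both) and C (targets only in species 2).  If the species-specific
designations are real, A should track B's expression within species 1
and C should track B within species 2, while randomized re-assignments
of A and C genes should not.  The permutation test re-deals the pooled
A+C genes into sets of the original sizes 1000 times; the p-value is
the fraction of re-deals whose A*-vs-B and C*-vs-B mean correlations
both beat the observed ones.  Expression is never compared across
species directly — each comparison stays within one species' dataset,
restricted to conditions where the motifs' targets respond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.01
MIN_TARGETS_FOR_CONDITION = 5


def read_ortholog_map(path) -> dict[str, str]:
    """One-to-one ortholog map from a 2-column TSV (species1, species2)."""
    pairs = pd.read_csv(path, sep="\t", header=None, names=["sp1", "sp2"],
                        dtype=str, comment="#")
    if pairs["sp1"].duplicated().any() or pairs["sp2"].duplicated().any():
        raise ValueError("ortholog map is not one-to-one")
    return dict(zip(pairs["sp1"], pairs["sp2"]))


@dataclass
class TargetPartition:
    """Ortholog-space target sets of a motif pair across two species.

    Gene ids are species-1 ids; set C genes are the species-1 orthologs
    of species-2-only targets.  ``unmapped`` counts targets excluded
    for lacking a one-to-one ortholog.
    """

    pair: tuple[str, str]
    set_A: set[str]
    set_B: set[str]
    set_C: set[str]
    unmapped: int = 0

    def __post_init__(self) -> None:
        if self.set_A & self.set_B or self.set_A & self.set_C or self.set_B & self.set_C:
            raise ValueError("sets A, B, C must be disjoint")


def combination_targets(table, tfA: str, tfB: str, max_gap: int = 25) -> set[str]:
    """Genes whose promoter has a non-overlapping A-B site pair with gap <= max_gap."""
    if tfA not in table.tf_names or tfB not in table.tf_names:
        return set()
    a, b = table.tf_index(tfA), table.tf_index(tfB)
    gap, la, lb, _, _ = table.gaps_for_labels(table.labels)
    pi, _ = table.slot_pairs()
    mask = (
        (((la == a) & (lb == b)) | ((la == b) & (lb == a)))
        & (gap >= 0)
        & (gap <= max_gap)
    )
    proms = np.unique(table.slot_promoter[pi][mask])
    return {table.promoter_ids[p] for p in proms}


def single_motif_targets(table, tf: str) -> set[str]:
    """Genes whose promoter carries at least one site for ``tf``."""
    if tf not in table.tf_names:
        return set()
    t = table.tf_index(tf)
    proms = np.unique(table.slot_promoter[table.labels == t])
    return {table.promoter_ids[p] for p in proms}


def partition_targets(
    table_sp1,
    table_sp2,
    orthologs: dict[str, str],
    tfA: str,
    tfB: str,
    max_gap: int = 25,
) -> TargetPartition:
    """Split a pair's targets into species-1-only / shared / species-2-only.

    Targets without a one-to-one ortholog are excluded and counted.
    """
    if not orthologs:
        raise ValueError("empty ortholog map")
    inv = {v: k for k, v in orthologs.items()}
    t1 = combination_targets(table_sp1, tfA, tfB, max_gap)
    t2 = combination_targets(table_sp2, tfA, tfB, max_gap)
    unmapped = len([g for g in t1 if g not in orthologs])
    unmapped += len([g for g in t2 if g not in inv])
    t1m = {g for g in t1 if g in orthologs}
    t2m = {inv[g] for g in t2 if g in inv}  # in species-1 id space
    return TargetPartition(
        pair=tuple(sorted((tfA, tfB))),
        set_A=t1m - t2m,
        set_B=t1m & t2m,
        set_C=t2m - t1m,
        unmapped=unmapped,
    )


def select_relevant_conditions(
    expr: pd.DataFrame,
    cre_targets,
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Conditions in which a motif's targets respond as a group.

    Per condition, all genes' log-ratios are standardized to Z-scores;
    the mean target Z times sqrt(n) is a standard normal under the null
    of no coordinate response, and the condition is kept when its
    two-sided p falls below ``alpha``.  Conditions with fewer than 5
    observed target values are skipped.
    """
    targets = [g for g in cre_targets if g in expr.index]
    if len(targets) < MIN_TARGETS_FOR_CONDITION:
        raise ValueError("need at least 5 target genes with expression data")
    kept = []
    for cond in expr.columns:
        col = expr[cond]
        mu, sd = col.mean(), col.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            continue
        z = (col.loc[col.index.intersection(targets)] - mu) / sd
        z = z.dropna()
        if len(z) < MIN_TARGETS_FOR_CONDITION:
            continue
        stat = z.mean() * np.sqrt(len(z))
        p = 2 * stats.norm.sf(abs(stat))
        if p < alpha:
            kept.append(cond)
    return kept


def relevant_conditions_for_pair(expr, targets_tfA, targets_tfB,
                                 alpha: float = DEFAULT_ALPHA) -> list[str]:
    """Union of conditions relevant for either motif of the pair."""
    kept_a = select_relevant_conditions(expr, targets_tfA, alpha)
    kept_b = select_relevant_conditions(expr, targets_tfB, alpha)
    seen = set()
    out = []
    for c in list(expr.columns):
        if (c in kept_a or c in kept_b) and c not in seen:
            seen.add(c)
            out.append(c)
    return out


def _mean_pcc_to_B(genes_x, genes_b, expr, conditions) -> np.ndarray:
    """Per-gene mean correlation of each X gene against all B genes."""
    sub = expr.loc[:, conditions] if conditions is not None else expr
    xs = [g for g in genes_x if g in sub.index]
    bs = [g for g in genes_b if g in sub.index]
    if not xs or not bs:
        raise ValueError("empty gene set after matching to expression data")
    out = np.zeros(len(xs))
    bmat = sub.loc[bs].to_numpy(dtype=float)
    xmat = sub.loc[xs].to_numpy(dtype=float)
    for i, xrow in enumerate(xmat):
        vals = []
        for brow in bmat:
            both = ~np.isnan(xrow) & ~np.isnan(brow)
            if both.sum() < 3:
                continue
            x, b = xrow[both], brow[both]
            if x.std() == 0 or b.std() == 0:
                continue
            vals.append(np.corrcoef(x, b)[0, 1])
        out[i] = np.mean(vals) if vals else 0.0
    return out


def cross_set_mean_pcc(set_X, set_B, expr, conditions=None) -> float:
    """Mean Pearson correlation over all (x, b) gene pairs."""
    return float(np.mean(_mean_pcc_to_B(set_X, set_B, expr, conditions)))


def rewiring_permutation_test(
    partition: TargetPartition,
    expr_sp1: pd.DataFrame,
    expr_sp2: pd.DataFrame,
    orthologs: dict[str, str],
    conditions_sp1=None,
    conditions_sp2=None,
    n_sims: int = 1000,
    seed=None,
):
    """Permutation test for species-specific target-set coherence.

    Pools A and C, re-deals them into sets of sizes |A| and |C|
    ``n_sims`` times, and counts a simulation as successful when the
    A*-vs-B mean PCC (species-1 data) and the C*-vs-B mean PCC
    (species-2 data) both reach or exceed the observed A-vs-B and
    C-vs-B values.  Returns the raw success fraction and an
    add-one-smoothed p that avoids exact zeros.
    """
    A = sorted(partition.set_A)
    C = sorted(partition.set_C)
    B = sorted(partition.set_B)
    if len(A) < 2 or len(C) < 2:
        raise ValueError("sets A and C must each have >= 2 genes")
    if len(B) < 2:
        raise ValueError("set B must have >= 2 genes")
    rng = np.random.default_rng(seed)

    def sp2_ids(genes):
        return [orthologs[g] for g in genes if g in orthologs]

    pooled = A + C
    # per-gene mean correlation to B, precomputed once per species; a
    # re-dealt set's mean PCC is then just the mean of its genes' values
    v1 = _mean_pcc_to_B(pooled, B, expr_sp1, conditions_sp1)
    v2 = _mean_pcc_to_B(sp2_ids(pooled), sp2_ids(B), expr_sp2, conditions_sp2)
    if v2.size != len(pooled):
        raise ValueError("pooled A+C genes must all map to species-2 ids")
    nA = len(A)
    obs_A = v1[:nA].mean()
    obs_C = v2[nA:].mean()

    successes = 0
    idx = np.arange(len(pooled))
    for _ in range(n_sims):
        perm = rng.permutation(idx)
        a_star = perm[:nA]
        c_star = perm[nA:]
        if v1[a_star].mean() >= obs_A and v2[c_star].mean() >= obs_C:
            successes += 1
    raw = successes / n_sims
    p = raw if successes > 0 else 1.0 / (n_sims + 1)
    return {
        "p_rewire": p,
        "raw_fraction": raw,
        "n_sims": n_sims,
        "mean_pcc_A_vs_B": float(obs_A),
        "mean_pcc_C_vs_B": float(obs_C),
        "sizes": (len(A), len(B), len(C)),
    }
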