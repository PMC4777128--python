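"""Independent-evidence scoring for candidate motif pairs.

Three evidence classes corroborate a co-occurrence call:

* expression coherence — pairwise Pearson correlations among the
  predicted joint targets are compared against targets of each motif
  alone with one-sided Mann-Whitney tests;
* occupancy / perturbation overlap — hypergeometric upper-tail test on
  shared bound (or differentially expressed) genes of the two factors;
* pathway membership — hypergeometric enrichment of annotation terms
  among the joint targets, Bonferroni corrected over the terms that
  touch the target set.

A pair counts as corroborated when at least one class is significant.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
MIN_SHARED_CONDITIONS = 3


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x conditions log-ratio table; 'NA' marks missing values."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    return df.astype(float)


def filter_expression_matrix(df: pd.DataFrame, min_conditions: int = 3) -> pd.DataFrame:
    """Drop genes observed in fewer than ``min_conditions`` conditions."""
    return df.loc[df.notna().sum(axis=1) >= min_conditions]


def read_gmt(path) -> dict[str, set[str]]:
    """GMT annotation file: term, description, member genes."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            terms[f[0]] = set(g for g in f[2:] if g)
    if not terms:
        raise ValueError(f"no terms in {path}")
    return terms


def pairwise_pcc(gene_set, expr: pd.DataFrame) -> np.ndarray:
    """Pearson correlation for every unordered pair of the gene set.

    Each pair's correlation uses the conditions where both genes are
    observed (>= 3 required, else the pair is skipped); pairs involving
    a zero-variance profile are skipped rather than yielding NaN.
    """
    genes = [g for g in gene_set if g in expr.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes with expression data")
    mat = expr.loc[genes].to_numpy(dtype=float)
    out = []
    for i, j in itertools.combinations(range(len(genes)), 2):
        both = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
        if both.sum() < MIN_SHARED_CONDITIONS:
            continue
        x, y = mat[i, both], mat[j, both]
        if x.std() == 0 or y.std() == 0:
            continue
        out.append(np.corrcoef(x, y)[0, 1])
    return np.asarray(out)


def coherence_test(
    targets_both,
    targets_onlyA,
    targets_onlyB,
    expr: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
):
    """Are joint targets more coherently expressed than single-motif targets?

    The PCC distribution of the joint-target set is tested against each
    single-motif set with a one-sided Mann-Whitney test (alternative:
    joint PCCs stochastically larger).  The verdict is "coherent" only
    when both comparisons fall below ``alpha``.
    """
    pcc_both = pairwise_pcc(targets_both, expr)
    pcc_a = pairwise_pcc(targets_onlyA, expr)
    pcc_b = pairwise_pcc(targets_onlyB, expr)
    if len(pcc_both) < 2 or len(pcc_a) < 2 or len(pcc_b) < 2:
        raise ValueError("each set must yield at least 2 correlation values")
    p_vs_a = float(stats.mannwhitneyu(pcc_both, pcc_a, alternative="greater").pvalue)
    p_vs_b = float(stats.mannwhitneyu(pcc_both, pcc_b, alternative="greater").pvalue)
    return {
        "p_vs_onlyA": p_vs_a,
        "p_vs_onlyB": p_vs_b,
        "median_pcc_both": float(np.median(pcc_both)),
        "median_pcc_onlyA": float(np.median(pcc_a)),
        "median_pcc_onlyB": float(np.median(pcc_b)),
        "coherent": p_vs_a < alpha and p_vs_b < alpha,
    }


def set_overlap_test(setX, setY, universe_size: int) -> float:
    """Hypergeometric upper-tail p for the overlap of two gene sets."""
    setX, setY = set(setX), set(setY)
    if len(setX) > universe_size or len(setY) > universe_size:
        raise ValueError("set larger than the universe")
    overlap = len(setX & setY)
    return float(
        stats.hypergeom.sf(overlap - 1, universe_size, len(setX), len(setY))
    )


def pathway_enrichment(
    target_genes,
    annotations: dict[str, set[str]],
    universe: set[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Hypergeometric term enrichment among the target genes.

    Only terms annotating at least one target are tested; the Bonferroni
    denominator is the number of such terms.  Targets outside the
    universe are dropped with a warning.
    """
    targets = set(target_genes)
    if not targets:
        raise ValueError("empty target set")
    outside = targets - universe
    if outside:
        log.warning("%d target gene(s) absent from the universe, dropped",
                    len(outside))
        targets -= outside
    if not targets:
        raise ValueError("no target genes in the annotation universe")
    touched = {
        term: genes & universe
        for term, genes in annotations.items()
        if (genes & targets)
    }
    rows = []
    M, n_draw = len(universe), len(targets)
    for term, genes in touched.items():
        k = len(genes & targets)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), n_draw))
        rows.append((term, len(genes), k, p))
    df = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * len(touched))
    df["significant"] = df["p_bonferroni"] < alpha
    return df.sort_values("p_bonferroni", ignore_index=True)


@dataclass
class EvidenceSummary:
    pair: tuple[str, str]
    coherence: bool
    overlap: bool
    pathway: bool

    @property
    def n_classes(self) -> int:
        return int(self.coherence) + int(self.overlap) + int(self.pathway)

    @property
    def corroborated(self) -> bool:
        return self.n_classes >= 1


def summarize_evidence(pair, coherence_results, overlap_ps, pathway_df,
                       alpha: float = DEFAULT_ALPHA) -> EvidenceSummary:
    """Fold the three evidence classes into one corroboration verdict.

    ``coherence_results``: iterable of :func:`coherence_test` dicts (one
    per expression dataset); ``overlap_ps``: iterable of hypergeometric
    p-values (ChIP colocalization and/or perturbation overlap);
    ``pathway_df``: :func:`pathway_enrichment` output or None.
    """
    coh = any(r["coherent"] for r in coherence_results)
    ovl = any(p < alpha for p in overlap_ps)
    pwy = bool(pathway_df is not None and pathway_df["significant"].any())
    return EvidenceSummary(pair=tuple(pair), coherence=coh, overlap=ovl,
                           pathway=pwy)
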