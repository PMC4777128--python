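"""Relative orientation of co-occurring site pairs and orientation bias.

Reading the two sites of a co-occurrence in promoter order (upstream
site first), the strand pattern falls into four classes: tandem on the
plus strand (+,+), tandem on the minus strand (-,-), convergent (+,-)
and divergent (-,+).  Cooperatively binding factors often prefer one
arrangement; the bias test asks, per class, whether its count exceeds
the uniform expectation n/4 by an exact binomial tail, Bonferroni
corrected over the four classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cooccurrence import SlotTable
from .motif_scan import BindingSite

ORIENTATION_CLASSES = ("tandem_plus", "tandem_minus", "convergent", "divergent")

_CLASS_BY_STRANDS = {
    ("+", "+"): "tandem_plus",
    ("-", "-"): "tandem_minus",
    ("+", "-"): "convergent",
    ("-", "+"): "divergent",
}


@dataclass
class OrientationCounts:
    pair: tuple[str, str]
    counts: dict[str, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def classify_pair_orientation(siteA: BindingSite, siteB: BindingSite) -> str:
    """Orientation class of one co-occurring site pair.

    Sites must lie in the same promoter and not overlap; the class
    depends only on the strand pattern in promoter order, not on which
    motif comes first.
    """
    if siteA.gene_id != siteB.gene_id:
        raise ValueError("sites are in different promoters")
    up, down = (siteA, siteB) if siteA.start <= siteB.start else (siteB, siteA)
    if down.start < up.end:
        raise ValueError("overlapping sites have no defined orientation")
    return _CLASS_BY_STRANDS[(up.strand, down.strand)]


def count_orientations(
    table: SlotTable, tfA: str, tfB: str, max_gap: int | None = None
) -> OrientationCounts:
    """Orientation class counts over all co-occurrences of a pair.

    ``max_gap`` restricts to short-gap co-occurrences (the interacting
    range); ``None`` counts all non-overlapping co-occurrences.
    """
    if tfA == tfB:
        raise ValueError("homotypic pairs unsupported")
    pair = tuple(sorted((tfA, tfB)))
    counts = dict.fromkeys(ORIENTATION_CLASSES, 0)
    if tfA in table.tf_names and tfB in table.tf_names:
        a, b = table.tf_index(tfA), table.tf_index(tfB)
        gap, la, lb, sa, sb = table.gaps_for_labels(table.labels)
        mask = (((la == a) & (lb == b)) | ((la == b) & (lb == a))) & (gap >= 0)
        if max_gap is not None:
            mask &= gap <= max_gap
        strands = "+-"
        for s_up, s_down in zip(sa[mask], sb[mask]):
            counts[_CLASS_BY_STRANDS[(strands[s_up], strands[s_down])]] += 1
    return OrientationCounts(pair=pair, counts=counts)


def orientation_bias_test(counts: OrientationCounts, alpha: float = 0.01):
    """Per-class exact binomial test against the uniform 1/4 expectation.

    Returns a dict with per-class corrected p-values (x4, capped at 1),
    the preferred class (smallest corrected p) and whether it clears
    ``alpha``.
    """
    n = counts.n
    if n == 0:
        raise ValueError("no co-occurrences to test")
    p_corr = {}
    for cls in ORIENTATION_CLASSES:
        k = counts.counts.get(cls, 0)
        p = stats.binom.sf(k - 1, n, 0.25)
        p_corr[cls] = min(1.0, 4.0 * float(p))
    preferred = min(ORIENTATION_CLASSES, key=lambda c: (p_corr[c], c))
    return {
        "pair": counts.pair,
        "n": n,
        "p_corrected": p_corr,
        "preferred": preferred,
        "significant": p_corr[preferred] < alpha,
    }


def split_targets_by_orientation(
    table: SlotTable, tfA: str, tfB: str, preferred: str,
    max_gap: int | None = None,
):
    """Partition target genes by whether they carry the preferred arrangement.

    Returns ``(preferred_genes, other_genes)``; a gene with
    co-occurrences in both arrangements lands in the preferred set.
    """
    a, b = table.tf_index(tfA), table.tf_index(tfB)
    gap, la, lb, sa, sb = table.gaps_for_labels(table.labels)
    pi, _ = table.slot_pairs()
    mask = (((la == a) & (lb == b)) | ((la == b) & (lb == a))) & (gap >= 0)
    if max_gap is not None:
        mask &= gap <= max_gap
    strands = "+-"
    pref, other = set(), set()
    proms = table.slot_promoter[pi]
    for k in np.flatnonzero(mask):
        cls = _CLASS_BY_STRANDS[(strands[sa[k]], strands[sb[k]])]
        gene = table.promoter_ids[proms[k]]
        (pref if cls == preferred else other).add(gene)
    return pref, other - pref
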