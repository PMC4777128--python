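"""Motif-pair co-occurrence screen with spacing-bias null models.

For every heterotypic pair of motifs, co-occurrences of their predicted
sites within each promoter are recorded as a distribution over the
edge-to-edge gap d.  Under label shuffling that preserves each motif's
genome-wide site count and every promoter's site slots, the expected
number of co-occurrences at gap d is closely approximated by

    S(d) = 2 N (B - d) / B**2

where N is the total number of co-occurrences and B is the maximum
possible gap (promoter length minus the two motif widths).  Pairs whose
short-gap (d <= 25 bp) co-occurrence count exceeds the Poisson
expectation sum_{d<=25} S(d) after Bonferroni correction are candidate
interacting pairs; a promoter-level permutation null then tests the
*shape* of the spacing distribution with a chi-square statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .motif_scan import DEFAULT_UPSTREAM, BindingSite

DEFAULT_MAX_GAP = 25
DEFAULT_ALPHA = 0.01

_STRAND_CODE = {"+": 0, "-": 1}


# ---------------------------------------------------------------------------
# site slot table: fixed (promoter, start, strand) slots with motif labels
# ---------------------------------------------------------------------------

@dataclass
class SlotTable:
    """One species' predicted sites as positional slots plus motif labels.

    The slot geometry (promoter, start, strand) is immutable under the
    permutation nulls; only the ``labels`` vector is shuffled.  Slots
    are sorted by (promoter, start) so promoter groups are contiguous.
    """

    species_id: str
    promoter_ids: list[str]
    promoter_len: np.ndarray          # per promoter, bp
    slot_promoter: np.ndarray         # per slot, promoter index
    slot_start: np.ndarray            # per slot
    slot_strand: np.ndarray           # per slot, 0=+ 1=-
    labels: np.ndarray                # per slot, motif index
    tf_names: list[str]
    tf_widths: np.ndarray             # per motif index, bp
    _pairs: tuple | None = field(default=None, repr=False)

    @property
    def n_slots(self) -> int:
        return self.slot_start.size

    def tf_index(self, name: str) -> int:
        return self.tf_names.index(name)

    def slot_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (i, j) of every intra-promoter slot pair, i upstream."""
        if self._pairs is None:
            pi_parts, pj_parts = [], []
            bounds = np.searchsorted(
                self.slot_promoter, np.arange(len(self.promoter_ids) + 1)
            )
            for g in range(len(self.promoter_ids)):
                lo, hi = bounds[g], bounds[g + 1]
                k = hi - lo
                if k < 2:
                    continue
                i, j = np.triu_indices(k, k=1)
                pi_parts.append(i + lo)
                pj_parts.append(j + lo)
            if pi_parts:
                self._pairs = (np.concatenate(pi_parts), np.concatenate(pj_parts))
            else:
                self._pairs = (np.empty(0, dtype=int), np.empty(0, dtype=int))
        return self._pairs

    def gaps_for_labels(self, labels: np.ndarray):
        """Edge-to-edge gap of every intra-promoter slot pair under ``labels``.

        A slot adopts the width of its assigned motif, anchored at the
        slot start and clipped at the promoter end.  Returns
        ``(gap, label_i, label_j, strand_i, strand_j)`` over pairs;
        negative gaps mark overlapping pairs.
        """
        pi, pj = self.slot_pairs()
        plen = self.promoter_len[self.slot_promoter]
        end = np.minimum(self.slot_start + self.tf_widths[labels], plen)
        gap = self.slot_start[pj] - end[pi]
        return gap, labels[pi], labels[pj], self.slot_strand[pi], self.slot_strand[pj]


def build_slot_table(
    sites: list[BindingSite],
    promoter_lengths: dict[str, int] | None = None,
    default_len: int = DEFAULT_UPSTREAM,
    tf_names: list[str] | None = None,
) -> SlotTable:
    """Assemble a :class:`SlotTable` from one species' binding sites.

    ``promoter_lengths`` maps gene_id -> promoter length; genes absent
    from the map (or when the map is omitted) get ``default_len``.
    ``tf_names`` fixes the motif universe (e.g. all scanned motifs, so
    motifs without sites still count toward the hypothesis space).
    """
    if not sites:
        raise ValueError("no sites")
    species = {s.species_id for s in sites}
    if len(species) != 1:
        raise ValueError(f"sites from multiple species: {sorted(species)}")
    if tf_names is None:
        tf_names = sorted({s.tf for s in sites})
    tf_idx = {t: i for i, t in enumerate(tf_names)}
    widths = np.zeros(len(tf_names), dtype=int)
    for s in sites:
        widths[tf_idx[s.tf]] = s.width

    order = sorted(range(len(sites)), key=lambda k: (sites[k].gene_id, sites[k].start))
    promoter_ids: list[str] = []
    prom_idx: dict[str, int] = {}
    cols = np.zeros((4, len(sites)), dtype=int)
    for out_k, k in enumerate(order):
        s = sites[k]
        if s.gene_id not in prom_idx:
            prom_idx[s.gene_id] = len(promoter_ids)
            promoter_ids.append(s.gene_id)
        cols[0, out_k] = prom_idx[s.gene_id]
        cols[1, out_k] = s.start
        cols[2, out_k] = _STRAND_CODE[s.strand]
        cols[3, out_k] = tf_idx[s.tf]
    plen = np.array(
        [
            (promoter_lengths or {}).get(g, default_len)
            for g in promoter_ids
        ],
        dtype=int,
    )
    return SlotTable(
        species_id=next(iter(species)),
        promoter_ids=promoter_ids,
        promoter_len=plen,
        slot_promoter=cols[0],
        slot_start=cols[1],
        slot_strand=cols[2],
        labels=cols[3].copy(),
        tf_names=list(tf_names),
        tf_widths=widths,
    )


# ---------------------------------------------------------------------------
# spacing distributions
# ---------------------------------------------------------------------------

@dataclass
class SpacingDistribution:
    """Gap distribution of co-occurrences for one motif pair in one species."""

    pair: tuple[str, str]
    species_id: str
    counts: np.ndarray   # index = gap d in bp
    B: int               # maximum possible gap

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    def padded(self, length: int) -> np.ndarray:
        out = np.zeros(length)
        out[: self.counts.size] = self.counts
        return out


def _pair_counts_from_table(
    table: SlotTable, labels: np.ndarray, a: int, b: int, B: int
) -> np.ndarray:
    gap, la, lb, _, _ = table.gaps_for_labels(labels)
    mask = (((la == a) & (lb == b)) | ((la == b) & (lb == a))) & (gap >= 0)
    gaps = gap[mask]
    return np.bincount(gaps, minlength=B + 1).astype(float)


def pair_spacing_distribution(
    sites_or_table,
    tfA: str,
    tfB: str,
    promoter_len: int = DEFAULT_UPSTREAM,
) -> SpacingDistribution:
    """Observed gap distribution for one heterotypic pair in one species.

    Every non-overlapping (A-site, B-site) pair within a promoter
    contributes one count at its edge-to-edge gap; overlapping site
    pairs are discarded.
    """
    if tfA == tfB:
        raise ValueError("homotypic pairs unsupported")
    table = (
        sites_or_table
        if isinstance(sites_or_table, SlotTable)
        else build_slot_table(sites_or_table, default_len=promoter_len)
    )
    wA = int(table.tf_widths[table.tf_index(tfA)]) if tfA in table.tf_names else 1
    wB = int(table.tf_widths[table.tf_index(tfB)]) if tfB in table.tf_names else 1
    B = promoter_len - (wA + wB)
    if B <= 0:
        raise ValueError("combined motif widths exceed the promoter length")
    if tfA not in table.tf_names or tfB not in table.tf_names:
        counts = np.zeros(B + 1)
    else:
        counts = _pair_counts_from_table(
            table, table.labels, table.tf_index(tfA), table.tf_index(tfB), B
        )
    pair = tuple(sorted((tfA, tfB)))
    return SpacingDistribution(pair=pair, species_id=table.species_id,
                               counts=counts, B=B)


def expected_spacing_profile(N: float, B: int, d) -> np.ndarray | float:
    """Analytic null expectation S(d) = 2 N (B - d) / B**2.

    Vectorized over ``d``; raises for d outside [0, B] or B <= 0.
    """
    if B <= 0:
        raise ValueError("B must be > 0")
    if N < 0:
        raise ValueError("N must be >= 0")
    d_arr = np.asarray(d)
    if np.any(d_arr < 0) or np.any(d_arr > B):
        raise ValueError("d must satisfy 0 <= d <= B")
    out = 2.0 * N * (B - d_arr) / (B * B)
    return float(out) if np.isscalar(d) else out


def expected_short_gap_lambda(N: float, B: int, max_gap: int = DEFAULT_MAX_GAP) -> float:
    """sum_{d=0..min(max_gap,B)} S(d) — the Poisson mean for short gaps."""
    m = min(max_gap, B)
    return float(expected_spacing_profile(N, B, np.arange(m + 1)).sum())


# ---------------------------------------------------------------------------
# permutation nulls
# ---------------------------------------------------------------------------

def genome_label_shuffle(table: SlotTable, rng) -> np.ndarray:
    """Uniform permutation of motif labels over all slots genome-wide.

    Preserves each motif's genome-wide site count and every promoter's
    slot count and positions.
    """
    rng = np.random.default_rng(rng)
    return rng.permutation(table.labels)


def promoter_label_shuffle(table: SlotTable, rng) -> np.ndarray:
    """Permute motif labels among slots within each promoter independently."""
    rng = np.random.default_rng(rng)
    keys = rng.random(table.n_slots)
    # slots are sorted by promoter: a within-group random order re-deals
    # each promoter's own labels over its own slots
    order = np.lexsort((keys, table.slot_promoter))
    return table.labels[order]


def null_profile(
    table: SlotTable,
    tfA: str,
    tfB: str,
    n_shuffles: int = 1000,
    seed=None,
    level: str = "genome",
    promoter_len: int | None = None,
):
    """Mean (and SD) spacing distribution over label-shuffle nulls.

    ``level='genome'`` permutes labels genome-wide (co-occurrence *and*
    spacing null); ``level='promoter'`` permutes within each promoter
    (spacing-shape null, which keeps every pair's total N fixed).
    """
    if tfA == tfB:
        raise ValueError("homotypic pairs unsupported")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    plen = promoter_len if promoter_len is not None else int(table.promoter_len.max())
    if tfA not in table.tf_names or tfB not in table.tf_names:
        B = plen - 2
        z = np.zeros(B + 1)
        return z, z.copy()
    a, b = table.tf_index(tfA), table.tf_index(tfB)
    B = plen - int(table.tf_widths[a] + table.tf_widths[b])
    shuffle = genome_label_shuffle if level == "genome" else promoter_label_shuffle
    acc = np.zeros(B + 1)
    acc2 = np.zeros(B + 1)
    for _ in range(n_shuffles):
        labels = shuffle(table, rng)
        c = _pair_counts_from_table(table, labels, a, b, B)
        c = c[: B + 1] if c.size > B + 1 else np.pad(c, (0, B + 1 - c.size))
        acc += c
        acc2 += c * c
    mean = acc / n_shuffles
    var = np.maximum(acc2 / n_shuffles - mean**2, 0.0)
    return mean, np.sqrt(var)


def promoter_level_null(
    table: SlotTable,
    tfA: str,
    tfB: str,
    n_sims: int = 1000,
    seed=None,
    promoter_len: int | None = None,
) -> np.ndarray:
    """Mean spacing distribution under within-promoter label permutation."""
    mean, _ = null_profile(
        table, tfA, tfB, n_shuffles=n_sims, seed=seed,
        level="promoter", promoter_len=promoter_len,
    )
    return mean


# ---------------------------------------------------------------------------
# significance tests
# ---------------------------------------------------------------------------

@dataclass
class PairTestResult:
    pair: tuple[str, str]
    observed_short: int
    lambda_expected: float
    p_poisson: float
    p_bonferroni: float
    n_tests: int
    significant: bool
    p_chisq: float | None = None
    N_total: int | None = None


def pair_cooccurrence_test(
    observed_short: int,
    lambda_expected: float,
    n_tests: int,
    alpha: float = DEFAULT_ALPHA,
    pair: tuple[str, str] = ("A", "B"),
) -> PairTestResult:
    """Upper-tail Poisson test of short-gap co-occurrence excess.

    p = P(X >= observed) for X ~ Poisson(lambda); Bonferroni-corrected
    over ``n_tests`` pair hypotheses.
    """
    if observed_short < 0:
        raise ValueError("observed count must be >= 0")
    if lambda_expected < 0:
        raise ValueError("lambda must be >= 0")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p = float(stats.poisson.sf(observed_short - 1, lambda_expected))
    p_bonf = min(1.0, p * n_tests)
    return PairTestResult(
        pair=tuple(pair),
        observed_short=int(observed_short),
        lambda_expected=float(lambda_expected),
        p_poisson=p,
        p_bonferroni=p_bonf,
        n_tests=int(n_tests),
        significant=p_bonf < alpha,
    )


def spacing_shape_test(observed, expected, min_expected: float = 5.0):
    """Chi-square comparison of observed vs permutation-mean spacing shape.

    Adjacent unit-gap bins are merged left-to-right until every merged
    bin holds expected mass >= ``min_expected``; a trailing light bin is
    folded into its predecessor.  Returns ``(statistic, p, df)``;
    ``(nan, nan, 0)`` flags an untestable (fewer than 2 bins) case.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    n = max(obs.size, exp.size)
    obs = np.pad(obs, (0, n - obs.size))
    exp = np.pad(exp, (0, n - exp.size))
    if abs(obs.sum() - exp.sum()) > 0.1 * max(1.0, obs.sum()):
        raise ValueError(
            "observed and expected totals differ; use the promoter-level null"
        )
    if exp.sum() > 0:
        # condition on the observed total: the permutation preserves N
        # exactly for non-overlapping sites and to within a few counts
        # when sites overlap, so the shape test rescales the null mass
        exp = exp * (obs.sum() / exp.sum())
    o_bins, e_bins = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(obs, exp):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            o_bins.append(o_acc)
            e_bins.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 or o_acc > 0:
        if e_bins:
            o_bins[-1] += o_acc
            e_bins[-1] += e_acc
        elif e_acc >= min_expected:
            o_bins.append(o_acc)
            e_bins.append(e_acc)
    if len(e_bins) < 2:
        return float("nan"), float("nan"), 0
    o_arr, e_arr = np.array(o_bins), np.array(e_bins)
    stat = float(((o_arr - e_arr) ** 2 / e_arr).sum())
    df = len(e_bins) - 1
    return stat, float(stats.chi2.sf(stat, df)), df


# ---------------------------------------------------------------------------
# screen driver
# ---------------------------------------------------------------------------

def n_heterotypic_pairs(n_motifs: int) -> int:
    """Size of the pairwise hypothesis space: C(n, 2)."""
    return n_motifs * (n_motifs - 1) // 2


def iter_heterotypic_pairs(tf_names) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(tf_names), 2))


def screen_pairs(
    tables: list[SlotTable],
    tf_names: list[str] | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
    alpha: float = DEFAULT_ALPHA,
    promoter_len: int = DEFAULT_UPSTREAM,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Genome-wide co-occurrence screen over all heterotypic pairs.

    Per species, counts every pair's total co-occurrences N and its
    short-gap count (d <= ``max_gap``); the Poisson mean is the
    analytic profile summed over the short-gap range.  Counts and means
    are pooled over species before a single Poisson test per pair with
    Bonferroni correction over the hypothesis space.
    """
    if isinstance(tables, SlotTable):
        tables = [tables]
    if tf_names is None:
        tf_names = sorted({t for tab in tables for t in tab.tf_names})
    pairs = iter_heterotypic_pairs(tf_names)
    if n_tests is None:
        n_tests = len(pairs)
    widths = {
        t: int(tab.tf_widths[tab.tf_index(t)])
        for tab in tables
        for t in tab.tf_names
    }

    idx = {p: k for k, p in enumerate(pairs)}
    N_tot = np.zeros(len(pairs))
    obs_short = np.zeros(len(pairs))
    lam = np.zeros(len(pairs))
    species_seen = np.zeros(len(pairs), dtype=int)

    for tab in tables:
        gap, la, lb, _, _ = tab.gaps_for_labels(tab.labels)
        valid = gap >= 0
        a = np.minimum(la[valid], lb[valid])
        b = np.maximum(la[valid], lb[valid])
        key = a * len(tab.tf_names) + b
        g = gap[valid]
        n_keys = len(tab.tf_names) ** 2
        N_sp = np.bincount(key, minlength=n_keys)
        short_sp = np.bincount(key[g <= max_gap], minlength=n_keys)
        for (ai, bi) in itertools.combinations(range(len(tab.tf_names)), 2):
            n_obs = int(N_sp[ai * len(tab.tf_names) + bi])
            if n_obs == 0:
                continue
            pa, pb = tab.tf_names[ai], tab.tf_names[bi]
            pair = (pa, pb) if pa < pb else (pb, pa)
            k = idx[pair]
            B = promoter_len - (widths[pa] + widths[pb])
            if B <= 0:
                continue
            N_tot[k] += n_obs
            obs_short[k] += int(short_sp[ai * len(tab.tf_names) + bi])
            lam[k] += expected_short_gap_lambda(n_obs, B, max_gap)
            species_seen[k] += 1

    p_poisson = stats.poisson.sf(obs_short - 1, lam)
    p_poisson = np.where(lam == 0, np.where(obs_short > 0, 0.0, 1.0), p_poisson)
    p_bonf = np.minimum(1.0, p_poisson * n_tests)
    return pd.DataFrame(
        {
            "tf1": [p[0] for p in pairs],
            "tf2": [p[1] for p in pairs],
            "species_count": species_seen,
            "N_total": N_tot.astype(int),
            f"observed_le{max_gap}": obs_short.astype(int),
            f"lambda_le{max_gap}": lam,
            "p_poisson": p_poisson,
            "p_bonferroni": p_bonf,
            "n_tests": n_tests,
            "significant": p_bonf < alpha,
        }
    )


def shape_test_for_pair(
    tables: list[SlotTable],
    tfA: str,
    tfB: str,
    n_sims: int = 1000,
    seed=None,
    promoter_len: int = DEFAULT_UPSTREAM,
):
    """Pooled-species chi-square spacing-shape test for one pair."""
    if isinstance(tables, SlotTable):
        tables = [tables]
    obs_total = None
    exp_total = None
    for i, tab in enumerate(tables):
        obs = pair_spacing_distribution(tab, tfA, tfB, promoter_len=promoter_len)
        sub_seed = None if seed is None else (int(seed) + 7919 * i) % (2**31)
        exp = promoter_level_null(
            tab, tfA, tfB, n_sims=n_sims, seed=sub_seed, promoter_len=promoter_len
        )
        n = max(obs.counts.size, exp.size)
        o = np.pad(obs.counts, (0, n - obs.counts.size))
        e = np.pad(exp, (0, n - exp.size))
        if obs_total is None:
            obs_total, exp_total = o, e
        else:
            n = max(obs_total.size, o.size)
            obs_total = np.pad(obs_total, (0, n - obs_total.size)) + np.pad(
                o, (0, n - o.size)
            )
            exp_total = np.pad(exp_total, (0, n - exp_total.size)) + np.pad(
                e, (0, n - e.size)
            )
    return spacing_shape_test(obs_total, exp_total)
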