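"""PWM handling, promoter extraction and binding-site prediction.

A transcription factor's binding specificity is modelled as a position
weight matrix (PWM) of per-position base probabilities.  Candidate
cis-regulatory elements (CREs) are windows of promoter sequence whose
predicted affinity, relative to the optimal (consensus) sequence, is
within a fold cutoff (default 25-fold) of the consensus affinity:

    rel_affinity(w) = prod_i f(b_i, i) / prod_i max_b f(b, i)

computed in log space.  Both strands are scanned; promoters are the
600 bp immediately upstream of the translational start of each gene.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from pyfaidx import Fasta

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_UPSTREAM = 600
DEFAULT_FOLD_CUTOFF = 25.0

#: log-space slack when comparing rel_affinity against 1/fold_cutoff
_LOG_TOL = 1e-12


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position frequency model for one TF, with a background model.

    ``freq`` is a (width, 4) array of per-position probabilities in
    A, C, G, T order; every row sums to 1 and every entry is strictly
    positive (a pseudocount is applied on loading).  ``background``
    holds the genome base composition used for log-odds reporting;
    the relative-affinity site call is a ratio of frequency products
    and is unaffected by it.
    """

    name: str
    freq: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4 or freq.shape[0] < 1:
            raise ValueError(f"PWM {self.name!r}: freq must be (width, 4)")
        if np.any(freq <= 0):
            raise ValueError(f"PWM {self.name!r}: frequencies must be > 0")
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: rows must sum to 1")
        if bg.shape != (4,) or np.any(bg <= 0):
            raise ValueError(f"PWM {self.name!r}: invalid background")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"PWM {self.name!r}: background must sum to 1")
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Per-position log(f/background), natural log."""
        return np.log(self.freq) - np.log(self.background)[None, :]

    def reverse_complement(self) -> "PWM":
        return replace(self, freq=self.freq[::-1, ::-1].copy())


@dataclass(frozen=True)
class Promoter:
    """Upstream regulatory sequence of one gene, 5'->3' toward the start codon."""

    gene_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if re.search(r"[^ACGTN]", seq):
            raise ValueError(f"promoter {self.gene_id}: non-ACGTN characters")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """One predicted CRE occurrence in promoter coordinates (0-based, half-open)."""

    gene_id: str
    species_id: str
    tf: str
    start: int
    width: int
    strand: str
    rel_affinity: float

    @property
    def end(self) -> int:
        return self.start + self.width


def _normalize_rows(counts: np.ndarray, pseudocount_frac: float) -> np.ndarray:
    """Counts/frequencies -> probabilities with a per-cell pseudocount.

    The pseudocount is ``pseudocount_frac`` of the row total per cell,
    floored at 0.01, so frequency-style rows (total 1) and count-style
    rows are handled uniformly and zeros are removed.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("PWM row with zero total")
    pc = np.maximum(pseudocount_frac * totals, 0.01)
    adj = counts + pc
    return adj / adj.sum(axis=1, keepdims=True)


def load_pwms(path, pseudocount_frac: float = 0.01) -> dict[str, PWM]:
    """Load PWMs from a motif file.

    Two layouts are accepted:

    * blocks of ``>name`` followed by one row per position with 4
      whitespace-separated numbers (counts or frequencies) in A C G T
      order;
    * MEME minimal format (``MOTIF name`` + ``letter-probability
      matrix`` blocks).

    Returns a name-keyed dict preserving file order.
    """
    with open(path) as fh:
        text = fh.read()
    pwms: dict[str, PWM] = {}

    def add(name: str, rows: list[list[float]]) -> None:
        if not name:
            raise ValueError("motif block without a name")
        if name in pwms:
            raise ValueError(f"duplicate motif name {name!r}")
        if not rows:
            raise ValueError(f"motif {name!r} has no position rows")
        freq = _normalize_rows(np.array(rows, dtype=float), pseudocount_frac)
        pwms[name] = PWM(name=name, freq=freq)

    if "MOTIF" in text and "letter-probability matrix" in text:
        for block in re.split(r"^MOTIF\s+", text, flags=re.M)[1:]:
            lines = block.strip().splitlines()
            name = lines[0].split()[0]
            rows = []
            in_matrix = False
            for line in lines[1:]:
                if "letter-probability matrix" in line:
                    in_matrix = True
                    continue
                parts = line.split()
                if in_matrix and len(parts) == 4:
                    rows.append([float(x) for x in parts])
                elif in_matrix and parts:
                    break
            add(name, rows)
        return pwms

    name = None
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if name is not None:
                add(name, rows)
            name = line[1:].split()[0]
            rows = []
        else:
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"motif {name!r}: expected 4 columns, got {len(parts)}")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"motif {name!r}: non-numeric entry") from exc
    if name is not None:
        add(name, rows)
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def adjust_background(pwm: PWM, composition) -> PWM:
    """Attach a species' base composition to a PWM.

    Relative-affinity site calling is a ratio of frequency products and
    is unchanged; only reported log-odds depend on the background.
    """
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,):
        raise ValueError("composition must have 4 entries (A,C,G,T)")
    if np.any(comp <= 0):
        raise ValueError("composition entries must be > 0")
    if not math.isclose(comp.sum(), 1.0, abs_tol=1e-6):
        raise ValueError(f"composition sums to {comp.sum():.4f}, expected 1")
    return replace(pwm, background=comp / comp.sum())


def genome_composition(fasta_path) -> np.ndarray:
    """A,C,G,T frequencies over all sequences of a FASTA file (N ignored)."""
    counts = np.zeros(4)
    with Fasta(str(fasta_path)) as fa:
        for rec in fa:
            seq = str(rec[:]).upper()
            for i, b in enumerate(BASES):
                counts[i] += seq.count(b)
    if counts.sum() == 0:
        raise ValueError("empty genome")
    return counts / counts.sum()


def _parse_gff3_genes(path):
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name") or attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"gene record without ID: {line!r}")
            # GFF3 is 1-based closed; convert to 0-based half-open
            genes.append((f[0], int(f[3]) - 1, int(f[4]), f[6], gid))
    return genes


def _parse_bed_genes(path):
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError("BED6 required for gene annotation")
            genes.append((f[0], int(f[1]), int(f[2]), f[5], f[3]))
    return genes


def read_gene_annotation(path):
    """Gene records from GFF3 (feature ``gene``) or BED6.

    Returns tuples ``(chrom, start, end, strand, gene_id)`` with 0-based
    half-open coordinates.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return _parse_gff3_genes(path)
    return _parse_bed_genes(path)


def extract_promoters(
    genome_fasta,
    genes,
    species_id: str = "sp",
    upstream_len: int = DEFAULT_UPSTREAM,
) -> list[Promoter]:
    """Extract the upstream promoter of every annotated gene.

    ``genes`` is a path to GFF3/BED6 or an iterable of
    ``(chrom, start, end, strand, gene_id)`` tuples (0-based half-open).
    For a + strand gene starting at s, the promoter is [s-upstream, s);
    for a - strand gene ending at e it is [e, e+upstream) reverse
    complemented, so the returned sequence always reads 5'->3' toward
    the start codon.  Intervals are clipped at chromosome ends.
    """
    if isinstance(genes, (str,)) or hasattr(genes, "__fspath__"):
        genes = read_gene_annotation(genes)
    promoters = []
    with Fasta(str(genome_fasta)) as fa:
        lengths = {name: len(fa[name]) for name in fa.keys()}
        for chrom, start, end, strand, gene_id in genes:
            if chrom not in lengths:
                raise KeyError(f"chromosome {chrom!r} absent from FASTA")
            clen = lengths[chrom]
            if start >= clen:
                raise ValueError(
                    f"gene {gene_id}: start {start} beyond chromosome "
                    f"{chrom} length {clen}"
                )
            if strand == "-":
                lo, hi = end, min(end + upstream_len, clen)
                seq = reverse_complement(str(fa[chrom][lo:hi]))
            else:
                lo, hi = max(start - upstream_len, 0), start
                seq = str(fa[chrom][lo:hi])
            if not seq:
                continue
            promoters.append(
                Promoter(gene_id=gene_id, species_id=species_id, sequence=seq)
            )
    ids = [p.gene_id for p in promoters]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids within one species")
    return promoters


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(logf: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Sum of per-position log frequencies for every window; NaN where N."""
    w = logf.shape[0]
    n_win = codes.size - w + 1
    padded = np.concatenate([logf, np.full((w, 1), np.nan)], axis=1)
    scores = np.zeros(n_win)
    for i in range(w):
        scores += padded[i, codes[i : i + n_win]]
    return scores


def scan_sites(
    pwm: PWM,
    promoter: Promoter,
    fold_cutoff: float = DEFAULT_FOLD_CUTOFF,
) -> list[BindingSite]:
    """Predict binding sites for one PWM in one promoter.

    Both strands are scanned; a window is reported when its affinity is
    within ``fold_cutoff`` of the consensus affinity.  Windows
    containing N are skipped.  Minus-strand sites carry the leftmost
    promoter coordinate of the window.  Both-strand hits at the same
    start (perfect palindromes) are collapsed to the + strand record.
    """
    if fold_cutoff <= 1:
        raise ValueError("fold_cutoff must be > 1")
    w = pwm.width
    if promoter.length < w:
        return []
    codes = _encode(promoter.sequence)
    log_consensus = np.log(pwm.freq.max(axis=1)).sum()
    threshold = log_consensus - math.log(fold_cutoff) - _LOG_TOL

    sites: dict[tuple[int, str], BindingSite] = {}
    for strand, freq in (("+", pwm.freq), ("-", pwm.reverse_complement().freq)):
        scores = _window_scores(np.log(freq), codes)
        hits = np.flatnonzero(~np.isnan(scores) & (scores >= threshold))
        for start in hits:
            key = (int(start), pwm.name)
            rel = math.exp(scores[start] - log_consensus)
            site = BindingSite(
                gene_id=promoter.gene_id,
                species_id=promoter.species_id,
                tf=pwm.name,
                start=int(start),
                width=w,
                strand=strand,
                rel_affinity=min(rel, 1.0),
            )
            if key in sites:
                continue  # palindrome: keep the + strand record
            sites[key] = site
    return sorted(sites.values(), key=lambda s: s.start)


def scan_promoters(
    pwms,
    promoters,
    fold_cutoff: float = DEFAULT_FOLD_CUTOFF,
) -> list[BindingSite]:
    """Scan every promoter with every PWM; flat site list."""
    if isinstance(pwms, PWM):
        pwms = {pwms.name: pwms}
    if isinstance(pwms, dict):
        pwms = list(pwms.values())
    out: list[BindingSite] = []
    for prom in promoters:
        for pwm in pwms:
            out.extend(scan_sites(pwm, prom, fold_cutoff=fold_cutoff))
    return out


def write_sites_bed(sites, path) -> None:
    """BED6 in promoter coordinates: chrom=gene_id, name=tf, score=1000*rel."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.gene_id}\t{s.start}\t{s.end}\t{s.tf}\t"
                f"{round(1000 * s.rel_affinity)}\t{s.strand}\n"
            )


def read_sites_bed(path, species_id: str = "sp") -> list[BindingSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sites.append(
                BindingSite(
                    gene_id=f[0],
                    species_id=species_id,
                    tf=f[3],
                    start=int(f[1]),
                    width=int(f[2]) - int(f[1]),
                    strand=f[5],
                    rel_affinity=float(f[4]) / 1000.0,
                )
            )
    return sites
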