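"""Exhaustive promoter k-mer enrichment and 3'UTR motif scanning.

All 4^k k-mers (4,096 six-mers by default) are counted in sliding
windows over each gene set's promoters (the 1 kb immediately upstream
of the transcription start, supplied 5'->3' on the gene's strand).
Windows containing the ambiguity code N are skipped.  A set's per-motif
frequency (occurrences / scanned windows) is divided by the same
frequency over all promoters in the genome, giving a genome-relative
ratio; significance comes from the same two-proportion z statistic used
for category enrichment.  Putative cis-acting regulatory elements are
short-listed when significant (p < 0.01) *and* at least 20% over- or
under-represented (ratio >= 1.2 or <= 0.8), and the shortlisted ratio
matrix is hierarchically clustered on both motifs and gene sets.

"Occurrence" counts total overlapping matches across the set's
promoters by default; a per-promoter presence mode (each gene counted
once) is available behind ``mode="presence"``.  Only the supplied
(sense) strand is scanned by default; ``both_strands=True`` adds
reverse-complement windows, so a motif and its reverse complement then
share counts.

The 3'UTR scan takes a user-editable catalog of named stabilising /
destabilising motifs (e.g. the DST element's conserved core) and tests
presence-based counts (genes with >= 1 hit) in a gene set against the
genome.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats

from .io_model import EnrichmentResult, ValidationError

logger = logging.getLogger("xstress")

_CODE = np.full(256, -1, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mer strings over {A, C, G, T} in lexicographic order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def _window_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer code of each k-window of a sequence plus a validity mask
    (windows containing N are invalid)."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n_win = len(seq) - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    val = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        c = codes[j:j + n_win]
        val = val * 4 + np.where(c < 0, 0, c).astype(np.int64)
        valid &= c >= 0
    return val, valid


@dataclass
class KmerCounts:
    """Aggregate k-mer occurrence counts over one gene set's promoters.

    ``counts[i]`` is the total occurrence count of the i-th k-mer in
    lexicographic order; ``windows`` the total number of valid (N-free)
    k-windows scanned.  ``per_gene_windows`` retains each promoter's
    valid-window count for audit; in presence mode ``counts`` holds the
    number of genes with >= 1 occurrence and ``windows`` the number of
    genes scanned.
    """

    k: int
    counts: np.ndarray
    windows: int
    n_genes: int
    mode: str = "occurrence"
    per_gene_windows: dict[str, int] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=all_kmers(self.k))


def count_kmers(sequences: Mapping[str, str], k: int = 6,
                gene_set: Iterable[str] | None = None,
                mode: str = "occurrence",
                both_strands: bool = False) -> KmerCounts:
    """Count all 4^k k-mers over a gene set's promoter sequences.

    ``gene_set`` restricts to a subset of genes (default: every gene
    with a sequence); set members lacking a sequence are reported as
    missing, with a warning when they exceed 5% of the set.
    """
    if mode not in ("occurrence", "presence"):
        raise ValidationError(f"unknown counting mode {mode!r}")
    genes = list(sequences) if gene_set is None else list(gene_set)
    missing = [g for g in genes if g not in sequences]
    if missing:
        frac = len(missing) / len(genes)
        (logger.warning if frac > 0.05 else logger.info)(
            "%d/%d genes in the set have no promoter sequence",
            len(missing), len(genes)
        )
    counts = np.zeros(4 ** k, dtype=np.int64)
    windows = 0
    n_genes = 0
    per_gene_windows: dict[str, int] = {}
    for gene in genes:
        seq = sequences.get(gene)
        if seq is None:
            continue
        val, valid = _window_codes(seq, k)
        if both_strands:
            rc = seq.translate(_COMPLEMENT)[::-1]
            val_rc, valid_rc = _window_codes(rc, k)
            val = np.concatenate([val, val_rc])
            valid = np.concatenate([valid, valid_rc])
        n_valid = int(valid.sum())
        per_gene_windows[gene] = n_valid
        n_genes += 1
        if mode == "occurrence":
            counts += np.bincount(val[valid], minlength=4 ** k)
            windows += n_valid
        else:
            hit = np.unique(val[valid])
            counts[hit] += 1
            windows += 1
    return KmerCounts(k=k, counts=counts, windows=windows, n_genes=n_genes,
                      mode=mode, per_gene_windows=per_gene_windows,
                      missing=missing)


def motif_ratios(subset: KmerCounts, genome: KmerCounts) -> pd.DataFrame:
    """Genome-relative frequency ratio plus z/p for every k-mer.

    ratio = (subset count / subset windows) / (genome count / genome
    windows); motifs absent from the genome get a NaN ratio.  z and the
    two-sided p-value come from the pooled two-proportion statistic on
    the (count, windows) pairs; degenerate motifs (zero count on both
    sides) get z = 0, p = 1.
    """
    if subset.k != genome.k:
        raise ValidationError("k mismatch between subset and genome counts")
    if subset.windows == 0:
        raise ValidationError("subset has zero scanned windows")
    if genome.windows == 0:
        raise ValidationError("genome has zero scanned windows")
    k1 = subset.counts.astype(float)
    k2 = genome.counts.astype(float)
    n1 = float(subset.windows)
    n2 = float(genome.windows)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (k1 / n1) / (k2 / n2)
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (k1 / n1 - k2 / n2) / np.where(se > 0, se, 1.0),
                     0.0)
    p = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return pd.DataFrame({
        "count_subset": subset.counts,
        "count_genome": genome.counts,
        "ratio": ratio,
        "z": z,
        "p_value": np.minimum(p, 1.0),
    }, index=pd.Index(all_kmers(subset.k), name="motif"))


def shortlist(ratios: pd.DataFrame, alpha: float = 0.01,
              min_dev: float = 0.20) -> pd.DataFrame:
    """Motifs both significant and >= min_dev over/under-represented.

    The compound rule: p < alpha AND (ratio >= 1 + min_dev OR
    ratio <= 1 - min_dev).  Returns the qualifying rows of the ratio
    table (NaN ratios never qualify).
    """
    r = ratios["ratio"]
    keep = (ratios["p_value"] < alpha) & (
        (r >= 1.0 + min_dev) | (r <= 1.0 - min_dev)
    )
    return ratios[keep.fillna(False)]


def top_ranked(ratios: pd.DataFrame, n: int = 3,
               alpha: float = 0.01) -> list[str]:
    """The n most over-represented significant motifs, descending ratio.

    Only motifs with p < alpha and ratio > 1 qualify; ties break
    lexicographically by motif string.  May return fewer than n.
    """
    sig = ratios[(ratios["p_value"] < alpha) & (ratios["ratio"] > 1.0)]
    # lexicographic index sort first, then stable ratio sort: ties break
    # by motif string
    sig = sig.sort_index(kind="stable")
    sig = sig.sort_values("ratio", ascending=False, kind="stable")
    return list(sig.index[:n])


def build_ratio_matrix(ratio_tables: Mapping[str, pd.DataFrame],
                       alpha: float = 0.01,
                       min_dev: float = 0.20) -> pd.DataFrame:
    """Motifs x gene-sets ratio matrix over the union of shortlists."""
    keep: set[str] = set()
    for name, table in ratio_tables.items():
        keep |= set(shortlist(table, alpha=alpha, min_dev=min_dev).index)
    rows = sorted(keep)
    data = {name: table.loc[rows, "ratio"]
            for name, table in ratio_tables.items()}
    return pd.DataFrame(data, index=pd.Index(rows, name="motif"))


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def row_newick(self) -> str:
        return _linkage_to_newick(self.row_linkage, self.row_order_input)

    def col_newick(self) -> str:
        return _linkage_to_newick(self.col_linkage, self.col_order_input)

    row_order_input: list[str] = field(default_factory=list)
    col_order_input: list[str] = field(default_factory=list)


def _linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = render(node.get_left())
        right = render(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return render(tree) + ";"


def cluster_ratio_matrix(matrix: pd.DataFrame) -> ClusterResult:
    """Agglomeratively cluster motifs (rows) and gene sets (columns).

    Average linkage on correlation distance, as used for the
    genome-relative ratio heat map.  Rows and columns are sorted by
    label before computing the linkage, so the result is deterministic
    and invariant to the input ordering.  A constant matrix has no
    defined correlation distance and is rejected with a hint to widen
    the shortlist.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValidationError(
            "need at least 2 motifs and 2 gene sets to cluster"
        )
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("ratio matrix contains NaN entries")

    def _cluster(data: np.ndarray, labels: list[str]):
        if np.allclose(data.std(axis=1), 0.0):
            raise ValidationError(
                "constant rows/columns: correlation distance undefined; "
                "widen the shortlist (raise alpha or lower min_dev)"
            )
        dist = pdist(data, metric="correlation")
        if np.isnan(dist).any():
            raise ValidationError(
                "correlation distance undefined for some pairs; widen the "
                "shortlist (raise alpha or lower min_dev)"
            )
        linkage = hierarchy.linkage(dist, method="average")
        order = hierarchy.leaves_list(linkage)
        return linkage, [labels[i] for i in order]

    row_linkage, row_order = _cluster(values, list(matrix.index))
    col_linkage, col_order = _cluster(values.T, list(matrix.columns))
    return ClusterResult(
        row_order=row_order, col_order=col_order,
        row_linkage=row_linkage, col_linkage=col_linkage,
        row_order_input=list(matrix.index),
        col_order_input=list(matrix.columns),
    )


# ---------------------------------------------------------------------------
# 3'UTR motif catalog and scan
# ---------------------------------------------------------------------------

UTR_CLASSES = ("stabilising", "destabilising")


@dataclass
class UtrMotifCatalog:
    """Named exact-string 3'UTR motifs with a stability class each."""

    entries: list[tuple[str, str, str]]  # (name, class, sequence)

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValidationError("catalog motif names must be unique")
        for name, cls, seq in self.entries:
            if cls not in UTR_CLASSES:
                raise ValidationError(
                    f"motif {name}: class must be one of {UTR_CLASSES}"
                )
            if not seq or set(seq) - set("ACGT"):
                raise ValidationError(
                    f"motif {name}: sequence must be a nonempty ACGT string"
                )

    def by_class(self, cls: str) -> list[tuple[str, str]]:
        return [(name, seq) for name, c, seq in self.entries if c == cls]


def read_utr_catalog(path) -> UtrMotifCatalog:
    """Read a catalog TSV with columns name, motif_class, sequence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "motif_class", "sequence"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"catalog lacks columns {sorted(required - set(df.columns))}"
        )
    entries = [(row["name"], row["motif_class"], row["sequence"].upper())
               for _, row in df.iterrows()]
    return UtrMotifCatalog(entries=entries)


def utr_scan(utrs: Mapping[str, str], catalog: UtrMotifCatalog,
             gene_set: Iterable[str],
             genome_genes: Iterable[str] | None = None,
             alpha: float = 0.01,
             ) -> tuple[list[EnrichmentResult], pd.DataFrame]:
    """Presence-based enrichment of catalog motifs in a gene set's UTRs.

    For each motif — and for each stability class as a whole (genes with
    >= 1 hit of any motif in the class) — the fraction of hit genes in
    the set is tested against the genome with the two-proportion z.
    Genes without a UTR sequence are excluded from both numerator and
    denominator and reported.  Returns the enrichment results and the
    per-gene boolean hit table (genome genes x motifs) for audit.
    """
    from .enrichment import two_prop_z  # local import: avoid cycle

    if not catalog.entries:
        raise ValidationError("empty UTR motif catalog")
    genome = list(utrs) if genome_genes is None else list(genome_genes)
    set_genes = list(gene_set)
    dropped = [g for g in set(set_genes) | set(genome) if g not in utrs]
    if dropped:
        logger.info("%d gene(s) without a 3'UTR sequence excluded from the "
                    "scan", len(dropped))
    genome = [g for g in genome if g in utrs]
    set_genes = [g for g in set_genes if g in utrs]
    if not genome or not set_genes:
        raise ValidationError("no genes with UTR sequences to scan")

    hits = pd.DataFrame(False, index=pd.Index(genome, name="gene"),
                        columns=[name for name, _, _ in catalog.entries])
    for name, _, seq in catalog.entries:
        hits[name] = [seq in utrs[g] for g in genome]

    set_idx = hits.index.isin(set(set_genes))
    n1 = int(set_idx.sum())
    n2 = len(genome)
    results = []
    for name, cls, _ in catalog.entries:
        k1 = int(hits.loc[set_idx, name].sum())
        k2 = int(hits[name].sum())
        z, p = two_prop_z(k1, n1, k2, n2)
        flag = ("over" if z > 0 else "under") if p < alpha else "none"
        results.append(EnrichmentResult(
            category=f"motif:{name}", k_subset=k1, n_subset=n1,
            k_genome=k2, n_genome=n2, z=z, p_value=p, flag=flag,
        ))
    for cls in UTR_CLASSES:
        names = [name for name, c, _ in catalog.entries if c == cls]
        if not names:
            continue
        class_hit = hits[names].any(axis=1)
        k1 = int(class_hit[set_idx].sum())
        k2 = int(class_hit.sum())
        z, p = two_prop_z(k1, n1, k2, n2)
        flag = ("over" if z > 0 else "under") if p < alpha else "none"
        results.append(EnrichmentResult(
            category=f"class:{cls}", k_subset=k1, n_subset=n1,
            k_genome=k2, n_genome=n2, z=z, p_value=p, flag=flag,
        ))
    return results, hits
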