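"""k-mer counting, genome-relative ratios, shortlist, clustering, UTRs."""

import numpy as np
import pandas as pd
import pytest

from xstress import (ValidationError, all_kmers, build_ratio_matrix,
                     cluster_ratio_matrix, count_kmers, motif_ratios,
                     shortlist, top_ranked, utr_scan)
from xstress.motif_scan import UtrMotifCatalog, read_utr_catalog


def test_overlapping_occurrences_counted():
    counts = count_kmers({"g": "AAAAAAA"}, k=6)
    series = counts.as_series()
    assert series["AAAAAA"] == 2
    assert series.sum() == 2
    assert counts.windows == 2


def test_window_count_is_length_minus_k_plus_one():
    seq = "ACGT" * 250  # 1000 bases, N-free
    counts = count_kmers({"g": seq}, k=6)
    assert counts.windows == 995


def test_windows_with_n_are_skipped():
    counts = count_kmers({"g": "ACGTNACGTACG"}, k=6)
    # valid windows: positions 5..6 only (0-4 all contain the N)
    assert counts.windows == 2
    assert counts.as_series()["ACGTAC"] == 1


def test_counts_match_string_oracle():
    """Sliding-window counts agree with a naive per-position string
    comparison on random promoters."""
    rng = np.random.default_rng(23)
    seqs = {}
    for i in range(100):
        bases = rng.choice(list("ACGTN"), size=60,
                           p=[0.24, 0.24, 0.24, 0.24, 0.04])
        seqs[f"g{i}"] = "".join(bases)
    counts = count_kmers(seqs, k=6).as_series()
    probe = list(rng.choice(all_kmers(6), size=30)) + ["AAAAAA", "ACGTAC"]
    for motif in probe:
        naive = sum(
            sum(1 for j in range(len(s) - 5) if s[j:j + 6] == motif)
            for s in seqs.values()
        )
        assert counts[motif] == naive, motif


def test_count_conservation_invariant(dataset_small):
    """Total k-mer occurrences equal total valid windows scanned."""
    counts = count_kmers(dataset_small.promoters_a, k=6)
    assert counts.counts.sum() == counts.windows
    assert counts.windows == sum(counts.per_gene_windows.values())


def test_presence_mode_counts_genes_once():
    seqs = {"g1": "AAAAAAAA", "g2": "AAAAAACC", "g3": "CCCCCCCC"}
    counts = count_kmers(seqs, k=6, mode="presence")
    series = counts.as_series()
    assert series["AAAAAA"] == 2   # g1 and g2, multiplicity ignored
    assert counts.windows == 3     # genes scanned


def test_both_strands_share_counts():
    seqs = {"g": "CACGTGAA"}
    plus = count_kmers(seqs, k=6).as_series()
    both = count_kmers(seqs, k=6, both_strands=True).as_series()
    # CACGTG is its own reverse complement: counted on both strands
    assert plus["CACGTG"] == 1
    assert both["CACGTG"] == 2
    # TTCACG appears only on the reverse strand
    assert plus["TTCACG"] == 0
    assert both["TTCACG"] == 1


def test_genome_against_itself_has_unit_ratios(dataset_small):
    genome = count_kmers(dataset_small.promoters_b, k=6)
    ratios = motif_ratios(genome, genome)
    defined = ratios["ratio"].dropna()
    assert np.allclose(defined, 1.0)
    nan_rows = ratios["ratio"].isna()
    assert (ratios.loc[nan_rows, "count_genome"] == 0).all()


def test_ratio_invariant_under_promoter_duplication():
    rng = np.random.default_rng(29)
    seqs = {f"g{i}": "".join(rng.choice(list("ACGT"), 80))
            for i in range(40)}
    genome = count_kmers(seqs, k=6)
    subset_genes = [f"g{i}" for i in range(10)]
    single = motif_ratios(count_kmers(seqs, 6, gene_set=subset_genes),
                          genome)
    doubled_seqs = dict(seqs)
    doubled_seqs.update({f"dup_{g}": seqs[g] for g in subset_genes})
    doubled = motif_ratios(
        count_kmers(doubled_seqs, 6,
                    gene_set=subset_genes + [f"dup_{g}"
                                             for g in subset_genes]),
        genome)
    pd.testing.assert_series_equal(single["ratio"], doubled["ratio"])


@pytest.mark.parametrize("ratio,p,listed", [
    (1.15, 1e-6, False),   # significant but below the 20% deviation
    (1.5, 0.5, False),     # deviant but not significant
    (0.75, 1e-4, True),    # significant under-representation
    (1.25, 5e-3, True),
    (0.80, 5e-3, True),    # boundary: ratio <= 0.8 qualifies
])
def test_shortlist_compound_rule(ratio, p, listed):
    table = pd.DataFrame({
        "count_subset": [10], "count_genome": [100],
        "ratio": [ratio], "z": [1.0], "p_value": [p],
    }, index=pd.Index(["AAAAAA"], name="motif"))
    assert (len(shortlist(table)) == 1) is listed


def test_top_ranked_ordering_and_ties():
    motifs = ["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT", "ACGTAC"]
    table = pd.DataFrame({
        "ratio": [3.0, 2.0, 1.5, 2.0, 4.0],
        "p_value": [1e-5, 1e-5, 1e-5, 1e-5, 0.5],
    }, index=pd.Index(motifs, name="motif"))
    # ACGTAC not significant; CCCCCC/TTTTTT tie broken lexicographically
    assert top_ranked(table, n=3) == ["AAAAAA", "CCCCCC", "TTTTTT"]
    assert top_ranked(table, n=10) == ["AAAAAA", "CCCCCC", "TTTTTT",
                                       "GGGGGG"]
    none_sig = table.assign(p_value=0.5)
    assert top_ranked(none_sig) == []


def test_planted_motif_recovery(dataset_motif500):
    """The motif planted at 2x in a ~500-promoter drought-up set comes
    back with a ratio near 2 and ranks first."""
    ds = dataset_motif500
    motif, label, fold = ds.truth.planted_motifs[0]
    genome = count_kmers(ds.promoters_a, 6)
    subset = count_kmers(ds.promoters_a, 6,
                         gene_set=ds.truth.gene_set(label))
    ratios = motif_ratios(subset, genome)
    assert ratios.loc[motif, "ratio"] == pytest.approx(fold, abs=0.25)
    assert top_ranked(ratios)[0] == motif
    # the planted motif does not leak into unrelated sets
    other = count_kmers(ds.promoters_a, 6,
                        gene_set=ds.truth.gene_set("a_heat_up"))
    other_ratios = motif_ratios(other, genome)
    assert motif not in set(shortlist(other_ratios).index)


def test_cluster_identical_columns_merge_first():
    rng = np.random.default_rng(31)
    base = rng.uniform(0.5, 2.0, 12)
    matrix = pd.DataFrame({
        "set1": base, "set2": base,              # identical pair
        "set3": rng.uniform(0.5, 2.0, 12),
    }, index=all_kmers(6)[:12])
    result = cluster_ratio_matrix(matrix)
    first_merge = result.col_linkage[0]
    assert first_merge[2] == pytest.approx(0.0, abs=1e-12)
    merged = {result.col_order_input[int(first_merge[0])],
              result.col_order_input[int(first_merge[1])]}
    assert merged == {"set1", "set2"}


def test_cluster_invariant_to_row_permutation():
    rng = np.random.default_rng(32)
    matrix = pd.DataFrame(rng.uniform(0.5, 2.0, (20, 4)),
                          index=all_kmers(6)[:20],
                          columns=["s1", "s2", "s3", "s4"])
    res1 = cluster_ratio_matrix(matrix)
    shuffled = matrix.sample(frac=1.0, random_state=5)
    res2 = cluster_ratio_matrix(shuffled)
    assert res1.row_order == res2.row_order
    assert res1.col_order == res2.col_order
    assert np.allclose(res1.row_linkage, res2.row_linkage)


def test_cluster_rejects_constant_matrix():
    matrix = pd.DataFrame(1.0, index=all_kmers(6)[:5],
                          columns=["s1", "s2", "s3"])
    with pytest.raises(ValidationError, match="shortlist"):
        cluster_ratio_matrix(matrix)


def test_species_sets_split_into_two_branches(dataset_species_motifs):
    """With species-wide planted motifs the column dendrogram's two
    top-level branches separate the species."""
    from scipy.cluster import hierarchy

    ds = dataset_species_motifs
    tables = {}
    for sp, seqs in (("a", ds.promoters_a), ("b", ds.promoters_b)):
        genome = count_kmers(seqs, 6)
        for stress in ds.config.stresses:
            gene_set = ds.truth.gene_set(f"{sp}_{stress}_up")
            tables[f"{sp}_{stress}_up"] = motif_ratios(
                count_kmers(seqs, 6, gene_set=gene_set), genome)
    matrix = build_ratio_matrix(tables)
    result = cluster_ratio_matrix(matrix)
    tree = hierarchy.to_tree(result.col_linkage)
    labels = result.col_order_input
    left = {labels[i][0] for i in tree.get_left().pre_order()}
    right = {labels[i][0] for i in tree.get_right().pre_order()}
    assert {frozenset(left), frozenset(right)} == {frozenset("a"),
                                                   frozenset("b")}


def test_newick_export_contains_all_leaves():
    rng = np.random.default_rng(33)
    matrix = pd.DataFrame(rng.uniform(0.5, 2.0, (8, 3)),
                          index=all_kmers(6)[:8],
                          columns=["s1", "s2", "s3"])
    result = cluster_ratio_matrix(matrix)
    newick = result.row_newick()
    assert newick.endswith(";")
    for motif in matrix.index:
        assert motif in newick


# ---------------------------------------------------------------------------
# 3'UTR catalog scan
# ---------------------------------------------------------------------------

def _catalog():
    return UtrMotifCatalog(entries=[
        ("DST_core", "destabilising", "ATAGAT"),
        ("stab_x", "stabilising", "GGCCGGTT"),
    ])


def test_catalog_validation():
    with pytest.raises(ValidationError):
        UtrMotifCatalog(entries=[("m", "destabilising", "ACGT"),
                                 ("m", "stabilising", "ACGT")])
    with pytest.raises(ValidationError):
        UtrMotifCatalog(entries=[("m", "sticky", "ACGT")])


def test_catalog_roundtrip(tmp_path):
    path = tmp_path / "catalog.tsv"
    path.write_text("name\tmotif_class\tsequence\n"
                    "DST_core\tdestabilising\tatagat\n")
    catalog = read_utr_catalog(path)
    assert catalog.entries == [("DST_core", "destabilising", "ATAGAT")]


def test_absent_motif_scores_null():
    utrs = {f"g{i}": "CCCCCCCCCCCC" for i in range(40)}
    results, hits = utr_scan(utrs, _catalog(), [f"g{i}" for i in range(10)])
    by_cat = {r.category: r for r in results}
    assert by_cat["motif:DST_core"].k_genome == 0
    assert by_cat["motif:DST_core"].flag == "none"
    assert not hits.any().any()


def test_planted_utr_motif_flagged_over():
    """A motif present in half the set but 5% of the genome is flagged
    as over-represented."""
    rng = np.random.default_rng(37)
    utrs = {}
    for i in range(400):
        seq = "".join(rng.choice(list("ACGT"), 50))
        seq = seq.replace("ATAGAT", "ACAGAC")  # scrub chance hits
        if (i < 40 and i % 2 == 0) or (i >= 40 and i % 20 == 0):
            seq = "ATAGAT" + seq[6:]
        utrs[f"g{i}"] = seq
    gene_set = [f"g{i}" for i in range(40)]
    results, hits = utr_scan(utrs, _catalog(), gene_set)
    by_cat = {r.category: r for r in results}
    assert by_cat["motif:DST_core"].flag == "over"
    assert by_cat["class:destabilising"].flag == "over"
    assert bool(hits.loc["g0", "DST_core"]) is True
    assert bool(hits.loc["g1", "DST_core"]) is False


def test_genes_without_utr_are_excluded():
    utrs = {"g1": "ATAGATCCC", "g2": "CCCCCCCCC"}
    results, hits = utr_scan(utrs, _catalog(), ["g1", "g2", "g3"])
    assert len(hits) == 2           # g3 has no sequence
    assert results[0].n_subset == 2


def test_planted_utr_motif_end_to_end(dataset_default):
    """The generator's planted destabilising motif is enriched in its
    target set when scanned with the emitted catalog."""
    ds = dataset_default
    motif, cls, label, _frac = ds.truth.planted_utr_motifs[0]
    gene_set = ds.truth.gene_set(label)
    results, _ = utr_scan(ds.utrs_a, ds.catalog, gene_set,
                          genome_genes=ds.universe.species_a_ids)
    by_cat = {r.category: r for r in results}
    [name] = [n for n, c, seq in ds.catalog.entries if seq == motif]
    assert by_cat[f"motif:{name}"].flag == "over"
    assert by_cat[f"class:{cls}"].flag == "over"
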