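"""Two-proportion z, Fisher ORA and category enrichment schemes."""

import numpy as np
import pytest
from scipy import stats

from xstress import (CategoryScheme, ValidationError, category_enrichment,
                     fisher_ora, relaxed_flag, two_prop_z)
from xstress.io_model import GeneAnnotation, GeneUniverse


def test_equal_proportions_give_null():
    for k1, n1, k2, n2 in [(5, 10, 50, 100), (0, 10, 0, 100),
                           (3, 3, 30, 30)]:
        z, p = two_prop_z(k1, n1, k2, n2)
        assert z == 0.0
        assert p == 1.0


def test_worked_proportion_example():
    """75/100 vs 37/100 (the constitutive-vs-genome ortholog scenario)
    gives z ~ 5.413 by direct evaluation of the pooled formula."""
    z, p = two_prop_z(75, 100, 37, 100)
    assert z == pytest.approx(5.4131, abs=1e-3)
    assert p < 1e-6


def test_z_squared_equals_pearson_chisquare():
    """On any 2x2 table the two-proportion z satisfies z^2 = X^2
    (Pearson, no continuity correction), to 1e-9."""
    rng = np.random.default_rng(17)
    checked = 0
    while checked < 50:
        n1, n2 = rng.integers(5, 200, 2)
        k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
        if (k1 + k2) in (0, n1 + n2):
            continue
        z, _ = two_prop_z(int(k1), int(n1), int(k2), int(n2))
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
        chi2 = stats.chi2_contingency(table, correction=False).statistic
        assert z ** 2 == pytest.approx(chi2, abs=1e-9)
        checked += 1


def test_z_antisymmetric_under_swap():
    rng = np.random.default_rng(18)
    for _ in range(25):
        n1, n2 = rng.integers(5, 100, 2)
        k1, k2 = rng.integers(1, n1), rng.integers(1, n2)
        z1, p1 = two_prop_z(int(k1), int(n1), int(k2), int(n2))
        z2, p2 = two_prop_z(int(k2), int(n2), int(k1), int(n1))
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


def test_two_prop_z_null_uniformity():
    """With both samples binomial at the same rate, the fraction of
    p < 0.01 stays within 3 SE of 0.01 over 10,000 replicates."""
    rng = np.random.default_rng(19)
    n1, n2, prob, reps = 400, 2000, 0.2, 10_000
    k1 = rng.binomial(n1, prob, reps)
    k2 = rng.binomial(n2, prob, reps)
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2 * stats.norm.sf(np.abs(z))
    frac = (p < 0.01).mean()
    band = 3 * np.sqrt(0.01 * 0.99 / reps)
    assert abs(frac - 0.01) < band


def _hypergeom_two_sided(k_subset, n_subset, k_genome, n_genome):
    """Exhaustive two-sided Fisher p: sum of all outcome probabilities
    no larger than the observed one."""
    lo = max(0, k_genome - (n_genome - n_subset))
    hi = min(n_subset, k_genome)
    pmf = {x: stats.hypergeom.pmf(x, n_genome, k_genome, n_subset)
           for x in range(lo, hi + 1)}
    obs = pmf[k_subset]
    return sum(v for v in pmf.values() if v <= obs * (1 + 1e-9))


def test_fisher_matches_hypergeometric_enumeration():
    """Fisher ORA equals exhaustive hypergeometric enumeration on every
    consistent small table and a random sample of larger ones."""
    tables = []
    for n_genome in range(2, 13):
        for n_subset in range(1, n_genome + 1):
            for k_genome in range(0, n_genome + 1):
                lo = max(0, k_genome - (n_genome - n_subset))
                hi = min(n_subset, k_genome)
                for k_subset in range(lo, hi + 1):
                    tables.append((k_subset, n_subset, k_genome, n_genome))
    rng = np.random.default_rng(20)
    for _ in range(300):
        n_genome = int(rng.integers(14, 31))
        n_subset = int(rng.integers(1, n_genome + 1))
        k_genome = int(rng.integers(0, n_genome + 1))
        lo = max(0, k_genome - (n_genome - n_subset))
        hi = min(n_subset, k_genome)
        k_subset = int(rng.integers(lo, hi + 1))
        tables.append((k_subset, n_subset, k_genome, n_genome))
    for tab in tables:
        _, p = fisher_ora(*tab)
        assert p == pytest.approx(_hypergeom_two_sided(*tab), abs=1e-9), tab


def test_fisher_zero_margin():
    _, p = fisher_ora(0, 10, 0, 100)
    assert p == 1.0


def test_fisher_rejects_inconsistent_counts():
    with pytest.raises(ValidationError):
        fisher_ora(5, 10, 3, 100)   # subset has more hits than genome


def test_fisher_and_z_agree_on_direction_for_large_tables():
    """For large balanced tables the exact and normal-approximation
    routes flag the same over/under direction."""
    rng = np.random.default_rng(21)
    agree = 0
    for _ in range(100):
        n_subset = int(rng.integers(200, 500))
        n_genome = n_subset + int(rng.integers(1000, 3000))
        rate = rng.uniform(0.2, 0.4)
        # clearly-null or clearly-shifted tables: at the significance
        # boundary the exact and normal routes may legitimately differ
        shift = 0.0 if rng.random() < 0.5 else rng.choice([-0.15, 0.15])
        k_subset = int(np.clip(rng.binomial(n_subset, rate + shift), 0,
                               n_subset))
        k_genome = k_subset + rng.binomial(n_genome - n_subset, rate)
        z, pz = two_prop_z(k_subset, n_subset, k_genome, n_genome)
        _, pf = fisher_ora(k_subset, n_subset, k_genome, n_genome)
        flag_z = ("over" if z > 0 else "under") if pz < 0.01 else "none"
        delta = k_subset / n_subset - k_genome / n_genome
        flag_f = ("over" if delta > 0 else "under") if pf < 0.01 else "none"
        agree += flag_z == flag_f
    assert agree >= 95


def test_flag_monotone_in_subset_count():
    """Increasing k1 with everything else fixed never moves a flag from
    over toward under."""
    order = {"under": 0, "none": 1, "over": 2}
    prev = -1
    for k1 in range(0, 101, 5):
        z, p = two_prop_z(k1, 100, 300, 1000)
        flag = ("over" if z > 0 else "under") if p < 0.01 else "none"
        assert order[flag] >= prev
        prev = order[flag]


# ---------------------------------------------------------------------------
# category schemes
# ---------------------------------------------------------------------------

def _toy_universe():
    ann = {}
    for i in range(200):
        gene = f"g{i}"
        funcat = ["kinase"] if i < 40 else ["metabolism"]
        if i % 10 == 0:
            funcat.append("redox")
        ann[gene] = GeneAnnotation(
            funcat=funcat,
            tf_family="AP2" if i < 10 else ("NAC" if i < 30 else None),
            lineage_specific=i < 6,
        )
    return GeneUniverse(species_a_ids={f"g{i}" for i in range(200)},
                        species_b_ids=set(), annotations=ann)


def test_category_at_genome_rate_not_flagged():
    universe = _toy_universe()
    scheme = CategoryScheme.funcat(universe)
    # subset drawn proportionally: 10 kinase of 50 vs 40 of 200 genome
    subset = [f"g{i}" for i in range(10)] + [f"g{i}" for i in range(40, 80)]
    results = {r.category: r
               for r in category_enrichment(subset, scheme,
                                            universe.species_a_ids)}
    assert results["kinase"].flag == "none"


def test_planted_category_enrichment_recovered(dataset_default):
    """The planted 3x-enriched category is flagged over at p < 0.01."""
    ds = dataset_default
    category, label, _fold = ds.truth.planted_categories[0]
    scheme = CategoryScheme.funcat(ds.universe)
    results = {r.category: r
               for r in category_enrichment(
                   ds.truth.gene_set(label), scheme,
                   ds.universe.species_a_ids)}
    assert results[category].flag == "over"
    assert results[category].p_value < 0.01


def test_lineage_scheme_matches_formula_oracle():
    """The lineage-specific enrichment of a subset equals a direct
    two-proportion evaluation on the same counts."""
    universe = _toy_universe()
    scheme = CategoryScheme.lineage_specific(universe)
    subset = [f"g{i}" for i in range(0, 80, 2)]  # 3 of the 6 lineage genes
    [res] = category_enrichment(subset, scheme, universe.species_a_ids)
    z_ref, p_ref = two_prop_z(res.k_subset, res.n_subset,
                              res.k_genome, res.n_genome)
    assert res.z == pytest.approx(z_ref, abs=1e-12)
    assert res.p_value == pytest.approx(p_ref, abs=1e-12)


def test_tf_scheme_uses_all_tf_denominator():
    """TF-family proportions are compared within the TF complement, not
    the whole genome."""
    universe = _toy_universe()
    scheme = CategoryScheme.tf_family(universe)
    subset = [f"g{i}" for i in range(5)] + ["g100", "g101"]  # 5 AP2 + 2 non-TF
    results = {r.category: r
               for r in category_enrichment(subset, scheme,
                                            universe.species_a_ids)}
    assert results["AP2"].n_subset == 5      # non-TF genes dropped
    assert results["AP2"].n_genome == 30     # all TFs, not 200
    assert results["AP2"].k_genome == 10


def test_relaxed_flag_threshold():
    """A category with 0.01 < p < 0.02 misses the strict flag but
    carries the relaxed cross-species flag."""
    from xstress.io_model import EnrichmentResult

    z, p = two_prop_z(33, 100, 220, 1000)
    assert 0.01 < p < 0.02
    res = EnrichmentResult("c", 33, 100, 220, 1000, z, p, flag="none")
    assert relaxed_flag(res) == "over"


def test_empty_gene_set_returns_empty():
    universe = _toy_universe()
    scheme = CategoryScheme.funcat(universe)
    assert category_enrichment([], scheme, universe.species_a_ids) == []


def test_degenerate_pooled_proportion():
    z, p = two_prop_z(0, 50, 0, 500)
    assert (z, p) == (0.0, 1.0)
    z, p = two_prop_z(50, 50, 500, 500)
    assert (z, p) == (0.0, 1.0)
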