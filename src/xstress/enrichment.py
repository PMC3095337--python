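"""Category over/under-representation statistics.

Two routes are provided, matching how the original analyses were run:

* a two-proportion z-score — the workhorse for functional-catalogue
  (FUNCAT), TF-family and lineage-specific enrichment, comparing the
  category proportion in a gene subset against the genome (or, for TF
  families, against the full TF complement):

      z = (p1 - p2) / sqrt( p(1-p) (1/n1 + 1/n2) ),   p = (k1+k2)/(n1+n2)

* Fisher's exact test, for PageMan-style over-representation analysis.

Both are two-sided; the over/under direction is read from the sign of
the subset-minus-genome difference.  No multiple-testing correction is
applied by default (the original thresholds are raw per-category
p < 0.01 with a relaxed p < 0.02 cross-species convention); an optional
Benjamini-Hochberg adjustment is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .io_model import EnrichmentResult, GeneUniverse, ValidationError

logger = logging.getLogger("xstress")


def two_prop_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-proportion z statistic and two-sided normal p-value.

    Compares k1/n1 against k2/n2 using the pooled-proportion standard
    error.  When the pooled proportion is degenerate (0 or 1) there is
    no variation to test against: z is defined as 0 and p as 1.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("counts must satisfy 0 <= k <= n")
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("both sample sizes must be positive")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.warning("degenerate pooled proportion %g: z := 0, p := 1",
                       pooled)
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def fisher_ora(k_subset: int, n_subset: int, k_genome: int,
               n_genome: int) -> tuple[float, float]:
    """Fisher's exact test for over-representation analysis.

    ``k_genome``/``n_genome`` are genome-wide category/total counts that
    *include* the subset; the 2x2 table is (subset in/out of category)
    versus (rest of genome in/out of category).
    """
    if not (0 <= k_subset <= n_subset and 0 <= k_genome <= n_genome):
        raise ValidationError("counts must satisfy 0 <= k <= n")
    if k_subset > k_genome or n_subset > n_genome:
        raise ValidationError(
            "subset counts exceed genome counts: "
            f"k {k_subset}>{k_genome} or n {n_subset}>{n_genome}"
        )
    rest_k = k_genome - k_subset
    rest_n = n_genome - n_subset
    if rest_k > rest_n:
        raise ValidationError("genome counts inconsistent with subset")
    table = [[k_subset, n_subset - k_subset], [rest_k, rest_n - rest_k]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def _flag(z: float, p: float, alpha: float) -> str:
    if p < alpha:
        return "over" if z > 0 else "under"
    return "none"


@dataclass
class CategoryScheme:
    """How genes map to categories and what the denominator set is.

    ``scheme`` is one of funcat, tf_family, lineage_specific or custom;
    ``labels`` maps gene -> list of category labels (a gene may carry
    several FUNCATs and is counted once in each it carries).  With
    ``denominator="all_tfs"`` both the subset and the genome side are
    restricted to TF genes, so family proportions are compared within
    the TF complement, as done for TF-family enrichment.
    """

    scheme: str
    labels: Mapping[str, list[str]]
    denominator: str = "genome"  # genome | all_tfs

    @classmethod
    def funcat(cls, universe: GeneUniverse) -> "CategoryScheme":
        labels = {g: list(ann.funcat)
                  for g, ann in universe.annotations.items() if ann.funcat}
        return cls("funcat", labels)

    @classmethod
    def tf_family(cls, universe: GeneUniverse) -> "CategoryScheme":
        labels = {g: [ann.tf_family]
                  for g, ann in universe.annotations.items()
                  if ann.tf_family is not None}
        return cls("tf_family", labels, denominator="all_tfs")

    @classmethod
    def lineage_specific(cls, universe: GeneUniverse) -> "CategoryScheme":
        labels = {g: ["lineage_specific"]
                  for g, ann in universe.annotations.items()
                  if ann.lineage_specific}
        return cls("lineage_specific", labels)


def category_enrichment(gene_set: Iterable[str], scheme: CategoryScheme,
                        universe_genes: Iterable[str],
                        alpha_strict: float = 0.01,
                        alpha_relaxed: float = 0.02,
                        method: str = "two_prop_z",
                        bh_correct: bool = False) -> list[EnrichmentResult]:
    """Test every category of a scheme for over/under-representation.

    ``universe_genes`` is the genome denominator (an explicit parameter:
    depending on the analysis it may be all genes or only expressed
    genes).  With the ``all_tfs`` denominator rule both sides are first
    restricted to genes carrying any label in the scheme.  One result is
    produced per category with at least one member in the universe;
    ``flag`` applies the strict threshold, and results also expose a
    relaxed flag through :func:`relaxed_flag`.
    """
    universe = set(universe_genes)
    subset = set(gene_set)
    if not subset <= universe:
        raise ValidationError(
            f"{len(subset - universe)} subset genes missing from the "
            "universe denominator"
        )
    if scheme.denominator == "all_tfs":
        labelled = set(scheme.labels)
        universe = universe & labelled
        subset = subset & labelled
    if not subset:
        logger.warning("empty gene set after denominator restriction")
        return []

    categories: dict[str, set[str]] = {}
    for gene, labels in scheme.labels.items():
        if gene in universe:
            for lab in labels:
                categories.setdefault(lab, set()).add(gene)

    n1, n2 = len(subset), len(universe)
    results = []
    for cat in sorted(categories):
        members = categories[cat]
        k1 = len(subset & members)
        k2 = len(members)
        if method == "two_prop_z":
            z, p = two_prop_z(k1, n1, k2, n2)
        elif method == "fisher":
            odds, p = fisher_ora(k1, n1, k2, n2)
            z = np.sign(k1 / n1 - k2 / n2) * abs(stats.norm.isf(p / 2.0))
        else:
            raise ValidationError(f"unknown method {method!r}")
        results.append(EnrichmentResult(
            category=cat, k_subset=k1, n_subset=n1, k_genome=k2, n_genome=n2,
            z=float(z), p_value=float(p),
            flag=_flag(z, p, alpha_strict), method=method,
        ))
    if bh_correct:
        _apply_bh(results, alpha_strict)
    return results


def relaxed_flag(result: EnrichmentResult,
                 alpha_relaxed: float = 0.02) -> str:
    """Direction flag at the relaxed threshold (used when a category is
    strictly significant in one species and nearly so in the other)."""
    return _flag(result.z, result.p_value, alpha_relaxed)


def _apply_bh(results: list[EnrichmentResult], alpha: float) -> None:
    """Re-flag results using Benjamini-Hochberg adjusted p-values."""
    m = len(results)
    if m == 0:
        return
    order = np.argsort([r.p_value for r in results])
    adj = np.empty(m)
    prev = 1.0
    for rank, idx in enumerate(reversed(order), start=0):
        i = m - rank
        val = results[idx].p_value * m / i
        prev = min(prev, val)
        adj[idx] = prev
    for r, q in zip(results, adj):
        r.p_value = float(min(q, 1.0))
        r.flag = _flag(r.z, r.p_value, alpha)
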