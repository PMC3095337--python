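"""Presence calling and expression-breadth / organ-specificity classes.

A gene is *present* in a biological sample when at least ``min_reps``
replicate arrays of that sample give a detection p-value strictly below
``alpha`` (default p < 0.05, >= 2 replicates).  Presence calls across
the whole compendium then partition genes by breadth:

* always      - present in every sample (constitutive expression)
* never       - present in no sample
* specific    - present in exactly one sample
* nonspecific - anything in between

Organ-specific sets refine this: a gene is e.g. leaf-specific when it
is present in one or more leaf samples (any developmental stage) and
has replicate support below the threshold in every sample of every
other organ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import ExpressionStudy, ValidationError

logger = logging.getLogger("xstress")

BREADTH_CLASSES = ("always", "never", "specific", "nonspecific")


@dataclass
class PresenceMatrix:
    """Genes x samples presence calls with supporting replicate counts."""

    present: pd.DataFrame        # bool, genes x samples
    support: pd.DataFrame        # int, replicates with p < alpha
    alpha: float
    min_reps: int

    def validate(self) -> None:
        if not self.present.equals(self.support >= self.min_reps):
            raise ValidationError(
                "presence must equal (support >= min_reps)"
            )


def call_presence(study: ExpressionStudy, alpha: float = 0.05,
                  min_reps: int = 2) -> PresenceMatrix:
    """Threshold detection p-values into per-sample presence calls.

    A cell is present iff the number of replicates with detection
    p < alpha (strict, so p exactly equal to alpha counts as absent) is
    at least ``min_reps``.  Samples with fewer than ``min_reps``
    replicates are still computed but flagged as low-power in the log.
    """
    support = {}
    for s in study.samples:
        cols = s.replicate_ids
        if len(cols) < min_reps:
            logger.warning(
                "sample %s has %d replicate(s) < min_reps=%d: presence "
                "calls are low-powered", s.sample_id, len(cols), min_reps
            )
        dp = study.detection_p[cols].to_numpy()
        support[s.sample_id] = (dp < alpha).sum(axis=1)
    support_df = pd.DataFrame(support, index=study.genes)
    return PresenceMatrix(
        present=support_df >= min_reps,
        support=support_df,
        alpha=alpha,
        min_reps=min_reps,
    )


@dataclass
class BreadthClass:
    """Per-gene expression-breadth labels and the breadth histogram."""

    labels: pd.Series            # gene -> class label
    n_samples_present: pd.Series
    histogram: pd.Series         # #samples present -> #genes

    def counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {c: int(vc.get(c, 0)) for c in BREADTH_CLASSES}

    def proportions(self) -> dict[str, float]:
        n = len(self.labels)
        return {c: k / n for c, k in self.counts().items()}


def classify_breadth(presence: PresenceMatrix) -> BreadthClass:
    """Partition genes into always/never/specific/nonspecific."""
    n_samples = presence.present.shape[1]
    if n_samples < 1:
        raise ValidationError("at least one sample required")
    n_present = presence.present.sum(axis=1)
    labels = pd.Series("nonspecific", index=presence.present.index)
    labels[n_present == n_samples] = "always"
    labels[n_present == 0] = "never"
    labels[n_present == 1] = "specific"
    if n_samples == 1:
        # degenerate compendium: present-in-the-only-sample is "always"
        labels[n_present == 1] = "always"
    histogram = n_present.value_counts().sort_index()
    histogram = histogram.reindex(range(n_samples + 1), fill_value=0)
    return BreadthClass(labels=labels, n_samples_present=n_present,
                        histogram=histogram)


def organ_specific_sets(presence: PresenceMatrix,
                        organ_of: Mapping[str, str]) -> dict[str, set[str]]:
    """Per-organ sets of genes expressed in that organ and nowhere else.

    ``organ_of`` maps sample id -> organ label; unlabeled samples should
    be mapped to "other".  A gene enters organ O's set iff it is present
    in >= 1 sample of O and its replicate support is below ``min_reps``
    in every sample of every other organ — exclusion is evaluated
    against *samples*, so a single replicate-supported presence in any
    non-target sample disqualifies.  Samples labeled "other" count for
    exclusion but get no set of their own.
    """
    samples = list(presence.present.columns)
    missing = [s for s in samples if s not in organ_of]
    if missing:
        raise ValidationError(
            f"samples without an organ label: {missing[:5]}"
        )
    organs = sorted({organ_of[s] for s in samples})
    out: dict[str, set[str]] = {}
    for organ in organs:
        if organ == "other":
            continue
        own = [s for s in samples if organ_of[s] == organ]
        rest = [s for s in samples if organ_of[s] != organ]
        if not own:
            logger.warning("organ %s has zero samples", organ)
            out[organ] = set()
            continue
        in_organ = presence.present[own].any(axis=1)
        excluded = (presence.present[rest].any(axis=1)
                    if rest else pd.Series(False, index=presence.present.index))
        out[organ] = set(presence.present.index[in_organ & ~excluded])
    return out
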