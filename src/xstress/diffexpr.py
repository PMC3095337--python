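"""Bayesian regularized differential expression with mixture-model FDR.

The two-condition test regularizes each gene's pooled variance toward a
*background* variance estimated from genes of similar expression level
(a sliding window over the intensity-ranked gene list), in the manner of
the Cyber-T family of tests:

    s~^2 = ( conf * bg + (n1 + n2 - 2) * s_pooled^2 ) / (conf + n1 + n2 - 2)
    t    = (mean(treated) - mean(control)) / sqrt( s~^2 (1/n1 + 1/n2) )
    df   = conf + n1 + n2 - 2

``conf`` acts as a pseudo-observation count for the background prior;
with conf = 0 the test reduces exactly to the pooled-variance Student
t-test.

False-discovery control uses the posterior probability of differential
expression (PPDE): the contrast's p-value distribution is fit by EM as a
two-component mixture of a Uniform(0,1) null and a Beta(a, 1) (a < 1)
alternative,

    f(p) = lam0 + (1 - lam0) * a * p^(a-1),

and each gene's PPDE is the posterior weight of the alternative at its
p-value.  A gene is called differentially expressed when p < 0.05 and
PPDE > 0.96 (strict inequalities), with direction from the sign of the
log2 fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (DEGRecord, ExpressionStudy, ValidationError,
                       deg_table)

logger = logging.getLogger("xstress")


@dataclass
class RegTParams:
    """Hyperparameters of the regularized t-test.

    conf: weight (pseudo-observations) of the background-variance prior.
    window: number of intensity-ranked neighbour genes averaged for the
        background variance; must be odd so the window is centred.
    """

    conf: float = 9.0
    window: int = 101

    def __post_init__(self) -> None:
        if self.conf < 0:
            raise ValidationError("conf must be >= 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be odd and >= 3")


def background_variance(mean_intensity: np.ndarray, variance: np.ndarray,
                        window: int = 101) -> np.ndarray:
    """Mean neighbour variance in a window over intensity-ranked genes.

    For each gene, the window covers the ``window`` genes nearest in
    rank of mean log2 intensity, truncated at the ends of the ranking.
    If fewer genes than ``window`` exist the window shrinks to the gene
    count (with a warning).
    """
    mean_intensity = np.asarray(mean_intensity, dtype=float)
    variance = np.asarray(variance, dtype=float)
    n = mean_intensity.size
    if n == 0:
        raise ValidationError("no genes")
    if n < window:
        logger.warning("only %d genes < window=%d: window shrunk", n, window)
        window = n if n % 2 == 1 else n - 1
        window = max(window, 1)
    half = (window - 1) // 2
    order = np.argsort(mean_intensity, kind="stable")
    ranked_var = variance[order]
    csum = np.concatenate([[0.0], np.cumsum(ranked_var)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    win_mean = (csum[hi] - csum[lo]) / (hi - lo)
    out = np.empty(n)
    out[order] = win_mean
    return out


def regularized_t(control: np.ndarray, treated: np.ndarray,
                  params: RegTParams,
                  background_var: float) -> tuple[float, float, float, float]:
    """Regularized two-sample test on one gene's log2 replicate values.

    Returns (t, df, two-sided p, log2fc) with log2fc = mean(treated) -
    mean(control).  Degenerate zero-variance data (possible in
    noise-free simulations) yields p = 0 for a nonzero difference and
    t = 0, p = 1 otherwise.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    n1, n2 = control.size, treated.size
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"need >= 2 replicates per group (got {n1} control, {n2} treated)"
        )
    diff = float(treated.mean() - control.mean())
    df_pool = n1 + n2 - 2
    s2_pooled = ((control.var(ddof=1) * (n1 - 1)
                  + treated.var(ddof=1) * (n2 - 1)) / df_pool)
    s2_reg = ((params.conf * background_var + df_pool * s2_pooled)
              / (params.conf + df_pool))
    df = params.conf + df_pool
    if s2_reg <= 0:
        if diff == 0.0:
            return 0.0, float(df), 1.0, 0.0
        t = np.inf if diff > 0 else -np.inf
        return float(t), float(df), 0.0, diff
    t = diff / np.sqrt(s2_reg * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0)), diff


@dataclass
class PpdeFit:
    """Fitted uniform + Beta(a,1) mixture over a contrast's p-values.

    The raw mixture lam * 1 + (1 - lam) * Beta(a, 1) is not identifiable
    as a -> 1 (the alternative itself contains a uniform sub-component
    of mass a), so the fit is canonicalized: ``lambda0`` is the total
    flat mass lam + (1 - lam) * a — the weight of p-values
    indistinguishable from uniform — and PPDE is the posterior weight of
    the strictly decreasing remainder of the density,

        ppde(p) = (1 - lam) * a * (p^(a-1) - 1) / f(p).

    Under a pure-uniform null lambda0 -> 1 and every PPDE -> 0; for
    genuinely enriched small p-values the flat correction is negligible
    and ppde(p) -> 1 as p -> 0.
    """

    lambda0: float               # identifiable non-DE (flat) mass
    beta_shape: float            # a < 1 of the Beta(a, 1) alternative
    mix_weight: float            # raw EM mixture weight lam
    ppde: np.ndarray             # per-gene posterior P(DE | p)
    converged: bool = True
    n_iter: int = 0

    def ppde_at(self, p: np.ndarray) -> np.ndarray:
        """Posterior P(DE) on an arbitrary p-value grid."""
        p = np.clip(np.asarray(p, dtype=float), _P_FLOOR, 1.0)
        lam, a = self.mix_weight, self.beta_shape
        dens = lam + (1.0 - lam) * a * p ** (a - 1.0)
        return (1.0 - lam) * a * (p ** (a - 1.0) - 1.0) / dens


_P_FLOOR = 1e-300


def fit_ppde(pvals: np.ndarray, max_iter: int = 1000,
             tol: float = 1e-8) -> PpdeFit:
    """EM fit of f(p) = lam + (1-lam) * a * p^(a-1), a < 1.

    The alternative component's shape MLE given posterior weights r_i is
    a = -sum(r) / sum(r * log p); lam is the mean null weight.  The
    shape is clamped to (1e-4, 1 - 1e-6) to keep the alternative a
    proper, decreasing density.  The reported ``lambda0`` and ``ppde``
    use the canonical (identifiable) decomposition documented on
    :class:`PpdeFit`.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size < 100:
        logger.warning("PPDE fit on only %d p-values; the mixture "
                       "estimate will be unstable", p.size)
    p = np.clip(p, _P_FLOOR, 1.0)
    logp = np.log(p)

    lam, a = 0.9, 0.3
    flat_old = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        alt = a * p ** (a - 1.0)
        dens = lam + (1.0 - lam) * alt
        r = (1.0 - lam) * alt / dens           # P(alt | p_i)
        lam = float(np.clip(1.0 - r.mean(), 1e-6, 1.0 - 1e-6))
        sr = r.sum()
        if sr > 0 and (r * logp).sum() < 0:
            a = float(np.clip(-sr / (r * logp).sum(), 1e-4, 1.0 - 1e-6))
        # convergence on the identifiable parameters (flat mass, shape):
        # along the a -> 1 ridge the raw lam wanders while the flat mass
        # is already determined
        flat = lam + (1.0 - lam) * a
        if abs(flat - flat_old) < tol and it > 1:
            converged = True
            break
        flat_old = flat
    if not converged:
        logger.warning("PPDE EM did not converge in %d iterations", max_iter)
    dens = lam + (1.0 - lam) * a * p ** (a - 1.0)
    ppde = (1.0 - lam) * a * (p ** (a - 1.0) - 1.0) / dens
    lambda0 = lam + (1.0 - lam) * a
    return PpdeFit(lambda0=lambda0, beta_shape=a, mix_weight=lam,
                   ppde=ppde, converged=converged, n_iter=it)


def call_degs(genes: list[str], pvals: np.ndarray, ppde: np.ndarray,
              log2fc: np.ndarray, contrast: str = "",
              p_cut: float = 0.05,
              ppde_cut: float = 0.96) -> pd.DataFrame:
    """Apply the compound DEG rule: p < p_cut AND ppde > ppde_cut.

    Direction is up/down from the sign of log2fc; a gene passing both
    gates with log2fc exactly 0 has no assignable direction and stays
    unchanged (with a warning).
    """
    pvals = np.asarray(pvals, float)
    ppde = np.asarray(ppde, float)
    log2fc = np.asarray(log2fc, float)
    if not (np.isfinite(pvals).all() and np.isfinite(ppde).all()
            and np.isfinite(log2fc).all()):
        raise ValidationError("p, PPDE and log2fc must be finite")
    sig = (pvals < p_cut) & (ppde > ppde_cut)
    n_zero = int((sig & (log2fc == 0.0)).sum())
    if n_zero:
        logger.warning("%d significant gene(s) with log2fc exactly 0 left "
                       "unchanged (no direction assignable)", n_zero)
    records = []
    for g, p, q, fc, s in zip(genes, pvals, ppde, log2fc, sig):
        if s and fc > 0:
            direction = "up"
        elif s and fc < 0:
            direction = "down"
        else:
            direction = "unchanged"
        records.append(DEGRecord(g, contrast, float(fc), float(p), float(q),
                                 direction))
    return deg_table(records)


def timecourse_call(records: pd.DataFrame) -> str:
    """Collapse one gene's per-time-point calls into a single direction.

    A gene is up if it is called up at one or more time points and never
    down; symmetrically for down; any conflict (or no significant time
    point) yields unchanged.
    """
    dirs = set(records["direction"])
    if "up" in dirs and "down" not in dirs:
        return "up"
    if "down" in dirs and "up" not in dirs:
        return "down"
    return "unchanged"


def select_display_fc(records: pd.DataFrame, direction: str) -> float:
    """log2fc of the earliest significant time point in the called
    direction (for single-value display of a time-course gene)."""
    if direction == "unchanged":
        raise ValidationError("no display fold change for an unchanged gene")
    hits = records[records["direction"] == direction]
    if hits.empty:
        raise ValidationError(
            f"no time point called {direction} in the records"
        )
    hits = hits.sort_values("time_point_h", kind="stable")
    return float(hits.iloc[0]["log2fc"])


def deg_contrast(study: ExpressionStudy, treated: str, control: str,
                 params: RegTParams | None = None,
                 genes: list[str] | None = None,
                 p_cut: float = 0.05, ppde_cut: float = 0.96,
                 ) -> tuple[pd.DataFrame, PpdeFit]:
    """Full single-contrast pipeline on an expression study.

    Runs the regularized t-test for every gene (optionally restricted to
    a present set), fits the PPDE mixture on the contrast's p-values and
    applies the compound DEG rule.  One shared intensity-ranked
    background is computed per contrast from the pooled per-gene
    variance of both groups.
    """
    params = params or RegTParams()
    log2_ctl = study.log2_intensity(control)
    log2_trt = study.log2_intensity(treated)
    if genes is not None:
        keep = [study.genes.index(g) for g in genes]
        gene_list = list(genes)
        log2_ctl = log2_ctl[keep]
        log2_trt = log2_trt[keep]
    else:
        gene_list = list(study.genes)
    n1 = log2_ctl.shape[1]
    n2 = log2_trt.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"contrast {treated}:{control} needs >= 2 replicates per group"
        )
    mean_all = np.concatenate([log2_ctl, log2_trt], axis=1).mean(axis=1)
    df_pool = n1 + n2 - 2
    s2_pooled = ((log2_ctl.var(axis=1, ddof=1) * (n1 - 1)
                  + log2_trt.var(axis=1, ddof=1) * (n2 - 1)) / df_pool)
    bg = background_variance(mean_all, s2_pooled, params.window)

    diff = log2_trt.mean(axis=1) - log2_ctl.mean(axis=1)
    s2_reg = (params.conf * bg + df_pool * s2_pooled) / (params.conf + df_pool)
    df = params.conf + df_pool
    denom = np.sqrt(s2_reg * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.minimum(p, 1.0)

    fit = fit_ppde(p)
    contrast = f"{treated}:{control}"
    table = call_degs(gene_list, p, fit.ppde, diff, contrast=contrast,
                      p_cut=p_cut, ppde_cut=ppde_cut)
    return table, fit
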