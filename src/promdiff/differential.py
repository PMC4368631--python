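"""Differential promoter occupancy between patient and control groups.

The model is the classic count-based differential test for small designs:
raw promoter read counts ``k_ij`` (gene i, sample j) are assumed negative
binomial with mean ``s_j * q_i(group)`` and variance ``mu + alpha_i mu^2``,
where ``s_j`` is a per-sample size factor and ``alpha_i`` the per-gene
overdispersion. Three estimation steps feed the test:

1. *Size factors* by median-of-ratios: ``s_j = median_i k_ij / g_i`` with
   ``g_i`` the geometric mean of gene i across samples, taken over genes
   with all-positive counts.
2. *Dispersion* by method-of-moments on size-factor-normalized counts
   pooled across both groups, with an optional conservative shrinkage that
   takes the maximum of the gene-wise estimate and a log-log linear trend
   fit against the mean. Pooling ignores the group label, which inflates
   the dispersion of genuinely changed genes — a deliberately conservative
   choice at n = 2 vs 4.
3. A *conditional exact test* on the group-summed counts: given the total
   K_S = K_A + K_B, the two-sided p-value sums the probabilities of all
   splits (a, b) with a + b = K_S that are no more probable than the
   observed one,

       p = sum_{P(a)P(b) <= P(K_A)P(K_B)} P(a)P(b) / sum_{a+b=K_S} P(a)P(b)

   with P the negative binomial masses whose means are scaled by the
   group-summed size factors. Dispersion 0 degrades gracefully to the
   Poisson (binomial-conditional) case. Everything is evaluated in log
   space so totals up to ~1e6 are numerically safe.

Fold changes are reported as log2(patients / controls) of pseudocount-
protected normalized group means; a gene is *selected* when at least one
histone mark passes both the |log2FC| and the p-value threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson

from .io_formats import ValidationError
from .promoters import PromoterCountMatrix

__all__ = [
    "size_factors",
    "normalized_counts",
    "estimate_dispersion",
    "nb_exact_test",
    "log2_fold_change",
    "differential_table",
    "select_significant",
    "SignificanceCall",
]

DISPERSION_FLOOR = 1e-8


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per column/sample).

    Genes containing any zero are excluded from the geometric-mean
    reference. Raises if no gene has all-positive counts.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValidationError("counts must be a genes x samples matrix")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene with all-positive counts: size factors are undefined; "
            "supply deeper libraries or a restricted gene set"
        )
    logc = np.log(counts[positive])
    log_geo = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - log_geo, axis=0))


def normalized_counts(counts: np.ndarray, factors: np.ndarray) -> np.ndarray:
    return np.asarray(counts, dtype=float) / np.asarray(factors, dtype=float)


def estimate_dispersion(
    counts: np.ndarray,
    factors: np.ndarray,
    groups: Sequence[str] | None = None,
    shrink: bool = True,
    floor: float = DISPERSION_FLOOR,
) -> np.ndarray:
    """Per-gene NB dispersion alpha by method-of-moments, optionally shrunk.

    With z_ij = k_ij / s_j, q_i = mean_j z_ij, v_i the residual variance of
    the normalized counts and xi = mean_j 1/s_j (the Poisson part of the
    variance of a normalized count), the raw estimate is

        alpha_i = max(floor, (v_i - q_i * xi) / q_i^2).

    When ``groups`` (one label per sample) is given, v_i is the
    within-group variance pooled across groups (residuals around each
    group's own mean, n - G denominator), so a real between-group shift
    does not masquerade as overdispersion. Without labels, the plain
    across-sample variance is used.

    ``shrink=True`` additionally fits a linear trend of log alpha on log q
    over genes with above-floor raw estimates and returns
    max(gene-wise, trend) — conservative at very small sample numbers.
    All-zero genes get the floor.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValidationError("dispersion estimation needs >= 2 samples")
    z = normalized_counts(counts, factors)
    q = z.mean(axis=1)
    if groups is None:
        v = z.var(axis=1, ddof=1)
    else:
        labels = np.asarray(groups)
        if labels.size != counts.shape[1]:
            raise ValidationError("one group label per sample required")
        uniq = np.unique(labels)
        rss = np.zeros(counts.shape[0])
        for g in uniq:
            cols = labels == g
            zg = z[:, cols]
            rss += ((zg - zg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof = counts.shape[1] - uniq.size
        if dof < 1:
            raise ValidationError("dispersion needs more samples than groups")
        v = rss / dof
    xi = float(np.mean(1.0 / np.asarray(factors, dtype=float)))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - q * xi) / np.square(q)
    raw = np.where(q > 0, raw, floor)
    alpha = np.maximum(raw, floor)
    if shrink:
        fit_mask = (alpha > floor) & (q > 0)
        if fit_mask.sum() >= 10:
            x = np.log(q[fit_mask])
            y = np.log(alpha[fit_mask])
            slope, intercept = np.polyfit(x, y, 1)
            with np.errstate(divide="ignore"):
                trend = np.exp(intercept + slope * np.log(np.maximum(q, 1e-300)))
            trend = np.where(q > 0, trend, floor)
            alpha = np.maximum(alpha, trend)
    return alpha


def _group_log_pmf(k: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    """log NB(mean=mu, var=mu+alpha*mu^2) mass at k; Poisson when alpha=0."""
    if mu <= 0:
        # degenerate at zero
        return np.where(k == 0, 0.0, -np.inf)
    if alpha <= 1e-12:
        # Poisson limit; also guards nbinom against astronomically large r
        return poisson.logpmf(k, mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return nbinom.logpmf(k, r, p)


def nb_exact_test(
    k_a: int,
    k_b: int,
    s_a: float,
    s_b: float,
    dispersion: float,
) -> float:
    """Two-sided conditional exact test on group-summed counts.

    ``k_a``/``k_b`` are the summed counts of the two groups, ``s_a``/``s_b``
    the summed size factors. Outcome splits of the total are ranked by
    probability; the p-value is the total mass of splits no more probable
    than the observed one, conditioned on the total. Returns a p in (0, 1].
    """
    if k_a < 0 or k_b < 0:
        raise ValidationError("counts must be non-negative")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    total = k_a + k_b
    if total == 0:
        return 1.0
    q = total / (s_a + s_b)
    mu_a, mu_b = q * s_a, q * s_b
    a = np.arange(total + 1)
    lp = _group_log_pmf(a, mu_a, dispersion) + _group_log_pmf(total - a, mu_b, dispersion)
    lp_obs = lp[k_a]
    # small slack so exactly tied splits (mirror symmetry) are kept despite
    # floating-point noise
    mask = lp <= lp_obs + 1e-10
    p = float(np.exp(logsumexp(lp[mask]) - logsumexp(lp)))
    return min(p, 1.0)


def log2_fold_change(
    counts: np.ndarray,
    factors: np.ndarray,
    patient_cols: np.ndarray,
    control_cols: np.ndarray,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """log2((patient mean + c) / (control mean + c)) of normalized counts."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    z = normalized_counts(counts, factors)
    mean_p = z[:, patient_cols].mean(axis=1)
    mean_c = z[:, control_cols].mean(axis=1)
    return np.log2((mean_p + pseudocount) / (mean_c + pseudocount))


def differential_table(
    matrix: PromoterCountMatrix,
    pseudocount: float = 1.0,
    shrink_dispersion: bool = True,
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full per-gene differential analysis for one mark.

    Returns a DataFrame indexed by gene_id with columns baseMean_control,
    baseMean_patient, log2FC (patients vs controls), pval and dispersion.
    """
    pat = matrix.group_columns("patient")
    ctl = matrix.group_columns("control")
    if pat.size == 0 or ctl.size == 0:
        raise ValidationError("both groups need at least one sample")
    counts = matrix.counts
    if factors is None:
        factors = size_factors(counts)
    labels = [matrix.groups[s] for s in matrix.sample_ids]
    alpha = estimate_dispersion(counts, factors, groups=labels, shrink=shrink_dispersion)
    z = normalized_counts(counts, factors)
    lfc = log2_fold_change(counts, factors, pat, ctl, pseudocount)
    s_a = float(np.sum(factors[pat]))
    s_b = float(np.sum(factors[ctl]))
    k_a = counts[:, pat].sum(axis=1)
    k_b = counts[:, ctl].sum(axis=1)
    pvals = np.array(
        [nb_exact_test(int(ka), int(kb), s_a, s_b, float(al)) for ka, kb, al in zip(k_a, k_b, alpha)]
    )
    return pd.DataFrame(
        {
            "baseMean_control": z[:, ctl].mean(axis=1),
            "baseMean_patient": z[:, pat].mean(axis=1),
            "log2FC": lfc,
            "pval": pvals,
            "dispersion": alpha,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


@dataclass(slots=True)
class SignificanceCall:
    """Per-gene selection across marks: flagged per mark, selected if any."""

    table: pd.DataFrame  # boolean columns per mark + "selected"
    lfc_threshold: float
    p_threshold: float

    @property
    def selected_genes(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()


def select_significant(
    tables: Mapping[str, pd.DataFrame],
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> SignificanceCall:
    """Flag genes with |log2FC| >= threshold and p <= threshold in >= 1 mark.

    This is the two-fold / p <= 0.05 "changed in at least one modification"
    selection rule; both cutoffs are configurable.
    """
    marks = list(tables)
    if not marks:
        raise ValidationError("no differential tables supplied")
    index = tables[marks[0]].index
    for m in marks[1:]:
        if not tables[m].index.equals(index):
            raise ValidationError(f"mark {m}: gene universe differs")
    flags = {}
    for m in marks:
        t = tables[m]
        flags[m] = (t["log2FC"].abs() >= lfc_threshold) & (t["pval"] <= p_threshold)
    df = pd.DataFrame(flags, index=index)
    df["selected"] = df.any(axis=1)
    return SignificanceCall(df, lfc_threshold, p_threshold)
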