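"""Per-group summaries, fold changes and empirical-Bayes moderated t-tests.

Fold change between two groups is the linear-scale ratio ``2**(A - B)`` of
their log2 mean intensities. For lineage-specificity each target category is
compared against the *maximum-expressing* reference group per probe — the
most conservative specificity estimate. Significance uses a moderated
two-sample t-statistic: the per-probe pooled variance is shrunk toward a
prior variance (d0, s0²) fitted across all probes by moment-matching on the
log variance scale, which stabilizes inference at the study's small replicate
counts (down to n = 2). p-values are adjusted per contrast family by the
Benjamini–Hochberg step-up procedure (q-values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, SampleSheet, LOG2

#: d0 above this is treated as infinite (no residual inter-probe variance
#: dispersion beyond sampling noise)
D0_CAP = 1e6

#: direction label for a non-significant reference-vs-reference contrast
NS = "NS"


@dataclass
class VariancePrior:
    """Scaled-inverse-chi-square prior for per-probe residual variances.

    ``d0`` is the prior degrees of freedom (``np.inf`` allowed; 0 means no
    shrinkage, the ordinary-t limit), ``s0_sq`` the prior variance on the
    squared log2 scale.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be positive")


class GroupSummary:
    """Per-probe per-group mean (log2), sample SD and replicate count."""

    def __init__(self, means: pd.DataFrame, sds: pd.DataFrame, n: pd.Series):
        self.means = means
        self.sds = sds
        self.n = n

    @property
    def groups(self) -> list[str]:
        return list(self.means.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.means.index


def group_summary(matrix: ExpressionMatrix, sheet: SampleSheet) -> GroupSummary:
    """Compute per-group means and sample SDs (denominator n−1).

    Every group must have at least two replicates; a single replicate gives
    no within-group variance and would poison the variance prior.
    """
    if matrix.scale != LOG2:
        raise ValueError("group_summary expects a log2-scale matrix")
    sheet.validate_against(matrix)
    means, sds, ns = {}, {}, {}
    for group in sheet.groups:
        samples = [s for s in sheet.samples_of(group) if s in matrix.sample_ids]
        if len(samples) < 2:
            raise ValueError(f"group {group!r} has {len(samples)} sample(s); need ≥ 2")
        sub = matrix.values[samples]
        means[group] = sub.mean(axis=1)
        sds[group] = sub.std(axis=1, ddof=1)
        ns[group] = len(samples)
    return GroupSummary(pd.DataFrame(means), pd.DataFrame(sds), pd.Series(ns))


def fold_change(a_mean, b_mean):
    """Linear-scale fold change ``2**(a - b)`` from log2 means."""
    return np.power(2.0, np.asarray(a_mean, dtype=float) - np.asarray(b_mean, dtype=float))


def max_reference_fold_change(
    summary: GroupSummary, target: str, references: list[str]
) -> pd.DataFrame:
    """Fold change of ``target`` vs the per-probe maximum-expressing reference.

    Returns a DataFrame with columns ``fold_change`` and ``chosen_reference``.
    Ties between references resolve to the first group in ``references``.
    """
    if not references:
        raise ValueError("at least one reference group required")
    ref_means = summary.means[list(references)]
    # idxmax is first-wins on ties, matching the fixed-group-order tie rule
    chosen = ref_means.idxmax(axis=1)
    max_ref = ref_means.max(axis=1)
    return pd.DataFrame(
        {
            "fold_change": fold_change(summary.means[target], max_ref),
            "chosen_reference": chosen,
        },
        index=summary.probe_ids,
    )


def pooled_family_variance(
    summary: GroupSummary, groups: list[str]
) -> tuple[pd.Series, float]:
    """Pooled within-group variance over ``groups`` and its common df."""
    n = summary.n[list(groups)]
    df = float((n - 1).sum())
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    weighted = sum((summary.sds[g] ** 2) * (summary.n[g] - 1) for g in groups)
    return weighted / df, df


def fit_variance_prior(s_sq: np.ndarray, d_g: float) -> VariancePrior:
    """Fit (d0, s0²) by moment-matching log sample variances.

    Under ``s² ~ s0² · χ²(d_g)/d_g`` with an inverse-chi-square prior of d0
    degrees of freedom on the true variance, ``z = log s²`` has

        E[z]   = log s0² + ψ(d_g/2) − log(d_g/2) − ψ(d0/2) + log(d0/2)
        Var[z] = ψ'(d_g/2) + ψ'(d0/2)

    Excess dispersion of z beyond the sampling term ψ'(d_g/2) identifies d0.
    When no excess exists, d0 = ∞ and s0² is the bias-corrected geometric
    mean of the sample variances.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq)]
    positive = s_sq[s_sq > 0]
    if positive.size == 0:
        raise ValueError("all variances are zero: degenerate data")
    if positive.size < 50:
        raise ValueError(f"need ≥ 50 positive variances to fit the prior, got {positive.size}")
    z = np.log(positive)
    mean_z = z.mean()
    var_z = z.var(ddof=1)
    sampling_var = special.polygamma(1, d_g / 2.0)
    excess = var_z - sampling_var
    gm_log_s0 = mean_z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    if excess <= 0:
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(gm_log_s0)))

    # invert the trigamma function: ψ'(d0/2) = excess
    def f(log_half_d0: float) -> float:
        return special.polygamma(1, np.exp(log_half_d0)) - excess

    lo, hi = np.log(1e-8), np.log(1e8)
    if f(lo) < 0:  # excess larger than any achievable → tiny d0
        half_d0 = 1e-8
    elif f(hi) > 0:  # excess negligible → effectively infinite
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(gm_log_s0)))
    else:
        sol = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-10)
        half_d0 = np.exp(sol)
    d0 = 2.0 * half_d0
    if d0 > D0_CAP:
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(gm_log_s0)))
    log_s0_sq = gm_log_s0 + special.digamma(half_d0) - np.log(half_d0)
    return VariancePrior(d0=float(d0), s0_sq=float(np.exp(log_s0_sq)))


def moderated_t_test(
    summary: GroupSummary,
    target: str,
    reference,
    prior: VariancePrior,
) -> pd.DataFrame:
    """Moderated two-sample t-test of ``target`` vs ``reference``.

    ``reference`` is either a single group name or a per-probe Series of
    chosen reference groups (from :func:`max_reference_fold_change`). The
    pooled two-sample variance ``s_g²`` (df = n1+n2−2) is shrunk to the
    posterior ``s̃² = (d0·s0² + d_g·s_g²)/(d0 + d_g)`` and the statistic is
    referred to a t distribution on d0 + d_g df (normal when d0 = ∞).

    Returns columns ``t_stat``, ``p_value``, ``df_total``.
    """
    n1 = int(summary.n[target])
    if n1 < 2:
        raise ValueError(f"target group {target!r} has n < 2")
    if isinstance(reference, str):
        reference = pd.Series(reference, index=summary.probe_ids)
    reference = reference.reindex(summary.probe_ids)

    ref_mean = pd.Series(index=summary.probe_ids, dtype=float)
    ref_var = pd.Series(index=summary.probe_ids, dtype=float)
    n2 = pd.Series(index=summary.probe_ids, dtype=float)
    for g in reference.unique():
        if int(summary.n[g]) < 2:
            raise ValueError(f"reference group {g!r} has n < 2")
        mask = reference == g
        ref_mean[mask] = summary.means.loc[mask, g]
        ref_var[mask] = summary.sds.loc[mask, g] ** 2
        n2[mask] = summary.n[g]

    diff = summary.means[target] - ref_mean
    d_g = n1 + n2 - 2
    s_g_sq = ((n1 - 1) * summary.sds[target] ** 2 + (n2 - 1) * ref_var) / d_g
    inv_n = 1.0 / n1 + 1.0 / n2

    if np.isinf(prior.d0):
        s_tilde_sq = pd.Series(prior.s0_sq, index=summary.probe_ids)
        df_total = pd.Series(np.inf, index=summary.probe_ids)
        t = diff / np.sqrt(s_tilde_sq * inv_n)
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + d_g * s_g_sq) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(s_tilde_sq * inv_n)
        t = t.replace([np.inf, -np.inf], np.nan).fillna(0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"t_stat": t, "p_value": p, "df_total": df_total}, index=summary.probe_ids
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def reference_contrast(
    summary: GroupSummary,
    ref_a: str,
    ref_b: str,
    prior: VariancePrior,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Absolute fold change and direction between the two reference tissues.

    A probe expressed nowhere outside the target lineage shows no difference
    between the references; a significant difference flags an expression
    domain in one of them. Direction is the higher-mean group when q < q_cut,
    else ``NS``.

    Returns columns ``fold_change_abs``, ``direction``, ``q_value``,
    ``p_value``.
    """
    diff = summary.means[ref_a] - summary.means[ref_b]
    fold_abs = np.power(2.0, np.abs(diff))
    test = moderated_t_test(summary, ref_a, ref_b, prior)
    q = bh_adjust(test["p_value"].to_numpy())
    direction = np.where(q < q_cut, np.where(diff > 0, ref_a, ref_b), NS)
    direction = np.where((q < q_cut) & (diff == 0), NS, direction)
    return pd.DataFrame(
        {
            "fold_change_abs": fold_abs,
            "direction": direction,
            "q_value": q,
            "p_value": test["p_value"],
        },
        index=summary.probe_ids,
    )
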