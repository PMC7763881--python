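"""Negative-binomial pairwise differential expression and additivity calls.

A simplified NB Wald test: median-of-ratios size factors, per-feature
method-of-moments dispersion shrunk halfway toward a fitted
mean-dispersion trend, and a Wald statistic on the log2 fold change of
normalized group means (pseudo-count 0.5). The study thresholds are
BH-adjusted p < 1e-4 together with |log2FC| > 2. Species-specific
expression (all-zero counts in one group, expressed in the other) is
treated as a class of differential expression and merged into the calls,
bypassing the Wald p whose standard error is undefined at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_DEFAULT = 1e-4
LFC_MIN_DEFAULT = 2.0
TPM_EXPRESSED = 0.3

#: The eight study contrasts, (A, B) tested as A vs B.
STUDY_CONTRASTS = [
    ("HH", "CC"),
    ("S14", "CC"),
    ("S14", "HH"),
    ("S14", "MPV"),
    ("F1", "CC"),
    ("F1", "HH"),
    ("F1", "MPV"),
    ("S14", "F1"),
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios normalization factors.

    Falls back to total-count ratios (geometric mean 1) with a warning
    when no feature is nonzero in every sample.
    """
    arr = counts.values.astype(float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() == 0:
        warnings.warn(
            "no feature nonzero in all samples; falling back to total-count ratios",
            RuntimeWarning,
        )
        totals = arr.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=counts.columns)
    log_sub = np.log(arr[positive])
    log_geo = log_sub.mean(axis=1)
    factors = np.exp(np.median(log_sub - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through and do
    not count toward m."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    ps = p[mask]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards, cap at 1
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[mask] = result
    return out


def _dispersion_mom(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion per feature."""
    num = np.zeros(norm.shape[0])
    den = 0.0
    for cols in groups:
        sub = norm[:, cols]
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(m > 0, (v - m) / np.square(m), 0.0)
        num += np.clip(alpha, 0.0, None) * (n - 1)
        den += n - 1
    return num / den if den else num


def _dispersion_trend(mean: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by least squares over informative features."""
    use = (mean > 0) & (alpha > 0)
    if use.sum() < 10:
        a0 = float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else 0.01
        return max(a0, 1e-6), 0.0
    x = 1.0 / mean[use]
    y = alpha[use]
    design = np.column_stack([np.ones(use.sum()), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0 = max(float(coef[0]), 1e-6)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


@dataclass
class DETable:
    """Per-feature results of one pairwise contrast (A vs B)."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # base_mean, log2fc, wald_p, padj, call, species_specific

    @property
    def de_features(self) -> pd.Index:
        return self.table.index[self.table["call"] != "ns"]


def nb_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    contrast: tuple[str, str],
    alpha: float = ALPHA_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
    tpm_a: pd.DataFrame | None = None,
    tpm_b: pd.DataFrame | None = None,
) -> DETable:
    """Wald test of A vs B on two replicate count blocks (same index).

    Positive log2FC means higher in A ("up_in_A"). When TPM blocks are
    given, species-specific features (zero counts throughout one group,
    mean TPM > 0.3 in the other) are called without a Wald p.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per side")
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count blocks must share one feature index")
    joint = pd.concat([counts_a, counts_b], axis=1)
    sf = size_factors(joint)
    norm = joint.values / sf.values[None, :]
    na, nb = counts_a.shape[1], counts_b.shape[1]
    cols_a = np.arange(na)
    cols_b = np.arange(na, na + nb)

    mean_a = norm[:, cols_a].mean(axis=1)
    mean_b = norm[:, cols_b].mean(axis=1)
    base_mean = norm.mean(axis=1)

    alpha_mom = _dispersion_mom(norm, [cols_a, cols_b])
    a0, a1 = _dispersion_trend(base_mean, alpha_mom)
    with np.errstate(divide="ignore"):
        alpha_tr = np.where(base_mean > 0, a0 + a1 / np.maximum(base_mean, 1e-8), a0)
    disp = np.maximum(0.5 * alpha_mom + 0.5 * alpha_tr, 1e-8)

    lfc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    var_a = (mean_a + disp * mean_a**2) / na
    var_b = (mean_b + disp * mean_b**2) / nb
    ln2 = np.log(2.0)
    se = np.sqrt(var_a / (mean_a + 0.5) ** 2 + var_b / (mean_b + 0.5) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    wald_p[base_mean == 0] = np.nan  # zero in both groups: untestable

    padj = bh_adjust(wald_p)
    call = np.where(
        (padj < alpha) & (np.abs(lfc) > lfc_min),
        np.where(lfc > 0, "up_in_A", "down_in_A"),
        "ns",
    )
    call[np.isnan(padj)] = "ns"

    species = np.full(len(joint), "none", dtype=object)
    if tpm_a is not None and tpm_b is not None:
        zero_b = (counts_b.values == 0).all(axis=1)
        zero_a = (counts_a.values == 0).all(axis=1)
        a_only = zero_b & (tpm_a.values.mean(axis=1) > TPM_EXPRESSED)
        b_only = zero_a & (tpm_b.values.mean(axis=1) > TPM_EXPRESSED)
        species[a_only] = "A_only"
        species[b_only] = "B_only"
        call = call.astype(object)
        call[a_only] = "up_in_A"
        call[b_only] = "down_in_A"

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": lfc,
            "wald_p": wald_p,
            "padj": padj,
            "call": call,
            "species_specific": species,
        },
        index=counts_a.index,
    )
    return DETable(contrast=contrast, table=table)


def classify_additivity(de_vs_mpv: DETable) -> pd.Series:
    """Additivity class from the progeny-vs-MPV contrast: nonadditive_up /
    nonadditive_down where the DE thresholds are met, additive otherwise."""
    mapping = {"up_in_A": "nonadditive_up", "down_in_A": "nonadditive_down", "ns": "additive"}
    return de_vs_mpv.table["call"].map(mapping).rename("additivity")


def detect_species_specific(
    tpm_a: pd.DataFrame, tpm_b: pd.DataFrame, counts_a: pd.DataFrame, counts_b: pd.DataFrame
) -> pd.Series:
    """Standalone species-specific flags: A_only iff mean TPM > 0.3 in A
    and every replicate count in B is exactly zero (and symmetrically)."""
    zero_b = (counts_b.values == 0).all(axis=1)
    zero_a = (counts_a.values == 0).all(axis=1)
    flags = np.full(len(tpm_a), "none", dtype=object)
    flags[zero_b & (tpm_a.values.mean(axis=1) > TPM_EXPRESSED)] = "A_only"
    flags[zero_a & (tpm_b.values.mean(axis=1) > TPM_EXPRESSED)] = "B_only"
    return pd.Series(flags, index=tpm_a.index, name="species_specific")
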