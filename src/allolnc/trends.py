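"""Model-profile clustering of short expression series (STEM-style).

Expression over the ordered series MPV -> F1 -> S14 is reduced to a
difference-from-start series and assigned to the closest of the
(2c+1)^(T-1) model profiles (unit changes in [-c, +c] per step) by
Pearson correlation. Profile significance is assessed by permuting each
gene's series independently and comparing observed assignment counts to
the permutation-expected proportion with a binomial upper tail, BH
corrected. Significant profiles with correlated shapes (r >= 0.7) are
grouped by single linkage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass
class TrendProfile:
    profile_id: int
    unit_changes: tuple[int, ...]
    values: tuple[float, ...]  # cumulative from 0, length T

    @property
    def is_flat(self) -> bool:
        return all(c == 0 for c in self.unit_changes)


def enumerate_profiles(T: int = 3, c: int = 2) -> list[TrendProfile]:
    """All model profiles for T timepoints and unit-change bound c, in
    lexicographic order of change vectors (-c first), IDs from 0."""
    if T < 2:
        raise ValueError("need T >= 2 timepoints")
    if c < 1:
        raise ValueError("need c >= 1")
    profiles = []
    for pid, changes in enumerate(itertools.product(range(-c, c + 1), repeat=T - 1)):
        values = (0.0, *np.cumsum(changes).astype(float))
        profiles.append(TrendProfile(pid, tuple(changes), values))
    return profiles


def flat_profile_id(profiles: list[TrendProfile]) -> int:
    return next(p.profile_id for p in profiles if p.is_flat)


def _correlation_matrix(series: np.ndarray, profile_values: np.ndarray) -> np.ndarray:
    """Pearson r between each row of `series` and each profile row;
    NaN where either side has zero variance."""
    s = series - series.mean(axis=1, keepdims=True)
    p = profile_values - profile_values.mean(axis=1, keepdims=True)
    s_norm = np.linalg.norm(s, axis=1)
    p_norm = np.linalg.norm(p, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (s @ p.T) / np.outer(s_norm, p_norm)
    corr[s_norm == 0, :] = np.nan
    corr[:, p_norm == 0] = np.nan
    return corr


def assign_genes(series: pd.DataFrame, profiles: list[TrendProfile]) -> pd.Series:
    """Assign each gene series (rows = genes, columns = ordered stages,
    raw scale e.g. log2(TPM+1)) to the best-correlated model profile.

    The series is first transformed to differences from the first stage.
    Zero-variance (flat) genes go to the flat profile; ties break to the
    lowest profile id (argmax on NaN-safe correlations scans in id order).
    """
    values = np.array([p.values for p in profiles])
    diffs = series.values - series.values[:, [0]]
    corr = _correlation_matrix(diffs, values)
    flat_id = flat_profile_id(profiles)
    corr_filled = np.where(np.isnan(corr), -np.inf, corr)
    best = corr_filled.argmax(axis=1)
    gene_flat = np.all(diffs == diffs[:, [0]], axis=1) | (diffs.std(axis=1) == 0)
    best[gene_flat] = flat_id
    return pd.Series(best, index=series.index, name="profile_id")


def profile_significance(
    series: pd.DataFrame,
    profiles: list[TrendProfile],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation significance of assignment counts per profile.

    Every permutation shuffles each gene's stage values independently,
    reassigns all genes, and contributes to the expected assignment
    proportion pi_p; the observed count is tested against
    Binomial(n_genes, pi_p) on the upper tail, BH across profiles.
    """
    if series.shape[1] < 2:
        raise ValueError("need >= 2 timepoints")
    if len(series) < 1:
        raise ValueError("need >= 1 gene")
    rng = np.random.default_rng(seed)
    observed = assign_genes(series, profiles)
    n_genes = len(series)
    n_prof = len(profiles)
    obs_counts = np.bincount(observed.values, minlength=n_prof)

    perm_counts = np.zeros(n_prof)
    vals = series.values
    for _ in range(n_perm):
        perm = np.take_along_axis(
            vals, rng.permuted(np.tile(np.arange(vals.shape[1]), (n_genes, 1)), axis=1), axis=1
        )
        assigned = assign_genes(pd.DataFrame(perm, index=series.index), profiles)
        perm_counts += np.bincount(assigned.values, minlength=n_prof)
    pi = perm_counts / (n_perm * n_genes)

    pvals = stats.binom.sf(obs_counts - 1, n_genes, np.clip(pi, 1e-12, 1.0))
    padj = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "changes": ["/".join(map(str, p.unit_changes)) for p in profiles],
            "n_assigned": obs_counts,
            "expected": pi * n_genes,
            "p_value": pvals,
            "padj": padj,
            "significant": padj < 0.05,
        },
        index=pd.Index([p.profile_id for p in profiles], name="profile_id"),
    )


def cluster_profiles(
    profiles: list[TrendProfile], significant_ids: list[int], min_corr: float = 0.7
) -> pd.Series:
    """Single-linkage grouping of significant profiles whose value-vector
    Pearson correlation is >= ``min_corr`` (connected components)."""
    by_id = {p.profile_id: p for p in profiles}
    ids = sorted(significant_ids)
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    values = {i: np.array(by_id[i].values) for i in ids}
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            a, b = ids[a_idx], ids[b_idx]
            va, vb = values[a], values[b]
            if va.std() == 0 or vb.std() == 0:
                r = 1.0 if np.allclose(va, vb) else -1.0
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            if r >= min_corr:
                parent[find(a)] = find(b)
    roots = {i: find(i) for i in ids}
    cluster_of_root = {r: k for k, r in enumerate(sorted(set(roots.values())))}
    return pd.Series({i: cluster_of_root[roots[i]] for i in ids}, name="cluster_id")
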