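"""TPM normalization, replicate QC, and mid-parent values.

The mid-parent value (MPV) is the per-feature average of the two parental
expression levels — the expected value under purely additive inheritance
in the hybrid/allopolyploid. MPV pseudo-replicates pair parental
replicates by index so the negative-binomial test downstream keeps three
replicates per side; count MPVs are rounded half-up to stay integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gtfio import CountMatrix


@dataclass
class ExpressionTable:
    """TPM per feature x sample, plus per-group means."""

    tpm: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame

    def group_means(self) -> pd.DataFrame:
        cols = {}
        for group in sorted(self.design["group"].unique()):
            samples = self.design.index[self.design["group"] == group]
            cols[group] = self.tpm[list(samples)].mean(axis=1)
        return pd.DataFrame(cols)

    def log_tpm(self) -> pd.DataFrame:
        return np.log2(self.tpm + 1.0)


def compute_tpm(cm: CountMatrix) -> ExpressionTable:
    """Transcripts-per-million: counts scaled by length (kb), then
    normalized so each sample sums to 1e6."""
    rate = cm.counts.div(cm.lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample(s), TPM undefined: {bad}")
    tpm = rate.div(totals, axis=1) * 1e6
    return ExpressionTable(tpm=tpm, lengths=cm.lengths, design=cm.design)


def replicate_correlation(table: ExpressionTable) -> pd.Series:
    """Mean pairwise Pearson r of log2(TPM+1) within each group.

    Pairs where either replicate has zero variance are undefined and are
    excluded from the mean; a group with no defined pair reports NaN.
    """
    log = table.log_tpm()
    out = {}
    for group in sorted(table.design["group"].unique()):
        samples = list(table.design.index[table.design["group"] == group])
        if len(samples) < 2:
            raise ValueError(f"group {group} needs >= 2 replicates")
        rs = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a, b = log[samples[i]], log[samples[j]]
                if a.std() == 0 or b.std() == 0:
                    continue
                rs.append(a.corr(b))
        out[group] = float(np.mean(rs)) if rs else float("nan")
    return pd.Series(out)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


@dataclass
class MPVSeries:
    """Mid-parent pseudo-replicates; columns MPV_1..MPV_k."""

    values: pd.DataFrame
    rounded: bool


def mid_parent(
    table: pd.DataFrame, design: pd.DataFrame, as_counts: bool = True
) -> MPVSeries:
    """Per-feature mid-parent value, (CC_i + HH_i)/2 paired by replicate
    index. With ``as_counts=True`` the result is rounded half-up so MPV
    pseudo-replicates can enter count-based tests."""
    cc = design[design["group"] == "CC"].sort_values("replicate")
    hh = design[design["group"] == "HH"].sort_values("replicate")
    if len(cc) != len(hh):
        raise ValueError(
            f"unequal parental replicate numbers: CC={len(cc)}, HH={len(hh)}"
        )
    cols = {}
    for (_, crow), (_, hrow) in zip(cc.iterrows(), hh.iterrows()):
        rep = crow["replicate"]
        vals = (table[crow.name] + table[hrow.name]) / 2.0
        cols[f"MPV_{rep}"] = _round_half_up(vals.values) if as_counts else vals.values
    values = pd.DataFrame(cols, index=table.index)
    return MPVSeries(values=values, rounded=as_counts)
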