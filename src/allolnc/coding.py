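"""Coding-potential scoring and the consensus noncoding filter.

A self-contained CPAT-style scorer: longest-ORF features, the Fickett
(1982) TESTCODE statistic, an in-frame hexamer log-ratio trained from
user-supplied coding/noncoding sequence sets, and a logistic model
combining them into a coding probability in [0, 1].

Candidate lncRNAs are kept only when *every* supplied tool score falls
strictly below its threshold (intersection rule); scores from external
predictors (CPC2, PLEK, CNCI) can be merged from plain TSV tables, with
the internal probability playing the CPAT-score role against the 0.36
cutoff.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STOP_CODONS = ("TAA", "TAG", "TGA")

#: Default per-tool thresholds: noncoding requires score strictly below.
DEFAULT_THRESHOLDS: dict[str, float] = {"CPC2": 0.0, "PLEK": 0.0, "CNCI": 0.0, "CPAT": 0.36}

# ---------------------------------------------------------------------------
# ORF search


def find_longest_orf(seq: str) -> tuple[int, int, int]:
    """Longest forward-strand ATG..stop open reading frame.

    Scans all three frames; the ORF must terminate at an in-frame stop
    codon and its length includes the stop. Returns
    ``(orf_length_nt, frame, start_pos)`` with a 0-based start position,
    or ``(0, -1, -1)`` when no complete ORF exists.
    """
    seq = seq.upper()
    n = len(seq)
    best = (0, -1, -1)
    for frame in range(3):
        open_start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - open_start
                if length > best[0]:
                    best = (length, frame, open_start)
                open_start = None
        # unterminated ORFs do not count: require a stop codon
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE
#
# Published lookup tables from Fickett (1982), as used by CPAT: for each
# base, a position-bias value max/(min+1) over the three codon positions
# and a composition fraction are binned against the threshold rows below
# and converted to coding probabilities, then combined as a weighted sum.

_FICKETT_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_FICKETT_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_FICKETT_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_FICKETT_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, para: list[float], probs: list[float]) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE score of a nucleotide sequence (>= 200 nt)."""
    seq = seq.upper()
    if len(seq) < 200:
        raise ValueError(f"Fickett score undefined for length {len(seq)} < 200")
    score = 0.0
    total = len(seq)
    for base in "ACGT":
        # occurrences of `base` at each codon position
        counts = [0, 0, 0]
        for i, ch in enumerate(seq):
            if ch == base:
                counts[i % 3] += 1
        position_value = max(counts) / (min(counts) + 1)
        content_value = sum(counts) / total
        score += _FICKETT_POSITION_WEIGHT[base] * _lookup(
            position_value, _FICKETT_POSITION_PARA, _FICKETT_POSITION_PROB[base]
        )
        score += _FICKETT_CONTENT_WEIGHT[base] * _lookup(
            content_value, _FICKETT_CONTENT_PARA, _FICKETT_CONTENT_PROB[base]
        )
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias

ALL_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
_HEX_INDEX = {h: i for i, h in enumerate(ALL_HEXAMERS)}


@dataclass
class HexamerTable:
    """Hexamer frequencies under a coding and a noncoding model.

    Frequencies are add-one smoothed and each sum to 1, so the log-ratio
    is finite for every hexamer.
    """

    coding: np.ndarray  # length 4096
    noncoding: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.coding, self.noncoding):
            if abs(float(arr.sum()) - 1.0) > 1e-9:
                raise ValueError("hexamer frequencies must sum to 1")
            if (arr <= 0).any():
                raise ValueError("hexamer frequencies must be positive after smoothing")

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log(self.coding / self.noncoding)


def _count_hexamers(seqs: Iterable[str], step: int) -> np.ndarray:
    counts = np.zeros(4096, dtype=float)
    for seq in seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - 5, step):
            idx = _HEX_INDEX.get(seq[i : i + 6])
            if idx is not None:
                counts[idx] += 1
    return counts


def train_hexamer_table(
    coding_seqs: Sequence[str], noncoding_seqs: Sequence[str]
) -> HexamerTable:
    """Train the hexamer model: in-frame (step 3) counts on coding
    sequences, every-position (step 1) counts on noncoding background;
    add-one smoothing then normalization."""
    if len(coding_seqs) < 10 or len(noncoding_seqs) < 10:
        raise ValueError("need >= 10 training sequences per class")
    c = _count_hexamers(coding_seqs, step=3) + 1.0
    n = _count_hexamers(noncoding_seqs, step=1) + 1.0
    return HexamerTable(coding=c / c.sum(), noncoding=n / n.sum())


def hexamer_bias(seq: str, table: HexamerTable) -> float:
    """Mean log(F_coding/F_noncoding) over in-frame hexamers of the
    longest ORF (whole sequence in frame 0 when there is no ORF)."""
    seq = seq.upper()
    orf_len, _frame, start = find_longest_orf(seq)
    region = seq[start : start + orf_len] if orf_len > 0 else seq
    log_ratio = table.log_ratio
    total, m = 0.0, 0
    for i in range(0, len(region) - 5, 3):
        idx = _HEX_INDEX.get(region[i : i + 6])
        if idx is not None:
            total += log_ratio[idx]
            m += 1
    return total / m if m else 0.0


# ---------------------------------------------------------------------------
# Logistic combination


@dataclass
class LogisticModel:
    """Standardized-feature logistic model p(coding | features)."""

    intercept: float
    coef: np.ndarray  # per feature, on standardized scale
    mean: np.ndarray
    scale: np.ndarray
    feature_names: tuple[str, ...] = ("orf_length", "orf_coverage", "fickett", "hexamer")

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(features) - self.mean) / self.scale
        z = self.intercept + x @ self.coef
        return 1.0 / (1.0 + np.exp(-z))


def train_logistic(features: np.ndarray, labels: np.ndarray) -> LogisticModel:
    """Fit the coding/noncoding logistic model (ridge-penalized).

    ``features`` columns are (orf_length, orf_coverage, fickett, hexamer);
    ``labels`` are 1 for coding, 0 for noncoding. ORF length separates
    real training sets almost perfectly, so a small L2 penalty keeps the
    fit well-defined under (near-)separation.
    """
    from sklearn.linear_model import LogisticRegression

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels are degenerate (single class)")
    features = np.asarray(features, dtype=float)
    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    scale[scale == 0] = 1.0
    x = (features - mean) / scale
    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(x, labels)
    return LogisticModel(
        intercept=float(clf.intercept_[0]),
        coef=clf.coef_[0].astype(float),
        mean=mean,
        scale=scale,
    )


@dataclass
class CodingScores:
    """All coding-potential evidence for one transcript."""

    transcript_id: str
    orf_length: int
    fickett: float
    hexamer: float
    coding_prob: float
    external: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.orf_length < 0 or (self.orf_length > 0 and self.orf_length % 3):
            raise ValueError("orf_length must be >= 0 and a codon multiple")
        if not 0.0 <= self.coding_prob <= 1.0:
            raise ValueError("coding_prob must lie in [0, 1]")

    def tool_score(self, tool: str) -> float | None:
        if tool == "CPAT":
            return self.coding_prob
        return self.external.get(tool)


def score_transcript(
    transcript_id: str, seq: str, table: HexamerTable, model: LogisticModel
) -> CodingScores:
    orf_len, _f, _s = find_longest_orf(seq)
    fick = fickett_score(seq) if len(seq) >= 200 else 0.0
    hexa = hexamer_bias(seq, table)
    coverage = orf_len / len(seq) if seq else 0.0
    prob = float(model.predict_proba(np.array([orf_len, coverage, fick, hexa]))[0])
    return CodingScores(
        transcript_id=transcript_id,
        orf_length=orf_len,
        fickett=fick,
        hexamer=hexa,
        coding_prob=prob,
    )


def read_score_table(path: str | Path, tool: str) -> dict[str, float]:
    """Read an external predictor's per-transcript score TSV
    (columns: transcript_id, score)."""
    tab = pd.read_csv(path, sep="\t")
    return dict(zip(tab.iloc[:, 0].astype(str), tab.iloc[:, 1].astype(float)))


class ConsensusError(ValueError):
    pass


def consensus_noncoding(
    scores: CodingScores, thresholds: Mapping[str, float] | None = None
) -> bool:
    """Intersection filter: noncoding iff every required tool score is
    strictly below its threshold.

    By default only tools with an available score are required; pass an
    explicit ``thresholds`` mapping to demand specific tools (a missing
    score then raises :class:`ConsensusError` naming the tool).
    """
    if thresholds is None:
        thresholds = {
            tool: thr
            for tool, thr in DEFAULT_THRESHOLDS.items()
            if scores.tool_score(tool) is not None
        }
    for tool, threshold in thresholds.items():
        value = scores.tool_score(tool)
        if value is None:
            raise ConsensusError(f"no score available for required tool {tool}")
        if not value < threshold:
            return False
    return True
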