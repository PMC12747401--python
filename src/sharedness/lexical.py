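"""Word odds ratios between high/low classes and emotion-conditional summaries.

High/low classes are defined by the quartiles of a target value over the
merged reports: the high class holds reports at or above the third
quartile, the low class those at or below the first quartile (inclusive on
both boundaries, so ties at a quartile enter the class). The target is
either the report's own well-being score or the score-based sharedness
index of its team-week.

Word-class association uses document-frequency 2x2 tables with the
Haldane-Anscombe 0.5 correction, so odds ratios stay finite and positive
even at zero counts. Emotion labels come from a pluggable classifier; the
built-in stand-in is a deterministic lexicon vote (majority token emotion,
ties abstain).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import EMOTIONS, EMOTION_LEXICON
from .tsi import Tokenizer, tokenize

__all__ = [
    "ClassSpec",
    "OddsRatioRow",
    "EmotionSummaryRow",
    "build_classes",
    "word_odds",
    "LexiconClassifier",
    "classify_emotions",
    "emotion_summary",
]


@dataclass(frozen=True)
class ClassSpec:
    """Realized quartile thresholds and class sizes for a high/low split."""

    target: str
    q1: float
    q3: float
    n_high: int
    n_low: int


@dataclass(frozen=True)
class OddsRatioRow:
    word: str
    count_high: int
    count_low: int
    odds_ratio: float


@dataclass(frozen=True)
class EmotionSummaryRow:
    emotion: str
    n: int
    wb_mean: float
    wb_sd: float
    delta: float


def build_classes(
    reports: pd.DataFrame,
    target: str,
    index_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ClassSpec]:
    """Split reports into high (>= Q3) and low (<= Q1) classes on a target.

    ``target`` is ``"wellbeing"`` (the report's own score) or ``"ssi"``
    (the report's team-week index, joined from ``index_table`` with columns
    team_id, week, ssi). Quartiles use linear interpolation between order
    statistics; fewer than four distinct target values is an error.
    """
    df = reports.copy()
    if target == "wellbeing":
        df["_target"] = df["wellbeing"]
    elif target == "ssi":
        if index_table is None:
            raise ValueError("target 'ssi' needs an index_table with team-week SSI values")
        joined = df.merge(
            index_table[["team_id", "week", "ssi"]], on=["team_id", "week"], how="left"
        )
        df["_target"] = joined["ssi"].to_numpy()
        df = df[df["_target"].notna()]
    else:
        raise ValueError(f"unknown target {target!r}")

    values = df["_target"].to_numpy(dtype=float)
    if len(np.unique(values)) < 4:
        raise ValueError("need at least 4 distinct target values for quartiles")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    high = df[df["_target"] >= q3].drop(columns="_target")
    low = df[df["_target"] <= q1].drop(columns="_target")
    return high, low, ClassSpec(target=target, q1=float(q1), q3=float(q3), n_high=len(high), n_low=len(low))


def word_odds(
    high_docs: Sequence[str],
    low_docs: Sequence[str],
    tokenizer: Tokenizer | None = None,
    min_df: int = 5,
    smoothing: float = 0.5,
    mode: str = "presence",
) -> list[OddsRatioRow]:
    """Per-word smoothed odds ratios between the two classes, ranked descending.

    In presence mode (default) the 2x2 table counts documents containing
    the word; in count mode it counts token occurrences against the class
    total. OR = ((a+s)/(b+s)) / ((c+s)/(d+s)) with s the smoothing constant
    (Haldane-Anscombe 0.5), finite and positive even at zero counts. Words
    seen fewer than ``min_df`` times across both classes are dropped.
    """
    if not len(high_docs) or not len(low_docs):
        raise ValueError("both classes must be nonempty")
    if mode not in {"presence", "count"}:
        raise ValueError(f"mode must be 'presence' or 'count', got {mode!r}")

    def _tally(docs: Sequence[str]) -> tuple[Counter, int]:
        c: Counter = Counter()
        total = 0
        for doc in docs:
            toks = tokenize(doc, tokenizer)
            total += len(toks)
            c.update(set(toks) if mode == "presence" else toks)
        return c, (len(docs) if mode == "presence" else total)

    high_counts, n_high = _tally(high_docs)
    low_counts, n_low = _tally(low_docs)
    s = smoothing
    rows = []
    for word in set(high_counts) | set(low_counts):
        a = high_counts.get(word, 0)
        c = low_counts.get(word, 0)
        if a + c < min_df:
            continue
        b = n_high - a
        d = n_low - c
        orr = ((a + s) / (b + s)) / ((c + s) / (d + s))
        rows.append(OddsRatioRow(word=word, count_high=a, count_low=c, odds_ratio=orr))
    rows.sort(key=lambda r: (-r.odds_ratio, r.word))
    return rows


class LexiconClassifier:
    """Deterministic emotion stand-in: majority vote over a token lexicon.

    Each token mapped by the lexicon casts one vote for its emotion; the
    report gets the majority label, or abstains (None) on a tie or when no
    token is mapped.
    """

    def __init__(self, lexicon: Mapping[str, Sequence[str]] | None = None):
        lexicon = lexicon if lexicon is not None else EMOTION_LEXICON
        unknown = set(lexicon) - set(EMOTIONS)
        if unknown:
            raise ValueError(f"lexicon maps unknown emotions: {sorted(unknown)}")
        self._token_emotion = {
            tok: emo for emo, toks in lexicon.items() for tok in toks
        }

    def __call__(self, text: str) -> str | None:
        votes = Counter(
            self._token_emotion[t] for t in tokenize(text) if t in self._token_emotion
        )
        if not votes:
            return None
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return None  # tie -> abstain
        return ranked[0][0]


def classify_emotions(
    diaries: Sequence[str],
    classifier_plugin: Callable[[str], str | None] | None = None,
) -> list[str | None]:
    """Label each diary with one of the seven emotions, or None (abstain).

    Any callable mapping text to a label/None can stand in for the default
    lexicon classifier; labels outside the emotion set are rejected.
    """
    clf = classifier_plugin or LexiconClassifier()
    labels = []
    for text in diaries:
        label = clf(text)
        if label is not None and label not in EMOTIONS:
            raise ValueError(f"classifier returned unknown label {label!r}")
        labels.append(label)
    return labels


def emotion_summary(
    wellbeing: Sequence[float],
    labels: Sequence[str | None],
) -> list[EmotionSummaryRow]:
    """Per-emotion well-being summary with deltas against the pooled mean.

    Abstentions (None) are excluded. delta = group mean - overall labeled
    mean, so the n-weighted deltas sum to zero by construction.
    """
    wb = np.asarray(wellbeing, dtype=float)
    if len(wb) != len(labels):
        raise ValueError("wellbeing and labels must be aligned")
    mask = np.array([lab is not None for lab in labels])
    if not mask.any():
        raise ValueError("no labeled reports")
    wb = wb[mask]
    labs = np.array([lab for lab in labels if lab is not None])
    overall = float(wb.mean())
    rows = []
    for emo in EMOTIONS:
        sel = wb[labs == emo]
        if sel.size == 0:
            continue
        sd = float(sel.std(ddof=1)) if sel.size > 1 else math.nan
        rows.append(
            EmotionSummaryRow(
                emotion=emo,
                n=int(sel.size),
                wb_mean=float(sel.mean()),
                wb_sd=sd,
                delta=float(sel.mean()) - overall,
            )
        )
    rows.sort(key=lambda r: -r.n)
    return rows
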