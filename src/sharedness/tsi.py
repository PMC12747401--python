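"""Text-based sharedness index (TSI).

Each member's diary entries within a week are concatenated into one
document, represented as a normalized bag-of-words (nBOW) over the
embedding vocabulary. The semantic distance between two members' weekly
documents is the Word Mover's Distance: the minimum cost of transporting
one document's word distribution onto the other's, with ground cost the
Euclidean distance between word vectors. TSI for a team-week is the mean of
a similarity transform of the distance over all C = k(k-1)/2 unique pairs
of the k usable member documents; it is missing (NaN) when k < 2.

The transportation problem is solved exactly (HiGHS dual simplex on the
full LP) — weekly diary vocabularies are small, so exactness is cheap and
keeps results reproducible against brute-force oracles. The default
similarity transform is negation: any strictly decreasing affine transform
leaves the magnitude of every downstream Pearson correlation unchanged, so
nothing is lost, and the index keeps the distance's scale. ``inv``
(1/(1+d)) and ``exp`` (e^-d) are available for sensitivity analyses.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix
from scipy.spatial.distance import cdist

from .embeddings import EmbeddingTable

__all__ = [
    "NBowDoc",
    "PairSimilarity",
    "tokenize",
    "build_nbow",
    "wmd",
    "similarity",
    "compute_tsi",
    "tsi_table",
    "SIM_TRANSFORMS",
]

Tokenizer = Callable[[str], list[str]]

_WORD_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str, tokenizer_plugin: Tokenizer | None = None) -> list[str]:
    """Split text into tokens.

    The default plugin lowercases and splits on whitespace and punctuation
    (any non-word character). A morphological analyzer can be supplied as
    ``tokenizer_plugin``; it must map a string to a list of tokens.
    """
    if tokenizer_plugin is not None:
        return tokenizer_plugin(text)
    return _WORD_RE.findall(text.lower())


@dataclass(frozen=True)
class NBowDoc:
    """Normalized bag-of-words over in-vocabulary tokens.

    ``support`` holds the unique tokens, ``weights`` their normalized term
    frequencies (sum 1). An empty support marks the document unusable.
    """

    support: tuple[str, ...]
    weights: np.ndarray
    member_id: str | None = None
    week: int | None = None

    @property
    def usable(self) -> bool:
        return len(self.support) > 0

    def __post_init__(self) -> None:
        if len(self.support) != len(set(self.support)):
            raise ValueError("support tokens must be unique")
        if self.usable and abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class PairSimilarity:
    member_i: str
    member_j: str
    distance: float
    similarity: float
    team_id: str | None = None
    week: int | None = None


def build_nbow(
    tokens: Sequence[str],
    embeddings: EmbeddingTable,
    member_id: str | None = None,
    week: int | None = None,
) -> NBowDoc:
    """Count in-vocabulary tokens and normalize to a probability vector.

    Out-of-vocabulary tokens are dropped; a document left with no
    in-vocabulary token is returned with empty support (unusable).
    """
    counts: dict[str, int] = {}
    for tok in tokens:
        if tok in embeddings:
            counts[tok] = counts.get(tok, 0) + 1
    if not counts:
        return NBowDoc(support=(), weights=np.empty(0), member_id=member_id, week=week)
    support = tuple(counts)
    w = np.array([counts[t] for t in support], dtype=float)
    return NBowDoc(support=support, weights=w / w.sum(), member_id=member_id, week=week)


# Transportation-LP equality constraints depend only on the support sizes;
# cache them across the many small solves a study produces.
_A_CACHE: dict[tuple[int, int], csr_matrix] = {}


def _transport_constraints(m: int, n: int) -> csr_matrix:
    key = (m, n)
    A = _A_CACHE.get(key)
    if A is None:
        rows, cols = [], []
        for i in range(m):
            for j in range(n):
                k = i * n + j
                rows.append(i)
                cols.append(k)
                if j < n - 1:  # last column constraint is redundant
                    rows.append(m + j)
                    cols.append(k)
        A = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m + n - 1, m * n))
        _A_CACHE[key] = A
    return A


def _ground_costs(a: NBowDoc, b: NBowDoc, embeddings: EmbeddingTable, metric: str) -> np.ndarray:
    va = embeddings.matrix(a.support)
    vb = embeddings.matrix(b.support)
    if metric == "euclidean":
        return cdist(va, vb, metric="euclidean")
    if metric == "cosine":
        return cdist(va, vb, metric="cosine")
    raise ValueError(f"unknown ground metric {metric!r}")


def wmd(a: NBowDoc, b: NBowDoc, embeddings: EmbeddingTable, metric: str = "euclidean") -> float:
    """Exact Word Mover's Distance between two usable nBOW documents.

    Solves min_T sum_uv T_uv d(u, v) s.t. row sums = a.weights, column sums
    = b.weights, T >= 0. Raises ``ValueError`` on an unusable document; the
    caller should skip such pairs.
    """
    if not a.usable or not b.usable:
        raise ValueError("wmd needs usable documents on both sides; skip this pair")
    C = _ground_costs(a, b, embeddings, metric)
    m, n = C.shape
    if m == 1 or n == 1:
        # all mass from/to a single point: cost is the weighted ground distance
        return float(a.weights @ C @ b.weights)
    res = linprog(
        C.ravel(),
        A_eq=_transport_constraints(m, n),
        b_eq=np.concatenate([a.weights, b.weights[:-1]]),
        bounds=(0, None),
        method="highs-ds",
    )
    if not res.success:  # pragma: no cover - balanced transport is always feasible
        raise RuntimeError(f"transport LP failed: {res.message}")
    return max(float(res.fun), 0.0)


def _sim_neg(d: float) -> float:
    return -d


def _sim_inv(d: float) -> float:
    return 1.0 / (1.0 + d)


def _sim_exp(d: float) -> float:
    return math.exp(-d)


SIM_TRANSFORMS: Mapping[str, Callable[[float], float]] = {
    "neg": _sim_neg,
    "inv": _sim_inv,
    "exp": _sim_exp,
}


def similarity(distance: float, transform: str = "neg") -> float:
    """Map a semantic distance (>= 0) to a similarity, strictly decreasing in d."""
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    try:
        fn = SIM_TRANSFORMS[transform]
    except KeyError:
        raise ValueError(f"unknown transform {transform!r}; choose from {sorted(SIM_TRANSFORMS)}") from None
    return fn(distance)


def compute_tsi(
    weekly_docs: Sequence[NBowDoc],
    embeddings: EmbeddingTable,
    transform: str = "neg",
    metric: str = "euclidean",
    team_id: str | None = None,
    week: int | None = None,
) -> tuple[float, list[PairSimilarity]]:
    """TSI for one team-week: mean pairwise similarity of usable member docs.

    Returns ``(tsi, pair_records)``; tsi is NaN when fewer than two usable
    documents exist (C = 0).
    """
    usable = [d for d in weekly_docs if d.usable]
    pairs: list[PairSimilarity] = []
    for a, b in combinations(usable, 2):
        d = wmd(a, b, embeddings, metric=metric)
        pairs.append(
            PairSimilarity(
                member_i=a.member_id or "?",
                member_j=b.member_id or "?",
                distance=d,
                similarity=similarity(d, transform),
                team_id=team_id,
                week=week,
            )
        )
    if not pairs:
        return math.nan, []
    return float(np.mean([p.similarity for p in pairs])), pairs


def tsi_table(
    days,
    embeddings: EmbeddingTable,
    transform: str = "neg",
    metric: str = "euclidean",
    tokenizer: Tokenizer | None = None,
):
    """TSI per team-week from a merged-record table.

    ``days`` is a pandas DataFrame with columns team_id, week,
    participant_id, diary. Each member's diaries within a team-week are
    concatenated (newline-joined) into one weekly document. Returns
    ``(table, pair_records)`` where the table has one row per team-week
    holding tsi (NaN when fewer than two usable documents) and
    n_tsi_members, and pair_records lists every pairwise distance.
    """
    import pandas as pd

    rows = []
    all_pairs: list[PairSimilarity] = []
    weekly = days.groupby(["team_id", "week", "participant_id"])["diary"].apply("\n".join)
    for (team, week), docs in weekly.groupby(level=[0, 1]):
        nbows = [
            build_nbow(tokenize(text, tokenizer), embeddings, member_id=member, week=week)
            for (_, _, member), text in docs.items()
        ]
        usable = [d for d in nbows if d.usable]
        tsi, pairs = compute_tsi(
            usable, embeddings, transform=transform, metric=metric, team_id=team, week=week
        )
        all_pairs.extend(pairs)
        rows.append(
            {"team_id": team, "week": week, "tsi": tsi, "n_tsi_members": len(usable)}
        )
    return pd.DataFrame(rows, columns=["team_id", "week", "tsi", "n_tsi_members"]), all_pairs
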