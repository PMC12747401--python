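"""Word-embedding tables and the word2vec text format.

A table maps tokens to fixed-dimension real vectors; unknown tokens are
reported as absent (``None`` / ``in`` checks), never silently mapped to a
default vector. The on-disk dialect is the plain word2vec text format: a
``count dim`` header line, then one ``token v1 v2 ...`` line per token.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = ["EmbeddingTable", "read_word2vec_text", "write_word2vec_text"]


class EmbeddingTable:
    """Token -> vector lookup with a single shared dimension."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding table must be non-empty")
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError(f"all vectors must be 1-D with one shared dimension, got shapes {dims}")
        self._vectors = {t: np.asarray(v, dtype=float) for t, v in vectors.items()}
        self.dim = next(iter(dims))[0]

    def __contains__(self, token: str) -> bool:
        return token in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def __getitem__(self, token: str) -> np.ndarray:
        return self._vectors[token]

    def get(self, token: str) -> np.ndarray | None:
        return self._vectors.get(token)

    @property
    def vocabulary(self) -> set[str]:
        return set(self._vectors)

    def matrix(self, tokens: Iterable[str]) -> np.ndarray:
        """Stack vectors for in-vocabulary tokens, in the given order."""
        return np.stack([self._vectors[t] for t in tokens])


def read_word2vec_text(path: str | Path) -> EmbeddingTable:
    """Read the word2vec text dialect (``count dim`` header, one token per line)."""
    vectors: dict[str, np.ndarray] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("expected a 'count dim' header line")
        count, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < dim + 1:
                raise ValueError(f"malformed vector line for token {parts[0]!r}")
            vectors[parts[0]] = np.array(parts[1 : dim + 1], dtype=float)
    if len(vectors) != count:
        raise ValueError(f"header promised {count} vectors, file holds {len(vectors)}")
    return EmbeddingTable(vectors)


def write_word2vec_text(table: EmbeddingTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dim}\n")
        for token in sorted(table.vocabulary):
            vec = " ".join(repr(float(x)) for x in table[token])
            fh.write(f"{token} {vec}\n")
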