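"""Document chunking for transformer encoders, with a pluggable backend.

Long notes exceed encoder context windows, so a note is encoded as the
elementwise average of fixed-width segment vectors.  Two chunking strategies
are implemented:

``whole_note``
    Greedy sentence packing into segments of at most ``max_tokens`` tokens,
    consecutive segments overlapping by exactly the previous segment's last
    sentence (when the pair fits).

``keyword_window``
    One segment per anchor-phrase occurrence ("chf", "congestive heart
    failure"), spanning ``window_radius`` tokens each side of the anchor,
    clipped to the note.  With no anchor, the document vector is all zeros.

The bundled :class:`HashingEncoder` is a deterministic, dependency-free
backend used throughout the test suite; real pretrained encoders plug in by
satisfying the same contract.  "Token" means whatever the attached backend
tokenizes — whitespace/alphanumeric tokens for the hashing backend.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = [
    "EncoderBackend",
    "HashingEncoder",
    "ChunkingConfig",
    "chunk_whole",
    "chunk_keyword_window",
    "encode_document",
    "embed_note",
]


@runtime_checkable
class EncoderBackend(Protocol):
    """Contract for segment encoders."""

    max_tokens: int
    dimension: int

    def encode(self, segment: list[str]) -> np.ndarray: ...


class HashingEncoder:
    """Deterministic stub encoder: hashed bag-of-tokens with signed buckets.

    Bit-reproducible across processes and platforms (md5-based), needs no
    weights, and respects the backend contract including segment-length
    rejection.
    """

    def __init__(self, dimension: int = 16, max_tokens: int = 512):
        if dimension < 1 or max_tokens < 2:
            raise ValueError("dimension >= 1 and max_tokens >= 2 required")
        self.dimension = dimension
        self.max_tokens = max_tokens

    def encode(self, segment: list[str]) -> np.ndarray:
        if len(segment) > self.max_tokens:
            raise ValueError(
                f"segment of {len(segment)} tokens exceeds max_tokens={self.max_tokens}"
            )
        vec = np.zeros(self.dimension, dtype=float)
        for tok in segment:
            h = hashlib.md5(tok.encode("utf-8")).digest()
            idx = int.from_bytes(h[:4], "little") % self.dimension
            sign = 1.0 if h[4] % 2 == 0 else -1.0
            vec[idx] += sign
        n = len(segment)
        return vec / np.sqrt(n) if n else vec


@dataclass
class ChunkingConfig:
    strategy: str = "whole_note"  # or "keyword_window"
    max_tokens: int = 512
    window_radius: int = 250
    anchor_phrases: tuple[str, ...] = ("chf", "congestive heart failure")

    def __post_init__(self):
        if self.strategy not in ("whole_note", "keyword_window"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.max_tokens < 2:
            raise ValueError("max_tokens must be >= 2")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


def _hard_split(sentence: list[str], max_tokens: int) -> list[list[str]]:
    return [sentence[i : i + max_tokens] for i in range(0, len(sentence), max_tokens)]


def chunk_whole(sentences: list[list[str]], config: ChunkingConfig) -> list[list[str]]:
    """Greedy sentence packing with one-sentence overlap.

    Grow a segment sentence by sentence until the next sentence would exceed
    ``max_tokens``; the next segment starts with the previous segment's last
    sentence, provided that overlap still leaves room for the new sentence.
    Every input token appears in at least one segment.  A single sentence
    longer than ``max_tokens`` is hard-split with a warning.
    """
    max_t = config.max_tokens
    prepared: list[list[str]] = []
    for s in sentences:
        if len(s) > max_t:
            warnings.warn(
                f"sentence of {len(s)} tokens exceeds max_tokens={max_t}; hard-splitting",
                stacklevel=2,
            )
            prepared.extend(_hard_split(list(s), max_t))
        elif s:
            prepared.append(list(s))

    segments: list[list[list[str]]] = []
    current: list[list[str]] = []

    def flush():
        if current:
            segments.append(list(current))

    for sent in prepared:
        cur_len = sum(len(x) for x in current)
        if current and cur_len + len(sent) > max_t:
            flush()
            overlap = current[-1]
            current = [overlap, sent] if len(overlap) + len(sent) <= max_t else [sent]
        else:
            current.append(sent)
    flush()
    return [[tok for s in seg for tok in s] for seg in segments]


def _find_anchor_spans(tokens: list[str], anchors: tuple[str, ...]) -> list[tuple[int, int]]:
    low = [t.lower() for t in tokens]
    spans = []
    anchor_tuples = [tuple(a.lower().split()) for a in anchors]
    for i in range(len(low)):
        for a in anchor_tuples:
            if tuple(low[i : i + len(a)]) == a:
                spans.append((i, i + len(a)))
    return sorted(spans)


def chunk_keyword_window(tokens: list[str], config: ChunkingConfig) -> list[list[str]]:
    """One segment per anchor occurrence, radius tokens each side, clipped.

    Anchors are matched on the lowercased raw token stream (not stemmed).
    Zero segments when no anchor occurs.
    """
    out = []
    r = config.window_radius
    for start, end in _find_anchor_spans(tokens, config.anchor_phrases):
        out.append(tokens[max(0, start - r) : min(len(tokens), end + r)])
    return out


def encode_document(segments: list[list[str]], backend: EncoderBackend) -> np.ndarray:
    """Elementwise mean of segment encodings; zero vector for no segments.

    Permutation-invariant in the segments.  Raises on encoder outputs of
    mismatched width.
    """
    if not segments:
        return np.zeros(backend.dimension, dtype=float)
    encoded = [np.asarray(backend.encode(s), dtype=float) for s in segments]
    widths = {e.shape for e in encoded}
    if len(widths) > 1:
        raise ValueError(f"backend returned mismatched dimensions: {widths}")
    return np.mean(encoded, axis=0)


def embed_note(
    text: str, backend: EncoderBackend, config: ChunkingConfig | None = None
) -> np.ndarray:
    """Chunk a raw note per the config and encode it to one vector."""
    from ._text import split_sentences, tokenize

    config = config or ChunkingConfig()
    sentence_tokens = [tokenize(s) for s in split_sentences(text)]
    if config.strategy == "whole_note":
        segments = chunk_whole(sentence_tokens, config)
    else:
        flat = [t for s in sentence_tokens for t in s]
        segments = chunk_keyword_window(flat, config)
        segments = [
            s if len(s) <= backend.max_tokens else s[: backend.max_tokens] for s in segments
        ]
    return encode_document(segments, backend)
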