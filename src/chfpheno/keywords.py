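"""CHF keyword lexicon: curated phrases, data-driven n-grams, negations.

Candidate 1/2/3-grams are counted per note (overlapping occurrences on the
normalized token stream, never crossing sentence boundaries) and compared
between proxy-positive and proxy-negative notes with a Mann-Whitney U test.
The proxy label is the patient's ICD screening status — a rough approximation
of CHF status — so discovery never touches manual annotations.  Significant
grams are merged with the curated clinician list and the result is augmented
with negated forms ("no chf", "chf mother", "[] chf", ...), which downstream
models can weight negatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._text import normalize_text, sentence_token_lists
from .cohort import NoteDocument

__all__ = [
    "NGramStat",
    "LexiconEntry",
    "KeywordLexicon",
    "DEFAULT_CURATED_KEYWORDS",
    "DEFAULT_NEGATION_TEMPLATES",
    "extract_ngrams",
    "rank_test",
    "select_keywords",
    "augment_negations",
    "discover_keywords",
]

#: Knowledge-driven seed list (clinician-style phrasing, pre-normalization).
DEFAULT_CURATED_KEYWORDS: tuple[str, ...] = (
    "chf",
    "congestive heart failure",
    "heart failure",
    "history of chf",
    "chf exacerbation",
    "with chf",
    "dx chf",
    "ascites",
)

#: Negation/confounder patterns; ``{p}`` is the base-phrase slot.
DEFAULT_NEGATION_TEMPLATES: tuple[str, ...] = (
    "no {p}",
    "unlikely {p}",
    "{p} father",
    "{p} mother",
    "[] {p}",
    "() {p}",
)


@dataclass
class NGramStat:
    """Rank-test summary for one candidate gram."""

    gram: tuple[str, ...]
    u_statistic: float
    p_value: float
    n_pos: int
    n_neg: int
    counts_pos: np.ndarray | None = None
    counts_neg: np.ndarray | None = None

    @property
    def phrase(self) -> str:
        return " ".join(self.gram)


@dataclass(frozen=True)
class LexiconEntry:
    phrase: str
    source: str  # "curated" | "data-driven" | "negation"
    base: str | None = None  # for negation entries: the phrase negated
    u: float | None = None
    p: float | None = None
    p_corrected: float | None = None


@dataclass
class KeywordLexicon:
    """Selected phrases with provenance; unique after normalization."""

    entries: list[LexiconEntry] = field(default_factory=list)
    selection_config: dict = field(default_factory=dict)

    def phrases(self) -> list[str]:
        return [e.phrase for e in self.entries]

    def normalized_phrases(self, mode: str = "both") -> list[tuple[str, ...]]:
        seen, out = set(), []
        for e in self.entries:
            toks = tuple(normalize_text(e.phrase, mode))
            if toks and toks not in seen:
                seen.add(toks)
                out.append(toks)
        return out

    def add(self, entry: LexiconEntry, mode: str = "both") -> bool:
        """Add an entry unless its normalized form is already present."""
        key = tuple(normalize_text(entry.phrase, mode))
        existing = {tuple(normalize_text(e.phrase, mode)) for e in self.entries}
        if key in existing or not key:
            return False
        self.entries.append(entry)
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "phrase": e.phrase,
                    "source": e.source,
                    "base": e.base,
                    "u": e.u,
                    "p": e.p,
                    "p_corrected": e.p_corrected,
                }
                for e in self.entries
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "KeywordLexicon":
        df = pd.read_csv(path)
        entries = [
            LexiconEntry(
                phrase=row["phrase"],
                source=row["source"],
                base=row["base"] if pd.notna(row.get("base")) else None,
                u=row["u"] if pd.notna(row.get("u")) else None,
                p=row["p"] if pd.notna(row.get("p")) else None,
                p_corrected=row["p_corrected"] if pd.notna(row.get("p_corrected")) else None,
            )
            for _, row in df.iterrows()
        ]
        return cls(entries=entries)


def _sentence_grams(tokens: tuple[str, ...], max_n: int):
    for n in range(1, max_n + 1):
        for i in range(len(tokens) - n + 1):
            yield tokens[i : i + n]


def extract_ngrams(
    notes: list[NoteDocument] | list[str],
    max_n: int = 3,
    mode: str = "both",
) -> dict[tuple[str, ...], np.ndarray]:
    """Per-note occurrence counts for every 1..max_n gram in the corpus.

    Grams are counted on the normalized token stream with overlap ("chf chf"
    holds two "chf" 1-grams and one "chf chf" 2-gram) and never cross
    sentence boundaries.  Returns gram -> integer count vector aligned with
    the input note order; an empty corpus yields an empty mapping.
    """
    if max_n not in (1, 2, 3):
        raise ValueError("max_n must be 1, 2, or 3")
    n_notes = len(notes)
    counts: dict[tuple[str, ...], dict[int, int]] = {}
    sentence_cache: dict[tuple[str, ...], dict[tuple[str, ...], int]] = {}
    for j, note in enumerate(notes):
        text = note.text if isinstance(note, NoteDocument) else note
        for sent in sentence_token_lists(text, mode):
            per_sent = sentence_cache.get(sent)
            if per_sent is None:
                per_sent = {}
                for gram in _sentence_grams(sent, max_n):
                    per_sent[gram] = per_sent.get(gram, 0) + 1
                sentence_cache[sent] = per_sent
            for gram, c in per_sent.items():
                row = counts.setdefault(gram, {})
                row[j] = row.get(j, 0) + c
    out: dict[tuple[str, ...], np.ndarray] = {}
    for gram, row in counts.items():
        vec = np.zeros(n_notes, dtype=np.int64)
        for j, c in row.items():
            vec[j] = c
        out[gram] = vec
    return out


def _tie_corrected_u_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Asymptotic two-sided Mann-Whitney with tie and continuity correction."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all observations identical
        return u1, 1.0
    mu = n1 * n2 / 2.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return u1, p


def rank_test(counts_pos, counts_neg, gram: tuple[str, ...] = ()) -> NGramStat:
    """Mann-Whitney U comparing per-note counts between proxy groups.

    U is the number of (positive, negative) pairs won by the positive group
    plus half-ties.  The exact null distribution is used for small tie-free
    samples (n_pos * n_neg <= 400); otherwise the normal approximation with
    tie and continuity correction.  Swapping the groups maps U to
    n_pos*n_neg - U with the same two-sided p.
    """
    x = np.asarray(counts_pos, dtype=float)
    y = np.asarray(counts_neg, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) * len(y) <= 400 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        u, p = float(res.statistic), float(res.pvalue)
    else:
        u, p = _tie_corrected_u_p(x, y)
    return NGramStat(
        gram=gram, u_statistic=u, p_value=p, n_pos=len(x), n_neg=len(y),
        counts_pos=np.asarray(counts_pos), counts_neg=np.asarray(counts_neg),
    )


def rank_test_matrix(X: np.ndarray, is_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise tie-corrected asymptotic U test; returns (U1, p) arrays.

    Vectorized counterpart of :func:`rank_test` for wide count matrices.
    """
    is_pos = np.asarray(is_pos, dtype=bool)
    n1 = int(is_pos.sum())
    n2 = int((~is_pos).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    ranks = sps.rankdata(X, axis=0)
    u1 = ranks[is_pos].sum(axis=0) - n1 * (n1 + 1) / 2.0
    # per-column tie correction
    Xs = np.sort(X, axis=0)
    new_val = np.vstack([np.ones((1, X.shape[1]), dtype=bool), Xs[1:] != Xs[:-1]])
    tie_terms = np.empty(X.shape[1])
    for j in range(X.shape[1]):  # modest column counts; clarity over speed
        counts = np.diff(np.flatnonzero(np.append(new_val[:, j], True)))
        tie_terms[j] = float((counts.astype(float) ** 3 - counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_terms / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    z = np.where(sigma2 <= 0, 0.0, np.maximum(z, 0.0))
    p = np.where(sigma2 <= 0, 1.0, np.minimum(1.0, 2.0 * sps.norm.sf(z)))
    return u1, p


def select_keywords(
    stats_list: list[NGramStat],
    alpha: float = 0.05,
    correction: str = "bh",
    curated: tuple[str, ...] = DEFAULT_CURATED_KEYWORDS,
    mode: str = "both",
) -> KeywordLexicon:
    """Keep grams with (corrected) p < alpha; merge with the curated list.

    ``correction``: "bh" (Benjamini-Hochberg step-up), "bonferroni", or
    "none".  Entries are de-duplicated on their normalized token form, with
    curated entries taking precedence.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if correction not in ("bh", "bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")

    lexicon = KeywordLexicon(
        selection_config={"alpha": alpha, "correction": correction, "mode": mode}
    )
    for phrase in curated:
        lexicon.add(LexiconEntry(phrase=phrase, source="curated"), mode)

    if stats_list:
        p = np.array([s.p_value for s in stats_list])
        if correction == "bh":
            p_adj = sps.false_discovery_control(p, method="bh")
        elif correction == "bonferroni":
            p_adj = np.minimum(1.0, p * len(p))
        else:
            p_adj = p
        order = np.argsort([s.phrase for s in stats_list])  # deterministic
        for i in order:
            s = stats_list[i]
            if p_adj[i] < alpha:
                lexicon.add(
                    LexiconEntry(
                        phrase=s.phrase, source="data-driven",
                        u=s.u_statistic, p=s.p_value, p_corrected=float(p_adj[i]),
                    ),
                    mode,
                )
    return lexicon


def augment_negations(
    lexicon: KeywordLexicon,
    templates: tuple[str, ...] = DEFAULT_NEGATION_TEMPLATES,
    mode: str = "both",
    sources: tuple[str, ...] = ("curated", "data-driven"),
) -> KeywordLexicon:
    """Add a negated form of every base phrase for each template.

    Templates must contain the ``{p}`` slot.  Duplicates (after
    normalization) are dropped; an empty template list is the identity.
    ``sources`` selects which entries count as bases; restricting to
    ``("curated",)`` avoids negating incidental context fragments from
    discovery (negated forms that truly occur in notes are discoverable as
    n-grams in their own right).
    """
    for t in templates:
        if "{p}" not in t:
            raise ValueError(f"negation template {t!r} lacks the {{p}} slot")
    out = KeywordLexicon(
        entries=list(lexicon.entries), selection_config=dict(lexicon.selection_config)
    )
    bases = [e for e in lexicon.entries if e.source in sources]
    for base in bases:
        for t in templates:
            out.add(
                LexiconEntry(phrase=t.format(p=base.phrase), source="negation", base=base.phrase),
                mode,
            )
    return out


def discover_keywords(
    notes: list[NoteDocument],
    proxy_positive: dict[str, bool] | list[bool],
    max_n: int = 3,
    min_notes: int = 5,
    alpha: float = 0.05,
    correction: str = "bh",
    curated: tuple[str, ...] = DEFAULT_CURATED_KEYWORDS,
    negation_templates: tuple[str, ...] = DEFAULT_NEGATION_TEMPLATES,
    mode: str = "both",
    negate_sources: tuple[str, ...] = ("curated",),
) -> KeywordLexicon:
    """End-to-end lexicon construction from a corpus and proxy labels.

    Grams occurring in fewer than ``min_notes`` notes are pruned before
    testing (rank tests on near-constant vectors are noise).  The vectorized
    asymptotic test is used corpus-wide; see `rank_test` for the small-sample
    path used on individual grams.
    """
    if isinstance(proxy_positive, dict):
        is_pos = np.array([bool(proxy_positive[n.note_id]) for n in notes])
    else:
        is_pos = np.asarray(proxy_positive, dtype=bool)
    if is_pos.sum() == 0 or (~is_pos).sum() == 0:
        raise ValueError("proxy labels must contain both classes")

    gram_counts = extract_ngrams(notes, max_n=max_n, mode=mode)
    grams = [g for g, v in gram_counts.items() if int((v > 0).sum()) >= min_notes]
    stats_list: list[NGramStat] = []
    if grams:
        X = np.stack([gram_counts[g] for g in grams], axis=1).astype(float)
        u, p = rank_test_matrix(X, is_pos)
        stats_list = [
            NGramStat(gram=g, u_statistic=float(u[j]), p_value=float(p[j]),
                      n_pos=int(is_pos.sum()), n_neg=int((~is_pos).sum()))
            for j, g in enumerate(grams)
        ]
    lexicon = select_keywords(stats_list, alpha=alpha, correction=correction,
                              curated=curated, mode=mode)
    if negation_templates:
        lexicon = augment_negations(lexicon, negation_templates, mode, sources=negate_sources)
    return lexicon
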