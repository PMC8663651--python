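"""Skip-gram embeddings, neighbor extraction, and candidate pruning.

Embeddings are trained with a self-contained, seeded skip-gram with
negative sampling (batched numpy SGD), so the package has no external
model dependency. The tested surface downstream of training is:
cosine similarity, extraction of up to ``max_neighbors`` positively
similar words per keyword, the three pruning rules (contrasting meaning,
shared root stem, configured stoplist), and provenance tagging of the
merged candidate list.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import Post
from .stemming import stem

logger = logging.getLogger(__name__)

PROVENANCE_LABELS = ("MPQ_only", "thesaurus_only", "both")


@dataclass
class EmbeddingConfig:
    dimension: int = 100
    context_window: int = 5
    min_count: int = 5
    epochs: int = 5
    negative_samples: int = 5
    seed: int = 0
    max_neighbors: int = 20
    learning_rate: float = 0.025
    batch_size: int = 1024
    # "mean_in_out" surfaces both first-order (co-occurrence) and
    # second-order (shared-context) association; "input" is the classic
    # input-matrix-only similarity.
    vector_mode: str = "mean_in_out"

    def __post_init__(self):
        if self.vector_mode not in ("mean_in_out", "input"):
            raise ValueError(f"unknown vector_mode {self.vector_mode!r}")
        for name in ("dimension", "context_window", "min_count", "epochs", "max_neighbors", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.negative_samples < 0:
            raise ValueError("negative_samples must be >= 0")


@dataclass
class EmbeddingModel:
    """Vocabulary plus one vector per token (rows of ``vectors``)."""

    vocabulary: list
    vectors: np.ndarray

    def __post_init__(self):
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError("vocabulary / vector row count mismatch")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vectors contain non-finite entries")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word]]
        except KeyError:
            raise KeyError(f"word not in vocabulary: {word!r}") from None

    def save_word2vec_text(self, path) -> None:
        """De-facto word2vec text format: header line, then word + vector."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocabulary)} {self.vectors.shape[1]}\n")
            for word, vec in zip(self.vocabulary, self.vectors):
                fh.write(word + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def load_word2vec_text(cls, path) -> "EmbeddingModel":
        with Path(path).open("r", encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            words, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"malformed vector line for {parts[0]!r}")
                words.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(words) != n:
            raise ValueError(f"expected {n} vectors, found {len(words)}")
        return cls(vocabulary=words, vectors=np.asarray(rows, dtype=np.float32))


@dataclass
class AssociationCandidate:
    keyword: str
    word: str
    similarity: float
    rank: int
    provenance: str | None = None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _skipgram_pairs(sentences: list, window: int):
    """All (center, context) id pairs within the positional window."""
    kept = [s for s in sentences if len(s) > 1]
    if not kept:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    toks = np.concatenate(kept)
    sent_idx = np.concatenate([np.full(len(s), i, dtype=np.int64) for i, s in enumerate(kept)])
    centers, contexts = [], []
    for d in range(1, window + 1):
        if d >= len(toks):
            break
        mask = sent_idx[:-d] == sent_idx[d:]
        a, b = toks[:-d][mask], toks[d:][mask]
        centers.append(a)
        contexts.append(b)
        centers.append(b)
        contexts.append(a)
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def train_embeddings(posts: Sequence[Post], cfg: EmbeddingConfig) -> EmbeddingModel:
    """Train skip-gram-with-negative-sampling vectors on cleaned posts.

    Tokens occurring fewer than ``min_count`` times are dropped from the
    vocabulary (and from the context sequences). Deterministic for a
    fixed (corpus, config) pair: one seeded generator drives
    initialization, pair shuffling and negative sampling.
    """
    counts: dict[str, int] = {}
    for post in posts:
        for tok in post.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(
        (w for w, c in counts.items() if c >= cfg.min_count),
        key=lambda w: (-counts[w], w),
    )
    if not vocab:
        raise ValueError("empty effective vocabulary after min_count pruning")
    index = {w: i for i, w in enumerate(vocab)}
    sentences = [
        np.asarray([index[t] for t in post.tokens if t in index], dtype=np.int64)
        for post in posts
    ]
    centers, contexts = _skipgram_pairs(sentences, cfg.context_window)

    rng = np.random.default_rng(cfg.seed)
    v, dim = len(vocab), cfg.dimension
    w_in = ((rng.random((v, dim)) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((v, dim), dtype=np.float32)
    n_pairs = len(centers)
    if n_pairs == 0:
        return EmbeddingModel(vocabulary=vocab, vectors=w_in)

    freq = np.asarray([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())
    k = cfg.negative_samples
    batch = cfg.batch_size
    steps_per_epoch = (n_pairs + batch - 1) // batch
    total_steps = cfg.epochs * steps_per_epoch
    step = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            idx = order[start : start + batch]
            c, o = centers[idx], contexts[idx]
            lr = cfg.learning_rate * max(1.0 - step / total_steps, 1e-4)
            step += 1
            wc = w_in[c]
            co = w_out[o]
            g_pos = (_sigmoid(np.einsum("bd,bd->b", wc, co)) - 1.0).astype(np.float32)
            grad_wc = g_pos[:, None] * co
            np.add.at(w_out, o, -lr * g_pos[:, None] * wc)
            if k > 0:
                neg = np.searchsorted(noise_cdf, rng.random((len(idx), k)))
                cn = w_out[neg]
                g_neg = _sigmoid(np.einsum("bd,bkd->bk", wc, cn)).astype(np.float32)
                grad_wc += np.einsum("bk,bkd->bd", g_neg, cn)
                np.add.at(
                    w_out,
                    neg.ravel(),
                    (-lr * g_neg[..., None] * wc[:, None, :]).reshape(-1, dim),
                )
            np.add.at(w_in, c, -lr * grad_wc)
    vectors = w_in if cfg.vector_mode == "input" else (w_in + w_out) / 2.0
    return EmbeddingModel(vocabulary=vocab, vectors=vectors)


def similarity(model: EmbeddingModel, w1: str, w2: str) -> float:
    """Cosine similarity in [-1, 1]; errors name any out-of-vocabulary word."""
    for w in (w1, w2):
        if w not in model:
            raise KeyError(f"word not in vocabulary: {w!r}")
    a, b = model.vector(w1), model.vector(w2)
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def associated_words(model: EmbeddingModel, keyword: str, cfg: EmbeddingConfig) -> list:
    """Up to ``max_neighbors`` positively similar words, ranked descending.

    The keyword itself is excluded; ties break alphabetically so rankings
    are reproducible. An out-of-vocabulary keyword yields an empty list
    with a logged warning (the keyword may simply be rare in the corpus).
    """
    if keyword not in model:
        logger.warning("keyword %r not in embedding vocabulary; no candidates", keyword)
        return []
    q = model.vector(keyword).astype(np.float64)
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(model.vectors, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    sims = (model.vectors.astype(np.float64) @ q) / (safe * (qn if qn else 1.0))
    sims[norms == 0.0] = 0.0
    scored = [
        (float(sims[i]), w)
        for i, w in enumerate(model.vocabulary)
        if w != keyword and sims[i] > 0.0
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [
        AssociationCandidate(keyword=keyword, word=w, similarity=s, rank=r)
        for r, (s, w) in enumerate(scored[: cfg.max_neighbors], start=1)
    ]


def prune_candidates(
    candidates: Sequence[AssociationCandidate],
    rootword_stems: Iterable[str],
    antonym_map: dict | None = None,
    stoplist: Iterable[str] | None = None,
):
    """Apply the three exclusion rules; returns (pruned, removal_log).

    Rules, in order: ``contrast`` — the (keyword, word) pair is listed in
    the antonym map (checked in both directions); ``same_root`` — the
    word's stem equals a root-descriptor stem; ``stoplist`` — the word is
    configured as irrelevant to pain description. Order-preserving, never
    adds words.
    """
    stems = set(rootword_stems)
    antonyms = {k: set(v) for k, v in (antonym_map or {}).items()}
    stop = set(stoplist or ())
    pruned, log = [], []
    for cand in candidates:
        if cand.word in antonyms.get(cand.keyword, ()) or cand.keyword in antonyms.get(cand.word, ()):
            log.append((cand, "contrast"))
        elif stem(cand.word) in stems:
            log.append((cand, "same_root"))
        elif cand.word in stop:
            log.append((cand, "stoplist"))
        else:
            pruned.append(cand)
    return pruned, log


def merge_and_tag_provenance(
    per_keyword_candidates: dict,
    mpq_keywords: Iterable[str],
    thesaurus_keywords: Iterable[str],
):
    """Deduplicate candidate words and tag each by its keyword class(es).

    Returns (tagged, counts): ``tagged`` is a list of ``(word, label)``
    in first-seen order with label in ``MPQ_only`` / ``thesaurus_only`` /
    ``both``; ``counts`` maps each label to its group size. The three
    groups partition the deduplicated words, so the sizes always sum to
    the total.
    """
    mpq = set(mpq_keywords)
    thes = set(thesaurus_keywords)
    overlap = mpq & thes
    if overlap:
        raise ValueError(f"keyword classes must be disjoint; shared: {sorted(overlap)}")
    from_mpq: set[str] = set()
    from_thes: set[str] = set()
    order: list[str] = []
    seen: set[str] = set()
    for keyword, cands in per_keyword_candidates.items():
        if keyword in mpq:
            bucket = from_mpq
        elif keyword in thes:
            bucket = from_thes
        else:
            raise ValueError(f"keyword {keyword!r} belongs to neither keyword class")
        for cand in cands:
            word = cand.word if isinstance(cand, AssociationCandidate) else str(cand)
            bucket.add(word)
            if word not in seen:
                seen.add(word)
                order.append(word)
    tagged = []
    for word in order:
        if word in from_mpq and word in from_thes:
            label = "both"
        elif word in from_mpq:
            label = "MPQ_only"
        else:
            label = "thesaurus_only"
        tagged.append((word, label))
    counts = {label: 0 for label in PROVENANCE_LABELS}
    for _w, label in tagged:
        counts[label] += 1
    return tagged, counts


def write_candidates_csv(
    candidates: Iterable[AssociationCandidate],
    path,
    removal_log: Iterable[tuple] = (),
) -> None:
    """Candidate table as CSV; pruned candidates carry their prune rule."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["keyword", "word", "similarity", "rank", "provenance", "prune_rule"])
        for c in candidates:
            writer.writerow([c.keyword, c.word, f"{c.similarity:.6f}", c.rank, c.provenance or "", ""])
        for c, rule in removal_log:
            writer.writerow([c.keyword, c.word, f"{c.similarity:.6f}", c.rank, "", rule])
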