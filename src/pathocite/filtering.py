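"""Relevance filtering of pathogen mentions with a linear classifier.

A linear support vector machine is trained by stochastic gradient
descent on the modified Huber loss over binary bag-of-n-gram features
(unigrams, optionally bigrams, after lower-casing and stop-word
removal).  The modified Huber loss

    L(m) = max(0, 1 - m)^2   for m >= -1
    L(m) = -4 m              for m <  -1

(with margin m = y * s, y in {-1, +1}) is a smoothed hinge whose
linear tail tolerates outliers and label noise — a good fit for weakly
labeled, imbalanced data.  The raw score is mapped to a confidence in
[0, 1] by clip((1 + s) / 2, 0, 1), the standard probability link for
this loss; a (citation, pathogen) pair is kept when its confidence
reaches the decision threshold, and dropped — all of that pathogen's
mentions in that citation — otherwise.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Corpus
from .labeling import (
    IRRELEVANT,
    MASK_TOKEN,
    RELEVANT,
    LabeledExample,
    mask,
)
from .recognizer import Mention
from .stopwords import STOPWORDS, STOPWORDS_VERSION

# The mask token survives tokenization as a single feature token so the
# classifier can condition on the masked entity position.
_FEATURE_TOKEN_RE = re.compile(r"@PATHOGEN\$|[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


@dataclass
class TrainConfig:
    epochs: int = 10
    lambda_reg: float = 1e-4  # L2 strength
    eta0: float = 0.1  # initial learning rate of the 1/(lambda*(t+t0)) schedule
    seed: int = 42
    ngram_order: int = 1
    stopword_list: str = f"builtin-v{STOPWORDS_VERSION}"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.ngram_order not in (1, 2):
            raise ValueError("ngram_order must be 1 or 2")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")


def feature_tokens(text: str) -> list[str]:
    """Lower-cased token stream minus stop words; mask token preserved."""
    out = []
    for tok in _FEATURE_TOKEN_RE.findall(text):
        if tok == MASK_TOKEN:
            out.append(tok)
            continue
        low = tok.lower()
        if low not in STOPWORDS:
            out.append(low)
    return out


def featurize(text: str, config: TrainConfig) -> set[str]:
    """Binary n-gram presence features for ``text`` (up to ngram_order)."""
    toks = feature_tokens(text)
    feats = set(toks)
    if config.ngram_order >= 2:
        feats.update(f"{a} {b}" for a, b in zip(toks, toks[1:]))
    return feats


def modified_huber_loss(margin: float) -> float:
    """Modified Huber loss of a signed margin (continuous, convex)."""
    if margin >= -1.0:
        return max(0.0, 1.0 - margin) ** 2
    return -4.0 * margin


def _dloss_dscore(margin: float, y: float) -> float:
    """d L(y*s) / d s."""
    if margin >= 1.0:
        return 0.0
    if margin >= -1.0:
        return -2.0 * (1.0 - margin) * y
    return -4.0 * y


@dataclass
class FilterModel:
    vocabulary: dict[str, int]
    weights: np.ndarray
    bias: float
    config: TrainConfig

    def raw_score(self, text: str) -> float:
        idx = [
            self.vocabulary[f]
            for f in featurize(text, self.config)
            if f in self.vocabulary
        ]
        return float(self.weights[idx].sum() + self.bias)

    def predict(self, text: str) -> tuple[str, float]:
        conf = confidence(self.raw_score(text))
        label = RELEVANT if conf >= self.config.threshold else IRRELEVANT
        return label, conf

    # -- serialization ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        obj = {
            "vocabulary": self.vocabulary,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(obj), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "FilterModel":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            vocabulary=obj["vocabulary"],
            weights=np.asarray(obj["weights"], dtype=np.float64),
            bias=float(obj["bias"]),
            config=TrainConfig(**obj["config"]),
        )


def confidence(raw_score: float) -> float:
    """Monotone link from raw score to [0, 1]; score 0 maps to 0.5."""
    return float(np.clip((1.0 + raw_score) / 2.0, 0.0, 1.0))


def train(
    examples: Sequence[LabeledExample], config: TrainConfig | None = None
) -> FilterModel:
    """Fit the linear model by seeded SGD on the modified Huber loss.

    The learning rate follows eta_t = 1 / (lambda * (t + t0)) with t0
    chosen so that eta_0 equals ``config.eta0``; examples are shuffled
    each epoch with the configured seed; an L2 penalty of strength
    lambda is applied at every step.
    """
    config = config or TrainConfig()
    labels = {ex.label for ex in examples}
    for required in (RELEVANT, IRRELEVANT):
        if required not in labels:
            raise ValueError(f"training set has no {required!r} examples")

    vocabulary: dict[str, int] = {}
    featurized: list[np.ndarray] = []
    ys = np.empty(len(examples))
    for i, ex in enumerate(examples):
        idx = []
        for f in sorted(featurize(ex.masked_text, config)):
            if f not in vocabulary:
                vocabulary[f] = len(vocabulary)
            idx.append(vocabulary[f])
        featurized.append(np.asarray(idx, dtype=np.intp))
        ys[i] = 1.0 if ex.label == RELEVANT else -1.0

    rng = np.random.default_rng(config.seed)
    w = np.zeros(len(vocabulary))
    b = 0.0
    lam = config.lambda_reg
    t0 = 1.0 / (lam * config.eta0)
    t = 0
    order = np.arange(len(examples))
    for _ in range(config.epochs):
        rng.shuffle(order)
        for i in order:
            eta = 1.0 / (lam * (t + t0))
            idx = featurized[i]
            y = ys[i]
            s = w[idx].sum() + b
            g = _dloss_dscore(y * s, y)
            # L2 shrink on all weights, then the sparse loss update
            w *= 1.0 - eta * lam
            if g != 0.0:
                w[idx] -= eta * g
                b -= eta * g
            t += 1
    return FilterModel(vocabulary=vocabulary, weights=w, bias=b, config=config)


def predict(model: FilterModel, text: str) -> tuple[str, float]:
    return model.predict(text)


def filter_mentions(
    mentions: Sequence[Mention],
    model: FilterModel,
    corpus: Corpus,
    threshold: float | None = None,
) -> list[Mention]:
    """Drop all mentions of (citation, pathogen) pairs predicted irrelevant.

    For each pair the citation is masked for that pathogen, scored, and
    the pair's mentions retained iff the confidence reaches
    ``threshold`` (defaults to the model's trained threshold).
    """
    threshold = model.config.threshold if threshold is None else threshold
    groups: dict[tuple[str, str], list[Mention]] = {}
    for m in mentions:
        if m.pmid not in corpus:
            raise KeyError(f"mention references unknown pmid {m.pmid!r}")
        groups.setdefault((m.pmid, m.pathogen_id), []).append(m)

    retained: list[Mention] = []
    for (pmid, pathogen_id) in sorted(groups):
        masked = mask(corpus[pmid], groups[(pmid, pathogen_id)])
        if confidence(model.raw_score(masked)) >= threshold:
            retained.extend(groups[(pmid, pathogen_id)])
    retained.sort()
    return retained
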