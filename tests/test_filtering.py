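"""Featurization, modified Huber loss, SGD training and mention filtering."""

from __future__ import annotations

import random

import numpy as np
import pytest

from helpers import oracle_ngrams
from pathocite.corpus import Corpus
from pathocite.filtering import (
    FilterModel,
    TrainConfig,
    confidence,
    feature_tokens,
    featurize,
    filter_mentions,
    modified_huber_loss,
    train,
)
from pathocite.fixtures import GeneratorConfig, fixture_lexicon, generate_corpus
from pathocite.labeling import (
    IRRELEVANT,
    MASK_TOKEN,
    RELEVANT,
    LabeledExample,
    MeshLink,
    build_training_set,
)
from pathocite.recognizer import annotate_corpus, compile as compile_matcher
from pathocite.stopwords import STOPWORDS


def example(text, label, pmid="1", pid="org-1"):
    return LabeledExample(pmid=pmid, pathogen_id=pid, masked_text=text, label=label)


class TestFeaturize:
    def test_stop_words_removed(self):
        feats = featurize("the pathogen was isolated", TrainConfig(ngram_order=1))
        assert feats == {"pathogen", "isolated"}
        assert "the" in STOPWORDS and "was" in STOPWORDS

    def test_bigram_count_identity(self):
        cfg = TrainConfig(ngram_order=2)
        text = "alpha beta gamma delta epsilon"
        feats = featurize(text, cfg)
        n = len(feature_tokens(text))
        assert len(feats) == n + (n - 1)

    def test_mask_token_survives_as_single_feature(self):
        feats = featurize(f"{MASK_TOKEN} replication dynamics", TrainConfig())
        assert MASK_TOKEN in feats

    def test_empty_text_empty_vector(self):
        assert featurize("", TrainConfig()) == set()

    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_enumeration_oracle(self, order):
        rng = random.Random(6)
        vocab = ["alpha", "beta", "gamma", "delta", "kappa"]
        cfg = TrainConfig(ngram_order=order)
        for _ in range(30):
            text = " ".join(rng.choices(vocab, k=rng.randrange(0, 15)))
            toks = feature_tokens(text)
            assert featurize(text, cfg) == oracle_ngrams(toks, order)


class TestModifiedHuberLoss:
    @pytest.mark.parametrize(
        "margin,expected", [(1.0, 0.0), (0.0, 1.0), (-1.0, 4.0), (-2.0, 8.0)]
    )
    def test_reference_values(self, margin, expected):
        assert modified_huber_loss(margin) == expected

    def test_branches_agree_at_minus_one(self):
        quad = max(0.0, 1.0 - (-1.0)) ** 2
        linear = -4.0 * (-1.0)
        assert quad == linear == modified_huber_loss(-1.0)

    def test_continuity_and_convexity_on_grid(self):
        grid = np.linspace(-4, 3, 1401)
        vals = np.array([modified_huber_loss(m) for m in grid])
        # continuity: small steps give small changes
        assert np.max(np.abs(np.diff(vals))) < 0.05
        # convexity: second differences non-negative (to fp tolerance)
        assert np.min(np.diff(vals, 2)) > -1e-9
        # flat beyond the hinge point
        assert modified_huber_loss(2.5) == 0.0


class TestTrain:
    def test_separable_two_examples_perfect_accuracy(self):
        examples = [
            example("positivecue", RELEVANT),
            example("negativecue", IRRELEVANT),
        ]
        model = train(examples, TrainConfig(epochs=5))
        assert model.predict("positivecue")[0] == RELEVANT
        assert model.predict("negativecue")[0] == IRRELEVANT

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError, match="irrelevant"):
            train([example("aaa", RELEVANT), example("bbb", RELEVANT)])

    def test_same_seed_identical_weights(self, cue_examples):
        cfg = TrainConfig(seed=42, epochs=3)
        m1 = train(cue_examples[:400], cfg)
        m2 = train(cue_examples[:400], cfg)
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.bias == m2.bias
        assert m1.vocabulary == m2.vocabulary

    def test_save_load_roundtrip_identical_predictions(self, cue_examples, tmp_path):
        model = train(cue_examples[:300], TrainConfig(epochs=3))
        p = tmp_path / "model.json"
        model.save(p)
        loaded = FilterModel.load(p)
        assert np.array_equal(loaded.weights, model.weights)
        for ex in cue_examples[300:340]:
            assert loaded.predict(ex.masked_text) == model.predict(ex.masked_text)

    def test_sklearn_sgd_agrees_on_separable_cue_data(self, cue_examples):
        """Independent learner cross-check: scikit-learn's SGD with the
        same loss reaches the same predictions on held-out cue data."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.feature_extraction.text import CountVectorizer
        from sklearn.linear_model import SGDClassifier

        train_set, test_set = cue_examples[:800], cue_examples[800:1000]
        model = train(train_set, TrainConfig())
        vec = CountVectorizer(binary=True, token_pattern=r"[^\W_]+")
        X = vec.fit_transform([e.masked_text for e in train_set])
        y = [1 if e.label == RELEVANT else -1 for e in train_set]
        ref = SGDClassifier(loss="modified_huber", random_state=0).fit(X, y)
        X_test = vec.transform([e.masked_text for e in test_set])
        ref_pred = ref.predict(X_test)
        ours = [
            1 if model.predict(e.masked_text)[0] == RELEVANT else -1
            for e in test_set
        ]
        agreement = np.mean(np.asarray(ours) == ref_pred)
        assert agreement >= 0.95


class TestPredict:
    def test_all_oov_uses_bias_alone(self, cue_examples):
        model = train(cue_examples[:200], TrainConfig(epochs=3))
        _, conf = model.predict("zzzz qqqq wwww")
        assert conf == confidence(model.bias)

    def test_zero_score_confidence_half(self):
        assert confidence(0.0) == 0.5

    def test_label_consistent_with_score_sign_at_default_threshold(
        self, cue_examples
    ):
        model = train(cue_examples[:400], TrainConfig())
        rng = random.Random(8)
        for ex in rng.sample(cue_examples[400:], 50):
            label, conf = model.predict(ex.masked_text)
            score = model.raw_score(ex.masked_text)
            assert (label == RELEVANT) == (conf >= 0.5)
            if abs(score) > 1e-9:
                assert (label == RELEVANT) == (score > 0)


@pytest.fixture(scope="module")
def pipeline():
    cfg = GeneratorConfig(seed=5, n_species=4, n_citations=150)
    records, dictionary = fixture_lexicon(cfg)
    corpus, gold = generate_corpus(cfg, records, dictionary)
    matcher = compile_matcher(dictionary)
    mentions = annotate_corpus(corpus, matcher)
    link = MeshLink({r.pathogen_id: set(r.mesh_descriptors) for r in records})
    examples = build_training_set(corpus, mentions, link)
    model = train(examples, TrainConfig(epochs=5))
    return corpus, mentions, model, examples


class TestFilterMentions:
    def test_irrelevant_pair_mentions_all_removed(self, pipeline):
        corpus, mentions, model, examples = pipeline
        kept = filter_mentions(mentions, model, corpus)
        kept_pairs = {(m.pmid, m.pathogen_id) for m in kept}
        for ex in examples:
            label, _ = model.predict(ex.masked_text)
            assert ((ex.pmid, ex.pathogen_id) in kept_pairs) == (label == RELEVANT)

    def test_threshold_monotonicity(self, pipeline):
        corpus, mentions, model, _ = pipeline
        sizes = [
            len(filter_mentions(mentions, model, corpus, threshold=t))
            for t in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] == len(mentions)  # threshold 0 removes nothing

    def test_retained_equals_predict_then_drop_oracle(self, pipeline):
        corpus, mentions, model, _ = pipeline
        kept = filter_mentions(mentions, model, corpus, threshold=0.5)
        oracle = []
        groups: dict[tuple[str, str], list] = {}
        for m in mentions:
            groups.setdefault((m.pmid, m.pathogen_id), []).append(m)
        from pathocite.labeling import mask

        for pair, ms in groups.items():
            masked = mask(corpus[pair[0]], ms)
            if confidence(model.raw_score(masked)) >= 0.5:
                oracle.extend(ms)
        assert sorted(kept) == sorted(oracle)

    def test_unknown_pmid_rejected(self, pipeline):
        corpus, mentions, model, _ = pipeline
        from pathocite.recognizer import Mention

        bad = [Mention("nope", "title", 0, 4, "xxxx", "org-0001", "dictionary")]
        with pytest.raises(KeyError):
            filter_mentions(bad, model, corpus)
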