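"""Shared fixtures.

Expensive artifacts (the pre-trained language models, the fine-tuned motif
classifier) are session-scoped so the transfer-learning, ensemble and
attribution tests share one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from protlm import (
    AminoAcidVocabulary,
    ClassifierConfig,
    LMConfig,
    ProteinLanguageModel,
    SyntheticCorpusConfig,
    generate_corpus,
)
from protlm.classifier import (
    _clip_gradients,
    _iter_batches,
    build_classifier,
)
from protlm.nn import AdamW, cross_entropy_logits
from protlm.vocab import BACKWARD, tokenize

# shared study conditions: the six-family pre-training corpus and the
# cluster-held-out task corpus drawn from the same families
PRETRAIN_SEED = 100
TASK_SEED = 107


@pytest.fixture(scope="session")
def vocab():
    return AminoAcidVocabulary()


@pytest.fixture(scope="session")
def pretrain_corpus():
    return generate_corpus(
        SyntheticCorpusConfig(clusters_per_family=40, members_per_cluster=3,
                              seed=PRETRAIN_SEED)
    )


@pytest.fixture(scope="session")
def task_corpus():
    return generate_corpus(
        SyntheticCorpusConfig(clusters_per_family=20, members_per_cluster=4,
                              seed=TASK_SEED, family_seed=PRETRAIN_SEED)
    )


@pytest.fixture(scope="session")
def lm_config():
    return LMConfig(seed=0)


@pytest.fixture(scope="session")
def pretrained_lm(pretrain_corpus, lm_config, vocab):
    """Forward language model pre-trained on the six-family corpus."""
    tokens = [tokenize(r, vocab).ids for r in pretrain_corpus.records]
    return ProteinLanguageModel(tokens, lm_config, vocab).fit(epochs=20)


@pytest.fixture(scope="session")
def pretrained_lm_backward(pretrain_corpus, lm_config, vocab):
    """Backward-direction counterpart (shorter budget: ensembling only)."""
    tokens = [tokenize(r, vocab, BACKWARD).ids for r in pretrain_corpus.records]
    return ProteinLanguageModel(tokens, lm_config, vocab).fit(epochs=10)


@pytest.fixture(scope="session")
def motif_classifier(vocab):
    """Two-family classifier whose only usable signal is the implanted motif
    (composition bias off), trained to convergence; used by attribution tests.

    Returns (classifier, corpus, held-out indices).
    """
    cfg = SyntheticCorpusConfig(
        n_families=2, motifs=("DEAHW", "HIGHM"), length_range=(40, 60),
        clusters_per_family=40, members_per_cluster=3,
        family_composition_bias=0.0, mutation_rate=0.1, seed=42,
    )
    corpus = generate_corpus(cfg)
    tokens = [tokenize(r, vocab).ids for r in corpus.records]
    labels = np.array([r.labels for r in corpus.records])
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(corpus.records))
    train_idx, heldout_idx = idx[:200], idx[200:]
    lmc = LMConfig(embedding_dim=24, hidden_dim=48, seed=0)
    cc = ClassifierConfig(n_outputs=2, head_hidden=32, base_lr=5e-3, seed=0)
    clf = build_classifier(None, cc, lmc, vocab)
    clf.set_unfrozen(4)
    opt = AdamW(clf.parameters(), lr=cc.base_lr, weight_decay=1e-6)
    shuffler = np.random.default_rng(1)
    for _ in range(16):
        for ids, lengths, yb, _ in _iter_batches(
            [tokens[i] for i in train_idx], labels[train_idx],
            cc.batch_size, vocab.pad_id, shuffler,
        ):
            logits = clf.forward(ids, lengths, train=True)
            loss = cross_entropy_logits(logits, yb)
            opt.zero_grad()
            loss.backward()
            _clip_gradients(clf.parameters(), cc.grad_clip)
            opt.step()
    return clf, corpus, heldout_idx
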