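"""Shared fixtures: tiny corpora, reduced-scale models, and the (expensive)
memorization runs reused by several tests."""

from __future__ import annotations

import numpy as np
import pytest

from mode import (ATRModel, GeneratorConfig, ModelConfig, SeverityModel,
                  SummaryModel, Template, build_vocabulary, generate_corpus)
from mode.training import overfit

# deliberately small: fast to generate and train on, same schema as default
TINY_GEN = dict(n_records=24, mean_finding_len=16, mean_impression_len=10,
                mean_treatment_len=12, finding_pool=40, impression_pool=30,
                treatment_pool=30, seed=7)


@pytest.fixture(scope="session")
def tiny_cfg() -> GeneratorConfig:
    return GeneratorConfig(**TINY_GEN)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_cfg):
    return generate_corpus(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_vocab(tiny_cfg):
    return build_vocabulary(tiny_cfg)


@pytest.fixture(scope="session")
def default_corpus():
    """The full default synthetic corpus (513 records)."""
    return generate_corpus(GeneratorConfig())


@pytest.fixture(scope="session")
def overfit_runs(default_corpus):
    """Drive each templated task model to memorize a 16-record subset.

    Session-scoped because the runs take minutes; the traces and trained
    models feed both the capacity checks and the decoding tests.  Hidden
    size 64, 2 layers, shared template (8, 96, 96); constant-lr Adam.
    """
    records = default_corpus[:16]
    vocab = build_vocabulary(GeneratorConfig())
    cfg = ModelConfig(n=64, L=2, vocab=len(vocab), templated=True, dropout=0.0)
    out = {}
    settings = {"summary": (SummaryModel, 2e-3, 700, 0.004),
                "severity": (SeverityModel, 5e-4, 300, 0.005),
                "atr": (ATRModel, 5e-4, 500, 0.02)}
    for task, (cls, lr, max_steps, stop) in settings.items():
        template = Template.create(8, 96, 96, seed=42)
        model = cls(cfg, template, seed=3)
        losses = overfit(task, records, model, template, lr=lr,
                         max_steps=max_steps, stop_below=stop)
        out[task] = {"model": model, "losses": losses, "records": records,
                     "template": template}
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
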