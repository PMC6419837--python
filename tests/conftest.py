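"""Shared fixtures: toy spaces and two reference training runs.

The expensive artifacts (the enumerated toy space, a normally trained model
with per-epoch checkpoints, and an overfit-by-construction run) are built
once per session and shared across test modules.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from chemcover import chemspace as cs
from chemcover import evaluate as ev
from chemcover import idealmodel, lm, monitor
from chemcover.cli import derive_seed, split_space


@pytest.fixture(scope="session")
def toy_space() -> cs.ReferenceSpace:
    """Default toy space: exhaustive C/N/O enumeration at <=5 heavy atoms."""
    return cs.enumerate_toy_space(cs.default_filters(5))


@pytest.fixture(scope="session")
def toy_filters() -> cs.EnumerationFilters:
    return cs.default_filters(5)


@pytest.fixture(scope="session")
def toy_split(toy_space):
    return split_space(toy_space, 300, 80, seed=11)


@pytest.fixture(scope="session")
def toy_run(toy_space, toy_split, tmp_path_factory) -> lm.TrainingResult:
    """A converging training run on the toy space, checkpoints kept."""
    train_set, valid_set = toy_split
    cfg = lm.ModelConfig(epochs=40, seed=11)
    out = tmp_path_factory.mktemp("toy_run")
    return lm.train(cfg, train_set, valid_set, out_dir=out)


@pytest.fixture(scope="session")
def overfit_diagnostics(toy_space, tmp_path_factory):
    """Per-epoch diagnostics of an overfit-by-construction run.

    A tiny training set (12 molecules) and many epochs force memorization:
    the sampled set converges onto the training set while the validation set
    drifts away.
    """
    train_set, valid_set = split_space(toy_space, 12, 60, seed=13)
    cfg = lm.ModelConfig(epochs=60, seed=13)
    out = tmp_path_factory.mktemp("overfit_run")
    res = lm.train(cfg, train_set, valid_set, out_dir=out)
    mu, _ = idealmodel.uniform_nll_stats(toy_space.n)
    edges = monitor.default_bin_edges(mu)
    diags = []
    for ckpt in res.checkpoints[1::2]:
        model = lm.SmilesLM.load(ckpt)
        epoch = int(ckpt.stem.split("_")[1])
        sampled = model.sample(300, seed=derive_seed(13, "monitor", epoch))
        diags.append(
            monitor.epoch_diagnostics(
                monitor.nll_distribution(model, train_set, "training", epoch, edges),
                monitor.nll_distribution(model, valid_set, "validation", epoch, edges),
                monitor.NllDistribution(
                    "sampled", epoch, np.array([r.nll for r in sampled]), edges
                ),
            )
        )
    return diags


@pytest.fixture(scope="session")
def coverage_trajectory(toy_space, toy_run):
    """Unique coverage of k=2000 samples at every 5th checkpoint."""
    rows = []
    for ckpt in toy_run.checkpoints[4::5]:
        model = lm.SmilesLM.load(ckpt)
        epoch = int(ckpt.stem.split("_")[1])
        sample = model.sample(2000, seed=derive_seed(11, "sample", epoch))
        rep = ev.evaluate_sample(sample, toy_space, 2000)
        rows.append((epoch, rep))
    return rows
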