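"""Shared fixtures: synthetic cores, labelled patch banks and trained
networks reused across the suite (training is deterministic, so session
scope is safe)."""

from __future__ import annotations

import numpy as np
import pytest

from lgan_dcis import gan, preprocess, synthetic


def _labelled_patches(n_cores, aggressive_fraction, seed0, label,
                      core_size=256, patch_size=64):
    patches = []
    for k in range(n_cores):
        spec = synthetic.SyntheticCoreSpec(
            width=core_size, height=core_size, n_ducts=8,
            aggressive_fraction=aggressive_fraction, seed=seed0 + k)
        sample = synthetic.generate_core(spec)
        mask = preprocess.segment_tissue(sample.image)
        patches.extend(preprocess.extract_patches(
            sample.image, mask, size=patch_size, stride=patch_size,
            min_tissue=0.5, weak_label=label))
    return patches


@pytest.fixture(scope="session")
def core_sample():
    """One aggressive-heavy core with its ground-truth mask and render log."""
    spec = synthetic.SyntheticCoreSpec(width=256, height=256, n_ducts=8,
                                       aggressive_fraction=0.7, seed=7)
    return synthetic.generate_core(spec)


@pytest.fixture(scope="session")
def patch_bank():
    """Cleanly separable labelled patches (pure aggressive / pure normal
    cores) for encoder, generator and classifier tests."""
    return (_labelled_patches(22, 1.0, 1000, "aggressive")
            + _labelled_patches(22, 0.0, 2000, "non-aggressive"))


@pytest.fixture(scope="session")
def patch_bank_heldout():
    """Same construction, disjoint core seeds: a held-out evaluation set."""
    return (_labelled_patches(8, 1.0, 5000, "aggressive")
            + _labelled_patches(8, 0.0, 6000, "non-aggressive"))


@pytest.fixture(scope="session")
def trained_generator(patch_bank):
    return gan.train_generator(patch_bank, gan.GANConfig(seed=0))


@pytest.fixture(scope="session")
def trained_encoder(patch_bank):
    return gan.finetune_encoder(patch_bank, gan.EncoderConfig(seed=0))


@pytest.fixture(scope="session")
def bank_embeddings(trained_encoder, patch_bank):
    agg = [p for p in patch_bank if p.weak_label == "aggressive"]
    non = [p for p in patch_bank if p.weak_label == "non-aggressive"]
    return {
        "aggressive": trained_encoder.embed(agg),
        "non-aggressive": trained_encoder.embed(non),
    }


def labelled_patches(n_cores, aggressive_fraction, seed0, label, **kw):
    """Module-level accessor so individual tests can build small banks."""
    return _labelled_patches(n_cores, aggressive_fraction, seed0, label,
                             **kw)
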