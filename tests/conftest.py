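"""Shared fixtures: congener sets and synthetic study scenarios.

Everything is generated programmatically; session scope keeps the expensive
objects (the 1,701-congener enumeration, default descriptor tables) shared
across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import nanoqspr.congeners as cg
import nanoqspr.generator as gen
from nanoqspr.selection import autoscale, kennard_stone, split_train_validation

TRUE_DESCRIPTORS = ["nH", "TE", "Dx", "Dy"]


@pytest.fixture(scope="session")
def group():
    return cg.dioxin_symmetry_group()


@pytest.fixture(scope="session")
def all_congeners(group):
    return cg.enumerate_congeners(group)


@pytest.fixture(scope="session")
def default_table(all_congeners):
    """Default-parameter descriptor table with ground-truth energies, seed 0."""
    params = gen.GeneratorParams(seed=0)
    table = gen.generate_descriptor_table(all_congeners, params)
    records = gen.generate_adsorption_energies(table, params)
    return gen.attach_energies(table, records)


def make_study(states, noise_sd, data_seed, subset_size=32, n_val=8):
    """Generate a table, KS-select and split - one synthetic 'study'."""
    params = gen.GeneratorParams(noise_sd=noise_sd, seed=data_seed)
    table = gen.generate_descriptor_table(states, params)
    table = gen.attach_energies(table, gen.generate_adsorption_energies(table, params))
    desc = [c for c in table.columns if c in gen.ALL_DESCRIPTORS]
    Xs, means, sds = autoscale(table[desc])
    picked = [int(table["index"].iloc[r]) for r in kennard_stone(Xs, subset_size)]
    split = split_train_validation(
        picked, n_val, n_total=len(table), scaling_means=means, scaling_sds=sds
    )
    train = table[table["index"].isin(split.training_indices)]
    val = table[table["index"].isin(split.validation_indices)]
    return table, split, train, val, params


@pytest.fixture(scope="session")
def noiseless_study(all_congeners):
    """Zero-noise scenario: the ground truth is exactly linear."""
    return make_study(all_congeners, noise_sd=0.0, data_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
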