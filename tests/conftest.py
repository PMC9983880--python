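"""Shared fixtures: synthetic bundles and assembled design tables.

Session-scoped because bundle generation refits ~1200 dose-response curves;
every test that mutates a fixture must copy it first.
"""

from __future__ import annotations

import logging

import pytest

import kinoviab as kv

logging.getLogger("kinoviab").setLevel(logging.ERROR)


def build_table(bundle, cfg, classes=("expression",)):
    """Standard pipeline: densify -> impute gaps -> truncate -> growth filter
    -> impute viability -> prefix omics -> assemble."""
    profile = kv.densify_inhibition(bundle.inhibition_records, cfg.compounds,
                                    cfg.proteins, cfg.dose_grid)
    profile = kv.impute_missing_concentrations(profile)
    profile, _ = kv.truncate_outliers(profile)
    kept, _ = kv.filter_growth_enhancing(bundle.dose_response, cfg.dose_grid)
    viability = kv.impute_viability(kept, cfg.dose_grid)
    omics = kv.prefix_features({c: bundle.omics[c] for c in classes})
    table = kv.assemble_design(viability, profile, omics, classes=classes)
    return table, profile, viability


@pytest.fixture(scope="session")
def default_config():
    """The pinned study conditions: 40 lines x 30 compounds x 8 doses."""
    return kv.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    return kv.generate_bundle(default_config)


@pytest.fixture(scope="session")
def default_table(default_bundle, default_config):
    table, profile, viability = build_table(default_bundle, default_config)
    return table


@pytest.fixture(scope="session")
def default_folds(default_table):
    combos = sorted(set(zip(default_table["cell_line"],
                            default_table["compound"])))
    return kv.make_group_folds(combos, n_folds=10, seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A fast configuration for unit tests that refit models."""
    return kv.SyntheticConfig(n_cell_lines=12, n_compounds=8, n_proteins=30,
                              n_genes=60, targets_per_compound=2,
                              n_driver_genes=2, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return kv.generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_table(small_bundle, small_config):
    table, profile, viability = build_table(small_bundle, small_config)
    return table


@pytest.fixture(scope="session")
def small_folds(small_table):
    combos = sorted(set(zip(small_table["cell_line"],
                            small_table["compound"])))
    return kv.make_group_folds(combos, n_folds=5, seed=7)
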