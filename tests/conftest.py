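"""Shared fixtures: hand-buildable tables and planted simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from diffmet import qc, synth
from diffmet.datatypes import FeatureTable


def make_table(values, sample_ann=None, snr=None, column="C18", feature_ids=None):
    """Build a FeatureTable from a 2-D array (features x samples)."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    fids = feature_ids or [f"F{i + 1:04d}" for i in range(p)]
    sids = [f"S{j + 1:03d}" for j in range(n)]
    features = pd.DataFrame(
        {
            "mz": np.linspace(100, 900, p),
            "rt": np.linspace(30, 600, p),
            "column": [column] * p if isinstance(column, str) else list(column),
            "snr": [20.0] * p if snr is None else list(snr),
        },
        index=pd.Index(fids, name="feature_id"),
    )
    if sample_ann is None:
        sample_ann = pd.DataFrame(index=pd.Index(sids, name="sample_id"))
        sample_ann["sex"] = ["male" if j % 2 == 0 else "female" for j in range(n)]
        sample_ann["biological_id"] = sids
    else:
        sample_ann = sample_ann.copy()
        sample_ann.index = pd.Index(sids[: len(sample_ann)], name="sample_id")
    intens = pd.DataFrame(values, index=features.index, columns=sample_ann.index)
    return FeatureTable(intens, features, sample_ann)


@pytest.fixture
def table_factory():
    return make_table


def two_condition_design(n_per_condition=30, duplicates=1):
    """Minimal design with two developmental-temperature conditions."""
    spec = synth.DesignSpec(
        genotypes=("G1",),
        sexes=("female",),
        temperature_groups=((18, 18), (27, 27)),
        biological_replicates=n_per_condition,
        technical_duplicates=duplicates,
    )
    return synth.generate_design(spec)


def planted_network_table(seed=7, n_background=200, n_per_condition=30):
    """One plastic (r 0.8 vs 0) + one preserved (r 0.8/0.8) 20-feature
    module over independent background; log scale, collapsed.

    Returns (table, plastic_ids, preserved_ids).
    """
    design = two_condition_design(n_per_condition)
    mods = [
        synth.ModulePlantSpec(20, 0.8, 0.0, label="plastic", name="plastic"),
        synth.ModulePlantSpec(20, 0.8, 0.8, label="preserved", name="preserved"),
    ]
    table = synth.generate_table(
        design,
        n_features=40 + n_background,
        modules=mods,
        noise_sd=0.0,
        missing_rate=0.0,
        columns=("C18",),
        seed=seed,
    )
    table = qc.collapse_replicates(qc.log_transform(table))
    plastic = [f"F{i:04d}" for i in range(1, 21)]
    preserved = [f"F{i:04d}" for i in range(21, 41)]
    return table, plastic, preserved


@pytest.fixture(scope="session")
def planted_network():
    return planted_network_table()
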