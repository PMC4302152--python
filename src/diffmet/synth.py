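"""Synthetic LC-MS feature tables with planted network structure.

Emulates a factorial fly-metabolomics design: inbred genotypes crossed
with sex and with a developmental/adult temperature regime (18 °C or
27 °C at each stage), biological replicates measured as technical
duplicates on two chromatography columns (C18 and AE). Intensities are
log-normal; selected groups of features ("planted modules") share a
latent factor whose loading can differ between the two developmental
temperatures, producing condition-dependent ("plastic") or
condition-invariant ("preserved") correlation structure for the network
stages to detect. Mean shifts tied to design factors give the
differential-abundance stage something to find.

The generator is fully deterministic given its seed, so every other
module of the package can be exercised end to end without external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import FeatureTable

DEFAULT_GENOTYPES = ("DGRP-25180", "DGRP-25184", "DGRP-25189", "DGRP-25198")
DEFAULT_SEXES = ("male", "female")
#: (developmental temperature, adult temperature) in °C
DEFAULT_TEMPERATURE_GROUPS = ((18, 18), (18, 27), (27, 18), (27, 27))


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class DesignSpec:
    """Experimental design: which samples exist.

    ``drop_samples`` removes one biological replicate per listed cell;
    each entry is a dict of factor values identifying the cell (partial
    keys allowed, e.g. ``{"genotype": "DGRP-25189"}`` drops a replicate
    from the first matching cell). This mirrors studies in which one
    genotype contributes one sample fewer than the full factorial.
    """

    genotypes: Sequence[str] = DEFAULT_GENOTYPES
    sexes: Sequence[str] = DEFAULT_SEXES
    temperature_groups: Sequence[tuple[int, int]] = DEFAULT_TEMPERATURE_GROUPS
    biological_replicates: int = 3
    technical_duplicates: int = 2
    drop_samples: Sequence[dict] = ()

    def __post_init__(self) -> None:
        for name in ("genotypes", "sexes", "temperature_groups"):
            if len(getattr(self, name)) == 0:
                raise ConfigurationError(f"{name} must not be empty")
        if self.biological_replicates < 1 or self.technical_duplicates < 1:
            raise ConfigurationError("replicate counts must be >= 1")


@dataclass
class ModulePlantSpec:
    """A block of features sharing a latent factor.

    ``r_cond1``/``r_cond2`` are the target pairwise correlations under
    the two levels of the condition factor (sorted order, so 18 °C then
    27 °C by default). A *preserved* module has equal, high targets; a
    *plastic* module has very different targets. Targets must lie in
    [0, 1]: a common negative pairwise correlation is not realisable for
    more than two features (the implied correlation matrix would not be
    positive semi-definite).
    """

    size: int
    r_cond1: float
    r_cond2: float
    label: str = "plastic"
    column: str = "C18"
    name: Optional[str] = None

    def __post_init__(self) -> None:
        for r in (self.r_cond1, self.r_cond2):
            if not -1.0 <= r <= 1.0:
                raise ConfigurationError(f"correlation target {r} outside [-1, 1]")
            if r < 0:
                raise ConfigurationError(
                    "negative within-module correlation targets are not realisable "
                    "for modules of more than two features"
                )
        if self.size < 2:
            raise ConfigurationError("module size must be >= 2")


@dataclass
class EffectSpec:
    """A planted mean shift on one design factor.

    ``shift`` is in log-intensity SD units (biological noise has unit
    SD). The shift is added to samples at ``level`` of ``factor``; if
    ``level`` is None the highest sorted level is used (e.g. 27 °C for a
    temperature factor). ``features`` may be feature ids (``"F0042"``)
    or integer positions.
    """

    factor: str
    features: Sequence
    shift: float
    level: Optional[object] = None


def generate_design(spec: DesignSpec, seed: int = 0) -> pd.DataFrame:
    """Expand a :class:`DesignSpec` into a technical-replicate annotation table.

    Returns a DataFrame with one row per technical replicate, indexed by
    technical sample id, with columns ``biological_id``, ``genotype``,
    ``sex``, ``dev_temp``, ``adult_temp``, ``replicate``, ``tech_rep``.
    The layout is a deterministic function of the spec; ``seed`` is
    accepted for interface symmetry with :func:`generate_table`.
    """
    del seed  # layout is combinatorial, nothing to draw
    cells = list(
        itertools.product(spec.genotypes, spec.sexes, spec.temperature_groups)
    )
    # replicate ranges per cell, after applying drops
    reps_per_cell = {cell: spec.biological_replicates for cell in cells}
    for drop in spec.drop_samples:
        matched = False
        for geno, sex, (dev, adult) in cells:
            cell = (geno, sex, (dev, adult))
            values = {"genotype": geno, "sex": sex, "dev_temp": dev, "adult_temp": adult}
            if all(values.get(k) == v for k, v in drop.items()) and reps_per_cell[cell] > 0:
                reps_per_cell[cell] -= 1
                matched = True
                break
        if not matched:
            raise ConfigurationError(f"drop_samples entry matches no cell: {drop!r}")

    rows = []
    for geno, sex, (dev, adult) in cells:
        for rep in range(1, reps_per_cell[(geno, sex, (dev, adult))] + 1):
            bio_id = f"{geno}_{sex}_{dev}to{adult}_r{rep}"
            for tech in range(1, spec.technical_duplicates + 1):
                rows.append(
                    {
                        "sample_id": f"{bio_id}_t{tech}",
                        "biological_id": bio_id,
                        "genotype": geno,
                        "sex": sex,
                        "dev_temp": dev,
                        "adult_temp": adult,
                        "replicate": rep,
                        "tech_rep": tech,
                    }
                )
    design = pd.DataFrame(rows).set_index("sample_id")
    return design


def generate_table(
    design: pd.DataFrame,
    n_features: int = 200,
    modules: Sequence[ModulePlantSpec] = (),
    effects: Sequence[EffectSpec] = (),
    noise_sd: float = 0.2,
    missing_rate: float = 0.003,
    snr_range: tuple[float, float] = (5.0, 60.0),
    condition_factor: str = "dev_temp",
    columns: Sequence[str] = ("C18", "AE"),
    seed: int = 0,
) -> FeatureTable:
    """Simulate raw (linear-scale) intensities for a design.

    Biological log2 intensities follow ``mu_f + x_fs`` where ``x`` is a
    unit-variance deviation: for a planted module, a single-latent-factor
    model ``x = lambda * z + sqrt(1 - lambda^2) * eps`` with ``z`` shared
    by all module features of a sample and loading
    ``lambda = sqrt(r_cond)`` chosen from the sample's level of
    ``condition_factor``, giving exact expected pairwise correlation
    ``r_cond``; background features are independent noise. Mean shifts
    from ``effects`` are added in SD units, technical replicates add
    independent N(0, noise_sd) noise, cells go missing completely at
    random at ``missing_rate``, and each feature receives a
    signal-to-noise ratio drawn uniformly from ``snr_range`` as metadata.
    """
    if not 0 <= missing_rate < 1:
        raise ConfigurationError("missing_rate must be in [0, 1)")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    total_planted = sum(m.size for m in modules)
    if total_planted > n_features:
        raise ConfigurationError(
            f"planted module sizes sum to {total_planted} > n_features={n_features}"
        )

    rng = np.random.default_rng(seed)
    bio = design.drop_duplicates("biological_id").set_index("biological_id")
    n_bio = len(bio)
    feature_ids = [f"F{i + 1:04d}" for i in range(n_features)]

    cond = bio[condition_factor].to_numpy()
    levels = sorted(pd.unique(cond))
    if modules and len(levels) != 2:
        raise ConfigurationError(
            f"condition factor {condition_factor!r} must have exactly 2 levels "
            f"to plant per-condition correlations (found {len(levels)})"
        )

    # unit-variance biological deviations
    x = rng.standard_normal((n_features, n_bio))
    planted = np.array([""] * n_features, dtype=object)
    feat_column = np.empty(n_features, dtype=object)
    pos = 0
    for i, m in enumerate(modules):
        rows = slice(pos, pos + m.size)
        r_by_level = {levels[0]: m.r_cond1, levels[1]: m.r_cond2}
        lam = np.sqrt([r_by_level[c] for c in cond])  # per biological sample
        z = rng.standard_normal(n_bio)
        eps = rng.standard_normal((m.size, n_bio))
        x[rows] = lam * z + np.sqrt(1.0 - lam**2) * eps
        name = m.name or f"{m.label}{i + 1}"
        planted[rows] = name
        feat_column[rows] = m.column
        pos += m.size
    # background features alternate across chromatography columns
    for j in range(pos, n_features):
        feat_column[j] = columns[(j - pos) % len(columns)]

    mu = rng.uniform(14.0, 22.0, size=n_features)
    log_bio = mu[:, None] + x

    id_to_pos = {fid: i for i, fid in enumerate(feature_ids)}
    for e in effects:
        if e.factor not in bio.columns:
            raise ConfigurationError(f"effect factor {e.factor!r} not in design")
        level = e.level
        if level is None:
            level = sorted(pd.unique(bio[e.factor]))[-1]
        col_mask = (bio[e.factor] == level).to_numpy()
        if not col_mask.any():
            raise ConfigurationError(f"effect level {level!r} absent from factor {e.factor!r}")
        for f in e.features:
            idx = f if isinstance(f, (int, np.integer)) else id_to_pos.get(f)
            if idx is None or not 0 <= idx < n_features:
                raise ConfigurationError(f"effect feature {f!r} not in table")
            log_bio[idx, col_mask] += e.shift

    # technical replicates: biological value + independent technical noise
    bio_pos = {b: i for i, b in enumerate(bio.index)}
    cols = [bio_pos[b] for b in design["biological_id"]]
    log_tech = log_bio[:, cols] + rng.normal(0.0, noise_sd, size=(n_features, len(design)))
    raw = np.power(2.0, log_tech)

    if missing_rate > 0:
        raw[rng.random(raw.shape) < missing_rate] = np.nan

    features = pd.DataFrame(
        {
            "mz": rng.uniform(85.0, 1250.0, size=n_features),
            "rt": rng.uniform(15.0, 900.0, size=n_features),
            "column": feat_column,
            "snr": rng.uniform(snr_range[0], snr_range[1], size=n_features),
            "planted": planted,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    intensities = pd.DataFrame(raw, index=features.index, columns=design.index)
    return FeatureTable(intensities, features, design.copy())
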