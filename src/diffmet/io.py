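"""TSV readers/writers for feature tables and analysis outputs.

A feature table is stored as two files: ``<stem>.tsv`` holding feature
metadata plus intensities (one row per feature, first columns mz / rt /
column / snr and any extra metadata, then one column per sample) and
``<stem>.samples.tsv`` holding the sample annotations. Missing cells are
written as empty strings — unambiguous against true zeros — and parsed
back to NaN, so a write/read round trip is lossless.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datatypes import REQUIRED_FEATURE_COLS, FeatureTable, SchemaError


def _samples_path(path: Path) -> Path:
    return path.with_name(path.stem + ".samples" + path.suffix)


def write_feature_table(table: FeatureTable, path) -> tuple[Path, Path]:
    """Write a table to ``path`` and its annotations next to it."""
    path = Path(path)
    spath = _samples_path(path)
    joint = pd.concat([table.features, table.intensities], axis=1)
    joint.index.name = "feature_id"
    # shortest round-trippable float representation keeps the file lossless
    joint.to_csv(path, sep="\t", na_rep="", float_format=lambda x: repr(float(x)))
    samples = table.samples.copy()
    samples.index.name = "sample_id"
    samples.to_csv(spath, sep="\t", na_rep="")
    return path, spath


def read_feature_table(path, samples_path=None) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    spath = Path(samples_path) if samples_path else _samples_path(path)
    if not spath.exists():
        raise SchemaError(f"sample annotation file not found: {spath}")
    samples = pd.read_csv(
        spath, sep="\t", index_col=0, keep_default_na=False, na_values=[""]
    )
    joint = pd.read_csv(
        path, sep="\t", index_col=0, keep_default_na=False, na_values=[""],
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_FEATURE_COLS if c not in joint.columns]
    if missing:
        raise SchemaError(f"feature table lacks required column(s): {', '.join(missing)}")
    sample_cols = [c for c in joint.columns if c in set(samples.index)]
    meta_cols = [c for c in joint.columns if c not in set(samples.index)]
    if set(sample_cols) != set(samples.index):
        absent = sorted(set(samples.index) - set(sample_cols))
        raise SchemaError(f"intensity columns missing for annotated sample(s): {absent[:3]}")
    samples.index.name = "sample_id"
    features = joint[meta_cols].copy()
    features.index.name = "feature_id"
    if "planted" in features.columns:
        features["planted"] = features["planted"].fillna("").astype(str)
    intensities = joint[list(samples.index)].astype(float)
    intensities.index.name = "feature_id"
    intensities.columns = samples.index
    return FeatureTable(intensities, features, samples)


def load_config(path) -> dict:
    """Load a (possibly nested) YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="")
    return path
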