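"""Quality control for LC-MS feature tables.

Fixed stage order: signal-to-noise filter, log transform, per-group
missingness filter, imputation of the (by then sparse) missing cells,
and collapsing of technical replicates into biological samples. The two
filters are idempotent; feature counts never increase through the
pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FeatureTable

log = logging.getLogger(__name__)


class DataError(ValueError):
    """Input data violates a QC precondition."""


class ConfigurationError(ValueError):
    pass


@dataclass
class QCParams:
    """QC thresholds. Defaults: SNR >= 14, drop features missing from
    more than 5% of either sex's samples, log base 2."""

    snr_min: float = 14.0
    max_missing_frac: float = 0.05
    grouping: str = "sex"
    log_base: float = 2.0
    impute_seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_min < 0:
            raise ConfigurationError("snr_min must be >= 0")
        if not 0 <= self.max_missing_frac <= 1:
            raise ConfigurationError("max_missing_frac must be in [0, 1]")


def filter_snr(table: FeatureTable, snr_min: float = 14.0) -> FeatureTable:
    """Keep features with signal-to-noise ratio >= ``snr_min`` (inclusive)."""
    snr = table.features["snr"]
    if snr.isna().any():
        bad = snr.index[snr.isna()][0]
        raise DataError(f"feature {bad!r} has no SNR value")
    keep = table.features.index[snr >= snr_min]
    return table.subset_features(keep)


def log_transform(table: FeatureTable, base: float = 2.0) -> FeatureTable:
    """Elementwise log of intensities; missing cells stay missing."""
    vals = table.intensities.to_numpy(dtype=float)
    nonpos = (vals <= 0) & ~np.isnan(vals)
    if nonpos.any():
        i, j = np.argwhere(nonpos)[0]
        raise DataError(
            f"non-positive intensity for feature {table.feature_ids[i]!r} "
            f"in sample {table.sample_ids[j]!r}"
        )
    out = table.copy()
    with np.errstate(invalid="ignore"):
        out.intensities = pd.DataFrame(
            np.log(vals) / np.log(base),
            index=table.intensities.index,
            columns=table.intensities.columns,
        )
    return out


def filter_missingness(
    table: FeatureTable, max_frac: float = 0.05, grouping: str = "sex"
) -> FeatureTable:
    """Drop features missing from more than ``max_frac`` of any group's samples.

    Groups are the levels of ``grouping`` in the sample annotations (by
    default sex, so a feature is dropped if missing from more than 5% of
    male *or* more than 5% of female samples).
    """
    if grouping not in table.samples.columns:
        raise ConfigurationError(f"grouping factor {grouping!r} not in sample annotations")
    miss = table.intensities.isna()
    drop = pd.Series(False, index=table.features.index)
    for level, ann in table.samples.groupby(grouping, sort=True):
        if len(ann) == 0:  # pragma: no cover - groupby never yields empty groups
            raise ConfigurationError(f"group {level!r} has zero samples")
        frac = miss.loc[:, ann.index].mean(axis=1)
        drop |= frac > max_frac
    out = table.subset_features(table.features.index[~drop])
    log.info(
        "missingness filter: kept %d/%d features; residual missing fraction %.4f%%",
        out.n_features,
        table.n_features,
        100 * out.missing_fraction(),
    )
    return out


def impute(
    table: FeatureTable,
    seed: int = 0,
    k: int = 5,
    ridge: float = 1e-6,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> FeatureTable:
    """Fill missing cells by EM-style iterative local regression.

    Missing cells are initialised with feature means, then each
    incomplete feature is repeatedly regressed (ridge-stabilised least
    squares, intercept included) on its ``k`` most-correlated other
    features, the regression being fitted on the samples where the
    feature is observed and used to re-predict its missing cells, until
    the largest change falls below ``tol`` or ``max_iter`` sweeps.
    Observed cells are never altered. The algorithm is deterministic;
    ``seed`` is part of the interface for forward compatibility.
    """
    del seed
    X = table.intensities.to_numpy(dtype=float).copy()
    mask = np.isnan(X)
    if not mask.any():
        return table.copy()
    all_missing = mask.all(axis=1)
    if all_missing.any():
        fid = table.feature_ids[int(np.argmax(all_missing))]
        raise DataError(f"feature {fid!r} has no observed cells; cannot impute")
    frac = mask.mean()
    if frac > 0.05:
        warnings.warn(
            f"imputing {100 * frac:.1f}% missing cells; imputation is intended "
            "for residual (<5%) missingness after filtering",
            stacklevel=2,
        )

    # initialise with feature means
    row_means = np.nanmean(np.where(mask, np.nan, X), axis=1)
    X[mask] = np.broadcast_to(row_means[:, None], X.shape)[mask]

    incomplete = np.flatnonzero(mask.any(axis=1))
    n = X.shape[1]
    for _ in range(max_iter):
        # rank candidate predictors on the current filled matrix
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X)
        corr = np.nan_to_num(corr, nan=0.0)
        delta = 0.0
        for f in incomplete:
            obs = ~mask[f]
            order = np.argsort(-np.abs(corr[f]))
            predictors = [j for j in order if j != f][:k]
            if not predictors:
                continue
            P = X[predictors][:, obs].T  # (n_obs, k)
            A = np.column_stack([np.ones(obs.sum()), P])
            # ridge on slopes only, to stabilise collinear predictors
            reg = ridge * np.eye(A.shape[1])
            reg[0, 0] = 0.0
            coef = np.linalg.solve(A.T @ A + reg, A.T @ X[f, obs])
            Pm = X[predictors][:, mask[f]].T
            pred = coef[0] + Pm @ coef[1:]
            delta = max(delta, float(np.max(np.abs(pred - X[f, mask[f]]), initial=0.0)))
            X[f, mask[f]] = pred
        if delta < tol:
            break

    out = table.copy()
    out.intensities = pd.DataFrame(
        X, index=table.intensities.index, columns=table.intensities.columns
    )
    return out


def collapse_replicates(table: FeatureTable) -> FeatureTable:
    """Average technical replicates into one column per biological sample.

    Values are arithmetic means on the (post-log) scale. Sample
    annotations collapse to one row per biological sample; the
    ``tech_rep`` column is dropped.
    """
    if "biological_id" not in table.samples.columns:
        raise DataError("sample annotations lack a 'biological_id' column")
    bio = table.samples["biological_id"]
    if bio.isna().any() or (bio.astype(str) == "").any():
        orphan = table.samples.index[bio.isna() | (bio.astype(str) == "")][0]
        raise DataError(f"technical sample {orphan!r} has no biological id")

    order = list(dict.fromkeys(bio))  # first-appearance order
    grouped = table.intensities.T.groupby(bio, sort=False).mean().T
    grouped = grouped.loc[:, order]
    ann = (
        table.samples.drop(columns=["tech_rep"], errors="ignore")
        .groupby(bio, sort=False)
        .first()
        .loc[order]
    )
    ann.index.name = "sample_id"
    grouped.columns = ann.index
    return FeatureTable(grouped, table.features.copy(), ann)


def apply_qc(table: FeatureTable, params: QCParams | None = None) -> tuple[FeatureTable, dict]:
    """Run the full QC pipeline; returns the collapsed table and stage counts."""
    params = params or QCParams()
    counts = {"input_features": table.n_features, "input_samples": table.n_samples}
    t = filter_snr(table, params.snr_min)
    counts["after_snr_filter"] = t.n_features
    t = log_transform(t, params.log_base)
    t = filter_missingness(t, params.max_missing_frac, params.grouping)
    counts["after_missingness_filter"] = t.n_features
    counts["residual_missing_frac"] = t.missing_fraction()
    t = impute(t, seed=params.impute_seed)
    t = collapse_replicates(t)
    counts["biological_samples"] = t.n_samples
    return t, counts
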