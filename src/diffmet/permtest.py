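"""Permutation significance for differential and preserved modules.

The dispersion statistic of a module M between two conditions is the
root-mean-square half correlation difference over its pairs,

    d(M) = sqrt( mean_{i<j in M} ((r_ij,1 - r_ij,2) / 2)^2 ),

and analogously over cross pairs for a pair of modules. Differential
significance shuffles the condition labels across samples (preserving
group sizes), recomputes both correlation matrices and the statistic,
and reports the plus-one upper-tail p-value over (by default) 1000
permutations.

Label shuffling cannot serve as a null for *preservation*: mixing the
two conditions makes every module's correlation structure trivially
similar between the shuffled "conditions". Preserved modules are
therefore tested against a random-feature-set null: the observed mean
within-module similarity S is compared with the same statistic on
randomly drawn feature sets of equal size.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CorrelationMatrix,
    DispersionResult,
    FeatureTable,
    ModuleAssignment,
    SimilarityMatrix,
)


class ConfigurationError(ValueError):
    pass


def _indices(features: Sequence[str], members: Sequence) -> np.ndarray:
    if len(members) and isinstance(next(iter(members)), (int, np.integer)):
        return np.asarray(list(members), dtype=int)
    pos = {f: i for i, f in enumerate(features)}
    try:
        return np.asarray([pos[m] for m in members], dtype=int)
    except KeyError as e:  # pragma: no cover - defensive
        raise ConfigurationError(f"module member {e.args[0]!r} not in matrix") from None


def _dispersion_within(R1: np.ndarray, R2: np.ndarray, idx: np.ndarray) -> float:
    sub = ((R1[np.ix_(idx, idx)] - R2[np.ix_(idx, idx)]) / 2.0) ** 2
    iu, ju = np.triu_indices(len(idx), k=1)
    return float(np.sqrt(sub[iu, ju].mean()))


def _dispersion_cross(
    R1: np.ndarray, R2: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
) -> float:
    sub = ((R1[np.ix_(idx1, idx2)] - R2[np.ix_(idx1, idx2)]) / 2.0) ** 2
    return float(np.sqrt(sub.mean()))


def module_dispersion(C1: CorrelationMatrix, C2: CorrelationMatrix, members) -> float:
    """Dispersion d of one module between two conditions."""
    idx = _indices(C1.features, members)
    if len(idx) < 2:
        raise ConfigurationError("module dispersion needs at least 2 members")
    return _dispersion_within(C1.values, C2.values, idx)


def cross_module_dispersion(
    C1: CorrelationMatrix, C2: CorrelationMatrix, members1, members2
) -> float:
    """Dispersion over all cross pairs of two disjoint modules."""
    idx1 = _indices(C1.features, members1)
    idx2 = _indices(C1.features, members2)
    if len(idx1) == 0 or len(idx2) == 0:
        raise ConfigurationError("module pair members must be nonempty")
    if set(idx1) & set(idx2):
        raise ConfigurationError("module pair members must be disjoint")
    return _dispersion_cross(C1.values, C2.values, idx1, idx2)


def _plus_one_p(perm_stats: np.ndarray, observed: float) -> float:
    return (1 + int((perm_stats >= observed).sum())) / (1 + len(perm_stats))


def permutation_pvalues(
    table: FeatureTable,
    condition,
    modules,
    n_perm: int = 1000,
    seed: int = 0,
    include_pairs: bool = True,
) -> list[DispersionResult]:
    """Permutation p-values for every module (and module pair).

    ``condition`` is a sample-annotation column with exactly two levels,
    or an explicit per-sample label array. ``modules`` is a
    :class:`ModuleAssignment` or a mapping label -> member feature ids.
    Each permutation shuffles the condition labels across samples
    (group sizes preserved), recomputes the two correlation matrices and
    every statistic; p = (1 + #{d_perm >= d_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if isinstance(modules, ModuleAssignment):
        module_map = modules.modules()
    else:
        module_map = {k: list(v) for k, v in dict(modules).items()}
    if not module_map:
        return []

    if isinstance(condition, str):
        labels = table.samples[condition].to_numpy()
    else:
        labels = np.asarray(condition)
        if len(labels) != table.n_samples:
            raise ConfigurationError("condition labels do not match sample count")
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ConfigurationError(f"condition must have exactly 2 levels, found {len(levels)}")
    g1 = labels == levels[0]
    if g1.sum() < 4 or (~g1).sum() < 4:
        raise ConfigurationError("each condition group needs at least 4 samples")

    # restrict to the features any module uses
    used = sorted({f for ids in module_map.values() for f in ids})
    sub = table.subset_features(used)
    X = sub.intensities.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ConfigurationError("intensities contain missing values; impute first")
    feat = sub.feature_ids
    idx_map = {lab: _indices(feat, ids) for lab, ids in module_map.items()}
    pairs = []
    if include_pairs:
        labs = sorted(module_map)
        pairs = [(a, b) for i, a in enumerate(labs) for b in labs[i + 1 :]]

    def stats_for(mask: np.ndarray) -> dict:
        R1 = np.corrcoef(X[:, mask])
        R2 = np.corrcoef(X[:, ~mask])
        out = {lab: _dispersion_within(R1, R2, idx) for lab, idx in idx_map.items()}
        for a, b in pairs:
            out[(a, b)] = _dispersion_cross(R1, R2, idx_map[a], idx_map[b])
        return out

    observed = stats_for(g1)
    rng = np.random.default_rng(seed)
    perm = {key: np.empty(n_perm) for key in observed}
    for t in range(n_perm):
        shuffled = g1[rng.permutation(len(g1))]
        for key, val in stats_for(shuffled).items():
            perm[key][t] = val

    results = []
    for key, obs in observed.items():
        kind = "differential_pair" if isinstance(key, tuple) else "differential"
        results.append(
            DispersionResult(
                module=key,
                statistic=obs,
                p_value=_plus_one_p(perm[key], obs),
                n_permutations=n_perm,
                seed=seed,
                kind=kind,
            )
        )
    return results


def mean_module_similarity(S: SimilarityMatrix | np.ndarray, members, features=None) -> float:
    """Mean off-diagonal similarity within a feature set."""
    if isinstance(S, SimilarityMatrix):
        values, feats = S.values, S.features
    else:
        values, feats = np.asarray(S, dtype=float), features
    idx = _indices(feats, members)
    if len(idx) < 2:
        raise ConfigurationError("need at least 2 members")
    sub = values[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(idx), k=1)
    return float(sub[iu, ju].mean())


def preserved_significance(
    S: SimilarityMatrix,
    members,
    n_random_sets: int = 1000,
    seed: int = 0,
) -> DispersionResult:
    """Random-feature-set test of one module's preservation.

    The observed mean within-module similarity is compared against the
    same statistic on ``n_random_sets`` feature sets of equal size drawn
    uniformly (without replacement within a set) from all analysed
    features; p uses the plus-one rule.
    """
    if n_random_sets < 1:
        raise ConfigurationError("n_random_sets must be >= 1")
    idx = _indices(S.features, members)
    n = len(S.features)
    if len(idx) < 2:
        raise ConfigurationError("module must have at least 2 members")
    if len(idx) >= n:
        raise ConfigurationError("module must be smaller than the analysed feature set")
    observed = mean_module_similarity(S, members)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(len(idx), k=1)
    null = np.empty(n_random_sets)
    for t in range(n_random_sets):
        pick = rng.choice(n, size=len(idx), replace=False)
        null[t] = S.values[np.ix_(pick, pick)][iu, ju].mean()
    return DispersionResult(
        module=tuple(members) if not isinstance(members, str) else members,
        statistic=observed,
        p_value=_plus_one_p(null, observed),
        n_permutations=n_random_sets,
        seed=seed,
        kind="preserved",
    )


def preserved_pvalues(
    S: SimilarityMatrix,
    modules,
    n_random_sets: int = 1000,
    seed: int = 0,
) -> list[DispersionResult]:
    """Preservation test for every module in an assignment."""
    if isinstance(modules, ModuleAssignment):
        module_map = modules.modules()
    else:
        module_map = {k: list(v) for k, v in dict(modules).items()}
    results = []
    for i, (lab, ids) in enumerate(sorted(module_map.items())):
        res = preserved_significance(S, ids, n_random_sets, seed=seed + i)
        res.module = lab
        results.append(res)
    return results
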