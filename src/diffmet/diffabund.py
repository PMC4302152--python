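"""Per-metabolite fixed-effects linear models.

Each feature's (QC'd, collapsed, log-scale) intensity is modelled as

    y = mu + L + A + G + L:A + L:G + A:G + eps

with developmental temperature L, adult temperature A and genotype G as
categorical fixed effects and all pairwise interactions. Sexes are
analysed separately. Per-factor F tests use Type II sums of squares
(model-comparison based, invariant to factor order in this near-balanced
design); interactions can also be tested by a Gaussian likelihood-ratio
test. Multiplicity across features is controlled by Benjamini-Hochberg
FDR, by default at q = 0.01.

Fits are vectorised across features: the design matrix is shared, so all
residual sums of squares come from a handful of QR projections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import FeatureTable

DEFAULT_FACTORS = ("dev_temp", "adult_temp", "genotype")
_RSS_TOL = 1e-10


class ConfigurationError(ValueError):
    pass


class DesignError(ValueError):
    """Model matrix is rank-deficient after subsetting."""


def _model_terms(factors: Sequence[str], interactions: bool) -> list[tuple[str, ...]]:
    terms: list[tuple[str, ...]] = [(f,) for f in factors]
    if interactions:
        terms += [
            (factors[i], factors[j])
            for i in range(len(factors))
            for j in range(i + 1, len(factors))
        ]
    return terms


def term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


def _dummies(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Treatment coding, first sorted level as reference."""
    levels = sorted(pd.unique(values))
    cols = np.column_stack([(values == lv).to_numpy(float) for lv in levels[1:]])
    names = [f"[{lv}]" for lv in levels[1:]]
    return cols, names


def build_design_matrix(
    samples: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_FACTORS,
    interactions: bool = True,
) -> tuple[np.ndarray, list[str], list[Optional[tuple[str, ...]]]]:
    """Model matrix for the factorial model.

    Returns (X, column names, per-column term), where the intercept
    column carries term ``None``.
    """
    mains: dict[str, tuple[np.ndarray, list[str]]] = {}
    for f in factors:
        if f not in samples.columns:
            raise ConfigurationError(f"factor {f!r} not in sample annotations")
        if samples[f].nunique() < 2:
            raise ConfigurationError(f"factor {f!r} has fewer than 2 levels in this subset")
        mains[f] = _dummies(samples[f])

    cols: list[np.ndarray] = [np.ones((len(samples), 1))]
    names: list[str] = ["Intercept"]
    terms: list[Optional[tuple[str, ...]]] = [None]
    for t in _model_terms(factors, interactions):
        if len(t) == 1:
            block, block_names = mains[t[0]]
            block_names = [t[0] + n for n in block_names]
        else:
            b1, n1 = mains[t[0]]
            b2, n2 = mains[t[1]]
            block = np.einsum("ni,nj->nij", b1, b2).reshape(len(samples), -1)
            block_names = [f"{t[0]}{a}:{t[1]}{b}" for a in n1 for b in n2]
        cols.append(block)
        names.extend(block_names)
        terms.extend([t] * block.shape[1])
    X = np.hstack(cols)
    return X, names, terms


def _projection_rss(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares of each row of Y regressed on X, and rank(X)."""
    if X.shape[1] == 0:
        return np.einsum("ij,ij->i", Y, Y), 0
    q, r, _ = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    q = q[:, :rank]
    proj = q.T @ Y.T  # (rank, p)
    rss = np.einsum("ij,ij->i", Y, Y) - np.einsum("ji,ji->i", proj, proj)
    return np.maximum(rss, 0.0), rank


@dataclass
class DiffAbundResult:
    """Per-feature, per-term F statistics with optional FDR annotation."""

    stats: pd.DataFrame  # columns: feature, term, F, p
    coefficients: pd.DataFrame  # features x named design columns
    df_resid: int
    n_samples: int

    def with_fdr(self, q: float = 0.01) -> pd.DataFrame:
        """Benjamini-Hochberg adjust within each term across features."""
        out = self.stats.copy()
        out["p_adj"] = np.nan
        out["significant"] = False
        for _, idx in out.groupby("term").groups.items():
            flags, adj = fdr_adjust(out.loc[idx, "p"].to_numpy(), q)
            out.loc[idx, "p_adj"] = adj
            out.loc[idx, "significant"] = flags
        return out

    def significant_features(self, term: str, q: float = 0.01) -> list[str]:
        t = self.with_fdr(q)
        sel = t[(t["term"] == term) & t["significant"]]
        return list(sel["feature"])


def fit_model(
    table: FeatureTable,
    sex: Optional[str] = None,
    factors: Sequence[str] = DEFAULT_FACTORS,
    interactions: bool = True,
) -> DiffAbundResult:
    """Fit the factorial model to every feature and test each term.

    ``sex`` restricts the fit to that sex's samples (the analysis design
    treats sexes as separate datasets). The F statistic for a term
    compares, per Type II convention, the model of all terms not
    containing the term's factors against that model plus the term,
    scaled by the full model's residual mean square.
    """
    sub = table
    if sex is not None:
        mask = (table.samples["sex"] == sex).to_numpy()
        if not mask.any():
            raise ConfigurationError(f"no samples with sex {sex!r}")
        sub = table.subset_samples(mask)

    X, names, col_terms = build_design_matrix(sub.samples, factors, interactions)
    Y = sub.intensities.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ConfigurationError("intensities contain missing values; impute before modelling")
    n = X.shape[0]

    rss_full, rank_full = _projection_rss(X, Y)
    if rank_full < X.shape[1]:
        _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        aliased = sorted({names[j] for j in piv[rank_full:]})
        raise DesignError(
            "model matrix is rank deficient after subsetting; aliased columns: "
            + ", ".join(aliased)
        )
    df_resid = n - rank_full
    if df_resid <= 0:
        raise DesignError("no residual degrees of freedom")

    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    coefficients = pd.DataFrame(coef.T, index=sub.intensities.index, columns=names)

    terms = _model_terms(factors, interactions)
    rows = []
    scale = rss_full / df_resid
    for term in terms:
        keep_reduced = [
            j for j, t in enumerate(col_terms) if t is None or not set(term) <= set(t)
        ]
        keep_cmp = keep_reduced + [j for j, t in enumerate(col_terms) if t == term]
        rss_r, rank_r = _projection_rss(X[:, keep_reduced], Y)
        rss_c, rank_c = _projection_rss(X[:, sorted(keep_cmp)], Y)
        df1 = rank_c - rank_r
        num = np.maximum(rss_r - rss_c, 0.0) / max(df1, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = num / scale
        # constant / perfectly explained responses: no evidence either way
        F = np.where(num <= _RSS_TOL, 0.0, F)
        F = np.where(np.isnan(F), np.inf, F)
        p = np.where(
            F == 0.0,
            1.0,
            stats.f.sf(np.where(np.isinf(F), np.finfo(float).max, F), df1, df_resid),
        )
        p = np.where(np.isinf(F), 0.0, p)
        for i, fid in enumerate(sub.intensities.index):
            rows.append({"feature": fid, "term": term_name(term), "F": F[i], "p": p[i]})

    stats_df = pd.DataFrame(rows)
    return DiffAbundResult(stats_df, coefficients, df_resid, n)


def fdr_adjust(pvals, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (flags at q, adjusted p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return flags, adj


def lrt_interaction(
    table: FeatureTable,
    term,
    sex: Optional[str] = None,
    factors: Sequence[str] = DEFAULT_FACTORS,
    interactions: bool = True,
) -> pd.DataFrame:
    """Likelihood-ratio test of one model term per feature.

    Statistic ``2 (ll_full - ll_reduced) = n log(RSS_r / RSS_f)`` under
    the Gaussian likelihood, referred to chi-squared with df equal to
    the rank difference of the two model matrices.
    """
    if isinstance(term, str):
        term = tuple(term.split(":"))
    term = tuple(term)
    terms = _model_terms(factors, interactions)
    if term not in terms and tuple(reversed(term)) in terms:
        term = tuple(reversed(term))
    if term not in terms:
        raise ConfigurationError(f"term {term_name(term)!r} not in model")

    sub = table
    if sex is not None:
        mask = (table.samples["sex"] == sex).to_numpy()
        if not mask.any():
            raise ConfigurationError(f"no samples with sex {sex!r}")
        sub = table.subset_samples(mask)
    X, _, col_terms = build_design_matrix(sub.samples, factors, interactions)
    Y = sub.intensities.to_numpy(dtype=float)
    n = X.shape[0]

    keep_reduced = [j for j, t in enumerate(col_terms) if t != term]
    rss_f, rank_f = _projection_rss(X, Y)
    rss_r, rank_r = _projection_rss(X[:, keep_reduced], Y)
    df = rank_f - rank_r
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (np.log(rss_r) - np.log(rss_f))
    stat = np.where(np.abs(rss_r - rss_f) <= _RSS_TOL, 0.0, stat)
    stat = np.where(np.isnan(stat) | (stat < 0), 0.0, stat)
    if df == 0:
        p = np.ones_like(stat)
    else:
        p = np.where(stat == 0.0, 1.0, stats.chi2.sf(stat, df))
    return pd.DataFrame(
        {"feature": sub.intensities.index, "statistic": stat, "df": df, "p": p}
    ).reset_index(drop=True)


def subset_warm_cool(table: FeatureTable) -> FeatureTable:
    """Keep flies kept at one temperature for life (18->18 or 27->27).

    Adds a combined ``temperature`` factor; downstream models should use
    ``factors=("temperature", "genotype")`` since adult temperature is
    no longer a free factor.
    """
    for c in ("dev_temp", "adult_temp"):
        if c not in table.samples.columns:
            raise ConfigurationError(f"sample annotations lack {c!r}")
    mask = (table.samples["dev_temp"] == table.samples["adult_temp"]).to_numpy()
    if not mask.any():
        raise ConfigurationError("no samples with equal developmental and adult temperature")
    out = table.subset_samples(mask)
    out.samples = out.samples.copy()
    out.samples["temperature"] = out.samples["dev_temp"]
    return out
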