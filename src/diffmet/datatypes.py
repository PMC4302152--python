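"""Core in-memory containers shared across the pipeline.

The central object is the :class:`FeatureTable`: an (features x samples)
intensity matrix from a dual-column LC-MS run, together with per-feature
metadata (m/z, retention time, chromatography column, signal-to-noise
ratio) and per-sample annotations (sex, genotype, developmental and adult
temperature, replicate structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: feature metadata columns every table must carry
REQUIRED_FEATURE_COLS = ("mz", "rt", "column", "snr")


class SchemaError(ValueError):
    """A table violates the feature-table schema."""


@dataclass
class FeatureTable:
    """Features x samples intensity matrix plus metadata.

    Parameters
    ----------
    intensities:
        DataFrame indexed by feature id, one column per sample (technical
        replicate before collapsing, biological sample after). Missing
        cells are NaN.
    features:
        Feature metadata, index aligned with ``intensities.index``. Must
        contain :data:`REQUIRED_FEATURE_COLS`; extra columns (e.g. the
        ``planted`` ground-truth label written by the simulator) are
        carried along untouched.
    samples:
        Sample annotations, index aligned with ``intensities.columns``.
        Typical columns: ``sex``, ``genotype``, ``dev_temp``,
        ``adult_temp``, ``biological_id``, ``tech_rep``.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.features.index):
            raise SchemaError("feature metadata index does not match intensity rows")
        if not self.intensities.columns.equals(self.samples.index):
            raise SchemaError("sample annotation index does not match intensity columns")
        missing = [c for c in REQUIRED_FEATURE_COLS if c not in self.features.columns]
        if missing:
            raise SchemaError(f"feature metadata lacks required column(s): {', '.join(missing)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.features.copy(), self.samples.copy()
        )

    def subset_features(self, ids: Sequence) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(
            self.intensities.loc[ids], self.features.loc[ids], self.samples.copy()
        )

    def subset_samples(self, mask) -> "FeatureTable":
        """Subset samples by boolean mask or list of sample ids."""
        if isinstance(mask, (pd.Series, np.ndarray, list)) and np.asarray(mask).dtype == bool:
            cols = self.intensities.columns[np.asarray(mask)]
        else:
            cols = pd.Index(mask)
        return FeatureTable(
            self.intensities.loc[:, cols], self.features.copy(), self.samples.loc[cols]
        )

    def missing_fraction(self) -> float:
        """Fraction of missing cells in the whole table."""
        if self.intensities.size == 0:
            return 0.0
        return float(self.intensities.isna().to_numpy().mean())


@dataclass
class CorrelationMatrix:
    """Signed Pearson correlation r_ij across one condition's samples.

    Serves as the adjacency of the co-expression network under that
    condition; entries lie in [-1, 1] with a unit diagonal.
    """

    values: np.ndarray
    features: list[str]
    condition: str
    n_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if v.shape[0] != len(self.features):
            raise ValueError("feature labels do not match matrix dimension")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.features)


@dataclass
class DifferenceMatrix:
    """Soft-thresholded half difference of two adjacencies.

    ``D_ij = |(r_ij,1 - r_ij,2) / 2| ** (beta / 2)``; entries in [0, 1],
    zero diagonal. Large values mark metabolite pairs whose correlation
    changes between conditions.
    """

    values: np.ndarray
    features: list[str]
    beta: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.features)


@dataclass
class SimilarityMatrix:
    """Preservation similarity ``S = (1 - D) * |A| * |A'|``.

    High where the two conditions' correlations are both strong and
    equal; reduces to r^2 elementwise when the conditions agree exactly.
    """

    values: np.ndarray
    features: list[str]
    beta: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.features)


#: label given to features not assigned to any module
UNASSIGNED = "grey"


@dataclass
class ModuleAssignment:
    """Feature -> module label map produced by one clustering analysis.

    ``kind`` is ``"differential"`` (clustering driven by the difference
    matrix D) or ``"preserved"`` (driven by the similarity matrix S).
    Features in no module carry the label :data:`UNASSIGNED`.
    """

    labels: pd.Series
    kind: str
    params: dict = field(default_factory=dict)

    def modules(self) -> dict[str, list[str]]:
        """Mapping module label -> member feature ids, unassigned excluded."""
        out: dict[str, list[str]] = {}
        for fid, lab in self.labels.items():
            if lab == UNASSIGNED:
                continue
            out.setdefault(lab, []).append(fid)
        return out

    @property
    def n_modules(self) -> int:
        return len(self.modules())


@dataclass
class DispersionResult:
    """Permutation-test outcome for one module (or module pair).

    ``statistic`` is the dispersion d for differential tests or the mean
    within-module similarity for preservation tests. ``p_value`` uses the
    plus-one rule, so it is never exactly zero.
    """

    module: object
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    kind: str = "differential"

    @property
    def significant(self) -> bool:  # at the conventional 0.05; callers may re-flag
        return self.p_value <= 0.05


@dataclass
class EnrichmentResult:
    """Over-representation of one pathway in a hit list."""

    pathway: str
    overlap_size: int
    pathway_size: int
    overlap: tuple
    p_value: float
    p_adjusted: float = float("nan")
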