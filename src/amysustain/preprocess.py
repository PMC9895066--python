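"""SUVR preprocessing: covariate adjustment, CN-referenced z-scores, and
calibration of region-specific abnormality cutoffs.

The pipeline order is fixed: adjust SUVR for age/gender/education, convert
to z-scores against the cognitively-normal reference, then derive per-ROI
z-score cutoffs from the global amyloid-positivity ratio (fraction of
subjects whose cortical-composite SUVR exceeds 1.1): each ROI's cutoff is
the (1 - p) empirical quantile of its z-distribution, so the fraction of
supra-threshold subjects per ROI equals the global ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

try:
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

    class TransformerMixin:  # type: ignore[no-redef]
        def fit_transform(self, X, y=None, **kw):
            return self.fit(X, y, **kw).transform(X)

from .rois import COMPOSITE_ROIS, COVARIATE_COLUMNS, ROI_NAMES, SUVR_COLUMNS

__all__ = ["CovariateAdjuster", "CognitiveNormalScaler", "ZMatrix",
           "CutoffSet", "adjust_covariates", "cn_zscore",
           "global_positivity", "regional_cutoffs"]


@dataclass
class ZMatrix:
    """Per-subject z-scores plus the CN reference statistics behind them."""

    z: pd.DataFrame            # columns = ROI names
    cn_mean: np.ndarray
    cn_sd: np.ndarray
    roi_names: tuple = ROI_NAMES

    @property
    def values(self) -> np.ndarray:
        return self.z[list(self.roi_names)].to_numpy(dtype=float)


@dataclass
class CutoffSet:
    """Region-specific z-score cutoffs tied to a global positivity ratio."""

    suvr_cutoff: float
    positivity: float
    z_cut: dict  # ROI name -> cutoff (z units)

    def __post_init__(self) -> None:
        if not 0.0 <= self.positivity <= 1.0:
            raise ValueError("positivity must lie in [0, 1]")
        if any(v <= 0 for v in self.z_cut.values()):
            raise ValueError("z-score cutoffs must be positive")

    def as_array(self, roi_names=ROI_NAMES) -> np.ndarray:
        return np.array([self.z_cut[r] for r in roi_names], dtype=float)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"suvr_cutoff": self.suvr_cutoff, "positivity": self.positivity,
             "z_cut": self.z_cut}, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "CutoffSet":
        d = json.loads(Path(path).read_text())
        return cls(suvr_cutoff=d["suvr_cutoff"], positivity=d["positivity"],
                   z_cut=dict(d["z_cut"]))


class CovariateAdjuster(BaseEstimator, TransformerMixin):
    """Remove linear age/gender/education effects from each ROI's SUVR.

    Per ROI, fits an ordinary least-squares model of SUVR on the three
    covariates over the whole dataset and replaces the value with the
    residual plus the fitted value at the covariate means (which, with an
    intercept, is the ROI's sample mean) — so per-ROI means are preserved
    and covariate slopes are removed.  Discovery and validation cohorts are
    adjusted separately by fitting one adjuster per dataset.
    """

    def __init__(self, suvr_columns=SUVR_COLUMNS,
                 covariate_columns=COVARIATE_COLUMNS):
        self.suvr_columns = suvr_columns
        self.covariate_columns = covariate_columns

    def fit(self, X: pd.DataFrame, y=None):
        covs = X[list(self.covariate_columns)].to_numpy(dtype=float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), covs])) \
                < covs.shape[1] + 1:
            raise ValueError("rank-deficient covariate design (a covariate "
                             "is constant or collinear)")
        self.covariate_means_ = covs.mean(axis=0)
        centered = covs - self.covariate_means_
        Y = X[list(self.suvr_columns)].to_numpy(dtype=float)
        # slopes of each ROI on the centered covariates
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(X)), centered]), Y, rcond=None)
        self.intercepts_ = coef[0]
        self.slopes_ = coef[1:]         # (3, n_rois)
        self.n_features_in_ = Y.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        centered = (X[list(self.covariate_columns)].to_numpy(dtype=float)
                    - self.covariate_means_)
        out = X.copy()
        adj = (X[list(self.suvr_columns)].to_numpy(dtype=float)
               - centered @ self.slopes_)
        out[list(self.suvr_columns)] = adj
        return out


class CognitiveNormalScaler(BaseEstimator, TransformerMixin):
    """z-score SUVRs against the cognitively-normal reference group.

    ``fit`` learns per-ROI mean and SD (ddof=1) over rows whose diagnosis
    equals ``reference``; ``transform`` returns the z-scores for all rows.
    """

    def __init__(self, suvr_columns=SUVR_COLUMNS, diagnosis_column="diagnosis",
                 reference="CN", roi_names=ROI_NAMES):
        self.suvr_columns = suvr_columns
        self.diagnosis_column = diagnosis_column
        self.reference = reference
        self.roi_names = roi_names

    def fit(self, X: pd.DataFrame, y=None):
        ref = X[X[self.diagnosis_column] == self.reference]
        if len(ref) < 2:
            raise ValueError("need at least 2 reference (CN) subjects")
        vals = ref[list(self.suvr_columns)].to_numpy(dtype=float)
        self.cn_mean_ = vals.mean(axis=0)
        self.cn_sd_ = vals.std(axis=0, ddof=1)
        if (self.cn_sd_ == 0).any():
            bad = [self.roi_names[i]
                   for i in np.where(self.cn_sd_ == 0)[0]]
            raise ValueError(f"zero CN variance in ROI(s) {bad}")
        self.n_features_in_ = vals.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        vals = X[list(self.suvr_columns)].to_numpy(dtype=float)
        z = (vals - self.cn_mean_) / self.cn_sd_
        return pd.DataFrame(z, columns=list(self.roi_names), index=X.index)

    def to_zmatrix(self, X: pd.DataFrame) -> ZMatrix:
        return ZMatrix(z=self.transform(X), cn_mean=self.cn_mean_,
                       cn_sd=self.cn_sd_, roi_names=tuple(self.roi_names))


# ---------------------------------------------------------------------------
# functional surface


def adjust_covariates(cohort: pd.DataFrame, suvr_columns=SUVR_COLUMNS,
                      covariate_columns=COVARIATE_COLUMNS) -> pd.DataFrame:
    """Covariate-adjust a cohort in one shot (fit and transform on itself)."""
    adj = CovariateAdjuster(suvr_columns, covariate_columns)
    return adj.fit(cohort).transform(cohort)


def cn_zscore(cohort: pd.DataFrame, suvr_columns=SUVR_COLUMNS,
              diagnosis_column="diagnosis", reference="CN") -> ZMatrix:
    """CN-referenced z-scores for every subject."""
    scaler = CognitiveNormalScaler(suvr_columns, diagnosis_column, reference)
    scaler.fit(cohort)
    return scaler.to_zmatrix(cohort)


def global_positivity(cohort: pd.DataFrame, suvr_cutoff: float = 1.1,
                      composite_rois=COMPOSITE_ROIS) -> float:
    """Fraction of subjects whose global composite SUVR exceeds the cutoff.

    The composite is the unweighted mean of the configured ROI SUVRs
    (default: frontal, temporal, parietal, cingulate).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    cols = [f"suvr_{r}" for r in composite_rois]
    composite = cohort[cols].to_numpy(dtype=float).mean(axis=1)
    return float((composite > suvr_cutoff).mean())


def regional_cutoffs(z: ZMatrix, positivity: float, suvr_cutoff: float = 1.1,
                     min_cut: float = 0.05) -> CutoffSet:
    """Per-ROI z cutoff at the (1 - p) empirical quantile (linear
    interpolation between order statistics), so each ROI's supra-threshold
    fraction matches the global positivity ratio up to quantile granularity.

    Regions that become abnormal late in every sequence can have their
    (1 - p) quantile inside (or below) the normal bulk; a threshold at or
    under the normal mean is vacuous, so cutoffs are floored at ``min_cut``
    (z units).  Pass ``min_cut=0`` to forbid the floor and fail instead.
    """
    if not 0.0 < positivity < 1.0:
        raise ValueError("positivity must lie strictly between 0 and 1")
    vals = z.values
    cuts = np.quantile(vals, 1.0 - positivity, axis=0)
    if min_cut > 0:
        cuts = np.maximum(cuts, min_cut)
    z_cut = {roi: float(c) for roi, c in zip(z.roi_names, cuts)}
    return CutoffSet(suvr_cutoff=suvr_cutoff, positivity=float(positivity),
                     z_cut=z_cut)
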