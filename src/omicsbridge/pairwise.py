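"""Cross-layer pairwise association screen and Benjamini–Hochberg FDR.

Every molecule of the response layer is regressed on every molecule of the
exposure layer with covariate adjustment; the exposure coefficient, its
standard error and two-sided p-value populate an association table that is
then BH-adjusted over the full test grid.

The regressions are computed by Frisch–Waugh–Lovell partialling: both layers
are residualized on the covariate design once, after which all slopes, SEs
and t-tests follow from cross-products.  This is algebraically identical to
fitting each pair's full OLS model (the degrees of freedom account for the
partialled covariates) and keeps a 24 × 14 grid at a few milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AssociationTable, CovariateTable, DataError, OmicsMatrix
from .preprocess import _check_full_rank, build_design

DEFAULT_COVARIATES = ["age", "sex", "race_ethnicity", "batch_a", "cvd_event"]


@dataclass
class PairwiseConfig:
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    fdr_level: float = 0.05
    #: total number of tests for BH; None means the full response × exposure grid
    m_total: int | None = None
    min_samples: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.fdr_level < 1):
            raise DataError("fdr_level must be in (0, 1)")


def bh_adjust(p_values: np.ndarray, m_total: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with an explicit test count.

    ``m_total`` may exceed ``len(p_values)`` when the supplied values are
    known to be the smallest of a larger family (e.g. the published subset of
    a full screen); ranks are then still 1..len(p) while the multiplier uses
    the family size.  Output preserves input order and is capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataError("p_values must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values outside [0, 1]")
    k = len(p)
    m = k if m_total is None else int(m_total)
    if m < k:
        raise DataError(f"m_total ({m}) smaller than number of p-values ({k})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(k)
    out[order] = adjusted_sorted
    return out


def bulk_slope_tests(
    Y: np.ndarray, X: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope, SE and p-value of each X column in OLS fits of each Y column.

    For every (response j, exposure k) pair the model is
    ``y_j ~ intercept + covariates + x_k`` with design ``C`` holding the
    intercept and covariates.  Returns (effects, ses, pvalues), each shaped
    (n_exposures, n_responses).
    """
    n = Y.shape[0]
    q, _ = np.linalg.qr(C)
    Yr = Y - q @ (q.T @ Y)
    Xr = X - q @ (q.T @ X)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    if np.any(sxx <= 0):
        raise DataError("exposure column collinear with covariates")
    sxy = Xr.T @ Yr  # (n_exposures, n_responses)
    beta = sxy / sxx[:, None]
    syy = np.einsum("ij,ij->j", Yr, Yr)
    rss = syy[None, :] - beta**2 * sxx[:, None]
    rss = np.maximum(rss, 0.0)
    df = n - C.shape[1] - 1
    if df < 1:
        raise DataError("not enough samples for covariate-adjusted regression")
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def fit_pairwise(
    a: OmicsMatrix,
    b: OmicsMatrix,
    cov: CovariateTable | None,
    cfg: PairwiseConfig | None = None,
) -> AssociationTable:
    """Regress each layer-A molecule on each layer-B molecule with covariates.

    Layers are intersected on samples (in layer-A order); each pair
    contributes one row with the exposure coefficient, SE, p-value and the
    BH-adjusted value over the full grid.  Rows are ordered response
    molecule first, then FDR.
    """
    cfg = cfg or PairwiseConfig()
    common = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if len(common) < cfg.min_samples:
        raise DataError(
            f"only {len(common)} overlapping samples (< {cfg.min_samples})"
        )
    A = a.subset_samples(common)
    B = b.subset_samples(common)
    if A.missing_mask.any() or B.missing_mask.any():
        raise DataError("fit_pairwise expects fully observed (preprocessed) layers")
    if cov is not None and cfg.covariates:
        C, names = build_design(cov.subset_samples(common), cfg.covariates)
        _check_full_rank(C, names)
    else:
        C = np.ones((len(common), 1))
    beta, se, p = bulk_slope_tests(A.values, B.values, C)
    rows = []
    for k, mb in enumerate(B.molecule_ids):
        for j, ma in enumerate(A.molecule_ids):
            rows.append((ma, mb, beta[k, j], se[k, j], p[k, j]))
    df = pd.DataFrame(rows, columns=["molecule_a", "molecule_b", "effect", "se", "p_value"])
    m_total = cfg.m_total if cfg.m_total is not None else A.n_molecules * B.n_molecules
    df["fdr"] = bh_adjust(df["p_value"].to_numpy(), m_total)
    df = df.sort_values(["molecule_a", "fdr", "molecule_b"], kind="stable").reset_index(drop=True)
    return AssociationTable(df)
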