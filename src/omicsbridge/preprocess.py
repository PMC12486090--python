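"""Pre-analysis transforms: normalization, winsorization, missingness policy,
standardization, and covariate/batch residualization.

The fixed stage order is: total-area normalization (compositional layers
only) → winsorization → missingness policy → standardization →
residualization.  Winsorization happens on the raw scale so the 5th/95th
percentile thresholds are interpretable in the layer's original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CATEGORICAL_COVARIATES, CovariateTable, DataError, OmicsMatrix


@dataclass
class PreprocessConfig:
    winsor_lower_pct: float = 5.0
    winsor_upper_pct: float = 95.0
    #: molecules with missing fraction below this are mean-imputed
    impute_max_missing_frac: float = 0.10
    #: molecules with missing fraction above this are dropped
    drop_min_missing_frac: float = 0.50
    total_area_normalize: bool = False
    covariates_to_remove: list[str] = field(default_factory=list)
    #: policy for molecules whose missing fraction falls between the impute
    #: ceiling and the drop floor: "drop" (conservative default) or "impute"
    midband_action: str = "drop"

    def __post_init__(self) -> None:
        if not (0 <= self.winsor_lower_pct < self.winsor_upper_pct <= 100):
            raise DataError("winsor percentiles must satisfy 0 <= lower < upper <= 100")
        if not (0 <= self.impute_max_missing_frac <= self.drop_min_missing_frac <= 1):
            raise DataError("require 0 <= impute_max <= drop_min <= 1")
        if self.midband_action not in ("drop", "impute"):
            raise DataError("midband_action must be 'drop' or 'impute'")


def total_area_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Express each sample's molecule values as percent of its total.

    After the transform the non-missing values of every sample sum to 100
    (chromatographic percent-of-total-area convention).
    """
    vals = m.values.copy()
    obs = ~m.missing_mask
    if np.any(vals[obs] < 0):
        raise DataError(f"negative abundance in layer {m.layer_id!r}; cannot normalize")
    totals = np.where(obs, vals, 0.0).sum(axis=1)
    for i, t in enumerate(totals):
        if t <= 0:
            raise DataError(f"sample {m.sample_ids[i]!r} has zero total area")
    vals = np.where(obs, vals / totals[:, None] * 100.0, np.nan)
    out = m.copy()
    out.values = vals
    return out


def winsorize(values: np.ndarray, lower_pct: float = 5.0, upper_pct: float = 95.0) -> np.ndarray:
    """Clip a vector to its empirical [lower, upper] percentile band.

    Percentiles use linear interpolation between closest ranks over the
    non-missing entries; NaN entries pass through untouched.
    """
    values = np.asarray(values, dtype=float)
    obs = np.isfinite(values)
    if obs.sum() < 2:
        raise DataError("winsorize needs at least 2 non-missing values")
    lo, hi = np.percentile(values[obs], [lower_pct, upper_pct])
    out = values.copy()
    out[obs] = np.clip(values[obs], lo, hi)
    return out


def standardize(values: np.ndarray, name: str = "") -> np.ndarray:
    """Center/scale to mean 0 and sample SD 1 over non-missing entries."""
    values = np.asarray(values, dtype=float)
    obs = np.isfinite(values)
    if obs.sum() < 2:
        raise DataError(f"standardize needs >= 2 non-missing values ({name})")
    mu = values[obs].mean()
    sd = values[obs].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DataError(f"zero variance; cannot standardize molecule {name!r}")
    out = values.copy()
    out[obs] = (values[obs] - mu) / sd
    return out


def apply_missingness_policy(m: OmicsMatrix, cfg: PreprocessConfig) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Impute low-missingness molecules with the mean, drop high-missingness ones.

    Returns the filtered matrix and a per-molecule report with columns
    molecule, missing_frac, action (keep / impute / drop).
    """
    fracs = m.missing_mask.mean(axis=0)
    actions = []
    for j, f in enumerate(fracs):
        if f == 0:
            actions.append("keep")
        elif f < cfg.impute_max_missing_frac:
            actions.append("impute")
        elif f > cfg.drop_min_missing_frac:
            actions.append("drop")
        else:
            actions.append(cfg.midband_action)
    report = pd.DataFrame(
        {"molecule": m.molecule_ids, "missing_frac": fracs, "action": actions}
    )
    keep = [j for j, a in enumerate(actions) if a != "drop"]
    vals = m.values[:, keep].copy()
    mask = m.missing_mask[:, keep].copy()
    for col, j in enumerate(keep):
        if actions[j] == "impute":
            obs = ~mask[:, col]
            if not obs.any():
                raise DataError(f"molecule {m.molecule_ids[j]!r} entirely missing")
            vals[~obs, col] = vals[obs, col].mean()
            mask[:, col] = False
    out = OmicsMatrix(
        layer_id=m.layer_id,
        sample_ids=list(m.sample_ids),
        molecule_ids=[m.molecule_ids[j] for j in keep],
        values=vals,
        missing_mask=mask,
    )
    return out, report


def build_design(cov: CovariateTable, covariate_names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + listed covariates as a design matrix.

    Categorical covariates (race/ethnicity, batch) are expanded to 0/1
    indicators dropping the first level; numeric covariates enter as-is.
    """
    cols: list[np.ndarray] = [np.ones(len(cov.table))]
    names: list[str] = ["intercept"]
    for name in covariate_names:
        if name not in cov.table.columns:
            raise DataError(f"covariate {name!r} not in covariate table")
        col = cov.table[name]
        if name in CATEGORICAL_COVARIATES or col.dtype == object:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            for dcol in dummies.columns:
                cols.append(dummies[dcol].to_numpy(dtype=float))
                names.append(str(dcol))
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    X = np.column_stack(cols) if cols else np.ones((len(cov.table), 1))
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the normal equations
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise DataError(f"rank-deficient design; collinear columns: {bad or names}")


def residualize(m: OmicsMatrix, cov: CovariateTable, covariate_names: list[str]) -> OmicsMatrix:
    """Replace each molecule by its least-squares residual on the covariates.

    An intercept is always included, so an empty covariate list simply
    centers each molecule.  Residuals are orthogonal to every design column.
    """
    if m.missing_mask.any():
        raise DataError("residualize expects no missing values (run missingness policy first)")
    cov = cov.subset_samples(m.sample_ids)
    X, names = build_design(cov, covariate_names)
    _check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, m.values, rcond=None)
    resid = m.values - X @ beta
    out = m.copy()
    out.values = resid
    return out


def preprocess_layer(
    m: OmicsMatrix,
    cov: CovariateTable | None,
    cfg: PreprocessConfig,
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Run the full fixed-order preprocessing pipeline on one layer.

    Returns the processed matrix (standardized residuals when covariates are
    given) and the missingness report.
    """
    out = m
    if cfg.total_area_normalize:
        out = total_area_normalize(out)
    vals = out.values.copy()
    vals[out.missing_mask] = np.nan
    for j in range(vals.shape[1]):
        vals[:, j] = winsorize(vals[:, j], cfg.winsor_lower_pct, cfg.winsor_upper_pct)
    out = out.copy()
    out.values = np.where(out.missing_mask, np.nan, vals)
    out, report = apply_missingness_policy(out, cfg)
    vals = out.values.copy()
    for j, name in enumerate(out.molecule_ids):
        vals[:, j] = standardize(vals[:, j], name)
    out.values = vals
    if cov is not None and cfg.covariates_to_remove:
        out = residualize(out, cov, cfg.covariates_to_remove)
    elif cov is not None:
        out = residualize(out, cov, [])
    return out, report
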