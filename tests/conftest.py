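import numpy as np
import pytest

from omicsbridge import CovariateTable, OmicsMatrix
import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_matrix(values, layer="layer", sample_prefix="S", molecules=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    mask = ~np.isfinite(values)
    return OmicsMatrix(
        layer_id=layer,
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n)],
        molecule_ids=molecules or [f"M{j + 1}" for j in range(p)],
        values=np.where(mask, np.nan, values),
        missing_mask=mask,
    )


def skewed(rng, size, sigma=0.8):
    """Centered, unit-variance log-normal draw (right-skewed)."""
    raw = rng.lognormal(0.0, sigma, size=size)
    mu = np.exp(sigma**2 / 2)
    sd = np.sqrt((np.exp(sigma**2) - 1) * np.exp(sigma**2))
    return (raw - mu) / sd


@pytest.fixture
def small_covariates():
    n = 40
    r = np.random.default_rng(7)
    return CovariateTable(
        pd.DataFrame(
            {
                "age": r.normal(60, 8, n),
                "sex": r.binomial(1, 0.4, n),
                "race_ethnicity": r.choice(["W", "B", "H"], n),
                "batch_a": r.choice(["A1", "A2"], n),
                "cvd_event": r.binomial(1, 0.1, n),
                "statin_use": r.binomial(1, 0.5, n),
            },
            index=[f"S{i + 1}" for i in range(n)],
        )
    )
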