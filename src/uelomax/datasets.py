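"""Bundled data, synthetic generators and CSV input/output.

The only bundled sample is the 38-day Covid-19 mortality-rate series for
Saudi Arabia (22 July - 28 August 2021), the real-data example used for
univariate model comparison.  Synthetic generators wrap the inverse
transform sampler of the UEL law and the quantile-regression model, always
seeded for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distribution import UELParams, sample
from .regression import inverse_link, lambda_from_mu

__all__ = [
    "Dataset",
    "covid_fixture",
    "make_synthetic",
    "make_regression_synthetic",
    "read_dataset",
    "write_report",
]

# Daily Covid-19 mortality rates, Saudi Arabia, 22 Jul - 28 Aug 2021 (38 days),
# in reading order.
_COVID = (
    0.2375, 0.2962, 0.2167, 0.2752, 0.2353, 0.2347, 0.1951, 0.2140, 0.2329,
    0.2711, 0.2126, 0.2314, 0.1924, 0.2113, 0.2683, 0.2487, 0.2674, 0.1716,
    0.2666, 0.2091, 0.2278, 0.1706, 0.2271, 0.1890, 0.2077, 0.2452, 0.1319,
    0.2259, 0.1504, 0.1879, 0.1689, 0.2063, 0.2249, 0.1686, 0.1310, 0.1497,
    0.1309, 0.1495,
)


@dataclass(frozen=True)
class Dataset:
    """A unit-interval sample with provenance metadata."""

    values: np.ndarray
    name: str
    source: str  # fixture | file | synthetic
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any((v <= 0) | (v >= 1)):
            raise ValueError("dataset values must lie strictly in (0, 1)")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def covid_fixture() -> Dataset:
    """The bundled 38-value Covid-19 mortality-rate sample (immutable)."""
    return Dataset(values=np.array(_COVID), name="covid19-saudi-arabia", source="fixture")


def make_synthetic(params: UELParams, n: int, seed=None) -> Dataset:
    """Seeded UEL sample of size n with generating parameters recorded."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    values = sample(n, params, seed)
    return Dataset(
        values=values,
        name=f"uel-synthetic-n{n}",
        source="synthetic",
        metadata={
            "seed": seed,
            "delta": params.delta,
            "lam": params.lam,
            "theta": params.theta,
        },
    )


def make_regression_synthetic(
    B,
    delta: float,
    theta: float,
    q: float = 0.5,
    X=None,
    n: int | None = None,
    seed=None,
    link: str = "logit",
):
    """Design matrix and quantile-regression responses with known truth.

    If ``X`` is omitted, a design with an intercept column and standard
    normal covariates (one per slope coefficient) is drawn.  Responses are
    UEL variates whose per-row scale parameter comes from the quantile
    reparametrization at ``mu_i = linkinv(x_i' B)``.

    Returns ``(X, y)`` as arrays.
    """
    B = np.asarray(B, dtype=float)
    rng = np.random.default_rng(seed)
    if X is None:
        if n is None or n < 1:
            raise ValueError("need n >= 1 when X is not supplied")
        X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(B.size - 1)])
    else:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
    if X.shape[1] != B.size:
        raise ValueError("design width does not match coefficient vector")
    mu = inverse_link(X @ B, link)
    u = rng.uniform(size=n)
    u[u == 0.0] = 0.5 / n
    y = np.empty(n)
    from .distribution import quantile

    for i in range(n):
        lam_i = lambda_from_mu(mu[i], delta, theta, q)
        y[i] = quantile(u[i], UELParams(delta, lam_i, theta))
    y = np.clip(y, np.finfo(float).tiny, np.nextafter(1.0, 0.0))
    return X, y


def read_dataset(path, column: str | None = None) -> Dataset:
    """Read a unit-interval sample from CSV (header row expected).

    ``column`` selects a named column; by default the first numeric column
    is used.  Rows outside (0, 1) are rejected with their indices listed.
    """
    df = pd.read_csv(path)
    if column is not None:
        if column not in df.columns:
            raise ValueError(f"column {column!r} not found in {path}")
        series = df[column]
    else:
        numeric = df.select_dtypes("number")
        if numeric.shape[1] == 0:
            raise ValueError(f"no numeric column found in {path}")
        series = numeric.iloc[:, 0]
    values = pd.to_numeric(series, errors="coerce")
    if values.isna().any():
        bad = values.index[values.isna()].tolist()
        raise ValueError(f"non-numeric entries at rows {bad[:10]}")
    v = values.to_numpy(dtype=float)
    bad = np.nonzero(~((v > 0) & (v < 1)))[0]
    if bad.size:
        raise ValueError(
            f"values outside the open interval (0, 1) at rows {bad[:10].tolist()}"
        )
    return Dataset(values=v, name=str(path), source="file", metadata={"column": series.name})


def write_report(obj, path, format: str = "json") -> None:
    """Serialize a report-like object (dataclass, dict or DataFrame)."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_to_jsonable(obj), fh, indent=2)
    elif format == "csv":
        frame = obj if isinstance(obj, pd.DataFrame) else pd.DataFrame(_to_jsonable(obj))
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def _to_jsonable(obj):
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj
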