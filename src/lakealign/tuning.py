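"""Coefficient tuning: robust nonlinear least squares under an
equal-lake-weight bootstrap.

The alignment problem is a regression of the test sensor's product onto the
reference sensor's product.  Because per-lake observation counts span four
orders of magnitude, a plain fit would be dominated by the largest lakes, so
each bootstrap replicate draws the *same* number of observations (with
replacement) from every eligible lake, fits once with a Cauchy-robustified
trust-region-reflective solver, and the replicate coefficient samples are
aggregated by their median.  Lakes with too few unique matchups are excluded
up front.  Per-lake (non-bootstrap) fits and ordinary linear scaling fits are
also provided, along with the tuned/initial deviation report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .coefficients import (
    CoefficientSet,
    GilersonCoefficients,
    GonsCoefficients,
    LinearCalibration,
    OcxCoefficients,
)
from .retrievals import table_band_ratio


@dataclass(frozen=True)
class TuningSettings:
    """Bootstrap and solver settings.

    ``n_per_lake`` observations are drawn with replacement from each eligible
    lake per replicate; lakes with fewer than ``min_unique_per_lake`` unique
    matchups are excluded.  ``loss`` is the robust loss of the residuals
    (``cauchy`` by default, scale ``loss_scale`` in the residual's units);
    ``objective_space`` forms residuals in linear product units or in log10.
    """

    n_per_lake: int = 150
    min_unique_per_lake: int = 140
    n_replicates: int = 10_000
    loss: str = "cauchy"
    loss_scale: float = 1.0
    seed: int = 0
    objective_space: str = "linear"
    xtol: float = 1e-8
    ftol: float = 1e-8
    max_nfev: int = 1000

    def __post_init__(self) -> None:
        if self.n_per_lake < 1 or self.n_replicates < 1:
            raise ValueError("n_per_lake and n_replicates must be >= 1")
        if self.loss not in ("cauchy", "linear"):
            raise ValueError("loss must be 'cauchy' or 'linear'")
        if self.objective_space not in ("linear", "log10"):
            raise ValueError("objective_space must be 'linear' or 'log10'")


@dataclass
class TuningResult:
    """Bootstrap coefficient samples and their summary.

    ``samples`` is (successful replicates) x (parameters); ``median`` is the
    operational tuned coefficient set.
    """

    algorithm: str
    parameter_names: tuple[str, ...]
    samples: np.ndarray
    lakes_included: list[str]
    lakes_excluded: list[str]
    settings: TuningSettings
    n_failures: int = 0

    @property
    def median(self) -> np.ndarray:
        return np.median(self.samples, axis=0)

    @property
    def iqr(self) -> np.ndarray:
        q1, q3 = np.percentile(self.samples, [25, 75], axis=0)
        return q3 - q1

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "median": self.median,
                "iqr": self.iqr,
                "min": self.samples.min(axis=0),
                "max": self.samples.max(axis=0),
            },
            index=list(self.parameter_names),
        )

    def median_coefficients(self, template: CoefficientSet) -> CoefficientSet:
        return _theta_to_coefficients(self.algorithm, self.median, template)

    def as_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "parameter_names": list(self.parameter_names),
            "median": self.median.tolist(),
            "iqr": self.iqr.tolist(),
            "min": self.samples.min(axis=0).tolist(),
            "max": self.samples.max(axis=0).tolist(),
            "n_replicates_successful": int(self.samples.shape[0]),
            "n_failures": int(self.n_failures),
            "lakes_included": list(self.lakes_included),
            "lakes_excluded": list(self.lakes_excluded),
            "settings": {
                "n_per_lake": self.settings.n_per_lake,
                "min_unique_per_lake": self.settings.min_unique_per_lake,
                "n_replicates": self.settings.n_replicates,
                "loss": self.settings.loss,
                "loss_scale": self.settings.loss_scale,
                "seed": self.settings.seed,
                "objective_space": self.settings.objective_space,
            },
        }


# ---------------------------------------------------------------------------
# model plumbing: each algorithm maps a predictor array to a prediction


def _ocx_predict(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    poly = theta[0] + x * (theta[1] + x * (theta[2] + x * (theta[3] + x * theta[4])))
    return 10.0 ** np.clip(poly, -30, 30)


def _gilerson_predict(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    a, b, c = theta
    base = np.clip(a * x + b, 1e-12, None)
    return base ** c


def _make_gons_predict(template: GonsCoefficients) -> Callable:
    def predict(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        p, a_star = theta
        ratio, bb = x[:, 0], x[:, 1]
        a_star = max(a_star, 1e-9)
        return (ratio * (template.aw709 + bb) - template.aw665
                - np.clip(bb, 1e-12, None) ** p) / a_star

    return predict


def _linear_predict(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    return theta[0] * x + theta[1]


def _theta_to_coefficients(algorithm, theta, template):
    if algorithm in ("oc2", "oc3"):
        return OcxCoefficients(*map(float, theta), sensor=template.sensor,
                               algorithm=template.algorithm)
    if algorithm == "gilerson":
        return GilersonCoefficients(*map(float, theta))
    if algorithm == "gons05":
        return replace(template, p=float(theta[0]), a_chl_star=float(theta[1]))
    if algorithm.startswith("turbidity"):
        return LinearCalibration(float(theta[0]), float(theta[1]))
    raise ValueError(f"unknown algorithm tag {algorithm!r}")


def _coefficients_to_theta(algorithm, coeffs) -> np.ndarray:
    return np.asarray(coeffs.values, dtype=float)


def model_for(algorithm: str, init: CoefficientSet) -> tuple[Callable, tuple[str, ...]]:
    """Prediction function and parameter names for an algorithm tag."""
    if algorithm in ("oc2", "oc3"):
        return _ocx_predict, ("a0", "a1", "a2", "a3", "a4")
    if algorithm == "gilerson":
        return _gilerson_predict, ("a", "b", "c")
    if algorithm == "gons05":
        return _make_gons_predict(init), ("p", "a_chl_star")
    if algorithm.startswith("turbidity"):
        return _linear_predict, ("gain", "offset")
    raise ValueError(f"unknown algorithm tag {algorithm!r}")


def tuning_predictors(
    df: pd.DataFrame, algorithm: str, gons: "GonsCoefficients | None" = None
) -> tuple[np.ndarray, np.ndarray]:
    """Predictor matrix/vector (test sensor) and target (reference product).

    OCx: x = MSI log blue:green ratio, y = OLCI chl-a.  Gilerson: x = MSI
    NIR:red ratio.  Gons05: x = (MSI NIR:red ratio, MSI bb) columns.
    Turbidity: x = uncalibrated MSI turbidity, y = OLCI turbidity.
    """
    if algorithm in ("oc2", "oc3"):
        x = table_band_ratio(df, "msi", algorithm)
        y = df["chla_olci"].to_numpy(float)
    elif algorithm == "gilerson":
        x = table_band_ratio(df, "msi", "nir_red")
        y = df["chla_olci"].to_numpy(float)
    elif algorithm == "gons05":
        from .bands import reflectance_column
        from .retrievals import gons_backscatter

        ratio = table_band_ratio(df, "msi", "nir_red")
        bb = gons_backscatter(
            df[reflectance_column("msi", "b778")].to_numpy(float),
            gons if gons is not None else GonsCoefficients(1.0, 1.0),
        )
        x = np.column_stack([ratio, bb])
        y = df["chla_olci"].to_numpy(float)
    elif algorithm.startswith("turbidity"):
        x = df["turbidity_msi"].to_numpy(float)
        y = df["turbidity_olci"].to_numpy(float)
    else:
        raise ValueError(f"unknown algorithm tag {algorithm!r}")
    return x, y


def fit_once(
    x: np.ndarray,
    y: np.ndarray,
    algorithm: str,
    init: CoefficientSet,
    settings: TuningSettings,
) -> CoefficientSet:
    """One robust nonlinear least-squares fit (trust-region reflective,
    unbounded).  Deterministic given inputs and init; raises on
    non-convergence or an underdetermined system."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(y) & (np.isfinite(x).all(axis=1) if x.ndim == 2 else np.isfinite(x))
    x, y = (x[ok], y[ok])
    predict, names = model_for(algorithm, init)
    theta0 = _coefficients_to_theta(algorithm, init)
    if len(y) < len(theta0):
        raise ValueError(
            f"{len(y)} observations cannot determine {len(theta0)} parameters"
        )

    if settings.objective_space == "log10":
        def residuals(theta):
            pred = np.clip(predict(x, theta), 1e-12, None)
            return np.log10(pred) - np.log10(np.clip(y, 1e-12, None))
    else:
        def residuals(theta):
            return predict(x, theta) - y

    result = least_squares(
        residuals,
        theta0,
        method="trf",
        loss=settings.loss,
        f_scale=settings.loss_scale,
        xtol=settings.xtol,
        ftol=settings.ftol,
        gtol=1e-12,
        max_nfev=settings.max_nfev,
    )
    if not result.success:
        raise RuntimeError(f"solver did not converge: {result.message}")
    return _theta_to_coefficients(algorithm, result.x, init)


def _unique_match_counts(df: pd.DataFrame) -> pd.Series:
    """Unique (pixel, timestamp) matchups per lake."""
    keys = [c for c in ("lake_id", "timestamp", "lat", "lon") if c in df.columns]
    return df.drop_duplicates(subset=keys).groupby("lake_id").size()


def _normalized_order(df: pd.DataFrame) -> pd.DataFrame:
    keys = [c for c in ("lake_id", "timestamp", "lat", "lon") if c in df.columns]
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)


def bootstrap_tune(
    df: pd.DataFrame,
    algorithm: str,
    init: CoefficientSet,
    settings: TuningSettings,
) -> TuningResult:
    """Equal-lake-weight bootstrap tuning.

    Each replicate draws ``n_per_lake`` rows with replacement from every
    eligible lake and refits from ``init``; the result aggregates the
    replicate coefficient samples.  Bit-reproducible from ``settings.seed``
    (the input is ordering-normalized by lake/time/position before drawing).
    """
    df = _normalized_order(df)
    counts = _unique_match_counts(df)
    included = sorted(counts.index[counts >= settings.min_unique_per_lake])
    excluded = sorted(set(df["lake_id"].unique()) - set(included))
    if not included:
        raise ValueError(
            f"no lake has >= {settings.min_unique_per_lake} unique matchups"
        )

    gons = init if algorithm == "gons05" else None
    x_all, y_all = tuning_predictors(df, algorithm, gons=gons)
    lake_indices = {
        lake: np.flatnonzero((df["lake_id"] == lake).to_numpy()) for lake in included
    }
    _, names = model_for(algorithm, init)

    root = np.random.SeedSequence(settings.seed)
    children = root.spawn(settings.n_replicates)
    samples = []
    failures = 0
    for child in children:
        rng = np.random.default_rng(child)
        idx = np.concatenate(
            [rng.choice(lake_indices[lake], size=settings.n_per_lake, replace=True)
             for lake in included]
        )
        x = x_all[idx] if x_all.ndim == 1 else x_all[idx, :]
        try:
            fitted = fit_once(x, y_all[idx], algorithm, init, settings)
            samples.append(_coefficients_to_theta(algorithm, fitted))
        except (RuntimeError, ValueError):
            failures += 1
    if not samples:
        raise RuntimeError("all bootstrap replicates failed to converge")
    return TuningResult(
        algorithm=algorithm,
        parameter_names=names,
        samples=np.asarray(samples),
        lakes_included=list(included),
        lakes_excluded=list(excluded),
        settings=settings,
        n_failures=failures,
    )


def bootstrap_draw_counts(
    df: pd.DataFrame, settings: TuningSettings, n_replicates: int | None = None
) -> pd.DataFrame:
    """Audit helper: per-replicate draw counts per lake under the same seed
    stream as :func:`bootstrap_tune` (row = replicate, column = lake)."""
    df = _normalized_order(df)
    counts = _unique_match_counts(df)
    included = sorted(counts.index[counts >= settings.min_unique_per_lake])
    n_rep = n_replicates or settings.n_replicates
    root = np.random.SeedSequence(settings.seed)
    out = []
    for child in root.spawn(n_rep):
        rng = np.random.default_rng(child)
        row = {}
        for lake in included:
            pool = np.flatnonzero((df["lake_id"] == lake).to_numpy())
            row[lake] = len(rng.choice(pool, size=settings.n_per_lake, replace=True))
        out.append(row)
    return pd.DataFrame(out)


def per_lake_tune(
    df: pd.DataFrame,
    algorithm: str,
    init: CoefficientSet,
    settings: TuningSettings,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One non-bootstrap fit per lake.

    Returns (per-lake coefficient table indexed by lake, summary table with
    mean/sd/min/median/max per parameter).  Lakes with fewer observations
    than parameters are skipped with a warning.
    """
    import warnings

    _, names = model_for(algorithm, init)
    rows = {}
    gons = init if algorithm == "gons05" else None
    for lake, sub in df.groupby("lake_id", sort=True):
        x, y = tuning_predictors(sub, algorithm, gons=gons)
        try:
            fitted = fit_once(x, y, algorithm, init, settings)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"per-lake fit skipped for {lake!r}: {exc}")
            continue
        rows[lake] = dict(zip(names, _coefficients_to_theta(algorithm, fitted)))
    table = pd.DataFrame.from_dict(rows, orient="index")[list(names)]
    summary = pd.DataFrame(
        {
            "mean": table.mean(),
            "sd": table.std(ddof=1),
            "min": table.min(),
            "median": table.median(),
            "max": table.max(),
        }
    )
    return table, summary


def fit_linear_scaling(x: np.ndarray, y: np.ndarray) -> LinearCalibration:
    """Ordinary least squares of y on x; returns the gain/offset pair."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("need at least 2 finite points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) predictor")
    gain, offset = np.polyfit(x, y, 1)
    return LinearCalibration(float(gain), float(offset))


def coefficient_deviation(
    initial: CoefficientSet, tuned: CoefficientSet, digits: int | None = None
) -> dict[str, float]:
    """Element-wise tuned/initial multipliers (NaN where initial is zero)."""
    if initial.names != tuned.names:
        raise ValueError(
            f"parameter names differ: {initial.names} vs {tuned.names}"
        )
    out = {}
    for name, a, b in zip(initial.names, initial.values, tuned.values):
        if a == 0:
            out[name] = float("nan")
        else:
            m = b / a
            out[name] = round(m, digits) if digits is not None else m
    return out
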