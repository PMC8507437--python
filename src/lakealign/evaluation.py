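"""Agreement statistics between the two sensors' products.

Conventions: ``x`` is the test-sensor (MSI) product, ``y`` the reference
(OLCI) product, and the residual is ``x - y``, so a positive bias means the
test sensor overestimates relative to the reference.  The regression slope
for chl-a reports is fitted in log10 space (matching how chl-a scatter is
conventionally displayed); turbidity slopes are fitted in linear space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

RESIDUAL_PERCENTILES = (5.0, 50.0, 95.0)


def load_owt_reference(path=None) -> pd.DataFrame:
    """Optical-water-type reference spectra, indexed by class id.

    With no path, loads the bundled *synthetic* 13-class fixture
    (``data/owt_reference_synthetic.csv``) — plausible spectral shapes for
    testing, not spectra derived from any sensor archive.  Real analyses
    should pass their own CSV (column ``owt`` + one column per band).
    """
    if path is None:
        from importlib import resources

        with resources.files("lakealign.data").joinpath(
            "owt_reference_synthetic.csv"
        ).open() as fh:
            return pd.read_csv(fh, index_col="owt")
    return pd.read_csv(path, index_col="owt")


@dataclass(frozen=True)
class MetricsReport:
    """Pairwise agreement metrics.

    mad    -- mean absolute difference, (1/N) sum |x_i - y_i| (product units)
    mapd   -- mean absolute percentage difference, (100/N) sum |x_i - y_i|/y_i
    rmsd   -- root mean squared difference (product units)
    r      -- Pearson correlation
    bias   -- mean signed difference, (1/N) sum (x_i - y_i)
    rp5/rp50/rp95 -- percentiles of the residual x - y
    slope  -- OLS slope of x on y (log10 space for chl-a, linear otherwise)
    n      -- number of pairs; n_mapd_excluded counts y == 0 rows dropped
              from the MAPD term only
    """

    mad: float
    mapd: float
    rmsd: float
    r: float
    bias: float
    rp5: float
    rp50: float
    rp95: float
    slope: float
    n: int
    n_mapd_excluded: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "mad", "mapd", "rmsd", "r", "bias", "rp5", "rp50", "rp95",
            "slope", "n", "n_mapd_excluded",
        )}


def compute_metrics(x, y, slope_space: str = "log10") -> MetricsReport:
    """Full agreement report for paired products (see class docstring)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 finite pairs")
    d = x - y
    mad = float(np.mean(np.abs(d)))
    rmsd = float(np.sqrt(np.mean(d ** 2)))
    bias = float(np.mean(d))
    nonzero = y != 0
    n_excluded = int((~nonzero).sum())
    if nonzero.any():
        mapd = float(100.0 * np.mean(np.abs(d[nonzero]) / np.abs(y[nonzero])))
    else:
        mapd = float("nan")
        warnings.warn("MAPD undefined: all reference values are zero")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    rp5, rp50, rp95 = np.percentile(d, RESIDUAL_PERCENTILES)
    if slope_space == "log10":
        pos = (x > 0) & (y > 0)
        lx, ly = np.log10(x[pos]), np.log10(y[pos])
        slope = float(np.polyfit(ly, lx, 1)[0]) if len(lx) >= 2 and np.ptp(ly) > 0 else float("nan")
    elif slope_space == "linear":
        slope = float(np.polyfit(y, x, 1)[0]) if np.ptp(y) > 0 else float("nan")
    else:
        raise ValueError("slope_space must be 'log10' or 'linear'")
    return MetricsReport(
        mad=mad, mapd=mapd, rmsd=rmsd, r=r, bias=bias,
        rp5=float(rp5), rp50=float(rp50), rp95=float(rp95),
        slope=slope, n=n, n_mapd_excluded=n_excluded,
    )


def welch_test(sample_a, sample_b, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sided Welch's t-test for unequal-variance samples.

    Returns (t, p, reject-at-alpha).  If both samples are degenerate with
    equal means, (0, 1, False) by convention.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return float("inf"), 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), bool(p < alpha)


def residuals_by_distance(
    dist_km, residuals, bin_edges_km: Sequence[float], near_threshold_km: float = 5.0
) -> tuple[pd.DataFrame, dict]:
    """Residual spread as a function of distance to the nearest land.

    Returns a per-bin table (n, median, 2.5/97.5 percentiles, max |residual|;
    empty bins reported with n=0) and a near/far split summary at
    ``near_threshold_km``.
    """
    dist = np.asarray(dist_km, float)
    res = np.asarray(residuals, float)
    if dist.shape != res.shape:
        raise ValueError("distances and residuals must align")
    edges = np.asarray(bin_edges_km, float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    ok = np.isfinite(dist) & np.isfinite(res)
    dist, res = dist[ok], res[ok]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist >= lo) & (dist < hi)
        vals = res[sel]
        if len(vals):
            p2, p50, p97 = np.percentile(vals, [2.5, 50, 97.5])
            rows.append({"lo_km": lo, "hi_km": hi, "n": len(vals),
                         "median": p50, "p2_5": p2, "p97_5": p97,
                         "max_abs": float(np.max(np.abs(vals)))})
        else:
            rows.append({"lo_km": lo, "hi_km": hi, "n": 0,
                         "median": np.nan, "p2_5": np.nan, "p97_5": np.nan,
                         "max_abs": np.nan})
    table = pd.DataFrame(rows)

    def _split(sel):
        vals = res[sel]
        if not len(vals):
            return {"n": 0}
        p2, p97 = np.percentile(vals, [2.5, 97.5])
        return {"n": int(len(vals)), "median": float(np.median(vals)),
                "p2_5": float(p2), "p97_5": float(p97),
                "spread_95": float(p97 - p2),
                "max_abs": float(np.max(np.abs(vals)))}

    split = {
        "threshold_km": near_threshold_km,
        "near": _split(dist < near_threshold_km),
        "far": _split(dist >= near_threshold_km),
    }
    return table, split


def spectral_angle(s, r) -> float:
    """Angle (radians) between two spectra; scale-invariant."""
    s = np.asarray(s, float)
    r = np.asarray(r, float)
    ns, nr = np.linalg.norm(s), np.linalg.norm(r)
    if ns == 0 or nr == 0:
        raise ValueError("zero-norm spectrum")
    cosine = np.clip(np.dot(s, r) / (ns * nr), -1.0, 1.0)
    return float(np.arccos(cosine))


def classify_owt(spectrum, references: pd.DataFrame) -> tuple[object, float]:
    """Dominant optical water type by minimum spectral angle.

    ``references`` is indexed by class id with one column per band, in the
    same band order as ``spectrum``.  Returns (class id, angle in radians);
    raises on a zero-norm query.
    """
    if len(references) < 2:
        raise ValueError("need at least 2 reference classes")
    angles = {cid: spectral_angle(spectrum, row.to_numpy(float))
              for cid, row in references.iterrows()}
    best = min(angles, key=angles.get)
    return best, angles[best]


def classify_owt_table(spectra: np.ndarray, references: pd.DataFrame) -> np.ndarray:
    """Vectorized dominant-class assignment for an (n, bands) spectra array.

    Rows with zero norm or missing values get a missing (None) class.
    """
    spectra = np.asarray(spectra, float)
    ref = references.to_numpy(float)
    ref_norm = np.linalg.norm(ref, axis=1)
    norms = np.linalg.norm(np.nan_to_num(spectra), axis=1)
    valid = np.isfinite(spectra).all(axis=1) & (norms > 0)
    cos = np.full((len(spectra), len(ref)), -np.inf)
    cos[valid] = (spectra[valid] @ ref.T) / np.outer(norms[valid], ref_norm)
    idx = np.argmax(cos, axis=1)  # max cosine == min angle
    classes = np.asarray(references.index.to_numpy())[idx].astype(object)
    classes[~valid] = None
    return classes


def stratified_metrics(
    x,
    y,
    labels,
    label_sets: Mapping[str, Sequence] | None = None,
    min_n: int = 2,
    slope_space: str = "log10",
) -> pd.DataFrame:
    """One metrics row per group label plus one per declared label-set union.

    Groups with fewer than ``min_n`` finite pairs are flagged
    (``flagged_small=True``) and carry no metrics.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    labels = np.asarray(labels, object)
    rows = {}

    def _one(name, sel):
        ok = sel & np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_n:
            rows[name] = {"n": int(ok.sum()), "flagged_small": True}
            return
        rep = compute_metrics(x[ok], y[ok], slope_space=slope_space).as_dict()
        rep["flagged_small"] = False
        rows[name] = rep

    for lab in pd.unique(labels):
        _one(lab, labels == lab)
    for name, members in (label_sets or {}).items():
        _one(name, np.isin(labels, list(members)))
    return pd.DataFrame.from_dict(rows, orient="index")
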