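"""Matchup masking and filtering cascade with per-step survivor accounting.

The cascade reproduces a fixed seven-step quality screen followed by
per-algorithm validity ranges:

1. pixel-quality flags on the test sensor (cloud/cirrus/shadow/land raised,
   or clear-water not set) remove the row;
2. any reflectance > 1 on either sensor;
3. atmospheric-correction out-of-bounds flag on either sensor;
4. snow/ice flag on the reference sensor;
5. fewer than five valid neighbours in the 3x3 macro-pixel;
6. the top and bottom 0.05% of each sensor's product distribution
   (keeping the central 99.9%);
7. test-sensor products further than two standard deviations from the mean.

Finally each algorithm gates its own product ranges (e.g. OC2/OC3 keep only
reference chl-a between 0.2 and 10 mg m^-3 in clear, low-turbidity water).
Every removal is attributed to exactly one (first-triggering) step in a
:class:`FilterReport` whose counts telescope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import CANONICAL_BANDS, reflectance_column
from .coefficients import CoefficientRegistry
from .retrievals import retrieve_products, table_band_ratio

# flags whose raising removes the row (step 1), plus the required clear flag
MASK_FLAGS = (
    "cloud_buffer",
    "cloud_sure",
    "cloud",
    "cloud_ambiguous",
    "cirrus_sure",
    "cirrus_ambiguous",
    "potential_shadow",
    "land",
)
REQUIRED_FLAG = "clear_water"
OOB_FLAGS = ("out_of_bounds_msi", "out_of_bounds_olci")
SNOW_ICE_FLAG = "snow_ice_olci"

TRIM_TAIL_FRACTION = 0.0005  # 0.05% per tail, keeping the central 99.9%
SIGMA_MULTIPLE = 2.0
MIN_VALID_NEIGHBOURS = 5


@dataclass
class FilterStep:
    name: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class FilterReport:
    """Ordered per-step accounting; ``n_out`` of each step feeds the next."""

    steps: list[FilterStep] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        self.steps.append(FilterStep(name, int(n_in), int(n_in - n_out), int(n_out)))

    @property
    def n_initial(self) -> int:
        return self.steps[0].n_in if self.steps else 0

    @property
    def n_final(self) -> int:
        return self.steps[-1].n_out if self.steps else 0

    def telescopes(self) -> bool:
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if prev.n_out != nxt.n_in:
                return False
        return all(s.n_removed >= 0 and s.n_in - s.n_removed == s.n_out for s in self.steps)

    def extend(self, other: "FilterReport") -> None:
        self.steps.extend(other.steps)

    def as_dict(self) -> dict:
        return {
            "steps": [vars(s) for s in self.steps],
            "n_initial": self.n_initial,
            "n_final": self.n_final,
        }

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def _flag(df: pd.DataFrame, name: str) -> np.ndarray:
    col = f"flag_{name}"
    if col not in df.columns:
        raise KeyError(f"matchup table is missing required flag column {col!r}")
    return df[col].to_numpy() != 0


def apply_pixel_masks(df: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Steps 1-5: flags, reflectance > 1, out-of-bounds, snow/ice, neighbours."""
    report = FilterReport()
    n = len(df)

    bad = np.zeros(n, dtype=bool)
    for name in MASK_FLAGS:
        bad |= _flag(df, name)
    bad |= ~_flag(df, REQUIRED_FLAG)
    df = df.loc[~bad]
    report.record("pixel_flags", n, len(df))

    rw_cols = [
        reflectance_column(sensor, band)
        for sensor in ("msi", "olci")
        for band in CANONICAL_BANDS
        if reflectance_column(sensor, band) in df.columns
    ]
    rw = df[rw_cols].to_numpy(float)
    keep = ~(np.nan_to_num(rw, nan=-np.inf) > 1.0).any(axis=1)
    n = len(df)
    df = df.loc[keep]
    report.record("reflectance_gt_1", n, len(df))

    bad = np.zeros(len(df), dtype=bool)
    for name in OOB_FLAGS:
        bad |= _flag(df, name)
    n = len(df)
    df = df.loc[~bad]
    report.record("out_of_bounds", n, len(df))

    n = len(df)
    df = df.loc[~_flag(df, SNOW_ICE_FLAG)]
    report.record("snow_ice", n, len(df))

    n = len(df)
    df = df.loc[df["n_valid_neighbours"].to_numpy() >= MIN_VALID_NEIGHBOURS]
    report.record("valid_neighbours", n, len(df))
    return df, report


def trim_extreme_chla(msi: np.ndarray, olci: np.ndarray) -> np.ndarray:
    """Step 6 keep-mask: drop values strictly outside each sensor's central
    99.9% (linear-interpolation percentiles at 0.05 and 99.95).

    A row is kept only if kept under both sensors' trims; rows whose product
    is missing on a sensor are not trimmed by that sensor.  Percentiles use
    Hazen plotting positions, which leave the tails empty on small samples
    (nothing is removed below n = 1/(2*tail fraction) = 1000) and remove
    exactly floor(0.0005*n) per tail on large distinct samples.
    """
    msi = np.asarray(msi, float)
    olci = np.asarray(olci, float)
    keep = np.ones(msi.shape, dtype=bool)
    for values in (msi, olci):
        finite = np.isfinite(values)
        if not finite.any():
            warnings.warn("trim_extreme_chla: all values missing for one sensor")
            continue
        lo, hi = np.percentile(
            values[finite],
            [100 * TRIM_TAIL_FRACTION, 100 * (1 - TRIM_TAIL_FRACTION)],
            method="hazen",
        )
        keep &= ~(finite & ((values < lo) | (values > hi)))
    return keep


def sigma_filter_chla(msi: np.ndarray) -> np.ndarray:
    """Step 7 keep-mask: drop values with |v - mean| strictly > 2*sd (sample
    sd, n-1 denominator).  Zero-variance input retains everything."""
    msi = np.asarray(msi, float)
    finite = np.isfinite(msi)
    vals = msi[finite]
    if vals.size < 2:
        return np.ones(msi.shape, dtype=bool)
    sd = vals.std(ddof=1)
    if sd == 0:
        return np.ones(msi.shape, dtype=bool)
    mean = vals.mean()
    return ~(finite & (np.abs(msi - mean) > SIGMA_MULTIPLE * sd))


# Table of per-algorithm product gates.  MSI is the tuning response variable
# for the OCx algorithms, so it is deliberately not range-filtered there.
def _range_mask(df: pd.DataFrame, algorithm: str, registry: CoefficientRegistry) -> np.ndarray:
    n = len(df)
    keep = np.ones(n, dtype=bool)

    def col(name):
        if name not in df.columns:
            raise KeyError(f"range filter for {algorithm!r} needs column {name!r}")
        return df[name].to_numpy(float)

    if algorithm in ("oc2", "oc3"):
        msi_ratio = table_band_ratio(df, "msi", algorithm)
        olci_ratio = table_band_ratio(df, "olci", algorithm)
        olci_chla = col("chla_olci")
        # reference-sensor turbidity at 708 nm gates the clear-water domain
        rw708 = df[reflectance_column("olci", "b708")].to_numpy(float)
        from .retrievals import nechad_turbidity

        t708 = nechad_turbidity(rw708, registry.get("nechad", "shared", "b708"))
        keep &= np.isfinite(msi_ratio)  # ratio > 0 is finiteness of the log ratio
        keep &= np.isfinite(olci_ratio)
        keep &= np.isfinite(olci_chla) & (olci_chla > 0.2) & (olci_chla < 10.0)
        keep &= np.isfinite(t708) & (t708 < 0.5)
        return keep
    if algorithm == "gilerson":
        msi_ratio = table_band_ratio(df, "msi", "nir_red")
        keep &= np.isfinite(msi_ratio) & (msi_ratio > 0)
        msi_chla = col("chla_msi")
        keep &= np.isfinite(msi_chla) & (msi_chla > 0) & (msi_chla < 250.0)
        olci_chla = col("chla_olci")
        keep &= np.isfinite(olci_chla) & (olci_chla > 2.0) & (olci_chla < 200.0)
        return keep
    if algorithm == "gons05":
        msi_chla = col("chla_msi")
        keep &= np.isfinite(msi_chla) & (msi_chla > 0) & (msi_chla < 250.0)
        olci_chla = col("chla_olci")
        keep &= np.isfinite(olci_chla) & (olci_chla > 2.0) & (olci_chla < 200.0)
        return keep
    if algorithm.startswith("turbidity_"):
        t_msi = col("turbidity_msi")
        t_olci = col("turbidity_olci")
        keep &= np.isfinite(t_msi) & (t_msi > 0)
        keep &= np.isfinite(t_olci) & (t_olci > 0)
        return keep
    raise ValueError(f"unknown algorithm tag {algorithm!r}")


def algorithm_range_filter(
    df: pd.DataFrame, algorithm: str, registry: CoefficientRegistry
) -> tuple[pd.DataFrame, FilterReport]:
    """Per-algorithm product-range gates (applied after the generic steps)."""
    report = FilterReport()
    n = len(df)
    keep = _range_mask(df, algorithm, registry)
    df = df.loc[keep]
    report.record(f"range_{algorithm}", n, len(df))
    return df, report


def run_filter_cascade(
    df: pd.DataFrame, algorithm: str, registry: CoefficientRegistry
) -> tuple[pd.DataFrame, FilterReport]:
    """Full deterministic cascade for one algorithm.

    Products are computed with the ``initial`` coefficient group (trimming is
    defined on pre-tuning products so it cannot see the tuning outcome); the
    returned table carries the product columns used by the gates.
    """
    df, report = apply_pixel_masks(df)

    df, _ = retrieve_products(df, algorithm, registry)
    if algorithm.startswith("turbidity_"):
        msi_vals = df["turbidity_msi"].to_numpy(float)
        olci_vals = df["turbidity_olci"].to_numpy(float)
    else:
        msi_vals = df["chla_msi"].to_numpy(float)
        olci_vals = df["chla_olci"].to_numpy(float)

    n = len(df)
    keep = trim_extreme_chla(msi_vals, olci_vals)
    df = df.loc[keep]
    report.record("trim_extreme", n, len(df))

    n = len(df)
    keep = sigma_filter_chla(msi_vals[np.asarray(keep)])
    df = df.loc[keep]
    report.record("sigma_filter", n, len(df))

    df, range_report = algorithm_range_filter(df, algorithm, registry)
    report.extend(range_report)
    return df, report
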