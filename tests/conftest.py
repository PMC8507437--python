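"""Shared fixtures: the shipped registry and small synthetic tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

from lakealign import LinearCalibration, default_registry

hypothesis_settings.register_profile("repeatable", derandomize=True)
hypothesis_settings.load_profile("repeatable")
from lakealign.simulate import LakeSpec, SyntheticConfig


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_flag_columns(n, raised=()):
    """All-clear flag columns for n rows (clear_water set, others clear)."""
    from lakealign.simulate import ALL_FLAGS

    cols = {}
    for flag in ALL_FLAGS:
        if flag == "clear_water":
            cols[f"flag_{flag}"] = np.ones(n, dtype=int)
        else:
            cols[f"flag_{flag}"] = np.zeros(n, dtype=int)
    for flag, rows in raised:
        col = f"flag_{flag}"
        vals = cols[col].copy()
        if flag == "clear_water":
            vals[list(rows)] = 0
        else:
            vals[list(rows)] = 1
        cols[col] = vals
    return cols


@pytest.fixture
def identity_config():
    """Zero distortion, zero noise, zero contamination: both sensors agree
    exactly row-by-row."""
    lakes = [
        LakeSpec(f"lake{i}", 300, chla_median=m, chla_sigma_log=0.4,
                 turbidity_median=0.8, turbidity_sigma_log=0.6, owt=3)
        for i, m in enumerate([1.0, 3.0, 8.0], start=1)
    ]
    return SyntheticConfig(
        lakes=lakes,
        seed=42,
        bluegreen_distortion=LinearCalibration(1.0, 0.0),
        nirred_distortion=LinearCalibration(1.0, 0.0),
        nir_amplitude_gain={},
    )


def recovery_config(kind: str, seed: int = 11, n_per_lake: int = 1000,
                    n_lakes: int = 16) -> SyntheticConfig:
    """Sixteen-lake scenario generated from known coefficient sets with small
    Gaussian ratio noise, per algorithm family."""
    if kind in ("oc2", "oc3"):
        medians = np.geomspace(0.6, 5.0, n_lakes)
        t_med = 0.15
        extra = dict(bluegreen_noise_sd=0.01)
    elif kind == "gilerson":
        medians = np.geomspace(5, 50, n_lakes)
        t_med = 2.0
        extra = dict(nirred_noise_sd=0.005)
    elif kind == "gons05":
        medians = np.geomspace(5, 50, n_lakes)
        t_med = 2.0
        extra = dict(nirred_noise_sd=0.005, nir_red_inversion="gons05")
    else:
        raise ValueError(kind)
    lakes = [
        LakeSpec(f"lk{i:02d}", n_per_lake, chla_median=float(m),
                 chla_sigma_log=0.5, turbidity_median=t_med,
                 turbidity_sigma_log=0.5, owt=3)
        for i, m in enumerate(medians)
    ]
    return SyntheticConfig(
        lakes=lakes,
        seed=seed,
        bluegreen_distortion=LinearCalibration(1.0, 0.0),
        nirred_distortion=LinearCalibration(1.0, 0.0),
        nir_amplitude_gain={},
        **extra,
    )


def random_spectra_frame(rng, n):
    """Matchup-shaped frame with random valid reflectances on both sensors."""
    cols = {
        "lake_id": ["lakeA"] * n,
        "timestamp": pd.date_range("2017-06-01", periods=n, freq="h").astype(str),
        "lat": np.round(rng.uniform(-60, 60, n), 6),
        "lon": np.round(rng.uniform(-180, 180, n), 6),
        "dist_land_km": rng.uniform(0.5, 50, n),
        "n_valid_neighbours": np.full(n, 8),
    }
    cols.update(make_flag_columns(n))
    for sensor in ("msi", "olci"):
        for band, lo, hi in [
            ("b443", 0.001, 0.02), ("b490", 0.002, 0.03), ("b560", 0.002, 0.03),
            ("b665", 0.001, 0.02), ("b708", 0.001, 0.02), ("b778", 0.0005, 0.01),
            ("b865", 0.0002, 0.01),
        ]:
            cols[f"rw_{sensor}_{band}"] = rng.uniform(lo, hi, n)
    return pd.DataFrame(cols)
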