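"""Water-quality retrieval formulas and their vectorized table application.

Four chlorophyll-a algorithms and one turbidity algorithm are implemented:

* OC2 / OC3 — degree-4 polynomial in the log10 blue:green reflectance ratio,
  ``chla = 10**(a0 + a1*x + ... + a4*x**4)``, suited to clear (oligo- and
  mesotrophic) water.
* Gilerson-style NIR:red ratio — ``chla = (a*x + b)**c`` with
  ``x = rw708/rw665``, for moderately turbid, chl-rich water.
* Gons05 semi-analytical — inverts NIR reflectance for the particulate
  backscattering coefficient ``bb`` and solves the reflectance-ratio model
  for chl-a using pure-water absorption coefficients.
* Nechad single-band turbidity — ``T = A*rw / (1 - rw/C)`` in FNU.

Scalar functions raise on invalid input; the bulk entry point
:func:`retrieve_products` converts invalid domains to missing values (NaN)
and tallies an enumerated rejection reason per row instead of raising.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bands import reflectance_column
from .coefficients import (
    CoefficientRegistry,
    GilersonCoefficients,
    GonsCoefficients,
    LinearCalibration,
    NechadCoefficients,
    OcxCoefficients,
)

# Enumerated rejection reasons used in bulk mode.
REASON_MISSING_BAND = "missing_band"
REASON_NONPOS_DENOMINATOR = "nonpositive_denominator"
REASON_NONPOS_RATIO = "nonpositive_ratio"
REASON_NONPOS_BASE = "nonpositive_power_base"
REASON_BB_DOMAIN = "backscatter_domain"
REASON_RW_DOMAIN = "reflectance_out_of_domain"


@dataclass
class RejectionTally:
    """Counts of rows whose product is missing, keyed by reason code."""

    counts: Counter = field(default_factory=Counter)

    def add(self, reason: str, n: int) -> None:
        if n:
            self.counts[reason] += int(n)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict:
        return dict(self.counts)


def band_ratio(spectrum: Mapping[str, float], kind: str) -> float:
    """Band ratio feeding a retrieval: log10 blue:green for OC2/OC3, plain
    708:665 for the NIR:red algorithms.

    Scalar form; raises ``ValueError`` outside the domain.
    """
    kind = kind.lower()
    if kind == "oc2":
        num, den = spectrum.get("b490"), spectrum.get("b560")
    elif kind == "oc3":
        b443, b490 = spectrum.get("b443"), spectrum.get("b490")
        den = spectrum.get("b560")
        if b490 is None:
            raise ValueError("band b490 missing")
        num = b490 if b443 is None else max(b443, b490)
    elif kind == "nir_red":
        num, den = spectrum.get("b708"), spectrum.get("b665")
    else:
        raise ValueError(f"unknown ratio kind {kind!r}")
    if num is None or den is None or not (np.isfinite(num) and np.isfinite(den)):
        raise ValueError(f"missing band for ratio kind {kind!r}")
    if den <= 0:
        raise ValueError("non-positive denominator")
    ratio = num / den
    if kind == "nir_red":
        return float(ratio)
    if ratio <= 0:
        raise ValueError("non-positive blue:green ratio")
    return float(np.log10(ratio))


def ocx_chla(x, coeffs: OcxCoefficients):
    """Evaluate ``10**poly(x)``; strictly positive for any finite x."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    a = coeffs.values
    poly = a[0] + x * (a[1] + x * (a[2] + x * (a[3] + x * a[4])))
    out = 10.0 ** poly
    return float(out[0]) if scalar else out


def gilerson_chla(ratio, coeffs: GilersonCoefficients):
    """``(a*ratio + b)**c``; NaN (scalar: ValueError) where the base <= 0."""
    ratio = np.asarray(ratio, dtype=float)
    base = coeffs.a * ratio + coeffs.b
    if ratio.ndim == 0:
        if not np.isfinite(base) or base <= 0:
            raise ValueError(f"non-positive power base {float(base):g}")
        # same ufunc call as the vector path so both agree bit-for-bit
        return float((np.atleast_1d(base) ** coeffs.c)[0])
    out = np.full(base.shape, np.nan)
    ok = np.isfinite(base) & (base > 0)
    out[ok] = base[ok] ** coeffs.c
    return out


def gons_backscatter(rw779, coeffs: GonsCoefficients):
    """Particulate backscattering ``bb`` (m^-1) inverted from NIR reflectance:
    ``bb = k_scatter*aw779*rw779 / (k_gamma - k_scatter*rw779)``.

    Valid for ``0 <= rw779 < k_gamma/k_scatter``; monotone increasing there.
    """
    rw779 = np.asarray(rw779, dtype=float)
    den = coeffs.k_gamma - coeffs.k_scatter * rw779
    num = coeffs.k_scatter * coeffs.aw779 * rw779
    if rw779.ndim == 0:
        if not np.isfinite(den) or den <= 0 or rw779 < 0:
            raise ValueError("NIR reflectance outside backscatter inversion domain")
        return float(num / den)
    out = np.full(rw779.shape, np.nan)
    ok = np.isfinite(den) & (den > 0) & (rw779 >= 0)
    out[ok] = num[ok] / den[ok]
    return out


def gons_chla(rw665, rw708, rw779, coeffs: GonsCoefficients):
    """Semi-analytical chl-a:
    ``[(rw708/rw665)*(aw709 + bb) - aw665 - bb**p] / a_chl_star``.

    May legitimately be negative (range-filtered downstream); scalar form
    raises only on domain violations, not on negative output.
    """
    scalar = np.ndim(rw665) == 0 and np.ndim(rw708) == 0 and np.ndim(rw779) == 0
    if scalar:
        if rw665 <= 0:
            raise ValueError("non-positive red reflectance")
        # route through the vector path so scalar and bulk agree bit-for-bit
        gons_backscatter(float(rw779), coeffs)  # raises on domain violation
        out = gons_chla(
            np.atleast_1d(float(rw665)),
            np.atleast_1d(float(rw708)),
            np.atleast_1d(float(rw779)),
            coeffs,
        )
        return float(out[0])
    rw665 = np.asarray(rw665, dtype=float)
    rw708 = np.asarray(rw708, dtype=float)
    bb = gons_backscatter(rw779, coeffs)
    out = np.full(np.broadcast(rw665, rw708, bb).shape, np.nan)
    ok = np.isfinite(bb) & np.isfinite(rw665) & np.isfinite(rw708) & (rw665 > 0)
    ratio = np.where(ok, rw708 / np.where(rw665 > 0, rw665, np.nan), np.nan)
    out[ok] = (ratio[ok] * (coeffs.aw709 + bb[ok]) - coeffs.aw665
               - bb[ok] ** coeffs.p) / coeffs.a_chl_star
    return out


def nechad_turbidity(rw, coeffs: NechadCoefficients):
    """``T = A*rw / (1 - rw/C)`` in FNU; valid for ``0 <= rw < C``."""
    rw = np.asarray(rw, dtype=float)
    if rw.ndim == 0:
        if not np.isfinite(rw) or rw < 0 or rw >= coeffs.C:
            raise ValueError(f"reflectance {float(rw):g} outside [0, C={coeffs.C})")
        return float(coeffs.A * rw / (1.0 - rw / coeffs.C))
    out = np.full(rw.shape, np.nan)
    ok = np.isfinite(rw) & (rw >= 0) & (rw < coeffs.C)
    out[ok] = coeffs.A * rw[ok] / (1.0 - rw[ok] / coeffs.C)
    return out


def apply_linear_calibration(value, cal: LinearCalibration):
    """``gain*value + offset`` in the units of the input."""
    value = np.asarray(value, dtype=float)
    out = cal.gain * value + cal.offset
    return float(out) if out.ndim == 0 else out


def scaled_ratio_chla(x, scaling: LinearCalibration, coeffs: OcxCoefficients):
    """OC2 via linear rescaling of the log blue:green ratio.

    The test-sensor ratio ``x`` is mapped onto the reference sensor's ratio
    scale with ``scaling`` and the reference sensor's polynomial applied —
    the alternative alignment pathway to retuning the polynomial itself.
    """
    return ocx_chla(apply_linear_calibration(x, scaling), coeffs)


# ---------------------------------------------------------------------------
# vectorized table application


def _table_ratio(df: pd.DataFrame, sensor: str, kind: str, tally: RejectionTally):
    """Vectorized band_ratio over a matchup table; NaN + tallied reason."""
    n = len(df)
    if kind in ("oc2", "oc3"):
        den = df[reflectance_column(sensor, "b560")].to_numpy(float)
        b490 = df[reflectance_column(sensor, "b490")].to_numpy(float)
        if kind == "oc3":
            b443 = df[reflectance_column(sensor, "b443")].to_numpy(float)
            num = np.fmax(b443, b490)  # fmax ignores NaN in b443
        else:
            num = b490
        present = np.isfinite(num) & np.isfinite(den)
        tally.add(REASON_MISSING_BAND, n - int(present.sum()))
        pos_den = present & (den > 0)
        tally.add(REASON_NONPOS_DENOMINATOR, int((present & ~pos_den).sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pos_den, num / den, np.nan)
        pos_ratio = pos_den & (ratio > 0)
        tally.add(REASON_NONPOS_RATIO, int((pos_den & ~pos_ratio).sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(pos_ratio, np.log10(np.where(ratio > 0, ratio, np.nan)), np.nan)
    if kind == "nir_red":
        num = df[reflectance_column(sensor, "b708")].to_numpy(float)
        den = df[reflectance_column(sensor, "b665")].to_numpy(float)
        present = np.isfinite(num) & np.isfinite(den)
        tally.add(REASON_MISSING_BAND, n - int(present.sum()))
        ok = present & (den > 0)
        tally.add(REASON_NONPOS_DENOMINATOR, int((present & ~ok).sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(ok, num / den, np.nan)
    raise ValueError(f"unknown ratio kind {kind!r}")


def table_band_ratio(df: pd.DataFrame, sensor: str, kind: str) -> np.ndarray:
    """Band ratio column for a whole table (NaN where undefined)."""
    return _table_ratio(df, sensor, kind, RejectionTally())


def _retrieve_chla_column(df, sensor, algorithm, coeffs, tally):
    if algorithm in ("oc2", "oc3"):
        x = _table_ratio(df, sensor, algorithm, tally)
        return ocx_chla(x, coeffs)
    if algorithm == "gilerson":
        x = _table_ratio(df, sensor, "nir_red", tally)
        out = gilerson_chla(x, coeffs)
        tally.add(REASON_NONPOS_BASE, int((np.isfinite(x) & ~np.isfinite(out)).sum()))
        return out
    if algorithm == "gons05":
        rw665 = df[reflectance_column(sensor, "b665")].to_numpy(float)
        rw708 = df[reflectance_column(sensor, "b708")].to_numpy(float)
        rw779 = df[reflectance_column(sensor, "b778")].to_numpy(float)
        present = np.isfinite(rw665) & np.isfinite(rw708) & np.isfinite(rw779)
        tally.add(REASON_MISSING_BAND, len(df) - int(present.sum()))
        bb_ok = present & (coeffs.k_gamma - coeffs.k_scatter * rw779 > 0) & (rw779 >= 0)
        tally.add(REASON_BB_DOMAIN, int((present & ~bb_ok).sum()))
        den_ok = bb_ok & (rw665 > 0)
        tally.add(REASON_NONPOS_DENOMINATOR, int((bb_ok & ~den_ok).sum()))
        out = gons_chla(
            np.where(den_ok, rw665, np.nan),
            rw708,
            np.where(bb_ok, rw779, np.nan),
            coeffs,
        )
        return out
    raise ValueError(f"unknown chl-a algorithm {algorithm!r}")


def retrieve_products(
    df: pd.DataFrame,
    algorithm: str,
    registry: CoefficientRegistry,
    group: str = "initial",
    sensors: tuple[str, ...] = ("msi", "olci"),
    nechad_group: str = "nechad",
    nechad_sensor: str = "shared",
) -> tuple[pd.DataFrame, dict[str, RejectionTally]]:
    """Add per-sensor product columns for one algorithm to a matchup table.

    ``algorithm`` is one of ``oc2|oc3|gilerson|gons05`` (adds
    ``chla_<sensor>``) or ``turbidity_<band>`` (adds ``turbidity_<sensor>``).
    Row count is unchanged; invalid rows get NaN and a tallied reason.
    Unknown algorithm tags and absent coefficient sets are hard errors.
    """
    out = df.copy()
    tallies: dict[str, RejectionTally] = {}
    if algorithm.startswith("turbidity_"):
        band = algorithm.split("_", 1)[1]
        coeffs = registry.get(nechad_group, nechad_sensor, band)
        for sensor in sensors:
            tally = RejectionTally()
            rw = out[reflectance_column(sensor, band)].to_numpy(float)
            tally.add(REASON_MISSING_BAND, int((~np.isfinite(rw)).sum()))
            t = nechad_turbidity(rw, coeffs)
            tally.add(REASON_RW_DOMAIN, int((np.isfinite(rw) & ~np.isfinite(t)).sum()))
            out[f"turbidity_{sensor}"] = t
            tallies[sensor] = tally
        return out, tallies
    if algorithm not in ("oc2", "oc3", "gilerson", "gons05"):
        raise ValueError(f"unknown algorithm tag {algorithm!r}")
    for sensor in sensors:
        tally = RejectionTally()
        # the reference sensor always keeps its published set; only the test
        # sensor switches to a tuned group
        coeffs = registry.get(group if sensor == "msi" else "initial", sensor, algorithm)
        out[f"chla_{sensor}"] = _retrieve_chla_column(out, sensor, algorithm, coeffs, tally)
        tallies[sensor] = tally
    return out, tallies
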