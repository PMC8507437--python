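"""Canonical waveband labels shared by both sensors.

The two sensors place their red-edge and NIR bands at slightly different
centre wavelengths (705 vs 708.75 nm, 783 vs 778.75 nm).  Retrieval formulas
treat these as the same spectral feature, so all tables in this package key
reflectance by a canonical label.  The mapping from nominal centre wavelength
to label is an explicit table so a run can log exactly which physical band
fed each symbol.
"""

from __future__ import annotations

CANONICAL_BANDS: tuple[str, ...] = (
    "b443",
    "b490",
    "b560",
    "b665",
    "b708",
    "b778",
    "b865",
)

#: nominal centre wavelength (nm) -> canonical label.  Both sensors' red-edge
#: and NIR bands collapse onto b708 / b778; 709/779 are alternative spellings
#: of the same bands found in algorithm coefficient sources.
WAVELENGTH_TO_BAND: dict[float, str] = {
    442.5: "b443",
    443.0: "b443",
    490.0: "b490",
    560.0: "b560",
    665.0: "b665",
    705.0: "b708",
    708.0: "b708",
    708.75: "b708",
    709.0: "b708",
    778.0: "b778",
    778.75: "b778",
    779.0: "b778",
    783.0: "b778",
    865.0: "b865",
}

SENSORS: tuple[str, str] = ("msi", "olci")


def band_label(wavelength_nm: float) -> str:
    """Map a nominal band centre (nm) to its canonical label.

    Raises ``KeyError`` naming the wavelength if it is not a recognised band.
    """
    try:
        return WAVELENGTH_TO_BAND[float(wavelength_nm)]
    except KeyError:
        raise KeyError(
            f"no canonical band for wavelength {wavelength_nm} nm; "
            f"known centres: {sorted(WAVELENGTH_TO_BAND)}"
        ) from None


def reflectance_column(sensor: str, band: str) -> str:
    """Column name used in matchup tables, e.g. ``rw_msi_b490``."""
    if sensor not in SENSORS:
        raise ValueError(f"unknown sensor {sensor!r}; expected one of {SENSORS}")
    if band not in CANONICAL_BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {CANONICAL_BANDS}")
    return f"rw_{sensor}_{band}"
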