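"""Coefficient sets for the retrieval algorithms and their JSON registry.

Every algorithm family has a small frozen dataclass holding its parameters,
with validation of the invariants that make the formula well defined (e.g. a
Nechad asymptote strictly between 0 and 1).  A :class:`CoefficientRegistry`
bundles named sets per sensor and algorithm and round-trips losslessly through
JSON; the package ships a registry with the published pre-tuning sets, the
bootstrap-tuned sets and the per-band turbidity gain/offset calibrations.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

ALGORITHMS = ("oc2", "oc3", "gilerson", "gons05")
TURBIDITY_BANDS = ("b665", "b708", "b778", "b865")


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite coefficient {v!r}")


@dataclass(frozen=True)
class OcxCoefficients:
    """Degree-4 polynomial coefficients of an ocean-chlorophyll (OCx) algorithm.

    The retrieval is ``log10 chla = a0 + a1*x + a2*x**2 + a3*x**3 + a4*x**4``
    with ``x`` the log10 blue:green band ratio.
    """

    a0: float
    a1: float
    a2: float
    a3: float
    a4: float
    sensor: str = ""
    algorithm: str = "oc2"

    def __post_init__(self) -> None:
        _require_finite("OcxCoefficients", self.a0, self.a1, self.a2, self.a3, self.a4)
        if self.algorithm not in ("oc2", "oc3"):
            raise ValueError(f"OCx algorithm tag must be oc2 or oc3, got {self.algorithm!r}")

    @property
    def values(self) -> tuple[float, float, float, float, float]:
        return (self.a0, self.a1, self.a2, self.a3, self.a4)

    @property
    def names(self) -> tuple[str, ...]:
        return ("a0", "a1", "a2", "a3", "a4")


@dataclass(frozen=True)
class GilersonCoefficients:
    """NIR:red ratio algorithm ``chla = (a*x + b)**c``.

    ``b`` is stored signed (the published set has b = -19.30) so the formula
    written with a plus sign reproduces the published ``35.75*x - 19.30`` form.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        _require_finite("GilersonCoefficients", self.a, self.b, self.c)
        if self.a == 0:
            raise ValueError("GilersonCoefficients: a must be nonzero")
        if self.c <= 0:
            raise ValueError("GilersonCoefficients: c must be positive")

    @property
    def values(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def names(self) -> tuple[str, ...]:
        return ("a", "b", "c")


@dataclass(frozen=True)
class GonsCoefficients:
    """Semi-analytical NIR:red algorithm parameters.

    Only ``p`` (backscatter exponent) and ``a_chl_star`` (chl-a specific
    absorption at 665 nm, m^2 mg^-1) are tunable.  The pure-water absorptions
    ``aw665/aw709/aw779`` (m^-1) and the backscatter-inversion constants
    ``k_scatter``/``k_gamma`` are fixed configuration.
    """

    p: float
    a_chl_star: float
    aw665: float = 0.40
    aw709: float = 0.70
    aw779: float = 2.71
    k_scatter: float = 0.6
    k_gamma: float = 0.082

    def __post_init__(self) -> None:
        _require_finite(
            "GonsCoefficients",
            self.p, self.a_chl_star, self.aw665, self.aw709, self.aw779,
            self.k_scatter, self.k_gamma,
        )
        if self.a_chl_star <= 0:
            raise ValueError("GonsCoefficients: a_chl_star must be positive")
        if min(self.aw665, self.aw709, self.aw779) <= 0:
            raise ValueError("GonsCoefficients: pure-water absorptions must be positive")

    @property
    def values(self) -> tuple[float, float]:
        return (self.p, self.a_chl_star)

    @property
    def names(self) -> tuple[str, ...]:
        return ("p", "a_chl_star")


@dataclass(frozen=True)
class NechadCoefficients:
    """Single-band turbidity model ``T = A*rw / (1 - rw/C)`` (T in FNU)."""

    A: float
    C: float
    band: str = "b708"

    def __post_init__(self) -> None:
        _require_finite("NechadCoefficients", self.A, self.C)
        if self.A <= 0:
            raise ValueError("NechadCoefficients: amplitude A must be positive")
        if not (0 < self.C < 1):
            raise ValueError("NechadCoefficients: asymptote C must lie in (0, 1)")

    @property
    def values(self) -> tuple[float, float]:
        return (self.A, self.C)

    @property
    def names(self) -> tuple[str, ...]:
        return ("A", "C")


@dataclass(frozen=True)
class LinearCalibration:
    """Gain/offset pair ``y = gain*x + offset``.

    Used both for the per-band turbidity calibration (offset in FNU) and for
    the blue-green log-ratio rescaling (dimensionless).
    """

    gain: float
    offset: float

    def __post_init__(self) -> None:
        _require_finite("LinearCalibration", self.gain, self.offset)
        if self.gain == 0:
            raise ValueError("LinearCalibration: gain must be nonzero")

    @property
    def values(self) -> tuple[float, float]:
        return (self.gain, self.offset)

    @property
    def names(self) -> tuple[str, ...]:
        return ("gain", "offset")


CoefficientSet = Union[
    OcxCoefficients, GilersonCoefficients, GonsCoefficients,
    NechadCoefficients, LinearCalibration,
]

_FAMILY_BY_KIND = {
    "ocx": OcxCoefficients,
    "gilerson": GilersonCoefficients,
    "gons05": GonsCoefficients,
    "nechad": NechadCoefficients,
    "linear": LinearCalibration,
}
_KIND_BY_FAMILY = {v: k for k, v in _FAMILY_BY_KIND.items()}


def coefficients_to_dict(coeffs: CoefficientSet) -> dict:
    d = asdict(coeffs)
    d["kind"] = _KIND_BY_FAMILY[type(coeffs)]
    return d


def coefficients_from_dict(d: Mapping) -> CoefficientSet:
    d = dict(d)
    kind = d.pop("kind")
    return _FAMILY_BY_KIND[kind](**d)


@dataclass
class CoefficientRegistry:
    """Named coefficient sets keyed ``group -> sensor -> algorithm``.

    Groups in the shipped registry: ``initial`` (published pre-tuning sets),
    ``tuned`` (bootstrap-tuned sets for the high-resolution sensor),
    ``turbidity_calibration`` (per-band gain/offset), ``nechad`` (per-band
    A/C), ``ratio_scaling`` (blue-green log-ratio rescaling).
    """

    groups: dict = field(default_factory=dict)

    def get(self, group: str, sensor: str, algorithm: str) -> CoefficientSet:
        try:
            return self.groups[group][sensor][algorithm]
        except KeyError:
            raise KeyError(
                f"registry has no coefficient set for group={group!r} "
                f"sensor={sensor!r} algorithm={algorithm!r}"
            ) from None

    def put(self, group: str, sensor: str, algorithm: str, coeffs: CoefficientSet) -> None:
        self.groups.setdefault(group, {}).setdefault(sensor, {})[algorithm] = coeffs

    def sensors(self, group: str) -> Iterable[str]:
        return self.groups.get(group, {}).keys()

    def to_json(self) -> str:
        payload = {
            g: {s: {a: coefficients_to_dict(c) for a, c in algs.items()}
                for s, algs in sensors.items()}
            for g, sensors in self.groups.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CoefficientRegistry":
        return cls.from_mapping(json.loads(text))

    def save(self, path: Path | str) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Path | str) -> "CoefficientRegistry":
        return cls.from_json(Path(path).read_text())


    @classmethod
    def from_mapping(cls, raw: Mapping) -> "CoefficientRegistry":
        groups = {
            g: {s: {a: coefficients_from_dict(c) for a, c in algs.items()}
                for s, algs in sensors.items()}
            for g, sensors in raw.items() if not g.startswith("_")
        }
        return cls(groups=groups)


def default_registry() -> CoefficientRegistry:
    """The registry shipped with the package.

    Carries the published pre-tuning coefficient sets, the bootstrap-tuned
    sets, the per-band turbidity calibrations and the blue-green ratio
    rescaling.  The ``nechad`` group is a synthetic per-band A/C fixture
    (see ``data/nechad_synthetic.json``): the study underlying the tuned sets
    uses external look-up tables it does not reprint, so real applications
    should supply their own.
    """
    data = resources.files("lakealign.data")
    reg = CoefficientRegistry.from_json(data.joinpath("registry.json").read_text())
    nechad = json.loads(data.joinpath("nechad_synthetic.json").read_text())
    for g, sensors in CoefficientRegistry.from_mapping(nechad).groups.items():
        for s, algs in sensors.items():
            for a, c in algs.items():
                reg.put(g, s, a, c)
    return reg
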