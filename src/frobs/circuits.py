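"""Equivalent-circuit models of the electrode–tissue interface (ETI).

The recording chain is modeled as the electrode impedance ``Z(jw)`` feeding
a high-impedance amplifier through a shunt capacitance ``Cs`` (wires,
connectors, amplifier input), which together form a voltage divider

    H(jw) = 1 / (jw * Cs * Z(jw) + 1).

Two electrode topologies are supported:

* ``uncoated`` (bare gold): a Randles-type circuit — spreading resistance
  ``Rs`` in series with the double-layer capacitance ``Cdl`` in parallel
  with the faradaic branch (charge-transfer resistance ``RCT`` in series
  with a constant phase element ``Q``).
* ``coated`` (conducting-polymer, e.g. PEDOT:PSS): ``Rs`` in series with
  ``Cdl`` in parallel with a semi-infinite Warburg diffusion element.

Conventions (engineering, +jwt): capacitive impedances carry a negative
imaginary part; CPE impedance is ``1/(Q*(jw)**n)``; Warburg impedance is
``sigma*(1-1j)/sqrt(w)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

__all__ = [
    "ConfigurationError",
    "DEFAULT_SHUNT",
    "ElementParams",
    "CircuitParams",
    "ShuntSpec",
    "ImpedanceSpectrum",
    "TransferCurve",
    "element_impedance",
    "circuit_impedance",
    "transfer_function",
    "cutoff_frequency",
    "shunt_total",
    "log_grid",
    "PRESETS",
]

TWO_PI = 2.0 * math.pi


class ConfigurationError(ValueError):
    """Raised when a circuit/band/pipeline configuration is inconsistent."""


@dataclass(frozen=True)
class ElementParams:
    """A single circuit element; only the fields relevant to ``kind`` are set."""

    kind: Literal["resistor", "capacitor", "cpe", "warburg"]
    resistance: Optional[float] = None       # Ohm
    capacitance: Optional[float] = None      # F
    cpe_magnitude: Optional[float] = None    # F-equivalent (Q)
    cpe_exponent: Optional[float] = None     # dimensionless n in (0, 1]
    warburg_coeff: Optional[float] = None    # Ohm * s^-0.5

    def __post_init__(self) -> None:
        required = {
            "resistor": ("resistance",),
            "capacitor": ("capacitance",),
            "cpe": ("cpe_magnitude", "cpe_exponent"),
            "warburg": ("warburg_coeff",),
        }
        if self.kind not in required:
            raise ConfigurationError(f"unknown element kind {self.kind!r}")
        for name in required[self.kind]:
            value = getattr(self, name)
            if value is None or not value > 0:
                raise ConfigurationError(f"{self.kind}: {name} must be set and > 0")
        if self.kind == "cpe" and not 0 < self.cpe_exponent <= 1:
            raise ConfigurationError("cpe_exponent n must lie in (0, 1]")


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of one ETI equivalent circuit.

    ``uncoated`` requires Rs, Cdl, RCT, Q and n; ``coated`` requires Rs, Cdl
    and the Warburg coefficient ``sigma_w``.
    """

    topology: Literal["uncoated", "coated"]
    Rs: float                       # Ohm, spreading resistance
    Cdl: float                      # F, double-layer capacitance
    RCT: Optional[float] = None     # Ohm, charge-transfer resistance
    Q: Optional[float] = None       # F-equivalent, CPE magnitude
    n: Optional[float] = None       # CPE exponent
    sigma_w: Optional[float] = None  # Ohm * s^-0.5, Warburg coefficient

    def __post_init__(self) -> None:
        if self.topology not in ("uncoated", "coated"):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if not (self.Rs > 0 and self.Cdl > 0):
            raise ConfigurationError("Rs and Cdl must be > 0")
        if self.topology == "uncoated":
            if self.RCT is None or self.Q is None or self.n is None:
                raise ConfigurationError("uncoated topology needs RCT, Q and n")
            if not (self.RCT > 0 and self.Q > 0):
                raise ConfigurationError("RCT and Q must be > 0")
            if not 0 < self.n <= 1:
                raise ConfigurationError("CPE exponent n must lie in (0, 1]")
        else:
            if self.sigma_w is None or not self.sigma_w > 0:
                raise ConfigurationError("coated topology needs sigma_w > 0")

    def free_names(self) -> tuple[str, ...]:
        """Names of the parameters that define this topology, fit order."""
        if self.topology == "uncoated":
            return ("Rs", "Cdl", "RCT", "Q", "n")
        return ("Rs", "Cdl", "sigma_w")


@dataclass(frozen=True)
class ShuntSpec:
    """Total shunt capacitance between electrode and amplifier input."""

    C_wires_connector: float = 0.0  # F
    C_amplifier: float = 0.0        # F
    Cs: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.C_wires_connector < 0 or self.C_amplifier < 0:
            raise ConfigurationError("shunt capacitances must be >= 0")
        total = self.C_wires_connector + self.C_amplifier
        if self.Cs is None:
            object.__setattr__(self, "Cs", total)
        elif not math.isclose(self.Cs, total, rel_tol=1e-12, abs_tol=1e-18):
            raise ConfigurationError("Cs must equal C_wires_connector + C_amplifier")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance sampled on a strictly increasing positive grid."""

    frequencies: np.ndarray  # Hz
    impedances: np.ndarray   # complex Ohm

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.impedances, dtype=complex)
        if f.ndim != 1 or z.ndim != 1 or f.size != z.size:
            raise ValueError("frequencies and impedances must be 1-D, same length")
        if f.size and (np.any(f <= 0) or np.any(np.diff(f) <= 0)):
            raise ValueError("frequencies must be positive and strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "impedances", z)

    def __len__(self) -> int:
        return self.frequencies.size


@dataclass(frozen=True)
class TransferCurve:
    """Voltage-divider gain H(jw) = Vout/Vin on a frequency grid."""

    frequencies: np.ndarray  # Hz
    gains: np.ndarray        # complex, dimensionless

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        g = np.asarray(self.gains, dtype=complex)
        if f.shape != g.shape or f.ndim != 1:
            raise ValueError("frequencies and gains must be 1-D, same length")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "gains", g)

    def magnitude_db(self) -> np.ndarray:
        return 20.0 * np.log10(np.abs(self.gains))


def element_impedance(element: ElementParams, frequency: float) -> complex:
    """Impedance of a single element at one frequency (Hz)."""
    if not frequency > 0:
        raise ValueError("frequency must be > 0")
    w = TWO_PI * frequency
    if element.kind == "resistor":
        return complex(element.resistance)
    if element.kind == "capacitor":
        return 1.0 / (1j * w * element.capacitance)
    if element.kind == "cpe":
        return 1.0 / (element.cpe_magnitude * (1j * w) ** element.cpe_exponent)
    # warburg, semi-infinite
    return element.warburg_coeff * (1.0 - 1.0j) / math.sqrt(w)


def circuit_impedance(
    params: CircuitParams,
    frequencies: np.ndarray,
    coated_form: Literal["parallel", "series"] = "parallel",
) -> ImpedanceSpectrum:
    """Evaluate the circuit impedance on a frequency grid.

    Default reading is the Randles form: Rs in series with [Cdl parallel to
    the faradaic branch].  ``coated_form="series"`` switches the coated
    circuit to the literal series sum Rs + 1/(jwCdl) + Z_W.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be > 0")
    w = TWO_PI * f
    jw = 1j * w
    if params.topology == "uncoated":
        z_cpe = 1.0 / (params.Q * jw ** params.n)
        z = params.Rs + 1.0 / (jw * params.Cdl + 1.0 / (params.RCT + z_cpe))
    else:
        z_w = params.sigma_w * (1.0 - 1.0j) / np.sqrt(w)
        if coated_form == "parallel":
            z = params.Rs + 1.0 / (jw * params.Cdl + 1.0 / z_w)
        elif coated_form == "series":
            z = params.Rs + 1.0 / (jw * params.Cdl) + z_w
        else:
            raise ConfigurationError(f"unknown coated_form {coated_form!r}")
    return ImpedanceSpectrum(f, z)


def transfer_function(Z: ImpedanceSpectrum, shunt: ShuntSpec) -> TransferCurve:
    """Recording-chain transfer function H(jw) = 1 / (jw * Cs * Z + 1)."""
    if shunt.Cs < 0:
        raise ConfigurationError("Cs must be >= 0")
    w = TWO_PI * Z.frequencies
    gains = 1.0 / (1j * w * shunt.Cs * Z.impedances + 1.0)
    return TransferCurve(Z.frequencies, gains)


def cutoff_frequency(T: TransferCurve, drop_db: float = 3.0) -> Optional[float]:
    """Lowest frequency where |H| has dropped ``drop_db`` below its
    low-frequency value, located by log-linear interpolation.

    Returns None if the curve never drops that far.
    """
    if len(T.frequencies) == 0:
        raise ValueError("empty transfer curve")
    mag_db = T.magnitude_db()
    target = mag_db[0] - drop_db
    below = np.nonzero(mag_db <= target)[0]
    if below.size == 0 or below[0] == 0:
        return None if below.size == 0 else float(T.frequencies[0])
    i = below[0]
    # interpolate in (log f, dB) between grid points i-1 and i
    lf0, lf1 = math.log(T.frequencies[i - 1]), math.log(T.frequencies[i])
    d0, d1 = mag_db[i - 1], mag_db[i]
    frac = (target - d0) / (d1 - d0)
    return math.exp(lf0 + frac * (lf1 - lf0))


def shunt_total(C_wires_connector: float, C_amplifier: float) -> ShuntSpec:
    """Sum the parasitic wire/connector and amplifier capacitances."""
    return ShuntSpec(C_wires_connector=C_wires_connector, C_amplifier=C_amplifier)


def log_grid(f_min: float = 1.0, f_max: float = 1e4, points_per_decade: int = 50) -> np.ndarray:
    """Log-spaced frequency grid, default 50 points per decade over 1 Hz–10 kHz."""
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    n = int(round(math.log10(f_max / f_min) * points_per_decade)) + 1
    return np.geomspace(f_min, f_max, n)


#: Canonical parameter presets.  `au` / `au_pedot` are the fitted mean values
#: of the gold and polymer-coated electrode circuits; the `_reported`
#: variants are the alternative in-text figures, kept for reference only.
PRESETS: dict[str, CircuitParams] = {
    "au": CircuitParams(
        topology="uncoated", Rs=3e3, Cdl=1.036e-9, RCT=12.24e3, Q=10.97e-9, n=0.890
    ),
    "au_pedot": CircuitParams(topology="coated", Rs=3e3, Cdl=1.73e-6, sigma_w=10.24e3),
    "au_reported": CircuitParams(
        topology="uncoated", Rs=2e3, Cdl=6e-9, RCT=1e-6, Q=10.97e-9, n=0.890
    ),
    "au_pedot_reported": CircuitParams(topology="coated", Rs=2e3, Cdl=1.32e-6, sigma_w=11.0),
}

#: Default shunt capacitance: 1 nF wires/connectors + 2 nF amplifier = 3 nF total.
DEFAULT_SHUNT = ShuntSpec(C_wires_connector=1e-9, C_amplifier=2e-9)
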