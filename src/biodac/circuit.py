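"""Analog conditioning-circuit model: attenuation, calibration, noise budget.

The conditioning stage is a two-resistor voltage divider — a coarse switched
resistor R1 (1 MΩ or 10 MΩ) in series with a 2 kΩ potentiometer Rp to ground
— optionally followed by a unity-gain op-amp buffer.  The divider scales the
line-level DAC output down to physiological amplitudes:

    attenuation ratio = (R1 + Rp) / Rp          (input : output)

With R1 ∈ {1 MΩ, 10 MΩ} and Rp ∈ [100 Ω, 2 kΩ] the ratio spans 501:1 to
100 001:1, i.e. a 6.4 Vpp full-scale converter output becomes anything from
12.77 mVpp down to 64 μVpp at the output terminals.  Amplitudes below the
analog floor are reached by additionally scaling the digital samples, at a
proportional cost in dynamic range.

The noise model sums, in quadrature, the three dominant sources referred to
the circuit output:

* Johnson (thermal) noise of the divider's parallel source resistance
  R_s = R1 ∥ Rp:  e_J = √(4 k T R_s),
* the buffer op-amp's input voltage noise with a 1/f corner:
  e_v(f) = e_white · √(1 + f_c / f),
* the op-amp's input current noise flowing through R_s:  i_n · R_s.

Integrating the squared total density over a band gives the cumulative RMS
noise, the figure compared against a recording amplifier's noise floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.constants import Boltzmann as _K_BOLTZMANN
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, DomainError, UnreachableTargetError

#: Allowed values of the coarse switched resistor, in ohms.
COARSE_RESISTANCES = (1e6, 1e7)

#: Potentiometer travel actually used, in ohms.  The lower bound reflects the
#: operating rule that the pot is never turned below 100 Ω.
POT_MIN = 100.0
POT_MAX = 2000.0


@dataclass(frozen=True)
class DividerSetting:
    """One channel's analog configuration.

    Attributes
    ----------
    coarse_resistance
        Series resistor R1 in ohms; must be 1e6 or 1e7.
    pot_resistance
        Potentiometer (shunt) resistance Rp in ohms, continuous in
        [100, 2000].
    buffered
        Whether the unity-gain output buffer is engaged.
    """

    coarse_resistance: float
    pot_resistance: float
    buffered: bool = True

    def __post_init__(self):
        if self.coarse_resistance not in COARSE_RESISTANCES:
            raise ConfigurationError(
                f"coarse_resistance must be one of {COARSE_RESISTANCES} ohm, "
                f"got {self.coarse_resistance!r}"
            )
        if not (POT_MIN <= self.pot_resistance <= POT_MAX):
            raise ConfigurationError(
                f"pot_resistance must lie in [{POT_MIN}, {POT_MAX}] ohm, "
                f"got {self.pot_resistance!r}"
            )

    @property
    def source_resistance(self) -> float:
        """Parallel combination R1 ∥ Rp seen looking back into the divider."""
        r1, rp = self.coarse_resistance, self.pot_resistance
        return r1 * rp / (r1 + rp)

    def to_dict(self) -> dict:
        return {
            "coarse_resistance_ohm": self.coarse_resistance,
            "pot_resistance_ohm": self.pot_resistance,
            "buffered": self.buffered,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DividerSetting":
        return cls(
            coarse_resistance=float(d["coarse_resistance_ohm"]),
            pot_resistance=float(d["pot_resistance_ohm"]),
            buffered=bool(d.get("buffered", True)),
        )


@dataclass(frozen=True)
class NoiseModelParams:
    """Parameters of the analog noise model.

    Defaults are the buffer op-amp's datasheet figures (a low-voltage-noise
    bipolar part): 2.5 nV/√Hz white voltage noise with a 2 Hz 1/f corner and
    0.4 pA/√Hz current noise.  Temperature defaults to 300 K.
    """

    temperature: float = 300.0                      # K
    opamp_voltage_noise_white: float = 2.5e-9       # V/√Hz
    opamp_current_noise: float = 0.4e-12            # A/√Hz
    flicker_corner: float = 2.0                     # Hz

    def __post_init__(self):
        for name in (
            "temperature",
            "opamp_voltage_noise_white",
            "opamp_current_noise",
            "flicker_corner",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")


@dataclass
class NoiseBudget:
    """Per-source and total noise densities on a frequency grid.

    ``cumulative_rms`` is the RMS noise integrated from the grid's lowest
    frequency up to each grid point, so it is non-decreasing.
    """

    frequencies: np.ndarray          # Hz
    johnson_density: np.ndarray      # V/√Hz
    opamp_voltage_density: np.ndarray
    opamp_current_density: np.ndarray
    total_density: np.ndarray
    cumulative_rms: np.ndarray       # Vrms

    def to_table(self) -> np.ndarray:
        """Columns: frequency, per-source densities, total, cumulative RMS."""
        return np.column_stack(
            [
                self.frequencies,
                self.johnson_density,
                self.opamp_voltage_density,
                self.opamp_current_density,
                self.total_density,
                self.cumulative_rms,
            ]
        )

    def save(self, path: str | Path, delimiter: str = "\t") -> None:
        header = delimiter.join(
            [
                "frequency_hz",
                "johnson_v_per_rthz",
                "opamp_voltage_v_per_rthz",
                "opamp_current_v_per_rthz",
                "total_v_per_rthz",
                "cumulative_vrms",
            ]
        )
        np.savetxt(path, self.to_table(), delimiter=delimiter, header=header)


# ---------------------------------------------------------------------------
# divider arithmetic
# ---------------------------------------------------------------------------

def attenuation_ratio(setting: DividerSetting) -> float:
    """Input:output voltage ratio (R1 + Rp) / Rp of the divider.

    Strictly decreasing in the pot resistance and increasing in the coarse
    resistor; spans exactly [501, 100001] over the allowed settings.
    """
    return (setting.coarse_resistance + setting.pot_resistance) / setting.pot_resistance


def output_dynamic_range(setting: DividerSetting, dac_fullscale: float) -> float:
    """Peak-to-peak output span (volts) for a given DAC full scale (Vpp)."""
    if not dac_fullscale > 0:
        raise DomainError("dac_fullscale must be positive")
    return dac_fullscale / attenuation_ratio(setting)


def settings_for_target_peak(
    target_peak: float,
    dac_fullscale: float = 6.4,
    buffered: bool = True,
) -> tuple[DividerSetting, float]:
    """Divider setting (and digital scale) whose output peak equals a target.

    Inverts the ratio formula so that the converter's maximum output
    amplitude (``dac_fullscale / 2``) maps onto ``target_peak`` volts.  Pure
    analog attenuation (digital scale 1) is preferred; only targets below the
    minimum analog range fall back to digital scaling at the
    maximum-attenuation setting, trading away dynamic range proportionally.

    Returns
    -------
    (setting, digital_scale)
        ``digital_scale`` ∈ (0, 1]; forward-evaluating
        ``digital_scale * (dac_fullscale / 2) / attenuation_ratio(setting)``
        reproduces ``target_peak``.

    Raises
    ------
    UnreachableTargetError
        If the target exceeds the maximum achievable analog peak.
    """
    if not target_peak > 0:
        raise DomainError("target_peak must be positive")
    peak_in = dac_fullscale / 2.0
    ratio_needed = peak_in / target_peak

    min_ratio = (COARSE_RESISTANCES[0] + POT_MAX) / POT_MAX          # 501
    max_ratio_1m = (COARSE_RESISTANCES[0] + POT_MIN) / POT_MIN       # 10 001
    max_ratio = (COARSE_RESISTANCES[1] + POT_MIN) / POT_MIN          # 100 001

    if ratio_needed < min_ratio:
        raise UnreachableTargetError(
            f"target peak {target_peak:g} V exceeds the maximum analog peak "
            f"{peak_in / min_ratio:g} V"
        )
    if ratio_needed <= max_ratio_1m:
        r1 = COARSE_RESISTANCES[0]
    elif ratio_needed <= max_ratio:
        r1 = COARSE_RESISTANCES[1]
    else:
        # below the analog floor: max attenuation + digital scaling
        setting = DividerSetting(COARSE_RESISTANCES[1], POT_MIN, buffered)
        return setting, max_ratio / ratio_needed

    rp = r1 / (ratio_needed - 1.0)
    rp = min(max(rp, POT_MIN), POT_MAX)  # guard float round-off at the ends
    return DividerSetting(r1, rp, buffered), 1.0


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

def johnson_noise_density(resistance: float, temperature: float = 300.0) -> float:
    """Thermal noise voltage density √(4 k T R) in V/√Hz."""
    if resistance < 0:
        raise DomainError("resistance must be non-negative")
    if not temperature > 0:
        raise DomainError("temperature must be positive")
    return float(np.sqrt(4.0 * _K_BOLTZMANN * temperature * resistance))


def opamp_voltage_noise_density(frequency, params: NoiseModelParams | None = None):
    """Op-amp input voltage noise density with 1/f corner, V/√Hz.

    Uses the standard single-corner form e(f) = e_white · √(1 + f_c / f):
    flat well above the corner, rising as 1/√f below it.  Accepts scalar or
    array frequency.
    """
    params = params or NoiseModelParams()
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequency must be strictly positive")
    out = params.opamp_voltage_noise_white * np.sqrt(1.0 + params.flicker_corner / f)
    return float(out) if np.isscalar(frequency) else out


def total_output_noise_density(
    setting: DividerSetting,
    frequency,
    params: NoiseModelParams | None = None,
):
    """Total output-referred noise density, V/√Hz, at one or more frequencies.

    Quadrature sum of the Johnson noise of the source resistance R1 ∥ Rp,
    the op-amp voltage noise, and the op-amp current noise converted through
    that same source resistance.
    """
    params = params or NoiseModelParams()
    r_s = setting.source_resistance
    e_j = johnson_noise_density(r_s, params.temperature)
    e_v = opamp_voltage_noise_density(frequency, params)
    e_i = params.opamp_current_noise * r_s
    out = np.sqrt(e_j**2 + np.square(e_v) + e_i**2)
    return float(out) if np.isscalar(frequency) else out


def _log_grid(band_low: float, band_high: float, points_per_band: int) -> np.ndarray:
    return np.logspace(np.log10(band_low), np.log10(band_high), points_per_band)


def cumulative_rms_noise(
    setting: DividerSetting,
    band_low: float,
    band_high: float,
    params: NoiseModelParams | None = None,
    points: int = 4000,
) -> float:
    """RMS noise √(∫ e_total²(f) df) over [band_low, band_high], in Vrms.

    Integrated by the trapezoidal rule on a log-spaced grid, which resolves
    the 1/f region without wasting points at high frequency.  ``points``
    defaults to 4000 per band (≥ 1000 keeps the closed-form white-noise check
    well inside 0.1 %).
    """
    if not (0 < band_low <= band_high):
        raise DomainError("require 0 < band_low <= band_high")
    if band_low == band_high:
        return 0.0
    f = _log_grid(band_low, band_high, points)
    density = total_output_noise_density(setting, f, params)
    power = np.trapezoid(np.square(density), f)
    return float(np.sqrt(power))


def noise_budget(
    setting: DividerSetting,
    band_low: float = 0.1,
    band_high: float = 1e4,
    params: NoiseModelParams | None = None,
    points: int = 4000,
) -> NoiseBudget:
    """Full per-source noise budget on a log-spaced grid over a band."""
    if not (0 < band_low < band_high):
        raise DomainError("require 0 < band_low < band_high")
    params = params or NoiseModelParams()
    f = _log_grid(band_low, band_high, points)
    r_s = setting.source_resistance
    e_j = np.full_like(f, johnson_noise_density(r_s, params.temperature))
    e_v = opamp_voltage_noise_density(f, params)
    e_i = np.full_like(f, params.opamp_current_noise * r_s)
    total = np.sqrt(e_j**2 + e_v**2 + e_i**2)
    cum_power = cumulative_trapezoid(total**2, f, initial=0.0)
    return NoiseBudget(
        frequencies=f,
        johnson_density=e_j,
        opamp_voltage_density=e_v,
        opamp_current_density=e_i,
        total_density=total,
        cumulative_rms=np.sqrt(cum_power),
    )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def loaded_output_voltage(
    setting: DividerSetting,
    open_circuit_voltage: float,
    load_impedance: float,
) -> float:
    """Output voltage into a finite load.

    A buffered channel is modeled as an ideal unity-gain buffer: the load
    sees the open-circuit voltage regardless of its impedance.  Unbuffered,
    the divider's output impedance Z_out = R1 ∥ Rp forms a further divider
    with the load: V = V_oc · Z_L / (Z_L + Z_out).
    """
    if setting.buffered:
        if not (load_impedance > 0 or np.isinf(load_impedance)):
            raise DomainError("load_impedance must be positive or infinite")
        return open_circuit_voltage
    if np.isinf(load_impedance):
        return open_circuit_voltage
    if not load_impedance > 0:
        raise DomainError("load_impedance must be positive or infinite")
    z_out = setting.source_resistance
    return open_circuit_voltage * load_impedance / (load_impedance + z_out)


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def save_setting(setting: DividerSetting, path: str | Path) -> None:
    Path(path).write_text(json.dumps(setting.to_dict(), indent=2))


def load_setting(path: str | Path) -> DividerSetting:
    return DividerSetting.from_dict(json.loads(Path(path).read_text()))
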