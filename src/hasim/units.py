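"""Unit conversions and project-wide sign conventions.

Sign convention (fixed everywhere in this package): time dependence is
``e^{-j omega t}``, so forward propagation over a distance z multiplies a
plane wave by ``e^{+j k z}`` and a lossy medium attenuates amplitudes by
``e^{-alpha z}`` with ``alpha`` in Np/m.  Attenuation coefficients are
*stored* frequency-normalized in dB/(cm MHz) and converted per run
frequency with :func:`attenuation_to_neper`.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

#: amplitude dB per neper: 20*log10(e) ~= 8.6859
DB_PER_NEPER = 20.0 * np.log10(np.e)

#: default homogeneous-water properties (speed m/s, attenuation dB/(cm MHz), density kg/m^3)
WATER_SPEED = 1500.0
WATER_ATTENUATION = 0.0
WATER_DENSITY = 1000.0


def attenuation_to_neper(a_db_cm_mhz, frequency_hz: float):
    """Convert a frequency-normalized attenuation to Np/m at a given frequency.

    ``a`` in dB/(cm MHz) becomes ``a * (f/1 MHz) * 100 / (20 log10 e)`` Np/m:
    linear in both the coefficient and the frequency.
    """
    a = np.asarray(a_db_cm_mhz, dtype=float)
    if np.any(a < 0):
        raise InvalidParameterError("attenuation coefficient must be >= 0")
    if frequency_hz <= 0:
        raise InvalidParameterError("frequency must be > 0")
    out = a * (frequency_hz / 1e6) * 100.0 / DB_PER_NEPER
    return float(out) if np.isscalar(a_db_cm_mhz) else out


def propagation_constant(speed_m_s, frequency_hz: float):
    """Per-voxel propagation constant b = 2 pi f / c in rad/m."""
    c = np.asarray(speed_m_s, dtype=float)
    if np.any(c <= 0):
        raise InvalidParameterError("speed of sound must be > 0")
    out = 2.0 * np.pi * frequency_hz / c
    return float(out) if np.isscalar(speed_m_s) else out


def wrap_phase(phi):
    """Wrap angles to the principal interval (-pi, pi]."""
    w = np.mod(np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    return float(w) if np.isscalar(phi) else w
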