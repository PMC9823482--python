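"""Periodic waveform templates shared by the simulator and the detector.

Every shape is a 24 h-periodic function of ``t`` = hours after the peak, with
its maximum at ``t = 0 (mod 24)``.  The same functions generate synthetic
cycling genes and build the detector's model library, so parameter recovery
is well-posed by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SHAPES", "DEFAULT_SHAPES", "evaluate"]

_PERIOD = 24.0


def _circular_distance(t: np.ndarray) -> np.ndarray:
    """Shortest circular distance (hours) from the peak."""
    d = np.mod(t, _PERIOD)
    return np.minimum(d, _PERIOD - d)


def cosine(t):
    return np.cos(2.0 * np.pi * np.asarray(t, dtype=float) / _PERIOD)


def sharp_cosine(t):
    """Sharpened cosine: squared raised cosine, a peakier symmetric bump."""
    return ((1.0 + cosine(t)) / 2.0) ** 2


def box(t):
    """50%-duty square wave, high within 6 h of the peak."""
    return (_circular_distance(np.asarray(t, dtype=float)) <= 6.0).astype(float)


def spike(t):
    """Narrow pulse, high within 1 h of the peak (one or two grid samples)."""
    return (_circular_distance(np.asarray(t, dtype=float)) <= 1.0).astype(float)


def ramp_up(t):
    """Asymmetric sawtooth rising linearly all day to the peak, then dropping."""
    return 1.0 - np.mod(-np.asarray(t, dtype=float), _PERIOD) / _PERIOD


def ramp_down(t):
    """Asymmetric sawtooth jumping at the peak, then decaying linearly."""
    return 1.0 - np.mod(np.asarray(t, dtype=float), _PERIOD) / _PERIOD


#: shape id -> callable(hours after peak) -> unit-scale waveform value
SHAPES = {
    "cosine": cosine,
    "sharp_cosine": sharp_cosine,
    "box": box,
    "spike": spike,
    "ramp_up": ramp_up,
    "ramp_down": ramp_down,
}

DEFAULT_SHAPES = tuple(SHAPES)


def evaluate(shape: str, zt: np.ndarray, phase: float) -> np.ndarray:
    """Evaluate ``shape`` on the sampling grid ``zt`` with its peak at ``phase``."""
    try:
        fn = SHAPES[shape]
    except KeyError:
        raise ValueError(f"unknown waveform shape: {shape!r}") from None
    return fn(np.asarray(zt, dtype=float) - float(phase))
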