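"""Small numeric helpers shared across the package."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase into [-pi, pi).

    The single wrap convention used throughout the package; ``pi`` maps
    to ``-pi``.
    """
    return (np.asarray(phi) + np.pi) % TWO_PI - np.pi


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer, ties away from zero.

    numpy's ``round`` ties to even; the cycle-count estimator needs the
    away-from-zero convention so that a residual of exactly half a
    wavelength is pushed outward symmetrically for both signs.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)
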