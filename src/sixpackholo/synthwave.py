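"""Synthetic-wavelength (beat) phase algebra.

Subtracting the phase maps of two wavelengths yields a phase map at the
much longer beat wavelength ``Lambda_D = l1*l2/(l2 - l1)`` (with l1 < l2),
which tolerates proportionally larger optical path delays before wrapping;
adding them yields ``Lambda_S = l1*l2/(l1 + l2)``, shorter than either and
proportionally less noisy in OPD terms.  From three illumination
wavelengths this module builds the full nine-map ladder per field of view:
three subtraction maps, the three illumination maps, and three addition
maps, ordered by descending wavelength for hierarchical unwrapping.

The ladder keeps unrounded wavelengths internally (6206.67 nm, not the
display value 6207 nm): rounding the ladder corrupts the integer cycle
estimation on thick samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._utils import wrap_phase
from .reconstruct import ComplexWavefront


@dataclass
class PhaseMap:
    """A 2D phase field at an effective (illumination or synthetic) wavelength.

    ``amplitude`` optionally carries the magnitude of the complex field(s)
    the phase was read from; it serves as a quality map (near-zero
    amplitude means the phase is undefined, e.g. inside steep edge
    transitions the band-limited field cannot follow).
    """

    phase_rad: np.ndarray
    wavelength_nm: float
    wrapped: bool
    fov: str = "left"
    provenance: str = ""
    amplitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phase_rad = np.asarray(self.phase_rad, dtype=float)
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.wrapped:
            lo, hi = self.phase_rad.min(), self.phase_rad.max()
            if lo < -np.pi - 1e-12 or hi >= np.pi + 1e-12:
                raise ValueError("wrapped phase must lie in [-pi, pi)")

    @property
    def opd_nm(self) -> np.ndarray:
        return self.phase_rad * self.wavelength_nm / (2 * np.pi)


def synthetic_wavelength(l1_nm: float, l2_nm: float, mode: str) -> float:
    """Beat wavelength of two illuminations, unrounded.

    ``subtract`` requires ``l1 < l2`` and returns ``l1*l2/(l2-l1)`` (longer
    than both); ``add`` returns ``l1*l2/(l1+l2)`` (shorter than both).
    """
    if l1_nm <= 0 or l2_nm <= 0:
        raise ValueError("wavelengths must be positive")
    if mode == "subtract":
        if l1_nm >= l2_nm:
            raise ValueError("subtract requires l1 < l2 (reorder at the call site)")
        return l1_nm * l2_nm / (l2_nm - l1_nm)
    if mode == "add":
        return l1_nm * l2_nm / (l1_nm + l2_nm)
    raise ValueError(f"mode must be 'subtract' or 'add', got {mode!r}")


def combine_phases(
    w1: ComplexWavefront, w2: ComplexWavefront, mode: str
) -> PhaseMap:
    """Beat-wavelength phase map from two wavefronts of the same FOV.

    Subtraction divides the complex fields pixelwise (phase difference in
    the exponent); addition multiplies them (phase sum).  The phase is read
    out with the two-argument arctangent and wrapped to [-pi, pi).
    """
    if w1.field.shape != w2.field.shape:
        raise ValueError("wavefront grids differ")
    if w1.fov != w2.fov:
        raise ValueError("wavefronts belong to different FOVs")
    if mode == "subtract" and w1.wavelength_nm >= w2.wavelength_nm:
        raise ValueError("subtract requires w1.wavelength < w2.wavelength")
    z = w1.field * (np.conj(w2.field) if mode == "subtract" else w2.field)
    phase = wrap_phase(np.arctan2(z.imag, z.real))
    lam = synthetic_wavelength(w1.wavelength_nm, w2.wavelength_nm, mode)
    sign = "-" if mode == "subtract" else "+"
    return PhaseMap(
        phase_rad=phase,
        wavelength_nm=lam,
        wrapped=True,
        fov=w1.fov,
        provenance=f"{w1.wavelength_nm:g}nm {sign} {w2.wavelength_nm:g}nm",
        amplitude=np.abs(z),
    )


def nine_map_stack(channels: list[ComplexWavefront]) -> list[PhaseMap]:
    """All nine wrapped phase maps of one FOV, longest wavelength first.

    Input: exactly one wavefront per illumination wavelength (same FOV).
    Output: three subtraction maps, three illumination maps, three addition
    maps, sorted by strictly descending unrounded wavelength — e.g.
    6206.67, 2300.90, 1678.61, 692, 532, 490, 300.77, 286.87, 255.07 nm for
    692/532/490 nm illumination.
    """
    if len(channels) != 3:
        raise ValueError("need exactly three wavefronts (one per wavelength)")
    fovs = {w.fov for w in channels}
    if len(fovs) != 1:
        raise ValueError("wavefronts must share one FOV")
    wavelengths = [w.wavelength_nm for w in channels]
    if len(set(wavelengths)) != 3:
        raise ValueError("need one wavefront per distinct wavelength")
    by_wl = sorted(channels, key=lambda w: w.wavelength_nm)  # ascending
    maps: list[PhaseMap] = []
    for w1, w2 in combinations(by_wl, 2):  # w1.wavelength < w2.wavelength
        maps.append(combine_phases(w1, w2, "subtract"))
        maps.append(combine_phases(w1, w2, "add"))
    for w in by_wl:
        maps.append(
            PhaseMap(
                phase_rad=w.phase,
                wavelength_nm=w.wavelength_nm,
                wrapped=True,
                fov=w.fov,
                provenance=f"{w.wavelength_nm:g}nm",
                amplitude=np.abs(w.field),
            )
        )
    maps.sort(key=lambda m: -m.wavelength_nm)
    wl = [m.wavelength_nm for m in maps]
    if any(later >= earlier for later, earlier in zip(wl[1:], wl[:-1])):
        raise ValueError("ladder wavelengths are not strictly descending")
    return maps
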