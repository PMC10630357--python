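"""Optical data model and frequency-plane carrier geometry.

Six-pack holography multiplexes six off-axis interference channels
(three illumination wavelengths x two fields of view) in a single camera
frame.  Each channel rides on a spatial carrier frequency; in the 2D
Fourier plane of the hologram every channel contributes a cross-correlation
(CC) disk at ``+f``, its complex conjugate at ``-f``, and all channels share
the central autocorrelation (DC) disk.  Reconstruction is only possible if
the six CC disks, their six conjugates, and the DC disk are pairwise
disjoint and contained in the Nyquist square.  This module holds the
configuration types, the coherent-bandwidth formula that sets the disk
radii, a validated default carrier placement, and the constraint checker.

Frequency units are cycles per (camera) pixel everywhere, which makes the
carrier geometry independent of the grid size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

FOV_LABELS = ("left", "right")


class ConfigurationError(ValueError):
    """Raised when an optical configuration cannot satisfy its constraints."""


@dataclass(frozen=True)
class OpticsConfig:
    """Geometry of the microscope + camera that formed the hologram.

    Defaults describe a 20x/0.42 objective with a doubling relay (total
    lateral magnification 40x) and a 12-bit camera with 5.86 um square
    pixels, illuminated at 692/532/490 nm.
    """

    wavelengths_nm: tuple[float, float, float] = (692.0, 532.0, 490.0)
    na: float = 0.42
    magnification: float = 40.0
    pixel_pitch_um: float = 5.86
    bit_depth: int = 12
    grid_shape: tuple[int, int] = (1024, 1024)
    coherence_length_um: float = 25.4  # metadata only; not used numerically

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths_nm)
        if len(wl) != 3 or any(w <= 0 for w in wl) or len(set(wl)) != 3:
            raise ConfigurationError(
                "wavelengths_nm must be three positive, pairwise distinct values"
            )
        object.__setattr__(self, "wavelengths_nm", wl)
        if not 0 < self.na <= 1:
            raise ConfigurationError("na must lie in (0, 1]")
        if self.magnification <= 0:
            raise ConfigurationError("magnification must be positive")
        if self.pixel_pitch_um <= 0:
            raise ConfigurationError("pixel_pitch_um must be positive")
        if self.bit_depth not in (8, 12, 16):
            raise ConfigurationError("bit_depth must be one of 8, 12, 16")
        h, w = self.grid_shape
        if h < 128 or w < 128 or h % 2 or w % 2:
            raise ConfigurationError("grid dimensions must be even and >= 128")
        object.__setattr__(self, "grid_shape", (int(h), int(w)))

    @property
    def object_pixel_um(self) -> float:
        """Sampling interval in the object plane (camera pitch / magnification)."""
        return self.pixel_pitch_um / self.magnification

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": list(self.wavelengths_nm),
            "na": self.na,
            "magnification": self.magnification,
            "pixel_pitch_um": self.pixel_pitch_um,
            "bit_depth": self.bit_depth,
            "grid_shape": list(self.grid_shape),
            "coherence_length_um": self.coherence_length_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsConfig":
        d = dict(d)
        if "wavelengths_nm" in d:
            d["wavelengths_nm"] = tuple(d["wavelengths_nm"])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def with_grid(self, shape: tuple[int, int]) -> "OpticsConfig":
        return replace(self, grid_shape=shape)


@dataclass(frozen=True)
class Carrier:
    """One channel's carrier frequency, tagged with its identity."""

    fy: float
    fx: float
    wavelength_nm: float
    fov: str

    def __post_init__(self) -> None:
        if self.fov not in FOV_LABELS:
            raise ConfigurationError(f"fov must be one of {FOV_LABELS}")

    @property
    def f(self) -> np.ndarray:
        return np.array([self.fy, self.fx])


@dataclass(frozen=True)
class CarrierSet:
    """Six carriers, one per (wavelength, fov), plus the common CC radius."""

    carriers: tuple[Carrier, ...]
    cc_radius: float

    def __post_init__(self) -> None:
        if len(self.carriers) != 6:
            raise ConfigurationError("a carrier set holds exactly six carriers")
        keys = {(c.wavelength_nm, c.fov) for c in self.carriers}
        if len(keys) != 6:
            raise ConfigurationError(
                "each (wavelength, fov) pair must appear exactly once"
            )
        if self.cc_radius <= 0:
            raise ConfigurationError("cc_radius must be positive")
        object.__setattr__(self, "carriers", tuple(self.carriers))

    def get(self, wavelength_nm: float, fov: str) -> Carrier:
        for c in self.carriers:
            if np.isclose(c.wavelength_nm, wavelength_nm) and c.fov == fov:
                return c
        raise KeyError((wavelength_nm, fov))

    def to_rows(self) -> list[list]:
        return [[c.fy, c.fx, c.wavelength_nm, c.fov] for c in self.carriers]

    @classmethod
    def from_rows(cls, rows: Iterable[Iterable], cc_radius: float) -> "CarrierSet":
        carriers = tuple(
            Carrier(float(fy), float(fx), float(wl), str(fov))
            for fy, fx, wl, fov in rows
        )
        return cls(carriers=carriers, cc_radius=float(cc_radius))


@dataclass(frozen=True)
class CropWindow:
    """Disk in the frequency plane used to extract one CC term.

    The radius is common to all six channels (set by the longest
    wavelength's coherent cutoff) so every reconstructed wavefront has the
    same lateral resolution.
    """

    center: tuple[float, float]  # (fy, fx), cycles/pixel
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("crop radius must be positive")


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def coherent_cutoff(config: OpticsConfig, wavelength_nm: float) -> float:
    """Radius of one CC term in cycles per camera pixel.

    Coherent imaging passes object frequencies up to ``NA / lambda``;
    referred to the camera plane this becomes
    ``NA / (lambda * M) * pixel_pitch`` cycles per pixel.  Shorter
    wavelengths have a wider band.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    wavelength_um = wavelength_nm * 1e-3
    return config.na / (wavelength_um * config.magnification) * config.pixel_pitch_um


# Vertex selection on the 3x3 grid of squares (16 vertices at
# {-1.5,-0.5,0.5,1.5} x {-1.5,-0.5,0.5,1.5} in units of the grid pitch).
# The inner four vertices are too close to the DC disk at the default NA,
# and the eight edge vertices split into four antipodal pairs, so six
# antipodal-free carriers force four edge vertices plus two corners.  All
# six are taken in the positive-fy half-plane, which makes the no-opposing-
# beams rule hold by construction; the left/right FOV halves are the
# fx<0 / fx>0 halves.  Coordinates are (fy, fx) in units of the pitch.
_LEFT_VERTICES = ((1.5, -0.5), (0.5, -1.5), (1.5, -1.5))
_RIGHT_VERTICES = ((1.5, 0.5), (0.5, 1.5), (1.5, 1.5))

# Smallest |f| coefficient among chosen vertices (edge type) and largest
# (corner), plus the smallest pairwise |f_i - f_j| and |f_i + f_j|
# coefficients, all in pitch units; derived once from the fixed selection.
_MIN_NORM = float(np.hypot(0.5, 1.5))     # 1.5811
_MAX_NORM = float(np.hypot(1.5, 1.5))     # 2.1213
_MIN_PAIR_GAP = 1.0                        # adjacent vertices
_MIN_CONJ_GAP = 1.0                        # (1.5,+-0.5) sum -> (1,0); etc.


def default_carrier_set(config: OpticsConfig) -> CarrierSet:
    """Deterministic carrier placement passing all disjointness constraints.

    The grid pitch is chosen as the midpoint of the feasible interval
    implied by the validator's inequalities with the common CC radius set
    to the longest wavelength's coherent cutoff.  Raises
    :class:`ConfigurationError` naming the violated constraint when no
    pitch can satisfy them (e.g. NA too large for the Nyquist square).
    """
    wl = sorted(config.wavelengths_nm, reverse=True)  # (longest first)
    r = coherent_cutoff(config, wl[0])
    # s >= from DC separation (a), pairwise (b) and conjugate (c) gaps;
    # s <= from Nyquist containment (d).
    s_min = max(3.0 * r / _MIN_NORM,
                2.0 * r / _MIN_PAIR_GAP,
                2.0 * r / _MIN_CONJ_GAP)
    s_max = (0.5 - r) / _MAX_NORM
    if s_min > s_max:
        raise ConfigurationError(
            "cannot place six CC terms: Nyquist containment "
            f"(pitch <= {s_max:.4f}) conflicts with disk separation "
            f"(pitch >= {s_min:.4f}) at cc_radius {r:.4f} cycles/pixel"
        )
    s = 0.5 * (s_min + s_max)
    carriers = []
    for fov, vertices in (("left", _LEFT_VERTICES), ("right", _RIGHT_VERTICES)):
        for wavelength, (vy, vx) in zip(wl, vertices):
            carriers.append(Carrier(vy * s, vx * s, wavelength, fov))
    cs = CarrierSet(carriers=tuple(carriers), cc_radius=r)
    report = validate_carrier_set(cs, config)
    if not report:  # pragma: no cover - guarded by the interval above
        raise ConfigurationError(
            "default placement failed validation: " + "; ".join(report.violations)
        )
    return cs


def validate_carrier_set(cs: CarrierSet, config: OpticsConfig) -> ValidationReport:
    """Check the disjointness constraints of a six-carrier layout.

    With the common CC radius r:

    a. DC separation: ``|f_i| >= 2*r_max + r`` — the autocorrelation disk
       has twice the single-channel bandwidth.
    b. Pairwise CC separation: ``|f_i - f_j| >= 2r``.
    c. Conjugate separation: ``|f_i + f_j| >= 2r`` for all i, j (i = j
       included), which encodes the no-opposing-carriers rule.
    d. Nyquist containment: ``|f_i| + r <= 0.5``.

    Always returns a report; never raises.
    """
    r = cs.cc_radius
    r_max = r
    violations: list[str] = []
    f = [c.f for c in cs.carriers]
    names = [f"({c.wavelength_nm:g} nm, {c.fov})" for c in cs.carriers]
    for i, (fi, ni) in enumerate(zip(f, names)):
        norm = float(np.linalg.norm(fi))
        if norm < 2 * r_max + r - 1e-12:
            violations.append(
                f"DC separation: |f|={norm:.4f} < {2 * r_max + r:.4f} for {ni}"
            )
        if norm + r > 0.5 + 1e-12:
            violations.append(
                f"Nyquist containment: |f|+r={norm + r:.4f} > 0.5 for {ni}"
            )
        for j in range(i, len(f)):
            if j > i:
                gap = float(np.linalg.norm(fi - f[j]))
                if gap < 2 * r - 1e-12:
                    violations.append(
                        f"CC overlap: |f_i-f_j|={gap:.4f} < {2 * r:.4f} "
                        f"for {ni}, {names[j]}"
                    )
            conj = float(np.linalg.norm(fi + f[j]))
            if conj < 2 * r - 1e-12:
                violations.append(
                    f"conjugate overlap: |f_i+f_j|={conj:.4f} < {2 * r:.4f} "
                    f"for {ni}, {names[j]}"
                )
    return ValidationReport(ok=not violations, violations=violations)


def cycles_per_mm(f_cycles_per_px: float, config: OpticsConfig) -> float:
    """Display helper: convert camera-plane cycles/pixel to cycles/mm."""
    return f_cycles_per_px / (config.pixel_pitch_um * 1e-3)
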