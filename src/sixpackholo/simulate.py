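"""Synthetic six-pack holograms with known ground truth.

The simulator stands in for the optical bench: it builds optical-path-delay
(OPD) phantoms — an air-filled microchannel in PDMS, an onion-epidermis-like
cell mosaic, or a flat field — and renders them into a single quantized
interferogram that multiplexes six channels (three wavelengths x two
laterally shifted fields of view).  Crosstalk between non-matching beam
pairs is absent by construction, emulating the wavelength separation and
orthogonal polarization of the physical system.

Per channel, the object field ``exp(i phi)`` with ``phi = 2*pi*OPD/lambda``
is low-passed before interference — the imaging NA acts on the complex
field, which keeps each cross-correlation term strictly band-limited (and
gives the autocorrelation term its doubled bandwidth).  By default all
six fields share the common reconstruction bandwidth (the longest
wavelength's coherent cutoff, i.e. the constant crop radius): the shorter
wavelengths' full per-wavelength bands are wider than any disjoint
six-disk packing allows at the default NA, and the constant-radius crop
discards the excess band anyway, so the common band is the configuration
the carrier geometry is actually valid for.  ``field_band="per-wavelength"``
restores the physically wider bands for leakage studies.  The
band-limited field is then interfered with a tilted plane-wave reference
at the channel's carrier frequency.  Carriers are snapped to the nearest
DFT bin so the fringes are periodic on the grid and the CC terms are
leakage-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._utils import TWO_PI
from .optics import CarrierSet, OpticsConfig, coherent_cutoff, validate_carrier_set


@dataclass
class PhantomOPD:
    """Ground-truth OPD field (nm) on the object-plane grid.

    ``opd_nm = (n_sample - n_medium) * height`` wherever a physical height
    is defined.  ``masks`` labels regions for metrics (e.g. ``channel``,
    ``channel_interior``, ``background``); interior masks are eroded away
    from edges so that diffraction-limited edge transitions do not enter
    region statistics.
    """

    opd_nm: np.ndarray
    n_sample: float = 1.0
    n_medium: float = 1.0
    height_um: np.ndarray | float = 0.0
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.opd_nm = np.asarray(self.opd_nm, dtype=float)
        if not np.all(np.isfinite(self.opd_nm)):
            raise ValueError("phantom OPD must be finite everywhere")


@dataclass
class NoiseSpec:
    """Stochastic degradations applied during hologram synthesis."""

    phase_noise_rad: float = 0.0
    shot_noise: bool = False
    full_well_e: float = 10_000.0
    read_noise_e: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_noise_rad < 0 or self.read_noise_e < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.full_well_e <= 0:
            raise ValueError("full_well_e must be positive")

    def to_dict(self) -> dict:
        return {
            "phase_noise_rad": self.phase_noise_rad,
            "shot_noise": self.shot_noise,
            "full_well_e": self.full_well_e,
            "read_noise_e": self.read_noise_e,
            "seed": self.seed,
        }


@dataclass
class SixPackHologram:
    """One quantized camera frame carrying six interference channels."""

    intensity: np.ndarray
    config: OpticsConfig
    carriers: CarrierSet
    kind: str = "sample"  # sample | background
    fov_shift_px: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.shape != self.config.grid_shape:
            raise ValueError("hologram grid does not match config.grid_shape")
        levels = 2 ** self.config.bit_depth - 1
        if self.intensity.min() < 0 or self.intensity.max() > levels:
            raise ValueError(f"intensity must lie in [0, {levels}]")


def _edge_margin_px(config: OpticsConfig) -> int:
    """Width of the diffraction-limited edge transition, in pixels."""
    r = coherent_cutoff(config, max(config.wavelengths_nm))
    return max(2, int(np.ceil(1.0 / r)))


def make_flat_phantom(config: OpticsConfig) -> PhantomOPD:
    """Zero-OPD field (the background / empty medium)."""
    opd = np.zeros(config.grid_shape)
    masks = {"background": np.ones(config.grid_shape, dtype=bool)}
    return PhantomOPD(opd_nm=opd, masks=masks)


def make_channel_phantom(
    config: OpticsConfig,
    height_um: float = 7.0,
    n_sample: float = 1.00,
    n_medium: float = 1.39,
    geometry: str = "cross",
    width_frac: float = 0.14,
) -> PhantomOPD:
    """Air-filled microchannel in PDMS, as a hard-edged OPD step.

    The cross geometry places a horizontal channel across the full width
    (so a horizontally shifted second field of view sees its straight
    continuation) and a vertical arm left of center forming the
    intersection.  With the defaults, OPD inside the channel is
    ``(1.00 - 1.39) * 7000 nm = -2730 nm``.
    """
    if height_um < 0:
        raise ValueError("height_um must be >= 0")
    if n_sample < 1 or n_medium < 1:
        raise ValueError("refractive indices must be >= 1")
    h, w = config.grid_shape
    half = max(2, int(round(width_frac * h / 2)))
    yy, xx = np.indices((h, w))
    horiz = np.abs(yy - h // 2) < half
    if geometry == "cross":
        vert = np.abs(xx - w // 4) < half
        channel = horiz | vert
    elif geometry == "straight":
        channel = horiz
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    opd = np.where(channel, (n_sample - n_medium) * height_um * 1e3, 0.0)
    margin = _edge_margin_px(config)
    interior = ndimage.binary_erosion(channel, iterations=margin)
    background = ndimage.binary_erosion(~channel, iterations=margin)
    return PhantomOPD(
        opd_nm=opd,
        n_sample=n_sample,
        n_medium=n_medium,
        height_um=np.where(channel, height_um, 0.0),
        masks={
            "channel": channel,
            "channel_interior": interior,
            "background": background,
        },
    )


def make_cell_phantom(
    config: OpticsConfig,
    seed: int = 0,
    n_cells: int = 30,
    interior_opd_nm: float = -100.0,
    wall_opd_typ_nm: float = 1600.0,
    wall_opd_max_nm: float = 3000.0,
    wall_width_px: int = 5,
) -> PhantomOPD:
    """Onion-epidermis-like mosaic: polygonal cells with high-OPD wall ridges.

    A seeded Voronoi tessellation of ``n_cells`` sites defines the cell
    interiors (slightly negative OPD relative to the medium, with smooth
    variation); the tessellation boundaries are dilated into ridges whose
    OPD varies smoothly between the typical and maximum wall values.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    h, w = config.grid_shape
    rng = np.random.default_rng(seed)
    sites = rng.uniform(0, 1, size=(n_cells, 2)) * np.array([h, w])
    yy, xx = np.indices((h, w))
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    from scipy.spatial import cKDTree

    _, labels = cKDTree(sites).query(pts, workers=-1)
    labels = labels.reshape(h, w)
    # Boundary = pixels adjacent to another cell.
    boundary = np.zeros((h, w), dtype=bool)
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    wall = ndimage.binary_dilation(boundary, iterations=max(1, wall_width_px // 2))

    def smooth_field(lo: float, hi: float, sigma: float) -> np.ndarray:
        f = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
        f -= f.min()
        rng_span = f.max() - f.min()
        f = f / rng_span if rng_span > 0 else np.zeros_like(f)
        return lo + (hi - lo) * f

    interior_field = interior_opd_nm + smooth_field(-20.0, 20.0, sigma=h / 16)
    wall_field = smooth_field(wall_opd_typ_nm, wall_opd_max_nm, sigma=h / 32)
    opd = np.where(wall, wall_field, interior_field)
    margin = _edge_margin_px(config)
    interior_mask = ndimage.binary_erosion(~wall, iterations=margin)
    return PhantomOPD(
        opd_nm=opd,
        masks={"wall": wall, "interior": interior_mask},
    )


def snap_carrier(fy: float, fx: float, grid_shape: tuple[int, int]) -> tuple[float, float]:
    """Round a carrier to the nearest DFT bin so fringes are grid-periodic."""
    h, w = grid_shape
    return round(fy * h) / h, round(fx * w) / w


def lowpass(field2d: np.ndarray, radius_cpp: float,
            taper: float = 0.35) -> np.ndarray:
    """Isotropic frequency-domain low-pass (disk support, cycles/pixel).

    The disk edge is softened with a raised-cosine taper over the outer
    ``taper`` fraction of the radius, emulating the partially coherent
    illumination of the instrument: a hard coherent pupil would produce
    Gibbs overshoot at step edges strong enough to push the phase across
    the wrap boundary, an artifact the partially coherent source is there
    to suppress.  ``taper=0`` gives the ideal hard disk.
    """
    h, w = field2d.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    rho = np.sqrt(fy**2 + fx**2)
    if taper > 0:
        r0 = radius_cpp * (1.0 - taper)
        ramp = np.clip((rho - r0) / (radius_cpp - r0), 0.0, 1.0)
        mask = np.where(rho <= radius_cpp, 0.5 * (1 + np.cos(np.pi * ramp)), 0.0)
    else:
        mask = (rho <= radius_cpp).astype(float)
    out = np.fft.ifft2(np.fft.fft2(field2d) * mask)
    return out.real if np.isrealobj(field2d) else out


def fov_shift(fov: str, fov_shift_px: int) -> int:
    """Horizontal roll applied to the phantom for a given FOV."""
    return -fov_shift_px // 2 if fov == "left" else fov_shift_px - fov_shift_px // 2


def channel_phase(phantom: PhantomOPD, wavelength_nm: float, fov: str,
                  fov_shift_px: int = 0) -> np.ndarray:
    """Raw (pre-NA) object phase of one channel: ``2 pi OPD_fov / lambda``."""
    opd = np.roll(phantom.opd_nm, fov_shift(fov, fov_shift_px), axis=1)
    return TWO_PI * opd / wavelength_nm


def band_limited_field(
    phantom: PhantomOPD,
    config: OpticsConfig,
    wavelength_nm: float,
    fov: str,
    fov_shift_px: int = 0,
    radius_cpp: float | None = None,
) -> np.ndarray:
    """Ground-truth complex field of one channel after the NA low-pass.

    This is exactly the field the simulator interferes with the reference;
    ``radius_cpp`` overrides the cutoff (e.g. to match a reconstruction
    crop radius in recovery tests — nested disk low-passes compose to the
    smaller radius, so the override is exact).
    """
    phi = channel_phase(phantom, wavelength_nm, fov, fov_shift_px)
    r = radius_cpp if radius_cpp is not None else coherent_cutoff(config, wavelength_nm)
    return lowpass(np.exp(1j * phi), r)


def band_limited_phase(
    phantom: PhantomOPD,
    config: OpticsConfig,
    wavelength_nm: float,
    fov: str,
    fov_shift_px: int = 0,
    radius_cpp: float | None = None,
) -> np.ndarray:
    """Phase of :func:`band_limited_field` — the recovery-test reference."""
    return np.angle(
        band_limited_field(phantom, config, wavelength_nm, fov, fov_shift_px,
                           radius_cpp)
    )


def _channel_rng(noise: NoiseSpec, kind: str) -> np.random.Generator:
    return np.random.default_rng([int(noise.seed), 0 if kind == "sample" else 1])


def synthesize_hologram(
    phantom: PhantomOPD,
    config: OpticsConfig,
    carriers: CarrierSet,
    noise: NoiseSpec | None = None,
    fov_shift_px: int = 0,
    amplitudes: dict | float | None = None,
    aberration_phase: np.ndarray | None = None,
    kind: str = "sample",
    field_band: str = "common",
) -> SixPackHologram:
    """Render a phantom into one quantized six-pack interference frame.

    Each channel contributes the interference of its band-limited object
    field ``E_k`` with a tilted plane-wave reference:
    ``I_k = a_k^2 |E_k|^2 + b_k^2 + 2 a_k b_k Re[E_k exp(i 2 pi f_k . x)]``,
    with equal sample/reference amplitudes (``a_k = b_k``) per channel by
    default and no cross terms between non-matching pairs.  For a smooth
    phantom this reduces to the classical fringe
    ``2a^2 [1 + cos(2 pi f . x + phi)]``.  ``amplitudes`` may be a scalar
    or a ``{(wavelength, fov): a}`` mapping for contrast-robustness
    studies.  An ``aberration_phase`` array is added to every channel's
    phase (use the same array for sample and background frames to emulate
    a common, compensable aberration).
    """
    report = validate_carrier_set(carriers, config)
    if not report:
        raise ValueError("carrier set invalid: " + "; ".join(report.violations))
    h, w = config.grid_shape
    if phantom.opd_nm.shape != (h, w):
        raise ValueError("phantom grid does not match config.grid_shape")
    noise = noise or NoiseSpec()
    rng = _channel_rng(noise, kind)
    yy, xx = np.indices((h, w))
    intensity = np.zeros((h, w))
    for c in carriers.carriers:
        if isinstance(amplitudes, dict):
            a = float(amplitudes.get((c.wavelength_nm, c.fov), 1.0))
        elif amplitudes is not None:
            a = float(amplitudes)
        else:
            a = 1.0
        phi = channel_phase(phantom, c.wavelength_nm, c.fov, fov_shift_px)
        if aberration_phase is not None:
            phi = phi + aberration_phase
        if noise.phase_noise_rad > 0:
            phi = phi + rng.normal(0.0, noise.phase_noise_rad, size=(h, w))
        if field_band == "common":
            band = carriers.cc_radius
        elif field_band == "per-wavelength":
            band = coherent_cutoff(config, c.wavelength_nm)
        else:
            raise ValueError("field_band must be 'common' or 'per-wavelength'")
        field = lowpass(np.exp(1j * phi), band)
        fy, fx = snap_carrier(c.fy, c.fx, (h, w))
        carrier_wave = np.exp(1j * TWO_PI * (fy * yy + fx * xx))
        intensity += a * a * (
            np.abs(field) ** 2 + 1.0 + 2.0 * np.real(field * carrier_wave)
        )
    levels = 2 ** config.bit_depth - 1
    peak = intensity.max()
    if peak > 0:
        scaled = intensity / peak
    else:
        scaled = intensity
    if noise.shot_noise or noise.read_noise_e > 0:
        electrons = scaled * noise.full_well_e
        if noise.shot_noise:
            electrons = rng.poisson(np.clip(electrons, 0, None)).astype(float)
        if noise.read_noise_e > 0:
            electrons = electrons + rng.normal(0, noise.read_noise_e, size=(h, w))
        scaled = electrons / noise.full_well_e
    quantized = np.clip(np.round(scaled * levels), 0, levels)
    # clipped = pushed past full scale (noise), not merely filling it
    n_clip = int(np.count_nonzero(scaled * levels > levels + 0.5))
    if peak > 0 and n_clip > 1e-3 * quantized.size:
        warnings.warn(
            f"{100 * n_clip / quantized.size:.2f}% of pixels saturate at "
            f"level {levels}",
            RuntimeWarning,
            stacklevel=2,
        )
    return SixPackHologram(
        intensity=quantized.astype(np.uint16),
        config=config,
        carriers=carriers,
        kind=kind,
        fov_shift_px=fov_shift_px,
        seed=noise.seed,
    )


def synthesize_background(
    config: OpticsConfig,
    carriers: CarrierSet,
    noise: NoiseSpec | None = None,
    aberration_phase: np.ndarray | None = None,
    fov_shift_px: int = 0,
) -> SixPackHologram:
    """Sample-free reference frame (flat phantom), optionally aberrated."""
    return synthesize_hologram(
        make_flat_phantom(config),
        config,
        carriers,
        noise=noise,
        fov_shift_px=fov_shift_px,
        aberration_phase=aberration_phase,
        kind="background",
    )
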