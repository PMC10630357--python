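"""Wavefront retrieval from a six-pack hologram.

The chain per channel: 2D FT of the frame -> crop the channel's
cross-correlation (CC) disk with the constant-radius window and re-center
it at zero frequency -> numerically refocus by angular-spectrum
propagation -> inverse FT to the complex wavefront -> pixelwise division
by the matching background wavefront -> windowed-Fourier denoising.

All spectra are origin-centered (``fftshift`` convention); crop supports
are disks, not squares, and every channel uses the same radius so the six
wavefronts share one lateral resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import CarrierSet, CropWindow
from .simulate import SixPackHologram


@dataclass
class ComplexWavefront:
    """Complex field of one channel, tagged with its identity."""

    field: np.ndarray
    wavelength_nm: float
    fov: str
    refocus_um: float = 0.0
    valid: np.ndarray | None = None  # False where background division failed

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=complex)
        if not np.all(np.isfinite(self.field)):
            raise ValueError("wavefront contains non-finite values")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase in [-pi, pi)."""
        from ._utils import wrap_phase

        return wrap_phase(np.angle(self.field))

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.field)


def extract_cc(hologram: SixPackHologram, window: CropWindow) -> np.ndarray:
    """Crop one CC disk from the hologram spectrum, re-centered at DC.

    Returns a full-grid, origin-centered complex spectrum tile (common
    dimensions for all six channels).  The carrier is rounded to the
    nearest DFT bin for the re-centering shift.
    """
    fy, fx = window.center
    if np.hypot(fy, fx) + window.radius > 0.5 + 1e-12:
        raise ValueError(
            f"crop window at ({fy:.4f}, {fx:.4f}) with radius "
            f"{window.radius:.4f} extends past the Nyquist limit"
        )
    h, w = hologram.intensity.shape
    spectrum = np.fft.fftshift(np.fft.fft2(hologram.intensity.astype(float)))
    cy = h // 2 + int(round(fy * h))
    cx = w // 2 + int(round(fx * w))
    yy, xx = np.indices((h, w))
    mask = ((yy - cy) / h) ** 2 + ((xx - cx) / w) ** 2 <= window.radius**2
    return np.roll(spectrum * mask, (h // 2 - cy, w // 2 - cx), axis=(0, 1))


def refocus(
    tile: np.ndarray,
    distance_um: float,
    wavelength_nm: float,
    object_pixel_um: float,
    max_distance_um: float = 50.0,
) -> np.ndarray:
    """Propagate a spectrum tile by the angular-spectrum kernel.

    The kernel ``exp(i 2 pi d sqrt(1/lambda^2 - fy^2 - fx^2))`` is exact
    scalar diffraction at these NAs and reduces to the paraxial Fresnel
    kernel for small angles.  Evanescent components are zeroed; energy in
    the propagating band is conserved (|kernel| = 1 there).
    """
    if not np.all(np.isfinite(tile)):
        raise ValueError("spectrum tile contains non-finite values")
    if abs(distance_um) > max_distance_um:
        raise ValueError(
            f"|distance| = {abs(distance_um):g} um exceeds the sanity bound "
            f"{max_distance_um:g} um"
        )
    if distance_um == 0:
        return tile.copy()
    h, w = tile.shape
    lam_um = wavelength_nm * 1e-3
    fy = np.fft.fftshift(np.fft.fftfreq(h, d=object_pixel_um))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(w, d=object_pixel_um))[None, :]
    arg = 1.0 / lam_um**2 - fy**2 - fx**2
    propagating = arg > 0
    kernel = np.where(
        propagating,
        np.exp(1j * 2 * np.pi * distance_um * np.sqrt(np.clip(arg, 0, None))),
        0.0,
    )
    return tile * kernel


def to_image(
    tile: np.ndarray,
    wavelength_nm: float,
    fov: str,
    refocus_um: float = 0.0,
) -> ComplexWavefront:
    """Inverse FT of an origin-centered spectrum tile."""
    if not np.all(np.isfinite(tile)):
        raise ValueError("spectrum tile contains non-finite values")
    field = np.fft.ifft2(np.fft.ifftshift(tile))
    return ComplexWavefront(
        field=field, wavelength_nm=wavelength_nm, fov=fov, refocus_um=refocus_um
    )


def compensate_background(
    sample: ComplexWavefront,
    background: ComplexWavefront,
    tau: float = 1e-3,
) -> ComplexWavefront:
    """Divide sample by background pixelwise, removing shared aberrations.

    Pixels where the background amplitude falls below ``tau * max`` are set
    to zero and flagged False in the validity mask.
    """
    if sample.wavelength_nm != background.wavelength_nm or sample.fov != background.fov:
        raise ValueError("sample/background wavelength or fov mismatch")
    if sample.field.shape != background.field.shape:
        raise ValueError("sample/background grid mismatch")
    mag = np.abs(background.field)
    ok = mag >= tau * mag.max()
    quotient = np.zeros_like(sample.field)
    np.divide(sample.field, background.field, out=quotient, where=ok)
    return ComplexWavefront(
        field=quotient,
        wavelength_nm=sample.wavelength_nm,
        fov=sample.fov,
        refocus_um=sample.refocus_um,
        valid=ok,
    )


def wft_denoise(
    w: ComplexWavefront,
    window_sigma_px: float = 6.0,
    band_limit: float | None = None,
    threshold: float = 0.03,
    stride: int | None = None,
) -> ComplexWavefront:
    """Windowed-Fourier filtering of a complex wavefront.

    Gaussian-windowed patches are transformed locally; coefficients whose
    magnitude falls below ``threshold * max|coefficient|`` of the patch are
    zeroed (and, when ``band_limit`` is given in cycles/pixel, coefficients
    outside that band as well); patches are inverse-transformed and
    accumulated with window-squared overlap normalization.  With
    ``threshold = 0`` and no band limit the transform is an exact identity.
    """
    if window_sigma_px <= 0:
        raise ValueError("window_sigma_px must be positive")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    f = w.field
    h_img, w_img = f.shape
    patch = int(4 * round(window_sigma_px))
    patch = max(8, min(patch, min(h_img, w_img)))
    stride = stride or max(1, patch // 4)
    ax = np.arange(patch) - (patch - 1) / 2.0
    win = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * window_sigma_px**2))
    pad = patch
    fp = np.pad(f, pad)
    out = np.zeros_like(fp)
    weight = np.zeros(fp.shape)
    if band_limit is not None:
        fy = np.fft.fftfreq(patch)[:, None]
        fx = np.fft.fftfreq(patch)[None, :]
        band_mask = fy**2 + fx**2 <= band_limit**2
    ys = range(0, fp.shape[0] - patch + 1, stride)
    xs = range(0, fp.shape[1] - patch + 1, stride)
    for y0 in ys:
        for x0 in xs:
            block = fp[y0 : y0 + patch, x0 : x0 + patch] * win
            coeff = np.fft.fft2(block)
            if threshold > 0:
                mags = np.abs(coeff)
                keep = mags >= threshold * mags.max()
                if band_limit is not None:
                    keep &= band_mask
                coeff = coeff * keep
            elif band_limit is not None:
                coeff = coeff * band_mask
            out[y0 : y0 + patch, x0 : x0 + patch] += win * np.fft.ifft2(coeff)
            weight[y0 : y0 + patch, x0 : x0 + patch] += win**2
    filtered = out[pad:-pad, pad:-pad] / weight[pad:-pad, pad:-pad]
    return ComplexWavefront(
        field=filtered,
        wavelength_nm=w.wavelength_nm,
        fov=w.fov,
        refocus_um=w.refocus_um,
        valid=w.valid,
    )


def sharpness(w: ComplexWavefront | np.ndarray) -> float:
    """Tenengrad edge-sharpness metric on the field amplitude.

    Utility for refocus-distance sweeps; not part of the reconstruction
    contract.
    """
    amp = np.abs(w.field if isinstance(w, ComplexWavefront) else w)
    gy, gx = np.gradient(amp)
    return float(np.mean(gy**2 + gx**2))


def sharpness_sweep(
    tile: np.ndarray,
    distances_um: np.ndarray,
    wavelength_nm: float,
    object_pixel_um: float,
) -> tuple[float, np.ndarray]:
    """Best-effort autofocus: return (best distance, metric per distance)."""
    scores = np.array(
        [
            sharpness(
                np.fft.ifft2(
                    np.fft.ifftshift(refocus(tile, d, wavelength_nm, object_pixel_um))
                )
            )
            for d in distances_um
        ]
    )
    return float(distances_um[int(np.argmax(scores))]), scores


def reconstruct_all(
    hologram: SixPackHologram,
    background_hologram: SixPackHologram,
    carriers: CarrierSet,
    refocus_table: dict | None = None,
    wft_params: dict | None = None,
    apply_wft: bool = True,
    tau: float = 1e-3,
) -> dict[tuple[float, str], ComplexWavefront]:
    """Full per-channel chain for all six channels of a frame pair.

    Returns wavefronts keyed by ``(wavelength_nm, fov)``.  ``refocus_table``
    maps the same keys to propagation distances in um (default 0); the
    windowed-Fourier filter can be bypassed with ``apply_wft=False``.
    """
    if background_hologram is None:
        raise ValueError("a background hologram is required")
    if hologram.config.grid_shape != background_hologram.config.grid_shape:
        raise ValueError("sample and background grids differ")
    refocus_table = refocus_table or {}
    wft_params = wft_params or {}
    obj_px = hologram.config.object_pixel_um
    out: dict[tuple[float, str], ComplexWavefront] = {}
    for c in carriers.carriers:
        key = (c.wavelength_nm, c.fov)
        window = CropWindow(center=(c.fy, c.fx), radius=carriers.cc_radius)
        d = float(refocus_table.get(key, 0.0))
        try:
            pair = []
            for holo in (hologram, background_hologram):
                tile = extract_cc(holo, window)
                tile = refocus(tile, d, c.wavelength_nm, obj_px)
                pair.append(to_image(tile, c.wavelength_nm, c.fov, refocus_um=d))
            wf = compensate_background(pair[0], pair[1], tau=tau)
            if apply_wft:
                wf = wft_denoise(wf, **wft_params)
        except Exception as exc:
            raise RuntimeError(
                f"reconstruction failed for channel {c.wavelength_nm:g} nm / "
                f"{c.fov}: {exc}"
            ) from exc
        out[key] = wf
    return out
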