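"""Optical-path-delay conversion, evaluation metrics, and FOV stitching.

OPD relates phase, wavelength and sample geometry through
``OPD = (n_s - n_m) h = phi * lambda / (2 pi)``: a phase map at a known
wavelength converts to physical path delay in nm, and a known thickness
converts OPD to an integral refractive-index difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import TWO_PI
from .optics import OpticsConfig
from .synthwave import PhaseMap


@dataclass
class OPDMap:
    """Real-valued OPD field in nm with provenance and validity mask."""

    opd_nm: np.ndarray
    fov: str = "left"
    source: str = ""
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.opd_nm = np.asarray(self.opd_nm, dtype=float)
        check = self.opd_nm if self.valid is None else self.opd_nm[self.valid]
        if not np.all(np.isfinite(check)):
            raise ValueError("OPD map contains non-finite values on valid pixels")


def phase_to_opd(p: PhaseMap | np.ndarray, wavelength_nm: float | None = None,
                 fov: str | None = None) -> OPDMap:
    """Convert phase (rad) at a wavelength to OPD in nm: ``phi*lambda/2pi``."""
    if isinstance(p, PhaseMap):
        wavelength_nm = wavelength_nm or p.wavelength_nm
        fov = fov or p.fov
        phase = p.phase_rad
        source = p.provenance
    else:
        phase = np.asarray(p, dtype=float)
        source = ""
        fov = fov or "left"
    if wavelength_nm is None or wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return OPDMap(
        opd_nm=phase * wavelength_nm / TWO_PI,
        fov=fov,
        source=source or f"{wavelength_nm:g} nm",
    )


def implied_index_difference(opd_nm: float | np.ndarray,
                             thickness_um: float) -> float | np.ndarray:
    """Integral refractive-index difference implied by an OPD and thickness.

    Inverts ``OPD = (n_s - n_m) h``: ``delta_n = OPD / h`` in consistent
    units (nm / (um * 1000)).
    """
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    return np.asarray(opd_nm, dtype=float) / (thickness_um * 1e3) if isinstance(
        opd_nm, np.ndarray
    ) else float(opd_nm) / (thickness_um * 1e3)


def region_stats(
    m: OPDMap | np.ndarray,
    mask: np.ndarray,
    expected_nm: float | None = None,
) -> dict:
    """Mean/std over a labeled region, plus accuracy vs an expected value.

    ``accuracy_pct = 100 * mean / expected`` when an expectation is given
    (e.g. a known channel OPD).
    """
    opd = m.opd_nm if isinstance(m, OPDMap) else np.asarray(m, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("region mask is empty")
    values = opd[mask]
    stats = {
        "mean_nm": float(values.mean()),
        "std_nm": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "n_pixels": int(values.size),
    }
    if expected_nm is not None:
        stats["expected_nm"] = float(expected_nm)
        stats["accuracy_pct"] = float(100.0 * stats["mean_nm"] / expected_nm)
    return stats


def diffraction_limit(config: OpticsConfig) -> float:
    """Worst-case Rayleigh spot size in um: ``1.22 * lambda_max / NA``."""
    lam_um = max(config.wavelengths_nm) * 1e-3
    return 1.22 * lam_um / config.na


def stitch_fovs(
    left: OPDMap, right: OPDMap, shift_px: int
) -> tuple[OPDMap, np.ndarray, float]:
    """Place the two FOVs on a widened canvas and blend the overlap.

    ``shift_px`` is the horizontal offset of the right FOV relative to the
    left.  In the overlap strip the output is the average of the two and
    the strip is returned as a mask, together with the std of the
    left-right disagreement there (a consistency metric of the two views).
    Symmetric under swapping the maps and negating the shift.
    """
    if left.opd_nm.shape != right.opd_nm.shape:
        raise ValueError("FOV grids differ")
    h, w = left.opd_nm.shape
    if abs(shift_px) >= w:
        raise ValueError("shift must be smaller than the image width")
    if shift_px < 0:
        combined, overlap, disagreement = stitch_fovs(right, left, -shift_px)
        return combined, overlap, disagreement
    cw = w + shift_px
    canvas = np.zeros((h, cw))
    counts = np.zeros((h, cw))
    canvas[:, :w] += left.opd_nm
    counts[:, :w] += 1
    canvas[:, shift_px:] += right.opd_nm
    counts[:, shift_px:] += 1
    combined = canvas / np.maximum(counts, 1)
    overlap = counts == 2
    if overlap.any():
        diff = left.opd_nm[:, shift_px:] - right.opd_nm[:, : w - shift_px]
        disagreement = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    else:
        disagreement = float("nan")
    return (
        OPDMap(opd_nm=combined, fov="combined",
               source=f"stitch({left.source}, {right.source})"),
        overlap,
        disagreement,
    )
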