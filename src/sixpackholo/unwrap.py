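"""Spatial and hierarchical phase unwrapping.

A wrapped phase map only determines the true phase up to an integer number
of 2*pi cycles per pixel.  Spatial unwrappers recover smooth fields but
fail across steps taller than half a wavelength (the 2*pi ambiguity).
Hierarchical unwrapping sidesteps this: starting from a spatially
unwrapped map at the longest (synthetic) wavelength — whose OPD never
wraps on the samples of interest but is noisy — it walks down a ladder of
wrapped maps at decreasing wavelengths, transferring the integer cycle
count at each rung by rounding the OPD difference.  Each transfer keeps
the long-wavelength accuracy while inheriting the shorter wavelength's
lower OPD noise, so the final map is both ambiguity-free and low-noise.

The transfer at one rung (unwrapped ``phi_n`` at ``l_n``, wrapped
``phi_{n+1}`` at ``l_{n+1} < l_n``):

    m_n = phi_n / 2pi                    (real-valued phase order)
    F_n = phi_{n+1} / 2pi  in [-0.5, 0.5)
    I_n = round((m_n l_n - F_n l_{n+1}) / l_{n+1})   (ties away from zero)
    phi'_{n+1} = 2pi (I_n + F_n)

which is exact whenever the current map's OPD error is below
``l_{n+1}/2``; each transition can raise an advisory flag when an OPD
noise estimate violates that condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.restoration import unwrap_phase as _reliability_unwrap

from ._utils import TWO_PI, round_half_away, wrap_phase
from .synthwave import PhaseMap


@dataclass
class PhaseLadder:
    """Ordered wrapped maps of one FOV, strictly descending in wavelength."""

    rungs: list[PhaseMap]
    fov: str = "left"

    def __post_init__(self) -> None:
        if len(self.rungs) < 2:
            raise ValueError("a ladder needs at least two rungs")
        wl = [r.wavelength_nm for r in self.rungs]
        if any(later >= earlier for later, earlier in zip(wl[1:], wl[:-1])):
            raise ValueError("ladder wavelengths must be strictly descending")
        shapes = {r.phase_rad.shape for r in self.rungs}
        if len(shapes) != 1:
            raise ValueError("all rungs must share one grid")
        if not all(r.wrapped for r in self.rungs):
            raise ValueError("ladder rungs must be wrapped phase maps")

    @property
    def wavelengths_nm(self) -> list[float]:
        return [r.wavelength_nm for r in self.rungs]


@dataclass
class UnwrapResult:
    """Per-rung unwrapped maps, the final OPD map, and advisory flags."""

    unwrapped: list[PhaseMap]
    opd_nm: np.ndarray
    flags: list[str] = field(default_factory=list)
    noise_nm: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.opd_nm)):
            raise ValueError("final OPD map contains non-finite values")


def standard_unwrap(
    p: PhaseMap,
    background_mask: np.ndarray | None = None,
    quality_threshold: float = 0.5,
) -> PhaseMap:
    """2D spatial unwrapping by reliability-ordered integration.

    Pixels are unwrapped in order of a local second-difference reliability
    metric along non-continuous paths (the algorithm of Herraez /
    Arevalillo-Miguel et al., as implemented in scikit-image).  The global
    2*pi-multiple offset is fixed by shifting the median of
    ``background_mask`` (or of the whole image) to the value nearest zero.
    Output differs from input by integer multiples of 2*pi pixelwise.

    When the map carries an amplitude (quality) channel, pixels whose
    amplitude falls below ``quality_threshold`` times the median are
    excluded from the spatial unwrap and keep their wrapped values: at a
    steep edge the band-limited field cannot follow the object phase, its
    amplitude collapses, and the meaningless transition phase would
    otherwise let the unwrapper carry a spurious 2*pi cycle into the
    enclosed region.  Set ``quality_threshold=0`` to disable masking.
    """
    if not p.wrapped:
        raise ValueError("standard_unwrap expects a wrapped phase map")
    low_quality = None
    if p.amplitude is not None and quality_threshold > 0:
        low_quality = p.amplitude < quality_threshold * np.median(p.amplitude)
        if low_quality.all():
            low_quality = None
    if low_quality is not None and low_quality.any():
        masked = np.ma.masked_array(p.phase_rad, mask=low_quality)
        u = np.asarray(_reliability_unwrap(masked).data, dtype=float)
        u = np.where(low_quality, p.phase_rad, u)
    else:
        u = np.asarray(_reliability_unwrap(p.phase_rad), dtype=float)
    ref_sel = background_mask if background_mask is not None else slice(None)
    ref = np.median(u[ref_sel])
    u = u - TWO_PI * np.round(ref / TWO_PI)
    return PhaseMap(
        phase_rad=u,
        wavelength_nm=p.wavelength_nm,
        wrapped=False,
        fov=p.fov,
        provenance=p.provenance + " [unwrapped]",
        amplitude=p.amplitude,
    )


def hierarchical_step(phi_n: PhaseMap, phi_next: PhaseMap) -> PhaseMap:
    """Transfer the integer cycle count from one rung to the next.

    ``phi_n`` must be unwrapped at a strictly longer wavelength than the
    wrapped ``phi_next``.  The result wraps back to ``phi_next`` exactly
    (only whole cycles are added) and its OPD lies within half of
    ``phi_next``'s wavelength of ``phi_n``'s OPD at every pixel.
    """
    if phi_n.wrapped:
        raise ValueError("phi_n must be unwrapped")
    if not phi_next.wrapped:
        raise ValueError("phi_next must be wrapped")
    l_n, l_next = phi_n.wavelength_nm, phi_next.wavelength_nm
    if l_n <= l_next:
        raise ValueError(
            f"ladder order violated: {l_n:g} nm is not longer than {l_next:g} nm"
        )
    if phi_n.phase_rad.shape != phi_next.phase_rad.shape:
        raise ValueError("rung grids differ")
    m_n = phi_n.phase_rad / TWO_PI
    w_next = wrap_phase(phi_next.phase_rad)
    f_n = w_next / TWO_PI  # in [-0.5, 0.5)
    i_n = round_half_away((m_n * l_n - f_n * l_next) / l_next)
    # 2*pi*(I + F) assembled as 2*pi*I + wrapped so that the wrapped part
    # is carried bit-exactly (and the output wraps back to the input
    # exactly wherever no whole cycle is added).
    return PhaseMap(
        phase_rad=TWO_PI * i_n + w_next,
        wavelength_nm=l_next,
        wrapped=False,
        fov=phi_next.fov,
        provenance=phi_next.provenance + " [hierarchical]",
        amplitude=phi_next.amplitude,
    )


def estimate_noise(opd_nm: np.ndarray, region) -> float:
    """Sample standard deviation (nm) of an OPD map over a flat region.

    ``region`` is a boolean mask or an index expression (e.g. a tuple of
    slices); it must select at least 4 pixels.
    """
    values = np.asarray(opd_nm)[region].ravel()
    if values.size < 4:
        raise ValueError("noise region must contain at least 4 pixels")
    return float(np.std(values, ddof=1))


def hierarchical_unwrap(
    ladder: PhaseLadder,
    noise_region: np.ndarray | tuple | None = None,
    final_rung: int | None = None,
) -> UnwrapResult:
    """Unwrap a full ladder: spatial seed, then rung-by-rung cycle transfer.

    The longest-wavelength rung is unwrapped spatially; every following
    rung is unwrapped by :func:`hierarchical_step`.  When ``noise_region``
    is given, the OPD noise of the current map is estimated before each
    transition and an advisory flag is recorded whenever it exceeds half
    the next wavelength — the regime in which rounding no longer removes
    the noise and whole spurious cycles appear.  The final OPD map comes
    from ``final_rung`` (default: the last, shortest-wavelength rung).
    """
    bg = noise_region if isinstance(noise_region, np.ndarray) else None
    current = standard_unwrap(ladder.rungs[0], background_mask=bg)
    unwrapped = [current]
    flags: list[str] = []
    noises: list[float | None] = []
    for nxt in ladder.rungs[1:]:
        noise = None
        if noise_region is not None:
            noise = estimate_noise(current.opd_nm, noise_region)
            if noise > nxt.wavelength_nm / 2:
                flags.append(
                    f"OPD noise {noise:.1f} nm at the {current.wavelength_nm:.2f} nm "
                    f"rung exceeds half of the next rung's wavelength "
                    f"{nxt.wavelength_nm:g} nm; cycle transfer unreliable"
                )
        noises.append(noise)
        current = hierarchical_step(current, nxt)
        unwrapped.append(current)
    idx = len(unwrapped) - 1 if final_rung is None else final_rung
    final = unwrapped[idx]
    return UnwrapResult(
        unwrapped=unwrapped,
        opd_nm=final.phase_rad * final.wavelength_nm / TWO_PI,
        flags=flags,
        noise_nm=noises,
    )
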