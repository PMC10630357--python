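"""Persistence for holograms, wavefronts, phase maps, and OPD maps.

Every array goes to TIFF (unsigned 16-bit container for quantized
holograms, 32-bit float for everything else; complex fields as paired
amplitude/phase TIFFs) with a JSON sidecar carrying all metadata.  Reads
validate the sidecar against the type invariants, so a round trip is
bit-identical and self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .optics import CarrierSet, OpticsConfig
from .reconstruct import ComplexWavefront
from .metrics import OPDMap
from .simulate import PhantomOPD, SixPackHologram
from .synthwave import PhaseMap


class SidecarError(ValueError):
    """Missing or inconsistent JSON sidecar metadata."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read_sidecar(path: Path, required: tuple[str, ...]) -> dict:
    sp = _sidecar_path(path)
    if not sp.exists():
        raise SidecarError(f"sidecar {sp} not found")
    meta = json.loads(sp.read_text())
    for key in required:
        if key not in meta:
            raise SidecarError(f"sidecar {sp} is missing required field {key!r}")
    return meta


def write_hologram(h: SixPackHologram, path: str | Path) -> Path:
    path = Path(path)
    levels = 2 ** h.config.bit_depth - 1
    if h.intensity.max() > levels:
        raise ValueError(
            f"intensity exceeds {h.config.bit_depth}-bit range (max {levels})"
        )
    tifffile.imwrite(path, np.asarray(h.intensity, dtype=np.uint16))
    _write_sidecar(
        path,
        {
            "type": "hologram",
            "kind": h.kind,
            "optics": h.config.to_dict(),
            "carriers": h.carriers.to_rows(),
            "cc_radius": h.carriers.cc_radius,
            "fov_shift_px": h.fov_shift_px,
            "seed": h.seed,
        },
    )
    return path


def read_hologram(path: str | Path) -> SixPackHologram:
    path = Path(path)
    meta = _read_sidecar(path, ("type", "optics", "carriers", "cc_radius", "kind"))
    if meta["type"] != "hologram":
        raise SidecarError(f"{path} is not a hologram (type={meta['type']!r})")
    config = OpticsConfig.from_dict(meta["optics"])
    carriers = CarrierSet.from_rows(meta["carriers"], meta["cc_radius"])
    return SixPackHologram(
        intensity=tifffile.imread(path),
        config=config,
        carriers=carriers,
        kind=meta["kind"],
        fov_shift_px=int(meta.get("fov_shift_px", 0)),
        seed=meta.get("seed"),
    )


def write_wavefront(w: ComplexWavefront, stem: str | Path) -> Path:
    """Write amplitude/phase float TIFF pair ``<stem>.amp.tif``/``.phase.tif``."""
    stem = Path(stem)
    amp_path = stem.with_suffix(".amp.tif")
    phase_path = stem.with_suffix(".phase.tif")
    tifffile.imwrite(amp_path, np.abs(w.field).astype(np.float32))
    tifffile.imwrite(phase_path, np.angle(w.field).astype(np.float32))
    _write_sidecar(
        amp_path,
        {
            "type": "wavefront",
            "wavelength_nm": w.wavelength_nm,
            "fov": w.fov,
            "refocus_um": w.refocus_um,
            "phase_file": phase_path.name,
        },
    )
    return amp_path


def read_wavefront(amp_path: str | Path) -> ComplexWavefront:
    amp_path = Path(amp_path)
    meta = _read_sidecar(amp_path, ("type", "wavelength_nm", "fov", "phase_file"))
    if meta["type"] != "wavefront":
        raise SidecarError(f"{amp_path} is not a wavefront")
    amp = tifffile.imread(amp_path).astype(float)
    phase = tifffile.imread(amp_path.parent / meta["phase_file"]).astype(float)
    return ComplexWavefront(
        field=amp * np.exp(1j * phase),
        wavelength_nm=float(meta["wavelength_nm"]),
        fov=meta["fov"],
        refocus_um=float(meta.get("refocus_um", 0.0)),
    )


def write_phasemap(p: PhaseMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, p.phase_rad.astype(np.float32))
    meta = {
        "type": "phasemap",
        "wavelength_nm": p.wavelength_nm,
        "wrapped": p.wrapped,
        "fov": p.fov,
        "provenance": p.provenance,
    }
    if p.amplitude is not None:
        amp_path = path.with_suffix(".amp.tif")
        tifffile.imwrite(amp_path, p.amplitude.astype(np.float32))
        meta["amplitude_file"] = amp_path.name
    _write_sidecar(path, meta)
    return path


def read_phasemap(path: str | Path) -> PhaseMap:
    path = Path(path)
    meta = _read_sidecar(path, ("type", "wavelength_nm", "wrapped", "fov"))
    if meta["type"] != "phasemap":
        raise SidecarError(f"{path} is not a phase map")
    amplitude = None
    if "amplitude_file" in meta:
        amplitude = tifffile.imread(path.parent / meta["amplitude_file"]).astype(float)
    return PhaseMap(
        phase_rad=tifffile.imread(path).astype(float),
        wavelength_nm=float(meta["wavelength_nm"]),
        wrapped=bool(meta["wrapped"]),
        fov=meta["fov"],
        provenance=meta.get("provenance", ""),
        amplitude=amplitude,
    )


def write_opd(m: OPDMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, m.opd_nm.astype(np.float32))
    _write_sidecar(
        path,
        {"type": "opd", "fov": m.fov, "source": m.source},
    )
    return path


def read_opd(path: str | Path) -> OPDMap:
    path = Path(path)
    meta = _read_sidecar(path, ("type", "fov"))
    if meta["type"] != "opd":
        raise SidecarError(f"{path} is not an OPD map")
    return OPDMap(
        opd_nm=tifffile.imread(path).astype(float),
        fov=meta["fov"],
        source=meta.get("source", ""),
    )


def write_phantom(p: PhantomOPD, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, p.opd_nm.astype(np.float32))
    _write_sidecar(
        path,
        {
            "type": "phantom",
            "n_sample": p.n_sample,
            "n_medium": p.n_medium,
            "masks": sorted(p.masks),
        },
    )
    for name, mask in p.masks.items():
        tifffile.imwrite(
            path.with_suffix(f".mask_{name}.tif"), mask.astype(np.uint8)
        )
    return path


def read_phantom(path: str | Path) -> PhantomOPD:
    path = Path(path)
    meta = _read_sidecar(path, ("type",))
    if meta["type"] != "phantom":
        raise SidecarError(f"{path} is not a phantom")
    masks = {
        name: tifffile.imread(path.with_suffix(f".mask_{name}.tif")).astype(bool)
        for name in meta.get("masks", [])
    }
    return PhantomOPD(
        opd_nm=tifffile.imread(path).astype(float),
        n_sample=float(meta.get("n_sample", 1.0)),
        n_medium=float(meta.get("n_medium", 1.0)),
        masks=masks,
    )


def render_png(array: np.ndarray, path: str | Path, cmap: str = "inferno") -> Path:
    """8-bit PNG render with a perceptually uniform colormap (display only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    plt.imsave(path, np.asarray(array, dtype=float), cmap=cmap)
    return path
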