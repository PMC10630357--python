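"""End-to-end orchestration: simulate -> reconstruct -> combine -> unwrap -> metrics.

A run is described by a single YAML/JSON config (optics, carriers, noise,
phantom, refocus table, filter parameters, ladder, evaluation regions,
seed).  Every stage validates its block before computing, writes
self-describing outputs into the run directory, and the driver records a
manifest (inputs, outputs, config hash, seed, versions) so a run can be
reproduced from its output directory alone.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as spio
from .metrics import OPDMap, region_stats, stitch_fovs
from .optics import (
    CarrierSet,
    ConfigurationError,
    OpticsConfig,
    default_carrier_set,
    validate_carrier_set,
)
from .reconstruct import reconstruct_all
from .simulate import (
    NoiseSpec,
    make_cell_phantom,
    make_channel_phantom,
    make_flat_phantom,
    synthesize_background,
    synthesize_hologram,
)
from .synthwave import nine_map_stack
from .unwrap import PhaseLadder, hierarchical_unwrap


@dataclass
class RunConfig:
    """Validated, serializable description of one pipeline run."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    carriers: CarrierSet | None = None  # None -> default placement
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    phantom_kind: str = "channel"
    phantom_params: dict = field(default_factory=dict)
    fov_shift_px: int = 0
    refocus_um: dict = field(default_factory=dict)  # {(wavelength, fov): um}
    wft_enabled: bool = True
    wft_params: dict = field(default_factory=dict)
    ladder_wavelengths_nm: list[float] | None = None  # None -> full nine
    noise_region: list[int] | None = None  # [y0, y1, x0, x1]
    region_mask_name: str = "channel_interior"
    expected_opd_nm: float | None = None
    final_rung: int | None = None
    seed: int = 0
    raw: dict = field(default_factory=dict)

    def resolve_carriers(self) -> CarrierSet:
        cs = self.carriers or default_carrier_set(self.optics)
        report = validate_carrier_set(cs, self.optics)
        if not report:
            raise ConfigurationError("; ".join(report.violations))
        return cs

    def to_dict(self) -> dict:
        d = dict(self.raw) if self.raw else {}
        d.setdefault("optics", self.optics.to_dict())
        d.setdefault("noise", self.noise.to_dict())
        d.setdefault("phantom", {"kind": self.phantom_kind, **self.phantom_params})
        d.setdefault("fov_shift_px", self.fov_shift_px)
        d.setdefault("seed", self.seed)
        return d


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return run_config_from_dict(raw)


def run_config_from_dict(raw: dict) -> RunConfig:
    try:
        optics = OpticsConfig.from_dict(raw.get("optics", {}))
        carriers = None
        cblock = raw.get("carriers", "auto")
        if isinstance(cblock, dict):
            carriers = CarrierSet.from_rows(cblock["rows"], cblock["cc_radius"])
        noise = NoiseSpec(**{**raw.get("noise", {}), "seed": int(
            raw.get("noise", {}).get("seed", raw.get("seed", 0))
        )})
        phantom = dict(raw.get("phantom", {"kind": "channel"}))
        kind = phantom.pop("kind", "channel")
        if kind not in ("channel", "cells", "flat"):
            raise ConfigurationError(f"unknown phantom kind {kind!r}")
        refocus = {}
        for key, val in (raw.get("refocus_um") or {}).items():
            wl, fov = str(key).rsplit("_", 1)
            refocus[(float(wl), fov)] = float(val)
        wft = dict(raw.get("wft", {}))
        cfg = RunConfig(
            optics=optics,
            carriers=carriers,
            noise=noise,
            phantom_kind=kind,
            phantom_params=phantom,
            fov_shift_px=int(raw.get("fov_shift_px", 0)),
            refocus_um=refocus,
            wft_enabled=bool(wft.pop("enabled", True)),
            wft_params=wft,
            ladder_wavelengths_nm=raw.get("ladder"),
            noise_region=raw.get("regions", {}).get("noise_region"),
            region_mask_name=raw.get("regions", {}).get(
                "mask", "channel_interior"
            ),
            expected_opd_nm=raw.get("regions", {}).get("expected_opd_nm"),
            final_rung=raw.get("final_rung"),
            seed=int(raw.get("seed", 0)),
            raw=raw,
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(f"invalid run config: {exc}") from exc
    cfg.resolve_carriers()  # fail fast on an invalid carrier block
    return cfg


def _make_phantom(cfg: RunConfig):
    if cfg.phantom_kind == "channel":
        return make_channel_phantom(cfg.optics, **cfg.phantom_params)
    if cfg.phantom_kind == "cells":
        params = dict(cfg.phantom_params)
        params.setdefault("seed", cfg.seed)
        return make_cell_phantom(cfg.optics, **params)
    return make_flat_phantom(cfg.optics)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(outdir: Path, cfg: RunConfig, inputs: list, outputs: list) -> None:
    import sixpackholo

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "versions": {
            "sixpackholo": sixpackholo.__version__,
            "numpy": np.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    )


def run_simulate(cfg: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Phantom + sample and background six-pack holograms."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    carriers = cfg.resolve_carriers()
    phantom = _make_phantom(cfg)
    sample = synthesize_hologram(
        phantom, cfg.optics, carriers, noise=cfg.noise,
        fov_shift_px=cfg.fov_shift_px,
    )
    background = synthesize_background(
        cfg.optics, carriers, noise=cfg.noise, fov_shift_px=cfg.fov_shift_px
    )
    paths = {
        "phantom": spio.write_phantom(phantom, outdir / "phantom.tif"),
        "sample": spio.write_hologram(sample, outdir / "sample.tif"),
        "background": spio.write_hologram(background, outdir / "background.tif"),
    }
    _write_manifest(outdir, cfg, [], list(paths.values()))
    return paths


def run_reconstruct(cfg: RunConfig, sample_path, background_path,
                    outdir: str | Path) -> dict:
    """Holograms -> six background-compensated wavefronts on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample = spio.read_hologram(sample_path)
    background = spio.read_hologram(background_path)
    wavefronts = reconstruct_all(
        sample, background, sample.carriers,
        refocus_table=cfg.refocus_um,
        wft_params=cfg.wft_params,
        apply_wft=cfg.wft_enabled,
    )
    paths = {}
    for (wl, fov), wf in wavefronts.items():
        paths[(wl, fov)] = spio.write_wavefront(
            wf, outdir / f"wavefront_{wl:g}_{fov}"
        )
    _write_manifest(outdir, cfg, [sample_path, background_path],
                    list(paths.values()))
    return paths


def run_synthesize_maps(cfg: RunConfig, wavefront_dir: str | Path,
                        outdir: str | Path) -> dict[str, list[Path]]:
    """Wavefronts -> the nine-map wrapped stack per FOV, with a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wavefront_dir = Path(wavefront_dir)
    stacks: dict[str, list[Path]] = {}
    for fov in ("left", "right"):
        channels = [
            spio.read_wavefront(p)
            for p in sorted(wavefront_dir.glob(f"wavefront_*_{fov}.amp.tif"))
        ]
        if len(channels) != 3:
            raise FileNotFoundError(
                f"expected 3 wavefronts for fov {fov!r} in {wavefront_dir}, "
                f"found {len(channels)}"
            )
        maps = nine_map_stack(channels)
        paths = [
            spio.write_phasemap(m, outdir / f"phase_{fov}_{i:02d}.tif")
            for i, m in enumerate(maps)
        ]
        (outdir / f"stack_{fov}.json").write_text(
            json.dumps(
                [
                    {"file": p.name, "wavelength_nm": m.wavelength_nm,
                     "provenance": m.provenance}
                    for p, m in zip(paths, maps)
                ],
                indent=2,
            )
        )
        stacks[fov] = paths
    _write_manifest(outdir, cfg, [wavefront_dir],
                    [p for ps in stacks.values() for p in ps])
    return stacks


def _noise_region_mask(cfg: RunConfig, shape) -> np.ndarray | None:
    if cfg.noise_region is None:
        return None
    y0, y1, x0, x1 = cfg.noise_region
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = True
    return mask


def run_unwrap(cfg: RunConfig, stack_dir: str | Path,
               outdir: str | Path) -> dict[str, Path]:
    """Nine-map stacks -> hierarchically unwrapped OPD maps + JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack_dir = Path(stack_dir)
    results = {}
    report = {}
    for fov in ("left", "right"):
        manifest = json.loads((stack_dir / f"stack_{fov}.json").read_text())
        maps = [spio.read_phasemap(stack_dir / row["file"]) for row in manifest]
        if cfg.ladder_wavelengths_nm:
            chosen = set(round(w, 2) for w in cfg.ladder_wavelengths_nm)
            maps = [m for m in maps if round(m.wavelength_nm, 2) in chosen]
        ladder = PhaseLadder(rungs=maps, fov=fov)
        region = _noise_region_mask(cfg, maps[0].phase_rad.shape)
        result = hierarchical_unwrap(
            ladder, noise_region=region, final_rung=cfg.final_rung
        )
        opd = OPDMap(opd_nm=result.opd_nm, fov=fov, source="hierarchical")
        results[fov] = spio.write_opd(opd, outdir / f"opd_{fov}.tif")
        for i, rung in enumerate(result.unwrapped):
            spio.write_phasemap(rung, outdir / f"unwrapped_{fov}_{i:02d}.tif")
        report[fov] = {
            "ladder_wavelengths_nm": ladder.wavelengths_nm,
            "advisory_flags": result.flags,
            "noise_nm": result.noise_nm,
        }
    (outdir / "unwrap_report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(outdir, cfg, [stack_dir], list(results.values()))
    return results


def run_metrics(cfg: RunConfig, opd_paths: dict[str, Path],
                phantom_path, outdir: str | Path) -> Path:
    """Region statistics per FOV plus the stitched-FOV consistency metric."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phantom = spio.read_phantom(phantom_path) if phantom_path else None
    rows = []
    opds = {fov: spio.read_opd(p) for fov, p in opd_paths.items()}
    for fov, opd in opds.items():
        if phantom is not None and cfg.region_mask_name in phantom.masks:
            shift = (
                -cfg.fov_shift_px // 2
                if fov == "left"
                else cfg.fov_shift_px - cfg.fov_shift_px // 2
            )
            mask = np.roll(phantom.masks[cfg.region_mask_name], shift, axis=1)
            stats = region_stats(opd, mask, expected_nm=cfg.expected_opd_nm)
            rows.append({"region": f"{cfg.region_mask_name}_{fov}", **stats})
        if cfg.noise_region is not None:
            mask = _noise_region_mask(cfg, opd.opd_nm.shape)
            stats = region_stats(opd, mask)
            rows.append({"region": f"noise_region_{fov}", **stats})
    if {"left", "right"} <= set(opds):
        _, _, disagreement = stitch_fovs(
            opds["left"], opds["right"], cfg.fov_shift_px
        )
        rows.append({"region": "fov_overlap", "std_nm": disagreement})
    out_csv = outdir / "metrics.csv"
    fieldnames = ["region", "mean_nm", "std_nm", "n_pixels", "expected_nm",
                  "accuracy_pct"]
    with out_csv.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in fieldnames})
    (outdir / "metrics.json").write_text(json.dumps(rows, indent=2))
    _write_manifest(outdir, cfg, list(opd_paths.values()), [out_csv])
    return out_csv


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """The whole chain in one call; returns key output paths and metrics."""
    outdir = Path(outdir)
    sim = run_simulate(cfg, outdir / "simulate")
    run_reconstruct(cfg, sim["sample"], sim["background"], outdir / "reconstruct")
    run_synthesize_maps(cfg, outdir / "reconstruct", outdir / "maps")
    opd_paths = run_unwrap(cfg, outdir / "maps", outdir / "unwrap")
    metrics_csv = run_metrics(cfg, opd_paths, sim["phantom"], outdir / "metrics")
    _write_manifest(outdir, cfg, [], [metrics_csv])
    return {
        "opd": opd_paths,
        "metrics_csv": metrics_csv,
        "metrics": json.loads((outdir / "metrics" / "metrics.json").read_text()),
    }
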