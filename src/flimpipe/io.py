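"""On-disk formats: HDF5 waveform containers, label rasters, CSV tables.

A simulated (or imported) cohort is laid out as one directory per run:

    scans.h5                  /patient_<id>/{waveforms, gain, xy, point_id}
    masks/<id>_mask.png       integer label raster (uint8 PNG)
    masks/<id>_legend.json    {code: class name} legend + geometry
    truth.csv                 ground-truth table (synthetic cohorts only)
    manifest.json             seed, config digest, stage record
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .coregister import PathologyMask
from .records import WaveformSet

__all__ = [
    "write_cohort",
    "read_waveforms",
    "write_mask",
    "read_mask",
    "config_digest",
    "write_manifest",
    "update_manifest",
]


def config_digest(obj) -> str:
    """Stable short digest of a (dataclass or dict) configuration."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_mask(mask: PathologyMask, png_path: Path, legend_path: Path) -> None:
    Image.fromarray(mask.label_raster.astype(np.uint8), mode="L").save(png_path)
    meta = {
        "legend": {str(k): v for k, v in mask.legend.items()},
        "pixel_size_mm": mask.pixel_size_mm,
        "origin_mm": list(mask.origin_mm),
    }
    legend_path.write_text(json.dumps(meta, indent=2))


def read_mask(png_path: Path, legend_path: Path) -> PathologyMask:
    raster = np.asarray(Image.open(png_path), dtype=np.uint8)
    meta = json.loads(Path(legend_path).read_text())
    return PathologyMask(
        label_raster=raster,
        pixel_size_mm=float(meta["pixel_size_mm"]),
        origin_mm=tuple(meta["origin_mm"]),
        legend={int(k): v for k, v in meta["legend"].items()},
    )


def write_cohort(cohort, outdir: Path) -> None:
    """Write a generated cohort (waveforms, masks, truth) to a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    with h5py.File(outdir / "scans.h5", "w") as f:
        f.attrs["phase"] = cohort.config.phase
        for p in cohort.patients:
            if p.waveforms is None:
                continue
            g = f.create_group(f"patient_{p.patient_id}")
            g.create_dataset("waveforms", data=p.waveforms.samples.astype(np.float32))
            g.create_dataset("gain", data=p.waveforms.gains)
            g.create_dataset("xy", data=p.waveforms.xy_mm)
            g.create_dataset("point_id", data=p.waveforms.point_ids)
            g.attrs["sample_rate"] = p.waveforms.sample_rate
            g.attrs["phase"] = p.phase
    for p in cohort.patients:
        write_mask(
            p.mask,
            outdir / "masks" / f"{p.patient_id}_mask.png",
            outdir / "masks" / f"{p.patient_id}_legend.json",
        )
    cohort.truth.to_csv(outdir / "truth.csv", index=False)


def read_waveforms(h5_path: Path) -> dict[str, WaveformSet]:
    """Load every patient's waveform set from a scans container."""
    out: dict[str, WaveformSet] = {}
    with h5py.File(h5_path, "r") as f:
        for key in sorted(f):
            g = f[key]
            pid = key.removeprefix("patient_")
            out[pid] = WaveformSet(
                samples=g["waveforms"][...].astype(float),
                gains=g["gain"][...],
                xy_mm=g["xy"][...],
                point_ids=g["point_id"][...],
                patient_id=pid,
                phase=str(g.attrs["phase"]),
                sample_rate=float(g.attrs["sample_rate"]),
            )
    return out


def write_manifest(outdir: Path, seed: int, digest: str, extra: dict | None = None) -> Path:
    path = Path(outdir) / "manifest.json"
    manifest = {"seed": seed, "config_digest": digest, "stages": {}}
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def update_manifest(outdir: Path, stage: str, record: dict) -> None:
    path = Path(outdir) / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest.setdefault("stages", {})[stage] = record
    path.write_text(json.dumps(manifest, indent=2, default=str))


def write_table(df: pd.DataFrame, path: Path, seed: int | None = None, digest: str | None = None) -> None:
    """CSV with a provenance header comment (seed + config digest)."""
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None or digest is not None:
            fh.write(f"# seed={seed} config_digest={digest}\n")
        df.to_csv(fh, index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
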