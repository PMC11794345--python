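"""File formats: multi-page TIFF frame stacks with JSON sidecars, map TIFFs,
phantom reference text files, and study-table CSVs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .scenes import FrameStack

STUDY_COLUMNS = ["animal_id", "group", "lobe", "timepoint", "sto2", "lactate", "ref_sto2"]


def write_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write frames as a multi-page float TIFF plus a ``.json`` sidecar
    describing (wavelength, fx, phase) per page and the pixel pitch."""
    path = Path(path)
    n_wl, n_fx, n_ph, h, w = stack.frames.shape
    pages = stack.frames.reshape(n_wl * n_fx * n_ph, h, w).astype(np.float32)
    tifffile.imwrite(path, pages)
    index = [
        {"page": i, "wavelength_nm": wl, "fx_mm": fx, "phase_rad": ph}
        for i, (wl, fx, ph) in enumerate(
            (wl, fx, ph)
            for wl in stack.wavelengths
            for fx in stack.spatial_frequencies
            for ph in stack.phases
        )
    ]
    sidecar = {
        "pixel_pitch_mm": stack.pixel_pitch,
        "wavelengths_nm": list(stack.wavelengths),
        "spatial_frequencies_mm": list(stack.spatial_frequencies),
        "phases_rad": list(stack.phases),
        "pages": index,
        "metadata": stack.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_frame_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("pixel_pitch_mm", "wavelengths_nm", "spatial_frequencies_mm", "phases_rad"):
        if key not in meta:
            raise KeyError(f"sidecar lacks required field '{key}'")
    pages = tifffile.imread(path)
    wl = tuple(int(x) for x in meta["wavelengths_nm"])
    fxs = tuple(float(x) for x in meta["spatial_frequencies_mm"])
    phs = tuple(float(x) for x in meta["phases_rad"])
    n = len(wl) * len(fxs) * len(phs)
    if pages.shape[0] != n:
        raise ValueError(f"stack has {pages.shape[0]} pages, sidecar implies {n}")
    frames = pages.reshape(len(wl), len(fxs), len(phs), *pages.shape[1:]).astype(float)
    return FrameStack(
        frames=frames, wavelengths=wl, spatial_frequencies=fxs, phases=phs,
        pixel_pitch=float(meta["pixel_pitch_mm"]), metadata=meta.get("metadata", {}),
    )


def write_map(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def read_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def write_phantom_properties(
    mu_a: Mapping[int, float], mu_s_prime: Mapping[int, float],
    refractive_index: float, path: str | Path,
) -> Path:
    path = Path(path)
    payload = {
        "refractive_index": refractive_index,
        "properties": [
            {"wavelength_nm": wl, "mu_a_mm": mu_a[wl], "mu_s_prime_mm": mu_s_prime[wl]}
            for wl in sorted(mu_a)
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_phantom_properties(path: str | Path) -> tuple[dict, dict, float]:
    payload = json.loads(Path(path).read_text())
    mu_a = {int(p["wavelength_nm"]): float(p["mu_a_mm"]) for p in payload["properties"]}
    mu_s = {int(p["wavelength_nm"]): float(p["mu_s_prime_mm"]) for p in payload["properties"]}
    return mu_a, mu_s, float(payload["refractive_index"])


def write_study_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, columns=[c for c in STUDY_COLUMNS if c in table.columns])
    return path


def read_study_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
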