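"""File I/O: 16-bit grayscale TIFFs with JSON sidecars, dataset manifests,
and CSV outputs stamped with the seed and configuration hash."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .records import AcquisitionMeta, Kymograph

__all__ = ["write_kymograph", "read_kymograph", "write_zstack",
           "write_csv_with_header", "read_csv_with_header"]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    return obj


def write_kymograph(path: str | Path, kymo: Kymograph,
                    extra: dict[str, Any] | None = None) -> Path:
    """Write a kymograph as 16-bit grayscale TIFF plus a JSON sidecar
    carrying the acquisition metadata (and any ``extra`` entries, e.g. the
    generative ground truth and seed).  Returns the sidecar path."""
    path = Path(path)
    img = kymo.image
    if img.dtype != np.uint16:
        img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, img)
    sidecar = path.with_suffix(".json")
    payload = {"meta": _jsonable(kymo.meta)}
    if extra:
        payload.update(_jsonable(extra))
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar


def read_kymograph(path: str | Path) -> tuple[Kymograph, dict[str, Any]]:
    """Read a TIFF + sidecar pair; returns the kymograph and the full
    sidecar payload (which includes any stored ground truth)."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ParameterError(f"missing sidecar {sidecar}")
    payload = json.loads(sidecar.read_text())
    m = payload["meta"]
    meta = AcquisitionMeta(
        line_period_s=m["line_period_s"], pixel_size_um=m["pixel_size_um"],
        n_lines=m["n_lines"], n_pixels=m["n_pixels"],
        stimulus_onsets=tuple(m.get("stimulus_onsets", ())))
    image = tifffile.imread(path)
    return Kymograph(image=image, meta=meta), payload


def write_zstack(path: str | Path, stack: np.ndarray) -> Path:
    """Write a multi-page 16-bit grayscale TIFF z-stack."""
    path = Path(path)
    img = np.clip(np.rint(np.asarray(stack)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, img)
    return path


def write_csv_with_header(df: pd.DataFrame, path: str | Path,
                          seed: int | None = None,
                          config_hash: str | None = None) -> Path:
    """RFC-4180 CSV with ``#``-prefixed provenance comment lines on top."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv_with_header(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
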