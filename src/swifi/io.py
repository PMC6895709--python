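"""File formats: TIFF movies with YAML sidecars, CSV tables, configs.

Movies travel as multi-page 16-bit TIFF stacks (one page per frame,
both channels side by side) with a small YAML sidecar holding the
acquisition metadata the pixel data cannot carry: pixel size, frame
time, excitation schedule, chip layout and the simulation seed where
applicable.  Tabular interchange (localizations, tracks, FRET records,
ground truth) is plain CSV with documented headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .movie import ChannelLayout, Movie

__all__ = [
    "write_movie",
    "read_movie",
    "sidecar_path",
    "write_table",
    "read_table",
    "write_json",
    "load_yaml",
]


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".yaml")


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as multi-page uint16 TIFF plus a YAML sidecar."""
    path = Path(path)
    data = movie.data
    if data.dtype != np.uint16:
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_size_nm": float(movie.pixel_size_nm),
        "frame_time_ms": float(movie.frame_time_ms),
        "excitation": [str(e) for e in movie.excitation],
        "layout": {
            "split": movie.layout.split,
            "split_index": movie.layout.split_index,
            "channel_offset": [float(v) for v in movie.layout.channel_offset],
            "roles": list(movie.layout.roles),
        },
        "seed": movie.seed,
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def _layout_from_dict(d: dict) -> ChannelLayout:
    return ChannelLayout(
        split=d.get("split", "left_right"),
        split_index=d.get("split_index"),
        channel_offset=tuple(d.get("channel_offset", (0.0, 0.0))),
        roles=tuple(d.get("roles", ("donor", "acceptor"))),
    )


def read_movie(
    path: str | Path,
    layout: ChannelLayout | None = None,
    pixel_size_nm: float | None = None,
    frame_time_ms: float | None = None,
) -> Movie:
    """Read a TIFF stack (and its sidecar, if present) into a Movie.

    Explicit arguments override sidecar values; without a sidecar the
    pixel size and frame time must be supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie not found: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF shape {data.shape} in {path}")

    meta: dict = {}
    sp = sidecar_path(path)
    if sp.exists():
        with open(sp) as fh:
            meta = yaml.safe_load(fh) or {}
    if layout is None:
        layout = _layout_from_dict(meta.get("layout", {}))
    pixel = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    ftime = frame_time_ms if frame_time_ms is not None else meta.get("frame_time_ms")
    if pixel is None or ftime is None:
        raise ValueError(
            f"{path}: pixel size / frame time missing (no sidecar found)"
        )
    exc = meta.get("excitation")
    if exc is None:
        exc = ["D"] * data.shape[0]
    layout.resolve_split((data.shape[1], data.shape[2]))  # validate geometry
    return Movie(
        data=data,
        pixel_size_nm=float(pixel),
        frame_time_ms=float(ftime),
        excitation=np.asarray(exc),
        layout=layout,
        seed=meta.get("seed"),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
    return path


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
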