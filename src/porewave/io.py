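"""File I/O: TIFF movies with JSON sidecars, CSV kymographs and tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kmc import Event, EventKind, RingTrajectory
from .synthetic import Kymograph, TopographyMovie


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: TopographyMovie, path) -> None:
    """Multi-page 32-bit float TIFF (heights in nm) + JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32), photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {"pixel_size_nm": movie.pixel_size, "frame_interval_s": movie.frame_interval}
        )
        + "\n"
    )


def read_movie(path) -> TopographyMovie:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata sidecar {sidecar} missing; refusing to guess pixel size / frame interval"
        )
    meta = json.loads(sidecar.read_text())
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # corrupt / truncated stack
        raise OSError(f"failed to parse TIFF movie {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    return TopographyMovie(
        frames=frames,
        pixel_size=float(meta["pixel_size_nm"]),
        frame_interval=float(meta["frame_interval_s"]),
    )


def write_kymograph(kymo: Kymograph, path) -> None:
    """CSV with one scan line per row; metadata in a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, kymo.lines, fmt="%.8g", delimiter=",")
    _sidecar_path(path).write_text(
        json.dumps(
            {"line_interval_s": kymo.line_interval, "pixel_size_nm": kymo.pixel_size}
        )
        + "\n"
    )


def read_kymograph(path) -> Kymograph:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} missing")
    meta = json.loads(sidecar.read_text())
    lines = np.loadtxt(path, delimiter=",", ndmin=2)
    return Kymograph(
        lines=lines,
        line_interval=float(meta["line_interval_s"]),
        pixel_size=float(meta["pixel_size_nm"]),
    )


def write_trajectories(trajs: list[RingTrajectory], path) -> None:
    """Event-list CSV: time_s,event,subunit,ring_id (one row per event)."""
    frames = [t.to_dataframe() for t in trajs]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["time_s", "event", "subunit", "ring_id"]
    )
    df.to_csv(path, index=False)


def read_trajectories(path, t_end: float) -> list[RingTrajectory]:
    df = pd.read_csv(path)
    out = []
    for ring_id, g in df.groupby("ring_id", sort=True):
        events = [
            Event(
                float(r.time_s),
                EventKind(r.event),
                None if pd.isna(r.subunit) else int(r.subunit),
            )
            for r in g.itertuples()
        ]
        events.sort(key=lambda e: e.time)
        site = next(
            (e.subunit for e in events if e.kind is EventKind.NUCLEATE), None
        )
        out.append(
            RingTrajectory(events=events, ring_id=int(ring_id), t_end=t_end, breakage_site=site)
        )
    return out
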