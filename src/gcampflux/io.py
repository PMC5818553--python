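"""Reading and writing the pipeline's file formats.

Movies travel as multi-page 16-bit grayscale TIFF (via tifffile) or as NPZ
array containers (lossless float); either carries a JSON sidecar with the
protocol, imaging parameters and any ground truth.  ROIs are label-image
TIFFs or polygon JSON; traces and focal records are plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .extract import BoutonTrace, RoiSet
from .simulate import FrameStack

__all__ = [
    "save_movie", "load_movie",
    "save_rois", "load_rois",
    "save_traces", "load_traces",
    "save_focal", "load_focal",
    "write_sidecar",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if callable(obj):
        return repr(obj)
    return obj


def write_sidecar(path: str | Path, **payload) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(payload), indent=2))
    return path


def save_movie(stack: FrameStack, path: str | Path, **sidecar) -> Path:
    """NPZ (.npz, lossless) or multi-page 16-bit TIFF (.tif/.tiff, scaled)."""

    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, frames=stack.frames,
                            frame_rate=stack.frame_rate, channel=stack.channel)
    elif path.suffix in (".tif", ".tiff"):
        lo, hi = float(stack.frames.min()), float(stack.frames.max())
        scale = (65535.0 / (hi - lo)) if hi > lo else 1.0
        data = np.round((stack.frames - lo) * scale).astype(np.uint16)
        tifffile.imwrite(path, data, metadata={
            "frame_rate": stack.frame_rate, "channel": stack.channel,
            "offset": lo, "scale": scale})
        sidecar.setdefault("intensity_offset", lo)
        sidecar.setdefault("intensity_scale", scale)
    else:
        raise ValueError("movie path must end in .npz, .tif or .tiff")
    if sidecar:
        write_sidecar(path.with_suffix(path.suffix + ".json"),
                      frame_rate=stack.frame_rate, channel=stack.channel,
                      **sidecar)
    return path


def load_movie(path: str | Path) -> FrameStack:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return FrameStack(frames=z["frames"],
                              frame_rate=float(z["frame_rate"]),
                              channel=str(z["channel"]))
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    meta_path = path.with_suffix(path.suffix + ".json")
    frame_rate, channel = 25.0, "green"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        frame_rate = float(meta.get("frame_rate", frame_rate))
        channel = meta.get("channel", channel)
        scale = float(meta.get("intensity_scale", 1.0))
        frames = frames / scale + float(meta.get("intensity_offset", 0.0))
    return FrameStack(frames=frames, frame_rate=frame_rate, channel=channel)


def save_rois(rois: RoiSet, path: str | Path) -> Path:
    """Label-image TIFF (bouton label i+1, background label -(i+1) in a
    second page) plus a JSON with type/NMJ tags."""

    path = Path(path)
    shape = next(iter(rois.boutons.values())).shape
    bouton_img = np.zeros(shape, dtype=np.int32)
    bg_img = np.zeros(shape, dtype=np.int32)
    for label, mask in rois.boutons.items():
        bouton_img[mask] = label + 1
        bg_img[rois.backgrounds[label]] = label + 1
    tifffile.imwrite(path, np.stack([bouton_img, bg_img]))
    write_sidecar(path.with_suffix(path.suffix + ".json"),
                  terminal_type=rois.terminal_type, nmj_id=rois.nmj_id)
    return path


def load_rois(path: str | Path) -> RoiSet:
    path = Path(path)
    img = tifffile.imread(path)
    bouton_img, bg_img = img[0], img[1]
    meta = {}
    meta_path = path.with_suffix(path.suffix + ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    boutons, backgrounds = {}, {}
    for raw in np.unique(bouton_img):
        if raw == 0:
            continue
        label = int(raw) - 1
        boutons[label] = bouton_img == raw
        backgrounds[label] = bg_img == raw
    return RoiSet(
        boutons=boutons, backgrounds=backgrounds,
        terminal_type={int(k): v for k, v in meta.get("terminal_type", {}).items()},
        nmj_id={int(k): int(v) for k, v in meta.get("nmj_id", {}).items()},
    )


def save_traces(traces: list[BoutonTrace], path: str | Path) -> Path:
    rows = []
    for tr in traces:
        for i in range(tr.time.size):
            rows.append({
                "bouton_id": tr.bouton_id, "nmj_id": tr.nmj_id,
                "terminal_type": tr.terminal_type,
                "time_s": tr.time[i], "f_raw": tr.f_raw[i],
                "f_bg": tr.f_bg[i], "f_t": tr.f_t[i],
                "dff": tr.dff[i] if tr.dff is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def load_traces(path: str | Path) -> list[BoutonTrace]:
    df = pd.read_csv(path)
    traces = []
    for bid, g in df.groupby("bouton_id"):
        g = g.sort_values("time_s")
        dff = g["dff"].to_numpy()
        traces.append(BoutonTrace(
            bouton_id=int(bid),
            time=g["time_s"].to_numpy(),
            f_raw=g["f_raw"].to_numpy(),
            f_bg=g["f_bg"].to_numpy(),
            f_t=g["f_t"].to_numpy(),
            terminal_type=str(g["terminal_type"].iloc[0]),
            nmj_id=int(g["nmj_id"].iloc[0]),
            dff=None if np.isnan(dff).all() else dff,
        ))
    return traces


def save_focal(t: np.ndarray, y: np.ndarray, path: str | Path) -> Path:
    pd.DataFrame({"time_s": t, "amplitude": y}).to_csv(path, index=False)
    return Path(path)


def load_focal(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), df["amplitude"].to_numpy()
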