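"""File interchange: TIFF/HDF5 movies, label-image masks, CSV tables."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .masks import PixelMask, masks_to_label_image, label_image_to_masks

MOVIE_DATASET = "movie"


def save_movie(path: str | Path, movie: np.ndarray) -> None:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, movie)
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset(MOVIE_DATASET, data=movie)
    else:
        raise ValueError(f"unsupported movie format {path.suffix!r}")


def load_movie(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f[MOVIE_DATASET][...]
    raise ValueError(f"unsupported movie format {path.suffix!r}")


def save_masks(path: str | Path, masks: list[PixelMask], shape: tuple[int, int]) -> None:
    """16-bit label TIFF (0 background, k = dendrite k) + JSON manifest."""
    path = Path(path)
    tifffile.imwrite(path, masks_to_label_image(masks, shape))
    manifest = {
        str(m.id): {"pixels": m.area, "centroid": list(m.centroid)} for m in masks
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_masks(path: str | Path) -> list[PixelMask]:
    return label_image_to_masks(tifffile.imread(path))


def save_trials(path: str | Path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def load_trials(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_licks(path: str | Path, licks: np.ndarray) -> None:
    pd.DataFrame({"lick_time_s": licks}).to_csv(path, index=False)


def load_licks(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["lick_time_s"].to_numpy(dtype=float)


def save_piezo(path: str | Path, samples: np.ndarray, rate: float) -> None:
    pd.DataFrame({"time_s": np.arange(samples.size) / rate, "value": samples}).to_csv(
        path, index=False
    )


def load_piezo(path: str | Path):
    from .synth import PiezoTrace

    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    rate = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
    return PiezoTrace(samples=df["value"].to_numpy(dtype=float), rate=float(rate))


def save_shifts(path: str | Path, shifts: np.ndarray) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(shifts)), "dy": shifts[:, 0], "dx": shifts[:, 1]}
    ).to_csv(path, index=False)


def load_shifts(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["dy", "dx"]].to_numpy(dtype=float)


def save_events(path: str | Path, trains, frame_rate: float) -> None:
    rows = []
    for tr in trains:
        for f in tr.frames:
            rows.append((tr.dendrite_id, int(f), f / frame_rate))
    pd.DataFrame(rows, columns=["dendrite_id", "frame", "time_s"]).to_csv(
        path, index=False
    )


def load_events(path: str | Path, frame_rate: float):
    from .events import EventTrain

    df = pd.read_csv(path)
    trains = []
    for did, grp in df.groupby("dendrite_id"):
        trains.append(
            EventTrain(
                frames=np.sort(grp["frame"].to_numpy(dtype=np.int64)),
                frame_rate=frame_rate,
                dendrite_id=int(did),
            )
        )
    return trains


def save_traces(path: str | Path, traces: list[np.ndarray]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=np.stack(traces) if traces else np.zeros((0, 0)))


def load_traces(path: str | Path) -> list[np.ndarray]:
    with h5py.File(path, "r") as f:
        arr = f["traces"][...]
    return [arr[i] for i in range(arr.shape[0])]


def save_psth(path: str | Path, psth) -> None:
    pd.DataFrame(
        {
            "bin_center_s": psth.bin_centers,
            "mean_rate_hz": psth.mean_rate,
            "sem_hz": psth.sem,
        }
    ).to_csv(path, index=False)


def load_psth_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
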