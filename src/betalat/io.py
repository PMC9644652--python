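"""Serialization: HDF5 epoch containers, NIfTI volumes, CSV exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .core import HeadModel, InvalidInputError, SensorEpochs, SourceGrid, SourceStatMap
from .spectral import TFR


def save_epochs(path: str | Path, epochs: SensorEpochs, grid: SourceGrid | None = None) -> None:
    """Write epochs (and optionally head/grid geometry) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sfreq"] = epochs.sfreq
        if epochs.head is not None:
            g = f.create_group("head")
            g.create_dataset("sphere_center", data=epochs.head.sphere_center)
            g.create_dataset("sensor_positions", data=epochs.head.sensor_positions)
            g.create_dataset("sensor_orientations", data=epochs.head.sensor_orientations)
        if grid is not None:
            g = f.create_group("grid")
            g.create_dataset("positions", data=grid.positions)
            g.create_dataset("inside_mask", data=grid.inside_mask)
            g.create_dataset("atlas_labels", data=grid.atlas_labels)
            g.attrs["spacing"] = grid.spacing
            g.attrs["shape"] = grid.shape


def load_epochs(path: str | Path) -> tuple[SensorEpochs, SourceGrid | None]:
    with h5py.File(path, "r") as f:
        head = None
        if "head" in f:
            head = HeadModel(
                sphere_center=f["head/sphere_center"][()],
                sensor_positions=f["head/sensor_positions"][()],
                sensor_orientations=f["head/sensor_orientations"][()],
            )
        epochs = SensorEpochs(data=f["data"][()], times=f["times"][()],
                              sfreq=float(f.attrs["sfreq"]), head=head)
        grid = None
        if "grid" in f:
            grid = SourceGrid(
                positions=f["grid/positions"][()],
                inside_mask=f["grid/inside_mask"][()].astype(bool),
                atlas_labels=f["grid/atlas_labels"][()].astype(int),
                spacing=float(f["grid"].attrs["spacing"]),
                shape=tuple(int(x) for x in f["grid"].attrs["shape"]),
            )
    return epochs, grid


def read_fif_epochs(path: str | Path) -> SensorEpochs:
    """Optional adapter: import epoched MEG data from a FIF file."""
    import mne

    ep = mne.read_epochs(str(path), preload=True, verbose="error")
    return SensorEpochs(data=ep.get_data(copy=True), times=ep.times,
                        sfreq=float(ep.info["sfreq"]), head=None)


def save_map_nifti(stat_map: SourceStatMap, path: str | Path) -> None:
    img = nib.Nifti1Image(stat_map.to_volume().astype(np.float32),
                          stat_map.grid.affine)
    nib.save(img, str(path))


def load_map_nifti(path: str | Path, grid: SourceGrid) -> SourceStatMap:
    img = nib.load(str(path))
    vol = np.asarray(img.get_fdata(), float)
    if vol.shape != grid.shape:
        raise InvalidInputError(
            f"volume shape {vol.shape} does not match grid shape {grid.shape}")
    if not np.allclose(img.affine, grid.affine, atol=1e-3):
        raise InvalidInputError("volume affine does not match the grid affine")
    values = vol.ravel()
    return SourceStatMap(values=values, mask=grid.inside_mask.copy(), grid=grid,
                         info={"source": str(path)})


def map_to_csv(stat_map: SourceStatMap, path: str | Path) -> None:
    idx = np.flatnonzero(stat_map.mask)
    pd.DataFrame({
        "voxel": idx,
        "x_mm": stat_map.grid.positions[idx, 0],
        "y_mm": stat_map.grid.positions[idx, 1],
        "z_mm": stat_map.grid.positions[idx, 2],
        "value": stat_map.values[idx],
    }).to_csv(path, index=False)


def tfr_to_csv(tfr: TFR, path: str | Path) -> None:
    """Long-format export: channel, freq, time, value."""
    n_chan, n_freq, n_time = tfr.power.shape
    chan, freq, time = np.meshgrid(np.arange(n_chan), tfr.freqs, tfr.times,
                                   indexing="ij")
    pd.DataFrame({
        "channel": chan.ravel(),
        "freq_hz": freq.ravel(),
        "time_s": time.ravel(),
        "value": tfr.power.ravel(),
    }).to_csv(path, index=False)


def save_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
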