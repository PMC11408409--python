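"""HDF5 container for epoch tensors.

Layout: datasets ``/data`` (float32, epochs x channels x samples, uV) and
``/times`` (ms); file attributes ``fs`` and ``channel_names``; per-epoch
string datasets ``/group``, ``/subject_id``, ``/stimulus_code`` and, for
averaged records, ``/block_index``.
"""

from __future__ import annotations

import h5py
import numpy as np

from .synthcohort import EpochSet

__all__ = ["save_epochs", "load_epochs"]

_STR = h5py.string_dtype(encoding="utf-8")


def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times", data=np.asarray(epochs.times, dtype=float))
        f.attrs["fs"] = float(epochs.fs)
        f.attrs.create("channel_names", data=list(epochs.channel_names), dtype=_STR)
        for name in ("group", "subject_id", "stimulus_code"):
            f.create_dataset(name, data=np.asarray(getattr(epochs, name), dtype=object),
                             dtype=_STR)
        if epochs.block_index is not None:
            f.create_dataset("block_index", data=np.asarray(epochs.block_index, dtype=int))


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            fs=float(f.attrs["fs"]),
            stimulus_code=f["stimulus_code"].asstr()[()],
            group=f["group"].asstr()[()],
            subject_id=f["subject_id"].asstr()[()],
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            block_index=f["block_index"][()] if "block_index" in f else None,
        )
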