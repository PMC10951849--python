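"""HDF5 persistence for epochs, leadfields and TFRs.

Epochs layout (one group per participant):

    /<participant_id>/epochs      (channels × time × trials, µV)
    /<participant_id>/labels      per-trial condition strings
    /<participant_id>/time_axis   seconds, t = 0 at instruction onset
    /<participant_id>/montage     channel positions (channels × 3, m)
    attrs: sfreq, channel_labels, group, provenance flags
"""

from __future__ import annotations

import numpy as np
import h5py

from .containers import EpochedRecording, Provenance
from .headmodel import HeadModel, Leadfield

__all__ = ["write_epochs", "read_epochs", "write_leadfield", "read_leadfield"]


def write_epochs(path: str, recordings: dict, groups: dict | None = None,
                 mode: str = "w") -> None:
    """Write ``{participant_id: EpochedRecording}`` to an HDF5 store."""
    with h5py.File(path, mode) as fh:
        for pid, rec in recordings.items():
            g = fh.create_group(pid)
            g.create_dataset("epochs", data=rec.data, compression="gzip",
                             compression_opts=1)
            g.create_dataset("labels",
                             data=np.array([str(c) for c in rec.condition],
                                           dtype=h5py.string_dtype()))
            g.create_dataset("time_axis", data=rec.time_axis)
            g.create_dataset("montage", data=rec.channel_positions)
            g.attrs["sfreq"] = rec.sfreq
            g.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
            if groups and pid in groups:
                g.attrs["group"] = groups[pid]
            for k, v in vars(rec.provenance).items():
                g.attrs[f"prov_{k}"] = bool(v)


def read_epochs(path: str) -> dict:
    """Read an epochs store back to ``{participant_id: EpochedRecording}``."""
    out = {}
    with h5py.File(path, "r") as fh:
        for pid in fh:
            g = fh[pid]
            prov = Provenance(**{
                k[len("prov_"):]: bool(v) for k, v in g.attrs.items()
                if k.startswith("prov_")})
            out[pid] = EpochedRecording(
                data=g["epochs"][()],
                time_axis=g["time_axis"][()],
                condition=np.array([s.decode() if isinstance(s, bytes) else str(s)
                                    for s in g["labels"][()]], dtype=object),
                channel_labels=[str(c) for c in g.attrs["channel_labels"]],
                channel_positions=g["montage"][()],
                sfreq=float(g.attrs["sfreq"]),
                provenance=prov,
            )
    return out


def write_leadfield(path: str, leadfield: Leadfield) -> None:
    hm = leadfield.head_model
    with h5py.File(path, "w") as fh:
        fh.create_dataset("gain", data=leadfield.gain)
        fh.create_dataset("channel_positions", data=hm.channel_positions)
        fh.create_dataset("voxel_positions", data=hm.voxel_positions)
        fh.attrs["channel_labels"] = [str(c) for c in hm.channel_labels]
        fh.attrs["radius"] = hm.radius


def read_leadfield(path: str) -> Leadfield:
    with h5py.File(path, "r") as fh:
        hm = HeadModel(
            channel_labels=[str(c) for c in fh.attrs["channel_labels"]],
            channel_positions=fh["channel_positions"][()],
            voxel_positions=fh["voxel_positions"][()],
            radius=float(fh.attrs["radius"]),
        )
        return Leadfield(fh["gain"][()], hm)
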