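"""BrainVision (.vhdr/.vmrk/.eeg) writing and reading.

The writer emits the minimal multiplexed binary dialect (INT_16 or
IEEE_FLOAT_32); the reader decodes it bit-exactly after a validation
pass that produces precise format errors (missing companion files,
unknown binary format, channel-count/size mismatch) with file context.
"""

from __future__ import annotations

import configparser
import os
import re

import numpy as np

from .containers import ContinuousRecording

__all__ = ["write_brainvision", "read_brainvision", "FormatError"]


class FormatError(ValueError):
    """Raised when a BrainVision file set is malformed."""


_HEADER_MAGIC = "Brain Vision Data Exchange Header File Version 1.0"
_MARKER_MAGIC = "Brain Vision Data Exchange Marker File, Version 1.0"


def write_brainvision(
    rec: ContinuousRecording,
    header_path: str,
    binary_format: str = "IEEE_FLOAT_32",
    resolution: float = 0.1,
) -> None:
    """Write a recording as .vhdr/.vmrk/.eeg next to ``header_path``.

    ``resolution`` (µV per least-significant bit) applies to INT_16 only.
    """
    if binary_format not in ("IEEE_FLOAT_32", "INT_16"):
        raise FormatError(f"unsupported binary format {binary_format!r}")
    base, ext = os.path.splitext(header_path)
    if ext != ".vhdr":
        raise FormatError(f"header path must end in .vhdr, got {header_path!r}")
    data_file, marker_file = base + ".eeg", base + ".vmrk"
    stem = os.path.basename(base)

    lines = [
        _HEADER_MAGIC,
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.sfreq:.6g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    res = resolution if binary_format == "INT_16" else 1
    for i, lab in enumerate(rec.channel_labels):
        lines.append(f"Ch{i + 1}={lab},,{res:g},µV")
    with open(header_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")

    mlines = [
        _MARKER_MAGIC,
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for i, (sample, desc) in enumerate(rec.events):
        # BrainVision marker positions are 1-based
        mlines.append(f"Mk{i + 2}=Stimulus,{desc},{sample + 1},1,0")
    with open(marker_file, "w", encoding="utf-8") as fh:
        fh.write("\n".join(mlines) + "\n")

    flat = rec.data.T  # (samples, channels) = multiplexed
    if binary_format == "IEEE_FLOAT_32":
        flat.astype("<f4").tofile(data_file)
    else:
        np.clip(np.round(flat / resolution), -32768, 32767).astype("<i2").tofile(data_file)


def _validate(header_path: str) -> None:
    if not os.path.exists(header_path):
        raise FormatError(f"{header_path}: header file not found")
    cp = configparser.ConfigParser(strict=False)
    with open(header_path, encoding="utf-8", errors="replace") as fh:
        first = fh.readline().strip()
        if "Brain Vision Data Exchange Header File" not in first:
            raise FormatError(f"{header_path}:1: not a BrainVision header ({first!r})")
        cp.read_string(fh.read())
    try:
        common = cp["Common Infos"]
        n_chan = int(common["NumberOfChannels"])
        data_file = common["DataFile"]
        marker_file = common.get("MarkerFile")
        fmt = cp["Binary Infos"]["BinaryFormat"].strip()
    except KeyError as exc:
        raise FormatError(f"{header_path}: missing required field {exc}") from exc

    dirname = os.path.dirname(os.path.abspath(header_path))
    data_path = os.path.join(dirname, data_file)
    if not os.path.exists(data_path):
        raise FormatError(f"{header_path}: companion data file {data_file!r} not found")
    if marker_file and not os.path.exists(os.path.join(dirname, marker_file)):
        raise FormatError(f"{header_path}: companion marker file {marker_file!r} not found")

    itemsize = {"IEEE_FLOAT_32": 4, "INT_16": 2}.get(fmt)
    if itemsize is None:
        raise FormatError(f"{header_path}: unknown binary format {fmt!r}")
    size = os.path.getsize(data_path)
    if size % (itemsize * n_chan):
        raise FormatError(
            f"{data_path}: size {size} bytes is not a whole number of "
            f"{n_chan}-channel {fmt} frames"
        )


def read_brainvision(header_path: str) -> ContinuousRecording:
    """Read a BrainVision file set into a :class:`ContinuousRecording` (µV).

    The multiplexed binary payload is decoded directly (bit-exact for
    IEEE_FLOAT_32, resolution-scaled for INT_16); header and marker
    files are parsed as the INI dialect the format specifies.
    """
    _validate(header_path)
    cp = configparser.ConfigParser(strict=False)
    with open(header_path, encoding="utf-8", errors="replace") as fh:
        fh.readline()
        cp.read_string(fh.read())
    common = cp["Common Infos"]
    n_chan = int(common["NumberOfChannels"])
    sfreq = 1e6 / float(common["SamplingInterval"])
    fmt = cp["Binary Infos"]["BinaryFormat"].strip()
    dirname = os.path.dirname(os.path.abspath(header_path))

    labels, resolutions = [], []
    for i in range(1, n_chan + 1):
        raw = cp["Channel Infos"][f"Ch{i}"]
        parts = raw.split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)

    dtype = "<f4" if fmt == "IEEE_FLOAT_32" else "<i2"
    flat = np.fromfile(os.path.join(dirname, common["DataFile"]), dtype=dtype)
    data = flat.reshape(-1, n_chan).T.astype(float)
    if fmt == "INT_16":
        data *= np.asarray(resolutions)[:, None]

    events = []
    marker_file = common.get("MarkerFile")
    if marker_file:
        with open(os.path.join(dirname, marker_file), encoding="utf-8",
                  errors="replace") as fh:
            for line in fh:
                m = re.match(r"Mk\d+=([^,]*),([^,]*),(\d+),", line.strip())
                if m and m.group(1) != "New Segment":
                    events.append((int(m.group(3)) - 1, m.group(2)))
    return ContinuousRecording(data=data, sfreq=sfreq, channel_labels=labels,
                               events=events)
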