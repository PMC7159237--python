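"""Recording I/O: internal HDF5 container, EDF/BDF reading, BDF export.

The internal container is an HDF5 file holding the float64 data in μV,
the sampling rate, channel labels, events and provenance history; it
round-trips bit-exactly, unlike the 16/24-bit integer quantization of
EDF/BDF.  EDF and BDF files (the Biosemi acquisition container) are
read through MNE.  A minimal 24-bit BDF writer is provided for
interchange; BDF stores quantized integers, so that path is lossy at
the quantization step and carries the signal only (events live in the
internal container).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .preprocess import Recording


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording to the internal HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, dtype="f8")
        f.attrs["fs"] = rec.fs
        f.attrs["units"] = "uV"
        f.create_dataset("labels", data=[s.encode() for s in rec.labels])
        f.create_dataset("event_samples",
                         data=np.array([s for s, _ in rec.events], dtype="i8"))
        f.create_dataset("event_codes",
                         data=[c.encode() for _, c in rec.events])
        f.attrs["montage"] = json.dumps(rec.montage) if rec.montage else ""
        f.attrs["rois"] = json.dumps(rec.rois) if rec.rois else ""
        f.attrs["history"] = json.dumps(rec.history)


def load_recording(path: str | Path) -> Recording:
    """Read a Recording from the internal HDF5 container."""
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        labels = [s.decode() for s in f["labels"][()]]
        events = list(zip((int(s) for s in f["event_samples"][()]),
                          (c.decode() for c in f["event_codes"][()])))
        montage = json.loads(f.attrs["montage"]) if f.attrs["montage"] else None
        rois = json.loads(f.attrs["rois"]) if f.attrs["rois"] else None
        history = json.loads(f.attrs["history"])
    return Recording(data=data, fs=fs, labels=labels, events=events,
                     montage=montage, rois=rois, history=history)


def _read_edf_bdf(path: Path) -> Recording:
    import mne
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" \
        else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE works in volts
    events = []
    for ann in raw.annotations:
        sample = int(round(ann["onset"] * raw.info["sfreq"]))
        if 0 <= sample < data.shape[1]:
            events.append((sample, str(ann["description"])))
    events.sort(key=lambda e: e[0])
    # drop events sharing a sample (Recording requires strict ordering)
    dedup, last = [], -1
    for s, c in events:
        if s > last:
            dedup.append((s, c))
            last = s
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     labels=list(raw.ch_names), events=dedup,
                     history=[f"read {path.name}"])


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read a recording; format inferred from the extension by default.

    ``.h5``/``.hdf5`` is the internal container; ``.edf``/``.bdf`` go
    through MNE and return data in μV with annotations as events.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt in ("h5", "hdf5", "internal"):
        return load_recording(path)
    if fmt in ("edf", "bdf"):
        return _read_edf_bdf(path)
    raise ValueError(f"unsupported recording format {fmt!r}")


def write_recording(rec: Recording, path: str | Path,
                    fmt: str | None = None) -> None:
    """Write a recording (internal HDF5, or 24-bit BDF for interchange)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt in ("h5", "hdf5", "internal"):
        save_recording(rec, path)
    elif fmt == "bdf":
        write_bdf(rec, path)
    else:
        raise ValueError(f"unsupported recording format {fmt!r}")


def write_spectrum(spec, path: str | Path, fmax: float | None = None) -> None:
    """Export an amplitude spectrum as a TSV table.

    Columns: bin index, frequency in Hz, one amplitude column per
    channel.  ``fmax`` limits the exported band (full spectrum when
    omitted).
    """
    n = spec.n_bins if fmax is None else min(
        spec.n_bins, int(np.floor(fmax / spec.df)) + 1)
    with open(path, "w") as fh:
        fh.write("bin\tfreq_hz\t" + "\t".join(spec.labels) + "\n")
        for b in range(n):
            vals = "\t".join(f"{v:.6g}" for v in spec.amps[:, b])
            fh.write(f"{b}\t{b * spec.df:.6f}\t{vals}\n")


def _pad_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_bdf(rec: Recording, path: str | Path) -> None:
    """Write a minimal 24-bit BDF file (signal only, 1-s data records).

    Physical range is set symmetrically from the data extremum, so the
    quantization step is ``2 * max|x| / 2**24``.  The last record is
    zero-padded when the duration is not a whole number of seconds.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("BDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    n_rec = int(np.ceil(n_samp / fs))
    phys_max = float(np.max(np.abs(rec.data)))
    phys_max = max(np.ceil(phys_max), 1.0)
    dig_max, dig_min = 8388607, -8388608
    gain = (2 * phys_max) / (dig_max - dig_min)

    hdr = bytearray()
    hdr += b"\xffBIOSEMI"
    hdr += _pad_field("fpvs export", 80)
    hdr += _pad_field("simulated session", 80)
    hdr += _pad_field("01.01.00", 8) + _pad_field("00.00.00", 8)
    hdr += _pad_field((n_ch + 1) * 256, 8)
    hdr += _pad_field("24BIT", 44)
    hdr += _pad_field(n_rec, 8)
    hdr += _pad_field(1, 8)  # record duration, s
    hdr += _pad_field(n_ch, 4)
    for lab in rec.labels:
        hdr += _pad_field(lab[:16], 16)
    hdr += _pad_field("", 80) * n_ch          # transducer
    hdr += _pad_field("uV", 8) * n_ch         # physical dimension
    hdr += _pad_field(-phys_max, 8) * n_ch
    hdr += _pad_field(phys_max, 8) * n_ch
    hdr += _pad_field(dig_min, 8) * n_ch
    hdr += _pad_field(dig_max, 8) * n_ch
    hdr += _pad_field("", 80) * n_ch          # prefiltering
    hdr += _pad_field(fs, 8) * n_ch           # samples per record
    hdr += _pad_field("", 32) * n_ch

    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = rec.data
    digital = np.clip(np.round(padded / gain), dig_min, dig_max).astype("<i4")

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            raw = block.astype("<i4").tobytes()  # 4-byte LE ints
            arr = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)
            fh.write(arr[:, :3].tobytes())  # keep low 3 bytes (LE 24-bit)
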