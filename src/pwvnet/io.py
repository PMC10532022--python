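"""Record and container I/O.

Three families:

* plain-text CSV records (one sample per line, ``# fs=<Hz>`` header
  comment, optional second column with per-sample class labels) -- the
  fixture format;
* a minimal reader/writer for PhysioNet WFDB records (``.hea`` header +
  ``.dat`` signal in formats 16 and 212) and MIT-format annotation files,
  with rhythm annotations mapped to the four classes through a
  user-supplied label map;
* HDF5 containers for window sets and image stacks (datasets ``windows``
  [n x 150], ``labels`` [n], ``origins`` [n]).

The WFDB support intentionally covers only what single-lead rhythm analysis
needs (first signal, formats 16/212, rhythm + beat annotations).
"""

from __future__ import annotations

import struct
from pathlib import Path

import h5py
import numpy as np

from .preprocess import EcgRecord, RhythmClass
from .segment import WindowSet

# ---------------------------------------------------------------- CSV records


def write_csv_record(path: str | Path, record: EcgRecord) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={record.fs}\n")
        if record.record_id:
            fh.write(f"# record_id={record.record_id}\n")
        if record.labels is None:
            for v in record.samples:
                fh.write(f"{v:.6f}\n")
        else:
            for v, lab in zip(record.samples, record.labels):
                fh.write(f"{v:.6f},{int(lab)}\n")


def read_csv_record(path: str | Path) -> EcgRecord:
    path = Path(path)
    fs = None
    record_id = path.stem
    samples: list[float] = []
    labels: list[int] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                if key.strip() == "fs":
                    fs = float(value)
                elif key.strip() == "record_id":
                    record_id = value.strip()
                continue
            parts = line.split(",")
            samples.append(float(parts[0]))
            if len(parts) > 1:
                labels.append(int(parts[1]))
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' header comment")
    lab = np.asarray(labels) if len(labels) == len(samples) and labels else None
    return EcgRecord(np.asarray(samples), fs, labels=lab, record_id=record_id)


# ------------------------------------------------------------- WFDB records

def read_wfdb(path: str | Path, channel: int = 0) -> EcgRecord:
    """Read one channel of a WFDB record given the ``.hea`` path or stem."""
    hea = Path(path).with_suffix(".hea")
    lines = [ln.split("#")[0].strip() for ln in hea.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    sig_lines = lines[1:1 + n_sig]
    if channel >= n_sig:
        raise ValueError(f"record {name} has {n_sig} signals; channel {channel}")

    specs = []
    for ln in sig_lines:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, None
        if len(tok) > 2:
            g = tok[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        specs.append((fname, int(fmt), gain, baseline))

    fname, fmt, gain, baseline = specs[channel]
    if any(s[0] != specs[0][0] for s in specs):
        raise NotImplementedError("multi-file WFDB records are not supported")
    raw = (hea.parent / fname).read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2").reshape(-1, n_sig)
        adc = data[:, channel]
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3)
        first = (b[:, 0].astype(np.int32) | ((b[:, 1].astype(np.int32) & 0x0F) << 8))
        second = (b[:, 2].astype(np.int32) | ((b[:, 1].astype(np.int32) & 0xF0) << 4))
        first[first > 2047] -= 4096
        second[second > 2047] -= 4096
        inter = np.empty(2 * len(b), dtype=np.int32)
        inter[0::2], inter[1::2] = first, second
        adc = inter.reshape(-1, n_sig)[:, channel] if n_sig > 1 else inter
    else:
        raise NotImplementedError(f"WFDB format {fmt} not supported")
    if n_samp:
        adc = adc[:n_samp]
    samples = (adc.astype(np.float64) - baseline) / gain
    return EcgRecord(samples, fs, record_id=name)


def write_wfdb(path: str | Path, record: EcgRecord, gain: float = 200.0) -> None:
    """Export a record as a single-signal format-16 WFDB pair."""
    stem = Path(path).with_suffix("")
    adc = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    (stem.with_suffix(".dat")).write_bytes(adc.tobytes())
    fs = int(record.fs) if float(record.fs).is_integer() else record.fs
    header = (f"{stem.name} 1 {fs} {len(record)}\n"
              f"{stem.name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 ECG\n")
    (stem.with_suffix(".hea")).write_text(header)


# --------------------------------------------------- MIT-format annotations

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63
RHYTHM_CODE = 28  # '+' rhythm-change annotation


def read_annotations(path: str | Path) -> list[tuple[int, int, str]]:
    """Parse a MIT-format annotation file into (sample, code, aux) tuples."""
    raw = Path(path).read_bytes()
    out: list[tuple[int, int, str]] = []
    time = 0
    i = 0
    while i + 1 < len(raw):
        word = struct.unpack_from("<H", raw, i)[0]
        i += 2
        code, data = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            # SKIP stores a 4-byte interval, most significant 16 bits first
            jump = struct.unpack_from("<H", raw, i + 2)[0] | (
                struct.unpack_from("<h", raw, i)[0] << 16)
            time += jump
            i += 4
        elif code == _AUX:
            aux = raw[i:i + data].split(b"\x00")[0].decode("ascii", "replace")
            i += data + (data & 1)
            if out:
                sample, c, _ = out[-1]
                out[-1] = (sample, c, aux)
        elif code in (_NUM, _SUB, _CHN):
            pass
        else:
            time += data
            out.append((time, code, ""))
    return out


def write_annotations(path: str | Path,
                      annotations: list[tuple[int, int, str]]) -> None:
    """Write (sample, code, aux) tuples in MIT format (round-trip helper)."""
    buf = bytearray()
    prev = 0
    for sample, code, aux in annotations:
        delta = sample - prev
        while delta > 1023:
            chunk = min(delta, 0x7FFFFFFF)
            buf += struct.pack("<H", (_SKIP << 10))
            buf += struct.pack("<h", chunk >> 16) + struct.pack("<H", chunk & 0xFFFF)
            prev += chunk
            delta = sample - prev
        buf += struct.pack("<H", (code << 10) | delta)
        prev = sample
        if aux:
            data = aux.encode("ascii")
            buf += struct.pack("<H", (_AUX << 10) | len(data)) + data
            if len(data) & 1:
                buf += b"\x00"
    buf += struct.pack("<H", 0)
    Path(path).write_bytes(buf)


def labels_from_annotations(n_samples: int,
                            annotations: list[tuple[int, int, str]],
                            label_map: dict[str, RhythmClass]) -> np.ndarray:
    """Per-sample labels by forward-filling mapped rhythm annotations.

    ``label_map`` maps aux strings (e.g. ``"(N"``, ``"(VT"``, ``"(VF"``) to
    classes; samples before the first mapped annotation inherit its label.
    Unmapped aux strings are ignored.
    """
    changes = [(s, label_map[aux]) for s, code, aux in annotations
               if aux in label_map]
    if not changes:
        raise ValueError("no annotation matched the label map")
    labels = np.empty(n_samples, dtype=np.int64)
    labels[: changes[0][0]] = int(changes[0][1])
    for (s, cls), nxt in zip(changes, [c[0] for c in changes[1:]] + [n_samples]):
        labels[s:nxt] = int(cls)
    return labels


# ------------------------------------------------------------ HDF5 containers

def save_windows(path: str | Path, ws: WindowSet) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("windows", data=ws.windows)
        fh.create_dataset("origins", data=ws.origins)
        if ws.labels is not None:
            fh.create_dataset("labels", data=ws.labels)
        fh.attrs["fs"] = ws.fs


def load_windows(path: str | Path) -> WindowSet:
    with h5py.File(path, "r") as fh:
        labels = fh["labels"][...] if "labels" in fh else None
        return WindowSet(fh["windows"][...], fh["origins"][...], labels,
                         fs=float(fh.attrs["fs"]))


def save_images(path: str | Path, images: np.ndarray,
                labels: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("images", data=np.asarray(images, dtype=np.float32))
        if labels is not None:
            fh.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))


def load_images(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    with h5py.File(path, "r") as fh:
        labels = fh["labels"][...] if "labels" in fh else None
        return fh["images"][...], labels
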