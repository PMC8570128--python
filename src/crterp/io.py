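"""Recording container and format readers/writers.

Internal unit is microvolts; sample 0 of an epoch is stimulus onset and
all sample indices are 0-based.

Three dialects are supported:

* ``csv`` — a matrix file (one row per channel, header carries the
  sampling rate) plus a ``*.events.tsv`` sidecar with columns
  sample_index / condition / correct.  Lossless round-trip.
* ``edf`` — 16-bit European Data Format.  Events travel in a ``Status``
  signal holding an integer trial code at each stimulus-onset sample
  (see ``EVENT_CODES``; +10 marks a correct response).  Reading goes
  through :mod:`mne`; writing uses a minimal single-sample-per-record
  EDF writer since no packaged EDF writer exists.
* ``brainvision`` — read-only, via :mod:`mne`; events are decoded from
  ``Stimulus/S<code>`` annotations with the same code table.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "FormatError",
    "EVENT_CODES",
    "read_recording",
    "write_recording",
]


class FormatError(ValueError):
    """Raised when a file cannot be parsed under the named dialect."""


#: trial-type <-> integer event code; +10 encodes a correct response
EVENT_CODES = {
    "New": 1, "Rep1": 2, "Rep2": 3, "Rep3": 4, "Rep4": 5, "NBack": 6, "Catch": 7,
}
_CODE_TO_TYPE = {v: k for k, v in EVENT_CODES.items()}


@dataclass
class Recording:
    """A continuous multichannel recording in microvolts.

    Attributes
    ----------
    data : (n_channels, n_samples) ndarray, uV
    srate : float, Hz
    channel_labels : list of str
    events : list of (sample_index, condition_code, correct)
        condition_code is a trial-type string from ``EVENT_CODES``.
    """

    data: np.ndarray
    srate: float
    channel_labels: list[str]
    events: list[tuple[int, str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.srate <= 0:
            raise FormatError(f"srate must be positive, got {self.srate}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise FormatError("recording must have at least one channel and sample")
        if len(self.channel_labels) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("channel labels must be unique")
        n = self.data.shape[1]
        for s, code, _ in self.events:
            if not 0 <= s < n:
                raise FormatError(f"event sample {s} outside recording of {n} samples")
            if code not in EVENT_CODES:
                raise FormatError(f"unknown condition code {code!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# dispatch

def read_recording(path, format: str | None = None) -> Recording:
    """Read a recording; format inferred from the suffix when omitted."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "brainvision":
        return _read_brainvision(path)
    raise FormatError(f"unknown recording format {fmt!r} for {path}")


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    """Write a recording (csv or edf)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise FormatError(f"no writer for format {fmt!r}")


def _infer_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf == ".csv":
        return "csv"
    if suf == ".edf":
        return "edf"
    if suf == ".vhdr":
        return "brainvision"
    raise FormatError(f"cannot infer format from suffix {suf!r} of {path}")


# ---------------------------------------------------------------------------
# csv + events sidecar

def _events_path(path: Path) -> Path:
    return path.with_name(path.stem + ".events.tsv")


def _read_csv(path: Path) -> Recording:
    srate = None
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "srate:" in line:
                    srate = float(line.split("srate:")[1])
                continue
            parts = line.split(",")
            labels.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    if srate is None:
        raise FormatError(f"{path}: missing '# srate:' header line")
    if not rows:
        raise FormatError(f"{path}: no channel rows")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged channel rows, lengths {sorted(lengths)}")
    events = _read_events_tsv(_events_path(path)) if _events_path(path).exists() else []
    return Recording(np.vstack(rows), srate, labels, events)


def _write_csv(rec: Recording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# crterp recording, one row per channel, values in uV\n")
        fh.write(f"# srate: {rec.srate!r}\n")
        for lab, row in zip(rec.channel_labels, rec.data):
            fh.write(lab + "," + ",".join(repr(float(v)) for v in row) + "\n")
    _write_events_tsv(rec.events, _events_path(path))


def _read_events_tsv(path: Path) -> list[tuple[int, str, bool]]:
    events = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["sample_index", "condition", "correct"]:
            raise FormatError(f"{path}: unexpected events header {header}")
        for line in fh:
            if not line.strip():
                continue
            s, cond, corr = line.strip().split("\t")
            events.append((int(s), cond, corr == "1"))
    return events


def _write_events_tsv(events, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_index\tcondition\tcorrect\n")
        for s, cond, corr in events:
            fh.write(f"{s}\t{cond}\t{1 if corr else 0}\n")


# ---------------------------------------------------------------------------
# EDF

def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = f"{float(value):.{max(width - 6, 1)}g}"[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal 16-bit EDF writer: one sample per data record, a Status
    signal carrying event codes."""
    data = rec.data
    n_sig = rec.n_channels + 1  # + Status
    n_samp = rec.n_samples
    status = np.zeros(n_samp, dtype=np.int16)
    for s, cond, corr in rec.events:
        status[s] = EVENT_CODES[cond] + (10 if corr else 0)

    # physical scaling per channel (symmetric, 16-bit)
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-9) * 1.0001
    dig_max, dig_min = 32767, -32767
    scaled = np.round(data / phys_max[:, None] * dig_max).astype(np.int16)

    now = _dt.datetime(2000, 1, 1)
    header = b""
    header += _ascii("0", 8)
    header += _ascii("X", 80)
    header += _ascii("crterp", 80)
    header += now.strftime("%d.%m.%y").encode()
    header += now.strftime("%H.%M.%S").encode()
    header += _ascii(256 * (1 + n_sig), 8)
    # exact sampling rate survives in the reserved field; the 8-char
    # record-duration field below cannot represent 1/srate exactly
    header += _ascii(f"srate={rec.srate!r}", 44)
    header += _ascii(n_samp, 8)                    # n data records
    header += _ascii(f"{1.0 / rec.srate:.7f}"[:8], 8)  # record duration, s
    header += _ascii(n_sig, 4)

    labels = list(rec.channel_labels) + ["Status"]
    fieldspec = [
        (16, labels),
        (80, [""] * n_sig),
        (8, ["uV"] * rec.n_channels + [""]),
        (8, [f"{-m:.5g}" for m in phys_max] + [str(dig_min)]),
        (8, [f"{m:.5g}" for m in phys_max] + [str(dig_max)]),
        (8, [str(dig_min)] * n_sig),
        (8, [str(dig_max)] * n_sig),
        (80, [""] * n_sig),
        (8, ["1"] * n_sig),
        (32, [""] * n_sig),
    ]
    for width, values in fieldspec:
        for v in values:
            header += _ascii(v, width)

    frames = np.vstack([scaled, status[None, :]])  # n_sig x n_samp
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(frames.T.astype("<i2").tobytes())  # record-major = sample-major


def _read_edf(path: Path) -> Recording:
    import mne

    if not Path(path).exists():
        raise FormatError(f"{path}: no such file")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, stim_channel=None, verbose="error")
    except Exception as e:  # mne raises various types for malformed files
        raise FormatError(f"{path}: not a readable EDF file ({e})") from e
    labels = list(raw.ch_names)
    if "Status" not in labels:
        raise FormatError(f"{path}: EDF file has no 'Status' event channel")
    data = raw.get_data()  # volts for channels mne recognized as uV
    si = labels.index("Status")
    ch_idx = [i for i in range(len(labels)) if i != si]
    eeg = data[ch_idx] * 1e6
    status = np.round(data[si]).astype(int)
    events = []
    for s in np.flatnonzero(status):
        code = int(status[s])
        corr = code >= 10
        ttype = _CODE_TO_TYPE.get(code - 10 if corr else code)
        if ttype is None:
            raise FormatError(f"{path}: unknown event code {code} at sample {s}")
        events.append((int(s), ttype, corr))
    srate = float(raw.info["sfreq"])
    with open(path, "rb") as fh:
        reserved = fh.read(236)[192:236].decode("ascii", "ignore").strip()
    if reserved.startswith("srate="):
        try:
            srate = float(reserved[6:])
        except ValueError:
            pass
    return Recording(eeg, srate, [labels[i] for i in ch_idx], events)


# ---------------------------------------------------------------------------
# BrainVision (read-only)

def _read_brainvision(path: Path) -> Recording:
    import mne

    if not Path(path).exists():
        raise FormatError(f"{path}: no such file")
    try:
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    except Exception as e:
        raise FormatError(f"{path}: not a readable BrainVision file ({e})") from e
    data = raw.get_data() * 1e6
    events = []
    for ann in raw.annotations:
        desc = ann["description"]
        if not desc.startswith("Stimulus"):
            continue
        try:
            code = int(desc.split("S")[-1])
        except ValueError:
            continue
        corr = code >= 10
        ttype = _CODE_TO_TYPE.get(code - 10 if corr else code)
        if ttype is None:
            continue
        sample = int(round(ann["onset"] * raw.info["sfreq"]))
        events.append((sample, ttype, corr))
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names), events)
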