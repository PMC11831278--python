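"""Minimal European Data Format (EDF) I/O.

Writing uses a small in-package EDF encoder (16-bit samples, 1-second
data records, symmetric physical range per channel); reading validates
the fixed-width header with byte-accurate error reporting and then
delegates the actual decoding to MNE's EDF reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from microband.containers import Recording


class EdfParseError(ValueError):
    """Malformed EDF input; carries the byte offset of the offending field."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> Path:
    """Write one recording as a plain EDF file.

    Samples are quantized to 16 bits over a symmetric per-channel
    physical range, in microvolts, with 1-second data records.  The
    recording is zero-padded to a whole number of records.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    ns = int(round(fs))
    c = recording.n_channels
    n = recording.n_samples
    n_records = int(np.ceil(n / ns))
    data = np.zeros((c, n_records * ns))
    data[:, :n] = recording.data

    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dmin, dmax = -32768, 32767
    scale = (2 * pmax) / (dmax - dmin)
    digital = np.clip(np.round(data / scale[:, None]), dmin, dmax
                      ).astype("<i2")

    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii(f"X X X {recording.subject or 'X'}", 80)
    header += _ascii(f"Startdate X X X {recording.condition or 'X'}", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (1 + c), 8)
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii(1, 8)           # record duration, seconds
    header += _ascii(c, 4)
    for name in recording.ch_names:
        header += _ascii(name, 16)
    header += b"".join(_ascii("AgAgCl electrode", 80) for _ in range(c))
    header += b"".join(_ascii("uV", 8) for _ in range(c))
    for p in pmax:
        header += _ascii(f"{-p:.6g}"[:8], 8)
    for p in pmax:
        header += _ascii(f"{p:.6g}"[:8], 8)
    header += b"".join(_ascii(dmin, 8) for _ in range(c))
    header += b"".join(_ascii(dmax, 8) for _ in range(c))
    header += b"".join(_ascii("", 80) for _ in range(c))
    header += b"".join(_ascii(ns, 8) for _ in range(c))
    header += b"".join(_ascii("", 32) for _ in range(c))
    assert len(header) == 256 * (1 + c)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            fh.write(digital[:, r * ns:(r + 1) * ns].tobytes())
    return path


def _validate_header(path: Path) -> None:
    raw = path.read_bytes()
    if len(raw) < 256:
        raise EdfParseError("file shorter than the 256-byte fixed header",
                            len(raw))
    def field(start: int, width: int, name: str):
        text = raw[start:start + width].decode("ascii", errors="replace")
        return text.strip(), start

    version, off = field(0, 8, "version")
    if version != "0":
        raise EdfParseError(f"unsupported EDF version {version!r}", off)
    hbytes_s, off = field(184, 8, "header bytes")
    nrec_s, off_nrec = field(236, 8, "record count")
    nsig_s, off_nsig = field(252, 4, "signal count")
    try:
        hbytes = int(hbytes_s)
    except ValueError:
        raise EdfParseError(f"non-numeric header-size field {hbytes_s!r}", 184)
    try:
        nsig = int(nsig_s)
    except ValueError:
        raise EdfParseError(f"non-numeric signal-count field {nsig_s!r}",
                            off_nsig)
    if hbytes != 256 * (1 + nsig):
        raise EdfParseError(
            f"header size {hbytes} inconsistent with {nsig} signals", 184)
    if len(raw) < hbytes:
        raise EdfParseError("file truncated inside the signal headers",
                            len(raw))
    try:
        nrec = int(nrec_s)
    except ValueError:
        raise EdfParseError(f"non-numeric record-count field {nrec_s!r}",
                            off_nrec)
    ns_start = 256 + nsig * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    try:
        ns_per_sig = [int(raw[ns_start + 8 * i:ns_start + 8 * (i + 1)]
                          .decode("ascii").strip()) for i in range(nsig)]
    except ValueError:
        raise EdfParseError("non-numeric samples-per-record field", ns_start)
    expected = hbytes + nrec * sum(ns_per_sig) * 2
    if len(raw) != expected:
        raise EdfParseError(
            f"file size {len(raw)} != header-implied size {expected}",
            min(len(raw), expected))


def read_edf(path) -> Recording:
    """Read an EDF file into a Recording (data in microvolts).

    The fixed-width header is validated first so malformed files fail
    with a byte-offset diagnostic; decoding is then delegated to
    ``mne.io.read_raw_edf``.
    """
    path = Path(path)
    _validate_header(path)
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     ch_names=tuple(raw.ch_names))
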