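"""Reading and writing Flow Cytometry Standard (FCS) files.

CyTOF instruments and their downstream tools exchange data as FCS files:
a text HEADER naming segment offsets, a delimited TEXT segment of
keyword/value pairs, and a binary DATA segment holding the events x
channels matrix. This module reads FCS 2.0/3.0/3.1 list-mode files and
writes FCS 3.1 (float32, little-endian), exposing each file as an
:class:`EventTable`.

Only the first dataset of a multi-dataset file is read; CyTOF exports are
single-dataset.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventTable", "read_fcs", "write_fcs", "FcsFormatError"]

#: TEXT keywords added by the adjustment pipeline are namespaced under this
#: prefix so that standard FCS readers ignore them.
CUSTOM_KEYWORD_PREFIX = "BATCHADJ"

_DELIM = "/"
_HEADER_LEN = 58  # 6-char version + 4 spaces + 6 x 8-char offsets


class FcsFormatError(ValueError):
    """Raised when a file is not a readable list-mode FCS file."""


@dataclass
class EventTable:
    """One FCS sample: an events x channels matrix of nonnegative ion counts.

    Parameters
    ----------
    sample_id : str
        Identifier of the sample (defaults to the file basename on read).
    batch_id : str
        Identifier of the batch (barcode set) the sample belongs to.
    role : str
        ``"anchor"`` for the technical-replicate calibration sample,
        ``"study"`` for everything else.
    channels : list of (str, str)
        Ordered ``(short_name, antibody_label)`` pairs ($PnN, $PnS).
    data : ndarray
        ``(n_events, n_channels)`` float array of nonnegative intensities.
    keywords : dict
        FCS TEXT-segment keyword/value pairs carried through verbatim.
    condition : str or None
        Optional condition tag (e.g. ``"stim"``/``"unstim"`` for anchor
        replicate sets); carried, never interpreted by the adjustment.
    """

    sample_id: str
    batch_id: str
    role: str
    channels: list[tuple[str, str]]
    data: np.ndarray
    keywords: dict[str, str] = field(default_factory=dict)
    condition: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D events x channels matrix")
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_events, n_channels = self.data.shape
        if n_events < 1:
            raise ValueError(f"sample {self.sample_id!r}: at least one event required")
        if n_channels < 1:
            raise ValueError(f"sample {self.sample_id!r}: at least one channel required")
        if len(self.channels) != n_channels:
            raise ValueError(
                f"sample {self.sample_id!r}: {len(self.channels)} channel names "
                f"for {n_channels} data columns"
            )
        names = [c[0] for c in self.channels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"sample {self.sample_id!r}: duplicate channel short names {dupes}"
            )
        if self.role not in ("anchor", "study"):
            raise ValueError(f"role must be 'anchor' or 'study', got {self.role!r}")
        if np.any(self.data < 0) or not np.all(np.isfinite(self.data)):
            raise ValueError(
                f"sample {self.sample_id!r}: intensities must be finite and >= 0"
            )

    # -- convenience --------------------------------------------------------
    @property
    def channel_names(self) -> list[str]:
        return [c[0] for c in self.channels]

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    def channel_values(self, short_name: str) -> np.ndarray:
        """Return the 1-D intensity vector for one channel."""
        try:
            idx = self.channel_names.index(short_name)
        except ValueError:
            raise KeyError(
                f"channel {short_name!r} not present in sample {self.sample_id!r}"
            ) from None
        return self.data[:, idx]

    def with_data(self, data: np.ndarray, **keyword_updates: str) -> "EventTable":
        """Copy of this table with replaced data and supplemented keywords."""
        kw = dict(self.keywords)
        kw.update(keyword_updates)
        return EventTable(
            sample_id=self.sample_id,
            batch_id=self.batch_id,
            role=self.role,
            channels=list(self.channels),
            data=data,
            keywords=kw,
            condition=self.condition,
        )


# ---------------------------------------------------------------------------
# TEXT segment parsing / serialization
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    # strip leading delimiter; a trailing delimiter terminates the last value
    body = body[1:]
    if body.endswith(delim):
        body = body[:-1]
    # doubled delimiters escape a literal delimiter inside a value
    sentinel = "\x00"
    body = body.replace(delim + delim, sentinel)
    parts = [p.replace(sentinel, delim) for p in body.split(delim)]
    if len(parts) % 2 != 0:
        # tolerate a dangling empty value
        parts.append("")
    keywords: dict[str, str] = {}
    for key, value in zip(parts[0::2], parts[1::2]):
        keywords[key.strip()] = value
    return keywords


def _serialize_text_segment(keywords: dict[str, str]) -> bytes:
    parts = [""]
    for key, value in keywords.items():
        parts.append(str(key).replace(_DELIM, _DELIM * 2))
        parts.append(str(value).replace(_DELIM, _DELIM * 2))
    parts.append("")
    return _DELIM.join(parts).encode("latin-1")


def _read_segment_offsets(header: bytes, start: int) -> tuple[int, int]:
    begin = int(header[start : start + 8].decode("ascii").strip() or 0)
    end = int(header[start + 8 : start + 16].decode("ascii").strip() or 0)
    return begin, end


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_fcs(path: str | os.PathLike) -> EventTable:
    """Read an FCS 2.0/3.0/3.1 file into an :class:`EventTable`.

    Intensities are returned exactly as stored (no transform). ``sample_id``
    defaults to the file basename without extension; ``batch_id`` and
    ``role`` default to ``""`` and ``"study"`` and are normally assigned by
    the batch manifest.

    Raises
    ------
    FcsFormatError
        If the file is unreadable, has zero events, or violates an
        :class:`EventTable` invariant (e.g. duplicate channel names).
    """
    path = os.fspath(path)
    try:
        with open(path, "rb") as fh:
            blob = fh.read()
    except OSError as exc:
        raise IOError(f"cannot read FCS file {path!r}: {exc}") from exc

    if len(blob) < _HEADER_LEN:
        raise FcsFormatError(f"{path!r}: too short to contain an FCS header")
    version = blob[:6].decode("latin-1", "replace")
    if not version.startswith("FCS"):
        raise FcsFormatError(f"{path!r}: not an FCS file (version field {version!r})")

    text_begin, text_end = _read_segment_offsets(blob, 10)
    data_begin, data_end = _read_segment_offsets(blob, 26)
    if text_end <= text_begin:
        raise FcsFormatError(f"{path!r}: invalid TEXT segment offsets")
    keywords = _parse_text_segment(blob[text_begin : text_end + 1])

    # large files store data offsets only in TEXT
    if data_begin == 0 or data_end == 0:
        data_begin = int(keywords.get("$BEGINDATA", 0))
        data_end = int(keywords.get("$ENDDATA", 0))
    if data_end <= data_begin:
        raise FcsFormatError(f"{path!r}: invalid DATA segment offsets")

    mode = keywords.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise FcsFormatError(f"{path!r}: only list mode ($MODE/L) is supported")

    try:
        n_par = int(keywords["$PAR"])
        n_tot = int(keywords["$TOT"])
    except (KeyError, ValueError) as exc:
        raise FcsFormatError(f"{path!r}: missing or invalid $PAR/$TOT") from exc
    if n_tot < 1:
        raise FcsFormatError(f"{path!r}: file contains zero events")

    datatype = keywords.get("$DATATYPE", "").strip().upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"

    bits = [int(keywords.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
        if any(b != 32 for b in bits):
            raise FcsFormatError(f"{path!r}: $DATATYPE/F requires 32-bit parameters")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
        if any(b != 64 for b in bits):
            raise FcsFormatError(f"{path!r}: $DATATYPE/D requires 64-bit parameters")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32, 64):
            raise FcsFormatError(
                f"{path!r}: integer data requires uniform $PnB of 8/16/32/64"
            )
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise FcsFormatError(f"{path!r}: unsupported $DATATYPE {datatype!r}")

    expected = n_tot * n_par * dtype.itemsize
    raw = blob[data_begin : data_begin + expected]
    if len(raw) < expected:
        raise FcsFormatError(
            f"{path!r}: DATA segment truncated ({len(raw)} of {expected} bytes)"
        )
    data = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)

    channels = []
    for i in range(1, n_par + 1):
        short = keywords.get(f"$P{i}N", f"P{i}")
        label = keywords.get(f"$P{i}S", "")
        channels.append((short, label))

    basename = os.path.splitext(os.path.basename(path))[0]
    try:
        return EventTable(
            sample_id=keywords.get(f"{CUSTOM_KEYWORD_PREFIX}_SAMPLE", basename),
            batch_id=keywords.get(f"{CUSTOM_KEYWORD_PREFIX}_BATCH", ""),
            role=keywords.get(f"{CUSTOM_KEYWORD_PREFIX}_ROLE", "study"),
            channels=channels,
            data=data,
            keywords=keywords,
            condition=keywords.get(f"{CUSTOM_KEYWORD_PREFIX}_CONDITION") or None,
        )
    except ValueError as exc:
        raise FcsFormatError(f"{path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_fcs(table: EventTable, path: str | os.PathLike) -> str:
    """Write an :class:`EventTable` as an FCS 3.1 file (float32, little-endian).

    Original TEXT keywords are preserved and supplemented; keywords that
    describe the data block ($TOT, $PAR, $PnN, ...) are regenerated so they
    stay consistent with what is written. Output is byte-deterministic for
    identical inputs (no timestamps are added).

    Returns the path written.
    """
    table.validate()
    path = os.fspath(path)
    n_events, n_par = table.data.shape
    payload = np.ascontiguousarray(table.data, dtype="<f4").tobytes()

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # fixed-width placeholders keep the TEXT length stable (filled below)
        "$BEGINDATA": "0" * 12,
        "$ENDDATA": "0" * 12,
        "$NEXTDATA": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    col_max = table.data.max(axis=0)
    for i, (short, label) in enumerate(table.channels, start=1):
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}N"] = short
        keywords[f"$P{i}R"] = str(int(np.ceil(col_max[i - 1])) + 1)
        if label:
            keywords[f"$P{i}S"] = label
    # carry through non-reserved keywords from the source file
    for key, value in table.keywords.items():
        if not key.startswith("$"):
            keywords.setdefault(key, value)
    keywords[f"{CUSTOM_KEYWORD_PREFIX}_SAMPLE"] = table.sample_id
    keywords[f"{CUSTOM_KEYWORD_PREFIX}_BATCH"] = table.batch_id
    keywords[f"{CUSTOM_KEYWORD_PREFIX}_ROLE"] = table.role
    if table.condition:
        keywords[f"{CUSTOM_KEYWORD_PREFIX}_CONDITION"] = table.condition

    text = _serialize_text_segment(keywords)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(payload) - 1
    keywords["$BEGINDATA"] = f"{data_begin:012d}"
    keywords["$ENDDATA"] = f"{data_end:012d}"
    text = _serialize_text_segment(keywords)
    assert text_end == text_begin + len(text) - 1  # fixed-width fill kept length

    def _off(value: int) -> bytes:
        # header offsets are 8 ASCII chars; 0 defers to TEXT for huge files
        return (b"%8d" % value) if value <= 99_999_999 else b"%8d" % 0

    header = b"FCS3.1    " + _off(text_begin) + _off(text_end)
    header += _off(data_begin) + _off(data_end) + _off(0) + _off(0)
    assert len(header) == _HEADER_LEN

    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(text)
            fh.write(payload)
    except OSError as exc:
        raise IOError(f"cannot write FCS file {path!r}: {exc}") from exc
    return path
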