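"""Minimal read-only FCS 3.0/3.1 list-mode parser.

Supports the subset needed to ingest per-event scatter/fluorescence tables:
fixed-offset HEADER, TEXT segment keywords, and a DATA segment of datatype
``F`` (float32), ``D`` (float64) or ``I`` (unsigned integer, uniform bit
width of 8/16/32/64), little- or big-endian.  Not supported: doubled-delimiter
escapes inside TEXT values, per-parameter bit widths for integer data,
histogram mode, and the ANALYSIS segment.
"""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd

_SUPPORTED_VERSIONS = (b"FCS3.0", b"FCS3.1")


def _read_header_offsets(buf: bytes) -> tuple[int, int, int, int]:
    if len(buf) < 58:
        raise IOError("truncated FCS file: header shorter than 58 bytes")
    if buf[0:6] not in _SUPPORTED_VERSIONS:
        raise IOError(f"unsupported FCS version {buf[0:6]!r}")

    def off(a: int, b: int) -> int:
        field = buf[a:b].decode("ascii", errors="replace").strip()
        return int(field) if field else 0

    return off(10, 18), off(18, 26), off(26, 34), off(34, 42)


def _parse_text(segment: bytes) -> dict[str, str]:
    if not segment:
        raise IOError("empty TEXT segment")
    delim = segment[0:1].decode("latin-1")
    parts = segment.decode("latin-1").split(delim)
    # parts[0] is empty (segment starts with the delimiter)
    items = [p for p in parts[1:]]
    if items and items[-1] == "":
        items = items[:-1]
    if len(items) % 2:
        items = items[:-1]
    return {
        items[i].strip().upper(): items[i + 1]
        for i in range(0, len(items), 2)
    }


def read_fcs(path) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 file and return events as a DataFrame.

    Columns are named from the ``$PnN`` (short name) keywords.
    """
    with open(path, "rb") as fh:
        buf = fh.read()

    text_beg, text_end, data_beg, data_end = _read_header_offsets(buf)
    if text_end <= text_beg or text_end >= len(buf):
        raise IOError("truncated FCS file: invalid TEXT segment offsets")
    text = _parse_text(buf[text_beg : text_end + 1])

    if data_beg == 0:
        data_beg = int(text.get("$BEGINDATA", "0"))
    if data_end == 0:
        data_end = int(text.get("$ENDDATA", "0"))

    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text["$DATATYPE"].strip().upper()
        byteord = text["$BYTEORD"].strip()
    except KeyError as exc:
        raise IOError(f"FCS TEXT segment lacks required keyword {exc}") from exc

    mode = text.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise IOError(f"only list-mode FCS is supported, got $MODE={mode}")

    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32, 64):
            raise IOError("integer FCS data requires a uniform $PnB of 8/16/32/64")
        nbytes = int(text["$P1B"]) // 8
        dtype = np.dtype(f"{endian}u{nbytes}")
    else:
        raise IOError(f"unsupported $DATATYPE={datatype!r}")

    need = n_par * n_tot * dtype.itemsize
    raw = buf[data_beg : data_beg + need]
    if len(raw) < need:
        raise IOError(
            f"truncated FCS DATA segment: need {need} bytes, have {len(raw)}"
        )
    data = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par)

    names = [
        text.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)
    ]
    return pd.DataFrame(np.asarray(data, dtype=float), columns=names)


def sniff_fcs(path) -> bool:
    """True if the file starts with an FCS 3.x magic string."""
    with open(path, "rb") as fh:
        return fh.read(6) in _SUPPORTED_VERSIONS


def write_minimal_fcs(df: pd.DataFrame, path) -> None:
    """Write a bare-bones float32 FCS 3.0 file (testing/simulation aid).

    Produces just enough structure for :func:`read_fcs` and common readers:
    HEADER, TEXT with the required keywords, and a little-endian float32
    DATA segment.
    """
    n_tot, n_par = df.shape
    delim = "/"
    kv = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(df.columns, start=1):
        kv[f"$P{i}N"] = str(name)
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = "262144"

    data = np.ascontiguousarray(df.to_numpy(dtype=np.float32))
    payload = data.tobytes()

    # iterate: offsets depend on the length of the text segment
    text_beg = 58
    data_beg = 0
    for _ in range(3):
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
        text_end = text_beg + len(text) - 1
        data_beg = text_end + 1
        data_end = data_beg + len(payload) - 1
        kv["$BEGINDATA"] = str(data_beg)
        kv["$ENDDATA"] = str(data_end)

    header = b"FCS3.0    " + (
        f"{text_beg:>8d}{text_end:>8d}{data_beg:>8d}{data_end:>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("latin-1"))
        fh.write(struct.pack(f"<{data.size}f", *data.ravel()))
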