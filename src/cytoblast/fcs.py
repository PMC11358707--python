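"""Minimal reader for FCS 3.0 / 3.1 flow cytometry files.

Supports the subset of the standard that cytometer exports in practice use
for already-unmixed data: list-mode (``$MODE L``) events stored as IEEE
float32 (``$DATATYPE F``) or float64 (``$DATATYPE D``), little- or big-endian.
Integer data types, multi-dataset files and the ANALYSIS segment are out of
scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class FCSError(IOError):
    """Raised for files this reader cannot parse."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    # Trailing delimiter is required by the standard; tolerate its absence.
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FCSError("TEXT segment has an odd number of delimited fields")
    text: dict[str, str] = {}
    for key, value in zip(parts[0::2], parts[1::2]):
        text[key.decode("ascii", "replace").strip().upper()] = value.decode(
            "ascii", "replace"
        ).strip()
    return text


def read_fcs(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read one FCS 3.0/3.1 dataset into a DataFrame of events.

    Returns
    -------
    events : pandas.DataFrame
        ``$TOT`` rows by ``$PAR`` columns, named by ``$PnN``.
    text : dict
        The raw TEXT-segment keywords.
    """
    with open(path, "rb") as fh:
        header = fh.read(58)
        if len(header) < 58:
            raise FCSError("file too short for an FCS header")
        version = header[:6].decode("ascii", "replace")
        if version not in ("FCS3.0", "FCS3.1"):
            raise FCSError(f"unsupported FCS version {version!r}")
        offsets = []
        for i in range(4):  # text begin/end, data begin/end
            fieldstr = header[10 + 8 * i : 18 + 8 * i].decode("ascii", "replace")
            try:
                offsets.append(int(fieldstr.strip() or "0"))
            except ValueError:
                raise FCSError(f"malformed header offset {fieldstr!r}")
        text_begin, text_end, data_begin, data_end = offsets

        fh.seek(text_begin)
        text = _parse_text_segment(fh.read(text_end - text_begin + 1))

        # Large files record data offsets only in TEXT.
        if data_begin == 0:
            data_begin = int(text.get("$BEGINDATA", "0"))
        if data_end == 0:
            data_end = int(text.get("$ENDDATA", "0"))
        if data_begin <= 0 or data_end <= data_begin:
            raise FCSError("cannot locate DATA segment")

        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text.get("$DATATYPE", "F").upper()
        if datatype == "F":
            itemsize, kind = 4, "f4"
        elif datatype == "D":
            itemsize, kind = 8, "f8"
        else:
            raise FCSError(f"unsupported $DATATYPE {datatype!r} (need F or D)")
        byteord = text.get("$BYTEORD", "1,2,3,4")
        endian = "<" if byteord.startswith("1") else ">"
        if text.get("$MODE", "L").upper() != "L":
            raise FCSError("only list mode ($MODE L) is supported")

        fh.seek(data_begin)
        n_bytes = n_par * n_tot * itemsize
        buf = fh.read(n_bytes)
        if len(buf) < n_bytes:
            raise FCSError("DATA segment truncated")

    data = np.frombuffer(buf, dtype=endian + kind).reshape(n_tot, n_par)
    names = [
        text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)
    ]
    return pd.DataFrame(np.asarray(data, dtype=np.float64), columns=names), text


def write_fcs(path, events: pd.DataFrame) -> None:
    """Write a minimal FCS 3.1 file (float32 little-endian list mode).

    Provided so synthetic cohorts can be exported in the instrument-native
    format; real acquisitions carry many more keywords than are written here.
    """
    values = np.ascontiguousarray(events.to_numpy(dtype=np.float32))
    n_tot, n_par = values.shape
    delim = "/"
    keywords = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(events.columns, start=1):
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(np.nanmax(values[:, i - 1]) + 1) if n_tot else 1)

    # Fixed-width offsets require knowing the TEXT length; iterate once.
    text_begin = 58
    body = delim + delim.join(f"{k}{delim}{v}" for k, v in keywords.items()) + delim
    while True:  # offset digits can change the TEXT length; iterate to fixpoint
        text_end = text_begin + len(body) - 1
        data_begin = text_end + 1
        data_end = data_begin + values.nbytes - 1
        keywords["$BEGINDATA"] = str(data_begin)
        keywords["$ENDDATA"] = str(data_end)
        new_body = delim + delim.join(f"{k}{delim}{v}" for k, v in keywords.items()) + delim
        if len(new_body) == len(body) and "$BEGINDATA" in keywords:
            body = new_body
            break
        body = new_body

    header = (
        "FCS3.1    "
        + f"{text_begin:>8d}{text_end:>8d}{data_begin:>8d}{data_end:>8d}"
        + f"{0:>8d}{0:>8d}"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(body.encode("ascii"))
        fh.write(values.tobytes())
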