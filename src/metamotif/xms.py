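"""Readers and writers for motif and metamotif files.

Two formats are supported:

* an XMS-dialect XML format: a ``<motifset>`` root with one ``<motif>``
  element per record, each holding a ``<name>`` and a ``<weightmatrix>`` of
  ``<column>`` elements with four ``<weight symbol="...">`` children in
  A, C, G, T order.  Metamotifs use the same layout with the column means
  as weights plus a ``precision`` attribute per column, so the Dirichlet
  parameters are exactly recoverable.  The dialect is self-consistent and
  versioned (``version="metamotif-1"``); it is not claimed bit-compatible
  with other tools' XMS variants.

* a plain whitespace-delimited matrix format: either 4 rows (A/C/G/T) by L
  columns or L rows by 4 columns, auto-detected with an explicit override.

Round-trips preserve names, column order and weights to 12 significant
digits.  Columns whose weights sum to 1 within 1e-6 are renormalised with a
logged notice; larger deviations are parse errors.
"""

from __future__ import annotations

import io
import logging
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .model import PWM, Metamotif

logger = logging.getLogger(__name__)

FORMAT_VERSION = "metamotif-1"

_SYMBOLS = ("adenine", "cytosine", "guanine", "thymine")
_SYMBOL_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}
#: Tolerance within which non-normalised columns are silently renormalised.
NORMALISE_TOL = 1e-6


class MotifParseError(ValueError):
    """Raised for malformed motif documents."""


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _open_for(path_or_stream, mode):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    return open(Path(path_or_stream), mode), True


# -- XMS dialect -----------------------------------------------------------


def _column_element(weights, pos: int, precision: float | None) -> ET.Element:
    col = ET.Element("column", pos=str(pos))
    if precision is not None:
        col.set("precision", _fmt(precision))
    for sym, w in zip(_SYMBOLS, weights):
        el = ET.SubElement(col, "weight", symbol=sym)
        el.text = _fmt(w)
    return col


def _motif_element(name: str, weights: np.ndarray, precisions=None) -> ET.Element:
    motif = ET.Element("motif")
    ET.SubElement(motif, "name").text = name
    wm = ET.SubElement(
        motif, "weightmatrix", alphabet="DNA", columns=str(weights.shape[0])
    )
    for i, row in enumerate(weights):
        wm.append(
            _column_element(row, i, None if precisions is None else precisions[i])
        )
    return motif


def _serialise(records, metamotif: bool) -> ET.Element:
    root = ET.Element("motifset", version=FORMAT_VERSION)
    for rec in records:
        if metamotif:
            root.append(_motif_element(rec.name, rec.means, rec.precisions))
        else:
            root.append(_motif_element(rec.name, rec.weights))
    return root


def write_motifset(motifs, path_or_stream) -> None:
    """Write PWMs to an XMS-dialect XML document."""
    _write_xml(_serialise(list(motifs), metamotif=False), path_or_stream)


def write_metamotifset(metamotifs, path_or_stream) -> None:
    """Write metamotifs (column means + precision attributes) to XML."""
    _write_xml(_serialise(list(metamotifs), metamotif=True), path_or_stream)


def _write_xml(root: ET.Element, path_or_stream) -> None:
    ET.indent(root)
    data = ET.tostring(root, encoding="unicode", xml_declaration=True)
    fh, close = _open_for(path_or_stream, "w")
    try:
        fh.write(data + "\n")
    finally:
        if close:
            fh.close()


def _parse_columns(wm: ET.Element, where: str):
    cols = []
    precisions = []
    for col in wm.findall("column"):
        row = np.full(4, np.nan)
        for w in col.findall("weight"):
            sym = w.get("symbol")
            if sym not in _SYMBOL_INDEX:
                raise MotifParseError(f"{where}: unknown symbol {sym!r}")
            row[_SYMBOL_INDEX[sym]] = float(w.text)
        if np.isnan(row).any():
            raise MotifParseError(f"{where}: column is missing weights")
        s = row.sum()
        if abs(s - 1.0) > NORMALISE_TOL:
            raise MotifParseError(
                f"{where}: column pos={col.get('pos')} sums to {s:.6g}, not 1"
            )
        if s != 1.0:
            logger.info("%s: renormalising column with sum %.12g", where, s)
            row = row / s
        cols.append(row)
        prec = col.get("precision")
        precisions.append(None if prec is None else float(prec))
    if not cols:
        raise MotifParseError(f"{where}: weight matrix has no columns")
    return np.vstack(cols), precisions


def _parse_root(path_or_stream) -> ET.Element:
    fh, close = _open_for(path_or_stream, "r")
    try:
        try:
            tree = ET.parse(fh)
        except ET.ParseError as e:
            raise MotifParseError(f"malformed XML: {e}") from e
    finally:
        if close:
            fh.close()
    root = tree.getroot()
    if root.tag != "motifset":
        raise MotifParseError(f"expected <motifset> root, found <{root.tag}>")
    return root


def read_motifset(path_or_stream) -> list[PWM]:
    """Read PWMs from an XMS-dialect XML document."""
    root = _parse_root(path_or_stream)
    out = []
    for i, motif in enumerate(root.findall("motif")):
        name = motif.findtext("name") or f"motif{i}"
        wm = motif.find("weightmatrix")
        if wm is None:
            raise MotifParseError(f"motif {name!r}: no <weightmatrix>")
        weights, _ = _parse_columns(wm, f"motif {name!r}")
        out.append(PWM(name, weights))
    return out


def read_metamotifset(
    path_or_stream, default_precision: float | None = None
) -> list[Metamotif]:
    """Read metamotifs from an XMS-dialect XML document.

    Columns lacking a ``precision`` attribute are treated as a PWM import:
    a ``default_precision`` must then be supplied (the means are scaled by
    it), otherwise the record is rejected.
    """
    root = _parse_root(path_or_stream)
    out = []
    for i, motif in enumerate(root.findall("motif")):
        name = motif.findtext("name") or f"metamotif{i}"
        wm = motif.find("weightmatrix")
        if wm is None:
            raise MotifParseError(f"metamotif {name!r}: no <weightmatrix>")
        means, precisions = _parse_columns(wm, f"metamotif {name!r}")
        filled = []
        for j, p in enumerate(precisions):
            if p is None:
                if default_precision is None:
                    raise MotifParseError(
                        f"metamotif {name!r}: column {j} has no precision "
                        "attribute; supply a default precision to import a "
                        "PWM file as metamotifs"
                    )
                logger.info(
                    "metamotif %r: column %d missing precision, using %g",
                    name, j, default_precision,
                )
                p = default_precision
            filled.append(p)
        out.append(Metamotif(name, means * np.asarray(filled)[:, None]))
    return out


# -- plain matrix format ---------------------------------------------------


def read_plain_matrix(path_or_stream, name=None, orient: str = "auto") -> PWM:
    """Read one PWM from a plain whitespace-delimited matrix.

    ``orient``: ``"bases-as-rows"`` (4 rows A/C/G/T by L columns),
    ``"bases-as-columns"`` (L rows by 4 columns) or ``"auto"``, which picks
    the orientation whose columns sum to 1 (ambiguous 4x4 matrices default
    to bases-as-columns when both normalise).
    """
    fh, close = _open_for(path_or_stream, "r")
    try:
        raw = fh.read()
    finally:
        if close:
            fh.close()
    rows = [
        [float(tok) for tok in line.split()]
        for line in raw.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not rows or len({len(r) for r in rows}) != 1:
        raise MotifParseError("plain matrix: empty or ragged rows")
    arr = np.array(rows)

    def ok(mat):
        return mat.shape[1] == 4 and np.allclose(mat.sum(axis=1), 1.0, atol=1e-6)

    if orient == "bases-as-rows":
        mat = arr.T
    elif orient == "bases-as-columns":
        mat = arr
    elif orient == "auto":
        if ok(arr):
            mat = arr
        elif ok(arr.T):
            mat = arr.T
        else:
            raise MotifParseError(
                "plain matrix: neither orientation yields normalised columns"
            )
    else:
        raise ValueError(f"unknown orient {orient!r}")
    if not ok(mat):
        raise MotifParseError("plain matrix: columns do not sum to 1")
    mat = mat / mat.sum(axis=1, keepdims=True)
    if name is None:
        name = getattr(path_or_stream, "name", None)
        name = Path(name).stem if isinstance(name, str) else "motif"
    return PWM(str(name), mat)


def write_plain_matrix(pwm: PWM, path_or_stream, orient="bases-as-columns") -> None:
    """Write one PWM as a plain whitespace-delimited matrix."""
    mat = pwm.weights if orient == "bases-as-columns" else pwm.weights.T
    fh, close = _open_for(path_or_stream, "w")
    try:
        for row in mat:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    finally:
        if close:
            fh.close()


# -- manifests -------------------------------------------------------------


def write_manifest(manifest: dict, path_or_stream) -> None:
    """Write a key=value manifest, one entry per line."""
    fh, close = _open_for(path_or_stream, "w")
    try:
        for k, v in manifest.items():
            fh.write(f"{k}={v}\n")
    finally:
        if close:
            fh.close()


def read_manifest(path_or_stream) -> dict:
    fh, close = _open_for(path_or_stream, "r")
    try:
        out = {}
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            out[k] = v
        return out
    finally:
        if close:
            fh.close()


def motifset_to_string(motifs) -> str:
    buf = io.StringIO()
    write_motifset(motifs, buf)
    return buf.getvalue()


def metamotifset_to_string(metamotifs) -> str:
    buf = io.StringIO()
    write_metamotifset(metamotifs, buf)
    return buf.getvalue()
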