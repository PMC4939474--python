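"""Curve file format: two-column CSV plus JSON metadata sidecar.

A curve is stored as ``lag_s,g`` CSV with a header row; floats are written
with 17 significant digits so that ``read_curve(write_curve(c)) == c`` at
full double precision.  Sample metadata (sample id, pH, buffer, mean
intensity) lives in a sidecar ``<stem>.meta.json`` next to the curve file; a
missing sidecar is tolerated (the curve loads with empty metadata and a
logged warning) so that bare correlator exports can still be read.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .correlation import CurveMeta, FCSCurve

__all__ = ["CurveParseError", "read_curve", "write_curve", "sidecar_path"]

logger = logging.getLogger(__name__)

_HEADER = "lag_s,g"


class CurveParseError(ValueError):
    """Malformed curve file; the message names the file, line and offense."""


def sidecar_path(path: Union[str, Path]) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.json")


def _meta_to_dict(meta: CurveMeta) -> dict:
    return {
        "sample_id": meta.sample_id,
        "pH": meta.pH,
        "buffer_name": meta.buffer_name,
        "buffer_conc_M": meta.buffer_conc,
        "mean_intensity_cps": meta.mean_intensity,
    }


def _meta_from_dict(d: dict) -> CurveMeta:
    return CurveMeta(
        sample_id=d.get("sample_id", ""),
        pH=d.get("pH"),
        buffer_name=d.get("buffer_name"),
        buffer_conc=d.get("buffer_conc_M", 0.0) or 0.0,
        mean_intensity=d.get("mean_intensity_cps"),
    )


def write_curve(curve: FCSCurve, path: Union[str, Path]) -> Path:
    """Write a curve as CSV (17 significant digits) plus a metadata sidecar."""
    path = Path(path)
    lines = [_HEADER]
    for lag, g in zip(curve.lags, curve.values):
        lines.append(f"{lag:.17g},{g:.17g}")
    path.write_text("\n".join(lines) + "\n")
    if curve.meta is not None:
        sidecar_path(path).write_text(json.dumps(_meta_to_dict(curve.meta), indent=1) + "\n")
    return path


def read_curve(path: Union[str, Path]) -> FCSCurve:
    """Read a curve CSV and its metadata sidecar, validating as it parses.

    Raises :class:`CurveParseError` (with the offending line number) on
    missing/unknown columns, unparsable rows, NaN values or non-increasing
    lag grids.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or lines[0].strip() != _HEADER:
        raise CurveParseError(
            f"{path}: line 1: expected header {_HEADER!r}, got {lines[0].strip() if lines else ''!r}"
        )
    lags = []
    values = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise CurveParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            lag, g = float(parts[0]), float(parts[1])
        except ValueError:
            raise CurveParseError(f"{path}: line {lineno}: unparsable number in {line!r}") from None
        if math.isnan(lag) or math.isnan(g):
            raise CurveParseError(f"{path}: line {lineno}: NaN value")
        if lags and lag <= lags[-1]:
            raise CurveParseError(
                f"{path}: line {lineno}: lag times must be strictly increasing "
                f"({lag:g} after {lags[-1]:g})"
            )
        lags.append(lag)
        values.append(g)

    meta: Optional[CurveMeta] = None
    sidecar = sidecar_path(path)
    if sidecar.exists():
        meta = _meta_from_dict(json.loads(sidecar.read_text()))
    else:
        logger.warning("no metadata sidecar for %s; curve loads with empty metadata", path)
    try:
        return FCSCurve(lags=np.array(lags), values=np.array(values), meta=meta)
    except ValueError as exc:
        raise CurveParseError(f"{path}: {exc}") from exc
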