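"""File formats: elevation-map CSV grids and case-record JSONL.

Elevation CSV layout::

    # center=corneal_vertex
    # diameter_mm=10
    # landmark_pupil_center=0.2;0.1
    z_um,-5.0,-4.9,...        <- header row: x coordinates (mm)
    -5.0,12.3,11.9,...        <- first column: y coordinate (mm), then μm
    ...

Blank cells are missing samples.  The top-left tag must read ``z_um`` so a
file in the wrong units cannot be loaded silently.

Case records are one JSON object per line with named fields (pre/post
coefficient vectors at 8 mm, acuities in decimal, spherical equivalents in
diopters, RMS groups in μm at 6 mm, and the implanted segments).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np

from .clinical import CaseRecord, VAMeasure
from .segments import SegmentSpec
from .zernike import ElevationMap, RmsGroups, ZernikeCoefficients

__all__ = [
    "ParseError",
    "read_elevation_csv",
    "write_elevation_csv",
    "read_case_records",
    "write_case_records",
    "case_to_dict",
    "case_from_dict",
]

_UNIT_TAG = "z_um"


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line."""


def write_elevation_csv(emap: ElevationMap, path: str | Path) -> None:
    lines = [f"# center={emap.center}", f"# diameter_mm={emap.diameter_mm:g}"]
    for name, (lx, ly) in sorted(emap.landmarks.items()):
        lines.append(f"# landmark_{name}={lx:g};{ly:g}")
    lines.append(_UNIT_TAG + "," + ",".join(f"{x:g}" for x in emap.xs))
    for yi, row in zip(emap.ys, emap.z):
        cells = ["" if not np.isfinite(v) else f"{v:.6g}" for v in row]
        lines.append(f"{yi:g}," + ",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_elevation_csv(path: str | Path) -> ElevationMap:
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[float] | None = None
    ys: list[float] = []
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, _, v = line.lstrip("# ").partition("=")
                meta[k.strip()] = v.strip()
            continue
        cells = line.split(",")
        if header is None:
            tag = cells[0].strip()
            if tag != _UNIT_TAG:
                raise ParseError(
                    f"{path.name}:{lineno}: unit tag {tag!r} does not match "
                    f"expected {_UNIT_TAG!r}"
                )
            try:
                header = [float(c) for c in cells[1:]]
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: bad x coordinate: {exc}"
                ) from None
            continue
        if len(cells) != len(header) + 1:
            raise ParseError(
                f"{path.name}:{lineno}: ragged row has {len(cells) - 1} "
                f"values, expected {len(header)}"
            )
        try:
            ys.append(float(cells[0]))
            rows.append(
                [float(c) if c.strip() else np.nan for c in cells[1:]]
            )
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: bad value: {exc}") from None
    if header is None or not rows:
        raise ParseError(f"{path.name}: no grid data found")
    landmarks = {}
    for k, v in meta.items():
        if k.startswith("landmark_"):
            try:
                lx, ly = (float(t) for t in v.split(";"))
            except ValueError:
                raise ParseError(f"{path.name}: bad landmark entry {k}={v}")
            landmarks[k[len("landmark_"):]] = (lx, ly)
    try:
        return ElevationMap(
            xs=np.asarray(header),
            ys=np.asarray(ys),
            z=np.asarray(rows),
            center=meta.get("center", "corneal_vertex"),
            diameter_mm=float(meta.get("diameter_mm", 8.0)),
            landmarks=landmarks,
        )
    except ValueError as exc:
        raise ParseError(f"{path.name}: {exc}") from None


# ---------------------------------------------------------------------------
# case records
# ---------------------------------------------------------------------------

def _coeffs_to_dict(c: ZernikeCoefficients) -> dict:
    return {
        "values": [float(v) for v in c.values],
        "pupil_diameter_mm": c.pupil_diameter_mm,
        "max_order": c.max_order,
    }


def _coeffs_from_dict(d: dict) -> ZernikeCoefficients:
    return ZernikeCoefficients(
        np.asarray(d["values"], dtype=float),
        pupil_diameter_mm=d["pupil_diameter_mm"],
        max_order=d["max_order"],
    )


def _rms_to_dict(r: RmsGroups) -> dict:
    return {
        "total": r.total,
        "hoa": r.hoa,
        "astigmatism": r.astigmatism,
        "coma_like": r.coma_like,
        "spherical_like": r.spherical_like,
        "pupil_diameter_mm": r.pupil_diameter_mm,
    }


def case_to_dict(case: CaseRecord) -> dict:
    return {
        "preop": {
            "coeffs": _coeffs_to_dict(case.preop_coeffs),
            "udva": case.preop_udva.decimal,
            "cdva": case.preop_cdva.decimal,
            "se": case.preop_se,
            "rms": _rms_to_dict(case.preop_rms),
        },
        "postop": {
            "coeffs": _coeffs_to_dict(case.postop_coeffs),
            "udva": case.postop_udva.decimal,
            "cdva": case.postop_cdva.decimal,
            "se": case.postop_se,
            "rms": _rms_to_dict(case.postop_rms),
        },
        "implant": [
            {
                "model": s.model,
                "arc_deg": s.arc_deg,
                "thickness_um": s.thickness_um,
                "bisecting_line_deg": s.bisecting_line_deg,
            }
            for s in case.implant
        ],
        "months_followup": case.months_followup,
    }


def case_from_dict(d: dict) -> CaseRecord:
    return CaseRecord(
        preop_coeffs=_coeffs_from_dict(d["preop"]["coeffs"]),
        postop_coeffs=_coeffs_from_dict(d["postop"]["coeffs"]),
        preop_udva=VAMeasure.from_decimal(d["preop"]["udva"]),
        postop_udva=VAMeasure.from_decimal(d["postop"]["udva"]),
        preop_cdva=VAMeasure.from_decimal(d["preop"]["cdva"]),
        postop_cdva=VAMeasure.from_decimal(d["postop"]["cdva"]),
        preop_se=d["preop"]["se"],
        postop_se=d["postop"]["se"],
        preop_rms=RmsGroups(**d["preop"]["rms"]),
        postop_rms=RmsGroups(**d["postop"]["rms"]),
        implant=[SegmentSpec(**s) for s in d["implant"]],
        months_followup=d.get("months_followup", 6),
    )


def write_case_records(cases: Iterable[CaseRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for case in cases:
            fh.write(json.dumps(case_to_dict(case), sort_keys=True) + "\n")


def read_case_records(path: str | Path) -> list[CaseRecord]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            out.append(case_from_dict(json.loads(line)))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: bad case record: {exc}") from None
    return out
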