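"""Height-map and metadata I/O.

Coordinate conventions used throughout the package:

* 0-based pixel indices; ``heights[j, i]`` is the height at pixel column
  ``i`` (x) and row ``j`` (y); pixel centres sit at ``(i * dx, j * dy)``.
* After side standardization, +x is the buccal-to-lingual axis and +y is
  the mesial direction, so a texture direction of 90 degrees (measured
  counterclockwise from +x) is purely mesial.
* Non-measured points are carried in ``valid_mask`` and are excluded from
  every parameter computation; they are never silently filled.

Two plain-text formats are supported: a whitespace-separated matrix with
optional ``# dx=... dy=...`` header comments ("matrix_text"), and a minimal
ASCII surface-data-file dialect in the style of ISO 25178-71 ("sdf") with an
explicit header block.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "HeightMap",
    "SpecimenRecord",
    "FormatError",
    "ValidationError",
    "read_height_map",
    "write_height_map",
    "read_metadata",
    "write_metadata",
]

LOCALITIES = frozenset({"Kilpisjärvi", "Pallasjärvi"})
SEASONS = frozenset({"autumn", "spring"})
FACETS = frozenset({"T2", "T3"})
SIDES = frozenset({"L", "R"})

#: orientation tag recorded on every standardized map
STANDARD_FRAME = "+y=mesial,+x=buccal-to-lingual"


class FormatError(ValueError):
    """Malformed surface file (ragged rows, bad header, missing spacing)."""


class ValidationError(ValueError):
    """Metadata violates the closed vocabularies or uniqueness rules."""


@dataclass
class HeightMap:
    """A gridded surface height map in micrometres.

    Parameters
    ----------
    heights
        2-D array of heights (µm), shape ``(ny, nx)``; row index is y.
    dx, dy
        Lateral pixel spacing (µm/pixel), both > 0.
    valid_mask
        Boolean array of the same shape; False marks non-measured points.
    frame
        Orientation tag; :data:`STANDARD_FRAME` once side-standardized.
    meta
        Free-form specimen metadata (id, side, facet, locality, season).
    """

    heights: np.ndarray
    dx: float
    dy: float
    valid_mask: np.ndarray | None = None
    frame: str = STANDARD_FRAME
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if self.heights.shape[0] < 2 or self.heights.shape[1] < 2:
            raise ValueError("height map must be at least 2x2 pixels")
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("lateral spacings dx, dy must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.heights)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.heights.shape:
                raise ValueError("valid_mask shape must match heights shape")
            self.valid_mask = self.valid_mask & np.isfinite(self.heights)

    @property
    def nx(self) -> int:
        return self.heights.shape[1]

    @property
    def ny(self) -> int:
        return self.heights.shape[0]

    @property
    def all_valid(self) -> bool:
        return bool(self.valid_mask.all())

    def valid_heights(self) -> np.ndarray:
        """Heights at valid points, flattened."""
        return self.heights[self.valid_mask]

    def copy_with(self, heights: np.ndarray, **kwargs: Any) -> "HeightMap":
        """New map with replaced heights; spacing/mask/meta preserved."""
        defaults = dict(
            dx=self.dx,
            dy=self.dy,
            valid_mask=self.valid_mask.copy(),
            frame=self.frame,
            meta=dict(self.meta),
        )
        defaults.update(kwargs)
        return HeightMap(heights=np.asarray(heights, dtype=float), **defaults)


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen-facet observation with its aggregated parameter values."""

    specimen_id: str
    locality: str
    season: str
    facet: str
    side: str
    parameters: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for value, vocab, name in (
            (self.locality, LOCALITIES, "locality"),
            (self.season, SEASONS, "season"),
            (self.facet, FACETS, "facet"),
            (self.side, SIDES, "side"),
        ):
            if value not in vocab:
                raise ValidationError(
                    f"{name}={value!r} for specimen {self.specimen_id!r} not in "
                    f"{sorted(vocab)}"
                )


def _parse_header_floats(lines: list[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        for tok in body.replace(",", " ").split():
            if "=" in tok:
                key, _, val = tok.partition("=")
                try:
                    out[key.strip()] = float(val)
                except ValueError as exc:
                    raise FormatError(f"bad header token {tok!r}") from exc
    return out


def _read_matrix_text(path: Path) -> HeightMap:
    header_lines: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header_lines.append(line)
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric token in data row") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    hdr = _parse_header_floats(header_lines)
    if "dx" not in hdr or "dy" not in hdr:
        raise FormatError(f"{path}: missing dx/dy spacing metadata in header")
    if hdr["dx"] <= 0 or hdr["dy"] <= 0:
        raise FormatError(f"{path}: non-positive spacing in header")
    heights = np.array(rows, dtype=float)
    return HeightMap(heights=heights, dx=hdr["dx"], dy=hdr["dy"])


def _write_matrix_text(hmap: HeightMap, path: Path) -> None:
    z = hmap.heights.copy()
    z[~hmap.valid_mask] = np.nan
    with open(path, "w") as fh:
        fh.write(f"# dx={float(hmap.dx)!r} dy={float(hmap.dy)!r}\n")
        for row in z:
            fh.write(" ".join(repr(float(v)) if np.isfinite(v) else "NaN" for v in row))
            fh.write("\n")


# Minimal ASCII SDF-style dialect: a header block terminated by '*', then a
# whitespace-separated data block in raster order (row = y), then '*'.
_SDF_MAGIC = "aISO-1.0"
_SDF_BAD = "BAD"  # token marking a non-measured point


def _read_sdf(path: Path) -> HeightMap:
    with open(path) as fh:
        text = fh.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != _SDF_MAGIC:
        raise FormatError(f"{path}: not a {_SDF_MAGIC} surface data file")
    try:
        star1 = lines.index("*")
    except ValueError:
        raise FormatError(f"{path}: missing header terminator '*'")
    hdr = _parse_header_floats(lines[1:star1])
    for key in ("NumPoints", "NumProfiles", "Xscale", "Yscale"):
        if key not in hdr:
            raise FormatError(f"{path}: header missing {key}")
    nx, ny = int(hdr["NumPoints"]), int(hdr["NumProfiles"])
    dx, dy = hdr["Xscale"], hdr["Yscale"]
    if dx <= 0 or dy <= 0:
        raise FormatError(f"{path}: non-positive Xscale/Yscale")
    zscale = hdr.get("Zscale", 1.0)
    tokens: list[str] = []
    for ln in lines[star1 + 1 :]:
        if ln == "*":
            break
        tokens.extend(ln.split())
    if len(tokens) != nx * ny:
        raise FormatError(
            f"{path}: expected {nx * ny} data values, found {len(tokens)}"
        )
    z = np.empty(nx * ny, dtype=float)
    for k, tok in enumerate(tokens):
        if tok == _SDF_BAD or tok.lower() == "nan":
            z[k] = np.nan
        else:
            try:
                z[k] = float(tok) * zscale
            except ValueError as exc:
                raise FormatError(f"{path}: bad data token {tok!r}") from exc
    return HeightMap(heights=z.reshape(ny, nx), dx=dx, dy=dy)


def _write_sdf(hmap: HeightMap, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_SDF_MAGIC}\n")
        fh.write(f"NumPoints={hmap.nx}\n")
        fh.write(f"NumProfiles={hmap.ny}\n")
        fh.write(f"Xscale={float(hmap.dx)!r}\n")
        fh.write(f"Yscale={float(hmap.dy)!r}\n")
        fh.write("Zscale=1.0\n")
        fh.write("*\n")
        for j in range(hmap.ny):
            toks = []
            for i in range(hmap.nx):
                if hmap.valid_mask[j, i] and np.isfinite(hmap.heights[j, i]):
                    toks.append(repr(float(hmap.heights[j, i])))
                else:
                    toks.append(_SDF_BAD)
            fh.write(" ".join(toks) + "\n")
        fh.write("*\n")


_READERS = {"matrix_text": _read_matrix_text, "sdf": _read_sdf}
_WRITERS = {"matrix_text": _write_matrix_text, "sdf": _write_sdf}


def _resolve_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _READERS:
            raise ValueError(f"unknown format {fmt!r}; choose from {sorted(_READERS)}")
        return fmt
    return "sdf" if path.suffix.lower() == ".sdf" else "matrix_text"


def read_height_map(path: str | Path, format: str | None = None) -> HeightMap:
    """Read a gridded height map from a plain-text surface file.

    ``format`` is ``"matrix_text"`` or ``"sdf"``; when omitted it is inferred
    from the file extension (``.sdf`` → sdf dialect, anything else → matrix
    text). Non-measured points (``NaN`` / ``BAD`` tokens) come back masked
    invalid, never filled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _READERS[_resolve_format(path, format)](path)


def write_height_map(hmap: HeightMap, path: str | Path, format: str | None = None) -> None:
    """Write a height map; the file round-trips through :func:`read_height_map`.

    Heights are written with full ``repr`` precision, so a round trip
    preserves heights bit-for-bit along with shape, spacings and mask.
    """
    path = Path(path)
    _WRITERS[_resolve_format(path, format)](hmap, path)


_REQUIRED_COLUMNS = ("specimen_id", "locality", "season", "facet", "side")


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read a specimen metadata CSV into validated records.

    Requires columns ``specimen_id, locality, season, facet, side``; enforces
    the closed vocabularies and rejects duplicate (specimen_id, facet) pairs.
    """
    path = Path(path)
    records: list[SpecimenRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _REQUIRED_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValidationError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = SpecimenRecord(
                    specimen_id=row["specimen_id"].strip(),
                    locality=row["locality"].strip(),
                    season=row["season"].strip(),
                    facet=row["facet"].strip(),
                    side=row["side"].strip(),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from exc
            key = (rec.specimen_id, rec.facet)
            if key in seen:
                raise ValidationError(
                    f"{path} line {lineno}: duplicate (specimen_id, facet) {key}"
                )
            seen.add(key)
            records.append(rec)
    return records


def write_metadata(records: list[SpecimenRecord], path: str | Path) -> None:
    """Write specimen records to a metadata CSV readable by :func:`read_metadata`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REQUIRED_COLUMNS)
        for rec in records:
            writer.writerow([rec.specimen_id, rec.locality, rec.season, rec.facet, rec.side])
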