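"""Point-cloud file I/O and measurement-job configuration.

Supported cloud formats:

* **PLY** — ascii 1.0 and binary_little_endian 1.0, vertex element with at
  least float ``x y z`` properties and optionally ``nx ny nz`` normals.
  Writing emits ascii by default (diffable); a header comment records the
  declared length unit.
* **XYZ / CSV** — whitespace- or comma-delimited ``x y z [nx ny nz]`` rows;
  lines starting with ``#`` are comments.

The measurement configuration serialises a repeated-trials measurement of
one target feature: per-trial endpoint coordinate pairs, the feature's
physically measured true length, and the coordinate unit.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import ARBITRARY, InvalidInputError, PointCloud, convert_unit

__all__ = [
    "CloudParseError",
    "ConfigError",
    "MeasurementConfig",
    "read_cloud",
    "write_cloud",
    "read_measurement_config",
    "write_measurement_config",
]

log = logging.getLogger(__name__)

_VALID_UNITS = {"mm", "cm", "m", ARBITRARY}


class CloudParseError(ValueError):
    """A cloud file failed to parse; the message names the offending line/offset."""


class ConfigError(ValueError):
    """A measurement configuration failed schema validation."""


# ---------------------------------------------------------------------------
# PLY


_PLY_TYPES = {
    "float": ("f", 4), "float32": ("f", 4),
    "double": ("d", 8), "float64": ("d", 8),
    "uchar": ("B", 1), "uint8": ("B", 1), "char": ("b", 1), "int8": ("b", 1),
    "short": ("h", 2), "int16": ("h", 2), "ushort": ("H", 2), "uint16": ("H", 2),
    "int": ("i", 4), "int32": ("i", 4), "uint": ("I", 4), "uint32": ("I", 4),
}


def _parse_ply_header(fh):
    """Parse a PLY header; returns (format, n_vertex, property names/types, unit?)."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise CloudParseError("line 1: not a PLY file (missing 'ply' magic)")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    unit = None
    in_vertex = False
    lineno = 1
    while True:
        raw = fh.readline()
        if not raw:
            raise CloudParseError(f"line {lineno}: unexpected end of header")
        lineno += 1
        tokens = raw.decode("ascii", errors="replace").split()
        if not tokens:
            continue
        kw = tokens[0]
        if kw == "format":
            if tokens[1] not in ("ascii", "binary_little_endian"):
                raise CloudParseError(f"line {lineno}: unsupported PLY format {tokens[1]!r}")
            fmt = tokens[1]
        elif kw == "comment":
            if len(tokens) >= 3 and tokens[1] == "unit":
                unit = tokens[2]
        elif kw == "element":
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                n_vertex = int(tokens[2])
            elif int(tokens[2]) > 0:
                raise CloudParseError(
                    f"line {lineno}: non-empty element {tokens[1]!r} not supported"
                )
        elif kw == "property" and in_vertex:
            if tokens[1] == "list":
                raise CloudParseError(f"line {lineno}: list properties not supported")
            if tokens[1] not in _PLY_TYPES:
                raise CloudParseError(f"line {lineno}: unknown property type {tokens[1]!r}")
            props.append((tokens[2], tokens[1]))
        elif kw == "end_header":
            break
    if fmt is None or n_vertex is None:
        raise CloudParseError("header missing 'format' or vertex element")
    for needed in ("x", "y", "z"):
        if needed not in [p[0] for p in props]:
            raise CloudParseError(f"vertex element lacks required property {needed!r}")
    return fmt, n_vertex, props, unit, lineno


def _read_ply(path: Path, unit: str | None):
    with open(path, "rb") as fh:
        fmt, n, props, header_unit, header_lines = _parse_ply_header(fh)
        names = [p[0] for p in props]
        if fmt == "ascii":
            rows = np.empty((n, len(props)), dtype=float)
            for i in range(n):
                raw = fh.readline()
                lineno = header_lines + 1 + i
                if not raw:
                    raise CloudParseError(f"line {lineno}: truncated body ({i} of {n} vertices)")
                fields = raw.split()
                if len(fields) < len(props):
                    raise CloudParseError(
                        f"line {lineno}: expected {len(props)} fields, got {len(fields)}"
                    )
                try:
                    rows[i] = [float(v) for v in fields[: len(props)]]
                except ValueError:
                    raise CloudParseError(f"line {lineno}: non-numeric field") from None
        else:
            fmt_str = "<" + "".join(_PLY_TYPES[t][0] for _, t in props)
            stride = struct.calcsize(fmt_str)
            body = fh.read(stride * n)
            if len(body) < stride * n:
                raise CloudParseError(
                    f"byte offset {len(body)}: truncated binary body "
                    f"(need {stride * n} bytes for {n} vertices)"
                )
            rows = np.array(
                [struct.unpack_from(fmt_str, body, i * stride) for i in range(n)],
                dtype=float,
            ).reshape(n, len(props))
    cols = {name: rows[:, i] for i, name in enumerate(names)} if n else {}
    if n:
        pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
        nrm = None
        if all(k in cols for k in ("nx", "ny", "nz")):
            nrm = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
            norms = np.linalg.norm(nrm, axis=1)
            nrm = nrm / np.where(norms == 0.0, 1.0, norms)[:, None]  # re-unitise f32
    else:
        pts, nrm = np.zeros((0, 3)), None
        if any(p[0] == "nx" for p in props):
            nrm = np.zeros((0, 3))
    return PointCloud(pts, unit=unit or header_unit or "mm", normals=nrm)


def _write_ply(cloud: PointCloud, path: Path, binary: bool = False):
    props = ["x", "y", "z"] + (["nx", "ny", "nz"] if cloud.has_normals else [])
    data = cloud.points if not cloud.has_normals else np.hstack([cloud.points, cloud.normals])
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"comment unit {cloud.unit}", f"element vertex {len(cloud)}"]
    header += [f"property float {p}" for p in props]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        data32 = data.astype(np.float32)
        if binary:
            fh.write(data32.tobytes())
        else:
            for row in data32:
                fh.write((" ".join(repr(float(v)) for v in row) + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# XYZ / CSV text


def _read_text_cloud(path: Path, unit: str | None):
    pts_rows, nrm_rows = [], []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) not in (3, 6):
                raise CloudParseError(
                    f"line {lineno}: expected 3 or 6 numeric fields, got {len(fields)}"
                )
            try:
                vals = [float(v) for v in fields]
            except ValueError:
                raise CloudParseError(f"line {lineno}: non-numeric field") from None
            pts_rows.append(vals[:3])
            if len(vals) == 6:
                nrm_rows.append(vals[3:])
    if nrm_rows and len(nrm_rows) != len(pts_rows):
        raise CloudParseError("mixed rows: some lines carry normals, some do not")
    if not pts_rows:
        log.warning("empty cloud file %s (N = 0)", path)
        return PointCloud(np.zeros((0, 3)), unit=unit or "mm")
    return PointCloud(
        np.asarray(pts_rows),
        unit=unit or "mm",
        normals=np.asarray(nrm_rows) if nrm_rows else None,
    )


def _write_text_cloud(cloud: PointCloud, path: Path, sep: str):
    with open(path, "w") as fh:
        fh.write(f"# unit {cloud.unit}\n")
        data = (
            cloud.points
            if not cloud.has_normals
            else np.hstack([cloud.points, cloud.normals])
        )
        for row in data:
            fh.write(sep.join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# public cloud API


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    return {"ply": "ply", "xyz": "xyz", "csv": "csv", "txt": "xyz"}.get(suffix, "ply")


def read_cloud(path, format: str | None = None, unit: str | None = None) -> PointCloud:
    """Read a point cloud.

    Parameters
    ----------
    path
        Input file.
    format
        ``"ply"``, ``"xyz"`` or ``"csv"``; inferred from the suffix when
        omitted.
    unit
        Unit tag to declare on the loaded cloud.  When omitted, a unit
        recorded in the file (PLY ``comment unit`` line) is honoured,
        defaulting to ``"mm"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if unit is not None and unit not in _VALID_UNITS:
        raise ConfigError(f"unknown unit tag {unit!r}")
    fmt = _infer_format(path, format)
    if fmt == "ply":
        return _read_ply(path, unit)
    if fmt in ("xyz", "csv"):
        return _read_text_cloud(path, unit)
    raise ConfigError(f"unknown cloud format {fmt!r}")


def write_cloud(cloud: PointCloud, path, format: str | None = None, *, binary: bool = False):
    """Write a point cloud; PLY records the unit in a header comment."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "xyz":
        _write_text_cloud(cloud, path, " ")
    elif fmt == "csv":
        _write_text_cloud(cloud, path, ",")
    else:
        raise ConfigError(f"unknown cloud format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# measurement configuration


@dataclass
class MeasurementConfig:
    """Repeated endpoint-pair measurements of one target feature.

    ``trials`` holds ``(endpoint_a, endpoint_b)`` coordinate pairs in
    ``coordinate_unit``; ``true_length_mm`` is the physically measured
    ground-truth length of the feature.
    """

    trials: list[tuple[np.ndarray, np.ndarray]]
    true_length_mm: float
    coordinate_unit: str = "mm"
    label: str = ""

    def __post_init__(self):
        if len(self.trials) < 1:
            raise ConfigError("at least one trial is required")
        if not (self.true_length_mm > 0):
            raise ConfigError("true_length must be positive")
        if self.coordinate_unit not in _VALID_UNITS:
            raise ConfigError(f"unknown coordinate unit {self.coordinate_unit!r}")
        clean = []
        for i, pair in enumerate(self.trials):
            if len(pair) != 2:
                raise ConfigError(f"trial {i}: expected exactly two endpoints")
            a = np.asarray(pair[0], dtype=float).reshape(-1)
            b = np.asarray(pair[1], dtype=float).reshape(-1)
            if a.shape != (3,) or b.shape != (3,):
                raise ConfigError(f"trial {i}: endpoints must be 3D coordinate triples")
            if not (np.isfinite(a).all() and np.isfinite(b).all()):
                raise ConfigError(f"trial {i}: non-finite endpoint coordinate")
            clean.append((a, b))
        self.trials = clean

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def endpoints_mm(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Trial endpoints converted to millimetres."""
        if self.coordinate_unit == ARBITRARY:
            raise InvalidInputError(
                "coordinates are in arbitrary units; recover the scale first"
            )
        return [
            (
                convert_unit(a, self.coordinate_unit, "mm"),
                convert_unit(b, self.coordinate_unit, "mm"),
            )
            for a, b in self.trials
        ]


def _length_to_mm(entry, what: str) -> float:
    if isinstance(entry, dict):
        try:
            value, unit = float(entry["value"]), entry["unit"]
        except KeyError as exc:
            raise ConfigError(f"{what}: missing key {exc.args[0]!r}") from None
        if unit not in ("mm", "cm", "m"):
            raise ConfigError(f"{what}: unit must be metric, got {unit!r}")
        return float(convert_unit(value, unit, "mm"))
    return float(entry)  # bare number → mm


def read_measurement_config(path) -> MeasurementConfig:
    """Load a measurement config from YAML (JSON is a subset and also accepted).

    Schema::

        label: free text                # optional
        coordinate_unit: mm|cm|m|arbitrary
        true_length: {value: 36.04, unit: mm}   # or a bare number in mm
        trials:
          - a: [x, y, z]
            b: [x, y, z]
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if "true_length" not in doc:
        raise ConfigError(f"{path}: missing required key 'true_length'")
    if "trials" not in doc or not isinstance(doc["trials"], list) or not doc["trials"]:
        raise ConfigError(f"{path}: 'trials' must be a non-empty list")
    trials = []
    for i, entry in enumerate(doc["trials"]):
        if not isinstance(entry, dict) or "a" not in entry or "b" not in entry:
            raise ConfigError(f"{path}: trial {i} must carry endpoints 'a' and 'b'")
        trials.append((entry["a"], entry["b"]))
    return MeasurementConfig(
        trials=trials,
        true_length_mm=_length_to_mm(doc["true_length"], "true_length"),
        coordinate_unit=doc.get("coordinate_unit", "mm"),
        label=str(doc.get("label", "")),
    )


def write_measurement_config(config: MeasurementConfig, path):
    doc = {
        "label": config.label,
        "coordinate_unit": config.coordinate_unit,
        "true_length": {"value": config.true_length_mm, "unit": "mm"},
        "trials": [
            {"a": [float(v) for v in a], "b": [float(v) for v in b]}
            for a, b in config.trials
        ],
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path
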