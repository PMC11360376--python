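"""Point-cloud and polygon I/O.

Point clouds are exchanged as LAS 1.2 (point formats 0-3, with an
optional extra-bytes dimension carrying the synthetic truth label) or as
plain ``x,y,z`` CSV. Vine footprints are GeoJSON FeatureCollections (a
``vine_id`` property per feature) or WKT-in-CSV. All coordinates are
assumed to live in a projected metric CRS; no geodetic transforms are
performed.

The LAS codec here is deliberately minimal: uncompressed LAS only,
little-endian, scale/offset applied on read, default scale 0.001 m
(millimetre quantization, matching survey-grade TLS accuracy).
"""

from __future__ import annotations

import csv
import json
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon, shape

logger = logging.getLogger(__name__)

#: truth-label codes carried through the synthetic pipeline (0 = unknown)
TRUTH_CODES = {"unknown": 0, "ground": 1, "grass": 2, "canopy": 3, "trunk": 4}
TRUTH_NAMES = {v: k for k, v in TRUTH_CODES.items()}

#: LAS classification code for ground (ASPRS standard)
LAS_GROUND = 2


class CloudIOError(RuntimeError):
    """Raised for unreadable, empty or malformed point-cloud input."""


class PolygonValidationError(ValueError):
    """Raised when a footprint polygon fails validation."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PointCloud:
    """A set of 3D points with optional per-point attributes.

    ``z`` is elevation for raw clouds; after ground normalization it is
    height above ground (see :class:`NormalizedPointCloud`).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    classification: np.ndarray | None = None
    return_number: np.ndarray | None = None
    number_of_returns: np.ndarray | None = None
    rgb: np.ndarray | None = None  # (n, 3) uint16
    truth: np.ndarray | None = None  # uint8 codes, see TRUTH_CODES
    crs_tag: str = ""
    sensor_name: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.x.size
        if self.y.size != n or self.z.size != n:
            raise CloudIOError("coordinate arrays must have equal length")
        if n == 0:
            raise CloudIOError("point cloud is empty")

    def __len__(self) -> int:
        return self.x.size

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def _attr_fields(self) -> tuple[str, ...]:
        return ("classification", "return_number", "number_of_returns", "rgb", "truth")

    def subset(self, index: np.ndarray) -> "PointCloud":
        """Return the cloud restricted to ``index`` (mask or indices), order preserved."""
        kw = {}
        for name in self._attr_fields():
            a = getattr(self, name)
            kw[name] = a[index] if a is not None else None
        return replace(
            self, x=self.x[index], y=self.y[index], z=self.z[index], **kw
        )

    def drop_nonfinite(self) -> "PointCloud":
        ok = np.isfinite(self.x) & np.isfinite(self.y) & np.isfinite(self.z)
        dropped = int((~ok).sum())
        if dropped:
            logger.warning("dropped %d non-finite points", dropped)
            return self.subset(ok)
        return self


@dataclass
class NormalizedPointCloud(PointCloud):
    """Point cloud whose ``z`` is height above the interpolated ground."""

    ground_flag: np.ndarray | None = None

    def _attr_fields(self) -> tuple[str, ...]:
        return super()._attr_fields() + ("ground_flag",)


@dataclass
class VinePolygon:
    """One grapevine's footprint: a closed, simple XY ring."""

    vine_id: str
    ring: np.ndarray  # (n, 2), not explicitly closed
    provenance: str = "built"  # {"built", "loaded"}

    def __post_init__(self) -> None:
        ring = np.asarray(self.ring, dtype=float)
        # drop an explicit closing vertex
        if ring.shape[0] >= 2 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        if ring.shape[0] < 3 or len(np.unique(ring, axis=0)) < 3:
            raise PolygonValidationError(
                f"polygon {self.vine_id!r}: ring needs >= 3 distinct vertices"
            )
        poly = Polygon(ring)
        if not poly.is_valid:
            raise PolygonValidationError(
                f"polygon {self.vine_id!r}: invalid ring (self-intersecting?)"
            )
        if poly.area <= 0:
            raise PolygonValidationError(f"polygon {self.vine_id!r}: zero area")
        self.ring = ring

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.ring)

    @property
    def area(self) -> float:
        return self.shapely.area


# ---------------------------------------------------------------------------
# LAS 1.2 codec
# ---------------------------------------------------------------------------

_HEADER_FMT = "<4sHH16sBB32s32sHHHLLBHL5L12d"
_HEADER_SIZE = 227
_VLR_FMT = "<H16sHH32s"
_VLR_SIZE = 54

_POINT_BASE = [
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
    ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
    ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
]
_GPS = [("gps_time", "<f8")]
_RGB = [("red", "<u2"), ("green", "<u2"), ("blue", "<u2")]
_POINT_DTYPES = {
    0: _POINT_BASE,
    1: _POINT_BASE + _GPS,
    2: _POINT_BASE + _RGB,
    3: _POINT_BASE + _GPS + _RGB,
}

_EXTRA_NAME = b"truth"


def _extra_bytes_vlr_payload(name: bytes, data_type: int = 1) -> bytes:
    """One 192-byte extra-bytes descriptor (data_type 1 = uint8)."""
    return struct.pack(
        "<2B B B 32s 4B 24s 24s 24s 24s 24s 32s",
        0, 0, data_type, 0, name.ljust(32, b"\0"), 0, 0, 0, 0,
        b"\0" * 24, b"\0" * 24, b"\0" * 24, b"\0" * 24, b"\0" * 24,
        b"synthetic truth label".ljust(32, b"\0"),
    )


def write_las(
    cloud: PointCloud,
    path: str | Path,
    scale: float = 0.001,
    point_format: int | None = None,
) -> None:
    """Write an uncompressed LAS 1.2 file.

    The point format is chosen from the attributes present (GPS time is
    never written; RGB selects format 2). A truth-label extra byte is
    appended when ``cloud.truth`` is set, described by an extra-bytes VLR.
    """
    path = Path(path)
    n = len(cloud)
    if point_format is None:
        point_format = 2 if cloud.rgb is not None else 0
    if point_format not in _POINT_DTYPES:
        raise CloudIOError(f"unsupported LAS point format {point_format}")

    fields = list(_POINT_DTYPES[point_format])
    has_truth = cloud.truth is not None
    if has_truth:
        fields = fields + [("truth", "u1")]
    dtype = np.dtype(fields)

    offsets = np.array(
        [cloud.x.min(), cloud.y.min(), cloud.z.min()], dtype=float
    )
    rec = np.zeros(n, dtype=dtype)
    rec["X"] = np.round((cloud.x - offsets[0]) / scale).astype(np.int64)
    rec["Y"] = np.round((cloud.y - offsets[1]) / scale).astype(np.int64)
    rec["Z"] = np.round((cloud.z - offsets[2]) / scale).astype(np.int64)
    if cloud.classification is not None:
        rec["classification"] = np.asarray(cloud.classification, dtype=np.uint8)
    rn = cloud.return_number
    nr = cloud.number_of_returns
    if rn is not None:
        flags = (np.asarray(rn, dtype=np.uint8) & 0x7)
        if nr is not None:
            flags |= (np.asarray(nr, dtype=np.uint8) & 0x7) << 3
        rec["flags"] = flags
    if cloud.rgb is not None and "red" in dtype.names:
        rgb = np.asarray(cloud.rgb, dtype=np.uint16)
        rec["red"], rec["green"], rec["blue"] = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    if has_truth:
        rec["truth"] = np.asarray(cloud.truth, dtype=np.uint8)

    vlrs = []
    if has_truth:
        vlrs.append((b"LASF_Spec", 4, _extra_bytes_vlr_payload(_EXTRA_NAME)))

    vlr_bytes = b""
    for user_id, record_id, payload in vlrs:
        vlr_bytes += struct.pack(
            _VLR_FMT, 0, user_id.ljust(16, b"\0"), record_id, len(payload),
            b"".ljust(32, b"\0"),
        )
        vlr_bytes += payload

    offset_to_points = _HEADER_SIZE + len(vlr_bytes)
    by_return = [0, 0, 0, 0, 0]
    if rn is not None:
        counts = np.bincount(np.clip(np.asarray(rn, int), 1, 5), minlength=6)
        by_return = list(counts[1:6])
    else:
        by_return[0] = n

    header = struct.pack(
        _HEADER_FMT,
        b"LASF", 0, 0, b"\0" * 16, 1, 2,
        b"vinemetrics".ljust(32, b"\0"), b"vinemetrics".ljust(32, b"\0"),
        0, 0,  # creation day/year fixed at 0 for byte-reproducible output
        _HEADER_SIZE, offset_to_points, len(vlrs),
        point_format, dtype.itemsize, n, *by_return,
        scale, scale, scale, *offsets,
        cloud.x.max(), cloud.x.min(),
        cloud.y.max(), cloud.y.min(),
        cloud.z.max(), cloud.z.min(),
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(vlr_bytes)
        fh.write(rec.tobytes())
    logger.info("wrote %d points to %s (LAS fmt %d)", n, path, point_format)


def _read_las(path: Path) -> PointCloud:
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE or raw[:4] != b"LASF":
        raise CloudIOError(f"{path}: not a LAS file")
    hdr = struct.unpack(_HEADER_FMT, raw[:_HEADER_SIZE])
    ver_major, ver_minor = hdr[4], hdr[5]
    header_size, offset_to_points, n_vlrs = hdr[10], hdr[11], hdr[12]
    point_format, rec_len, n_points = hdr[13] & 0x3F, hdr[14], hdr[15]
    scales = np.array(hdr[21:24])
    offsets = np.array(hdr[24:27])
    if n_points == 0:
        # LAS 1.4 stores the count past the legacy field; we only support <=1.3
        raise CloudIOError(f"{path}: zero points")
    if point_format not in _POINT_DTYPES:
        raise CloudIOError(f"{path}: unsupported point format {point_format}")

    # parse VLRs for extra-bytes names
    extra_names: list[str] = []
    pos = header_size
    for _ in range(n_vlrs):
        _, user_id, record_id, length, _ = struct.unpack(
            _VLR_FMT, raw[pos:pos + _VLR_SIZE]
        )
        payload = raw[pos + _VLR_SIZE:pos + _VLR_SIZE + length]
        if user_id.rstrip(b"\0") == b"LASF_Spec" and record_id == 4:
            for off in range(0, len(payload), 192):
                desc = payload[off:off + 192]
                if len(desc) == 192:
                    name = desc[4:36].rstrip(b"\0").decode("ascii", "replace")
                    extra_names.append(name)
        pos += _VLR_SIZE + length

    fields = list(_POINT_DTYPES[point_format])
    base_len = np.dtype(fields).itemsize
    n_extra = rec_len - base_len
    if n_extra < 0:
        raise CloudIOError(f"{path}: point record shorter than format requires")
    for i in range(n_extra):  # extra bytes are read as uint8 columns
        name = extra_names[i] if i < len(extra_names) else f"extra_{i}"
        fields.append((name, "u1"))
    dtype = np.dtype(fields)

    rec = np.frombuffer(
        raw, dtype=dtype, count=n_points, offset=offset_to_points
    )
    rgb = None
    if "red" in dtype.names:
        rgb = np.column_stack([rec["red"], rec["green"], rec["blue"]])
    truth = rec["truth"].copy() if "truth" in dtype.names else None
    flags = rec["flags"]
    cloud = PointCloud(
        x=rec["X"] * scales[0] + offsets[0],
        y=rec["Y"] * scales[1] + offsets[1],
        z=rec["Z"] * scales[2] + offsets[2],
        classification=rec["classification"].copy(),
        return_number=(flags & 0x7).astype(np.uint8),
        number_of_returns=((flags >> 3) & 0x7).astype(np.uint8),
        rgb=rgb,
        truth=truth,
        crs_tag="",
        sensor_name="",
    )
    logger.info(
        "read %d points from %s (LAS %d.%d fmt %d)",
        n_points, path, ver_major, ver_minor, point_format,
    )
    return cloud


# ---------------------------------------------------------------------------
# public readers / writers
# ---------------------------------------------------------------------------


def read_point_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read a point cloud from ``las`` or ``xyz-csv``.

    The format is inferred from the suffix when not given. Non-finite
    rows are dropped (with a logged count); an empty result raises.
    """
    path = Path(path)
    if not path.exists():
        raise CloudIOError(f"{path}: no such file")
    if format is None:
        suffix = path.suffix.lower()
        format = {".las": "las", ".laz": "laz", ".csv": "xyz-csv",
                  ".xyz": "xyz-csv", ".txt": "xyz-csv"}.get(suffix, "las")
    if format == "laz":
        raise CloudIOError("LAZ (compressed) input is not supported; decompress to LAS")
    if format == "las":
        cloud = _read_las(path)
    elif format == "xyz-csv":
        cloud = _read_xyz_csv(path)
    else:
        raise CloudIOError(f"unknown point-cloud format {format!r}")
    return cloud.drop_nonfinite()


def _read_xyz_csv(path: Path) -> PointCloud:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        has_header = not sample.splitlines()[0].replace(",", " ").replace(
            ".", "").replace("-", "").replace("e", "").replace(" ", "").isdigit()
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        raise CloudIOError(f"{path}: empty file")
    cols = {"x": 0, "y": 1, "z": 2}
    if has_header:
        header = [c.strip().lower() for c in rows[0]]
        for key in cols:
            if key in header:
                cols[key] = header.index(key)
        rows = rows[1:]
    if not rows:
        raise CloudIOError(f"{path}: zero points")
    data = np.array(
        [[float(r[cols["x"]]), float(r[cols["y"]]), float(r[cols["z"]])]
         for r in rows]
    )
    logger.info("read %d points from %s (xyz-csv)", len(data), path)
    return PointCloud(x=data[:, 0], y=data[:, 1], z=data[:, 2])


def write_point_cloud(cloud: PointCloud, path: str | Path, scale: float = 0.001) -> None:
    """Write ``las`` or ``xyz-csv`` depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() in (".csv", ".xyz", ".txt"):
        arr = cloud.xyz
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "z"])
            for row in arr:
                writer.writerow([f"{v:.4f}" for v in row])
    else:
        write_las(cloud, path, scale=scale)


def read_polygons(path: str | Path, format: str | None = None) -> list[VinePolygon]:
    """Read vine footprints from GeoJSON or a WKT CSV (columns vine_id, wkt)."""
    path = Path(path)
    if not path.exists():
        raise CloudIOError(f"{path}: no such file")
    if format is None:
        format = "geojson" if path.suffix.lower() in (".json", ".geojson") else "wkt-csv"
    polys: list[VinePolygon] = []
    if format == "geojson":
        data = json.loads(path.read_text())
        features = data.get("features", [])
        for i, feat in enumerate(features):
            vine_id = str(feat.get("properties", {}).get("vine_id", i))
            geom = shape(feat["geometry"])
            if geom.geom_type != "Polygon":
                raise PolygonValidationError(
                    f"polygon {vine_id!r}: geometry type {geom.geom_type}"
                )
            polys.append(
                VinePolygon(vine_id, np.asarray(geom.exterior.coords),
                            provenance="loaded")
            )
    elif format == "wkt-csv":
        from shapely import wkt as shapely_wkt

        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                geom = shapely_wkt.loads(row["wkt"])
                polys.append(
                    VinePolygon(str(row["vine_id"]),
                                np.asarray(geom.exterior.coords),
                                provenance="loaded")
                )
    else:
        raise CloudIOError(f"unknown polygon format {format!r}")
    return polys


def write_polygons(polys: list[VinePolygon], path: str | Path) -> None:
    """Write footprints as a GeoJSON FeatureCollection with vine_id properties."""
    features = []
    for p in polys:
        ring = np.vstack([p.ring, p.ring[:1]])
        features.append({
            "type": "Feature",
            "properties": {"vine_id": p.vine_id},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[round(float(x), 4), round(float(y), 4)]
                                 for x, y in ring]],
            },
        })
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

#: column order and printed precision for the per-vine metrics table
METRICS_COLUMNS = [
    ("vine_id", None), ("sensor", None),
    ("h_max", 3), ("h90", 3), ("h95", 3),
    ("area_m2", 2), ("volume_m3", 3),
    ("n_points", 0), ("n_canopy_points", 0),
]


def write_metrics_table(records: list[dict], path: str | Path,
                        columns: list[tuple[str, int | None]] | None = None) -> None:
    """Write records as CSV with deterministic column order and fixed precision.

    Heights print at 3 decimals, areas at 2, volumes at 3 (table-style
    precision); missing values print empty.
    """
    if columns is None:
        columns = METRICS_COLUMNS
    names = [c for c, _ in columns]
    extra = sorted({k for r in records for k in r} - set(names))
    names_all = names + extra
    prec = dict(columns)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(names_all)
        for rec in records:
            row = []
            for name in names_all:
                v = rec.get(name)
                p = prec.get(name)
                if v is None or (isinstance(v, float) and not np.isfinite(v)):
                    row.append("")
                elif p == 0:
                    row.append(str(int(v)))
                elif p is not None:
                    row.append(f"{v:.{p}f}")
                else:
                    row.append(str(v))
            writer.writerow(row)
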