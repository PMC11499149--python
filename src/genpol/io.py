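"""Raster containers and flat-binary I/O.

Rasters travel as flat binary payloads (band-sequential, little-endian)
with a JSON sidecar header at ``<path>.json`` declaring shape, dtype and
channel order.  This mirrors the header+payload dialect of the classic
PolSAR processing ecosystem without binding to any vendor product.

Conventions: row-major storage, 0-based indexing, pixel (0, 0) at the
top-left.  Invalid pixels carry NaN plus an explicit validity mask, so a
physically meaningful 0 (e.g. alpha = 0 deg for a flat surface) is never
confused with missing data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from genpol.exceptions import FormatError, ValidationError

logger = logging.getLogger("genpol")

_MAGIC = "genpol-raster"
_CHANNELS = ("shh", "shv", "svh", "svv")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ScatteringImage:
    """Per-pixel 2x2 complex Sinclair scattering matrix raster.

    Four complex channels (HH, HV, VH, VV) in linear amplitude units.
    Monostatic backscatter is assumed, so reciprocal images have
    ``svh == shv``; :meth:`reciprocal` enforces that by averaging.
    """

    shh: np.ndarray
    shv: np.ndarray
    svh: np.ndarray
    svv: np.ndarray
    date_tag: str = ""
    pixel_spacing: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        arrs = [np.asarray(getattr(self, c)) for c in _CHANNELS]
        shape = arrs[0].shape
        if len(shape) != 2:
            raise ValidationError(f"channels must be 2-D rasters, got shape {shape}")
        for name, a in zip(_CHANNELS, arrs):
            if a.shape != shape:
                raise ValidationError(
                    f"channel {name} has shape {a.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"channel {name} contains non-finite values")
            setattr(self, name, a.astype(np.complex128, copy=False))

    @property
    def rows(self) -> int:
        return self.shh.shape[0]

    @property
    def cols(self) -> int:
        return self.shh.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.shh.shape

    def reciprocal(self) -> "ScatteringImage":
        """Return a copy with the cross channels replaced by their mean."""
        hv = 0.5 * (self.shv + self.svh)
        return ScatteringImage(self.shh, hv, hv.copy(), self.svv,
                               date_tag=self.date_tag,
                               pixel_spacing=self.pixel_spacing)

    def scaled(self, factor: complex) -> "ScatteringImage":
        return ScatteringImage(self.shh * factor, self.shv * factor,
                               self.svh * factor, self.svv * factor,
                               date_tag=self.date_tag,
                               pixel_spacing=self.pixel_spacing)


@dataclass
class ParamRaster:
    """A named real-valued parameter raster with a validity mask."""

    values: np.ndarray
    name: str
    units: str = "degrees"
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("ParamRaster values must be 2-D")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValidationError("valid_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.valid_mask] = np.nan
        return out


@dataclass
class LabelMask:
    """Integer class raster (0 = unlabeled) with parcel structure.

    ``parcel_ids`` identifies contiguous field parcels (0 = no parcel) and
    ``split`` assigns each parcel to the training or verification set.  The
    two sets are parcel-disjoint by construction, mirroring a 50/50
    ground-truth split with no overlap.
    """

    labels: np.ndarray
    class_names: list[str]
    parcel_ids: np.ndarray | None = None
    split: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValidationError("labels must be a 2-D raster")
        k = len(self.class_names)
        mx = int(self.labels.max(initial=0))
        if mx > k:
            raise ValidationError(
                f"label {mx} exceeds class-table length {k}")
        if self.labels.min(initial=0) < 0:
            raise ValidationError("negative labels are not allowed")
        if self.parcel_ids is None:
            self.parcel_ids = np.zeros_like(self.labels)
        else:
            self.parcel_ids = np.asarray(self.parcel_ids, dtype=np.int32)
            if self.parcel_ids.shape != self.labels.shape:
                raise ValidationError("parcel_ids shape mismatch")
        bad = set(self.split.values()) - {"train", "verify"}
        if bad:
            raise ValidationError(f"unknown split tags: {sorted(bad)}")
        for name, n in zip(self.class_names,
                           np.bincount(self.labels.ravel(),
                                       minlength=k + 1)[1:]):
            logger.debug("class %s: %d labeled pixels", name, int(n))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def _split_mask(self, tag: str) -> np.ndarray:
        ids = [p for p, t in self.split.items() if t == tag]
        return np.isin(self.parcel_ids, ids) & (self.labels > 0)

    def train_mask(self) -> np.ndarray:
        return self._split_mask("train")

    def verify_mask(self) -> np.ndarray:
        return self._split_mask("verify")

    def class_mask(self, class_id: int, split: str | None = None) -> np.ndarray:
        m = self.labels == class_id
        if split is not None:
            m &= self._split_mask(split)
        return m


# ---------------------------------------------------------------------------
# flat-binary read / write
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def _write_payload(path: Path, bands: list[np.ndarray], header: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        for b in bands:
            fh.write(np.ascontiguousarray(b).tobytes())
    with open(_sidecar(path), "w") as fh:
        json.dump(header, fh, indent=1)


def _read_header(path: Path) -> dict:
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"missing sidecar header {side}")
    with open(side) as fh:
        header = json.load(fh)
    if header.get("magic") != _MAGIC:
        raise FormatError(f"{side}: not a genpol raster header")
    return header


def _read_payload(path: Path, header: dict, dtype: np.dtype,
                  n_bands: int) -> list[np.ndarray]:
    rows, cols = int(header["rows"]), int(header["cols"])
    expected = rows * cols * n_bands * dtype.itemsize
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing payload {path} (expected {expected} bytes)")
    raw = path.read_bytes()
    if len(raw) != expected:
        raise FormatError(
            f"{path}: payload holds {len(raw)} bytes but header "
            f"{rows}x{cols}x{n_bands} ({dtype}) requires {expected}")
    flat = np.frombuffer(raw, dtype=dtype)
    return [flat[i * rows * cols:(i + 1) * rows * cols].reshape(rows, cols)
            for i in range(n_bands)]


def write_scattering_image(img: ScatteringImage, path) -> None:
    """Write the four complex channels band-sequentially as complex64."""
    header = {
        "magic": _MAGIC, "kind": "scattering",
        "rows": img.rows, "cols": img.cols,
        "dtype": "complex64", "byteorder": "little",
        "interleave": "bsq", "channels": list(_CHANNELS),
        "date_tag": img.date_tag,
        "pixel_spacing": list(img.pixel_spacing) if img.pixel_spacing else None,
    }
    bands = [getattr(img, c).astype("<c8") for c in _CHANNELS]
    _write_payload(Path(path), bands, header)


def read_scattering_image(path) -> ScatteringImage:
    header = _read_header(Path(path))
    if header.get("kind") != "scattering":
        raise FormatError(f"{path}: header kind {header.get('kind')!r}, "
                          "expected 'scattering'")
    bands = _read_payload(Path(path), header, np.dtype("<c8"), 4)
    order = header.get("channels", list(_CHANNELS))
    if sorted(order) != sorted(_CHANNELS):
        raise FormatError(f"{path}: unknown channel order {order}")
    chans = dict(zip(order, bands))
    spacing = header.get("pixel_spacing")
    return ScatteringImage(
        chans["shh"], chans["shv"], chans["svh"], chans["svv"],
        date_tag=header.get("date_tag", ""),
        pixel_spacing=tuple(spacing) if spacing else None)


def write_param_raster(r: ParamRaster, path) -> None:
    """Bit-exact round trip of values (float32) and mask; NaN outside mask."""
    if not np.all(np.isfinite(r.values[r.valid_mask])):
        raise ValidationError("NaN/inf inside valid_mask")
    if not r.valid_mask.any():
        logger.warning("writing %s: raster has zero valid pixels", r.name)
    vals = r.values.astype("<f4")
    vals[~r.valid_mask] = np.nan
    header = {
        "magic": _MAGIC, "kind": "param",
        "rows": r.shape[0], "cols": r.shape[1],
        "dtype": "float32", "byteorder": "little",
        "name": r.name, "units": r.units,
    }
    _write_payload(Path(path), [vals], header)


def read_param_raster(path) -> ParamRaster:
    header = _read_header(Path(path))
    if header.get("kind") != "param":
        raise FormatError(f"{path}: header kind {header.get('kind')!r}, "
                          "expected 'param'")
    (vals,) = _read_payload(Path(path), header, np.dtype("<f4"), 1)
    vals = vals.astype(np.float64)
    return ParamRaster(vals, name=header.get("name", ""),
                       units=header.get("units", ""),
                       valid_mask=np.isfinite(vals))


def save_label_mask(mask: LabelMask, path) -> None:
    header = {
        "magic": _MAGIC, "kind": "labels",
        "rows": mask.shape[0], "cols": mask.shape[1],
        "dtype": "int32", "byteorder": "little",
        "class_names": mask.class_names,
        "split": {str(k): v for k, v in mask.split.items()},
    }
    bands = [mask.labels.astype("<i4"), mask.parcel_ids.astype("<i4")]
    _write_payload(Path(path), bands, header)


def load_label_mask(path) -> LabelMask:
    header = _read_header(Path(path))
    if header.get("kind") != "labels":
        raise FormatError(f"{path}: header kind {header.get('kind')!r}, "
                          "expected 'labels'")
    labels, parcels = _read_payload(Path(path), header, np.dtype("<i4"), 2)
    split = {int(k): v for k, v in header.get("split", {}).items()}
    mask = LabelMask(labels.astype(np.int32), list(header["class_names"]),
                     parcel_ids=parcels.astype(np.int32), split=split)
    train = {p for p, t in mask.split.items() if t == "train"}
    verify = {p for p, t in mask.split.items() if t == "verify"}
    if train & verify:
        raise ValidationError("train and verify parcel sets overlap")
    return mask


def validate_raster(path) -> dict:
    """Header/payload consistency check used by the CLI; returns the header."""
    header = _read_header(Path(path))
    kind = header.get("kind")
    dtypes = {"scattering": ("<c8", 4), "param": ("<f4", 1), "labels": ("<i4", 2)}
    if kind not in dtypes:
        raise FormatError(f"{path}: unknown raster kind {kind!r}")
    dt, nb = dtypes[kind]
    _read_payload(Path(path), header, np.dtype(dt), nb)
    return header
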