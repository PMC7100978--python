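"""Shared data model and standardized on-disk layout.

Every pipeline stage exchanges a :class:`MeasurementTable` — one row per
segmented nucleus with its centroid position, per-channel mean fluorescence,
and (once annotated) a clonal-marker gene dosage with a confidence.  Tables
are plain comma-separated text so that output from any external segmentation
platform with the mandatory columns (``cell_id``, ``x``, ``y``, and at least
one ``ch<i>`` intensity column) drops straight into the downstream stages.

On disk an experiment is organised as::

    experiment/
      disc_<i>/
        layer_<j>/
          image.tif          # multipage TIFF, one page per channel (optional)
          measurements.csv   # raw (and corrected) per-nucleus intensities
          annotation.csv     # measurements + dosage/confidence/border columns
          metadata.json      # channel roles, ROI polygon, model summaries

Coordinates are 0-based pixel indices with ``x`` = column and ``y`` = row
(origin top-left, raster convention).  Optional fields are encoded as empty
CSV fields and surface as pandas nullable values.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, GeometryError

MANDATORY_COLUMNS = ("cell_id", "x", "y")

_CH_RE = re.compile(r"^ch(\d+)$")
_CH_CORR_RE = re.compile(r"^ch(\d+)_corrected$")

CHANNEL_ROLES = ("nuclear_stain", "clonal_marker", "reporter")


def channel_column(channel: int) -> str:
    return f"ch{channel}"


def corrected_column(channel: int) -> str:
    return f"ch{channel}_corrected"


@dataclass
class MeasurementTable:
    """Per-nucleus measurement records backed by a pandas DataFrame.

    Columns
    -------
    cell_id : int64, unique
    x, y : float64 centroid position in pixels
    ch<i> : float64 mean raw intensity of channel ``i`` (>= 0)
    ch<i>_corrected : float64, optional background-subtracted intensity
    dosage : nullable Int64 in {0, 1, 2}
    confidence : float64 in [0, 1] (NaN when unset)
    border : nullable boolean
    """

    data: pd.DataFrame

    def __post_init__(self):
        self.data = _coerce_schema(self.data)
        self.validate()

    # -- schema ----------------------------------------------------------

    @property
    def channels(self) -> list[int]:
        """Channel indices with a raw-intensity column, ascending."""
        return sorted(
            int(m.group(1)) for c in self.data.columns if (m := _CH_RE.match(c))
        )

    @property
    def corrected_channels(self) -> list[int]:
        return sorted(
            int(m.group(1))
            for c in self.data.columns
            if (m := _CH_CORR_RE.match(c))
        )

    def __len__(self) -> int:
        return len(self.data)

    def raw_level(self, channel: int) -> np.ndarray:
        col = channel_column(channel)
        if col not in self.data.columns:
            raise SchemaError(f"missing channel column '{col}'")
        return self.data[col].to_numpy(dtype=float)

    def corrected_level(self, channel: int) -> np.ndarray:
        col = corrected_column(channel)
        if col not in self.data.columns:
            raise SchemaError(f"missing corrected channel column '{col}'")
        return self.data[col].to_numpy(dtype=float)

    def level(self, channel: int) -> np.ndarray:
        """Corrected level if available for ``channel``, else the raw level."""
        if channel in self.corrected_channels:
            return self.corrected_level(channel)
        return self.raw_level(channel)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) centroids."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def dosages(self) -> np.ndarray:
        """Float array of dosages with NaN where unset."""
        return self.data["dosage"].to_numpy(dtype=float, na_value=np.nan)

    def validate(self) -> None:
        for col in MANDATORY_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"missing mandatory column '{col}'")
        if not self.channels:
            raise SchemaError("table has no channel column (expected 'ch<i>')")
        ids = self.data["cell_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise IntegrityError(
                f"duplicate cell_id values: {sorted(set(dup.tolist()))}"
            )
        for c in self.channels:
            col = channel_column(c)
            vals = self.data[col].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise IntegrityError(f"negative raw intensity in column '{col}'")
        conf = self.data["confidence"]
        labeled = self.data["dosage"].notna()
        bad = labeled & (conf.isna() | (conf < 0) | (conf > 1))
        if bad.any():
            raise IntegrityError(
                "confidence must lie in [0, 1] wherever dosage is set"
            )

    def copy(self) -> "MeasurementTable":
        return MeasurementTable(self.data.copy())

    def equals(self, other: "MeasurementTable") -> bool:
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if sorted(a.columns) != sorted(b.columns):
            return False
        return a[sorted(a.columns)].equals(b[sorted(b.columns)])


def _coerce_schema(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "cell_id" in df.columns:
        df["cell_id"] = df["cell_id"].astype("int64", errors="ignore")
    for col in df.columns:
        if col in ("x", "y", "confidence") or _CH_RE.match(col) or _CH_CORR_RE.match(col):
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("float64")
    if "dosage" not in df.columns:
        df["dosage"] = pd.array([pd.NA] * len(df), dtype="Int64")
    else:
        df["dosage"] = pd.array(
            pd.to_numeric(df["dosage"], errors="coerce").round(), dtype="Int64"
        )
    if "confidence" not in df.columns:
        df["confidence"] = np.full(len(df), np.nan)
    if "border" not in df.columns:
        df["border"] = pd.array([pd.NA] * len(df), dtype="boolean")
    else:
        df["border"] = _parse_boolean(df["border"])
    return df


def _parse_boolean(col: pd.Series) -> pd.array:
    def one(v):
        if pd.isna(v) or v == "":
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in ("true", "1", "1.0"):
            return True
        if s in ("false", "0", "0.0"):
            return False
        return pd.NA

    return pd.array([one(v) for v in col], dtype="boolean")


def read_measurements(path) -> MeasurementTable:
    """Read a delimited-text measurement table.

    Raises
    ------
    SchemaError
        If a mandatory column (cell_id, x, y, or any channel) is absent.
    IntegrityError
        On duplicated cell ids or negative raw intensities.
    """
    df = pd.read_csv(path, sep=",")
    return MeasurementTable(df)


def write_measurements(table: MeasurementTable, path) -> Path:
    """Write the table as comma-separated UTF-8 text (empty field = unset).

    The output is bitwise stable for identical input and round-trips through
    :func:`read_measurements` without loss.
    """
    path = Path(path)
    df = table.data.copy()
    # stable column order: mandatory, raw channels, corrected, annotations
    cols = list(MANDATORY_COLUMNS)
    cols += [channel_column(c) for c in table.channels]
    cols += [corrected_column(c) for c in table.corrected_channels]
    cols += ["dosage", "confidence", "border"]
    extras = [c for c in df.columns if c not in cols]
    df = df[cols + extras]
    df.to_csv(path, sep=",", index=False, na_rep="", encoding="utf-8")
    return path


# -- layer metadata ------------------------------------------------------


@dataclass
class LayerRecord:
    """Identity and channel-role metadata for one image layer.

    Exactly one channel must be designated ``clonal_marker``.  The optional
    region of interest is a simple polygon given as (x, y) vertices in pixel
    coordinates.
    """

    disc_id: str
    layer_id: str
    channel_roles: Mapping[int, str] = field(default_factory=dict)
    image_path: str | None = None
    roi: Sequence[tuple[float, float]] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channel_roles = {int(k): str(v) for k, v in self.channel_roles.items()}
        for role in self.channel_roles.values():
            if role not in CHANNEL_ROLES:
                raise SchemaError(f"unknown channel role '{role}'")
        markers = [c for c, r in self.channel_roles.items() if r == "clonal_marker"]
        if len(markers) != 1:
            raise SchemaError(
                "exactly one channel must be designated clonal_marker "
                f"(got {len(markers)})"
            )
        if self.roi is not None:
            self.roi = [(float(x), float(y)) for x, y in self.roi]
            _require_simple_polygon(self.roi)

    @property
    def clonal_marker(self) -> int:
        return next(
            c for c, r in self.channel_roles.items() if r == "clonal_marker"
        )

    @property
    def nuclear_stain(self) -> int | None:
        for c, r in self.channel_roles.items():
            if r == "nuclear_stain":
                return c
        return None

    def save(self, layer_dir) -> Path:
        layer_dir = Path(layer_dir)
        layer_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "disc_id": self.disc_id,
            "layer_id": self.layer_id,
            "channel_roles": {str(k): v for k, v in self.channel_roles.items()},
            "image_path": self.image_path,
            "roi": [list(v) for v in self.roi] if self.roi is not None else None,
            "extra": self.extra,
        }
        out = layer_dir / "metadata.json"
        out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return out

    @classmethod
    def load(cls, layer_dir) -> "LayerRecord":
        payload = json.loads((Path(layer_dir) / "metadata.json").read_text())
        return cls(
            disc_id=payload["disc_id"],
            layer_id=payload["layer_id"],
            channel_roles={int(k): v for k, v in payload["channel_roles"].items()},
            image_path=payload.get("image_path"),
            roi=payload.get("roi"),
            extra=payload.get("extra", {}),
        )


def _require_simple_polygon(vertices) -> None:
    from shapely.geometry import Polygon

    if len(vertices) < 3:
        raise GeometryError("ROI polygon needs at least 3 vertices")
    if not Polygon(vertices).is_valid:
        raise GeometryError("ROI polygon is self-intersecting")


def layer_dir(experiment_dir, disc: int | str, layer: int | str) -> Path:
    """Path of one layer directory under the standardized layout."""
    return Path(experiment_dir) / f"disc_{disc}" / f"layer_{layer}"
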