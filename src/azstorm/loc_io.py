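"""Localization-table and ROI input/output, filtering, and image rendering.

The universal currency of the pipeline is the :class:`LocalizationTable`:
one row per fitted single-molecule emitter, with planar coordinates in
nanometres, the camera frame index the fit came from, and the fitted
intensity in camera A/D counts.  Tables arrive either as rapidSTORM-style
whitespace text (header comment naming the columns) or as generic CSV with
named columns; both dialects round-trip losslessly through
:func:`write_localizations` / :func:`read_localizations`.

Conventions: coordinates are in nm with the origin at the top-left of the
camera field and y increasing downward; histogram bins are half-open
``[lo, hi)``; ROI boundary points count as inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "LocalizationTable",
    "RoiSet",
    "ImageSummary",
    "FormatError",
    "read_localizations",
    "write_localizations",
    "read_rois",
    "write_rois",
    "filter_min_intensity",
    "crop_to_rois",
    "render_binned_image",
    "write_binned_tiff",
    "image_summary",
]

MANDATORY_COLUMNS = ("x", "y", "frame", "intensity")

#: rapidSTORM header identifiers -> canonical column names
RAPIDSTORM_FIELDS = {
    "Position-0-0": "x",
    "Position-1-0": "y",
    "ImageNumber-0-0": "frame",
    "Amplitude-0-0": "intensity",
}
_RAPIDSTORM_INVERSE = {v: k for k, v in RAPIDSTORM_FIELDS.items()}


class FormatError(ValueError):
    """Raised when a localization or ROI file violates its dialect."""


@dataclass
class LocalizationTable:
    """Frame-resolved 2D localizations with intensities.

    Parameters
    ----------
    data:
        DataFrame with at least columns ``x``, ``y`` (nm), ``frame``
        (0-based integer) and ``intensity`` (A/D counts).  Extra columns
        are carried along untouched.
    n_frames:
        Total number of acquisition frames (default 15000, a standard
        dSTORM movie length).
    source_id:
        Label of the image/specimen the table came from.
    """

    data: pd.DataFrame
    n_frames: int = 15000
    source_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        self.data = self.data.reset_index(drop=True)
        xy = self.data[["x", "y"]].to_numpy(float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError("non-finite coordinates in localization table")
        frames = self.data["frame"].to_numpy()
        if frames.size:
            if frames.min() < 0 or frames.max() >= self.n_frames:
                raise ValueError(
                    f"frame indices must lie in [0, {self.n_frames}); "
                    f"got range [{frames.min()}, {frames.max()}]"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of coordinates in nm."""
        return self.data[["x", "y"]].to_numpy(float)

    def select(self, mask_or_indices) -> "LocalizationTable":
        """Row subset preserving order and metadata."""
        sub = self.data.loc[mask_or_indices] if np.asarray(mask_or_indices).dtype == bool \
            else self.data.iloc[np.asarray(mask_or_indices)]
        return replace(self, data=sub.reset_index(drop=True))

    def sort_by_frame(self) -> "LocalizationTable":
        return replace(self, data=self.data.sort_values("frame", kind="stable").reset_index(drop=True))


@dataclass
class RoiSet:
    """A set of polygonal regions of interest, in nm.

    At most ``max_count`` polygons per image (default 6, one per analysed
    presynaptic bouton).  Each polygon must be simple with >= 3 vertices.
    """

    polygons: list[Polygon] = field(default_factory=list)
    max_count: int = 6

    def __post_init__(self) -> None:
        polys = []
        for p in self.polygons:
            poly = p if isinstance(p, Polygon) else Polygon(p)
            if len(poly.exterior.coords) - 1 < 3:
                raise ValueError("ROI polygon needs at least 3 vertices")
            if not poly.is_valid:
                raise ValueError("ROI polygon is self-intersecting or invalid")
            polys.append(poly)
        if len(polys) > self.max_count:
            raise ValueError(
                f"{len(polys)} ROI polygons exceed the maximum of {self.max_count}"
            )
        self.polygons = polys

    def __len__(self) -> int:
        return len(self.polygons)


@dataclass(frozen=True)
class ImageSummary:
    """Per-image summary of an (already filtered and cropped) table."""

    n_localizations: int
    mean_brightness: float  # A/D counts; NaN when the table is empty
    locs_per_100_frames: float


def read_localizations(path, dialect: str = "generic-csv",
                       n_frames: int = 15000, source_id: str | None = None) -> LocalizationTable:
    """Read a localization table from disk.

    ``dialect`` is ``"rapidstorm-txt"`` (whitespace-separated values, first
    line a ``#`` comment listing rapidSTORM field identifiers) or
    ``"generic-csv"`` (comma-separated with a header naming at least
    x/x_nm, y/y_nm, frame and intensity).  Unknown columns are preserved.
    """
    path = Path(path)
    if source_id is None:
        source_id = path.stem
    if dialect == "rapidstorm-txt":
        with open(path) as fh:
            header = fh.readline()
        if not header.startswith("#"):
            raise FormatError("rapidstorm-txt requires a '#' header line")
        names = header.lstrip("#").split()
        columns = [RAPIDSTORM_FIELDS.get(tok, tok) for tok in names]
        df = pd.read_csv(path, sep=r"\s+", comment=None, skiprows=1,
                         header=None, names=columns,
                         float_precision="round_trip")
    elif dialect == "generic-csv":
        df = pd.read_csv(path, float_precision="round_trip")
        df = df.rename(columns={"x_nm": "x", "y_nm": "y"})
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'rapidstorm-txt' or 'generic-csv'")

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory column(s): {', '.join(missing)}")
    for col in MANDATORY_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            line = int(bad.idxmax()) + 2 if bad.any() else -1  # +2: header + 1-based
            raise FormatError(f"{path.name}: non-numeric value in column {col!r} "
                              f"near line {line}") from exc
    df["frame"] = df["frame"].astype(int)
    return LocalizationTable(df, n_frames=n_frames, source_id=source_id)


def write_localizations(table: LocalizationTable, path, dialect: str = "generic-csv") -> None:
    """Write a table in one of the supported dialects.

    Floats are written with ``repr`` round-trip precision so that
    write -> read reproduces every value bit-identically.
    """
    path = Path(path)
    df = table.data
    # shortest float representation that round-trips exactly
    def fmt(v):
        return repr(float(v))
    if dialect == "rapidstorm-txt":
        names = [_RAPIDSTORM_INVERSE.get(c, c) for c in df.columns]
        with open(path, "w") as fh:
            fh.write("# " + " ".join(names) + "\n")
            df.to_csv(fh, sep=" ", header=False, index=False, float_format=fmt)
    elif dialect == "generic-csv":
        df.to_csv(path, index=False, float_format=fmt)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_rois(path, max_count: int = 6) -> RoiSet:
    """Read ROI polygons from CSV: blocks of ``x,y`` vertex lines (nm),
    blank line or a line starting with ``#`` separating polygons."""
    blocks: list[list[tuple[float, float]]] = [[]]
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                if blocks[-1]:
                    blocks.append([])
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise FormatError(f"ROI vertex line needs x,y: {line!r}")
            blocks[-1].append((float(parts[0]), float(parts[1])))
    polygons = [Polygon(b) for b in blocks if b]
    return RoiSet(polygons, max_count=max_count)


def write_rois(rois: RoiSet, path) -> None:
    with open(path, "w") as fh:
        for i, poly in enumerate(rois.polygons):
            fh.write(f"# polygon {i}\n")
            for x, y in list(poly.exterior.coords)[:-1]:
                fh.write(f"{x!r},{y!r}\n")


def filter_min_intensity(table: LocalizationTable, min_adc: float) -> LocalizationTable:
    """Keep localizations with intensity >= ``min_adc`` (inclusive), order preserved.

    The per-dye defaults of the imaging protocol are 3000 A/D for AF647
    and 1000 A/D for CF568/CF583R.
    """
    if min_adc < 0:
        raise ValueError("min_adc must be >= 0")
    mask = table.data["intensity"].to_numpy() >= min_adc
    return replace(table, data=table.data[mask].reset_index(drop=True))


def crop_to_rois(table: LocalizationTable, rois: RoiSet) -> LocalizationTable:
    """Keep localizations inside the union of ROI polygons (boundary inclusive)."""
    if not rois.polygons:
        return replace(table, data=table.data.iloc[0:0].reset_index(drop=True))
    import shapely

    points = shapely.points(table.xy)
    mask = np.zeros(len(table), dtype=bool)
    for poly in rois.polygons:
        # covers(): boundary points count as inside
        mask |= shapely.covers(poly, points)
    return replace(table, data=table.data[mask].reset_index(drop=True))


def render_binned_image(table: LocalizationTable, pixel_size_nm: float = 10.0,
                        shape: tuple[int, int] | None = None) -> np.ndarray:
    """2D localization-count image with half-open square bins.

    Pixel ``(i, j)`` counts localizations with ``y in [i*p, (i+1)*p)`` and
    ``x in [j*p, (j+1)*p)``.  The image sum always equals the number of
    localizations.  ``shape`` fixes the output dimensions (rows, cols);
    otherwise the image is sized to cover all points.  An empty table with
    no ``shape`` yields a 0x0 image.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    xy = table.xy
    if shape is None:
        if len(xy) == 0:
            return np.zeros((0, 0), dtype=np.uint16)
        n_rows = int(math.floor(xy[:, 1].max() / pixel_size_nm)) + 1
        n_cols = int(math.floor(xy[:, 0].max() / pixel_size_nm)) + 1
    else:
        n_rows, n_cols = shape
    img = np.zeros((n_rows, n_cols), dtype=np.int64)
    if len(xy):
        rows = np.floor(xy[:, 1] / pixel_size_nm).astype(int)
        cols = np.floor(xy[:, 0] / pixel_size_nm).astype(int)
        ok = (rows >= 0) & (rows < n_rows) & (cols >= 0) & (cols < n_cols)
        np.add.at(img, (rows[ok], cols[ok]), 1)
    return img


def write_binned_tiff(image: np.ndarray, path) -> None:
    """Write a count image as 16-bit TIFF (counts clipped at 65535)."""
    import tifffile

    tifffile.imwrite(path, np.clip(image, 0, 65535).astype(np.uint16))


def image_summary(table: LocalizationTable) -> ImageSummary:
    """Mean brightness and localization yield for one (cropped, filtered) image."""
    n = len(table)
    mean_brightness = float(table.data["intensity"].mean()) if n else float("nan")
    return ImageSummary(
        n_localizations=n,
        mean_brightness=mean_brightness,
        locs_per_100_frames=n / table.n_frames * 100.0,
    )
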