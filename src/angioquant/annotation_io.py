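"""Reading, calibrating, resampling and color-splitting vessel annotation images.

Annotation images are histologic scans on which every vessel cross section
has been painted by hand in one of three reserved colors: the central artery
in red, the central vein in blue and every other vessel (including de novo
capillaries) in green, on an otherwise neutral background.  This module turns
such a raster plus a physical pixel scale into per-vessel-class binary masks,
and serializes the downstream tabular results.

Coordinate convention: the origin is the center of the top-left pixel, x runs
rightward (columns), y downward (rows).  All geometry downstream of
calibration is expressed in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ColorAmbiguityError

#: Background color assumed when padding non-square images to a square canvas.
BACKGROUND_COLOR = (255, 255, 255)

VESSEL_TABLE_COLUMNS = [
    "id",
    "vessel_type",
    "centroid_x_um",
    "centroid_y_um",
    "area_um2",
    "major_axis_um",
    "minor_axis_um",
    "pixel_count",
    "is_central",
]

SAMPLE_METRIC_COLUMNS = [
    "sample_id",
    "total_vessel_count",
    "total_perfused_area_mm2",
    "vessel_density_per_mm2",
    "mean_ingrowth_distance_um",
    "mean_diameter_um",
]


@dataclass
class CalibratedImage:
    """An RGB raster with an isotropic physical pixel scale.

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` uint8 array of RGB triplets.
    scale
        Micrometres per pixel (one value; pixels are assumed square).
    """

    pixels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"pixels must have shape (H, W, 3), got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit per channel (uint8)")
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_um(self) -> float:
        return self.width_px * self.scale

    @property
    def height_um(self) -> float:
        return self.height_px * self.scale


@dataclass(frozen=True)
class ColorConvention:
    """The three reserved annotation colors and the per-channel match tolerance.

    Defaults are pure red / blue / green with a tolerance of 40 per channel,
    wide enough to absorb mild anti-aliasing or JPEG-era color drift while
    keeping the three classes unambiguous.
    """

    artery_color: tuple[int, int, int] = (255, 0, 0)
    vein_color: tuple[int, int, int] = (0, 0, 255)
    capillary_color: tuple[int, int, int] = (0, 255, 0)
    tolerance: int = 40

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        refs = [self.artery_color, self.vein_color, self.capillary_color]
        for i in range(3):
            for j in range(i + 1, 3):
                dist = max(abs(a - b) for a, b in zip(refs[i], refs[j]))
                if dist <= 2 * self.tolerance:
                    raise ValueError(
                        "reference colors must be pairwise distinct beyond "
                        f"2x tolerance; {refs[i]} vs {refs[j]} differ by {dist}"
                    )

    @property
    def reference_colors(self) -> dict[str, tuple[int, int, int]]:
        return {
            "artery": self.artery_color,
            "vein": self.vein_color,
            "capillary": self.capillary_color,
        }


@dataclass
class ChannelMasks:
    """Per-vessel-class binary masks produced by :func:`color_split`.

    Masks are pairwise disjoint and share the source image's dimensions and
    physical scale.
    """

    artery_mask: np.ndarray
    vein_mask: np.ndarray
    capillary_mask: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        shapes = {
            self.artery_mask.shape,
            self.vein_mask.shape,
            self.capillary_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"masks must share one shape, got {shapes}")
        overlap = (
            self.artery_mask.astype(np.uint8)
            + self.vein_mask.astype(np.uint8)
            + self.capillary_mask.astype(np.uint8)
        )
        if (overlap > 1).any():
            raise ValueError("masks must be pairwise disjoint")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.artery_mask.shape

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "artery": self.artery_mask,
            "vein": self.vein_mask,
            "capillary": self.capillary_mask,
        }


def read_annotation_image(path: str | Path, scale: float) -> CalibratedImage:
    """Read a PNG/TIFF annotation raster and attach its physical calibration.

    An alpha channel, if present, is discarded.  ``scale`` is micrometres per
    pixel (e.g. 0.644 for a native 200x scan).
    """
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            if img.mode != "RGB":
                # drops alpha / expands palettes; annotation colors survive
                img = img.convert("RGB")
            pixels = np.asarray(img, dtype=np.uint8)
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read annotation image {path}: {exc}") from exc
    return CalibratedImage(pixels=pixels, scale=float(scale))


def write_annotation_image(image: CalibratedImage, path: str | Path) -> None:
    """Write an annotation raster as PNG/TIFF (format inferred from suffix)."""
    Image.fromarray(image.pixels, mode="RGB").save(Path(path))


def resample(image: CalibratedImage, target_px: int) -> CalibratedImage:
    """Resample to a ``target_px`` x ``target_px`` square, preserving extent.

    Nearest-neighbor interpolation only, so the output color set is a subset
    of the input's and class labels are never corrupted by blending.  The
    scale is multiplied by ``max(width, height) / target_px`` so the physical
    extent of the larger dimension is unchanged.  Non-square inputs keep their
    aspect ratio and are padded with the background color to the square.
    """
    if target_px < 1:
        raise ValueError("target_px must be >= 1")
    h, w = image.height_px, image.width_px
    if h == w == target_px:
        return image
    factor = max(h, w) / target_px
    new_h = min(target_px, max(1, round(h / factor)))
    new_w = min(target_px, max(1, round(w / factor)))
    rows = np.minimum(np.floor((np.arange(new_h) + 0.5) * factor).astype(int), h - 1)
    cols = np.minimum(np.floor((np.arange(new_w) + 0.5) * factor).astype(int), w - 1)
    resampled = image.pixels[rows][:, cols]
    if (new_h, new_w) != (target_px, target_px):
        canvas = np.full((target_px, target_px, 3), BACKGROUND_COLOR, dtype=np.uint8)
        canvas[:new_h, :new_w] = resampled
        resampled = canvas
    return CalibratedImage(pixels=resampled, scale=image.scale * factor)


def color_split(
    image: CalibratedImage, convention: ColorConvention | None = None
) -> ChannelMasks:
    """Split a tricolor annotation raster into per-vessel-class binary masks.

    A pixel belongs to a class when every channel lies within
    ``convention.tolerance`` of that class's reference color; all other
    pixels are background.  A pixel matching two classes at once indicates a
    misconfigured tolerance and raises :class:`ColorAmbiguityError`.
    """
    convention = convention or ColorConvention()
    px = image.pixels.astype(np.int16)
    masks = {}
    for name, ref in convention.reference_colors.items():
        masks[name] = np.all(
            np.abs(px - np.asarray(ref, dtype=np.int16)) <= convention.tolerance,
            axis=-1,
        )
    membership = sum(m.astype(np.uint8) for m in masks.values())
    if (membership > 1).any():
        n_bad = int((membership > 1).sum())
        raise ColorAmbiguityError(
            f"{n_bad} pixel(s) match two reference colors; reduce the "
            f"tolerance (currently {convention.tolerance}) or separate the "
            "reference colors"
        )
    return ChannelMasks(
        artery_mask=masks["artery"],
        vein_mask=masks["vein"],
        capillary_mask=masks["capillary"],
        scale=image.scale,
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_vessel_table(table, path: str | Path) -> None:
    """Write one CSV row per detected vessel mark (RFC-4180, UTF-8).

    Pixel footprints are not serialized; the CSV stores the measured
    geometry only.  Central artery/vein are flagged in the ``is_central``
    column.
    """
    rows = []
    central_ids = {
        m.id for m in (table.central_artery, table.central_vein) if m is not None
    }
    for mark in table.marks:
        rows.append(
            {
                "id": mark.id,
                "vessel_type": mark.vessel_type,
                "centroid_x_um": mark.centroid[0],
                "centroid_y_um": mark.centroid[1],
                "area_um2": mark.area,
                "major_axis_um": mark.major_axis,
                "minor_axis_um": mark.minor_axis,
                "pixel_count": mark.pixel_count,
                "is_central": mark.id in central_ids,
            }
        )
    df = pd.DataFrame(rows, columns=VESSEL_TABLE_COLUMNS)
    df.to_csv(Path(path), index=False)


def read_vessel_table(path: str | Path, sample_id: str = "", scale: float = 1.0):
    """Read a vessel table CSV back into a :class:`~angioquant.vessel_detection.VesselTable`.

    The round trip is lossless for the measured geometry; pixel footprints
    are not restored (``pixels`` is ``None`` on every mark).
    """
    from .vessel_detection import VesselMark, VesselTable

    df = pd.read_csv(Path(path))
    marks = []
    central_artery = central_vein = None
    for _, row in df.iterrows():
        mark = VesselMark(
            id=int(row["id"]),
            vessel_type=str(row["vessel_type"]),
            centroid=(float(row["centroid_x_um"]), float(row["centroid_y_um"])),
            area=float(row["area_um2"]),
            major_axis=float(row["major_axis_um"]),
            minor_axis=float(row["minor_axis_um"]),
            pixel_count=int(row["pixel_count"]),
        )
        marks.append(mark)
        if bool(row["is_central"]) and mark.vessel_type == "artery":
            central_artery = mark
        elif bool(row["is_central"]) and mark.vessel_type == "vein":
            central_vein = mark
    return VesselTable(
        sample_id=sample_id,
        marks=marks,
        central_artery=central_artery,
        central_vein=central_vein,
        scale=scale,
    )


def write_sample_metrics(metrics, path: str | Path) -> None:
    """Write a one-row CSV with the five per-sample read-out parameters."""
    row = {
        "sample_id": metrics.sample_id,
        "total_vessel_count": metrics.total_vessel_count,
        "total_perfused_area_mm2": metrics.total_perfused_area,
        "vessel_density_per_mm2": metrics.vessel_density,
        "mean_ingrowth_distance_um": metrics.mean_ingrowth_distance,
        "mean_diameter_um": metrics.mean_diameter,
    }
    pd.DataFrame([row], columns=SAMPLE_METRIC_COLUMNS).to_csv(Path(path), index=False)


def write_study_summary(summary, path: str | Path) -> None:
    """Serialize a study summary (group stats + ANOVA + post hoc) to JSON."""
    payload = summary.to_dict() if hasattr(summary, "to_dict") else summary
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_metrics(metrics, path: str | Path) -> None:
    """Dispatch: per-sample metrics go to CSV, study summaries to JSON."""
    if hasattr(metrics, "to_dict"):
        write_study_summary(metrics, path)
    else:
        write_sample_metrics(metrics, path)


def write_histogram(centers: np.ndarray, heights: np.ndarray, path: str | Path) -> None:
    """Write a histogram as a two-column CSV (bin_center, height)."""
    pd.DataFrame({"bin_center": centers, "height": heights}).to_csv(
        Path(path), index=False
    )
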