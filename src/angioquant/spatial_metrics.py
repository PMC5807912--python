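"""The five per-sample read-out parameters of the spatial angiogenesis assay.

1. Total vessel count — number of vessel cross sections excluding the
   central artery and vein.
2. Total perfused area — area of the union of all marks dilated by a fixed
   radius (default 150 um), approximating the tissue reachable by oxygen
   diffusion; overlaps are counted once.
3. Perfused-area vessel density — count / perfused area (vessels per mm^2).
4. Vessel ingrowth distance — Euclidean distance from each counted vessel's
   centroid to the central vein's centroid, a proxy for penetration depth
   into the scaffold.
5. Vessel diameter — the minor axis of the mark's moment-equivalent ellipse,
   wall included.

The dilated union is computed on the raster: the union of the marks' pixel
footprints is distance-transformed and every pixel whose Euclidean distance
to the nearest mark pixel is at most the perfusion radius counts as
perfused.  This expands the actual painted shape, not an equivalent disk,
and handles overlapping halos exactly (single counting is inherent to the
union).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.transform import resize

from .vessel_detection import VesselMark, VesselTable
from .errors import MissingReferenceError

#: Virtual oxygen perfusion radius in micrometres.
DEFAULT_PERFUSION_RADIUS = 150.0


@dataclass
class HistogramSpec:
    """Binning/normalization recipe for diameter and ingrowth histograms.

    ``normalized`` divides bin counts by the in-range total so heights sum
    to one (a fraction of the total vessel count); ``smoothing_window``
    applies a centered moving average of that many bins after
    normalization (0 disables smoothing; otherwise must be odd).
    """

    bin_width: float
    range: tuple[float, float]
    normalized: bool = False
    smoothing_window: int = 0

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        lo, hi = self.range
        if not hi > lo:
            raise ValueError("histogram range must be increasing")
        if self.smoothing_window != 0 and self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd or 0")

    @property
    def edges(self) -> np.ndarray:
        lo, hi = self.range
        n_bins = max(1, math.ceil((hi - lo) / self.bin_width - 1e-9))
        return lo + np.arange(n_bins + 1) * self.bin_width


@dataclass
class SampleMetrics:
    """The five read-out parameters for one sample.

    ``ingrowth_distances`` and ``diameters`` carry one value per counted
    vessel (capillary class); the central artery's distance to the vein is
    kept separately and never pooled.  When the sample has no identifiable
    central vein, ``vein_present`` is False and the distance list is empty.
    """

    sample_id: str
    total_vessel_count: int
    total_perfused_area: float  # mm^2
    vessel_density: float  # vessels / mm^2
    ingrowth_distances: list[float] = field(default_factory=list)  # um
    diameters: list[float] = field(default_factory=list)  # um
    perfusion_radius: float = DEFAULT_PERFUSION_RADIUS  # um
    central_artery_distance: float | None = None  # um
    vein_present: bool = True

    @property
    def mean_ingrowth_distance(self) -> float:
        return float(np.mean(self.ingrowth_distances)) if self.ingrowth_distances else float("nan")

    @property
    def mean_diameter(self) -> float:
        return float(np.mean(self.diameters)) if self.diameters else float("nan")


def total_vessel_count(table: VesselTable) -> int:
    """Number of capillary-class marks; the central artery/vein never count."""
    return len(table.capillaries)


def dilated_union_area(mask: np.ndarray, scale: float, radius: float) -> float:
    """Area (um^2) of the union of mask pixels dilated by a Euclidean disk.

    The canvas is padded by the dilation radius so halos extending past the
    image border are not clipped.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    if not mask.any():
        return 0.0
    r_px = radius / scale
    pad = int(math.ceil(r_px)) + 1
    padded = np.pad(mask, pad)
    dist = distance_transform_edt(~padded)
    return float(np.count_nonzero(dist <= r_px) * scale**2)


def perfused_area(
    table: VesselTable,
    radius: float = DEFAULT_PERFUSION_RADIUS,
    raster_scale: float | None = None,
    include_central: bool = True,
) -> float:
    """Total virtually perfused area of one sample, in mm^2.

    Every mark's pixel footprint is expanded by ``radius`` micrometres and
    the union area is measured by pixel counting at ``raster_scale``
    (default: the table's own detection scale).  ``include_central``
    controls whether the central artery/vein halos join the union (they do
    by default; the count never includes them either way).
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    if raster_scale is not None and not raster_scale > 0:
        raise ValueError("raster_scale must be positive")
    marks = list(table.marks)
    if not include_central:
        central = {id(table.central_artery), id(table.central_vein)}
        marks = [m for m in marks if id(m) not in central]
    marks = [m for m in marks if m.pixels is not None and len(m.pixels)]
    if not marks:
        return 0.0
    if table.image_shape is not None:
        shape = table.image_shape
    else:
        all_px = np.vstack([m.pixels for m in marks])
        shape = (int(all_px[:, 0].max()) + 1, int(all_px[:, 1].max()) + 1)
    canvas = np.zeros(shape, dtype=bool)
    for m in marks:
        canvas[m.pixels[:, 0], m.pixels[:, 1]] = True
    scale = table.scale
    if raster_scale is not None and not math.isclose(raster_scale, scale):
        zoom = scale / raster_scale
        out_shape = (max(1, round(shape[0] * zoom)), max(1, round(shape[1] * zoom)))
        canvas = resize(canvas, out_shape, order=0, anti_aliasing=False)
        scale = raster_scale
    return dilated_union_area(canvas, scale, radius) / 1e6


def vessel_density(count: int, area_mm2: float) -> float:
    """Vessels per mm^2 of virtually perfused tissue.

    An empty sample (count 0, area 0) has density 0 by convention; a
    positive count with zero area is an impossible state (every counted
    vessel contributes a dilated footprint to the union).
    """
    if area_mm2 == 0:
        if count == 0:
            return 0.0
        raise ValueError(
            f"impossible state: {count} vessels but zero perfused area"
        )
    return count / area_mm2


def ingrowth_distance(mark: VesselMark, vein: VesselMark | None) -> float:
    """Euclidean centroid distance (um) from a mark to the central vein."""
    if vein is None:
        raise MissingReferenceError(
            "no central vein available to measure ingrowth distance against"
        )
    dx = mark.centroid[0] - vein.centroid[0]
    dy = mark.centroid[1] - vein.centroid[1]
    return math.hypot(dx, dy)


def diameter(mark: VesselMark) -> float:
    """Vessel diameter: the minor axis of the mark's equivalent ellipse (um)."""
    return mark.minor_axis


def histogram(
    values, spec: HistogramSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Bin values per ``spec``; returns (bin_centers, heights).

    Normalization divides by the number of in-range values, so non-empty
    input yields heights summing to one.  Smoothing is a centered moving
    average applied after normalization, with zero-padding at the edges.
    """
    values = np.asarray(list(values), dtype=float)
    edges = spec.edges
    counts, _ = np.histogram(values, bins=edges)
    heights = counts.astype(float)
    if spec.normalized:
        total = heights.sum()
        if total > 0:
            heights = heights / total
    if spec.smoothing_window:
        kernel = np.ones(spec.smoothing_window) / spec.smoothing_window
        heights = np.convolve(heights, kernel, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, heights


def compute_sample_metrics(
    table: VesselTable,
    radius: float = DEFAULT_PERFUSION_RADIUS,
    raster_scale: float | None = None,
    include_central_in_area: bool = True,
) -> SampleMetrics:
    """Assemble all five read-out parameters for one identified vessel table.

    The table should have passed :func:`~angioquant.vessel_detection.identify_central_vessels`;
    if no central vein is present the distance-dependent outputs are left
    empty and ``vein_present`` is False, while count/area/density are still
    reported.
    """
    count = total_vessel_count(table)
    area = perfused_area(
        table, radius=radius, raster_scale=raster_scale,
        include_central=include_central_in_area,
    )
    density = vessel_density(count, area)
    caps = table.capillaries
    diameters = [diameter(m) for m in caps]
    vein = table.central_vein
    if vein is not None:
        distances = [ingrowth_distance(m, vein) for m in caps]
        artery_dist = (
            ingrowth_distance(table.central_artery, vein)
            if table.central_artery is not None
            else None
        )
    else:
        distances = []
        artery_dist = None
    return SampleMetrics(
        sample_id=table.sample_id,
        total_vessel_count=count,
        total_perfused_area=area,
        vessel_density=density,
        ingrowth_distances=distances,
        diameters=diameters,
        perfusion_radius=radius,
        central_artery_distance=artery_dist,
        vein_present=vein is not None,
    )
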