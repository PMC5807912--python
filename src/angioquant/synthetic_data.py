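"""Synthetic color-coded annotation images with exact ground truth.

The generator emulates the geometry of a mid-cylinder histologic cross
section from the silicone-tube implantation assay: one centric vein (blue)
and one centric artery (red) surrounded by a population of elliptical
capillary marks (green) on a white background, rendered in the three-color
annotation convention at a stated physical scale.  Every placement is
recorded, so each pipeline stage can be validated against exact ground
truth without real histology.

Defaults approximate the assay's working conditions: a 2,500 px square
field at 2 um/px (a 5 mm field, matching the ~4-5 mm tissue cylinder), a
~300 um vein with a ~180 um artery beside it, capillary diameters drawn
log-normally with median 15 um, and radial placement uniform over the
tissue annulus.  Capillaries are rejection-sampled so that distinct marks
never touch (separation >= 3 px by default), because the analysis assumes
one connected component per vessel.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .annotation_io import CalibratedImage, ColorConvention, write_annotation_image
from .errors import PackingError


@dataclass(frozen=True)
class SampleSpec:
    """Full parameterization of one synthetic sample; the seed fixes everything."""

    image_px: int = 2500
    scale: float = 2.0  # um per pixel
    vein_diameter: float = 300.0  # um
    artery_diameter: float = 180.0  # um
    artery_offset: float = 450.0  # um from vein center
    n_capillaries: int = 100
    radial_distribution: tuple[str, dict] = ("uniform", {"low": 200.0, "high": 2000.0})
    diameter_distribution: tuple[str, dict] = (
        "lognormal",
        {"median": 15.0, "sigma": 0.5, "min": 5.0, "max": 300.0},
    )
    eccentricity_range: tuple[float, float] = (0.6, 1.0)  # minor/major axis ratio
    seed: int = 0
    min_separation_px: float = 3.0
    #: reject placements that rasterize to fewer pixels than this, so every
    #: ground-truth mark is resolvable at the raster scale (matches the
    #: detector's default stray-pixel filter)
    min_render_pixels: int = 4
    max_attempts: int = 1000
    antialias: bool = False

    def __post_init__(self) -> None:
        if self.image_px < 1 or self.scale <= 0:
            raise ValueError("image_px and scale must be positive")
        if self.n_capillaries < 0:
            raise ValueError("n_capillaries must be >= 0")
        half = self.image_px * self.scale / 2.0
        if self.vein_diameter / 2.0 >= half or (
            self.artery_offset + self.artery_diameter / 2.0 >= half
        ):
            raise ValueError("central vessels must fit inside the image")


@dataclass
class GroundTruthRecord:
    vessel_type: str
    x: float  # um
    y: float  # um
    major_axis: float  # um
    minor_axis: float  # um
    orientation: float  # rad, major axis vs +x
    radius: float  # um, placement distance from the vein center


@dataclass
class GroundTruth:
    records: list[GroundTruthRecord]

    @property
    def realized_count(self) -> int:
        return sum(1 for r in self.records if r.vessel_type == "capillary")

    @property
    def capillaries(self) -> list[GroundTruthRecord]:
        return [r for r in self.records if r.vessel_type == "capillary"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "vessel_type": r.vessel_type,
                    "x_um": r.x,
                    "y_um": r.y,
                    "major_axis_um": r.major_axis,
                    "minor_axis_um": r.minor_axis,
                    "orientation_rad": r.orientation,
                    "radius_um": r.radius,
                }
                for r in self.records
            ]
        )


@dataclass
class StudySample:
    group: str
    sample_id: str
    seed: int
    image: CalibratedImage
    ground_truth: GroundTruth


def _sample_distance(rng: np.random.Generator, dist: tuple[str, dict]) -> float:
    name, params = dist
    if name == "uniform":
        return float(rng.uniform(params["low"], params["high"]))
    if name == "normal":
        return abs(float(rng.normal(params["mean"], params["sd"])))
    if name == "exponential":
        return params.get("min", 0.0) + float(rng.exponential(params["scale"]))
    raise ValueError(f"unknown radial distribution {name!r}")


def _sample_diameter(rng: np.random.Generator, dist: tuple[str, dict]) -> float:
    name, params = dist
    if name == "lognormal":
        lo = params.get("min", 0.0)
        hi = params.get("max", math.inf)
        mu = math.log(params["median"])
        for _ in range(10_000):
            d = float(rng.lognormal(mu, params["sigma"]))
            if lo <= d <= hi:
                return d
        raise ValueError("diameter truncation bounds reject essentially all draws")
    if name == "uniform":
        return float(rng.uniform(params["low"], params["high"]))
    if name == "constant":
        return float(params["value"])
    raise ValueError(f"unknown diameter distribution {name!r}")


def _render_ellipse(
    canvas: np.ndarray,
    color: tuple[int, int, int],
    center_um: tuple[float, float],
    major: float,
    minor: float,
    orientation: float,
    scale: float,
    antialias: bool,
) -> None:
    """Paint a filled ellipse (geometry in um) onto an RGB pixel canvas."""
    r0 = center_um[1] / scale
    c0 = center_um[0] / scale
    # skimage's rotation convention maps r_radius toward columns as rotation
    # grows; with r_radius=semi-minor and c_radius=semi-major, `orientation`
    # is the major axis angle against +x.
    if not antialias:
        rr, cc = draw_ellipse(
            r0, c0, minor / (2 * scale), major / (2 * scale),
            shape=canvas.shape[:2], rotation=orientation,
        )
        canvas[rr, cc] = color
        return
    # supersample 4x and box-average the coverage for soft (blended) edges
    ss = 4
    rr, cc = draw_ellipse(
        (r0 + 0.5) * ss - 0.5,
        (c0 + 0.5) * ss - 0.5,
        minor / (2 * scale) * ss,
        major / (2 * scale) * ss,
        shape=(canvas.shape[0] * ss, canvas.shape[1] * ss),
        rotation=orientation,
    )
    hi = np.zeros((canvas.shape[0] * ss, canvas.shape[1] * ss), dtype=np.uint8)
    hi[rr, cc] = 1
    coverage = hi.reshape(canvas.shape[0], ss, canvas.shape[1], ss).mean(axis=(1, 3))
    alpha = coverage[..., None]
    blended = alpha * np.asarray(color, float) + (1 - alpha) * canvas.astype(float)
    mask = coverage > 0
    canvas[mask] = np.round(blended[mask]).astype(np.uint8)


def generate_sample(
    spec: SampleSpec, convention: ColorConvention | None = None
) -> tuple[CalibratedImage, GroundTruth]:
    """Render one synthetic annotation image and its exact ground truth.

    Identical specs (including the seed) produce byte-identical images.
    Raises :class:`PackingError` when a capillary cannot be placed without
    violating the separation constraint within ``max_attempts`` draws.
    """
    convention = convention or ColorConvention()
    rng = np.random.default_rng(spec.seed)
    extent = spec.image_px * spec.scale
    vein_center = (extent / 2.0, extent / 2.0)
    canvas = np.full((spec.image_px, spec.image_px, 3), 255, dtype=np.uint8)

    records: list[GroundTruthRecord] = []
    # (x, y, bounding radius) of every placed mark, for the separation check
    placed: list[tuple[float, float, float]] = []
    sep_um = spec.min_separation_px * spec.scale

    artery_angle = rng.uniform(0.0, 2.0 * math.pi)
    artery_center = (
        vein_center[0] + spec.artery_offset * math.cos(artery_angle),
        vein_center[1] + spec.artery_offset * math.sin(artery_angle),
    )
    for vessel_type, color, center, diam, radius in (
        ("vein", convention.vein_color, vein_center, spec.vein_diameter, 0.0),
        ("artery", convention.artery_color, artery_center, spec.artery_diameter,
         spec.artery_offset),
    ):
        _render_ellipse(
            canvas, color, center, diam, diam, 0.0, spec.scale, spec.antialias
        )
        records.append(
            GroundTruthRecord(
                vessel_type=vessel_type, x=center[0], y=center[1],
                major_axis=diam, minor_axis=diam, orientation=0.0, radius=radius,
            )
        )
        placed.append((center[0], center[1], diam / 2.0))

    ecc_lo, ecc_hi = spec.eccentricity_range
    margin = sep_um  # keep marks clear of the border
    for idx in range(spec.n_capillaries):
        for attempt in range(spec.max_attempts):
            radius = _sample_distance(rng, spec.radial_distribution)
            angle = rng.uniform(0.0, 2.0 * math.pi)
            minor = _sample_diameter(rng, spec.diameter_distribution)
            ratio = rng.uniform(ecc_lo, ecc_hi)
            major = minor / ratio
            orientation = rng.uniform(0.0, math.pi)
            x = vein_center[0] + radius * math.cos(angle)
            y = vein_center[1] + radius * math.sin(angle)
            bound = major / 2.0
            if not (
                bound + margin <= x <= extent - bound - margin
                and bound + margin <= y <= extent - bound - margin
            ):
                continue
            if not all(
                math.hypot(x - px, y - py) >= bound + pb + sep_um
                for px, py, pb in placed
            ):
                continue
            rr, _cc = draw_ellipse(
                y / spec.scale, x / spec.scale,
                minor / (2 * spec.scale), major / (2 * spec.scale),
                shape=(spec.image_px, spec.image_px), rotation=orientation,
            )
            if len(rr) >= spec.min_render_pixels:
                break
        else:
            raise PackingError(
                f"could not place capillary {idx} after {spec.max_attempts} "
                "attempts; reduce n_capillaries or widen the radial range"
            )
        _render_ellipse(
            canvas, convention.capillary_color, (x, y), major, minor,
            orientation, spec.scale, spec.antialias,
        )
        records.append(
            GroundTruthRecord(
                vessel_type="capillary", x=x, y=y, major_axis=major,
                minor_axis=minor, orientation=orientation,
                radius=math.hypot(x - vein_center[0], y - vein_center[1]),
            )
        )
        placed.append((x, y, bound))

    image = CalibratedImage(pixels=canvas, scale=spec.scale)
    return image, GroundTruth(records=records)


def generate_study(
    group_specs: dict[str, SampleSpec],
    n_per_group: int,
    seed: int,
    count_variation: str = "poisson",
) -> list[StudySample]:
    """Generate a labelled multi-group study with per-sample derived seeds.

    ``count_variation="poisson"`` draws each sample's capillary count from a
    Poisson with the group template's ``n_capillaries`` as mean, giving
    realistic between-sample spread; ``"none"`` keeps the count fixed.
    Per-sample seeds are spawned deterministically from the study seed.
    """
    if len(group_specs) < 2:
        raise ValueError("a study requires at least two groups")
    if count_variation not in ("poisson", "none"):
        raise ValueError(f"unknown count_variation {count_variation!r}")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(group_specs) * n_per_group)
    samples: list[StudySample] = []
    i = 0
    for group, template in group_specs.items():
        for s in range(n_per_group):
            meta_rng = np.random.default_rng(children[i])
            n_cap = template.n_capillaries
            if count_variation == "poisson":
                n_cap = int(meta_rng.poisson(template.n_capillaries))
            sample_seed = int(meta_rng.integers(0, 2**31))
            spec = dataclasses.replace(
                template, n_capillaries=n_cap, seed=sample_seed
            )
            image, gt = generate_sample(spec)
            samples.append(
                StudySample(
                    group=group,
                    sample_id=f"{group}_{s:02d}",
                    seed=sample_seed,
                    image=image,
                    ground_truth=gt,
                )
            )
            i += 1
    return samples


def match_detections(table, gt: GroundTruth, tol_um: float | None = None) -> tuple[int, int]:
    """Greedy 1:1 match of detected marks to ground-truth records, per class.

    Each ground-truth record may claim at most one detection of the same
    vessel class within ``tol_um`` of its center (default: 3 px in um —
    centroid recovery is sub-pixel, and marks are separated by at least the
    generator's 3 px minimum, so the nearest match is unambiguous).
    Returns ``(matched, total_ground_truth)``.
    """
    from scipy.spatial import cKDTree

    tol = tol_um if tol_um is not None else 3.0 * table.scale
    matched = 0
    for vtype in ("artery", "vein", "capillary"):
        gt_pts = np.array(
            [(r.x, r.y) for r in gt.records if r.vessel_type == vtype]
        ).reshape(-1, 2)
        det_pts = np.array(
            [m.centroid for m in table.marks if m.vessel_type == vtype]
        ).reshape(-1, 2)
        if len(gt_pts) == 0 or len(det_pts) == 0:
            continue
        tree = cKDTree(det_pts)
        dists, idx = tree.query(gt_pts)
        used: set[int] = set()
        for d, j in sorted(zip(dists, idx)):
            if d <= tol and j not in used:
                used.add(int(j))
                matched += 1
    return matched, len(gt.records)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write the per-vessel ground truth records as CSV."""
    gt.to_frame().to_csv(Path(path), index=False)


def write_study(samples: list[StudySample], outdir: str | Path) -> Path:
    """Write study images, ground truths, and a manifest CSV; returns its path.

    The manifest (filename, group, seed, scale) is consumable by the
    pipeline's group-allocation step.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        fname = f"{s.sample_id}.png"
        write_annotation_image(s.image, outdir / fname)
        write_ground_truth(s.ground_truth, outdir / f"{s.sample_id}_truth.csv")
        rows.append(
            {"filename": fname, "group": s.group, "seed": s.seed,
             "scale": s.image.scale}
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
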