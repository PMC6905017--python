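"""Synthetic root-image generator with analytically known morphology.

Emulates the photographs the measurement system consumes: dark branched
tube structures (root segments of known centerline and width) on a light
background plate of known physical size, with optional salt-and-pepper
noise and a small illumination gradient.  Every rendered image carries a
:class:`GroundTruth` computed from the segment *geometry* — never from the
rendered raster — so the morphometry pipeline can be validated against an
independent oracle.

Geometry conventions
--------------------
Physical coordinates are (x, y) in millimetres with x along the plate
width and y along the plate height, origin at the plate's top-left corner.
Pixel (row, col) has its center at ((col + 0.5)·p, (row + 0.5)·p) where p
is the pixel pitch in mm.  A pixel is root iff its center falls in the
half-open band of signed perpendicular distance [−w/2, w/2) around a
segment's centerline *and* its axial projection falls in the half-open
extent [0, length) of the segment (flat end caps), or strictly inside a
disk.  Half-open bounds keep pixel counts exact and deterministic while
avoiding the systematic one-pixel thinning that a strict-on-both-sides
rule produces whenever a band edge lands exactly on pixel centers.  Flat
caps make the analytic silhouette area of an isolated segment exactly
length × width.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError

__all__ = ["Segment", "Disk", "RootSpec", "GroundTruth", "render", "fixture_suite"]

Point = tuple[float, float]


@dataclass(frozen=True)
class Segment:
    """Straight constant-width root piece: centerline start→end, width, in mm."""

    start: Point
    end: Point
    width: float

    @property
    def length(self) -> float:
        return math.dist(self.start, self.end)


@dataclass(frozen=True)
class Disk:
    """Filled circle (diameter-calibration target), center and radius in mm."""

    center: Point
    radius: float


@dataclass
class RootSpec:
    """Full description of a synthetic plate photograph.

    Defaults reproduce the acquisition setup the system targets: a white
    297 × 420 mm background plate and dark roots whose blue channel is far
    below the plate's, which is why blue-channel grayscale separates them.
    """

    segments: Sequence[Segment] = ()
    disks: Sequence[Disk] = ()
    plate_mm: tuple[float, float] = (297.0, 420.0)  # (width, height)
    mm_per_pixel: float = 0.1
    root_color: tuple[int, int, int] = (60, 40, 30)
    plate_color: tuple[int, int, int] = (250, 250, 250)
    noise_fraction: float = 0.0
    illumination_gradient: float = 0.0  # max additive offset, gray levels
    seed: int = 0

    def validate(self) -> None:
        pw, ph = self.plate_mm
        if pw <= 0 or ph <= 0 or self.mm_per_pixel <= 0:
            raise ParameterError("plate dims and pixel pitch must be positive")
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise ParameterError("noise_fraction must be in [0, 1]")
        for s in self.segments:
            if s.width <= 0:
                raise ParameterError("segment width must be positive")
            for x, y in (s.start, s.end):
                if not (0 <= x <= pw and 0 <= y <= ph):
                    raise ParameterError(f"segment endpoint ({x}, {y}) outside plate")
        for d in self.disks:
            if d.radius <= 0:
                raise ParameterError("disk radius must be positive")
            x, y = d.center
            if not (d.radius <= x <= pw - d.radius and d.radius <= y <= ph - d.radius):
                raise ParameterError("disk extends outside plate")


@dataclass
class GroundTruth:
    """Analytic morphology of a :class:`RootSpec`, the oracle for measurement.

    All quantities derive from the segment/disk geometry.  ``projected_area``
    is the area of the union of the bands (overlap at junctions is corrected
    by numeric integration on a sub-pixel grid, so nothing is double-counted);
    ``lateral_area`` uses the cylinder-projection identity π × projected area;
    ``volume`` stacks cylinders per segment.
    """

    total_length: float  # mm, sum of centerline lengths
    mean_width: float  # mm, length-weighted
    projected_area: float  # mm², union of bands
    lateral_area: float  # mm², π × projected_area
    volume: float  # mm³, Σ π (w/2)² l
    root_pixel_count: int
    root_pixel_set: np.ndarray  # (N, 2) array of (row, col), sorted

    def to_manifest(self) -> dict:
        return {
            "total_length_mm": self.total_length,
            "mean_width_mm": self.mean_width,
            "projected_area_mm2": self.projected_area,
            "lateral_area_mm2": self.lateral_area,
            "volume_mm3": self.volume,
            "root_pixel_count": self.root_pixel_count,
        }


def _inside_mask(spec: RootSpec, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Strict membership of points (xx, yy) in the union of bands and disks."""
    inside = np.zeros(xx.shape, dtype=bool)
    for s in spec.segments:
        ax, ay = s.start
        bx, by = s.end
        dx, dy = bx - ax, by - ay
        L2 = dx * dx + dy * dy
        if L2 == 0:
            continue
        L = math.sqrt(L2)
        t = ((xx - ax) * dx + (yy - ay) * dy) / L2
        perp = ((xx - ax) * dy - (yy - ay) * dx) / L  # signed
        inside |= (
            (t * L >= 0.0)
            & (t * L < L)
            & (perp >= -s.width / 2.0)
            & (perp < s.width / 2.0)
        )
    for d in spec.disks:
        cx, cy = d.center
        inside |= (xx - cx) ** 2 + (yy - cy) ** 2 < d.radius**2
    return inside


def _union_area(spec: RootSpec, subdiv: int = 4) -> float:
    """Union silhouette area by numeric integration on a sub-pixel grid.

    Exact closed forms are used when no overlap is possible (single band or
    disjoint pieces are still integrated for uniformity only when counting
    the union of several pieces).
    """
    if len(spec.segments) + len(spec.disks) == 0:
        return 0.0
    if len(spec.segments) == 1 and not spec.disks:
        s = spec.segments[0]
        return s.length * s.width
    if len(spec.segments) == 0 and len(spec.disks) == 1:
        return math.pi * spec.disks[0].radius ** 2
    # bounding box of all pieces, padded by max half-width
    xs, ys, pad = [], [], 0.0
    for s in spec.segments:
        xs += [s.start[0], s.end[0]]
        ys += [s.start[1], s.end[1]]
        pad = max(pad, s.width / 2.0)
    for d in spec.disks:
        xs.append(d.center[0])
        ys.append(d.center[1])
        pad = max(pad, d.radius)
    step = spec.mm_per_pixel / subdiv
    x0, x1 = min(xs) - pad - step, max(xs) + pad + step
    y0, y1 = min(ys) - pad - step, max(ys) + pad + step
    gx = np.arange(x0 + step / 2, x1, step)
    gy = np.arange(y0 + step / 2, y1, step)
    xx, yy = np.meshgrid(gx, gy)
    return float(_inside_mask(spec, xx, yy).sum()) * step * step


def ground_truth(spec: RootSpec, root_pixel_set: np.ndarray) -> GroundTruth:
    total_len = sum(s.length for s in spec.segments)
    if total_len > 0:
        mean_w = sum(s.length * s.width for s in spec.segments) / total_len
    elif spec.disks:
        mean_w = 2.0 * float(np.mean([d.radius for d in spec.disks]))
    else:
        mean_w = 0.0
    area = _union_area(spec)
    vol = sum(math.pi * (s.width / 2.0) ** 2 * s.length for s in spec.segments)
    vol += sum((4.0 / 3.0) * math.pi * d.radius**3 for d in spec.disks)
    return GroundTruth(
        total_length=total_len,
        mean_width=mean_w,
        projected_area=area,
        lateral_area=math.pi * area,
        volume=vol,
        root_pixel_count=len(root_pixel_set),
        root_pixel_set=root_pixel_set,
    )


def render(spec: RootSpec) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a :class:`RootSpec` into an RGB image plus its ground truth.

    Anti-aliasing is off: a pixel is root iff its center is strictly inside
    the root geometry, which fixes exact pixel counts.  Salt-and-pepper
    noise (half salt, half pepper, seeded) is applied after rasterization;
    the ground-truth pixel set refers to the noise-free geometry.
    """
    spec.validate()
    pw, ph = spec.plate_mm
    p = spec.mm_per_pixel
    W = int(round(pw / p))
    H = int(round(ph / p))
    cols = (np.arange(W) + 0.5) * p
    rows = (np.arange(H) + 0.5) * p
    xx, yy = np.meshgrid(cols, rows)
    inside = _inside_mask(spec, xx, yy)

    img = np.empty((H, W, 3), dtype=np.uint8)
    img[:] = np.asarray(spec.plate_color, dtype=np.uint8)
    img[inside] = np.asarray(spec.root_color, dtype=np.uint8)

    if spec.illumination_gradient:
        ramp = np.linspace(0.0, spec.illumination_gradient, W)
        img = np.clip(img.astype(np.int16) + ramp[None, :, None], 0, 255).astype(
            np.uint8
        )

    if spec.noise_fraction > 0:
        rng = np.random.default_rng(spec.seed)
        n_noise = int(round(spec.noise_fraction * H * W))
        idx = rng.choice(H * W, size=n_noise, replace=False)
        values = rng.choice([0, 255], size=n_noise)
        flat = img.reshape(-1, 3)
        flat[idx] = values[:, None]

    rr, cc = np.nonzero(inside)
    pixel_set = np.column_stack([rr, cc])
    return img, ground_truth(spec, pixel_set)


# ---------------------------------------------------------------------------
# Canonical fixtures

_FIXTURE_PLATE = (150.0, 100.0)  # mm — a small plate keeps the suite fast
# 0.05 mm/px puts ~40 pixels across a 2 mm root, so the quarter-pixel
# quantization of the inscribed-radius estimator stays near 1% of the
# diameter — comfortably inside measurement tolerances.
_FIXTURE_PITCH = 0.05  # mm/px
_TUBE_W = 2.0  # mm, typical lateral-root diameter


def _rotated_tube(angle_deg: float, length: float = 120.0, width: float = _TUBE_W) -> Segment:
    """Tube of given length centered on the fixture plate at the given angle."""
    cx, cy = _FIXTURE_PLATE[0] / 2, _FIXTURE_PLATE[1] / 2
    a = math.radians(angle_deg)
    hx, hy = math.cos(a) * length / 2, math.sin(a) * length / 2
    return Segment((cx - hx, cy - hy), (cx + hx, cy + hy), width)


def fixture_suite(seed: int = 0) -> dict[str, tuple[RootSpec, np.ndarray, GroundTruth]]:
    """The canonical test fixtures: name → (spec, image, ground truth).

    Covers an axial tube, a shorter diagonal (45°) tube, the axial tube
    rotated 45° about the plate center, a Y-branched root, a two-disk
    diameter target, a blank plate, and noisy variants of the axial tube at
    0.5% and 1% salt-and-pepper.
    """
    cx, cy = _FIXTURE_PLATE[0] / 2, _FIXTURE_PLATE[1] / 2
    base = dict(plate_mm=_FIXTURE_PLATE, mm_per_pixel=_FIXTURE_PITCH, seed=seed)

    axial = _rotated_tube(0.0)
    specs: dict[str, RootSpec] = {
        "axial_tube": RootSpec(segments=[axial], **base),
        "diagonal_tube": RootSpec(segments=[_rotated_tube(45.0, length=100.0)], **base),
        "rotated_tube_45": RootSpec(segments=[_rotated_tube(45.0)], **base),
        "y_branch": RootSpec(
            segments=[
                Segment((cx, cy + 40.0), (cx, cy - 10.0), 3.0),
                Segment((cx, cy - 10.0), (cx - 35.0, cy - 45.0), 2.0),
                Segment((cx, cy - 10.0), (cx + 35.0, cy - 45.0), 2.0),
            ],
            **base,
        ),
        "two_disks": RootSpec(
            disks=[Disk((45.0, 50.0), 1.0), Disk((105.0, 50.0), 3.0)], **base
        ),
        "blank_plate": RootSpec(**base),
        "axial_noisy_half_pct": RootSpec(
            segments=[axial], noise_fraction=0.005, **base
        ),
        "axial_noisy_1pct": RootSpec(segments=[axial], noise_fraction=0.01, **base),
    }
    return {name: (spec, *render(spec)) for name, spec in specs.items()}


def write_fixture(name: str, spec: RootSpec, out_dir) -> None:
    """Render and write one fixture as PNG + manifest JSON."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img, gt = render(spec)
    iio.imwrite(out / f"{name}.png", img)
    manifest = gt.to_manifest()
    manifest["mm_per_pixel"] = spec.mm_per_pixel
    manifest["plate_mm"] = list(spec.plate_mm)
    manifest["noise_fraction"] = spec.noise_fraction
    (out / f"{name}.json").write_text(json.dumps(manifest, indent=2))
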