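"""Laser raster planning, ON/OFF gating and dose/time accounting.

The dose model is deliberately simple and matches how the instrument's
operating points are specified: a beam of power P (W) scanned at v (mm/s)
deposits P/v joules per millimetre of line; spreading that over the beam
width w gives an areal energy flux P/(v·w) in J/mm².  Any power/speed
pair with equal P/v is therefore iso-dose.

Paths are ordered line segments in physical µm coordinates; gating
restricts the ON state to the arc-length spans where the beam center lies
over target pixels, so target-free stretches cost travel time but no
energy.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .colony_sim import DIFF, LabelMask
from .patch_cnn import ProbabilityMap


@dataclass(frozen=True)
class LaserParams:
    # defaults are the purification operating point
    power_W: float = 0.8
    speed_mm_s: float = 100.0
    beam_width_um: float = 50.0
    line_interval_um: float = 25.0

    def __post_init__(self) -> None:
        if self.power_W < 0:
            raise ValueError("power must be nonnegative")
        if self.speed_mm_s <= 0:
            raise ValueError("speed must be positive")
        if self.beam_width_um <= 0:
            raise ValueError("beam width must be positive")
        if self.line_interval_um <= 0:
            raise ValueError("line interval must be positive")


@dataclass
class Segment:
    """One straight scan stroke with ON spans given in arc-length µm."""

    start_um: tuple[float, float]
    end_um: tuple[float, float]
    speed_mm_s: float
    power_W: float
    on_intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def length_um(self) -> float:
        return float(np.hypot(self.end_um[0] - self.start_um[0],
                              self.end_um[1] - self.start_um[1]))

    def on_length_um(self) -> float:
        return float(sum(b - a for a, b in self.on_intervals))


@dataclass
class ScanPath:
    segments: list[Segment]
    turnaround_s: float = 0.0


@dataclass(frozen=True)
class PathStats:
    active_length_mm: float
    total_length_mm: float
    total_time_s: float
    delivered_energy_J: float
    dose_J_per_mm: float
    flux_J_per_mm2: float
    throughput_cells_per_s: float


# --- regions ----------------------------------------------------------------


@dataclass(frozen=True)
class CircleRegion:
    center_um: tuple[float, float]
    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("empty region")

    @property
    def bounds_um(self):
        cx, cy = self.center_um
        r = self.radius_um
        return (cx - r, cy - r, cx + r, cy + r)

    def clip_horizontal(self, y: float):
        cx, cy = self.center_um
        dy = y - cy
        if abs(dy) > self.radius_um:
            return None
        half = float(np.sqrt(self.radius_um**2 - dy**2))
        return (cx - half, cx + half)

    def clip_vertical(self, x: float):
        cx, cy = self.center_um
        dx = x - cx
        if abs(dx) > self.radius_um:
            return None
        half = float(np.sqrt(self.radius_um**2 - dx**2))
        return (cy - half, cy + half)

    @classmethod
    def from_area_cm2(cls, area_cm2: float,
                      center_um: tuple[float, float] = (0.0, 0.0)) -> "CircleRegion":
        """Circle with the given scannable area (1 cm² = 1e8 µm²)."""
        radius_um = float(np.sqrt(area_cm2 * 1e8 / np.pi))
        return cls(center_um, radius_um)


@dataclass(frozen=True)
class RectRegion:
    x0_um: float
    y0_um: float
    x1_um: float
    y1_um: float

    def __post_init__(self) -> None:
        if self.x1_um <= self.x0_um or self.y1_um <= self.y0_um:
            raise ValueError("empty region")

    @property
    def bounds_um(self):
        return (self.x0_um, self.y0_um, self.x1_um, self.y1_um)

    def clip_horizontal(self, y: float):
        if not self.y0_um <= y <= self.y1_um:
            return None
        return (self.x0_um, self.x1_um)

    def clip_vertical(self, x: float):
        if not self.x0_um <= x <= self.x1_um:
            return None
        return (self.y0_um, self.y1_um)


# --- scalar dose model -------------------------------------------------------


def dose_per_length(power_W: float, speed_mm_s: float) -> float:
    """Energy deposited per unit scan length, P/v in J/mm."""
    if speed_mm_s <= 0:
        raise ValueError("speed must be positive")
    if power_W < 0:
        raise ValueError("power must be nonnegative")
    return power_W / speed_mm_s


def energy_flux(power_W: float, speed_mm_s: float, beam_width_um: float = 50.0) -> float:
    """Areal energy flux P/(v·w) in J/mm² for a beam of width w."""
    if beam_width_um <= 0:
        raise ValueError("beam width must be positive")
    return dose_per_length(power_W, speed_mm_s) / (beam_width_um / 1000.0)


def throughput(speed_mm_s: float, cell_diameter_um: float = 10.0) -> float:
    """Cells traversed per second along the scan line (v / cell diameter)."""
    if speed_mm_s <= 0 or cell_diameter_um <= 0:
        raise ValueError("arguments must be positive")
    return speed_mm_s * 1000.0 / cell_diameter_um


# --- pattern planning --------------------------------------------------------


def _line_offsets(lo: float, hi: float, interval: float) -> np.ndarray:
    """Line coordinates lo, lo+d, ... covering [lo, hi]; at least one line."""
    n = int(np.floor((hi - lo) / interval)) + 1
    return lo + interval * np.arange(n)


def plan_pattern(kind: str, region, laser: LaserParams) -> ScanPath:
    """Plan an ungated (fully ON) scan of a region.

    ``raster``: one family of horizontal lines at the laser's line
    interval, serpentine-ordered and clipped to the region (chords for a
    circular dish).  ``lattice``: the raster plus the orthogonal family.
    ``rectangle``/``circle``: the region outline.  ``line``: one
    horizontal stroke through the region center.
    """
    x0, y0, x1, y1 = region.bounds_um
    segs: list[Segment] = []

    def add(p0, p1):
        seg = Segment(tuple(map(float, p0)), tuple(map(float, p1)),
                      laser.speed_mm_s, laser.power_W)
        seg.on_intervals = [(0.0, seg.length_um)]
        segs.append(seg)

    if kind in ("raster", "lattice"):
        for i, y in enumerate(_line_offsets(y0, y1, laser.line_interval_um)):
            span = region.clip_horizontal(y)
            if span is None or span[1] <= span[0]:
                continue
            a, b = ((span[0], y), (span[1], y))
            add(*((a, b) if i % 2 == 0 else (b, a)))
        if kind == "lattice":
            for i, x in enumerate(_line_offsets(x0, x1, laser.line_interval_um)):
                span = region.clip_vertical(x)
                if span is None or span[1] <= span[0]:
                    continue
                a, b = ((x, span[0]), (x, span[1]))
                add(*((a, b) if i % 2 == 0 else (b, a)))
    elif kind == "rectangle":
        corners = [(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)]
        for p0, p1 in zip(corners[:-1], corners[1:]):
            add(p0, p1)
    elif kind == "circle":
        if not isinstance(region, CircleRegion):
            raise ValueError("circle pattern requires a CircleRegion")
        cx, cy = region.center_um
        t = np.linspace(0, 2 * np.pi, 361)
        pts = np.stack([cx + region.radius_um * np.cos(t),
                        cy + region.radius_um * np.sin(t)], axis=1)
        for p0, p1 in zip(pts[:-1], pts[1:]):
            add(p0, p1)
    elif kind == "line":
        yc = 0.5 * (y0 + y1)
        span = region.clip_horizontal(yc)
        if span is None:
            raise ValueError("region has no interior line")
        add((span[0], yc), (span[1], yc))
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")

    if not segs:
        raise ValueError("empty region produced no scan lines")
    return ScanPath(segs)


# --- gating ------------------------------------------------------------------


def _target_mask(targets, threshold: float) -> tuple[np.ndarray, float]:
    if isinstance(targets, ProbabilityMap):
        return targets.probs >= threshold, targets.pixel_size_um
    if isinstance(targets, LabelMask):
        return targets.labels == DIFF, targets.pixel_size_um
    raise TypeError("targets must be a ProbabilityMap or LabelMask")


def gate_path(path: ScanPath, targets, threshold: float = 0.5,
              dilate_um: float | None = None,
              beam_width_um: float = 50.0) -> ScanPath:
    """Switch the laser ON only where the beam center is over target pixels.

    The target set is ``probability >= threshold`` (or mask ==
    differentiated), optionally dilated by ``dilate_um`` (default half
    the beam width) so target edges receive full-width coverage.  Beam
    positions outside the map are OFF.
    """
    mask, px = _target_mask(targets, threshold)
    if dilate_um is None:
        dilate_um = beam_width_um / 2.0
    r = int(round(dilate_um / px))
    if r > 0 and mask.any():
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        mask = ndimage.binary_dilation(mask, structure=yy**2 + xx**2 <= r**2)

    h, w = mask.shape
    step = px / 2.0  # sample the centerline at half-pixel resolution
    out_segments: list[Segment] = []
    for seg in path.segments:
        length = seg.length_um
        n = max(int(np.ceil(length / step)) + 1, 2)
        s = np.linspace(0.0, length, n)
        t = s / length if length > 0 else s
        xs = seg.start_um[0] + t * (seg.end_um[0] - seg.start_um[0])
        ys = seg.start_um[1] + t * (seg.end_um[1] - seg.start_um[1])
        ix = np.round(xs / px).astype(int)
        iy = np.round(ys / px).astype(int)
        inside = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        on = np.zeros(n, dtype=bool)
        on[inside] = mask[iy[inside], ix[inside]]
        intervals = _runs_to_intervals(on, s)
        out_segments.append(replace(seg, on_intervals=intervals))
    return ScanPath(out_segments, path.turnaround_s)


def _runs_to_intervals(on: np.ndarray, s: np.ndarray) -> list[tuple[float, float]]:
    if not on.any():
        return []
    d = np.diff(on.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if on[0]:
        starts.insert(0, 0)
    if on[-1]:
        ends.append(len(on) - 1)
    return [(float(s[a]), float(s[b])) for a, b in zip(starts, ends)]


def skip_empty_lines(path: ScanPath) -> ScanPath:
    """Drop segments whose gated ON length is zero (shortens a gated scan)."""
    kept = [s for s in path.segments if s.on_length_um() > 0]
    return ScanPath(kept, path.turnaround_s)


# --- accounting --------------------------------------------------------------


def path_stats(path: ScanPath, beam_width_um: float | None = None,
               cell_diameter_um: float = 10.0) -> PathStats:
    """Aggregate length, time, energy and dose figures for a path.

    Time covers the full traversal of every segment (ON or OFF) plus one
    turnaround per inter-segment transition; energy counts ON spans only.
    Dose and flux are those of the first segment's operating point (all
    segments share it in the planned patterns).
    """
    if not path.segments:
        raise ValueError("empty path")
    if beam_width_um is None:
        beam_width_um = 50.0
    total_len = sum(s.length_um for s in path.segments)
    active_len = sum(s.on_length_um() for s in path.segments)
    total_time = sum(s.length_um / 1000.0 / s.speed_mm_s for s in path.segments)
    total_time += path.turnaround_s * max(len(path.segments) - 1, 0)
    energy = sum(
        s.power_W * (s.on_length_um() / 1000.0) / s.speed_mm_s
        for s in path.segments
    )
    first = path.segments[0]
    return PathStats(
        active_length_mm=active_len / 1000.0,
        total_length_mm=total_len / 1000.0,
        total_time_s=total_time,
        delivered_energy_J=energy,
        dose_J_per_mm=dose_per_length(first.power_W, first.speed_mm_s),
        flux_J_per_mm2=energy_flux(first.power_W, first.speed_mm_s, beam_width_um),
        throughput_cells_per_s=throughput(first.speed_mm_s, cell_diameter_um),
    )


# --- path I/O ----------------------------------------------------------------


def write_path(prefix: str | Path, path: ScanPath) -> None:
    """CSV of segments plus JSON sidecar with ON intervals and overhead."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".csv"), "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["x0_um", "y0_um", "x1_um", "y1_um", "speed_mm_s", "power_W"])
        for s in path.segments:
            wr.writerow([*s.start_um, *s.end_um, s.speed_mm_s, s.power_W])
    sidecar = {
        "turnaround_s": path.turnaround_s,
        "on_intervals": [[list(iv) for iv in s.on_intervals] for s in path.segments],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def read_path(prefix: str | Path) -> ScanPath:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    segments = []
    with open(prefix.with_suffix(".csv")) as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            segments.append(
                Segment(
                    (float(row["x0_um"]), float(row["y0_um"])),
                    (float(row["x1_um"]), float(row["y1_um"])),
                    float(row["speed_mm_s"]),
                    float(row["power_W"]),
                    [tuple(iv) for iv in sidecar["on_intervals"][i]],
                )
            )
    return ScanPath(segments, sidecar["turnaround_s"])
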