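"""Moving-source surface heat diffusion for the light-responsive layer.

A 405 nm beam scanned over the azobenzene polymer film deposits heat only
in the film (trans-cis-trans photo-isomerization), which then spreads
laterally and relaxes toward ambient.  The film is thin, so the model is
a 2-D surface field:

    dT/dt = D * laplacian(T) - loss_rate * (T - T_ambient) + S(x, y, t)

with D the lateral thermal diffusion coefficient (~0.1 mm²/s for this
substrate stack), Newton cooling to ambient standing in for conduction
into dish and air, and S a top-hat (or Gaussian) spot of the beam width
moving along the scan segment.  The source strength is the absorbed
optical power, P * (1 - 10^-A) for substrate absorbance A, converted to a
heating rate by ``coupling`` — the inverse areal heat capacity of the
film stack (°C·mm²/J).  ``coupling`` and ``loss_rate_s`` collapse
unpublished material properties into two constants calibrated once (see
scripts/calibrate_thermal.py) so that a 0.3 W beam at 80 mm/s peaks just
above 50 °C and relaxes to physiological temperature on the ~10 ms scale,
reproducing the "comet" seen in thermal imaging of the scanned film.

Integration is explicit forward-time centered-space with the time step
chosen from the diffusive stability bound; boundaries are held at ambient
(Dirichlet) on a domain padded well beyond the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .scan_planner import LaserParams, Segment

PHYSIOLOGICAL_C = 37.0

# calibrated so 0.3 W @ 80 mm/s, 50 µm beam peaks just above 50 °C with
# decay to physiological temperature completing on the ~10 ms scale
DEFAULT_COUPLING_C_MM2_PER_J = 620.0
DEFAULT_LOSS_RATE_S = 25.0


@dataclass(frozen=True)
class ThermalParams:
    D_mm2_s: float = 0.1
    ambient_C: float = 29.5
    absorbance_405: float = 0.25
    coupling_C_mm2_per_J: float = DEFAULT_COUPLING_C_MM2_PER_J
    loss_rate_s: float = DEFAULT_LOSS_RATE_S
    grid_um: float = 5.0
    dt_s: float | None = None  # None -> safety * grid^2 / (4 D)
    stability_safety: float = 0.5
    source_profile: str = "tophat"  # "tophat" | "gaussian"
    pad_diffusion_lengths: float = 10.0

    def __post_init__(self) -> None:
        if self.D_mm2_s <= 0 or self.grid_um <= 0:
            raise ValueError("D and grid step must be positive")
        if self.absorbance_405 < 0:
            raise ValueError("absorbance must be nonnegative")
        if self.loss_rate_s < 0 or self.coupling_C_mm2_per_J < 0:
            raise ValueError("loss rate and coupling must be nonnegative")
        if self.source_profile not in ("tophat", "gaussian"):
            raise ValueError(f"unknown source profile {self.source_profile!r}")

    def stable_dt_s(self) -> float:
        g_mm = self.grid_um / 1000.0
        return self.stability_safety * g_mm**2 / (4.0 * self.D_mm2_s)


@dataclass
class ThermalField:
    """Simulation output: sparse full-frame snapshots plus per-step probe traces."""

    snapshots: np.ndarray  # (n_snap, H, W) °C
    snapshot_times_s: np.ndarray
    snapshot_beam_s_um: np.ndarray  # beam arc position at each snapshot (nan if off)
    probe_times_s: np.ndarray  # every integration step
    probe_temps_C: np.ndarray  # (n_steps, n_probes)
    probe_points_um: np.ndarray  # (n_probes, 2)
    origin_um: tuple[float, float]  # physical position of grid pixel (0, 0)
    grid_um: float
    ambient_C: float
    segment: Segment
    speed_mm_s: float

    def temp_at(self, snap: int, x_um: float, y_um: float) -> float:
        i = int(round((y_um - self.origin_um[1]) / self.grid_um))
        j = int(round((x_um - self.origin_um[0]) / self.grid_um))
        return float(self.snapshots[snap, i, j])

    def peak_C(self) -> float:
        return float(self.snapshots.max())


@dataclass(frozen=True)
class CometMetrics:
    rise_time_ms: float
    decay_time_ms: float
    tail_length_um: float
    defined: bool


def absorbed_fraction(absorbance: float) -> float:
    """Fraction of incident power absorbed by a film of the given absorbance."""
    if absorbance < 0:
        raise ValueError("absorbance must be nonnegative")
    return 1.0 - 10.0 ** (-absorbance)


def transit_time(beam_width_um: float, speed_mm_s: float) -> float:
    """Time (ms) for the beam to cross a point: w / v."""
    if beam_width_um <= 0 or speed_mm_s <= 0:
        raise ValueError("arguments must be positive")
    return beam_width_um / speed_mm_s


def diffusion_length(D_mm2_s: float, t_s: float) -> float:
    """Characteristic spread sqrt(4 D t), reported in µm."""
    if D_mm2_s <= 0 or t_s < 0:
        raise ValueError("D must be positive and t nonnegative")
    return float(np.sqrt(4.0 * D_mm2_s * t_s)) * 1000.0


def simulate(
    segment: Segment,
    laser: LaserParams,
    params: ThermalParams = ThermalParams(),
    extra_time_s: float = 0.0,
    duration_s: float | None = None,
    probe_points_um: list[tuple[float, float]] | None = None,
    n_snapshots: int = 60,
    initial_excess_C=None,  # array over the domain, or callable(x_um, y_um)
    source_on: bool = True,
) -> ThermalField:
    """Integrate the surface temperature while the beam traverses a segment.

    A zero-length segment models a stationary spot and requires
    ``duration_s``.  ``extra_time_s`` extends the run after the traversal
    to watch the decay.  ``initial_excess_C`` (a full-domain array,
    advanced users/tests) seeds the field above ambient; ``source_on=False``
    disables the beam entirely.  Probes default to the segment midpoint;
    their temperature is recorded at every integration step.
    """
    g_mm = params.grid_um / 1000.0
    dt = params.dt_s if params.dt_s is not None else params.stable_dt_s()
    limit = params.grid_um**2 / 1e6 / (4.0 * params.D_mm2_s)
    if dt > limit:
        raise ValueError(
            f"dt={dt:g}s violates the explicit stability bound; admissible dt <= {limit:g}s"
        )

    seg_len_um = segment.length_um
    travel_s = seg_len_um / 1000.0 / segment.speed_mm_s if seg_len_um > 0 else 0.0
    if seg_len_um == 0 and duration_s is None:
        raise ValueError("stationary spot (zero-length segment) requires duration_s")
    t_end = (duration_s if duration_s is not None else travel_s) + extra_time_s
    n_steps = max(int(np.ceil(t_end / dt)), 1)

    pad_um = max(
        params.pad_diffusion_lengths * diffusion_length(params.D_mm2_s, t_end),
        3.0 * laser.beam_width_um,
    )
    x_lo = min(segment.start_um[0], segment.end_um[0]) - pad_um
    x_hi = max(segment.start_um[0], segment.end_um[0]) + pad_um
    y_lo = min(segment.start_um[1], segment.end_um[1]) - pad_um
    y_hi = max(segment.start_um[1], segment.end_um[1]) + pad_um
    w = int(np.ceil((x_hi - x_lo) / params.grid_um)) + 1
    h = int(np.ceil((y_hi - y_lo) / params.grid_um)) + 1
    origin = (x_lo, y_lo)

    T = np.full((h, w), params.ambient_C, dtype=np.float64)
    if initial_excess_C is not None:
        if callable(initial_excess_C):
            gy, gx = np.mgrid[0:h, 0:w]
            initial_excess_C = initial_excess_C(
                origin[0] + gx * params.grid_um, origin[1] + gy * params.grid_um
            )
        if initial_excess_C.shape != (h, w):
            raise ValueError(f"initial_excess_C must have shape {(h, w)}")
        T += initial_excess_C

    # absorbed power -> heating rate, conserved over the rasterized spot
    p_abs_W = laser.power_W * absorbed_fraction(params.absorbance_405)
    radius_um = laser.beam_width_um / 2.0
    r_px = int(np.ceil(radius_um / params.grid_um))
    yy, xx = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
    dist_um = np.hypot(xx, yy) * params.grid_um
    if params.source_profile == "tophat":
        stamp = (dist_um <= radius_um).astype(np.float64)
    else:
        sigma = radius_um / 2.0
        stamp = np.exp(-0.5 * (dist_um / sigma) ** 2)
        stamp[dist_um > 3 * sigma] = 0.0
    stamp_area_mm2 = stamp.sum() * g_mm**2
    heat_stamp = (
        params.coupling_C_mm2_per_J * p_abs_W / stamp_area_mm2 * stamp
        if stamp_area_mm2 > 0
        else stamp
    )

    # ON spans along the segment (empty list on a hand-built segment = fully ON)
    on_iv = segment.on_intervals or [(0.0, seg_len_um)]

    if probe_points_um is None:
        probe_points_um = [
            (
                0.5 * (segment.start_um[0] + segment.end_um[0]),
                0.5 * (segment.start_um[1] + segment.end_um[1]),
            )
        ]
    probes = np.asarray(probe_points_um, dtype=float)
    pj = np.round((probes[:, 0] - origin[0]) / params.grid_um).astype(int)
    pi = np.round((probes[:, 1] - origin[1]) / params.grid_um).astype(int)

    snap_every = max(n_steps // max(n_snapshots - 1, 1), 1)
    snaps, snap_t, snap_s = [], [], []
    probe_t = np.empty(n_steps + 1)
    probe_T = np.empty((n_steps + 1, len(probes)))

    alpha = params.D_mm2_s * dt / g_mm**2
    lam = params.loss_rate_s
    amb = params.ambient_C
    ex = (segment.end_um[0] - segment.start_um[0]) / seg_len_um if seg_len_um else 0.0
    ey = (segment.end_um[1] - segment.start_um[1]) / seg_len_um if seg_len_um else 0.0

    def record(step: int, t: float, s_um: float | None) -> None:
        probe_t[step] = t
        probe_T[step] = T[pi, pj]
        if step % snap_every == 0 or step == n_steps:
            snaps.append(T.copy())
            snap_t.append(t)
            snap_s.append(np.nan if s_um is None else s_um)

    record(0, 0.0, 0.0 if source_on else None)
    for step in range(1, n_steps + 1):
        t = step * dt
        lap = np.zeros_like(T)
        lap[1:-1, 1:-1] = (
            T[:-2, 1:-1] + T[2:, 1:-1] + T[1:-1, :-2] + T[1:-1, 2:]
            - 4.0 * T[1:-1, 1:-1]
        )
        T[1:-1, 1:-1] += alpha * lap[1:-1, 1:-1] - dt * lam * (T[1:-1, 1:-1] - amb)

        s_um = None
        if source_on and p_abs_W > 0:
            t_mid = t - 0.5 * dt
            s_now = min(t_mid, travel_s) * segment.speed_mm_s * 1000.0 if seg_len_um else 0.0
            active = t_mid <= travel_s or seg_len_um == 0
            if seg_len_um == 0 and duration_s is not None:
                active = t_mid <= duration_s
            if active and any(a - 1e-9 <= s_now <= b + 1e-9 for a, b in on_iv):
                cx = segment.start_um[0] + ex * s_now
                cy = segment.start_um[1] + ey * s_now
                ci = int(round((cy - origin[1]) / params.grid_um))
                cj = int(round((cx - origin[0]) / params.grid_um))
                i0, i1 = ci - r_px, ci + r_px + 1
                j0, j1 = cj - r_px, cj + r_px + 1
                if i0 >= 0 and j0 >= 0 and i1 <= h and j1 <= w:
                    T[i0:i1, j0:j1] += dt * heat_stamp
                s_um = s_now
        record(step, t, s_um)

    return ThermalField(
        snapshots=np.stack(snaps),
        snapshot_times_s=np.asarray(snap_t),
        snapshot_beam_s_um=np.asarray(snap_s),
        probe_times_s=probe_t,
        probe_temps_C=probe_T,
        probe_points_um=probes,
        origin_um=origin,
        grid_um=params.grid_um,
        ambient_C=amb,
        segment=segment,
        speed_mm_s=segment.speed_mm_s,
    )


def comet_metrics(
    field: ThermalField,
    physiological_C: float = PHYSIOLOGICAL_C,
    probe: int = 0,
) -> CometMetrics:
    """Rise/decay timing at a probe point and the trailing-tail length.

    Rise time is 10%-to-90% of the probe's peak excess over ambient;
    decay time runs from the peak until the probe first returns to
    ``physiological_C``.  Tail length is the instantaneous distance from
    the beam center to the farthest trailing point on the scan line still
    above ``physiological_C``, measured at the last snapshot with the
    beam on the path.  All three are flagged undefined when the probe
    never exceeds ``physiological_C``.
    """
    trace = field.probe_temps_C[:, probe]
    times = field.probe_times_s
    peak_idx = int(trace.argmax())
    peak = trace[peak_idx]
    if peak <= physiological_C:
        return CometMetrics(np.nan, np.nan, np.nan, defined=False)

    excess = trace - field.ambient_C
    peak_ex = excess[peak_idx]
    lo, hi = 0.1 * peak_ex, 0.9 * peak_ex
    above_lo = np.nonzero(excess[: peak_idx + 1] >= lo)[0]
    above_hi = np.nonzero(excess[: peak_idx + 1] >= hi)[0]
    rise_ms = (times[above_hi[0]] - times[above_lo[0]]) * 1000.0

    after = trace[peak_idx:]
    below = np.nonzero(after <= physiological_C)[0]
    decay_ms = (
        (times[peak_idx + below[0]] - times[peak_idx]) * 1000.0
        if len(below)
        else np.nan
    )

    on_path = np.nonzero(np.isfinite(field.snapshot_beam_s_um))[0]
    tail_um = np.nan
    if len(on_path):
        k = int(on_path[-1])
        s_beam = field.snapshot_beam_s_um[k]
        seg = field.segment
        n = max(int(seg.length_um / field.grid_um), 2)
        s_line = np.linspace(0.0, seg.length_um, n)
        tt = s_line / seg.length_um if seg.length_um else s_line
        xs = seg.start_um[0] + tt * (seg.end_um[0] - seg.start_um[0])
        ys = seg.start_um[1] + tt * (seg.end_um[1] - seg.start_um[1])
        jj = np.round((xs - field.origin_um[0]) / field.grid_um).astype(int)
        ii = np.round((ys - field.origin_um[1]) / field.grid_um).astype(int)
        line_T = field.snapshots[k, ii, jj]
        trailing = (s_line <= s_beam) & (line_T > physiological_C)
        if trailing.any():
            tail_um = float(s_beam - s_line[trailing].min())

    return CometMetrics(float(rise_ms), float(decay_ms), tail_um, defined=True)


def total_excess_heat(field_snapshot: np.ndarray, ambient_C: float,
                      grid_um: float) -> float:
    """Integral of (T - ambient) over the surface, in °C·mm²."""
    return float((field_snapshot - ambient_C).sum() * (grid_um / 1000.0) ** 2)


def write_field(path: str | Path, field: ThermalField) -> None:
    """Multi-page 32-bit float TIFF of the snapshots (°C)."""
    tifffile.imwrite(Path(path), field.snapshots.astype(np.float32))
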