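"""Calibrate the photothermal coupling and loss-rate constants.

The film stack's areal heat capacity and its interface losses are not
measurable in-silico, so they are collapsed into two constants of the
surface-diffusion model: ``coupling`` (°C·mm²/J, inverse areal heat
capacity) and ``loss_rate_s`` (Newton cooling to ambient).  This script
sweeps coupling at a fixed small loss rate and reports, for the
reference stroke (0.3 W, 80 mm/s, 50 µm beam), the peak film temperature
and the comet timing, so the defaults in ``lilack.photothermal`` can be
pinned to the regime where the peak sits just above 50 °C and the decay
back to physiological temperature completes on the ~10 ms scale.

Run:  python scripts/calibrate_thermal.py
"""

from __future__ import annotations

import dataclasses

from lilack.photothermal import ThermalParams, comet_metrics, simulate
from lilack.scan_planner import LaserParams, Segment

LASER = LaserParams(power_W=0.3, speed_mm_s=80.0, beam_width_um=50.0,
                    line_interval_um=25.0)
SEGMENT_MM = 0.5


def run(coupling: float, loss_rate: float):
    params = ThermalParams(coupling_C_mm2_per_J=coupling, loss_rate_s=loss_rate)
    seg = Segment((0.0, 0.0), (SEGMENT_MM * 1000.0, 0.0),
                  LASER.speed_mm_s, LASER.power_W)
    field = simulate(seg, LASER, params, extra_time_s=0.020)
    return field.peak_C(), comet_metrics(field)


def main() -> None:
    loss_rate = 25.0
    print(f"loss_rate_s = {loss_rate}")
    print(f"{'coupling':>10} {'peak_C':>8} {'rise_ms':>8} {'decay_ms':>9} {'tail_um':>8}")
    for coupling in (300, 350, 400, 450, 500, 600):
        peak, met = run(coupling, loss_rate)
        print(f"{coupling:>10} {peak:8.1f} {met.rise_time_ms:8.3f} "
              f"{met.decay_time_ms:9.3f} {met.tail_length_um:8.1f}")


if __name__ == "__main__":
    main()
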