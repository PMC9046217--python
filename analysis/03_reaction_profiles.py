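#!/usr/bin/env python
"""IRC-profile and scission-scan analysis on synthetic ground truth.

Generates seeded hydrogen-transfer IRC profiles for ThiH- and NosL-like
barriers, recovers the barriers by stationary-point detection, fits the
Eckart form (yielding an implied imaginary wavenumber), and measures the
migrating-hydrogen transfer distance over the 5-frame window around the TS.
Then analyzes two C-C distance scans: a stalled scission (minimum near
2.7 A, residual spin on the remaining fragment) and a completed one
(monotone decrease to 3.4 A with full spin transfer).

Writes results/irc_analysis.csv and results/scan_analysis.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from radtunnel.profiles import (
    analyze_scan, detect_stationary_points, fit_eckart, transfer_distance,
)
from radtunnel.synth import make_irc, make_scan

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rows = []
    cases = {
        "ThiH-like": dict(V_forward=20.0, V_reverse=20.0, L=0.35, h=0.45, seed=1),
        "NosL-like": dict(V_forward=18.3, V_reverse=18.3, L=0.35, h=0.40, seed=2),
    }
    for label, c in cases.items():
        prof, truth = make_irc(V_forward=c["V_forward"], V_reverse=c["V_reverse"],
                               L=c["L"], h_displacement=c["h"], noise=0.02,
                               seed=c["seed"])
        roles = detect_stationary_points(prof)
        prof.roles = roles
        fit = fit_eckart(np.column_stack([prof.s_values(), prof.energies()]))
        td = transfer_distance(prof)
        rows.append(dict(case=label, barrier_in=c["V_forward"],
                         barrier_detected=roles.forward_barrier,
                         fit_V_forward=fit.V_forward, fit_L=fit.L,
                         implied_nu=fit.implied_nu,
                         h_in=c["h"], transfer_distance=td.net_displacement))
        print(f"{label}: detected barrier {roles.forward_barrier:.2f} kcal/mol "
              f"(input {c['V_forward']}), Eckart fit implies "
              f"nu = {fit.implied_nu:.0f} cm^-1, H transfer distance "
              f"{td.net_displacement:.3f} A (< 0.5 A short-transfer regime)")
    pd.DataFrame(rows).to_csv(OUT / "irc_analysis.csv", index=False, float_format="%.4f")

    scan_rows = []
    stalled, _ = make_scan(minimum_x=2.70, endpoint_spin=0.55, x_range=(2.2, 3.1))
    relaxed, _ = make_scan(endpoint_spin=1.0, monotone=True, x_range=(2.2, 3.4))
    for label, curve in (("crystal-derived (stalled)", stalled),
                         ("MD-frame (relaxed)", relaxed)):
        a = analyze_scan(curve)
        scan_rows.append(dict(case=label, x_min=a.x_min,
                              endpoint=a.endpoint_distance,
                              leaving_spin=a.leaving_spin_fraction, status=a.status))
        print(f"{label}: minimum at {a.x_min:.2f} A, endpoint {a.endpoint_distance:.1f} A, "
              f"leaving-fragment spin {a.leaving_spin_fraction:.2f} -> {a.status}")
    pd.DataFrame(scan_rows).to_csv(OUT / "scan_analysis.csv", index=False,
                                   float_format="%.3f")


if __name__ == "__main__":
    main()
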