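#!/usr/bin/env python
"""Tunneling corrections for the two hydrogen-abstraction steps.

For the ThiH (20.0 kcal/mol, 333.15 K) and NosL (18.3 kcal/mol, 298.15 K)
barriers this driver:
  1. tabulates kappa and the effective barrier over a grid of imaginary
     wavenumbers for the Eckart, Bell and Wigner models;
  2. inverts the printed effective barriers (9.6 and 10.7 kcal/mol) to the
     implied wavenumber under both Eckart-symmetric and Bell models;
  3. reports the percent barrier reductions and the H/D kinetic isotope
     effect a 2800 cm^-1 transition state would produce.

Writes results/tunneling_corrections.csv and results/tunneling_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from radtunnel.tunneling import (
    BarrierSpec, invert_frequency, kappa_bell, kappa_eckart, kappa_wigner,
    kie, reduction_percent,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

ENZYMES = {
    "ThiH": dict(V=20.0, V_eff=9.6, T=333.15),
    "NosL": dict(V=18.3, V_eff=10.7, T=298.15),
}


def main() -> None:
    rows = []
    for name, pars in ENZYMES.items():
        for nu in np.arange(1000.0, 4600.0, 200.0):
            spec = BarrierSpec.symmetric(pars["V"], nu, pars["T"])
            ke = kappa_eckart(spec)
            kb = kappa_bell(pars["V"], nu, pars["T"])
            kw = kappa_wigner(nu, pars["T"])
            rows.append(dict(enzyme=name, nu_imag=nu,
                             kappa_eckart=ke.kappa, eff_eckart=ke.effective_barrier,
                             kappa_bell=kb.kappa, eff_bell=kb.effective_barrier,
                             kappa_wigner=kw.kappa))
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "tunneling_corrections.csv", index=False, float_format="%.6g")

    summary = {}
    for name, pars in ENZYMES.items():
        nu_eck, _ = invert_frequency(pars["V"], pars["V_eff"], pars["T"],
                                     model="eckart-symmetric")
        nu_bell, _ = invert_frequency(pars["V"], pars["V_eff"], pars["T"], model="bell")
        ratio = kie(BarrierSpec.symmetric(pars["V"], 2800.0, pars["T"]))
        summary[name] = {
            "V_forward_kcal": pars["V"],
            "V_effective_kcal": pars["V_eff"],
            "T_K": pars["T"],
            "reduction_percent": round(reduction_percent(pars["V"], pars["V_eff"]), 1),
            "implied_nu_eckart_cm-1": round(nu_eck, 1),
            "implied_nu_bell_cm-1": round(nu_bell, 1),
            "kie_H_D_at_2800cm-1": round(ratio, 1),
        }
        print(f"{name}: {pars['V']} -> {pars['V_eff']} kcal/mol "
              f"({summary[name]['reduction_percent']}% reduction) implies "
              f"nu = {summary[name]['implied_nu_eckart_cm-1']} cm^-1 (Eckart) / "
              f"{summary[name]['implied_nu_bell_cm-1']} cm^-1 (Bell); "
              f"both exceed the 2000 cm^-1 bound. KIE(2800 cm^-1) ~ "
              f"{summary[name]['kie_H_D_at_2800cm-1']}")
    (OUT / "tunneling_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
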