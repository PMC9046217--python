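#!/usr/bin/env python
"""Newman-projection regiospecificity of the C-C bond scission.

Classifies the two candidate bonds (Calpha-Cbeta and Calpha-C) of the
aminyl-radical products from their Phi(Cb-Ca-N-H) dihedrals: 39.6 degrees
for the ThiH tyrosyl product, 174.5 degrees for the NosL tryptophanyl
product.  Also locates the substrate-orientation minima on a synthetic
periodic dihedral scan with wells at -48 and +55 degrees, emulating the
reactant-orientation landscape.

Writes results/newman_zones.csv and results/dihedral_scan_minima.csv.
"""

from pathlib import Path

import pandas as pd

from radtunnel.geometry import newman_assess
from radtunnel.profiles import find_local_minima
from radtunnel.synth import make_dihedral_scan

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

PRODUCTS = {"ThiH [L-Tyr-NH*]": 39.6, "NosL [L-Trp-NH*]": 174.5}


def main() -> None:
    rows = []
    for label, phi in PRODUCTS.items():
        res = newman_assess(phi)
        for b in res.bonds:
            rows.append(dict(product=label, phi_NH=phi, bond=b.bond,
                             omega=b.omega, zone=b.zone))
            print(f"{label}: Phi={phi:6.1f}  {b.bond:<5} omega={b.omega:5.1f}  -> {b.zone}")
    pd.DataFrame(rows).to_csv(OUT / "newman_zones.csv", index=False)
    print("ThiH can only break Ca-Cb (intermediate overlap); "
          "NosL has optimal overlap for Ca-C and cannot break Ca-Cb.")

    curve, _ = make_dihedral_scan(wells=((-48.0, 5.0), (55.0, 3.5)), seed=0)
    minima = find_local_minima(curve)
    dfm = pd.DataFrame([dict(phi=m.x, energy=m.energy, is_global=m.is_global)
                        for m in minima])
    dfm.to_csv(OUT / "dihedral_scan_minima.csv", index=False, float_format="%.3f")
    for m in minima:
        print(f"orientation minimum at Phi = {m.x:6.1f} deg "
              f"({'global' if m.is_global else 'local'}, E = {m.energy:.2f} kcal/mol)")


if __name__ == "__main__":
    main()
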