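# radtunnel

Desk-scale analysis of the computations behind C–C bond-scission
regiospecificity in the radical SAM lyases ThiH (L-tyrosine → dehydroglycine
+ *p*-cresyl•) and NosL (L-tryptophan → 3-methylindole-2-carboxylic acid).
Both enzymes start by letting the 5´-deoxyadenosyl radical abstract the
substrate's amino hydrogen; which C–C bond then breaks, and how fast the
abstraction itself can be, are questions this package answers from tabulated
quantities — barrier heights, dihedral angles, reaction profiles, scan
curves and atomic coordinates — without running any electronic-structure or
MD calculation itself.

## What it computes

**Tunneling corrections** (`radtunnel.tunneling`).  For a 1-D Eckart barrier
with forward/reverse heights V_f, V_r and transition-state imaginary
wavenumber ν̃, the exact transmission probability T(E) is thermally averaged,

    κ(T) = e^{V_f/k_BT} (1/k_BT) ∫₀^∞ T(E) e^{−E/k_BT} dE,

and converts the classical barrier into an effective one,
ΔE‡_eff = V_f − RT·ln κ.  Bell's truncated-parabola series
κ = (u/2)/sin(u/2) + Σₙ (−1)ⁿ [u/(2nπ−u)] e^{α(1−2nπ/u)} (u = hcν̃/k_BT,
α = V_f/RT) and the Wigner limit 1 + u²/24 are provided alongside, as are
barrier inversion (which ν̃ explains a given effective barrier) and H/D
kinetic isotope effects.

**Profile & scan analysis** (`radtunnel.profiles`): stationary points and
barriers of IRC profiles, least-squares Eckart fits with the implied
ν̃ = (1/2πc)√(|V″(s₀)|/μ), migrating-hydrogen transfer distances over the
5-frame TS window, scission-completion classification of C–C distance scans
(complete ⇔ separation > 3.0 Å with ≥ 95 % of the unpaired spin on the
leaving fragment), and prominence-based local minima with dihedral
periodicity.

**Site geometry** (`radtunnel.geometry`): IUPAC dihedrals, Newman-projection
classification of candidate scission bonds (ω = angle between the bond and
the nitrogen radical orbital, folded to [0°, 90°]; periplanar ≤ 30° <
intermediate ≤ 60° < clinal), polar-contact census with a square-pyramidal
angular test, Kabsch superposition with iterative outlier trimming, and
side-chain χ1 rotamer deltas.

**Cavity mapping** (`radtunnel.cavity`): grid/flood-fill detection of
probe-accessible interior cavities vs. surface-connected channels, volumes,
and channel-lining residues.

**Synthetic data** (`radtunnel.synth`): seeded generators with ground-truth
sidecars for every input class — Eckart-shaped IRC profiles, scission scans
with spin columns, square-pyramidal sites, rigid-motion structure pairs with
prescribed χ1 changes, and hollow/channeled shells.

## Worked example

```
$ radtunnel invert --vf 20.0 --veff 9.6 --temp 333.15 --json
{"nu_imag": 4425.79, "model": "eckart-symmetric", ...}

$ radtunnel newman --phi 174.5
                phi_NH: 174.5
                 bonds: [{'bond': 'Ca-Cb', 'theta': 174.5, 'omega': 84.5, 'zone': 'clinal'},
                         {'bond': 'Ca-C', 'theta': 294.5, 'omega': 24.5, 'zone': 'periplanar'}]
```

The first call asks: what imaginary wavenumber must the ThiH abstraction
transition state have for tunneling to lower its 20.0 kcal/mol barrier to
the effective 9.6 kcal/mol at 333.15 K?  The answer, ≈ 4426 cm⁻¹ under the
symmetric Eckart model (≈ 2892 cm⁻¹ under Bell), is consistent with a
transition state whose imaginary mode exceeds 2000 cm⁻¹.  The second call
classifies the NosL product dihedral Φ = 174.5°: the Cα–C bond lies 24.5°
from the radical orbital (periplanar — scission favored) while Cα–Cβ is
84.5° away (clinal — scission impeded), which is the regiospecificity
observed for NosL.

The numbered drivers under `analysis/` run the full story (tunneling table
and inversions, Newman zones, profile/scan analysis, structural emulation)
and write their tables to `results/`.

## Layout

- `src/radtunnel/` — library (tunneling, profiles, geometry, cavity, synth, io, cli)
- `analysis/` — numbered narrative drivers writing tables to `results/`
- `tests/` — pytest suite, including independent Numerov-Schrödinger and
  Boltzmann-integration oracles the analytic formulas are verified against
- `docs/methods.md` — models, assumptions, parameter choices, limitations
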