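# Methods

## Tunneling model

The hydrogen-atom abstraction by the 5´-deoxyadenosyl radical is treated as
one-dimensional motion of a particle of mass 1.00783 u across an Eckart
barrier characterized by the forward barrier V_f, the reverse barrier V_r
and the transition-state imaginary wavenumber ν̃.  The transmission
probability uses the Johnston–Heicklen dimensionless closed form
(α₁ = 2πV_f/hcν̃, α₂ = 2πV_r/hcν̃, ξ = E/V_f):

    2πa = 2√(α₁ξ)/(α₁^{−1/2}+α₂^{−1/2}),
    2πb = 2√((ξ−1)α₁+α₂)/(α₁^{−1/2}+α₂^{−1/2}),
    2πd = 2√(α₁α₂ − π²/4),
    T(E) = 1 − [cosh 2π(a−b) + cosh 2πd] / [cosh 2π(a+b) + cosh 2πd],

with cosh 2πd → cos 2π|d| when α₁α₂ < π²/4, and log-space evaluation of the
cosh ratio so arbitrarily large barriers never overflow.  Energies below the
product asymptote (E < V_f − V_r) are a closed channel: T = 0.

The thermal transmission coefficient is the Boltzmann average
κ(T) = e^{α}∫₀^{α+40} T(εk_BT) e^{−ε} dε (α = V_f/k_BT), computed by
adaptive quadrature at relative tolerance 1e−8 with the barrier top as an
explicit break point; the classical tail beyond the cutoff is added
analytically (e^{−40}, far below every tolerance used).  The cutoff
α + 40 was checked for independence: the integrand at the cutoff is smaller
than the retained value by ≳ e^{−40}.  Reduced frequencies u = hcν̃/k_BT
above 60 are refused — the quadrature is validated only up to u = 20 against
the independent Schrödinger oracle, and u = 60 is already far beyond any
physically printed wavenumber at the temperatures involved.

Bell's truncated-parabola correction is the analytic series
κ = (u/2)/sin(u/2) + Σ_{n≥1} (−1)ⁿ[u/(2nπ−u)]e^{α(1−2nπ/u)}, summed until
|term| < 1e−12 (continuing past n = u/2π where terms first decay).  Within
0.1 of a pole u = 2nπ the series is replaced by numerical Boltzmann
integration of the parabolic (Kemble) transmission
1/(1+e^{2π(V−E)/hcν̃}) and the substitution is flagged in the result.
Wigner's κ = 1 + u²/24 serves as the small-u comparator.

Barrier inversion solves V_f − RT ln κ(ν̃) = V_eff for ν̃ by Brent's method
on [50, 6000] cm⁻¹ (interior tolerance 0.01 cm⁻¹, well inside the 1 cm⁻¹
contract); κ is strictly increasing in ν̃, so the root is unique when it
exists, and the error on an empty bracket reports κ at both ends.

**Model choice for the headline inversions.**  The reverse barriers of the
two abstraction steps are not tabulated, so the default inversion model is
the *symmetric* Eckart barrier (V_r = V_f); asymmetric and Bell variants are
exposed and reported side by side by `analysis/01_tunneling_correction.py`.
Symmetric Eckart is the single-parameter choice and is conservative for the
"ν̃ ≥ 2000 cm⁻¹" consistency check (a thinner asymmetric barrier would imply
an even larger wavenumber at fixed barrier reduction).  With it, the
20.0 → 9.6 kcal/mol reduction at 333.15 K implies ν̃ ≈ 4426 cm⁻¹ and the
18.3 → 10.7 kcal/mol reduction at 298.15 K implies ν̃ ≈ 3129 cm⁻¹; under
Bell the same reductions imply ≈ 2892 and ≈ 2115 cm⁻¹.  All four exceed
2000 cm⁻¹.

**Constants** are frozen at 7 significant digits (R = 1.987204e−3
kcal mol⁻¹ K⁻¹, hc/k_B = 1.438777 cm·K, 1 kcal/mol = 349.755 cm⁻¹,
1 hartree = 627.5095 kcal/mol) so double-precision results are
reproducible bit-for-bit.  Stated temperatures 60 °C and 25 °C are taken as
333.15 K and 298.15 K.  Reduced-mass corrections for heavy-atom coupling
are not modeled: the transferring particle is a bare ¹H (²H for KIEs, mass
2.0141 u, with ν̃_D = ν̃_H√(m_H/m_D)).

**Verification strategy.**  The analytic transmission is tested against an
independent Numerov integration of the 1-D Schrödinger equation for the
physical Eckart potential (the length scale fixed from the top curvature,
μω² = λ²(B²−A²)²/8B³), and the thermal averages against trapezoidal
Boltzmann sums over that oracle; Bell is tested against dense numerical
integration of the Kemble transmission.  Agreement is at the 1e−5 level,
asserted at 1–2 % in the suite.

## Profiles and scans

IRC profiles are ordered frames with energies re-zeroed to the first frame;
all barrier arithmetic is on relative energies.  The TS is the interior
global maximum (ties to the lower index, flagged); reactant and product are
the lowest frames on either side.  The "transfer distance" of the migrating
hydrogen is defined operationally as its net displacement across the 5-frame
window centered on the TS (index-based, since even arc-length spacing of IRC
frames cannot be assumed); donor–H and acceptor–H distances at every window
frame are reported alongside so alternative definitions can be audited.

Eckart fits use bounded Levenberg–Marquardt (scipy `curve_fit`) on
(V_f, V_r, L, s₀) with initial guesses from the discrete extrema and the
half-maximum width; the implied wavenumber comes from the analytic curvature
of the fitted form.  Scan minima are refined by a 3-point parabola around
the discrete minimum (boundary or non-convex cases fall back to the grid
point, flagged "no curvature" when the scan is flat).  Scission completion
maps the qualitative criterion — separation beyond 3.0 Å with the spin
"exclusively" on the leaving fragment — to endpoint distance > 3.0 Å AND
leaving-fragment spin fraction ≥ 0.95; the 0.95 is this package's
quantification of "exclusively" and is a keyword argument.  Dihedral scans
are periodic: the curve is tiled over ±360° before prominence-based minimum
detection and results are de-duplicated modulo 360°.

## Site geometry

Dihedrals follow the IUPAC sign convention (the torsion is invariant under
atom-order reversal and antisymmetric under mirror reflection — both are
property-tested).  The Newman classifier places the nitrogen radical
orbital perpendicular to the remaining N–H bond; with the N–H hydrogen at
0° in the projection along Cα–N, the Cα–Cβ bond projects at Φ(Cβ–Cα–N–H)
and the Cα–C bond at Φ + 120° (ideal sp³ offset; the +120° sign is fixed by
L-amino-acid chirality).  The overlap angle ω = |(θ mod 180°) − 90°| folds
the two-lobe orbital symmetry into [0°, 90°].  Zone boundaries 30°/60°
(periplanar/intermediate/clinal) are configurable; they were chosen so the
four qualitative scission outcomes (allowed-not-optimal, impossible,
maximized, impeded) map onto distinct zones.

The contact census takes N/O partners within 3.5 Å of the target
(same-residue atoms excluded, hydrogens ignored).  Square-pyramidal means:
four contacts admit a cyclic basal ordering with adjacent
basal–target–basal angles in [70°, 110°], and any fifth (apical) contact
makes [70°, 110°] angles with all four basal ones.  Fewer than three
contacts is "underdetermined"; four contacts with all pairwise angles in
[95°, 125°] is "tetrahedral-like"; anything else "irregular".

Superposition is the Kabsch SVD solution restricted to proper rotations
(det +1).  Trimming, when enabled, iteratively drops pairs deviating by
more than 2× the current RMSD, with a floor of 70 % of the original pairs —
the deposited-model Cα counts imply some trimming rule was used upstream,
but not which one, so this one is the package's own and both n_used and
n_total are always reported.  PDB conventions: first model only, altloc by
highest occupancy then 'A', residue numbering verbatim.

## Cavity mapping

Voxels (default spacing 0.4 Å; spacing > probe is refused) are blocked
within vdW + probe of any heavy atom (Bondi radii: C 1.70, N 1.55, O 1.52,
S 1.80, Fe 2.00 Å; table configurable).  The exterior is the set of
accessible voxels 26-connected to the box boundary (box = structure bound +
probe + 2 Å margin); remaining accessible components are closed cavities,
volume = voxel count × spacing³.  Surface-connected components are reported
with a flag rather than counted as cavities, so "channel vs closed cavity"
is an explicit property, not a rendering convention.  Bound ligands can be
excluded by residue name before the calculation, matching the practice of
mapping the emptied active site.  Probe radius defaults to 1.0 Å.

## Synthetic data: what it emulates and what it does not

The generators produce the *shapes and invariants* of the study's inputs
with exactly known ground truth: Eckart-profile energetics, a hydrogen that
moves a prescribed net distance within the TS window, scans that stall at a
prescribed minimum (≈ 2.7 Å with residual spin) or complete (monotone to
3.4 Å, full spin transfer), ideal square-pyramidal donor cages, structure
pairs related by an exact rigid motion plus a constructed χ1 change (−60°
vs +50° → 110°), and hollow shells whose accessible volume is analytic.
Noise is isotropic Gaussian with test-chosen σ (0.02–0.05 kcal/mol on
energies, 0.1–0.3 Å on coordinates) — the source study does not
characterize noise for these quantities, so σ values are test parameters,
not claims.  Passing on this data demonstrates correctness of the
*computations*; it does not validate force-field realism, QM/MM energetics,
or crystallographic accuracy, and the structural generators produce
schematic (not stereochemically realistic) protein geometry.  Every
generator is a pure function of (parameters, seed) and emits a
ground-truth sidecar.

## Problem sizes

The suite and drivers use profile lengths of 21–41 frames, 50-seed fit
ensembles, 300–500-atom superpositions, and ~8 Å shells on 0.2–0.4 Å grids
(≈ 10⁵–10⁶ voxels) — sizes at which every analytic/numeric cross-check
resolves well below its asserted tolerance while the whole suite runs in
well under a minute.

## Known limitations

- One-dimensional tunneling only: no variational TST, no multidimensional
  small/large-curvature corrections, no fit to experimental kinetics.
- The symmetric-barrier default for inversion is a declared assumption, not
  a tabulated fact; asymmetric mode exists but needs a reverse barrier.
- The trimming rule, the 0.95 spin threshold, and the 30°/60° Newman
  boundaries quantify qualitative statements; all are configurable.
- No solvent-excluded (Connolly) surfaces, tunnel cost functions or
  electrostatics in the cavity mapper; no mmCIF writing; no remote
  structure fetching (analyses of deposited models require a manual
  download and are exercised here on synthetic emulations instead).
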