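"""Independent numeric oracles used by the test suite.

These deliberately avoid the package's analytic code paths: the barrier
transmission is obtained by direct Numerov integration of the 1-D
Schrodinger equation for the physical Eckart potential, and thermal
transmission coefficients by explicit trapezoidal Boltzmann averaging.
Everything here works in Hartree atomic units.
"""

from __future__ import annotations

import math

import numpy as np

HARTREE_TO_KCAL = 627.5095
HARTREE_TO_CM = 219474.6
AMU_TO_ME = 1822.888
R_KCAL = 1.987204e-3


def eckart_potential_au(V_f_kcal: float, V_r_kcal: float, nu_cm: float, mass_amu: float):
    """Physical Eckart potential matching (V_f, V_r, nu) in atomic units.

    V(x) = A*y/(1+y) + B*y/(1+y)^2,  y = exp(lam*x), with
    A = V1 - V2, B = (sqrt(V1)+sqrt(V2))^2 and lam fixed by the requirement
    that the top curvature reproduces the imaginary frequency:
    mu*omega^2 = lam^2 * (B^2-A^2)^2 / (8*B^3).
    """
    V1 = V_f_kcal / HARTREE_TO_KCAL
    V2 = V_r_kcal / HARTREE_TO_KCAL
    mu = mass_amu * AMU_TO_ME
    omega = nu_cm / HARTREE_TO_CM
    A = V1 - V2
    B = (math.sqrt(V1) + math.sqrt(V2)) ** 2
    lam = omega * math.sqrt(8.0 * mu * B ** 3) / (B ** 2 - A ** 2)

    def V(x):
        y = np.exp(lam * np.asarray(x, dtype=float))
        return A * y / (1.0 + y) + B * y / (1.0 + y) ** 2

    return V, A, lam, mu


def numerov_transmission(E_kcal: float, V_f_kcal: float, V_r_kcal: float,
                         nu_cm: float, mass_amu: float = 1.00783,
                         h: float = 0.01, tail: float = 36.0) -> float:
    """Transmission probability by backward Numerov integration.

    Outgoing plane wave is imposed on the product side; the wavefunction is
    stepped back across the barrier and decomposed into incident + reflected
    waves on the reactant side.  Returns 0 for energies below either
    asymptote.
    """
    V, A, lam, mu = eckart_potential_au(V_f_kcal, V_r_kcal, nu_cm, mass_amu)
    E = E_kcal / HARTREE_TO_KCAL
    if E <= 0.0 or E <= A:
        return 0.0
    k1 = math.sqrt(2.0 * mu * E)            # reactant side (V -> 0)
    k2 = math.sqrt(2.0 * mu * (E - A))      # product side (V -> A)
    half = tail / lam
    # resolve both the potential scale and the oscillations
    h_eff = min(h, 0.2 / max(k1, k2))
    n = int(2.0 * half / h_eff) + 1
    x = np.linspace(-half, half, n)
    hh = x[1] - x[0]
    f = 2.0 * mu * (V(x) - E)
    w = 1.0 - hh * hh * f / 12.0

    psi = np.empty(n, dtype=complex)
    psi[-1] = np.exp(1j * k2 * x[-1])
    psi[-2] = np.exp(1j * k2 * x[-2])
    for i in range(n - 2, 0, -1):
        psi[i - 1] = ((12.0 - 10.0 * w[i]) * psi[i] - w[i + 1] * psi[i + 1]) / w[i - 1]

    # psi(x) = a e^{i k1 x} + b e^{-i k1 x} on the two leftmost points
    m = np.array(
        [[np.exp(1j * k1 * x[0]), np.exp(-1j * k1 * x[0])],
         [np.exp(1j * k1 * x[1]), np.exp(-1j * k1 * x[1])]]
    )
    a, _b = np.linalg.solve(m, psi[:2])
    return float((k2 / k1) / abs(a) ** 2)


def kappa_numerov(V_f_kcal: float, V_r_kcal: float, nu_cm: float, T: float,
                  mass_amu: float = 1.00783, n_grid: int = 600) -> float:
    """Thermal transmission coefficient by trapezoidal Boltzmann averaging
    of the Numerov transmission."""
    kT = R_KCAL * T
    alpha = V_f_kcal / kT
    eps = np.linspace(1e-6, alpha + 40.0, n_grid)
    t = np.array([numerov_transmission(e * kT, V_f_kcal, V_r_kcal, nu_cm, mass_amu)
                  for e in eps])
    integrand = np.exp(alpha - eps) * t
    return float(np.trapezoid(integrand, eps))


def kappa_kemble_numeric(V_kcal: float, nu_cm: float, T: float, n_grid: int = 20000) -> float:
    """Boltzmann average of the parabolic (Kemble) transmission
    1/(1 + exp(2 pi (V - E)/(hc nu))), evaluated by dense trapezoid."""
    kT = R_KCAL * T
    alpha = V_kcal / kT
    c = 2.0 * math.pi * 349.755 / nu_cm  # exponent per kcal/mol
    eps = np.linspace(0.0, alpha + 40.0, n_grid)
    x = c * (V_kcal - eps * kT)
    with np.errstate(over="ignore"):
        t = np.where(x > 700.0, np.exp(-np.minimum(x, 1400.0)), 1.0 / (1.0 + np.exp(np.minimum(x, 700.0))))
    integrand = np.exp(alpha - eps) * t
    return float(np.trapezoid(integrand, eps))


def dihedral_reference(p1, p2, p3, p4) -> float:
    """Independent dihedral via the atan2(cross, dot) construction on
    normal vectors (distinct from the package's praxeides formulation)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    b0 = -b1                          # front arm, p2 -> p1
    axis = b2 / np.linalg.norm(b2)
    v = b0 - np.dot(b0, axis) * axis  # arms projected off the bond axis
    w = b3 - np.dot(b3, axis) * axis
    return math.degrees(math.atan2(np.dot(np.cross(axis, v), w), np.dot(v, w)))
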