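"""Tunneling corrections for hydrogen-atom transfer barriers.

A 1-D Eckart barrier parameterized by the forward/reverse barrier heights and
the transition-state imaginary wavenumber admits an exact transmission
probability T(E).  The thermal transmission coefficient

    kappa(T) = exp(Vf/kBT) / kBT * Int_0^inf T(E) exp(-E/kBT) dE

then converts a classical barrier Vf into an effective barrier
Vf - R*T*ln(kappa).  Alongside the Eckart treatment this module provides
Bell's truncated-parabola series, the Wigner small-u limit, barrier
inversion (which imaginary wavenumber explains a given effective barrier),
and H/D kinetic isotope effects.

Internally the Johnston-Heicklen dimensionless form is used:

    alpha1 = 2*pi*Vf/(hc*nu),  alpha2 = 2*pi*Vr/(hc*nu),  xi = E/Vf
    2*pi*a = 2*sqrt(alpha1*xi) / (alpha1**-0.5 + alpha2**-0.5)
    2*pi*b = 2*sqrt((xi-1)*alpha1 + alpha2) / (alpha1**-0.5 + alpha2**-0.5)
    2*pi*d = 2*sqrt(alpha1*alpha2 - pi**2/4)

    T(E) = 1 - [cosh(2pi(a-b)) + cosh(2pi d)] / [cosh(2pi(a+b)) + cosh(2pi d)]

with cosh(2pi d) -> cos(2pi|d|) when alpha1*alpha2 < pi**2/4, and log-space
evaluation when the cosh arguments would overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .constants import HC_OVER_KB, KCAL_TO_CM, MASS_D, MASS_H, R_KCAL

__all__ = [
    "BarrierSpec",
    "EckartParameters",
    "KappaResult",
    "eckart_transmission",
    "kappa_eckart",
    "kappa_bell",
    "kappa_wigner",
    "effective_barrier",
    "invert_frequency",
    "kie",
    "reduction_percent",
]

#: kappa_eckart refuses above this reduced frequency (deep tunneling).
U_MAX = 60.0

#: Bell series switches to the numerical integral within this distance of a
#: pole u = 2*n*pi.
BELL_POLE_WINDOW = 0.1


@dataclass(frozen=True)
class BarrierSpec:
    """Barrier parameters for a hydrogen-transfer step.

    Parameters
    ----------
    V_forward, V_reverse : float
        Barrier heights in kcal/mol measured from the reactant and product
        asymptotes.  The study-default model is symmetric
        (``V_reverse == V_forward``).
    nu_imag : float
        Magnitude of the transition-state imaginary wavenumber, cm^-1.
    T : float
        Temperature, K.
    mass : float
        Transferring-particle mass in u (protium by default).
    """

    V_forward: float
    V_reverse: float
    nu_imag: float
    T: float
    mass: float = MASS_H

    def __post_init__(self) -> None:
        for name in ("V_forward", "V_reverse", "nu_imag", "T", "mass"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"BarrierSpec.{name} must be finite and > 0, got {v!r}")

    @property
    def u(self) -> float:
        """Reduced frequency hc*nu/(kB*T), dimensionless."""
        return HC_OVER_KB * self.nu_imag / self.T

    @property
    def kT(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return R_KCAL * self.T

    @classmethod
    def symmetric(cls, V: float, nu_imag: float, T: float, mass: float = MASS_H) -> "BarrierSpec":
        return cls(V, V, nu_imag, T, mass)


@dataclass(frozen=True)
class EckartParameters:
    """Dimensionless Johnston-Heicklen parameters of an Eckart barrier."""

    u: float
    alpha1: float
    alpha2: float

    @classmethod
    def from_spec(cls, spec: BarrierSpec) -> "EckartParameters":
        nu = spec.nu_imag
        return cls(
            u=spec.u,
            alpha1=2.0 * math.pi * spec.V_forward * KCAL_TO_CM / nu,
            alpha2=2.0 * math.pi * spec.V_reverse * KCAL_TO_CM / nu,
        )

    @property
    def _denom(self) -> float:
        return self.alpha1 ** -0.5 + self.alpha2 ** -0.5

    def two_pi_a(self, xi: float) -> float:
        return 2.0 * math.sqrt(self.alpha1 * max(xi, 0.0)) / self._denom

    def two_pi_b(self, xi: float) -> float:
        """Real 2*pi*b; raises below the imaginary-branch threshold."""
        arg = (xi - 1.0) * self.alpha1 + self.alpha2
        if arg < 0.0:
            raise ValueError("b imaginary: E below the product asymptote")
        return 2.0 * math.sqrt(arg) / self._denom

    def imaginary_branch(self, xi: float) -> bool:
        return (xi - 1.0) * self.alpha1 + self.alpha2 < 0.0

    def d_term(self) -> tuple[float, bool]:
        """(|2*pi*d|, is_cosh): the argument and whether d is real."""
        disc = self.alpha1 * self.alpha2 - math.pi ** 2 / 4.0
        if disc >= 0.0:
            return 2.0 * math.sqrt(disc), True
        return 2.0 * math.sqrt(-disc), False


@dataclass(frozen=True)
class KappaResult:
    """Transmission coefficient and the effective barrier it implies."""

    kappa: float
    method: str
    effective_barrier: float
    u: float
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "method": self.method,
            "effective_barrier": self.effective_barrier,
            "u": self.u,
            "warnings": list(self.warnings),
        }


def _logcosh(x: float) -> float:
    x = abs(x)
    return x + math.log1p(math.exp(-2.0 * x)) - math.log(2.0)


def eckart_transmission(E: float, spec: BarrierSpec) -> float:
    """Exact Eckart transmission probability T(E), E in kcal/mol >= 0.

    Returns 0 for energies below the product asymptote (no open channel).
    Evaluated in log space so large barriers never overflow to NaN.
    """
    if not math.isfinite(E) or E < 0.0:
        raise ValueError(f"energy must be finite and >= 0, got {E!r}")
    if E == 0.0:
        return 0.0
    par = EckartParameters.from_spec(spec)
    xi = E / spec.V_forward
    if par.imaginary_branch(xi):
        return 0.0
    A = par.two_pi_a(xi)
    B = par.two_pi_b(xi)
    p, q = abs(A - B), A + B
    d_arg, d_is_cosh = par.d_term()

    # log(cosh p + D) and log(cosh q + D) where D = cosh(d) or cos(d)
    if d_is_cosh:
        log_num = np.logaddexp(_logcosh(p), _logcosh(d_arg))
        log_den = np.logaddexp(_logcosh(q), _logcosh(d_arg))
    else:
        c = math.cos(d_arg)  # in [-1, 1], negligible against huge cosh
        lp, lq = _logcosh(p), _logcosh(q)
        np_corr = c * math.exp(-lp) if lp < 700 else 0.0
        nq_corr = c * math.exp(-lq) if lq < 700 else 0.0
        if 1.0 + np_corr <= 0.0:
            return 1.0  # numerator vanished: full transmission
        log_num = lp + math.log1p(np_corr)
        log_den = lq + math.log1p(nq_corr)
    t = -math.expm1(log_num - log_den)
    return min(max(t, 0.0), 1.0)


def _boltzmann_average(transmission, spec: BarrierSpec, epsrel: float = 1e-10) -> float:
    """exp(Vf/kT)/kT * Int T(E) exp(-E/kT) dE via adaptive quadrature.

    Integration variable is eps = E/kT; cutoff Vf/kT + 40 (documented check:
    the result is cutoff-independent beyond Vf + 40 kT).  The classical tail
    above the cutoff is added analytically assuming T(E) = 1 there.
    """
    kT = spec.kT
    alpha = spec.V_forward / kT
    cutoff = alpha + 40.0

    def integrand(eps: float) -> float:
        return math.exp(alpha - eps) * transmission(eps * kT, spec)

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(
            integrand, 0.0, cutoff, epsrel=epsrel, epsabs=0.0, limit=400, points=[alpha]
        )
    # quad's error estimate is conservative once roundoff dominates; reject
    # only genuine non-convergence
    if not math.isfinite(val) or val <= 0.0 or err / val > 1e-4:
        raise ArithmeticError(f"quadrature did not converge for {spec}")
    return val + math.exp(-40.0)  # analytic classical tail


def kappa_eckart(spec: BarrierSpec) -> KappaResult:
    """Thermal Eckart transmission coefficient kappa(T)."""
    if spec.u > U_MAX:
        raise ValueError(
            f"u = {spec.u:.2f} > {U_MAX}: deep-tunneling regime outside validated domain"
        )
    kappa = _boltzmann_average(eckart_transmission, spec)
    return KappaResult(kappa, "eckart", effective_barrier(spec, kappa), spec.u)


def _kemble_transmission(E: float, spec: BarrierSpec) -> float:
    """Parabolic-barrier (Kemble) transmission 1/(1 + exp(2*pi*(V-E)/(hc*nu)))."""
    x = 2.0 * math.pi * (spec.V_forward - E) * KCAL_TO_CM / spec.nu_imag
    if x > 700.0:
        return math.exp(-x)
    return 1.0 / (1.0 + math.exp(x))


def kappa_bell(V_forward: float, nu_imag: float, T: float) -> KappaResult:
    """Bell's truncated-parabola tunneling correction.

    kappa = (u/2)/sin(u/2) + sum_{n>=1} (-1)^n [u/(2n pi - u)] exp[alpha(1 - 2n pi/u)]

    with u = hc*nu/(kB T) and alpha = V/(R T), summed until |term| < 1e-12.
    Within 0.1 of a pole u = 2n pi the series is replaced by numerical
    Boltzmann integration of the Kemble transmission (flagged).
    """
    if V_forward <= 0 or nu_imag <= 0 or T <= 0:
        raise ValueError("V_forward, nu_imag and T must all be > 0")
    u = HC_OVER_KB * nu_imag / T
    if u > U_MAX:
        raise ValueError(
            f"u = {u:.2f} > {U_MAX}: deep-tunneling regime outside validated domain"
        )
    alpha = V_forward / (R_KCAL * T)
    spec = BarrierSpec.symmetric(V_forward, nu_imag, T)
    near_pole = abs(u / (2.0 * math.pi) - round(u / (2.0 * math.pi))) * 2.0 * math.pi < BELL_POLE_WINDOW
    warnings: tuple[str, ...] = ()
    if near_pole and u > 1.0:
        kappa = _boltzmann_average(_kemble_transmission, spec)
        warnings = (f"u = {u:.3f} within {BELL_POLE_WINDOW} of a series pole; "
                    "numerical Kemble integral substituted",)
    else:
        kappa = (u / 2.0) / math.sin(u / 2.0)
        n = 1
        while n < 1000:
            term = ((-1.0) ** n) * (u / (2.0 * n * math.pi - u)) * math.exp(
                alpha * (1.0 - 2.0 * n * math.pi / u)
            )
            kappa += term
            if abs(term) < 1e-12 and 2.0 * n * math.pi > u:
                break
            n += 1
    eff = V_forward - R_KCAL * T * math.log(kappa)
    return KappaResult(kappa, "bell", eff, u, warnings)


def kappa_wigner(nu_imag: float, T: float) -> KappaResult:
    """Wigner's leading-order correction kappa = 1 + u**2/24."""
    if nu_imag <= 0 or T <= 0:
        raise ValueError("nu_imag and T must be > 0")
    u = HC_OVER_KB * nu_imag / T
    kappa = 1.0 + u * u / 24.0
    return KappaResult(kappa, "wigner", float("nan"), u)


def effective_barrier(spec: BarrierSpec, kappa: float) -> float:
    """Tunneling-corrected barrier V_forward - R*T*ln(kappa), kcal/mol."""
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa!r}")
    return spec.V_forward - R_KCAL * spec.T * math.log(kappa)


def reduction_percent(V_forward: float, V_effective: float) -> float:
    """Barrier reduction 100*(Vf - Veff)/Vf, percent."""
    return 100.0 * (V_forward - V_effective) / V_forward


_NU_BRACKET = (50.0, 6000.0)


def _kappa_for_model(model: str, V_forward: float, V_reverse: float | None,
                     T: float, nu: float, mass: float = MASS_H) -> float:
    if model == "eckart-symmetric":
        return kappa_eckart(BarrierSpec.symmetric(V_forward, nu, T, mass)).kappa
    if model == "eckart":
        vr = V_forward if V_reverse is None else V_reverse
        return kappa_eckart(BarrierSpec(V_forward, vr, nu, T, mass)).kappa
    if model == "bell":
        return kappa_bell(V_forward, nu, T).kappa
    raise ValueError(f"unknown model {model!r}")


def invert_frequency(
    V_forward: float,
    V_effective: float,
    T: float,
    model: str = "eckart-symmetric",
    V_reverse: float | None = None,
    mass: float = MASS_H,
) -> tuple[float, tuple[str, ...]]:
    """Imaginary wavenumber whose tunneling correction yields ``V_effective``.

    Solves effective_barrier(kappa_model(nu)) = V_effective by bracketing
    search on [50, 6000] cm^-1 to 1 cm^-1 tolerance.  Returns
    ``(nu_imag, warnings)``.
    """
    if not 0.0 < V_effective <= V_forward:
        raise ValueError(
            f"need 0 < V_effective <= V_forward, got {V_effective} vs {V_forward}"
        )
    gap = V_forward - V_effective
    if gap == 0.0:
        return _NU_BRACKET[0], ("no tunneling required: V_effective equals V_forward",)

    def f(nu: float) -> float:
        return R_KCAL * T * math.log(_kappa_for_model(model, V_forward, V_reverse, T, nu, mass)) - gap

    lo, hi = _NU_BRACKET
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no root in [{lo}, {hi}] cm^-1: residual {flo:.3g} at {lo}, {fhi:.3g} at {hi} "
            f"(kappa too {'large' if flo > 0 else 'small'} across the bracket)"
        )
    nu = optimize.brentq(f, lo, hi, xtol=0.01)
    return float(nu), ()


def kie(spec: BarrierSpec, heavy_mass: float = MASS_D, model: str = "eckart") -> float:
    """H/D kinetic isotope effect of the tunneling correction.

    The heavy-isotope wavenumber is nu * sqrt(m_light/m_heavy); the ratio
    kappa_H/kappa_D is >= 1 for any positive barrier.
    """
    if heavy_mass <= spec.mass:
        raise ValueError("heavy_mass must exceed the light transferring mass")
    nu_d = spec.nu_imag * math.sqrt(spec.mass / heavy_mass)
    if model == "wigner":
        k_h = kappa_wigner(spec.nu_imag, spec.T).kappa
        k_d = kappa_wigner(nu_d, spec.T).kappa
    elif model == "bell":
        k_h = kappa_bell(spec.V_forward, spec.nu_imag, spec.T).kappa
        k_d = kappa_bell(spec.V_forward, nu_d, spec.T).kappa
    else:
        k_h = kappa_eckart(spec).kappa
        k_d = kappa_eckart(
            BarrierSpec(spec.V_forward, spec.V_reverse, nu_d, spec.T, heavy_mass)
        ).kappa
    return k_h / k_d
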