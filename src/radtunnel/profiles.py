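"""Reaction-path and scan-curve analysis.

Consumes tabulated outputs of electronic-structure calculations: intrinsic
reaction coordinate (IRC) profiles as ordered frames with energies, and
bond/dihedral scan curves with optional per-fragment spin populations.
Provides stationary-point detection, migrating-hydrogen transfer distances,
Eckart-form barrier fits (feeding the tunneling module), scission-completion
classification and local-minimum enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .constants import (
    AMU_TO_ME,
    BOHR_TO_ANG,
    HARTREE_TO_CM,
    HARTREE_TO_KCAL,
    MASS_H,
)

__all__ = [
    "PathFrame",
    "ReactionProfile",
    "StationaryPoints",
    "EckartFit",
    "ScanCurve",
    "ScissionAssessment",
    "TransferDistance",
    "detect_stationary_points",
    "transfer_distance",
    "eckart_energy",
    "fit_eckart",
    "implied_wavenumber",
    "analyze_scan",
    "find_local_minima",
]


@dataclass
class PathFrame:
    index: int
    s: float
    energy: float                       # kcal/mol relative to first frame
    coords: np.ndarray | None = None    # (n_atoms, 3), angstrom
    elements: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
            if self.elements and len(self.elements) != len(self.coords):
                raise ValueError(
                    f"frame {self.index}: {len(self.elements)} elements vs "
                    f"{len(self.coords)} coordinates"
                )


@dataclass
class ReactionProfile:
    frames: list[PathFrame]
    atom_map: dict[str, int] = field(default_factory=dict)  # donor/H_transfer/acceptor
    roles: "StationaryPoints | None" = None
    s_units: str = "angstrom"

    def __post_init__(self) -> None:
        s = self.s_values()
        if len(s) >= 2 and not np.all(np.diff(s) > 0):
            raise ValueError("path coordinate s must be strictly increasing")

    def energies(self) -> np.ndarray:
        return np.array([f.energy for f in self.frames], dtype=float)

    def s_values(self) -> np.ndarray:
        return np.array([f.s for f in self.frames], dtype=float)


@dataclass(frozen=True)
class StationaryPoints:
    reactant: int
    ts: int
    product: int
    forward_barrier: float
    reverse_barrier: float
    warnings: tuple[str, ...] = ()


def detect_stationary_points(profile: ReactionProfile) -> StationaryPoints:
    """Locate reactant, transition state and product frames.

    The TS is the interior global energy maximum; reactant and product are
    the lowest frames on either side of it.  A global maximum at a terminus
    means the profile has no interior barrier.
    """
    e = profile.energies()
    if len(e) < 5:
        raise ValueError(f"need >= 5 frames, got {len(e)}")
    ts = int(np.argmax(e))  # argmax takes the lower index on ties
    warnings: tuple[str, ...] = ()
    if ts == 0 or ts == len(e) - 1:
        raise ValueError("no interior barrier: energy maximum at a terminus")
    if np.sum(e == e[ts]) > 1:
        warnings = ("tied maxima: TS assigned to the lowest index",)
    reactant = int(np.argmin(e[: ts + 1]))
    product = ts + int(np.argmin(e[ts:]))
    return StationaryPoints(
        reactant, ts, product,
        forward_barrier=float(e[ts] - e[reactant]),
        reverse_barrier=float(e[ts] - e[product]),
        warnings=warnings,
    )


@dataclass(frozen=True)
class TransferDistance:
    net_displacement: float             # |r_H(last) - r_H(first)| over the window
    window_frames: tuple[int, ...]
    donor_h: tuple[float, ...]          # donor-H distance at each window frame
    acceptor_h: tuple[float, ...]
    warnings: tuple[str, ...] = ()


def transfer_distance(profile: ReactionProfile, window: int = 5) -> TransferDistance:
    """Net displacement of the transferring hydrogen over an odd ``window``
    of frames centered on the TS, with donor-H and acceptor-H distances at
    each window frame.  A window extending past the profile is shrunk
    symmetrically (warned)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if profile.roles is None:
        raise ValueError("roles not assigned: run detect_stationary_points first")
    for key in ("donor", "H_transfer", "acceptor"):
        if key not in profile.atom_map:
            raise ValueError(f"atom_map missing {key!r}")
    ts = profile.roles.ts
    half = window // 2
    warnings: tuple[str, ...] = ()
    shrink = max(half - ts, half - (len(profile.frames) - 1 - ts), 0)
    if shrink > 0:
        half -= shrink
        warnings = (f"window shrunk to {2 * half + 1} frames to fit the profile",)
    idx = tuple(range(ts - half, ts + half + 1))
    ih = profile.atom_map["H_transfer"]
    idn = profile.atom_map["donor"]
    ia = profile.atom_map["acceptor"]
    frames = [profile.frames[i] for i in idx]
    if any(f.coords is None for f in frames):
        raise ValueError("window frames lack coordinates")
    net = float(np.linalg.norm(frames[-1].coords[ih] - frames[0].coords[ih]))
    dh = tuple(float(np.linalg.norm(f.coords[ih] - f.coords[idn])) for f in frames)
    ah = tuple(float(np.linalg.norm(f.coords[ih] - f.coords[ia])) for f in frames)
    return TransferDistance(net, idx, dh, ah, warnings)


# ---------------------------------------------------------------------------
# Eckart fitting

def eckart_energy(s, V_forward: float, V_reverse: float, L: float, s0: float):
    """Asymmetric Eckart profile E(s) = A y/(1+y) + B y/(1+y)^2,
    y = exp(2 pi (s - s0)/L), zero at the reactant asymptote."""
    s = np.asarray(s, dtype=float)
    A = V_forward - V_reverse
    B = (math.sqrt(V_forward) + math.sqrt(V_reverse)) ** 2
    y = np.exp(np.clip(2.0 * math.pi * (s - s0) / L, -500.0, 500.0))
    return A * y / (1.0 + y) + B * y / (1.0 + y) ** 2


def implied_wavenumber(V_forward: float, V_reverse: float, L: float,
                       mass: float = MASS_H) -> float:
    """Imaginary wavenumber (cm^-1) from the analytic curvature of the
    Eckart form at its maximum: mu omega^2 = lam^2 (B^2-A^2)^2 / (8 B^3),
    lam = 2 pi / L."""
    A = V_forward - V_reverse
    B = (math.sqrt(V_forward) + math.sqrt(V_reverse)) ** 2
    lam = 2.0 * math.pi / L                       # 1/angstrom
    vpp = lam ** 2 * (B ** 2 - A ** 2) ** 2 / (8.0 * B ** 3)  # kcal/mol/A^2
    vpp_au = vpp / HARTREE_TO_KCAL * BOHR_TO_ANG ** 2
    omega = math.sqrt(vpp_au / (mass * AMU_TO_ME))
    return omega * HARTREE_TO_CM


@dataclass(frozen=True)
class EckartFit:
    V_forward: float
    V_reverse: float
    L: float
    s0: float
    rss: float
    implied_nu: float


def fit_eckart(points, mass: float = MASS_H, symmetric: bool = False) -> EckartFit:
    """Nonlinear least-squares fit of the (a)symmetric Eckart form to
    (s, energy) samples spanning both asymptotes and the maximum."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 7:
        raise ValueError("need >= 7 (s, energy) points")
    s, e = pts[:, 0], pts[:, 1]
    span = float(e.max() - e.min())
    if span < 1e-6:
        raise ValueError("no barrier detected: flat data")
    imax = int(np.argmax(e))
    if imax in (0, len(e) - 1):
        raise ValueError("no barrier detected: maximum at a terminus")
    vf0 = max(float(e[imax] - e[0]), 1e-3)
    vr0 = max(float(e[imax] - e[-1]), 1e-3)
    # half-maximum width as the length-scale guess
    above = np.where(e > e[imax] / 2.0)[0]
    l0 = max(float(s[above[-1]] - s[above[0]]), float(s[1] - s[0]))
    s00 = float(s[imax])

    if symmetric:
        def model(sv, vf, L, s0):
            return eckart_energy(sv, vf, vf, L, s0)
        p0 = [vf0, l0, s00]
        lower = [1e-6, 1e-6, s.min() - (s.max() - s.min())]
        upper = [np.inf, np.inf, s.max() + (s.max() - s.min())]
    else:
        def model(sv, vf, vr, L, s0):
            return eckart_energy(sv, vf, vr, L, s0)
        p0 = [vf0, vr0, l0, s00]
        lower = [1e-6, 1e-6, 1e-6, s.min() - (s.max() - s.min())]
        upper = [np.inf, np.inf, np.inf, s.max() + (s.max() - s.min())]
    try:
        popt, _ = optimize.curve_fit(model, s, e, p0=p0, bounds=(lower, upper), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Eckart fit did not converge (initial guess {p0}): {exc}") from exc
    if symmetric:
        vf, L, s0 = popt
        vr = vf
    else:
        vf, vr, L, s0 = popt
    rss = float(np.sum((model(s, *popt) - e) ** 2))
    return EckartFit(float(vf), float(vr), float(L), float(s0), rss,
                     implied_wavenumber(float(vf), float(vr), float(L), mass))


# ---------------------------------------------------------------------------
# scan curves

@dataclass
class ScanCurve:
    x: np.ndarray
    energy: np.ndarray
    spins: dict[str, np.ndarray] = field(default_factory=dict)
    kind: str = "distance"              # distance | dihedral

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.x.shape != self.energy.shape:
            raise ValueError("x and energy must have the same length")
        d = np.diff(self.x)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("scanned coordinate must be strictly monotone")
        self.spins = {k: np.asarray(v, dtype=float) for k, v in self.spins.items()}
        for k, v in self.spins.items():
            if v.shape != self.x.shape:
                raise ValueError(f"spin column {k!r} length mismatch")


@dataclass(frozen=True)
class ScissionAssessment:
    x_min: float
    e_min: float
    endpoint_distance: float
    leaving_spin_fraction: float | None
    status: str                         # complete | incomplete | undetermined
    monotone_decreasing: bool
    warnings: tuple[str, ...] = ()


def _quadratic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabola through (i-1, i, i+1); falls back to the grid point
    at the boundary or for degenerate curvature."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    if a <= 0:
        return float(x1), float(y1)
    b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    xm = -b / (2.0 * a)
    if not (min(x0, x2) <= xm <= max(x0, x2)):
        return float(x1), float(y1)
    c = y1 - a * x1 ** 2 - b * x1
    return float(xm), float(a * xm ** 2 + b * xm + c)


def analyze_scan(curve: ScanCurve, completion_distance: float = 3.0,
                 spin_threshold: float = 0.95, leaving: str | None = None) -> ScissionAssessment:
    """Assess a bond-scission distance scan.

    The scission is complete when the scan endpoint exceeds
    ``completion_distance`` (default 3.0 A) AND the unpaired spin has moved
    essentially entirely (fraction >= ``spin_threshold``) onto the leaving
    fragment; without spin columns the status is undetermined.  ``leaving``
    names the spin column of the leaving fragment (default: first column).
    """
    if len(curve.x) < 5:
        raise ValueError("need >= 5 scan points")
    x, e = curve.x, curve.energy
    warnings: tuple[str, ...] = ()
    imin = int(np.argmin(e))
    if np.sum(e == e[imin]) > 1:
        warnings += ("tied minima: lowest coordinate reported",)
    if float(e.max() - e.min()) < 1e-9:
        warnings += ("no curvature: flat scan",)
        x_min, e_min = float(x.min()), float(e[0])
    else:
        x_min, e_min = _quadratic_refine(x, e, imin)
    endpoint = float(x[-1])
    monotone = bool(np.all(np.diff(e) <= 1e-12))
    frac: float | None = None
    if curve.spins:
        name = leaving if leaving is not None else next(iter(curve.spins))
        if name not in curve.spins:
            raise KeyError(f"no spin column {name!r}")
        total = sum(v[-1] for v in curve.spins.values())
        frac = float(curve.spins[name][-1] / total) if total > 0 else 0.0
        status = "complete" if (endpoint > completion_distance and frac >= spin_threshold) \
            else "incomplete"
    else:
        status = "undetermined"
        warnings += ("spin populations absent: completion undetermined",)
    return ScissionAssessment(x_min, e_min, endpoint, frac, status, monotone, warnings)


@dataclass(frozen=True)
class LocalMinimum:
    x: float
    energy: float
    is_global: bool


def find_local_minima(curve: ScanCurve, prominence: float = 0.5) -> list[LocalMinimum]:
    """Interior local minima with at least ``prominence`` kcal/mol depth.

    Dihedral scans are treated as periodic on 360 degrees: the curve is
    tiled before peak finding and minima are de-duplicated modulo 360, so a
    well straddling +/-180 is reported once.
    """
    if len(curve.x) < 5:
        raise ValueError("need >= 5 scan points")
    x, e = curve.x, curve.energy
    if x[0] > x[-1]:
        x, e = x[::-1], e[::-1]
    if curve.kind == "dihedral":
        # drop a duplicated wrap point (e.g. both -180 and +180 sampled)
        if math.isclose((x[-1] - x[0]) % 360.0, 0.0, abs_tol=1e-6) and \
                math.isclose(e[0], e[-1], abs_tol=1e-6):
            x, e = x[:-1], e[:-1]
        xx = np.concatenate([x - 360.0, x, x + 360.0])
        ee = np.concatenate([e, e, e])
        idx, _ = signal.find_peaks(-ee, prominence=prominence)
        found = {}
        for i in idx:
            xm, em = _quadratic_refine(xx, ee, int(i))
            xm_w = ((xm + 180.0) % 360.0) - 180.0
            key = round(xm_w, 3)
            if key not in found:
                found[key] = (xm_w, em)
        minima = sorted(found.values())
    else:
        idx, _ = signal.find_peaks(-e, prominence=prominence)
        minima = [_quadratic_refine(x, e, int(i)) for i in idx]
    if not minima:
        return []
    e_best = min(m[1] for m in minima)
    return [LocalMinimum(xm, em, math.isclose(em, e_best, abs_tol=1e-12)) for xm, em in minima]
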