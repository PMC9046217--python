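"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its parameters and seed, and returns
the generated object together with a machine-readable ground-truth record,
so every analysis stage can be tested against known answers without any
quantum-chemistry or crystallographic input.  Geometry is schematic: atoms
are placed to realize prescribed distances, dihedrals and displacements
exactly, not to satisfy a force field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Atom, Structure
from .profiles import PathFrame, ReactionProfile, ScanCurve, eckart_energy

__all__ = [
    "GroundTruth",
    "make_irc",
    "make_scan",
    "make_dihedral_scan",
    "make_site",
    "make_structure_pair",
    "make_hollow_structure",
]


@dataclass(frozen=True)
class GroundTruth:
    kind: str
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"kind": self.kind, **self.parameters}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# IRC profiles

def make_irc(V_forward: float = 20.0, V_reverse: float = 20.0, L: float = 0.4,
             h_displacement: float = 0.45, n_frames: int = 21,
             noise: float = 0.0, seed: int = 0) -> tuple[ReactionProfile, GroundTruth]:
    """Synthetic IRC for a donor-H-acceptor hydrogen transfer.

    Energies follow the asymmetric Eckart form (+ optional Gaussian noise);
    the transferring H moves ``h_displacement`` net across the 5-frame
    window centered on the TS (linear steps inside the window, stationary
    outside), emulating the short transfer distances of a compact active
    site.
    """
    _require(n_frames >= 9 and n_frames % 2 == 1, "n_frames must be odd and >= 9")
    _require(V_forward > 0 and V_reverse > 0 and L > 0, "barriers and width must be > 0")
    _require(h_displacement >= 0, "h_displacement must be >= 0")
    _require(noise >= 0, "noise must be >= 0")
    rng = np.random.default_rng(seed)
    # center the grid on the analytic barrier top so the sampled maximum
    # equals the prescribed barrier height
    A = V_forward - V_reverse
    B = (math.sqrt(V_forward) + math.sqrt(V_reverse)) ** 2
    s_max = L / (2.0 * math.pi) * math.log((A + B) / (B - A))
    s = s_max + np.linspace(-3.0 * L, 3.0 * L, n_frames)
    e_clean = eckart_energy(s, V_forward, V_reverse, L, 0.0)
    e = e_clean + (rng.normal(0.0, noise, n_frames) if noise > 0 else 0.0)
    ts = int(np.argmax(e_clean))

    elements = ("N", "H", "C", "C", "C")
    donor = np.array([0.0, 0.0, 0.0])
    acceptor = np.array([2.7, 0.0, 0.0])
    spect1 = np.array([-1.4, 0.8, 0.3])
    spect2 = np.array([3.6, -0.9, 0.5])
    frames = []
    for i in range(n_frames):
        # H advances h/4 per frame inside [ts-2, ts+2], frozen outside
        k = min(max(i, ts - 2), ts + 2) - (ts - 2)
        hx = 1.0 + h_displacement * k / 4.0
        coords = np.vstack([donor, [hx, 0.0, 0.0], acceptor, spect1, spect2])
        frames.append(PathFrame(i, float(s[i]), float(e[i] - e[0]), coords, elements))
    profile = ReactionProfile(frames, atom_map={"donor": 0, "H_transfer": 1, "acceptor": 2})
    truth = GroundTruth("irc", {
        "V_forward": V_forward, "V_reverse": V_reverse, "L": L,
        "h_displacement": h_displacement, "ts_index": ts,
        "noise": noise, "seed": seed,
    })
    return profile, truth


# ---------------------------------------------------------------------------
# scan curves

def make_scan(minimum_x: float = 2.70, depth: float = 1.0,
              endpoint_spin: float = 0.55, seed: int = 0,
              x_range: tuple[float, float] = (2.2, 3.4), n_points: int = 25,
              monotone: bool = False,
              with_spins: bool = True) -> tuple[ScanCurve, GroundTruth]:
    """Synthetic C-C distance scan with per-fragment spin columns.

    Default shape: a parabolic well of the given ``depth`` at ``minimum_x``
    (the energy rises again at larger separation, an incomplete scission);
    ``monotone=True`` yields a monotonically decreasing curve with its
    minimum at the endpoint (a completed scission).  The leaving-fragment
    spin rises smoothly to ``endpoint_spin``; the remaining fragment
    carries the complement.
    """
    _require(x_range[0] < minimum_x < x_range[1] or monotone,
             "minimum_x must lie inside x_range")
    _require(0.0 <= endpoint_spin <= 1.0, "endpoint_spin must be in [0, 1]")
    x = np.linspace(x_range[0], x_range[1], n_points)
    if monotone:
        e = -depth * (x - x[0]) / (x[-1] - x[0])
    else:
        e = depth * ((x - minimum_x) / (x_range[1] - x_range[0])) ** 2
        e -= e[0]
    spins = {}
    if with_spins:
        ramp = 1.0 / (1.0 + np.exp(-(x - 0.5 * (x[0] + x[-1])) / 0.12))
        ramp = (ramp - ramp[0]) / (ramp[-1] - ramp[0])
        leaving = 0.05 + (endpoint_spin - 0.05) * ramp
        spins = {"leaving": leaving, "remaining": 1.0 - leaving}
    curve = ScanCurve(x, e, spins, kind="distance")
    truth = GroundTruth("scan", {
        "minimum_x": float(x[-1]) if monotone else minimum_x,
        "depth": depth, "endpoint_spin": endpoint_spin if with_spins else None,
        "endpoint_x": float(x[-1]), "monotone": monotone, "seed": seed,
    })
    return curve, truth


def make_dihedral_scan(wells: tuple[tuple[float, float], ...] = ((-48.0, 5.0), (55.0, 3.5)),
                       width: float = 30.0, n_points: int = 73,
                       noise: float = 0.0, seed: int = 0) -> tuple[ScanCurve, GroundTruth]:
    """Periodic dihedral scan with prescribed (position, depth) wells on
    [-180, 180), emulating the amino-group rotation scans that locate the
    reactive substrate orientations."""
    rng = np.random.default_rng(seed)
    x = np.linspace(-180.0, 180.0, n_points)
    e = np.zeros_like(x)
    for pos, depth in wells:
        d = (x - pos + 180.0) % 360.0 - 180.0
        e -= depth * np.exp(-0.5 * (d / width) ** 2)
    e -= e.min()
    if noise > 0:
        e = e + rng.normal(0.0, noise, n_points)
    curve = ScanCurve(x, e, {}, kind="dihedral")
    truth = GroundTruth("dihedral-scan", {"wells": list(map(list, wells)),
                                          "width": width, "noise": noise, "seed": seed})
    return curve, truth


# ---------------------------------------------------------------------------
# structures

def _atom(serial: int, name: str, element: str, resname: str, chain: str,
          resnum: int, xyz, het: bool = False) -> Atom:
    return Atom(serial, name, element, "", resname, chain, resnum, "",
                np.asarray(xyz, dtype=float), 1.0, 20.0, het)


def make_site(n_basal: int = 4, basal_distance: float = 2.8, apical: bool = True,
              jitter: float = 0.0, seed: int = 0,
              apical_distance: float = 2.9) -> tuple[Structure, GroundTruth]:
    """Toy phenolate pocket: a target oxygen anion with hydroxyl donors at
    ideal square-pyramidal positions (basal ring in the equatorial plane,
    optional apical donor on +z) plus Gaussian positional jitter.

    ``jitter`` is the r.m.s. 3-D displacement of each donor in angstrom
    (per-coordinate sigma = jitter/sqrt(3))."""
    _require(n_basal >= 0, "n_basal must be >= 0")
    _require(jitter >= 0, "jitter must be >= 0")
    rng = np.random.default_rng(seed)
    atoms = [
        _atom(1, "OH", "O", "TYR", "A", 500, (0.0, 0.0, 0.0), het=True),
        _atom(2, "CZ", "C", "TYR", "A", 500, (0.0, 0.0, -1.36), het=True),
    ]
    serial = 3
    resnum = 1
    positions = []
    for k in range(n_basal):
        ang = 2.0 * math.pi * k / max(n_basal, 1)
        positions.append(np.array([basal_distance * math.cos(ang),
                                   basal_distance * math.sin(ang), 0.0]))
    if apical:
        positions.append(np.array([0.0, 0.0, apical_distance]))
    sigma = jitter / math.sqrt(3.0)
    for pos in positions:
        p = pos + (rng.normal(0.0, sigma, 3) if jitter > 0 else 0.0)
        cb = p * (1.0 + 1.5 / np.linalg.norm(p))
        atoms.append(_atom(serial, "OG", "O", "SER", "A", resnum, p))
        atoms.append(_atom(serial + 1, "CB", "C", "SER", "A", resnum, cb))
        serial += 2
        resnum += 1
    truth = GroundTruth("site", {
        "n_basal": n_basal, "basal_distance": basal_distance, "apical": apical,
        "n_donors": len(positions), "jitter": jitter, "seed": seed,
    })
    return Structure(atoms, name="synthetic-site"), truth


def _place_by_zmatrix(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                      bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position a fourth atom D with |CD| = bond, angle(BCD) = angle and
    dihedral(ABCD) = dihedral (NeRF construction)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def _backbone(n_residues: int) -> list[tuple[str, str, np.ndarray]]:
    """Schematic helical backbone (N, CA, C, O, CB per residue)."""
    out = []
    rise, radius, turn = 1.5, 2.3, math.radians(100.0)
    for i in range(n_residues):
        th = i * turn
        ca = np.array([radius * math.cos(th), radius * math.sin(th), rise * i])
        th_n = th - 0.35
        n = np.array([radius * math.cos(th_n), radius * math.sin(th_n), rise * i - 0.8])
        th_c = th + 0.35
        c = np.array([radius * math.cos(th_c), radius * math.sin(th_c), rise * i + 0.8])
        o = c + np.array([0.4, 0.4, 1.0])
        cb = ca + 1.53 * (ca - np.array([0.0, 0.0, rise * i])) / radius \
            + np.array([0.0, 0.0, 0.6])
        out.append(("N", "N", n))
        out.append(("CA", "C", ca))
        out.append(("CB", "C", cb))
        out.append(("C", "C", c))
        out.append(("O", "O", o))
    return out


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * k + (1.0 - math.cos(a)) * (k @ k)


def make_structure_pair(rotation: float = 37.0, translation: float = 8.0,
                        noise: float = 0.0, chi1_pair: tuple[float, float] = (-60.0, 50.0),
                        n_residues: int = 60, seed: int = 0
                        ) -> tuple[Structure, Structure, GroundTruth]:
    """Paired structures related by a rigid motion plus a serine chi1 change.

    A schematic polyalanine helix with one serine (at the middle residue,
    OG placed by exact dihedral construction) is duplicated; the copy is
    rotated by ``rotation`` degrees about a seeded random axis, translated
    by ``translation`` A, perturbed with isotropic Gaussian noise of sigma
    ``noise`` per coordinate, and its serine chi1 set to the second value.
    """
    _require(n_residues >= 5, "need >= 5 residues")
    rng = np.random.default_rng(seed)
    ser_res = n_residues // 2 + 1
    bb = _backbone(n_residues)

    def build(chain_noise: float, chi1_val: float, rot: np.ndarray | None,
              trans: np.ndarray | None) -> Structure:
        atoms: list[Atom] = []
        serial = 1
        coords_per_res: dict[int, dict[str, np.ndarray]] = {}
        for i, (name, elem, xyz) in enumerate(bb):
            resnum = i // 5 + 1
            p = xyz.copy()
            if rot is not None:
                p = rot @ p + trans
            if chain_noise > 0:
                p = p + rng.normal(0.0, chain_noise, 3)
            coords_per_res.setdefault(resnum, {})[name] = p
        for resnum in sorted(coords_per_res):
            resname = "SER" if resnum == ser_res else "ALA"
            res = coords_per_res[resnum]
            for name in ("N", "CA", "CB", "C", "O"):
                atoms.append(_atom(serial, name, name[0], resname, "A", resnum, res[name]))
                serial += 1
            if resname == "SER":
                og = _place_by_zmatrix(res["N"], res["CA"], res["CB"], 1.41, 110.5, chi1_val)
                atoms.append(_atom(serial, "OG", "O", "SER", "A", resnum, og))
                serial += 1
        return Structure(atoms)

    a = build(0.0, chi1_pair[0], None, None)
    axis = rng.normal(size=3)
    rot = _rotation_matrix(axis, rotation)
    direction = rng.normal(size=3)
    trans = translation * direction / np.linalg.norm(direction)
    b = build(noise, chi1_pair[1], rot, trans)
    d = abs(chi1_pair[0] - chi1_pair[1]) % 360.0
    truth = GroundTruth("structure-pair", {
        "rotation": rotation, "translation": translation, "noise": noise,
        "chi1_pair": list(chi1_pair), "chi1_delta": min(d, 360.0 - d),
        "serine_residue": ser_res, "n_residues": n_residues, "seed": seed,
    })
    return a, b, truth


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_hollow_structure(shell_radius: float = 8.0, channel_width: float | None = None,
                          atom_spacing: float = 1.4, seed: int = 0,
                          gate_residues: tuple[int, int] = (76, 181)
                          ) -> tuple[Structure, GroundTruth]:
    """Hollow carbon shell with an optional open channel to the exterior.

    Atoms tile a sphere of the given radius densely enough that no probe
    leaks between them.  With ``channel_width`` set, atoms within
    (channel_width/2 + r_vdW) of the +z axis are removed, leaving a tube of
    the requested free width; the two rim atoms closest to the opening are
    renamed TYR with the given residue numbers so channel-lining detection
    can be tested against known gate residues.
    """
    _require(shell_radius > 3.0, "shell_radius too small")
    r_c = 1.70  # carbon vdW, matches the default cavity radii
    n = int(math.ceil(4.0 * math.pi * shell_radius ** 2 / atom_spacing ** 2))
    pts = _fibonacci_sphere(n, shell_radius)
    gate_ids = []
    if channel_width is not None:
        _require(channel_width > 0, "channel_width must be > 0")
        rho = np.linalg.norm(pts[:, :2], axis=1)
        keep = ~((pts[:, 2] > 0) & (rho < channel_width / 2.0 + r_c))
        removed_any = bool((~keep).sum())
        _require(removed_any, "channel_width too small to open the shell")
        pts = pts[keep]
        # rim atoms: nearest survivors to the channel axis on the +z side
        rho = np.linalg.norm(pts[:, :2], axis=1)
        rim = np.where(pts[:, 2] > 0)[0]
        rim = rim[np.argsort(rho[rim])][:2]
        gate_ids = sorted(int(i) for i in rim)
    atoms = []
    for i, p in enumerate(pts):
        if i in gate_ids:
            resnum = gate_residues[gate_ids.index(i)]
            atoms.append(_atom(i + 1, "CZ", "C", "TYR", "A", resnum, p, het=False))
        else:
            atoms.append(_atom(i + 1, "C1", "C", "SPH", "B", i + 1, p, het=True))
    truth = GroundTruth("hollow-structure", {
        "shell_radius": shell_radius, "channel_width": channel_width,
        "atom_spacing": atom_spacing, "n_atoms": len(atoms),
        "gate_residues": list(gate_residues) if channel_width else [],
        "seed": seed,
    })
    return Structure(atoms, name="synthetic-shell"), truth
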