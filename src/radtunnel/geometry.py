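"""Structure-based geometry: dihedrals, Newman-projection scission
classification, polar-contact census, trimmed superposition and side-chain
rotamer deltas.

The Newman classifier encodes the regiospecificity argument for radical C-C
beta-scission: after H abstraction from the substrate amino group, the
singly-occupied nitrogen p orbital lies perpendicular to the remaining N-H
bond.  Scission of a Calpha-X bond requires overlap between that orbital and
the breaking bond, so the angular distance omega between the bond and the
nearest orbital lobe (folded to [0, 90] degrees) classifies each candidate
bond as periplanar (favorable), intermediate, or clinal (forbidden).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "NewmanAssessment",
    "BondZone",
    "ContactCensus",
    "SuperpositionResult",
    "dihedral",
    "newman_assess",
    "contact_census",
    "superpose",
    "superpose_structures",
    "chi1",
    "chi1_delta",
]


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    altloc: str
    resname: str
    chain: str
    resnum: int
    icode: str
    coords: np.ndarray
    occupancy: float = 1.0
    b: float = 20.0
    het: bool = False

    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)

    def key(self) -> tuple:
        return (self.chain, self.resnum, self.icode, self.name, self.altloc)


@dataclass
class Structure:
    """Flat atom list with residue/chain identity (single model)."""

    atoms: list[Atom] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]

    def select(self, selector: str) -> list[Atom]:
        """Resolve a ``chain:resnum[:icode]:atomname`` selector."""
        parts = selector.split(":")
        if len(parts) == 3:
            chain, resnum, name = parts
            icode = ""
        elif len(parts) == 4:
            chain, resnum, icode, name = parts
        else:
            raise ValueError(f"bad selector {selector!r}: expected chain:resnum[:icode]:atomname")
        resnum = int(resnum)
        return [
            a for a in self.atoms
            if a.chain == chain and a.resnum == resnum and a.icode.strip() == icode
            and a.name == name
        ]

    def one(self, selector: str) -> Atom:
        hits = self.select(selector)
        if len(hits) != 1:
            listing = ", ".join(f"{a.chain}:{a.resnum}:{a.name}({a.altloc or '-'})" for a in hits)
            raise ValueError(
                f"selector {selector!r} matched {len(hits)} atoms: [{listing}]"
            )
        return hits[0]

    def residue(self, chain: str, resnum: int, icode: str = "") -> dict[str, Atom]:
        return {
            a.name: a for a in self.atoms
            if a.chain == chain and a.resnum == resnum and a.icode.strip() == icode
        }


# ---------------------------------------------------------------------------
# dihedrals

def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180].

    Looking from p2 toward p3, a clockwise rotation carrying the p1 arm onto
    the p4 arm is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for i, b in enumerate((b1, b2, b3)):
        if np.linalg.norm(b) < 1e-8:
            raise ValueError(f"degenerate geometry: points {i + 1} and {i + 2} coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise ValueError("degenerate geometry: three consecutive points are collinear")
    b2n = b2 / np.linalg.norm(b2)
    ang = math.degrees(math.atan2(float(np.dot(np.cross(n1, n2), b2n)), float(np.dot(n1, n2))))
    if ang <= -180.0 + 1e-9:
        ang += 360.0
    return ang


# ---------------------------------------------------------------------------
# Newman classification

@dataclass(frozen=True)
class BondZone:
    bond: str
    theta: float            # projected dihedral of the bond, degrees
    omega: float            # orbital-bond overlap angle folded to [0, 90]
    zone: str               # periplanar | intermediate | clinal


@dataclass(frozen=True)
class NewmanAssessment:
    phi_NH: float
    bonds: tuple[BondZone, ...]

    def zone(self, bond: str) -> str:
        for b in self.bonds:
            if b.bond == bond:
                return b.zone
        raise KeyError(bond)


def _omega_from_theta(theta: float) -> float:
    """Angular distance from the bond at projection angle theta to the
    orbital lobes at +/-90 (perpendicular to the remaining N-H), folded to
    [0, 90].  Two-lobe symmetry makes this |(theta mod 180) - 90|."""
    return abs((theta % 180.0) - 90.0)


def _zone(omega: float, boundaries: tuple[float, float]) -> str:
    lo, hi = boundaries
    if omega <= lo:
        return "periplanar"
    if omega <= hi:
        return "intermediate"
    return "clinal"


def newman_assess(
    phi_NH: float,
    substituent_offset: float = 120.0,
    boundaries: tuple[float, float] = (30.0, 60.0),
) -> NewmanAssessment:
    """Classify the two candidate scission bonds from the product dihedral.

    ``phi_NH`` is Phi(Cbeta-Calpha-N-H) of the aminyl-radical product.  In
    the Newman projection along Calpha-N (H of the remaining N-H at 0), the
    Calpha-Cbeta bond projects at ``phi_NH`` and the Calpha-C(carboxyl)
    bond at ``phi_NH + substituent_offset`` (ideal sp3, +120 for an L-amino
    acid).  omega measures each bond's misalignment with the radical
    orbital; zones: periplanar <= 30 < intermediate <= 60 < clinal.
    """
    if not math.isfinite(phi_NH):
        raise ValueError("phi_NH must be finite")
    bonds = []
    for label, theta in (("Ca-Cb", phi_NH), ("Ca-C", phi_NH + substituent_offset)):
        om = _omega_from_theta(theta)
        bonds.append(BondZone(label, theta % 360.0, om, _zone(om, boundaries)))
    return NewmanAssessment(phi_NH, tuple(bonds))


# ---------------------------------------------------------------------------
# contact census

@dataclass(frozen=True)
class Contact:
    atom: Atom
    distance: float
    donor_class: str


@dataclass(frozen=True)
class ContactCensus:
    target: Atom
    contacts: tuple[Contact, ...]
    geometry: str  # square-pyramidal | tetrahedral-like | irregular | underdetermined


_HYDROXYL = {"OG", "OG1", "OH"}


def _donor_class(a: Atom) -> str:
    if a.resname in ("HOH", "WAT"):
        return "water"
    if a.name in _HYDROXYL:
        return "hydroxyl"
    if a.name == "N":
        return "backbone-N"
    if a.name == "O":
        return "backbone-O"
    return "side-chain" if a.element.upper() in ("N", "O") else "other"


def _angle_at(center: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a - center, b - center
    c = float(np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _square_pyramid_test(center: np.ndarray, pts: list[np.ndarray],
                         lo: float = 70.0, hi: float = 110.0) -> bool:
    """True if 4 of the points admit a cyclic basal ordering with adjacent
    basal-target-basal angles in [lo, hi], and any remaining (apical) point
    makes angles in [lo, hi] with all four basal ones."""
    n = len(pts)
    if n not in (4, 5):
        return False
    idx = range(n)
    apical_choices = [None] if n == 4 else list(idx)
    for apical in apical_choices:
        basal = [i for i in idx if i != apical]
        if apical is not None:
            if not all(lo <= _angle_at(center, pts[apical], pts[j]) <= hi for j in basal):
                continue
        first = basal[0]
        for perm in itertools.permutations(basal[1:]):
            order = (first,) + perm
            ok = all(
                lo <= _angle_at(center, pts[order[k]], pts[order[(k + 1) % 4]]) <= hi
                for k in range(4)
            )
            if ok:
                return True
    return False


def contact_census(structure: Structure, target: str, cutoff: float = 3.5,
                   include_hydrogens: bool = False) -> ContactCensus:
    """Polar contacts (N/O partners) of one target atom within ``cutoff`` A,
    excluding same-residue atoms, with coordination-geometry assessment."""
    t = structure.one(target)
    contacts = []
    for a in structure.atoms:
        if a.residue_id() == t.residue_id():
            continue
        if a.element.upper() not in ("N", "O"):
            continue
        if not include_hydrogens and a.element.upper() in ("H", "D"):
            continue
        d = float(np.linalg.norm(a.coords - t.coords))
        if d <= cutoff:
            contacts.append(Contact(a, d, _donor_class(a)))
    contacts.sort(key=lambda c: c.distance)
    pts = [c.atom.coords for c in contacts]
    if len(contacts) < 3:
        geometry = "underdetermined"
    elif _square_pyramid_test(t.coords, pts):
        geometry = "square-pyramidal"
    elif len(contacts) == 4 and all(
        95.0 <= _angle_at(t.coords, a, b) <= 125.0
        for a, b in itertools.combinations(pts, 2)
    ):
        geometry = "tetrahedral-like"
    else:
        geometry = "irregular"
    return ContactCensus(t, tuple(contacts), geometry)


# ---------------------------------------------------------------------------
# superposition

@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray     # 3x3 proper rotation
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_used: int
    n_total: int
    rounds: int
    used_mask: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation + translation mapping mov onto ref."""
    rc, mc = ref.mean(axis=0), mov.mean(axis=0)
    h = (mov - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose(ref: np.ndarray, mov: np.ndarray, trim: bool = False,
              trim_factor: float = 2.0, keep_floor: float = 0.70) -> SuperpositionResult:
    """Rigid least-squares superposition (Kabsch), optionally with
    iterative outlier trimming.

    With ``trim`` on, pairs deviating by more than ``trim_factor`` times the
    current RMSD are dropped and the fit repeated, until no pair is dropped
    or fewer than ``keep_floor`` of the pairs would remain.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mov must be matching (n, 3) arrays")
    n_total = ref.shape[0]
    if n_total < 3:
        raise ValueError(f"need >= 3 paired atoms, got {n_total}")
    mask = np.ones(n_total, dtype=bool)
    rounds = 0
    rot, transl, rmsd = _kabsch(ref, mov)
    while trim:
        moved = mov @ rot.T + transl
        dev = np.sqrt(np.sum((moved - ref) ** 2, axis=1))
        new_mask = mask & (dev <= max(trim_factor * rmsd, 1e-12))
        if new_mask.sum() < max(3, int(math.ceil(keep_floor * n_total))):
            break
        if new_mask.sum() == mask.sum():
            break
        mask = new_mask
        rot, transl, rmsd = _kabsch(ref[mask], mov[mask])
        rounds += 1
    return SuperpositionResult(rot, transl, rmsd, int(mask.sum()), n_total, rounds, mask)


def superpose_structures(ref: Structure, mov: Structure, atom_name: str = "CA",
                         trim: bool = False) -> SuperpositionResult:
    """Superpose two structures on atoms named ``atom_name``, paired by
    (chain, residue number, insertion code)."""
    ref_map = {a.residue_id(): a for a in ref.atoms if a.name == atom_name}
    mov_map = {a.residue_id(): a for a in mov.atoms if a.name == atom_name}
    common = sorted(set(ref_map) & set(mov_map), key=lambda k: (k[0], k[1], k[2]))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} paired {atom_name} atoms")
    r = np.array([ref_map[k].coords for k in common])
    m = np.array([mov_map[k].coords for k in common])
    return superpose(r, m, trim=trim)


# ---------------------------------------------------------------------------
# chi1

_GAMMA_ATOM = {
    "SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1", "ILE": "CG1",
    "ALA": None,  # no chi1
}


def chi1(structure: Structure, chain: str, resnum: int, icode: str = "") -> float:
    """First side-chain dihedral N-CA-CB-Xgamma in degrees."""
    res = structure.residue(chain, resnum, icode)
    if not res:
        raise ValueError(f"residue {chain}:{resnum}{icode} not found")
    resname = next(iter(res.values())).resname
    gname = _GAMMA_ATOM.get(resname, "CG")
    if gname is None:
        raise ValueError(f"residue {resname} {chain}:{resnum} has no chi1")
    missing = [n for n in ("N", "CA", "CB", gname) if n not in res]
    if missing:
        raise ValueError(
            f"residue {chain}:{resnum} missing atoms {missing} required for chi1"
        )
    return dihedral(res["N"].coords, res["CA"].coords, res["CB"].coords, res[gname].coords)


def chi1_delta(structA: Structure, structB: Structure, residue: str) -> float:
    """|delta chi1| between two structures, folded to [0, 180] degrees.

    ``residue`` is ``chain:resnum[:icode]``.
    """
    parts = residue.split(":")
    chain, resnum = parts[0], int(parts[1])
    icode = parts[2] if len(parts) > 2 else ""
    a = chi1(structA, chain, resnum, icode)
    b = chi1(structB, chain, resnum, icode)
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)
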