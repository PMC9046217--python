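"""Readers and writers for the interchange formats.

PDB structures are parsed with gemmi (first model by default; altloc
duplicates resolved to the highest occupancy, then 'A').  Reaction profiles
travel as multi-frame XYZ with an ``E=<value>`` token (optionally
``s=<value>``) on each comment line; scan curves as CSV with header
``x,energy[,spin_<fragment>...]``.  Cavity grids can be written as OpenDX
scalar fields or PDB pseudo-atom clouds for visualization.

All writers use stable ordering and fixed float formats (energies %.6f,
coordinates %.3f) so identical inputs yield byte-identical files.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .cavity import Grid3D
from .geometry import Atom, Structure
from .profiles import PathFrame, ReactionProfile, ScanCurve

__all__ = [
    "read_structure",
    "write_structure",
    "read_profile",
    "write_profile",
    "read_curve",
    "write_curve",
    "write_dx",
    "write_grid_pdb",
    "ENERGY_UNITS",
]

log = logging.getLogger("radtunnel")

#: accepted energy units -> conversion factor to kcal/mol
ENERGY_UNITS = {
    "kcal/mol": 1.0,
    "kcal": 1.0,
    "kj/mol": 1.0 / 4.184,
    "kj": 1.0 / 4.184,
    "hartree": 627.5095,
}


def _pick_altloc(atoms: list) -> "gemmi.Atom":
    best = max(atoms, key=lambda a: (a.occ, -ord(a.altloc or "A")))
    return best


def read_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Parse a PDB file into a Structure (heavy validation left to gemmi).

    Only ATOM/HETATM/MODEL/ENDMDL/TER records contribute; anything else is
    dropped with a debug log.  Altloc groups collapse to the
    highest-occupancy member ('A' on ties, logged).
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed PDB: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[model_index]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            groups: dict[str, list] = {}
            for a in res:
                groups.setdefault(a.name, []).append(a)
            for name, group in groups.items():
                if len(group) > 1:
                    log.debug("%s %s/%s %s: %d altlocs, keeping highest occupancy",
                              path.name, chain.name, res.seqid.num, name, len(group))
                a = _pick_altloc(group)
                atoms.append(Atom(
                    serial=a.serial,
                    name=name,
                    element=a.element.name.upper(),
                    altloc=(a.altloc or "").strip(),
                    resname=res.name,
                    chain=chain.name,
                    resnum=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    b=a.b_iso,
                    het=res.het_flag == "H",
                ))
    if not atoms:
        raise ValueError(f"{path}: no atoms parsed")
    return Structure(atoms, name=path.stem)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as single-model PDB (ATOM/HETATM + TER + END)."""
    path = Path(path)
    lines = []
    last_chain = None
    for a in structure.atoms:
        if last_chain is not None and a.chain != last_chain:
            lines.append("TER")
        last_chain = a.chain
        rec = "HETATM" if a.het else "ATOM  "
        lines.append(
            f"{rec}{a.serial:>5} {_format_atom_name(a.name, a.element)}"
            f"{(a.altloc or ' ')[:1]}{a.resname:>3} {a.chain[:1]}{a.resnum:>4}"
            f"{(a.icode or ' ')[:1]}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b:6.2f}          {a.element:>2}"
        )
    lines += ["TER", "END"]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# multi-frame XYZ

def _comment_tokens(comment: str) -> dict[str, float]:
    out = {}
    for tok in comment.split():
        if "=" in tok:
            k, _, v = tok.partition("=")
            try:
                out[k] = float(v)
            except ValueError:
                continue
    return out


def read_profile(path: str | Path, units: str = "kcal/mol",
                 atom_map: dict[str, int] | None = None) -> ReactionProfile:
    """Read a multi-frame XYZ reaction profile.

    Each frame's comment line must carry ``E=<value>`` (in ``units``) and
    may carry ``s=<value>``; energies are converted to kcal/mol and
    re-zeroed to the first frame, s defaults to the frame index.
    """
    units = units.lower()
    if units not in ENERGY_UNITS:
        raise ValueError(f"unknown energy units {units!r}; accepted: {sorted(ENERGY_UNITS)}")
    factor = ENERGY_UNITS[units]
    lines = Path(path).read_text().splitlines()
    frames: list[PathFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 1}: expected atom count") from exc
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            raise ValueError(f"{path}: truncated frame starting at line {i + 1}")
        tokens = _comment_tokens(lines[i + 1])
        if "E" not in tokens:
            raise ValueError(f"{path}: frame {len(frames)}: missing E= token on line {i + 2}")
        coords, elements = [], []
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {i + 3 + j}: malformed atom line")
            elements.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        s = tokens.get("s", float(len(frames)))
        frames.append(PathFrame(len(frames), s, tokens["E"] * factor,
                                np.array(coords), tuple(elements)))
        i += 2 + natoms
    if not frames:
        raise ValueError(f"{path}: no frames")
    e0 = frames[0].energy
    for f in frames:
        f.energy -= e0
    return ReactionProfile(frames, atom_map=atom_map or {})


def write_profile(profile: ReactionProfile, path: str | Path,
                  units: str = "kcal/mol") -> None:
    factor = ENERGY_UNITS[units.lower()]
    out = []
    for f in profile.frames:
        if f.coords is None:
            raise ValueError(f"frame {f.index} has no coordinates")
        out.append(str(len(f.coords)))
        out.append(f"E={f.energy / factor:.6f} s={f.s:.6f}")
        for el, xyz in zip(f.elements, f.coords):
            out.append(f"{el:<2} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# scan CSV

def read_curve(path: str | Path, kind: str = "distance") -> ScanCurve:
    """Read a scan curve CSV with header ``x,energy[,spin_<fragment>...]``."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2 or cols[0] != "x" or cols[1] != "energy":
        raise ValueError(f"{path}: expected header x,energy[,spin_...], got {cols}")
    spins = {}
    for c in cols[2:]:
        if not c.startswith("spin_"):
            raise ValueError(f"{path}: unexpected column {c!r}")
        spins[c[len("spin_"):]] = df[c].to_numpy(dtype=float)
    try:
        return ScanCurve(df["x"].to_numpy(dtype=float),
                         df["energy"].to_numpy(dtype=float), spins, kind=kind)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_curve(curve: ScanCurve, path: str | Path) -> None:
    data = {"x": curve.x, "energy": curve.energy}
    for name, v in curve.spins.items():
        data[f"spin_{name}"] = v
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# grids

def write_dx(grid: Grid3D, path: str | Path) -> None:
    """Write a grid as an OpenDX scalar field (VMD/PyMOL readable)."""
    nx, ny, nz = grid.dims
    o = grid.origin
    sp = grid.spacing
    head = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.3f} {o[1]:.3f} {o[2]:.3f}",
        f"delta {sp:.3f} 0.000 0.000",
        f"delta 0.000 {sp:.3f} 0.000",
        f"delta 0.000 0.000 {sp:.3f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    vals = grid.values.astype(float).ravel(order="C")
    body = []
    for i in range(0, len(vals), 3):
        body.append(" ".join(f"{v:.1f}" for v in vals[i:i + 3]))
    tail = ['attribute "dep" string "positions"',
            'object "density" class field']
    Path(path).write_text("\n".join(head + body + tail) + "\n")


def write_grid_pdb(grid: Grid3D, path: str | Path, mask: np.ndarray | None = None) -> None:
    """Write occupied voxels as a HETATM pseudo-atom cloud."""
    mask = grid.values.astype(bool) if mask is None else mask
    centers = grid.voxel_centers(mask)
    lines = []
    for i, c in enumerate(centers, start=1):
        serial = i % 100000
        lines.append(
            f"HETATM{serial:>5}  C   VOX A{(i % 10000):>4}    "
            f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
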