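"""Grid-based cavity and channel detection at a given probe radius.

A voxel is probe-accessible when its center lies at least (vdW radius +
probe) from every heavy-atom center.  Flood fill from the box boundary
through accessible voxels (26-connectivity) defines the exterior; accessible
voxels not reachable from the boundary are closed interior cavities.
Surface-connected accessible regions (channels, clefts) are labeled too but
flagged rather than counted as cavities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, spatial

from .geometry import Structure

__all__ = [
    "BONDI_RADII",
    "Grid3D",
    "CavityComponent",
    "CavityMap",
    "cavity_map",
    "lining_residues",
    "hollow_shell_expected_volume",
]

#: Bondi van der Waals radii (angstrom) for the elements of deposited
#: metalloprotein models; anything absent falls back to carbon.
BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "FE": 2.00, "P": 1.80}
_DEFAULT_RADIUS = 1.70

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Grid3D:
    origin: np.ndarray           # (3,) angstrom
    spacing: float
    values: np.ndarray           # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid must be 3-D with dims >= 2")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.spacing


@dataclass(frozen=True)
class CavityComponent:
    component_id: int
    voxel_count: int
    volume: float                # angstrom^3
    bounding_box: tuple[tuple[float, float], ...]
    surface_connected: bool


@dataclass
class CavityMap:
    grid: Grid3D                 # closed-cavity (interior accessible) voxels
    labels: np.ndarray           # component label per accessible voxel (0 = blocked)
    components: list[CavityComponent]
    probe_radius: float

    def cavities(self) -> list[CavityComponent]:
        return [c for c in self.components if not c.surface_connected]

    def total_cavity_volume(self) -> float:
        return sum(c.volume for c in self.cavities())


def cavity_map(structure: Structure, probe: float = 1.0, spacing: float = 0.4,
               exclude: tuple[str, ...] = (), margin: float = 2.0,
               radii: dict[str, float] | None = None) -> CavityMap:
    """Map probe-accessible interior cavities of a structure.

    ``exclude`` lists residue names removed before the calculation (bound
    ligands and substrate, following the convention of computing the empty
    active-site cavity).  Refuses spacing > probe (undersampling would let
    the probe leak between voxels).
    """
    if spacing > probe:
        raise ValueError(f"spacing {spacing} > probe {probe}: grid undersamples the probe")
    radii = dict(BONDI_RADII if radii is None else radii)
    atoms = [a for a in structure.heavy_atoms() if a.resname not in exclude]
    if not atoms:
        raise ValueError("no heavy atoms after exclusion")
    coords = np.array([a.coords for a in atoms])
    r_atom = np.array([radii.get(a.element.upper(), _DEFAULT_RADIUS) for a in atoms])

    pad = probe + margin
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 2)
    blocked = np.zeros(tuple(dims), dtype=bool)

    # rasterize each atom's blocked sphere on its local subgrid
    for c, r in zip(coords, r_atom):
        rr = r + probe
        i_lo = np.maximum(np.floor((c - rr - lo) / spacing - 0.5).astype(int), 0)
        i_hi = np.minimum(np.ceil((c + rr - lo) / spacing - 0.5).astype(int) + 1, dims)
        if np.any(i_lo >= i_hi):
            continue
        ax = [lo[k] + (np.arange(i_lo[k], i_hi[k]) + 0.5) * spacing - c[k] for k in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = blocked[i_lo[0]:i_hi[0], i_lo[1]:i_hi[1], i_lo[2]:i_hi[2]]
        sub |= d2 <= rr * rr

    accessible = ~blocked
    labels, n_comp = ndimage.label(accessible, structure=_CONN26)

    boundary_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            boundary_labels.update(np.unique(face[face > 0]).tolist())

    components: list[CavityComponent] = []
    interior = np.zeros_like(accessible)
    voxel_vol = spacing ** 3
    slices = ndimage.find_objects(labels)
    for comp_id in range(1, n_comp + 1):
        mask = labels == comp_id
        count = int(mask.sum())
        surf = comp_id in boundary_labels
        if not surf:
            interior |= mask
        sl = slices[comp_id - 1]
        bbox = tuple(
            (float(lo[k] + sl[k].start * spacing), float(lo[k] + sl[k].stop * spacing))
            for k in range(3)
        )
        components.append(
            CavityComponent(comp_id, count, count * voxel_vol, bbox, surf)
        )
    components.sort(key=lambda c: (c.surface_connected, -c.volume))
    return CavityMap(Grid3D(lo, spacing, interior), labels, components, probe)


def lining_residues(cav: CavityMap, structure: Structure, component_id: int,
                    shell: float = 4.5) -> list[tuple[str, int, str, float]]:
    """Residues owning a heavy atom within ``shell`` A of any voxel of the
    component, as (chain, resnum, resname, min_distance) sorted by distance."""
    mask = cav.labels == component_id
    if not mask.any():
        raise ValueError(f"no component with id {component_id}")
    centers = cav.grid.voxel_centers(mask)
    tree = spatial.cKDTree(centers)
    per_residue: dict[tuple[str, int, str], float] = {}
    resnames: dict[tuple[str, int, str], str] = {}
    for a in structure.heavy_atoms():
        d, _ = tree.query(a.coords, k=1)
        key = a.residue_id()
        if d <= shell and d < per_residue.get(key, math.inf):
            per_residue[key] = float(d)
            resnames[key] = a.resname
    out = [(chain, resnum, resnames[(chain, resnum, icode)], dist)
           for (chain, resnum, icode), dist in per_residue.items()]
    out.sort(key=lambda t: t[3])
    return out


def hollow_shell_expected_volume(shell_radius: float, probe: float,
                                 atom_radius: float = BONDI_RADII["C"]) -> float:
    """Analytic accessible volume of a spherical shell of atoms: a ball of
    radius (shell_radius - atom_radius - probe)."""
    r = shell_radius - atom_radius - probe
    if r <= 0:
        return 0.0
    return 4.0 / 3.0 * math.pi * r ** 3
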