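"""Solvent-accessible surface area by the Shrake–Rupley method.

Each atom is inflated by the probe radius and covered with a deterministic
quasi-uniform point set (a Fibonacci/golden-angle spiral); a test point is
exposed when it lies outside every neighbouring atom's inflated sphere.  The
atom's area is then

    area = (exposed points / total points) × 4π (r_vdw + r_probe)²

The point set is fixed, so results are exactly reproducible with no random
seed.  Neighbour candidates come from a k-d tree query at radius
r_i + r_j + 2·r_probe, the largest centre distance at which sphere j can
occlude sphere i.

The van der Waals radii are a small fixed table (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20 Å) with a 1.70 Å fallback for other elements; the fallback
can be disabled, in which case an unknown element raises ``RadiiError``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConsistencyError, RadiiError
from .structures import Structure, ResidueKey

__all__ = [
    "DEFAULT_RADII",
    "SasaParams",
    "SasaProfile",
    "fibonacci_sphere",
    "shrake_rupley",
    "residue_sasa",
    "write_residue_sasa",
]

DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}

FALLBACK_RADIUS = 1.70


@dataclass(frozen=True)
class SasaParams:
    """Parameters of the numerical SASA computation.

    probe_radius : water-probe radius in Å (1.4 is the conventional value).
    points_per_atom : quadrature points per sphere; ≥ 92; 960 gives ≲1 %
        error on an isolated sphere.
    radii_table : element symbol → van der Waals radius, Å.
    fallback_radius : radius for elements missing from the table, or None to
        make unknown elements an error.
    """

    probe_radius: float = 1.4
    points_per_atom: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    fallback_radius: float | None = FALLBACK_RADIUS

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.points_per_atom < 92:
            raise ValueError("points_per_atom must be >= 92")
        if any(r <= 0 for r in self.radii_table.values()):
            raise ValueError("all radii must be > 0")

    def radius_of(self, element: str) -> float:
        el = element.capitalize()
        if el in self.radii_table:
            return self.radii_table[el]
        if self.fallback_radius is not None:
            return self.fallback_radius
        raise RadiiError(f"no van der Waals radius for element {element!r} and fallback disabled")


@dataclass
class SasaProfile:
    """Per-atom and per-residue accessible areas for one structure."""

    per_atom: dict[int, float]  # atom serial → Å²
    per_residue: dict[ResidueKey, float]  # residue key → Å²
    params: SasaParams
    structure_id: str

    def total(self) -> float:
        return float(sum(self.per_atom.values()))


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    # latitudes at midpoints avoid clustering at the poles
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(structure: Structure, params: SasaParams | None = None) -> SasaProfile:
    """Compute SASA of every atom (and residue) of ``structure``."""
    if params is None:
        params = SasaParams()

    atoms = structure.atoms
    coords = structure.coords()
    radii = np.array([params.radius_of(a.element) for a in atoms])
    expanded = radii + params.probe_radius
    serials = np.array([a.serial for a in atoms])

    unit = fibonacci_sphere(params.points_per_atom)
    n_atoms = len(atoms)
    tree = cKDTree(coords)
    max_exp = expanded.max()

    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        # any sphere j with |c_i - c_j| < e_i + e_j can occlude points of i
        cand = tree.query_ball_point(coords[i], expanded[i] + max_exp)
        cand = [j for j in cand if j != i]
        pts = coords[i] + expanded[i] * unit
        if cand:
            cj = coords[cand]
            ej = expanded[cand]
            d = np.linalg.norm(cj - coords[i], axis=0 if cj.ndim == 1 else 1)
            keep = d < expanded[i] + ej
            cj, ej = cj[keep], ej[keep]
            exposed = np.ones(len(pts), dtype=bool)
            for c, e in zip(cj, ej):
                if not exposed.any():
                    break
                d2 = np.einsum("ij,ij->i", pts - c, pts - c)
                exposed &= d2 >= e * e
            frac = exposed.sum() / params.points_per_atom
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2

    per_atom = {int(s): float(a) for s, a in zip(serials, areas)}
    per_residue: dict[ResidueKey, float] = {}
    for res in structure.residues:
        per_residue[res.key] = float(sum(per_atom[a.serial] for a in res.atoms))
    return SasaProfile(
        per_atom=per_atom,
        per_residue=per_residue,
        params=params,
        structure_id=structure.id,
    )


def residue_sasa(profile: SasaProfile, structure: Structure) -> dict[ResidueKey, float]:
    """Aggregate a per-atom profile to per-residue areas.

    Raises ``ConsistencyError`` if the profile does not cover exactly the
    atoms of ``structure``.
    """
    serials = {a.serial for a in structure.atoms}
    if serials != set(profile.per_atom):
        raise ConsistencyError(
            f"profile (structure {profile.structure_id!r}) does not match "
            f"structure {structure.id!r}: atom serials differ"
        )
    return {
        res.key: float(sum(profile.per_atom[a.serial] for a in res.atoms))
        for res in structure.residues
    }


def write_residue_sasa(profile: SasaProfile, path) -> None:
    """Tab-separated per-residue SASA export: chain, resnum, icode, area."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tarea\n")
        for (chain, num, icode), area in profile.per_residue.items():
            fh.write(f"{chain}\t{num}\t{icode}\t{area:.4f}\n")
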