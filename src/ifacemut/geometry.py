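"""Distance queries and docking-restraint derivation.

Provides the minimum inter-residue atom distance used by the anchor-proximity
rule, the centroid-closest-residue selection used to pick a representative
residue of a binding region, and the construction of a maximum-distance
attraction restraint between two chains for restrained docking (e.g. a 20 Å
restraint between an anchor residue of one chain and the residue closest to
the centroid of a mapped binding region of the other).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import GeometryError
from .structures import Structure, Residue, ResidueKey

__all__ = [
    "RestraintSpec",
    "min_atom_distance",
    "centroid_closest_residue",
    "build_restraint",
    "write_restraint",
]


@dataclass(frozen=True)
class RestraintSpec:
    """A maximum-distance restraint between residues of two different chains."""

    residue_a: ResidueKey
    residue_b: ResidueKey
    max_distance: float  # Å
    rationale: str = ""

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if self.residue_a[0] == self.residue_b[0]:
            raise ValueError("restraint residues must be on different chains")


def _qualifying_coords(res: Residue, heavy_only: bool) -> np.ndarray:
    coords = res.heavy_coords() if heavy_only else res.coords
    if coords.size == 0:
        raise GeometryError(
            f"residue {res.key} has no {'heavy ' if heavy_only else ''}atoms"
        )
    return coords


def min_atom_distance(
    structure: Structure,
    res_a: ResidueKey | tuple[str, int],
    res_b: ResidueKey | tuple[str, int],
    heavy_only: bool = True,
) -> float:
    """Minimum pairwise Euclidean distance between atoms of two residues.

    A residue compared with itself has distance 0.  ``heavy_only`` (default)
    ignores hydrogens — predicted models usually lack them, so heavy-atom
    distance is the reproducible reading of "nearest atoms".
    """
    ra = structure.residue(res_a)
    rb = structure.residue(res_b)
    if ra.key == rb.key:
        # still validate that the residue has qualifying atoms
        _qualifying_coords(ra, heavy_only)
        return 0.0
    ca = _qualifying_coords(ra, heavy_only)
    cb = _qualifying_coords(rb, heavy_only)
    return float(cdist(ca, cb).min())


def centroid_closest_residue(
    structure: Structure,
    chain: str,
    region: tuple[int, int],
    ca_only: bool = False,
) -> ResidueKey:
    """Residue of ``chain`` whose centroid is closest to the region centroid.

    The region ``[start, end]`` is inclusive in author numbering.  The
    centroid is the unweighted mean of all atom coordinates of the region's
    residues (or of Cα atoms only with ``ca_only``); each candidate residue
    is represented by its own atom centroid.  Ties are broken by the lower
    residue number.
    """
    lo, hi = region
    members = [
        res
        for res in structure.residues
        if res.chain_id == chain and lo <= res.seq_number <= hi
    ]
    if not members:
        raise ValueError(f"region {region} of chain {chain!r} contains no residues")

    def res_coords(res: Residue) -> np.ndarray:
        if ca_only:
            coords = np.array([a.coord for a in res.atoms if a.name == "CA"])
            if coords.size == 0:
                raise GeometryError(f"residue {res.key} has no CA atom")
            return coords
        return res.coords

    all_coords = np.vstack([res_coords(r) for r in members])
    centroid = all_coords.mean(axis=0)

    best: Residue | None = None
    best_d = np.inf
    for res in members:
        d = float(np.linalg.norm(res_coords(res).mean(axis=0) - centroid))
        if d < best_d or (d == best_d and best is not None and res.seq_number < best.seq_number):
            best, best_d = res, d
    assert best is not None
    return best.key


def build_restraint(
    structure: Structure,
    anchor: ResidueKey | tuple[str, int],
    partner_chain: str,
    partner_region: tuple[int, int],
    max_distance: float = 20.0,
    ca_only: bool = False,
) -> RestraintSpec:
    """Pair an anchor residue with the centroid residue of a partner region.

    The default 20 Å bound deliberately leaves a large rotational space for
    docking decoys while keeping the partner region in reach of the anchor.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be > 0")
    anchor_res = structure.residue(anchor)
    partner = centroid_closest_residue(structure, partner_chain, partner_region, ca_only)
    return RestraintSpec(
        residue_a=anchor_res.key,
        residue_b=partner,
        max_distance=float(max_distance),
        rationale=(
            f"anchor {anchor_res.chain_id}:{anchor_res.seq_number} to residue "
            f"closest to centroid of {partner_chain}:{partner_region[0]}-{partner_region[1]}"
        ),
    )


def write_restraint(spec: RestraintSpec, path) -> None:
    """Plain-text attraction-restraint record for restrained-docking input."""
    a, b = spec.residue_a, spec.residue_b
    with open(path, "w") as fh:
        fh.write("# attraction restraint: chain:resnum chain:resnum max_distance_A\n")
        fh.write(f"{a[0]}:{a[1]}\t{b[0]}:{b[1]}\t{spec.max_distance:g}\n")
        if spec.rationale:
            fh.write(f"# {spec.rationale}\n")
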