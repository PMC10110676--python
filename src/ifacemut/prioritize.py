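"""Saturation enumeration and the four-rule prioritization cascade.

Candidate substitutions are every non-wild-type amino acid (19 per position)
at each interface residue.  The cascade then, in order:

1. excludes substitutions observed as standing population variation
   (presence in the supplied variant list alone excludes, no frequency
   considered);
2. keeps substitutions whose ΔΔG in the monomer lies inside a window around
   zero (default −0.5..+0.5 kcal/mol, inclusive) — the protein must still
   fold;
3. keeps substitutions destabilising the complex, ΔΔG_full strictly greater
   than the threshold (default 2 kcal/mol) — the interface must be
   disrupted;
4. keeps substitutions at residues no more than a maximum distance (default
   5 Å, inclusive) from the nearest atom of any anchor residue — proximity
   to positions of known biological importance.

The audit attributes each removed candidate to the FIRST rule, in this
order, that rejects it, so the counts always conserve:
input = surviving + Σ removed.  Because the four predicates are independent,
the surviving SET does not depend on rule order — only the attribution does.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .ddg import DdgRecord, Substitution
from .errors import MissingDataError
from .geometry import min_atom_distance
from .interface import InterfaceResidue
from .structures import Structure, ResidueKey

__all__ = [
    "RuleConfig",
    "ShortlistEntry",
    "Shortlist",
    "enumerate_substitutions",
    "distance_annotation",
    "apply_rules",
    "write_shortlist",
    "write_audit",
]

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class RuleConfig:
    """Parameters of the four-rule cascade (defaults follow the study design)."""

    monomer_window: tuple[float, float] = (-0.5, 0.5)  # kcal/mol, inclusive
    full_threshold: float = 2.0  # kcal/mol, strict >
    anchor_residues: tuple[ResidueKey, ...] = ()
    anchor_max_distance: float = 5.0  # Å, inclusive ("no more than")
    population_variants: frozenset[Substitution] = frozenset()
    require_all_anchors: bool = False  # True: within range of EVERY anchor
    heavy_only: bool = True

    def __post_init__(self):
        lo, hi = self.monomer_window
        if lo > hi:
            raise ValueError("monomer_window low must be <= high")
        object.__setattr__(self, "population_variants", frozenset(self.population_variants))
        object.__setattr__(self, "anchor_residues", tuple(self.anchor_residues))


@dataclass(frozen=True)
class ShortlistEntry:
    substitution: Substitution
    ddg_monomer: float
    ddg_full: float
    min_anchor_distance: float  # Å


@dataclass
class Shortlist:
    entries: list[ShortlistEntry]
    audit: dict[str, int] = field(default_factory=dict)

    def substitutions(self) -> set[Substitution]:
        return {e.substitution for e in self.entries}


def enumerate_substitutions(interface: list[InterfaceResidue]) -> list[Substitution]:
    """All 19 non-wild-type substitutions at every interface residue.

    Residues with a non-canonical ('X') wild type are skipped with a logged
    warning.  Order is deterministic: residues in the given order, mutant
    letters alphabetical.
    """
    out: list[Substitution] = []
    for res in interface:
        if res.aa not in AA_ALPHABET:
            logger.warning(
                "skipping non-canonical interface residue %s:%s (%s)",
                res.chain_id, res.seq_number, res.aa,
            )
            continue
        for mut in AA_ALPHABET:
            if mut != res.aa:
                out.append(
                    Substitution(
                        chain=res.chain_id,
                        position=res.seq_number,
                        wt_aa=res.aa,
                        mut_aa=mut,
                    )
                )
    return out


def distance_annotation(
    candidates: list[Substitution],
    structure: Structure,
    anchors: list[ResidueKey] | tuple[ResidueKey, ...],
    heavy_only: bool = True,
) -> dict[Substitution, float]:
    """Minimum over anchors of the nearest-atom distance to each candidate's residue."""
    if not anchors:
        raise ValueError("at least one anchor residue is required")
    per_residue: dict[tuple[str, int], float] = {}
    out = {}
    for cand in candidates:
        rk = (cand.chain, cand.position)
        if rk not in per_residue:
            per_residue[rk] = min(
                min_atom_distance(structure, rk, anchor, heavy_only=heavy_only)
                for anchor in anchors
            )
        out[cand] = per_residue[rk]
    return out


def apply_rules(
    candidates: list[Substitution],
    ddg_records: list[DdgRecord] | dict[Substitution, DdgRecord],
    structure: Structure,
    config: RuleConfig,
) -> Shortlist:
    """Run the four-rule cascade and return the shortlist with its audit.

    ``ddg_records`` must contain one aggregated record per candidate.
    Survivors are ranked by ΔΔG_full descending (most interface-disrupting
    first), ties broken by (chain, position, mutant letter).
    """
    if not isinstance(ddg_records, dict):
        ddg_map = {rec.substitution: rec for rec in ddg_records}
    else:
        ddg_map = ddg_records
    missing = [c for c in candidates if c not in ddg_map]
    if missing:
        raise MissingDataError(
            "no ΔΔG record for candidate(s): " + ", ".join(str(m) for m in missing[:10])
            + ("..." if len(missing) > 10 else "")
        )

    use_distance_rule = bool(config.anchor_residues)
    _dist_cache: dict[tuple[str, int], list[float]] = {}

    def anchor_distances(cand: Substitution) -> list[float]:
        rk = (cand.chain, cand.position)
        if rk not in _dist_cache:
            _dist_cache[rk] = [
                min_atom_distance(structure, rk, a, heavy_only=config.heavy_only)
                for a in config.anchor_residues
            ]
        return _dist_cache[rk]

    lo, hi = config.monomer_window
    audit = {
        "input": len(candidates),
        "removed_by_population": 0,
        "removed_by_monomer_window": 0,
        "removed_by_full_threshold": 0,
        "removed_by_distance": 0,
        "surviving": 0,
    }
    survivors: list[ShortlistEntry] = []
    for cand in candidates:
        rec = ddg_map[cand]
        if cand in config.population_variants:
            audit["removed_by_population"] += 1
            continue
        if not (lo <= rec.ddg_monomer <= hi):
            audit["removed_by_monomer_window"] += 1
            continue
        if not (rec.ddg_full > config.full_threshold):
            audit["removed_by_full_threshold"] += 1
            continue
        if use_distance_rule:
            all_d = anchor_distances(cand)
            within = (
                all(d <= config.anchor_max_distance for d in all_d)
                if config.require_all_anchors
                else min(all_d) <= config.anchor_max_distance
            )
            if not within:
                audit["removed_by_distance"] += 1
                continue
            dist = min(all_d)
        else:
            dist = float("nan")
        survivors.append(
            ShortlistEntry(
                substitution=cand,
                ddg_monomer=rec.ddg_monomer,
                ddg_full=rec.ddg_full,
                min_anchor_distance=dist,
            )
        )
    survivors.sort(
        key=lambda e: (
            -e.ddg_full,
            e.substitution.chain,
            e.substitution.position,
            e.substitution.mut_aa,
        )
    )
    audit["surviving"] = len(survivors)
    assert audit["input"] == audit["surviving"] + sum(
        audit[k] for k in audit if k.startswith("removed_by_")
    )
    return Shortlist(entries=survivors, audit=audit)


def write_shortlist(shortlist: Shortlist, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tposition\twt\tmut\tddg_monomer\tddg_full\tmin_anchor_distance\n")
        for e in shortlist.entries:
            s = e.substitution
            fh.write(
                f"{s.chain}\t{s.position}\t{s.wt_aa}\t{s.mut_aa}\t"
                f"{e.ddg_monomer:.6f}\t{e.ddg_full:.6f}\t{e.min_anchor_distance:.6f}\n"
            )


def write_audit(shortlist: Shortlist, path) -> None:
    with open(path, "w") as fh:
        json.dump(shortlist.audit, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_population_variants(path) -> frozenset[Substitution]:
    """Population-variant list as TSV: chain, position, wt, mut (with header)."""
    subs = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("chain"):
            raise ValueError("expected header line starting with 'chain'")
        for raw in fh:
            if not raw.strip():
                continue
            chain, position, wt, mut = raw.rstrip("\n").split("\t")[:4]
            subs.add(Substitution(chain=chain, position=int(position), wt_aa=wt, mut_aa=mut))
    return frozenset(subs)


def write_population_variants(variants, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tposition\twt\tmut\n")
        for v in sorted(variants):
            fh.write(f"{v.chain}\t{v.position}\t{v.wt_aa}\t{v.mut_aa}\n")
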