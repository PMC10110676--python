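"""Interface-residue detection by SASA difference.

A residue of the target chain is called an interface residue when its
accessible surface in the isolated chain exceeds its accessible surface in
the full complex by at least ``min_delta`` Å² — complex formation can only
bury surface, so the per-residue difference is always non-negative.

There is no universal ΔSASA cutoff for calling a residue "interface"; the
default of 1.0 Å² is inclusive and exposed as a parameter so the count can
be tuned when real docked models are analysed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import IfacemutError
from .sasa import SasaParams, shrake_rupley
from .structures import Structure, ResidueKey, subset

__all__ = ["InterfaceResidue", "interface_residues", "write_interface_report"]


@dataclass(frozen=True)
class InterfaceResidue:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa: str
    delta_sasa: float  # Å², monomer minus complex
    rank: int  # 1-based, by descending delta_sasa

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)


def interface_residues(
    complex_structure: Structure,
    target_chain: str,
    partner_chains: set[str] | list[str] | str,
    params: SasaParams | None = None,
    min_delta: float = 1.0,
) -> list[InterfaceResidue]:
    """Interface residues of ``target_chain`` against ``partner_chains``.

    Computes SASA of the target chain alone and within the complex restricted
    to target ∪ partner chains, and returns residues with
    ``delta_sasa >= min_delta`` sorted by descending delta (ties broken by
    (chain, seq_number) ascending).  Deterministic for fixed parameters.
    """
    if isinstance(partner_chains, str):
        partner_chains = {partner_chains}
    partner_chains = set(partner_chains)
    if target_chain in partner_chains:
        raise IfacemutError(
            f"target chain {target_chain!r} also listed as a partner chain"
        )
    present = set(complex_structure.chains)
    missing = ({target_chain} | partner_chains) - present
    if missing:
        raise KeyError(f"chain(s) {sorted(missing)} not present in structure")

    if params is None:
        params = SasaParams()

    mono = subset(complex_structure, {target_chain})
    pair = subset(complex_structure, {target_chain} | partner_chains)
    prof_mono = shrake_rupley(mono, params)
    prof_pair = shrake_rupley(pair, params)

    hits = []
    for res in mono.residues:
        delta = prof_mono.per_residue[res.key] - prof_pair.per_residue[res.key]
        if delta >= min_delta:
            hits.append((res, delta))
    hits.sort(key=lambda rd: (-rd[1], rd[0].chain_id, rd[0].seq_number))
    return [
        InterfaceResidue(
            chain_id=res.chain_id,
            seq_number=res.seq_number,
            insertion_code=res.insertion_code,
            aa=res.aa,
            delta_sasa=float(delta),
            rank=i + 1,
        )
        for i, (res, delta) in enumerate(hits)
    ]


def write_interface_report(residues: list[InterfaceResidue], path) -> None:
    """Tab-separated interface report: chain, resnum, aa, delta_sasa, rank."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\taa\tdelta_sasa\trank\n")
        for r in residues:
            fh.write(
                f"{r.chain_id}\t{r.seq_number}\t{r.insertion_code}\t{r.aa}\t"
                f"{r.delta_sasa:.4f}\t{r.rank}\n"
            )
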