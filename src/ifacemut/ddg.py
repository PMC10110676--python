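"""Per-substitution stability changes (ΔΔG).

This module supplies ΔΔG values from three routes:

* parsing an external empirical-force-field predictor's output (the
  BuildModel ``Dif_*.fxout`` dialect, or a plain TSV),
* averaging replicate runs into one record per substitution,
* a deliberately coarse, explicitly-labelled surrogate score so the whole
  pipeline can run self-contained.  The surrogate is NOT an energy function:
  it combines residue burial with the hydropathy and side-chain-volume change
  of the substitution on a kcal/mol-like scale, adding an interface-burial
  term in the complex.  Its only job is to produce stable, ordered numbers
  for tests and demonstrations.

Sign convention throughout: positive ΔΔG = destabilising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import defaultdict

from .errors import ParseError, MissingDataError, IfacemutError
from .sasa import SasaProfile
from .structures import Structure, CANONICAL_AA

__all__ = [
    "Substitution",
    "DdgRecord",
    "read_ddg_table",
    "write_plain_tsv",
    "write_foldx_dif",
    "aggregate_replicates",
    "surrogate_ddg",
    "HYDROPATHY",
    "SIDECHAIN_VOLUME",
    "MAX_SASA",
    "SURROGATE_WEIGHTS",
]

# Kyte-Doolittle hydropathy index
HYDROPATHY: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Zamyatnin residue volumes, Å³
SIDECHAIN_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Theoretical maximum accessible areas (Tien et al. 2013), Å²
MAX_SASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Fixed surrogate coefficients (kcal/mol per property unit); documented in
# docs/methods.md.  Tests depend on these being stable.
SURROGATE_WEIGHTS: dict[str, float] = {
    "hydropathy_monomer": 0.12,   # per hydropathy unit, scaled by burial
    "volume_monomer": 0.015,      # per Å³ volume change, scaled by burial
    "hydropathy_interface": 0.35, # per hydropathy unit, scaled by ΔSASA fraction
    "volume_interface": 0.030,    # per Å³, scaled by ΔSASA fraction
}


@dataclass(frozen=True, order=True)
class Substitution:
    """One point substitution in author numbering, e.g. A:219 A→V."""

    chain: str
    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"{self}: wild-type and mutant amino acid are identical")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in CANONICAL_AA:
                raise ValueError(f"non-canonical amino acid {aa!r} in substitution")

    @property
    def code(self) -> str:
        """Individual-list mutant code: wt letter + chain + position + mut letter."""
        return f"{self.wt_aa}{self.chain}{self.position}{self.mut_aa}"

    def __str__(self) -> str:
        return self.code


@dataclass(frozen=True)
class DdgRecord:
    substitution: Substitution
    ddg_monomer: float  # kcal/mol
    ddg_full: float  # kcal/mol
    n_replicates: int = 1
    source: str = "external_table"  # or "surrogate"
    replicate: int | None = None  # set on per-replicate records

    def __post_init__(self):
        import math

        if not (math.isfinite(self.ddg_monomer) and math.isfinite(self.ddg_full)):
            raise ValueError(f"{self.substitution}: ΔΔG values must be finite")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _parse_mutant_code(code: str, line_number: int) -> Substitution:
    code = code.strip()
    if len(code) < 4 or code[0] not in CANONICAL_AA or code[-1] not in CANONICAL_AA:
        raise ParseError(f"malformed mutant code {code!r}", line_number)
    try:
        position = int(code[2:-1])
    except ValueError:
        raise ParseError(f"malformed mutant code {code!r}", line_number) from None
    try:
        return Substitution(chain=code[1], position=position, wt_aa=code[0], mut_aa=code[-1])
    except ValueError as exc:
        raise ParseError(str(exc), line_number) from None


def _read_foldx_dif(path) -> dict[tuple[Substitution, int], float]:
    """Parse one Dif_*.fxout file → {(substitution, replicate): ddg}.

    Layout: free-text banner lines, then a header line starting with "Pdb",
    then tab-separated rows whose first field names the mutant model,
    ``<code>_<replicate>.pdb``, and whose second field is the total energy
    difference.
    """
    values: dict[tuple[Substitution, int], float] = {}
    with open(path) as fh:
        in_table = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if not in_table:
                if line.split("\t")[0].strip().lower() == "pdb":
                    in_table = True
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"expected >=2 tab-separated fields, got {len(fields)}", lineno)
            name = fields[0].strip()
            if name.endswith(".pdb"):
                name = name[: -len(".pdb")]
            if "_" not in name:
                raise ParseError(f"mutant file name {fields[0]!r} lacks a replicate suffix", lineno)
            code, _, rep_str = name.rpartition("_")
            try:
                replicate = int(rep_str)
                ddg = float(fields[1])
            except ValueError:
                raise ParseError(f"malformed row {line!r}", lineno) from None
            sub = _parse_mutant_code(code, lineno)
            values[(sub, replicate)] = ddg
    return values


def read_ddg_table(
    path,
    dialect: str = "plain_tsv",
    complex_path=None,
    structure: Structure | None = None,
) -> list[DdgRecord]:
    """Read per-replicate ΔΔG records.

    dialect="plain_tsv": tab-separated columns
        chain, position, wt, mut, ddg_monomer, ddg_full, replicate.
    dialect="foldx_dif": BuildModel Dif_*.fxout output; the monomer run is
        at ``path`` and the matching complex run at ``complex_path`` (both
        are required because the predictor writes one file per input model).

    If ``structure`` is given, a wild-type letter disagreeing with the
    structure's residue triggers a consistency warning (not an error).
    """
    records: list[DdgRecord] = []
    if dialect == "plain_tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["chain", "position", "wt", "mut", "ddg_monomer", "ddg_full", "replicate"]
            if [h.strip() for h in header] != expected:
                raise ParseError(f"expected header {expected}, got {header}", 1)
            for lineno, raw in enumerate(fh, start=2):
                if not raw.strip():
                    continue
                fields = raw.rstrip("\n").split("\t")
                if len(fields) != 7:
                    raise ParseError(f"expected 7 fields, got {len(fields)}", lineno)
                try:
                    sub = Substitution(
                        chain=fields[0].strip(),
                        position=int(fields[1]),
                        wt_aa=fields[2].strip(),
                        mut_aa=fields[3].strip(),
                    )
                    rec = DdgRecord(
                        substitution=sub,
                        ddg_monomer=float(fields[4]),
                        ddg_full=float(fields[5]),
                        replicate=int(fields[6]),
                    )
                except ValueError as exc:
                    raise ParseError(str(exc), lineno) from None
                records.append(rec)
    elif dialect == "foldx_dif":
        if complex_path is None:
            raise IfacemutError(
                "foldx_dif dialect needs both the monomer file (path) and the "
                "complex file (complex_path); the predictor writes one Dif file per run"
            )
        mono = _read_foldx_dif(path)
        full = _read_foldx_dif(complex_path)
        if set(mono) != set(full):
            raise ParseError(
                "monomer and complex Dif files do not cover the same "
                "(substitution, replicate) set"
            )
        for (sub, rep) in sorted(mono, key=lambda sr: (sr[0], sr[1])):
            records.append(
                DdgRecord(
                    substitution=sub,
                    ddg_monomer=mono[(sub, rep)],
                    ddg_full=full[(sub, rep)],
                    replicate=rep,
                )
            )
    else:
        raise IfacemutError(f"unknown ΔΔG dialect {dialect!r}")

    if structure is not None:
        for rec in records:
            try:
                res = structure.residue((rec.substitution.chain, rec.substitution.position))
            except KeyError:
                continue
            if res.aa != rec.substitution.wt_aa:
                warnings.warn(
                    f"ΔΔG table wild type {rec.substitution.code} disagrees with "
                    f"structure residue {res.key} ({res.aa})",
                    stacklevel=2,
                )
    return records


def write_plain_tsv(records: list[DdgRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tposition\twt\tmut\tddg_monomer\tddg_full\treplicate\n")
        for rec in records:
            s = rec.substitution
            fh.write(
                f"{s.chain}\t{s.position}\t{s.wt_aa}\t{s.mut_aa}\t"
                f"{rec.ddg_monomer:.6f}\t{rec.ddg_full:.6f}\t{rec.replicate or 1}\n"
            )


def write_foldx_dif(records: list[DdgRecord], monomer_path, complex_path) -> None:
    """Write per-replicate records in the Dif_*.fxout dialect (two files)."""

    def _write(path, attr):
        with open(path, "w") as fh:
            fh.write("BuildModel output file\n")
            fh.write("energy differences relative to wild type\n")
            fh.write("Pdb\ttotal energy\n")
            for rec in records:
                fh.write(
                    f"{rec.substitution.code}_{rec.replicate or 1}.pdb\t"
                    f"{getattr(rec, attr):.6f}\n"
                )

    _write(monomer_path, "ddg_monomer")
    _write(complex_path, "ddg_full")


def aggregate_replicates(records: list[DdgRecord]) -> list[DdgRecord]:
    """Average per-replicate records into one record per substitution.

    The order of the input records does not matter; output is sorted by
    substitution.  Predictors of this kind are conventionally run ~10 times
    per mutation and the arithmetic mean reported.
    """
    groups: dict[Substitution, list[DdgRecord]] = defaultdict(list)
    for rec in records:
        groups[rec.substitution].append(rec)
    out = []
    for sub in sorted(groups):
        reps = groups[sub]
        n = len(reps)
        out.append(
            DdgRecord(
                substitution=sub,
                ddg_monomer=sum(r.ddg_monomer for r in reps) / n,
                ddg_full=sum(r.ddg_full for r in reps) / n,
                n_replicates=n,
                source=reps[0].source,
            )
        )
    return out


def surrogate_ddg(
    structure: Structure,
    substitution: Substitution,
    profile_monomer: SasaProfile,
    profile_complex: SasaProfile,
) -> DdgRecord:
    """Coarse, deterministic surrogate stability score (NOT an energy function).

    monomer term: burial × (w_h·|Δhydropathy| + w_v·|Δvolume|), where burial
    is 1 − SASA_monomer/maxSASA(wt) clipped to [0, 1].

    complex term adds (ΔSASA/maxSASA) × (w_ih·|Δhydropathy| + w_iv·|Δvolume|),
    so ddg_full ≥ ddg_monomer whenever the residue loses surface in the
    complex, and the two are equal for a residue the partner does not touch.
    """
    res = structure.residue((substitution.chain, substitution.position))
    if res.aa == "X":
        raise IfacemutError(f"cannot score substitution at non-canonical residue {res.key}")
    if res.aa != substitution.wt_aa:
        raise MissingDataError(
            f"substitution {substitution.code} wild type disagrees with structure ({res.aa})"
        )
    key = res.key
    try:
        sasa_mono = profile_monomer.per_residue[key]
        sasa_full = profile_complex.per_residue[key]
    except KeyError:
        raise MissingDataError(f"SASA profiles do not cover residue {key}") from None

    wt, mut = substitution.wt_aa, substitution.mut_aa
    dhyd = abs(HYDROPATHY[mut] - HYDROPATHY[wt])
    dvol = abs(SIDECHAIN_VOLUME[mut] - SIDECHAIN_VOLUME[wt])
    max_area = MAX_SASA[wt]

    burial = min(max(1.0 - sasa_mono / max_area, 0.0), 1.0)
    w = SURROGATE_WEIGHTS
    ddg_monomer = burial * (w["hydropathy_monomer"] * dhyd + w["volume_monomer"] * dvol)

    delta_frac = max(sasa_mono - sasa_full, 0.0) / max_area
    ddg_full = ddg_monomer + delta_frac * (
        w["hydropathy_interface"] * dhyd + w["volume_interface"] * dvol
    )
    return DdgRecord(
        substitution=substitution,
        ddg_monomer=ddg_monomer,
        ddg_full=ddg_full,
        n_replicates=1,
        source="surrogate",
    )
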