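"""Synthetic fixtures with planted ground truth.

Everything the pipeline consumes can be generated here with a known answer:

* toy two-chain complexes whose interface membership, anchor distances and
  region-centroid residue are planted by construction;
* ΔΔG replicate tables whose rule-cascade outcome is planted candidate by
  candidate (including exact boundary cases);
* population-variant lists;
* probe-count and Ct matrices emulating a 29-control interferon-signature
  cohort with one elevated sample.

Geometry is fully deterministic and uses dyadic-rational coordinates
(multiples of 0.25 Å), so planted distances such as "exactly 5.0 Å" are
exact in IEEE arithmetic, not merely close.  The seed drives only the
stochastic tables (ΔΔG noise, expression counts); for a fixed recipe the
structure is byte-identical run to run.

The toy complex layout: chain A carries a contiguous contact block whose
residues sit directly under buried partner residues of chain B; the rest of
chain A resumes after an 18 Å gap along the chain axis, and the rest of
chain B runs parallel 25 Å away, so every non-contact residue is ≥ 15 Å
from the partner chain.  Two contact residues are designated anchors (the
analogues of the R148/A219 positions of the STAT2 coiled-coil domain), and
one further contact residue is displaced below the chain so that its
nearest-atom distance to the first anchor is exactly 5.0 Å, with its own
buried partner moved along with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ddg import DdgRecord, Substitution, aggregate_replicates
from .errors import RecipeError
from .interface import InterfaceResidue
from .prioritize import RuleConfig, enumerate_substitutions
from .signature import CtTable, ExpressionMatrix
from .structures import Atom, Residue, Structure, ResidueKey

import pandas as pd

__all__ = [
    "ComplexRecipe",
    "DdgRecipe",
    "StudyCase",
    "make_toy_complex",
    "make_ddg_table",
    "default_planted_shortlist",
    "make_expression_matrix",
    "make_ct_table",
    "make_study_case",
    "ISG_PANEL_PROBES",
    "REFERENCE_PROBES",
    "QPCR_PANEL_GENES",
    "QPCR_REFERENCE_GENES",
]

# 24-gene interferon-stimulated-gene panel and its reference probes
ISG_PANEL_PROBES = [
    "IFI27", "IFI44L", "IFIT1", "ISG15", "RSAD2", "SIGLEC1", "CMPK2", "DDX60",
    "EPSTI1", "FBXO39", "HERC5", "HES4", "IFI44", "IFI6", "IFIH1", "IRF7",
    "LAMP3", "LY6E", "MX1", "NRIR", "OAS1", "OASL", "OTOF", "SPATS2L",
]
REFERENCE_PROBES = ["HPRT1", "NRDC", "OTUD5"]

# 6-gene qPCR signature panel and its housekeeping genes
QPCR_PANEL_GENES = ["IFI27", "IFI44L", "IFIT1", "ISG15", "RSAD2", "SIGLEC1"]
QPCR_REFERENCE_GENES = ["BACT", "GAPDH"]

# idealized 5-heavy-atom pseudo-residue, offsets relative to CA (dyadic)
_ATOM_TEMPLATE = [
    ("N", "N", np.array([-1.25, 0.75, 0.0])),
    ("CA", "C", np.array([0.0, 0.0, 0.0])),
    ("C", "C", np.array([1.25, 0.75, 0.0])),
    ("O", "O", np.array([1.25, 2.0, 0.0])),
    ("CB", "C", np.array([0.0, -1.5, 0.5])),
]

_SPACING = 8.0       # Å between consecutive residues along the chain axis
_GAP = 18.0          # extra Å between the contact block and the rest of chain A
_PARTNER_Y = 5.75    # chain-B partner CA height above a contact residue
_REMOTE_Y = 25.0     # chain-B non-contact line
_AA_CYCLE = "ILKEDSTVQNFYHMGWCP"  # wild-type identities, cycled per residue


@dataclass(frozen=True)
class ComplexRecipe:
    """Recipe for a planted two-chain toy complex.

    n_residues : (chain A length, chain B length)
    contact_count : number of chain-A residues buried by chain B
    anchor_positions : chain-A residue numbers designated as anchors; must
        lie in the contact block.  The first two default to analogues of the
        R148/A219 pair and get wild types R and A.
    exact5_position : chain-A contact residue displaced to exactly 5.0 Å
        (nearest atom) from the first anchor, or None.
    centroid_region : inclusive chain-B residue range whose centroid-closest
        residue is planted (must lie in the non-contact part of chain B).
    """

    n_residues: tuple[int, int] = (40, 120)
    contact_count: int = 24
    anchor_positions: tuple[int, ...] = (5, 17)
    exact5_position: int | None = 11
    centroid_region: tuple[int, int] | None = (51, 112)
    seed: int = 0

    def validate(self) -> None:
        n_a, n_b = self.n_residues
        k = self.contact_count
        if n_a < 1 or n_b < 1:
            raise RecipeError("both chains must be non-empty")
        if not (0 <= k <= min(n_a, n_b)):
            raise RecipeError(
                f"contact_count {k} infeasible for chain lengths {self.n_residues}"
            )
        for a in self.anchor_positions:
            if not (1 <= a <= k):
                raise RecipeError(f"anchor position {a} outside the contact block 1..{k}")
        if self.exact5_position is not None:
            p = self.exact5_position
            if not (1 <= p <= k):
                raise RecipeError(f"exact5 position {p} outside the contact block 1..{k}")
            if not self.anchor_positions:
                raise RecipeError("exact5 plant requires at least one anchor")
            if p in self.anchor_positions:
                raise RecipeError("exact5 plant cannot be an anchor itself")
        if self.centroid_region is not None:
            lo, hi = self.centroid_region
            if not (k < lo <= hi <= n_b):
                raise RecipeError(
                    f"centroid region {self.centroid_region} must lie in the "
                    f"non-contact part of chain B ({k + 1}..{n_b})"
                )


def _make_residue(chain: str, seq: int, aa: str, ca: np.ndarray, serial0: int) -> Residue:
    res = Residue(chain_id=chain, seq_number=seq, aa=aa)
    for i, (name, element, offset) in enumerate(_ATOM_TEMPLATE):
        res.atoms.append(
            Atom(serial=serial0 + i, name=name, element=element, coord=ca + offset)
        )
    return res


def make_toy_complex(recipe: ComplexRecipe) -> tuple[Structure, dict]:
    """Build the planted two-chain complex and its truth record."""
    recipe.validate()
    n_a, n_b = recipe.n_residues
    k = recipe.contact_count
    anchors = recipe.anchor_positions
    plant = recipe.exact5_position

    def wt_aa(chain: str, seq: int) -> str:
        if chain == "A" and anchors:
            if seq == anchors[0]:
                return "R"
            if len(anchors) > 1 and seq == anchors[1]:
                return "A"
        return _AA_CYCLE[(seq - 1) % len(_AA_CYCLE)]

    residues: list[Residue] = []
    serial = 1

    plant_ca: np.ndarray | None = None
    if plant is not None:
        # nearest-atom pair is (plant O, anchor CB), axis-aligned: exactly 5 Å
        anchor_ca = np.array([_SPACING * (anchors[0] - 1), 0.0, 0.0])
        anchor_cb = anchor_ca + _ATOM_TEMPLATE[4][2]
        plant_o = anchor_cb + np.array([0.0, -5.0, 0.0])
        plant_ca = plant_o - _ATOM_TEMPLATE[3][2]

    # chain A
    for i in range(1, n_a + 1):
        if plant is not None and i == plant:
            ca = plant_ca
        elif i <= k:
            ca = np.array([_SPACING * (i - 1), 0.0, 0.0])
        else:
            ca = np.array([_SPACING * (i - 1) + _GAP, 0.0, 0.0])
        residues.append(_make_residue("A", i, wt_aa("A", i), ca, serial))
        serial += len(_ATOM_TEMPLATE)

    # chain B: buried partners opposite the contact block, the rest remote.
    # For an even-count centroid region, nudge the middle residue toward the
    # region centroid so the planted answer is strictly (not tie-) closest.
    centroid_plant_seq = None
    centroid_nudge = 0.0
    if recipe.centroid_region is not None:
        lo, hi = recipe.centroid_region
        centroid_plant_seq = (lo + hi) // 2
        if (hi - lo + 1) % 2 == 0:
            centroid_nudge = 2.0
    for j in range(1, n_b + 1):
        if j <= k:
            if plant is not None and j == plant:
                # partner follows the displaced plant, buried from below
                ca = plant_ca + np.array([1.25, -6.0, 0.5])
            else:
                ca = np.array([_SPACING * (j - 1), _PARTNER_Y, 0.0])
        else:
            x = _SPACING * (j - 1) + _GAP
            if j == centroid_plant_seq:
                x += centroid_nudge
            ca = np.array([x, _REMOTE_Y, 0.0])
        residues.append(_make_residue("B", j, wt_aa("B", j), ca, serial))
        serial += len(_ATOM_TEMPLATE)

    structure = Structure(id="toy_complex", residues=residues)

    truth: dict = {
        "target_chain": "A",
        "partner_chain": "B",
        "contact_count": k,
        "interface": [["A", i, ""] for i in range(1, k + 1)],
        "anchors": [["A", a, ""] for a in anchors],
        "contact_pairs": [[i, i] for i in range(1, k + 1)],
    }
    if plant is not None:
        truth["exact5"] = {"position": plant, "anchor": anchors[0], "distance": 5.0}
    if recipe.centroid_region is not None:
        lo, hi = recipe.centroid_region
        # uniform spacing on a line: the (possibly nudged) middle residue is
        # strictly closest to the region centroid
        truth["centroid_region"] = [lo, hi]
        truth["centroid_residue"] = ["B", centroid_plant_seq, ""]
    return structure, truth


@dataclass(frozen=True)
class DdgRecipe:
    """Recipe for a planted ΔΔG replicate table.

    neutral_mean/neutral_sd parameterise the population-variant monomer
    distribution (standing variation observed at interfaces is mildly
    destabilising on average, ~0.3 kcal/mol).  planted_shortlist members are
    constructed to satisfy all four cascade rules; every other candidate
    violates exactly one rule, assigned round-robin within its geometric
    stratum.  Boundary substitutions get zero replicate noise so their
    aggregated means hit the rule boundaries exactly.
    """

    neutral_mean: float = 0.309
    neutral_sd: float = 0.45
    disruptive_full_min: float = 2.5
    planted_shortlist: tuple[Substitution, ...] = ()
    n_population: int = 14
    n_replicates: int = 10
    replicate_sd: float = 0.1
    anchor_max_distance: float = 5.0
    monomer_window: tuple[float, float] = (-0.5, 0.5)
    full_threshold: float = 2.0
    seed: int = 0


def default_planted_shortlist(
    candidates: list[Substitution], truth: dict, size: int = 10
) -> tuple[Substitution, ...]:
    """Pick a deterministic planted surviving set at rule-4-eligible residues.

    Members are spread over the anchor residues and the exact-5 plant (the
    only residues within the anchor-distance rule by construction), taking
    the alphabetically first mutant letters at each.
    """
    eligible_positions = [a[1] for a in truth["anchors"]]
    if "exact5" in truth:
        eligible_positions.append(truth["exact5"]["position"])
    pools = {
        pos: sorted(
            (c for c in candidates if c.chain == truth["target_chain"] and c.position == pos),
            key=lambda c: c.mut_aa,
        )
        for pos in eligible_positions
    }
    picked: list[Substitution] = []
    i = 0
    while len(picked) < size:
        progressed = False
        for pos in eligible_positions:
            if i < len(pools[pos]):
                picked.append(pools[pos][i])
                progressed = True
                if len(picked) == size:
                    break
        if not progressed:
            raise RecipeError(
                f"cannot plant a shortlist of {size}: only "
                f"{sum(len(p) for p in pools.values())} eligible candidates"
            )
        i += 1
    return tuple(picked)


def make_ddg_table(
    candidates: list[Substitution],
    recipe: DdgRecipe,
    anchor_distance: dict[Substitution, float],
) -> tuple[list[DdgRecord], list[Substitution]]:
    """Generate per-replicate ΔΔG records plus the population-variant list.

    ``anchor_distance`` maps every candidate to its min nearest-atom anchor
    distance (as produced by :func:`ifacemut.prioritize.distance_annotation`).
    Returns (per-replicate records, population variants).
    """
    rng = np.random.default_rng(recipe.seed)
    planted = list(recipe.planted_shortlist)
    cand_set = set(candidates)
    if not set(planted) <= cand_set:
        raise RecipeError("planted shortlist is not a subset of the candidates")
    missing = cand_set - set(anchor_distance)
    if missing:
        raise RecipeError(f"anchor_distance missing {len(missing)} candidate(s)")

    near = [c for c in candidates if anchor_distance[c] <= recipe.anchor_max_distance]
    far = [c for c in candidates if c not in set(near)]
    bad = [c for c in planted if c not in set(near)]
    if bad:
        raise RecipeError(
            f"planted substitution(s) beyond the anchor distance rule: {bad[:5]}"
        )

    lo, hi = recipe.monomer_window
    margin = 0.8 * (hi - lo) / 2.0  # noisy targets stay clear of the window edges
    mid = (lo + hi) / 2.0

    # population variants live on far residues so the near stratum stays clean
    far_nonplanted = sorted(set(far) - set(planted))
    if len(far_nonplanted) < recipe.n_population:
        raise RecipeError(
            f"need {recipe.n_population} far candidates for population variants, "
            f"have {len(far_nonplanted)}"
        )
    pop_idx = rng.choice(len(far_nonplanted), size=recipe.n_population, replace=False)
    population = [far_nonplanted[i] for i in sorted(pop_idx)]
    pop_set = set(population)

    # (monomer target, full target, exact?) per candidate
    targets: dict[Substitution, tuple[float, float, bool]] = {}

    for idx, cand in enumerate(planted):
        if idx == 0:
            mono, exact = hi, True  # kept at the inclusive upper boundary
        elif idx == 1:
            mono, exact = lo, True  # kept at the inclusive lower boundary
        else:
            mono, exact = mid + rng.uniform(-margin, margin), False
        full = recipe.disruptive_full_min + rng.uniform(0.0, 2.0)
        targets[cand] = (mono, full, exact)

    for cand in population:
        mono = recipe.neutral_mean + rng.normal(0.0, recipe.neutral_sd)
        full = rng.normal(1.2, 0.8)
        targets[cand] = (mono, full, False)

    # far non-population candidates violate exactly the distance rule
    for cand in far_nonplanted:
        if cand in pop_set:
            continue
        mono = mid + rng.uniform(-margin, margin)
        full = recipe.full_threshold + rng.uniform(0.5, 2.5)
        targets[cand] = (mono, full, False)

    # near non-planted candidates: one exact full-threshold boundary case,
    # the rest alternate between violating the monomer window and the
    # full-complex threshold
    near_nonplanted = sorted(set(near) - set(planted))
    toggle = 0
    for i, cand in enumerate(near_nonplanted):
        if i == 0:
            # removed at the strict full threshold despite a perfect monomer
            targets[cand] = (mid, recipe.full_threshold, True)
            continue
        if toggle == 0:
            mono = hi + rng.uniform(0.3, 1.5) if rng.uniform() < 0.5 else lo - rng.uniform(0.3, 1.5)
            full = recipe.full_threshold + rng.uniform(0.5, 2.5)
        else:
            mono = mid + rng.uniform(-margin, margin)
            full = recipe.full_threshold - rng.uniform(0.5, 1.5)
        targets[cand] = (mono, full, False)
        toggle ^= 1

    records: list[DdgRecord] = []
    for cand in sorted(candidates):
        mono, full, exact = targets[cand]
        if exact or recipe.replicate_sd == 0:
            mono_reps = np.full(recipe.n_replicates, mono)
            full_reps = np.full(recipe.n_replicates, full)
        else:
            em = rng.normal(0.0, recipe.replicate_sd, recipe.n_replicates)
            ef = rng.normal(0.0, recipe.replicate_sd, recipe.n_replicates)
            # recentre so the aggregated mean stays at the designed target
            mono_reps = mono + (em - em.mean())
            full_reps = full + (ef - ef.mean())
        for r in range(recipe.n_replicates):
            records.append(
                DdgRecord(
                    substitution=cand,
                    ddg_monomer=float(mono_reps[r]),
                    ddg_full=float(full_reps[r]),
                    replicate=r + 1,
                )
            )
    return records, population


def make_expression_matrix(
    n_controls: int = 29,
    n_cases: int = 1,
    case_elevation: float = 10.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Probe-count matrix: noisy log-normal controls plus elevated case(s).

    Case panel counts are built from the per-probe control medians scaled by
    ``case_elevation``, so after normalisation a uniformly elevated case has
    fold change ``case_elevation`` at every probe (and hence that score).
    """
    if n_controls < 2:
        raise RecipeError("need at least 2 control samples")
    rng = np.random.default_rng(seed)
    probes = ISG_PANEL_PROBES + REFERENCE_PROBES
    n_panel, n_ref = len(ISG_PANEL_PROBES), len(REFERENCE_PROBES)

    panel_base = rng.lognormal(np.log(300.0), 0.8, n_panel)
    ref_base = rng.lognormal(np.log(800.0), 0.3, n_ref)

    rows, index, roles = [], [], []
    for i in range(n_controls):
        factor = rng.lognormal(0.0, 0.15)
        panel = panel_base * factor * rng.lognormal(0.0, 0.2, n_panel)
        ref = ref_base * factor * rng.lognormal(0.0, 0.05, n_ref)
        rows.append(np.concatenate([panel, ref]))
        index.append(f"control_{i + 1:02d}")
        roles.append("control")

    ctrl = np.array([r[:n_panel] for r in rows])
    ctrl_geo = np.exp(np.log(np.array([r[n_panel:] for r in rows])).mean(axis=1))
    probe_median = np.median(ctrl / ctrl_geo[:, None], axis=0)

    for j in range(n_cases):
        ref = ref_base.copy()
        geo = np.exp(np.log(ref).mean())
        panel = case_elevation * geo * probe_median
        rows.append(np.concatenate([panel, ref]))
        index.append(f"case_{j + 1}")
        roles.append("case")

    counts = pd.DataFrame(rows, index=index, columns=probes)
    return ExpressionMatrix(
        counts=counts,
        roles=pd.Series(roles, index=index),
        reference_probes=list(REFERENCE_PROBES),
    )


def make_ct_table(
    n_donors: int = 29,
    case_fold: float = 8.0,
    seed: int = 0,
) -> CtTable:
    """qPCR Ct table: healthy-donor calibrators plus one elevated sample.

    The case sample's target Ct values sit ``log2(case_fold)`` cycles below
    the donor mean ΔCt, i.e. ~``case_fold``-fold higher expression.
    """
    if n_donors < 1:
        raise RecipeError("need at least 1 calibrator donor")
    rng = np.random.default_rng(seed)
    genes = QPCR_PANEL_GENES + QPCR_REFERENCE_GENES
    n_t, n_r = len(QPCR_PANEL_GENES), len(QPCR_REFERENCE_GENES)

    target_base = rng.normal(26.0, 1.0, n_t)
    ref_base = rng.normal(20.0, 0.5, n_r)

    rows, index = [], []
    for i in range(n_donors):
        shift = rng.normal(0.0, 0.3)
        targets = target_base + shift + rng.normal(0.0, 0.3, n_t)
        refs = ref_base + shift + rng.normal(0.0, 0.1, n_r)
        rows.append(np.concatenate([targets, refs]))
        index.append(f"donor_{i + 1:02d}")

    refs = ref_base + rng.normal(0.0, 0.1, n_r)
    targets = target_base - np.log2(case_fold) + rng.normal(0.0, 0.2, n_t)
    rows.append(np.concatenate([targets, refs]))
    index.append("case_1")

    values = pd.DataFrame(rows, index=index, columns=genes)
    return CtTable(
        values=values,
        reference_genes=list(QPCR_REFERENCE_GENES),
        calibrators=[s for s in index if s.startswith("donor_")],
    )


@dataclass
class StudyCase:
    """A complete planted pipeline fixture under the study conditions."""

    structure: Structure
    truth: dict
    candidates: list[Substitution]
    planted: tuple[Substitution, ...]
    population: list[Substitution]
    replicate_records: list[DdgRecord]
    aggregated: list[DdgRecord]
    rule_config: RuleConfig
    anchor_distance: dict[Substitution, float]


def make_study_case(seed: int = 0, complex_recipe: ComplexRecipe | None = None) -> StudyCase:
    """Toy complex + planted ΔΔG table wired into a ready-to-run rule config.

    Defaults mirror the study conditions: 24 interface residues, 456
    candidate substitutions, a 10-member planted shortlist, 14 population
    variants, 10 replicates per substitution, window ±0.5, threshold 2,
    anchor distance 5 Å.
    """
    from .prioritize import distance_annotation

    if complex_recipe is None:
        complex_recipe = ComplexRecipe(seed=seed)
    structure, truth = make_toy_complex(complex_recipe)

    iface = []
    for i, (chain, seq, icode) in enumerate(truth["interface"]):
        res = structure.residue((chain, seq, icode))
        iface.append(
            InterfaceResidue(
                chain_id=chain, seq_number=seq, insertion_code=icode,
                aa=res.aa, delta_sasa=0.0, rank=i + 1,
            )
        )
    candidates = enumerate_substitutions(iface)

    anchors: list[ResidueKey] = [tuple(a) for a in truth["anchors"]]
    dist = distance_annotation(candidates, structure, anchors)

    planted = default_planted_shortlist(candidates, truth, size=10)
    ddg_recipe = DdgRecipe(planted_shortlist=planted, seed=seed)
    records, population = make_ddg_table(candidates, ddg_recipe, dist)

    config = RuleConfig(
        monomer_window=ddg_recipe.monomer_window,
        full_threshold=ddg_recipe.full_threshold,
        anchor_residues=tuple(anchors),
        anchor_max_distance=ddg_recipe.anchor_max_distance,
        population_variants=frozenset(population),
    )
    return StudyCase(
        structure=structure,
        truth=truth,
        candidates=candidates,
        planted=planted,
        population=population,
        replicate_records=records,
        aggregated=aggregate_replicates(records),
        rule_config=config,
        anchor_distance=dist,
    )
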