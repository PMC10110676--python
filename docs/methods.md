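# Methods

This note documents the models, numerical choices, and deliberate
limitations of each pipeline stage, and what the synthetic fixtures do and
do not establish about behaviour on real structures.

## Structure model and PDB handling

The in-memory model is atoms (serial, name, element, coordinate, occupancy)
grouped into residues keyed by `(chain, author residue number, insertion
code)`. Author numbering is authoritative everywhere and never rewritten,
because the prioritization rules and restraints cite residues (e.g. the
R148/A219 anchor pair of the STAT2 coiled-coil domain) in author numbering.
On read, waters and non-protein heteroatoms are dropped, and only the
highest-occupancy alternate conformer is kept — SASA and distance queries
assume single-conformer geometry. Hydrogens are retained in the model but
excluded from "heavy-atom" queries; predicted models (AlphaFold, homology
models) are normally hydrogen-free, so heavy-atom distances are the
reproducible reading of "nearest atoms". Non-canonical residues map to `X`
and are skipped by substitution enumeration, whose 19-letter alphabet is
canonical. Parsing and serialisation use biotite's fixed-column PDB reader
and writer; mmCIF, assemblies and trajectories are out of scope.

## Solvent-accessible surface area

SASA uses the Shrake–Rupley construction: each atom's van der Waals sphere
is inflated by the probe radius (default 1.4 Å, the conventional water
probe) and covered with a deterministic Fibonacci (golden-angle spiral)
point set; a point survives if it lies outside every neighbour's inflated
sphere, and

    area = exposed fraction × 4π (r_vdw + r_probe)².

A deterministic point set was chosen over random sampling so results are
bit-reproducible without seeds. The default 960 points per atom give < 1 %
error on an isolated sphere and < 2 % against the analytic two-sphere
spherical-cap formula (measured ≈ 0.4 %); the tests also verify that
doubling the point count moves no atom by more than 2 Å². Neighbour
candidates come from a scipy k-d tree queried at radius
`r_i + r_j + 2·probe`. The radii table is a deliberately small fixed set
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å) with a 1.70 Å fallback that can
be disabled; matching any particular external tool's radii classifier
bit-for-bit is a non-goal, and the test suite instead cross-checks
per-residue areas against biotite's independent implementation with matched
radii (agreement within 5 %).

## Interface definition

A residue of the target chain is an interface residue when
`SASA(monomer) − SASA(complex) ≥ min_delta`. The difference is provably
non-negative with a shared point set (adding atoms can only occlude
points), and this is asserted as an invariant. There is no community
cutoff for `min_delta`; the default 1.0 Å² is inclusive and exposed as a
parameter, so an interface count on a real docked model can be calibrated
when one is available. Ranking is by descending ΔSASA with (chain, residue
number) tie-breaks for determinism.

## Geometry and docking restraints

`min_atom_distance` is the exact minimum over all qualifying atom pairs
(vectorised, verified against brute force in tests); a residue against
itself is 0, which makes a candidate at an anchor residue trivially pass
the proximity rule. `centroid_closest_residue` uses the unweighted
all-atom centroid of the region and of each member residue; whether a Cα
or all-atom centroid is meant is genuinely open, so a `ca_only` switch is
provided with all-atom as default (predicted side chains carry real
information about the binding region's mass distribution). Restraints pair
an anchor with that centroid residue at a maximum distance, default 20 Å —
wide enough to let docking decoys explore the full rotational space over a
~60-residue binding region. Export is a plain-text record; engine-specific
schemas are out of scope.

## ΔΔG supply

Three routes, never mixed silently:

* **External tables.** The `plain_tsv` dialect carries
  (chain, position, wt, mut, ΔΔG_monomer, ΔΔG_full, replicate). The
  `foldx_dif` dialect parses BuildModel `Dif_*.fxout` files — banner lines,
  a `Pdb`-headed tab-separated table, and mutant model names of the form
  `<wt><chain><pos><mut>_<replicate>.pdb`; because the predictor writes one
  Dif file per input model, the monomer and complex runs are two files and
  both are required. Monomer and complex values are stored verbatim; the
  package never subtracts them to form a binding ΔΔG, since whether a
  "full" value is complex stability or binding energy depends on how the
  external runs were set up.
* **Replicate averaging.** Arithmetic mean per substitution, order
  independent, with the replicate count recorded (the conventional protocol
  is ~10 replicates per mutation).
* **Surrogate.** An explicitly-labelled coarse score
  (`source="surrogate"`) so the pipeline runs with no licensed predictor:
  monomer term = burial × (0.12·|Δhydropathy| + 0.015·|Δvolume|), complex
  term adds (ΔSASA/maxSASA) × (0.35·|Δhydropathy| + 0.030·|Δvolume|), using
  Kyte–Doolittle hydropathy, Zamyatnin volumes, and theoretical maximum
  accessible areas. The coefficients are fixed constants chosen once to
  land on a kcal/mol-like scale; the surrogate's guarantees are structural,
  not energetic: zero for property-neutral changes, no interface term for
  untouched residues, ΔΔG_full ≥ ΔΔG_monomer at buried interfaces, and
  monotone growth with volume change. It must not be interpreted as a
  stability prediction.

## Prioritization cascade

Boundary semantics follow the natural-language reading of the design:
the monomer window is **inclusive** ("between −0.5 and +0.5"), the complex
threshold **strict** ("> 2"), and the anchor distance **inclusive** ("no
more than 5 Å"); all three are configurable. The anchor rule is an OR over
anchors (proximity to either of the R148/A219 analogues suffices), with a
flag for AND. Population-variant exclusion matches the exact protein-level
substitution; presence alone excludes, no frequency is consulted. The four
predicates are independent, so the surviving set is order-invariant — the
tests assert equality with a brute-force filter over all 24 rule orders —
but the audit attributes each removal to the first failing rule in the
stated order, making the counts conserve exactly. Survivors are ranked by
ΔΔG_full descending (most interface-disrupting first), a package choice
since no ranking key is canonical.

## Interferon-signature statistics

Panel counts are scaled by the geometric mean of each sample's reference
probes (standard practice for count-based housekeeping normalisation; the
instrument vendor's exact normalisation is proprietary), then converted to
fold changes against the per-probe control median, so control fold changes
centre on 1. The per-sample score is the median fold change over the
24-probe panel; the positivity threshold is mean + 2 SD of the control
scores. "2 SD" is two **sample** standard deviations (ddof 1), not two
standard errors: with ~29 controls scoring near 1, a SEM-based threshold
would sit implausibly close to 1 compared with thresholds reported for
such panels (≈ 2.75); `sd_mode="sem"` and a mean-based fold-change
baseline remain available as switches. Calls are strict
(score > threshold). ΔΔCt follows the textbook definition: ΔCt against the
mean of the reference genes, ΔΔCt against the calibrator-group mean,
RQ = 2^−ΔΔCt.

## Synthetic fixtures and what they establish

The toy complex is two chains of idealized 5-heavy-atom pseudo-residues on
straight-line backbones with dyadic-rational coordinates (multiples of
0.25 Å). A contiguous contact block of chain A sits under buried partner
residues of chain B at 4–6 Å; the remainder of chain A resumes after an
18 Å gap and the remainder of chain B runs 25 Å away, so non-contact
residues are ≥ 15 Å from the partner and interface membership is exact by
construction. Two contact residues are anchors (wild types R and A,
mirroring the anchor pair); one contact residue is displaced below the
chain so its nearest-atom anchor distance is **exactly** 5.0 Å in IEEE
arithmetic (an axis-aligned 5.0 Å pair of dyadic coordinates), with its
buried partner moved along with it; and the middle residue of the partner
region is nudged 2 Å so it is strictly closest to the region centroid.
Geometry is a pure function of the recipe — the seed drives only the
stochastic tables.

The default study conditions are: 24 contact residues (hence 456
candidates), a 10-member planted shortlist, 14 population variants placed
on rule-4-ineligible residues with ΔΔG_monomer ~ Normal(0.309, 0.45) —
standing variation at interfaces is mildly destabilising on average — 10
replicates per substitution with 0.1 kcal/mol replicate noise, a 29-control
expression cohort, and one case elevated 10-fold. Replicate noise is
recentred onto each substitution's target mean so the planted rule
structure (every non-planted candidate violates exactly one rule;
boundary cases sit exactly at ±0.5, 2.0, and 5.0) holds for every seed,
and boundary substitutions carry zero replicate noise so their aggregated
means are exact. The case expression sample is built from the per-probe
control medians times the elevation, so a uniformly elevated case scores
exactly the elevation factor.

What passing these tests shows: the set logic, arithmetic, boundary
semantics, audit conservation, determinism, and numerical SASA/geometry of
every stage are correct. What they do not show: behaviour on real docked
models (side-chain packing, hydrogens, alternate conformers, non-trivial
interface topology), realism of any ΔΔG value, or the instrument-level
properties of real expression data. Interface counts, shortlist identities
and thresholds on real inputs are model-dependent quantities, not
constants of the method.

## Problem sizes and runtime

The default toy complex is 160 residues / 800 atoms, for which a full
SASA + interface + cascade run takes well under a second; the test suite
uses 196–960 quadrature points depending on whether the check is
qualitative (set recovery) or quantitative (closed-form error bounds).
These sizes were chosen as the smallest at which every planted feature
(24-residue block, two separated anchors, an off-block exact-5 plant, a
62-residue centroid region) coexists without geometric interference.

## Known limitations

* The SASA implementation targets correctness and reproducibility, not
  throughput; very large complexes would benefit from a compiled kernel.
* The surrogate ΔΔG is ordinal at best; any real prioritization should use
  an established predictor via the table interface.
* The PDB writer emits minimal single-model files (no CONECT, no
  secondary-structure records).
* Fold-change normalisation assumes positive reference counts; zeros are
  an error rather than being imputed.
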