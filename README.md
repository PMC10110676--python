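# ifacemut

Interface-targeted in-silico deep mutagenesis of protein–protein complexes,
docking-restraint derivation, and interferon-signature scoring.

## What this is for

When a missense variant is suspected of disrupting a specific
protein–protein interaction — the motivating case is a substitution in the
STAT2 coiled-coil domain that abolishes binding of USP18, the negative
regulator of type I interferon signalling — a common computational workup
is:

1. **Find the interface.** Compute the solvent-accessible surface area
   (SASA) of one chain alone and in the complex; residues that lose surface
   on complex formation (ΔSASA > 0) are interface residues.
2. **Saturate the interface.** Enumerate all 19 non-wild-type substitutions
   at each interface residue (24 interface residues → 456 candidates) and
   obtain predicted stability changes ΔΔG_monomer and ΔΔG_full (complex)
   for each, conventionally averaged over ~10 predictor replicates.
3. **Prioritize by a rule cascade.** Exclude substitutions seen as standing
   population variation; keep −0.5 ≤ ΔΔG_monomer ≤ +0.5 kcal/mol (the
   protein must still fold); keep ΔΔG_full > 2 kcal/mol (the interface must
   be disrupted); keep residues within 5 Å (nearest atom) of known anchor
   residues. An audit trail counts removals per rule.
4. **Prepare restrained docking input.** Pick the residue closest to the
   centroid of the partner's mapped binding region and emit a maximum-
   distance attraction restraint (default 20 Å) from an anchor residue to
   it.
5. **Quantify the downstream phenotype.** Score blood interferon signatures:
   the median fold change of a 24-gene ISG panel normalised to 3 reference
   probes, called positive above the healthy-control mean + 2 SD; and ΔΔCt
   relative expression (RQ = 2^−ΔΔCt) for a 6-gene qPCR panel.

Every stage is implemented as a small, tested library module, with a
from-scratch Shrake–Rupley SASA implementation, a FoldX-style `Dif_*.fxout`
table parser, an explicitly-labelled coarse ΔΔG surrogate for self-contained
runs, and a synthetic-fixture generator that plants known answers (interface
membership, centroid residues, exact rule-boundary cases) so the whole
pipeline is verifiable without any external structure or licensed predictor.

## Worked example

```sh
ifacemut simulate --out fixtures --seed 3
ifacemut mutscan fixtures/complex.pdb \
    --target A --partners B --anchors A:5,A:17 \
    --ddg fixtures/ddg.tsv --variants fixtures/population_variants.tsv \
    --out run
```

prints

```
wrote fixtures to fixtures
24 interface residues, 456 candidates, 10 shortlisted -> run
```

i.e. the 24 planted contact residues were detected by ΔSASA, saturation
enumeration produced 456 candidate substitutions, and the four-rule cascade
kept exactly the 10 planted survivors. `run/audit.json` shows the per-rule
removals summing back to 456:

```json
{
  "input": 456,
  "removed_by_distance": 385,
  "removed_by_full_threshold": 24,
  "removed_by_monomer_window": 23,
  "removed_by_population": 14,
  "surviving": 10
}
```

A docking restraint from the first anchor to the planted centroid residue of
the partner region 51–112:

```sh
ifacemut restraint fixtures/complex.pdb \
    --anchor A:5 --partner-chain B --region 51:112 --distance 20 \
    --out run/restraint.txt
# -> restraint A:5 - B:81 at 20 A
```

Signature scoring on the simulated 29-control cohort with one 10-fold
elevated sample:

```sh
ifacemut ifnscore fixtures/counts.tsv --out run/scores.tsv
# -> threshold 1.1067 from 29 controls, 1 positive
```

The elevated sample scores 10.0 (median fold change across the 24-probe
panel) against a control-derived threshold of ≈1.11, and is called positive.

Everything is available as plain library calls too — see
`ifacemut.synthetic.make_study_case` for the one-call version of the
fixture + cascade pipeline used in the tests.

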