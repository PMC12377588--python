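# Methods

## Residue classification from pLDDT

AlphaFold2's per-residue confidence (pLDDT, 0–100) correlates inversely with
structural flexibility, and long low-confidence stretches are an established
proxy for intrinsic disorder. `idrbench` classifies each residue of a
protein as:

- **disordered** — pLDDT < `disorder_plddt_max` (default 50, strict) *and*
  inside a contiguous low-confidence stretch of at least `stretch_min_len`
  residues (default 30, inclusive) with mean pLDDT < `stretch_mean_max`
  (default 70, strict);
- **ordered** — pLDDT ≥ `ordered_plddt_min` (default 70, inclusive);
- **intermediate** — everything else.

"Contiguous stretch" admits two readings, both implemented:

- `maximal_run` (default): maximal runs of consecutive residues with
  pLDDT < 70, kept when ≥ 30 long. A 20-residue dip flanked by confident
  structure is *not* disordered — it stays intermediate, which is the
  conservative intent of the rule (mobile loops inside folded domains should
  not count as IDRs).
- `any_window`: a residue qualifies if any 30-residue window containing it
  has mean pLDDT < 70. More permissive (the same 20-residue dip *is* called
  disordered because windows overlapping its confident flanks still average
  below 70); retained for sensitivity analysis.

Every residue disordered under `maximal_run` is disordered under
`any_window` (any ≥30 run of values < 70 contains qualifying windows), so
the default is the stricter of the two. Note that in `any_window` mode the
*union* of qualifying windows can have mean pLDDT ≥ 70; the reported segment
mean is informational there, whereas in `maximal_run` mode it is provably
< 70 and asserted.

pLDDT inputs must be on the 0–100 scale. Files whose values all lie in
[0, 1] are rejected unless an explicit rescale flag is passed — a silent
unit error would flip every classification. Structure files (PDB/mmCIF) are
read with biotite, taking the B-factor of each residue's first atom
(AlphaFold DB writes identical values for all atoms of a residue; on
disagreement the CA atom is used and a warning logged). Coordinates are
1-based with inclusive segment ends, matching protein-sequence convention;
the segment TSV is therefore *not* half-open like genomic BED. Proteins shorter
than 30 residues can never contain a disordered residue; this is accepted
behaviour, not an error. Multi-fragment AlphaFold DB entries (proteins
longer than ~2700 aa split across files) are not reassembled; supply a
per-residue TSV for those.

A protein is *highly disordered* when ≥ 30% (inclusive) of its residues are
disordered. Proteome summaries are residue-weighted, not protein-averaged.

## Variant statistics

Variants carry a class (`clinvar_pathogenic`, `clinvar_benign`,
`gnomad_benign`), optional inheritance (AD/AR) and mechanism (LOF/GOF/DN)
labels. Inheritance and mechanism are *inputs*, taken from existing
classifications — the package does not re-derive them. Loading
deduplicates identical (protein, position, alt, class) rows within a class
and reports, without resolving, variants that appear under more than one
class.

Collagen-helix genes are excluded up front (case-folded exact symbol match
against a user-supplied list; no alias resolution). Collagens are fibrous
proteins consistently predicted disordered; without this step they dominate
the disordered pathogenic class and confound every downstream comparison.

Variants without pLDDT coverage stay `unassigned` and are excluded from
distributions (denominators are region-assigned variants) with a logged
count; a strict mode turns them into errors.

Enrichment uses the two-sided Fisher's exact test under the
minimum-likelihood rule (sum of hypergeometric probabilities ≤ the observed
table's), computed by scipy and verified in the tests against exhaustive
enumeration over every table with total ≤ 40. The odds ratio is the sample
odds ratio ad/bc (∞ when bc = 0 and ad > 0); a zero-margin table is flagged
degenerate with p = 1.

Binomial confidence intervals default to the Wilson score interval (good
coverage at small counts, never leaves [0, 1]); Clopper–Pearson is available
by flag. Both are exact at the boundary cases k = 0 (lower = 0) and
k = n (upper = 1).

## VEP benchmarking

Filtering order is normative: first drop VEPs scoring < 75% (inclusive
boundary) of the pathogenic + putatively-benign variant set, then keep
exactly the variants scored by every retained VEP. Reversing the order
yields different retained sets; the tests pin the normative order on a toy.
The 75% denominator is computed after collagen exclusion. Evaluation
outcomes are binary: ClinVar pathogenic = 1, gnomAD putatively benign = 0
(ClinVar benign records are kept for distributions but not scored — using
population variants as the negative class reduces the circularity risk of
VEPs trained on clinical labels).

Score orientation is explicit per-VEP metadata (`higher_is_pathogenic`);
scores are negated when false, never silently auto-flipped. An audit mode
warns when an oriented VEP's AUROC falls below 0.5.

Conventions, used identically everywhere (ROC, Youden, binarisation):

- call rule: pathogenic ⇔ score ≥ threshold;
- candidate thresholds: the distinct observed scores plus +∞ (ROC
  vertices); no interpolation, so results are exactly reproducible;
- AUROC: Mann–Whitney ranks with ties ½ (equals trapezoidal ROC area);
- Youden ties: maximal J, then higher sensitivity, then lower threshold.
  Rationale for the sensitivity preference: the motivating failure mode is
  missed pathogenic variants in IDRs.

Region-specific thresholds re-run the Youden scan within one region's
variants. They are prioritisation aids for research use, not clinical
cutoffs — far stricter thresholds would be required for clinical
classification. Cohen's κ is computed on binary calls at each VEP's
*global* threshold; when expected agreement is 1 (both call vectors
constant) κ is defined as 1 if identical and 0 otherwise. Group summaries
average κ over unordered VEP pairs, each counted once, with SEM taken over
pairs (not variants).

## Synthetic data

The generator states a world and keeps it fixed:

- **Profiles**: alternating blocks; ordered blocks 60–200 residues emitting
  N(90, 4²), low-confidence blocks either disordered (30–90 residues,
  N(40, 6²)) or milder intermediate-type (20–60 residues, N(60, 4²), drawn
  with probability 0.3). Emissions are independent per residue, truncated to
  [0, 100]; block structure supplies the long-range correlation the
  run-based classifier needs, and within-block autocorrelation is
  deliberately omitted. Ground truth is the generating state, except that
  disordered blocks shorter than 30 residues are truthed intermediate so
  classifier-vs-truth comparisons respect the classifier's own definition.
  With these defaults a disordered-block residue emits pLDDT ≥ 50 with
  probability 1 − Φ(10/6) ≈ 4.8% and is then (correctly, per the rule)
  labelled intermediate although its block is disordered; per-residue
  agreement with block truth is therefore ≈ 1 − 0.048·f_dis ≈ 98.5%, not
  100%, and the tests assert agreement against this analytic rate rather
  than an arbitrary round number. With noiseless emissions agreement is
  exact.
- **Variants**: expected counts per (class, region), Poisson-drawn (a
  fixed-count mode exists for golden tests), placed uniformly on that
  region's residues with replacement. Defaults: pathogenic split
  54/226/1220 across disordered/intermediate/ordered (the strong depletion
  of pathogenic variants in disorder, ~3.6%/15.1%/81.3%), gnomAD benign
  900/600/1500 (enriched in disorder relative to pathogenic), ClinVar benign
  60/80/260. P(AD | region) for pathogenic variants is 0.75/0.65/0.50 (AD
  enrichment in disorder); AD mechanisms are drawn per region and AR
  variants are always LOF. These are qualitative templates of the real
  class-by-region structure, not numeric reproduction targets.
- **Scores**: binormal per (VEP, region, class) with a shared per-variant
  latent factor (ρ = 0.7) so VEPs agree more than chance. The `paper-like`
  preset gives, on the oriented scale, ordered (μ_ben, μ_path) = (0, 2),
  intermediate (−0.5, 1.6) and disordered (−1.5, 0.8) with σ_ben = 0.6 in
  disorder. The design point: the disordered *benign* class sits far below
  the global threshold (easy true negatives → high disordered AUROC and
  specificity) while the disordered *pathogenic* mean lies below the
  globally optimal threshold (≈ 1), so global-threshold sensitivity
  collapses in disorder. This reproduces the AUROC/sensitivity dissociation
  mechanistically: in a binormal world, "weak pathogenic signal in absolute
  score units" and "high region AUROC" coexist only because the benign
  distribution shifts down more than the pathogenic one. A preset in which
  Δμ/σ itself were smaller in disorder would *lower* disordered AUROC
  (AUROC = Φ(Δμ/√(σ₁²+σ₀²)) is monotone in it) and could not show the
  dissociation. Missingness is applied per VEP (default preset: one VEP at
  30%, which the 75% coverage filter removes).

All randomness derives from one seed via named `SeedSequence` substreams,
so outputs are byte-identical across reruns and adding a generator does not
perturb existing ones.

What a green synthetic test does *not* establish: real pLDDT profiles are
autocorrelated and multi-modal; real VEP scores are bounded, skewed and
correlated through shared training data rather than a single latent factor;
real class labels carry curation biases. The synthetic checks validate the
*machinery* (filters, metrics, thresholds, bookkeeping), not empirical
claims about any particular proteome or predictor.

## Numerical choices

- Youden tie tolerance 1e−12 on J; exact ties keep the lower threshold.
- Fisher enumeration comparisons use relative tolerance 1e−7 (matching the
  scipy convention of accepting tables within a (1+1e−7) factor of the
  observed probability).
- Label fractions sum to 1 exactly (integer counts over a common
  denominator); proteome summaries are residue-weighted.
- Empty strata yield NaN proportions flagged `undefined`, not errors; a
  region stratum lacking an outcome class is skipped with a warning, but a
  class vanishing *globally* is an error.
- Degenerate κ (both vectors constant): 1 if identical else 0.

## Pipeline configuration

`run_all` takes a single mapping (YAML via `idrbench run-all --config`):

```yaml
inputs:
  plddt: inputs/plddt.tsv          # or use the classify CLI for PDB/mmCIF
  variants: inputs/variants.tsv
  scores: inputs/vep_scores.tsv    # long form; score_form: wide also supported
  vep_metadata: inputs/vep_metadata.yaml
  exclusion_list: inputs/collagen_genes.txt
classifier:                        # defaults shown
  disorder_plddt_max: 50.0
  stretch_min_len: 30
  stretch_mean_max: 70.0
  ordered_plddt_min: 70.0
  stretch_mode: maximal_run
analysis:
  min_coverage: 0.75
  ci_level: 0.95
  highly_disordered_min: 0.30
outdir: out
```

Unknown keys are rejected; all paths are checked before any stage runs.
Stages can be run individually (`classify`, `variants`, `evaluate`) against
the same `outdir` with identical results to a single `run_all`. The run
report records input fingerprints (SHA-256), per-stage counts and the
parameter echo.

## Known limitations

- No genome→protein coordinate mapping: variant tables must already be in
  protein coordinates.
- Gene exclusion is exact-symbol (case-folded) matching; aliases are the
  caller's responsibility.
- κ group SEMs with a single constituent pair are reported as missing, not
  zero.
- The `any_window` stretch mode can include residues with pLDDT ≥ 70 inside
  a qualifying union; interpret its segments accordingly.
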