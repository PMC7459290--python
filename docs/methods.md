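# Methods

## Scope and data model

`pedbreed` operates on a single in-memory object, the `PedimapDataset`: a
header (population name, ploidy, missing/null codes, founder-allele count),
an ordered pedigree-and-phenotype table, linkage-group maps, observed marker
alleles, and founder-allele IBD probability blocks.  The on-disk form is the
keyword-sectioned tab-delimited dialect specified in `FORMAT.md`; reading and
writing are exact inverses (`parse(write(d)) == d` field-for-field), which the
test suite enforces as a property over randomly generated datasets.  Floats
are therefore written with the shortest representation that round-trips the
value rather than at a fixed decimal count.

Generic ploidy k is supported by the file layer and the exact IBD recursion;
the gene-drop transmission model and the kinship recursion are diploid, which
covers rice.

## Pedigree graph

Founders are records with both parents unknown.  A record with exactly one
known parent is accepted with a warning: the unknown gamete becomes a
*phantom founder*, an internal node that keeps gene-flow accounting
conservative (such records arise in practice when intermediate generations —
F1s, F2s — were never registered).  Phantom founders are excluded from
user-facing founder lists but occupy founder-allele slots, so the
founder-allele count generalizes to ploidy × (founders + phantoms).

Generation layering uses longest paths (child = 1 + max over parents), which
places backcross offspring below both parents, matching the drawing
convention for crossing schemes.  Kinship uses the standard recursive tabular
method in topological order: f(x,x) = ½(1 + f(mother, father)),
f(x,y) = ½(f(mother,y) + f(father,y)) with missing-parent terms zero.  Cycle
detection reports one witness cycle.

## Founder-allele IBD

`ibd_exact` computes the *marker-unconditioned* pedigree expectation: the
expected count of gene copies an individual carries from each founder allele.
Founder rows are unit indicators on their own slots; every other row is the
mean of the two parental rows.  This expectation does not vary along the
genome, so one vector serves all positions.  This deliberately differs from
marker-conditioned IBD (as produced by MCMC-based QTL software): conditioning
on observed genotypes is out of scope here, so numbers written into the IBD
section are pedigree expectations, not posterior probabilities given markers.

`gene_drop` is the Monte-Carlo counterpart and the generator of synthetic
marker data: founder alleles are labelled and dropped down the pedigree; the
copy transmitted at the first position is uniform, and between adjacent
positions the choice flips with the Haldane (no-interference) recombination
fraction r = ½(1 − e^(−2d/100)) for d in cM.  Rows are normalized to expected
counts (sum = ploidy), so founder rows are unit indicators — the
normalization is per individual, not per gene copy, and is recorded in
`FORMAT.md`.  One master seed drives the whole simulation via NumPy
`SeedSequence` substreams, so identical seeds give identical output.

Cross-checks tie the three computations together: gene-drop frequencies
converge to the exact recursion; single-replicate gamete coincidence
converges to pedigree kinship.  Where such a check compares thousands of
entries at once, the 3σ per-entry confidence level is applied family-wise
(Bonferroni over the stochastic entries); a plain per-entry 3 SE bound over
that many comparisons would flag chance excursions by construction.

## Trait filtering

Criteria are inclusive thresholds / ranges on quantitative traits and set
membership on categorical ones, combined by conjunction.  The breeder's
priority order is retained for reporting (the pass/fail matrix and summaries
follow it) but never changes membership, because selections of this kind are
stated as all thresholds holding simultaneously.  The default missing policy
excludes an individual missing any filtered trait; an `include` policy exists
for display-style selections where missing values are shown (white boxes)
rather than selected on.  Category vocabularies are file-driven, never
hard-coded; the packaged example criteria are plain YAML.

## Estimated breeding values

EBV = H²(P − P̄) with P̄ the mean over non-missing records — the choice of
record set matters and is the package's convention.  A *recovered-mean* mode
inverts the formula on a published (P, EBV) pair, allowing a printed table
excerpt to be reproduced without the full underlying database; the packaged
34-cultivar RRDI reference table is internally consistent under this
inversion to the printed rounding (±0.01).  EBVs are computed and ranked at
full precision and rounded only for display.  Competition ranking ("1, 2, 2,
2, 2, 6") is used throughout; ties are broken for display order only by file
order.  Accuracy (correlation of EBV with TBV) is only computable when TBVs
exist, i.e. in simulation; since the EBV is a positive scaling of the
centered phenotype, accuracy of EBV and of raw phenotype are identical, and
the theoretical value for mass selection is √H².

The reference table's maturity and plant-height *ranks* were published
against the full 188-cultivar germplasm and are not recomputable from the
34-row excerpt; the yield ranks 1–30 are, and are asserted.  Published
per-cultivar accuracies have no reproducible definition from the excerpt and
are carried as annotations only.

## Synthetic germplasm

The generator emulates a breeding-program database: founders (landraces/old
varieties), per-generation crosses, selfings and backcrosses, and optionally
a block of unreported F1 intermediates each selfed into a named line.  The
study-scale configuration produces 224 records of which 36 are intermediates
without trait records (188 named).

Quantitative traits follow the additive infinitesimal model: founder TBV ~
N(0, σ²_A), offspring TBV = midparent + N(0, σ²_A/2), phenotype = μ + TBV +
N(0, σ²_E).  Defaults: yield μ 5.5 mt/ha, σ²_A = σ²_E = 0.40 (H² = 0.50);
maturity (both seasons) μ 105/107 days, σ²_A = 161.5, σ²_E = 28.5 (H² =
0.85); plant height μ 70 cm, σ²_A = 122.4, σ²_E = 21.6 (H² = 0.85).  The
variances are chosen so simulated ranges match the published trait ranges
(yield ≈ 4–8 mt/ha, maturity ≈ 80–135 d, height ≈ 48–104 cm); no empirical
variance components exist for this germplasm, so these are conventions, and
all are config-overridable.  Categorical traits (pericarp color, grain shape,
BPH/blast resistance, amylose class, PDT rank) are fully penetrant
single-locus characters with the first listed level dominant; PDT uses a high
per-trait missing rate (0.85) to emulate a sparsely scored trait.  Default
missing rate elsewhere is 0.05.

Known simplifications: Mendelian-sampling variance stays σ²_A/2 under
selfing (no inbreeding adjustment of segregation variance); no dominance,
epistasis, G×E or LD structure; the two seasonal maturity traits are
simulated as separate traits, not a mechanistic seasonal effect; marker maps
are short and artificial.  Passing tests therefore demonstrate correctness of
the algorithms under the additive model, not realism of rice genetics.

Problem sizes used by the test suite and acceptance checks: the published
table computations are exact on 34 rows; Monte-Carlo cross-checks use a
50-individual pedigree at 4,000–20,000 replicates; parameter-recovery runs
use ≈2,000 individuals, where ±0.05 tolerances on H², midparent slope and
accuracy are several standard errors wide.

## Rendering

Drawings are layered by generation with deterministic barycenter ordering
within layers.  Each distinct mating pair becomes an explicit '×' junction
node (circled for selfing); maternal edges are red, paternal purple,
junction-to-child black; node boxes are filled by trait value, quantitative
traits binned into at most seven equal-width classes (configurable), missing
values white, context-only ancestors uncolored.  SVG is canonical; DOT is
emitted for external graph tooling.  Published figure palettes are not
machine-readable, so palettes are configurable rather than asserted.
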