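# Methods

## Scope and pipeline position

`biogeopath` starts where the heavyweight upstream tools stop. Assembly
(Megahit/metaSPAdes), gene calling (Prodigal), homology search (hmmsearch
against KO profile HMMs and a custom organosulfur database) and read mapping
(BWA-MEM + coverage summarization) are external pre-steps; this package
ingests their tabular outputs and owns everything bespoke after them:
threshold-based annotation, TPM quantification, the route/mean pathway
formula, cross-sample comparison and the synthetic validation. Isolating the
bespoke computation keeps the analysis reproducible without any external
binaries.

## Annotation

Each KO family carries its own bit-score cutoff and a score type: `full`
cutoffs compare against the full-sequence bit score, `domain` cutoffs against
the best-domain score. Acceptance is inclusive (`score >= threshold`,
`evalue <= ceiling`), matching the reporting semantics of `hmmsearch -T` /
`--domT`. Some KO rows in a `ko_list`-dialect table carry no usable threshold
(`-`); these are retained and fall back to an E-value ceiling, default 1e-5
(configurable) — a pragmatic default near common annotation practice for
profile searches. A gene keeps every family it is accepted against, across
both databases; there is no best-hit resolution, so a bifunctional gene
contributes to all of its functions. Monotonicity holds by construction:
lowering a threshold can only add assignments.

### The organosulfur database config

The shipped DMSP config (`data/dmsp_cutoffs.tsv`) lists exactly 20 families
with curated E-value ceilings: DSYB 1e-30, DsyB 1e-67, MmtN 1e-98 (synthesis);
DmdA 1e-130, DmdB 1e-75, DmdC 1e-100, DmdD 1e-30, AcuH 1e-56 (demethylation);
DddD 1e-97, DddK 1e-35, DddL 1e-33, DddP 1e-83, DddQ 1e-20, DddW 1e-49,
DddY 1e-64, Alma1 1e-26 (cleavage); DmoA 1e-34, DorA 1e-30, MddA 1e-30,
MTO 1e-20. DorA's ceiling is not independently curated; 1e-30 is the default
used for the remaining oxidoreductase-type families.

Known ambiguity: the DMS→DMSO step is catalyzed by the three-subunit DMS
dehydrogenase (DdhABC) or trimethylamine monooxygenase (Tmm). The source
material for these cutoffs names "DdhABC, DdhB, and Tmm" jointly at 1e-30 —
DdhB both inside and outside the complex name. We resolve this by giving each
subunit DdhA, DdhB, DdhC and Tmm its own 1e-30 ceiling, shipped as an
extension file (`data/organosulfur_extra.tsv`) so the core DMSP set stays at
its documented 20 families while the DMS→DMSO pathway remains annotatable
via `organosulfur_family_cutoffs()`.

## Quantification

TPM_i = 10^6 · rate_i / Σ rate_j with rate_i = X_i/L_i in reads mode. In
coverage mode the per-base average coverage is used as the rate directly:
coverage = X·readlen/L, and the constant read length cancels in the ratio, so
the two modes agree exactly up to that factor (pinned by a test). An all-zero
sample yields all-zero TPM rather than an error so empty controls flow
through. Family abundance is the raw sum of member-gene TPM with no
copy-number correction — multi-copy inflation (e.g. a multi-copy nirK-like
nitrite reductase) is intended signal, not bias.

Whether multi-mapped reads are counted once or per alignment is a property of
the upstream counts table, not of this package.

## Pathway formula

A_pathway = Σ_routes mean(component abundances). Numerical choices:

- **Within-component alternatives pool by sum.** The alternatives are
  interchangeable enzymes for one step (eight DMSP lyases, three DMSP
  synthesis methyltransferases), so the step's genetic potential is their
  pooled abundance. Max or mean would understate communities that split the
  function across families.
- **Missing component = 0, divisor unchanged.** The divisor is the number of
  *essential* components (n = 3 for phsABC even with phsB undetected): an
  incomplete complex is diluted, not renormalized.
- Route and component order never affect values (commutative sums and means);
  file order is kept only for reporting.
- Definitions are data: the engine evaluates whatever the TSV schema encodes
  (`pathway_id, display_name, cycle, route_index, component_index,
  families`), so the built-in set can be extended without touching code.

The built-in sulfo-ED and SF-transaldolase sulfoquinovose definitions use
descriptive custom family names (`sqDH`, `sglLact`, `sgDehyd`, `kdsgAld`,
`slaDH`, `sfTal`) because those enzymes have no KO ids; they are placeholders
matching whatever labels the user's custom search produces, synthetic in the
sense that no public reference set fixes them.

## Synthetic benchmark

`generate_genomes` builds genomes in three guilds with group-exclusive marker
families (photosystem-like genes only in photoautotrophs, ammonia
monooxygenase subunits plus a multi-copy nirK-like marker only in
chemoautotrophs, catabolism genes in heterotrophs), shared housekeeping
families, and unannotated filler genes. Gene lengths are uniform on 300–3000
nt. Shared families carry a genome-specific copy number of 1–3: without some
copy-number variation every genome of a guild would have identical
single-copy content and a single-guild community's expected profile would be
constant, making correlation undefined; dosage variation is also what real
genomes exhibit. Default design: five samples — photoautotrophs only,
heterotrophs only, chemoautotrophs only, a 1:1:1 mix, and a 3:1:2 mix. These
ratios are structural stand-ins spanning single-guild and mixed communities.

Counts are drawn from one multinomial per sample with gene selection
probability ∝ weight × copies × length at 100,000 reads per sample (depth is
a parameter; recovery improves monotonically with depth in expectation and
the suite checks this over seeds). Expected reads ∝ w·c·L makes the expected
length-normalized rate ∝ w·c, so the ground-truth profile has the closed form
a_f = 10^6 · Σ_{genes of f} w·c / Σ_{all genes} w·c, with filler genes kept
in the denominator exactly as unannotated ORFs absorb reads in the real
pipeline. Recovery is scored per sample as the Pearson correlation between
the recovered and expected profiles over the union of families.

What this validates — and what it does not: the benchmark exercises the
quantification/aggregation/correlation machinery (optionally routing labels
through the annotation module via synthetic hits) under multinomial sampling
noise only. Assembly fragmentation, chimeras, mapping ambiguity,
sequencing-error and inter-genome homology effects are explicitly not
modeled, so a high benchmark correlation bounds pipeline error, not
end-to-end error on real reads.

All randomness flows through explicit seeds; identical seeds give
bit-identical genomes, counts and results.

## Comparison and figures

Cross-sample normalization divides each pathway row by its total over samples
(all-zero rows stay zero; idempotent on normalized rows). Bubble-plot values
use log10(x·10³) with zeros masked rather than pseudo-counted — undetected
pathways are drawn as absent. Sample clustering uses Bray–Curtis
dissimilarity with average linkage, the community-ecology default (both
configurable); columns are sorted by sample id before clustering so the tree
is independent of input order. Figures are written atomically as both SVG
and PNG, and the sketch renderer returns its marker geometry
({(pathway, sample): area in pt²}, area linear in the normalized fraction)
so figures are testable without rasterization.

## Limitations

- Pathway abundance is genetic potential, not flux or expression.
- The within-route mean assumes each component is genuinely essential to the
  route; promiscuous or redundant subunits bias pathways downward.
- No between-sample compositional correction (TPM is per-sample relative).
- The shipped definition set is the documented core; a comprehensive pathway
  catalog is expected to arrive as user data files in the same schema.
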