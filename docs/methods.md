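# Methods

## Scope and model

`fammod` implements a gene-content comparison pipeline for archaeal genome
collections.  The object of study is the boolean incidence of protein
families across genomes; all clustering operates on presence/absence only
(copy number is discarded, since the biological signal of interest —
correlated gain/loss of family blocks across lineages — lives in incidence,
not dosage).

### Presence calls

A family is present in a genome iff at least one homology hit passes the
E-value threshold (default 0.001, inclusive).  Subfamily-level hits
aggregate to families by union: one passing subfamily hit suffices.  The
matrix keeps all-false genome columns (a genome with no detected family is
still a leaf of the genome dendrogram) and by default drops all-false family
rows, which carry no clustering information.

### Module detection

Families are clustered agglomeratively on the Jaccard distance between
their genome profiles.  Conventions:

* distance between two empty profiles is 0 (identical); such rows are
  normally excluded before clustering;
* linkage is **complete** by default, matching the genome-side clustering;
  average linkage is available via configuration.  The family-side linkage
  is a design choice: complete linkage guarantees that every pair of
  families inside a module is mutually similar, which is what "block of
  co-occurring families" means;
* the dendrogram is cut at **cophenetic distance 0.95**.  Jaccard distance
  is bounded by 1, so the cutoff is on the natural distance scale, not a
  height fraction;
* flat clusters with ≥ 20 families become modules; smaller clusters are
  reported in a residuals table.  Modules are numbered by descending size,
  ties broken by lexicographically smallest member, so numbering is
  independent of input row order.

A 0.95 cutoff is deliberately permissive: any family whose Jaccard
similarity to *every* member of a cluster is at least 0.05 will join it.
Under complete linkage this is self-limiting (an absorbed outlier family
then raises the cluster's distance to everything resembling it), but exact
recovery of a planted block can still acquire a few sparse hangers-on; the
tests therefore distinguish exact recovery (noise-free structured fixtures)
from tolerant recovery (family-set Jaccard overlap ≥ 0.8 under noise).

### Module taxonomy: the median-genome rule

For a module: compute each member family's genome count; let *m* be the
median, rounded half-up when fractional (a module of even size retains at
least the median-typical number of genomes); rank genomes by the number of
member families they carry, ties broken by lexicographic genome id; retain
the top *m*; the retained genomes' phylum tally is the module's taxonomic
assignment.

Two derived labels are reported:

* `dominant_lineage` — the unique modal phylum of the retained set (None on
  a tie), with its share;
* `assigned_single_lineage` — set when the dominant phylum's share reaches
  the `purity` parameter.  The default `purity = 1.0` demands unanimity of
  the retained genomes.  Under presence noise the top-*m* ranking provably
  admits a minority of non-carrier genomes (the median count *m* exceeds the
  true carrier count by roughly `flip_noise × non-carriers`), so unanimity
  is only attainable on clean data; analyses of noisy collections should
  judge assignments by the dominant lineage or relax `purity` (e.g. 2/3).
  Keeping unanimity as the default preserves the strict reading of
  "assigned to a single lineage" while making the noise-tolerant behaviour
  an explicit, visible choice.

### Occurrence and enrichment

A module *occurs* in the flagged group (DPANN) when at least one flagged
genome carries ≥ 1 member family — no minimum-carriage threshold is
imposed, so under flip noise essentially every module occurs somewhere; the
discriminating statistic is enrichment.  Prevalences are means over member
families of the fraction of group genomes carrying the family, computed
separately for flagged and unflagged *archaeal* genomes; `enriched` is a
plain comparison of the two means.  No significance test is attached: the
statistic is descriptive, and the family counts per module (20–60) with
hundreds of genomes make the direction of the comparison stable.  Both
prevalences are undefined (and flagged as such) when either group is empty.

### Genome QC

Completeness = 100 × (SCGs present) / 38; contamination = 100 × (total
copies − SCGs present) / 38.  The contamination definition is a proxy —
monotone in duplication and exactly testable — chosen because the 38-SCG
panel has no published contamination formula (CheckM-style percentages come
from a different marker model).  Rule boundaries follow the printed
thresholds exactly: the draft rule is strict on both sides (> 22 present,
< 4 duplicated); the representative-set rule fails at completeness < 70,
contamination > 10, alignment coverage < 0.5, or ribosomal proteins on more
than one scaffold, and passes at the boundary values 70 / 10 / 0.5.  Both
rule families are pure per-genome predicates, so the surviving set is
independent of application order.

Dereplication replaces a two-stage sketch/alignment tool with single-linkage
connected components on a user-supplied ANI table, with the edge condition
ANI ≥ 95 (inclusive).  The contract is the threshold plus the representative
rule — most complete, then least contaminated, then lexicographic id — not
any particular ANI implementation.  Dereplication runs on the QC survivors,
so the representative of each cluster is chosen among genomes already known
to be usable.

### Breadth

For each (family, phylum): incidence = 100 × (genomes of the phylum with a
passing hit) / (genomes of the phylum).  A phylum passes for a family when
its incidence reaches one third, inclusive (a phylum with 2 hits among 6
genomes counts; the comparison carries an epsilon of 1e-9 in percentage
points to absorb last-ulp float noise, far below any attainable incidence
gap).  Breadth = 100 × passing phyla / all surveyed phyla — the denominator
includes phyla with zero hits for the family, because the statistic reads
as "percentage of unique bacterial phyla".  Families with no passing
bacterial hit at all have null breadth, not zero.  The supplied bacterial
metadata *is* the representative set; no internal re-selection is done.  A
`min_phylum_size` option can exclude barely-sampled phyla from the survey
(default: none excluded).

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes, not
biology: no sequences, gene order or trees are simulated, and the alignment
rows are random residues with controlled gap fractions (sufficient for
column-coverage accounting only).  Passing tests therefore demonstrate that
the rules and statistics are implemented correctly and are robust to
exchangeable presence noise — not that real genome collections satisfy the
generator's assumptions (independent flips, block-structured truth,
lineage-aligned carriers).

Components and defaults:

* **Planted modules** — each module's families share one carrier-genome set
  before noise.  Carriers are drawn per lineage at the configured occupancy;
  when several modules claim the same lineage they draw from one shuffled
  pool *without replacement*, emulating sub-clade structure.  This is a
  modelling necessity, not a convenience: two modules with identical carrier
  sets have identical expected profiles and are a single co-occurrence block
  by definition, so a truth table that overlapped carriers heavily would be
  unrecoverable by *any* profile clustering.
* **Background families** — independent Bernoulli presence at
  `background_presence_prob = 0.02` by default.  Real family collections
  are sparse (on the order of 10⁴ families over ~2×10³ genomes, most of
  them lineage-confined), and a 2% marginal prevalence reproduces that
  regime; it also keeps random background similarity to any module below
  the 5% Jaccard similarity that the 0.95 cutoff tolerates, which is what
  makes planted structure recoverable at all.
* **Flip noise** — each cell toggles independently with probability
  `flip_noise`; the simplest exchangeable corruption that degrades Jaccard
  distances smoothly.
* **E-values** — present cells draw log-uniform in [1e-30, 1e-4]; absent
  cells emit a decoy hit with probability 0.02, log-uniform in (2e-3, 10],
  exercising threshold filtering without flipping presence.
* **Bacterial survey** — per-genome Bernoulli hits at a per-family-class
  rate (defaults: module families 0.05, background 0.25), over 5 phyla of
  10 genomes; with 10-genome phyla the pass threshold is ≥ 4 hits, so the
  defaults yield a broad spread of breadth values.
* **QC planting** — one genome per failure mode by default (19/38 SCGs;
  6 duplicated SCGs; 60% alignment gaps; ribosomal proteins split across
  two scaffolds) plus one 97%-ANI pair; all other genomes are constructed
  to pass every rule (≤ 2 duplicated SCGs, ≤ 10% gaps, background ANI in
  75–90).
* **Randomness** — one `numpy` Generator per artifact, all spawned from a
  single `SeedSequence(seed)`, so outputs are individually stable and the
  whole dataset is byte-reproducible.

The standard recovery benchmark (`recovery_benchmark_config`) uses 300
genomes in 6 lineages (3 DPANN), 1,500 background families, 12 planted
single-lineage modules with sizes 20–60 carried by disjoint half-lineages
(25 genomes each), and 5% flip noise — small enough to run in seconds on
one CPU, large enough that per-family counts concentrate and the noise
phenomena discussed above (inflated *m*, stray absorptions) actually occur.

## Numerical and determinism choices

* All tie-breaks are lexicographic on identifiers (genome ranking, module
  numbering, representative selection), making every output independent of
  input row order.
* The analysis path contains no randomness; the pipeline seed exists only
  to pin the generator that produced a run's inputs.  Outputs are written
  atomically (`.partial` then rename) and the manifest contains no
  timestamps, so reruns are byte-identical.
* Median rounding is half-up via `floor(x + 0.5)`; integer medians are
  untouched.
* Degenerate inputs: single-genome matrices cannot be genome-clustered
  (error); a single family is its own cluster; empty-profile rows are
  excluded from family clustering by default; asymmetric distance or ANI
  matrices are rejected rather than symmetrised.

## Known limitations

* The contamination proxy is not comparable numerically to marker-set tools;
  only its ordering and the 10% threshold semantics are meaningful.
* Enrichment is a descriptive mean comparison without uncertainty; with few
  flagged genomes the direction can be unstable.
* The generator's independence assumptions (flips, background families)
  ignore phylogenetic autocorrelation; real presence noise is structured,
  and recovery rates measured here are optimistic in that respect.
* Breadth conflates lateral transfer with shared core function by design;
  it is a screen, and distinguishing the two (or contamination) requires
  phylogenetic follow-up outside this package's scope.
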