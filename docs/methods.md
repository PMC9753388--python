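# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `barcodeauth`.

## Distances

Site patterns are counted under **pairwise deletion**: for each sequence
pair, a column contributes only if both rows carry an unambiguous base
(A/C/G/T); gaps and IUPAC ambiguity codes are skipped for that pair only.
This matches the common default of desktop phylogenetics packages and keeps
every pair's denominator as large as its data allow. Transitions are A↔G and
C↔T; all other mismatches are transversions.

The K2P distance is d = −½·ln[(1 − 2P − Q)·√(1 − 2Q)] with P, Q the
transition/transversion proportions. The formula's domain excludes
1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 (and n = 0 compared sites); such entries are
flagged undefined (NaN), excluded from all summaries, and counted in the
report — never silently replaced by zero. The uncorrected p-distance is kept
alongside as a sanity bound (d ≥ p wherever d is defined, and d ≈ p below
1 % divergence). Human-facing reports round to 2 decimals; machine outputs
keep full precision.

## Alignment

Pairwise alignment is plain Needleman–Wunsch with linear gaps
(match +1, mismatch −1, gap −2, configurable) in a numba-compiled kernel.
The scoring is deliberately simple so the implementation can be checked
against exhaustive enumeration of all alignments of short pairs. Tie-breaking
is fixed — diagonal, then gap-in-second, then gap-in-first, applied while
walking the traceback from the table corner — so results are bitwise
deterministic. The semiglobal (overlap) mode makes terminal gaps free in
both sequences.

**Percent identity** — the quantity thresholded during authentication — is
matched columns over counted columns, where counted columns exclude terminal
gap overhangs (semiglobal only) and columns containing an ambiguity symbol;
internal gap columns count as mismatches. This approximates BLAST percent
identity over an HSP for a full-length amplicon against a reference.

Multiple alignment is progressive: a UPGMA guide tree on pairwise distances
(normalized edit distances computed with edlib — a p-distance analogue chosen
for speed; the realized columns always come from the package's own profile
DP), then profile–profile alignment at each internal node using mean
pairwise column scores over the 6-symbol alphabet {A,C,G,T,missing,gap}.
Input order is preserved in the output; guide-tree ties resolve by input
order. On indel-free input (all synthetic data here) the MSA is expected to
stay at, or within a few columns of, the input length; the tests assert that
residues and within-clade distances are preserved rather than exact column
counts, since very divergent profiles can legitimately absorb a gap column.

## Barcoding gap

The distance criterion is strict: a group is discriminated iff its minimum
inter-group distance is **greater than** (not equal to) its maximum
intra-group distance, at either species or genus level. Singleton groups get
NA intra statistics and are directed to diagnostic-site mode.

A column is a **diagnostic site** for a target group against a contrast set
iff (i) all non-missing target states are identical, (ii) target missingness
(gap or ambiguity) is at most 1 − min_coverage (default min_coverage = 1.0,
i.e. no target missingness — diagnostic claims should be conservative for the
reference species), (iii) at least one contrast state is observed, and
(iv) every observed contrast state differs from the target state. Missing
data in a contrast row never disqualifies a column, so adding contrast rows
can only shrink the position set. Indel columns (target all-gap, contrast
all-base) are collected in a separate list, off by default. All reported
positions are 1-based alignment columns.

## Trees

NJ follows the Saitou–Nei Q-criterion; the pair minimizing Q is chosen by
scanning pairs in label order and keeping the first strict minimum, which
makes tie-breaking deterministic. The output is unrooted, represented with a
trifurcating root. Negative branch lengths (possible on non-additive input)
are clamped to zero with a log entry. On additive matrices the reconstruction
is exact to floating-point precision. UPGMA is average linkage with
size-weighted cluster updates; the output is rooted and ultrametric to 1e−9.

**Bootstrap**: alignment columns are resampled with replacement; each
replicate rebuilds the distance matrix and tree from scratch; a replicate
whose matrix contains undefined distances is skipped and counted. The support
of an internal bipartition of the point-estimate tree is the percentage of
non-skipped replicates that realize that bipartition *with positive edge
length* — a zero-length split is an arbitrary resolution of a polytomy and
carries no signal, which also yields the natural convention that identical
sequences give all-zero supports. Supports are reported as integers. The
default is 1000 replicates (configurable); the analysis scripts use 200 to
keep desk-scale runtimes in seconds.

**Clade test**: walking up from the query leaf, the first ancestor whose
subtree contains any labelled (non-unknown) leaf defines the smallest
enclosing clade; the query is concordant with a group iff every labelled
leaf in that clade belongs to it. For NJ the tree is midpoint-rooted first so
clades are well defined regardless of where the algorithm happened to place
the trifurcation.

## Authentication

Each query is scored against every panel member by semiglobal identity. The
top group is the group of the best hit; ties go to the group with higher mean
identity, then label order. Verdict rules:

* reference-species top hit at identity ≥ threshold (default **0.97**) →
  `authentic`, subject to tree concordance;
* non-reference top hit at identity ≥ a secondary floor (default **0.80**) →
  `adulterant:<species>`, even below the main threshold — a sub-threshold
  but clearly attributable hit is an informative non-match, which is how
  market surveys report e.g. 85 % hits to a wrong genus;
* otherwise `unidentified`.

Tree verification rebuilds an NJ tree over panel + queries and applies the
clade test. Discordance downgrades `authentic` to `unidentified` (never the
reverse); adulterant calls keep their verdict but record the discordance.
When several loci are available, verdicts should be combined conservatively —
authentic only if no locus contradicts; the package exposes per-locus runs
and leaves combination to the caller, since a single shared sequence space
per locus is assumed throughout.

The adulteration rate is 1 − authentic/total, undefined on empty input.

## Synthetic data

The generator is the generative counterpart of the K2P distance: a
continuous-time two-parameter process with uniform base frequencies and
transition/transversion rate ratio κ (default 2.0, a typical plant
ITS/plastid value), rate-normalized so branch lengths are expected
substitutions/site; per-branch transition matrices come from the matrix
exponential of the rate generator. The default study emulates a market
survey: 750 nt amplicons; a reference panel of 4 accessions with terminal
branches ≤ 0.001 (intra rounds to 0.00 at 2 dp); a congener (3 accessions)
sharing a 0.05 stem, confamilial genera at 0.075 stems (pairwise divergence
to the reference 0.10–0.125, inside the canonical 0.08–0.20 barcoding-gap
band), and two off-family contaminants at 0.18 stems; 22 market samples of
which 7 are authentic and the rest drawn from the adulterant groups
(7/4/2/2), each attached inside its true clade with the same terminal-branch
spread as panel members. One master seed drives every stage, so studies are
byte-reproducible.

Planted diagnostic sites overwrite k random columns with a fixed target
state and per-row different contrast states. Exact-recovery checks use a
zero-divergence background (all sequences identical before planting) so no
diagnostic columns can arise by chance; on divergent backgrounds the
guaranteed property is containment (every planted site is recovered,
possibly among natural ones), and both properties are tested.

What the generator does **not** emulate: indels and alignment uncertainty
(sequences are generated ungapped), rate heterogeneity across sites, base
composition bias, PCR/sequencing error, and mixed-taxon (powder blend)
samples. Passing tests therefore demonstrate the correctness of the
algorithms and the internal consistency of the workflow under its own model —
not robustness to misalignment or contamination in real amplicons.

## Problem sizes and determinism

Monte-Carlo checks use 200 replicates (estimator recovery, gap power), 100
random additive matrices for NJ exactness, 200 random short pairs for the
brute-force alignment oracle, and 50 independent seeds for the end-to-end
market study; these sizes give stable verdicts at desk scale while keeping
the full suite in the low minutes. All randomness flows through
`numpy.random.default_rng` seeded explicitly; hypothesis-based property
tests run derandomized.

## Known limitations

* Identity is computed from a single global/semiglobal alignment, not the
  best local HSP; for near-full-length amplicons the two agree closely.
* The diagnostic-site scan treats each column independently; linked sites and
  indel polymorphisms are not modelled.
* NJ/UPGMA only; likelihood and parsimony tree inference are out of scope
  (distance methods are what the verification step requires, and on these
  data the methods agree).
* Column numbering of diagnostic sites depends on the multiple alignment;
  two different aligners can report different absolute positions for the
  same biological variants.
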