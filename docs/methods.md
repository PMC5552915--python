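# Methods

This note documents the models, parameter choices and numerical
decisions behind `phoscan`, and what the synthetic-data tests do and do
not establish about real data.

## Profile HMM construction

Each family profile is a plan7-style match/insert/delete model
estimated from a multiple alignment of the family's curated reference
proteins (the alignment is an input; the package does not align).
Columns whose non-gap occupancy is at least the `occupancy_threshold`
(default 0.5) become match states; residues falling in other columns
are insertions, gaps in match columns deletions.

Smoothing is background-weighted Laplace with total pseudocount weight
1.0 (configurable): the match emission for residue *r* at state *k* is
`(c_kr + α·q_r) / (C_k + α)` with `q` the background and `C_k` the
column's non-gap, non-X count; transition rows are smoothed the same
way with the pseudocount spread uniformly over each state's allowed
moves (M→{M,I,D} gets α/3 each, I→{M,I} and D→{M,D} α/2 each).  We
chose this over Dirichlet-mixture priors deliberately: every worked
example stays hand-checkable, and all probabilities are strictly
positive so log-space scoring never sees a -inf emission.  Sequence
weighting (Henikoff) is not implemented; with the synthetic families'
i.i.d. references it would be a no-op, and for real alignments it is a
known extension point.

The background is uniform (q_r = 0.05) by default and overridable by a
20-vector.  `X` residues are scored as a 1/20 emission against the
1/20 background — unit odds — and are excluded from emission counts at
build time.  `B/Z/U/J` are rejected at parse time so the scoring engine
handles exactly 21 symbols.

Observed alignment transitions that the plan7 topology cannot represent
(insert directly followed by delete or vice versa) are tallied to the
continuation move (I→I, D→D); they arise only in unusual gap patterns
and are dominated by the pseudocount.

`reference_length` — the family length used by the normalization — is
the median (configurable to mean) of the ungapped reference-sequence
lengths, rounded half-up.  Median rather than a single representative
because curated families vary in length and the statistic should not
chase one outlier.

## Scoring

Both scores are log₂ odds of the profile against an i.i.d. background
over the full sequence, computed in log space throughout.

* **Global mode** is the classic begin-to-end recursion over nodes
  0..L including the terminal inserts I₀ and I_L.
* **Local mode** (the default, because predicted CDS from short reads
  are fragments): a hit enters the core at any match state with uniform
  probability 1/L, walks match/insert/delete states under the profile's
  transitions, and exits freely after any match state; flanking
  residues are emitted by the background and contribute zero log-odds.
  Local hits start and end on match states, and the terminal inserts
  are not used (flanks subsume them).

The forward score sums over all paths, Viterbi maximizes; forward ≥
Viterbi always.  Log-sums use `max + log1p(exp(·))` with terms more
than 45 bits below the running maximum dropped — each dropped term
perturbs the sum by < 2⁻⁴⁵, so scores are exact to well below the 1e-9
tolerance the oracle tests assert.  The kernels are numba-compiled;
a brute-force path-enumeration oracle (test suite) checks both modes
exactly on all profiles with L ≤ 4 against all sequences of length ≤ 5.

**Acceptance threshold.** 25 bits per sequence by default.  The
threshold is deliberately explicit rather than an E-value: analytic
E-values require database-size and length calibration that would bring
HMMER's Gumbel machinery in scope.  `decoy_fdr` estimates the empirical
false-hit rate at any threshold from per-sequence residue-shuffled
decoys (composition preserved), which is how a user should justify a
site-specific threshold.  At the synthetic study's scale, 25 bits
accepts essentially every true fragment (a 20-aa fragment of a
0.15-diverged protein scores ≈ 35–45 bits) and no shuffled or
background sequence in practice.

One CDS counts at most once per family (best per-sequence score, no
domain splitting) because the normalization consumes per-site hit
counts.  An optional adapter delegates build+search to `pyhmmer`
(HMMER3) and returns the identical `HitTable` schema; downstream stages
cannot tell the engines apart.  HMMER applies its own priors and
E-value machinery, so its bit scores are not numerically comparable to
the native engine's — the adapter exists for users who want fidelity to
the standard toolchain on real data.

## Normalization and gene frequency

Raw per-family hit counts are normalized by the RecA length ratio:
ñ = n · L(RecA)/L(family).  The direction matters and the package
divides longer families *down*: shotgun-read-derived CDS counts scale
with protein length, so an unnormalized count overstates long genes.
(The config exposes `normalization_direction` for the opposite
convention.)  The mean of ñ over the five housekeeping families —
RecA, RpoB, AtpB, GyrB, SucD, all effectively single-copy — estimates
the *average genome equivalent* G of the site, and
f = ñ / (G·c) with copy number c (default 1 for every family) is the
fraction of genomes carrying the gene.  G includes RecA itself; the
housekeeping set is configurable.  Frequencies above 1 are flagged
(`frequency>100%`) and never clamped: they diagnose multi-copy genes or
a threshold problem, and hiding them would hide the diagnosis.

Key identities (enforced by property tests): ñ = n when lengths match;
multiplying all counts at a site by k scales ñ and G by k and leaves
every f unchanged; f is monotone in ñ and antitone in G and c.

## Group comparison

Per family, the per-site gene frequencies of the low-pH group are
compared with the high-pH group by an unpaired two-sample t-test —
pooled-variance Student's t by default (df = n₁+n₂−2), which is the
standard reading of "unpaired t-test"; Welch with Satterthwaite df is a
config switch.  Tests are two-tailed with α = 0.05, run on frequencies
(not counts — the quantity with a per-genome interpretation;
configurable), untransformed, and uncorrected for multiple testing by
default since each gene is reported individually; Benjamini–Hochberg is
available behind a flag.  The t statistic is oriented low − high, so a
gene depleted in acid soils is negative.  Degenerate inputs (zero
variance in both groups) yield t=0, p=1 for equal means, p=0 flagged
`degenerate` otherwise; degenerate families are never marked
significant.  p-values come from the t distribution's survival
function; the test suite checks them to 1e-6 against an independent
continued-fraction incomplete-beta oracle and to 1e-10 against
`scipy.stats.ttest_ind`.

Calibration is part of the acceptance suite: under a null design the
empirical type-I error over 1000 seeded frequency-level replicates must
lie in [0.03, 0.07], and under the planted effect design all three
alkaline phosphatases must be flagged in ≥ 95 of 100 replicates.  These
replicates draw realized per-site carriage from the community model's
binomial distribution without materializing sequences — they calibrate
the statistics, not the search engine, which the recovery test (below)
covers separately.

## Taxonomy

Accepted hits are assigned the lineage of their single best
Smith–Waterman match (BLOSUM62; a gap of length g costs 11 + (g−1)·1)
in a reference FASTA whose headers carry
`lineage=Domain;Phylum;Class;...`.  Raw scores are converted to bits
with the standard gapped BLOSUM62-11-1 Karlin–Altschul parameters
(λ=0.267, K=0.041); the acceptance floor is 50 bits, a fixed desk-scale
stand-in for a relaxed E-value cutoff (at these query lengths 50 bits
corresponds to roughly E ≤ 1e-10 against a database of ~10⁷ residues;
the floor, unlike an E-value, needs no database-size calibration).
Hits below the floor against every reference are reported unassigned.
Score ties break by higher percent identity, then lexicographic
reference id.  Percent identity counts identical columns over all
aligned columns, gaps included in the denominator.  Mean identity is
computed over best hits only.

Rank aggregation builds a count tree in which every node's count equals
its children's counts plus the assignments whose lineage ends there
(conservation is asserted, not assumed), and the Krona export writes
one `count<TAB>rank...` line per leaf, sorted by lineage for
determinism.

In the full pipeline the all-vs-all alignment is capped at 100 hits per
(site, family) — deterministically the first in CDS order — because
taxonomy is a diversity summary, not an abundance estimate; the cap is
configurable.

## The synthetic study

The generator emulates the statistical structure of an 8-site,
two-pH-group soil survey with everything known:

* **Families.** A random consensus per family; 60 references per family
  (within the 50–80 range typical of curated sets) as i.i.d.
  substituted copies at rate 0.30 — no indels, so the true alignment is
  gapless and reference length equals consensus length.  Consensus
  lengths are desk-scale, 80–120 aa (RecA 90; the others deliberately
  different so the length normalization is exercised, not a no-op).
  These are domain-sized rather than full-protein lengths; all
  quantities of interest are length-normalized, so the absolute scale
  only sets compute cost.
* **Communities.** 500 genomes per site; every genome carries each
  housekeeping family exactly once and each target family independently
  with the planted carriage probability.  Carried sequences are
  0.15-diverged copies of the family consensus — community sequences
  sit nearer the family centroid than the most diverged references, so
  hits land around 70–76% identity to their best reference, in the
  range real soil screens report.  Lineages are drawn from a weighted
  pool in which Proteobacteria, Actinobacteria and Firmicutes together
  hold 70%.
* **Fragmentation.** Each protein sheds a Poisson number of fragments
  with mean `coverage` (default 2) — scaled by protein length relative
  to RecA in the study generator, because shotgun reads sample long
  genes proportionally more; without that scaling the length
  normalization itself would bias recovered frequencies.  (The
  unscaled, plain-Poisson behaviour remains the `fragment_cds` default
  and is what its mean-count invariant tests.)  Fragment lengths are
  minimum 20 aa plus a geometric tail with overall mean 45 aa, clipped
  to the protein; starts are uniform.  200 unrelated background
  proteins are added per site.
* **Design.** 4+4 sites.  Planted carriage (high-pH / low-pH): PhoX
  0.47/0.03, PhoD 0.56/0.07, PhoA 0.20/0.01 (strong depletion in acid
  soils); ClassB 0.20/0.10 and UshA 0.35/0.10 (milder depletion);
  ClassA 0.30, ClassC 0.25, GlpQ 0.20, PhnI 0.15 unchanged between
  groups.
* **Determinism.** Every generator is a pure function of (parameters,
  seed); per-family and per-site child seeds are spawned from one
  `SeedSequence`, and regenerating a study is byte-identical.

The end-to-end recovery property — pipeline estimate of per-site
carriage within MAE ≤ 0.05 of the planted truth, with no systematic
sign bias — holds with margin (observed MAE ≈ 0.016 at seed 1) because
the dominant error terms cancel by construction: fragment recall and
false-hit contamination affect target and housekeeping families
equally, and the length-proportional sampling makes the RecA ratio
exact in expectation.

**What this does and does not show.**  Passing tests demonstrate that
the screening, normalization, statistics and bookkeeping are correct
under the generative model.  Real metagenomes differ in ways the
generator deliberately omits: no phylogenetic correlation among
sequences (references and hits are i.i.d. around a consensus), no
indels within families, no codon/ORF structure or sequencing-error
model, no log-normal community abundance structure, no multi-copy or
horizontally transferred genes, and lineage labels that are sampled
rather than phylogenetically coherent (so taxonomy tests verify
bookkeeping and identity statistics, not phylogenetic placement).
Consequently a passing suite says the method is implemented correctly,
not that a 25-bit threshold or a single housekeeping panel is optimal
for any particular soil dataset — that calibration is what `decoy_fdr`
and the config exist for.

## Problem sizes and numerics

The acceptance-scale study (8 sites × ~6–8k CDS fragments × 14
profiles) is the package's chosen study condition; unit tests run on
miniatures (tens of genomes, 2+2 sites).  Degenerate inputs are defined
everywhere: empty CDS sets give zero counts; all-zero housekeeping
counts give G=0 with a warning and undefined frequencies (flagged, not
fabricated); an all-gap alignment column can never become a match
state; empty sequences are rejected before scoring.  All tabular output
is TSV (lineage strings contain commas), floats printed to 10
significant digits so stage-to-stage round-trips are exact to < 1e-9.
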