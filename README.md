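# phoscan

Profile-HMM screening of phosphorus-scavenging gene families in soil
metagenomes, with single-copy-gene normalization, two-group statistics,
best-hit taxonomy, and a synthetic-community simulator that provides
ground truth for every stage.

## The problem

In soil, bioavailable orthophosphate (Pi) is scarce; bacteria liberate
it from organic phosphorus esters by secreting nonspecific phosphatases
— the alkaline phosphatases PhoX, PhoD and PhoA (pH optima 9–11) and
the class A/B/C acid phosphatases (optima 4.8–7) — alongside other
P-scavenging enzymes (UshA, GlpQ, PhnI).  A natural ecological question
is how the *genetic potential* for organic-P mineralization differs
between acidic and alkaline soils.  `phoscan` answers it the way a
metagenome screen does:

1. **Profiles** — build a profile hidden Markov model (match / insert /
   delete states, background-smoothed emissions) from a curated
   alignment of each family's reference proteins.
2. **Search** — score every predicted-CDS protein of every site against
   every profile with the forward algorithm (log₂-odds bits against an
   i.i.d. background model, local alignment with free flanking residues,
   since read-derived CDS are fragments).  A sequence is a hit for a
   family when its bit score reaches the acceptance threshold (default
   25 bits; `decoy_fdr` calibrates this against shuffled decoys).
3. **Quantify** — longer proteins shed more CDS fragments, so each
   family's raw hit count n is normalized by the RecA length ratio,
   ñ = n·L(RecA)/L(family).  The mean normalized count of five
   single-copy housekeeping genes (RecA, RpoB, AtpB, GyrB, SucD) is the
   site's *average genome equivalent* G, and

   f = ñ / (G · c),  with per-genome copy number c = 1,

   is the gene frequency: the fraction of bacteria at the site carrying
   the gene, reported as a percentage.
4. **Compare** — per family, an unpaired two-sample t-test
   (pooled-variance Student's t by default, Welch optional) between the
   low-pH and high-pH site groups, two-tailed, α = 0.05.
5. **Taxonomy** — accepted hits are assigned to the lineage of their
   best Smith–Waterman match (BLOSUM62, gap open 11 / extend 1) in a
   lineage-labeled reference database, aggregated over ranks, and
   exported as Krona `ktImportText` text; the mean percent amino-acid
   identity of hits to their best references summarizes how diverged the
   environmental sequences are.

A genome-census mode (`phoscan.quantify.census_genomes`) additionally
reports, for whole genomes, the per-taxon fraction possessing at least
one alkaline phosphatase.

Because real screens depend on external archives, the package ships a
first-class synthetic-data module: communities of genomes with known
(planted) per-family carriage fractions, sequence divergence, CDS
fragmentation and an 8-site two-pH-group design, so recovery of the
truth is a testable property.

## Worked example

```bash
# generate a small synthetic study: 2+2 sites, 40 genomes/site
phoscan simulate --out demo --seed 4 --n-genomes 40 --sites-per-group 2 --n-refs 15
phoscan run-all --config demo/config.yaml
```

`run-all` logs one line per stage; the comparison stage prints, for this
seed:

```
family ClassA: mean low=0.2624 high=0.3000 t=-0.562 p=0.6307
family ClassB: mean low=0.0679 high=0.1912 t=-2.287 p=0.1494
family ClassC: mean low=0.2551 high=0.2982 t=-0.392 p=0.7328
family GlpQ: mean low=0.1806 high=0.1565 t=0.521 p=0.6545
family PhnI: mean low=0.1343 high=0.1267 t=0.104 p=0.9265
family PhoA: mean low=0.0190 high=0.1826 t=-8.315 p=0.01416 *
family PhoD: mean low=0.0435 high=0.7988 t=-12.895 p=0.00596 *
family PhoX: mean low=0.0459 high=0.5717 t=-15.036 p=0.004394 *
family UshA: mean low=0.1191 high=0.4108 t=-4.178 p=0.0528
```

Reading: each target family's per-site gene frequency (fraction of
bacteria carrying the gene) is averaged within the low- and high-pH
groups and tested with a pooled t (df = 2 here, since only 2+2 sites).
The planted design carries the three alkaline phosphatases at 0.47 /
0.56 / 0.20 in high-pH communities but 0.03 / 0.07 / 0.01 in low-pH
ones; even this miniature study flags all three (starred), while the
equal-carriage acid phosphatases and the milder ClassB/UshA contrasts
stay below significance at only 2+2 sites.  At 40 genomes per site the
per-site frequency estimates are still noisy (PhoD's high-pH mean of
0.80 vs its planted 0.56); the default 4+4-site, 500-genome scale
recovers the planted fractions to within a few percent.  Outputs
land in `demo/results/`: `abundance.tsv` (raw and normalized counts,
genome equivalents, frequencies per site), `comparisons.tsv`,
`assignments.tsv` + `krona.txt` (taxonomy), and `manifest.json` with
the config hash and seed.

The stages also run individually (`build-profiles`, `search`,
`quantify`, `compare`, `taxonomy`) and compose to byte-identical
outputs.

## Configuration

One YAML file drives a run (relative paths resolve against the file's
directory; `simulate` writes a ready-made one).  The example below is
exactly the shape `phoscan simulate` emits, trimmed to two families and
two sites:

```yaml
families:
  RecA:   {reference: refs/RecA.afa, role: housekeeping, copy_number: 1.0}
  PhoX:   {reference: refs/PhoX.afa, role: target, copy_number: 1.0}
sites:
  siteL1: {cds: [sites/siteL1.faa], group: low_pH}
  siteH1: {cds: [sites/siteH1.faa], group: high_pH}
parameters:
  threshold_bits: 25.0          # forward-bit acceptance cutoff
  reference_statistic: median   # family length statistic (median|mean)
  ttest_variant: pooled         # pooled|welch
  alpha: 0.05
  seed: 0
  occupancy_threshold: 0.5      # match-column assignment
  pseudocount: 1.0
  alignment_mode: local         # local|global
  normalization_direction: divide_by_ratio
  housekeeping: [RecA, RpoB, AtpB, GyrB, SucD]
  multiple_testing: none        # none|bh
  refdb: refdb.faa              # lineage-labeled reference DB (optional)
  min_align_score: 50.0         # bit floor for best-hit assignment
  max_taxonomy_hits_per_site: 100
  output_dir: results
```

Each family's `reference` is an aligned FASTA (or Stockholm) of curated
homologs; each site lists one or more CDS FASTA files (pooled as a
union) and its pH-group label.  The manifest must include the five
housekeeping families with RecA as the normalization anchor and at
least one target family; `RunConfig.from_yaml` validates all of this
and the CLI exits with code 2 on a validation error.

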