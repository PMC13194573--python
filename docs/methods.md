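# Methods

This note documents the models, estimators and design choices behind
`kaspfp`, in the spirit of a statistical-software methods appendix.

## Genotype model and data representation

The central object is a dense matrix of unphased diploid biallelic calls
(`GenotypeMatrix`): rows are accessions, columns are SNP loci, cells are
two-letter nucleotide strings (`"AG"`) or the missing marker `"NN"`.
Calls are stored in REF/ALT orientation because the fingerprint color
legend distinguishes some heterozygote orientations; every statistical or
discrimination comparison treats calls as unordered pairs. Interchange
formats are a minimal VCF 4.2 (GT only, `./.` for missing; read back
through pysam) and a plain genotype table.

## Per-locus statistics

All statistics are plug-in estimators over the allele frequencies of the
non-missing calls:

- expected heterozygosity He = 1 − Σpᵢ²,
- effective number of alleles Ne = 1/Σpᵢ²,
- Shannon's information index I = −Σpᵢ ln pᵢ (natural log),
- observed heterozygosity Ho (fraction heterozygous among non-missing),
- Botstein's PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ²,
- MAF = min(p, q).

He carries **no** small-sample (2N/(2N−1)) correction: only the
uncorrected form preserves the exact identity Ne = 1/(1−He) that published
core-panel tables in this domain satisfy row by row. `invert_he` solves
2pq = He for (p, q), which reconstructs every frequency-derived column
from a printed He value; `stats_from_frequencies` computes the same
statistics directly from frequencies when genotype counts are unavailable.

Values are kept at full precision internally and rounded only at
serialization, to 3 decimals, **half away from zero** — half-even rounding
would print Ne = 1.5625 (He = 0.36) as 1.562, whereas diversity tables in
the field print 1.563.

## Group differentiation

`fst` implements Nei's Gst for exactly two groups: per locus, Hs is the
unweighted mean of the two within-group plug-in He values and Ht the He of
the unweighted mean frequency vector; the global value is
(mean Ht − mean Hs)/mean Ht over loci polymorphic in the pooled sample.
This is the simplest estimator consistent with reporting a single global
Fst for a two-group panel; Weir–Cockerham's variance-component estimator
would be the natural alternative for unbalanced designs but is not needed
here. Gene flow uses Wright's island-model identity Nm = (1 − Fst)/(4 Fst);
Fst = 0 is reported as "unbounded" rather than silently returning infinity.
Loci monomorphic overall are skipped in Fst but contribute He = 0 to panel
means.

## Synthetic panels

`simulate_genotypes` emulates a KASP-validated germplasm panel:

- **Spectrum.** Per-locus minor allele frequencies come either from a
  uniform range or an explicit list; the shipped `CORE_PANEL_HE` spectrum
  (13 He values from 0.026 to 0.5, inverted to MAFs) reproduces the
  frequency profile of a validated garlic core panel.
- **Structure.** With two groups, each group's allele frequency is drawn
  Balding–Nichols style: p_g ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around the
  ancestral p. For Nei's Gst over two equally weighted groups,
  E[Hs] ≈ 2pq(1−F) and E[Ht] ≈ 2pq(1−F/2), giving expected
  Gst ≈ (F/2)/(1−F/2). The dispersion parameter is therefore set to
  F = 2t/(1+t) so the realized Gst matches the target t; Monte-Carlo
  recovery at t = 0.099 (200 accessions × 500 loci) lands within ±0.01.
- **Genotypes.** Hardy–Weinberg draws per accession. Garlic itself is
  clonal; clonality is represented only through explicit clone pairs whose
  rows are copied byte-identically (including the missing pattern) — the
  analysis consumes genotypes, not pedigrees, so HW sampling is an
  adequate source of multilocus diversity.
- **Missing data.** Injected i.i.d. per call (default rate 0.3%, matching
  the sub-percent missing rates of validated KASP panels).
- **Uniqueness enforcement.** By default, accidental multilocus-genotype
  collisions among non-clone accessions are resampled away (bounded at 200
  sweeps) so the clone-pair list is the *exact* ground truth for
  indistinguishability. With 13 loci and 77 accessions, roughly one chance
  collision per panel would otherwise be expected. The enforcement
  slightly biases realized frequencies toward rare genotypes when the
  genotype space saturates (many accessions, few loci); spectrum-accuracy
  checks therefore disable it (`ensure_unique=False`).

`simulate_candidate_table` plants exactly two defect types — a secondary
variant within ±50 bp, and a copy of the flanking context elsewhere in the
reference — and returns per-candidate truth labels. Flanks are generated
design-feasible by construction (homopolymer runs ≤ 4, proximal-window GC
in [0.35, 0.65]), so planted defects are the only causes of filter
failure and a defect-free table passes every stage. The reference is
uniform-random nucleotide sequence; GC structure beyond the feasibility
windows is irrelevant to the implemented filters. What the generator does
**not** model: read-level error, restriction-site sampling bias, linkage
between loci, genotyping-platform artifacts. Tests passing on this
generator establish the pipeline's correctness contracts, not performance
on real GBS data.

## Filter cascade

Stage order is fixed: flanking conservation → genotype quality → unique
mapping → design feasibility. Choices worth noting:

- "within 50 bp" is read as the closed interval [pos−50, pos+50]
  (conservative for primer design).
- Calls failing depth or GQ are converted to missing rather than dropping
  the locus, making missing rate the single quality gatekeeper; default
  thresholds (depth ≥ 8, GQ ≥ 20, missing ≤ 0.1, MAF ≥ 0.05) are config
  values, with the depth default motivated by typical ~8× GBS coverage.
- Uniqueness is exact substring search of the ~100 bp probe
  (50 bp 5′ tail + reference base + 49 bp 3′ head, both strands) instead
  of BLAST: self-contained, deterministic, and exactly testable against
  planted duplicates. It is stricter than BLAST (no tolerance for
  near-duplicates diverged by even one base).
- The KASP feasibility screen (proximal-flank GC in [0.3, 0.7], no
  homopolymer > 4, no ambiguous bases) is a simplified stand-in for a
  primer-design pipeline; the thresholds are package defaults, not
  field-calibrated constants.

All thresholds are boundary-inclusive (a locus at exactly the maximum
missing rate passes).

## Marker selection

`pair_distinguished` encodes the identification rule: a locus separates
two accessions only when both calls are non-missing and differ as
unordered pairs. Missing calls never discriminate, which makes the
distinguished-pair count monotone non-increasing under data loss.

`greedy_min_set` is greedy set cover over the C(n,2) accession pairs,
ties broken by higher PIC then lexicographic locus ID. Because a locus
picked early can be made redundant by later picks, a pruning post-pass
removes any locus whose pairs are covered by the rest (iterated to a
fixpoint); the resulting set is irredundant — removing any single locus
strictly decreases coverage — and the selection trace is replayed over
the final set so every step shows a positive gain. Greedy always reaches
the maximum achievable coverage (it only stops when no locus adds a pair);
the classical set-cover guarantee bounds its size, and
`exhaustive_min_set` (subset enumeration by increasing size, with an
enumeration budget) quantifies the gap exactly on small instances. In
seeded benchmarks (8–10 accessions × 8–10 loci) greedy matched the
optimal size in ≥ 9 of 12 instances and never exceeded it by more than one
locus.

`mlg_groups` partitions accessions by the *transitive closure* of the
pairwise not-distinguished relation: with missing data the relation is not
transitive (y can match both x and z through an NN call although x and z
differ), and closure is the conservative choice — an accession is called
"uniquely identified" only when nothing links it to any other.

Stability / cluster-clarity QC is consumed as external per-locus
annotations (KASP fluorescence plots are not data this package computes);
absent annotations default to stable.

## Fingerprints

The 13-label genotype color legend maps homozygotes and heterozygotes to
named colors with N/N white. The legend lists both T/C (dark green) and
C/T (gray) — and G/T vs T/G — so heterozygote labels follow the locus's
declared REF/ALT orientation; the four orientations the legend omits
(T/A, G/A, C/A, G/C) fall back to their listed mirror. Fingerprint codes
are `accession|panel-hash|genotype-string` with an 8-hex-digit SHA-256
panel digest, version-prefixed for the QR payload; payloads are plain
text (rasterization is deliberately out of scope). The heatmap grid is
serialized loci-as-rows × accessions-as-columns.

## Pipeline and problem sizes

`run_pipeline` chains cascade → statistics → screening → selection →
fingerprints → differentiation from a single serializable config; the run
report embeds the config, per-stage counts and the accession bookkeeping
identity (distinguished + unresolved = total), and is byte-identical
across reruns up to timestamps.

Default study sizes mirror a realistic KASP validation: 77 accessions,
13–30 loci, 2 clonal duplicate pairs, sub-percent missing data, two
groups at Fst ≈ 0.1. Recovery checks use 200 accessions × 500 loci
(10 seeds) for Fst and ≤ 10-locus instances for the exhaustive oracle —
sizes at which the relevant sampling error is already far smaller than
the tolerances being checked.

## Known limitations

- The uniqueness proxy cannot emulate BLAST's tolerance to small
  divergences; real paralogs with >1 mismatch in the probe would pass.
- Nei's Gst with equal group weights is the only Fst estimator; small or
  very unbalanced groups would favor Weir–Cockerham.
- The feasibility screen ignores primer thermodynamics (Tm, secondary
  structure).
- Clonal population structure beyond explicit duplicate pairs (e.g.
  somatic mutation families) is not modelled.
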