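# Methods

## Coordinates and data model

All coordinates are 1-based and fully closed on hg19 chromosome labels.
The unit record is a `VariantObservation`: one variant (chrom, pos, ref,
alt) in one sample with reference/variant read counts. Printed loci for
the panel omit the chromosome; it is resolved from the gene (APC, MSH3,
DHFR → chr5; MSH6 → chr2) via a shipped map. Sample sheets pair tumors
with normals explicitly; when no pairing column is filled in, a
trailing-"N" naming heuristic (tumor `CC1018` ↔ normal `CC1018N`) is
applied and logged.

VCF input is read through pysam: per-sample read counts come from AD when
present, otherwise from DP together with an allele-fraction field (logged,
since the inference loses integer exactness); multi-allelic records are
split into one observation per alternate allele because the imbalance
ratio is defined per variant allele. All writers emit TSV/CSV/JSON, and
every writer round-trips through its reader.

## Zygosity and carrier frequencies

VAF = var / (ref + var); undefined (an error) at zero depth. Zygosity is
called from VAF with two cut points, default 0.20 / 0.80: below the first
the variant is not carried (nocall), between them het, at or above the
second hom. The source analysis reports het/hom calls without stating its
caller's internal rule; the defaults are chosen so that binomial noise at
~1000× depth essentially never flips a true het (VAF 0.5) or hom (VAF 1.0)
call — at depth 1000 the probability that a het site leaves [0.2, 0.8)
is below 10⁻⁸⁰.

Carrier frequency per lesion group is (het + hom) / n with n the full
group size (30/21/33/56 by default), whether or not every sample has
coverage at the locus — matching how the published fractions are formed.
Rounding is half-up to 2 decimals (0.0357 → 0.04); percentages elsewhere
are half-up to integers and averages to one decimal. Duplicate
observations of one sample at one variant are counted once. A frequency-
table row with zero carriers in every group is retained but flagged with a
warning (the packaged confirmed-variant table contains one such published
row).

## CNV/LOH run scan

Within one sample, variants are grouped by gene and sorted by position.
A variant is *imbalanced* when VAF ≥ τ (default 0.6). A maximal stretch of
consecutive imbalanced variants of length ≥ k (default 3) is an imbalance
run. "Consecutive" is rank adjacency in the sample's called-variant list
for that gene — genomic distance is never used, so panel spacing does not
affect the scan — and runs never span gene boundaries. Each qualifying
variant belongs to exactly one emitted run (maximal runs are disjoint).

Design choices, made where the criterion is silent:

- Only variant-allele excess is flagged by default; `symmetric=True` also
  flags VAF ≤ 1 − τ (reference-allele excess), off by default.
- Near-homozygous variants (VAF ≈ 1.0) are included in runs by default:
  the somatic definition requires tumors to look homozygous. The caveat is
  that germline homozygous stretches can mimic events; a `max_vaf` cap is
  available to exclude them, and the simulator measures the resulting
  false-event rate (about 1.4 × 10⁻³ events per tumor at the default
  population allele frequency of 0.10 — reported, not asserted, since no
  published specificity value exists for the criterion).
- Tie-break in pair classification: overlap with a normal run (germline)
  takes precedence over normal-het evidence; a run cannot be both.
- Tumor runs with no normal coverage at any member locus stay
  `tumor_only_unclassified`, as do all runs of unpaired tumors.
  Normal-only runs are not counted as events.

Monotonicity: raising k never increases the number of runs. For τ the
run *count* is not monotone — tightening τ can split one long run into two
(VAFs [0.9, 0.9, 0.7, 0.9, 0.9] with k = 2 give one run at τ = 0.6 but two
at τ = 0.8) — whereas the number of run-covered variants is monotone
non-increasing; tests assert these corrected quantities.

The cohort summary counts events by label, samples with ≥ 1 event (overall
and per gene), and both events-per-sample and events-per-altered-sample
averages. Germline/somatic percentages are shares of the classified
matched-pair events only. The published accounting of the study cohort is
internally inconsistent in two places (the per-gene germline breakdown
sums to 15 while the total is 30; the per-tumor average is printed as 1.6
where the ratio is 2.6), so the deterministic cohort fixture reproduces
the totals and per-gene sample coverage, distributing the extra germline
events as second events within already-altered pair/gene combinations, and
both averages are exposed without forcing agreement.

## Annotation

Depth filter: keep observations with total reads strictly greater than
the cutoff (default 10, so exactly 10 reads is dropped). Novelty: novel
iff absent from the union of all supplied catalogs; the somatic-mutation
catalog is treated exactly like the germline ones; matching is exact on
(chrom, pos, ref, alt) with no position-only fallback (conservative and
reproducible). Novelty is monotone: adding catalog entries never makes a
variant novel.

Consequences are classified codon-locally against a minimal transcript
model (ordered CDS intervals plus plus-strand reference sequence): SNVs in
the CDS compare the reference and mutant codon (same amino acid →
synonymous; new stop → stopgain; loss of the native stop → other;
otherwise nonsynonymous); minus-strand alleles are complemented before
lookup (standard convention). Indels touching the CDS are frameshift when
the length change is not a multiple of 3, otherwise other. Positions
between CDS intervals are intronic; inside the gene span but outside the
CDS extent, UTR. A ref allele disagreeing with the transcript sequence is
an error, not a silent skip. The classifier is verified exhaustively
against an independent oracle that translates the entire mutant CDS and
diffs the protein, over all 270 SNVs of a 30-codon two-exon toy
transcript, on both strands.

## Protein-domain mapping

CDS offset o maps to residue ⌈o/3⌉, consistent with the classifier's
codon indexing. Domain models are ordered disjoint closed intervals in
protein coordinates; positions between intervals are reported as "prior
to" the next downstream domain, positions past the last as "after" it.
Default intervals for MSH3 (1137 aa), MSH6 (1360 aa) and APC (2843 aa)
are editable approximations drawn from standard protein annotations
(Pfam/UniProt-style); exact boundaries for regions like the EXO1
interaction or the MSH2-binding segment vary between annotation sources,
so these defaults are a documented judgment call and any YAML/JSON config
can replace them. Per-domain tallies conserve counts: they sum to the
number of variants with a protein position.

## Synthetic cohorts

`simulate_cohort` draws, per patient and locus, a genotype from
Hardy–Weinberg at the configured population alt-allele frequency (default
0.10; members of a tumor–normal pair share their germline genotypes), a
depth from a negative binomial around the mean (default mean 1000,
dispersion 50 — mild overdispersion typical of amplicon panels), and
variant reads from binomial(depth, expected VAF) with expected VAF 0.5
(het) or 1.0 (hom). Hom-reference sites produce no observation. Default
cohort structure is the study's: 30/21/33/56 samples by lesion group with
16 tumor–normal pairs; the remaining samples are unpaired singletons.

Planted events occupy ≥ 3 consecutive panel loci with target VAF in
[0.6, 1.0]: germline events shift the expected VAF in both members of the
pair; somatic events shift the tumor only and force the matched normal
heterozygous at those loci. Affected loci are forced heterozygous so the
variants are always called. Identical configuration and seed give
byte-identical output. At depth 1000 and target VAF ≥ 0.7 the probability
that a planted locus falls below the 0.6 threshold is < 10⁻¹¹, so
recovery of planted events by the scan is effectively certain; recovery
tests run 100 small seeded cohorts (4 pairs, 20 loci per gene) with four
planted events each, sized to keep the full suite fast while still
exercising every code path of the pair classifier.

The generator does **not** model sequencing error, mapping bias, FFPE
artifacts, tumor purity mixtures (purity enters only via target VAF), or
linkage between loci. Passing recovery tests therefore demonstrate the
correctness of the scan logic under the stated statistical model, not its
operating characteristics on real amplicon data, where PCR bias and
homozygous germline stretches are the dominant confounders.

`make_cnvloh_fixture` is a separate deterministic builder (exact read
counts: depth 1000, event VAF 0.75, het 0.5) that encodes the published
event composition — 15 matched pairs with 30 germline + 9 somatic events,
83 unpaired tumors with 117 events in 71 of them, per-gene sample coverage
MSH6 59 / APC 49 / MSH3 33 of 98 — so that the cohort-summary arithmetic
is exercised through the real scan with no stochastic slack. Within one
gene, consecutive planted events are separated by one balanced
heterozygous locus so each remains a distinct maximal run.

The packaged confirmed-variant table (59 rows × 4 lesion groups × het/hom)
ships as data with the package; all quoted carrier frequencies are
recomputed from its counts, never stored.

## Problem sizes and determinism

Property tests compare the scan against a brute-force maximal-window
enumeration on 10,000 random VAF vectors of length ≤ 12 across a τ/k
grid, plus derandomized hypothesis suites. The acceptance script uses
5,000 oracle vectors and 100 recovery cohorts; it derives all randomness
from its `--seed` argument and finishes in a few seconds. Hypothesis
suites are derandomized; every simulation is seeded explicitly.

## Known limitations

- Zygosity thresholds are heuristic; at depths far below 1000× the
  default cut points will miscall more often, and no genotype-likelihood
  model is provided.
- The ≥ 0.6 / ≥ 3 run criterion has no published specificity; the
  simulator measures a false-event rate under its own model only.
- Domain boundaries are approximate; per-domain counts depend on them.
- The consequence classifier handles one transcript per gene and no
  splice-site or regulatory effect prediction.
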