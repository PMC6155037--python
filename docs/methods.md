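# Methods

`mirmint` re-implements, as a tested desk-scale pipeline, the integrative
miRNA–mRNA analysis used to study the telogen→anagen transition of
cashmere-goat secondary hair follicles: small-RNA read filtering and
accounting, two-condition differential expression, seed/energy-based target
prediction, fold-change quadrant classification, hypergeometric GO/KEGG
enrichment, negative-regulation network construction, and 2^−ΔΔCt qPCR
quantitation.  Because the original raw reads and database snapshots are not
public, every stage is exercised against a synthetic study generator with a
recorded answer key; this note describes each model, its parameters and the
design choices that were genuinely open.

## Small-RNA filtering (srna_qc)

Reads pass through a fixed cascade — low quality → 3′-adaptor absent →
empty insert → 5′-adaptor contaminant → insert < 18 nt → polyA — and land in
the **first** failing category, so category counts are disjoint and satisfy
the accounting identity `total = Σ categories + high_quality`.  The cascade
order follows the order in which such tallies are conventionally tabulated;
published reports give disjoint counts but not the order, so the order here
is a package choice.

Quantitative definitions the field leaves informal are made explicit and
configurable:

* *low quality*: mean Phred < 20, or more than 10% `N` calls;
* *adaptor3 null*: the 3′ adaptor's first 8 nt not found with ≤ 1 mismatch.
  This check applies only to reads at the configured raw read length
  (default 50 nt); shorter adaptor-free reads are treated as already-trimmed
  inserts.  That convention makes filtering idempotent — re-filtering the
  clean output filters nothing — which would otherwise be impossible, since
  trimmed inserts no longer contain the adaptor;
* *insert null*: adaptor found at position 0;
* *adaptor5 contaminant*: the 5′ adaptor's leading 8 nt within the first 8
  positions of the trimmed insert (≤ 1 mismatch);
* *polyA*: trimmed insert ≥ 80% A.

Qualities are Phred+33 throughout; a Solexa conversion flag exists on the
FASTQ reader for legacy data.  Known-miRNA annotation is database-free:
a distinct clean sequence is *known* when it matches a reference mature
sequence exactly or with up to 2 nt added/removed at the 3′ end (where
biological mature-miRNA length heterogeneity concentrates).  This replaces
genome mapping plus precursor comparison and will under-call isomiRs with
5′ or internal variation.

The module ships the published six-sample (T1–T3, A1–A3) goat-skin filter
tallies as a worked accounting example; the polyA row of that table is
typographically garbled in print, and the shipped values are back-solved
from the accounting identity (they reconcile exactly for all six samples).

## Differential expression (expression)

Counts are CPM-normalized (every library rescaled to 10^6).  Fold change is
`log2((mean CPM_anagen + c)/(mean CPM_telogen + c))` with pseudocount
c = 0.5, which keeps values finite for zero counts; swapping condition
labels negates every fold change exactly.

Significance uses an exact conditional binomial test on pooled per-condition
counts (the Audic–Claverie construction): conditional on a feature's pooled
total, the anagen count is Binomial(total, anagen library share) under the
null.  This replaces negative-binomial empirical-Bayes machinery (edgeR) —
a deliberate simplification.  The test is exact under Poisson sampling and
anti-conservative under between-replicate overdispersion, because pooling
discards the replicate structure; the null-calibration property test
therefore generates Poisson (dispersion 0) counts, and on overdispersed data
the raw p-values should be read as planted-effect detectors, not calibrated
error rates.  Calls are made at raw P ≤ 0.05 by default, matching common
practice in this design; Benjamini–Hochberg adjustment is available behind
a flag and is monotone (adjusted ≥ raw).

## Target prediction (targets)

Canonical seed matching reports maximal sites of the standard four types
(6mer, 7mer-A1, 7mer-m8, 8mer; seed = miRNA nucleotides 2–8, the A1
adenosine being site recognition rather than a base pair).  Overlapping
matches collapse to the longest type.  T and U are interchangeable on
input; coordinates are 0-based half-open on the UTR as given.

**Duplex energy.**  ΔG is a nearest-neighbor stack sum over a gap-free
antiparallel register anchored on the seed: the miRNA 3′ region is laid
against up to `flank` (default 15) UTR bases 5′ of the site, each position
pairs if Watson–Crick or G:U, and every run of consecutive pairs contributes
published ΔG°37 stacking energies plus a +4.09 kcal/mol initiation penalty.
There is no loop/bulge model — a full secondary-structure fold is out of
scope — so every energy is a hand-checkable short sum, and adding a paired
position can never raise ΔG.  The Watson–Crick stack table is the published
Turner-2004/Xia-1998 set; the G:U wobble entries are embedded approximate
parameter data, and the two destabilizing tandem-wobble stacks are clamped
to zero to preserve the monotonicity just stated.  Pairs are filtered at
ΔG ≤ −20 kcal/mol, the conventional miRanda-style energy cutoff.

**Context score and percentile.**  Each site scores
`w_type·type_points + w_au·AU + w_pos·pos + w_3p·pair3p` with type points
8mer 3 > 7mer-m8 2 > 7mer-A1 1.5 > 6mer 1, AU the A/U fraction of 30-nt
flanks, pos the distance to the nearer UTR end (capped at 1500 nt,
normalized), and pair3p the fraction of miRNA 3′-region positions paired at
the site.  Default weights are 1, 1, 0.5 and 2.  The 3′-pairing term mirrors
TargetScan's 3′-supplementary-pairing feature and is load-bearing: the
percentile filter keeps the top decile of sites in a run, and without a term
that separates extended-complementarity duplexes from chance seed matches,
genuine sites are statistically indistinguishable from the background 7mers
that any UTR set contains, making a ≥ 90th-percentile criterion unable to
retain them.  Percentiles are empirical over all sites in the run
(`100·#{score ≤ s}/n`; a singleton universe scores 100), and pairs are kept
at percentile ≥ 90, the conventional TargetScan-style setting.  "UTR base
distribution" effects are interpreted as the local-AU term.  Sequence
conservation is not implemented (it needs multi-species alignments).

A pair passes when its best-site energy and best-site percentile both clear
their thresholds; the two bests may come from different sites of the pair.

## Quadrant integration (integration)

Pairs whose members are both differential are placed at
(x, y) = (mRNA log2FC, miRNA log2FC) and classified against inclusive
demarcation lines at t = log2(1.5) on both axes; quadrants II (mRNA down,
miRNA up) and IV (mRNA up, miRNA down) are flagged as negative regulation.
The axis convention follows the explicit definition used with such plots
(x = target gene, y = miRNA); boundary points belong to the adjacent
quadrant.  Degree summaries (targets per miRNA, miRNAs per transcript:
min/max/mean) describe the many-to-many structure of the retained pair set.

## Enrichment (enrichment)

The exact upper-tail hypergeometric probability
`P = 1 − Σ_{i<S} C(B,i)·C(TB−B,TS−i)/C(TB,TS) = P(X ≥ S)` is computed by
renormalizing log-space pmf weights over the whole support, which keeps the
complement identity `P(X≥S) + P(X≤S−1) = 1` true to machine precision and
avoids overflow for large universes.  S = 0 returns P = 1 (empty-sum
convention, the probabilistic meaning).  TB is the per-namespace annotated
background (configurable to a user universe), terms with S = 0 are
suppressed, raw p-values are reported (BH behind a flag), ties order by term
id, and the top 8 terms per namespace are the default reporting focus.
The rich factor is S/B.  GO graph propagation is not performed.

## Network (network)

Negative-regulation pairs contribute miRNA→gene `targets` edges; pair genes
link to included enriched terms (top 8 per namespace by default) via
`annotated` edges; an external BioGRID-style two-column gene-pair table can
be merged as gene–gene `interacts` edges — by default only between genes
already in the network, optionally expanding to first neighbors.  Self
loops are dropped, duplicates (either orientation) collapse, malformed rows
are skipped with a warning and abort above 10%.  Exports: Cytoscape SIF
(whitespace-containing names quoted; isolated nodes as bare lines), GraphML
(full attribute round trip) and edge TSV.  Hub genes rank by total degree,
ties by id — degree, not betweenness, because "associated with more genes"
is a degree notion.

## qPCR (qpcr)

Technical replicates are averaged per (sample, gene); ΔCt subtracts the
same sample's reference-gene mean (so any whole-sample Ct offset cancels);
ΔΔCt subtracts the calibrator-stage mean ΔCt per gene; RQ = 2^−ΔΔCt
(efficiency fixed at 2, no standard-curve correction).  Stage-level RQ is
the geometric mean of per-sample RQs — the quantity is multiplicative — with
an arithmetic-mean flag.  Stage comparisons: one-way ANOVA on log2 RQ, then
Fisher's LSD pairwise t tests on the pooled within-stage mean square with
N−k degrees of freedom.  Duncan's multiple range test is omitted (its
critical-value tables add nothing methodological here).  Zero within-stage
variance is degenerate and flagged: p = 0 for unequal means, 1 for equal.
Single-sample stages are excluded with a warning.

## Synthetic studies (synthetic_data)

The generator emulates the study design: two conditions × 3 biological
replicates, negative-binomial counts (mean–dispersion parameterization, the
standard model family for small-replicate RNA-seq) with baseline means
log-uniform over 10^1–10^3, dispersion 0.1, and planted |log2FC| = 2 split
symmetrically across conditions.  Defaults: 60 miRNAs (15 up, 15 down),
300 mRNAs (60 up, 60 down), 50 planted negative-regulation pairs, each
pairing a differential miRNA with a distinct, oppositely differential
transcript (one planted cassette per UTR — real UTRs host multiple miRNAs;
this is a simplification that keeps the answer key unambiguous).

UTRs (300–600 nt, uniform base composition) carry for each true pair one
exact 7mer-m8 seed site; by default the planted cassette is the reverse
complement of miRNA positions 2..L, so the miRNA 3′ region finds full
complementary pairing upstream of the seed.  A bare 7-bp seed duplex tops
out near −12 kcal/mol and cannot clear the −20 kcal/mol filter, so planting
the extended complement is what makes planted pairs pass both thresholds,
exactly as genuine strongly bound sites would (`plant_3p_complement=False`
restores seed-only planting as a difficulty knob; wobble/mismatch seeds are
likewise off by default).  All UTRs are screened against every truth
miRNA's seed core; collisions are removed by redrawing the 6-nt match
window (capped at 100 rounds) rather than regenerating whole UTRs — with
~30 truth seeds a 450-nt random UTR is collision-free with probability only
~4%, so whole-sequence rejection would routinely exhaust any sane retry
cap.  Chance seed matches of *non-truth* panel miRNAs are deliberately left
in place: they populate the context-score percentile universe the way real
UTR sets do, and the energy filter removes them.

Reads: 50-nt raw reads, clean insert lengths 18–30 nt with the canonical
22-nt mode at 31%, Illumina-style 3′/5′ adaptors, and planted artifact
fractions of a few percent (matching well-run libraries).  Each read's
category is drawn multinomially, constructed, then *verified against the
QC classifier* at generation time (resampling on collision, cap 100), so
the truth tallies round-trip exactly through the filter.  The FASTQ is
byte-identical under a fixed seed.  The only quality-error model is the
low-quality category itself.

Annotations: 50 terms of 20 genes (GO/KEGG namespaces alternating,
configurable), 5 planted enriched terms receiving 15 true-pair transcripts
each, background terms uniform, and every otherwise-unannotated gene
attached to one background term so the annotated universe spans all
transcripts.  qPCR: 3×3 replicates, reference at Ct 20, per-sample offsets
N(0, 0.3) that cancel in ΔCt, technical noise sd 0.2, planted log2 RQs
{CHP1: 2, FZD6: 1, SIAH1: 1.5, SMAD2: 0.5} against a β-actin-style
reference.

What passing recovery tests does *not* show: real libraries have sequence-
composition bias, isomiR heterogeneity, rRNA/tRNA contamination classes,
expression-dependent dispersion trends, correlated annotations (GO ancestor
closure) and conserved-but-weak sites — none of which the generator
emulates.  Recovery here demonstrates internal consistency of the pipeline
at realistic effect sizes, not field performance.

## Numerical choices and degenerate inputs

Percentile of a singleton site universe is 100.  Zero-total-count features
get p = 1/`ns` without error.  Zero-sum libraries, empty backgrounds,
missing reference genes and unresolvable ids raise errors naming the
offender.  Hypergeometric weights are renormalized before tail sums
(complement identity to 1e-12; verified against exact integer enumeration
for TB ≤ 30).  Ties break lexicographically everywhere (terms, hubs,
collapsed-FASTA headers order by abundance then sequence).  All generator
streams derive from the master seed by fixed offsets, so individual
fixtures regenerate independently.

## Known limitations

* The exact conditional test is anti-conservative under overdispersion
  (see above); it is a planted-effect detector, not an edgeR replacement.
* Wobble stack energies are approximate; only Watson–Crick entries are
  exercised by frozen expected values.
* No bulge/loop thermodynamics, no conservation, no CLIP evidence.
* Known/unknown miRNA classification misses 5′-variant isomiRs.
* The quadrant threshold applies to CPM-based fold changes; with very low
  counts the pseudocount shrinks |log2FC| and boundary pairs may drop out.
* Acceptance-style recovery runs use the default study sizes above (10
  simulated studies per quantity), chosen to keep the full loop
  seconds-fast while leaving thousands of background seed sites in the
  percentile universe.
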