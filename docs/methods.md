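# Methods

This note records the models, statistical constructions and numerical
choices behind `symsrna`, and what the synthetic studies do and do not
demonstrate about real data.

## Coordinate and sequence conventions

All genomic intervals are 1-based and inclusive at every I/O boundary
(GFF3 dialect); any internal half-open arithmetic is invisible
externally. Sequences are uppercase DNA over {A,C,G,T}. IUPAC
ambiguity codes are rejected by default; the `mask` option replaces
them with A (the sensible prior at ~84% AT) and logs a warning.
Genomes are treated as linear by default; endosymbiont chromosomes are
circular, but wrap-around upstream extraction is opt-in (`circular`)
so results do not depend on origin bookkeeping.

Upstream positions: position 1 is the nucleotide immediately 5' of a
feature's start on its strand, position 61 the farthest upstream; the
region string reads 5'→3' so its last character is position 1. Window
w (of 55 = 61 − 7 + 1) covers positions w..w+6. Published analyses of
this kind describe the window↔position mapping inconsistently; this
package fixes the convention above rather than reverse-engineering
figures.

## sRNA categorization

Antisense requires ≥1 nt overlap with an opposite-strand CDS (the most
inclusive reading; no threshold is established in the literature this
mirrors). The target is the CDS with maximal overlap, ties broken to
the lexicographically smallest feature id (logged). "UTR" sRNAs are
within a configurable 50-nt same-strand flank without overlapping the
CDS; both *Carsonella*-like lineages analysed by the upstream studies
yielded zero UTR sRNAs, so this default cannot affect the category
reproduction. Everything else is intergenic. Differential-expression
statistics are consumed, not computed: the package applies only the
candidate filter (q ≤ 0.05 and mean raw reads ≥ 9 across replicates)
and upper-quartile normalization (each library scaled so the 75th
percentile of its nonzero counts equals the mean of those percentiles
across libraries — idempotent by construction).

## Conserved-asRNA calling

Coordinates are translated between genomes through blockwise offset
maps (the coordinate correspondence a whole-genome aligner emits).
An interval is mapped via the block covering its largest share (flagged
when it straddles blocks; unmapped when coverage is below 50%);
reverse-orientation blocks flip interval and strand. A pair is
conserved when both |Δstart| and |Δend| ≤ 15 nt after mapping
(configurable to start-only) and, when per-base coverage is supplied,
no transcript base falls below depth 1 — a numerical stand-in for the
visual continuous-coverage check in genome browsers, switchable off.
Pairing is greedy on smallest |Δstart| + |Δend| with deterministic id
tie-breaks, so each sRNA joins at most one pair and reruns are
reproducible. The z-proportion test is one-sample with the null
variance p₀(1−p₀)/n and no continuity correction.

## Selection test on asRNA-encoding protein regions

Amino-acid distance uses the 20-state equal-rates model, whose ML
estimate has the closed form d = −(19/20)·ln(1 − (20/19)·p) for
mismatch fraction p over comparable (ungapped, non-stop) codon
columns; p ≥ 19/20 is flagged saturated. Empirical-matrix ML is a
deliberate non-goal: at the divergences involved the equal-rates form
is monotone in p and the test below depends only on relative
divergence.

The tested region is the asRNA overlap extended 15 nt each side,
converted to whole codons (length L_c). Windows of the same codon
length slide over the full alignment at a 1-codon step; windows
sharing any codon with the region are excluded from the null (an
overlapping window would leak the region into its own null
distribution — the exclusion fraction is configurable). The region
distance is compared with the null-window mean by a one-tailed t-test,
alternative "region more conserved".

The standard error is the delta-method form rather than the
window-sample standard deviation: with pooled mismatch fraction q over
the N non-region codons,

    se² = d'(q)² · q(1−q) · (1/L_c + 1/N),   d'(q) = 1/(1 − q/(19/20)).

Overlapping windows make the window-sample sd nearly useless — the
windows carry only ≈ n/L independent draws, so a t-test built on that
sd is either anti-conservative (df = n−1) or badly underpowered
(autocorrelation-corrected df) — while the underlying information is
one mismatch indicator per codon. The delta-method SE has effectively
N + L_c degrees of freedom. Calibration and power are measured, not
assumed: under the null (equal rates inside and outside footprints,
genes of 450 codons, footprints 30–110 codons — the span of the
conserved-region sizes this package mirrors) the rejection rate at
P < 0.01 is 0.4–0.8% across seeds; with divergence 0.05 inside vs 0.4
outside, power is 97–99%. Degenerate cases: identical distances give
t = 0, P = 0.5; fewer than 3 usable null windows, or a saturated
region or null, flag the gene untestable.

The dS screen is NG86-style counting (pathway-averaged differences,
Jukes–Cantor correction dS = −(3/4)·ln(1 − (4/3)·ps)), used only to
establish that synonymous signal is exhausted. At extreme AT bias the
JC correction alone can never report saturation — the expected
mismatch fraction at full randomization is 1 − Σfᵢ² ≈ 0.63, below the
3/4 singularity — so saturation is also flagged when ps reaches 85% of
that composition ceiling (estimated from fourfold-degenerate third
positions).

## Structure covariation

A consensus pair is compensatory when ≥2 distinct canonical pair types
(AU, UA, GC, CG, GU, UG — GU counted as canonical) are realized across
sequences, ignoring rows gapped at either partner; pairs with no
canonical realization are reported separately as inconsistent, not
counted. Shared pairs between a pairwise and a multi-genome consensus
are counted after column mapping, with the pairwise structure's pair
count as the denominator of the percentage (which bounds it at 100% by
construction). Both definitions are stated explicitly because the
covariation statistic and denominator used by folding tools are
tool-internal; counts are therefore comparative, not exact matches to
any specific tool output.

## Upstream composition analysis

Regions overlapping a CDS other than the feature's own target are
excluded (reason-coded). For asRNAs the own-target exemption is
essential: an asRNA's upstream region lies inside its target CDS by
construction, so a literal any-CDS rule would exclude every asRNA in a
gene-dense genome. For CDS upstream sets the rule is any adjacent CDS
— in a genome with ~25-nt spacers this can exclude nearly all CDSs,
which the per-stage logs make visible.

GC% windows are tested against a 100× mononucleotide-reshuffle null
(uniform Fisher–Yates permutation of each 61-mer; a
dinucleotide-preserving Altschul–Erikson shuffle is available as an
option): per window, a paired two-sided t-test across regions of
observed GC% against each region's own null mean, significant at
P < 0.05, no multiple-testing correction by default (per-window flags;
Benjamini–Hochberg behind a flag). Type-I error measured over 200
replicate null region sets is ≈5% per window.

Because permutation redistributes each region's fixed base
composition, a genuine GC dip in one band necessarily makes the
remaining windows look GC-enriched relative to the null — a
compensation artifact intrinsic to composition-preserving nulls, not a
defect. Recovery of planted dips is therefore scored by windows
flagged *with negative direction*: with a 0.10 GC dip planted in
windows 33–48 of 200 regions, 100% of in-band windows flag negative
and 0% of windows sharing no position with the band do (edge windows
straddling the band boundary carry part of the signal by construction
and are scored on neither side).

GC-skew profiles (zero-denominator windows score 0 — at 84% AT,
dropping G+C-free windows would bias profiles) are compared
qualitatively between asRNA and CDS sets, mean ± SE per window with no
hypothesis test: the entire qualifying population is profiled, not a
sample. Motif scanning expands IUPAC codes to character classes;
discovery itself is exported to external tools as FASTA.

## Synthetic data: what it emulates, and what it does not

The generator builds paired syntenic genomes: CDS sequences sampled
codon-wise at the target composition (default 16% GC) with start/stop
bookkeeping; lineage B derived codon-by-codon from lineage A —
amino-acid-changing single-nt substitutions at rate 1 − exp(−d) per
codon (d = 0.4/site outside conserved asRNA footprints, 0.05 inside),
composition-weighted so the AT bias survives, plus deliberate
synonymous randomization (probability 0.7/codon) so synonymous signal
is saturated and only amino-acid divergence is informative. asRNAs are
placed antisense within CDSs with margins that keep their 61-nt
upstream regions inside the host; conserved pairs share mapped
footprints with Normal(0, 5 nt) jitter truncated at ±3σ and the CDS
margins (truncation keeps the category invariant and, at σ ≤ 5,
bounds the offset by the 15-nt rule); lineage-specific asRNAs occupy
disjoint host CDSs. The offset map is exact by construction. All
randomness flows from one seed through named sub-streams; identical
configurations give byte-identical outputs.

Planted upstream signals rewrite only the 61-nt regions: GC dip
(composition decrement over the band's window positions), skew bump
(C:G rebalanced to the target skew), and a TANAAT-style motif at a
fixed offset (~10 nt upstream, the classic σ70 −10 position) with
configurable probability. Because an asRNA's upstream region lies
inside its target CDS, planting necessarily edits protein-coding
sequence — the motif at positions 8–13 can fall inside the 15-nt flank
of the selection-test region and add one or two amino-acid changes,
which is why a few planted footprints in the end-to-end demo miss the
P < 0.01 cutoff. The calibration and power studies plant no upstream
signals, so their rates are clean. Real promoter-like signals inside
coding sequence would impose exactly this kind of joint constraint;
the generator makes the interaction visible rather than hiding it.

Not emulated: indels and rearrangements (these genomes are syntenic
and the offset map is exact, so mapping robustness to misalignment is
untested), read-level sequencing noise (coverage is Poisson per base),
transcription-start uncertainty beyond coordinate jitter, and any
correlation between expression level and conservation. Passing the
synthetic studies shows the estimators and callers are correct and
calibrated under the stated generative model, not that the model
captures every property of real RNA-seq.

## Problem sizes

The shipped studies use: survey-scale genome pairs (196 CDSs, ~165 kb,
36/32 asRNAs, 11 conserved); 200 replicate sets of 36 regions × 100
shuffles for GC% null calibration; 500 null genes and 300 signal genes
(450 codons, footprints 30–110 codons) for the selection test; 200
regions for dip recovery. The full test suite runs in well under a
minute; the reproduction script in ~15 s.
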