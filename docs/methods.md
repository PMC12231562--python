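# Methods

## Scope and model

The package analyzes small-variant and SV call sets from resequenced
mutant cohorts: several sequenced lines (plants) per genotype, each
irradiated at a known dose, each carrying heterozygous induced mutations
in the M2 generation. The analysis assumes calling and alignment happened
upstream (SAMtools/VarScan2-style small variants with per-sample
supporting-read information; interval-scale SVs from breakpoint callers).
Everything downstream of the caller — retention filtering, classification,
microhomology signatures, effect tiers, statistics — is implemented here.

## Coordinates and normalization

External formats are 1-based inclusive (VCF/GFF3); arithmetic is done on
string offsets inside function bodies only. Before any analysis, InDels
are canonicalized with the standard trim/extend algorithm: shared trailing
bases are trimmed and, whenever an allele empties, both alleles are
extended one reference base to the left, shifting the InDel to its
smallest position that preserves the alternate haplotype; shared leading
bases are trimmed last, keeping the anchor base. The operation is
idempotent and haplotype-preserving (fuzz-tested on 1000 random cases
against an independent haplotype-reconstruction check, plus a brute-force
leftmost-placement check). All microhomology quantities are measured on
this left-aligned form, which makes them representation-invariant.

## Retention filter

A call is retained iff (i) supporting-read fraction ≥ `af_target_min`
(default 0.25) in the owning line, (ii) < `af_other_max` (default 0.05) in
every other line, and (iii) the exact normalized (contig, pos, ref, alt)
tuple is not carried at ≥ `af_other_max` by ≥ `shared_line_min` (default
2) lines. Threshold (i) reflects a heterozygous mutation sequenced at
~40×; (ii)/(iii) remove standing variation and recurrent artifacts, which
by construction appear in multiple independently derived lines. Both
thresholds are inclusive at the boundary (0.25 retained; 0.05 in another
line counts as carried). Removed calls carry one reason each, with
precedence low_af_target → shared → present_in_other.

## Event classification

Categories: SBS, −1 bp, +1 bp, Dels ≥ 2 bp, Ins ≥ 2 bp, complex, SV.
Complex events chain same-line calls whose reference footprints are within
10 bp (gap measured end-of-previous to start-of-next, transitively); a
complex event counts as one event, and its members are excluded from the
SBS/InDel sub-spectra to avoid double counting (a switch restores them).
Balanced multi-base substitutions are decomposed to per-base SBSs first;
since their parts lie within the window they re-join as one complex event.
The SV category is only ever assigned by the SV module — small-variant
InDels keep their length category no matter how long. Clustering is
validated against an independent connected-components oracle on 500 fuzz
instances, with call-count conservation.

## Microhomology signatures

For an InDel with allele A (deleted bases, or inserted bases):

* `mh_len` = max k ≤ min(|A|, 20) with prefix_k(A) equal to the k bases
  immediately 3′ of the junction, or suffix_k(A) equal to the k bases
  immediately 5′; the 20 bp cap and scan window follow the 2–20 bp range
  Alt-EJ typically uses. Windows containing N never match.
* `homopolymer_run` H = longest single-base reference run overlapping the
  junction (deleted bases included; for insertions, the two flanking
  bases).
* `repeat_unit` = shortest unit u (2 ≤ |u| ≤ 10) whose perfect tandem
  array of ≥ 2 copies within ±20 bp covers the junction (contains the
  deleted interval; touches the insertion point). Mononucleotide units are
  excluded — a homopolymer array is scored by the homopoly feature, not as
  a polynucleotide repeat.

Dependency classes are mutually exclusive with priority homopoly >
polynucleotide_repeat > independent:

* **homopoly** — A is a single repeated base and H ≥ 3 (the canonical
  slippage context; single-base InDels in runs land here);
* **polynucleotide_repeat** — a covering tandem array exists, or |A| ≥ 2
  with mh_len ≥ 1 (junction microhomology of even 1 bp counts as
  repeat-mediated, matching a length distribution that starts at 1 bp);
* **independent** — neither feature; also the fallback for junctions with
  N in the window, flagged `ambiguous_context`.

The decision rule is a design choice — published three-class accountings
rarely state one — and every threshold sits in `MHConfig`. Both scanners
are equality-tested against naive brute-force oracles on ≥ 1000 random
junctions, and deleting one unit of a two-copy tandem repeat provably
yields mh_len = |unit|.

## Impact tiers

Subclass by overlap priority: splice donor/acceptor (first/last 2 intron
bases) → CDS (SBSs translated with the standard genetic code to
synonymous/missense/stop_gained/stop_lost/start_lost; InDels frameshift
iff |Δ| mod 3 ≠ 0 else inframe) → UTR → intron → upstream/downstream
(within 5 kb, the common annotator default) → intergenic. Tier map: HIGH =
{frameshift, stop_gained, stop_lost, start_lost, splice_donor,
splice_acceptor}; MODERATE = {missense, inframe_indel, utr5, utr3}; LOW =
{synonymous, intron}; MODIFIER = {upstream, downstream, intergenic}. Note
UTR→MODERATE and intron→LOW deliberately follow the tiering used in the
reports this package emits rather than stock SnpEff. When an event touches
several genes or features the most severe subclass wins; complex events
take the most severe subclass among members; each event is counted once.
The first mRNA isoform per gene (file order) defines the structure.

## SV analysis

Size is defined as end − start, the definition consistent with the
embedded reference table (19 of its 20 printed rows; the remaining row is
internally inconsistent as printed and the `verify` self-check flags it
rather than reproducing it). Consensus merging is single-linkage over
same-line, same-type records with reciprocal overlap ≥ 0.8; coordinates
are member medians, callers are unioned, and records below 2 supporting
callers are dropped unless manually validated (IGV-style validation enters
as a passthrough flag, not automation). The small-InDel/SV boundary is
50 bp, the smallest size in the reference table.

## Statistics

Mutation frequency f = (total events / n_lines) / L_ref / dose, reported
×10¹⁰; with L_ref = 119,146,348 bp (five nuclear chromosomes of the
TAIR10 assembly) this reproduces the published totals exactly from the
published counts. Controls (dose 0) are reported as counts; the frequency
is undefined there. Proportions and the Ts/Tv, Ins/Dels, SBS/InDel ratios
are computed per line first and averaged across a genotype's lines (equal
plant weighting; SEM with n = lines); lines with a zero denominator are
excluded from that ratio's mean. TSS distances are signed along the
transcription direction (negative upstream), measured to the annotated
gene's TSS by default or the nearest TSS on request, binned over ±10 kb.

Group comparison is one-way ANOVA plus Duncan's multiple-range test:
means sorted descending, critical range for a span of p means using the
studentized range at protection level 1−(1−α)^(p−1) with the ANOVA error
df and the harmonic mean group size; ranges nested inside a
non-significant range are never declared significant, and the compact
letter display is read off the maximal non-significant runs. The
studentized-range quantile is cached per (span, df, α) — it dominates
runtime otherwise. With zero within-group variance everywhere, letters
fall back to exact mean equality. Duncan's test is implemented here
because no installed package provides it with letters; its type-I
behavior is simulation-checked.

## Synthetic data generator

The generator emulates the study conditions so the pipeline is testable
end to end without downloads:

* **Genome** — i.i.d. bases at GC 0.36 (the *A. thaliana* nuclear value),
  with homopolymer runs (3–12 bp) and perfect tandem arrays (unit 2–6 bp,
  2–5 copies) stamped at 2 features/kb each, flanks broken so features are
  maximal; defaults 100 kb and 20 three-exon genes (UTRs, two introns,
  ATG/stop forced on the coding strand). Fully deterministic per seed.
* **Mutations** — per line, event counts are Poisson with the profile
  mean; categories, SBS classes, InDel length bins and microhomology
  classes are i.i.d. draws from the profile. InDels targeted at homopoly
  or polynucleotide-repeat context are placed inside seeded runs/arrays
  (whole-unit deletions, run deletions, tandem expansions); lengths beyond
  any seeded array fall back to junction-microhomology placement
  (deletions whose edge matches the following sequence; insertions as
  tandem duplications) — the long-deletion MMEJ signature. Independent
  InDels go to unique context. Every placement is verified against the
  package's own classifier and re-drawn until the target class holds, so
  truth labels are exact by construction; recovery tests therefore
  exercise the full filter→classify→signature path, not the labels.
  Distinct events keep ≥ 12 bp clearance (more than the complex window)
  and never recur across lines. Supporting-read fractions are
  Beta(20, 20) around 0.5 (heterozygous M2 expectation); shared background
  variants (≥ 2 carrier lines) and low-support noise calls are appended to
  exercise the filter. 60% of placements decay exponentially (Laplace,
  3 kb scale) from a random gene's TSS, 40% uniform, reproducing the
  TSS-proximal concentration qualitatively.
* **Packaged profiles** — WT-200 Gy (10 lines, 31.8 events/line),
  teb-8-100 Gy (11 lines, 224/11) and lig4-4-100 Gy (14 lines, 192/14),
  with category mixes from the published per-genotype proportions. Where
  minor categories were published only as "not significantly different",
  the residual mass is allocated consistently with the published
  per-category frequencies and Ins/Dels ratios; the teb-8 mix implies a
  single-base InDel fraction of exactly 67.65% and carries the hard 30 bp
  cap (no longer InDel was observed in that genotype). The lig4-4
  microhomology mix is the published 7.60 / 67.62 / 24.78% split; WT and
  teb-8 splits are calibrated so ~50% of InDels are
  microhomology-associated, as published only in aggregate.

What the generator does **not** emulate: read-level noise (calls are
emitted directly, not from alignments), mapping artifacts, clustered
multi-kb damage tracts, genome-wide repeat families (only short local
repeats), or linked mutations on one chromatid. Passing recovery tests
therefore demonstrates correctness of the analysis logic under the stated
noise model, not robustness to upstream calling errors.

## Problem sizes and tolerances

Tests and the acceptance script use the 100 kb genome with the packaged
cohort sizes, giving ~170–350 events (≈ 50–80 InDels) per genotype run —
the same per-line statistics as the study at a desk-scale genome.
Recovered class fractions consequently carry binomial noise of ~5 pp SD;
recovery assertions use 3 SEM at the measured n. Frequency and fold-change
checks are exact to the printed precision. The Duncan null-rate simulation
uses 800 replicates (k = 3, n = 5) and accepts a familywise separation
rate in [0.01, 0.15] around α = 0.05.

## Known limitations

* The microhomology dependency rule is one defensible reading of a
  three-class scheme; alternative thresholds (e.g. requiring mh_len ≥ 2)
  change the repeat/independent split and are exposed in `MHConfig`.
* Impact annotation handles one isoform per gene and no regulatory
  features; splice-region (beyond ±2), HGVS and MNV-joint-codon effects
  are out of scope.
* The filter treats "other lines" genome-wide; restricting sharing checks
  to within-genotype is a configuration choice left to the caller by
  passing per-genotype line subsets.
* BND records pass through SV I/O but have no size or merge semantics.
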