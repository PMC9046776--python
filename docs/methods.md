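# Methods

`matesv` implements the analysis chain used with large-insert mate-pair
libraries sequenced at low base coverage: a single sequencing run (~60 M
read pairs of 2×100 bp with ~5 kb inserts, i.e. ~4× base coverage but
~100× *physical* coverage) supports three complementary detectors —
read-depth copy-number analysis, chimeric read-pair junction analysis,
and windowed absence-of-heterozygosity (AOH) detection. This note
records the models, the tunable parameters, the numerical choices, and
what the synthetic-data studies do and do not demonstrate.

## Coordinate and orientation conventions

Positions are 1-based inclusive everywhere except the BED boundary
(0-based half-open). Read pairs are stored with ends in canonical order
under the chromosome map, so each junction has exactly one key. All
orientation logic assumes FR (inward-facing) pairs; outward-facing RF
mate-pair chemistry is normalised by flipping both strands at ingest
(`library_type="rf"`). A mapped `+` read lies left of any junction its
fragment spans (innermost evidence = max position), a `-` read lies
right of it (innermost = min position); this single rule drives every
breakpoint estimate.

"Uniquely aligned" is operationalised as MAPQ ≥ 20 at ingest
(`min_mapq`, configurable); duplicate-flagged pairs pass through the
readers and are excluded by the counting/clustering steps.

## Read-depth CNV model

Read ends are counted in two tilings: 50-kb windows advanced in 5-kb
steps (coarse segmentation) and non-overlapping 5-kb windows (boundary
refinement, homozygous-deletion calling). Counts are normalised by the
median of their 1%-GC stratum (strata under 30 windows fall back to the
global median), optionally divided by a reference-panel per-window
median (panel windows with median 0 are masked), and rescaled so the
autosomal median ratio is 1.0.

* `gain_thr=1.25`, `loss_thr=0.75`: midway between diploid (1.0) and
  the one-copy states (1.5 gain, 0.5 heterozygous loss). At 4× a 50-kb
  window holds ~2,000 ends (CV ≈ 2%), so these thresholds separate
  states by many standard errors.
* `min_run=3` flagged windows, merging runs split by a single
  sub-threshold window. Coarse boundaries are the run's outermost
  window edges — with a 0.75 threshold they overshoot a deletion by up
  to ~25 kb per side (a window must be ≥50% inside the event to cross
  threshold), which is why refinement exists.
* Boundary refinement moves each edge to the 5-kb window edge
  maximising |mean(ratio right flank) − mean(ratio left flank)| with
  50-kb flanks, searching ±50 kb around the coarse edge and clipping at
  the call midpoint; ties break toward the coarse edge; a fully masked
  flank leaves the boundary unrefined and flags the call. The exact
  statistic behind the published "increment rate of coverage" step is
  not printed anywhere we could consult; this step statistic is our
  concrete reading of it.
* Homozygous/hemizygous deletions: maximal runs of ≥2 consecutive 5-kb
  windows at ratio ≤0.1 (isolated single windows are never reported),
  giving the ~10-kb minimum reportable size.
* Counting unit is read *ends*; whether the original ratios were read-
  or fragment-based is unstated in the source, and at uniform insert
  size the two differ only by a factor absorbed by normalisation.

Fine-scale loss evidence (runs of ≥2 5-kb windows at ≤0.75) is computed
alongside and used only to corroborate junction-based deletion calls
below the 50-kb segmentation resolution — this is how exonic-scale
(~8–46 kb) deletions retain joint depth+junction support.

A known edge artifact: fragments cannot overhang chromosome ends, so
coverage rolls off over the last insert-length of each chromosome and
may produce short spurious loss calls there. A reference panel (which
shares the roll-off) removes the effect; without one, calls at
chromosome ends warrant scepticism.

## Chimeric-pair model

Chimeric pairs (different chromosomes, or same-chromosome span ≥10 kb
— inclusive, per the published rule) are single-linkage clustered
within each junction key; two pairs link when both side-a and side-b
positions are within `cluster_radius=8000` bp (≥ the maximum insert).
Clusters below `min_support=6` distinct pairs, or touching a blacklist
or known-population-SV interval, are dropped. The published pipeline's
exact support threshold and clustering distance live in its prior
methodological references; our defaults derive from the implied ~100×
physical coverage (an expected ~50 spanning fragments per heterozygous
junction leaves min_support=6 far below the signal but above sporadic
artifacts). Breakpoint estimates are innermost read coordinates; true
breakpoints lie up to one insert beyond, an uncertainty inherited by
all reported junction coordinates.

Classification grammar (same-chromosome keys after canonical
ordering): `(+,-)` = deletion-type junction, reported as DEL only with
corroborating depth loss (dispersed-repeat artifacts produce the same
signature without dosage change); `(-,+)` = forward tandem duplication
when the junction *brackets* a depth gain — both sides within
2×`cluster_radius` of the gain's boundaries; mere overlap is not
enough, because a junction spanning a wider interval that happens to
contain a gain belongs to a complex rearrangement; matched
`(+,+)`/`(-,-)` pairs with consistent flanks = inversion (an unmatched
half is emitted single-sided and flagged); two clusters tying one locus
to both ends of a distant gained segment = duplicated-segment
insertion, with any additional gain at the insertion site noted as a
flanking duplication; remaining inter-chromosomal clusters =
translocation; connected components of ≥3 interdependent clusters
(sharing a locus within 2×insert, or touching the two ends of one
gained segment) = complex; depth gains with no usable cluster whose
flanks intersect segmental-duplication annotation = unresolved (LCR).

Duplication-orientation resolution applies the same logic per gain:
exactly one bracketing `(-,+)` cluster ⇒ forward tandem; boundary
clusters reaching a remote locus ⇒ complex; no usable cluster with LCR
flanks ⇒ unresolved; otherwise no junction.

## AOH model

Sites at 5–20× depth with ≥1 alternate read are genotyped by allele
fraction: heterozygous in [0.2, 0.8], homozygous-ALT at ≥0.9, the
(0.8, 0.9) band dropped as ambiguous (cutoffs chosen for binomial
separation at these depths; the source gates only on depth and the
≥1-alt requirement). Reference-homozygous sites carry no information
under that gate, so "hom rate" means hom-ALT rate throughout.

Counts per fixed 100-kb window are normalised by the sample's
autosome-wide mean of the same class (empty windows are missing, not
zero, and excluded from the means). AOH windows show the joint
signature — normalised het rate < 0.3 AND hom rate > 1.3 — which
coverage dropout cannot mimic (dropout depresses both). Flagged runs
bridging ≤5 unflagged/missing windows merge; run edges then extend
across contiguous windows het-depleted *alone*, because the het signal
is overwhelming (expected ~1.3 residual het sites per window inside
AOH vs ~67 outside) while the hom-ALT rise is Poisson-noisy at ~40
baseline sites per window — demanding the joint rule at the very edge
window would clip true boundaries about 10% of the time. Regions with
inclusive span ≥5 Mb are reported: the inclusive reading keeps a run
of exactly fifty 100-kb windows reportable at the stated 5-Mb
resolution (the region's `size_bp` field keeps the end − start
difference convention that the size arithmetic of the reference tables
fixes). Reporting rules: terminal regions are within one window of a
chromosome end; UPD is suspected for interstitial AOH >15 Mb or
terminal AOH >5 Mb; AOH on ≥3 autosomes raises the consanguinity flag;
sex chromosomes are excluded from totals; regions on the imprinted
chromosome list (6, 7, 11, 14, 15, 20 by default) are marked.

Because the normalising baseline is the sample itself, sensitivity
degrades when AOH occupies a large fraction of the genome (the inside
hom-rate enrichment is diluted by its own contribution to the mean);
at the ~7% genome fraction of the motivating consanguinity case this
is negligible, and the recovery studies keep implanted fractions
≤~26%.

## Nomenclature

Dosage events render as
`seq[GRCh37] del(5)(q14.3) chr5:g.90028949_90237360del`; tandem
duplications, inversions and insertions render in junction form with
`::` at junctions and `->`/`<-` segment reading directions. Event size
is max(breakpoint) − min(breakpoint) — the difference, not +1 — which
reproduces every verifiable printed size exactly. Insertions get no
single size (ambiguous); segment length and junction coordinates are
reported separately. The parser normalises typeset quirks (`- >`,
thousands separators inside coordinates) and round-trips the
formatter's output.

## Synthetic data

The simulator builds a diploid donor genome from the reference map by
implanting events on one haplotype (het) or both (hom): deletions,
forward tandem duplications, inversions, duplicated-segment insertions
(either orientation), reciprocal translocations, and
duplication-with-remote-insertion complexes. Fragments are sampled
uniformly along each rearranged molecule (counts multinomial in
molecule length, total = ⌈coverage × genome / (2 × read length)⌉),
with truncated-normal inserts (mean 5,000, SD 700, bounds 3,000–8,000)
and 100-bp reads mapped back to reference coordinates; fragments
spanning an implanted junction yield chimeric pairs with the
orientation the geometry dictates, and reads that would cross a
junction are dropped (split-read alignment is out of scope). Ends are
emitted pre-mapped at MAPQ 60; an LCR mask zeroes MAPQ inside its
intervals, which is how segmental-duplication-defeated junctions are
modelled. Defaults mirror the protocol the package targets: 2×30 Mb
toy genome, 4× base coverage, FR output.

Pileups are simulated independently at mean site depth 8 (not 4): the
5–20× genotyping gate would discard most sites at 4×, and the gate's
existence in the published protocol implies usable site depths; this
divergence affects nothing downstream of genotyping. Het candidate
sites occur every ~1.5 kb and hom-ALT sites every ~2.5 kb; inside AOH
regions a 2% residual of het candidates stays het (genotyping error)
and the rest become hom-REF or hom-ALT with equal probability.
Homozygously deleted intervals yield neither fragments nor sites.

What the simulator does **not** model: alignment ambiguity outside the
binary LCR mask, GC-coupled coverage bias (available but off by
default; the GC track itself is synthetic), sequencing error in reads,
mosaicism, and overlapping/nested events outside the explicit complex
type. Passing recovery suites therefore demonstrate the *engines'*
correctness on geometrically faithful evidence, not robustness to real
alignment noise.

The reference panel stand-in takes per-window median raw counts over
≥10 simulated replicates (median robustness is what makes a one-
replicate event invisible in the panel).

## Problem sizes in the test and acceptance studies

Statistical suites run 50 seeds each: CNV/SV recovery on the default
2×30 Mb genome at 4× (one 300-kb deletion, 250-kb tandem duplication,
150-kb inversion per genome); AOH recovery on a 150+100 Mb genome with
50/10/5-Mb implants; false-positive control on AOH-free 2×30 Mb
genomes. The acceptance script re-derives the duplication-orientation
split from 15 simulated gains (12 tandem, 1 complex, 2 LCR-flanked),
CNV/SV detection rates from 13 simulated cases carrying 25 CNVs, an
exonic-scale 8,484-bp deletion delineated by junction evidence, and a
214.5-Mb/13-autosome AOH profile on an hg19-scaled 13-autosome genome.
These sizes were chosen so each estimate's sampling error sits well
inside the tolerance it is compared at.

## Known limitations

Breakpoints are insert-resolution, not base-pair (the published
workflow used Sanger sequencing for that). DEL calls require depth
corroboration, so balanced artifacts of dispersed repeats are
suppressed at the cost of missing deletions with no dosage signal.
Sex-chromosome ploidy is not modelled (XX/XY expectation only via a
config ploidy map would be future work; autosomal medians drive
normalisation). Mosaic AOH and mosaic CNV fractions are out of scope.
COMPLEX events report their junction graph and provenance clusters,
not a full haplotype reconstruction.
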