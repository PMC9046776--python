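# matesv

Structural-variant, copy-number and absence-of-heterozygosity calling
from **mate-pair low-pass genome sequencing**.

Clinical laboratories investigating neurodevelopmental disorders often
end a chromosomal-microarray or shallow-sequencing CNV work-up with an
inconclusive answer: a duplication of unknown orientation (tandem?
inserted elsewhere? part of a complex rearrangement?), a variant of
uncertain significance, or no finding at all. A large-insert (~5 kb)
mate-pair library sequenced to only ~4× base coverage changes the
evidence available: 60 M read pairs spaced 5 kb apart give ~100×
*physical* coverage, so nearly every rearrangement junction in the
genome is spanned by dozens of fragments even though most bases are
read only four times. `matesv` implements the three detectors such data
supports, for people building or studying this kind of pipeline:

* **Read-depth CNV calling** — read ends counted in 50-kb sliding
  (5-kb step) and fixed 5-kb windows, GC- and panel-normalised to copy
  ratios (diploid = 1.0), segmented at gain/loss thresholds 1.25/0.75,
  boundaries refined by a coverage-step statistic on the 5-kb profile;
  homozygous/hemizygous deletions are runs of >1 window at ratio ≤0.1
  (minimum reportable size ~10 kb).
* **Chimeric read-pair SV analysis** — pairs mapping to two chromosomes
  or ≥10 kb apart are clustered per junction orientation key
  (chromA, chromB, strandA, strandB) by single linkage within 8 kb;
  clusters with ≥6 supporting pairs are classified jointly with the
  depth calls into DEL, forward tandem duplication, inversion,
  duplicated-segment insertion, translocation, complex rearrangement,
  or unresolved-LCR (duplication whose flanking segmental duplications
  defeat junction mapping). The same logic resolves the
  *orientation* of a depth-detected duplication.
* **AOH detection** — SNVs genotyped from 5–20× pileup sites, het/hom
  rates per 100-kb window normalised to the sample mean; a simultaneous
  het-rate drop (<0.3) and hom-rate rise (>1.3) marks absence of
  heterozygosity; regions ≥5 Mb are reported with
  uniparental-disomy (interstitial >15 Mb, terminal >5 Mb) and
  consanguinity (≥3 autosomes) flags.

Events are reported with ISCN-like nomenclature, e.g.
`seq[GRCh37] dup(13)(q13.3)(pter->q13.3(+)(37430811)::q13.3(+)(37267951)->qter)`
for a forward tandem duplication, with event size defined as
max(breakpoint) − min(breakpoint).

A first-class **simulator** generates aligned pair tables, pileups, GC
tracks and truth files for a toy diploid genome with implanted events
(deletions, tandem duplications, inversions, insertions,
translocations, complexes, AOH, LCR masks), so every engine is testable
offline — no patient data or aligner required.

## Worked example

Simulate a sample carrying a 300-kb heterozygous deletion, a 200-kb
forward tandem duplication and a 10-Mb AOH region, then run the whole
workflow:

```bash
cat > sim.yaml <<'YAML'
genome: [[chr1, 30000000], [chr2, 30000000]]
events:
  - {type: dup, chrom: chr1, start: 12000000, end: 12200000}
  - {type: del, chrom: chr1, start: 5000000, end: 5300000}
aoh_regions: [[chr2, 15000001, 25000000]]
seed: 7
YAML

printf 'chr1\t0\t15000000\tp11\tgneg\nchr1\t15000000\t30000000\tq11\tgpos50\nchr2\t0\t15000000\tp11\tgneg\nchr2\t15000000\t30000000\tq11\tgpos50\n' > cytoband.txt

matesv simulate -c sim.yaml -o sample/
matesv all --pairs sample/pairs.tsv --pileup sample/pileup.tsv \
           --gc sample/gc_track.tsv --genome sample/genome.tsv \
           --cytoband cytoband.txt -o out/
```

The `all` command prints a summary —

```
{
 "cnv": 4,
 "homdel": 0,
 "sv": 2,
 "aoh": 1
}
```

— and `out/report.json` carries the calls. For this seed the depth
engine reports (type, interval, mean ratio, nomenclature):

```
loss chr1 5000001 5300000 0.53  seq[GRCh37] del(1)(p11) chr1:g.5000001_5300000del
gain chr1 12000001 12200000 1.48  seq[GRCh37] dup(1)(p11) chr1:g.12000001_12200000dup
```

both refined to the exact implanted boundaries (the two additional
sub-threshold `loss` calls at the chromosome tails are the documented
end-of-chromosome coverage roll-off; a reference panel removes them).
The junction engine types both events and delineates them to read
resolution (size, support, nomenclature):

```
DEL 300297 45  seq[GRCh37] del(1)(p11) chr1:g.4999787_5300084del
DUP_TANDEM_FWD 199628 40  seq[GRCh37] dup(1)(p11)(pter->p11(+)(12199863)::p11(+)(12000235)->qter)
```

i.e. the duplication is resolved as *forward tandem* — its junction
joins the segment's end back to its start in `+` orientation — with
breakpoints within ~250 bp of truth. The AOH engine recovers the
implanted region exactly:

```
chr2:15000001-25000000  interstitial  mean het rate 0.05, mean hom rate 1.57
autosomal_total_bp 9999999, consanguinity_suspected false
```

The same pipeline is available as a library (`matesv.run_sample`) on
in-memory tables; `matesv cnv`, `matesv sv`, `matesv aoh` run the
engines separately.

## Layout

```
src/matesv/pairio.py          pair/pileup/BED/VCF-BND I/O, genome map
src/matesv/depth_cnv.py       windowing, normalisation, segmentation,
                              refinement, homozygous deletions
src/matesv/chimeric_sv.py     chimeric selection, clustering,
                              classification, dup orientation
src/matesv/aoh.py             genotyping, window rates, AOH regions,
                              UPD/consanguinity rules
src/matesv/nomenclature.py    ISCN-like strings, sizes, annotation
src/matesv/synthetic_data.py  diploid rearrangement simulator + panel
src/matesv/cli.py             click front end and run_sample pipeline
docs/methods.md               models, parameters, design choices
```
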