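# arfcaliper

Comparative analysis of AUXIN RESPONSE FACTOR (ARF) DAP-seq binding in
maize: peak-set overlap and clade classification, the TGTC
orientation/spacing ("molecular caliper") grammar, target-gene
co-occupancy and auxin-response enrichment, open-chromatin integration,
and sequence-to-binding-strength cross-prediction — exercised
end-to-end on synthetic genomes with planted ground truth.

## Who this is for

Regulatory genomicists working with in-vitro TF binding data (DAP-seq
/ ChIP-seq style peak calls) who need the downstream comparative
machinery: reciprocal-overlap peak matrices, consensus/occupancy
classification, core-motif spacing spectra, peak-to-gene assignment
with enrichment statistics, open-chromatin overlap, and supervised
sequence-to-signal models. Every operation runs on standard flat files
(narrowPeak, BED, FASTA, bedGraph, TSV), and a synthetic-data module
generates genomes, planted motif architectures, peak families, gene
models, expression responses and open-chromatin sets with known truth,
so the full pipeline is testable without any download.

## The science in brief

ARFs bind the 4-bp core *TGTC*; its reverse complement *GACA* marks a
reverse-strand site. ARFs dimerize, so functional elements are often
two cores in one of three orientations on a fragment —

* **DR** (direct repeat) `TGTC …spacer… TGTC`
* **ER** (everted repeat) `TGTC …spacer… GACA`
* **IR** (inverted repeat) `GACA …spacer… TGTC`

with the spacer counted in bases between the two 4-mers. The protein
pair acts as a molecular caliper: each ARF clade prefers particular
orientation/spacer combinations, visible as sharp cells (and ~10-bp
helical phasing) in the orientation × spacer spectrum of peaks that
contain exactly two cores. Around this sit the dataset-level analyses:
pairwise shared-peak percentages (reciprocal 50% overlap, smaller set
as denominator), clade A/B consensus classification of merged regions,
strand-aware peak→gene assignment (proximal: TSS−1.1 kb … TTS+0.9 kb;
distal: TSS−10 kb … TTS+3 kb), Fisher's exact enrichment of
TSS-proximal binding at auxin-induced genes, ≥1-bp overlap with
tissue open-chromatin sets, Tn5-density refinement of ATAC regions
(50-bp windows, 25-bp step, ≥25× average, 150-bp merge gap), and a
201-bp sequence→signal regressor whose cross-dataset percent variance
explained (100·r²) separates the two ARF clades.

## Worked example

The `analysis/` scripts run the whole study on a simulated 2-Mb genome
(GC 0.47) with planted DR7, ER11 and IR2 elements, 4 clade A + 4 clade
B peak families, 1,200 genes, a DE table, and tissue open-chromatin
sets:

```bash
python analysis/01_simulate_data.py --seed 1   # writes results/sim/
python analysis/02_peak_overlap.py
python analysis/03_motif_grammar.py --seed 1
python analysis/04_target_genes.py --seed 1
python analysis/05_chromatin.py
python analysis/06_binding_model.py --seed 1
```

Selected output (seed 1):

```
shared-peak matrix: mean within-clade 79.2%, mean cross-clade 12.4%
consensus regions: 862 total; 420 A-only, 356 B-only, 86 shared (10.0%)
A1: multi-TGTC enrichment OR=inf (p=5.42e-262); modal grammar DR7 over 222 two-instance peaks
B1: multi-TGTC enrichment OR=inf (p=1.23e-201); modal grammar IR2 over 163 two-instance peaks
random windows: 41.2% zero, 34.3% one, 24.5% two+
TSS-proximal enrichment of induced genes: OR=4.93, p=2.38e-12
tissue-specific regions (ear): 60 found, planted truth recovered exactly: True
ATAC refinement: 310 primary regions -> 60 refined regions covering 13000 bp
variance explained: mean within-clade 50.9%, mean cross-clade 10.2%
two-way cut groups: {'A1': 1, 'A2': 1, 'A3': 1, 'A4': 1, 'B1': 2, 'B2': 2, 'B3': 2, 'B4': 2}
```

Reading it: within-clade peak sharing (~79%) far exceeds cross-clade
sharing; 10% of merged consensus regions are bound by both clades; the
spacing spectrum recovers each clade's planted grammar (DR7 for clade
A, IR2 for clade B) as its modal cell; ARF peaks are hugely enriched
for multiple TGTCs relative to random windows; auxin-induced genes are
~5× enriched for TSS-proximal peaks; tissue-specific open-chromatin
regions and Tn5-dense ATAC cores are recovered exactly; and the
cross-prediction matrix (within-clade 51% vs cross-clade 10% variance
explained) clusters the TFs into their two clades.

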