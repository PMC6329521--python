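# Methods

## The problem and the model

UV light forms cyclobutane pyrimidine dimers (CPDs) at adjacent
pyrimidines (TT, TC, CT, CC) on one DNA strand; error-prone replication
over unrepaired dimers yields the C>T-dominated mutational signature of
skin cancers. Recurrently mutated promoter bases in melanoma cluster at
cytosines one or two bases 5′ of TTCCG elements (ETS-family binding
sites read on the pyrimidine strand), and the working model implemented
here is that protein binding locally elevates CPD *formation* at
specific bases, producing recurrent passenger mutations without
selection. The package provides the four computational stages needed to
test this model on any cohort/lesion dataset, plus generators that
emulate the data-generating process with known ground truth.

## Coordinate and strand conventions

All internal coordinates are 0-based, half-open; VCF/GTF convert at the
I/O boundary. Every mutation is standardized to its *pyrimidine
strand*: the strand on which the reference base is C or T
(`pyrimidine_strand == "-"` exactly when the plus-strand reference base
is A or G). Sequence context, TTCCG flags and motif classes are always
read on the pyrimidine strand. Dinucleotides are read 5′→3′ on the
strand they live on; a CPD event stores the position of its 5′ base on
the damaged strand (`pos5`), which on the minus strand is the
*rightmost* of the two plus-strand positions. TSS distances are
orientation-adjusted: negative = upstream of the gene; nearest-TSS ties
break toward the lexicographically smaller gene id.

## Hotspot catalog

Recurrence counts **distinct tumors** per base (multiple calls by one
sample count once). A catalogued site carries its ±10 bp pyrimidine-
strand context (N-padded at contig edges), a TTCCG flag (plain substring
test), and a motif class: if the mutated base lies 1–2 bp 5′ of a TTCCG
and the heptamer is CC/TC/CT + TTCCG, the class is that heptamer; if it
lies inside the TTCC core, `TTCCG-internal`; otherwise `other`. Sites
anchored on the same genomic TTCCG pentamer (e.g. both 5′ cytosines of
one CCTTCCG) collapse to one locus for motif-centred profiles, keeping
per-base recurrence. TTCCG fractions by recurrence threshold (default
thresholds 5, 8, 12, 16, 20, promoter window ±500 bp inclusive) accept
an exclusion list of known driver positions so that selection-driven
sites (e.g. *TERT* C228T/C250T) do not inflate the non-TTCCG count; the
list is configuration, not code, keeping the pipeline assembly-agnostic.
Burden coupling is Spearman rank correlation (ties mid-ranked, as in
`scipy.stats.spearmanr`) between per-tumor total SNVs and per-tumor
mutated-catalog-site counts.

## CPD extraction

CPD-seq places the sequencing start immediately 3′ of the lesion on the
opposite strand, so the dimer is recovered from the first mate of each
pair: plus-strand mate with leftmost aligned base *p* → minus-strand
dimer over reference *p*−2, *p*−1; minus-strand mate with rightmost
aligned base *e* → plus-strand dimer over *e*+1, *e*+2. Events falling
outside the contig are rejected and counted. Soft-clips are ignored
(*p*/*e* are aligned reference positions). PCR duplicates are removed by
fragment-coordinate key (first-mate contig, leftmost position, strand,
mate position), approximating MarkDuplicates semantics; callers wanting
cross-replicate deduplication merge SAM streams before extraction. Only
dipyrimidine events are biologically possible CPDs and enter downstream
counts; the full 16-class tally is retained for spectra. Spectrum rates
are `raw / (genomic count × depth) × 1e6` with depth defaulting to the
library's retained event total — the constant cancels in every ratio
taken. The false-positive rate per dipyrimidine is the median
non-dipyrimidine rate divided by that dipyrimidine's rate (non-
dipyrimidine detections can only be artifacts). Subsampling keeps each
first mate independently with probability *f* (seeded), reruns the full
pipeline, and reports the maximum relative deviation of count/*f* from
the full-depth count. Default MAPQ threshold is 0 (all mapped
primaries), configurable.

## Profiles and null models

Offset 0 is the anchored base; offsets increase 3′ on the orienting
strand (site pyrimidine strand, motif strand, or gene strand), so
minus-strand anchors are coordinate-flipped before summation. Profiles
divide by the anchor count and carry a cross-library scale factor
(ratio of genome-wide totals) for naked/no-UV comparability; raw counts
are retained. A CPD contributes at its 5′ base by default; a flag lets
it contribute at both dimer bases. Motif-centred profiles anchor at the
TTCCG's 5′ T: the flank dimer of CC/TC/CT + TTCCG heptamers sits at
offsets −2/−1 and the middle TC of the core at +1/+2. Overlapping
anchor windows double-count events (each anchor is an independent
alignment — aggregate-density semantics). TSS profiles use 20 bp bins
tiling ±1000 bp by default (bin width must divide the window); the
ΔTTCCG variant removes mutations whose ±10 bp context carries a TTCCG
before binning.

Expected ("null") profiles re-place exactly the observed number of
events in the same windows: per-position probability proportional to
the 96-channel signature's mass on that position's pyrimidine-centred
trinucleotide (mutations), or to per-dinucleotide weights summed over
both strands' dinucleotides whose 5′ base sits there (lesions; default
weight 1 per dipyrimidine, or a library's normalized spectrum rates).
Zero total mass in the windows is an error. The default is 100 seeded
multinomial replicates reporting mean and 2.5/97.5 percentiles; a
single replicate reproduces a plain one-draw null. Placement conserves
the observed count exactly in every replicate by construction. The
observed signature is computed as class counts divided by genomic
trinucleotide totals (both strands, pyrimidine-centred), renormalized
to sum 1; mutations with N in context are skipped and counted.

## Consensus amplicon quantification

Reads are grouped by a 5′ molecular barcode (default 12 nt). A family
is accepted when it has ≥10 reads and all read sequences are identical,
or, for families of more than 20 reads, when the modal sequence reaches
90 %. Identity is whole-read equality (quality scores are ignored); a
per-base column-wise mode with the same thresholds is available for
comparison. VAFs are mismatch counts over accepted consensus reads;
length-discordant consensus reads are excluded. Hotspot flagging marks
positions exceeding a configurable multiple (default 5×) of the profile
median, with a 1/total floor when the median is zero.

## Synthetic-data generators: what they emulate

`gen_genome` plants promoters on a jittered grid (error if denser than
capacity) with motif heptamers written verbatim 20–200 bp upstream of
each TSS on a random strand; defaults are one 450 kb contig at GC 0.41
with 82/57/27/44 loci of classes CCTTCCG/TCTTCCG/CTTTCCG/ACTTCCG (the
observed class ratio among unique loci) plus 90 motif-free promoters —
292 mutable hotspot cytosines in total. `gen_cohort` draws per-tumor
burdens from a log-normal (default median 16 SNVs on 450 kb, matching
a genome-wide rate of order 10⁵ SNVs per 3 Gb; σ = 0.8 for the wide
burden spread of melanoma), places background mutations with
probability proportional to the signature mass of each position's
trinucleotide (without within-tumor site collisions), and mutates each
planted hotspot base C>T with extra probability
min(1, (φ−1)·burden·w/W) on top of its background chance, so φ = 1 is
exactly background. Default φ = 300 puts per-tumor hotspot
probabilities in the few-percent-to-tens-of-percent range, i.e.
recurrences of roughly 5–60 per 221 tumors. Because the enrichment is
multiplicative on the context rate, hotspot bases with a purine 5′
neighbour recur more weakly — an intended, biologically faithful
consequence.

`gen_cpd_reads` samples one lesion per fragment with probability
proportional to per-dinucleotide weights (defaults TT 1.0, TC 0.35,
CT 0.25, CC 0.10; zero elsewhere), multiplied by `motif_multiplier`
(default 10) at each planted motif's key dinucleotides — the 5′-flank
dimer (absent for ACTTCCG, which has no flank dipyrimidine) and the
middle TC. Multiplier 1 emulates naked DNA. A `background_rate`
fraction (default 0.10) of lesions is placed uniformly at
non-dipyrimidine positions to emulate assay background. Fragments are
~N(400, 50) bp with paired 2×75 bp reads, single lesion at the ligation
end, clipped to fit the contig; lesions are only sampled outside a
contig-edge margin so every fragment is emittable. An optional
`duplicate_fraction` re-emits exact coordinate duplicates for
deduplication tests. `gen_amplicon_reads` writes barcode+insert reads
for a synthetic 46 bp amplicon carrying a CCTTCCG element (a
constructed stand-in window, not a genomic sequence), with
molecule-level variants drawn from truth VAFs (bounded at 5 %,
default 0.4 % C>T at the second flank cytosine), Poisson family sizes
(mean 30) and independent per-base errors (default 10⁻³) applied to
barcode and insert alike — so barcode errors realistically spawn
singleton families.

What the generators deliberately do **not** model: repair kinetics and
NER inhibition, chromatin or replication-timing covariates, UV
dose-response, CC>TT doublet calls, indels, alignment artifacts and
mapping ambiguity. Passing the closed-loop tests therefore demonstrates
correctness of the bookkeeping (coordinates, strands, normalization,
thresholds) and statistical recovery under the stated generative model
— not robustness to every artifact of real sequencing data.

## Problem sizes and numerical choices

Tests and the acceptance script run on the 450 kb default genome with
cohorts of 200–221 tumors, CPD libraries of 10⁵–2.5×10⁵ fragments and
amplicon runs of 10⁴–2.5×10⁴ molecules; these sizes give every
statistical check comfortable power on a single CPU in minutes.
Recovery checks use explicit sampling-error bands (binomial or Poisson
SEs propagated through each ratio) rather than fixed tolerances.
Degenerate inputs raise: empty TSS lists, zero-variance correlation
axes, zero library totals, zero placement mass, bin widths not dividing
the window. All randomness flows through `numpy.random.Generator`
seeded from explicit spec fields or function arguments; equal seeds
give bit-identical outputs, including FASTA/FASTQ/SAM bytes.

## Known limitations

The consensus caller assumes one amplicon and a fixed-position barcode;
demultiplexing and primer trimming live upstream. The motif classifier
assigns one class per site (flank placement takes priority over
internal when a context offers both). XR-seq repair profiling,
enhancer-overlap analysis and expression stratification are out of
scope.
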