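"""Genome-wide CPD lesion mapping from aligned CPD-seq read pairs.

CPD-seq libraries are constructed so that sequencing starts immediately
3' of the lesion on the strand opposite the damaged one.  The lesion is
therefore encoded by the first mate of each pair: the two reference
bases immediately upstream of the first mate, on the opposite strand,
are the dimer.  Concretely, with 0-based coordinates:

* first mate on the plus strand, leftmost aligned base ``p`` -> the
  dimer lies on the minus strand over reference positions ``p-2`` and
  ``p-1``; its 5' base (minus-strand reading) is ``p-1``;
* first mate on the minus strand, rightmost aligned base ``e`` -> the
  dimer lies on the plus strand over ``e+1`` and ``e+2``; its 5' base is
  ``e+1``.

Events whose bases fall outside the contig are rejected and counted.
Only dimers at dipyrimidines (TT, TC, CT, CC read 5'->3' on the damaged
strand) are biologically possible CPDs; the full 16-class tally is kept
for spectra and false-positive-rate estimation.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import DIPYRIMIDINES, DINUCLEOTIDES, NON_DIPYRIMIDINES, Genome


@dataclass(frozen=True, slots=True)
class CPDEvent:
    """One detected dimer on the damaged strand.

    ``pos5`` is the 0-based reference position of the dinucleotide's 5'
    base *on the damaged strand*: for plus-strand events the leftmost of
    the two bases, for minus-strand events the rightmost.
    """

    chrom: str
    pos5: int
    strand: str
    dinuc: str


@dataclass
class ExtractionStats:
    n_records: int = 0
    n_skipped: int = 0              # unmapped / secondary / supplementary / not read1
    n_low_mapq: int = 0
    n_first_mates: int = 0          # usable first mates before dedup
    n_duplicates: int = 0
    n_boundary_rejected: int = 0
    n_events: int = 0               # events emitted (all 16 classes)


def cpd_from_first_mate(aln: pysam.AlignedSegment, genome: Genome) -> CPDEvent | None:
    """Map one first mate to its encoded dimer, or ``None`` at a boundary."""
    chrom = aln.reference_name
    if aln.is_reverse:
        return event_from_span(chrom, aln.reference_start, aln.reference_end, "-", genome)
    return event_from_span(chrom, aln.reference_start, aln.reference_end, "+", genome)


def event_from_span(chrom: str, start: int, end: int, mate_strand: str,
                    genome: Genome) -> CPDEvent | None:
    """Core extraction rule on a first-mate reference span ``[start, end)``."""
    if mate_strand == "+":
        pos5, strand = start - 1, "-"
    else:
        pos5, strand = end, "+"           # end is half-open: rightmost base is end-1
    dinuc = genome.dinucleotide_at(chrom, pos5, strand)
    if dinuc is None:
        return None
    return CPDEvent(chrom, pos5, strand, dinuc)


def _usable_first_mates(bam: pysam.AlignmentFile, min_mapq: int, stats: ExtractionStats):
    for aln in bam:
        stats.n_records += 1
        if (not aln.is_read1 or aln.is_unmapped or aln.is_secondary
                or aln.is_supplementary or not aln.is_proper_pair):
            stats.n_skipped += 1
            continue
        if aln.mapping_quality < min_mapq:
            stats.n_low_mapq += 1
            continue
        stats.n_first_mates += 1
        yield aln


def dedup_first_mates(alignments, stats: ExtractionStats | None = None):
    """Drop PCR duplicates: pairs sharing first-mate contig, leftmost
    position, strand and mate position beyond the first occurrence.

    This keys on fragment coordinates (both mates), approximating
    MarkDuplicates semantics without external tooling.
    """
    seen: set[tuple] = set()
    for aln in alignments:
        key = (aln.reference_id, aln.reference_start, aln.is_reverse,
               aln.next_reference_start)
        if key in seen:
            if stats is not None:
                stats.n_duplicates += 1
            continue
        seen.add(key)
        yield aln


def extract_events(
    sam_path: str | Path,
    genome: Genome,
    *,
    dedup: bool = True,
    min_mapq: int = 0,
    keep_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[CPDEvent], ExtractionStats]:
    """Run first-mate extraction over a SAM/BAM file.

    ``keep_fraction`` < 1 retains each first mate independently with that
    probability (seeded via ``rng``) before deduplication, emulating
    lower sequencing depth.
    """
    stats = ExtractionStats()
    events: list[CPDEvent] = []
    if keep_fraction < 1.0 and rng is None:
        rng = np.random.default_rng()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as bam:
        stream = _usable_first_mates(bam, min_mapq, stats)
        if keep_fraction < 1.0:
            stream = (a for a in stream if rng.random() < keep_fraction)
        if dedup:
            stream = dedup_first_mates(stream, stats)
        for aln in stream:
            ev = cpd_from_first_mate(aln, genome)
            if ev is None:
                stats.n_boundary_rejected += 1
                continue
            stats.n_events += 1
            events.append(ev)
    return events, stats


def filter_dipyrimidine(events) -> tuple[list[CPDEvent], Counter, int]:
    """Keep biologically possible CPDs; tally all 16 classes.

    Returns ``(retained, tally, n_with_N)``: events at dipyrimidines, a
    full dinucleotide tally (dipyrimidines included), and the count of
    events whose dinucleotide contains N (excluded from both).
    """
    tally: Counter = Counter()
    retained: list[CPDEvent] = []
    n_with_n = 0
    dipyr = set(DIPYRIMIDINES)
    for e in events:
        if "N" in e.dinuc:
            n_with_n += 1
            continue
        tally[e.dinuc] += 1
        if e.dinuc in dipyr:
            retained.append(e)
    return retained, tally, n_with_n


@dataclass
class LibrarySpectrum:
    """Per-dinucleotide detection rates for one library.

    ``rates[d] = raw[d] / (genomic[d] * depth) * 1e6`` -- detections per
    genomic occurrence of the class, per depth unit, scaled to a
    readable magnitude.  ``depth`` defaults to the library's retained
    (dipyrimidine) event total so that libraries of different size are
    comparable; the constant cancels in every ratio the pipeline takes.
    """

    label: str
    raw: dict[str, int]
    genomic: dict[str, int]
    depth: float
    rates: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self):
        if not self.rates:
            self.rates = {}
            for d in DINUCLEOTIDES:
                g = self.genomic.get(d, 0)
                if g == 0:
                    self.rates[d] = None          # undefined: no genomic occurrences
                else:
                    self.rates[d] = self.raw.get(d, 0) / (g * self.depth) * 1e6

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dinucleotide": list(DINUCLEOTIDES),
            "raw": [self.raw.get(d, 0) for d in DINUCLEOTIDES],
            "genomic": [self.genomic.get(d, 0) for d in DINUCLEOTIDES],
            "rate": [self.rates[d] for d in DINUCLEOTIDES],
        })


def spectrum(
    tally: Counter | dict,
    genome: Genome,
    label: str = "",
    depth: float | None = None,
    genomic_counts: dict | None = None,
) -> LibrarySpectrum:
    """Normalized dinucleotide spectrum from a 16-class tally."""
    genomic = dict(genomic_counts) if genomic_counts is not None else dict(genome.dinucleotide_counts())
    if depth is None:
        depth = sum(tally.get(d, 0) for d in DIPYRIMIDINES)
    if depth <= 0:
        depth = 1.0                               # empty library: rates all zero
    return LibrarySpectrum(label=label, raw=dict(tally), genomic=genomic, depth=float(depth))


def estimate_fpr(spec: LibrarySpectrum) -> dict[str, float]:
    """False-positive rate per dipyrimidine, as a percentage.

    Non-dipyrimidine detections can only be background (no CPD can form
    there), so the median non-dipyrimidine rate estimates the background
    level and ``FPR(d) = median_background / rate(d) * 100``.
    """
    bg = [spec.rates[d] for d in NON_DIPYRIMIDINES]
    if any(r is None for r in bg):
        raise ValueError("all 12 non-dipyrimidine rates must be defined")
    med = float(np.median(bg))
    out = {}
    for d in DIPYRIMIDINES:
        r = spec.rates[d]
        if not r:
            raise ValueError(f"rate for {d} is zero or undefined; FPR undefined")
        out[d] = med / r * 100.0
    return out


def subsample_scaling(
    sam_path: str | Path,
    genome: Genome,
    fractions=(0.25, 0.5, 0.75),
    seed: int = 0,
    *,
    min_mapq: int = 0,
    dedup: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Re-run the pipeline on random read subsets to probe depth scaling.

    Returns a table ``fraction -> unique dipyrimidine CPD count`` (always
    including 1.0 = full depth) and the linearity statistic: the maximum
    relative deviation of ``count / fraction`` from the full-depth count.
    """
    fractions = sorted(set(fractions))
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")

    def run(frac: float, rng=None) -> int:
        events, _ = extract_events(sam_path, genome, dedup=dedup, min_mapq=min_mapq,
                                   keep_fraction=frac, rng=rng)
        retained, _, _ = filter_dipyrimidine(events)
        return len(retained)

    full = run(1.0)
    rows = []
    max_dev = 0.0
    for i, f in enumerate(fractions):
        n = full if f == 1.0 else run(f, np.random.default_rng([seed, i]))
        scaled = n / f
        if f != 1.0 and full > 0:
            max_dev = max(max_dev, abs(scaled - full) / full)
        rows.append({"fraction": f, "unique_cpds": n, "scaled": scaled})
    if 1.0 not in fractions:
        rows.append({"fraction": 1.0, "unique_cpds": full, "scaled": float(full)})
    return pd.DataFrame(rows), max_dev
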