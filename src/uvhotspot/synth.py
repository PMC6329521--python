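"""Synthetic genomes, cohorts, CPD-seq read pairs and barcoded amplicons.

Every generator is seeded and bit-reproducible, and returns the ground
truth alongside the data so that each downstream stage has a closed-loop
test: planted TTCCG promoter motifs with known hotspot bases, cohorts
whose mutations follow a known trinucleotide signature with a known
per-base enrichment at planted hotspots, CPD-seq read pairs encoding a
known lesion list, and amplicon reads with known molecule-level variant
allele frequencies.

Hotspot enrichment is modelled as a per-base mutation-rate multiplier
``phi`` at planted hotspot bases -- the generative stand-in for elevated
dimer formation at protein-bound motifs.  Elevated lesion formation
itself is modelled in the read generator as a motif-local multiplier on
the lesion weight of the motif's key dinucleotides (the two bases 5' of
the TTCC core, and its middle TC), applied for "cellular" libraries and
absent (multiplier 1) for protein-free "naked DNA" libraries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .cpd import CPDEvent
from .genome import DINUCLEOTIDES, Genome, revcomp
from .io import MutationRecord, TssRecord
from .profiles import SBS96_KEYS, Trinuc96Signature

import pandas as pd

log = logging.getLogger(__name__)

_BASE = np.frombuffer(b"ACGTN", np.uint8)
_CODE = np.full(256, 4, np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

# hotspot base indices within each 7-mer (positions 0..6 = XX + TTCCG)
_HOTSPOT_IDX = {"CCTTCCG": (0, 1), "TCTTCCG": (1,), "CTTTCCG": (0,), "ACTTCCG": (4,)}
_DIPYR_CODES = frozenset({15, 13, 7, 5})          # TT, TC, CT, CC as 4*c0+c1


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), np.uint8)]


# ---------------------------------------------------------------------------
# UV-type mutational signature
# ---------------------------------------------------------------------------

def uv_signature(dipyrimidine_weight: float = 19.0,
                 other_ct_weight: float = 1.0,
                 noise_weight: float = 0.05) -> Trinuc96Signature:
    """A UV-like 96-channel signature: C>T dominated, dipyrimidine-biased.

    C>T classes whose 5' flank is a pyrimidine (the dipyrimidine
    contexts where dimers form) carry ``dipyrimidine_weight`` each;
    remaining C>T classes carry ``other_ct_weight``; every other class a
    small ``noise_weight``.  Weights are normalized to sum 1.
    """
    w = {}
    for k in SBS96_KEYS:
        f5, ref, alt = k[0], k[2], k[4]
        if ref == "C" and alt == "T":
            w[k] = dipyrimidine_weight if f5 in "CT" else other_ct_weight
        else:
            w[k] = noise_weight
    return Trinuc96Signature(pd.Series(w))


# ---------------------------------------------------------------------------
# genome with planted promoters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticGenomeSpec:
    n_contigs: int = 1
    contig_length: int = 450_000
    gc: float = 0.41
    # planted promoter counts per motif class; "none" = promoter without motif
    promoters: dict = field(default_factory=lambda: {
        "CCTTCCG": 82, "TCTTCCG": 57, "CTTTCCG": 27, "ACTTCCG": 44, "none": 90})
    motif_upstream_range: tuple[int, int] = (20, 200)
    seed: int = 0


@dataclass(frozen=True)
class PlantedPromoter:
    """Ground truth for one planted promoter."""

    gene_id: str
    chrom: str
    tss_pos: int
    gene_strand: str
    motif_class: str | None
    motif_start: int | None          # plus-strand leftmost base of the 7-mer
    motif_strand: str | None         # strand carrying the TTCCG (pyrimidine strand)
    hotspot_positions: tuple[int, ...]   # plus-strand coordinates of mutable Cs
    cpd_positions: tuple[tuple[int, str], ...]  # (pos5, strand) of key dinucleotides

    @property
    def ttccg_anchor(self) -> int | None:
        """Motif-strand position of the TTCCG's 5' T (profile offset 0)."""
        if self.motif_start is None:
            return None
        return self.motif_start + 2 if self.motif_strand == "+" else self.motif_start + 4


def gen_genome(spec: SyntheticGenomeSpec):
    """Random genome with planted promoters and TTCCG motifs.

    Returns ``(genome, tss_records, planted)``.  Each motif heptamer is
    written verbatim on its recorded strand within 20-200 bp upstream of
    its planted TSS; promoters are laid on a jittered grid so that
    neighbouring plants never overlap.
    """
    rng = np.random.default_rng(spec.seed)
    classes = [c for c, k in spec.promoters.items() for _ in range(k)]
    n_prom = len(classes)
    rng.shuffle(classes)
    per_contig = -(-n_prom // spec.n_contigs)
    spacing = spec.contig_length // (per_contig + 1)
    if spacing < 2 * (spec.motif_upstream_range[1] + 50):
        raise ValueError("promoters denser than contig capacity")
    p = [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    contigs: dict[str, np.ndarray] = {}
    for i in range(spec.n_contigs):
        contigs[f"chr{i + 1}"] = rng.choice(_BASE[:4], size=spec.contig_length, p=p)

    planted: list[PlantedPromoter] = []
    tss_records: list[TssRecord] = []
    for idx, cls in enumerate(classes):
        ci = idx // per_contig
        chrom = f"chr{ci + 1}"
        j = idx % per_contig
        tss = spacing * (j + 1) + int(rng.integers(-spacing // 4, spacing // 4 + 1))
        gene_strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{idx:04d}"
        tss_records.append(TssRecord(gene_id, chrom, tss, gene_strand))
        if cls == "none":
            planted.append(PlantedPromoter(gene_id, chrom, tss, gene_strand,
                                           None, None, None, (), ()))
            continue
        motif_strand = "+" if rng.random() < 0.5 else "-"
        d = int(rng.integers(*spec.motif_upstream_range))
        start = (tss - d - 7) if gene_strand == "+" else (tss + d + 1)
        hept = cls if motif_strand == "+" else revcomp(cls)
        contigs[chrom][start: start + 7] = np.frombuffer(hept.encode(), np.uint8)

        def g(i7: int) -> int:            # heptamer index -> plus-strand position
            return start + i7 if motif_strand == "+" else start + 6 - i7

        hot = tuple(sorted(g(i) for i in _HOTSPOT_IDX[cls]))
        cpd: list[tuple[int, str]] = []
        if cls != "ACTTCCG":              # 5'-flank dipyrimidine (heptamer 0-1)
            cpd.append((start if motif_strand == "+" else start + 6, motif_strand))
        cpd.append((start + 3, motif_strand))   # middle TC (heptamer 3-4)
        planted.append(PlantedPromoter(gene_id, chrom, tss, gene_strand, cls,
                                       start, motif_strand, hot, tuple(cpd)))
    genome = Genome({c: a.tobytes().decode() for c, a in contigs.items()})
    return genome, tss_records, planted


# ---------------------------------------------------------------------------
# cohort of tumors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    n_tumors: int = 221
    burden_median: float = 16.0          # per-tumor SNV count, log-normal median
    burden_sigma: float = 0.8            # log-normal sigma (natural log); 0 = fixed
    signature: Trinuc96Signature = field(default_factory=uv_signature)
    phi: float = 300.0                   # hotspot per-base rate multiplier, >= 1
    seed: int = 0

    def __post_init__(self):
        if self.phi < 1:
            raise ValueError("phi must be >= 1")


def _position_weights(genome: Genome, signature: Trinuc96Signature):
    """Per-position signature mass and conditional alt tables.

    Returns, per contig: weight array (mass of the position's pyrimidine
    trinucleotide context), plus genome-wide lookup tables mapping the
    64 plus-strand trinucleotide codes to cumulative alt probabilities
    and plus-strand alt bases.
    """
    ctx_w = signature.context_weights()
    w_table = np.zeros(64)
    alt_cum = np.zeros((64, 3))
    alt_chars = np.zeros((64, 3), dtype="U1")
    bases = "ACGT"
    for c0 in range(4):
        for c1 in range(4):
            for c2 in range(4):
                code = 16 * c0 + 4 * c1 + c2
                tri = bases[c0] + bases[c1] + bases[c2]
                pyr_tri = tri if tri[1] in "CT" else revcomp(tri)
                w_table[code] = ctx_w.get(pyr_tri, 0.0)
                ap = signature.alt_probs(pyr_tri)
                cum = np.cumsum(ap.values)
                alt_cum[code] = cum / cum[-1]
                alts = [k[4] for k in ap.index]
                if tri[1] not in "CT":    # map pyrimidine-strand alts back to plus
                    alts = [revcomp(a) for a in alts]
                alt_chars[code] = alts
    weights = {}
    codes = {}
    for chrom in genome:
        c = _encode(genome[chrom]).astype(np.int64)
        code = 16 * c[:-2] + 4 * c[1:-1] + c[2:]
        valid = (c[:-2] < 4) & (c[1:-1] < 4) & (c[2:] < 4)
        w = np.zeros(len(c))
        w[1:-1] = np.where(valid, w_table[code], 0.0)
        weights[chrom] = w
        cc = np.zeros(len(c), dtype=np.int64)
        cc[1:-1] = np.where(valid, code, 0)
        codes[chrom] = cc
    return weights, codes, alt_cum, alt_chars


def gen_cohort(genome: Genome, planted, spec: CohortSpec) -> list[MutationRecord]:
    """Simulate somatic SNVs for a cohort with planted hotspot enrichment.

    Background mutations are placed with probability proportional to the
    signature's mass on each position's trinucleotide context (hence
    weighted by genomic context counts); each tumor's count follows the
    log-normal burden distribution, sampled without within-tumor site
    collisions.  Each planted hotspot base additionally mutates (C>T on
    its pyrimidine strand) with probability
    ``min(1, (phi - 1) * burden * w_base / W)``, on top of its ordinary
    background chance -- so ``phi = 1`` leaves hotspot bases
    statistically indistinguishable from matched-context background.
    """
    rng = np.random.default_rng(spec.seed)
    weights, codes, alt_cum, alt_chars = _position_weights(genome, spec.signature)
    chroms = list(genome)
    offsets = np.cumsum([0] + [genome.length(c) for c in chroms])
    flat_w = np.concatenate([weights[c] for c in chroms])
    W = flat_w.sum()
    if W <= 0:
        raise ValueError("signature has no support on this genome")
    cum = np.cumsum(flat_w)

    hot_flat = []
    for pp in planted:
        ci = chroms.index(pp.chrom)
        for pos in pp.hotspot_positions:
            hot_flat.append(offsets[ci] + pos)
    hot_flat = np.asarray(hot_flat, dtype=np.int64)
    hot_w = flat_w[hot_flat] if len(hot_flat) else np.empty(0)

    max_extra = (spec.phi - 1) * spec.burden_median * np.exp(3 * spec.burden_sigma)
    if len(hot_flat) and hot_w.max() * max_extra / W > 1:
        log.warning("phi so large that hotspot rates are capped at 1 per tumor per base")

    def decode(flat_pos: np.ndarray):
        ci = np.searchsorted(offsets, flat_pos, "right") - 1
        return ci, flat_pos - offsets[ci]

    records: list[MutationRecord] = []
    for t in range(spec.n_tumors):
        sample = f"tumor{t:03d}"
        if spec.burden_sigma > 0:
            burden = max(1, int(round(rng.lognormal(np.log(spec.burden_median),
                                                    spec.burden_sigma))))
        else:
            burden = int(round(spec.burden_median))
        # draw distinct background sites (rejection on collisions)
        taken: set[int] = set()
        while len(taken) < burden:
            need = burden - len(taken)
            for fp in np.searchsorted(cum, rng.random(need) * W, "right"):
                if len(taken) < burden:
                    taken.add(int(fp))
        sites = np.fromiter(taken, dtype=np.int64, count=burden)
        ci_arr, pos_arr = decode(sites)
        for ci, pos, u in zip(ci_arr, pos_arr, rng.random(len(sites))):
            chrom = chroms[ci]
            code = codes[chrom][pos]
            k = int(np.searchsorted(alt_cum[code], u, "right"))
            k = min(k, 2)
            ref = genome[chrom][pos]
            alt = str(alt_chars[code][k])
            records.append(MutationRecord(chrom, int(pos), ref, alt, sample))
        # planted hotspot extras
        if len(hot_flat) and spec.phi > 1:
            p_extra = np.clip((spec.phi - 1) * burden * hot_w / W, 0, 1)
            hits = hot_flat[rng.random(len(hot_flat)) < p_extra]
            for fp in hits:
                if int(fp) in taken:
                    continue
                taken.add(int(fp))
                ci = int(np.searchsorted(offsets, fp, "right") - 1)
                pos = int(fp - offsets[ci])
                chrom = chroms[ci]
                ref = genome[chrom][pos]
                alt = "T" if ref == "C" else "A"      # C>T on the pyrimidine strand
                records.append(MutationRecord(chrom, pos, ref, alt, sample))
    return records


# ---------------------------------------------------------------------------
# CPD-seq read pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpdReadSpec:
    n_fragments: int = 100_000
    fragment_length_mean: float = 400.0
    fragment_length_sd: float = 50.0
    read_length: int = 75
    # relative lesion-formation weight per dinucleotide (missing = 0)
    lesion_weights: dict = field(default_factory=lambda: {
        "TT": 1.0, "TC": 0.35, "CT": 0.25, "CC": 0.10})
    motif_multiplier: float = 10.0       # cellular libraries; 1.0 emulates naked DNA
    background_rate: float = 0.10        # fraction of lesions at non-dipyrimidines
    duplicate_fraction: float = 0.0      # extra PCR-duplicate pairs emitted
    seed: int = 0


@dataclass(frozen=True, slots=True)
class LesionTruth:
    event: CPDEvent
    background: bool


def gen_cpd_reads(genome: Genome, planted, spec: CpdReadSpec, sam_path):
    """Write aligned CPD-seq read pairs (SAM) encoding sampled lesions.

    Lesion positions are sampled per strand with probability proportional
    to the dinucleotide lesion weight, multiplied by ``motif_multiplier``
    at the planted motifs' key dinucleotides; a ``background_rate``
    fraction is placed uniformly at non-dipyrimidine positions instead.
    Each fragment encodes one lesion at its ligation end with paired
    2 x ``read_length`` reads; fragments that would not fit the contig
    have their length clipped.  Returns the truth lesion list.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.read_length
    margin = int(spec.fragment_length_mean + 5 * spec.fragment_length_sd + r)
    w16 = np.zeros(16)
    for d, wt in spec.lesion_weights.items():
        w16[DINUCLEOTIDES.index(d)] = wt

    mult: dict[str, dict[str, np.ndarray]] = {}
    for pp in planted:
        for pos5, strand in pp.cpd_positions:
            mult.setdefault(pp.chrom, {"+": [], "-": []})[strand].append(pos5)

    chroms = list(genome)
    w_all = []
    bg_all = []                       # rows (chrom_index, pos5, strand_is_plus)
    for ci, chrom in enumerate(chroms):
        c = _encode(genome[chrom]).astype(np.int64)
        L = len(c)
        valid = np.zeros(L, bool)
        valid[:-1] = (c[:-1] < 4) & (c[1:] < 4)
        plus_code = np.zeros(L, np.int64)
        plus_code[:-1] = 4 * c[:-1] + c[1:]
        wp = np.where(valid, w16[plus_code], 0.0)
        minus_code = np.zeros(L, np.int64)
        minus_code[1:] = 4 * (3 - c[1:]) + (3 - c[:-1])
        validm = np.zeros(L, bool)
        validm[1:] = (c[1:] < 4) & (c[:-1] < 4)
        wm = np.where(validm, w16[minus_code], 0.0)
        if chrom in mult:
            for p in mult[chrom]["+"]:
                wp[p] *= spec.motif_multiplier
            for p in mult[chrom]["-"]:
                wm[p] *= spec.motif_multiplier
        edge = np.zeros(L, bool)
        edge[margin: L - margin] = True
        wp = np.where(edge, wp, 0.0)
        wm = np.where(edge, wm, 0.0)
        w_all.append(np.concatenate([wp, wm]))
        for code_arr, vmask, strand_plus in ((plus_code, valid & edge, 1),
                                             (minus_code, validm & edge, 0)):
            nd = vmask & ~np.isin(code_arr, list(_DIPYR_CODES))
            idx = np.nonzero(nd)[0]
            bg_all.append(np.stack([np.full(len(idx), ci), idx,
                                    np.full(len(idx), strand_plus)], axis=1))

    flat_w = np.concatenate(w_all)
    Wtot = flat_w.sum()
    if Wtot <= 0:
        raise ValueError("lesion weights give zero total mass")
    cumw = np.cumsum(flat_w)
    contig_sizes = [genome.length(c) for c in chroms]
    block = np.cumsum([0] + [2 * s for s in contig_sizes])
    bg_pool = np.concatenate(bg_all) if bg_all else np.empty((0, 3), np.int64)

    n_bg = rng.binomial(spec.n_fragments, spec.background_rate) if spec.background_rate else 0
    n_sig = spec.n_fragments - n_bg

    lesions: list[tuple[int, int, bool, bool]] = []   # (ci, pos5, plus_strand, is_bg)
    draws = np.searchsorted(cumw, rng.random(n_sig) * Wtot, "right")
    for fp in draws:
        ci = int(np.searchsorted(block, fp, "right") - 1)
        rel = fp - block[ci]
        L = contig_sizes[ci]
        plus_strand = rel < L
        pos5 = int(rel if plus_strand else rel - L)
        lesions.append((ci, pos5, bool(plus_strand), False))
    if n_bg:
        picks = bg_pool[rng.integers(0, len(bg_pool), n_bg)]
        for ci, pos5, sp in picks:
            lesions.append((int(ci), int(pos5), bool(sp), True))
    order = rng.permutation(len(lesions))
    lesions = [lesions[i] for i in order]

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in chroms],
    })
    truth: list[LesionTruth] = []
    frag_coords: list[tuple] = []
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        lengths = np.clip(rng.normal(spec.fragment_length_mean,
                                     spec.fragment_length_sd,
                                     len(lesions)).round().astype(int),
                          2 * r, margin - r)
        for i, ((ci, pos5, plus_strand, is_bg), L) in enumerate(zip(lesions, lengths)):
            chrom = chroms[ci]
            L = int(L)
            if plus_strand:
                # plus-strand lesion at (pos5, pos5+1): first mate minus,
                # rightmost base pos5 - 1, fragment on [pos5 - L, pos5)
                m1_start, m1_end = pos5 - r, pos5
                m2_start = pos5 - L
                coords = (ci, m1_start, True, m2_start)
                _write_pair(out, genome, f"frag{i:08d}", chrom,
                            m1_start, m2_start, r, L, first_reverse=True)
            else:
                # minus-strand lesion at (pos5-1, pos5): first mate plus,
                # leftmost base pos5 + 1, fragment on [pos5+1, pos5+1+L)
                m1_start = pos5 + 1
                m2_start = m1_start + L - r
                coords = (ci, m1_start, False, m2_start)
                _write_pair(out, genome, f"frag{i:08d}", chrom,
                            m1_start, m2_start, r, L, first_reverse=False)
            frag_coords.append(coords)
            dinuc = genome.dinucleotide_at(chrom, pos5, "+" if plus_strand else "-")
            truth.append(LesionTruth(
                CPDEvent(chrom, pos5, "+" if plus_strand else "-", dinuc), is_bg))
        if spec.duplicate_fraction > 0:
            n_dup = int(round(spec.duplicate_fraction * len(frag_coords)))
            for j, k in enumerate(rng.integers(0, len(frag_coords), n_dup)):
                ci, m1_start, first_reverse, m2_start = frag_coords[k]
                chrom = chroms[ci]
                L = abs(m2_start - m1_start) + r
                _write_pair(out, genome, f"dup{j:07d}", chrom,
                            m1_start, m2_start, r,
                            L, first_reverse=first_reverse)
    return truth


def _write_pair(out, genome, name, chrom, m1_start, m2_start, r, L, first_reverse):
    tid = out.header.references.index(chrom)
    a = pysam.AlignedSegment(out.header)
    b = pysam.AlignedSegment(out.header)
    for seg in (a, b):
        seg.query_name = name
        seg.reference_id = tid
        seg.next_reference_id = tid
        seg.mapping_quality = 60
        seg.cigar = [(0, r)]
    if first_reverse:
        a.flag = 83          # paired, proper, reverse, first
        b.flag = 163         # paired, proper, mate reverse, second
        a.template_length = -L
        b.template_length = L
    else:
        a.flag = 99
        b.flag = 147
        a.template_length = L
        b.template_length = -L
    a.reference_start = m1_start
    b.reference_start = m2_start
    a.next_reference_start = m2_start
    b.next_reference_start = m1_start
    seq1 = genome.fetch(chrom, m1_start, m1_start + r)
    seq2 = genome.fetch(chrom, m2_start, m2_start + r)
    a.query_sequence = revcomp(seq1) if first_reverse else seq1
    b.query_sequence = seq2 if first_reverse else revcomp(seq2)
    a.query_qualities = pysam.qualitystring_to_array("I" * r)
    b.query_qualities = pysam.qualitystring_to_array("I" * r)
    out.write(a)
    out.write(b)


# ---------------------------------------------------------------------------
# barcoded amplicon reads
# ---------------------------------------------------------------------------

# Synthetic 46 bp amplicon window: a stand-in promoter fragment carrying a
# CCTTCCG element at positions 16..22, hotspot cytosines at 16 and 17.
DEFAULT_AMPLICON = "ATGACGTCAGGTTACACCTTCCGAGGCTATCGGATCTTAGCAAGTC"
assert len(DEFAULT_AMPLICON) == 46 and DEFAULT_AMPLICON[16:23] == "CCTTCCG"


@dataclass(frozen=True)
class AmpliconSpec:
    amplicon: str = DEFAULT_AMPLICON
    # position -> {alt: molecule-level VAF}; VAFs must lie in [0, 0.05]
    truth_vafs: dict = field(default_factory=lambda: {17: {"T": 0.004}})
    n_molecules: int = 10_000
    barcode_length: int = 12
    family_size_model: str = "poisson"   # or "fixed"
    family_size_mean: float = 30.0
    error_rate: float = 1e-3             # per base, applied to barcode + insert
    seed: int = 0

    def __post_init__(self):
        for pos, alts in self.truth_vafs.items():
            for alt, v in alts.items():
                if not 0 <= v <= 0.05:
                    raise ValueError("truth VAFs must lie in [0, 0.05]")
                if self.amplicon[pos] == alt:
                    raise ValueError(f"alt equals reference at position {pos}")


def gen_amplicon_reads(spec: AmpliconSpec, fastq_path) -> pd.DataFrame:
    """Write barcoded amplicon reads (FASTQ); return the molecule truth.

    Each molecule gets a random barcode, its variants drawn from the
    molecule-level truth VAFs, and a family of reads (barcode + insert)
    with independent per-base sequencing errors.  Barcode collisions are
    allowed and logged.  The returned frame has one row per molecule:
    barcode, family size and the variant carried (if any).
    """
    rng = np.random.default_rng(spec.seed)
    amp = _encode(spec.amplicon)
    L = spec.barcode_length + len(spec.amplicon)
    rows = []
    with open(fastq_path, "w") as fh:
        for m in range(spec.n_molecules):
            bc = _BASE[rng.integers(0, 4, spec.barcode_length)]
            mol = amp.copy()
            variant = ""
            for pos, alts in spec.truth_vafs.items():
                for alt, v in alts.items():
                    if rng.random() < v:
                        mol[pos] = _CODE[ord(alt)]
                        variant = f"{pos}{spec.amplicon[pos]}>{alt}"
            if spec.family_size_model == "fixed":
                size = int(spec.family_size_mean)
            else:
                size = max(1, int(rng.poisson(spec.family_size_mean)))
            full = np.concatenate([bc, _BASE[mol]])
            reads = np.tile(full, (size, 1))
            if spec.error_rate > 0:
                err = rng.random((size, L)) < spec.error_rate
                n_err = int(err.sum())
                if n_err:
                    shifts = rng.integers(1, 4, n_err).astype(np.uint8)
                    codes = _CODE[reads[err]]
                    reads[err] = _BASE[(codes + shifts) % 4]
            qual = "I" * L
            bcs = bc.tobytes().decode()
            for k in range(size):
                fh.write(f"@mol{m:06d}_r{k:03d}\n{reads[k].tobytes().decode()}\n+\n{qual}\n")
            rows.append({"molecule": m, "barcode": bcs, "size": size,
                         "variant": variant})
    df = pd.DataFrame(rows)
    n_coll = df["barcode"].duplicated().sum()
    if n_coll:
        log.info("%d barcode collisions among %d molecules", n_coll, len(df))
    return df
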