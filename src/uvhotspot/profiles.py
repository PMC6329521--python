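"""Density meta-profiles around anchors, and expected-count null models.

Anchors are hotspot bases, TTCCG motif starts or transcription starts.
Offset 0 is the anchored base and offsets increase 3' on the orienting
strand (the site's pyrimidine strand, the motif strand, or the gene
strand), so that minus-strand anchors are flipped before aggregation.
Profiles carry raw summed counts plus a per-anchor divisor and an
optional cross-library scale factor; normalization is applied lazily.

The null models mirror the observed data: the same number of mutations
(or lesions) as observed is re-placed at random, with per-position
probability proportional to the trinucleotide mutational signature (or
the per-dinucleotide lesion weights), then binned identically.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import DIPYRIMIDINES, Genome, PYRIMIDINES, revcomp

_BASES = "ACGT"
_ALTS = {"C": ("A", "G", "T"), "T": ("A", "C", "G")}
SBS96_KEYS = tuple(
    f"{f5}[{ref}>{alt}]{f3}"
    for ref in "CT" for alt in _ALTS[ref] for f5 in _BASES for f3 in _BASES
)


# ---------------------------------------------------------------------------
# 96-channel trinucleotide signature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trinuc96Signature:
    """Probabilities over the 96 pyrimidine-centred substitution classes."""

    probs: pd.Series           # index = SBS96_KEYS, sums to 1

    def __post_init__(self):
        p = self.probs.reindex(SBS96_KEYS).fillna(0.0).astype(float)
        if (p < 0).any():
            raise ValueError("signature probabilities must be >= 0")
        tot = p.sum()
        if tot <= 0:
            raise ValueError("signature has zero mass")
        object.__setattr__(self, "probs", p / tot)

    @staticmethod
    def key(f5: str, ref: str, alt: str, f3: str) -> str:
        return f"{f5}[{ref}>{alt}]{f3}"

    def context_weights(self) -> pd.Series:
        """Total mass per pyrimidine-centred trinucleotide (32 contexts)."""
        ctx = defaultdict(float)
        for k, v in self.probs.items():
            ctx[k[0] + k[2] + k[6]] += v
        return pd.Series(ctx)

    def alt_probs(self, context: str) -> pd.Series:
        """Conditional alt distribution given a pyrimidine trinucleotide."""
        ref = context[1]
        keys = [self.key(context[0], ref, a, context[2]) for a in _ALTS[ref]]
        sub = self.probs[keys]
        tot = sub.sum()
        if tot == 0:
            return pd.Series(1 / 3, index=keys)
        return sub / tot

    def l1(self, other: "Trinuc96Signature") -> float:
        return float((self.probs - other.probs).abs().sum())


def signature_from_cohort(mutations, genome: Genome) -> Trinuc96Signature:
    """Observed 96-class signature, normalized for genomic trinucleotide
    background frequencies and rescaled to sum 1.

    Mutations whose context contains N are skipped (counted in the log).
    """
    counts = pd.Series(0.0, index=SBS96_KEYS)
    n_skipped = 0
    for m in mutations:
        ctx = genome.fetch_padded(m.chrom, m.pos - 1, m.pos + 2,
                                  strand=m.pyrimidine_strand)
        if "N" in ctx:
            n_skipped += 1
            continue
        counts[Trinuc96Signature.key(ctx[0], m.pyr_ref, m.pyr_alt, ctx[2])] += 1
    if counts.sum() == 0:
        raise ValueError("no usable mutations after N-filtering")
    bg = genome.trinucleotide_counts()
    freq = pd.Series(0.0, index=SBS96_KEYS)
    for k, c in counts.items():
        g = bg.get(k[0] + k[2] + k[6], 0)
        if g:
            freq[k] = c / g
    return Trinuc96Signature(freq)


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Binned, strand-aware counts around aligned anchors.

    ``offsets`` holds the left edge of each bin (bin width
    ``bin_width``); ``counts`` the summed events per bin.  Normalization
    divides by ``n_anchors`` and multiplies by ``scale`` (cross-library
    comparability factor, default 1).
    """

    offsets: np.ndarray
    counts: np.ndarray
    bin_width: int
    n_anchors: int
    scale: float = 1.0
    n_truncated: int = 0
    extra: dict = field(default_factory=dict)

    def normalized(self) -> np.ndarray:
        return self.counts * self.scale / max(self.n_anchors, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "count": self.counts,
                             "normalized": self.normalized()})

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def _positions_by_chrom(items, per_base_cpd: bool):
    """Sorted position arrays per chromosome from mutations or CPD events.

    CPD events contribute at their 5' base; with ``per_base_cpd`` both
    dimer bases contribute.
    """
    by: dict[str, list[int]] = defaultdict(list)
    for it in items:
        if hasattr(it, "pos5"):
            by[it.chrom].append(it.pos5)
            if per_base_cpd:
                by[it.chrom].append(it.pos5 + 1 if it.strand == "+" else it.pos5 - 1)
        else:
            by[it.chrom].append(it.pos)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by.items()}


def profile_at_sites(items, sites, window: int = 500, *,
                     per_base_cpd: bool = False,
                     genome: Genome | None = None) -> DensityProfile:
    """Single-base profile around hotspot sites on their pyrimidine strand.

    Each site's +/-``window`` neighborhood is read on the site's
    pyrimidine strand (offsets flipped for minus-strand sites) and
    summed; the divisor is the number of sites.  Windows truncated by a
    contig edge are flagged when a genome is supplied.
    """
    positions = _positions_by_chrom(items, per_base_cpd)
    counts = np.zeros(2 * window + 1, dtype=float)
    n_trunc = 0
    sites = list(sites)
    for s in sites:
        if genome is not None:
            if s.pos - window < 0 or s.pos + window >= genome.length(s.chrom):
                n_trunc += 1
        arr = positions.get(s.chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, s.pos - window, "left")
        hi = np.searchsorted(arr, s.pos + window, "right")
        off = arr[lo:hi] - s.pos
        if s.pyrimidine_strand == "-":
            off = -off
        np.add.at(counts, off + window, 1)
    return DensityProfile(np.arange(-window, window + 1), counts, 1,
                          len(sites), n_truncated=n_trunc)


def profile_by_motif_class(events, loci, motif_class: str, window: int = 20, *,
                           per_base_cpd: bool = False) -> dict[str, DensityProfile]:
    """Strand-specific CPD profiles anchored at the TTCCG motif start.

    Offset 0 is the 5' T of the TTCCG on the motif strand; the two
    flanking bases of the CC/TC/CT + TTCCG heptamers sit at offsets -2
    and -1, the TTCC core at 0..3.  Returns profiles for events on the
    motif strand and on the opposite strand.
    """
    sel = [l for l in loci if l.motif_class == motif_class]
    by: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for e in events:
        by[e.chrom].append((e.pos5, e.strand))
        if per_base_cpd:
            by[e.chrom].append((e.pos5 + 1 if e.strand == "+" else e.pos5 - 1, e.strand))
    arrs = {}
    for c, v in by.items():
        pos = np.asarray([p for p, _ in v], dtype=np.int64)
        strands = np.asarray([s == "+" for _, s in v])
        order = np.argsort(pos, kind="stable")
        arrs[c] = (pos[order], strands[order])
    size = 2 * window + 1
    same = np.zeros(size)
    opp = np.zeros(size)
    for l in sel:
        if l.chrom not in arrs:
            continue
        pos, plus = arrs[l.chrom]
        lo = np.searchsorted(pos, l.anchor_pos - window, "left")
        hi = np.searchsorted(pos, l.anchor_pos + window, "right")
        off = pos[lo:hi] - l.anchor_pos
        on_plus = plus[lo:hi]
        if l.strand == "-":
            off = -off
        same_mask = on_plus == (l.strand == "+")
        np.add.at(same, off[same_mask] + window, 1)
        np.add.at(opp, off[~same_mask] + window, 1)
    offs = np.arange(-window, window + 1)
    n = len(sel)
    return {"motif_strand": DensityProfile(offs, same, 1, n),
            "opposite_strand": DensityProfile(offs, opp, 1, n)}


def library_scale(profile_a: DensityProfile, profile_b: DensityProfile,
                  total_a: float, total_b: float) -> tuple[DensityProfile, DensityProfile]:
    """Scale library B onto library A's depth via genome-wide totals.

    Returns ``(profile_a, scaled_b)``; the unnormalized counts of B are
    retained, only its ``scale`` changes by ``total_a / total_b``.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    scaled = replace(profile_b, scale=profile_b.scale * total_a / total_b)
    return profile_a, scaled


def tss_binned_profile(items, tss_list, window: int = 1000, bin_width: int = 20, *,
                       genome: Genome | None = None,
                       exclude_ttccg: bool = False) -> DensityProfile:
    """Orientation-adjusted binned density around transcription starts.

    Every gene contributes its own window (aggregate semantics: an event
    near two TSSs counts in both).  Bins tile ``[-window, window)``;
    negative offsets are upstream of the gene.  With ``exclude_ttccg``
    (needs ``genome``), mutations whose +/-10 bp pyrimidine-strand
    context contains TTCCG are removed first -- the "delta-TTCCG"
    variant that isolates the motif-independent background.
    """
    if window % bin_width:
        raise ValueError("bin width must divide the window")
    items = list(items)
    if exclude_ttccg:
        if genome is None:
            raise ValueError("exclude_ttccg requires a genome")
        from .hotspots import annotate_ttccg
        items = [m for m in items
                 if not annotate_ttccg(genome, m.chrom, m.pos, m.pyrimidine_strand)[0]]
    positions = _positions_by_chrom(items, per_base_cpd=False)
    nbins = 2 * window // bin_width
    counts = np.zeros(nbins)
    tss_list = list(tss_list)
    for t in tss_list:
        arr = positions.get(t.chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, t.tss_pos - window, "left")
        hi = np.searchsorted(arr, t.tss_pos + window, "left")
        off = arr[lo:hi] - t.tss_pos
        if t.strand == "-":
            off = -off
        valid = (off >= -window) & (off < window)
        np.add.at(counts, (off[valid] + window) // bin_width, 1)
    offsets = np.arange(-window, window, bin_width)
    return DensityProfile(offsets, counts, bin_width, len(tss_list))


# ---------------------------------------------------------------------------
# expected-count null models
# ---------------------------------------------------------------------------

def _binned_from_placements(weights: np.ndarray, n_observed: int, rng,
                            nbins: int, bin_of: np.ndarray,
                            replicates: int) -> tuple[np.ndarray, np.ndarray]:
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total placement probability in the windows")
    p = weights / total
    mats = np.empty((replicates, nbins))
    for r in range(replicates):
        draws = rng.multinomial(n_observed, p)
        mats[r] = np.bincount(bin_of, weights=draws, minlength=nbins)
    return mats.mean(axis=0), mats


def expected_mutation_profile(window_sequences, signature: Trinuc96Signature,
                              n_observed: int, seed: int, *,
                              window: int = 1000, bin_width: int = 20,
                              replicates: int = 100) -> DensityProfile:
    """Null mutation profile: re-place the observed count by signature.

    ``window_sequences`` are the aligned windows (one string of length
    ``2 * window`` per anchor, 5'->3' along the orienting strand,
    covering offsets ``[-window, window)``).  Exactly ``n_observed``
    mutations are placed per replicate, with per-position probability
    proportional to the signature's mass on that position's trinucleotide
    context; the mean profile plus 2.5/97.5 percentiles over replicates
    is returned.  A single replicate reproduces the plain one-draw null.
    """
    ctx_w = signature.context_weights()
    weights, bin_of = [], []
    nbins = 2 * window // bin_width
    for seq in window_sequences:
        if len(seq) != 2 * window:
            raise ValueError("window sequence length must equal 2*window")
        for i in range(len(seq)):
            if i == 0 or i == len(seq) - 1:
                w = 0.0
            else:
                tri = seq[i - 1: i + 2]
                if "N" in tri:
                    w = 0.0
                else:
                    if tri[1] not in PYRIMIDINES:
                        tri = revcomp(tri)
                    w = float(ctx_w.get(tri, 0.0))
            weights.append(w)
            bin_of.append(i // bin_width)
    rng = np.random.default_rng(seed)
    mean, mats = _binned_from_placements(np.asarray(weights), n_observed, rng,
                                         nbins, np.asarray(bin_of), replicates)
    lo, hi = np.percentile(mats, [2.5, 97.5], axis=0)
    return DensityProfile(np.arange(-window, window, bin_width), mean, bin_width,
                          len(window_sequences),
                          extra={"lo": lo, "hi": hi,
                                 "replicate_totals": mats.sum(axis=1)})


def expected_cpd_profile(window_sequences, n_observed: int, seed: int, *,
                         window: int = 1000, bin_width: int = 20,
                         dinuc_weights: dict[str, float] | None = None,
                         replicates: int = 100) -> DensityProfile:
    """Null CPD profile: re-place the observed lesion count by dinucleotide.

    Default weights are 1 for every dipyrimidine and 0 elsewhere; pass a
    library's normalized spectrum rates to condition on observed
    genome-wide lesion propensities instead.  A position's weight sums
    the class weights of the dinucleotides whose 5' base sits there on
    either strand.
    """
    if dinuc_weights is None:
        dinuc_weights = {d: 1.0 for d in DIPYRIMIDINES}
    weights, bin_of = [], []
    nbins = 2 * window // bin_width
    for seq in window_sequences:
        if len(seq) != 2 * window:
            raise ValueError("window sequence length must equal 2*window")
        for i in range(len(seq)):
            w = 0.0
            if i + 2 <= len(seq):
                w += dinuc_weights.get(seq[i: i + 2], 0.0) or 0.0
            if i >= 1:
                w += dinuc_weights.get(revcomp(seq[i - 1: i + 1]), 0.0) or 0.0
            weights.append(w)
            bin_of.append(i // bin_width)
    rng = np.random.default_rng(seed)
    mean, mats = _binned_from_placements(np.asarray(weights), n_observed, rng,
                                         nbins, np.asarray(bin_of), replicates)
    lo, hi = np.percentile(mats, [2.5, 97.5], axis=0)
    return DensityProfile(np.arange(-window, window, bin_width), mean, bin_width,
                          len(window_sequences),
                          extra={"lo": lo, "hi": hi,
                                 "replicate_totals": mats.sum(axis=1)})
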