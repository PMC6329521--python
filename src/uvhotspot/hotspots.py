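"""Recurrence catalog of promoter mutation hotspots and TTCCG annotation.

A hotspot is an individual genomic base mutated in several distinct
tumors.  Each catalogued site carries its recurrence, orientation-
adjusted distance to the nearest transcription start, the +/-10 bp
sequence context read on the pyrimidine strand, whether that context
contains a TTCCG element (the reverse complement of the ETS-family
GGAA(G) core), and a motif class describing where the mutated base sits
relative to the element:

* ``CCTTCCG`` / ``TCTTCCG`` / ``CTTTCCG`` -- the mutated cytosine lies
  one or two bases 5' of the TTCCG, inside the named heptamer;
* ``TTCCG-internal`` -- the mutated base lies inside the TTCC core;
* ``other`` -- a TTCCG is present in context but the mutated base is
  elsewhere.
"""
from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Genome, PURINES
from .io import MutationRecord, TssRecord

MOTIF = "TTCCG"
FLANK_CLASSES = ("CCTTCCG", "TCTTCCG", "CTTTCCG")


@dataclass(frozen=True, slots=True)
class HotspotSite:
    chrom: str
    pos: int
    n: int
    pyrimidine_strand: str
    context_21: str
    ttccg_flag: bool
    tss_distance: int
    nearest_gene: str
    motif_class: str | None


@dataclass(frozen=True, slots=True)
class MotifLocus:
    """A deduplicated TTCCG locus anchoring one or more hotspot bases.

    ``ttccg_start`` is the plus-strand leftmost base of the TTCCG
    pentamer; ``anchor_pos`` is the position of its 5' T on the motif
    strand (equal to ``ttccg_start`` on plus, ``ttccg_start + 4`` on
    minus), which is offset 0 in motif-centred profiles.
    """

    chrom: str
    ttccg_start: int
    strand: str
    motif_class: str
    n_total: int
    sites: tuple[tuple[int, int], ...]      # (pos, n) per member base

    @property
    def anchor_pos(self) -> int:
        return self.ttccg_start if self.strand == "+" else self.ttccg_start + 4


# ---------------------------------------------------------------------------
# recurrence
# ---------------------------------------------------------------------------

def recurrence_table(mutations) -> dict[tuple[str, int], int]:
    """Distinct tumors mutated per base; a tumor contributes at most 1."""
    seen: dict[tuple[str, int], set[str]] = defaultdict(set)
    for m in mutations:
        seen[(m.chrom, m.pos)].add(m.sample_id)
    return {k: len(v) for k, v in seen.items()}


# ---------------------------------------------------------------------------
# nearest TSS
# ---------------------------------------------------------------------------

class TssIndex:
    """Sorted per-chromosome TSS arrays for nearest-neighbor queries.

    Equidistant genes break toward the lexicographically smaller
    ``gene_id``.
    """

    def __init__(self, tss_list):
        tss_list = list(tss_list)
        if not tss_list:
            raise ValueError("TSS list is empty")
        by_chrom: dict[str, list[TssRecord]] = defaultdict(list)
        for t in tss_list:
            by_chrom[t.chrom].append(t)
        self._pos: dict[str, list[int]] = {}
        self._recs: dict[str, list[TssRecord]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda t: (t.tss_pos, t.gene_id))
            self._pos[chrom] = [t.tss_pos for t in recs]
            self._recs[chrom] = recs

    def nearest(self, chrom: str, pos: int) -> tuple[int, str]:
        """Signed, orientation-adjusted distance to the nearest TSS.

        Negative means upstream of the gene: ``pos - tss`` for
        plus-strand genes, ``tss - pos`` for minus-strand genes.
        """
        if chrom not in self._pos:
            raise KeyError(f"no TSS on contig {chrom!r}")
        positions = self._pos[chrom]
        recs = self._recs[chrom]
        i = bisect.bisect_left(positions, pos)
        cands = []
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(recs):
                cands.append(recs[j])
        best = min(cands, key=lambda t: (abs(pos - t.tss_pos), t.gene_id))
        dist = pos - best.tss_pos if best.strand == "+" else best.tss_pos - pos
        return dist, best.gene_id


def tss_distance(chrom: str, pos: int, tss_list) -> tuple[int, str]:
    """Convenience wrapper building a throwaway :class:`TssIndex`."""
    return TssIndex(tss_list).nearest(chrom, pos)


# ---------------------------------------------------------------------------
# TTCCG annotation and motif classification
# ---------------------------------------------------------------------------

def pyrimidine_strand_of_base(genome: Genome, chrom: str, pos: int) -> str | None:
    base = genome.base(chrom, pos)
    if base == "N":
        return None
    return "-" if base in PURINES else "+"


def annotate_ttccg(genome: Genome, chrom: str, pos: int,
                   pyr_strand: str) -> tuple[bool, str]:
    """+/-10 bp context on the pyrimidine strand and the TTCCG flag.

    Near contig edges the context is padded with N and the flag is
    computed on the available bases.
    """
    ctx = genome.fetch_padded(chrom, pos - 10, pos + 11, strand=pyr_strand)
    return MOTIF in ctx, ctx


def _motif_occurrences(context: str) -> list[int]:
    out, i = [], context.find(MOTIF)
    while i != -1:
        out.append(i)
        i = context.find(MOTIF, i + 1)
    return out


def motif_anchor(context_21: str) -> tuple[str, int]:
    """Classify the central base against TTCCG occurrences in context.

    Returns ``(motif_class, ttccg_context_index)``.  The center of the
    21-mer (index 10) is the mutated base.  Flank placement (center 1 or
    2 bp 5' of a TTCCG start, i.e. starts at index 11 or 12) takes
    priority, naming the heptamer when it is CC/TC/CT + TTCCG; next a
    TTCCG whose TTCC core covers the center gives ``TTCCG-internal``;
    any other arrangement is ``other``.
    """
    occ = _motif_occurrences(context_21)
    if not occ:
        raise ValueError("context has no TTCCG element")
    for s in occ:
        if s in (11, 12):
            hept = context_21[s - 2: s + 5]
            return (hept, s) if hept in FLANK_CLASSES else ("other", s)
    for s in occ:
        if s <= 10 <= s + 3:
            return "TTCCG-internal", s
    return "other", occ[0]


def classify_motif(site_or_context) -> str:
    """Motif class of a hotspot site (precondition: TTCCG in context)."""
    ctx = site_or_context if isinstance(site_or_context, str) else site_or_context.context_21
    return motif_anchor(ctx)[0]


def _ttccg_genomic_start(pos: int, pyr_strand: str, ctx_index: int) -> int:
    """Plus-strand leftmost base of the TTCCG at context index ``ctx_index``."""
    if pyr_strand == "+":
        return pos + (ctx_index - 10)
    # context index i maps to plus position pos + 10 - i; the pentamer
    # covers plus positions [pos + 6 - i, pos + 11 - i)
    return pos + 6 - ctx_index


def unique_loci(sites) -> list[MotifLocus]:
    """Collapse hotspot bases anchored on the same TTCCG element.

    Two mutated bases of one CCTTCCG (both 5' cytosines) are one locus;
    per-base recurrence is retained in ``sites``.
    """
    groups: dict[tuple, list[tuple[HotspotSite, str]]] = defaultdict(list)
    for s in sites:
        if not s.ttccg_flag:
            continue
        cls, idx = motif_anchor(s.context_21)
        start = _ttccg_genomic_start(s.pos, s.pyrimidine_strand, idx)
        groups[(s.chrom, start, s.pyrimidine_strand)].append((s, cls))
    out = []
    for (chrom, start, strand), members in groups.items():
        members.sort(key=lambda t: -t[0].n)
        cls = next((c for _, c in members if c in FLANK_CLASSES), members[0][1])
        out.append(MotifLocus(
            chrom=chrom, ttccg_start=start, strand=strand, motif_class=cls,
            n_total=sum(s.n for s, _ in members),
            sites=tuple((s.pos, s.n) for s, _ in members),
        ))
    out.sort(key=lambda l: (l.chrom, l.ttccg_start))
    return out


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

def build_catalog(
    mutations,
    genome: Genome,
    tss_list,
    *,
    min_n: int = 5,
    window: int | None = None,
) -> list[HotspotSite]:
    """Full per-base catalog: recurrence, context, TTCCG flag, motif class.

    ``window`` restricts to promoter-proximal sites
    (``|tss_distance| <= window``); ``None`` keeps everything.
    """
    rec = recurrence_table(mutations)
    index = TssIndex(tss_list)
    sites = []
    for (chrom, pos), n in sorted(rec.items()):
        if n < min_n:
            continue
        pyr = pyrimidine_strand_of_base(genome, chrom, pos)
        if pyr is None:
            continue
        flag, ctx = annotate_ttccg(genome, chrom, pos, pyr)
        dist, gene = index.nearest(chrom, pos)
        if window is not None and abs(dist) > window:
            continue
        sites.append(HotspotSite(
            chrom=chrom, pos=pos, n=n, pyrimidine_strand=pyr, context_21=ctx,
            ttccg_flag=flag, tss_distance=dist, nearest_gene=gene,
            motif_class=motif_anchor(ctx)[0] if flag else None,
        ))
    return sites


def ttccg_fraction_by_recurrence(
    sites,
    thresholds=(5, 8, 12, 16, 20),
    *,
    window: int = 500,
    exclude: set[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """TTCCG-related fraction of promoter hotspots per recurrence cutoff.

    ``exclude`` removes known driver positions (e.g. TERT C228T/C250T)
    before counting.
    """
    exclude = exclude or set()
    kept = [s for s in sites
            if abs(s.tss_distance) <= window and (s.chrom, s.pos) not in exclude]
    rows = []
    for t in thresholds:
        sel = [s for s in kept if s.n >= t]
        total = len(sel)
        n_ttccg = sum(s.ttccg_flag for s in sel)
        rows.append({"threshold": t, "ttccg": n_ttccg, "total": total,
                     "fraction": n_ttccg / total if total else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-tumor burden coupling
# ---------------------------------------------------------------------------

def cohort_summary(mutations, catalog_sites) -> pd.DataFrame:
    """Per-tumor total SNV count and mutated-catalog-site count."""
    hot = {(s.chrom, s.pos) for s in catalog_sites}
    total: dict[str, int] = defaultdict(int)
    at_hot: dict[str, set] = defaultdict(set)
    for m in mutations:
        total[m.sample_id] += 1
        if (m.chrom, m.pos) in hot:
            at_hot[m.sample_id].add((m.chrom, m.pos))
    return pd.DataFrame({
        "sample_id": list(total),
        "total_snvs": [total[s] for s in total],
        "hotspot_sites": [len(at_hot.get(s, ())) for s in total],
    })


def burden_correlation(summary: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation of hotspot-site count vs total burden."""
    if len(summary) < 3:
        raise ValueError("need at least 3 tumors")
    x, y = summary["total_snvs"], summary["hotspot_sites"]
    if x.nunique() < 2 or y.nunique() < 2:
        raise ValueError("zero variance on one axis: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
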