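"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 0-based, half-open, everywhere.  VCF and GTF are
1-based on disk and are converted at this boundary; nothing downstream
ever sees a 1-based position.

Somatic SNVs are standardized to :class:`MutationRecord`, whose
``pyrimidine_strand`` identifies the strand on which the reference base
is C or T -- the convention under which UV mutagenesis (C>T at
dipyrimidines) is analysed.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .genome import Genome, PURINES, complement

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic SNV, 0-based, reported on the plus strand."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str

    def __post_init__(self):
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")

    @property
    def pyrimidine_strand(self) -> str:
        """Strand on which the reference base is a pyrimidine."""
        return "-" if self.ref in PURINES else "+"

    @property
    def pyr_ref(self) -> str:
        """Reference base read on the pyrimidine strand (always C or T)."""
        return complement(self.ref) if self.ref in PURINES else self.ref

    @property
    def pyr_alt(self) -> str:
        return complement(self.alt) if self.ref in PURINES else self.alt


@dataclass(frozen=True, slots=True)
class TssRecord:
    """Transcription start of one gene: the 5'-most annotated transcript."""

    gene_id: str
    chrom: str
    tss_pos: int
    strand: str


@dataclass(frozen=True, slots=True)
class HotspotTableRow:
    """One row of a recurrent-hotspot table (promoter sites, n >= 5)."""

    chrom: str
    pos: int
    n: int
    context: str
    gene: str
    tss_distance: int


@dataclass
class IngestStats:
    """Side counts accumulated while reading mutation calls."""

    rejected_ref_eq_alt: int = 0
    skipped_non_snv: int = 0
    dropped_population: int = 0
    dropped_unknown_contig: int = 0
    merged_duplicates: int = 0


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def read_mutations(
    path: str | Path,
    dialect: str = "auto",
    *,
    exclude: set[tuple[str, int]] | None = None,
    sample_map: dict[str, str] | None = None,
    sample_id: str | None = None,
    genome: Genome | None = None,
    stats: IngestStats | None = None,
) -> list[MutationRecord]:
    """Read somatic SNV calls from VCF or a 5-column TSV.

    ``dialect`` is one of ``vcf``, ``tsv0`` (0-based positions), ``tsv1``
    (1-based) or ``auto`` (by file suffix; TSVs default to 0-based, the
    convention this package writes).  ``exclude`` drops population
    variants given as ``(chrom, pos0)`` pairs; ``sample_map`` merges
    aliquot identifiers onto one sample; records on contigs absent from
    ``genome`` (when given) are dropped with a logged count.  Multiple
    calls by the same sample at the same base are merged to one record.
    """
    path = Path(path)
    if stats is None:
        stats = IngestStats()
    if dialect == "auto":
        dialect = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv0"
    if dialect == "vcf":
        raw = _read_vcf(path, sample_id, stats)
    elif dialect in ("tsv0", "tsv1"):
        raw = _read_tsv(path, one_based=(dialect == "tsv1"), stats=stats)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    out: list[MutationRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for rec in raw:
        if exclude and (rec.chrom, rec.pos) in exclude:
            stats.dropped_population += 1
            continue
        if genome is not None and rec.chrom not in genome:
            stats.dropped_unknown_contig += 1
            continue
        sid = sample_map.get(rec.sample_id, rec.sample_id) if sample_map else rec.sample_id
        key = (sid, rec.chrom, rec.pos)
        if key in seen:
            stats.merged_duplicates += 1
            continue
        seen.add(key)
        if sid != rec.sample_id:
            rec = MutationRecord(rec.chrom, rec.pos, rec.ref, rec.alt, sid)
        out.append(rec)
    if stats.dropped_unknown_contig:
        log.info("dropped %d records on contigs absent from the genome",
                 stats.dropped_unknown_contig)
    return out


def _read_vcf(path: Path, sample_id: str | None, stats: IngestStats):
    recs = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        for row in vf:
            ref = (row.ref or "").upper()
            for alt in row.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                    stats.skipped_non_snv += 1
                    continue
                if ref == alt:
                    stats.rejected_ref_eq_alt += 1
                    continue
                sids = _vcf_record_samples(row, vcf_samples, sample_id)
                for sid in sids:
                    recs.append(MutationRecord(row.chrom, row.pos - 1, ref, alt, sid))
    return recs


def _vcf_record_samples(row, vcf_samples, fallback):
    if "SAMPLE" in row.info:
        v = row.info["SAMPLE"]
        return [v if isinstance(v, str) else v[0]]
    if vcf_samples:
        carriers = []
        for s in vcf_samples:
            gt = row.samples[s].get("GT")
            if gt and any(a not in (0, None) for a in gt):
                carriers.append(s)
        if carriers:
            return carriers
        return vcf_samples if len(vcf_samples) == 1 else []
    return [fallback or "sample1"]


def _read_tsv(path: Path, one_based: bool, stats: IngestStats):
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and not parts[1].lstrip("-").isdigit():
                continue  # header
            if len(parts) < 5:
                raise ValueError(f"{path}: line {lineno}: expected >=5 columns, got {len(parts)}")
            chrom, pos_s, ref, alt, sid = parts[:5]
            try:
                pos = int(pos_s) - (1 if one_based else 0)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: bad position {pos_s!r}") from None
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1 or not {ref, alt} <= _BASES:
                stats.skipped_non_snv += 1
                continue
            if ref == alt:
                stats.rejected_ref_eq_alt += 1
                continue
            recs.append(MutationRecord(chrom, pos, ref, alt, sid))
    return recs


def write_mutations(records, path: str | Path) -> None:
    """Write records as a 0-based TSV (the package's ``tsv0`` dialect)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tsample_id\tpyrimidine_strand\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.sample_id}\t{r.pyrimidine_strand}\n")


def write_mutations_vcf(records, path: str | Path, genome: Genome | None = None) -> None:
    """Write records as minimal VCF 4.2, sample id carried in INFO/SAMPLE."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Tumor sample id">')
    contigs = genome.lengths if genome is not None else {}
    names = list(contigs) if contigs else sorted({r.chrom for r in records})
    for name in names:
        if contigs:
            header.contigs.add(name, length=contigs[name])
        else:
            header.contigs.add(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            rec = out.new_record(contig=r.chrom, start=r.pos, alleles=(r.ref, r.alt))
            rec.info["SAMPLE"] = r.sample_id
            out.write(rec)


# ---------------------------------------------------------------------------
# transcription starts
# ---------------------------------------------------------------------------

_GTF_COLS = ["seqname", "source", "feature", "start", "end", "score", "strand", "frame", "attribute"]
_ATTR_RE = {
    "gene_id": re.compile(r'gene_id "([^"]+)"'),
    "transcript_type": re.compile(r'transcript_type "([^"]+)"'),
    "gene_type": re.compile(r'gene_type "([^"]+)"'),
}


def read_tss(path: str | Path) -> list[TssRecord]:
    """One TSS per gene: 5'-most transcript start (rightmost end on minus).

    Accepts a GENCODE-style GTF or a 4-column TSV
    (``gene_id  chrom  tss_pos  strand``, 0-based).  In GTFs, genes with
    any protein-coding transcript keep only their coding isoforms; genes
    with no transcript rows are skipped with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_tss_gtf(path)
    return _read_tss_tsv(path)


def _read_tss_gtf(path: Path) -> list[TssRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", names=_GTF_COLS,
                     dtype={"seqname": str}, header=None)
    tx = df[df["feature"] == "transcript"].copy()
    genes_seen = set()
    if (df["feature"] == "gene").any():
        genes_seen = set(
            df.loc[df["feature"] == "gene", "attribute"].str.extract(
                _ATTR_RE["gene_id"], expand=False).dropna())
    tx["gene_id"] = tx["attribute"].str.extract(_ATTR_RE["gene_id"], expand=False)
    tx["transcript_type"] = tx["attribute"].str.extract(_ATTR_RE["transcript_type"], expand=False)
    tx = tx.dropna(subset=["gene_id"])
    out: list[TssRecord] = []
    for gid, grp in tx.groupby("gene_id", sort=True):
        coding = grp[grp["transcript_type"] == "protein_coding"]
        if len(coding):
            grp = coding
        strand = grp["strand"].iloc[0]
        if strand == "+":
            tss = int(grp["start"].min()) - 1          # GTF is 1-based inclusive
        else:
            tss = int(grp["end"].max()) - 1            # rightmost base, 0-based
        out.append(TssRecord(str(gid), str(grp["seqname"].iloc[0]), tss, strand))
    missing = genes_seen - {r.gene_id for r in out}
    if missing:
        log.warning("skipped %d genes with no transcript rows", len(missing))
    return out


def _read_tss_tsv(path: Path) -> list[TssRecord]:
    seen: dict[str, TssRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and not parts[2].lstrip("-").isdigit():
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            gid, chrom, pos_s, strand = parts[:4]
            if gid not in seen:                        # first row wins; one TSS per gene
                seen[gid] = TssRecord(gid, chrom, int(pos_s), strand)
    return list(seen.values())


def write_tss(records, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tchrom\ttss_pos\tstrand\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.tss_pos}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# hotspot tables
# ---------------------------------------------------------------------------

_HOTSPOT_SYNONYMS = {
    "chrom": {"chrom", "chr", "chromosome", "contig"},
    "pos": {"pos", "position", "bp", "coordinate"},
    "n": {"n", "recurrence", "count", "n_tumors", "tumors", "ntumors"},
    "context": {"context", "sequence", "sequence_context", "context_21", "seq"},
    "gene": {"gene", "nearest_gene", "gene_id", "nearestgene"},
    "tss_distance": {"tss_distance", "distance", "dist_tss", "tssdistance", "distance_to_tss"},
}


def read_hotspot_table(path: str | Path, one_based: bool = False) -> list[HotspotTableRow]:
    """Read a recurrent-hotspot table from XLSX or TSV, sniffing headers.

    Rows with recurrence below 5 are dropped (logged); a missing context
    column or a context whose length is not 21 is an error.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).lstrip("#").strip().lower().replace(" ", "_") for c in df.columns]
    cols: dict[str, str] = {}
    for canon, names in _HOTSPOT_SYNONYMS.items():
        for c in df.columns:
            if c in names:
                cols[canon] = c
                break
    if "context" not in cols:
        raise ValueError(
            "hotspot table has no sequence-context column; regenerate the "
            "+/-10 bp context from the reference genome and re-export")
    for req in ("chrom", "pos", "n"):
        if req not in cols:
            raise ValueError(f"hotspot table is missing a {req!r} column")
    rows: list[HotspotTableRow] = []
    dropped = 0
    for _, r in df.iterrows():
        n = int(r[cols["n"]])
        if n < 5:
            dropped += 1
            continue
        ctx = str(r[cols["context"]]).upper()
        if len(ctx) != 21:
            raise ValueError(f"context length {len(ctx)} != 21 at row {_}")
        rows.append(HotspotTableRow(
            chrom=str(r[cols["chrom"]]),
            pos=int(r[cols["pos"]]) - (1 if one_based else 0),
            n=n,
            context=ctx,
            gene=str(r[cols["gene"]]) if "gene" in cols else "",
            tss_distance=int(r[cols["tss_distance"]]) if "tss_distance" in cols else 0,
        ))
    if dropped:
        log.info("dropped %d hotspot rows with recurrence < 5", dropped)
    return rows


def write_hotspot_table(rows, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tn\tcontext\tgene\ttss_distance\n")
        for r in rows:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.n}\t{r.context}\t{r.gene}\t{r.tss_distance}\n")


# ---------------------------------------------------------------------------
# CPD events as BED6
# ---------------------------------------------------------------------------

def write_events_bed(events, path: str | Path) -> None:
    """BED6 export: leftmost plus-strand base of the dinucleotide, name =
    dinucleotide read on the damaged strand, strand = damaged strand."""
    with open(path, "w") as fh:
        for e in events:
            start = e.pos5 if e.strand == "+" else e.pos5 - 1
            fh.write(f"{e.chrom}\t{start}\t{start + 2}\t{e.dinuc}\t0\t{e.strand}\n")


def read_events_bed(path: str | Path):
    from .cpd import CPDEvent  # local import avoids a cycle

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: BED6 expected")
            chrom, start, _end, name, _score, strand = parts[:6]
            start = int(start)
            pos5 = start if strand == "+" else start + 1
            out.append(CPDEvent(chrom, pos5, strand, name))
    return out
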