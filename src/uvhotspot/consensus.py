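"""Error-corrected amplicon mutation quantification via barcode families.

Reads sharing a molecular barcode derive from one original DNA molecule;
a consensus over the family suppresses independent sequencing errors,
pushing the detection floor well below the raw per-base error rate.
Family acceptance follows the thresholds of the published procedure:
at least 10 reads, all identical, or a >= 90% modal sequence for
families larger than 20 reads.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class BarcodeSpec:
    """Barcode structure: first ``length`` bases of each read."""

    length: int = 12


@dataclass
class BarcodeFamily:
    barcode: str
    reads: list[str]
    status: str | None = None        # accepted / rejected-small / rejected-discordant
    consensus: str | None = None

    @property
    def size(self) -> int:
        return len(self.reads)


def group_families(
    reads,
    spec: BarcodeSpec = BarcodeSpec(),
    *,
    amplicon_length: int | None = None,
) -> tuple[list[BarcodeFamily], int]:
    """Group reads by barcode; returns ``(families, n_discarded)``.

    ``reads`` is an iterable of sequences or a FASTQ path.  Reads whose
    length does not match ``barcode + amplicon`` (when the amplicon
    length is known) or that are too short to carry an insert are
    discarded and counted.  The insert is trimmed to the amplicon window.
    """
    if isinstance(reads, (str, Path)):
        with pysam.FastxFile(str(reads)) as fh:
            seqs = [entry.sequence.upper() for entry in fh]
    else:
        seqs = [str(s).upper() for s in reads]
    fams: dict[str, list[str]] = {}
    n_discarded = 0
    for s in seqs:
        if len(s) <= spec.length:
            n_discarded += 1
            continue
        if amplicon_length is not None and len(s) != spec.length + amplicon_length:
            n_discarded += 1
            continue
        insert = s[spec.length:]
        if amplicon_length is not None:
            insert = insert[:amplicon_length]
        fams.setdefault(s[: spec.length], []).append(insert)
    return [BarcodeFamily(bc, rs) for bc, rs in fams.items()], n_discarded


def call_consensus(
    family: BarcodeFamily,
    *,
    min_family: int = 10,
    large_family: int = 20,
    majority: float = 0.9,
    mode: str = "per-read",
) -> BarcodeFamily:
    """Accept or reject a family and set its consensus sequence.

    Families below ``min_family`` reads are ``rejected-small``.  In the
    default ``per-read`` mode, families of ``min_family``..``large_family``
    reads must be unanimous (whole-read sequence identity); larger
    families accept their modal sequence when its frequency reaches
    ``majority``.  ``per-base`` mode applies the same thresholds column
    by column instead, for comparison.
    """
    n = family.size
    if n < min_family:
        family.status, family.consensus = "rejected-small", None
        return family
    if mode == "per-read":
        counts = Counter(family.reads)
        modal, top = counts.most_common(1)[0]
        if n <= large_family:
            ok = top == n
        else:
            ok = top / n >= majority
        family.status = "accepted" if ok else "rejected-discordant"
        family.consensus = modal if ok else None
        return family
    if mode == "per-base":
        L = len(family.reads[0])
        if any(len(r) != L for r in family.reads):
            family.status, family.consensus = "rejected-discordant", None
            return family
        cons = []
        for col in zip(*family.reads):
            base, top = Counter(col).most_common(1)[0]
            ok = top == n if n <= large_family else top / n >= majority
            if not ok:
                family.status, family.consensus = "rejected-discordant", None
                return family
            cons.append(base)
        family.status, family.consensus = "accepted", "".join(cons)
        return family
    raise ValueError(f"unknown consensus mode {mode!r}")


def call_all(families, **thresholds) -> list[BarcodeFamily]:
    return [call_consensus(f, **thresholds) for f in families]


def family_summary(families) -> pd.DataFrame:
    return pd.DataFrame({
        "barcode": [f.barcode for f in families],
        "size": [f.size for f in families],
        "status": [f.status for f in families],
    })


@dataclass
class VafProfile:
    """Per-position variant allele frequencies over consensus reads."""

    ref: str
    counts: pd.DataFrame            # index position, columns A/C/G/T mismatch counts
    total: int
    vaf: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.vaf = self.counts / self.total

    def position_vaf(self) -> pd.Series:
        """Summed non-reference VAF per position."""
        return self.vaf.sum(axis=1)

    def hotspot_positions(self, fold: float = 5.0) -> list[int]:
        """Positions whose VAF exceeds ``fold`` times the profile median."""
        v = self.position_vaf()
        med = float(v.median())
        floor = med if med > 0 else 1.0 / self.total
        return [int(i) for i, x in v.items() if x > fold * floor]

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "ref", list(self.ref))
        out["vaf"] = self.position_vaf()
        return out


def vaf_profile(consensus_reads, amplicon_ref: str) -> VafProfile:
    """Mismatch tallies and VAFs of accepted consensus reads vs the
    amplicon reference.  Consensus reads of a different length (indel
    bearing) are excluded and counted against the total."""
    reads = [r for r in consensus_reads if r is not None]
    same = [r for r in reads if len(r) == len(amplicon_ref)]
    if not same:
        raise ValueError("no accepted consensus reads to profile")
    counts = pd.DataFrame(0, index=range(len(amplicon_ref)), columns=list(_BASES))
    for r in same:
        for i, (a, b) in enumerate(zip(amplicon_ref, r)):
            if a != b and b in _BASES:
                counts.at[i, b] += 1
    return VafProfile(ref=amplicon_ref, counts=counts, total=len(same))
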