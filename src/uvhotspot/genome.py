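"""Genome sequence access and nucleotide-context utilities.

Every stage of the pipeline shares one coordinate convention: positions
are 0-based, intervals half-open, and strand-aware sequence is obtained
by reverse-complementing a plus-strand slice.  Dinucleotides and
trinucleotides are always read 5'->3' on the strand they live on.
"""
from __future__ import annotations

from collections import Counter
from collections.abc import Iterator, Mapping
from pathlib import Path

import pyfaidx

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
DIPYRIMIDINES = ("TT", "TC", "CT", "CC")
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")
NON_DIPYRIMIDINES = tuple(d for d in DINUCLEOTIDES if d not in DIPYRIMIDINES)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


class Genome(Mapping):
    """In-memory reference genome: contig name -> uppercase sequence.

    Lookups outside ``[0, length)`` raise; :meth:`fetch_padded` pads with
    ``N`` instead, which is what context extraction near contig edges
    wants.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            s = str(seq).upper()
            extra = set(s) - set("ACGTN")
            if extra:
                raise ValueError(
                    f"contig {name!r} contains letters outside ACGTN: {sorted(extra)}"
                )
            self._contigs[name] = s

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, name: str) -> str:
        return self._contigs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    # -- sequence access ---------------------------------------------------
    def length(self, chrom: str) -> int:
        return len(self._contigs[chrom])

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._contigs.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)``; minus strand is reverse-complemented."""
        seq = self._contigs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"{chrom}:{start}-{end} outside [0, {len(seq)})"
            )
        s = seq[start:end]
        return revcomp(s) if strand == "-" else s

    def fetch_padded(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Like :meth:`fetch` but pads out-of-range flanks with ``N``."""
        seq = self._contigs[chrom]
        left = max(0, -start)
        right = max(0, end - len(seq))
        core = seq[max(start, 0): min(end, len(seq))]
        s = "N" * left + core + "N" * right
        return revcomp(s) if strand == "-" else s

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos + 1)

    def dinucleotide_at(self, chrom: str, pos5: int, strand: str) -> str | None:
        """Dinucleotide whose 5' base sits at ``pos5`` on ``strand``.

        On the minus strand the 5' base is the *rightmost* of the two
        plus-strand positions, so the event covers ``pos5 - 1`` and
        ``pos5``.  Returns ``None`` when either base falls outside the
        contig.
        """
        try:
            if strand == "+":
                return self.fetch(chrom, pos5, pos5 + 2)
            return self.fetch(chrom, pos5 - 1, pos5 + 1, strand="-")
        except IndexError:
            return None

    # -- k-mer background counts -------------------------------------------
    def dinucleotide_counts(self) -> Counter:
        """Strand-resolved dinucleotide totals, both strands counted.

        A plus-strand occurrence of ``d`` is simultaneously a minus-strand
        occurrence of ``revcomp(d)``; the returned counter therefore adds
        each plus-strand window to its own class and its reverse
        complement to the opposite-strand class.  Windows containing N
        are skipped.
        """
        plus: Counter = Counter()
        for seq in self._contigs.values():
            plus.update(map("".join, zip(seq, seq[1:])))
        total: Counter = Counter()
        for d in DINUCLEOTIDES:
            total[d] = plus.get(d, 0) + plus.get(revcomp(d), 0)
        return total

    def trinucleotide_counts(self) -> Counter:
        """Pyrimidine-centred trinucleotide totals over both strands.

        Trinucleotides with a purine centre are counted under their
        reverse complement, so keys are the 32 contexts with C or T in
        the middle.  Windows containing N are skipped.
        """
        raw: Counter = Counter()
        for seq in self._contigs.values():
            raw.update(map("".join, zip(seq, seq[1:], seq[2:])))
        out: Counter = Counter()
        for t, n in raw.items():
            if "N" in t:
                continue
            out[t if t[1] in PYRIMIDINES else revcomp(t)] += n
        return out

    # -- FASTA round trip ----------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i: i + width] + "\n")
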