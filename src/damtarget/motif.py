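"""Degenerate consensus-motif scanning with TSS-relative coordinates.

The motif model is a per-position set of allowed bases, written either
as a dash/slash consensus string (``"T-A/T-A-G-A/C/G-C-G/A/T"``) or as
an IUPAC word (``"TWAGVCD"``).  Scanning slides the motif over every
window of the sequence on one or both strands, counting mismatches
(positions whose base is outside the allowed set; ``N`` never matches),
and reports hits at or under a mismatch budget.

Coordinates follow two conventions simultaneously: absolute positions
are 0-based half-open on the plus strand of the reference; TSS-relative
positions are signed and 1-based with no zero (+1 is the TSS base, -1
the first base upstream), measured along the gene's orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConsensusMotif",
    "MotifHit",
    "parse_consensus",
    "scan",
    "tss_relative",
    "relative_to_absolute",
    "extract_enhancer",
    "revcomp",
]

_IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
_IUPAC_INV = {v: k for k, v in _IUPAC.items()}

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.upper().translate(_COMP)[::-1]


@dataclass(frozen=True)
class ConsensusMotif:
    """Ordered allowed-base sets, one per motif position."""

    positions: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("motif must have at least one position")
        for pos in self.positions:
            if not pos or not pos <= set("ACGT"):
                raise ValueError(f"invalid position alphabet: {set(pos)}")

    def __len__(self) -> int:
        return len(self.positions)

    def to_iupac(self) -> str:
        return "".join(_IUPAC[p] for p in self.positions)

    def reverse_complement(self) -> "ConsensusMotif":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        return ConsensusMotif(
            tuple(
                frozenset(comp[b] for b in pos) for pos in reversed(self.positions)
            )
        )

    def mismatches(self, word: str) -> int:
        """Mismatch count of an equal-length word against the motif."""
        if len(word) != len(self):
            raise ValueError("word length differs from motif length")
        return sum(
            b not in pos for b, pos in zip(word.upper(), self.positions)
        )


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence in plus-strand absolute coordinates.

    ``rel_start``/``rel_end`` are filled by :func:`tss_relative` and are
    ``None`` for hits not yet anchored to a gene.  ``matched_seq`` is
    the motif-strand word (reverse-complemented for minus-strand hits).
    """

    seq_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    mismatches: int
    matched_seq: str
    rel_start: int | None = None
    rel_end: int | None = None


def parse_consensus(text: str) -> ConsensusMotif:
    """Parse a consensus from dash/slash notation or an IUPAC word.

    ``"T-A/T-A-G-A/C/G-C-G/A/T"`` and ``"TWAGVCD"`` denote the same
    motif.  Dash-separated tokens list allowed bases separated by
    slashes; a bare string without dashes is read as IUPAC.
    """
    text = text.strip().upper()
    if not text:
        raise ValueError("empty motif specification")
    positions = []
    if "-" in text or "/" in text:
        for token in text.split("-"):
            bases = token.split("/")
            for b in bases:
                if b not in ("A", "C", "G", "T"):
                    raise ValueError(f"invalid base {b!r} in consensus token {token!r}")
            positions.append(frozenset(bases))
    else:
        for ch in text:
            if ch not in _IUPAC_INV:
                raise ValueError(f"invalid IUPAC code {ch!r}")
            positions.append(_IUPAC_INV[ch])
    return ConsensusMotif(tuple(positions))


def _scan_one_strand(seq: np.ndarray, motif: ConsensusMotif) -> np.ndarray:
    """Mismatch count for every window start (vectorized)."""
    L = seq.size
    k = len(motif)
    n_windows = L - k + 1
    mm = np.zeros(n_windows, dtype=np.int32)
    for offset, allowed in enumerate(motif.positions):
        col = seq[offset : offset + n_windows]
        ok = np.zeros(n_windows, dtype=bool)
        for b in allowed:
            ok |= col == ord(b)
        mm += ~ok
    return mm


def scan(
    sequence: str,
    motif: ConsensusMotif,
    max_mismatch: int = 0,
    strands: str = "both",
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All motif occurrences with at most ``max_mismatch`` mismatches.

    Minus-strand hits are reported in plus-strand coordinates with
    ``strand="-"`` and the motif-strand word in ``matched_seq``.
    Overlapping hits are all reported; case is ignored; ``N`` matches
    nothing.
    """
    if strands not in ("both", "+", "-"):
        raise ValueError(f"strands must be 'both', '+' or '-', got {strands!r}")
    seq = sequence.upper()
    L, k = len(seq), len(motif)
    if L < k:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits: list[MotifHit] = []
    if strands in ("both", "+"):
        mm = _scan_one_strand(arr, motif)
        for i in np.flatnonzero(mm <= max_mismatch):
            i = int(i)
            hits.append(
                MotifHit(seq_id, i, i + k, "+", int(mm[i]), seq[i : i + k])
            )
    if strands in ("both", "-"):
        rc_motif = motif.reverse_complement()
        mm = _scan_one_strand(arr, rc_motif)
        for i in np.flatnonzero(mm <= max_mismatch):
            i = int(i)
            hits.append(
                MotifHit(seq_id, i, i + k, "-", int(mm[i]), revcomp(seq[i : i + k]))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _rel_coord(pos: int, tss: int, gene_strand: str) -> int:
    """Signed 1-based TSS-relative coordinate of one absolute base."""
    d = pos - tss if gene_strand == "+" else tss - pos
    return d + 1 if d >= 0 else d


def tss_relative(hit: MotifHit, tss: int, gene_strand: str) -> MotifHit:
    """Anchor a hit to a gene: fill in signed TSS-relative coordinates.

    The relative interval is reported (5'-most, 3'-most) along the gene
    orientation; +1 is the TSS base and there is no position 0.
    """
    if gene_strand not in ("+", "-"):
        raise ValueError("gene strand must be '+' or '-'")
    if gene_strand == "+":
        five, three = hit.start, hit.end - 1
    else:
        five, three = hit.end - 1, hit.start
    return MotifHit(
        hit.seq_id,
        hit.start,
        hit.end,
        hit.strand,
        hit.mismatches,
        hit.matched_seq,
        rel_start=_rel_coord(five, tss, gene_strand),
        rel_end=_rel_coord(three, tss, gene_strand),
    )


def relative_to_absolute(rel: int, tss: int, gene_strand: str) -> int:
    """Absolute 0-based position of one signed TSS-relative coordinate."""
    if rel == 0:
        raise ValueError("TSS-relative coordinates have no position 0")
    d = rel - 1 if rel > 0 else rel
    return tss + d if gene_strand == "+" else tss - d


def extract_enhancer(
    chrom_seq: str, tss: int, gene_strand: str, rel_start: int, rel_end: int
) -> str:
    """Sequence of a TSS-relative window, in gene orientation.

    ``rel_start``/``rel_end`` are the 5'-most and 3'-most coordinates of
    the window along the gene (e.g. ``(+1703, +2218)`` is a 516 bp
    window downstream of the TSS).  The returned sequence reads 5'->3'
    along the gene, so minus-strand genes yield the reverse complement
    of the plus-strand reference.
    """
    a = relative_to_absolute(rel_start, tss, gene_strand)
    b = relative_to_absolute(rel_end, tss, gene_strand)
    lo, hi = (a, b) if a <= b else (b, a)
    if lo < 0 or hi >= len(chrom_seq):
        raise ValueError(
            f"window [{lo}, {hi}] exceeds chromosome bounds [0, {len(chrom_seq) - 1}]"
        )
    seq = chrom_seq[lo : hi + 1].upper()
    return seq if gene_strand == "+" else revcomp(seq)
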