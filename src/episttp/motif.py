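"""Scan 3'UTR sequences for the consensus TTP-binding AU-rich element.

TTP (tristetraprolin) binds AU-rich elements in 3'UTRs; the consensus
binding site is the heptamer UAUUUAU, with the nonamer UUAUUUAUU as a
stricter consensus. Functional AREs are frequently clustered and built
from overlapping heptamers, so overlapping matches are counted.

Scanning is single-stranded (mRNA sense); T and U are equivalent and case
is ignored. ``N`` is tolerated in input but never matches.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

ARE_HEPTAMER = "UAUUUAU"
ARE_NONAMER = "UUAUUUAUU"

_VALID = set("ACGTUN")

__all__ = ["ARE_HEPTAMER", "ARE_NONAMER", "MotifHits", "scan_are", "scan_fasta"]


@dataclass(frozen=True)
class MotifHits:
    """Exact-match positions of one motif in one sequence."""

    seq_id: str
    motif: str
    positions: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.positions)


def _normalize(seq: str, what: str) -> str:
    out = seq.upper().replace("U", "T")
    for i, c in enumerate(out):
        if c not in _VALID:
            raise ValueError(f"illegal character {seq[i]!r} at position {i} in {what}")
    return out


def scan_are(sequence: str, motif: str = ARE_HEPTAMER, seq_id: str = "") -> MotifHits:
    """Report every (overlapping) exact occurrence of ``motif``.

    Parameters
    ----------
    sequence : str
        Nucleotide sequence over A/C/G/T/U/N, case-insensitive.
    motif : str
        Motif to search; default is the TTP consensus heptamer UAUUUAU.

    Returns
    -------
    MotifHits with 0-based start positions in ascending order.
    """
    seq = _normalize(sequence, "sequence")
    mot = _normalize(motif, "motif")
    if not mot:
        raise ValueError("motif must be non-empty")
    positions = []
    start = seq.find(mot)
    while start != -1:
        positions.append(start)
        start = seq.find(mot, start + 1)
    return MotifHits(seq_id=seq_id, motif=motif.upper(), positions=tuple(positions))


def scan_fasta(path, motif: str = ARE_HEPTAMER) -> list[MotifHits]:
    """Scan every record of a FASTA file (RNA or DNA alphabet)."""
    return [
        scan_are(str(rec.seq), motif=motif, seq_id=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
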