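"""Strand-resolved extraction of 3'ss-proximal intron windows.

Window bounds are given as distances upstream of the 3' splice site, both
inclusive: ``from_up`` is the 5'-most base of the window and ``to_up`` the
3'-most, so position -1 is the final intron nucleotide and a (60, 20) window
covers positions -60..-20 (41 nt). The defaults follow the two study
configurations: (60, 20) for mammalian branch-site scans that exclude the
polypyrimidine tract and 3'ss, and (80, 1) for yeast introns where the window
runs up to the junction.

Returned sequences always read 5'->3' on the transcript sense strand
(minus-strand windows are reverse-complemented).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import GenomeSequence, IntronRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqWindow:
    """A 3'ss-proximal intron subsequence with its genomic provenance."""

    intron_id: str
    from_up: int
    to_up: int
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    n_flagged: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.from_up - self.to_up + 1:
            raise ValueError(
                f"window {self.intron_id}: sequence length {len(self.sequence)} "
                f"!= from_up - to_up + 1 = {self.from_up - self.to_up + 1}"
            )


def window_coords(
    intron: IntronRecord, from_up: int = 60, to_up: int = 20, clip: bool = False
) -> tuple[str, int, int, str]:
    """Genomic half-open interval of the (from_up, to_up) upstream window.

    On '+' the 3'ss junction sits at the intron end, so position -k maps to
    genomic index end-k; on '-' it sits at the intron start and -k maps to
    start+k-1. With ``clip`` the window of an intron shorter than from_up is
    truncated at the intron 5' end instead of raising.
    """
    if not (from_up >= to_up >= 1):
        raise ValueError(f"need from_up >= to_up >= 1, got ({from_up}, {to_up})")
    if intron.length < from_up:
        if not clip:
            raise ValueError(
                f"intron {intron.intron_id} ({intron.length} nt) shorter than "
                f"window from_up={from_up}; pass clip=True to truncate"
            )
        logger.info(
            "clipping window of %s from %d to intron length %d",
            intron.intron_id,
            from_up,
            intron.length,
        )
        from_up = intron.length
    if intron.strand == "+":
        start = intron.end - from_up
        end = intron.end - to_up + 1
    else:
        start = intron.start + to_up - 1
        end = intron.start + from_up
    return intron.chrom, start, end, intron.strand


def extract_window(
    genome: GenomeSequence,
    intron: IntronRecord,
    from_up: int = 60,
    to_up: int = 20,
    clip: bool = False,
    max_n_fraction: float = 0.5,
) -> SeqWindow:
    """Extract the window sequence, reverse-complemented on the minus strand.

    Windows whose N fraction exceeds ``max_n_fraction`` are flagged; callers
    exclude flagged windows from enrichment by default.
    """
    chrom, start, end, strand = window_coords(intron, from_up, to_up, clip=clip)
    seq = genome.fetch(chrom, start, end)
    if strand == "-":
        seq = reverse_complement(seq)
    n_frac = seq.count("N") / len(seq) if seq else 1.0
    flagged = n_frac > max_n_fraction
    if flagged:
        logger.info("window %s flagged: N fraction %.2f", intron.intron_id, n_frac)
    eff_from_up = min(from_up, intron.length)
    return SeqWindow(
        intron_id=intron.intron_id,
        from_up=eff_from_up,
        to_up=to_up,
        sequence=seq,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        n_flagged=flagged,
    )


def extract_windows(
    genome: GenomeSequence,
    introns: list[IntronRecord],
    from_up: int = 60,
    to_up: int = 20,
    clip: bool = False,
) -> list[SeqWindow]:
    return [extract_window(genome, i, from_up, to_up, clip=clip) for i in introns]
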