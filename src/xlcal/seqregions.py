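"""Insert-region detection in multiple sequence alignments, hydropathy and charge.

A paralog family often differs by short insertions visible in an MSA as
column runs where some members are all-gap and the rest are occupied — the
LP21-style inserts that distinguish RGS6/RGS7 from RGS9/RGS11. Detected
regions are compared by Kyte–Doolittle hydropathy, Henderson–Hasselbalch
net charge (a sequence-level proxy for electrostatic surface character, not
a 3D potential) and pairwise-alignment identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio import Align, AlignIO

__all__ = [
    "KYTE_DOOLITTLE",
    "SequenceRegion",
    "InsertRegion",
    "read_alignment",
    "find_insert_regions",
    "hydropathy_profile",
    "region_charge",
    "compare_regions",
    "column_to_position",
    "position_to_column",
]

# Kyte–Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Side-chain pKa values (plus termini, off by default for internal regions)
PKA_SIDECHAIN = {"D": 3.65, "E": 4.25, "H": 6.00, "K": 10.53, "R": 12.48}
PKA_NTERM = 9.00
PKA_CTERM = 3.55

GAP_CHARS = set("-.")


@dataclass
class SequenceRegion:
    """A labelled span of a protein sequence, 1-based inclusive coordinates."""

    protein: str
    start: int
    end: int
    label: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("region end precedes start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("region sequence length does not match coordinates")


@dataclass
class InsertRegion:
    """An alignment-column run present in some members, all-gap in the rest."""

    columns: tuple[int, int]  # half-open [start, end) 0-based alignment columns
    members_with_insert: list[str]
    members_without: list[str]
    regions: dict[str, SequenceRegion]  # per member-with-insert


AlignmentLike = Union[dict, "AlignIO.MultipleSeqAlignment", Sequence]


def _as_dict(alignment: AlignmentLike) -> dict[str, str]:
    if isinstance(alignment, dict):
        aln = {k: str(v).upper() for k, v in alignment.items()}
    else:
        aln = {rec.id: str(rec.seq).upper() for rec in alignment}
    lengths = {len(s) for s in aln.values()}
    if len(aln) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have unequal lengths")
    return aln


def read_alignment(path: str | Path, fmt: Optional[str] = None) -> dict[str, str]:
    """Read an aligned FASTA or Clustal file into {id: aligned sequence}."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal", ".clw"} else "fasta"
    return _as_dict(AlignIO.read(str(path), fmt))


def column_to_position(aligned_seq: str, column: int) -> Optional[int]:
    """1-based sequence position at a 0-based alignment column; None on a gap."""
    if aligned_seq[column] in GAP_CHARS:
        return None
    return sum(1 for c in aligned_seq[: column + 1] if c not in GAP_CHARS)


def position_to_column(aligned_seq: str, position: int) -> int:
    """0-based alignment column holding the 1-based sequence position."""
    count = 0
    for col, c in enumerate(aligned_seq):
        if c not in GAP_CHARS:
            count += 1
            if count == position:
                return col
    raise IndexError(f"position {position} beyond sequence length {count}")


def find_insert_regions(
    alignment: AlignmentLike,
    min_length: int = 5,
    min_occupancy: float = 0.9,
) -> list[InsertRegion]:
    """Maximal column runs where a proper nonempty member subset is all-gap.

    A run qualifies when it spans >= ``min_length`` columns, some members are
    gap in every column of the run, and each remaining member is non-gap in
    >= ``min_occupancy`` of the run's columns. Member coordinates are
    converted from alignment columns to 1-based sequence positions.
    """
    aln = _as_dict(alignment)
    ids = list(aln)
    ncol = len(next(iter(aln.values())))
    gap = {i: np.array([c in GAP_CHARS for c in aln[i]]) for i in ids}

    regions: list[InsertRegion] = []
    col = 0
    while col < ncol:
        gapped = {i for i in ids if gap[i][col]}
        if not gapped or len(gapped) == len(ids):
            col += 1
            continue
        # extend while the common all-gap subset stays nonempty and proper
        end = col
        common = set(gapped)
        while end < ncol:
            here = {i for i in ids if gap[i][end]}
            nxt = common & here
            if not nxt or len(here) == len(ids):
                break
            common = nxt
            end += 1
        run = (col, end)
        length = end - col
        members_with = [i for i in ids if i not in common]
        ok = length >= min_length and all(
            (~gap[i][col:end]).mean() >= min_occupancy for i in members_with
        )
        if ok:
            per_member = {}
            for i in members_with:
                positions = [
                    column_to_position(aln[i], c)
                    for c in range(col, end)
                    if aln[i][c] not in GAP_CHARS
                ]
                start, stop = positions[0], positions[-1]
                seq = "".join(c for c in aln[i][col:end] if c not in GAP_CHARS)
                per_member[i] = SequenceRegion(
                    protein=i, start=start, end=stop,
                    label=f"insert_{col}_{end}", sequence=seq,
                )
            regions.append(
                InsertRegion(
                    columns=run,
                    members_with_insert=sorted(members_with),
                    members_without=sorted(common),
                    regions=per_member,
                )
            )
        col = end if end > col else col + 1
    return regions


def hydropathy_profile(
    sequence: str,
    window: int = 9,
    scale: Optional[dict[str, float]] = None,
    nonstandard: str = "error",
) -> list[float]:
    """Centered sliding-window mean hydropathy; termini use shrinking windows.

    ``window`` must be odd and no longer than the sequence; ``window=1``
    returns the raw per-residue scale values. Non-standard residues either
    raise (default) or are skipped from window means (``nonstandard="skip"``).
    """
    scale = scale or KYTE_DOOLITTLE
    sequence = sequence.upper()
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if window > len(sequence):
        raise ValueError("window exceeds sequence length")
    values: list[Optional[float]] = []
    for c in sequence:
        if c in scale:
            values.append(scale[c])
        elif nonstandard == "skip":
            values.append(None)
        else:
            raise ValueError(f"non-standard residue {c!r}")
    half = window // 2
    out = []
    for i in range(len(sequence)):
        lo, hi = max(0, i - half), min(len(sequence), i + half + 1)
        vals = [v for v in values[lo:hi] if v is not None]
        out.append(float(np.mean(vals)) if vals else float("nan"))
    return out


def region_charge(sequence: str, ph: float = 7.4, include_termini: bool = False) -> float:
    """Henderson–Hasselbalch net charge over D, E, H, K, R (elementary units).

    Termini are excluded by default since regions are typically internal
    spans, not whole chains.
    """
    sequence = sequence.upper()
    charge = 0.0
    for c in sequence:
        if c in ("K", "R", "H"):
            charge += 1.0 / (1.0 + 10.0 ** (ph - PKA_SIDECHAIN[c]))
        elif c in ("D", "E"):
            charge -= 1.0 / (1.0 + 10.0 ** (PKA_SIDECHAIN[c] - ph))
    if include_termini and sequence:
        charge += 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
        charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    return charge


def _identity_percent(seq_a: str, seq_b: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a, seq_b)[0]
    cols = alignment.length
    matches = sum(
        a == b for a, b in zip(str(alignment[0]), str(alignment[1])) if a != "-" and b != "-"
    )
    return 100.0 * matches / cols if cols else 0.0


def compare_regions(region_a: SequenceRegion, region_b: SequenceRegion) -> dict:
    """Mean-hydropathy delta, net-charge delta and alignment identity (%).

    Deltas are a − b; identity is matches over global-alignment columns.
    """
    if not region_a.sequence or not region_b.sequence:
        raise ValueError("both regions must be nonempty")
    mean_h = lambda s: float(np.mean(hydropathy_profile(s, window=1)))
    return {
        "hydropathy_delta": mean_h(region_a.sequence) - mean_h(region_b.sequence),
        "charge_delta": region_charge(region_a.sequence) - region_charge(region_b.sequence),
        "identity_percent": _identity_percent(region_a.sequence, region_b.sequence),
    }
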