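"""Crosslink identification tables: reading, peptide mapping, PSM deduplication.

A search engine emits one row per peptide-spectrum match (PSM); the same
lysine–lysine crosslink is typically supported by several PSMs, often at
different charge states. This module collapses PSM-level records into unique
residue pairs in full-protein (1-based) coordinates, classifying each as
intra- or inter-molecular. Upstream FDR control (the 1% target–decoy filter)
is consumed, not computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "CrosslinkRecord",
    "ResiduePair",
    "DEFAULT_DIALECT",
    "read_crosslink_table",
    "map_peptide_to_sequence",
    "dedupe_to_residue_pairs",
    "read_fasta",
    "pairs_to_csv",
    "pairs_from_csv",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# Documented CSV schema; a column-map dialect adapts third-party exports.
DEFAULT_DIALECT = {
    "protein_a": "protein_a",
    "peptide_a": "peptide_a",
    "link_pos_a": "link_pos_a",
    "protein_b": "protein_b",
    "peptide_b": "peptide_b",
    "link_pos_b": "link_pos_b",
    "charge": "charge",
    "psm_id": "psm_id",
    "score": "score",
    "qvalue": "qvalue",
}

REQUIRED_COLUMNS = (
    "protein_a", "peptide_a", "link_pos_a",
    "protein_b", "peptide_b", "link_pos_b",
)


@dataclass
class CrosslinkRecord:
    """One PSM-level crosslink identification in full-protein coordinates."""

    protein_a: str
    peptide_a: str
    link_pos_a: int
    protein_b: str
    peptide_b: str
    link_pos_b: int
    charge: Optional[int] = None
    psm_id: str = ""
    score: Optional[float] = None
    qvalue: Optional[float] = None


@dataclass
class ResiduePair:
    """A unique, canonically ordered lysine–lysine crosslinked pair."""

    protein_a: str
    pos_a: int
    protein_b: str
    pos_b: int
    kind: str  # "intra" | "inter"
    psm_count: int = 1
    charges_seen: set = field(default_factory=set)

    @property
    def key(self) -> tuple:
        return (self.protein_a, self.pos_a, self.protein_b, self.pos_b)


def read_crosslink_table(
    path: str | Path,
    dialect: Optional[dict] = None,
    qvalue_max: Optional[float] = None,
) -> list[CrosslinkRecord]:
    """Read a delimited crosslink table into PSM-level records.

    ``dialect`` maps canonical field names to the file's column names
    (defaults to the documented schema). Rows with unparsable or
    out-of-range (< 1) link positions are dropped and counted in the log;
    rows above ``qvalue_max`` (when given) are likewise dropped. Tables are
    assumed pre-filtered upstream, so the default keeps everything.
    """
    path = Path(path)
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [dialect[c] for c in REQUIRED_COLUMNS if dialect[c] not in df.columns]
    if missing:
        raise ValueError(f"crosslink table {path} missing required column(s): {', '.join(missing)}")

    records: list[CrosslinkRecord] = []
    n_bad = n_filtered = 0
    for idx, row in df.iterrows():
        try:
            pos_a = int(row[dialect["link_pos_a"]])
            pos_b = int(row[dialect["link_pos_b"]])
            if pos_a < 1 or pos_b < 1:
                raise ValueError("link positions are 1-based")
        except (ValueError, TypeError) as exc:
            n_bad += 1
            logger.warning("row %d rejected: %s", idx, exc)
            continue

        def _opt(col, cast):
            name = dialect.get(col)
            if name and name in df.columns and pd.notna(row[name]):
                return cast(row[name])
            return None

        qvalue = _opt("qvalue", float)
        if qvalue_max is not None and qvalue is not None and qvalue > qvalue_max:
            n_filtered += 1
            continue
        charge = _opt("charge", lambda v: int(float(v)))
        if charge is not None and charge < 1:
            n_bad += 1
            logger.warning("row %d rejected: charge %s < 1", idx, charge)
            continue
        records.append(
            CrosslinkRecord(
                protein_a=str(row[dialect["protein_a"]]),
                peptide_a=str(row[dialect["peptide_a"]]).upper(),
                link_pos_a=pos_a,
                protein_b=str(row[dialect["protein_b"]]),
                peptide_b=str(row[dialect["peptide_b"]]).upper(),
                link_pos_b=pos_b,
                charge=charge,
                psm_id=str(row[dialect["psm_id"]]) if dialect.get("psm_id") in df.columns else str(idx),
                score=_opt("score", float),
                qvalue=qvalue,
            )
        )
    if n_bad or n_filtered:
        logger.info(
            "%s: %d rows kept, %d rejected, %d dropped by q-value filter",
            path.name, len(records), n_bad, n_filtered,
        )
    return records


def map_peptide_to_sequence(peptide: str, protein_seq: str) -> list[int]:
    """All 1-based start offsets of ``peptide`` in ``protein_seq`` (overlaps included)."""
    if not peptide:
        raise ValueError("empty peptide")
    peptide = peptide.upper()
    protein_seq = protein_seq.upper()
    offsets = []
    start = protein_seq.find(peptide)
    while start != -1:
        offsets.append(start + 1)
        start = protein_seq.find(peptide, start + 1)
    return offsets


def _canonical(protein_a: str, pos_a: int, protein_b: str, pos_b: int) -> tuple:
    a, b = (protein_a, pos_a), (protein_b, pos_b)
    return a + b if a <= b else b + a


def dedupe_to_residue_pairs(
    records: Sequence[CrosslinkRecord],
    sequences: Optional[dict[str, str]] = None,
    strict_lysine: bool = False,
) -> list[ResiduePair]:
    """Collapse PSM-level records into unique canonical residue pairs.

    Pair orientation is normalised so (protein_a, pos_a) <= (protein_b, pos_b);
    psm_count counts supporting records and charges_seen their charge states.
    When ``sequences`` are supplied, records whose linked residue is not a
    lysine are excluded only in ``strict_lysine`` mode (protein N-terminal
    links are legitimate DSSO products), otherwise just logged.
    """
    grouped: dict[tuple, ResiduePair] = {}
    for rec in records:
        if sequences is not None:
            bad = []
            for prot, pos in ((rec.protein_a, rec.link_pos_a), (rec.protein_b, rec.link_pos_b)):
                seq = sequences.get(prot)
                if seq is None:
                    continue
                if pos > len(seq):
                    bad.append(f"{prot} position {pos} beyond length {len(seq)}")
                elif seq[pos - 1] != "K":
                    bad.append(f"{prot} position {pos} is {seq[pos - 1]}, not K")
            if bad:
                logger.warning("PSM %s: %s", rec.psm_id, "; ".join(bad))
                if strict_lysine or any("beyond length" in b for b in bad):
                    continue
        key = _canonical(rec.protein_a, rec.link_pos_a, rec.protein_b, rec.link_pos_b)
        if key not in grouped:
            grouped[key] = ResiduePair(
                protein_a=key[0], pos_a=key[1], protein_b=key[2], pos_b=key[3],
                kind="intra" if key[0] == key[2] else "inter",
                psm_count=0,
            )
        pair = grouped[key]
        pair.psm_count += 1
        if rec.charge is not None:
            pair.charges_seen.add(rec.charge)
    return sorted(grouped.values(), key=lambda p: p.key)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {id: uppercase sequence}; duplicate ids or bad symbols error."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        bad = sorted(set(seq) - AA_ALPHABET)
        if bad:
            raise ValueError(
                f"record {record.id!r} contains non-amino-acid symbol(s): {', '.join(bad)}"
            )
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return sequences


def pairs_to_csv(pairs: Sequence[ResiduePair], path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "protein_a": [p.protein_a for p in pairs],
            "pos_a": [p.pos_a for p in pairs],
            "protein_b": [p.protein_b for p in pairs],
            "pos_b": [p.pos_b for p in pairs],
            "kind": [p.kind for p in pairs],
            "psm_count": [p.psm_count for p in pairs],
            "charges_seen": [";".join(map(str, sorted(p.charges_seen))) for p in pairs],
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def pairs_from_csv(path: str | Path) -> list[ResiduePair]:
    df = pd.read_csv(path, dtype={"charges_seen": str}, keep_default_na=False)
    pairs = []
    for _, row in df.iterrows():
        charges = {int(c) for c in str(row["charges_seen"]).split(";") if c}
        pairs.append(
            ResiduePair(
                protein_a=str(row["protein_a"]), pos_a=int(row["pos_a"]),
                protein_b=str(row["protein_b"]), pos_b=int(row["pos_b"]),
                kind=str(row["kind"]), psm_count=int(row["psm_count"]),
                charges_seen=charges,
            )
        )
    return pairs
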