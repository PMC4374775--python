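"""Column conservation and covariation on multiple sequence alignments.

Positions are given in the *reference* sequence's own (1-based, ungapped)
numbering and mapped to alignment columns by counting non-gap reference
characters, the way positions are quoted against a canonical enzyme
numbering.  Frequencies are relative over all sequences, gap included;
covariation is the fraction of anchor-matching sequences that also carry a
specified residue motif at partner positions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio import SeqIO

__all__ = [
    "AlignmentProfile",
    "load_alignment",
    "column_profile",
    "covariation",
]

GAP_CHARS = {"-", "."}


@dataclass
class AlignmentProfile:
    """Residue frequency tables at reference-numbered positions."""

    positions: Dict[int, Dict[str, float]]
    reference: str
    n_sequences: int


def load_alignment(source: str | Path) -> List[Tuple[str, str]]:
    """Read a FASTA alignment into (id, sequence) pairs.

    ``source`` may be a path or the FASTA text itself.
    """
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(io.StringIO(text), "fasta")]
    if not records:
        raise ValueError("no sequences found in alignment input")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal aligned lengths: {sorted(lengths)}")
    return records


def _find_reference(records: Sequence[Tuple[str, str]], reference_id: str) -> str:
    for rid, seq in records:
        if rid == reference_id:
            return seq
    raise ValueError(f"reference sequence {reference_id!r} not in alignment")


def _reference_columns(ref_seq: str, positions: Iterable[int]) -> Dict[int, int]:
    """Map 1-based ungapped reference positions to 0-based alignment columns."""
    wanted = set(positions)
    bad = [p for p in wanted if p < 1]
    if bad:
        raise ValueError(f"positions must be >= 1, got {sorted(bad)}")
    mapping: Dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref_seq):
        if ch in GAP_CHARS:
            continue
        pos += 1
        if pos in wanted:
            mapping[pos] = col
    missing = wanted - mapping.keys()
    if missing:
        raise ValueError(
            f"positions {sorted(missing)} beyond reference length {pos}"
        )
    return mapping


def column_profile(
    alignment: str | Path | Sequence[Tuple[str, str]],
    reference_id: str,
    positions: Sequence[int],
) -> AlignmentProfile:
    """Relative residue frequencies at the given reference positions.

    Residues are upper-cased; '-' and '.' both count as the gap symbol '-'.
    Each frequency table sums to 1 over residues plus gap.
    """
    records = (
        load_alignment(alignment)
        if isinstance(alignment, (str, Path))
        else list(alignment)
    )
    ref_seq = _find_reference(records, reference_id)
    col_of = _reference_columns(ref_seq, positions)
    n = len(records)
    tables: Dict[int, Dict[str, float]] = {}
    for pos, col in col_of.items():
        counts: Dict[str, int] = {}
        for _, seq in records:
            ch = seq[col].upper()
            if ch in GAP_CHARS:
                ch = "-"
            counts[ch] = counts.get(ch, 0) + 1
        tables[pos] = {ch: c / n for ch, c in sorted(counts.items())}
    return AlignmentProfile(positions=tables, reference=reference_id, n_sequences=n)


def covariation(
    alignment: str | Path | Sequence[Tuple[str, str]],
    reference_id: str,
    anchor: Tuple[int, str],
    partners: Sequence[Tuple[int, Iterable[str]]],
) -> float:
    """Fraction of anchor-matching sequences carrying the partner motif.

    ``anchor`` is (reference position, residue); ``partners`` is a list of
    (reference position, allowed residue set).  Among the sequences whose
    anchor column holds the anchor residue, the returned fraction
    simultaneously matches every partner constraint.

    Raises
    ------
    ValueError
        If no sequence matches the anchor (the fraction is undefined).
    """
    records = (
        load_alignment(alignment)
        if isinstance(alignment, (str, Path))
        else list(alignment)
    )
    ref_seq = _find_reference(records, reference_id)
    anchor_pos, anchor_res = anchor
    all_positions = [anchor_pos] + [p for p, _ in partners]
    col_of = _reference_columns(ref_seq, all_positions)
    anchor_col = col_of[anchor_pos]
    constraints = [
        (col_of[p], {r.upper() for r in residues}) for p, residues in partners
    ]
    matching = [
        seq for _, seq in records if seq[anchor_col].upper() == anchor_res.upper()
    ]
    if not matching:
        raise ValueError(
            f"no sequence carries {anchor_res!r} at reference position {anchor_pos}"
        )
    hits = sum(
        1
        for seq in matching
        if all(seq[col].upper() in allowed for col, allowed in constraints)
    )
    return hits / len(matching)
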