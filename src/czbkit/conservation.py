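"""Per-column conservation and seven-residue motif logo matrices.

Alignments are consumed (aligned FASTA produced externally); gaps are
excluded from denominators and the gap fraction is reported separately.
Logo matrices carry raw residue frequencies, not information content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import AA20, _AA_INDEX

logger = logging.getLogger(__name__)

MOTIF_WIDTH = 7


@dataclass
class Alignment:
    """Equal-length gapped rows keyed by record id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows must be equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    @property
    def row_count(self) -> int:
        return len(self.rows)

    def row(self, record_id: str) -> str:
        try:
            return self.rows[self.ids.index(record_id)]
        except ValueError:
            raise KeyError(f"record {record_id!r} not in alignment") from None

    @classmethod
    def from_records(cls, records) -> "Alignment":
        return cls([r.id for r in records], [r.sequence for r in records])


def column_conservation(alignment: Alignment) -> pd.DataFrame:
    """Modal residue, percent identity and gap fraction per column.

    Identity is counted over non-gap rows; an all-gap column reports NaN
    identity and an empty modal residue.
    """
    n_rows = alignment.row_count
    records = []
    for j in range(alignment.column_count):
        col = [row[j] for row in alignment.rows]
        non_gap = [c for c in col if c != "-"]
        gap_fraction = 1.0 - len(non_gap) / n_rows
        if not non_gap:
            records.append(dict(column=j + 1, modal_residue="",
                                identity=np.nan, gap_fraction=1.0))
            continue
        values, counts = np.unique(non_gap, return_counts=True)
        top = counts.max()
        modal = min(v for v, c in zip(values, counts) if c == top)
        identity = 100.0 * top / len(non_gap)
        records.append(dict(column=j + 1, modal_residue=modal,
                            identity=identity, gap_fraction=gap_fraction))
    return pd.DataFrame(records)


def anchor_cys_column(
    alignment: Alignment, reference_id: str, reference_cys: int
) -> int:
    """Alignment column (1-based) holding the reference's conserved Cys.

    ``reference_cys`` is the 1-based ungapped residue position in the
    reference row.
    """
    row = alignment.row(reference_id)
    residue_index = 0
    for j, ch in enumerate(row):
        if ch == "-":
            continue
        residue_index += 1
        if residue_index == reference_cys:
            if ch != "C":
                raise ValueError(
                    f"{reference_id} position {reference_cys} is {ch!r}, not C"
                )
            return j + 1
    raise ValueError(
        f"{reference_id}: position {reference_cys} beyond ungapped length"
    )


@dataclass
class MotifLogoMatrix:
    """7 positions x 20 residue frequencies, position 1 = the Cys column."""

    frequencies: np.ndarray  # (7, 20); rows sum to 1 over non-gap rows
    anchor: int  # 1-based alignment column of position 1
    n_sequences: int = 0

    def frequency(self, position: int, residue: str) -> float:
        return float(self.frequencies[position - 1, _AA_INDEX[residue]])

    def top_residue(self, position: int) -> str:
        return AA20[int(np.argmax(self.frequencies[position - 1]))]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(AA20))
        df.insert(0, "position", np.arange(1, MOTIF_WIDTH + 1))
        return df


def motif_logo(alignment: Alignment, anchor: int) -> MotifLogoMatrix:
    """Residue frequencies for the 7 columns starting at ``anchor``.

    Frequencies at each position are normalized over non-gap rows; a
    position that is all gaps is left as zeros.
    """
    if anchor < 1 or anchor + MOTIF_WIDTH - 1 > alignment.column_count:
        raise ValueError(
            f"anchor {anchor} leaves fewer than {MOTIF_WIDTH} columns"
        )
    freqs = np.zeros((MOTIF_WIDTH, 20))
    for p in range(MOTIF_WIDTH):
        j = anchor - 1 + p
        counts = np.zeros(20)
        for row in alignment.rows:
            k = _AA_INDEX.get(row[j])
            if k is not None:
                counts[k] += 1
        total = counts.sum()
        if total > 0:
            freqs[p] = counts / total
    return MotifLogoMatrix(freqs, anchor, alignment.row_count)


def subgroup_logos(
    alignments: Mapping[str, tuple[Alignment, int]]
) -> tuple[dict[str, MotifLogoMatrix], pd.DataFrame]:
    """One anchored logo matrix per subgroup plus a position-2 comparison.

    ``alignments`` maps subgroup name to (alignment, anchor column).
    Subgroups with fewer than 2 members are skipped with a warning.
    """
    logos: dict[str, MotifLogoMatrix] = {}
    rows = []
    for name, (aln, anchor) in alignments.items():
        if aln.row_count < 2:
            logger.warning("subgroup %s has < 2 members; skipped", name)
            continue
        logo = motif_logo(aln, anchor)
        logos[name] = logo
        rows.append(
            dict(
                subgroup=name,
                position2_top=logo.top_residue(2),
                position2_frequency=logo.frequency(2, logo.top_residue(2)),
            )
        )
    return logos, pd.DataFrame(rows, columns=["subgroup", "position2_top",
                                              "position2_frequency"])


# ---------------------------------------------------------------------------
# Fixture-only center-star aligner (production consumes external alignments)
# ---------------------------------------------------------------------------

def center_star_align(sequences: Sequence[str]) -> list[str]:
    """Naive center-star multiple alignment for building test fixtures.

    Aligns every sequence pairwise to the longest one and merges by the
    union of gap patterns in the center; not intended for production use.
    """
    from Bio import Align

    if len(sequences) < 2:
        return list(sequences)
    center = max(range(len(sequences)), key=lambda i: len(sequences[i]))
    center_seq = sequences[center]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1

    m = len(center_seq)
    # gaps[i][j] = gaps inserted in the center before center position j
    # (j = m means trailing) in the pairwise alignment with sequence i
    pair_rows: dict[int, tuple[str, str]] = {}
    gaps_before = np.zeros((len(sequences), m + 1), dtype=int)
    for i, seq in enumerate(sequences):
        if i == center:
            continue
        aln = aligner.align(center_seq, seq)[0]
        a, b = str(aln[0]), str(aln[1])
        pair_rows[i] = (a, b)
        j = 0
        for ch in a:
            if ch == "-":
                gaps_before[i, j] += 1
            else:
                j += 1
    max_gaps = gaps_before.max(axis=0)

    # Rebuild each row column by column against the merged center frame.
    rows_out: list[str] = [""] * len(sequences)
    merged_center = []
    for j in range(m):
        merged_center.append("-" * max_gaps[j])
        merged_center.append(center_seq[j])
    merged_center.append("-" * max_gaps[m])
    rows_out[center] = "".join(merged_center)

    for i, seq in enumerate(sequences):
        if i == center:
            continue
        a, b = pair_rows[i]
        out = []
        j = 0
        block: list[str] = []
        for ch_a, ch_b in zip(a, b):
            if ch_a == "-":
                block.append(ch_b)
            else:
                out.append("-" * (max_gaps[j] - len(block)) + "".join(block))
                out.append(ch_b)
                block = []
                j += 1
        out.append("-" * (max_gaps[m] - len(block)) + "".join(block))
        rows_out[i] = "".join(out)
    return rows_out
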