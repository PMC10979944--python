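"""Per-column conservation statistics over protein multiple alignments.

Reproduces the logo-style analysis used to show that the membrane-central
histidines of DUF4405/PepSY/MsrQ-like cytochromes — and the flavin-facing
threonines of NqrB/RnfD — are the most conserved positions of their
families.  Information content follows the sequence-logo convention:
IC = log2(20) - H, with H the Shannon entropy of the column's non-gap
residue distribution against a uniform background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .genome_io import AMINO_ACIDS

__all__ = [
    "Alignment",
    "ColumnProfile",
    "MAX_IC",
    "read_alignment",
    "write_alignment",
    "column_profiles",
    "conserved_positions",
    "map_column_to_residue",
    "profiles_to_frame",
]

MAX_IC = math.log2(20)

GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """Aligned protein sequences; '.' is normalized to '-', case to upper."""

    sequences: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column(self, column_index: int) -> str:
        """1-based column as a string of residues/gaps."""
        if not 1 <= column_index <= self.n_columns:
            raise IndexError(f"column {column_index} outside [1, {self.n_columns}]")
        return "".join(s[column_index - 1] for _, s in self.sequences)


@dataclass(frozen=True)
class ColumnProfile:
    column_index: int
    frequencies: dict[str, float]
    gap_fraction: float
    information_content: float
    consensus: str
    excluded: bool


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    return Alignment(tuple((rec.id, _normalize(str(rec.seq))) for rec in aln))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.sequences:
            fh.write(f">{sid}\n{seq}\n")


def column_profiles(
    aln: Alignment, gap_exclude_threshold: float = 0.5, small_sample_correction: bool = False
) -> list[ColumnProfile]:
    """Compute residue frequencies, gap fraction, IC and consensus per column.

    Gaps are excluded from frequencies (not treated as a 21st symbol);
    columns whose gap fraction exceeds ``gap_exclude_threshold`` are flagged
    ``excluded`` but still profiled.  ``small_sample_correction`` subtracts
    the standard e_n = (19 / (2 ln 2 n)) approximation from the IC (floored
    at 0), as small-sample logo software does; off by default.
    """
    if not 0 <= gap_exclude_threshold <= 1:
        raise ValueError("gap_exclude_threshold must be in [0, 1]")
    profiles: list[ColumnProfile] = []
    for col in range(1, aln.n_columns + 1):
        column = aln.column(col)
        residues = [c for c in column if c != GAP]
        gap_fraction = 1.0 - len(residues) / len(column)
        if residues:
            counts: dict[str, int] = {}
            for c in residues:
                counts[c] = counts.get(c, 0) + 1
            n = len(residues)
            freqs = {aa: counts[aa] / n for aa in sorted(counts)}
            p = np.array(list(freqs.values()))
            entropy = float(-(p * np.log2(p)).sum())
            ic = MAX_IC - entropy
            if small_sample_correction:
                ic = max(0.0, ic - 19.0 / (2.0 * math.log(2) * n))
            # consensus: most frequent residue, ties broken alphabetically
            consensus = max(sorted(freqs), key=lambda aa: freqs[aa])
        else:
            freqs, ic, consensus = {}, 0.0, GAP
        profiles.append(
            ColumnProfile(
                column_index=col,
                frequencies=freqs,
                gap_fraction=gap_fraction,
                information_content=ic,
                consensus=consensus,
                excluded=gap_fraction > gap_exclude_threshold,
            )
        )
    return profiles


def conserved_positions(
    profiles: Iterable[ColumnProfile],
    min_frequency: float = 0.9,
    residues: Sequence[str] | set[str] = frozenset(AMINO_ACIDS),
) -> list[int]:
    """Columns whose consensus is in ``residues`` at >= ``min_frequency``.

    Gap-excluded columns are never reported.  Raising ``min_frequency``
    can only shrink the result (monotone).
    """
    if not 0 < min_frequency <= 1:
        raise ValueError("min_frequency must be in (0, 1]")
    residues = set(residues)
    out = []
    for p in profiles:
        if p.excluded or p.consensus == GAP:
            continue
        if p.consensus in residues and p.frequencies.get(p.consensus, 0.0) >= min_frequency:
            out.append(p.column_index)
    return out


def map_column_to_residue(aln: Alignment, sequence_id: str, column_index: int) -> int:
    """Map an alignment column to the 1-based ungapped position in one sequence.

    Links logo columns to residue numbers in a structure.  The column must
    not be a gap in that sequence.
    """
    for sid, seq in aln.sequences:
        if sid == sequence_id:
            if not 1 <= column_index <= len(seq):
                raise IndexError(f"column {column_index} outside alignment")
            if seq[column_index - 1] == GAP:
                raise ValueError(
                    f"column {column_index} is a gap in sequence {sequence_id!r}"
                )
            return column_index - seq[:column_index].count(GAP)
    raise KeyError(f"no sequence {sequence_id!r} in alignment")


def profiles_to_frame(profiles: Iterable[ColumnProfile]) -> pd.DataFrame:
    """Per-column TSV-ready table (column, consensus, frequency, gaps, IC)."""
    return pd.DataFrame(
        [
            {
                "column": p.column_index,
                "consensus": p.consensus,
                "consensus_frequency": p.frequencies.get(p.consensus, 0.0),
                "gap_fraction": p.gap_fraction,
                "information_content": p.information_content,
                "excluded": p.excluded,
            }
            for p in profiles
        ]
    )
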