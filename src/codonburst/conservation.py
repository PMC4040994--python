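"""Per-column conservation profiling (sequence-logo matrix) and mapping of
substitutions onto receptor domains (TM/EC/IC segments) and functionally
essential positions."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .seqio import RegionAnnotation

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_BITS = math.log2(len(AMINO_ACIDS))


@dataclass
class LogoColumn:
    position: int  # 0-based column index
    frequencies: dict[str, float]  # over non-gap residues; sums to 1
    information_bits: float | None  # None for all-gap columns
    gap_fraction: float


@dataclass
class LogoMatrix:
    columns: list[LogoColumn]
    n_sequences: int
    small_sample_corrected: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for col in self.columns:
            row = {"column": col.position + 1, "R_bits": col.information_bits,
                   "gap_fraction": col.gap_fraction}
            row.update({aa: col.frequencies.get(aa, 0.0) for aa in AMINO_ACIDS})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SubstitutionPlacement:
    position: int  # 0-based protein position
    region: str  # TM/EC/IC segment name or "unannotated"
    essential: bool


def logo_matrix(
    protein_alignment: list[str], small_sample_correction: bool = False
) -> LogoMatrix:
    """Residue frequencies and information content per alignment column.

    R = log2(20) - H(column), with H the Shannon entropy of the non-gap
    residue frequencies. Gaps are excluded from the normalization and
    reported as a per-column gap fraction. The optional small-sample
    correction subtracts e_n = (20-1)/(2 ln2 * n) (as sequence-logo tools
    do); it is off by default.
    """
    if not protein_alignment:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in protein_alignment}
    if len(lengths) > 1:
        raise ValueError("ragged protein alignment")
    n_rows = len(protein_alignment)
    L = lengths.pop()
    correction = (len(AMINO_ACIDS) - 1) / (2.0 * math.log(2) * n_rows)

    columns = []
    for j in range(L):
        col = [s[j].upper() for s in protein_alignment]
        residues = [c for c in col if c in AMINO_ACIDS]
        gap_frac = 1.0 - len(residues) / n_rows
        if not residues:
            columns.append(LogoColumn(j, {}, None, 1.0))
            continue
        counts = Counter(residues)
        total = len(residues)
        freqs = {aa: c / total for aa, c in counts.items()}
        H = -sum(f * math.log2(f) for f in freqs.values())
        R = MAX_BITS - H
        if small_sample_correction:
            R = max(0.0, R - correction)
        columns.append(LogoColumn(j, freqs, R, gap_frac))
    return LogoMatrix(columns, n_rows, small_sample_correction)


def place_substitutions(
    positions: list[int], annotation: RegionAnnotation
) -> list[SubstitutionPlacement]:
    """Map protein positions of substitutions onto annotated segments and
    flag hits to the essential-position set."""
    out = []
    for pos in positions:
        if not (0 <= pos < annotation.protein_length):
            raise ValueError(f"position {pos} outside protein length")
        out.append(
            SubstitutionPlacement(
                position=pos,
                region=annotation.region_of(pos),
                essential=pos in annotation.essential_positions,
            )
        )
    return out


def placement_summary(placements: list[SubstitutionPlacement]) -> dict:
    """Counts per region plus whether any essential position was hit."""
    counts = Counter(p.region for p in placements)
    return {
        "region_counts": dict(counts),
        "total": len(placements),
        "essential_hit": any(p.essential for p in placements),
    }
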