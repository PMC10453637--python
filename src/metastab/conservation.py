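"""Homolog filtering and per-position residue conservation profiles.

Hits from a protein homology search are filtered on query coverage (strictly
greater than 70% by default) and percent identity (inclusive 40-97% band by
default) before alignment; a multiple sequence alignment of the survivors is
then profiled column by column, mapped to ungapped query coordinates, as
frequencies of the 20 canonical amino acids among non-gap canonical residues
(gap and non-canonical fractions reported separately).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from metastab.errors import AlignmentFormatError, ValidationError

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
GAP_CHARS = {"-", "."}

#: Standard 12 columns of BLAST tabular output (outfmt 6).
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HomologHit:
    """One homology-search hit with the two filterable percentages."""

    subject_id: str
    percent_identity: float
    query_coverage: float

    def __post_init__(self) -> None:
        for label, v in (("percent_identity", self.percent_identity), ("query_coverage", self.query_coverage)):
            if not np.isfinite(v) or not 0.0 <= v <= 100.0:
                raise ValidationError(f"{label} must be within [0, 100], got {v}")


@dataclass(frozen=True)
class FrequencyTable:
    """Query-position x 20-amino-acid frequency matrix with gap bookkeeping.

    Each frequency row is normalized over non-gap canonical residues;
    ``gap_fraction`` and ``other_fraction`` are taken over all profiled
    sequences at that column.
    """

    query_positions: tuple[int, ...]
    frequencies: np.ndarray  # (n_positions, 20), rows sum to 1 where canonical count > 0
    gap_fraction: np.ndarray
    other_fraction: np.ndarray
    amino_acids: str = CANONICAL_AA

    def frequency(self, position: int, residue: str) -> float:
        row = self.query_positions.index(position)
        return float(self.frequencies[row, _AA_INDEX[residue.upper()]])


def filter_hits(
    hits,
    min_coverage: float = 70.0,
    id_low: float = 40.0,
    id_high: float = 97.0,
) -> list[HomologHit]:
    """Keep hits with coverage strictly above ``min_coverage`` and identity
    inclusively within ``[id_low, id_high]``."""
    for label, v in (("min_coverage", min_coverage), ("id_low", id_low), ("id_high", id_high)):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"{label} must be within [0, 100], got {v}")
    if id_low > id_high:
        raise ValidationError(f"id_low ({id_low}) must not exceed id_high ({id_high})")
    return [
        h
        for h in hits
        if h.query_coverage > min_coverage and id_low <= h.percent_identity <= id_high
    ]


def read_blast_tabular(
    path: str | Path,
    query_length: int | None = None,
    coverage_mode: str = "subject",
) -> list[HomologHit]:
    """Read a 12- or 13-column BLAST tabular (outfmt-6-style) hit file.

    A 13th column, when present, is taken as query coverage directly.
    Otherwise coverage is computed from the query alignment span and
    ``query_length``: per HSP row (``coverage_mode='hsp'``) or by merging
    each subject's HSP intervals (``coverage_mode='subject'``, default).
    The identity reported per subject is its best-HSP (first-row) identity.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == len(BLAST6_COLUMNS) + 1:
        df.columns = BLAST6_COLUMNS + ["qcovs"]
        return [
            HomologHit(str(r.sseqid), float(r.pident), float(r.qcovs)) for r in df.itertuples()
        ]
    if df.shape[1] != len(BLAST6_COLUMNS):
        raise ValidationError(
            f"{path}: expected 12 or 13 tab-separated columns, got {df.shape[1]}"
        )
    df.columns = BLAST6_COLUMNS
    if query_length is None or query_length <= 0:
        raise ValidationError(
            "query_length is required to derive coverage from a 12-column hit file"
        )
    if coverage_mode == "hsp":
        out = []
        for r in df.itertuples():
            span = abs(int(r.qend) - int(r.qstart)) + 1
            out.append(HomologHit(str(r.sseqid), float(r.pident), 100.0 * span / query_length))
        return out
    if coverage_mode != "subject":
        raise ValidationError(f"unknown coverage_mode {coverage_mode!r}")
    out = []
    for sseqid, grp in df.groupby("sseqid", sort=False):
        intervals = sorted(
            (min(int(a), int(b)), max(int(a), int(b))) for a, b in zip(grp.qstart, grp.qend)
        )
        covered, end = 0, 0
        for lo, hi in intervals:
            lo = max(lo, end + 1)
            if hi >= lo:
                covered += hi - lo + 1
                end = hi
            end = max(end, hi)
        out.append(
            HomologHit(str(sseqid), float(grp.pident.iloc[0]), 100.0 * covered / query_length)
        )
    return out


def _load_msa(msa: str | Path):
    try:
        alignment = AlignIO.read(str(msa), "fasta")
    except ValueError as exc:
        raise AlignmentFormatError(f"{msa}: {exc}") from exc
    return alignment


def map_alignment_columns(msa: str | Path, query_id: str) -> dict[int, int]:
    """Map 1-based alignment columns to 1-based ungapped query positions.

    Columns where the query carries a gap map to nothing.
    """
    alignment = _load_msa(msa)
    query = next((rec for rec in alignment if rec.id == query_id), None)
    if query is None:
        raise KeyError(f"query id {query_id!r} not present in alignment")
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(str(query.seq), start=1):
        if ch not in GAP_CHARS:
            pos += 1
            mapping[col] = pos
    if not mapping:
        warnings.warn(f"query {query_id!r} is all gaps; empty column map", stacklevel=2)
    return mapping


def residue_frequencies(msa: str | Path, query_id: str) -> FrequencyTable:
    """Canonical amino-acid frequencies at every ungapped query position.

    Frequencies are over the non-query sequences: counts of each canonical
    residue divided by the column's non-gap canonical count.  Gap and
    non-canonical fractions are reported over all non-query sequences.
    """
    alignment = _load_msa(msa)
    if len(alignment) == 0:
        raise ValidationError("empty alignment")
    mapping = map_alignment_columns(msa, query_id)
    others = [str(rec.seq).upper() for rec in alignment if rec.id != query_id]
    if not others:
        raise ValidationError("alignment holds only the query sequence")
    n_seq = len(others)
    columns = sorted(mapping)
    freqs = np.zeros((len(columns), len(CANONICAL_AA)))
    gap_fraction = np.zeros(len(columns))
    other_fraction = np.zeros(len(columns))
    for row, col in enumerate(columns):
        counts = np.zeros(len(CANONICAL_AA))
        gaps = other = 0
        for seq in others:
            ch = seq[col - 1]
            if ch in GAP_CHARS:
                gaps += 1
            elif ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
            else:
                other += 1
        canonical_total = counts.sum()
        if canonical_total > 0:
            freqs[row] = counts / canonical_total
        gap_fraction[row] = gaps / n_seq
        other_fraction[row] = other / n_seq
    return FrequencyTable(
        query_positions=tuple(mapping[c] for c in columns),
        frequencies=freqs,
        gap_fraction=gap_fraction,
        other_fraction=other_fraction,
    )


def position_report(table: FrequencyTable, positions, residue_set: str = "") -> dict:
    """Ranked residue frequencies at each position, plus a combined frequency
    for a user-specified residue set (e.g. ``"AG"``)."""
    report: dict = {"positions": {}, "residue_set": residue_set.upper()}
    for pos in positions:
        if pos not in table.query_positions:
            raise IndexError(f"position {pos} not in frequency table")
        row = table.query_positions.index(pos)
        ranked = sorted(
            zip(table.amino_acids, table.frequencies[row]), key=lambda t: (-t[1], t[0])
        )
        combined = float(sum(table.frequencies[row][_AA_INDEX[aa]] for aa in residue_set.upper()))
        report["positions"][int(pos)] = {
            "ranked": [(aa, float(f)) for aa, f in ranked if f > 0],
            "combined_frequency": combined,
            "gap_fraction": float(table.gap_fraction[row]),
            "other_fraction": float(table.other_fraction[row]),
        }
    return report


def write_frequency_tsv(table: FrequencyTable, path: str | Path) -> None:
    df = pd.DataFrame(table.frequencies, columns=list(table.amino_acids))
    df.insert(0, "position", table.query_positions)
    df["gap_fraction"] = table.gap_fraction
    df["other_fraction"] = table.other_fraction
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
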