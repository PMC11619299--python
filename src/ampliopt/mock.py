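"""Theoretical composition of DNA-pooled mock communities.

A mock community is assembled by mixing known masses of genomic DNA from
known organisms.  The number of 16S rRNA gene copies each organism
contributes to the pool is

    copies = dna_mass (g) * bp_per_gram (bp/g) / genome_size (bp)
             * copies_per_genome

and the ground-truth ("theoretical") relative abundance of each taxon in
an amplicon library is its copy count divided by the total.  These
abundances are the reference against which every downstream taxonomic
profile is graded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "BP_PER_GRAM_DSDNA",
    "MockMember",
    "TheoreticalComposition",
    "theoretical_copy_number",
    "theoretical_composition",
    "expected_read_counts",
    "read_mock_table",
    "write_mock_table",
]

#: Base pairs of double-stranded DNA per gram: Avogadro's number divided by
#: the mean molar mass of a base pair (~650 g/mol).
BP_PER_GRAM_DSDNA = 9.27e20


@dataclass(frozen=True)
class MockMember:
    """One organism in a DNA-pooled mock community.

    Parameters
    ----------
    taxon_id
        Canonical name, conventionally ``"Genus species"``.
    genome_size
        Genome length in base pairs (> 0).
    copies_per_genome
        Number of 16S rRNA operons per genome (>= 1).
    dna_mass
        Grams of genomic DNA contributed to the pool (>= 0).
    """

    taxon_id: str
    genome_size: float
    copies_per_genome: int
    dna_mass: float

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValueError("taxon_id must be non-empty")
        if self.genome_size <= 0:
            raise ValueError(f"genome_size must be > 0, got {self.genome_size}")
        if self.copies_per_genome < 1:
            raise ValueError(
                f"copies_per_genome must be >= 1, got {self.copies_per_genome}"
            )
        if self.dna_mass < 0:
            raise ValueError(f"dna_mass must be >= 0, got {self.dna_mass}")

    @property
    def genus(self) -> str:
        return self.taxon_id.split()[0]


@dataclass(frozen=True)
class TheoreticalComposition:
    """Ground-truth relative abundances of a mock community.

    ``abundances`` maps taxon_id to a dimensionless fraction; the values
    sum to 1 (within 1e-12) and are all non-negative.
    """

    abundances: Mapping[str, float]
    bp_per_gram: float = BP_PER_GRAM_DSDNA

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"abundances sum to {total!r}, expected 1")
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")

    @property
    def taxa(self) -> list[str]:
        return list(self.abundances)

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.abundances), name="abundance")


def theoretical_copy_number(
    member: MockMember, bp_per_gram: float = BP_PER_GRAM_DSDNA
) -> float:
    """16S gene copies contributed by one member of the pool.

    ``dna_mass * bp_per_gram / genome_size * copies_per_genome``;
    linear in ``dna_mass``.
    """
    if bp_per_gram <= 0:
        raise ValueError(f"bp_per_gram must be > 0, got {bp_per_gram}")
    return (
        member.dna_mass * bp_per_gram / member.genome_size * member.copies_per_genome
    )


def theoretical_composition(
    members: Sequence[MockMember], bp_per_gram: float = BP_PER_GRAM_DSDNA
) -> TheoreticalComposition:
    """Relative 16S copy-number composition of a mock community.

    Invariant to rescaling all masses by a common positive factor.

    Raises
    ------
    ValueError
        On duplicate taxon_ids, an empty member list, or an all-zero
        total copy number.
    """
    if not members:
        raise ValueError("at least one mock member is required")
    ids = [m.taxon_id for m in members]
    if len(set(ids)) != len(ids):
        dupes = sorted({t for t in ids if ids.count(t) > 1})
        raise ValueError(f"duplicate taxon_id(s): {dupes}")
    copies = {m.taxon_id: theoretical_copy_number(m, bp_per_gram) for m in members}
    total = sum(copies.values())
    if total <= 0:
        raise ValueError("total theoretical copy number is zero")
    return TheoreticalComposition(
        abundances={t: c / total for t, c in copies.items()}, bp_per_gram=bp_per_gram
    )


def expected_read_counts(
    comp: TheoreticalComposition, depth: int | float
) -> dict[str, float]:
    """Theoretical (real-valued, unrounded) read count per taxon at a depth.

    The per-taxon count is ``depth * abundance``; rounding is deferred to
    report time so that the composition is not distorted.
    """
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    return {t: depth * a for t, a in comp.abundances.items()}


# ---------------------------------------------------------------------------
# TSV interface: columns taxon_id, genome_size_bp, copies_per_genome,
# dna_mass_ng (nanograms in the file; converted to grams in memory).

_NG_TO_G = 1e-9


def read_mock_table(path: str | Path) -> list[MockMember]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"taxon_id", "genome_size_bp", "copies_per_genome", "dna_mass_ng"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mock table {path} is missing columns: {sorted(missing)}")
    return [
        MockMember(
            taxon_id=str(r.taxon_id),
            genome_size=float(r.genome_size_bp),
            copies_per_genome=int(r.copies_per_genome),
            dna_mass=float(r.dna_mass_ng) * _NG_TO_G,
        )
        for r in df.itertuples(index=False)
    ]


def write_mock_table(members: Sequence[MockMember], path: str | Path) -> None:
    pd.DataFrame(
        {
            "taxon_id": [m.taxon_id for m in members],
            "genome_size_bp": [int(m.genome_size) for m in members],
            "copies_per_genome": [m.copies_per_genome for m in members],
            "dna_mass_ng": [m.dna_mass / _NG_TO_G for m in members],
        }
    ).to_csv(path, sep="\t", index=False)
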