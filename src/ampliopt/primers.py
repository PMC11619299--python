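"""Degenerate-primer placement and paired-end merge geometry.

All trim lengths and amplicon lengths in this package are measured AFTER
primer removal: the "amplicon" is the stretch of template strictly
between the forward primer and the reverse-primer binding site, and a
read of length L covers the first L bases of that stretch (forward) or
of its reverse complement (reverse).  Coordinates are 0-based half-open
internally; lengths are plain bp externally.

The merge arithmetic follows the standard paired-end identity

    overlap = fwd_trim + rev_trim - amplicon_len

so a trim pair can only be merged when that overlap reaches the minimum
overlap the merger demands (16 bp by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import reverse_complement as _bio_revcomp

__all__ = [
    "IUPAC_SETS",
    "PrimerPair",
    "AmpliconGeometry",
    "TrimPair",
    "PrimerSiteNotFound",
    "reverse_complement",
    "find_primer_sites",
    "overlap_length",
    "merge_feasible",
    "min_required_total_length",
]

#: IUPAC nucleotide codes and the base sets they match.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_ALPHABET = frozenset(IUPAC_SETS)


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return str(_bio_revcomp(seq))


class PrimerSiteNotFound(ValueError):
    """A primer has no binding site on the reference under the mismatch budget."""


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair targeting one hypervariable region.

    Both sequences are given as synthesized, 5'->3'; the reverse primer
    therefore binds the reference as its reverse complement.
    """

    name: str
    forward_seq: str
    reverse_seq: str

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if not seq:
                raise ValueError(f"{label} primer of {self.name!r} is empty")
            bad = set(seq.upper()) - _IUPAC_ALPHABET
            if bad:
                raise ValueError(
                    f"{label} primer of {self.name!r} has non-IUPAC symbols: {sorted(bad)}"
                )


@dataclass(frozen=True)
class AmpliconGeometry:
    """Post-primer amplicon length together with the sequencing setup."""

    amplicon_len: int
    read_len: int
    min_overlap: int = 16

    def __post_init__(self) -> None:
        if self.amplicon_len <= 0:
            raise ValueError(f"amplicon_len must be > 0, got {self.amplicon_len}")
        if self.read_len <= 0:
            raise ValueError(f"read_len must be > 0, got {self.read_len}")
        if self.min_overlap < 1:
            raise ValueError(f"min_overlap must be >= 1, got {self.min_overlap}")


@dataclass(frozen=True, order=True)
class TrimPair:
    """Forward/reverse truncation lengths, measured on primer-removed reads."""

    fwd_trim: int
    rev_trim: int

    def __post_init__(self) -> None:
        if self.fwd_trim <= 0 or self.rev_trim <= 0:
            raise ValueError(f"trim lengths must be positive, got {self}")


def _matches_at(reference: str, pos: int, primer: str, max_mismatch: int) -> bool:
    mm = 0
    for off, code in enumerate(primer):
        if reference[pos + off] not in IUPAC_SETS[code]:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def _all_sites(reference: str, primer: str, max_mismatch: int) -> list[int]:
    n, k = len(reference), len(primer)
    return [i for i in range(n - k + 1) if _matches_at(reference, i, primer, max_mismatch)]


def find_primer_sites(
    reference: str, pair: PrimerPair, max_mismatch: int = 0
) -> tuple[int, int]:
    """Locate a primer pair on a reference and return the inter-primer span.

    Returns the 0-based half-open interval strictly between the 3' end of
    the forward primer site and the 5' end of the reverse-primer binding
    site (primer bases excluded).  The forward primer is matched on the
    given strand, the reverse primer as its reverse complement downstream
    of the forward site.  If several candidate sites exist, the 5'-most
    is taken for each primer (innermost span) and a warning reports the
    multiplicity.

    Raises
    ------
    PrimerSiteNotFound
        If either primer has no qualifying site.
    """
    reference = reference.upper()
    fwd = pair.forward_seq.upper()
    rev_rc = reverse_complement(pair.reverse_seq.upper())
    if len(reference) <= len(fwd) + len(rev_rc):
        raise PrimerSiteNotFound(
            f"reference ({len(reference)} bp) is not longer than the primers of {pair.name!r}"
        )
    fwd_sites = _all_sites(reference, fwd, max_mismatch)
    if not fwd_sites:
        raise PrimerSiteNotFound(f"forward primer of {pair.name!r} not found")
    if len(fwd_sites) > 1:
        warnings.warn(
            f"forward primer of {pair.name!r} matches at {len(fwd_sites)} sites; "
            "using the 5'-most",
            stacklevel=2,
        )
    start = fwd_sites[0] + len(fwd)
    rev_sites = [s for s in _all_sites(reference, rev_rc, max_mismatch) if s >= start]
    if not rev_sites:
        raise PrimerSiteNotFound(
            f"reverse primer of {pair.name!r} not found downstream of the forward site"
        )
    if len(rev_sites) > 1:
        warnings.warn(
            f"reverse primer of {pair.name!r} matches at {len(rev_sites)} sites; "
            "using the 5'-most",
            stacklevel=2,
        )
    return start, rev_sites[0]


def overlap_length(trim: TrimPair, amplicon_len: int) -> int:
    """Signed overlap of a merged pair: ``fwd_trim + rev_trim - amplicon_len``.

    Negative values mean the trimmed reads cannot meet in the middle;
    reports print them as "Less than 0".
    """
    if amplicon_len <= 0:
        raise ValueError(f"amplicon_len must be > 0, got {amplicon_len}")
    return trim.fwd_trim + trim.rev_trim - amplicon_len


def merge_feasible(trim: TrimPair, geom: AmpliconGeometry) -> bool:
    """Whether a trim pair can possibly merge under a geometry.

    True iff the implied overlap reaches ``min_overlap`` and neither trim
    exceeds what the sequencer or the amplicon can deliver (a read never
    extends past the amplicon end, so a truncation longer than
    ``min(read_len, amplicon_len)`` discards every read).
    """
    limit = min(geom.read_len, geom.amplicon_len)
    if trim.fwd_trim > limit or trim.rev_trim > limit:
        return False
    return overlap_length(trim, geom.amplicon_len) >= geom.min_overlap


def min_required_total_length(geom: AmpliconGeometry) -> int:
    """Smallest ``fwd_trim + rev_trim`` admitting a merge: amplicon + min overlap."""
    return geom.amplicon_len + geom.min_overlap
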