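"""Reference databases with controllable coverage, and top-hit assignment.

Real 16S reference databases differ in which taxa they contain at all —
a universal database may register every mock taxon while a
habitat-specific one misses some.  This module models a database as a
list of (full-length sequence, taxonomy) entries plus an alias map, lets
fixtures drop chosen taxa to emulate coverage gaps, and assigns ASVs by
best global-alignment identity against region-extracted references.

An ASV whose best hit falls below the identity threshold, whose taxon
was dropped from the database, or whose label is on the
inappropriate-name blocklist (e.g. "metagenome") is labelled
"Unassigned" — taxa absent from a database can never be returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .primers import PrimerPair
from .refs import extract_amplicon, lineage_for, synthetic_reference_set

__all__ = [
    "UNASSIGNED",
    "DEFAULT_BLOCKLIST",
    "DBEntry",
    "ReferenceDB",
    "TaxonomyAssignment",
    "build_fixture_db",
    "assign_taxon",
    "assign_all",
    "registered_count",
    "collapse_to_level",
    "read_reference_db",
    "write_reference_db",
]

UNASSIGNED = "Unassigned"

#: Labels that are not proper organism names and are never assigned.
DEFAULT_BLOCKLIST: frozenset[str] = frozenset({"metagenome", "uncultured", "unidentified"})

_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_INDEX = {r: i for i, r in enumerate(_RANKS)}

#: Default minimum global identity per rank.
DEFAULT_MIN_IDENTITY = {"genus": 0.90, "species": 0.97}


def _parse_ranks(taxonomy: str) -> list[str]:
    parts = [p.strip() for p in taxonomy.split(";")]
    if len(parts) < 6:
        raise ValueError(f"taxonomy string has {len(parts)} ranks, need >= 6: {taxonomy!r}")
    out = []
    for p in parts:
        if len(p) >= 3 and p[1:3] == "__":
            p = p[3:]
        out.append(p)
    return out


@dataclass(frozen=True)
class DBEntry:
    """One reference record: a full-length 16S sequence with its lineage."""

    seq_id: str
    sequence: str
    taxonomy: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"entry {self.seq_id!r} has an empty sequence")
        _parse_ranks(self.taxonomy)

    def label_at(self, rank: str) -> str:
        ranks = _parse_ranks(self.taxonomy)
        idx = _RANK_INDEX[rank]
        return ranks[idx] if idx < len(ranks) else ""


@dataclass
class ReferenceDB:
    """A named collection of reference entries with alias normalization."""

    name: str
    entries: list[DBEntry]
    canonical_map: dict[str, str] = field(default_factory=dict)
    blocklist: frozenset[str] = DEFAULT_BLOCKLIST
    _region_cache: dict[str, dict[str, str]] = field(default_factory=dict, repr=False)

    def canonicalize(self, label: str) -> str:
        label = self.canonical_map.get(label, label)
        if not label or label.lower() in self.blocklist:
            return UNASSIGNED
        return label

    def labels_at(self, rank: str) -> set[str]:
        out = set()
        for e in self.entries:
            label = self.canonicalize(e.label_at(rank))
            if label != UNASSIGNED:
                out.add(label)
        return out

    def extract_regions(
        self, pair: PrimerPair, max_mismatch: int = 0
    ) -> dict[str, str]:
        """Per-entry amplicon for a primer pair (cached by region name)."""
        if pair.name not in self._region_cache:
            self._region_cache[pair.name] = {
                e.seq_id: extract_amplicon(e.sequence, pair, max_mismatch)
                for e in self.entries
            }
        return self._region_cache[pair.name]


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Assignment of one ASV: a canonical label or "Unassigned"."""

    asv: str
    label: str
    best_hit: str | None
    identity: float


def build_fixture_db(
    name: str,
    taxa: Sequence[str],
    dropout: Sequence[str] = (),
    seed: int = 0,
    divergence: float = 0.10,
    canonical_map: Mapping[str, str] | None = None,
) -> ReferenceDB:
    """Synthetic reference database covering ``taxa`` minus ``dropout``.

    Entries reuse the same deterministic synthetic full-length sequences
    the read simulator's amplicons are cut from, so identity against the
    correct reference is exact.  Dropping taxa emulates a database that
    has never registered them.
    """
    extra = set(dropout) - set(taxa)
    if extra:
        raise ValueError(f"dropout taxa not in the taxon list: {sorted(extra)}")
    keep = [t for t in taxa if t not in set(dropout)]
    if not keep:
        warnings.warn(f"fixture database {name!r} is empty", stacklevel=2)
    refs = synthetic_reference_set(keep, seed=seed, divergence=divergence)
    entries = [
        DBEntry(
            seq_id=f"{name}_{i:04d}",
            sequence=refs[t],
            taxonomy=lineage_for(t),
        )
        for i, t in enumerate(keep)
    ]
    return ReferenceDB(name=name, entries=entries, canonical_map=dict(canonical_map or {}))


def _global_identity(a: str, b: str) -> float:
    d = edlib.align(a, b, task="distance", mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def assign_taxon(
    asv: str,
    db: ReferenceDB,
    rank: str = "genus",
    min_identity: float | None = None,
    region: PrimerPair | None = None,
) -> TaxonomyAssignment:
    """Top-hit assignment of one ASV by global identity.

    References are first cut down to the amplified region when a primer
    pair is given (full-length otherwise).  The best hit's label at the
    requested rank is returned if identity reaches the threshold
    (defaults: 0.90 at genus, 0.97 at species); otherwise "Unassigned".
    Ties on identity are broken by lexicographic label, then entry id.
    """
    if not asv:
        raise ValueError("empty ASV sequence")
    if rank not in _RANK_INDEX:
        raise KeyError(f"unknown rank {rank!r}")
    if min_identity is None:
        min_identity = DEFAULT_MIN_IDENTITY.get(rank, 0.90)
    if not db.entries:
        return TaxonomyAssignment(asv=asv, label=UNASSIGNED, best_hit=None, identity=0.0)

    targets = (
        db.extract_regions(region) if region is not None
        else {e.seq_id: e.sequence for e in db.entries}
    )
    by_id = {e.seq_id: e for e in db.entries}
    scored = []
    for seq_id, target in targets.items():
        ident = _global_identity(asv, target)
        label = db.canonicalize(by_id[seq_id].label_at(rank))
        scored.append((-ident, label, seq_id))
    scored.sort()
    neg_ident, label, seq_id = scored[0]
    identity = -neg_ident
    if identity < min_identity:
        return TaxonomyAssignment(asv=asv, label=UNASSIGNED, best_hit=seq_id, identity=identity)
    return TaxonomyAssignment(asv=asv, label=label, best_hit=seq_id, identity=identity)


def assign_all(
    asvs: Iterable[str],
    db: ReferenceDB,
    rank: str = "genus",
    min_identity: float | None = None,
    region: PrimerPair | None = None,
) -> dict[str, TaxonomyAssignment]:
    return {
        a: assign_taxon(a, db, rank=rank, min_identity=min_identity, region=region)
        for a in asvs
    }


def registered_count(
    mock_taxa: Sequence[str], db: ReferenceDB, rank: str = "genus"
) -> tuple[int, int]:
    """The (k, n) registered-taxon audit: k of n mock taxa present in the db."""
    labels = db.labels_at(rank)
    k = 0
    for taxon in mock_taxa:
        label = taxon.split()[0] if rank == "genus" else taxon
        if db.canonicalize(label) in labels:
            k += 1
    return k, len(mock_taxa)


def collapse_to_level(
    asv_table: pd.DataFrame, assignments: Mapping[str, TaxonomyAssignment]
) -> pd.DataFrame:
    """Sum ASV counts per canonical taxon label; "Unassigned" is kept as a row.

    Count-conserving: the collapsed table totals exactly match the input.
    """
    missing = [s for s in asv_table.index if s not in assignments]
    if missing:
        raise KeyError(f"{len(missing)} ASV(s) lack assignments")
    labels = [assignments[s].label for s in asv_table.index]
    return (
        asv_table.groupby(labels).sum().rename_axis(index="taxon").sort_index()
    )


# ---------------------------------------------------------------------------
# FASTA + taxonomy-TSV interface (the common database distribution format).


def write_reference_db(db: ReferenceDB, fasta_path: str | Path, tax_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for e in db.entries:
            fh.write(f">{e.seq_id}\n{e.sequence}\n")
    pd.DataFrame(
        {"id": [e.seq_id for e in db.entries], "taxonomy": [e.taxonomy for e in db.entries]}
    ).to_csv(tax_path, sep="\t", index=False, header=False)


def read_reference_db(
    fasta_path: str | Path, tax_path: str | Path, name: str = "db"
) -> ReferenceDB:
    from Bio import SeqIO

    tax = pd.read_csv(tax_path, sep="\t", header=None, names=["id", "taxonomy"])
    tax_map = dict(zip(tax["id"].astype(str), tax["taxonomy"].astype(str)))
    entries = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in tax_map:
            raise ValueError(f"sequence {rec.id!r} missing from taxonomy table")
        entries.append(DBEntry(seq_id=rec.id, sequence=str(rec.seq), taxonomy=tax_map[rec.id]))
    return ReferenceDB(name=name, entries=entries)
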