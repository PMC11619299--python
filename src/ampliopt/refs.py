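"""Synthetic 16S rRNA reference set, primer fixtures, and mock definitions.

Everything in this module is SYNTHETIC test substrate, not real biology.
It emulates the architecture that makes 16S amplicon sequencing work:
a gene in which conserved blocks (where universal primers bind) alternate
with hypervariable blocks (which carry the taxonomic signal).

The scaffold is::

    flank - C0 - V1 - C1 - V2 - C2 - ... - V8 - C8 - flank

where C0..C8 are conserved blocks shared by every taxon and V1..V8 are
taxon-specific variable blocks derived from a shared template by seeded
random substitutions.  A primer pair targeting regions Vi..Vj uses the
conserved block 5' of Vi as its forward primer and the reverse complement
of the conserved block 3' of Vj as its reverse primer, so the post-primer
amplicon is ``Vi Ci ... Vj``.

One primer pair is real — the widely used V3-V4 pair 341F/806R
(CCTACGGGNGGCWGCAG / GGACTACHVGGGTWTCTAAT) — and the scaffold's C2/C4
blocks are concrete IUPAC realizations of it, so the real degenerate
primers locate their sites on every synthetic reference.  The other
eight pairs are synthetic stand-ins named after the regions they span.

Variable-block lengths were chosen so post-primer amplicon lengths land
in the ranges familiar from real MiSeq work (V3-V4 ~410 bp, V4 ~250 bp,
V3 ~140 bp, ...), and so that the two longest regions (V1-V3, V3-V5)
cannot reach a 16 bp overlap on a 250 bp paired-end grid capped at
230 bp trims — the classic infeasible-merge geometry.
"""

from __future__ import annotations

import zlib
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mock import MockMember
from .primers import PrimerPair, find_primer_sites, reverse_complement

__all__ = [
    "REGION_SPANS",
    "VARIABLE_LENGTHS",
    "default_primer_pairs",
    "amplicon_lengths",
    "synthetic_reference_set",
    "extract_amplicon",
    "lineage_for",
    "mock1_members",
    "mock2_members",
    "MOCK1_TAXA",
    "MOCK2_TAXA",
    "read_primer_table",
    "write_primer_table",
    "packaged_data",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Region label -> (first, last) variable-block index spanned by the amplicon.
REGION_SPANS: dict[str, tuple[int, int]] = {
    "V1-V2": (1, 2),
    "V1-V3": (1, 3),
    "V3": (3, 3),
    "V3-V4": (3, 4),
    "V3-V5": (3, 5),
    "V4": (4, 4),
    "V4-V5": (4, 5),
    "V5-V6": (5, 6),
    "V6-V8": (6, 8),
}

#: Variable-block lengths (bp).
VARIABLE_LENGTHS: dict[int, int] = {1: 120, 2: 152, 3: 142, 4: 251, 5: 81, 6: 179, 7: 100, 8: 79}

# The real V3-V4 primer pair; C2/C4 are concrete realizations of it.
_341F = "CCTACGGGNGGCWGCAG"
_806R = "GGACTACHVGGGTWTCTAAT"
_C2 = "CCTACGGGGGGCTGCAG"  # 341F with N->G, W->T
_C4 = reverse_complement("GGACTACCGGGGTTTCTAAT")  # 806R with H->C, V->G, W->T

_SCAFFOLD_SEED = 716253  # fixes the conserved blocks and variable templates


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _conserved_blocks() -> list[str]:
    rng = np.random.default_rng(_SCAFFOLD_SEED)
    blocks = [_random_seq(rng, 18) for _ in range(9)]
    blocks[2] = _C2
    blocks[4] = _C4
    return blocks


_CONSERVED = _conserved_blocks()


def _variable_templates() -> dict[int, str]:
    rng = np.random.default_rng(_SCAFFOLD_SEED + 1)
    return {i: _random_seq(rng, n) for i, n in VARIABLE_LENGTHS.items()}


_TEMPLATES = _variable_templates()


def default_primer_pairs() -> dict[str, PrimerPair]:
    """The nine region-labelled primer pairs of the benchmark.

    V3-V4 is the real 341F/806R pair; V4's reverse primer is likewise the
    real 806R.  All other primer sequences are synthetic stand-ins
    reading the scaffold's conserved blocks.
    """
    pairs: dict[str, PrimerPair] = {}
    for name, (i, j) in REGION_SPANS.items():
        fwd = _341F if i == 3 else _CONSERVED[i - 1]
        rev = _806R if j == 4 else reverse_complement(_CONSERVED[j])
        pairs[name] = PrimerPair(name=name, forward_seq=fwd, reverse_seq=rev)
    return pairs


def amplicon_lengths() -> dict[str, int]:
    """Post-primer amplicon length of each region on the synthetic scaffold."""
    out = {}
    for name, (i, j) in REGION_SPANS.items():
        length = sum(VARIABLE_LENGTHS[k] for k in range(i, j + 1))
        length += sum(len(_CONSERVED[k]) for k in range(i, j))
        out[name] = length
    return out


def _taxon_rng(seed: int, taxon: str) -> np.random.Generator:
    # stable per-taxon stream: same taxon -> same sequence whatever the list
    return np.random.default_rng([seed, zlib.crc32(taxon.encode())])


def synthetic_reference_set(
    taxa: Iterable[str], seed: int = 0, divergence: float = 0.10
) -> dict[str, str]:
    """Full-length synthetic 16S-like sequence per taxon.

    Each taxon's variable blocks are the shared templates mutated by
    substitution at the given per-base ``divergence``; conserved blocks
    and flanks are identical across taxa.  Deterministic in
    ``(seed, taxon name)``: the same taxon always receives the same
    sequence regardless of which other taxa are requested.
    """
    if not 0 <= divergence < 1:
        raise ValueError(f"divergence must be in [0, 1), got {divergence}")
    flank_rng = np.random.default_rng(_SCAFFOLD_SEED + 2)
    flank5 = _random_seq(flank_rng, 30)
    flank3 = _random_seq(flank_rng, 30)
    out: dict[str, str] = {}
    for taxon in taxa:
        rng = _taxon_rng(seed, taxon)
        parts = [flank5, _CONSERVED[0]]
        for i in range(1, 9):
            tpl = np.frombuffer(_TEMPLATES[i].encode(), dtype=np.uint8).copy()
            hit = rng.random(tpl.size) < divergence
            # substitute with one of the three other bases
            idx = np.searchsorted(_BASES, tpl[hit])
            tpl[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.sum())) % 4]
            parts.append(tpl.tobytes().decode())
            parts.append(_CONSERVED[i])
        parts.append(flank3)
        out[taxon] = "".join(parts)
    return out


def extract_amplicon(reference: str, pair: PrimerPair, max_mismatch: int = 0) -> str:
    """The post-primer amplicon a primer pair cuts from a full-length reference."""
    start, end = find_primer_sites(reference, pair, max_mismatch=max_mismatch)
    return reference[start:end]


# ---------------------------------------------------------------------------
# Mock community fixtures (synthetic).
#
# Genome sizes and 16S copy numbers are SYNTHETIC plausible values — the
# strain-resolved values a real mock certificate would carry are not
# shipped here.  The two-tier copy-density profile is deliberate: every
# taxon's theoretical CLR is kept well away from 0, where relative-error
# grading is ill-conditioned (see docs/methods.md).

_MOCK1_ROWS: list[tuple[str, float, int]] = [
    # taxon, genome size (Mbp), 16S copies per genome
    ("Streptococcus mutans", 2.0, 8),
    ("Bacillus subtilis", 4.2, 14),
    ("Enterococcus faecalis", 2.9, 9),
    ("Lactobacillus gasseri", 1.9, 5),
    ("Staphylococcus epidermidis", 2.5, 6),
    ("Clostridium beijerinckii", 6.0, 13),
    ("Vibrio fluvialis", 4.8, 9),
    ("Escherichia coli", 4.6, 8),
    ("Pseudomonas aeruginosa", 6.3, 3),
    ("Parabacteroides distasonis", 4.8, 2),
    ("Deinococcus radiodurans", 2.9, 1),
    ("Cutibacterium acnes", 3.4, 1),
    ("Acinetobacter baumannii", 3.9, 1),
    ("Corynebacterium striatum", 4.4, 1),
    ("Bifidobacterium adolescentis", 4.9, 1),
]

_MOCK2_ROWS: list[tuple[str, float, int]] = [
    ("Aggregatibacter actinomycetemcomitans", 2.1, 6),
    ("Fusobacterium nucleatum", 2.2, 5),
    ("Streptococcus sanguinis", 2.2, 4),
    ("Porphyromonas gingivalis", 2.5, 2),
    ("Prevotella intermedia", 2.9, 2),
    ("Parvimonas micra", 1.9, 1),
]

MOCK1_TAXA: tuple[str, ...] = tuple(t for t, _, _ in _MOCK1_ROWS)
MOCK2_TAXA: tuple[str, ...] = tuple(t for t, _, _ in _MOCK2_ROWS)

_DEFAULT_MASS_G = 3e-9  # 3 ng of each genomic DNA in the pool


def _members(rows: Sequence[tuple[str, float, int]], dna_mass: float) -> list[MockMember]:
    return [
        MockMember(
            taxon_id=taxon,
            genome_size=mbp * 1e6,
            copies_per_genome=copies,
            dna_mass=dna_mass,
        )
        for taxon, mbp, copies in rows
    ]


def mock1_members(dna_mass: float = _DEFAULT_MASS_G) -> list[MockMember]:
    """The 15-taxon environmental mock community (equal DNA mass per member)."""
    return _members(_MOCK1_ROWS, dna_mass)


def mock2_members(dna_mass: float = _DEFAULT_MASS_G) -> list[MockMember]:
    """The 6-taxon oral mock community (equal DNA mass per member)."""
    return _members(_MOCK2_ROWS, dna_mass)


# Plausible lineage strings for the fixture taxa (7 semicolon-separated
# ranks: domain..species).  Used to build reference-database taxonomies.

_PHYLUM_CLASS: dict[str, tuple[str, str, str, str]] = {
    # genus -> (phylum, class, order, family)
    "Streptococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae"),
    "Bacillus": ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae"),
    "Enterococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae"),
    "Lactobacillus": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Staphylococcus": ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae"),
    "Clostridium": ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae"),
    "Vibrio": ("Proteobacteria", "Gammaproteobacteria", "Vibrionales", "Vibrionaceae"),
    "Escherichia": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    "Pseudomonas": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae"),
    "Parabacteroides": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Tannerellaceae"),
    "Deinococcus": ("Deinococcota", "Deinococci", "Deinococcales", "Deinococcaceae"),
    "Cutibacterium": ("Actinobacteriota", "Actinobacteria", "Propionibacteriales", "Propionibacteriaceae"),
    "Acinetobacter": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae"),
    "Corynebacterium": ("Actinobacteriota", "Actinobacteria", "Corynebacteriales", "Corynebacteriaceae"),
    "Bifidobacterium": ("Actinobacteriota", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae"),
    "Aggregatibacter": ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae"),
    "Fusobacterium": ("Fusobacteriota", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae"),
    "Porphyromonas": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae"),
    "Prevotella": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Parvimonas": ("Firmicutes", "Clostridia", "Peptostreptococcales", "Peptostreptococcaceae"),
}


def lineage_for(taxon: str) -> str:
    """Seven-rank taxonomy string ``d__...;p__...;...;g__Genus;s__Genus species``."""
    genus = taxon.split()[0]
    phylum, cls, order, family = _PHYLUM_CLASS.get(
        genus, ("Bacteria_incertae", "Unclassified", "Unclassified", "Unclassified")
    )
    return (
        f"d__Bacteria;p__{phylum};c__{cls};o__{order};f__{family};"
        f"g__{genus};s__{taxon}"
    )


# ---------------------------------------------------------------------------
# Primer-table TSV interface and packaged fixture files.


def write_primer_table(pairs: Mapping[str, PrimerPair], path) -> None:
    """Write a primer TSV with columns name, forward_seq, reverse_seq."""
    import pandas as pd

    pd.DataFrame(
        {
            "name": list(pairs),
            "forward_seq": [p.forward_seq for p in pairs.values()],
            "reverse_seq": [p.reverse_seq for p in pairs.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def read_primer_table(path) -> dict[str, PrimerPair]:
    """Load primer pairs from a TSV with columns name, forward_seq, reverse_seq."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"name", "forward_seq", "reverse_seq"} - set(df.columns)
    if missing:
        raise ValueError(f"primer table {path} is missing columns: {sorted(missing)}")
    return {
        str(r.name): PrimerPair(str(r.name), str(r.forward_seq), str(r.reverse_seq))
        for r in df.itertuples(index=False)
    }


def packaged_data(name: str):
    """Path of a fixture file shipped with the package (data/ directory)."""
    from importlib.resources import files

    return files("ampliopt") / "data" / name
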