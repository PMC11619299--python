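"""Paired-end amplicon read simulator with quality decay and chimeras.

Generates Illumina-style paired-end reads from a mock community of known
composition: templates are drawn multinomially from the theoretical
abundances, per-base Phred qualities decay toward the 3' end (reverse
reads worse), substitution errors occur with probability ``10**(-Q/10)``
at each base, and a configurable fraction of templates are two-parent
chimeras with a uniform interior breakpoint.  Every read carries full
ground-truth provenance in a sidecar truth table.

Two deliberate simplifications (see docs/methods.md):

* no read-through — a read stops at the amplicon end rather than running
  into adapter sequence, so truncation lengths longer than the available
  template discard the read downstream, reproducing the over-trimming
  survival collapse;
* substitutions only, no indels — the dominant MiSeq error mode, and it
  keeps exact-overlap merging decidable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .mock import TheoreticalComposition
from .primers import PrimerPair, reverse_complement

__all__ = [
    "QualityModel",
    "SimConfig",
    "SimulatedReadPair",
    "sample_quality",
    "make_chimera",
    "simulate_pairs",
    "truth_table",
    "DEFAULT_FORWARD_QUALITY",
    "DEFAULT_REVERSE_QUALITY",
    "ERROR_FREE_QUALITY",
]

_Q_MIN, _Q_MAX = 2, 41
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class QualityModel:
    """Positional Phred-quality model for one read direction.

    Mean quality decays from ``q_start`` at the 5' end to ``q_end`` at
    the 3' end, either linearly or along a logistic ramp (midpoint at
    60% of the read, which mimics the late collapse of real MiSeq
    reverse reads).  Gaussian jitter of ``jitter_sd`` Phred units is
    added per base and the result is clamped to [2, 41].
    """

    q_start: float = 38.0
    q_end: float = 24.0
    shape: str = "linear"
    jitter_sd: float = 2.0
    perfect: bool = False  # write qualities but introduce no errors at all

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "logistic"):
            raise ValueError(f"shape must be 'linear' or 'logistic', got {self.shape!r}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


#: Forward reads stay usable across the read; reverse reads decay harder.
DEFAULT_FORWARD_QUALITY = QualityModel(q_start=38.0, q_end=24.0)
DEFAULT_REVERSE_QUALITY = QualityModel(q_start=37.0, q_end=15.0)
#: Maximum quality everywhere, no jitter, and no substitutions: reads are
#: exact template prefixes.
ERROR_FREE_QUALITY = QualityModel(q_start=41.0, q_end=41.0, jitter_sd=0.0, perfect=True)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated sequencing run."""

    seed: int
    n_pairs: int
    read_len: int
    pair: PrimerPair
    composition: TheoreticalComposition
    chimera_rate: float = 0.05
    fwd_quality: QualityModel = DEFAULT_FORWARD_QUALITY
    rev_quality: QualityModel = DEFAULT_REVERSE_QUALITY

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.read_len <= 0:
            raise ValueError("read_len must be > 0")
        if not 0 <= self.chimera_rate < 1:
            raise ValueError(f"chimera_rate must be in [0, 1), got {self.chimera_rate}")


@dataclass(frozen=True)
class SimulatedReadPair:
    """One read pair plus its ground truth."""

    read_id: str
    fwd_seq: str
    fwd_qual: np.ndarray
    rev_seq: str
    rev_qual: np.ndarray
    taxon_id: str  # source taxon; for chimeras, the 5' parent
    is_chimera: bool = False
    parent_a: str | None = None
    parent_b: str | None = None
    breakpoint: int | None = None

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError("sequence and quality lengths differ")
        if self.is_chimera != (self.breakpoint is not None):
            raise ValueError("breakpoint must be present iff is_chimera")


def sample_quality(model: QualityModel, length: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a Phred vector of ``length`` bases from a quality model."""
    if length < 1:
        raise ValueError("length must be >= 1")
    pos = np.arange(length, dtype=float)
    frac = pos / (length - 1) if length > 1 else np.zeros(1)
    if model.shape == "linear":
        mean = model.q_start + (model.q_end - model.q_start) * frac
    else:  # logistic ramp down, midpoint at 60% of the read
        mean = model.q_end + (model.q_start - model.q_end) / (
            1.0 + np.exp((frac - 0.6) * 12.0)
        )
    if model.jitter_sd > 0:
        mean = mean + rng.normal(0.0, model.jitter_sd, size=length)
    return np.clip(np.rint(mean), _Q_MIN, _Q_MAX).astype(np.int64)


def make_chimera(parent_a: str, parent_b: str, breakpoint: int) -> str:
    """Two-parent chimeric template: ``parent_a[:breakpoint] + parent_b[breakpoint:]``."""
    if not 0 <= breakpoint <= len(parent_a):
        raise ValueError(
            f"breakpoint {breakpoint} outside [0, {len(parent_a)}]"
        )
    return parent_a[:breakpoint] + parent_b[breakpoint:]


def _sequence_read(
    template: str,
    read_len: int,
    quality: np.ndarray,
    rng: np.random.Generator,
    perfect: bool = False,
) -> str:
    """Prefix read of a template with quality-driven substitution errors."""
    n = min(read_len, len(template))
    if perfect:
        return template[:n]
    arr = np.frombuffer(template[:n].encode(), dtype=np.uint8).copy()
    p_err = 10.0 ** (-quality[:n] / 10.0)
    hit = rng.random(n) < p_err
    k = int(hit.sum())
    if k:
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, size=k)) % 4]
    return arr.tobytes().decode()


def simulate_pairs(
    config: SimConfig, references: Mapping[str, str]
) -> list[SimulatedReadPair]:
    """Simulate ``config.n_pairs`` read pairs from per-taxon amplicons.

    ``references`` maps each composition taxon to its amplicon sequence
    (post-primer).  Reads are 5' prefixes of the amplicon (forward) and
    of its reverse complement (reverse), of length
    ``min(read_len, amplicon_len)``.  Identical config => identical
    output, byte for byte.

    Raises
    ------
    KeyError
        If any composition taxon lacks a reference amplicon (checked
        before any read is produced).
    """
    taxa = list(config.composition.abundances)
    missing = [t for t in taxa if t not in references]
    if missing:
        raise KeyError(f"no reference amplicon for taxa: {missing}")
    probs = np.array([config.composition.abundances[t] for t in taxa])
    probs = probs / probs.sum()
    rng = np.random.default_rng(config.seed)

    amplicons = {t: references[t] for t in taxa}
    amplicons_rc = {t: reverse_complement(s) for t, s in amplicons.items()}

    n = config.n_pairs
    taxon_idx = rng.choice(len(taxa), size=n, p=probs) if n else np.empty(0, int)
    chim = rng.random(n) < config.chimera_rate if n else np.empty(0, bool)

    out: list[SimulatedReadPair] = []
    for i in range(n):
        if chim[i]:
            a = taxa[taxon_idx[i]]
            b = a
            while b == a:
                b = taxa[rng.choice(len(taxa), p=probs)]
            la = len(amplicons[a])
            lo, hi = int(np.ceil(0.2 * la)), int(np.floor(0.8 * la))
            bp = int(rng.integers(lo, hi + 1))
            template = make_chimera(amplicons[a], amplicons[b], bp)
            template_rc = reverse_complement(template)
            truth = dict(taxon_id=a, is_chimera=True, parent_a=a, parent_b=b, breakpoint=bp)
        else:
            t = taxa[taxon_idx[i]]
            template = amplicons[t]
            template_rc = amplicons_rc[t]
            truth = dict(taxon_id=t, is_chimera=False, parent_a=None, parent_b=None, breakpoint=None)

        fq = sample_quality(config.fwd_quality, min(config.read_len, len(template)), rng)
        fseq = _sequence_read(template, config.read_len, fq, rng, config.fwd_quality.perfect)
        rq = sample_quality(config.rev_quality, min(config.read_len, len(template_rc)), rng)
        rseq = _sequence_read(template_rc, config.read_len, rq, rng, config.rev_quality.perfect)
        out.append(
            SimulatedReadPair(
                read_id=f"sim_{config.seed}_{i:07d}",
                fwd_seq=fseq,
                fwd_qual=fq,
                rev_seq=rseq,
                rev_qual=rq,
                **truth,
            )
        )
    return out


def truth_table(pairs: list[SimulatedReadPair]) -> pd.DataFrame:
    """Ground-truth sidecar table (read_id, taxon, chimera provenance)."""
    return pd.DataFrame(
        {
            "read_id": [p.read_id for p in pairs],
            "taxon_id": [p.taxon_id for p in pairs],
            "is_chimera": [p.is_chimera for p in pairs],
            "parent_a": [p.parent_a or "" for p in pairs],
            "parent_b": [p.parent_b or "" for p in pairs],
            "breakpoint": [-1 if p.breakpoint is None else p.breakpoint for p in pairs],
        }
    )
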