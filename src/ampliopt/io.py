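"""FASTQ pair IO and report writers.

Reads and writes standard 4-line FASTQ (plain or gzip, Phred+33) via
Biopython's fast FASTQ iterator.  Pairs are matched by record order and
the two files must contain the same number of records.  Percentage
formatting and sentinel strings live in the report writers so the
numeric cores stay exact.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadPair",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "write_truth",
    "phred_to_ascii",
    "ascii_to_phred",
]

_OFFSET = 33


@dataclass(frozen=True)
class ReadPair:
    """A paired read as loaded from two FASTQ files."""

    read_id: str
    fwd_seq: str
    fwd_qual: np.ndarray
    rev_seq: str
    rev_qual: np.ndarray


def phred_to_ascii(quality: np.ndarray | Sequence[int]) -> str:
    q = np.asarray(quality, dtype=np.uint8) + _OFFSET
    return q.tobytes().decode("ascii")


def ascii_to_phred(text: str) -> np.ndarray:
    return np.frombuffer(text.encode("ascii"), dtype=np.uint8).astype(np.int64) - _OFFSET


def _open_text(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path, "r") as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{index} in {path}: {exc}") from exc
            yield rec
            index += 1


def read_fastq_pairs(path_f: str | Path, path_r: str | Path) -> list[ReadPair]:
    """Load paired FASTQ files; pairs are matched by record order.

    Raises
    ------
    ValueError
        On unequal record counts or a malformed record (with its index).
    """
    out: list[ReadPair] = []
    sentinel = object()
    it_f, it_r = _iter_fastq(path_f), _iter_fastq(path_r)
    while True:
        f = next(it_f, sentinel)
        r = next(it_r, sentinel)
        if f is sentinel and r is sentinel:
            return out
        if f is sentinel or r is sentinel:
            raise ValueError(
                f"unequal record counts: {path_f} and {path_r} diverge at pair {len(out)}"
            )
        (fid, fseq, fq), (_rid, rseq, rq) = f, r
        out.append(
            ReadPair(
                read_id=fid.split()[0],
                fwd_seq=fseq.upper(),
                fwd_qual=ascii_to_phred(fq),
                rev_seq=rseq.upper(),
                rev_qual=ascii_to_phred(rq),
            )
        )


def write_fastq_pairs(
    pairs: Iterable, path_f: str | Path, path_r: str | Path
) -> None:
    """Write paired reads as two FASTQ files (gzip when the name ends .gz)."""
    with _open_text(path_f, "w") as ff, _open_text(path_r, "w") as fr:
        for p in pairs:
            ff.write(f"@{p.read_id}\n{p.fwd_seq}\n+\n{phred_to_ascii(p.fwd_qual)}\n")
            fr.write(f"@{p.read_id}\n{p.rev_seq}\n+\n{phred_to_ascii(p.rev_qual)}\n")


def write_truth(pairs: Sequence, path: str | Path) -> None:
    """Write the simulator's ground-truth sidecar TSV."""
    from .simulate import truth_table

    truth_table(list(pairs)).to_csv(path, sep="\t", index=False)
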