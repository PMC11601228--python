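"""Read-to-protospacer counting: FASTQ in, guide x sample count matrix out.

Reads are assigned to library guides by extracting the protospacer slot
defined by a :class:`ReadStructure` and matching it against the library by
exact hash lookup (optionally tolerating one mismatch). Quality scores are
ignored; amplicon reads are assumed stranded, so no reverse complementing
unless explicitly requested.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .guide_library import GuideLibrary

__all__ = ["ReadStructure", "CountMatrix", "FastqParseError",
           "match_read", "count_reads", "UNASSIGNED"]

#: Sentinel returned for reads that match no guide (or >1 ambiguously).
UNASSIGNED = "unassigned"

_RC = str.maketrans("ACGT", "TGCA")


class FastqParseError(ValueError):
    """Raised for a malformed FASTQ record, naming the file and record index."""


@dataclass(frozen=True)
class ReadStructure:
    """Where the protospacer sits in a read.

    ``anchored`` mode extracts a single candidate at
    ``len(five_prime_constant)``; ``sliding`` mode scans every offset and
    takes the 5'-most offset yielding an assignment (ties across offsets at
    the same read are unambiguous by construction; distinct assignments at
    later offsets are never reached).
    """

    five_prime_constant: str = ""
    protospacer_length: int = 20
    search_mode: str = "anchored"

    def __post_init__(self) -> None:
        if self.search_mode not in ("anchored", "sliding"):
            raise ValueError("search_mode must be 'anchored' or 'sliding'")
        if self.protospacer_length < 1:
            raise ValueError("protospacer_length must be >= 1")

    @property
    def offset(self) -> int:
        return len(self.five_prime_constant)


@dataclass
class CountMatrix:
    """Guide x sample read counts plus per-sample unassigned tallies.

    Invariant: for each sample, ``counts[sample].sum() + unassigned[sample]``
    equals the number of reads processed.
    """

    counts: pd.DataFrame  # index guide_id, columns sample labels, int
    unassigned: pd.Series  # index sample labels, int

    @property
    def guides(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self, sample: str) -> int:
        return int(self.counts[sample].sum() + self.unassigned[sample])

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


class _Matcher:
    """Exact-hash protospacer matcher with optional 1-mismatch fallback."""

    def __init__(self, library: GuideLibrary, max_mismatch: int):
        if max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        self.max_mismatch = max_mismatch
        self.exact = {g.protospacer: g.guide_id for g in library}

    def __call__(self, candidate: str) -> str:
        hit = self.exact.get(candidate)
        if hit is not None:
            return hit
        if self.max_mismatch == 0:
            return UNASSIGNED
        hits: set[str] = set()
        for i, base in enumerate(candidate):
            prefix, suffix = candidate[:i], candidate[i + 1:]
            for alt in "ACGT":
                if alt == base:
                    continue
                h = self.exact.get(prefix + alt + suffix)
                if h is not None:
                    hits.add(h)
        if len(hits) == 1:
            return hits.pop()
        return UNASSIGNED  # no hit, or ambiguous between >=2 guides


def match_read(read: str, library: GuideLibrary, structure: ReadStructure,
               max_mismatch: int = 0, *, reverse_complement: bool = False) -> str:
    """Assign one read to a guide id, or :data:`UNASSIGNED`.

    At mismatch 0 only an exact protospacer hit counts; at mismatch 1 a
    unique guide within Hamming distance 1 wins and any ambiguity (two or
    more guides at the minimal distance) is unassigned. Reads too short for
    the structure are unassigned, never an error.
    """
    matcher = _Matcher(library, max_mismatch)
    return _match_with(matcher, read.upper(), structure, reverse_complement)


def _match_with(matcher: _Matcher, read: str, structure: ReadStructure,
                reverse_complement: bool) -> str:
    L = structure.protospacer_length
    strands = [read]
    if reverse_complement:
        strands.append(read.translate(_RC)[::-1])
    for seq in strands:
        if structure.search_mode == "anchored":
            cand = seq[structure.offset:structure.offset + L]
            if len(cand) == L:
                hit = matcher(cand)
                if hit != UNASSIGNED:
                    return hit
        else:  # sliding: 5'-most offset producing an assignment wins
            for off in range(0, len(seq) - L + 1):
                hit = matcher(seq[off:off + L])
                if hit != UNASSIGNED:
                    return hit
    return UNASSIGNED


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return path.open()


def count_reads(
    fastq_by_sample: Mapping[str, str | Path],
    library: GuideLibrary,
    structure: ReadStructure | None = None,
    max_mismatch: int = 0,
    *,
    reverse_complement: bool = False,
) -> CountMatrix:
    """Count reads per guide for each sample FASTQ (plain or gzipped).

    Sample order follows the input mapping order. Unmatched or too-short
    reads accumulate in the per-sample ``unassigned`` tally, so
    ``assigned + unassigned`` always equals the reads processed.
    """
    structure = structure or ReadStructure()
    matcher = _Matcher(library, max_mismatch)
    guide_ids = library.guide_ids
    index = {gid: i for i, gid in enumerate(guide_ids)}
    counts = np.zeros((len(guide_ids), len(fastq_by_sample)), dtype=np.int64)
    unassigned = np.zeros(len(fastq_by_sample), dtype=np.int64)
    for si, (sample, path) in enumerate(fastq_by_sample.items()):
        path = Path(path)
        record_index = 0
        with _open_maybe_gzip(path) as fh:
            try:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    hit = _match_with(matcher, seq.upper(), structure,
                                      reverse_complement)
                    if hit == UNASSIGNED:
                        unassigned[si] += 1
                    else:
                        counts[index[hit], si] += 1
                    record_index += 1
            except ValueError as exc:
                raise FastqParseError(
                    f"{path.name}: malformed FASTQ near record "
                    f"{record_index}: {exc}"
                ) from exc
    df = pd.DataFrame(counts, index=pd.Index(guide_ids, name="guide_id"),
                      columns=list(fastq_by_sample))
    return CountMatrix(df, pd.Series(unassigned, index=list(fastq_by_sample)))
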