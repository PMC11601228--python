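"""sgRNA library definition, validation, I/O and synthesis.

A pooled CRISPRi screen is defined by its guide library: a set of sgRNAs,
each identified by a short protospacer sequence, targeting a panel of genes,
plus a set of non-targeting controls (NTCs) that define the null behaviour
against which gene effects are measured. This module provides the in-memory
representation of such a library, a CSV loader/writer, an invariant checker,
and a deterministic synthetic-library builder used by the screen simulator.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GuideRecord",
    "GuideLibrary",
    "LibraryFormatError",
    "LibraryValidationError",
    "LibraryCapacityError",
    "NTC_GENE",
    "VALIDATION_GUIDES",
    "load_library",
    "write_library",
    "write_fasta",
    "build_synthetic_library",
    "validate_library",
    "example_validation_library",
]

#: Sentinel gene label for non-targeting control guides.
NTC_GENE = "NTC"

#: Default pattern recognising NTC guides from their gene label or guide id.
DEFAULT_NTC_PATTERN = r"^NTC([ _-]?\d+)?$"

_VALID_PROTOSPACER = re.compile(r"^[ACGT]{19,21}$")

#: The ten CRISPRi protospacers used for individual knockdown validation
#: (two NTCs plus two guides each against ADNP, TREM2, TCF4 and TCF7L2).
VALIDATION_GUIDES: tuple[tuple[str, str, str], ...] = (
    ("NTC_1", "NTC", "GGATCGCGTCTAGTGCAGAT"),
    ("NTC_2", "NTC", "GGGGTGAGGGTCCAATTCGG"),
    ("ADNP_1", "ADNP", "GGTGGGAGAGGCGGCTTCAC"),
    ("ADNP_2", "ADNP", "GCGTCGAGCGGTGCAGACAA"),
    ("TREM2_1", "TREM2", "GCCGACCGCGGCAAGCAAGC"),
    ("TREM2_2", "TREM2", "GCAGGAGGACGCAGGCCTAG"),
    ("TCF4_1", "TCF4", "GCCTCCCCGGAGAAGAGAGT"),
    ("TCF4_2", "TCF4", "GTGTGTCTGCGGATCTGTAG"),
    ("TCF7L2_1", "TCF7L2", "GGGATCGAAATCCGGAGGAA"),
    ("TCF7L2_2", "TCF7L2", "GGGAGCGGAGATTATTGACA"),
)


class LibraryFormatError(ValueError):
    """Raised when a library file lacks required structure (columns, header)."""


class LibraryValidationError(ValueError):
    """Raised when library content violates an invariant (duplicates, bad bases)."""


class LibraryCapacityError(ValueError):
    """Raised when more distinct protospacers are requested than exist."""


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: identifier, targeted gene (or ``"NTC"``) and protospacer."""

    guide_id: str
    gene: str
    protospacer: str
    is_ntc: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", self.protospacer.upper())


@dataclass
class GuideLibrary:
    """An ordered collection of :class:`GuideRecord` with fast protospacer lookup.

    Attributes
    ----------
    guides
        Guide records in input order.
    """

    guides: list[GuideRecord]
    _by_protospacer: dict[str, GuideRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_protospacer = {g.protospacer: g for g in self.guides}

    def __len__(self) -> int:
        return len(self.guides)

    def __iter__(self):
        return iter(self.guides)

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def targeting_genes(self) -> list[str]:
        """Distinct targeting genes, in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.guides:
            if not g.is_ntc:
                seen.setdefault(g.gene, None)
        return list(seen)

    @property
    def n_genes(self) -> int:
        return len(self.targeting_genes)

    @property
    def n_ntc(self) -> int:
        return sum(g.is_ntc for g in self.guides)

    @property
    def guides_per_gene(self) -> int:
        """Modal number of guides per targeting gene (0 for an NTC-only library)."""
        counts: dict[str, int] = {}
        for g in self.guides:
            if not g.is_ntc:
                counts[g.gene] = counts.get(g.gene, 0) + 1
        if not counts:
            return 0
        values = sorted(counts.values())
        return max(set(values), key=lambda v: (values.count(v), -v))

    def ntc_guides(self) -> list[GuideRecord]:
        return [g for g in self.guides if g.is_ntc]

    def lookup(self, protospacer: str) -> GuideRecord | None:
        """Exact protospacer lookup; ``None`` if absent."""
        return self._by_protospacer.get(protospacer.upper())

    def gene_of(self, guide_id: str) -> str:
        for g in self.guides:
            if g.guide_id == guide_id:
                return g.gene
        raise KeyError(guide_id)


def _is_ntc(gene: str, guide_id: str, ntc_pattern: str) -> bool:
    pat = re.compile(ntc_pattern, re.IGNORECASE)
    return bool(pat.match(gene)) or bool(pat.match(guide_id))


def _build_validated(rows: Iterable[tuple[str, str, str, bool | None]],
                     ntc_pattern: str) -> GuideLibrary:
    records: list[GuideRecord] = []
    seen_ids: set[str] = set()
    seen_ps: set[str] = set()
    for guide_id, gene, protospacer, is_ntc in rows:
        protospacer = protospacer.strip().upper()
        if not _VALID_PROTOSPACER.match(protospacer):
            raise LibraryValidationError(
                f"guide {guide_id!r}: protospacer {protospacer!r} is not a "
                "19-21 nt ACGT sequence"
            )
        if guide_id in seen_ids:
            raise LibraryValidationError(f"duplicate guide_id {guide_id!r}")
        if protospacer in seen_ps:
            raise LibraryValidationError(
                f"duplicate protospacer {protospacer!r} (guide {guide_id!r})"
            )
        seen_ids.add(guide_id)
        seen_ps.add(protospacer)
        if is_ntc is None:
            is_ntc = _is_ntc(gene, guide_id, ntc_pattern)
        gene = NTC_GENE if is_ntc else gene
        records.append(GuideRecord(guide_id, gene, protospacer, is_ntc))
    if not records:
        raise LibraryValidationError("library contains no guides")
    return GuideLibrary(records)


def load_library(path: str | Path, *, ntc_pattern: str = DEFAULT_NTC_PATTERN) -> GuideLibrary:
    """Load a guide library from CSV.

    The file must have a header with columns ``guide_id``, ``gene`` and
    ``protospacer``; an optional ``is_ntc`` column (true/false) overrides
    NTC inference from the gene label or guide id.

    Raises
    ------
    LibraryFormatError
        If a required column is missing.
    LibraryValidationError
        On duplicate ids/protospacers, non-ACGT characters or an empty file.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = {"guide_id", "gene", "protospacer"} - set(cols)
        if missing:
            raise LibraryFormatError(
                f"{path.name}: missing required column(s) {sorted(missing)}"
            )
        has_flag = "is_ntc" in cols
        rows = []
        for row in reader:
            flag: bool | None = None
            if has_flag and row["is_ntc"] not in (None, ""):
                flag = row["is_ntc"].strip().lower() in ("1", "true", "yes")
            rows.append((row["guide_id"].strip(), row["gene"].strip(),
                         row["protospacer"], flag))
    return _build_validated(rows, ntc_pattern)


def write_library(lib: GuideLibrary, path: str | Path, *, include_flag: bool = True) -> None:
    """Write a library to CSV in the format :func:`load_library` reads."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fields = ["guide_id", "gene", "protospacer"] + (["is_ntc"] if include_flag else [])
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for g in lib.guides:
            row = {"guide_id": g.guide_id, "gene": g.gene, "protospacer": g.protospacer}
            if include_flag:
                row["is_ntc"] = str(g.is_ntc).lower()
            writer.writerow(row)


def write_fasta(lib: GuideLibrary, path: str | Path) -> None:
    """Export protospacers as FASTA (record id = guide_id)."""
    with Path(path).open("w") as fh:
        for g in lib.guides:
            fh.write(f">{g.guide_id}\n{g.protospacer}\n")


def build_synthetic_library(
    n_genes: int,
    guides_per_gene: int,
    n_ntc: int,
    protospacer_length: int = 20,
    seed: int = 0,
) -> GuideLibrary:
    """Build a deterministic synthetic library.

    Gene labels are ``G0001`` style; guide ids ``G0001_1`` / ``NTC_1`` style.
    All protospacers are distinct uniformly random ACGT sequences.

    Raises
    ------
    LibraryCapacityError
        If more guides are requested than ``4**protospacer_length`` distinct
        sequences exist.
    """
    if n_genes < 1 or guides_per_gene < 1 or n_ntc < 1:
        raise ValueError("n_genes, guides_per_gene and n_ntc must all be >= 1")
    if protospacer_length < 10:
        raise ValueError("protospacer_length must be >= 10 for a usable barcode")
    n_total = n_genes * guides_per_gene + n_ntc
    if n_total > 4 ** protospacer_length:
        raise LibraryCapacityError(
            f"{n_total} distinct protospacers requested but only "
            f"4^{protospacer_length} exist"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n_total:
        draw = rng.integers(0, 4, size=protospacer_length)
        s = "".join(bases[draw])
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    records: list[GuideRecord] = []
    it = iter(seqs)
    for gi in range(n_genes):
        gene = f"G{gi + 1:04d}"
        for k in range(guides_per_gene):
            records.append(GuideRecord(f"{gene}_{k + 1}", gene, next(it), False))
    for k in range(n_ntc):
        records.append(GuideRecord(f"NTC_{k + 1}", NTC_GENE, next(it), True))
    return GuideLibrary(records)


def validate_library(lib: GuideLibrary) -> list[str]:
    """Check library invariants; returns a list of human-readable violations.

    An empty list means the library is valid. Never raises.
    """
    violations: list[str] = []
    ids: dict[str, int] = {}
    ps: dict[str, int] = {}
    for g in lib.guides:
        ids[g.guide_id] = ids.get(g.guide_id, 0) + 1
        ps[g.protospacer] = ps.get(g.protospacer, 0) + 1
        if not _VALID_PROTOSPACER.match(g.protospacer):
            violations.append(
                f"guide {g.guide_id!r}: protospacer is not a 19-21 nt ACGT sequence"
            )
        if g.is_ntc != (g.gene == NTC_GENE):
            violations.append(
                f"guide {g.guide_id!r}: is_ntc flag inconsistent with gene label"
            )
    violations.extend(f"duplicate guide_id {i!r}" for i, c in ids.items() if c > 1)
    violations.extend(f"duplicate protospacer {p!r}" for p, c in ps.items() if c > 1)
    if lib.n_ntc < 2:
        violations.append(
            f"insufficient NTC guides ({lib.n_ntc}); at least 2 are required to "
            "form empirical-FDR pseudo-genes"
        )
    if not lib.targeting_genes:
        violations.append("library has no targeting genes")
    return violations


def example_validation_library() -> GuideLibrary:
    """The ten-guide knockdown-validation library (ADNP/TREM2/TCF4/TCF7L2 + NTCs)."""
    return GuideLibrary(
        [GuideRecord(gid, gene, ps, gene == NTC_GENE) for gid, gene, ps in VALIDATION_GUIDES]
    )
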