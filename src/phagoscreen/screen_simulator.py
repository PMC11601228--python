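"""Synthetic FACS-sort CRISPRi screen generator with known ground truth.

The generative model mirrors the stages of a pooled fluorescence-sorted
screen:

1. **Infection** — each cell receives ``k ~ Poisson(moi)`` guides drawn
   uniformly from the library; cells with no guide are discarded (antibiotic
   selection). At the low multiplicities used in practice (MOI ~0.15) most
   surviving cells carry a single guide.
2. **Phenotype** — a cell's log2 fluorescence is the baseline ``mu0`` plus
   the mean of its guides' gene effects ``gamma`` plus Gaussian noise.
3. **Sorting** — cells are ranked by fluorescence and the bottom and top
   ``q`` fractions (default quartiles) are collected; the middle is discarded.
4. **Sequencing** — each bin's guide tallies are converted to reads with a
   Dirichlet-multinomial, which keeps exact depth conservation while adding
   negative-binomial-like overdispersion ``phi``; ``phi = 0`` degenerates to
   a plain multinomial.

Replicates are generated independently from sub-generators derived from the
master seed, so every stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .guide_library import GuideLibrary

__all__ = [
    "ScreenConfig",
    "SimulatedCell",
    "CellPopulation",
    "SortedBins",
    "assign_guides",
    "simulate_fluorescence",
    "sort_cells",
    "sequence_bin",
    "simulate_screen",
    "write_fastq",
    "sample_name",
    "config_to_yaml",
    "config_from_yaml",
]

# Stage indices for sub-seed derivation: rng = default_rng([seed, replicate, stage])
_STAGE_ASSIGN, _STAGE_FLUOR, _STAGE_SEQ_LOW, _STAGE_SEQ_HIGH = 0, 1, 2, 3


@dataclass
class ScreenConfig:
    """Parameters of one simulated screen.

    ``effects`` maps gene label -> true log2-fluorescence shift ``gamma``;
    NTCs and unlisted genes are null. ``cells_per_guide`` is the mean number
    of surviving cells per library guide (coverage).
    """

    library: GuideLibrary
    moi: float = 0.15
    cells_per_guide: float = 500.0
    baseline_log2_fluor: float = 10.0
    noise_sd: float = 1.0
    effects: Mapping[str, float] = dataclass_field(default_factory=dict)
    sort_fraction: float = 0.25
    reads_per_bin: int = 1_000_000
    overdispersion: float = 0.01
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sort_fraction <= 0.5):
            raise ValueError("sort_fraction must be in (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.moi <= 0:
            raise ValueError("moi must be > 0")
        if self.reads_per_bin < 1:
            raise ValueError("reads_per_bin must be >= 1")

    @property
    def n_cells_target(self) -> int:
        """Surviving cells needed for the requested coverage."""
        return int(round(self.cells_per_guide * len(self.library)))


@dataclass(frozen=True)
class SimulatedCell:
    """Per-cell latent state: carried guide ids and (once set) log2 fluorescence."""

    guide_ids: tuple[str, ...]
    log2_fluor: float | None = None


class CellPopulation:
    """Vectorised container for simulated cells.

    Cells are stored as a ragged array: ``flat_guides`` holds guide indices
    for all cells concatenated, ``offsets`` delimits each cell's slice.
    ``log2_fluor`` is ``None`` until :func:`simulate_fluorescence` runs.
    """

    def __init__(self, library: GuideLibrary, flat_guides: np.ndarray,
                 offsets: np.ndarray, log2_fluor: np.ndarray | None = None):
        self.library = library
        self.flat_guides = flat_guides
        self.offsets = offsets  # length n_cells + 1
        self.log2_fluor = log2_fluor

    def __len__(self) -> int:
        return len(self.offsets) - 1

    @property
    def guides_per_cell(self) -> np.ndarray:
        return np.diff(self.offsets)

    def cells(self) -> Iterator[SimulatedCell]:
        """Iterate cells as :class:`SimulatedCell` records."""
        ids = self.library.guide_ids
        for i in range(len(self)):
            sl = self.flat_guides[self.offsets[i]:self.offsets[i + 1]]
            fl = None if self.log2_fluor is None else float(self.log2_fluor[i])
            yield SimulatedCell(tuple(ids[j] for j in sl), fl)


@dataclass
class SortedBins:
    """Guide tallies of the low and high fluorescence gates of one replicate."""

    low_tally: np.ndarray  # cells per guide, aligned to library order
    high_tally: np.ndarray
    n_cells_total: int
    n_cells_per_bin: int


def assign_guides(n_cells: int, library: GuideLibrary, moi: float,
                  seed: int | np.random.Generator) -> CellPopulation:
    """Infect ``n_cells`` cells at the given MOI and discard uninfected cells.

    Guide counts are Poisson; guides are drawn uniformly with replacement
    from the library. The returned population contains only cells with at
    least one guide (puromycin selection).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if len(library) == 0:
        raise ValueError("library is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = rng.poisson(moi, size=n_cells)
    k = k[k > 0]
    flat = rng.integers(0, len(library), size=int(k.sum()))
    offsets = np.concatenate([[0], np.cumsum(k)])
    return CellPopulation(library, flat, offsets)


def simulate_fluorescence(cells: CellPopulation, config: ScreenConfig,
                          seed: int | np.random.Generator | None = None) -> CellPopulation:
    """Set each cell's log2 fluorescence from its guides' gene effects.

    ``log2_fluor = mu0 + mean_over_guides(gamma(gene)) + Normal(0, sigma^2)``.
    Multi-guide cells average their guides' effects.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    gamma_per_guide = np.array(
        [0.0 if g.is_ntc else config.effects.get(g.gene, 0.0) for g in cells.library]
    )
    per_cell_sum = np.add.reduceat(gamma_per_guide[cells.flat_guides],
                                   cells.offsets[:-1])
    k = cells.guides_per_cell
    # reduceat on an empty slice returns the element at the offset; guard k>0
    if np.any(k == 0):
        raise ValueError("population contains guide-free cells")
    mean_gamma = per_cell_sum / k
    noise = rng.normal(0.0, config.noise_sd, size=len(cells))
    fluor = config.baseline_log2_fluor + mean_gamma + noise
    return CellPopulation(cells.library, cells.flat_guides, cells.offsets, fluor)


def sort_cells(cells: CellPopulation, q: float) -> SortedBins:
    """Two-gate FACS sort: bottom and top ``q`` fractions by fluorescence.

    Exactly ``floor(q * n)`` cells enter each bin; the middle is discarded.
    Ties are broken by stable input order.
    """
    if not (0 < q <= 0.5):
        raise ValueError("sort fraction q must be in (0, 0.5]")
    if cells.log2_fluor is None:
        raise ValueError("fluorescence not simulated yet")
    n = len(cells)
    if n < 4:
        raise ValueError("need at least 4 cells to sort")
    n_bin = int(np.floor(q * n))
    order = np.argsort(cells.log2_fluor, kind="stable")
    low_idx, high_idx = order[:n_bin], order[n - n_bin:]

    k = cells.guides_per_cell

    def tally(idx: np.ndarray) -> np.ndarray:
        # cells contribute one count per carried guide (each integrated
        # cassette is sequenced); expand cell membership to the flat layout
        in_bin = np.zeros(n, dtype=bool)
        in_bin[idx] = True
        per_guide = np.repeat(in_bin, k)
        return np.bincount(cells.flat_guides[per_guide],
                           minlength=len(cells.library)).astype(np.int64)

    return SortedBins(tally(low_idx), tally(high_idx), n, n_bin)


def sequence_bin(tally: np.ndarray | Mapping[str, int], library: GuideLibrary,
                 reads: int, phi: float,
                 seed: int | np.random.Generator) -> np.ndarray:
    """Convert a guide tally into sequencing read counts at fixed depth.

    Read proportions are ``Dirichlet(alpha_g = tally_g / phi)`` for
    ``phi > 0`` (overdispersed, negative-binomial-like marginals), or exactly
    proportional to the tally for ``phi = 0``; counts are then
    ``Multinomial(reads, proportions)`` and always sum to ``reads``.
    Guides absent from the tally have zero probability mass.
    """
    if isinstance(tally, Mapping):
        arr = np.zeros(len(library), dtype=float)
        ids = {gid: i for i, gid in enumerate(library.guide_ids)}
        for gid, c in tally.items():
            arr[ids[gid]] = c
    else:
        arr = np.asarray(tally, dtype=float)
    if reads < 1:
        raise ValueError("reads must be >= 1")
    if arr.sum() <= 0:
        raise ValueError("tally is all zero; nothing to sequence")
    if phi < 0:
        raise ValueError("overdispersion phi must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if phi == 0:
        p = arr / arr.sum()
    else:
        # Dirichlet via gamma draws; alpha=0 components stay exactly zero
        g = np.zeros_like(arr)
        pos = arr > 0
        g[pos] = rng.gamma(shape=arr[pos] / phi, scale=1.0)
        if g.sum() == 0:  # pathological underflow guard
            g[pos] = arr[pos]
        p = g / g.sum()
    return rng.multinomial(reads, p)


def sample_name(replicate: int, bin_label: str) -> str:
    """Canonical sample label, e.g. ``r1_low``."""
    return f"r{replicate}_{bin_label}"


def simulate_screen(config: ScreenConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full generative model for all replicates.

    Returns
    -------
    counts : DataFrame
        Guide x sample integer read counts, samples named ``r<rep>_<low|high>``.
    truth : DataFrame
        Columns ``gene``, ``gamma`` — the true effect of every targeting gene.
    """
    lib = config.library
    n_cells_initial = _initial_cells_for_coverage(config)
    columns: dict[str, np.ndarray] = {}
    for rep in range(1, config.n_replicates + 1):
        cells = assign_guides(
            n_cells_initial, lib, config.moi,
            np.random.default_rng([config.seed, rep, _STAGE_ASSIGN]),
        )
        cells = simulate_fluorescence(
            cells, config, np.random.default_rng([config.seed, rep, _STAGE_FLUOR])
        )
        bins = sort_cells(cells, config.sort_fraction)
        columns[sample_name(rep, "low")] = sequence_bin(
            bins.low_tally, lib, config.reads_per_bin, config.overdispersion,
            np.random.default_rng([config.seed, rep, _STAGE_SEQ_LOW]),
        )
        columns[sample_name(rep, "high")] = sequence_bin(
            bins.high_tally, lib, config.reads_per_bin, config.overdispersion,
            np.random.default_rng([config.seed, rep, _STAGE_SEQ_HIGH]),
        )
    counts = pd.DataFrame(columns, index=pd.Index(lib.guide_ids, name="guide_id"))
    truth = pd.DataFrame(
        {
            "gene": lib.targeting_genes,
            "gamma": [config.effects.get(g, 0.0) for g in lib.targeting_genes],
        }
    )
    return counts, truth


def config_to_yaml(config: ScreenConfig, path: str | Path,
                   library_path: str | Path) -> None:
    """Write a ScreenConfig to YAML (library referenced by CSV path)."""
    import yaml

    data = {
        "library": str(library_path),
        "moi": config.moi,
        "cells_per_guide": config.cells_per_guide,
        "baseline_log2_fluor": config.baseline_log2_fluor,
        "noise_sd": config.noise_sd,
        "effects": dict(config.effects),
        "sort_fraction": config.sort_fraction,
        "reads_per_bin": config.reads_per_bin,
        "overdispersion": config.overdispersion,
        "n_replicates": config.n_replicates,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def config_from_yaml(path: str | Path) -> ScreenConfig:
    """Load a ScreenConfig from YAML; the ``library`` key is a library CSV path."""
    import yaml

    from .guide_library import load_library

    data = yaml.safe_load(Path(path).read_text())
    lib = load_library(data.pop("library"))
    return ScreenConfig(library=lib, **data)


def _initial_cells_for_coverage(config: ScreenConfig) -> int:
    """Cells to infect so that the surviving population hits the target coverage."""
    survive = 1.0 - np.exp(-config.moi)
    return max(4, int(np.ceil(config.n_cells_target / survive)))


def write_fastq(
    counts: Mapping[str, Mapping[str, int] | pd.Series],
    library: GuideLibrary,
    out_dir: str | Path,
    five_prime: str = "AAAA",
    three_prime: str = "TT",
    seed: int = 0,
) -> dict[str, Path]:
    """Emit synthetic amplicon FASTQ: one read per count unit, per sample.

    Each read is ``five_prime + protospacer + three_prime`` with a constant
    Phred+33 'I' quality string. Read order within a sample is a seeded
    shuffle, so files are deterministic for a fixed seed. Files are named
    ``<sample>.fastq`` under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {g.guide_id: g.protospacer for g in library}
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    for sample, tab in counts.items():
        items = tab.items() if hasattr(tab, "items") else tab
        reads: list[str] = []
        for gid, c in items:
            reads.extend([by_id[gid]] * int(c))
        order = rng.permutation(len(reads))
        path = out_dir / f"{sample}.fastq"
        with path.open("w") as fh:
            for ri, idx in enumerate(order):
                seq = five_prime + reads[idx] + three_prime
                fh.write(f"@{sample}_read{ri}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sample] = path
    return paths
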