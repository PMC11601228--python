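"""Gene-level scoring of a sorted CRISPRi screen.

From a guide x sample count matrix the pipeline computes, per guide, the
log2 enrichment between the high- and low-phenotype sort bins (LFC) and a
robust z-score against the non-targeting controls (NTCs); per gene, a
weighted geometric-mean fold change, a two-sided Mann-Whitney U p-value of
the gene's guides against the NTC guides, a volcano score
``phenotype_lfc * (-log10 p)``, and two multiple-testing summaries: a
Benjamini-Hochberg q and an empirical FDR derived from NTC pseudo-genes
(groups of NTC guides scored exactly like genes). Hits are genes whose
empirical FDR in the tail matching the sign of their phenotype falls below
the threshold (default 0.01).

The empirical-FDR construction is the screen's main guard against
overdispersed count noise: because the pseudo-genes inherit every artefact
of the real NTC guides, the null score distribution is estimated from the
data itself rather than from a parametric model.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .guide_library import GuideLibrary
from .sgrna_counting import CountMatrix

__all__ = [
    "normalize_counts",
    "infer_replicate_pairs",
    "guide_lfc",
    "gene_test",
    "gene_phenotype",
    "make_pseudogenes",
    "empirical_fdr",
    "call_hits",
    "score_screen",
    "compare_screens",
]

#: Floor applied to |z| guide weights so no guide is silenced entirely.
MIN_GUIDE_WEIGHT = 0.25

#: Default hit-calling empirical-FDR threshold.
DEFAULT_ALPHA = 0.01

#: Default pseudocount added to raw counts before RPM scaling.
DEFAULT_PSEUDOCOUNT = 0.5


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def normalize_counts(counts: CountMatrix | pd.DataFrame,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Reads-per-million normalisation with a pseudocount.

    Per sample: ``(count + pseudocount) / sum(count + pseudocount) * 1e6``.
    The pseudocount is added before scaling so zero-count guides stay finite
    in log space.
    """
    df = _as_frame(counts).astype(float) + pseudocount
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"sample(s) with zero total counts: {bad}")
    return df / totals * 1e6


def infer_replicate_pairs(samples: Sequence[str]) -> list[tuple[str, str]]:
    """Pair ``<prefix>_high`` with ``<prefix>_low`` columns.

    Returns (high, low) tuples in prefix order of first appearance.
    """
    highs = {m.group(1): s for s in samples
             if (m := re.match(r"^(.*)_high$", s))}
    lows = {m.group(1): s for s in samples
            if (m := re.match(r"^(.*)_low$", s))}
    prefixes = [p for p in dict.fromkeys(list(highs) + list(lows))]
    pairs = []
    for p in prefixes:
        if p not in highs or p not in lows:
            raise ValueError(f"replicate {p!r} is missing its high or low sample")
        pairs.append((highs[p], lows[p]))
    if not pairs:
        raise ValueError("no <prefix>_high / <prefix>_low sample pairs found")
    return pairs


def guide_lfc(
    normalized: pd.DataFrame,
    library: GuideLibrary,
    replicate_pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-guide enrichment statistics.

    For each replicate ``r``: ``lfc_r = log2(RPM_high_r / RPM_low_r)``.
    ``lfc_mean`` averages replicates; ``z`` is a robust z-score of
    ``lfc_mean`` against the NTC guides,
    ``(lfc_mean - median(NTC)) / (1.4826 * MAD(NTC))``.

    Returns a DataFrame indexed by guide_id with columns ``gene``,
    ``is_ntc``, one ``lfc_<prefix>`` per replicate, ``lfc_mean`` and ``z``.
    """
    if replicate_pairs is None:
        replicate_pairs = infer_replicate_pairs(list(normalized.columns))
    for high, low in replicate_pairs:
        if high not in normalized.columns or low not in normalized.columns:
            raise ValueError(f"missing sample column {high!r} or {low!r}")
    out = pd.DataFrame(index=normalized.index.copy())
    gene_by_id = {g.guide_id: (g.gene, g.is_ntc) for g in library}
    missing = [gid for gid in out.index if gid not in gene_by_id]
    if missing:
        raise ValueError(f"guides absent from library: {missing[:5]}")
    out["gene"] = [gene_by_id[g][0] for g in out.index]
    out["is_ntc"] = [gene_by_id[g][1] for g in out.index]
    lfc_cols = []
    for high, low in replicate_pairs:
        col = f"lfc_{high.removesuffix('_high') or high}"
        out[col] = np.log2(normalized[high] / normalized[low])
        lfc_cols.append(col)
    out["lfc_mean"] = out[lfc_cols].mean(axis=1)
    ntc_lfc = out.loc[out["is_ntc"], "lfc_mean"].to_numpy()
    if len(ntc_lfc) == 0:
        raise ValueError("library has no NTC guides; z-scores undefined")
    center = np.median(ntc_lfc)
    spread = 1.4826 * stats.median_abs_deviation(ntc_lfc, scale=1.0)
    out["z"] = (out["lfc_mean"] - center) / spread if spread > 0 else np.nan
    return out


def gene_test(gene_guide_lfcs: Sequence[float],
              ntc_guide_lfcs: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value: gene guides vs NTC guides.

    Exact enumeration for very small groups (n1 <= 3, n2 <= 40, no ties),
    the realistic regime for a 2-guides-per-gene library; otherwise the
    normal approximation with continuity and tie correction.
    """
    x = np.asarray(gene_guide_lfcs, dtype=float)
    y = np.asarray(ntc_guide_lfcs, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("gene_test requires non-empty groups")
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 3 and len(y) <= 40 and no_ties) else "asymptotic"
    p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    return float(min(p, 1.0))


def gene_phenotype(lfc_means: Sequence[float], zs: Sequence[float] | None = None,
                   weight_mode: str = "abs_z") -> tuple[float, float]:
    """Aggregate guide LFCs into a gene fold change (weighted geometric mean).

    In ``abs_z`` mode weights are proportional to ``max(|z|, 0.25)`` so more
    confidently shifted guides dominate without silencing null-looking ones;
    ``equal`` mode is the plain geometric mean. Returns
    ``(phenotype_lfc, phenotype_fc)`` with ``fc = 2**lfc``.
    """
    lfcs = np.asarray(lfc_means, dtype=float)
    if lfcs.size == 0:
        raise ValueError("gene has no guides")
    if weight_mode == "equal" or zs is None:
        w = np.ones_like(lfcs)
    elif weight_mode == "abs_z":
        z = np.abs(np.asarray(zs, dtype=float))
        z = np.where(np.isfinite(z), z, MIN_GUIDE_WEIGHT)
        w = np.maximum(z, MIN_GUIDE_WEIGHT)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    w = w / w.sum()
    lfc = float(np.sum(w * lfcs))
    return lfc, float(2.0 ** lfc)


def make_pseudogenes(ntc_guide_ids: Sequence[str], group_size: int,
                     seed: int = 0, max_enumerate: int = 10_000,
                     n_sampled: int = 1000) -> list[tuple[str, ...]]:
    """Form NTC pseudo-genes: groups of ``group_size`` distinct NTC guides.

    All combinations are enumerated when their number is at most
    ``max_enumerate`` (28 choose 2 = 378 falls well inside); otherwise
    ``n_sampled`` groups are drawn without replacement within each group,
    deterministically for a fixed seed.
    """
    ids = list(ntc_guide_ids)
    if group_size > len(ids):
        raise ValueError(
            f"group_size {group_size} exceeds available NTC guides ({len(ids)})"
        )
    from math import comb

    if comb(len(ids), group_size) <= max_enumerate:
        return [tuple(c) for c in itertools.combinations(ids, group_size)]
    rng = np.random.default_rng(seed)
    groups = set()
    while len(groups) < n_sampled:
        pick = tuple(sorted(rng.choice(len(ids), size=group_size, replace=False)))
        groups.add(pick)
    return [tuple(ids[i] for i in g) for g in sorted(groups)]


def empirical_fdr(gene_scores: Sequence[float], pseudo_scores: Sequence[float],
                  tail: str = "positive") -> np.ndarray:
    """Per-gene empirical FDR (q-value style) from NTC pseudo-gene scores.

    For the positive tail the raw FDR at threshold ``s`` is the pseudo-gene
    tail frequency over the gene tail frequency,
    ``[(#pseudo >= s)/N_pseudo] / [(#gene >= s)/N_gene]``, clipped to
    [0, 1]; a gene's q is the minimum raw FDR over all thresholds at or
    below its own score, which makes q monotone non-increasing in score.
    The negative tail is the mirror image.
    """
    g = np.asarray(gene_scores, dtype=float)
    p = np.asarray(pseudo_scores, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one pseudo-gene score")
    if tail not in ("positive", "negative"):
        raise ValueError("tail must be 'positive' or 'negative'")
    sign = 1.0 if tail == "positive" else -1.0
    gs, ps = sign * g, sign * p
    order = np.argsort(-gs, kind="stable")  # descending = most extreme first
    sorted_scores = gs[order]
    n_gene_ge = np.arange(1, len(gs) + 1)
    # ties: every gene at a tied score shares the full tie-block count
    for i in range(len(sorted_scores) - 2, -1, -1):
        if sorted_scores[i] == sorted_scores[i + 1]:
            n_gene_ge[i] = n_gene_ge[i + 1]
    n_pseudo_ge = len(ps) - np.searchsorted(np.sort(ps), sorted_scores, side="left")
    raw = (n_pseudo_ge / len(ps)) / (n_gene_ge / len(gs))
    raw = np.clip(raw, 0.0, 1.0)
    # q = min raw FDR over thresholds at or below this score (suffix min)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _score_gene_table(guide_stats: pd.DataFrame, groups: Mapping[str, Sequence[str]],
                      ntc_lfcs_by_id: Mapping[str, float],
                      weight_mode: str) -> pd.DataFrame:
    """Score each group of guide ids like a gene (used for genes and pseudo-genes)."""
    rows = []
    for name, guide_ids in groups.items():
        sub = guide_stats.loc[list(guide_ids)]
        background = np.array([v for gid, v in ntc_lfcs_by_id.items()
                               if gid not in set(guide_ids)])
        p = gene_test(sub["lfc_mean"].to_numpy(), background)
        lfc, fc = gene_phenotype(sub["lfc_mean"].to_numpy(),
                                 sub["z"].to_numpy(), weight_mode)
        score = lfc * (-np.log10(max(p, 1e-300)))
        rows.append((name, lfc, fc, p, score))
    return pd.DataFrame(
        rows, columns=["gene", "phenotype_lfc", "phenotype_fc", "p_value", "score"]
    ).set_index("gene")


def call_hits(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Set ``hit_class`` from the tail-matched empirical FDR.

    ``increase`` for positive phenotypes with positive-tail q < alpha,
    ``decrease`` for negative phenotypes with negative-tail q < alpha,
    otherwise ``none``. The tails partition genes by phenotype sign, so a
    gene can never be called in both directions.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    out = results.copy()
    pos = (out["phenotype_lfc"] > 0) & (out["q_pos"] < alpha)
    neg = (out["phenotype_lfc"] < 0) & (out["q_neg"] < alpha)
    out["hit_class"] = np.select([pos, neg], ["increase", "decrease"], "none")
    out["empirical_fdr"] = np.where(out["phenotype_lfc"] > 0, out["q_pos"],
                                    np.where(out["phenotype_lfc"] < 0,
                                             out["q_neg"], 1.0))
    return out


def score_screen(
    counts: CountMatrix | pd.DataFrame,
    library: GuideLibrary,
    *,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    alpha: float = DEFAULT_ALPHA,
    weight_mode: str = "abs_z",
    pooled: bool = False,
    replicate_pairs: Sequence[tuple[str, str]] | None = None,
    pseudo_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scoring pipeline: counts -> gene results + guide stats.

    With ``pooled=True`` raw counts are summed across replicates per bin
    before normalisation (one pooled LFC instead of a per-replicate mean).

    Returns ``(gene_results, guide_stats)``; ``gene_results`` has columns
    ``phenotype_lfc``, ``phenotype_fc``, ``p_value``, ``score``, ``q_pos``,
    ``q_neg``, ``empirical_fdr``, ``bh_q`` and ``hit_class``.
    """
    df = _as_frame(counts)
    if replicate_pairs is None:
        replicate_pairs = infer_replicate_pairs(list(df.columns))
    if pooled:
        pooled_df = pd.DataFrame({
            "pooled_high": df[[h for h, _ in replicate_pairs]].sum(axis=1),
            "pooled_low": df[[l for _, l in replicate_pairs]].sum(axis=1),
        })
        df, replicate_pairs = pooled_df, [("pooled_high", "pooled_low")]
    normalized = normalize_counts(df, pseudocount)
    guide_stats = guide_lfc(normalized, library, replicate_pairs)

    ntc_stats = guide_stats[guide_stats["is_ntc"]]
    ntc_lfcs_by_id = dict(zip(ntc_stats.index, ntc_stats["lfc_mean"]))
    gene_groups: dict[str, list[str]] = {}
    for gid, row in guide_stats[~guide_stats["is_ntc"]].iterrows():
        gene_groups.setdefault(row["gene"], []).append(gid)
    if not gene_groups:
        raise ValueError("no targeting guides in count matrix")
    group_size = int(np.median([len(v) for v in gene_groups.values()]))
    pseudo_groups = {
        f"pseudo_{i}": list(g)
        for i, g in enumerate(make_pseudogenes(list(ntc_stats.index),
                                               max(1, group_size), pseudo_seed))
    }

    gene_results = _score_gene_table(guide_stats, gene_groups,
                                     ntc_lfcs_by_id, weight_mode)
    pseudo_results = _score_gene_table(guide_stats, pseudo_groups,
                                       ntc_lfcs_by_id, weight_mode)

    gene_results["q_pos"] = empirical_fdr(gene_results["score"],
                                          pseudo_results["score"], "positive")
    gene_results["q_neg"] = empirical_fdr(gene_results["score"],
                                          pseudo_results["score"], "negative")
    gene_results["bh_q"] = multipletests(gene_results["p_value"],
                                         method="fdr_bh")[1]
    gene_results = call_hits(gene_results, alpha)
    return gene_results, guide_stats


def compare_screens(results_by_screen: Mapping[str, pd.DataFrame]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-screen phenotype matrix for genes hit in at least one screen.

    Returns ``(lfc_matrix, significant)``: gene x screen phenotype LFCs and
    a boolean flag matrix. Screens must share the same gene universe.
    """
    if len(results_by_screen) < 2:
        raise ValueError("need at least two screens to compare")
    names = list(results_by_screen)
    universe = set(results_by_screen[names[0]].index)
    for name in names[1:]:
        other = set(results_by_screen[name].index)
        if other != universe:
            diff = sorted(universe.symmetric_difference(other))
            raise ValueError(f"gene sets differ between screens: {diff}")
    lfc = pd.DataFrame({n: r["phenotype_lfc"] for n, r in results_by_screen.items()})
    sig = pd.DataFrame({n: r["hit_class"] != "none"
                        for n, r in results_by_screen.items()})
    keep = sig.any(axis=1)
    return lfc[keep], sig[keep]
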