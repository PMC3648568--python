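"""Sliding-window hotspot statistic for significant-feature aggregation.

The genome is tiled with 1000-kb blocks advancing by 500 kb; each window's
count of significant features (DEGs or differentially hybridized probes) is
tested against an upper-tail binomial null whose rate is the genome-wide
significant fraction.  Runs of significant windows that overlap or abut are
merged into aggregation regions.

The per-window binomial test carries no multiplicity adjustment (the window
scan reports a raw threshold); the chip-region caller, whose job is to
nominate a handful of polymorphic candidate regions genome-wide, applies a
Bonferroni-corrected threshold by default so that its output is controlled
at the genome level.  A label-permutation null is available as an
alternative to the binomial model for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .genome_model import (
    GeneRecord,
    GenomeWindow,
    chromosome_sort_key,
    chromosome_lengths as _catalog_lengths,
)

__all__ = [
    "AggregationRegion",
    "window_scan",
    "merge_regions",
    "chip_polymorphic_regions",
    "count_distinct_regions",
]


@dataclass
class AggregationRegion:
    """A maximal union of overlapping/abutting significant windows."""

    chromosome: str
    start_bp: int
    end_bp: int
    member_windows: list[GenomeWindow]
    n_hits: int | None = None
    n_features: int | None = None
    min_p: float = 1.0

    def overlaps_interval(self, chromosome: str, start_bp: int, end_bp: int) -> bool:
        return (
            self.chromosome == chromosome
            and self.start_bp < end_bp
            and start_bp < self.end_bp
        )


def _window_starts(length: int, step_bp: int) -> np.ndarray:
    return np.arange(0, max(length, 1), step_bp, dtype=np.int64)


def window_scan(
    catalog: Sequence[GeneRecord],
    significant: set[str] | Sequence[str],
    block_size_bp: int = 1_000_000,
    step_bp: int = 500_000,
    alpha: float = 0.01,
    chrom_lengths: dict[str, int] | None = None,
    method: Literal["binomial", "permutation"] = "binomial",
    n_permutations: int = 1_000,
    seed: int = 0,
) -> list[GenomeWindow]:
    """Tile each chromosome with sliding windows and test feature aggregation.

    Parameters
    ----------
    catalog : sequence of GeneRecord
        Positioned features (genes or probes); midpoints place features in
        windows.
    significant : set of feature ids
        Features flagged significant by the upstream per-feature test.
    block_size_bp, step_bp : int
        Window geometry; windows are clipped (not discarded) at chromosome
        ends, so every interior feature contributes to ``block//step``
        windows.
    alpha : float
        Raw per-window significance threshold.
    method : {"binomial", "permutation"}
        ``binomial``: exact upper-tail binomial test at the genome-wide
        significant fraction.  ``permutation``: significance labels are
        shuffled over feature positions; the p-value is the fraction of
        shuffles reaching the observed window count (add-one corrected).
    """
    if step_bp > block_size_bp:
        raise ValueError("step_bp must not exceed block_size_bp")
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")
    sig = set(significant)
    lengths = dict(_catalog_lengths(catalog))
    if chrom_lengths:
        lengths.update(chrom_lengths)

    total = len(catalog)
    n_sig = sum(1 for g in catalog if g.id in sig)
    p0 = n_sig / total if total else 0.0

    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in catalog:
        by_chrom.setdefault(g.chromosome, []).append(g)

    windows: list[GenomeWindow] = []
    rng = np.random.default_rng(seed)
    if method == "permutation":
        # permute labels over all feature positions genome-wide
        flags = np.array([g.id in sig for g in catalog])
        offsets = {}
        start = 0
        for chrom in sorted(by_chrom, key=chromosome_sort_key):
            offsets[chrom] = (start, start + len(by_chrom[chrom]))
            start += len(by_chrom[chrom])
        perm_flags = np.empty((n_permutations, total), dtype=bool)
        for b in range(n_permutations):
            perm_flags[b] = rng.permutation(flags)

    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        genes = by_chrom[chrom]
        mids = np.array([g.midpoint_bp for g in genes], dtype=np.int64)
        is_hit = np.array([g.id in sig for g in genes])
        order = np.argsort(mids, kind="stable")
        mids = mids[order]
        is_hit = is_hit[order]
        length = lengths.get(chrom, int(mids.max()) + 1 if len(mids) else 1)
        starts = _window_starts(length, step_bp)
        ends = np.minimum(starts + block_size_bp, length)
        lo = np.searchsorted(mids, starts, side="left")
        hi = np.searchsorted(mids, ends, side="left")
        cum_hits = np.concatenate([[0], np.cumsum(is_hit)])
        counts = hi - lo
        hits = cum_hits[hi] - cum_hits[lo]
        if method == "binomial":
            if p0 <= 0:
                p_vals = np.ones(len(starts))
            else:
                with np.errstate(divide="ignore"):
                    p_vals = stats.binom.sf(hits - 1, counts, p0)
                p_vals = np.where(counts == 0, 1.0, p_vals)
        else:
            s0, s1 = offsets[chrom]
            chrom_perm = perm_flags[:, s0:s1][:, order]
            cum = np.concatenate(
                [np.zeros((n_permutations, 1)), np.cumsum(chrom_perm, axis=1)], axis=1
            )
            perm_counts = cum[:, hi] - cum[:, lo]  # (B, windows)
            p_vals = (1.0 + (perm_counts >= hits).sum(axis=0)) / (n_permutations + 1.0)
            p_vals = np.where(counts == 0, 1.0, p_vals)
        p_vals = np.clip(p_vals, np.finfo(float).tiny, 1.0)
        for k in range(len(starts)):
            windows.append(
                GenomeWindow(
                    chromosome=chrom,
                    start_bp=int(starts[k]),
                    end_bp=int(ends[k]),
                    gene_count=int(counts[k]),
                    hit_count=int(hits[k]),
                    p_value=float(p_vals[k]),
                    significant=bool(p_vals[k] < alpha),
                )
            )
    return windows


def merge_regions(
    windows: Sequence[GenomeWindow],
    catalog: Sequence[GeneRecord] | None = None,
    significant: set[str] | Sequence[str] | None = None,
) -> list[AggregationRegion]:
    """Merge significant windows that overlap or abut into maximal regions.

    Non-significant windows are never included.  When the scanned ``catalog``
    (and its significant ids) is supplied, per-region feature and hit counts
    are recomputed exactly over the merged span; otherwise they are left as
    ``None`` (overlapping member windows double-count features).
    """
    sig_windows = sorted(
        (w for w in windows if w.significant),
        key=lambda w: (chromosome_sort_key(w.chromosome), w.start_bp),
    )
    regions: list[AggregationRegion] = []
    for w in sig_windows:
        if (
            regions
            and regions[-1].chromosome == w.chromosome
            and w.start_bp <= regions[-1].end_bp
        ):
            r = regions[-1]
            r.end_bp = max(r.end_bp, w.end_bp)
            r.member_windows.append(w)
            r.min_p = min(r.min_p, w.p_value)
        else:
            regions.append(
                AggregationRegion(
                    chromosome=w.chromosome,
                    start_bp=w.start_bp,
                    end_bp=w.end_bp,
                    member_windows=[w],
                    min_p=w.p_value,
                )
            )
    if catalog is not None:
        sig = set(significant or ())
        for r in regions:
            in_region = [
                g
                for g in catalog
                if g.chromosome == r.chromosome
                and r.start_bp <= g.midpoint_bp < r.end_bp
            ]
            r.n_features = len(in_region)
            r.n_hits = sum(1 for g in in_region if g.id in sig)
    return regions


def chip_polymorphic_regions(
    calls,
    probe_catalog: Sequence[GeneRecord],
    block_size_bp: int = 1_000_000,
    step_bp: int = 500_000,
    alpha: float = 0.01,
    chrom_lengths: dict[str, int] | None = None,
    genomewide_correction: bool = True,
) -> list[AggregationRegion]:
    """Polymorphic genome blocks from probe-level differential-hybridization calls.

    Composition ``window_scan`` then ``merge_regions`` with the standard
    1000 kb / 500 kb geometry.  By default the window threshold is Bonferroni
    corrected (``alpha / n_windows``) so the caller's output is controlled
    genome-wide: its purpose is to nominate the few truly polymorphic blocks
    for marker development, not to echo every locally elevated window.
    Set ``genomewide_correction=False`` for the raw per-window threshold.
    """
    from .diffexpr import significant_ids

    sig = significant_ids(calls) if not isinstance(calls, (set, frozenset)) else calls
    windows = window_scan(
        probe_catalog,
        sig,
        block_size_bp=block_size_bp,
        step_bp=step_bp,
        alpha=1.0,  # decide significance below, once n_windows is known
        chrom_lengths=chrom_lengths,
    )
    threshold = alpha / len(windows) if (genomewide_correction and windows) else alpha
    for w in windows:
        w.significant = w.p_value < threshold
    return merge_regions(windows, probe_catalog, sig)


def count_distinct_regions(
    region_sets: Sequence[Sequence[AggregationRegion]],
) -> int:
    """Number of distinct genome regions in the union of per-tissue region sets.

    Regions from different tissues that overlap or abut are counted once,
    matching the "distinct aggregation regions" bookkeeping used when
    summarizing scans across tissues.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for regions in region_sets:
        for r in regions:
            spans.setdefault(r.chromosome, []).append((r.start_bp, r.end_bp))
    n = 0
    for chrom, ivs in spans.items():
        ivs.sort()
        cur_end = None
        for s, e in ivs:
            if cur_end is None or s > cur_end:
                n += 1
                cur_end = e
            else:
                cur_end = max(cur_end, e)
    return n
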