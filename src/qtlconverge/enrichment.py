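"""Fisher-exact overlap tests: DEGs vs QTL intervals and annotation categories.

The 2x2 machinery conditions on both margins (hypergeometric null).  The
one-sided "greater" test answers the enrichment question and is the default;
two-sided p-values follow the minimum-likelihood rule (sum of all
margin-fixed tables no more probable than the observed one).  No
multiple-testing correction gates the primary output — the raw p < 0.05
decision rule is what the downstream candidate nomination consumes — but a
Benjamini-Hochberg column is emitted alongside in the tabular output for
the user's benefit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GeneRecord, QtlInterval, genes_in_interval

__all__ = [
    "EnrichmentResult",
    "fisher_exact_2x2",
    "qtl_region_enrichment",
    "category_enrichment",
    "enrichment_to_frame",
]

Sided = Literal["greater", "two_sided"]


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 overlap table with its Fisher test, plus the overlapping genes."""

    set_name: str
    universe_size: int
    set_size: int
    region_or_category_size: int
    overlap: int
    odds_ratio: float
    p_value: float
    genes_in_overlap: tuple[str, ...] = ()

    def __post_init__(self):
        if self.overlap > min(self.set_size, self.region_or_category_size):
            raise ValueError("overlap exceeds a margin")


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, sided: Sided = "greater"
) -> tuple[float, float]:
    """Fisher exact test for the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p_value)``.  The odds ratio is the sample
    cross-product ratio (``inf`` when only the concordant diagonal is
    populated, ``nan`` when a margin is zero).  A zero margin makes the
    table degenerate: p = 1.

    Raises
    ------
    ValueError
        If any count is negative or all counts are zero.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    if n == 0:
        raise ValueError("at least one count must be positive")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("inf") if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)

    if sided == "greater":
        p = float(stats.hypergeom.sf(a - 1, n, r1, c1))
    elif sided == "two_sided":
        k_lo = max(0, c1 - r2)
        k_hi = min(r1, c1)
        support = np.arange(k_lo, k_hi + 1)
        pmf = stats.hypergeom.pmf(support, n, r1, c1)
        p_obs = pmf[a - k_lo]
        p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    else:
        raise ValueError(f"unknown sidedness: {sided!r}")
    return odds, float(min(max(p, np.finfo(float).tiny), 1.0))


def _enrich(
    set_name: str,
    universe: set[str],
    gene_set: set[str],
    region_genes: set[str],
    sided: Sided,
) -> EnrichmentResult:
    overlap_genes = sorted(gene_set & region_genes)
    a = len(overlap_genes)
    b = len(region_genes) - a
    c = len(gene_set) - a
    d = len(universe) - a - b - c
    odds, p = fisher_exact_2x2(a, b, c, d, sided=sided)
    return EnrichmentResult(
        set_name=set_name,
        universe_size=len(universe),
        set_size=len(gene_set),
        region_or_category_size=len(region_genes),
        overlap=a,
        odds_ratio=odds,
        p_value=p,
        genes_in_overlap=tuple(overlap_genes),
    )


def qtl_region_enrichment(
    calls,
    catalog: Sequence[GeneRecord],
    intervals: Sequence[QtlInterval],
    universe: Literal["all_genes", "tested_genes"] = "all_genes",
    assignment: str = "midpoint",
    sided: Sided = "greater",
) -> list[EnrichmentResult]:
    """Fisher enrichment of DEGs within each QTL interval.

    The 2x2 table crosses {in-interval vs out} with {DEG vs non-DEG} over
    the chosen universe (all catalog genes, or only genes with a test
    result).  Each result carries the DEG-in-interval gene list for
    candidate nomination.
    """
    from .diffexpr import significant_ids

    if isinstance(calls, (set, frozenset)):
        sig = set(calls)
        tested = None
    else:
        sig = significant_ids(calls)
        tested = {c.feature_id for c in calls}
    if universe == "all_genes":
        uni = {g.id for g in catalog}
    elif universe == "tested_genes":
        if tested is None:
            raise ValueError("tested_genes universe requires full call objects")
        uni = tested
    else:
        raise ValueError(f"unknown universe: {universe!r}")
    if not uni:
        raise ValueError("empty universe")
    sig &= uni

    results = []
    for iv in intervals:
        region_genes = {
            g.id for g in genes_in_interval(catalog, iv, assignment=assignment)
        } & uni
        results.append(_enrich(iv.name, uni, sig, region_genes, sided))
    return results


def category_enrichment(
    gene_subset: set[str] | Sequence[str],
    annotation: pd.DataFrame,
    catalog: Sequence[GeneRecord] | set[str],
    sided: Sided = "greater",
) -> list[EnrichmentResult]:
    """Fisher enrichment of a gene subset against annotation categories.

    ``annotation`` maps gene ids to category ids (many-to-many) with columns
    ``gene_id, namespace, category_id, category_label``.  One result is
    returned per category with overlap >= 1, named
    ``"namespace|category_label"``.  Subset genes absent from the universe
    are excluded with a warning.
    """
    uni = (
        {g.id for g in catalog}
        if not isinstance(catalog, (set, frozenset))
        else set(catalog)
    )
    if not uni:
        raise ValueError("empty universe")
    subset = set(gene_subset)
    stray = subset - uni
    if stray:
        warnings.warn(
            f"{len(stray)} subset gene(s) absent from the universe were excluded",
            stacklevel=2,
        )
        subset &= uni

    results = []
    grouped = annotation.groupby(["namespace", "category_id", "category_label"])[
        "gene_id"
    ]
    for (namespace, _cat_id, label), members in grouped:
        cat_genes = set(members) & uni
        if not (subset & cat_genes):
            continue
        results.append(
            _enrich(f"{namespace}|{label}", uni, subset, cat_genes, sided)
        )
    return sorted(results, key=lambda r: (r.p_value, r.set_name))


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular output mirroring the enrichment-report schema.

    Columns: set name, counts, odds ratio, raw Fisher p, and a
    Benjamini-Hochberg adjusted column (informational; the raw p is the
    decision column).
    """
    from statsmodels.stats.multitest import multipletests

    df = pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "universe_size": [r.universe_size for r in results],
            "set_size": [r.set_size for r in results],
            "region_or_category_size": [r.region_or_category_size for r in results],
            "overlap": [r.overlap for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "genes_in_overlap": [",".join(r.genes_in_overlap) for r in results],
        }
    )
    if len(df):
        df["bh_fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["bh_fdr"] = pd.Series(dtype=float)
    return df
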