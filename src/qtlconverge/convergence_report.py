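"""Convergence step: candidate genes at the QTL x DEG x hotspot intersection,
multi-environment yield-advantage summaries, and the end-to-end pipeline.

A candidate gene is a DEG (any tissue) lying inside a named QTL interval;
its flag records whether it also falls in a DEG aggregation region, giving
the two headline counts (total DEGs in QTL, and the subset also inside
hotspots).  Yield advantages are exact cell differences against the check
entry; optionally, differences below the trial's printed LSD(0.05) are
excluded so the summary range covers only statistically supported
advantages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import AggregationRegion, chip_polymorphic_regions, merge_regions, window_scan
from .diffexpr import (
    call_degs,
    call_hybridization_polymorphisms,
    diffcalls_to_frame,
    significant_ids,
)
from .enrichment import enrichment_to_frame, qtl_region_enrichment
from .genome_model import (
    GeneRecord,
    QtlInterval,
    catalog_to_frame,
    genes_in_interval,
)
from .qtl_mapping import QTLScan
from .synthetic_data import (
    BIL_PAIRS,
    TISSUES,
    SimulationConfig,
    make_trial_table,
    simulate_expression,
    simulate_hybridization,
    simulate_mapping_population,
)

__all__ = [
    "CandidateGene",
    "AdvantageSummary",
    "nominate_candidates",
    "yield_advantage",
    "run_pipeline",
]


@dataclass(frozen=True)
class CandidateGene:
    """A DEG inside a named QTL interval, with its supporting evidence."""

    gene_id: str
    chromosome: str
    position_bp: int
    qtl_name: str
    in_aggregation_region: bool
    tissues_supporting: frozenset
    effect_direction: int  # sign of the +QTL minus -QTL effect
    categories: frozenset


@dataclass
class AdvantageSummary:
    """Per-cell yield advantages over the check entry, with their range."""

    advantages: pd.DataFrame  # entry, environment, advantage_kg_ha, significant
    check_entry: str
    regime: str
    min_advantage_kg_ha: float
    max_advantage_kg_ha: float


def nominate_candidates(
    calls_by_tissue: Mapping[str, Sequence],
    regions_by_tissue: Mapping[str, Sequence[AggregationRegion]],
    qtl_intervals: Sequence[QtlInterval],
    catalog: Sequence[GeneRecord],
    assignment: str = "midpoint",
) -> tuple[list[CandidateGene], dict[str, int]]:
    """Candidate genes and the headline convergence counts.

    Candidates are DEGs (union over tissues) whose gene lies in a QTL
    interval; ``in_aggregation_region`` is set by overlap with any tissue's
    aggregation regions.  Returns the candidate list plus
    ``{"degs_in_qtl": ..., "degs_in_qtl_and_region": ...}``.

    Raises ``ValueError`` if any call references a feature missing from the
    catalog (mismatched catalogs).
    """
    by_id = {g.id: g for g in catalog}
    deg_tissues: dict[str, set[str]] = {}
    deg_effect: dict[str, float] = {}
    for tissue, calls in calls_by_tissue.items():
        for call in calls:
            if call.feature_id not in by_id:
                raise ValueError(
                    f"call for {call.feature_id!r} does not match the gene catalog"
                )
            if call.significant:
                deg_tissues.setdefault(call.feature_id, set()).add(tissue)
                deg_effect.setdefault(call.feature_id, call.effect)

    all_regions = [r for regions in regions_by_tissue.values() for r in regions]
    candidates: list[CandidateGene] = []
    for iv in qtl_intervals:
        for g in genes_in_interval(catalog, iv, assignment=assignment):
            if g.id not in deg_tissues:
                continue
            in_region = any(
                r.overlaps_interval(g.chromosome, g.start_bp, g.end_bp)
                for r in all_regions
            )
            effect = deg_effect.get(g.id, 0.0)
            candidates.append(
                CandidateGene(
                    gene_id=g.id,
                    chromosome=g.chromosome,
                    position_bp=g.midpoint_bp,
                    qtl_name=iv.name,
                    in_aggregation_region=in_region,
                    tissues_supporting=frozenset(deg_tissues[g.id]),
                    effect_direction=int(np.sign(effect)),
                    categories=g.categories,
                )
            )
    counts = {
        "degs_in_qtl": len({c.gene_id for c in candidates}),
        "degs_in_qtl_and_region": len(
            {c.gene_id for c in candidates if c.in_aggregation_region}
        ),
    }
    return candidates, counts


def candidates_to_frame(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in candidates],
            "chromosome": [c.chromosome for c in candidates],
            "position_bp": [c.position_bp for c in candidates],
            "qtl_name": [c.qtl_name for c in candidates],
            "in_aggregation_region": [c.in_aggregation_region for c in candidates],
            "tissues_supporting": [
                ",".join(sorted(c.tissues_supporting)) for c in candidates
            ],
            "effect_direction": [c.effect_direction for c in candidates],
            "categories": [",".join(sorted(c.categories)) for c in candidates],
        }
    )


def yield_advantage(
    trial_table: pd.DataFrame,
    check_entry: str = "IR64",
    regime: str = "drought",
    entries: Sequence[str] | None = None,
    environments: Sequence[str] | None = None,
    exclude_below_lsd: bool = False,
    lsd_entry: str = "LSD",
) -> AdvantageSummary:
    """Per-environment yield advantage of each entry over the check.

    Works on the long trial-table schema (entry, environment, regime,
    yield_kg_ha).  Differences are exact cell arithmetic.  With
    ``exclude_below_lsd``, advantages smaller than the environment's LSD row
    are dropped from the summary range (only statistically supported
    advantages remain); all computed advantages stay in the table with their
    ``significant`` flag.  Environments missing the check value are excluded
    with a warning.
    """
    t = trial_table[trial_table["regime"] == regime]
    if environments is not None:
        t = t[t["environment"].isin(environments)]
    lsd = (
        t[t["entry"] == lsd_entry].set_index("environment")["yield_kg_ha"]
        if lsd_entry in set(t["entry"])
        else pd.Series(dtype=float)
    )
    t = t[t["entry"] != lsd_entry]
    if entries is None:
        entries = [e for e in t["entry"].unique() if e != check_entry]
    check = t[t["entry"] == check_entry].set_index("environment")["yield_kg_ha"]

    rows = []
    for env in t["environment"].unique():
        if env not in check.index:
            warnings.warn(f"check entry missing in {env!r}; environment excluded")
            continue
        sub = t[(t["environment"] == env) & (t["entry"].isin(entries))]
        for r in sub.itertuples(index=False):
            adv = r.yield_kg_ha - check[env]
            sig = bool(adv >= lsd[env]) if env in lsd.index else True
            rows.append(
                {
                    "entry": r.entry,
                    "environment": env,
                    "advantage_kg_ha": adv,
                    "significant": sig,
                }
            )
    adv_df = pd.DataFrame(rows, columns=["entry", "environment", "advantage_kg_ha", "significant"])
    scope = adv_df[adv_df["significant"]] if exclude_below_lsd else adv_df
    values = scope["advantage_kg_ha"]
    return AdvantageSummary(
        advantages=adv_df,
        check_entry=check_entry,
        regime=regime,
        min_advantage_kg_ha=float(values.min()) if len(values) else float("nan"),
        max_advantage_kg_ha=float(values.max()) if len(values) else float("nan"),
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    n_perm: int = 200,
    deg_alpha: float = 0.001,
    window_alpha: float = 0.01,
) -> dict:
    """Simulate the full study design and run every analysis stage.

    Returns a dict with the intermediate objects and headline numbers; when
    ``out_dir`` is given, writes deterministic TSV/BED outputs plus a
    markdown report.
    """
    expr = simulate_expression(config)
    hyb = simulate_hybridization(config)
    pop = simulate_mapping_population(config)
    chrom_lengths = {
        f"chr{i + 1}": config.chromosome_length_bp for i in range(config.n_chromosomes)
    }

    # per-tissue DEG calls pooled over the two BIL pairs
    calls_by_tissue: dict[str, list] = {}
    for tissue in TISSUES:
        calls: list = []
        for pair in BIL_PAIRS.values():
            calls.extend(
                call_degs(expr.matrix, expr.samples, pair, tissue, alpha=deg_alpha)
            )
        calls_by_tissue[tissue] = calls

    regions_by_tissue = {}
    for tissue, calls in calls_by_tissue.items():
        sig = significant_ids(calls)
        windows = window_scan(
            expr.catalog, sig, alpha=window_alpha, chrom_lengths=chrom_lengths
        )
        regions_by_tissue[tissue] = merge_regions(windows, expr.catalog, sig)

    sfp_calls = call_hybridization_polymorphisms(
        hyb.matrix, hyb.samples, BIL_PAIRS["pair1"]
    )
    chip_regions = chip_polymorphic_regions(
        sfp_calls, hyb.probes, chrom_lengths=chrom_lengths
    )
    qtl_intervals = [
        QtlInterval(f"q{r.chromosome[3:]}.{i + 1}", r.chromosome, r.start_bp, r.end_bp)
        for i, r in enumerate(chip_regions)
    ]

    scan = QTLScan(pop.genotypes, pop.phenotype, pop.marker_map).fit(
        method="interval", n_perm=n_perm, alpha=0.01, perm_seed=config.seed
    )

    pooled_calls = [c for calls in calls_by_tissue.values() for c in calls]
    enrich = qtl_region_enrichment(pooled_calls, expr.catalog, qtl_intervals)
    candidates, counts = nominate_candidates(
        calls_by_tissue, regions_by_tissue, qtl_intervals, expr.catalog
    )
    trial = make_trial_table("table6")
    adv = yield_advantage(trial, exclude_below_lsd=True)

    result = {
        "expression": expr,
        "hybridization": hyb,
        "population": pop,
        "calls_by_tissue": calls_by_tissue,
        "regions_by_tissue": regions_by_tissue,
        "chip_regions": chip_regions,
        "qtl_intervals": qtl_intervals,
        "scan": scan,
        "enrichment": enrich,
        "candidates": candidates,
        "counts": counts,
        "advantage": adv,
    }
    if out_dir is not None:
        _write_outputs(Path(out_dir), result)
    return result


def _write_outputs(out_dir: Path, result: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog_to_frame(result["expression"].catalog).to_csv(
        out_dir / "gene_catalog.tsv", sep="\t", index=False
    )
    for tissue, calls in result["calls_by_tissue"].items():
        diffcalls_to_frame(calls).to_csv(
            out_dir / f"deg_calls_{tissue}.tsv", sep="\t", index=False
        )
    with open(out_dir / "aggregation_regions.bed", "w") as fh:
        for tissue, regions in sorted(result["regions_by_tissue"].items()):
            for r in regions:
                fh.write(
                    f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{tissue}_hotspot\n"
                )
    with open(out_dir / "chip_regions.bed", "w") as fh:
        for r in result["chip_regions"]:
            fh.write(f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\tpolymorphic\n")
    enrichment_to_frame(result["enrichment"]).to_csv(
        out_dir / "qtl_enrichment.tsv", sep="\t", index=False
    )
    result["scan"].peaks().to_csv(out_dir / "qtl_peaks.tsv", sep="\t", index=False)
    candidates_to_frame(result["candidates"]).to_csv(
        out_dir / "candidate_genes.tsv", sep="\t", index=False
    )

    counts = result["counts"]
    adv = result["advantage"]
    lines = [
        "# Convergent QTL-transcriptome report",
        "",
        "## QTL scan",
        "",
        "```",
        result["scan"].summary(),
        "```",
        "",
        "## Chip-defined polymorphic regions",
        "",
    ]
    for r in result["chip_regions"]:
        lines.append(
            f"- {r.chromosome}:{(r.start_bp + 1) / 1e6:.1f}-{r.end_bp / 1e6:.1f} Mb "
            f"(min window p = {r.min_p:.3g})"
        )
    lines += [
        "",
        "## Convergence counts",
        "",
        f"- DEGs within QTL intervals: {counts['degs_in_qtl']}",
        f"- ... of which inside DEG aggregation regions: "
        f"{counts['degs_in_qtl_and_region']}",
        "",
        "## Yield advantage over the check (drought regime, above-LSD cells)",
        "",
        f"- range: {adv.min_advantage_kg_ha:.0f} to {adv.max_advantage_kg_ha:.0f} kg/ha",
        "",
    ]
    (out_dir / "report.md").write_text("\n".join(lines))
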