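"""Synthetic inputs emulating the IR64 x Aday Sel BIL study design.

Every stage of the pipeline can be exercised without downloading array or
field data: the generators here produce gene/probe catalogs, expression and
genomic-hybridization intensity matrices for the two +QTL/-QTL BIL pairs
(three tissues, two soil-drying severities), backcross-inbred mapping
populations with planted yield QTL, and multi-environment trial tables.
Each generator returns the ground truth it planted, so recall/precision and
calibration are computable exactly downstream.

All generators are pure functions of their :class:`SimulationConfig`: the
config seed is combined with a generator-specific stream tag, so repeated
calls are bit-identical and the individual generators are independent.

The packaged trial tables (``data/table5_irri_yield.tsv``,
``data/table6_target_sites_yield.tsv``) transcribe the multi-location grain
yields of the IR64 QTL-introgression lines (IRRI dry-season screening, and
the Bangladesh/Nepal/India target sites) cell by cell; ``make_trial_table``
loads them into the long trial-table schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    GeneRecord,
    QtlInterval,
    SampleMeta,
    ValidationError,
    normalize_chromosome,
    sort_catalog,
)

__all__ = [
    "ConfigError",
    "Hotspot",
    "PlantedQtl",
    "MappingPopulationConfig",
    "TrialConfig",
    "SimulationConfig",
    "DEFAULT_QTL_INTERVALS",
    "BIL_PAIRS",
    "ExpressionData",
    "HybridizationData",
    "MappingPopulation",
    "generate_gene_catalog",
    "simulate_expression",
    "simulate_hybridization",
    "simulate_mapping_population",
    "simulate_annotation",
    "make_trial_table",
]


class ConfigError(ValueError):
    """A simulation configuration violated an invariant."""


# the four chip-defined polymorphic regions of the study system
DEFAULT_QTL_INTERVALS: tuple[QtlInterval, ...] = (
    QtlInterval("qDTY2.2", "chr2", 6_800_000, 7_300_000, "chip_defined"),
    QtlInterval("qDTY4.1", "chr4", 6_700_000, 7_200_000, "chip_defined"),
    QtlInterval("qDTY9.1", "chr9", 14_600_000, 16_500_000, "chip_defined"),
    QtlInterval("qDTY10.1", "chr10", 18_600_000, 19_300_000, "chip_defined"),
)

#: (+QTL line, -QTL line) for the two contrasted BIL pairs
BIL_PAIRS: dict[str, tuple[str, str]] = {
    "pair1": ("IR77298-5-6-B-18", "IR77298-5-6-B-11"),
    "pair2": ("IR77298-14-1-2-B-10", "IR77298-14-1-2-B-13"),
}

TISSUES = ("root", "leaf", "panicle")
STRESS_LEVELS = ("FTSW_0.5", "FTSW_0.2")

# per-generator random-stream tags (combined with the config seed)
_STREAM_CATALOG = 11
_STREAM_EXPRESSION = 12
_STREAM_HYBRIDIZATION = 13
_STREAM_MAPPING = 14
_STREAM_TRIAL = 15
_STREAM_ANNOTATION = 16


@dataclass(frozen=True)
class Hotspot:
    """A genome interval with an elevated planted-DEG rate."""

    interval: QtlInterval
    elevated_deg_rate: float

    def __post_init__(self):
        if not (0.0 <= self.elevated_deg_rate <= 1.0):
            raise ConfigError("elevated_deg_rate must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedQtl:
    """A planted additive yield QTL with its requested variance share."""

    interval: QtlInterval
    r_squared: float

    def __post_init__(self):
        if not (0.0 <= self.r_squared < 1.0):
            raise ConfigError("r_squared must lie in [0, 1)")

    @property
    def position_bp(self) -> int:
        return (self.interval.start_bp + self.interval.end_bp) // 2


@dataclass(frozen=True)
class MappingPopulationConfig:
    """Backcross-inbred mapping population layout.

    ``donor_hom_freq`` is the per-locus frequency of the donor-homozygote
    class after collapsing residual heterozygosity (BC4-derived default
    1/16).  Recombination between loci follows a two-state chain whose
    autocorrelation decays as (1-2r)^2 with the Haldane recombination
    fraction r computed from bp via ``cm_per_mb``.
    """

    n_individuals: int = 450
    marker_spacing_bp: int = 2_000_000
    planted_qtl: tuple[PlantedQtl, ...] = tuple(
        PlantedQtl(iv, r2)
        for iv, r2 in zip(DEFAULT_QTL_INTERVALS, (0.091, 0.112, 0.130, 0.170))
    )
    error_variance: float = 160_000.0  # kg^2/ha^2; residual sd 400 kg/ha
    donor_hom_freq: float = 1.0 / 16.0
    cm_per_mb: float = 4.0
    mean_yield: float = 1_500.0  # kg/ha, drought-stress scale
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.error_variance <= 0:
            raise ConfigError("error_variance must be positive")
        if not (0.0 < self.donor_hom_freq < 1.0):
            raise ConfigError("donor_hom_freq must lie in (0, 1)")
        if sum(q.r_squared for q in self.planted_qtl) >= 1.0:
            raise ConfigError("planted QTL r_squared values must sum to < 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrialConfig:
    """Simulated multi-environment trial layout."""

    n_sites: int = 7
    n_entries: int = 4
    check_entry: str = "IR64"
    mean_yield_drought: float = 1_800.0
    mean_yield_non_stress: float = 4_500.0
    site_sd: float = 400.0
    entry_effect_sd: float = 0.0
    noise_sd: float = 150.0


@dataclass(frozen=True)
class SimulationConfig:
    """Genome layout, planted structure, and noise levels for all generators."""

    seed: int = 0
    n_chromosomes: int = 12
    chromosome_length_bp: int = 40_000_000
    n_genes: int = 40_000
    background_deg_rate: float = 0.01
    hotspots: tuple[Hotspot, ...] = tuple(
        Hotspot(iv, 0.5) for iv in DEFAULT_QTL_INTERVALS
    )
    n_replicates: int = 3
    expression_noise_sd: float = 0.4  # log2 scale
    deg_effect_size: float = 2.0  # |log2 fold change| of planted DEGs
    probe_density_per_gene: int = 1
    polymorphic_blocks: tuple[QtlInterval, ...] = DEFAULT_QTL_INTERVALS
    hybridization_shift: float = 2.0  # 5 x expression_noise_sd
    mapping_pop: MappingPopulationConfig = field(default_factory=MappingPopulationConfig)
    trial: TrialConfig = field(default_factory=TrialConfig)

    def __post_init__(self):
        if not (0.0 <= self.background_deg_rate <= 1.0):
            raise ConfigError("background_deg_rate must lie in [0, 1]")
        if self.expression_noise_sd <= 0:
            raise ConfigError("expression_noise_sd must be positive")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.probe_density_per_gene < 1:
            raise ConfigError("probe_density_per_gene must be >= 1")
        for hs in self.hotspots:
            self._check_on_genome(hs.interval, "hotspot")
        for block in self.polymorphic_blocks:
            self._check_on_genome(block, "polymorphic block")

    def _check_on_genome(self, interval: QtlInterval, what: str) -> None:
        chrom_ids = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        if interval.chromosome not in chrom_ids:
            raise ConfigError(
                f"{what} {interval.name!r} lies on {interval.chromosome}, "
                f"outside the simulated genome"
            )
        if interval.end_bp > self.chromosome_length_bp:
            raise ConfigError(
                f"{what} {interval.name!r} extends past the chromosome end"
            )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


# ---------------------------------------------------------------------------
# result containers


@dataclass
class ExpressionData:
    catalog: list[GeneRecord]
    matrix: pd.DataFrame  # genes x samples, log2 intensities
    samples: list[SampleMeta]
    truth: pd.DataFrame  # gene_id, pair, is_deg, effect


@dataclass
class HybridizationData:
    probes: list[GeneRecord]
    matrix: pd.DataFrame  # probes x samples, log2 intensities
    samples: list[SampleMeta]
    truth: pd.DataFrame  # probe_id, polymorphic, block


@dataclass
class MappingPopulation:
    marker_map: pd.DataFrame  # marker_id, chromosome, position_bp, position_cM
    genotypes: pd.DataFrame  # individuals x markers; codes 0/2 (NaN = missing)
    phenotype: pd.Series  # kg/ha
    truth: pd.DataFrame  # qtl, chromosome, position_bp, requested_r2, realized_r2, additive_effect


# ---------------------------------------------------------------------------
# gene catalog


def generate_gene_catalog(config: SimulationConfig) -> list[GeneRecord]:
    """Uniformly placed gene models across ``n_chromosomes`` equal chromosomes.

    Deterministic for a given config; shared by the expression and
    hybridization generators so their features are co-located.
    """
    rng = config.rng(_STREAM_CATALOG)
    records: list[GeneRecord] = []
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    for c in range(config.n_chromosomes):
        n = int(per_chrom[c])
        starts = np.sort(
            rng.integers(0, max(1, config.chromosome_length_bp - 20_000), size=n)
        )
        lengths = np.clip(
            rng.lognormal(mean=np.log(2_500.0), sigma=0.6, size=n), 200, 20_000
        ).astype(int)
        ends = np.minimum(starts + lengths, config.chromosome_length_bp)
        for j in range(n):
            records.append(
                GeneRecord(
                    id=f"Os{c + 1:02d}g{(j + 1) * 10:05d}",
                    chromosome=f"chr{c + 1}",
                    start_bp=int(starts[j]),
                    end_bp=int(ends[j]),
                )
            )
    return sort_catalog(records)


def _interval_membership(
    catalog: Sequence[GeneRecord], intervals: Sequence[QtlInterval]
) -> np.ndarray:
    """Index of the first interval containing each gene midpoint, else -1."""
    member = np.full(len(catalog), -1, dtype=int)
    for k, iv in enumerate(intervals):
        for i, g in enumerate(catalog):
            if member[i] < 0 and iv.contains(g.chromosome, g.midpoint_bp):
                member[i] = k
    return member


# ---------------------------------------------------------------------------
# expression


def simulate_expression(config: SimulationConfig) -> ExpressionData:
    """Log2 expression for the two BIL pairs x three tissues x two stress levels.

    Per gene: baseline + per-tissue offset + line effect + Gaussian noise.
    The line effect is nonzero only for planted DEGs of the sample's pair
    (+effect/2 on the +QTL line, -effect/2 on the -QTL line, so the +QTL
    minus -QTL contrast equals the planted effect).  Planted-DEG status is
    drawn per (gene, pair) at ``background_deg_rate``, elevated inside
    hotspot intervals.
    """
    catalog = generate_gene_catalog(config)
    rng = config.rng(_STREAM_EXPRESSION)
    n_genes = len(catalog)

    member = _interval_membership(catalog, [h.interval for h in config.hotspots])
    rates = np.full(n_genes, config.background_deg_rate)
    for k, hs in enumerate(config.hotspots):
        rates[member == k] = hs.elevated_deg_rate

    pairs = list(BIL_PAIRS)
    is_deg = {p: rng.random(n_genes) < rates for p in pairs}
    signs = {p: rng.choice([-1.0, 1.0], size=n_genes) for p in pairs}
    effects = {
        p: np.where(is_deg[p], signs[p] * config.deg_effect_size, 0.0) for p in pairs
    }

    baseline = rng.normal(8.0, 1.5, size=n_genes)
    tissue_offset = {t: rng.normal(0.0, 1.0, size=n_genes) for t in TISSUES}

    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    for pair in pairs:
        plus_line, minus_line = BIL_PAIRS[pair]
        for line, qtl_class, half in (
            (plus_line, "plusQTL", +0.5),
            (minus_line, "minusQTL", -0.5),
        ):
            for tissue in TISSUES:
                for stress in STRESS_LEVELS:
                    for rep in range(1, config.n_replicates + 1):
                        sid = f"{line}_{tissue}_{stress}_r{rep}"
                        samples.append(
                            SampleMeta(sid, line, qtl_class, tissue, stress, rep)
                        )
                        columns[sid] = (
                            baseline
                            + tissue_offset[tissue]
                            + half * effects[pair]
                            + rng.normal(0.0, config.expression_noise_sd, size=n_genes)
                        )

    matrix = pd.DataFrame(columns, index=[g.id for g in catalog])
    matrix.index.name = "gene_id"
    truth = pd.DataFrame(
        {
            "gene_id": np.tile([g.id for g in catalog], len(pairs)),
            "pair": np.repeat(pairs, n_genes),
            "is_deg": np.concatenate([is_deg[p] for p in pairs]),
            "effect": np.concatenate([effects[p] for p in pairs]),
        }
    )
    return ExpressionData(catalog, matrix, samples, truth)


# ---------------------------------------------------------------------------
# genomic hybridization (single-feature polymorphism genotyping)


def simulate_hybridization(config: SimulationConfig) -> HybridizationData:
    """Genomic-DNA hybridization intensities for the chip-genotyped BIL pair.

    One probe per gene (or ``probe_density_per_gene``) at the gene midpoint.
    Probes inside a planted polymorphic block hybridize weaker in the +QTL
    line (donor sequence mismatches) by ``hybridization_shift`` log2 units.
    """
    catalog = generate_gene_catalog(config)
    rng = config.rng(_STREAM_HYBRIDIZATION)

    probes: list[GeneRecord] = []
    for g in catalog:
        for k in range(config.probe_density_per_gene):
            offset = (k + 1) * (g.end_bp - g.start_bp) // (
                config.probe_density_per_gene + 1
            )
            pos = g.start_bp + offset
            suffix = "_at" if config.probe_density_per_gene == 1 else f"_at{k + 1}"
            probes.append(
                GeneRecord(
                    id=f"{g.id}{suffix}",
                    chromosome=g.chromosome,
                    start_bp=pos,
                    end_bp=pos + 25,
                )
            )
    probes = sort_catalog(probes)
    n_probes = len(probes)

    member = _interval_membership(probes, config.polymorphic_blocks)
    polymorphic = member >= 0
    block_names = np.where(
        polymorphic,
        np.array([iv.name for iv in config.polymorphic_blocks] + [""], dtype=object)[
            member
        ],
        "",
    )

    plus_line, minus_line = BIL_PAIRS["pair1"]
    baseline = rng.normal(10.0, 1.5, size=n_probes)
    shift = np.where(polymorphic, -config.hybridization_shift, 0.0)

    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    for line, qtl_class, shifted in (
        (plus_line, "plusQTL", True),
        (minus_line, "minusQTL", False),
    ):
        for rep in range(1, config.n_replicates + 1):
            sid = f"{line}_gDNA_r{rep}"
            samples.append(SampleMeta(sid, line, qtl_class, "root", "well_watered", rep))
            columns[sid] = (
                baseline
                + (shift if shifted else 0.0)
                + rng.normal(0.0, config.expression_noise_sd, size=n_probes)
            )

    matrix = pd.DataFrame(columns, index=[p.id for p in probes])
    matrix.index.name = "probe_id"
    truth = pd.DataFrame(
        {
            "probe_id": [p.id for p in probes],
            "polymorphic": polymorphic,
            "block": block_names,
        }
    )
    return HybridizationData(probes, matrix, samples, truth)


# ---------------------------------------------------------------------------
# mapping population


def _haldane_recomb(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _simulate_chain(
    rng: np.random.Generator,
    n: int,
    positions_cm: np.ndarray,
    donor_freq: float,
) -> np.ndarray:
    """Two-state donor-homozygote indicator along one chromosome.

    Adjacent-locus autocorrelation is (1 - 2 r)^2 for Haldane recombination
    fraction r, approximating the doubled meioses of an inbred pedigree;
    stationary donor frequency is ``donor_freq``.
    """
    m = len(positions_cm)
    states = np.empty((n, m), dtype=np.int8)
    states[:, 0] = rng.random(n) < donor_freq
    if m > 1:
        lam = (1.0 - 2.0 * _haldane_recomb(np.diff(positions_cm))) ** 2
        for k in range(1, m):
            keep = rng.random(n) < lam[k - 1]
            fresh = rng.random(n) < donor_freq
            states[:, k] = np.where(keep, states[:, k - 1], fresh)
    return states


def simulate_mapping_population(config: SimulationConfig) -> MappingPopulation:
    """Backcross-inbred genotypes, phenotype and planted-QTL truth.

    Genotypes take the two homozygote codes {0, 2}.  Phenotype is the sum of
    planted additive effects plus normal error; each effect is calibrated
    against the realized genotype variance (and the error vector is
    residualized against the planted genotype columns) so that the planted
    QTL explain their requested R^2 almost exactly.
    """
    mp = config.mapping_pop
    rng = config.rng(_STREAM_MAPPING)
    n = mp.n_individuals
    cm_per_bp = mp.cm_per_mb / 1e6

    qtl_by_chrom: dict[str, list[PlantedQtl]] = {}
    for q in mp.planted_qtl:
        config._check_on_genome(q.interval, "planted QTL")
        qtl_by_chrom.setdefault(q.interval.chromosome, []).append(q)

    marker_rows = []
    qtl_genotypes: dict[str, np.ndarray] = {}
    geno_cols: dict[str, np.ndarray] = {}
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        marker_bp = np.arange(0, config.chromosome_length_bp + 1, mp.marker_spacing_bp)
        qtl_here = qtl_by_chrom.get(chrom, [])
        for q in qtl_here:
            if not (marker_bp[0] <= q.position_bp <= marker_bp[-1]):
                raise ConfigError(f"markers do not span planted QTL {q.interval.name}")
        loci_bp = np.unique(
            np.concatenate([marker_bp, [q.position_bp for q in qtl_here]]).astype(
                np.int64
            )
        )
        states = _simulate_chain(rng, n, loci_bp * cm_per_bp, mp.donor_hom_freq)
        codes = (2 * states).astype(float)
        is_marker = np.isin(loci_bp, marker_bp)
        marker_idx = np.flatnonzero(is_marker)
        for j, li in enumerate(marker_idx):
            mid = f"RM{(c + 1) * 1000 + j}"
            marker_rows.append(
                {
                    "marker_id": mid,
                    "chromosome": chrom,
                    "position_bp": int(loci_bp[li]),
                    "position_cM": float(loci_bp[li] * cm_per_bp),
                }
            )
            geno_cols[mid] = codes[:, li].copy()
        for q in qtl_here:
            li = int(np.flatnonzero(loci_bp == q.position_bp)[0])
            qtl_genotypes[q.interval.name] = codes[:, li].copy()

    marker_map = pd.DataFrame(marker_rows)
    genotypes = pd.DataFrame(geno_cols, index=[f"ind{i + 1:04d}" for i in range(n)])

    # phenotype with per-realization effect calibration
    total_r2 = sum(q.r_squared for q in mp.planted_qtl)
    sigma_p2 = mp.error_variance / (1.0 - total_r2)
    X = np.column_stack(
        [qtl_genotypes[q.interval.name] for q in mp.planted_qtl]
    ) if mp.planted_qtl else np.empty((n, 0))
    Xc = X - X.mean(axis=0)
    betas = np.zeros(X.shape[1])
    for j, q in enumerate(mp.planted_qtl):
        var_x = Xc[:, j] @ Xc[:, j] / (n - 1)
        if var_x <= 0:
            import warnings

            warnings.warn(
                f"planted QTL {q.interval.name} drew a monomorphic genotype; "
                "its effect is zero in this realization"
            )
            continue
        betas[j] = np.sqrt(q.r_squared * sigma_p2 / var_x)

    e = rng.normal(0.0, 1.0, size=n)
    e -= e.mean()
    if X.shape[1]:
        # remove sample correlation with the planted genotypes
        coef, *_ = np.linalg.lstsq(Xc, e, rcond=None)
        e = e - Xc @ coef
    e *= np.sqrt(mp.error_variance * (n - 1) / (e @ e))
    y = mp.mean_yield + Xc @ betas + e
    phenotype = pd.Series(y, index=genotypes.index, name="grain_yield_kg_ha")

    truth_rows = []
    for j, q in enumerate(mp.planted_qtl):
        x = Xc[:, j]
        denom = (x @ x) * ((y - y.mean()) @ (y - y.mean()))
        realized = float((x @ (y - y.mean())) ** 2 / denom) if denom > 0 else 0.0
        truth_rows.append(
            {
                "qtl": q.interval.name,
                "chromosome": q.interval.chromosome,
                "position_bp": q.position_bp,
                "requested_r2": q.r_squared,
                "realized_r2": realized,
                "additive_effect": betas[j],
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "qtl",
            "chromosome",
            "position_bp",
            "requested_r2",
            "realized_r2",
            "additive_effect",
        ],
    )

    if mp.missing_rate > 0:
        mask = rng.random(genotypes.shape) < mp.missing_rate
        genotypes = genotypes.mask(mask)

    return MappingPopulation(marker_map, genotypes, phenotype, truth)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    config: SimulationConfig,
    n_categories: int = 50,
    genes_per_category: int = 40,
    namespace: str = "GO-SLIM_TG5",
) -> pd.DataFrame:
    """Random many-to-many gene-to-category annotation over the gene catalog."""
    catalog = generate_gene_catalog(config)
    rng = config.rng(_STREAM_ANNOTATION)
    ids = np.array([g.id for g in catalog])
    rows = []
    for k in range(n_categories):
        members = rng.choice(ids, size=min(genes_per_category, len(ids)), replace=False)
        for gid in members:
            rows.append(
                {
                    "gene_id": gid,
                    "namespace": namespace,
                    "category_id": f"CAT:{k + 1:04d}",
                    "category_label": f"category {k + 1}",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trial tables


def _load_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("qtlconverge").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _melt_trial(df: pd.DataFrame, id_cols: list[str]) -> pd.DataFrame:
    long = df.melt(id_vars=id_cols, var_name="cell", value_name="yield_kg_ha")
    env_regime = long["cell"].str.split("|", expand=True)
    long["environment"] = env_regime[0]
    long["regime"] = env_regime[1]
    long = long.drop(columns=["cell"]).dropna(subset=["yield_kg_ha"])
    long["yield_kg_ha"] = long["yield_kg_ha"].astype(float)
    cols = ["entry", "environment", "regime", "yield_kg_ha"]
    if "qtl" in long.columns:
        cols.insert(1, "qtl")
    return long[cols].reset_index(drop=True)


def make_trial_table(
    source: Literal["table5", "table6", "simulated"] = "table6",
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """A long-format trial-yield table: entry, environment, regime, yield_kg_ha.

    ``table5`` is the IRRI screening of the 14 QTL-introgression lines
    (environments DS10/DS11, regimes non_stress/drought); ``table6`` is the
    three best lines at the seven South Asia target sites.  Both include the
    printed ``LSD`` row as an entry named ``"LSD"`` (used by the
    significance filter of :func:`qtlconverge.convergence_report.yield_advantage`).
    ``simulated`` draws site x entry yields with configurable entry effects.
    """
    if source == "table5":
        return _melt_trial(_load_packaged_tsv("table5_irri_yield.tsv"), ["entry", "qtl"])
    if source == "table6":
        return _melt_trial(_load_packaged_tsv("table6_target_sites_yield.tsv"), ["entry"])
    if source != "simulated":
        raise ValueError(f"unknown trial-table source: {source!r}")

    config = config or SimulationConfig()
    tc = config.trial
    rng = config.rng(_STREAM_TRIAL)
    entries = [tc.check_entry] + [f"QTL-line-{i + 1}" for i in range(tc.n_entries - 1)]
    entry_effect = rng.normal(0.0, tc.entry_effect_sd, size=len(entries))
    entry_effect[0] = 0.0
    rows = []
    for regime, mean in (
        ("drought", tc.mean_yield_drought),
        ("non_stress", tc.mean_yield_non_stress),
    ):
        site_effect = rng.normal(0.0, tc.site_sd, size=tc.n_sites)
        for s in range(tc.n_sites):
            for j, entry in enumerate(entries):
                rows.append(
                    {
                        "entry": entry,
                        "environment": f"site{s + 1}",
                        "regime": regime,
                        "yield_kg_ha": mean
                        + site_effect[s]
                        + entry_effect[j]
                        + rng.normal(0.0, tc.noise_sd),
                    }
                )
    return pd.DataFrame(rows)
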