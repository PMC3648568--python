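"""Positioned genomic features, interval algebra, and catalog readers/writers.

Everything downstream (window scans, enrichment, candidate nomination) runs
on flat, gene-level position catalogs.  Internally all coordinates are
0-based half-open; display helpers render the 1-based megabase style used in
rice QTL reports ("6.8-7.3 Mb").  Chromosome names are normalized to
``chr<N>`` on read so that GFF3, BED and TSV inputs interoperate.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "QtlInterval",
    "GenomeWindow",
    "SampleMeta",
    "CatalogParseError",
    "ValidationError",
    "normalize_chromosome",
    "chromosome_sort_key",
    "read_gene_catalog",
    "write_gene_catalog",
    "catalog_to_frame",
    "frame_to_catalog",
    "chromosome_lengths",
    "genes_in_interval",
]

CatalogFormat = Literal["gff3", "bed", "tsv"]
Assignment = Literal["midpoint", "start", "any_overlap"]


class CatalogParseError(ValueError):
    """A catalog file line did not parse under the named standard."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{self.path}:{line_number}: {message}")


class ValidationError(ValueError):
    """A record or configuration violated an invariant."""


_CHROM_RE = re.compile(r"^(?:chr(?:omosome)?[_ ]?|os)?0*(\d+)$", re.IGNORECASE)


def normalize_chromosome(name: str) -> str:
    """Normalize chromosome naming to ``chr<N>`` (``Chr1``, ``01``, ``Os1`` -> ``chr1``).

    Non-numeric names are lower-cased and prefixed with ``chr`` if missing.
    """
    name = str(name).strip()
    m = _CHROM_RE.match(name)
    if m:
        return f"chr{int(m.group(1))}"
    low = name.lower()
    return low if low.startswith("chr") else f"chr{low}"


def chromosome_sort_key(chrom: str):
    """Natural sort key: chr2 < chr10; non-numeric chromosomes sort last, lexically."""
    m = re.match(r"^chr(\d+)$", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class GeneRecord:
    """A positioned genomic feature (gene or array probe) with optional categories.

    Coordinates are 0-based half-open.
    """

    id: str
    chromosome: str
    start_bp: int
    end_bp: int
    categories: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.start_bp < 0:
            raise ValidationError(f"{self.id}: start_bp must be non-negative")
        if self.end_bp <= self.start_bp:
            raise ValidationError(f"{self.id}: end_bp must exceed start_bp")
        object.__setattr__(self, "categories", frozenset(self.categories))

    @property
    def midpoint_bp(self) -> int:
        return (self.start_bp + self.end_bp) // 2


@dataclass(frozen=True)
class QtlInterval:
    """A named genomic interval (QTL region, polymorphic block, or hotspot)."""

    name: str
    chromosome: str
    start_bp: int
    end_bp: int
    source: Literal["chip_defined", "marker_defined"] = "chip_defined"

    def __post_init__(self):
        if not self.name:
            raise ValidationError("interval name must be non-empty")
        if self.end_bp <= self.start_bp:
            raise ValidationError(f"{self.name}: start_bp must precede end_bp")
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def contains(self, chromosome: str, position_bp: int) -> bool:
        return (
            normalize_chromosome(chromosome) == self.chromosome
            and self.start_bp <= position_bp < self.end_bp
        )

    def overlaps(self, other: "QtlInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start_bp < other.end_bp
            and other.start_bp < self.end_bp
        )

    def display(self) -> str:
        """QTL-literature 1-based Mb rendering, e.g. ``chr9:14.6-16.5 Mb``."""
        return (
            f"{self.chromosome}:{(self.start_bp + 1) / 1e6:.1f}-"
            f"{self.end_bp / 1e6:.1f} Mb"
        )


@dataclass
class GenomeWindow:
    """One sliding-window block with its feature counts and aggregation test."""

    chromosome: str
    start_bp: int
    end_bp: int
    gene_count: int = 0
    hit_count: int = 0
    p_value: float = 1.0
    significant: bool = False

    def __post_init__(self):
        if self.hit_count > self.gene_count:
            raise ValidationError("hit_count cannot exceed gene_count")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError("p_value must lie in (0, 1]")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one expression/hybridization sample."""

    sample_id: str
    line_id: str
    qtl_class: Literal["plusQTL", "minusQTL", "recurrent_parent"]
    tissue: Literal["root", "leaf", "panicle"]
    stress: Literal["FTSW_0.5", "FTSW_0.2", "well_watered"]
    replicate: int

    def __post_init__(self):
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


# ---------------------------------------------------------------------------
# readers / writers


def _infer_format(path: Path) -> CatalogFormat:
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return "gff3"
    if suffix == ".bed":
        return "bed"
    return "tsv"


_GFF3_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def _parse_gff3_attributes(text: str) -> dict:
    return {k.strip(): v.strip() for k, v in _GFF3_ATTR_RE.findall(text)}


def _read_gff3(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise CatalogParseError(path, lineno, "expected 9 tab-separated GFF3 fields")
            seqid, _source, ftype, start, end, _score, _strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start_1 = int(start)
                end_1 = int(end)
            except ValueError:
                raise CatalogParseError(path, lineno, "non-integer coordinates") from None
            attributes = _parse_gff3_attributes(attrs)
            gene_id = attributes.get("ID") or attributes.get("Name")
            if not gene_id:
                raise CatalogParseError(path, lineno, "gene feature lacks an ID attribute")
            categories = frozenset(
                c for c in attributes.get("categories", "").split(",") if c
            )
            # GFF3 is 1-based inclusive -> 0-based half-open
            records.append(
                GeneRecord(
                    id=gene_id,
                    chromosome=normalize_chromosome(seqid),
                    start_bp=start_1 - 1,
                    end_bp=end_1,
                    categories=categories,
                )
            )
    return records


def _read_bed(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CatalogParseError(
                    path, lineno, "expected at least 4 BED columns (chrom start end name)"
                )
            chrom, start, end, name = fields[:4]
            try:
                start_bp = int(start)
                end_bp = int(end)
            except ValueError:
                raise CatalogParseError(path, lineno, "non-integer coordinates") from None
            records.append(
                GeneRecord(
                    id=name,
                    chromosome=normalize_chromosome(chrom),
                    start_bp=start_bp,
                    end_bp=end_bp,
                )
            )
    return records


_TSV_COLUMNS = ["gene_id", "chromosome", "start_bp", "end_bp", "categories"]


def _read_tsv(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if header[:4] != _TSV_COLUMNS[:4]:
            raise CatalogParseError(
                path, 1, f"expected header starting with {_TSV_COLUMNS[:4]}"
            )
        has_categories = len(header) > 4 and header[4] == "categories"
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CatalogParseError(path, lineno, "expected at least 4 columns")
            try:
                start_bp = int(fields[2])
                end_bp = int(fields[3])
            except ValueError:
                raise CatalogParseError(path, lineno, "non-integer coordinates") from None
            categories = frozenset()
            if has_categories and len(fields) > 4 and fields[4]:
                categories = frozenset(fields[4].split(","))
            records.append(
                GeneRecord(
                    id=fields[0],
                    chromosome=normalize_chromosome(fields[1]),
                    start_bp=start_bp,
                    end_bp=end_bp,
                    categories=categories,
                )
            )
    return records


def sort_catalog(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    return sorted(
        records, key=lambda r: (chromosome_sort_key(r.chromosome), r.start_bp, r.end_bp)
    )


def read_gene_catalog(path, format: CatalogFormat | None = None) -> list[GeneRecord]:
    """Read a gene/probe position catalog and return records sorted by position.

    Parameters
    ----------
    path : path-like
        File to read.
    format : {"gff3", "bed", "tsv"}, optional
        Defaults to inference from the file suffix.

    Raises
    ------
    CatalogParseError
        On a malformed line (the message names the line number).
    ValidationError
        On duplicate record ids.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "gff3":
        records = _read_gff3(path)
    elif fmt == "bed":
        records = _read_bed(path)
    elif fmt == "tsv":
        records = _read_tsv(path)
    else:
        raise ValueError(f"unknown catalog format: {fmt!r}")
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
    return sort_catalog(records)


def write_gene_catalog(catalog: Sequence[GeneRecord], path, format: CatalogFormat | None = None) -> None:
    """Write a catalog; column order is deterministic for every format.

    BED output drops categories (no standard column); GFF3 stores them in a
    ``categories=`` attribute and TSV in a comma-joined ``categories`` column.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    records = sort_catalog(catalog)
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for r in records:
                attrs = f"ID={r.id}"
                if r.categories:
                    attrs += ";categories=" + ",".join(sorted(r.categories))
                fh.write(
                    f"{r.chromosome}\tqtlconverge\tgene\t{r.start_bp + 1}\t{r.end_bp}"
                    f"\t.\t+\t.\t{attrs}\n"
                )
        elif fmt == "bed":
            for r in records:
                fh.write(f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{r.id}\n")
        elif fmt == "tsv":
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for r in records:
                cats = ",".join(sorted(r.categories))
                fh.write(
                    f"{r.id}\t{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{cats}\n"
                )
        else:
            raise ValueError(f"unknown catalog format: {fmt!r}")


def catalog_to_frame(catalog: Sequence[GeneRecord]) -> pd.DataFrame:
    """Catalog as a DataFrame with a ``midpoint_bp`` convenience column."""
    return pd.DataFrame(
        {
            "gene_id": [r.id for r in catalog],
            "chromosome": [r.chromosome for r in catalog],
            "start_bp": [r.start_bp for r in catalog],
            "end_bp": [r.end_bp for r in catalog],
            "midpoint_bp": [r.midpoint_bp for r in catalog],
            "categories": [",".join(sorted(r.categories)) for r in catalog],
        }
    )


def frame_to_catalog(df: pd.DataFrame) -> list[GeneRecord]:
    records = []
    for row in df.itertuples(index=False):
        cats = getattr(row, "categories", "") or ""
        records.append(
            GeneRecord(
                id=row.gene_id,
                chromosome=normalize_chromosome(row.chromosome),
                start_bp=int(row.start_bp),
                end_bp=int(row.end_bp),
                categories=frozenset(c for c in str(cats).split(",") if c),
            )
        )
    return sort_catalog(records)


def chromosome_lengths(catalog: Sequence[GeneRecord]) -> dict[str, int]:
    """Per-chromosome extent implied by the catalog (max feature end)."""
    lengths: dict[str, int] = {}
    for r in catalog:
        lengths[r.chromosome] = max(lengths.get(r.chromosome, 0), r.end_bp)
    return lengths


def genes_in_interval(
    catalog: Sequence[GeneRecord],
    interval: QtlInterval,
    assignment: Assignment = "midpoint",
) -> list[GeneRecord]:
    """Features of ``catalog`` assigned to ``interval``.

    Under ``midpoint`` assignment a gene belongs to the interval iff its
    midpoint lies in the half-open span, so non-overlapping intervals induce a
    partition.  ``start`` assigns by start coordinate; ``any_overlap`` keeps
    every gene whose span intersects the interval.  An interval on a
    chromosome absent from the catalog yields an empty list with a warning.
    """
    chrom = interval.chromosome
    chrom_genes = [g for g in catalog if g.chromosome == chrom]
    if not chrom_genes:
        warnings.warn(
            f"interval {interval.name!r}: chromosome {chrom!r} not in catalog",
            stacklevel=2,
        )
        return []
    if assignment == "midpoint":
        return [
            g for g in chrom_genes if interval.start_bp <= g.midpoint_bp < interval.end_bp
        ]
    if assignment == "start":
        return [
            g for g in chrom_genes if interval.start_bp <= g.start_bp < interval.end_bp
        ]
    if assignment == "any_overlap":
        return [
            g
            for g in chrom_genes
            if g.start_bp < interval.end_bp and g.end_bp > interval.start_bp
        ]
    raise ValueError(f"unknown assignment rule: {assignment!r}")
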