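"""Gene models and strand-aware genomic windows.

All coordinates are 0-based half-open (BED convention).  Region windows are
defined as offsets from the transcription start site (TSS) and transcription
end site (TES) *in transcription orientation* and are mapped to genome
coordinates afterwards, so a window such as the promoter (TSS − 400 bp to
TSS + 100 bp) has length exactly 500 bp on either strand.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# annotation categories ordered by assignment priority (highest first)
CATEGORY_PRIORITY = (
    "promoter",
    "5utr",
    "3utr",
    "exon",
    "intron",
    "tes_downstream",
    "enhancer",
    "intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene with optional exon/CDS structure.

    ``start``/``end`` are genomic, 0-based half-open.  ``exons`` are
    (start, end) blocks within the gene span; ``cds`` is the genomic CDS
    extent used to infer UTRs.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    cds: tuple[int, int] | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene span")

    @property
    def tss(self) -> int:
        """TSS as a half-open boundary coordinate (start on +, end on −)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """TES boundary coordinate (end on +, start on −)."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def oriented_interval(
        self, anchor_start: str, off_start: int, anchor_end: str, off_end: int
    ) -> tuple[int, int]:
        """Map a transcription-orientation window to genome coordinates.

        Offsets are measured downstream-positive from the named anchor
        ('tss' or 'tes').  Returns a (start, end) half-open genomic interval;
        start may exceed end for degenerate windows (caller flags those).
        """

        def _map(anchor: str, off: int) -> int:
            base = self.tss if anchor == "tss" else self.tes
            return base + off if self.strand == "+" else base - off

        g1, g2 = _map(anchor_start, off_start), _map(anchor_end, off_end)
        return (g1, g2) if self.strand == "+" else (g2, g1)


@dataclass(frozen=True)
class RegionScheme:
    """Named windows as (anchor, offset, anchor, offset) in transcription orientation.

    The defaults: a 500-bp promoter (TSS − 400 to TSS + 100), gene body
    (TSS + 100 to TES − 100), TES/downstream region (TES − 100 to TES + 2000,
    always 2,100 bp), enhancer window (TSS − 5000 to TSS − 400), ±10-kb
    upstream/downstream windows, and the pausing-index denominator body
    (TSS + 100 to TES + 2000).
    """

    windows: Mapping[str, tuple[str, int, str, int]] = field(
        default_factory=lambda: {
            "promoter": ("tss", -400, "tss", 100),
            "gene_body": ("tss", 100, "tes", -100),
            "tes_region": ("tes", -100, "tes", 2000),
            "enhancer": ("tss", -5000, "tss", -400),
            "upstream": ("tss", -10000, "tss", 0),
            "downstream": ("tss", 0, "tss", 10000),
            "pi_body": ("tss", 100, "tes", 2000),
        }
    )

    def names(self) -> tuple[str, ...]:
        return tuple(self.windows)


DEFAULT_SCHEME = RegionScheme()


@dataclass
class GeneRegions:
    """Genomic intervals for one gene, one per scheme window."""

    gene_id: str
    chrom: str
    strand: str
    intervals: dict[str, tuple[int, int]]
    empty: set[str] = field(default_factory=set)
    clipped: set[str] = field(default_factory=set)

    def length(self, name: str) -> int:
        s, e = self.intervals[name]
        return max(0, e - s)


def derive_regions(
    gene: GeneModel,
    scheme: RegionScheme = DEFAULT_SCHEME,
    chrom_length: int | None = None,
) -> GeneRegions:
    """Derive every scheme window for one gene in genome coordinates.

    Windows whose oriented end does not exceed their start (e.g. the gene
    body of a gene ≤ 200 bp) are flagged ``empty`` and stored with zero
    length rather than raising.  Windows extending past [0, chrom_length)
    are clipped and flagged.
    """
    intervals: dict[str, tuple[int, int]] = {}
    empty: set[str] = set()
    clipped: set[str] = set()
    for name, (a0, o0, a1, o1) in scheme.windows.items():
        s, e = gene.oriented_interval(a0, o0, a1, o1)
        if e <= s:
            intervals[name] = (s, s)
            empty.add(name)
            continue
        cs, ce = max(0, s), e if chrom_length is None else min(e, chrom_length)
        if (cs, ce) != (s, e):
            clipped.add(name)
        if ce <= cs:
            intervals[name] = (cs, cs)
            empty.add(name)
        else:
            intervals[name] = (cs, ce)
    return GeneRegions(gene.gene_id, gene.chrom, gene.strand, intervals, empty, clipped)


def _midpoint_category(gene: GeneModel, regions: GeneRegions, pos: int) -> str | None:
    """Category of a point with respect to one gene, or None if outside all."""
    ps, pe = regions.intervals["promoter"]
    if ps <= pos < pe:
        return "promoter"
    in_gene = gene.start <= pos < gene.end
    if in_gene and gene.cds is not None and gene.exons:
        cs, ce = gene.cds
        exonic = any(s <= pos < e for s, e in gene.exons)
        if exonic:
            if pos < cs:
                return "5utr" if gene.strand == "+" else "3utr"
            if pos >= ce:
                return "3utr" if gene.strand == "+" else "5utr"
    if in_gene and gene.exons:
        if any(s <= pos < e for s, e in gene.exons):
            return "exon"
        return "intron"
    if in_gene:
        # no exon structure: treat whole body as exonic signal
        return "exon"
    ts, te = regions.intervals["tes_region"]
    if ts <= pos < te:
        return "tes_downstream"
    es, ee = regions.intervals["enhancer"]
    if es <= pos < ee:
        return "enhancer"
    return None


def annotate_peak(
    peak: tuple[str, int, int],
    genes: Sequence[GeneModel],
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> str:
    """Assign a peak to exactly one feature category by midpoint membership.

    Priority: promoter > 5′UTR > 3′UTR > exon > intron > TES/downstream >
    enhancer > intergenic.  When several genes claim the same category rank,
    the gene with the nearest TSS wins (which cannot change the returned
    category, only the implied gene).  Unknown chromosomes annotate as
    intergenic with a warning.
    """
    chrom, start, end = peak
    mid = (int(start) + int(end)) // 2
    chrom_genes = [g for g in genes if g.chrom == chrom]
    if genes and not chrom_genes:
        warnings.warn(f"peak chromosome {chrom!r} not in annotation; intergenic")
        return "intergenic"
    best: tuple[int, int] | None = None  # (priority index, |mid - TSS|)
    best_cat = "intergenic"
    for g in chrom_genes:
        cat = _midpoint_category(g, derive_regions(g, scheme), mid)
        if cat is None:
            continue
        key = (CATEGORY_PRIORITY.index(cat), abs(mid - g.tss))
        if best is None or key < best:
            best, best_cat = key, cat
    return best_cat


def peak_distribution(
    peaks: Iterable[tuple[str, int, int]],
    genes: Sequence[GeneModel],
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> pd.Series:
    """Count peaks per feature category; counts sum to the number of peaks."""
    counts = pd.Series(0, index=list(CATEGORY_PRIORITY), dtype=int)
    for peak in peaks:
        counts[annotate_peak(peak, genes, scheme)] += 1
    return counts


# ---------------------------------------------------------------------------
# I/O: BED12 / BED6 / GTF
# ---------------------------------------------------------------------------

BED12_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def read_bed12(path) -> list[GeneModel]:
    """Read gene models from a BED12 file (blocks = exons, thick = CDS)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED12_COLUMNS, comment="#")
    genes = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",") if x]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",") if x]
        exons = tuple(
            (row.start + off, row.start + off + size)
            for off, size in zip(starts, sizes)
        )
        cds = None
        if int(row.thickEnd) > int(row.thickStart):
            cds = (int(row.thickStart), int(row.thickEnd))
        genes.append(
            GeneModel(str(row.name), str(row.chrom), int(row.start), int(row.end),
                      str(row.strand), exons, cds)
        )
    return genes


def write_bed12(genes: Sequence[GeneModel], path) -> None:
    rows = []
    for g in genes:
        exons = g.exons if g.exons else ((g.start, g.end),)
        sizes = ",".join(str(e - s) for s, e in exons) + ","
        starts = ",".join(str(s - g.start) for s, e in exons) + ","
        thick = g.cds if g.cds is not None else (g.start, g.start)
        rows.append(
            [g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
             thick[0], thick[1], "0,0,0", len(exons), sizes, starts]
        )
    pd.DataFrame(rows, columns=BED12_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_regions_bed6(regions: Sequence[GeneRegions], name: str, path) -> None:
    """Write one region type across genes as BED6 (non-empty windows only)."""
    rows = [
        [r.chrom, *r.intervals[name], f"{r.gene_id}:{name}", 0, r.strand]
        for r in regions
        if name not in r.empty
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> list[GeneModel]:
    """Read gene models from a GTF file keyed on the ``gene_id`` attribute.

    Gene extent is the union of its exon (or feature) lines; CDS lines, when
    present, define the thick/CDS extent.  Coordinates are converted from
    GTF 1-based closed to 0-based half-open on read.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "feature", "start", "end",
               "score", "strand", "frame", "attributes"],
    )
    df["gene_id"] = df["attributes"].map(
        lambda a: dict(_GTF_ATTR.findall(a)).get("gene_id", "")
    )
    genes = []
    for gid, sub in df.groupby("gene_id", sort=False):
        if not gid:
            continue
        exon_rows = sub[sub["feature"] == "exon"]
        base = exon_rows if len(exon_rows) else sub
        start = int(base["start"].min()) - 1
        end = int(base["end"].max())
        exons = tuple(
            sorted((int(r.start) - 1, int(r.end)) for r in exon_rows.itertuples())
        )
        cds_rows = sub[sub["feature"] == "CDS"]
        cds = None
        if len(cds_rows):
            cds = (int(cds_rows["start"].min()) - 1, int(cds_rows["end"].max()))
        genes.append(
            GeneModel(str(gid), str(sub["chrom"].iloc[0]), start, end,
                      str(sub["strand"].iloc[0]), exons, cds)
        )
    return genes


def read_bed_intervals(path) -> pd.DataFrame:
    """Read BED3+ intervals (fragments or peaks) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df.astype({"start": int, "end": int})
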