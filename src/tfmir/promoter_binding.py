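"""Map scored TF binding clusters onto putative miR promoters.

Promoters here are H3K4me3-defined regions upstream of microRNA genes; a
promoter record may carry several miR gene names when the pre-miRs are
transcribed as a cluster (2-6 genes from one promoter).  Binding clusters are
ChIP-seq-derived intervals with an integer signal-strength score on [0, 1000].

Internally every interval is 0-based half-open.  External tables default to
genome-browser style 1-based inclusive coordinates; true BED input is selected
with ``dialect="bed0"``.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PromoterRecord",
    "BindingCluster",
    "PromoterBindingSummary",
    "read_promoters",
    "read_clusters",
    "intersect",
    "summarize_binding",
    "classify_promoters",
    "write_binding_table",
    "write_classification_json",
]

_STRANDS = {"+", "-", "."}


def _open_text(path: str | Path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval; strand '.' means unknown."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if different chromosomes or disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class PromoterRecord:
    promoter_id: str
    interval: GenomicInterval
    mir_genes: tuple[str, ...]
    band: str = ""

    def __post_init__(self) -> None:
        if not self.mir_genes:
            raise ValueError(f"promoter {self.promoter_id} has no gene names")

    @property
    def is_cluster_promoter(self) -> bool:
        """True when one promoter drives a cluster of >=2 pre-miR genes."""
        return len(self.mir_genes) >= 2


@dataclass(frozen=True)
class BindingCluster:
    interval: GenomicInterval
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 1000:
            raise ValueError(f"cluster score {self.score} outside [0, 1000]")


@dataclass(frozen=True)
class PromoterBindingSummary:
    """Per-promoter aggregate of overlapping binding clusters.

    ``median_score`` / ``min_score`` / ``max_score`` are ``None`` when no
    cluster overlaps the promoter.  The median of an even number of scores is
    the arithmetic mean of the two central values.
    """

    promoter_id: str
    mir_genes: tuple[str, ...]
    n_sites: int
    median_score: float | None = None
    min_score: int | None = None
    max_score: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.n_sites == 0:
            if self.median_score is not None:
                raise ValueError("unbound promoter cannot carry scores")
        else:
            assert self.min_score is not None and self.max_score is not None
            if not self.min_score <= self.median_score <= self.max_score:
                raise ValueError("min <= median <= max violated")

    @property
    def bound(self) -> bool:
        return self.n_sites >= 1

    def score_display(self) -> str:
        """Render as ``median (min-max)``, e.g. ``1000 (112-1000)``."""
        if self.n_sites == 0:
            return "NA"
        med = self.median_score
        med_str = f"{med:g}" if med != int(med) else f"{int(med)}"
        return f"{med_str} ({self.min_score}-{self.max_score})"


def _to_internal(start: int, end: int, dialect: str) -> tuple[int, int]:
    if dialect == "1based":
        return start - 1, end
    if dialect == "bed0":
        return start, end
    raise ValueError(f"unknown coordinate dialect {dialect!r}")


def _from_internal(start: int, end: int, dialect: str = "1based") -> tuple[int, int]:
    if dialect == "1based":
        return start + 1, end
    return start, end


def _parse_chrom_field(cell: str) -> tuple[str, str]:
    """Split a 'chrom [band]' cell such as '8 q24.21' into chrom and band."""
    parts = cell.split()
    if len(parts) == 1:
        return parts[0], ""
    return parts[0], " ".join(parts[1:])


def read_promoters(path: str | Path, dialect: str = "1based") -> list[PromoterRecord]:
    """Read a promoter table: chrom[+band] <TAB> start <TAB> end <TAB> genes.

    The gene cell may list several comma-separated names (cluster promoter).
    Extra trailing columns are ignored.  A first row whose start column is not
    an integer is treated as a header; a header starting with 'gene' selects
    the binding-table layout (gene(s), chrom, start, end) so written tables
    round-trip through this reader.  Coordinates are converted to the internal
    0-based half-open convention.
    """
    records: list[PromoterRecord] = []
    gene_first = False
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >=4 tab-separated columns")
            if lineno == 1 and cells[0].strip().lower() in {"gene", "genes", "gene(s)"}:
                gene_first = True
            if gene_first:
                genes_cell, chrom_cell, s_cell, e_cell = cells[:4]
            else:
                chrom_cell, s_cell, e_cell, genes_cell = cells[:4]
            try:
                start_ext, end_ext = int(s_cell), int(e_cell)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates {s_cell!r}/{e_cell!r}"
                ) from None
            chrom, band = _parse_chrom_field(chrom_cell)
            if end_ext <= start_ext:
                raise ValueError(f"{path}: line {lineno}: empty interval [{s_cell}, {e_cell}]")
            start, end = _to_internal(start_ext, end_ext, dialect)
            genes = tuple(g.strip() for g in genes_cell.split(",") if g.strip())
            if not genes:
                raise ValueError(f"{path}: line {lineno}: no gene names")
            records.append(
                PromoterRecord(
                    promoter_id=f"prom{len(records):05d}",
                    interval=GenomicInterval(chrom, start, end),
                    mir_genes=genes,
                    band=band,
                )
            )
    return records


def read_clusters(path: str | Path, dialect: str = "bed0") -> list[BindingCluster]:
    """Read binding clusters from a BED3+score table (score in [0, 1000])."""
    clusters: list[BindingCluster] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cells = line.split("\t")
            if len(cells) < 4:
                raise ValueError(f"{path}: line {lineno}: expected chrom/start/end/score")
            chrom, _ = _parse_chrom_field(cells[0])
            try:
                start_ext, end_ext, score = int(cells[1]), int(cells[2]), int(cells[3])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from None
            start, end = _to_internal(start_ext, end_ext, dialect)
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: empty interval")
            if not 0 <= score <= 1000:
                raise ValueError(f"{path}: line {lineno}: score {score} outside [0, 1000]")
            clusters.append(BindingCluster(GenomicInterval(chrom, start, end), score))
    return clusters


def intersect(
    promoters: Sequence[PromoterRecord],
    clusters: Sequence[BindingCluster],
    min_overlap_bp: int = 1,
) -> dict[str, list[BindingCluster]]:
    """Assign each cluster to every promoter it overlaps by >= min_overlap_bp.

    Overlap is tested on same-chromosome half-open intervals; strand is
    ignored (ChIP-seq clusters are unstranded).  The result holds an entry for
    every promoter, possibly an empty list; a cluster overlapping several
    promoters is counted for each.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for c in clusters:
        trees.setdefault(c.interval.chrom, IntervalTree()).addi(
            c.interval.start, c.interval.end, c
        )
    out: dict[str, list[BindingCluster]] = {}
    for p in promoters:
        hits: list[BindingCluster] = []
        tree = trees.get(p.interval.chrom)
        if tree is not None:
            for iv in tree.overlap(p.interval.start, p.interval.end):
                c: BindingCluster = iv.data
                if p.interval.overlap_bp(c.interval) >= min_overlap_bp:
                    hits.append(c)
        hits.sort(key=lambda c: (c.interval.start, c.interval.end, c.score))
        out[p.promoter_id] = hits
    return out


def summarize_binding(
    promoter: PromoterRecord, hits: Sequence[BindingCluster]
) -> PromoterBindingSummary:
    """Aggregate the clusters assigned to one promoter into median/range counts."""
    if not hits:
        return PromoterBindingSummary(promoter.promoter_id, promoter.mir_genes, 0)
    scores = [h.score for h in hits]
    return PromoterBindingSummary(
        promoter_id=promoter.promoter_id,
        mir_genes=promoter.mir_genes,
        n_sites=len(scores),
        median_score=float(median(scores)),
        min_score=min(scores),
        max_score=max(scores),
    )


def classify_promoters(summaries: Iterable[PromoterBindingSummary]) -> dict[str, int]:
    """Count bound single-gene promoters, bound cluster promoters, and unbound."""
    counts = {"bound_single": 0, "bound_cluster": 0, "unbound": 0}
    for s in summaries:
        if not s.bound:
            counts["unbound"] += 1
        elif len(s.mir_genes) >= 2:
            counts["bound_cluster"] += 1
        else:
            counts["bound_single"] += 1
    return counts


def write_binding_table(
    promoters: Sequence[PromoterRecord],
    summaries: Sequence[PromoterBindingSummary],
    path: str | Path,
    dialect: str = "1based",
) -> None:
    """Write the per-promoter binding table as TSV.

    Columns: gene(s), chrom+band, promoter start, promoter end (1-based
    inclusive by default), 'median (min-max)' score string.  Rows sorted by
    descending median score (unbound last) then by first gene name.
    """
    by_id = {p.promoter_id: p for p in promoters}
    rows = []
    for s in summaries:
        p = by_id[s.promoter_id]
        start, end = _from_internal(p.interval.start, p.interval.end, dialect)
        chrom_cell = f"{p.interval.chrom} {p.band}".strip()
        rows.append(
            (
                -(s.median_score if s.median_score is not None else float("-inf")),
                ", ".join(s.mir_genes),
                chrom_cell,
                start,
                end,
                s.score_display(),
            )
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with _open_text(path, "wt") as fh:
        fh.write("gene\tchrom\tstart\tend\tmedian_range_score\n")
        for _, gene, chrom_cell, start, end, disp in rows:
            fh.write(f"{gene}\t{chrom_cell}\t{start}\t{end}\t{disp}\n")


def write_classification_json(
    summaries: Iterable[PromoterBindingSummary], path: str | Path
) -> dict[str, int]:
    counts = classify_promoters(summaries)
    with _open_text(path, "wt") as fh:
        json.dump(counts, fh, indent=2)
        fh.write("\n")
    return counts
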