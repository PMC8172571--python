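"""Back-splice-junction catalog construction.

circRNA callers disagree substantially, so the catalog keeps only junctions
reported by both callers (coordinate intersection, optional slack), then
applies the replicate support rule: a junction survives iff at least one
replicate set (group x timepoint) has >= min_reads junction reads in every
sample. Surviving circRNAs are classified by genomic origin against a gene
annotation — exonic (both endpoints on exon boundaries of one gene),
intronic (span inside a single intron) or intergenic (no gene overlap) —
and summarised as a class-composition report.

Coordinates are 1-based inclusive in all input and output files and 0-based
half-open internally; the conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BsjCall",
    "CircRecord",
    "AnnotationIndex",
    "calls_from_table",
    "intersect_callers",
    "filter_junction_reads",
    "classify_circ",
    "composition_report",
    "catalog_table",
]


@dataclass
class BsjCall:
    """One back-splice-junction candidate from one caller.

    ``start``/``end`` are internal 0-based half-open; ``junction_reads``
    maps sample id to the number of reads spanning the junction.
    """

    chrom: str
    start: int
    end: int
    strand: str
    caller: str
    junction_reads: dict[str, int]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def circ_id(self) -> str:
        # 1-based inclusive in the public identifier
        return f"{self.chrom}:{self.start + 1}|{self.end}:{self.strand}"


@dataclass
class CircRecord:
    """A validated circRNA with genomic class and host gene."""

    circ_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    circ_class: str  # exonic | intronic | intergenic
    host_gene: str | None
    junction_reads: dict[str, int]

    def __post_init__(self) -> None:
        if (self.circ_class == "intergenic") != (self.host_gene is None):
            raise ValueError("intergenic iff host_gene is None")


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open span
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def introns(self) -> list[tuple[int, int]]:
        exons = sorted(self.exons)
        return [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i][1] < exons[i + 1][0]
        ]


class AnnotationIndex:
    """Gene/exon interval lookup built from a GTF table.

    Genes are indexed per chromosome and sorted by start for windowed
    overlap queries; exon intervals are pooled per gene across transcripts.
    """

    def __init__(self, genes: list[_Gene]):
        self._by_chrom: dict[str, list[_Gene]] = {}
        self._max_len: dict[str, int] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.end))
            self._max_len[chrom] = max(g.end - g.start for g in gs)

    @classmethod
    def from_gtf(cls, gtf: pd.DataFrame | str) -> "AnnotationIndex":
        """Build from a 9-column GTF DataFrame or file path (1-based inclusive)."""
        if isinstance(gtf, str):
            gtf = pd.read_csv(
                gtf,
                sep="\t",
                comment="#",
                header=None,
                names=[
                    "seqname", "source", "feature", "start", "end",
                    "score", "strand", "frame", "attribute",
                ],
            )
        genes: dict[str, _Gene] = {}
        for row in gtf.itertuples(index=False):
            gid = _gtf_attr(row.attribute, "gene_id")
            if gid is None:
                continue
            start0, end0 = int(row.start) - 1, int(row.end)  # to half-open
            if row.feature == "gene":
                genes[gid] = _Gene(gid, row.seqname, start0, end0, row.strand)
            elif row.feature == "exon":
                if gid not in genes:
                    genes[gid] = _Gene(gid, row.seqname, start0, end0, row.strand)
                g = genes[gid]
                g.exons.append((start0, end0))
                g.start, g.end = min(g.start, start0), max(g.end, end0)
        for g in genes.values():
            bad = [e for e in g.exons if e[0] < g.start or e[1] > g.end]
            if bad:
                raise ValueError(f"exon outside gene span for {g.gene_id}")
        return cls(list(genes.values()))

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[_Gene]:
        gs = self._by_chrom.get(chrom, [])
        if not gs:
            return []
        lo = bisect_right([g.start for g in gs], start - self._max_len[chrom])
        out = []
        for g in gs[lo:]:
            if g.start >= end:
                break
            if g.end > start:
                out.append(g)
        return out

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)


def _gtf_attr(attribute: str, key: str) -> str | None:
    for part in attribute.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return None


def calls_from_table(table: pd.DataFrame, sample_ids: list[str]) -> list[BsjCall]:
    """Parse a caller TSV frame (1-based inclusive) into internal calls."""
    read_cols = [f"reads_{s}" for s in sample_ids]
    missing = [c for c in read_cols if c not in table.columns]
    if missing:
        raise ValueError(f"caller table lacks read columns: {missing}")
    calls = []
    for row in table.itertuples(index=False):
        reads = {s: int(getattr(row, f"reads_{s}")) for s in sample_ids}
        calls.append(
            BsjCall(row.chrom, int(row.start) - 1, int(row.end), row.strand, row.caller, reads)
        )
    return calls


def intersect_callers(
    calls_a: list[BsjCall], calls_b: list[BsjCall], slack: int = 0
) -> list[BsjCall]:
    """Keep junctions reported by both callers.

    Two calls match when chrom and strand agree and both the start and the
    end coordinates differ by at most ``slack`` (default 0, exact match).
    Each call pairs at most once (nearest-coordinate first); the merged call
    takes caller A's coordinates and the per-sample maximum junction reads.
    Output is sorted by (chrom, start, end).
    """
    samples_a = {frozenset(c.junction_reads) for c in calls_a}
    samples_b = {frozenset(c.junction_reads) for c in calls_b}
    if (samples_a | samples_b) and len(samples_a | samples_b) != 1:
        raise ValueError("caller tables parsed against different sample sheets")

    by_key: dict[tuple[str, str], list[BsjCall]] = {}
    for c in calls_b:
        by_key.setdefault((c.chrom, c.strand), []).append(c)
    used: set[int] = set()
    merged = []
    for a in calls_a:
        candidates = [
            b
            for b in by_key.get((a.chrom, a.strand), [])
            if id(b) not in used
            and abs(b.start - a.start) <= slack
            and abs(b.end - a.end) <= slack
        ]
        if not candidates:
            continue
        b = min(candidates, key=lambda b: abs(b.start - a.start) + abs(b.end - a.end))
        used.add(id(b))
        reads = {
            s: max(a.junction_reads[s], b.junction_reads[s]) for s in a.junction_reads
        }
        merged.append(BsjCall(a.chrom, a.start, a.end, a.strand, "merged", reads))
    merged.sort(key=lambda c: (c.chrom, c.start, c.end))
    return merged


def replicate_sets(sample_sheet: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Sample ids per (group, timepoint) replicate set."""
    sets = {
        key: list(idx)
        for key, idx in sample_sheet.groupby(["group", "timepoint"]).groups.items()
    }
    if not sets or any(len(v) == 0 for v in sets.values()):
        raise ValueError("sample sheet defines an empty replicate set")
    return sets


def filter_junction_reads(
    calls: list[BsjCall], sample_sheet: pd.DataFrame, min_reads: int = 2
) -> list[BsjCall]:
    """Keep a call iff one replicate set has >= min_reads in every sample."""
    sets = replicate_sets(sample_sheet)
    kept = []
    for c in calls:
        if any(
            all(c.junction_reads.get(s, 0) >= min_reads for s in members)
            for members in sets.values()
        ):
            kept.append(c)
    return kept


def classify_circ(call: BsjCall, annotation: AnnotationIndex) -> CircRecord:
    """Assign exonic/intronic/intergenic class and host gene.

    Exonic: both junction endpoints coincide with exon boundaries of one
    gene. Intronic: the span lies strictly inside a single intron of one
    gene. Intergenic: no gene overlap. Ambiguous overlaps fall back to
    exonic when >= 1 bp of exon overlap exists, else intronic; the host is
    the gene with the longest overlap.
    """
    if call.chrom not in annotation.chroms:
        logger.warning("chromosome %s absent from annotation; calling intergenic", call.chrom)
        return _record(call, "intergenic", None)
    genes = annotation.overlapping_genes(call.chrom, call.start, call.end)
    if not genes:
        return _record(call, "intergenic", None)
    for g in genes:
        starts = {s for s, _ in g.exons}
        ends = {e for _, e in g.exons}
        if call.start in starts and call.end in ends:
            return _record(call, "exonic", g.gene_id)
    for g in genes:
        if any(s <= call.start and call.end <= e for s, e in g.introns()):
            return _record(call, "intronic", g.gene_id)
    # ambiguity rule: exon overlap wins, host = longest-overlap gene
    def overlap(g: _Gene) -> int:
        return min(call.end, g.end) - max(call.start, g.start)

    host = max(genes, key=overlap)
    exon_bp = sum(
        max(0, min(call.end, e) - max(call.start, s))
        for g in genes
        for s, e in g.exons
    )
    return _record(call, "exonic" if exon_bp >= 1 else "intronic", host.gene_id)


def _record(call: BsjCall, circ_class: str, host: str | None) -> CircRecord:
    return CircRecord(
        call.circ_id, call.chrom, call.start, call.end, call.strand,
        circ_class, host, dict(call.junction_reads),
    )


def composition_report(catalog: list[CircRecord] | dict[str, int]) -> dict:
    """Class counts and half-up-rounded percentages (2 decimals).

    Accepts either a catalog of records or a precomputed
    ``{class: count}`` mapping.
    """
    if isinstance(catalog, dict):
        counts = {k: int(v) for k, v in catalog.items()}
    else:
        counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
        for rec in catalog:
            counts[rec.circ_class] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty catalog")
    pct = {
        k: float(
            (Decimal(100 * v) / Decimal(total)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )
        for k, v in counts.items()
    }
    return {"counts": counts, "total": total, "percent": pct}


def catalog_table(catalog: list[CircRecord]) -> pd.DataFrame:
    """Catalog as a tidy 1-based-inclusive DataFrame for TSV export."""
    rows = []
    for r in catalog:
        rows.append(
            {
                "circ_id": r.circ_id,
                "chrom": r.chrom,
                "start": r.start + 1,
                "end": r.end,
                "strand": r.strand,
                "class": r.circ_class,
                "host_gene": r.host_gene if r.host_gene is not None else "",
                **{f"reads_{s}": v for s, v in r.junction_reads.items()},
            }
        )
    return pd.DataFrame(rows)
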