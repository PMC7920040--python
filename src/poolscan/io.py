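"""Readers, writers and masked genomic views for the pipeline's file formats.

Formats handled here: Popoolation2-style ``sync`` allele-count tables
(two pools), gene models as GFF3 or BED12, indel position lists (TSV),
and gene-to-term annotation maps (TSV).

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  GFF3 and sync positions
are 1-based at the file boundary only: a GFF3 feature ``start..end``
(1-based inclusive) becomes ``[start-1, end)`` internally, and a sync
``position`` is stored as printed (1-based) on :class:`SyncSite`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: fixed column order of a sync count field
SYNC_BASES = ("A", "T", "C", "G", "N", "del")

_VALID_REF = set("ACGTN")


class SyncParseError(ValueError):
    """Raised when a sync file line cannot be parsed."""


@dataclass(frozen=True)
class SyncSite:
    """Per-position allele counts for two pools.

    ``counts_pool1``/``counts_pool2`` are six non-negative integers in
    the fixed order A, T, C, G, N, deletion.  ``position`` is 1-based.
    """

    scaffold: str
    position: int
    reference_base: str
    counts_pool1: tuple[int, int, int, int, int, int]
    counts_pool2: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for counts in (self.counts_pool1, self.counts_pool2):
            if len(counts) != 6 or any(c < 0 for c in counts):
                raise ValueError(f"counts must be six non-negative ints, got {counts}")

    def coverage(self, pool: int) -> int:
        """Total count (all six fields) of pool 1 or 2."""
        return sum(self.counts_pool1 if pool == 1 else self.counts_pool2)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure; the aggregation unit for gene-level FST.

    Exons are 0-based half-open intervals, sorted and non-overlapping.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: exon start {s} >= end {e}")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Full gene span [first exon start, last exon end)."""
        return self.start, self.end


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class MaskSet:
    """Per-scaffold sets of masked intervals (0-based half-open, merged)."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._intervals: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for scaf, ivs in intervals.items():
                self._intervals[scaf] = _merge_intervals(ivs)

    def intervals(self, scaffold: str) -> list[tuple[int, int]]:
        return list(self._intervals.get(scaffold, []))

    @property
    def scaffolds(self) -> list[str]:
        return sorted(self._intervals)

    def add(self, scaffold: str, start: int, end: int) -> None:
        ivs = self._intervals.setdefault(scaffold, [])
        ivs.append((max(0, start), end))
        self._intervals[scaffold] = _merge_intervals(ivs)

    def contains(self, scaffold: str, pos0: int) -> bool:
        """True if 0-based position lies in a masked interval."""
        import bisect

        ivs = self._intervals.get(scaffold)
        if not ivs:
            return False
        i = bisect.bisect_right(ivs, (pos0, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos0 < ivs[i][1]

    def union(self, other: "MaskSet") -> "MaskSet":
        combined: dict[str, list[tuple[int, int]]] = {}
        for src in (self, other):
            for scaf in src._intervals:
                combined.setdefault(scaf, []).extend(src._intervals[scaf])
        return MaskSet(combined)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MaskSet) and self._intervals == other._intervals


class AnnotationMap:
    """term_id -> set of gene ids, with optional human-readable labels."""

    def __init__(
        self,
        terms: Mapping[str, Iterable[str]] | None = None,
        labels: Mapping[str, str] | None = None,
    ):
        self.terms: dict[str, frozenset[str]] = {
            t: frozenset(g) for t, g in (terms or {}).items()
        }
        self.labels: dict[str, str] = dict(labels or {})

    def add_term(self, term_id: str, genes: Iterable[str], label: str = "") -> None:
        """Add (or replace) a term, e.g. a custom candidate-gene term."""
        self.terms[term_id] = frozenset(genes)
        if label:
            self.labels[term_id] = label

    def restrict(self, background: Iterable[str], min_term_size: int = 5) -> "AnnotationMap":
        """Intersect every term with ``background`` and drop small terms.

        Terms retaining fewer than ``min_term_size`` background genes are
        removed (the node-size filter of GO enrichment practice).
        """
        bg = frozenset(background)
        kept: dict[str, frozenset[str]] = {}
        n_dropped = 0
        for term, genes in self.terms.items():
            present = genes & bg
            if len(present) >= min_term_size:
                kept[term] = present
            else:
                n_dropped += 1
        if n_dropped:
            log.info("dropped %d terms with < %d background genes", n_dropped, min_term_size)
        return AnnotationMap(kept, {t: self.labels.get(t, "") for t in kept})

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


# ---------------------------------------------------------------------------
# sync


def _parse_counts(fieldstr: str, lineno: int) -> tuple[int, ...]:
    parts = fieldstr.split(":")
    if len(parts) != 6:
        raise SyncParseError(f"line {lineno}: expected 6 colon-separated counts, got {fieldstr!r}")
    try:
        counts = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise SyncParseError(f"line {lineno}: malformed count string {fieldstr!r}") from exc
    if any(c < 0 for c in counts):
        raise SyncParseError(f"line {lineno}: negative count in {fieldstr!r}")
    return counts


def read_sync(path: str | Path) -> list[SyncSite]:
    """Read a two-pool Popoolation2 sync file.

    Each data line is tab-separated: scaffold, 1-based position,
    reference base, then one ``A:T:C:G:N:del`` count field per pool.
    """
    sites: list[SyncSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise SyncParseError(f"line {lineno}: expected >= 5 columns, got {len(cols)}")
            try:
                pos = int(cols[1])
            except ValueError as exc:
                raise SyncParseError(f"line {lineno}: non-integer position {cols[1]!r}") from exc
            ref = cols[2].upper()
            if ref not in _VALID_REF:
                raise SyncParseError(f"line {lineno}: invalid reference base {cols[2]!r}")
            sites.append(
                SyncSite(
                    scaffold=cols[0],
                    position=pos,
                    reference_base=ref,
                    counts_pool1=_parse_counts(cols[3], lineno),
                    counts_pool2=_parse_counts(cols[4], lineno),
                )
            )
    return sites


def write_sync(sites: Iterable[SyncSite], path: str | Path) -> None:
    """Write sites in the exact dialect :func:`read_sync` consumes."""
    with open(path, "w") as fh:
        for s in sites:
            c1 = ":".join(str(c) for c in s.counts_pool1)
            c2 = ":".join(str(c) for c in s.counts_pool2)
            fh.write(f"{s.scaffold}\t{s.position}\t{s.reference_base}\t{c1}\t{c2}\n")


# ---------------------------------------------------------------------------
# gene models


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _read_gff3(path: str | Path) -> list[GeneModel]:
    # gene features declare spans; exon features point at them via Parent
    # (directly, or through an mRNA-level intermediate).
    gene_span: dict[str, tuple[str, str, int, int]] = {}  # id -> scaf, strand, s, e
    parent_of: dict[str, str] = {}  # transcript id -> gene id
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            scaf, _, ftype, start_s, end_s, _, strand, _, attr_s = cols[:9]
            start, end = int(start_s), int(end_s)
            attrs = _parse_gff_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}: line {lineno}: gene without ID")
                gene_span[gid] = (scaf, strand, start - 1, end)
                order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid and parent:
                    parent_of[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}: line {lineno}: exon without Parent")
                gid = parent_of.get(parent, parent)
                exons.setdefault(gid, []).append((start - 1, end))
    models = []
    for gid in order:
        scaf, strand, gstart, gend = gene_span[gid]
        exon_list = _merge_intervals(exons.get(gid, [(gstart, gend)]))
        for s, e in exon_list:
            if s < gstart or e > gend:
                raise ValueError(f"gene {gid}: exon [{s},{e}) outside gene span [{gstart},{gend})")
        models.append(GeneModel(gid, scaf, strand, tuple(exon_list)))
    return models


def _read_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 BED columns")
            scaf, chrom_start, _, name, _, strand = cols[0], int(cols[1]), int(cols[2]), cols[3], cols[4], cols[5]
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}: line {lineno}: blockCount mismatch")
            exons = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            )
            models.append(GeneModel(name, scaf, strand, exons))
    return models


def read_gene_models(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (``format='gff3'``) or BED12 (``'bed12'``)."""
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + exon features, Parent = gene ID)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.scaffold}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# masks


def read_indel_positions(path: str | Path) -> list[tuple[str, int]]:
    """Read a TSV of (scaffold, 1-based indel position) pairs."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}: line {lineno}: expected scaffold<TAB>position")
            out.append((cols[0], int(cols[1])))
    return out


def build_indel_mask(indel_positions: Iterable[tuple[str, int]], window: int = 5) -> MaskSet:
    """Mask a ``window``-bp interval centred on each indel.

    An indel at 1-based position p masks 0-based
    ``[p-1-window//2, p-1+window//2+1)``, clipped at the scaffold start.
    Overlapping windows merge.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    half = window // 2
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for scaf, pos in indel_positions:
        p0 = pos - 1
        by_scaffold.setdefault(scaf, []).append((max(0, p0 - half), p0 + half + 1))
    return MaskSet(by_scaffold)


def exon_mask(genes: Iterable[GeneModel], use_gene_span: bool = False) -> MaskSet:
    """The genic view as a MaskSet: exons by default, whole spans on request."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        target = [g.span] if use_gene_span else list(g.exons)
        ivs.setdefault(g.scaffold, []).extend(target)
    return MaskSet(ivs)


def apply_masks(
    sites: Iterable[SyncSite],
    mask: MaskSet | None = None,
    gene_models: Sequence[GeneModel] | None = None,
    genic_only: bool = False,
    use_gene_span: bool = False,
) -> list[SyncSite]:
    """Drop sites in masked intervals; optionally keep only genic sites.

    With ``genic_only`` a site survives only if it falls inside an exon
    (or inside the whole gene span with ``use_gene_span``).  Input order
    is preserved.
    """
    genic: MaskSet | None = None
    if genic_only:
        genic = exon_mask(gene_models or [], use_gene_span=use_gene_span)
    out = []
    n_masked = n_nongenic = 0
    for site in sites:
        pos0 = site.position - 1
        if mask is not None and mask.contains(site.scaffold, pos0):
            n_masked += 1
            continue
        if genic is not None and not genic.contains(site.scaffold, pos0):
            n_nongenic += 1
            continue
        out.append(site)
    log.info("apply_masks: removed %d masked, %d non-genic sites", n_masked, n_nongenic)
    return out


# ---------------------------------------------------------------------------
# annotation maps


def read_annotation_map(
    path: str | Path,
    min_term_size: int = 5,
    background: Iterable[str] | None = None,
) -> AnnotationMap:
    """Read a TSV of ``gene_id<TAB>term_id[<TAB>term_label]`` pairs.

    If ``background`` is given, terms are restricted to background genes
    and terms with fewer than ``min_term_size`` background members drop.
    """
    terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}: line {lineno}: expected gene<TAB>term")
            gene, term = cols[0], cols[1]
            terms.setdefault(term, set()).add(gene)
            if len(cols) > 2 and cols[2]:
                labels[term] = cols[2]
    amap = AnnotationMap(terms, labels)
    if background is not None:
        amap = amap.restrict(background, min_term_size=min_term_size)
    return amap


def write_annotation_map(amap: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(amap.terms):
            label = amap.labels.get(term, "")
            for gene in sorted(amap.terms[term]):
                fh.write(f"{gene}\t{term}\t{label}\n" if label else f"{gene}\t{term}\n")
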