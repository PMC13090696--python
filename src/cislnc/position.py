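"""Strand-aware positional classification of lncRNAs relative to coding genes.

Every lncRNA is assigned exactly one of six positional categories —
``intergenic``, ``bidirectional``, ``intronic``, ``antisense``, ``sense``,
``overlapping`` — by an explicit precedence over interval relations with
protein-coding gene models:

1. **intronic** — the lncRNA span lies fully inside a single intron of some
   coding transcript, on either strand;
2. **antisense** — at least 1 bp of exonic overlap with a coding gene on the
   opposite strand;
3. **sense** — at least 1 bp of exonic overlap on the same strand, and the
   lncRNA span does not contain the whole coding gene;
4. **overlapping** — span overlap without exonic overlap, or the lncRNA span
   fully contains a coding gene;
5. **bidirectional** — no overlap, but the lncRNA TSS lies within a small
   window (default 1 kb) of a coding TSS in divergent, head-to-head
   orientation;
6. **intergenic** — everything else.

The first matching rule wins, which makes the six categories a partition.
Coordinates are handled 0-based half-open internally; GTF input/output is
1-based closed. "Overlap" always means a non-empty half-open intersection.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from intervaltree import IntervalTree

CATEGORIES = ("intergenic", "bidirectional", "intronic", "antisense", "sense", "overlapping")

#: window used when looking for a nearest coding neighbor of an intergenic lncRNA
NEIGHBOR_WINDOW = 100_000


@dataclass(frozen=True)
class GeneModel:
    """One gene: span, strand, biotype and per-transcript exon chains.

    ``start``/``end`` are 0-based half-open. ``transcripts`` maps transcript id
    to a sorted list of 0-based half-open exon intervals; a gene without
    annotated exons carries a single implicit exon spanning the gene.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for tid, exons in self.transcripts.items():
            prev_end = None
            for s, e in exons:
                if not (self.start <= s < e <= self.end):
                    raise ValueError(f"transcript {tid}: exon [{s},{e}) outside gene span")
                if prev_end is not None and s < prev_end:
                    raise ValueError(f"transcript {tid}: exons overlap or are unsorted")
                prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site: leftmost base on '+', rightmost on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    def exons(self) -> list[tuple[int, int]]:
        """Union of exon intervals over all transcripts (may overlap between transcripts)."""
        if not self.transcripts:
            return [(self.start, self.end)]
        out = []
        for ex in self.transcripts.values():
            out.extend(ex)
        return sorted(out)

    def introns(self) -> list[tuple[int, int]]:
        """Per-transcript intron intervals (gaps between consecutive exons), pooled."""
        out = []
        for exons in self.transcripts.values():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if e1 < s2:
                    out.append((e1, s2))
        return out


class GenomeAnnotation:
    """A set of gene models with per-chromosome interval indexes."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self.genes[g.gene_id] = g
        # span index of protein-coding genes only: classification and cis-candidate
        # search both ask "which coding genes are near this interval".
        self._coding_index: dict[str, IntervalTree] = {}
        for g in self.coding_genes():
            tree = self._coding_index.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start, g.end, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.biotype == "protein_coding"]

    def lncrnas(self) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.biotype == "lncRNA"]

    def coding_near(self, chrom: str, start: int, end: int, pad: int = 0) -> list[GeneModel]:
        """Coding genes whose span intersects [start-pad, end+pad), sorted by gene_id."""
        tree = self._coding_index.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(max(0, start - pad), end + pad)
        return sorted((self.genes[h.data] for h in hits), key=lambda g: g.gene_id)


@dataclass(frozen=True)
class PositionalCall:
    """Category assignment of one lncRNA plus its triggering coding partner."""

    lncrna_id: str
    category: str
    partner_gene_id: str | None
    signed_distance: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


# ---------------------------------------------------------------------------
# GTF input / output
# ---------------------------------------------------------------------------

_KNOWN_BIOTYPES = ("protein_coding", "lncRNA")


class GtfError(ValueError):
    pass


def _parse_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def load_annotation(path) -> GenomeAnnotation:
    """Load a GTF file (1-based closed) into a :class:`GenomeAnnotation`.

    Only ``gene``, ``transcript`` and ``exon`` features are read; the
    ``gene_biotype`` attribute selects protein_coding / lncRNA models. Genes
    with an unrecognized biotype are kept out of the annotation (they play no
    role in classification). Genes without exon features receive one implicit
    exon covering the gene span.
    """
    gene_rows: dict[str, dict] = {}
    tx_exons: dict[str, dict[str, list[tuple[int, int]]]] = {}
    warnings: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise GtfError(f"{path}:{lineno}: invalid interval {start1}-{end1}")
            attrs = _parse_attributes(attrs_s)
            gid = attrs.get("gene_id")
            if gid is None:
                raise GtfError(f"{path}:{lineno}: missing gene_id attribute")
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
            if feature == "gene":
                biotype = attrs.get("gene_biotype", "")
                if biotype not in _KNOWN_BIOTYPES:
                    warnings.append(f"gene {gid}: unknown biotype {biotype!r}, ignored")
                    continue
                gene_rows[gid] = dict(chrom=chrom, start=start, end=end, strand=strand, biotype=biotype)
            else:
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise GtfError(f"{path}:{lineno}: {feature} without transcript_id")
                per_gene = tx_exons.setdefault(gid, {})
                per_gene.setdefault(tid, [])
                if feature == "exon":
                    per_gene[tid].append((start, end))

    genes = []
    for gid, row in gene_rows.items():
        transcripts = {
            tid: sorted(ex) if ex else [(row["start"], row["end"])]
            for tid, ex in tx_exons.get(gid, {}).items()
        }
        if not transcripts:
            transcripts = {f"{gid}.t1": [(row["start"], row["end"])]}
        genes.append(GeneModel(gene_id=gid, transcripts=transcripts, **row))
    ann = GenomeAnnotation(genes)
    ann.load_warnings = warnings  # type: ignore[attr-defined]
    return ann


def write_gtf(ann: GenomeAnnotation, path_or_buf) -> None:
    """Serialize an annotation to GTF (1-based closed), genes sorted by position."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        for g in sorted(ann.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(f"{g.chrom}\tcislnc\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            for tid, exons in g.transcripts.items():
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}"; gene_biotype "{g.biotype}";'
                fh.write(
                    f"{g.chrom}\tcislnc\ttranscript\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in exons:
                    fh.write(f"{g.chrom}\tcislnc\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n")
    finally:
        if own:
            fh.close()


def gtf_string(ann: GenomeAnnotation) -> str:
    buf = io.StringIO()
    write_gtf(ann, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _exonic_overlap(lnc: GeneModel, gene: GeneModel) -> bool:
    for ls, le in lnc.exons():
        for gs, ge in gene.exons():
            if ls < ge and gs < le:
                return True
    return False


def _span_gap(a: GeneModel, b: GeneModel) -> int:
    """Distance between two gene spans; 0 when they overlap or touch."""
    if a.start >= b.end:
        return a.start - b.end
    if b.start >= a.end:
        return b.start - a.end
    return 0


def _signed_gap(lnc: GeneModel, partner: GeneModel) -> int:
    """Span gap signed by position relative to the partner's orientation.

    Positive when the lncRNA lies downstream (3') of the partner, negative
    upstream; 0 on overlap.
    """
    gap = _span_gap(lnc, partner)
    if gap == 0:
        return 0
    lnc_is_right = lnc.start >= partner.end
    downstream = lnc_is_right if partner.strand == "+" else not lnc_is_right
    return gap if downstream else -gap


def _pick_nearest(lnc: GeneModel, candidates: list[GeneModel]) -> GeneModel:
    """Nearest by span distance; ties broken by lexicographic gene_id."""
    return min(candidates, key=lambda g: (_span_gap(lnc, g), g.gene_id))


def classify_lncrna(
    ann: GenomeAnnotation, lncrna_id: str, bidirectional_window: int = 1000
) -> PositionalCall:
    """Classify one lncRNA by the documented precedence rules."""
    if lncrna_id not in ann:
        raise KeyError(f"unknown gene id {lncrna_id!r}")
    lnc = ann[lncrna_id]
    if lnc.biotype != "lncRNA":
        raise KeyError(f"{lncrna_id!r} has biotype {lnc.biotype!r}, not lncRNA")

    span = (lnc.start, lnc.end)
    overlapping_genes = [g for g in ann.coding_near(lnc.chrom, *span) if _spans_overlap(span, (g.start, g.end))]

    # 1. intronic: fully inside a single intron of some coding transcript
    intronic = [
        g for g in overlapping_genes
        if any(isn <= lnc.start and lnc.end <= ien for isn, ien in g.introns())
    ]
    if intronic:
        p = _pick_nearest(lnc, intronic)
        return PositionalCall(lncrna_id, "intronic", p.gene_id, 0)

    # 2/3. exonic overlap, split by strand
    exonic = [g for g in overlapping_genes if _exonic_overlap(lnc, g)]
    antis = [g for g in exonic if g.strand != lnc.strand]
    if antis:
        p = _pick_nearest(lnc, antis)
        return PositionalCall(lncrna_id, "antisense", p.gene_id, 0)
    sense = [
        g for g in exonic
        if g.strand == lnc.strand and not (lnc.start <= g.start and g.end <= lnc.end)
    ]
    if sense:
        p = _pick_nearest(lnc, sense)
        return PositionalCall(lncrna_id, "sense", p.gene_id, 0)

    # 4. span overlap without exonic overlap, or full containment of a coding gene
    if overlapping_genes:
        p = _pick_nearest(lnc, overlapping_genes)
        return PositionalCall(lncrna_id, "overlapping", p.gene_id, 0)

    # 5. bidirectional: divergent promoters within the window, no overlap
    nearby = ann.coding_near(lnc.chrom, *span, pad=bidirectional_window)
    divergent = []
    for g in nearby:
        if g.strand == lnc.strand:
            continue
        plus, minus = (g, lnc) if g.strand == "+" else (lnc, g)
        if minus.tss < plus.tss and plus.tss - minus.tss <= bidirectional_window:
            divergent.append(g)
    if divergent:
        p = _pick_nearest(lnc, divergent)
        return PositionalCall(lncrna_id, "bidirectional", p.gene_id, _signed_gap(lnc, p))

    # 6. intergenic, with the nearest coding gene within 100 kb as optional partner
    neighbors = ann.coding_near(lnc.chrom, *span, pad=NEIGHBOR_WINDOW)
    if neighbors:
        p = _pick_nearest(lnc, neighbors)
        return PositionalCall(lncrna_id, "intergenic", p.gene_id, _signed_gap(lnc, p))
    return PositionalCall(lncrna_id, "intergenic", None, 0)


def classify_all(
    ann: GenomeAnnotation, bidirectional_window: int = 1000
) -> tuple[list[PositionalCall], dict[str, int]]:
    """Classify every lncRNA; returns calls plus a category count table.

    The count table covers all six categories (zero-filled) and always sums to
    the number of lncRNAs in the annotation.
    """
    calls = [
        classify_lncrna(ann, g.gene_id, bidirectional_window)
        for g in sorted(ann.lncrnas(), key=lambda g: g.gene_id)
    ]
    counts = Counter(c.category for c in calls)
    table = {cat: counts.get(cat, 0) for cat in CATEGORIES}
    return calls, table
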