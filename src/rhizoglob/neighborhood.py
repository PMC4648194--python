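"""Gene-neighborhood mapping around focal globin genes.

Reports annotated genes whose nearest edge lies within a span (default
5 kb) of a focal gene's nearest edge, partitioned into upstream and
downstream relative to the focal gene's transcription direction; checks
for tandem arrays of same-type globins; and tags neighbor products by
keyword category (nitrate/nitrite metabolism, chemotaxis, transport,
nif/fix/nos symbiosis genes, transcriptional regulators, hypotheticals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree


@dataclass(frozen=True)
class AnnotatedGene:
    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass
class NeighborhoodReport:
    """Flanking genes of one focal gene.

    ``upstream``/``downstream`` hold (AnnotatedGene, signed distance)
    pairs sorted by |distance|; upstream distances are negative.  The
    distance is the gap between nearest edges, 0 for overlaps.
    """

    focal_id: str
    upstream: list = field(default_factory=list)
    downstream: list = field(default_factory=list)
    categories: dict = field(default_factory=dict)  # neighbor id -> set of tags


DEFAULT_KEYWORDS = {
    "nitrate/nitrite": ["nitrate", "nitrite", "nitropropane", "nsrr"],
    "chemotaxis": ["chemotaxis", "methyl-accepting", "chey", "chea"],
    "transport": ["transport", "permease", "efflux", "abc "],
    "nif/fix/nos": ["nif", "fix", "nos"],
    "transcriptional regulator": ["transcriptional regulator", "regulator"],
    "hypothetical": ["hypothetical", "unknown function"],
}


def _edge_gap(a_start, a_end, b_start, b_end) -> int:
    if b_start > a_end:
        return b_start - a_end - 1
    if b_end < a_start:
        return a_start - b_end - 1
    return 0


def flanking_genes(
    focal,
    annotation,
    span: int = 5000,
    keyword_map=None,
) -> NeighborhoodReport:
    """Neighbors within ``span`` nt (nearest-edge gap) of the focal gene.

    Up/downstream is defined relative to the focal gene's strand: on the
    minus strand the labels swap sides.  Overlapping neighbors are
    assigned by midpoint, ties going downstream.
    """
    tree = IntervalTree()
    for g in annotation:
        if g.scaffold_id != focal.scaffold_id or g.gene_id == focal.gene_id:
            continue
        tree.addi(g.start, g.end + 1, g)
    report = NeighborhoodReport(focal_id=focal.gene_id)
    lo = max(1, focal.start - span)
    hi = focal.end + span
    fmid = (focal.start + focal.end) / 2.0
    for iv in tree.overlap(lo, hi + 1):
        g = iv.data
        gap = _edge_gap(focal.start, focal.end, g.start, g.end)
        if gap > span:
            continue
        if g.start > focal.end:
            right = True
        elif g.end < focal.start:
            right = False
        else:
            right = (g.start + g.end) / 2.0 >= fmid
        downstream = right if focal.strand == "+" else not right
        if downstream:
            report.downstream.append((g, gap))
        else:
            report.upstream.append((g, -gap))
    report.upstream.sort(key=lambda t: (abs(t[1]), t[0].gene_id))
    report.downstream.sort(key=lambda t: (abs(t[1]), t[0].gene_id))
    kw = DEFAULT_KEYWORDS if keyword_map is None else keyword_map
    for g, _ in report.upstream + report.downstream:
        report.categories[g.gene_id] = categorize_product(g.product, kw)
    return report


def tandem_array_check(typed_calls, annotation=(), span: int = 5000) -> list:
    """Pairs of same-type globins that are adjacent with no gene between.

    ``typed_calls`` is an iterable of (AnnotatedGene-like, type_key) on a
    single scaffold.  A pair is tandem when the two calls have the same
    type, their nearest-edge gap is <= span, and no annotated gene lies
    strictly between them.  An empty result asserts "not tandemly
    arrayed".
    """
    items = sorted(typed_calls, key=lambda t: (t[0].start, t[0].end))
    pairs = []
    for (g1, t1), (g2, t2) in zip(items, items[1:]):
        if t1 != t2:
            continue
        gap = _edge_gap(g1.start, g1.end, g2.start, g2.end)
        if gap > span:
            continue
        between_lo, between_hi = g1.end, g2.start
        intervening = any(
            other.gene_id not in (g1.gene_id, g2.gene_id)
            and other.scaffold_id == g1.scaffold_id
            and other.start > between_lo
            and other.end < between_hi
            for other in annotation
        )
        if not intervening:
            pairs.append((g1.gene_id, g2.gene_id))
    return pairs


def categorize_product(product: str, keyword_map=None) -> set:
    """Case-insensitive substring tagging of one product label."""
    kw = DEFAULT_KEYWORDS if keyword_map is None else keyword_map
    label = product.lower()
    tags = {cat for cat, words in kw.items() if any(w in label for w in words)}
    return tags or {"other"}


def categorize_products(products, keyword_map=None) -> list:
    """Tag a list of product labels; untagged labels become {"other"}."""
    return [categorize_product(p, keyword_map) for p in products]
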