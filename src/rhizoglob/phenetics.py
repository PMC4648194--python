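"""Percent-identity phenetics: distance matrices, UPGMA phenograms,
progressive multiple alignment and lineage-segregation reports.

The tree built here is a phenogram (a similarity tree), not a model-based
phylogeny: pairwise distances are simply ``100 - percent identity`` from
global alignments, with no multiple-hit correction, and clustering is
classic UPGMA (unweighted pair-group method with arithmetic mean), which
yields an ultrametric tree.  Percent identity is, by default, the number
of identical aligned residue pairs over the number of columns where both
sequences carry a residue; this denominator is stable for globin sets
with large length differences (single-domain globins vs two-domain
flavohemoglobins and sensors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rhizoglob.align import (
    AlignParams,
    _matrix_as_dense,
    global_align,
    gotoh_dp,
)

# ---------------------------------------------------------------------------
# distances


def percent_identity(
    a: str,
    b: str,
    params: AlignParams = AlignParams(),
    denominator: str = "aligned",
) -> float:
    """Percent identity of the optimal global alignment of a and b."""
    return global_align(a, b, params).identity_pct(denominator)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of phenetic distances d = 100 - percent identity."""

    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("nonzero diagonal")
        if m.min() < -1e-9 or m.max() > 100 + 1e-9:
            raise ValueError("distances outside [0, 100]")
        self.matrix = m

    @classmethod
    def from_sequences(
        cls,
        sequences: dict,
        params: AlignParams = AlignParams(),
        denominator: str = "aligned",
    ) -> "DistanceMatrix":
        labels = list(sequences)
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pid = percent_identity(
                    sequences[labels[i]], sequences[labels[j]], params, denominator
                )
                m[i, j] = m[j, i] = 100.0 - pid
        return cls(labels=labels, matrix=m)

    def get(self, la: str, lb: str) -> float:
        return float(
            self.matrix[self.labels.index(la), self.labels.index(lb)]
        )


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class PhenogramNode:
    """Tree node; leaves have height 0 and a label."""

    height: float
    label: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()


@dataclass
class PhenogramTree:
    root: PhenogramNode
    labels: list = field(default_factory=list)

    def leaf_labels(self) -> list:
        return [leaf.label for leaf in self.root.leaves()]

    def cophenetic_matrix(self, order=None) -> tuple:
        """(labels, matrix) of cophenetic distances (2x merge height)."""
        labels = list(order) if order is not None else self.leaf_labels()
        idx = {lab: k for k, lab in enumerate(labels)}
        n = len(labels)
        m = np.zeros((n, n))

        def rec(node):
            if node.is_leaf:
                return [node.label]
            sets = [rec(c) for c in node.children]
            for a_i in range(len(sets)):
                for b_i in range(a_i + 1, len(sets)):
                    for la in sets[a_i]:
                        for lb in sets[b_i]:
                            d = 2.0 * node.height
                            m[idx[la], idx[lb]] = m[idx[lb], idx[la]] = d
            return [lab for s in sets for lab in s]

        rec(self.root)
        return labels, m

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []

        def rec(node, acc):
            if node.is_leaf:
                depths.append(acc + node.height)  # leaf height is 0
                return
            for child in node.children:
                rec(child, acc + (node.height - child.height))

        rec(self.root, 0.0)
        return max(depths) - min(depths) <= tol


def upgma(dm: DistanceMatrix) -> PhenogramTree:
    """Classic UPGMA agglomeration.

    Iteratively merges the closest pair of clusters at height d_min / 2;
    the distance from a merged cluster to any other is the size-weighted
    mean of its parts.  Ties are broken by the lexicographically smallest
    (min leaf label) pair, making the tree deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA requires at least two taxa")
    # cluster key: min leaf label (used only for deterministic tie-breaks)
    clusters = {
        lab: (PhenogramNode(height=0.0, label=lab), 1) for lab in dm.labels
    }
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            key = frozenset((dm.labels[i], dm.labels[j]))
            dist[key] = float(dm.matrix[i, j])

    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(kv[0]))),
        )
        (pair, dmin) = best
        ka, kb = sorted(pair)
        node_a, size_a = clusters.pop(ka)
        node_b, size_b = clusters.pop(kb)
        merged = PhenogramNode(height=dmin / 2.0, children=(node_a, node_b))
        knew = min(ka, kb)
        for kc, (node_c, size_c) in clusters.items():
            da = dist.pop(frozenset((ka, kc)))
            db = dist.pop(frozenset((kb, kc)))
            dist[frozenset((knew, kc))] = (size_a * da + size_b * db) / (
                size_a + size_b
            )
        del dist[pair]
        clusters[knew] = (merged, size_a + size_b)

    (root, _total) = next(iter(clusters.values()))
    return PhenogramTree(root=root, labels=list(dm.labels))


# ---------------------------------------------------------------------------
# Newick


def _newick_label(label: str) -> str:
    if any(ch in label for ch in " ():,;'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: PhenogramTree) -> str:
    """Newick text with branch lengths (parent height - child height)."""

    def rec(node, parent_height):
        blen = parent_height - node.height
        if node.is_leaf:
            return f"{_newick_label(node.label)}:{blen:.10g}"
        inner = ",".join(rec(c, node.height) for c in node.children)
        return f"({inner}):{blen:.10g}"

    root = tree.root
    if root.is_leaf:
        return f"{_newick_label(root.label)};"
    inner = ",".join(rec(c, root.height) for c in root.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# progressive MSA


def _profile_columns(rows: list) -> np.ndarray:
    """Count matrix (L, n_symbols) over the substitution alphabet."""
    alphabet = _MSA_ALPHABET
    lut = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    L = len(rows[0])
    counts = np.zeros((L, len(alphabet)))
    for row in rows:
        codes = lut[np.frombuffer(row.encode(), dtype=np.uint8)]
        keep = codes >= 0  # gaps and unknowns excluded from counts
        counts[np.flatnonzero(keep), codes[keep]] += 1.0
    return counts


_MSA_ALPHABET = None  # set lazily from the substitution matrix alphabet


def progressive_msa(
    sequences: dict,
    guide: PhenogramTree,
    params: AlignParams = AlignParams(),
) -> dict:
    """Profile-profile progressive alignment along a guide tree.

    Column score between two profiles is the average substitution score
    over non-gap residue pairs; gap handling uses the same affine
    penalties as pairwise alignment, so aligning two single sequences
    reduces exactly to :func:`global_align`.  Returns an ordered mapping
    label -> gapped row; removing gaps from any row recovers its input.
    """
    global _MSA_ALPHABET
    dense, _ = _matrix_as_dense(params.matrix)
    from rhizoglob.align import _load_matrix

    _MSA_ALPHABET = str(_load_matrix(params.matrix).alphabet)

    guide_labels = set(guide.leaf_labels())
    if guide_labels != set(sequences):
        raise ValueError("guide tree leaves do not match sequence labels")

    def align_profiles(labels_a, rows_a, labels_b, rows_b):
        ca = _profile_columns(rows_a)
        cb = _profile_columns(rows_b)
        na = ca.sum(axis=1)
        nb = cb.sum(axis=1)
        raw = ca @ dense @ cb.T
        denom = np.outer(na, nb)
        sub = np.divide(raw, denom, out=np.zeros_like(raw), where=denom > 0)
        _score, moves = gotoh_dp(sub, params.gap_open, params.gap_extend)
        out_a = ["" for _ in rows_a]
        out_b = ["" for _ in rows_b]
        i = j = 0
        for mv in moves:
            take_a = mv in ("M", "X")
            take_b = mv in ("M", "Y")
            for r, row in enumerate(rows_a):
                out_a[r] += row[i] if take_a else "-"
            for r, row in enumerate(rows_b):
                out_b[r] += row[j] if take_b else "-"
            i += take_a
            j += take_b
        return labels_a + labels_b, out_a + out_b

    def rec(node):
        if node.is_leaf:
            return [node.label], [sequences[node.label]]
        parts = [rec(c) for c in node.children]
        labels, rows = parts[0]
        for lb, rb in parts[1:]:
            labels, rows = align_profiles(labels, rows, lb, rb)
        return labels, rows

    labels, rows = rec(guide.root)
    return dict(zip(labels, rows))


# ---------------------------------------------------------------------------
# lineage segregation and domain conservation


def lineage_segregation(tree: PhenogramTree, group_of: dict) -> dict:
    """Monophyly check per group in a phenogram.

    For each group (set of leaves sharing a label in ``group_of``) finds
    the smallest clade containing all its leaves and reports whether the
    group is exactly that clade (pure) and the clade's purity fraction.
    """
    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in group_of]
    if missing:
        raise ValueError(f"untyped leaves: {missing}")
    groups = {}
    for leaf, grp in group_of.items():
        groups.setdefault(grp, set()).add(leaf)

    def leafset(node):
        return frozenset(l.label for l in node.leaves())

    def smallest_covering(node, target):
        if not target <= leafset(node):
            return None
        for child in node.children:
            hit = smallest_covering(child, target)
            if hit is not None:
                return hit
        return node

    report = {}
    for grp, members in sorted(groups.items()):
        clade = smallest_covering(tree.root, members)
        clade_leaves = leafset(clade)
        report[grp] = {
            "group_size": len(members),
            "clade_size": len(clade_leaves),
            "purity": len(members) / len(clade_leaves),
            "monophyletic": clade_leaves == frozenset(members),
        }
    return report


MULTIDOMAIN_TYPES = {"fHb", "GCS"}


def domain_split_identity(
    seq_a: str,
    seq_b: str,
    type_key: str,
    refs=None,
    params: AlignParams = AlignParams(),
    z_threshold: float = 6.0,
    seed: int = 0,
) -> tuple:
    """Separate percent identities for the globin and non-globin domains.

    Both sequences must be the same multidomain type (fHb or GCS).  The
    domain boundary in each sequence is the last residue aligned to the
    best-matching single-domain globin reference; identity is then
    computed independently for the two N-terminal (globin) segments and
    the two C-terminal (flavin/transmitter) segments.
    """
    if type_key not in MULTIDOMAIN_TYPES:
        raise ValueError(
            f"{type_key!r} is single-domain; domain split applies to fHb/GCS only"
        )
    if refs is None:
        from rhizoglob.synthetic_references import reference_globins

        refs = reference_globins()
    single = [r for r in refs if r.type in ("SDgb", "SSDgb")]
    if not single:
        raise ValueError("no single-domain globin reference available")

    from rhizoglob.identify import alignment_zscore

    def boundary(seq):
        best = max(single, key=lambda r: global_align(seq, r.sequence, params).score)
        z = alignment_zscore(seq, best, n_shuffles=50, seed=seed, params=params)
        if z < z_threshold:
            raise ValueError(
                f"globin domain not locatable (z={z:.2f} < {z_threshold})"
            )
        aln = global_align(seq, best.sequence, params)
        return max(ia for ia, _ in aln.pairs)

    ba = boundary(seq_a)
    bb = boundary(seq_b)
    globin_id = percent_identity(seq_a[:ba], seq_b[:bb], params)
    if ba >= len(seq_a) or bb >= len(seq_b):
        raise ValueError("no non-globin domain beyond the boundary")
    other_id = percent_identity(seq_a[ba:], seq_b[bb:], params)
    return globin_id, other_id
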