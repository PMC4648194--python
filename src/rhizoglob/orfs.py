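"""Open reading frame detection on nucleotide scaffolds.

Finds maximal ORFs on both strands under bacterial/archaeal genetic code
11 with start codons ATG/GTG/TTG and stops TAA/TAG/TGA.  "Maximal" means
each stop-to-stop segment contributes at most one ORF, beginning at the
first start codon in the segment; alternative starts translate to Met.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1)
def _code11() -> dict:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = dict(unambiguous_dna_by_id[11].forward_table)
    for stop in STOP_CODONS:
        table[stop] = "*"
    return table


def translate(nt: str, to_met_start: bool = True) -> str:
    """Translate an in-frame coding sequence (without its stop codon).

    Codons containing N translate to X.  The first codon becomes M when it
    is an alternative start.
    """
    table = _code11()
    if len(nt) % 3:
        raise ValueError(f"coding sequence length {len(nt)} not divisible by 3")
    residues = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        aa = table.get(codon, "X")
        if aa == "*":
            raise ValueError(f"internal stop codon at nt position {i + 1}")
        residues.append(aa)
    if residues and to_met_start and nt[:3] in START_CODONS:
        residues[0] = "M"
    return "".join(residues)


@dataclass(frozen=True)
class GeneModel:
    """A gene on a scaffold: 1-based inclusive nt coordinates, strand-aware.

    ``start``/``end`` are forward-strand coordinates (start <= end) and
    include the stop codon; ``protein`` excludes it.
    """

    scaffold_id: str
    start: int
    end: int
    strand: str
    protein: str
    gene_id: str

    def __post_init__(self):
        span = self.end - self.start + 1
        if span % 3:
            raise ValueError(f"{self.gene_id}: span {span} not divisible by 3")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if len(self.protein) != span // 3 - 1:
            raise ValueError(
                f"{self.gene_id}: protein length {len(self.protein)} "
                f"inconsistent with span {span}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.protein)


def _validate_nt(seq: str) -> None:
    for pos, ch in enumerate(seq, start=1):
        if ch not in "ACGTN":
            raise ValueError(f"non-IUPAC nucleotide {ch!r} at position {pos}")


def _scan_strand(seq: str, min_len_aa: int):
    """Yield (start0, end0, protein) of maximal ORFs in one orientation."""
    table = _code11()
    n = len(seq)
    for frame in range(3):
        seg_start = frame  # first codon position after the previous stop
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if table.get(codon, "X") == "*":
                orf = _first_orf(seq, seg_start, i)
                if orf is not None:
                    s0 = orf
                    prot = translate(seq[s0:i])
                    if len(prot) >= min_len_aa:
                        yield s0, i + 2, prot
                seg_start = i + 3
        # segments without a terminal stop codon are discarded


def _first_orf(seq: str, seg_start: int, stop_pos: int):
    for j in range(seg_start, stop_pos, 3):
        if seq[j : j + 3] in START_CODONS:
            return j
    return None


def extract_orfs(
    scaffold: str,
    min_len_aa: int = 100,
    scaffold_id: str = "scaffold",
) -> list:
    """All maximal ORFs (both strands) with protein length >= min_len_aa.

    Returns GeneModels sorted by forward-strand coordinate.
    """
    scaffold = scaffold.upper()
    _validate_nt(scaffold)
    n = len(scaffold)
    models = []
    for s0, e0, prot in _scan_strand(scaffold, min_len_aa):
        models.append((s0 + 1, e0 + 1, "+", prot))
    for s0, e0, prot in _scan_strand(revcomp(scaffold), min_len_aa):
        models.append((n - e0, n - s0, "-", prot))
    models.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        GeneModel(
            scaffold_id=scaffold_id,
            start=s,
            end=e,
            strand=st,
            protein=p,
            gene_id=f"{scaffold_id}_orf{i + 1}",
        )
        for i, (s, e, st, p) in enumerate(models)
    ]
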