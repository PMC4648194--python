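"""Mismatch-tolerant scanning of upstream windows for promoter elements.

Scans the 130 nt immediately 5' of a gene's start codon (on the coding
strand) for four elements: the -10 box (TATAAT), the -35 box (TTGACA),
the Fnr box (TTTAAGAGGCCAAT; the binding site of the O2/NO-responsive
fumarate-nitrate reduction regulator) and the Shine-Dalgarno ribosome
binding sequence (AGGAGG).

Position convention: -1 is the nucleotide immediately 5' of the start
codon's first base.  Hits are reported "near to far" (e.g. "-36 to -41")
and the matched sequence is case-coded: uppercase where identical to the
consensus, lowercase at mismatches.

Two matching modes:

* ``hamming`` - every full-length placement of the consensus with at
  most ``max_mismatches`` mismatches (defaults: 1 for -10/-35, 5 for the
  Fnr box, i.e. >= 9/14 identities);
* ``partial`` - maximal exact substring matches of the consensus of
  length >= ``min_match_len`` (default 3), used for the Shine-Dalgarno
  element whose reported hits are often shorter than the 6-nt consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from rhizoglob.orfs import GeneModel, revcomp

ND = "N.D."


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str
    mode: str = "hamming"            # "hamming" | "partial"
    max_mismatches: int = 0
    min_match_len: int = 3

    def __post_init__(self):
        if self.mode not in ("hamming", "partial"):
            raise ValueError(f"unknown motif mode {self.mode!r}")
        if any(c not in "ACGT" for c in self.consensus):
            raise ValueError(f"consensus {self.consensus!r} not over ACGT")
        if self.mode == "partial" and self.min_match_len < 3:
            raise ValueError("min_match_len must be >= 3")


def default_motifs() -> dict:
    """The four default elements with field-standard consensus strings."""
    return {
        "-10": MotifDefinition("-10", "TATAAT", "hamming", max_mismatches=1),
        "-35": MotifDefinition("-35", "TTGACA", "hamming", max_mismatches=1),
        "Fnr": MotifDefinition("Fnr", "TTTAAGAGGCCAAT", "hamming", max_mismatches=5),
        "SD": MotifDefinition("SD", "AGGAGG", "partial", min_match_len=3),
    }


@dataclass(frozen=True)
class UpstreamWindow:
    """Coding-strand nucleotides 5' of a start codon.

    The last character sits at offset -1; the first at -len(sequence).
    ``truncated`` marks windows shortened by a scaffold edge.
    """

    gene_id: str
    sequence: str
    truncated: bool = False

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """One motif match; ``near``/``far`` are negative offsets, |near| < |far|."""

    motif: str
    near: int
    far: int
    matched: str
    n_identical: int
    n_mismatch: int

    def __post_init__(self):
        assert self.near < 0 and self.far < 0 and abs(self.near) < abs(self.far)
        assert self.near - self.far + 1 == len(self.matched)
        assert self.n_identical + self.n_mismatch == len(self.matched)

    @property
    def position_str(self) -> str:
        return f"{self.near} to {self.far}"


def upstream_region(gene: GeneModel, scaffold: str, window: int = 130) -> UpstreamWindow:
    """Extract the coding-strand upstream window of a gene.

    For + strand genes this is scaffold[start-window .. start-1]; for -
    strand genes the reverse complement of scaffold[end+1 .. end+window].
    Shorter-than-requested windows at scaffold edges are truncated and
    flagged.
    """
    n = len(scaffold)
    if gene.start < 1 or gene.end > n:
        raise ValueError(
            f"gene {gene.gene_id} ({gene.start}..{gene.end}) not on scaffold of length {n}"
        )
    if gene.strand == "+":
        lo = max(0, gene.start - 1 - window)
        seq = scaffold[lo : gene.start - 1]
    else:
        hi = min(n, gene.end + window)
        seq = revcomp(scaffold[gene.end : hi])
    return UpstreamWindow(
        gene_id=gene.gene_id, sequence=seq, truncated=len(seq) < window
    )


def case_code(consensus: str, observed: str) -> str:
    """Uppercase where observed matches consensus, else lowercase observed."""
    if len(consensus) != len(observed):
        raise ValueError(
            f"length mismatch: consensus {len(consensus)} vs observed {len(observed)}"
        )
    return "".join(
        o.upper() if o.upper() == c.upper() else o.lower()
        for c, o in zip(consensus, observed)
    )


def _offsets(window_len: int, start_index: int, match_len: int) -> tuple:
    far = -(window_len - start_index)
    near = far + match_len - 1
    return near, far


def scan_hamming(window: UpstreamWindow, motif: MotifDefinition) -> list:
    """All full-length placements with <= max_mismatches, nearest first."""
    if motif.mode != "hamming":
        raise ValueError(f"motif {motif.name} is not in hamming mode")
    seq = window.sequence.upper()
    cons = motif.consensus
    m, w = len(cons), len(seq)
    hits = []
    for i in range(w - m + 1):
        segment = seq[i : i + m]
        mm = sum(1 for a, b in zip(segment, cons) if a != b)
        if mm <= motif.max_mismatches:
            near, far = _offsets(w, i, m)
            hits.append(
                MotifHit(
                    motif=motif.name,
                    near=near,
                    far=far,
                    matched=case_code(cons, segment),
                    n_identical=m - mm,
                    n_mismatch=mm,
                )
            )
    hits.sort(key=lambda h: abs(h.near))
    return hits


def scan_partial(window: UpstreamWindow, motif: MotifDefinition) -> list:
    """Maximal exact substring matches of the consensus, nearest first."""
    if motif.mode != "partial":
        raise ValueError(f"motif {motif.name} is not in partial mode")
    seq = window.sequence.upper()
    cons = motif.consensus
    w, m = len(seq), len(cons)
    hits = []
    for ws in range(w):
        for cs in range(m):
            if seq[ws] != cons[cs]:
                continue
            if ws > 0 and cs > 0 and seq[ws - 1] == cons[cs - 1]:
                continue  # not left-maximal on this diagonal
            k = 0
            while ws + k < w and cs + k < m and seq[ws + k] == cons[cs + k]:
                k += 1
            if k >= motif.min_match_len:
                near, far = _offsets(w, ws, k)
                hits.append(
                    MotifHit(
                        motif=motif.name,
                        near=near,
                        far=far,
                        matched=seq[ws : ws + k],
                        n_identical=k,
                        n_mismatch=0,
                    )
                )
    # drop hits wholly contained in a longer hit at the same location, and
    # duplicates arising from repeated substrings within the consensus
    seen = set()
    unique = []
    for h in hits:
        key = (h.near, h.far)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    maximal = [
        h
        for h in unique
        if not any(
            g is not h and g.far <= h.far and h.near <= g.near and len(g.matched) > len(h.matched)
            for g in unique
        )
    ]
    maximal.sort(key=lambda h: (abs(h.near), -len(h.matched)))
    return maximal


def scan_window(window: UpstreamWindow, motif: MotifDefinition) -> list:
    return scan_hamming(window, motif) if motif.mode == "hamming" else scan_partial(window, motif)


def primary_hit(hits):
    """Best hit: fewest mismatches, then nearest to the gene."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.n_mismatch, abs(h.near)))


def promoter_report(windows, motifs=None) -> pd.DataFrame:
    """Tabulate element positions per gene, one row per gene.

    ``windows`` is an iterable of UpstreamWindow.  Additional Fnr hits
    beyond the first get continuation rows with a blank gene cell,
    mirroring the usual table layout; absent elements render "N.D.".
    """
    motifs = motifs or default_motifs()
    columns = ["gene", "-10", "-35", "Fnr_sequence", "Fnr_position", "SD"]
    rows = []
    for win in windows:
        by_name = {name: scan_window(win, mot) for name, mot in motifs.items()}
        p10 = primary_hit(by_name.get("-10", []))
        p35 = primary_hit(by_name.get("-35", []))
        sd_hits = by_name.get("SD", [])
        if sd_hits:
            best_len = max(len(h.matched) for h in sd_hits)
            sd_cell = " and ".join(
                h.position_str for h in sd_hits if len(h.matched) == best_len
            )
        else:
            sd_cell = ND
        fnr_hits = sorted(
            by_name.get("Fnr", []), key=lambda h: (h.n_mismatch, abs(h.near))
        )
        first = {
            "gene": win.gene_id,
            "-10": p10.position_str if p10 else ND,
            "-35": p35.position_str if p35 else ND,
            "Fnr_sequence": fnr_hits[0].matched if fnr_hits else ND,
            "Fnr_position": fnr_hits[0].position_str if fnr_hits else "",
            "SD": sd_cell,
        }
        rows.append(first)
        for extra in fnr_hits[1:]:
            rows.append(
                {
                    "gene": "",
                    "-10": "",
                    "-35": "",
                    "Fnr_sequence": extra.matched,
                    "Fnr_position": extra.position_str,
                    "SD": "",
                }
            )
    return pd.DataFrame(rows, columns=columns)
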