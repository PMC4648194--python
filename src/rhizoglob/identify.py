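"""Globin identification and family/type classification.

A candidate protein is scored against every reference in the query panel
by global alignment; significance is assessed with a permutation Z score
(the alignment score of the query standardized against scores of
residue-shuffled copies of the query).  A candidate is accepted as a
globin when three criteria hold:

1. length >= ~100 amino acids,
2. Z score above the acceptance threshold (default 6),
3. proximal His at the myoglobin-fold position F8 mapped through the
   alignment to the best reference.

Family (M/S/T), type (fHb/SDgb/GCS/protoglobin/SSDgb/tHb) and truncated
hemoglobin class (1/2/3) are inherited from the best-matching reference
and then refined by domain architecture: a long protein whose best match
is a single-domain globin at its N-terminus is promoted to the
corresponding chimeric type (fHb for M-family, GCS for S-family).

Known caveat carried over from the literature on globin-coupled sensors:
some GCSs align with Glu rather than His at F8, possibly an alignment
artifact.  By default such candidates are accepted when typed as GCS but
flagged (``f8_exception``); set ``allow_gcs_glu_f8=False`` to enforce the
strict His gate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from rhizoglob.align import (
    AlignParams,
    Alignment,
    align_score,
    global_align,
)
from rhizoglob.orfs import GeneModel
from rhizoglob.synthetic_references import (
    FAMILY_OF_TYPE,
    ROLES,
    ReferenceGlobin,
)

MIN_SHUFFLES = 50

#: average residue masses (Da), used for molecular-mass estimates
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 110.0,
}
_WATER = 18.0153


@dataclass(frozen=True)
class ClassifyThresholds:
    """Acceptance and architecture thresholds for globin classification."""

    min_len_aa: int = 100
    z_threshold: float = 6.0
    t_fhb: int = 300       # min length to promote an SDgb-like match to fHb
    t_gcs: int = 350       # min length to promote an SSDgb-like match to GCS
    n_shuffles: int = MIN_SHUFFLES
    allow_gcs_glu_f8: bool = True
    align: AlignParams = AlignParams()


@dataclass
class GlobinCall:
    """Classification result for one gene."""

    gene_id: str
    best_reference: str
    family: str
    type: str
    thb_class: int | None
    alignment_score: float
    z_score: float
    percent_identity: float
    length_aa: int
    mass_kda: float
    key_residues: dict            # role -> (residue or None, 1-based query index or None)
    flags: dict                   # length_ok / z_ok / f8_his_ok
    accepted: bool
    f8_exception: bool = False
    zscores: dict = field(default_factory=dict)
    genome: str | None = None

    @property
    def type_key(self) -> str:
        """Collapsed lower-case type used in tallies: fhb/sdgb/gcs/thb/..."""
        t = self.type.lower()
        return "thb" if t.startswith("thb") else t


def protein_mass_kda(protein: str) -> float:
    mass = sum(_RESIDUE_MASS[res] for res in protein) + _WATER
    return mass / 1000.0


def alignment_zscore(
    query: str,
    ref,
    n_shuffles: int = 100,
    seed: int = 0,
    params: AlignParams = AlignParams(),
) -> float:
    """Permutation Z score of the global alignment score.

    The null distribution is built by uniformly permuting the query
    residues ``n_shuffles`` times (preserving length and composition) and
    re-scoring against the reference.  Returns +inf with a warning when
    the null is degenerate (zero spread).
    """
    if n_shuffles < MIN_SHUFFLES:
        raise ValueError(
            f"n_shuffles={n_shuffles} below the floor of {MIN_SHUFFLES}"
        )
    ref_seq = ref.sequence if isinstance(ref, ReferenceGlobin) else ref
    rng = np.random.default_rng(seed)
    observed = align_score(query, ref_seq, params)
    chars = np.frombuffer(query.encode(), dtype=np.uint8)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = rng.permutation(chars).tobytes().decode()
        null[k] = align_score(shuffled, ref_seq, params)
    sd = float(np.std(null, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "degenerate permutation null (zero spread); reporting +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return float((observed - float(np.mean(null))) / sd)


def map_fold_position(alignment: Alignment, ref_index: int):
    """Query residue index aligned to a 1-based reference position.

    Returns the 1-based query index, or None when the reference column is
    aligned to a gap.
    """
    return alignment.query_index_for_ref(ref_index)


def _globin_domain_at_nterm(alignment: Alignment) -> bool:
    """True when the reference aligns to the N-terminal half of the query."""
    if not alignment.pairs:
        return False
    qidx = [ia for ia, _ in alignment.pairs]
    return float(np.median(qidx)) <= 0.5 * len(alignment.a)


def classify_globin(
    gene,
    refs=None,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    seed: int = 0,
) -> GlobinCall:
    """Classify one gene (or bare protein sequence) against the panel.

    The best reference is the argmax of the permutation Z score; ties are
    broken by percent identity, then panel order.  A fresh sub-seed per
    reference keeps the call reproducible for a given (gene, seed).
    """
    if refs is None:
        from rhizoglob.synthetic_references import reference_globins

        refs = reference_globins()
    if not refs:
        raise ValueError("empty reference panel")
    if isinstance(gene, GeneModel):
        query, gene_id = gene.protein, gene.gene_id
    else:
        query, gene_id = str(gene), "query"

    zscores = {}
    for k, ref in enumerate(refs):
        zscores[ref.id] = alignment_zscore(
            query,
            ref,
            n_shuffles=thresholds.n_shuffles,
            seed=(seed * 1_000_003 + k) % (2**31),
            params=thresholds.align,
        )
    zbest = max(zscores.values())
    tied = [r for r in refs if zscores[r.id] == zbest]
    if len(tied) > 1:
        tied.sort(
            key=lambda r: -global_align(query, r.sequence, thresholds.align).identity_pct()
        )
    best = tied[0]
    alignment = global_align(query, best.sequence, thresholds.align)

    key_residues = {}
    for role in ROLES:
        qi = map_fold_position(alignment, best.fold_positions[role])
        res = query[qi - 1] if qi is not None else None
        key_residues[role] = (res, qi)

    # architecture refinement: single-domain best match on a long protein
    # with the globin domain at the N-terminus implies a chimeric type
    final_type = best.type
    if (
        best.type == "SDgb"
        and len(query) >= thresholds.t_fhb
        and _globin_domain_at_nterm(alignment)
    ):
        final_type = "fHb"
    elif (
        best.type == "SSDgb"
        and len(query) >= thresholds.t_gcs
        and _globin_domain_at_nterm(alignment)
    ):
        final_type = "GCS"

    f8_res = key_residues["F8"][0]
    f8_exception = False
    f8_ok = f8_res == "H"
    if not f8_ok and thresholds.allow_gcs_glu_f8 and final_type == "GCS" and f8_res == "E":
        f8_ok = True
        f8_exception = True
    flags = {
        "length_ok": len(query) >= thresholds.min_len_aa,
        "z_ok": zbest > thresholds.z_threshold,
        "f8_his_ok": f8_ok,
    }
    thb_class = best.thb_class if final_type.startswith("tHb") else None
    return GlobinCall(
        gene_id=gene_id,
        best_reference=best.id,
        family=FAMILY_OF_TYPE[final_type],
        type=final_type,
        thb_class=thb_class,
        alignment_score=alignment.score,
        z_score=zbest,
        percent_identity=alignment.identity_pct(),
        length_aa=len(query),
        mass_kda=protein_mass_kda(query),
        key_residues=key_residues,
        flags=flags,
        accepted=all(flags.values()),
        f8_exception=f8_exception,
        zscores=zscores,
    )


def with_genome(call: GlobinCall, genome: str) -> GlobinCall:
    return replace(call, genome=genome)


TALLY_TYPES = ("fhb", "sdgb", "gcs", "thb")


def tally_distribution(calls) -> tuple:
    """Copy-number table and per-genome type co-occurrence sets.

    Returns ``(copy_table, cooccurrence)`` where ``copy_table`` is a
    DataFrame indexed by (type, copies) giving the number of genomes with
    exactly that copy count, and ``cooccurrence`` maps each genome to the
    set of globin type keys it contains.  Every call must carry a genome
    label.
    """
    per_genome: dict = {}
    for call in calls:
        if call.genome is None:
            raise ValueError(f"call {call.gene_id} lacks a genome label")
        per_genome.setdefault(call.genome, []).append(call)

    rows = []
    cooccurrence = {}
    for genome, gcalls in sorted(per_genome.items()):
        counts = {t: 0 for t in TALLY_TYPES}
        for call in gcalls:
            key = call.type_key
            counts[key] = counts.get(key, 0) + 1
        cooccurrence[genome] = {t for t, n in counts.items() if n > 0}
        rows.append({"genome": genome, **counts})

    if rows:
        df = pd.DataFrame(rows).set_index("genome")
        records = []
        for t in df.columns:
            observed = df[t][df[t] > 0]
            for copies, n_genomes in observed.value_counts().sort_index().items():
                records.append(
                    {"type": t, "copies": int(copies), "n_genomes": int(n_genomes)}
                )
        copy_table = pd.DataFrame(
            records, columns=["type", "copies", "n_genomes"]
        ).set_index(["type", "copies"])
    else:
        copy_table = pd.DataFrame(
            columns=["type", "copies", "n_genomes"]
        ).set_index(["type", "copies"])
    return copy_table, cooccurrence
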