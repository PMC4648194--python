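"""Synthetic genomes, upstream windows and toy heme pockets with ground truth.

Every downstream stage of the pipeline (ORF detection, classification,
promoter scanning, neighborhood mapping, phenetics, pocket geometry) is
exercised against data produced here, because each planted feature is
recorded in a machine-readable truth table:

* scaffolds of i.i.d. background nucleotides at a chosen GC content
  (default 0.62, typical of rhizobial genomes) carrying planted globin
  ORFs - mutated copies of the reference panel back-translated with a
  fixed codon table - on either strand;
* promoter/Shine-Dalgarno motifs planted at exact offsets within the
  130-nt upstream window, with exact mismatch counts;
* flanking ORFs with product labels at exact edge-to-edge distances
  within +/- 5 kb;
* toy PDB heme pockets realizing requested Fe-probe distances and chi1
  dihedrals.

The background is the simplest null that cannot plausibly contain
spurious long motifs: for a k-mer, the expected number of exact hits in
a window of length L is about L / 4^k (~4e-7 per 130-nt window for the
14-nt Fnr box).  Shorter boxes (-10/-35) do arise by chance, which is
faithful to real scans.  The generator makes no attempt at realistic
codon usage, operon structure or phylogenetically correlated divergence.

Determinism: one ``numpy`` PCG64 generator seeded from the spec consumes
draws in a fixed order, so identical spec + seed gives byte-identical
FASTA/GFF3/truth outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from rhizoglob.align import AA_ALPHABET
from rhizoglob.neighborhood import AnnotatedGene
from rhizoglob.orfs import revcomp, translate
from rhizoglob.promoter import UpstreamWindow, default_motifs
from rhizoglob.synthetic_references import reference_by_id, reference_globins

MAX_PROMOTER_WINDOW = 130
MAX_NEIGHBOR_DISTANCE = 5000

#: fixed back-translation table: one deterministic, high-usage codon per
#: residue under genetic code 11 (invertible by translation)
CODON_OF = {
    "A": "GCG", "R": "CGC", "N": "AAC", "D": "GAT", "C": "TGC",
    "E": "GAA", "Q": "CAG", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}
STOP = "TAA"


def back_translate(protein: str) -> str:
    """Deterministic coding sequence (without stop) for a protein."""
    try:
        return "".join(CODON_OF[res] for res in protein)
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc.args[0]!r}") from None


def mutate_protein(sequence: str, rate: float, seed: int, protected=()) -> str:
    """Substitute each position independently with probability ``rate``.

    ``protected`` lists 1-based positions that are never substituted
    (typically the proximal F8 His, so truth labels stay valid under the
    classifier's His gate).  Replacement residues are drawn uniformly
    from the 19 alternatives.  Reproducible per seed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"substitution rate {rate} outside [0, 1]")
    for pos, res in enumerate(sequence, start=1):
        if res not in AA_ALPHABET:
            raise ValueError(f"non-standard residue {res!r} at position {pos}")
    protected = set(protected)
    rng = np.random.default_rng(seed)
    out = list(sequence)
    hit = rng.random(len(sequence)) < rate
    for i in np.flatnonzero(hit):
        if (i + 1) in protected:
            continue
        alternatives = [c for c in AA_ALPHABET if c != out[i]]
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


# ---------------------------------------------------------------------------
# genome generation


@dataclass(frozen=True)
class GlobinPlanting:
    """One globin gene to plant, with optional promoter/neighbor features.

    ``start`` is the leftmost forward-strand coordinate of the gene
    footprint (1-based).  Promoter plantings are (motif name, offset,
    n_mismatches) with the offset of the motif's 5'-most base in
    [-130, -1] on the coding strand.  Neighbor plantings are
    (product label, signed edge distance <= 5000 nt with positive =
    downstream of the globin, nt length).
    """

    reference_id: str
    substitution_rate: float = 0.0
    scaffold_index: int = 0
    strand: str = "+"
    start: int = 1
    promoter_plantings: tuple = ()
    neighbor_plantings: tuple = ()
    protect_f8: bool = True


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    seed: int
    n_scaffolds: int = 1
    scaffold_length: int = 20_000
    plantings: tuple = ()
    background_gc: float = 0.62


@dataclass
class GenomeBundle:
    """In-memory result of :func:`generate_genome`."""

    scaffolds: dict                  # scaffold id -> nucleotide string
    features: list                   # AnnotatedGene records (globins + neighbors)
    truth: pd.DataFrame              # one row per planted feature
    proteins: dict                   # globin gene id -> planted protein

    def write(self, outdir) -> dict:
        from rhizoglob import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "scaffolds.fna",
            "gff3": outdir / "annotation.gff3",
            "truth": outdir / "truth.tsv",
        }
        io.write_fasta(self.scaffolds, paths["fasta"])
        io.write_gff3(self.features, paths["gff3"])
        io.write_tsv(self.truth, paths["truth"])
        return paths


@lru_cache(maxsize=1)
def _consensus_by_name() -> dict:
    return {name: mot.consensus for name, mot in default_motifs().items()}


def _scaffold_id(index: int) -> str:
    return f"scaffold{index + 1}"


def _coding_to_forward(gene_start: int, gene_end: int, strand: str, offset: int, length: int):
    """Forward-strand (lo, hi) of a coding-strand upstream segment."""
    if strand == "+":
        lo = gene_start + offset
        return lo, lo + length - 1
    hi = gene_end - offset
    return hi - length + 1, hi


class _Occupancy:
    """Hard-interval registry with collision reporting."""

    def __init__(self):
        self._by_scaffold: dict = {}

    def claim(self, scaffold_index: int, lo: int, hi: int, label: str):
        intervals = self._by_scaffold.setdefault(scaffold_index, [])
        for (olo, ohi, olabel) in intervals:
            if lo <= ohi and olo <= hi:
                raise ValueError(
                    f"plantings overlap on scaffold {scaffold_index + 1}: "
                    f"{olabel} ({olo}..{ohi}) vs {label} ({lo}..{hi})"
                )
        intervals.append((lo, hi, label))

    def collides(self, scaffold_index: int, lo: int, hi: int, ignore=()):
        for (olo, ohi, olabel) in self._by_scaffold.get(scaffold_index, []):
            if olabel in ignore:
                continue
            if lo <= ohi and olo <= hi:
                return olabel
        return None


def _mutated_consensus(consensus: str, n_mismatches: int, rng) -> str:
    if not 0 <= n_mismatches < len(consensus):
        raise ValueError(
            f"n_mismatches {n_mismatches} invalid for consensus of length {len(consensus)}"
        )
    out = list(consensus)
    positions = rng.choice(len(consensus), size=n_mismatches, replace=False)
    for p in sorted(int(x) for x in positions):
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def generate_genome(spec: SyntheticGenomeSpec, refs=None) -> GenomeBundle:
    """Emit scaffolds, annotation and a truth table for a planting spec.

    Raises on overlapping plantings (naming the colliding pair), on
    promoter offsets outside the 130-nt window, and on neighbor
    distances beyond 5 kb.
    """
    if refs is None:
        refs = reference_globins()
    ref_by_id = {r.id: r for r in refs}
    if not 0.0 <= spec.background_gc <= 1.0:
        raise ValueError("background_gc outside [0, 1]")

    consensus = _consensus_by_name()
    rng = np.random.default_rng(spec.seed)

    # backgrounds first, in scaffold order, so planting edits are overlays
    p_gc = spec.background_gc / 2.0
    p_at = (1.0 - spec.background_gc) / 2.0
    arrays = []
    for _ in range(spec.n_scaffolds):
        draws = rng.choice(
            np.frombuffer(b"ACGT", dtype=np.uint8),
            size=spec.scaffold_length,
            p=[p_at, p_gc, p_gc, p_at],
        )
        arrays.append(bytearray(draws.tobytes()))

    occupancy = _Occupancy()
    plan = []  # resolved geometry per planting

    for i, planting in enumerate(spec.plantings):
        gene_id = f"glb{i + 1}"
        ref = ref_by_id.get(planting.reference_id)
        if ref is None:
            ref = reference_by_id(planting.reference_id)
        if planting.strand not in "+-":
            raise ValueError(f"{gene_id}: bad strand {planting.strand!r}")
        if not 0 <= planting.scaffold_index < spec.n_scaffolds:
            raise ValueError(f"{gene_id}: scaffold index out of range")

        length_nt = 3 * len(ref.sequence) + 3
        gs, ge = planting.start, planting.start + length_nt - 1
        if gs < 1 or ge > spec.scaffold_length:
            raise ValueError(
                f"{gene_id}: footprint {gs}..{ge} outside scaffold of "
                f"length {spec.scaffold_length}"
            )
        occupancy.claim(planting.scaffold_index, gs, ge, gene_id)

        neighbors = []
        for j, (product, distance, nt_len) in enumerate(planting.neighbor_plantings):
            if distance == 0 or abs(distance) > MAX_NEIGHBOR_DISTANCE:
                raise ValueError(
                    f"{gene_id}: neighbor distance {distance} outside "
                    f"+/-{MAX_NEIGHBOR_DISTANCE} (or zero)"
                )
            n_aa = max(3, round(nt_len / 3) - 1)
            n_len = 3 * n_aa + 3  # coding codons plus stop
            right = (distance > 0) == (planting.strand == "+")
            gap = abs(distance)
            if right:
                nlo = ge + gap + 1
                nhi = nlo + n_len - 1
            else:
                nhi = gs - gap - 1
                nlo = nhi - n_len + 1
            if nlo < 1 or nhi > spec.scaffold_length:
                raise ValueError(f"{gene_id}: neighbor {j + 1} falls off the scaffold")
            nb_id = f"{gene_id}_nb{j + 1}"
            occupancy.claim(planting.scaffold_index, nlo, nhi, nb_id)
            neighbors.append(
                {
                    "id": nb_id,
                    "product": product,
                    "distance": distance,
                    "lo": nlo,
                    "hi": nhi,
                    "n_aa": n_aa,
                }
            )

        motifs = []
        for (name, offset, n_mm) in planting.promoter_plantings:
            if name not in consensus:
                raise ValueError(f"{gene_id}: unknown motif {name!r}")
            m = len(consensus[name])
            if offset < -MAX_PROMOTER_WINDOW or offset + m - 1 > -1:
                raise ValueError(
                    f"{gene_id}: motif {name} at offset {offset} outside "
                    f"the {MAX_PROMOTER_WINDOW}-nt upstream window"
                )
            lo, hi = _coding_to_forward(gs, ge, planting.strand, offset, m)
            if lo < 1 or hi > spec.scaffold_length:
                raise ValueError(f"{gene_id}: motif {name} falls off the scaffold")
            motifs.append({"name": name, "offset": offset, "n_mm": n_mm, "lo": lo, "hi": hi})

        plan.append(
            {
                "gene_id": gene_id,
                "planting": planting,
                "ref": ref,
                "gs": gs,
                "ge": ge,
                "neighbors": neighbors,
                "motifs": motifs,
            }
        )

    # motif segments must not hit any hard feature
    for item in plan:
        for mot in item["motifs"]:
            hit = occupancy.collides(
                item["planting"].scaffold_index, mot["lo"], mot["hi"]
            )
            if hit is not None:
                raise ValueError(
                    f"{item['gene_id']}: motif {mot['name']} "
                    f"({mot['lo']}..{mot['hi']}) overlaps {hit}"
                )

    features = []
    truth_rows = []
    proteins = {}

    for item in plan:
        planting: GlobinPlanting = item["planting"]
        ref = item["ref"]
        gene_id = item["gene_id"]
        arr = arrays[planting.scaffold_index]
        sid = _scaffold_id(planting.scaffold_index)
        gs, ge = item["gs"], item["ge"]

        protected = {ref.fold_positions["F8"]} if planting.protect_f8 else set()
        mut_seed = int(rng.integers(0, 2**31))
        protein = mutate_protein(
            ref.sequence, planting.substitution_rate, mut_seed, protected
        )
        gene_nt = back_translate(protein) + STOP
        payload = gene_nt if planting.strand == "+" else revcomp(gene_nt)
        assert len(payload) == ge - gs + 1
        arr[gs - 1 : ge] = payload.encode()
        proteins[gene_id] = protein

        # in-frame guard stop immediately 5' of the start codon keeps the
        # planted ATG the first start of its ORF segment
        if not any(m["offset"] + len(consensus[m["name"]]) - 1 >= -3 for m in item["motifs"]):
            glo, ghi = _coding_to_forward(gs, ge, planting.strand, -3, 3)
            if glo >= 1 and ghi <= spec.scaffold_length and occupancy.collides(
                planting.scaffold_index, glo, ghi, ignore=(gene_id,)
            ) is None:
                guard = STOP if planting.strand == "+" else revcomp(STOP)
                arr[glo - 1 : ghi] = guard.encode()

        features.append(
            AnnotatedGene(
                gene_id=gene_id,
                scaffold_id=sid,
                start=gs,
                end=ge,
                strand=planting.strand,
                product="globin",
            )
        )
        truth_rows.append(
            {
                "feature": "globin",
                "scaffold": sid,
                "gene_id": gene_id,
                "reference_id": ref.id,
                "family": ref.family,
                "type": ref.type,
                "thb_class": ref.thb_class,
                "start": gs,
                "end": ge,
                "strand": planting.strand,
                "substitution_rate": planting.substitution_rate,
            }
        )

        for nb in item["neighbors"]:
            nb_prot_idx = rng.integers(0, len(AA_ALPHABET), size=nb["n_aa"])
            nb_prot = "M" + "".join(AA_ALPHABET[k] for k in nb_prot_idx)[1:]
            nb_nt = back_translate(nb_prot) + STOP
            payload = nb_nt if planting.strand == "+" else revcomp(nb_nt)
            assert len(payload) == nb["hi"] - nb["lo"] + 1
            arr[nb["lo"] - 1 : nb["hi"]] = payload.encode()
            features.append(
                AnnotatedGene(
                    gene_id=nb["id"],
                    scaffold_id=sid,
                    start=nb["lo"],
                    end=nb["hi"],
                    strand=planting.strand,
                    product=nb["product"],
                )
            )
            truth_rows.append(
                {
                    "feature": "neighbor",
                    "scaffold": sid,
                    "gene_id": nb["id"],
                    "focal_gene": gene_id,
                    "product": nb["product"],
                    "distance": nb["distance"],
                    "start": nb["lo"],
                    "end": nb["hi"],
                    "strand": planting.strand,
                }
            )

        for mot in item["motifs"]:
            cons = consensus[mot["name"]]
            planted = _mutated_consensus(cons, mot["n_mm"], rng)
            payload = planted if planting.strand == "+" else revcomp(planted)
            assert len(payload) == mot["hi"] - mot["lo"] + 1
            arr[mot["lo"] - 1 : mot["hi"]] = payload.encode()
            truth_rows.append(
                {
                    "feature": "motif",
                    "scaffold": sid,
                    "gene_id": gene_id,
                    "motif": mot["name"],
                    "offset_far": mot["offset"],
                    "offset_near": mot["offset"] + len(cons) - 1,
                    "n_mismatches": mot["n_mm"],
                    "planted_sequence": planted,
                }
            )

    scaffolds = {
        _scaffold_id(i): arrays[i].decode() for i in range(spec.n_scaffolds)
    }
    truth = pd.DataFrame(truth_rows)
    return GenomeBundle(
        scaffolds=scaffolds, features=features, truth=truth, proteins=proteins
    )


# ---------------------------------------------------------------------------
# standalone upstream windows (for scanner calibration experiments)


def synthetic_window(seed: int, plantings=(), length: int = MAX_PROMOTER_WINDOW, gene_id: str = "synthetic"):
    """A random upstream window with motifs planted at known offsets.

    ``plantings`` is an iterable of (motif name, offset of the 5'-most
    base, n_mismatches).  Returns (UpstreamWindow, truth rows) where each
    truth row is a dict with near/far offsets and the planted sequence.
    """
    consensus = _consensus_by_name()
    rng = np.random.default_rng(seed)
    arr = bytearray(
        rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length).tobytes()
    )
    truth = []
    for (name, offset, n_mm) in plantings:
        cons = consensus[name]
        m = len(cons)
        if offset < -length or offset + m - 1 > -1:
            raise ValueError(f"motif {name} at offset {offset} outside window")
        planted = _mutated_consensus(cons, n_mm, rng)
        start = length + offset
        arr[start : start + m] = planted.encode()
        truth.append(
            {
                "motif": name,
                "offset_far": offset,
                "offset_near": offset + m - 1,
                "n_mismatches": n_mm,
                "planted_sequence": planted,
            }
        )
    return UpstreamWindow(gene_id=gene_id, sequence=arr.decode()), truth


# ---------------------------------------------------------------------------
# toy heme pockets


_ROLE_BUILD = {
    "proximal": ("HIS", 93, "NE2", (0, 0, -1), (1, 0, 0), (0, 1, 0), 2.1),
    "distal": ("GLN", 64, "NE2", (0, 0, 1), (1, 0, 0), (0, 1, 0), 6.71),
    "B10": ("TYR", 33, "OH", (1, 0, 0), (0, 1, 0), (0, 0, 1), 5.0),
    "CD1": ("PHE", 43, "CZ", (0, 1, 0), (0, 0, 1), (1, 0, 0), 6.0),
}


def _round3(vec):
    return tuple(round(float(x), 3) for x in vec)


def generate_heme_pocket_pdb(distances: dict, dihedrals=None, seed: int = 0) -> str:
    """PDB text for a toy heme pocket with exact planted geometry.

    ``distances`` maps roles (proximal/distal/B10/CD1) to Fe-probe
    distances in Angstrom (> 0); ``dihedrals`` maps roles to chi1 values
    in degrees.  Roles appearing only in ``dihedrals`` get a default
    distance.  The construction is deterministic; ``seed`` is accepted
    for interface uniformity but unused.  Residue geometry is schematic
    (bond lengths of 2 A), not stereochemically realistic: the point is
    exact planted values, to 1e-3 A and better than 0.1 degrees despite
    PDB coordinate rounding.
    """
    from rhizoglob.heme_geometry import Atom, dihedral as measure_dihedral, write_pdb

    dihedrals = dict(dihedrals or {})
    roles = dict(distances)
    for role in dihedrals:
        roles.setdefault(role, _ROLE_BUILD.get(role, (None,) * 6 + (2.1,))[6])
    unknown = set(roles) - set(_ROLE_BUILD)
    if unknown:
        raise ValueError(f"unknown pocket roles: {sorted(unknown)}")
    atoms = []
    serial = 1

    def add(name, resname, resseq, xyz, het=False, element=None):
        nonlocal serial
        x, y, z = _round3(xyz)
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                resname=resname,
                chain="A",
                resseq=resseq,
                x=x,
                y=y,
                z=z,
                element=element or name[0],
                het=het,
            )
        )
        serial += 1

    for role in sorted(roles, key=list(_ROLE_BUILD).index):
        resname, resseq, probe_name, u, v, w, _default = _ROLE_BUILD[role]
        d = float(roles[role])
        if not np.isfinite(d) or d <= 0:
            raise ValueError(f"{role}: distance must be finite and > 0, got {d}")
        d = round(d, 3)
        u, v, w = (np.array(vec, dtype=float) for vec in (u, v, w))
        probe = d * u
        cb = probe + 2.0 * v
        ca = cb + 2.0 * w
        n_at = ca + 2.0 * v
        chi = float(dihedrals.get(role, 180.0))
        # orient CG on the cone about the CA->CB axis; resolve the sign
        # convention empirically so the measured chi1 equals the request
        axis = cb - ca
        e1 = v  # unit component of (N - CA) perpendicular to the axis
        e2 = np.cross(axis / np.linalg.norm(axis), e1)

        def cg_at(theta_deg):
            t = np.radians(theta_deg)
            return cb + 1.8 * (np.cos(t) * e1 + np.sin(t) * e2)

        probe_sign = measure_dihedral(n_at, ca, cb, cg_at(10.0))
        theta = chi if (probe_sign is not None and probe_sign > 0) else -chi
        cg = cg_at(theta)

        add("N", resname, resseq, n_at)
        add("CA", resname, resseq, ca)
        add("CB", resname, resseq, cb)
        add("CG", resname, resseq, cg)
        if probe_name != "CG":
            add(probe_name, resname, resseq, probe)

    add("FE", "HEM", 200, (0.0, 0.0, 0.0), het=True, element="FE")
    for name, xyz in (
        ("NA", (1.414, 1.414, 0.0)),
        ("NB", (-1.414, 1.414, 0.0)),
        ("NC", (-1.414, -1.414, 0.0)),
        ("ND", (1.414, -1.414, 0.0)),
    ):
        add(name, "HEM", 200, xyz, het=True, element="N")
    return write_pdb(atoms)
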