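"""Synthetic reference globin panel.

Classification needs a query panel covering the eight bacterial globin
types: flavohemoglobin (fHb) and single-domain globin (SDgb) from the M
family; globin-coupled sensor (GCS), protoglobin and sensor single-domain
globin (SSDgb) from the S family; and truncated hemoglobin (tHb) classes
1-3 from the T family.  The canonical panel used in the field consists of
database sequences (e.g. the *Vitreoscilla* SDgb or *M. tuberculosis*
tHb class 1).

The references shipped here are SYNTHETIC stand-ins, not the database
sequences: they are generated deterministically from a fixed seed so the
package is self-contained and every downstream test has exact ground
truth.  The panel preserves the properties classification relies on:

* realistic lengths per type (fHb ~400 aa, SDgb ~140 aa, GCS ~510 aa,
  tHb ~125-135 aa), matching the two-domain architecture of fHbs
  (globin + flavin reductase) and GCSs (globin + transmitter);
* a shared 3/3-fold ancestor for the M/S-family globin domains and a
  separate 2/2-fold ancestor for the tHbs, so phenograms segregate the
  two lineages the way real bacterial globins do;
* canonical key residues at myoglobin-fold positions: proximal His at F8
  in every reference, Tyr at B10, Phe at CD1, and type-appropriate
  distal residues at E7 (Gln in fHb/SDgb/GCS, variable in tHbs).

Users re-running the pipeline on real genomes should supply the canonical
panel as a FASTA plus fold-position table; see :func:`load_references`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from rhizoglob.align import AA_ALPHABET

#: module-level seed for the deterministic synthetic panel
_PANEL_SEED = 20150437

FAMILY_OF_TYPE = {
    "fHb": "M",
    "SDgb": "M",
    "GCS": "S",
    "protoglobin": "S",
    "SSDgb": "S",
    "tHb1": "T",
    "tHb2": "T",
    "tHb3": "T",
}

#: the two main phenetic lineages of bacterial globins
LINEAGE_OF_TYPE = {
    "fHb": "fHb/SDgb/GCS",
    "SDgb": "fHb/SDgb/GCS",
    "GCS": "fHb/SDgb/GCS",
    "protoglobin": "fHb/SDgb/GCS",
    "SSDgb": "fHb/SDgb/GCS",
    "tHb1": "tHb",
    "tHb2": "tHb",
    "tHb3": "tHb",
}

ROLES = ("F8", "E7", "B10", "CD1")


@dataclass(frozen=True)
class ReferenceGlobin:
    """One reference query globin.

    ``fold_positions`` maps myoglobin-fold roles (F8 proximal, E7 distal,
    B10, CD1) to 1-based residue indices in ``sequence``.
    """

    id: str
    family: str
    type: str
    sequence: str
    fold_positions: dict = field(hash=False)
    thb_class: int | None = None

    def __post_init__(self):
        assert self.family in "MST"
        assert self.type in FAMILY_OF_TYPE
        f8 = self.fold_positions["F8"]
        if self.sequence[f8 - 1] != "H":
            raise ValueError(f"reference {self.id}: residue at F8 is not H")

    @property
    def lineage(self) -> str:
        return LINEAGE_OF_TYPE[self.type]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AA_ALPHABET), size=length)
    return "".join(AA_ALPHABET[i] for i in idx)


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position with probability ``rate`` (no protection)."""
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        choices = [c for c in AA_ALPHABET if c != out[i]]
        out[i] = choices[rng.integers(0, 19)]
    return "".join(out)


def _set_positions(seq: str, assignments: dict) -> str:
    out = list(seq)
    for idx, res in assignments.items():
        out[idx - 1] = res
    return "".join(out)


# fold positions inside the two domain templates (1-based)
_POS_33 = {"B10": 33, "CD1": 46, "E7": 64, "F8": 88}   # 3/3-fold, 140 aa
_POS_22 = {"B10": 27, "CD1": 39, "E7": 51, "F8": 76}   # 2/2-fold, 124 aa


def _build_panel() -> list:
    rng = np.random.default_rng(_PANEL_SEED)
    anc33 = _random_protein(rng, 140)
    anc22 = _random_protein(rng, 124)

    def globin33(rate: float, e7: str) -> str:
        dom = _diverge(rng, anc33, rate)
        return _set_positions(
            dom,
            {
                _POS_33["F8"]: "H",
                _POS_33["E7"]: e7,
                _POS_33["B10"]: "Y",
                _POS_33["CD1"]: "F",
            },
        )

    def globin22(rate: float, e7: str) -> str:
        dom = _diverge(rng, anc22, rate)
        return _set_positions(
            dom,
            {
                _POS_22["F8"]: "H",
                _POS_22["E7"]: e7,
                _POS_22["B10"]: "Y",
                _POS_22["CD1"]: "F",
            },
        )

    refs = []

    # M family: fHb = globin domain + flavin reductase domain
    fhb_dom = globin33(0.25, "Q")
    flavin = _random_protein(rng, 260)
    refs.append(
        ReferenceGlobin(
            id="ref_fhb",
            family="M",
            type="fHb",
            sequence="M" + fhb_dom[1:] + flavin,
            fold_positions=dict(_POS_33),
        )
    )
    sdgb = globin33(0.25, "Q")
    refs.append(
        ReferenceGlobin(
            id="ref_sdgb",
            family="M",
            type="SDgb",
            sequence="M" + sdgb[1:],
            fold_positions=dict(_POS_33),
        )
    )

    # S family: GCS = globin domain + transmitter domain
    gcs_dom = globin33(0.30, "Q")
    transmitter = _random_protein(rng, 370)
    refs.append(
        ReferenceGlobin(
            id="ref_gcs",
            family="S",
            type="GCS",
            sequence="M" + gcs_dom[1:] + transmitter,
            fold_positions=dict(_POS_33),
        )
    )
    proto_dom = globin33(0.45, "V")
    proto_ext = _random_protein(rng, 55)
    proto_pos = {k: v + 55 for k, v in _POS_33.items()}
    refs.append(
        ReferenceGlobin(
            id="ref_protoglobin",
            family="S",
            type="protoglobin",
            sequence="M" + proto_ext[1:] + proto_dom,
            fold_positions=proto_pos,
        )
    )
    ssdgb = globin33(0.40, "M")
    refs.append(
        ReferenceGlobin(
            id="ref_ssdgb",
            family="S",
            type="SSDgb",
            sequence="M" + ssdgb[1:],
            fold_positions=dict(_POS_33),
        )
    )

    # T family: truncated hemoglobins, classes 1-3
    thb1 = globin22(0.25, "H")
    refs.append(
        ReferenceGlobin(
            id="ref_thb1",
            family="T",
            type="tHb1",
            sequence="M" + thb1[1:],
            fold_positions=dict(_POS_22),
            thb_class=1,
        )
    )
    thb2 = globin22(0.25, "F") + _random_protein(rng, 10)
    refs.append(
        ReferenceGlobin(
            id="ref_thb2",
            family="T",
            type="tHb2",
            sequence="M" + thb2[1:],
            fold_positions=dict(_POS_22),
            thb_class=2,
        )
    )
    thb3 = globin22(0.25, "L") + _random_protein(rng, 6)
    refs.append(
        ReferenceGlobin(
            id="ref_thb3",
            family="T",
            type="tHb3",
            sequence="M" + thb3[1:],
            fold_positions=dict(_POS_22),
            thb_class=3,
        )
    )
    return refs


@lru_cache(maxsize=1)
def reference_globins() -> tuple:
    """The eight-member synthetic reference panel, in canonical order."""
    return tuple(_build_panel())


def reference_by_id(ref_id: str) -> ReferenceGlobin:
    for ref in reference_globins():
        if ref.id == ref_id:
            return ref
    raise KeyError(f"unknown reference globin: {ref_id!r}")


def write_reference_fasta(path) -> None:
    """Write the panel as FASTA plus a sidecar JSON of fold positions."""
    from rhizoglob import io

    refs = reference_globins()
    io.write_fasta({r.id: r.sequence for r in refs}, path)
    meta = {
        r.id: {
            "family": r.family,
            "type": r.type,
            "thb_class": r.thb_class,
            "fold_positions": r.fold_positions,
        }
        for r in refs
    }
    meta_path = str(path) + ".json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def load_references(fasta_path) -> tuple:
    """Load a user-supplied panel from FASTA + ``<fasta>.json`` metadata.

    The JSON sidecar must map each record id to family, type, optional
    thb_class and 1-based fold_positions (F8 mandatory).
    """
    from rhizoglob import io

    seqs = io.read_fasta(fasta_path)
    with open(str(fasta_path) + ".json") as fh:
        meta = json.load(fh)
    refs = []
    for rid, seq in seqs.items():
        m = meta[rid]
        refs.append(
            ReferenceGlobin(
                id=rid,
                family=m["family"],
                type=m["type"],
                sequence=seq,
                fold_positions={k: int(v) for k, v in m["fold_positions"].items()},
                thb_class=m.get("thb_class"),
            )
        )
    return tuple(refs)
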