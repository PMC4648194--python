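"""End-to-end pipeline: identify -> promoters -> neighborhoods -> phenetics.

Orchestrates the library stages over one or more genome FASTA files
(optionally with GFF3 annotation), writes per-stage TSV/JSON/Newick
outputs under one run directory, and aggregates distribution summaries:
a per-(type, copy-number) table and the counts of genomes per region of
the four-set {fhb, sdgb, gcs, thb} Venn diagram.

Determinism contract: identical config + seed produces byte-identical
output files.  Provenance (config hash, package version, seed) is
embedded in the run report; wall-clock timestamps are deliberately kept
out of the report files and go to the run log only.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from rhizoglob import io
from rhizoglob.align import AlignParams
from rhizoglob.identify import (
    ClassifyThresholds,
    classify_globin,
    tally_distribution,
    with_genome,
)
from rhizoglob.neighborhood import flanking_genes, tandem_array_check
from rhizoglob.orfs import GeneModel, extract_orfs, revcomp, translate
from rhizoglob.phenetics import (
    DistanceMatrix,
    lineage_segregation,
    to_newick,
    upgma,
)
from rhizoglob.promoter import (
    MotifDefinition,
    default_motifs,
    promoter_report,
    upstream_region,
)
from rhizoglob.synthetic_references import (
    LINEAGE_OF_TYPE,
    load_references,
    reference_globins,
)

TALLY_TYPES = ("fhb", "sdgb", "gcs", "thb")


@dataclass
class PipelineConfig:
    scaffolds: tuple                 # FASTA paths; file stem = genome label
    gff: str | None = None
    refs_fasta: str | None = None    # user panel; default: packaged synthetic panel
    outdir: str = "rhizoglob_run"
    window: int = 130
    span: int = 5000
    z_threshold: float = 6.0
    min_len_aa: int = 100
    n_shuffles: int = 50
    seed: int = 0
    fnr_max_mismatches: int = 5
    box_max_mismatches: int = 1
    sd_min_match_len: int = 3
    genome_map: dict = field(default_factory=dict)  # file stem -> genome label

    def __post_init__(self):
        if isinstance(self.scaffolds, (str, Path)):
            self.scaffolds = (str(self.scaffolds),)
        else:
            self.scaffolds = tuple(str(p) for p in self.scaffolds)
        for name, value in (
            ("window", self.window),
            ("span", self.span),
            ("z_threshold", self.z_threshold),
            ("min_len_aa", self.min_len_aa),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def motifs(self) -> dict:
        return {
            "-10": MotifDefinition("-10", "TATAAT", "hamming", self.box_max_mismatches),
            "-35": MotifDefinition("-35", "TTGACA", "hamming", self.box_max_mismatches),
            "Fnr": MotifDefinition(
                "Fnr", "TTTAAGAGGCCAAT", "hamming", self.fnr_max_mismatches
            ),
            "SD": MotifDefinition(
                "SD", "AGGAGG", "partial", min_match_len=self.sd_min_match_len
            ),
        }

    def thresholds(self) -> ClassifyThresholds:
        return ClassifyThresholds(
            min_len_aa=self.min_len_aa,
            z_threshold=self.z_threshold,
            n_shuffles=self.n_shuffles,
            align=AlignParams(),
        )


@dataclass
class RunReport:
    calls: pd.DataFrame
    copy_table: pd.DataFrame
    venn: dict
    promoter_table: pd.DataFrame
    neighbors: pd.DataFrame
    tandem_pairs: list
    newick: str | None
    segregation: dict
    provenance: dict


def _gene_models_from_gff(genes, scaffolds_by_id) -> list:
    models = []
    for g in genes:
        scaffold = scaffolds_by_id.get(g.scaffold_id)
        if scaffold is None:
            continue
        nt = scaffold[g.start - 1 : g.end]
        if g.strand == "-":
            nt = revcomp(nt)
        try:
            protein = translate(nt[:-3])
        except ValueError:
            continue  # not a clean CDS; skip
        models.append(
            GeneModel(
                scaffold_id=g.scaffold_id,
                start=g.start,
                end=g.end,
                strand=g.strand,
                protein=protein,
                gene_id=g.gene_id,
            )
        )
    return models


def summarize_venn(cooccurrence: dict) -> dict:
    """Counts of genomes per non-empty region of the 4-set Venn diagram.

    ``cooccurrence`` maps genome -> set of type keys present.  Region
    keys are "+"-joined type names in canonical order; all 15 regions are
    reported, zero-filled.
    """
    regions = {}
    for r in range(1, 5):
        for combo in itertools.combinations(TALLY_TYPES, r):
            regions["+".join(combo)] = 0
    for _genome, present in sorted(cooccurrence.items()):
        core = tuple(t for t in TALLY_TYPES if t in present)
        if core:
            regions["+".join(core)] += 1
    return regions


def _calls_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        f8_res, f8_idx = c.key_residues["F8"]
        rows.append(
            {
                "genome": c.genome,
                "gene_id": c.gene_id,
                "type": c.type,
                "family": c.family,
                "thb_class": c.thb_class,
                "best_reference": c.best_reference,
                "z_score": round(c.z_score, 3),
                "percent_identity": round(c.percent_identity, 1),
                "length_aa": c.length_aa,
                "mass_kda": round(c.mass_kda, 1),
                "F8_residue": f8_res,
                "F8_query_index": f8_idx,
                "length_ok": c.flags["length_ok"],
                "z_ok": c.flags["z_ok"],
                "f8_his_ok": c.flags["f8_his_ok"],
                "f8_exception": c.f8_exception,
                "accepted": c.accepted,
            }
        )
    columns = [
        "genome", "gene_id", "type", "family", "thb_class", "best_reference",
        "z_score", "percent_identity", "length_aa", "mass_kda", "F8_residue",
        "F8_query_index", "length_ok", "z_ok", "f8_his_ok", "f8_exception",
        "accepted",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(config: PipelineConfig, resume: bool = False) -> RunReport:
    """Run all stages and write outputs under ``config.outdir``.

    With ``resume=True`` existing output files are left untouched
    (results are still recomputed in memory, which is cheap at desk
    scale and keeps the logic simple).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.refs_fasta is not None:
        refs = load_references(config.refs_fasta)
    else:
        refs = reference_globins()
    thresholds = config.thresholds()
    motifs = config.motifs()

    annotation = io.read_gff3(config.gff) if config.gff else []

    all_calls = []
    windows = []
    neighbor_rows = []
    tandem_pairs = []
    proteins_of_accepted = {}

    for fasta_path in config.scaffolds:
        stem = Path(fasta_path).stem
        genome = config.genome_map.get(stem, stem)
        scaffolds = io.read_fasta(fasta_path)

        if annotation:
            genes = _gene_models_from_gff(
                [g for g in annotation if g.scaffold_id in scaffolds], scaffolds
            )
            genome_annotation = [g for g in annotation if g.scaffold_id in scaffolds]
        else:
            genes = [
                m
                for sid, seq in scaffolds.items()
                for m in extract_orfs(seq, config.min_len_aa, scaffold_id=sid)
            ]
            from rhizoglob.neighborhood import AnnotatedGene

            genome_annotation = [
                AnnotatedGene(m.gene_id, m.scaffold_id, m.start, m.end, m.strand, "")
                for m in genes
            ]

        accepted_here = []
        for gene in genes:
            call = with_genome(
                classify_globin(gene, refs, thresholds, seed=config.seed), genome
            )
            if call.accepted:
                all_calls.append(call)
                accepted_here.append((gene, call))
                proteins_of_accepted[f"{genome}.{gene.gene_id}"] = gene.protein

        for gene, call in accepted_here:
            windows.append(
                upstream_region(gene, scaffolds[gene.scaffold_id], config.window)
            )
            report = flanking_genes(gene, genome_annotation, span=config.span)
            for side, entries in (("upstream", report.upstream), ("downstream", report.downstream)):
                for g, dist in entries:
                    neighbor_rows.append(
                        {
                            "genome": genome,
                            "focal": gene.gene_id,
                            "neighbor": g.gene_id,
                            "side": side,
                            "distance_nt": dist,
                            "product": g.product,
                            "categories": ";".join(sorted(report.categories[g.gene_id])),
                        }
                    )

        by_scaffold = {}
        for gene, call in accepted_here:
            by_scaffold.setdefault(gene.scaffold_id, []).append((gene, call.type_key))
        for sid, typed in by_scaffold.items():
            annotated_here = [g for g in genome_annotation if g.scaffold_id == sid]
            tandem_pairs.extend(tandem_array_check(typed, annotated_here, config.span))

    calls_df = _calls_frame(all_calls)
    copy_table, cooccurrence = tally_distribution(all_calls) if all_calls else (
        pd.DataFrame(columns=["type", "copies", "n_genomes"]).set_index(["type", "copies"]),
        {},
    )
    venn = summarize_venn(cooccurrence)
    prom_table = promoter_report(windows, motifs)

    newick = None
    segregation = {}
    if len(proteins_of_accepted) >= 2:
        dm = DistanceMatrix.from_sequences(proteins_of_accepted)
        tree = upgma(dm)
        newick = to_newick(tree)
        type_of = {
            f"{c.genome}.{c.gene_id}": LINEAGE_OF_TYPE[c.type] for c in all_calls
        }
        segregation = lineage_segregation(tree, type_of)
        if not resume or not (outdir / "identity_matrix.tsv").exists():
            io.write_tsv(
                pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels),
                outdir / "identity_matrix.tsv",
                index=True,
            )
        if not resume or not (outdir / "tree.nwk").exists():
            (outdir / "tree.nwk").write_text(newick + "\n")

    provenance = {
        "package": "rhizoglob",
        "version": __import__("rhizoglob").__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": {k: v for k, v in asdict(config).items()},
    }

    neighbors_df = pd.DataFrame(
        neighbor_rows,
        columns=["genome", "focal", "neighbor", "side", "distance_nt", "product", "categories"],
    )

    def _write(name, writer):
        path = outdir / name
        if resume and path.exists():
            return
        writer(path)

    _write("calls.tsv", lambda p: io.write_tsv(calls_df, p))
    _write("promoters.tsv", lambda p: io.write_tsv(prom_table, p))
    _write("neighbors.tsv", lambda p: io.write_tsv(neighbors_df, p))
    _write(
        "copy_number.tsv",
        lambda p: io.write_tsv(copy_table.reset_index(), p),
    )
    _write(
        "venn.json",
        lambda p: p.write_text(json.dumps(venn, indent=1, sort_keys=True) + "\n"),
    )
    _write(
        "report.json",
        lambda p: p.write_text(
            json.dumps(
                {
                    "provenance": provenance,
                    "n_genes_called": int(len(calls_df)),
                    "tandem_pairs": tandem_pairs,
                    "segregation": segregation,
                },
                indent=1,
                sort_keys=True,
                default=str,
            )
            + "\n"
        ),
    )
    return RunReport(
        calls=calls_df,
        copy_table=copy_table,
        venn=venn,
        promoter_table=prom_table,
        neighbors=neighbors_df,
        tandem_pairs=tandem_pairs,
        newick=newick,
        segregation=segregation,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# deposited-table label parsing (for re-counting published gene lists)

_GLB_LABEL = re.compile(
    r"^(?P<strain>.+?)(?P<type>fhb|sdgb|gcs|thb)(?P<copy>\d*)$", re.IGNORECASE
)


def parse_glb_label(label: str) -> dict:
    """Parse a globin gene label of the usual published form.

    Labels concatenate the first three binomial letters of genus and
    species, the strain name, the globin type and an optional copy
    number, e.g. ``brajapUSDA38sdgb2`` -> strain ``brajapUSDA38``, type
    ``sdgb``, copy 2.
    """
    m = _GLB_LABEL.match(label.strip())
    if not m:
        raise ValueError(f"unparseable globin label: {label!r}")
    return {
        "strain": m.group("strain"),
        "type": m.group("type").lower(),
        "copy": int(m.group("copy")) if m.group("copy") else 1,
    }


def tally_from_labels(labels) -> tuple:
    """Type totals and per-strain copy counts from a list of gene labels.

    Suitable for re-counting published globin gene tables.  Returns
    (totals dict incl. "total", per-strain DataFrame).
    """
    parsed = [parse_glb_label(l) for l in labels]
    totals = {t: 0 for t in TALLY_TYPES}
    for p in parsed:
        totals[p["type"]] += 1
    totals["total"] = len(parsed)
    df = pd.DataFrame(parsed)
    if df.empty:
        return totals, df
    per_strain = (
        df.groupby(["strain", "type"]).size().rename("copies").reset_index()
    )
    return totals, per_strain
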