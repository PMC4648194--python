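"""File I/O: FASTA, GFF3 and TSV helpers.

Writers are deliberately byte-deterministic (fixed wrapping, fixed
column order, no timestamps) so that identical inputs and seeds yield
identical output files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from rhizoglob.neighborhood import AnnotatedGene

FASTA_WRAP = 60


def read_fasta(path) -> dict:
    """Ordered mapping record id -> upper-case sequence."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: dict, path, wrap: int = FASTA_WRAP) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def write_gff3(features, path) -> None:
    """Write AnnotatedGene records as GFF3 (1-based closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in features:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                "\t".join(
                    [
                        g.scaffold_id,
                        "rhizoglob",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list:
    """Parse GFF3 gene records into AnnotatedGene objects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GFF3 file not found: {path}")
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, _ftype, start, end, _score, strand, _phase, attrs = fields
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k] = v
            genes.append(
                AnnotatedGene(
                    gene_id=attr_map.get("ID", f"gene{lineno}"),
                    scaffold_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    product=attr_map.get("product", ""),
                )
            )
    return genes


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
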