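"""Readers and writers for the pipeline's file formats.

GTF is written 1-based inclusive (standard); everything internal stays
0-based half-open. TSVs are tab-separated UTF-8 with '.' decimal. Read
tables use six columns: chrom, position, strand, sample, read_id,
unaligned_T. Every writer round-trips through its paired reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .models import GeneModel, GenomeAnnotation

READ_COLUMNS = ["chrom", "position", "strand", "sample", "read_id", "unaligned_T"]


# ---------------------------------------------------------------- annotation

def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    lines = []
    for gene in annotation:
        attrs = f'gene_id "{gene.gene_id}";'
        lines.append(
            "\t".join(
                [gene.chrom, "apakit", "gene", str(gene.start + 1), str(gene.end),
                 ".", gene.strand, ".", attrs]
            )
        )
        for s, e in gene.exons:
            lines.append(
                "\t".join(
                    [gene.chrom, "apakit", "exon", str(s + 1), str(e),
                     ".", gene.strand, ".", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path) -> GenomeAnnotation:
    genes: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _, feature, start, end, _, strand, _, attrs = line.split("\t")
        gene_id = attrs.split('gene_id "')[1].split('"')[0]
        rec = genes.setdefault(
            gene_id, {"chrom": chrom, "strand": strand, "exons": []}
        )
        iv = (int(start) - 1, int(end))
        if feature == "gene":
            rec["span"] = iv
        elif feature == "exon":
            rec["exons"].append(iv)
    ann = GenomeAnnotation()
    for gene_id, rec in genes.items():
        exons = tuple(sorted(rec["exons"]))
        span = rec.get("span", (exons[0][0], exons[-1][1]))
        ann.add(
            GeneModel(gene_id, rec["chrom"], rec["strand"], span[0], span[1], exons)
        )
    return ann


# ------------------------------------------------------------------- genome

def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                genome[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


# -------------------------------------------------------------------- reads

def write_reads_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str,
                                            "read_id": str})
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    return df[READ_COLUMNS]


# ----------------------------------------------------------- clusters/counts

def write_clusters_bed(clusters: pd.DataFrame, path: str | Path) -> None:
    """BED6: span as the interval, name = cluster_id, score = total reads."""
    bed = pd.DataFrame(
        {
            "chrom": clusters["chrom"],
            "start": clusters["start"],
            "end": clusters["end"],
            "name": clusters["cluster_id"],
            "score": clusters["n_reads"],
            "strand": clusters["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_clusters_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    return pd.DataFrame(
        {
            "cluster_id": bed["name"],
            "chrom": bed["chrom"],
            "strand": bed["strand"],
            "start": bed["start"],
            "end": bed["end"],
            "n_reads": bed["score"],
        }
    )


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="cluster_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cluster_id")


# -------------------------------------------------------------------- misc

def write_table(df: pd.DataFrame, path: str | Path,
                header_meta: Mapping[str, object] | None = None) -> None:
    """TSV with optional '#key=value' comment header lines."""
    with open(path, "w") as fh:
        if header_meta:
            for key, value in header_meta.items():
                fh.write(f"#{key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set format: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:50]!r}")
        sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def config_hash(config: Mapping[str, object]) -> str:
    payload = json.dumps({k: str(v) for k, v in sorted(config.items())})
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
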