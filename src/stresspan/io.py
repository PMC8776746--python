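"""Readers and writers for the pipeline's tab-delimited inputs and outputs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from stresspan.fst import SNPMatrix
from stresspan.network_traits import build_network
from stresspan.pangenome import PangenomeMatrix


def read_gene_counts(path: str | Path, strains_as_rows: bool = True) -> PangenomeMatrix:
    """Read a gene_presence_absence-style copy-count TSV.

    First column holds strain ids (rows) by default; set
    ``strains_as_rows=False`` for the transposed layout (genes as rows).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not strains_as_rows:
        df = df.T
    return PangenomeMatrix.from_frame(df)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"strain_id", "sample_id", "site_id"}
    if not needed.issubset(df.columns):
        raise ValueError(f"design table must have columns {sorted(needed)}")
    return df


def read_environment(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_edge_list(path: str | Path) -> nx.Graph:
    return build_network(pd.read_csv(path, sep="\t"))


def read_snp_matrix(path: str | Path, design: pd.DataFrame) -> SNPMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_of = dict(zip(design["strain_id"], design["sample_id"]))
    return SNPMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float), sample_of)


def snp_from_alignment(path: str | Path, design: pd.DataFrame) -> SNPMatrix:
    """Extract binary SNPs from a FASTA core-gene alignment.

    Record ids must be strain ids.  Variant columns with exactly two
    unambiguous bases among {A,C,G,T} are kept (major allele coded 0, minor
    1); gaps, N and IUPAC ambiguity codes become missing at that strain.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("alignment sequences have unequal lengths")
    strains = [r.id for r in records]
    arr = np.array([list(str(r.seq).upper()) for r in records])
    geno_cols, loci = [], []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        valid = np.isin(col, list("ACGT"))
        alleles, counts = np.unique(col[valid], return_counts=True)
        if len(alleles) != 2:
            continue  # monomorphic or multi-allelic column: not a biallelic SNP
        major = alleles[np.argmax(counts)]
        g = np.where(valid, (col != major).astype(float), np.nan)
        geno_cols.append(g)
        loci.append(f"pos{j + 1}")
    if not geno_cols:
        raise ValueError("no biallelic variant columns found in the alignment")
    genotypes = np.column_stack(geno_cols)
    sample_of = dict(zip(design["strain_id"], design["sample_id"]))
    return SNPMatrix(strains, loci, genotypes, sample_of)


def read_gene_dnds(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_population_dnds(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genome_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "position", "label", "genome_length"}
    if not needed.issubset(df.columns):
        raise ValueError(f"genome map must have columns {sorted(needed)}")
    return df


def load_dataset(indir: str | Path) -> dict:
    """Load the seven pipeline inputs from a directory of TSVs."""
    indir = Path(indir)
    design = read_design(indir / "design.tsv")
    data = {
        "design": design,
        "raw_env": read_environment(indir / "environment_raw.tsv"),
        "matrix": read_gene_counts(indir / "gene_counts.tsv"),
        "network": read_edge_list(indir / "network_edges.tsv"),
        "gene_dnds": read_gene_dnds(indir / "gene_dnds.tsv"),
        "pop_dnds": read_population_dnds(indir / "population_dnds.tsv"),
        "snp": read_snp_matrix(indir / "snp_matrix.tsv", design),
        "genome_map": read_genome_map(indir / "genome_map.tsv"),
    }
    return data


def write_track(track, path: str | Path) -> None:
    """Write a smoothed track as bedGraph-style TSV with band columns."""
    df = track.to_frame()
    step = np.diff(track.grid).mean()
    out = pd.DataFrame(
        {
            "chrom": "chromosome",
            "start": df["position"].astype(int),
            "end": (df["position"] + step).astype(int),
            "value": df["mean"],
            "lower95": df["lower95"],
            "upper95": df["upper95"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
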