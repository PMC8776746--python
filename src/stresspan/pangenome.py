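"""Strain x gene pangenome matrix: classification, richness and diversity.

The central container is :class:`PangenomeMatrix`, a strain x gene table of
orthologue copy counts with a derived presence view.  Genes are labelled core
(present in >= 99% of strains by default), singleton (present in exactly one
strain) or accessory.  Gene richness (genes per strain) and pangenome
diversity (distinct genes pooled per soil sample) are computed after removing
singletons and ubiquitous genes, which carry no information about variation
between strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CORE = "core"
ACCESSORY = "accessory"
SINGLETON = "singleton"


@dataclass
class PangenomeMatrix:
    """Copy-count matrix over strains (rows) and genes (columns).

    Attributes
    ----------
    strains : list of strain identifiers (row order)
    genes : list of gene identifiers (column order)
    counts : (n_strains, n_genes) non-negative integer array
    labels : optional gene -> {core, accessory, singleton} mapping,
        filled by :func:`classify_genes`
    """

    strains: list[str]
    genes: list[str]
    counts: np.ndarray
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.strains), len(self.genes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.strains)} strains x {len(self.genes)} genes"
            )
        if np.any(self.counts < 0):
            raise ValueError("copy counts must be non-negative")

    @property
    def presence(self) -> np.ndarray:
        """Boolean presence view: count >= 1."""
        return self.counts >= 1

    @property
    def gene_frequency(self) -> np.ndarray:
        """Per-gene fraction of strains carrying the gene."""
        return self.presence.mean(axis=0)

    def subset_genes(self, keep: np.ndarray | list) -> "PangenomeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        genes = [self.genes[i] for i in idx]
        labels = {g: self.labels[g] for g in genes if g in self.labels}
        return PangenomeMatrix(self.strains, genes, self.counts[:, idx], labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.strains, columns=self.genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PangenomeMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())


def classify_genes(matrix: PangenomeMatrix, core_threshold: float = 0.99) -> PangenomeMatrix:
    """Label each gene core / accessory / singleton.

    A gene is *core* when its presence frequency is at least ``core_threshold``
    (99% by default), *singleton* when present in exactly one strain, and
    *accessory* otherwise.  Labels are attached in place and the matrix is
    returned for chaining.
    """
    if len(matrix.genes) == 0 or len(matrix.strains) == 0:
        raise ValueError("cannot classify an empty matrix")
    if len(matrix.strains) < 2:
        raise ValueError("need at least 2 strains to classify genes")
    presence = matrix.presence
    n_present = presence.sum(axis=0)
    freq = n_present / len(matrix.strains)
    labels = {}
    for g, f, n in zip(matrix.genes, freq, n_present):
        if f >= core_threshold:
            labels[g] = CORE
        elif n == 1:
            labels[g] = SINGLETON
        else:
            labels[g] = ACCESSORY
    matrix.labels = labels
    return matrix


def filter_for_richness(
    matrix: PangenomeMatrix, ubiquity_threshold: float = 1.0
) -> PangenomeMatrix:
    """Drop singletons and ubiquitous genes before richness analysis.

    Removes genes present in exactly one strain and genes at presence
    frequency >= ``ubiquity_threshold`` (default 1.0: present in *every*
    strain — intentionally distinct from the 99% core label, so a gene at
    99.5% frequency stays in the analysis; set 0.99 to drop at the core
    label instead).  Both extremes are uninformative about between-strain
    variation.
    """
    n_present = matrix.presence.sum(axis=0)
    n_strains = len(matrix.strains)
    keep = (n_present > 1) & (n_present < ubiquity_threshold * n_strains)
    if not keep.any():
        warnings.warn("all genes are singletons or ubiquitous; filtered matrix is empty")
    return matrix.subset_genes(keep)


def gene_richness(matrix: PangenomeMatrix) -> pd.DataFrame:
    """Per-strain gene richness: number of distinct genes present.

    Returns a DataFrame with columns ``strain_id`` and ``richness``.
    """
    richness = matrix.presence.sum(axis=1).astype(int)
    return pd.DataFrame({"strain_id": matrix.strains, "richness": richness})


def pangenome_diversity(matrix: PangenomeMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Per-soil-sample pangenome diversity: distinct genes pooled over member strains.

    ``design`` maps strains to soil samples via columns ``strain_id`` and
    ``sample_id``.  Diversity is the size of the union of member gene sets,
    not the sum of member richnesses.
    """
    strain_to_sample = dict(zip(design["strain_id"], design["sample_id"]))
    missing = [s for s in matrix.strains if s not in strain_to_sample]
    if missing:
        raise ValueError(f"strains not mapped to a soil sample: {missing[:5]}")
    presence = matrix.presence
    rows = []
    samples = pd.unique(design["sample_id"])
    strain_idx = {s: i for i, s in enumerate(matrix.strains)}
    for sample in samples:
        members = [s for s in matrix.strains if strain_to_sample[s] == sample]
        if not members:
            continue
        idx = [strain_idx[s] for s in members]
        union = presence[idx].any(axis=0).sum()
        rows.append({"sample_id": sample, "diversity": int(union), "n_strains": len(idx)})
    return pd.DataFrame(rows)
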