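"""Nearest-TSS linking of genome partitions to genes, and linked metaclusters.

Every partition is assigned the gene whose TSS is nearest its midpoint
(same chromosome, within a 1 Mb search window); each (region, gene) pair
then falls into the bin indexed by the gene's RNA metacluster and the
region's DNA metacluster.  The full k_rna x k_dna grid of bins — the
linked metaclusters (LMs) — is enumerated, empty bins retained.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from somgrn.partition import GenomicInterval

logger = logging.getLogger(__name__)

MAX_LINK_DISTANCE = 1_000_000


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


class GeneIndex:
    """Per-chromosome TSS arrays for O(log n) nearest-gene queries."""

    def __init__(self, genes: list[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for chrom in {g.chrom for g in genes}:
            # sort by (tss, gene_id) so equal-TSS ties resolve to the
            # lexicographically smaller id
            gs = sorted((g for g in genes if g.chrom == chrom), key=lambda g: (g.tss, g.gene_id))
            self._by_chrom[chrom] = ([g.tss for g in gs], gs)

    def nearest(self, chrom: str, pos: float) -> tuple[GeneModel | None, float]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None, np.inf
        tss_list, gs = entry
        i = bisect.bisect_left(tss_list, pos)
        best: GeneModel | None = None
        best_d = np.inf
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(gs):
                d = abs(gs[j].tss - pos)
                if d < best_d or (d == best_d and best is not None and gs[j].gene_id < best.gene_id):
                    best, best_d = gs[j], d
        return best, best_d


def nearest_gene(
    region: GenomicInterval,
    genes: list[GeneModel] | GeneIndex,
    max_distance: int = MAX_LINK_DISTANCE,
) -> tuple[GeneModel | None, float]:
    """Gene minimizing |region midpoint - TSS| on the region's chromosome.

    Returns (gene, distance), or (None, inf) when no TSS lies within
    ``max_distance`` or the chromosome carries no genes.  Ties at equal
    distance go to the lexicographically smaller gene id.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    gene, dist = index.nearest(region.chrom, region.midpoint)
    if gene is None:
        logger.info("no genes on chromosome %s", region.chrom)
        return None, np.inf
    if dist > max_distance:
        return None, np.inf
    return gene, dist


@dataclass
class LinkedMetaclusterMap:
    """(rna metacluster, dna metacluster) bins of linked (region, gene) pairs."""

    k_rna: int
    k_dna: int
    bins: dict[tuple[int, int], list[tuple[int, str, float]]] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        for r in range(1, self.k_rna + 1):
            for d in range(1, self.k_dna + 1):
                self.bins.setdefault((r, d), [])

    @property
    def n_bins(self) -> int:
        return self.k_rna * self.k_dna

    def total_pairs(self) -> int:
        return sum(len(v) for v in self.bins.values())

    def counts(self) -> pd.DataFrame:
        mat = np.zeros((self.k_rna, self.k_dna), dtype=int)
        for (r, d), pairs in self.bins.items():
            mat[r - 1, d - 1] = len(pairs)
        return pd.DataFrame(mat, index=range(1, self.k_rna + 1), columns=range(1, self.k_dna + 1))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r, d, region, gene, dist)
            for (r, d), pairs in sorted(self.bins.items())
            for region, gene, dist in pairs
        ]
        return pd.DataFrame(rows, columns=["rna_mc", "dna_mc", "region", "gene", "distance"])


def link_soms(
    region_metaclusters: pd.Series,
    gene_metaclusters: pd.Series,
    regions: dict[int, GenomicInterval],
    genes: list[GeneModel],
    k_rna: int | None = None,
    k_dna: int | None = None,
    max_distance: int = MAX_LINK_DISTANCE,
) -> LinkedMetaclusterMap:
    """Build the LM map from region and gene metacluster assignments.

    ``region_metaclusters``: region id -> DNA metacluster label;
    ``gene_metaclusters``: gene id -> RNA metacluster label.
    Pairs whose nearest gene lacks an RNA metacluster are dropped and
    counted in ``n_skipped``.
    """
    k_rna = k_rna or int(gene_metaclusters.max())
    k_dna = k_dna or int(region_metaclusters.max())
    lm = LinkedMetaclusterMap(k_rna=k_rna, k_dna=k_dna)
    index = GeneIndex(genes)
    gene_mc = gene_metaclusters.to_dict()
    for region_id, dna_mc in region_metaclusters.items():
        region = regions[region_id]
        gene, dist = nearest_gene(region, index, max_distance=max_distance)
        if gene is None:
            continue
        rna_mc = gene_mc.get(gene.gene_id)
        if rna_mc is None:
            lm.n_skipped += 1
            continue
        lm.bins[(int(rna_mc), int(dna_mc))].append((region_id, gene.gene_id, dist))
    return lm


def joint_membership(
    spatial_map: pd.Series,
    full_map: pd.Series,
    row_fraction: bool = False,
) -> pd.DataFrame:
    """Count matrix of genes shared by spatial (sR) and full (R) metaclusters.

    Rows are spatial metaclusters, columns full-RNA metaclusters; the
    row-fraction form divides each row by the spatial metacluster's size.
    """
    shared = spatial_map.index.intersection(full_map.index)
    srs = sorted(spatial_map.unique())
    rs = sorted(full_map.unique())
    mat = pd.DataFrame(0, index=srs, columns=rs)
    for g in shared:
        mat.loc[spatial_map[g], full_map[g]] += 1
    if row_fraction:
        sizes = spatial_map.value_counts().reindex(srs).replace(0, 1)
        mat = mat.div(sizes, axis=0)
    return mat


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from a TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]
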