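"""Cross-species harmonization: ortholog intersection, per-individual read
combining, study (BioProject) batch-gene exclusion, outlier-sample removal by
dendrogram height, and clade-specific differential expression.

The harmonization order follows the study design: restrict to features
annotated in every genome, combine technical samples of the same individual,
drop outlier samples that cluster apart (height > 0.8 under 1 - Pearson
distance, complete linkage), then remove genes differentially expressed
between studies (FDR < 0.05) before any biological contrast.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .destats import exact_nb_de
from .matrix import CountMatrix

__all__ = [
    "intersect_orthologs",
    "merge_individuals",
    "filter_batch_genes",
    "detect_outliers",
    "clade_specific_de",
]

logger = logging.getLogger(__name__)

META_COLUMNS = ["sample", "individual", "species", "clade", "bioproject"]


def _check_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    sp_per_ind = meta.groupby("individual")["species"].nunique()
    bad = sp_per_ind[sp_per_ind > 1].index.tolist()
    if bad:
        raise ValueError(f"individuals labeled with multiple species: {bad}")
    return meta


def intersect_orthologs(
    ortholog_map: pd.DataFrame,
    genomes: Sequence[str],
    require_coding: bool = True,
) -> list[str]:
    """Features whose annotation transferred to every genome in ``genomes``,
    optionally restricted to protein-coding features.

    ``ortholog_map`` is long-format with columns feature, genome,
    transferred (yes/no), biotype.
    """
    if not len(genomes):
        raise ValueError("genomes list must be non-empty")
    known = set(ortholog_map["genome"].unique())
    unknown = [g for g in genomes if g not in known]
    if unknown:
        raise ValueError(f"unknown genome names: {unknown}")
    ok = ortholog_map["transferred"].astype(str).str.lower().isin(["yes", "true", "1"])
    sub = ortholog_map[ok & ortholog_map["genome"].isin(genomes)]
    status = sub.groupby("feature")["genome"].apply(set)
    keep = status[status.apply(lambda s: set(genomes) <= s)].index
    if require_coding:
        coding = ortholog_map[ortholog_map["biotype"] == "protein_coding"]["feature"].unique()
        keep = keep.intersection(pd.Index(coding))
    order = list(dict.fromkeys(ortholog_map["feature"]))
    keep_set = set(keep)
    return [f for f in order if f in keep_set]


def merge_individuals(
    matrix: CountMatrix, meta: pd.DataFrame
) -> tuple[CountMatrix, pd.DataFrame]:
    """Sum columns (and library sizes) of samples from the same individual.

    Merged sample ids are the individual ids; a merged individual's
    bioproject is the comma-joined sorted set of contributing BioProjects.
    Total counts are conserved.
    """
    meta = _check_meta(meta)
    absent = [s for s in matrix.samples if s not in set(meta["sample"])]
    if absent:
        raise ValueError(f"samples missing from metadata: {absent}")
    meta = meta.set_index("sample").loc[list(matrix.samples)].reset_index()
    individuals = list(dict.fromkeys(meta["individual"]))
    counts = matrix.counts.T.groupby(meta.set_index("sample")["individual"]).sum().T
    counts = counts[individuals]
    lib = matrix.library_sizes.groupby(meta.set_index("sample")["individual"]).sum()
    lib = lib[individuals]
    merged_meta = (
        meta.groupby("individual", sort=False)
        .agg(
            species=("species", "first"),
            clade=("clade", "first"),
            bioproject=("bioproject", lambda b: ",".join(sorted(set(b)))),
        )
        .loc[individuals]
        .reset_index()
    )
    merged_meta.insert(0, "sample", merged_meta["individual"])
    return CountMatrix(counts, lib, matrix.feature_lengths), merged_meta


def _bioproject_pairs(meta: pd.DataFrame) -> list[tuple[str, str]]:
    projects = sorted(
        {p for cell in meta["bioproject"] for p in str(cell).split(",")}
    )
    return list(itertools.combinations(projects, 2))


def filter_batch_genes(
    matrix: CountMatrix,
    meta: pd.DataFrame,
    fdr_max: float = 0.05,
) -> tuple[set, CountMatrix]:
    """Remove genes differentially expressed between studies.

    For every unordered pair of BioProjects, a DE comparison is run and all
    genes at FDR < ``fdr_max`` (no fold-change threshold) are removed; the
    removed set is the union over pairs.  When the two projects share
    species, the comparison is restricted to samples of the shared species
    (so species differences cannot masquerade as batch effects); otherwise
    whole projects are compared.  Samples merged across several BioProjects
    are excluded from these contrasts.  Pairs with fewer than two usable
    samples on either side are skipped with a warning.
    """
    meta = _check_meta(meta)
    meta = meta.set_index("sample").loc[list(matrix.samples)].reset_index()
    single = ~meta["bioproject"].astype(str).str.contains(",")
    pairs = _bioproject_pairs(meta[single])
    if len(pairs) == 0:
        if meta[single]["bioproject"].nunique() < 2:
            raise ValueError(
                "fewer than 2 usable BioProjects: skip batch filtering for this dataset"
            )
    removed: set = set()
    for pa, pb in pairs:
        sub = meta[single & meta["bioproject"].isin([pa, pb])]
        shared = set(sub[sub["bioproject"] == pa]["species"]) & set(
            sub[sub["bioproject"] == pb]["species"]
        )
        if shared:
            sub = sub[sub["species"].isin(shared)]
        n_a = (sub["bioproject"] == pa).sum()
        n_b = (sub["bioproject"] == pb).sum()
        if n_a < 2 or n_b < 2:
            warnings.warn(
                f"skipping BioProject pair ({pa}, {pb}): "
                f"insufficient samples ({n_a} vs {n_b})"
            )
            continue
        sub_matrix = matrix.subset_samples(sub["sample"])
        table = exact_nb_de(
            sub_matrix,
            sub["bioproject"].to_numpy(),
            pa,
            pb,
            fdr_max=fdr_max,
            lfc_min=0.0,
        )
        hits = set(table.loc[table["fdr"] < fdr_max, "feature"])
        logger.info("batch pair (%s, %s): %d genes flagged", pa, pb, len(hits))
        removed |= hits
    removed &= set(matrix.features)
    reduced = matrix.subset_features([f for f in matrix.features if f not in removed])
    return removed, reduced


def detect_outliers(expression: pd.DataFrame, height_max: float = 0.8) -> set:
    """Flag samples clustering apart from the majority.

    Distance between samples is 1 - Pearson correlation of log2(x + 1)
    profiles; a complete-linkage dendrogram is cut at ``height_max`` and all
    samples outside the largest resulting cluster are flagged.  If several
    clusters tie for largest, nothing is flagged (with a warning).
    """
    if expression.shape[1] < 3:
        raise ValueError("outlier detection needs >= 3 samples")
    x = np.log2(expression.to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    np.clip(dist, 0.0, None, out=dist)
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=height_max, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    if (sizes == sizes.max()).sum() > 1:
        warnings.warn("tie for the largest cluster: no outliers flagged")
        return set()
    majority = sizes.idxmax()
    return {s for s, lab in zip(expression.columns, labels) if lab != majority}


def clade_specific_de(
    matrix: CountMatrix,
    meta: pd.DataFrame,
    clade: str,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Differential expression of one clade against all other samples
    (TMM -> common dispersion -> exact test -> BH -> up/down calls at
    FDR < 0.05 and |log2FC| > 1)."""
    meta = _check_meta(meta)
    meta = meta.set_index("sample").loc[list(matrix.samples)].reset_index()
    in_clade = meta["clade"] == clade
    if in_clade.sum() == 0:
        raise ValueError(f"no samples in clade {clade!r}")
    if (~in_clade).sum() == 0:
        raise ValueError(f"clade {clade!r} covers every sample: no contrast possible")
    groups = np.where(in_clade, clade, "rest")
    return exact_nb_de(matrix, groups, clade, "rest", fdr_max=fdr_max, lfc_min=lfc_min)
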