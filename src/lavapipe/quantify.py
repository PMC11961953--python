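"""Read counting over exons and repeat tracks with the study's filtering
rules, plus TPM/RPM normalisation.

The counting conventions implemented here:

* PCR duplicates are removed at the placement level: one record per
  (sample, chrom, start, end, strand, mate) key.
* Multi-mapped reads are resolved by choosing one candidate placement
  uniformly at random with a fixed seed.
* Gene counts use mate-1 records only; a record overlapping any exon of a
  gene (>= 1 bp) increments that gene by exactly one, however many of its
  exons it touches; a record spanning exons of several genes increments each.
* TE counts are strand-aware: a record counts toward a repeat family only if
  its inferred transcript orientation (mate + alignment strand + library
  strandedness) matches the strand of an overlapping copy.  A record
  overlapping copies of several families goes to the family with the largest
  overlap, ties broken by family name.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .matrix import CountMatrix
from .repeats import RepeatTrack

__all__ = [
    "ALIGNMENT_COLUMNS",
    "read_alignment_tsv",
    "write_alignment_tsv",
    "read_exon_bed",
    "write_exon_bed",
    "dedup_alignments",
    "assign_multimappers",
    "count_genes",
    "count_te",
    "tpm",
    "rpm",
    "exon_union_lengths",
]

logger = logging.getLogger(__name__)

ALIGNMENT_COLUMNS = [
    "read_id",
    "mate",
    "chrom",
    "start",
    "end",
    "strand",
    "n_hits",
    "sample",
    "candidates",
]

Strandedness = Literal["forward", "reverse", "unstranded"]
_DEDUP_KEY = ["sample", "chrom", "start", "end", "strand", "mate"]


def _validate_alignments(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ALIGNMENT_COLUMNS[:-1] if c not in records.columns]
    if missing:
        raise ValueError(f"alignment table missing columns: {missing}")
    if "candidates" not in records.columns:
        records = records.assign(candidates=".")
    if (records["start"] >= records["end"]).any():
        raise ValueError("alignment records must have start < end")
    if not records["mate"].isin([1, 2]).all():
        raise ValueError("mate must be 1 or 2")
    return records


def read_alignment_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"candidates": str}, keep_default_na=False)
    df["mate"] = df["mate"].astype(int)
    df[["start", "end", "n_hits"]] = df[["start", "end", "n_hits"]].astype(int)
    return _validate_alignments(df)


def write_alignment_tsv(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ALIGNMENT_COLUMNS if c in records.columns]
    records[cols].to_csv(path, sep="\t", index=False)


def read_exon_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 exon track; the name column carries the gene id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str, "gene": str},
    )
    return df


def write_exon_bed(exons: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "gene", "score", "strand"]
    out = exons.copy()
    if "score" not in out.columns:
        out["score"] = 0
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def dedup_alignments(records: pd.DataFrame) -> pd.DataFrame:
    """Remove PCR duplicates: keep the first record per placement key
    (sample, chrom, start, end, strand, mate)."""
    records = _validate_alignments(records)
    return records.drop_duplicates(subset=_DEDUP_KEY, keep="first").reset_index(drop=True)


def parse_candidates(token: str) -> list[tuple[str, int, int, str]]:
    """Decode a 'chrom:start-end:strand|...' candidate-placement string."""
    placements = []
    for part in token.split("|"):
        chrom, span, strand = part.rsplit(":", 2)
        s, e = span.split("-")
        placements.append((chrom, int(s), int(e), strand))
    return placements


def format_candidates(placements: Iterable[tuple[str, int, int, str]]) -> str:
    return "|".join(f"{c}:{s}-{e}:{st}" for c, s, e, st in placements)


def assign_multimappers(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Resolve each multi-mapped read to one placement chosen uniformly at
    random (seeded, hence reproducible).  Uniquely mapped records pass through
    unchanged; resolved records get n_hits=1 and lose their candidate list."""
    records = _validate_alignments(records).reset_index(drop=True).copy()
    rng = np.random.default_rng(seed)
    multi = records.index[records["n_hits"] > 1]
    bad = multi[(records.loc[multi, "candidates"].isin([".", ""]))]
    if len(bad):
        raise ValueError(
            f"{len(bad)} records have n_hits>1 but no candidate placements "
            f"(first read_id: {records.loc[bad[0], 'read_id']})"
        )
    for i in multi:
        placements = parse_candidates(records.at[i, "candidates"])
        if len(placements) != records.at[i, "n_hits"]:
            raise ValueError(
                f"read {records.at[i, 'read_id']}: n_hits={records.at[i, 'n_hits']} "
                f"but {len(placements)} candidate placements"
            )
        chrom, start, end, strand = placements[rng.integers(len(placements))]
        records.loc[i, ["chrom", "start", "end", "strand"]] = (chrom, start, end, strand)
    records.loc[multi, "n_hits"] = 1
    records["candidates"] = "."
    records[["start", "end"]] = records[["start", "end"]].astype(int)
    return records


def _exon_trees(exons: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in exons.groupby("chrom"):
        tree = IntervalTree()
        for start, end, gene in zip(sub["start"], sub["end"], sub["gene"]):
            tree.addi(int(start), int(end), gene)
        trees[chrom] = tree
    return trees


def count_genes(records: pd.DataFrame, exons: pd.DataFrame) -> CountMatrix:
    """Count mate-1 records over gene exons (per-gene union semantics).

    A record overlapping exons of k distinct genes increments each of the k
    genes by one.  Deduplication is the caller's responsibility.  Features are
    all genes in the exon track, in first-appearance order; samples are all
    samples in the alignment table, sorted.
    """
    records = _validate_alignments(records)
    genes = list(dict.fromkeys(exons["gene"])) if len(exons) else []
    samples = sorted(records["sample"].unique())
    counts = pd.DataFrame(0, index=pd.Index(genes, name="feature"), columns=samples, dtype=np.int64)
    if not genes:
        warnings.warn("empty exon track: returning a zero gene-count matrix")
        return CountMatrix(counts, records.groupby("sample").size().reindex(samples, fill_value=0))
    trees = _exon_trees(exons)
    mate1 = records[records["mate"] == 1]
    for sample, chrom, start, end in zip(
        mate1["sample"], mate1["chrom"], mate1["start"], mate1["end"]
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hit_genes = {iv.data for iv in tree.overlap(start, end)}
        for g in hit_genes:
            counts.at[g, sample] += 1
    lib = records.groupby("sample").size().reindex(samples, fill_value=0).astype(float)
    return CountMatrix(counts, lib, exon_union_lengths(exons))


def _transcript_strand(mate: int, strand: str, strandedness: Strandedness) -> str:
    """Infer the orientation of the originating transcript for one record.

    'forward' libraries read mate 1 in the transcript's orientation;
    'reverse' (dUTP-type directional kits) read mate 1 opposite to it.
    """
    flip = {"+": "-", "-": "+"}
    if strandedness == "forward":
        return strand if mate == 1 else flip[strand]
    if strandedness == "reverse":
        return flip[strand] if mate == 1 else strand
    raise ValueError(f"unknown strandedness {strandedness!r}")


def count_te(
    records: pd.DataFrame,
    repeats: RepeatTrack,
    library_strandedness: Strandedness = "reverse",
    mates: tuple[int, ...] = (1, 2),
) -> CountMatrix:
    """Sense-orientation read counting over a repeat track, per family.

    A record counts toward a family iff it overlaps (>= 1 bp) a copy of that
    family whose strand equals the record's inferred transcript orientation.
    When copies of several families overlap the record, the family with the
    largest total overlap wins; ties break lexicographically.  Multimappers
    must be resolved beforehand.
    """
    if library_strandedness not in ("forward", "reverse", "unstranded"):
        raise ValueError(f"unknown strandedness {library_strandedness!r}")
    records = _validate_alignments(records)
    if (records["n_hits"] > 1).any():
        raise ValueError("unresolved multimappers: run assign_multimappers first")
    families = repeats.families()
    samples = sorted(records["sample"].unique())
    counts = pd.DataFrame(
        0, index=pd.Index(families, name="feature"), columns=samples, dtype=np.int64
    )
    trees = repeats.interval_trees()
    copies = repeats.copies
    use = records[records["mate"].isin(mates)]
    for sample, mate, chrom, start, end, strand in zip(
        use["sample"], use["mate"], use["chrom"], use["start"], use["end"], use["strand"]
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        if library_strandedness == "unstranded":
            want = None
        else:
            want = _transcript_strand(int(mate), strand, library_strandedness)
        overlap_by_family: dict[str, int] = {}
        for iv in tree.overlap(start, end):
            c = copies[iv.data]
            if want is not None and c.strand != want:
                continue
            ov = min(end, c.end) - max(start, c.start)
            overlap_by_family[c.family] = overlap_by_family.get(c.family, 0) + ov
        if overlap_by_family:
            best = min(overlap_by_family.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            counts.at[best, sample] += 1
    lib = records.groupby("sample").size().reindex(samples, fill_value=0).astype(float)
    return CountMatrix(counts, lib)


def exon_union_lengths(exons: pd.DataFrame) -> pd.Series:
    """Per-gene length as the number of bases in the union of its exons."""
    lengths = {}
    for gene, sub in exons.groupby("gene", sort=False):
        ivs = sorted(zip(sub["start"], sub["end"]))
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        lengths[gene] = total
    return pd.Series(lengths, dtype=float).reindex(list(dict.fromkeys(exons["gene"])))


def tpm(matrix: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million: length-normalised within-sample abundance.

    TPM_ij = (count_ij / length_i) / sum_k(count_kj / length_k) * 1e6.
    Non-degenerate columns sum to 1e6; an all-zero sample stays all-zero
    (with a warning).
    """
    if matrix.feature_lengths is None:
        raise ValueError("feature_lengths required for TPM")
    lengths = matrix.feature_lengths
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)].tolist()
        raise ValueError(f"zero or missing feature lengths for {bad[:5]}")
    rate = matrix.counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        warnings.warn(
            f"samples with zero counts get all-zero TPM: {list(denom.index[zero_cols])}"
        )
        denom = denom.replace(0, np.nan)
    out = rate.div(denom, axis=1) * 1e6
    return out.fillna(0.0)


def rpm(matrix: CountMatrix) -> pd.DataFrame:
    """Reads per million genome-mapped reads: count_ij / library_size_j * 1e6."""
    lib = matrix.library_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"non-positive library sizes for samples {bad}")
    return matrix.counts.div(lib, axis=1) * 1e6
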