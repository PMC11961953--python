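"""Planted-truth simulator for the whole pipeline.

Three generators, all seeded and byte-reproducible:

* :func:`generate_toy_genome` — a toy genome (FASTA-writable), an exon track,
  a background repeat track, and consensus hits for one lineage-specific TE
  family with repStart/repEnd drawn so a configurable fraction passes the
  full-length filter (repStart < 100, repEnd > 1200 on a 1,300 bp consensus).
* :func:`simulate_alignments` — stranded paired-end alignment coordinates
  over those features, with PCR duplicates planted as identical placements
  and multi-mapped reads carrying explicit candidate placements.
* :func:`simulate_count_matrix` — a cross-species gene count matrix with
  species/clade effects, study (BioProject) batch effects, and
  negative-binomial noise (Var = mu + phi mu^2; phi = 0 is Poisson).

Every generator returns a :class:`TruthSet` recording what was planted, so
downstream recovery (full-length selection, dedup, sense counting, batch-gene
removal, clade DE) can be scored exactly.

What is emulated: alignment coordinates, strand structure of a dUTP-type
directional library, duplicate/multimap bookkeeping, and count-level
between-group effects.  What is not: read sequences, base qualities,
sequencing error, spliced alignment, or phylogenetic covariance beyond clade
labels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .matrix import CountMatrix
from .quantify import format_candidates
from .repeats import RepeatCopy, RepeatTrack

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "ToyGenome",
    "ConfigError",
    "SizingError",
    "generate_toy_genome",
    "simulate_alignments",
    "simulate_count_matrix",
    "simulate_ortholog_map",
    "write_fasta",
]


class ConfigError(ValueError):
    pass


class SizingError(ValueError):
    """Genome too small to place the requested features."""


_DEFAULT_CLADES = {
    "hsap": "human",
    "ptro": "great_ape",
    "ggor": "great_ape",
    "hlar": "small_ape",
    "ssyn": "small_ape",
    "mmul": "macaque",
}


@dataclass
class SimulationConfig:
    """Knobs of the simulator.  Defaults describe a small but realistic study:
    six species in four clades, four individuals each, two studies
    (BioProjects), ~20x more unaffected than planted genes, moderate
    biological dispersion (phi=0.1), and ~1e6-read libraries."""

    seed: int = 0
    # toy genome
    genome_length: int = 150_000  # per chromosome
    n_chroms: int = 2
    n_genes: int = 40
    n_te_families: int = 3  # background families in the base track
    n_copies_per_family: int = 20
    consensus_length: int = 1300
    full_length_fraction: float = 0.5  # of target-family copies passing the filter
    target_family: str = "LAVA"
    # alignment simulation
    n_alignment_samples: int = 3
    n_fragments: int = 4000  # paired-end fragments per sample
    dup_rate: float = 0.1
    multimap_rate: float = 0.1
    antisense_fraction: float = 0.3  # of TE fragments transcribed antisense
    strandedness: str = "reverse"
    te_fraction: float = 0.4  # expression mass on TE copies vs genes
    # count-matrix simulation
    clade_map: dict = field(default_factory=lambda: dict(_DEFAULT_CLADES))
    target_clade: str = "small_ape"
    n_individuals_per_species: int = 4
    samples_per_individual: int = 1
    n_bioprojects: int = 2
    n_count_genes: int = 2000  # genes in the cross-species matrix
    n_clade_genes: int = 50
    clade_lfc: float = 2.0
    n_batch_genes: int = 50
    batch_lfc: float = 2.0
    nb_dispersion: float = 0.1
    lib_size_range: tuple = (8e5, 1.2e6)
    ortholog_dropout: float = 0.05
    coding_fraction: float = 0.9

    def validate(self) -> None:
        counts = {
            "genome_length": self.genome_length,
            "n_chroms": self.n_chroms,
            "n_genes": self.n_genes,
            "n_te_families": self.n_te_families,
            "n_copies_per_family": self.n_copies_per_family,
            "consensus_length": self.consensus_length,
            "n_alignment_samples": self.n_alignment_samples,
            "n_fragments": self.n_fragments,
            "n_individuals_per_species": self.n_individuals_per_species,
            "samples_per_individual": self.samples_per_individual,
            "n_bioprojects": self.n_bioprojects,
            "n_count_genes": self.n_count_genes,
            "n_clade_genes": self.n_clade_genes,
            "n_batch_genes": self.n_batch_genes,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        for name, v in (
            ("dup_rate", self.dup_rate),
            ("multimap_rate", self.multimap_rate),
            ("antisense_fraction", self.antisense_fraction),
            ("full_length_fraction", self.full_length_fraction),
            ("ortholog_dropout", self.ortholog_dropout),
            ("coding_fraction", self.coding_fraction),
        ):
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.dup_rate + self.multimap_rate > 1:
            raise ConfigError("dup_rate + multimap_rate must not exceed 1")
        if not (np.isfinite(self.clade_lfc) and np.isfinite(self.batch_lfc)):
            raise ConfigError("clade_lfc and batch_lfc must be finite")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if not self.clade_map:
            raise ConfigError("clade_map must name at least one species")
        if self.n_clade_genes and self.target_clade not in self.clade_map.values():
            raise ConfigError(
                f"target_clade {self.target_clade!r} absent from clade_map"
            )
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ConfigError(f"lib_size_range must satisfy 0 < lo <= hi, got {self.lib_size_range}")
        if self.n_clade_genes + self.n_batch_genes > self.n_count_genes:
            raise ConfigError(
                "n_clade_genes + n_batch_genes exceeds n_count_genes: "
                "planted gene sets must fit in the matrix"
            )
        if self.strandedness not in ("forward", "reverse", "unstranded"):
            raise ConfigError(f"unknown strandedness {self.strandedness!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "lib_size_range" in d:
            d = dict(d)
            d["lib_size_range"] = tuple(d["lib_size_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class TruthSet:
    """Ground truth planted by the simulator.

    ``clade_genes`` is a set of (gene id, 'up'|'down') pairs (direction in
    the target clade relative to the rest); ``batch_genes`` is disjoint from
    the clade genes by construction.  ``duplicate_groups`` maps each read id
    belonging to a planted duplicate group to its group id;
    ``multimap_groups`` maps multi-mapped read ids to their candidate count.
    ``sense_te_reads`` / ``gene_fragments`` record the exact post-dedup
    counting expectation per (sample, family) / (sample, gene) over the
    non-multimapped fragments: distinct fragments never share a placement
    key (the generator resamples colliding coordinates), so deduplication
    removes planted duplicate copies and nothing else.
    """

    clade_genes: set = field(default_factory=set)
    batch_genes: set = field(default_factory=set)
    te_copies: list = field(default_factory=list)
    full_length_copies: set = field(default_factory=set)  # (chrom, start, end) keys
    duplicate_groups: dict = field(default_factory=dict)
    multimap_groups: dict = field(default_factory=dict)
    sense_te_reads: dict = field(default_factory=dict)
    gene_fragments: dict = field(default_factory=dict)

    def validate(self) -> None:
        clade_ids = {g for g, _ in self.clade_genes}
        if clade_ids & self.batch_genes:
            raise ValueError("planted clade and batch gene sets overlap")


class ToyGenome(NamedTuple):
    genome: dict  # chrom -> sequence string
    exons: pd.DataFrame  # BED6-shaped: chrom, start, end, gene, score, strand
    base_track: RepeatTrack
    consensus_hits: RepeatTrack
    truth: TruthSet


def write_fasta(genome: dict, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Place genes (1-3 exons each), background repeat copies, and target-
    family TE copies non-overlapping along a toy genome.

    Exactly ``round(full_length_fraction * n_copies_per_family)`` of the
    target-family copies are given consensus coordinates passing the
    full-length filter (repStart < 100 and repEnd > 1200); the rest fail it.
    Raises :class:`SizingError` when the genome cannot hold the features.
    """
    config.validate()
    rng = _rng(config, 0)

    features: list[dict] = []
    for i in range(config.n_genes):
        n_exons = int(rng.integers(1, 4))
        exon_lens = rng.integers(200, 401, n_exons)
        intron_lens = rng.integers(100, 301, max(n_exons - 1, 0))
        features.append(
            {
                "kind": "gene",
                "name": f"g{i:04d}",
                "exon_lens": exon_lens,
                "intron_lens": intron_lens,
                "length": int(exon_lens.sum() + intron_lens.sum()),
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    n_target = config.n_copies_per_family
    n_pass = int(round(config.full_length_fraction * n_target))
    cl = config.consensus_length
    for i in range(n_target):
        if i < n_pass:
            rep_start = int(rng.integers(1, 100))
            rep_end = int(rng.integers(min(1201, cl), cl + 1))
        else:
            # violate at least one criterion
            mode = rng.integers(3)
            if mode == 0:
                rep_start = int(rng.integers(100, 500))
                rep_end = int(rng.integers(min(1201, cl), cl + 1))
            elif mode == 1:
                rep_start = int(rng.integers(1, 100))
                rep_end = int(rng.integers(600, 1201))
            else:
                rep_start = int(rng.integers(100, 500))
                rep_end = int(rng.integers(600, 1201))
        features.append(
            {
                "kind": "target_te",
                "name": config.target_family,
                "rep_start": rep_start,
                "rep_end": rep_end,
                "length": rep_end - rep_start + 1,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    for fam in range(config.n_te_families):
        for _ in range(config.n_copies_per_family):
            length = int(rng.integers(150, 801))
            features.append(
                {
                    "kind": "background_te",
                    "name": f"TEfam{fam + 1}",
                    "rep_start": 1,
                    "rep_end": length,
                    "length": length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )

    order = rng.permutation(len(features))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    cursors = {c: 0 for c in chrom_names}
    exon_rows: list[tuple] = []
    base_copies: list[RepeatCopy] = []
    target_copies: list[RepeatCopy] = []
    truth = TruthSet()
    chrom_idx = 0
    for fi in order:
        f = features[fi]
        gap = int(rng.integers(100, 301))
        placed = False
        for _ in range(config.n_chroms):
            chrom = chrom_names[chrom_idx % config.n_chroms]
            start = cursors[chrom] + gap
            if start + f["length"] <= config.genome_length:
                placed = True
                break
            chrom_idx += 1
        if not placed:
            raise SizingError(
                f"genome_length={config.genome_length} x {config.n_chroms} chroms "
                f"cannot hold the requested features (stuck at {f['name']})"
            )
        cursors[chrom] = start + f["length"]
        chrom_idx += 1
        if f["kind"] == "gene":
            pos = start
            for k, elen in enumerate(f["exon_lens"]):
                exon_rows.append((chrom, pos, pos + int(elen), f["name"], 0, f["strand"]))
                pos += int(elen)
                if k < len(f["intron_lens"]):
                    pos += int(f["intron_lens"][k])
        else:
            copy = RepeatCopy(
                chrom=chrom,
                start=start,
                end=start + f["length"],
                strand=f["strand"],
                family=f["name"],
                class_family=(
                    "Retroposon/LAVA" if f["kind"] == "target_te" else "Unknown/Toy"
                ),
                rep_start=f["rep_start"],
                rep_end=f["rep_end"],
                rep_left=max(cl - f["rep_end"], 0) if f["kind"] == "target_te" else 0,
                score=float(rng.integers(200, 3000)),
                divergence=float(np.round(rng.uniform(0.5, 25.0), 1)),
            )
            if f["kind"] == "target_te":
                target_copies.append(copy)
                truth.te_copies.append(copy)
                if copy.rep_start < 100 and copy.rep_end > 1200:
                    truth.full_length_copies.add((copy.chrom, copy.start, copy.end))
            else:
                base_copies.append(copy)

    genome = {
        c: "".join(rng.choice(list("ACGT"), config.genome_length))
        for c in chrom_names
    }
    exons = pd.DataFrame(
        exon_rows, columns=["chrom", "start", "end", "gene", "score", "strand"]
    )
    return ToyGenome(genome, exons, RepeatTrack(base_copies), RepeatTrack(target_copies), truth)


def _gene_spans(exons: pd.DataFrame) -> list[dict]:
    spans = []
    for gene, sub in exons.groupby("gene", sort=False):
        spans.append(
            {
                "name": gene,
                "chrom": sub["chrom"].iloc[0],
                "strand": sub["strand"].iloc[0],
                "exons": list(zip(sub["start"], sub["end"])),
            }
        )
    return spans


def simulate_alignments(
    annotation: ToyGenome, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate stranded paired-end alignment records over genes and
    target-family TE copies.

    Fragments are allocated to features proportionally to per-feature
    log-normal intensities.  With probability ``dup_rate`` a fragment is
    planted as a PCR duplicate (an identical-placement copy of both mates);
    with probability ``multimap_rate`` its records become multi-mapped with
    2-4 candidate placements (the true one plus random decoys).  TE fragments
    are transcribed antisense to their copy with probability
    ``antisense_fraction``; gene fragments are always sense.  Strand layout
    follows ``config.strandedness`` ('reverse' = dUTP-type kit: mate 1 aligns
    opposite to the transcript).
    """
    config.validate()
    rng = _rng(config, 1)
    exons, te_track = annotation.exons, annotation.consensus_hits
    truth = TruthSet(
        te_copies=list(annotation.truth.te_copies),
        full_length_copies=set(annotation.truth.full_length_copies),
    )

    feats: list[dict] = []
    for g in _gene_spans(exons):
        feats.append({**g, "kind": "gene"})
    for c in te_track:
        feats.append(
            {
                "name": c.family,
                "chrom": c.chrom,
                "strand": c.strand,
                "exons": [(c.start, c.end)],
                "kind": "te",
            }
        )
    if not feats:
        raise ConfigError("no features to simulate reads from")
    chrom_names = list(annotation.genome)
    glen = {c: len(annotation.genome[c]) for c in chrom_names}

    intensities = rng.lognormal(0.0, 1.0, len(feats))
    is_te = np.array([f["kind"] == "te" for f in feats])
    if is_te.any() and (~is_te).any():
        w = intensities.copy()
        w[is_te] *= config.te_fraction / max(w[is_te].sum(), 1e-300)
        w[~is_te] *= (1 - config.te_fraction) / max(w[~is_te].sum(), 1e-300)
        intensities = w
    probs = intensities / intensities.sum()
    # distinct fragment-start capacity per feature; allocations are capped at
    # half of it so every unique fragment can receive a unique placement key
    caps = np.array(
        [
            max(int(0.5 * sum(max(ee - es - 119, 1) for es, ee in f["exons"])), 1)
            for f in feats
        ]
    )

    flip = {"+": "-", "-": "+"}
    sense_counter: Counter = Counter()
    gene_counter: Counter = Counter()
    rows: list[tuple] = []
    for s in range(config.n_alignment_samples):
        sample = f"S{s + 1}"
        alloc = np.minimum(rng.multinomial(config.n_fragments, probs), caps)
        frag_idx = 0
        seen: set = set()  # only *planted* duplicates share a placement key
        for fi, n_frags in enumerate(alloc):
            f = feats[fi]
            for _ in range(n_frags):
                for _attempt in range(200):
                    es, ee = f["exons"][rng.integers(len(f["exons"]))]
                    iv_len = ee - es
                    flen = int(rng.integers(120, min(301, iv_len + 1)))
                    fs = int(rng.integers(es, ee - flen + 1))
                    rl = min(100, flen)
                    sigma = f["strand"]
                    if f["kind"] == "te" and rng.random() < config.antisense_fraction:
                        sigma = flip[sigma]
                        sense = False
                    else:
                        sense = True
                    if config.strandedness == "reverse":
                        s1, s2 = flip[sigma], sigma
                    elif config.strandedness == "forward":
                        s1, s2 = sigma, flip[sigma]
                    else:
                        s1, s2 = "+", "-"
                    keys = (
                        (f["chrom"], fs, fs + rl, s1, 1),
                        (f["chrom"], fs + flen - rl, fs + flen, s2, 2),
                    )
                    if not (keys[0] in seen or keys[1] in seen):
                        break
                seen.update(keys)
                read_id = f"{sample}.f{frag_idx:06d}"
                frag_idx += 1
                mates = [
                    (read_id, 1, f["chrom"], fs, fs + rl, s1),
                    (read_id, 2, f["chrom"], fs + flen - rl, fs + flen, s2),
                ]
                u = rng.random()
                is_dup = u < config.dup_rate
                is_multi = (not is_dup) and u < config.dup_rate + config.multimap_rate
                if is_multi:
                    k = int(rng.integers(2, 5))
                    truth.multimap_groups[read_id] = k
                    for rid, mate, chrom, a, b, st in mates:
                        cands = [(chrom, a, b, st)]
                        for _ in range(k - 1):
                            dc = chrom_names[rng.integers(len(chrom_names))]
                            da = int(rng.integers(0, glen[dc] - (b - a)))
                            cands.append(
                                (dc, da, da + (b - a), "+" if rng.random() < 0.5 else "-")
                            )
                        perm = rng.permutation(k)
                        cands = [cands[i] for i in perm]
                        rows.append(
                            (rid, mate, chrom, a, b, st, k, sample, format_candidates(cands))
                        )
                    continue
                for rec in mates:
                    rows.append((*rec, 1, sample, "."))
                if is_dup:
                    truth.duplicate_groups[read_id] = read_id
                    dup_id = f"{read_id}.dup1"
                    truth.duplicate_groups[dup_id] = read_id
                    for rid, mate, chrom, a, b, st in mates:
                        rows.append((dup_id, mate, chrom, a, b, st, 1, sample, "."))
                # post-dedup expectations (unique placements only)
                if f["kind"] == "te" and sense:
                    sense_counter[(sample, f["name"])] += 2  # both mates count
                elif f["kind"] == "gene":
                    gene_counter[(sample, f["name"])] += 1  # mate 1 only

    records = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "mate",
            "chrom",
            "start",
            "end",
            "strand",
            "n_hits",
            "sample",
            "candidates",
        ],
    )
    truth.sense_te_reads = dict(sense_counter)
    truth.gene_fragments = dict(gene_counter)
    truth.validate()
    return records, truth


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for sp, clade in config.clade_map.items():
        for i in range(config.n_individuals_per_species):
            individual = f"{sp}_i{i + 1}"
            bioproject = f"B{i % config.n_bioprojects + 1}"
            for r in range(config.samples_per_individual):
                rows.append(
                    {
                        "sample": f"{individual}_r{r + 1}",
                        "individual": individual,
                        "species": sp,
                        "clade": clade,
                        "bioproject": bioproject,
                    }
                )
    return pd.DataFrame(rows)


def simulate_count_matrix(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, TruthSet]:
    """Simulate the cross-species gene count matrix with planted effects.

    Per-gene baselines are log-normal (meanlog 4, sdlog 1).  The expected
    count is baseline x library factor, times 2^(+-clade_lfc) for planted
    clade genes in target-clade samples and 2^(batch_lfc) for planted batch
    genes in samples of the first BioProject.  Counts are negative binomial
    with dispersion ``nb_dispersion`` (Poisson at 0).  Clade and batch gene
    sets are disjoint.  Individuals are assigned to BioProjects round-robin
    within species, so every BioProject carries every clade.
    """
    config.validate()
    rng = _rng(config, 2)
    meta = _sample_sheet(config)
    clade_sizes = meta.groupby("clade")["sample"].size()
    if config.n_clade_genes and (clade_sizes < 2).any():
        raise ConfigError("every clade needs >= 2 samples when clade genes are planted")

    genes = [f"g{i:05d}" for i in range(config.n_count_genes)]
    baseline = rng.lognormal(4.0, 1.0, config.n_count_genes)

    planted = rng.choice(
        config.n_count_genes, config.n_clade_genes + config.n_batch_genes, replace=False
    )
    clade_idx = planted[: config.n_clade_genes]
    batch_idx = planted[config.n_clade_genes :]
    directions = np.where(np.arange(len(clade_idx)) % 2 == 0, 1.0, -1.0)

    truth = TruthSet(
        clade_genes={
            (genes[g], "up" if d > 0 else "down") for g, d in zip(clade_idx, directions)
        },
        batch_genes={genes[g] for g in batch_idx},
    )
    truth.validate()

    lo, hi = config.lib_size_range
    lib = rng.uniform(lo, hi, len(meta))
    factor = lib / ((lo + hi) / 2)

    in_target = (meta["clade"] == config.target_clade).to_numpy()
    in_batch = (meta["bioproject"] == "B1").to_numpy()

    log2mu = np.log2(baseline)[:, None] + np.log2(factor)[None, :]
    for g, d in zip(clade_idx, directions):
        log2mu[g, in_target] += d * config.clade_lfc
    for g in batch_idx:
        log2mu[g, in_batch] += config.batch_lfc
    mu = 2.0 ** log2mu

    phi = config.nb_dispersion
    if phi > 0:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    cm = CountMatrix(
        pd.DataFrame(
            counts, index=pd.Index(genes, name="feature"), columns=meta["sample"].tolist()
        )
    )
    return cm, meta, truth


def simulate_ortholog_map(
    config: SimulationConfig, genes: list[str], truth: TruthSet | None = None
) -> pd.DataFrame:
    """Long-format ortholog transfer table (feature, genome, transferred,
    biotype), one genome per species.  A random ``ortholog_dropout`` fraction
    of unplanted genes fails transfer to one genome; planted genes always
    transfer everywhere and are protein-coding, so harmonization keeps them."""
    config.validate()
    rng = _rng(config, 3)
    genomes = list(config.clade_map)
    protected = set()
    if truth is not None:
        protected = {g for g, _ in truth.clade_genes} | set(truth.batch_genes)
    droppable = [g for g in genes if g not in protected]
    n_drop = int(round(config.ortholog_dropout * len(droppable)))
    dropped = {droppable[i] for i in rng.choice(len(droppable), n_drop, replace=False)}
    rows = []
    for gene in genes:
        coding = gene in protected or rng.random() < config.coding_fraction
        lost = genomes[rng.integers(len(genomes))] if gene in dropped else None
        for genome in genomes:
            rows.append(
                {
                    "feature": gene,
                    "genome": genome,
                    "transferred": "no" if genome == lost else "yes",
                    "biotype": "protein_coding" if coding else "lncRNA",
                }
            )
    return pd.DataFrame(rows)
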