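"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates a multi-study compendium of sorted brain / immune cell
populations: each cell class has a log-scale expression profile with a
disjoint set of elevated marker genes, each study multiplies every gene by
its own log-normal distortion factor (a per-study "batch"), counts are
negative-binomial at a sampled library size, and class sizes default to the
imbalanced pattern typical of pooled public cohorts.  Mixture samples average
pure profiles on the linear scale (an ambiguous, heterogeneous sample);
single-cell mode adds Bernoulli dropout.  A separate generator produces toy
two-reference read sets with a shared rRNA-like segment for read-origin QC.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse

from .expr_io import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "CellTypeProfile",
    "MixtureSpec",
    "make_profiles",
    "simulate_bulk",
    "simulate_mixture",
    "simulate_single_cell",
    "simulate_reads",
    "make_read_origin_refs",
    "write_fasta",
    "write_fastq",
    "read_fasta",
]

DEFAULT_CLASSES = ("astrocyte", "microglia", "neuron", "endothelial", "monocyte")
# Imbalance mirroring pooled public cohorts of sorted brain cells
# (astro 32, microglia 140, neuron 46, endothelial 27, monocyte 13 -> 258).
DEFAULT_CLASS_SIZES = (32, 140, 46, 27, 13)


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-study bulk RNA-seq compendium.

    ``marker_effect`` is the marker elevation in natural-log units (2.0 is a
    ~7.4-fold change); ``batch_sigma`` is the SD of the per-(study, gene)
    log-normal distortion; ``dispersion`` is the negative-binomial size
    parameter (smaller = noisier); ``dropout`` only applies in single-cell
    mode.
    """

    seed: int
    n_classes: int = 5
    class_labels: tuple[str, ...] | None = None
    n_genes: int = 600
    n_markers_per_class: int = 20
    marker_effect: float = 2.0
    n_samples_per_class: tuple[int, ...] | None = None
    n_studies: int = 5
    batch_sigma: float = 0.5
    library_size: tuple[int, int] = (500_000, 1_500_000)
    dispersion: float = 10.0
    dropout: float = 0.0
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    marker_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_genes < 1:
            raise ValueError("n_classes and n_genes must be positive")
        if self.class_labels is None:
            if self.n_classes <= len(DEFAULT_CLASSES):
                self.class_labels = DEFAULT_CLASSES[: self.n_classes]
            else:
                self.class_labels = tuple(
                    f"class_{i}" for i in range(self.n_classes)
                )
        if len(self.class_labels) != self.n_classes:
            raise ValueError("class_labels length must equal n_classes")
        if self.n_samples_per_class is None:
            if self.n_classes <= len(DEFAULT_CLASS_SIZES):
                self.n_samples_per_class = DEFAULT_CLASS_SIZES[: self.n_classes]
            else:
                self.n_samples_per_class = tuple([30] * self.n_classes)
        if len(self.n_samples_per_class) != self.n_classes:
            raise ValueError("n_samples_per_class length must equal n_classes")
        if any(n < 1 for n in self.n_samples_per_class):
            raise ValueError("every class needs at least one sample")
        if not self.marker_overlap and (
            self.n_markers_per_class * self.n_classes > self.n_genes
        ):
            raise ValueError("too many disjoint markers for n_genes")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.dispersion <= 0 or self.batch_sigma < 0:
            raise ValueError("dispersion must be > 0 and batch_sigma >= 0")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclasses.dataclass
class CellTypeProfile:
    """Per-class log-scale mean expression with its marker gene set."""

    class_label: str
    log_mean: np.ndarray  # per gene, natural log of relative expression
    marker_genes: list[str]


@dataclasses.dataclass
class MixtureSpec:
    """Component class labels with non-negative weights summing to 1."""

    components: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights):
            raise ValueError("components and weights must align")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(self.weights)}")


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-stage generators from one seed (counter-based spawn)."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def make_profiles(config: SimulationConfig) -> dict[str, CellTypeProfile]:
    """Build the per-class log-mean profiles (deterministic in config.seed)."""
    rng = _rng_streams(config.seed, 4)[0]
    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    genes = config.gene_ids
    profiles: dict[str, CellTypeProfile] = {}
    if config.marker_overlap:
        marker_idx = [
            rng.choice(config.n_genes, config.n_markers_per_class, replace=False)
            for _ in range(config.n_classes)
        ]
    else:
        perm = rng.permutation(config.n_genes)
        marker_idx = [
            perm[i * config.n_markers_per_class : (i + 1) * config.n_markers_per_class]
            for i in range(config.n_classes)
        ]
    for label, idx in zip(config.class_labels, marker_idx):
        lm = base.copy()
        lm[idx] += config.marker_effect
        profiles[label] = CellTypeProfile(
            class_label=label,
            log_mean=lm,
            marker_genes=[genes[i] for i in sorted(idx)],
        )
    return profiles


def _study_distortions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-(study, gene) multiplicative log-normal batch factors."""
    return np.exp(
        rng.normal(0.0, config.batch_sigma, size=(config.n_studies, config.n_genes))
    )


def _draw_counts(
    mean_linear: np.ndarray,
    library_size: int,
    dispersion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial counts with expectation library_size * p(mean)."""
    p = mean_linear / mean_linear.sum()
    mu = library_size * p
    r = dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate_bulk(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict[str, CellTypeProfile]]:
    """Simulate the multi-study bulk compendium.

    Returns the counts matrix, the sample annotation (sample_id, class_label,
    study_id) and the true class profiles.
    """
    profiles = make_profiles(config)
    _, rng_batch, rng_counts, _ = _rng_streams(config.seed, 4)
    distort = _study_distortions(config, rng_batch)
    cols: dict[str, np.ndarray] = {}
    records = []
    for ci, (label, n_c) in enumerate(
        zip(config.class_labels, config.n_samples_per_class)
    ):
        lm = profiles[label].log_mean
        for j in range(n_c):
            study = (j + ci) % config.n_studies  # classes span studies
            mean = np.exp(lm) * distort[study]
            lib = int(rng_counts.integers(*config.library_size))
            sid = f"{label}_s{study}_{j:03d}"
            cols[sid] = _draw_counts(mean, lib, config.dispersion, rng_counts)
            records.append((sid, label, f"study{study}"))
    df = pd.DataFrame(cols, index=config.gene_ids)
    ann = pd.DataFrame(records, columns=["sample_id", "class_label", "study_id"])
    return ExpressionMatrix(df, unit="counts"), ann, profiles


def simulate_mixture(
    profiles: Mapping[str, CellTypeProfile],
    spec: MixtureSpec,
    n_samples: int,
    seed: int,
    config: SimulationConfig | None = None,
) -> ExpressionMatrix:
    """Samples drawn from the weight-averaged (linear-scale) mean profile.

    Emulates heterogeneous samples that blend two or more identities — the
    regime in which a classifier should spread its scores across the
    component classes rather than commit to one.
    """
    unknown = [c for c in spec.components if c not in profiles]
    if unknown:
        raise KeyError(f"unknown class labels in mixture: {unknown}")
    any_profile = next(iter(profiles.values()))
    n_genes = any_profile.log_mean.shape[0]
    lib_range = config.library_size if config else (500_000, 1_500_000)
    dispersion = config.dispersion if config else 10.0
    genes = (
        config.gene_ids if config else [f"G{i:04d}" for i in range(n_genes)]
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mean = np.zeros(n_genes)
    for label, w in zip(spec.components, spec.weights):
        mean += w * np.exp(profiles[label].log_mean)
    cols = {}
    tag = "+".join(spec.components)
    for j in range(n_samples):
        lib = int(rng.integers(*lib_range))
        cols[f"mix_{tag}_{j:03d}"] = _draw_counts(mean, lib, dispersion, rng)
    return ExpressionMatrix(pd.DataFrame(cols, index=genes), unit="counts")


def simulate_single_cell(
    config: SimulationConfig,
    n_cells_per_class: int = 50,
    cell_library_size: tuple[int, int] = (5_000, 20_000),
    profiles: Mapping[str, CellTypeProfile] | None = None,
) -> tuple[scipy.sparse.csr_matrix, pd.DataFrame, list[str]]:
    """Simulate sparse per-cell counts with Bernoulli dropout.

    Returns (genes x cells sparse counts, cell annotation with columns
    cell_id / sample_id / cell_type_label, gene ids).  Cells are spread over
    ``n_studies`` pseudo-donors.
    """
    if profiles is None:
        profiles = make_profiles(config)
    rng = _rng_streams(config.seed, 4)[3]
    genes = config.gene_ids
    blocks = []
    records = []
    for label in config.class_labels:
        lm = profiles[label].log_mean
        mean = np.exp(lm)
        for j in range(n_cells_per_class):
            lib = int(rng.integers(*cell_library_size))
            counts = _draw_counts(mean, lib, config.dispersion, rng)
            if config.dropout > 0:
                keep = rng.random(counts.shape[0]) >= config.dropout
                counts = counts * keep
            blocks.append(scipy.sparse.csr_matrix(counts[:, None]))
            donor = f"donor{j % config.n_studies}"
            records.append((f"{label}_cell{j:04d}", donor, label))
    mat = scipy.sparse.hstack(blocks, format="csr")
    ann = pd.DataFrame(
        records, columns=["cell_id", "donor_or_sample_id", "cell_type_label"]
    )
    return mat, ann, genes


# ---------------------------------------------------------------------------
# Read simulation for the read-origin QC module
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), length))


def make_read_origin_refs(
    seed: int,
    unique_len: int = 3000,
    shared_len: int = 1200,
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Toy two-species references sharing an rRNA-like conserved segment.

    Returns (ref_a, ref_b, shared) as name->sequence dicts; each reference is
    its own unique sequence with the shared segment appended, emulating two
    genomes that differ everywhere except a highly conserved rRNA locus.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shared = _random_seq(rng, shared_len)
    a_unique = _random_seq(rng, unique_len)
    b_unique = _random_seq(rng, unique_len)
    ref_a = {"refA_unique": a_unique, "refA_rrna": shared}
    ref_b = {"refB_unique": b_unique, "refB_rrna": shared}
    return ref_a, ref_b, {"rrna_shared": shared}


def simulate_reads(
    sources: Mapping[str, Mapping[str, str]],
    n_reads: Mapping[str, int],
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Draw uniform substrings from named reference sets, with substitutions.

    ``sources`` maps a source tag (e.g. ``a``, ``b``, ``shared``) to a
    name->sequence reference; reads are sampled uniformly over concatenable
    positions of a uniformly chosen record, half reverse-complemented.  The
    source tag is recorded in each read name.  Returns (name, sequence) pairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reads: list[tuple[str, str]] = []
    bases = np.array(list("ACGT"))
    for tag, ref in sources.items():
        n = n_reads.get(tag, 0)
        seqs = [s for s in ref.values()]
        if n > 0 and min(len(s) for s in seqs) < read_len:
            raise ValueError(
                f"read_len {read_len} exceeds shortest reference of source {tag!r}"
            )
        for i in range(n):
            seq = seqs[int(rng.integers(len(seqs)))]
            start = int(rng.integers(0, len(seq) - read_len + 1))
            read = seq[start : start + read_len]
            if error_rate > 0:
                arr = np.array(list(read))
                errs = np.flatnonzero(rng.random(read_len) < error_rate)
                for e in errs:
                    choices = bases[bases != arr[e]]
                    arr[e] = choices[int(rng.integers(3))]
                read = "".join(arr)
            if rng.random() < 0.5:
                read = read.translate(_COMP)[::-1]
            reads.append((f"read_{tag}_{i:06d} source={tag}", read))
    return reads


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
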