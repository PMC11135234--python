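"""Synthetic mutational catalogs and low-rank test fixtures.

A mutational catalog counts somatic single-base substitutions per genome in
their trinucleotide context: 6 pyrimidine-strand substitution subtypes
(C>A, C>G, C>T, T>A, T>C, T>G) times 4 flanking 5' bases times 4 flanking
3' bases = 96 mutation types.  A catalog generated by P mutational processes
is, in expectation, the product of a 96 x P signature matrix (each column a
probability distribution over the 96 types) and a P x G exposure matrix
(expected mutations each process contributes to each genome), observed with
Poisson counting noise.  Because the ground-truth rank P is known by
construction, these catalogs make automatic rank selection testable end to
end without any external download.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, GenerationError, RankError
from .matrix import TargetMatrix
from .nmf import derive_seed

__all__ = [
    "SUBSTITUTION_SUBTYPES",
    "default_alphabet",
    "make_signatures",
    "SimulationSpec",
    "SyntheticCatalog",
    "simulate_catalog",
    "make_lowrank_fixture",
]

#: Pyrimidine-strand notation for the six substitution subtypes
#: (C:G>A:T, C:G>G:C, C:G>T:A, T:A>A:T, T:A>C:G, T:A>G:C).
SUBSTITUTION_SUBTYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_BASES = ("A", "C", "G", "T")


def default_alphabet() -> list[str]:
    """The 96 trinucleotide-context mutation types, in deterministic order.

    Subtype-major, then 5' base, then 3' base, each alphabetical:
    ``A[C>A]A, A[C>A]C, ..., T[T>G]T``.
    """
    return [
        f"{five}[{sub}]{three}"
        for sub, five, three in itertools.product(SUBSTITUTION_SUBTYPES, _BASES, _BASES)
    ]


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def make_signatures(
    P: int, K: int, concentration: float = 0.1, seed: int = 0, max_cosine: float = 0.3
) -> np.ndarray:
    """K x P matrix of distinct signatures, columns i.i.d. Dirichlet.

    Each column is a probability distribution over the K mutation types
    (columns sum to 1).  Small ``concentration`` gives sharp, sparse motifs.
    Distinctness is enforced by resampling any column whose cosine
    similarity with an accepted column reaches ``max_cosine``; 100 failed
    draws for one column raise a generation error (the concentration is too
    large for K distinct motifs).
    """
    if P < 1:
        raise ArgumentError("P must be >= 1")
    if K < P:
        raise ArgumentError(f"need K >= P, got K={K} < P={P}")
    if concentration <= 0:
        raise ArgumentError("concentration must be positive")
    rng = np.random.default_rng(seed)
    alpha = np.full(K, concentration)
    cols: list[np.ndarray] = []
    for _ in range(P):
        for attempt in range(100):
            cand = rng.dirichlet(alpha)
            if all(_cosine(cand, c) < max_cosine for c in cols):
                cols.append(cand)
                break
        else:
            raise GenerationError(
                f"could not draw {P} signatures with pairwise cosine < {max_cosine} "
                f"(concentration {concentration} too large?)"
            )
    return np.column_stack(cols)


@dataclass(frozen=True)
class SimulationSpec:
    """Design of a synthetic catalog.

    Defaults are the benchmark conditions the package is validated under:
    10 processes, 100 genomes, the 96-type alphabet, Poisson counting noise,
    and an expected load of ``exposure_scale`` mutations per genome.  Each
    genome is dominated by one process (balanced across processes) with the
    remaining processes contributing a weak shared background
    (``background_fraction``), and per-process exposures are rescaled so all
    P planted processes carry equal signal power — a benchmark in which every
    planted process is, by design, comparably recoverable.
    """

    n_processes: int = 10
    n_genomes: int = 100
    mutation_alphabet: tuple[str, ...] = field(default_factory=lambda: tuple(default_alphabet()))
    signature_concentration: float = 0.1
    exposure_scale: float = 1000.0
    background_fraction: float = 0.1
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_processes < 1 or self.n_genomes < 1:
            raise ArgumentError("n_processes and n_genomes must be >= 1")
        if len(self.mutation_alphabet) < self.n_processes:
            raise ArgumentError("alphabet must have at least n_processes types")
        if len(set(self.mutation_alphabet)) != len(self.mutation_alphabet):
            raise ArgumentError("mutation alphabet labels must be unique")
        if self.exposure_scale <= 0 or self.signature_concentration <= 0:
            raise ArgumentError("exposure_scale and signature_concentration must be positive")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ArgumentError("background_fraction must lie in [0, 1]")


@dataclass
class SyntheticCatalog:
    """A simulated catalog with its ground truth attached.

    ``counts`` is K mutation types x G genomes; ``E[counts] =
    true_signatures @ true_exposures``.
    """

    counts: np.ndarray
    true_signatures: np.ndarray
    true_exposures: np.ndarray
    spec: SimulationSpec

    @property
    def true_rank(self) -> int:
        return self.spec.n_processes

    def to_target_matrix(self, drop_empty: bool = True) -> TargetMatrix:
        """Validated features x samples matrix for the pipeline.

        Mutation types never observed in any genome (all-zero rows — common
        under sharp signatures plus Poisson noise) carry no information and
        would fail validation, so ``drop_empty`` removes them, and any
        all-zero genomes, before constructing the matrix.
        """
        counts = self.counts
        rows = list(self.spec.mutation_alphabet)
        width = max(4, len(str(self.spec.n_genomes)))
        cols = [f"G{j + 1:0{width}d}" for j in range(self.spec.n_genomes)]
        if drop_empty:
            keep_r = counts.sum(axis=1) > 0
            keep_c = counts.sum(axis=0) > 0
            counts = counts[np.ix_(keep_r, keep_c)]
            rows = [x for x, k in zip(rows, keep_r) if k]
            cols = [x for x, k in zip(cols, keep_c) if k]
        return TargetMatrix(counts.astype(float), rows, cols)


def simulate_catalog(spec: SimulationSpec = SimulationSpec()) -> SyntheticCatalog:
    """Draw a catalog: Dirichlet signatures x structured exposures + Poisson.

    Each genome is dominated by one process (ownership balanced across
    processes, then shuffled) with a log-uniform [0.3, 1] amplitude; every
    other process contributes ``background_fraction`` of a log-uniform
    [0.05, 1] amplitude.  Per-process exposure rows are then rescaled so
    every process carries equal signal power ``||s_p|| * ||e_p||`` — without
    this, the sorted component spectrum decays and the RSS rank survey bends
    before the true rank — and the whole exposure matrix is scaled to an
    expected ``exposure_scale`` mutations per genome.  With
    ``poisson_noise`` each count is Poisson with mean
    ``(signatures @ exposures)_kg``; otherwise the mean is rounded to the
    nearest integer.  Fully deterministic per seed.
    """
    K = len(spec.mutation_alphabet)
    P, G = spec.n_processes, spec.n_genomes
    S = make_signatures(
        P, K, concentration=spec.signature_concentration, seed=derive_seed(spec.seed, 11)
    )
    rng = np.random.default_rng(derive_seed(spec.seed, 13))
    owner = rng.permutation(np.tile(np.arange(P), (G + P - 1) // P)[:G])
    A = spec.background_fraction * np.exp(rng.uniform(np.log(0.05), 0.0, size=(P, G)))
    A[owner, np.arange(G)] = np.exp(rng.uniform(np.log(0.3), 0.0, size=G))
    row_power = np.linalg.norm(S, axis=0) * np.linalg.norm(A, axis=1)
    if (row_power == 0).any():
        raise GenerationError(
            "a process has zero exposure everywhere; increase n_genomes or background_fraction"
        )
    A = A / row_power[:, None]
    E = A * (spec.exposure_scale * G / A.sum())
    lam = S @ E
    if spec.poisson_noise:
        counts = rng.poisson(lam).astype(float)
    else:
        counts = np.round(lam)
    return SyntheticCatalog(counts=counts, true_signatures=S, true_exposures=E, spec=spec)


def make_lowrank_fixture(
    m: int, n: int, r: int, noise_sd: float = 0.0, seed: int = 0
) -> TargetMatrix:
    """Positive exact-rank-r product, optionally with clipped Gaussian noise.

    Factors are uniform on [0.5, 1.5] so the product is strictly positive and
    numerically exactly rank r when ``noise_sd == 0``; noise is truncated at
    zero to keep the matrix nonnegative.
    """
    if r < 1 or r > min(m, n):
        raise RankError(f"rank {r} invalid for shape ({m}, {n})")
    if noise_sd < 0:
        raise ArgumentError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.5, 1.5, size=(m, r))
    H = rng.uniform(0.5, 1.5, size=(r, n))
    X = W @ H
    if noise_sd > 0:
        X = np.maximum(X + rng.normal(0.0, noise_sd, size=X.shape), 0.0)
    return TargetMatrix(X)
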