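"""Synthetic data matrices with planted constant-column biclusters.

The generative model is additive: every cell starts at a background level
``mu``; a cell that belongs to bicluster ``k`` (row member AND column member)
additionally receives that bicluster's column effect ``beta_jk``; overlapping
biclusters sum their effects.  Gaussian noise with standard deviation
``noise_sd`` is added on top:

    X_ij = mu + sum_k beta_jk * rho_ik * kappa_jk + eps_ij,   eps_ij ~ N(0, noise_sd)

where ``rho_ik`` / ``kappa_jk`` indicate row/column membership of ``i`` / ``j``
in bicluster ``k``.  "Constant column" means the effect ``beta_jk`` depends on
the column but is shared by every member row — the shape a metabolite peak
imprints on a spectroscopic matrix.

Blocks are planted on contiguous index ranges; :func:`permute_dataset`
scrambles rows and columns afterwards (recording the permutations) to mimic
the arbitrary ordering of a real experiment.

One seeded generator drives everything, consumed in a fixed, documented
order: block layout, beta draws, noise, permutations.  Identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .datatypes import Bicluster, BiclusterSet, DataMatrix, write_matrix

__all__ = [
    "SimParams",
    "SimulatedDataset",
    "generate_constant_column",
    "generate_block_example",
    "generate_benchmark_dataset1",
    "generate_gene_expression_style",
    "permute_dataset",
    "unpermute_dataset",
    "save_dataset",
]

DEFAULT_BETA_VALUES: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the constant-column bicluster generator.

    Attributes
    ----------
    m, n
        Sample (row) and variable (column) counts.
    k
        Number of planted biclusters.
    beta_values
        Pool of positive column-effect values; each bicluster draws one
        effect per member column, uniformly from this pool.
    mu
        Background level added to every cell.
    noise_sd
        Standard deviation of the additive Gaussian noise (>= 0).
    overlap_fraction
        Fraction in [0, 1) of the designated pair's indices shared between
        the first two biclusters, per dimension.  0 plants disjoint blocks.
    seed
        Seed of the single generator driving the whole construction.
    """

    m: int
    n: int
    k: int
    beta_values: tuple[float, ...] = DEFAULT_BETA_VALUES
    mu: float = 0.0
    noise_sd: float = 0.25
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1 or self.k < 1:
            raise ValueError("m, n and k must be positive")
        if self.k > min(self.m, self.n):
            raise ValueError(
                f"k={self.k} biclusters (minimum block size 1) exceed the "
                f"{self.m}x{self.n} matrix dimensions"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        betas = tuple(float(b) for b in self.beta_values)
        if not betas or any(b <= 0 for b in betas):
            raise ValueError("beta_values must be a non-empty set of positive values")
        object.__setattr__(self, "beta_values", betas)


@dataclass
class SimulatedDataset:
    """A generated matrix together with its ground truth and provenance.

    ``truth`` indexes the matrix as returned (i.e. after any permutation).
    ``row_perm[i]`` / ``col_perm[j]`` give the position in the pristine block
    layout of the row/column currently at ``i`` / ``j``; applying the inverse
    permutations (:func:`unpermute_dataset`) restores the block structure.
    ``betas[a]`` maps each member column of bicluster ``a`` (block-layout
    index) to its drawn column effect.
    """

    matrix: DataMatrix
    truth: BiclusterSet
    params: SimParams
    betas: list[dict[int, float]]
    row_perm: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_perm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m, n = self.matrix.shape
        if self.row_perm is None:
            self.row_perm = np.arange(m)
        if self.col_perm is None:
            self.col_perm = np.arange(n)
        self.row_perm = np.asarray(self.row_perm, dtype=int)
        self.col_perm = np.asarray(self.col_perm, dtype=int)


def _even_partition(total: int, k: int) -> list[np.ndarray]:
    """Split 0..total-1 into k contiguous, as-even-as-possible blocks."""
    return [np.asarray(c, dtype=int) for c in np.array_split(np.arange(total), k)]


def _block_layout(params: SimParams) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Contiguous row/column blocks; the first pair overlaps if requested.

    With ``overlap_fraction`` f > 0 and k >= 2, bicluster 1 additionally
    absorbs the trailing ``round(f * size)`` indices of bicluster 0 in each
    dimension, so the designated pair shares that fraction of its indices.
    """
    row_blocks = _even_partition(params.m, params.k)
    col_blocks = _even_partition(params.n, params.k)
    if params.overlap_fraction > 0 and params.k >= 2:
        for blocks in (row_blocks, col_blocks):
            size = min(len(blocks[0]), len(blocks[1]))
            ov = max(1, int(round(params.overlap_fraction * size)))
            shared = blocks[0][-ov:]
            blocks[1] = np.concatenate([shared, blocks[1]])
    return row_blocks, col_blocks


def _plant(
    m: int,
    n: int,
    row_blocks: list[np.ndarray],
    col_blocks: list[np.ndarray],
    betas: list[dict[int, float]],
    mu: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    X = np.full((m, n), float(mu))
    for rows, cols, beta in zip(row_blocks, col_blocks, betas):
        effect = np.array([beta[int(j)] for j in cols])
        X[np.ix_(rows, cols)] += effect[None, :]
    X += rng.normal(0.0, noise_sd, size=(m, n))
    return X


def _generate(params: SimParams, rng: np.random.Generator) -> SimulatedDataset:
    row_blocks, col_blocks = _block_layout(params)
    beta_pool = np.asarray(params.beta_values, dtype=float)
    betas = [
        {int(j): float(b) for j, b in zip(cols, rng.choice(beta_pool, size=len(cols)))}
        for cols in col_blocks
    ]
    X = _plant(params.m, params.n, row_blocks, col_blocks, betas, params.mu, params.noise_sd, rng)
    truth = BiclusterSet.from_index_lists(zip(row_blocks, col_blocks))
    return SimulatedDataset(DataMatrix.from_array(X), truth, params, betas)


def generate_constant_column(params: SimParams) -> SimulatedDataset:
    """Generate a matrix of (possibly overlapping) constant-column biclusters.

    Returns the raw model output: background ``mu`` plus planted effects plus
    Gaussian noise, unpermuted, with the ground truth recorded.  Note the
    noise can drive cells negative; clip or shift before a nonnegative
    factorization (the convenience constructors below clip).
    """
    return _generate(params, np.random.default_rng(params.seed))


def _clip_nonnegative(ds: SimulatedDataset) -> SimulatedDataset:
    """Clip negative noise tails at zero so the matrix is NMF-ready.

    Clipping only touches below-background noise excursions and preserves the
    planted low-rank structure, unlike a global shift which would add a
    constant (rank-one) background component as strong as the biclusters
    themselves.
    """
    values = np.maximum(ds.matrix.values, 0.0)
    return replace(ds, matrix=ds.matrix.with_values(values))


def _permute(ds: SimulatedDataset, rng: np.random.Generator) -> SimulatedDataset:
    m, n = ds.matrix.shape
    rp = rng.permutation(m)
    cp = rng.permutation(n)
    inv_r = np.empty(m, dtype=int)
    inv_r[rp] = np.arange(m)
    inv_c = np.empty(n, dtype=int)
    inv_c[cp] = np.arange(n)
    matrix = DataMatrix(
        ds.matrix.values[np.ix_(rp, cp)],
        [ds.matrix.row_labels[i] for i in rp],
        [ds.matrix.col_labels[j] for j in cp],
    )
    truth = BiclusterSet(
        [
            Bicluster(
                frozenset(int(inv_r[i]) for i in b.rows),
                frozenset(int(inv_c[j]) for j in b.cols),
            )
            for b in ds.truth
        ]
    )
    return SimulatedDataset(
        matrix,
        truth,
        ds.params,
        ds.betas,
        row_perm=ds.row_perm[rp],
        col_perm=ds.col_perm[cp],
    )


def permute_dataset(ds: SimulatedDataset, seed: int) -> SimulatedDataset:
    """Randomly shuffle rows and columns, remapping truth consistently."""
    return _permute(ds, np.random.default_rng(seed))


def unpermute_dataset(ds: SimulatedDataset) -> SimulatedDataset:
    """Undo the recorded permutations, restoring the pristine block layout."""
    m, n = ds.matrix.shape
    inv_r = np.empty(m, dtype=int)
    inv_r[ds.row_perm] = np.arange(m)
    inv_c = np.empty(n, dtype=int)
    inv_c[ds.col_perm] = np.arange(n)
    matrix = DataMatrix(
        ds.matrix.values[np.ix_(inv_r, inv_c)],
        [ds.matrix.row_labels[i] for i in inv_r],
        [ds.matrix.col_labels[j] for j in inv_c],
    )
    truth = BiclusterSet(
        [
            Bicluster(
                frozenset(int(ds.row_perm[i]) for i in b.rows),
                frozenset(int(ds.col_perm[j]) for j in b.cols),
            )
            for b in ds.truth
        ]
    )
    return SimulatedDataset(matrix, truth, ds.params, ds.betas)


def generate_benchmark_dataset1(seed: int, noise_sd: float = 0.25) -> SimulatedDataset:
    """The 50 x 250 spectroscopic benchmark: k=3 biclusters, two overlapping.

    Column effects are drawn from {1, ..., 5}, the background is 0, rows and
    columns of the three (as even as possible) blocks are randomly permuted,
    and negative noise tails are clipped at zero.  ``noise_sd`` defaults to
    the benchmark's headline noise level 0.25.
    """
    params = SimParams(
        m=50,
        n=250,
        k=3,
        beta_values=DEFAULT_BETA_VALUES,
        mu=0.0,
        noise_sd=noise_sd,
        overlap_fraction=0.25,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    ds = _generate(params, rng)
    ds = _clip_nonnegative(ds)
    return _permute(ds, rng)


def generate_block_example(
    betas: tuple[float, ...] = (1.0, 2.0, 3.0),
    m: int = 8,
    n: int = 8,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SimulatedDataset:
    """Small illustration matrix: one constant-value block per bicluster.

    Plants ``k = len(betas)`` disjoint contiguous blocks, block ``a``
    carrying the constant value ``betas[a]`` on all its cells, plus Gaussian
    noise.  The default is the classic 8 x 8, beta = {1, 2, 3} picture.
    Unpermuted and unclipped (at the default noise level the handful of
    negative tails are irrelevant; pass ``noise_sd=0`` for the exact
    deterministic case).
    """
    k = len(betas)
    params = SimParams(
        m=m, n=n, k=k, beta_values=tuple(betas), mu=0.0, noise_sd=noise_sd, seed=seed
    )
    rng = np.random.default_rng(seed)
    row_blocks = _even_partition(m, k)
    col_blocks = _even_partition(n, k)
    beta_maps = [
        {int(j): float(b) for j in cols} for cols, b in zip(col_blocks, betas)
    ]
    X = _plant(m, n, row_blocks, col_blocks, beta_maps, 0.0, noise_sd, rng)
    truth = BiclusterSet.from_index_lists(zip(row_blocks, col_blocks))
    ds = SimulatedDataset(DataMatrix.from_array(X), truth, params, beta_maps)
    return _clip_nonnegative(ds) if noise_sd > 0 else ds


def generate_gene_expression_style(
    k: int,
    seed: int,
    noise_sd: float = 0.25,
    beta_values: tuple[float, ...] = DEFAULT_BETA_VALUES,
) -> SimulatedDataset:
    """Gene-expression-style benchmark: 500 x 200 with disjoint 50 x 50 blocks.

    Each of the ``k`` biclusters occupies its own 50 rows and 50 columns
    (so ``k * 50`` must fit in the 200-column budget) and carries a single
    constant value drawn from ``beta_values``.  Unpermuted; apply
    :func:`permute_dataset` for a scrambled instance.
    """
    m, n, block = 500, 200, 50
    if k < 1:
        raise ValueError("k must be positive")
    if k * block > n:
        raise ValueError(f"k={k} blocks of {block} columns exceed the {n}-column budget")
    rng = np.random.default_rng(seed)
    row_blocks = [np.arange(a * block, (a + 1) * block) for a in range(k)]
    col_blocks = [np.arange(a * block, (a + 1) * block) for a in range(k)]
    betas = []
    for cols in col_blocks:
        value = float(rng.choice(np.asarray(beta_values, dtype=float)))
        betas.append({int(j): value for j in cols})
    X = _plant(m, n, row_blocks, col_blocks, betas, 0.0, noise_sd, rng)
    truth = BiclusterSet.from_index_lists(zip(row_blocks, col_blocks))
    params = SimParams(
        m=m,
        n=n,
        k=k,
        beta_values=tuple(float(b) for b in beta_values),
        mu=0.0,
        noise_sd=noise_sd,
        overlap_fraction=0.0,
        seed=seed,
    )
    ds = SimulatedDataset(DataMatrix.from_array(X, row_prefix="G", col_prefix="C"), truth, params, betas)
    return _clip_nonnegative(ds) if noise_sd > 0 else ds


def save_dataset(ds: SimulatedDataset, prefix: str | Path) -> dict[str, Path]:
    """Write matrix (TSV), truth (JSON) and generation parameters (JSON)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": write_matrix(ds.matrix, prefix.parent / (prefix.name + ".matrix.tsv")),
        "truth": ds.truth.save(prefix.parent / (prefix.name + ".truth.json")),
    }
    meta = {
        "params": {
            "m": ds.params.m,
            "n": ds.params.n,
            "k": ds.params.k,
            "beta_values": list(ds.params.beta_values),
            "mu": ds.params.mu,
            "noise_sd": ds.params.noise_sd,
            "overlap_fraction": ds.params.overlap_fraction,
            "seed": ds.params.seed,
        },
        "row_perm": ds.row_perm.tolist(),
        "col_perm": ds.col_perm.tolist(),
    }
    meta_path = prefix.parent / (prefix.name + ".params.json")
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    paths["params"] = meta_path
    return paths
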