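"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the three external data sources: two-cluster low-rank
expression matrices with planted causal directions, additive
perturbation-response libraries with planted feasible steering solutions, and
binary bipartite occurrence matrices with planted co-occurring column pairs.
All randomness flows from a single integer seed through named substreams, so
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .curation import NormalizedExpression
from .eigengenes import EigengeneBasis
from .transitions import PerturbationLibrary

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SteeringInstances",
    "generate_expression",
    "generate_perturbation_library",
    "generate_bipartite",
    "generate_steering_instances",
    "generate_counts_dataset",
    "write_counts_dataset",
]

# named substreams hanging off the one config seed
_STREAMS = {"expression": 0, "library": 1, "bipartite": 2, "steering": 3, "counts": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SynthConfig:
    n_genes: int = 500
    n_baseline: int = 100
    n_variant: int = 100
    latent_rank: int = 10
    class_shift: float | None = None  # defaults to 3 * causal_score_sd
    causal_score_sd: float | None = None  # within-class spread along causal dirs
    noise_sd: float = 0.5
    n_causal: int = 2
    n_perturbations: int = 40
    frac_overexpression: float = 0.1
    seed: int = 0
    base_level: float = 10.0  # log-NTPM-scale mean expression level
    factor_strength: float = 1.0  # latent score scale relative to noise_sd*sqrt(n_genes)

    def __post_init__(self) -> None:
        counts = dict(
            n_genes=self.n_genes,
            n_baseline=self.n_baseline,
            n_variant=self.n_variant,
            latent_rank=self.latent_rank,
            n_perturbations=self.n_perturbations,
        )
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.frac_overexpression <= 1:
            raise ValueError("frac_overexpression must lie in [0, 1]")
        n_samples = self.n_baseline + self.n_variant
        if not (0 <= self.n_causal <= self.latent_rank <= min(self.n_genes, n_samples)):
            raise ValueError(
                "require n_causal <= latent_rank <= min(n_genes, n_samples); got "
                f"n_causal={self.n_causal}, latent_rank={self.latent_rank}, "
                f"min={min(self.n_genes, n_samples)}"
            )
        if self.causal_score_sd is None:
            self.causal_score_sd = 3.0 * self.noise_sd
        if self.class_shift is None:
            # 3 sigma of the within-class spread along the causal directions:
            # recoverable by fine-mapping but not trivially separable
            self.class_shift = 3.0 * self.causal_score_sd

    @property
    def n_samples(self) -> int:
        return self.n_baseline + self.n_variant


@dataclass
class GroundTruth:
    """What was planted: causal directions and the class displacement."""

    causal_indices: np.ndarray  # indices into the planted direction columns
    directions: np.ndarray  # n_genes x latent_rank orthonormal planted directions
    class_mean_delta: np.ndarray  # gene-space displacement of the variant mean
    planted_u: dict = field(default_factory=dict)  # pair -> weight vector in [0,1]

    def match_eigengenes(self, basis: EigengeneBasis, which: str = "causal") -> np.ndarray:
        """Basis column best aligned (|cosine|) with each planted direction."""
        cols = self.causal_indices if which == "causal" else np.arange(self.directions.shape[1])
        overlaps = np.abs(basis.U.T @ self.directions[:, cols])  # l x len(cols)
        return np.argmax(overlaps, axis=0)


def generate_expression(config: SynthConfig) -> tuple[NormalizedExpression, GroundTruth]:
    """Two-cluster low-rank expression on the log scale.

    Samples are ``mean + scores @ directions.T + noise`` with orthonormal
    planted directions; the variant class mean is displaced by ``class_shift``
    along each of the ``n_causal`` planted causal directions.  Planted score
    variances dominate the isotropic noise, so the planted directions coincide
    with eigengenes of the generated matrix up to noise.
    """
    rng = _rng(config.seed, "expression")
    n, m = config.n_genes, config.n_samples

    Q, _ = np.linalg.qr(rng.standard_normal((n, config.latent_rank)))
    flip = np.sign(Q[np.argmax(np.abs(Q), axis=0), np.arange(Q.shape[1])])
    flip[flip == 0] = 1.0
    Q = Q * flip

    # mildly decreasing score scales keep the eigengene ordering stable
    base_scale = config.factor_strength * config.noise_sd * np.sqrt(n)
    scales = base_scale * (1.0 - 0.5 * np.arange(config.latent_rank) / config.latent_rank)
    causal = np.sort(rng.choice(config.latent_rank, size=config.n_causal, replace=False))
    # causal directions carry a small within-class spread so the class shift
    # separates the phenotypes along them (non-causal factors stay dominant)
    scales[causal] = config.causal_score_sd
    scores = rng.standard_normal((m, config.latent_rank)) * scales
    delta = config.class_shift * Q[:, causal].sum(axis=1) if config.n_causal else np.zeros(n)

    labels = np.concatenate(
        [np.zeros(config.n_baseline, dtype=int), np.ones(config.n_variant, dtype=int)]
    )
    gene_means = config.base_level + 0.25 * rng.standard_normal(n)
    values = (
        gene_means
        + scores @ Q.T
        + np.outer(labels, delta)
        + config.noise_sd * rng.standard_normal((m, n))
    )
    expr = NormalizedExpression(
        values=values,
        labels=labels,
        gene_ids=[f"SG{i:05d}" for i in range(n)],
        sample_ids=[f"sample{i:05d}" for i in range(m)],
    )
    truth = GroundTruth(causal_indices=causal, directions=Q, class_mean_delta=delta)
    return expr, truth


def generate_perturbation_library(
    config: SynthConfig,
    basis: EigengeneBasis,
    truth: GroundTruth,
    selected: np.ndarray | None = None,
    n_designated: int | None = None,
    response_scale: float = 1.0,
) -> PerturbationLibrary:
    """Additive response library whose designated columns span the class shift.

    The designated subset of columns sums exactly to ``class_mean_delta`` in
    gene space, so with the indicator vector as weights, ``B @ u`` equals the
    class displacement projected onto the selected eigengenes — a feasible
    steering solution exists by construction.
    """
    if basis.n_genes != truth.directions.shape[0]:
        raise ValueError(
            f"basis has {basis.n_genes} genes but the ground truth was planted "
            f"in {truth.directions.shape[0]} gene dimensions"
        )
    if selected is None:
        selected = np.arange(min(basis.l, 50))
    selected = np.asarray(selected, dtype=int)
    P = config.n_perturbations
    if n_designated is None:
        n_designated = max(2, config.n_causal)
    if n_designated > P:
        raise ValueError("n_designated cannot exceed n_perturbations")

    rng = _rng(config.seed, "library")
    n = basis.n_genes
    profiles = response_scale * rng.standard_normal((n, P))
    designated = np.arange(n_designated)
    profiles[:, designated[-1]] = truth.class_mean_delta - profiles[:, designated[:-1]].sum(axis=1)

    signs = ["OE" if rng.random() < config.frac_overexpression else "KD" for _ in range(P)]
    symbols = [f"PG{i:04d}" for i in range(P)]

    from .transitions import build_library

    lib = build_library(profiles, basis, selected, symbols, signs)
    truth.planted_u["designated"] = _indicator(designated, P)
    return lib


def _indicator(idx: np.ndarray, size: int) -> np.ndarray:
    u = np.zeros(size)
    u[np.asarray(idx, dtype=int)] = 1.0
    return u


def generate_bipartite(
    n_rows: int,
    n_cols: int,
    density: float,
    planted_pairs: list[tuple[int, int]] | None = None,
    boost: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Binary matrix with independent Bernoulli(density) entries.

    For each planted column pair, an extra joint event with probability
    ``boost`` forces both entries to one on the same row, raising the joint
    occurrence probability to ``boost + (1 - boost) * density**2``.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if not 0 <= boost < 1:
        raise ValueError("boost must lie in [0, 1)")
    if density + boost > 1:
        raise ValueError("density + boost must not exceed 1")
    planted_pairs = planted_pairs or []
    for a, b in planted_pairs:
        if not (0 <= a < n_cols and 0 <= b < n_cols):
            raise IndexError(f"planted pair ({a}, {b}) out of range for {n_cols} columns")

    rng = _rng(seed, "bipartite")
    M = (rng.random((n_rows, n_cols)) < density).astype(int)
    for a, b in planted_pairs:
        joint = rng.random(n_rows) < boost
        M[joint, a] = 1
        M[joint, b] = 1
    return M


@dataclass
class SteeringInstances:
    """Baseline/variant states in eigengene coordinates with a feasible library.

    The library contains paired +/- axis columns scaled past the largest
    coordinate difference between any cross-cluster pair, so every pairwise
    difference (in either direction) lies in ``{B u : u in [0,1]^P}`` exactly.
    """

    baseline: np.ndarray  # n_baseline x r
    variant: np.ndarray  # n_variant x r
    library: PerturbationLibrary
    axis_scale: float

    def planted_solution(self, x_from: np.ndarray, x_to: np.ndarray) -> np.ndarray:
        """Exact feasible weights: B @ u == x_to - x_from, entries in [0,1]."""
        delta = np.asarray(x_to) - np.asarray(x_from)
        r = delta.shape[0]
        u = np.zeros(self.library.n_perturbations)
        pos = delta >= 0
        u[:r][pos] = delta[pos] / self.axis_scale
        u[r : 2 * r][~pos] = -delta[~pos] / self.axis_scale
        return u


def generate_steering_instances(
    n_dims: int = 20,
    n_baseline: int = 30,
    n_variant: int = 30,
    n_perturbations: int = 60,
    cluster_sd: float = 1.0,
    cluster_shift: float = 3.0,
    seed: int = 0,
) -> SteeringInstances:
    """Plant steering problems that are feasible by construction."""
    if n_perturbations < 2 * n_dims:
        raise ValueError(
            f"need at least 2 * n_dims = {2 * n_dims} perturbations for the "
            "paired axis columns"
        )
    rng = _rng(seed, "steering")
    shift_dir = rng.standard_normal(n_dims)
    shift_dir *= cluster_shift / np.linalg.norm(shift_dir)
    baseline = cluster_sd * rng.standard_normal((n_baseline, n_dims))
    variant = shift_dir + cluster_sd * rng.standard_normal((n_variant, n_dims))

    diffs = variant[None, :, :] - baseline[:, None, :]
    c = 1.2 * float(np.abs(diffs).max())

    n_extra = n_perturbations - 2 * n_dims
    B = np.hstack(
        [c * np.eye(n_dims), -c * np.eye(n_dims), rng.standard_normal((n_dims, n_extra))]
    )
    signs = ["OE"] * n_dims + ["KD"] * n_dims + [
        "OE" if rng.random() < 0.5 else "KD" for _ in range(n_extra)
    ]
    symbols = [f"PG{i:04d}" for i in range(n_perturbations)]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.nan_to_num(np.corrcoef(B.T), nan=0.0)
    np.fill_diagonal(corr, 1.0)
    lib = PerturbationLibrary(B, symbols, signs, corr)
    return SteeringInstances(baseline=baseline, variant=variant, library=lib, axis_scale=c)


# ---------------------------------------------------------------------------
# Count-level generator (negative binomial) for exercising the curation path.


def generate_counts_dataset(
    n_genes: int = 100,
    n_samples: int = 20,
    mean_count: float = 50.0,
    dispersion: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], list[str], np.ndarray, dict[str, float]]:
    """Raw NB counts plus gene lengths and balanced labels.

    Returns ``(counts genes x samples, gene_ids, sample_ids, labels, lengths)``.
    """
    rng = _rng(seed, "counts")
    gene_means = rng.gamma(shape=2.0, scale=mean_count / 2.0, size=n_genes)
    # NB parameterized by (n, p): mean = n(1-p)/p with n = 1/dispersion
    n_param = 1.0 / dispersion
    p = n_param / (n_param + gene_means)
    counts = rng.negative_binomial(n_param, p[:, None], size=(n_genes, n_samples))
    gene_ids = [f"SG{i:05d}" for i in range(n_genes)]
    sample_ids = [f"sample{i:05d}" for i in range(n_samples)]
    labels = np.arange(n_samples) % 2
    lengths = {g: float(rng.integers(200, 10000)) for g in gene_ids}
    return counts, gene_ids, sample_ids, labels, lengths


def write_counts_dataset(out_dir: str, seed: int = 0, **kwargs) -> dict[str, str]:
    """Write counts/lengths/labels in the delimited formats curation reads."""
    import pandas as pd

    counts, gene_ids, sample_ids, labels, lengths = generate_counts_dataset(
        seed=seed, **kwargs
    )
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "counts": os.path.join(out_dir, "counts.tsv"),
        "lengths": os.path.join(out_dir, "gene_lengths.tsv"),
        "labels": os.path.join(out_dir, "labels.txt"),
    }
    pd.DataFrame(counts, index=gene_ids, columns=sample_ids).to_csv(
        paths["counts"], sep="\t", index_label="gene_id"
    )
    with open(paths["lengths"], "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\t{lengths[g]:.0f}\n")
    with open(paths["labels"], "w") as fh:
        for lab in labels:
            fh.write(f"{lab}\n")
    return paths
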