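"""Bounded L1-penalized steering between phenotype states.

Given a library ``B`` whose columns are average transcriptional responses to
single-gene perturbations, expressed in causal-eigengene coordinates, find
box-constrained weights ``u in [0,1]^P`` minimizing

    D(u) + lambda * sum(u),     D(u) = ||x_to - x_from - B u||  (Euclidean),

and score solutions with the coefficient of determination
``R^2 = 1 - D(u)/D(0)``.  A lambda sweep keeps the sparsest solution whose
R^2 still exceeds an acceptance bound (default 0.99); accepted solutions over
many sampled state pairs are binarized into the rows of a pair-by-perturbation
occurrence matrix ``A``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .eigengenes import EigengeneBasis

__all__ = [
    "PerturbationLibrary",
    "TransitionProblem",
    "TransitionSolution",
    "PairSweepResult",
    "build_library",
    "distance",
    "r_squared",
    "solve",
    "lambda_sweep",
    "sweep_pairs",
    "binarize",
    "default_lambda_grid",
]

DEFAULT_R2_MIN = 0.99
DEFAULT_BINARIZE_THRESHOLD = 0.01
_NORM_EPS = 1e-24  # smoothing for the gradient of the Euclidean norm at 0


def default_lambda_grid(n: int = 25, low: float = 1e-4, high: float = 10.0) -> np.ndarray:
    """Log-spaced L1-weight grid, ascending."""
    return np.logspace(np.log10(low), np.log10(high), n)


@dataclass
class PerturbationLibrary:
    """Response library in causal-eigengene coordinates.

    ``B`` is r x P (rows = selected causal eigengenes, columns = average
    response per perturbation).  Each column carries a gene symbol and a sign
    tag (``KD`` knockdown / ``OE`` overexpression); ``response_correlations``
    is the P x P Pearson correlation of the full response profiles.
    """

    B: np.ndarray
    gene_symbols: list[str]
    signs: list[str]
    response_correlations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 2:
            raise ValueError("B must be 2-D (eigengenes x perturbations)")
        P = self.B.shape[1]
        if len(self.gene_symbols) != P or len(self.signs) != P:
            raise ValueError("metadata length must match the number of columns")
        bad = set(self.signs) - {"KD", "OE"}
        if bad:
            raise ValueError(f"signs must be 'KD' or 'OE'; found {sorted(bad)}")
        if self.response_correlations is not None:
            C = np.asarray(self.response_correlations, dtype=float)
            if C.shape != (P, P):
                raise ValueError("response_correlations must be P x P")
            self.response_correlations = C

    @property
    def n_perturbations(self) -> int:
        return self.B.shape[1]

    def labels(self) -> list[str]:
        """Node labels 'GENE+' / 'GENE-' used in co-occurrence graphs."""
        mark = {"OE": "+", "KD": "-"}
        return [g + mark[s] for g, s in zip(self.gene_symbols, self.signs)]


@dataclass
class TransitionProblem:
    x_from: np.ndarray
    x_to: np.ndarray
    B: np.ndarray
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.x_from = np.asarray(self.x_from, dtype=float).ravel()
        self.x_to = np.asarray(self.x_to, dtype=float).ravel()
        self.B = np.asarray(self.B, dtype=float)
        r = self.x_from.shape[0]
        if self.x_to.shape[0] != r or self.B.shape[0] != r:
            raise ValueError("x_from, x_to and B rows must share the eigengene dimension")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class TransitionSolution:
    u: np.ndarray
    r_squared: float
    lam: float
    objective: float
    converged: bool


@dataclass
class PairSweepResult:
    """Accepted binarized solutions stacked into the occurrence matrix A."""

    A: np.ndarray  # accepted-pairs x P binary
    directions: list[str]  # 'forward' / 'reverse' per accepted row
    lambdas: np.ndarray
    r_squareds: np.ndarray
    pair_indices: list[tuple[int, int]]  # (baseline index, variant index)
    n_rejected: int
    perturbation_counts: np.ndarray  # per accepted row: number of selected columns

    @property
    def n_accepted(self) -> int:
        return self.A.shape[0]


def build_library(
    response_profiles: np.ndarray,
    basis: EigengeneBasis,
    selected: np.ndarray,
    gene_symbols: list[str],
    signs: list[str],
    perturbation_ids: list[str] | None = None,
) -> PerturbationLibrary:
    """Project gene-space response profiles onto the selected causal eigengenes.

    ``response_profiles`` is genes x P on the same gene set and ordering as the
    basis.  If ``perturbation_ids`` contains duplicates, replicate columns are
    averaged per perturbation (library columns are average responses).
    Correlations between perturbations are computed on the full-gene profiles.
    """
    R = np.asarray(response_profiles, dtype=float)
    if R.shape[0] != basis.n_genes:
        raise ValueError(
            f"response profiles have {R.shape[0]} genes but the basis has "
            f"{basis.n_genes}; gene sets must match exactly"
        )
    if perturbation_ids is not None:
        uniq = list(dict.fromkeys(perturbation_ids))
        ids = np.asarray(perturbation_ids)
        cols, syms, sgns = [], [], []
        for pid in uniq:
            mask = ids == pid
            cols.append(R[:, mask].mean(axis=1))
            first = int(np.flatnonzero(mask)[0])
            syms.append(gene_symbols[first])
            sgns.append(signs[first])
        R = np.column_stack(cols)
        gene_symbols, signs = syms, sgns

    selected = np.asarray(selected, dtype=int)
    B = basis.U[:, selected].T @ R
    zero_cols = np.flatnonzero(np.linalg.norm(B, axis=0) < 1e-12)
    if zero_cols.size:
        warnings.warn(
            f"{zero_cols.size} response columns are orthogonal to all selected "
            f"eigengenes (zero columns in B): indices {zero_cols.tolist()[:10]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(R.T)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return PerturbationLibrary(B, list(gene_symbols), list(signs), corr)


def distance(x_from: np.ndarray, x_to: np.ndarray, B: np.ndarray, u: np.ndarray) -> float:
    """Euclidean residual ||x_to - x_from - B u||."""
    return float(np.linalg.norm(np.asarray(x_to) - np.asarray(x_from) - B @ np.asarray(u)))


def r_squared(problem: TransitionProblem, u: np.ndarray) -> float:
    """Coefficient of determination 1 - D(u)/D(0); errors on degenerate pairs."""
    d0 = distance(problem.x_from, problem.x_to, problem.B, np.zeros(problem.B.shape[1]))
    if d0 == 0:
        raise ValueError("degenerate pair: x_from equals x_to (D(0) = 0)")
    return 1.0 - distance(problem.x_from, problem.x_to, problem.B, u) / d0


def solve(problem: TransitionProblem) -> TransitionSolution:
    """Minimize D(u) + lambda*sum(u) over the box [0,1]^P with L-BFGS-B.

    The objective is convex, so the bounded quasi-Newton minimizer reaches the
    global minimum; the start point is u = 0.
    """
    delta = problem.x_to - problem.x_from
    B, lam = problem.B, problem.lam
    P = B.shape[1]

    def fun_grad(u: np.ndarray) -> tuple[float, np.ndarray]:
        res = delta - B @ u
        smooth = np.sqrt(res @ res + _NORM_EPS)
        grad = -(B.T @ res) / smooth + lam
        return smooth + lam * u.sum(), grad

    out = minimize(
        fun_grad,
        np.zeros(P),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * P,
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
    )
    u = np.clip(out.x, 0.0, 1.0)
    obj = distance(problem.x_from, problem.x_to, B, u) + lam * u.sum()
    if not out.success:
        warnings.warn(f"optimizer did not report convergence: {out.message}")
    return TransitionSolution(
        u=u,
        r_squared=r_squared(problem, u),
        lam=lam,
        objective=obj,
        converged=bool(out.success),
    )


def lambda_sweep(
    x_from: np.ndarray,
    x_to: np.ndarray,
    B: np.ndarray,
    lambda_grid: np.ndarray,
    r2_min: float = DEFAULT_R2_MIN,
) -> TransitionSolution | None:
    """Sparsest acceptable solution: the largest lambda with R^2 > r2_min.

    Returns None (rejection) if no grid lambda qualifies.  The grid is scanned
    from the largest lambda down; the first qualifying solution is returned.
    """
    grid = np.sort(np.asarray(lambda_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    for lam in grid[::-1]:
        sol = solve(TransitionProblem(x_from, x_to, B, lam))
        if sol.r_squared > r2_min:
            return sol
    return None


def sweep_pairs(
    baseline_states: np.ndarray,
    variant_states: np.ndarray,
    B: np.ndarray,
    n_pairs: int = 2500,
    directions: tuple[str, ...] = ("forward", "reverse"),
    lambda_grid: np.ndarray | None = None,
    r2_min: float = DEFAULT_R2_MIN,
    binarize_threshold: float = DEFAULT_BINARIZE_THRESHOLD,
    seed: int = 0,
) -> PairSweepResult:
    """Solve the lambda sweep for many sampled baseline/variant state pairs.

    Pairs are sampled uniformly with replacement; 'forward' steers a baseline
    state to a variant state, 'reverse' the opposite.  Accepted solutions are
    binarized into rows of A.
    """
    baseline_states = np.atleast_2d(np.asarray(baseline_states, dtype=float))
    variant_states = np.atleast_2d(np.asarray(variant_states, dtype=float))
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    bad = set(directions) - {"forward", "reverse"}
    if bad:
        raise ValueError(f"unknown directions {sorted(bad)}")

    rng = np.random.default_rng(seed)
    b_idx = rng.integers(0, baseline_states.shape[0], size=n_pairs)
    v_idx = rng.integers(0, variant_states.shape[0], size=n_pairs)

    rows, row_dirs, lams, r2s, pairs, counts = [], [], [], [], [], []
    n_rejected = 0
    for j, i in zip(b_idx, v_idx):
        for direction in directions:
            if direction == "forward":
                x_from, x_to = baseline_states[j], variant_states[i]
            else:
                x_from, x_to = variant_states[i], baseline_states[j]
            sol = lambda_sweep(x_from, x_to, B, lambda_grid, r2_min)
            if sol is None:
                n_rejected += 1
                continue
            row = binarize(sol.u, binarize_threshold)
            rows.append(row)
            row_dirs.append(direction)
            lams.append(sol.lam)
            r2s.append(sol.r_squared)
            pairs.append((int(j), int(i)))
            counts.append(int(row.sum()))

    if not rows:
        raise ValueError("no pair was accepted at any lambda; nothing to report")
    return PairSweepResult(
        A=np.array(rows, dtype=int),
        directions=row_dirs,
        lambdas=np.array(lams),
        r_squareds=np.array(r2s),
        pair_indices=pairs,
        n_rejected=n_rejected,
        perturbation_counts=np.array(counts, dtype=int),
    )


def binarize(u: np.ndarray, threshold: float = DEFAULT_BINARIZE_THRESHOLD) -> np.ndarray:
    """Occurrence indicator: 1 where u exceeds the threshold (strict)."""
    return (np.asarray(u, dtype=float) > threshold).astype(int)
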