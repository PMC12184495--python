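"""Perturbation co-occurrence statistics against a maximum-entropy null.

Observed co-occurrence frequencies ``f = A.T A / N`` over the accepted
pair-solution matrix ``A`` are compared with a maximum-entropy bipartite null
model that fixes the expected row and column sums of ``A``.  The null
factorizes into independent Bernoulli cells

    p_ij = 1 / (1 + exp(-(beta_i + gamma_j))),

whose multipliers are found by iterating

    beta_i  <- log k_i    - log sum_j r(beta_i, gamma_j),
    gamma_j <- log kappa_j - log sum_i r(gamma_j, beta_i),

with ``r(x, y) = 1 / (exp(-y) + exp(x))``.  Since rows (state pairs) and
columns (perturbations) index different entities, the sums run over all
opposite-side indices with no diagonal exclusion.  Expected frequencies,
error-propagated standard errors, and z-scores follow, and pairs with z above
a threshold form the co-occurrence graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "NullModel",
    "CooccurrenceStats",
    "cooccurrence_freq",
    "fit_null",
    "expected_freq",
    "sigma_freq",
    "z_scores",
    "compute_stats",
    "qq_points",
    "build_graph",
    "sample_null",
]

DEFAULT_Z_THRESHOLD = 20.0


@dataclass
class NullModel:
    beta_row: np.ndarray  # per-row multipliers (+/-inf for saturated rows)
    gamma_col: np.ndarray
    p: np.ndarray  # rows x columns edge probabilities
    converged: bool
    iterations: int


@dataclass
class CooccurrenceStats:
    f: np.ndarray
    f_null: np.ndarray
    sigma: np.ndarray
    z: np.ndarray
    n_rows: int
    undefined: np.ndarray  # cells where sigma == 0 (z set to 0 there)


def _check_binary(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if not np.isin(A, (0, 1)).all():
        raise ValueError("A must be binary")
    return A.astype(float)


def cooccurrence_freq(A: np.ndarray) -> np.ndarray:
    """Observed co-occurrence frequencies f = A.T A / N."""
    A = _check_binary(A)
    if A.shape[0] < 1:
        raise ValueError("A must have at least one row")
    return A.T @ A / A.shape[0]


def fit_null(
    A: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000
) -> NullModel:
    """Maximum-entropy null with fixed expected row and column sums.

    Saturated rows/columns (all zeros or all ones) make the multipliers
    diverge; they are peeled off first and reinserted with p fixed to 0 or 1,
    adjusting the opposite-side degree targets.  The remaining core is solved
    by damped fixed-point iteration, converging when the largest change in p
    falls below ``tol``.
    """
    A = _check_binary(A)
    N, M = A.shape
    p = np.full((N, M), np.nan)
    beta = np.full(N, np.nan)
    gamma = np.full(M, np.nan)

    row_keep = np.ones(N, dtype=bool)
    col_keep = np.ones(M, dtype=bool)
    k = A.sum(axis=1).astype(float)
    kappa = A.sum(axis=0).astype(float)

    # peel saturated rows/columns; their cells are deterministic under the null
    changed = True
    while changed:
        changed = False
        m_eff = col_keep.sum()
        for i in np.flatnonzero(row_keep):
            if k[i] <= 0 or k[i] >= m_eff:
                val = 0.0 if k[i] <= 0 else 1.0
                p[i, col_keep] = val
                beta[i] = -np.inf if val == 0.0 else np.inf
                # a deterministic row contributes `val` to every kept column target
                kappa[col_keep] -= val
                row_keep[i] = False
                changed = True
        n_eff = row_keep.sum()
        for j in np.flatnonzero(col_keep):
            if kappa[j] <= 0 or kappa[j] >= n_eff:
                val = 0.0 if kappa[j] <= 0 else 1.0
                p[row_keep, j] = val
                gamma[j] = -np.inf if val == 0.0 else np.inf
                k[row_keep] -= val
                col_keep[j] = False
                changed = True

    rows = np.flatnonzero(row_keep)
    cols = np.flatnonzero(col_keep)
    if rows.size == 0 or cols.size == 0:
        return NullModel(beta, gamma, np.nan_to_num(p, nan=0.0), True, 0)

    kr = k[rows]
    kc = kappa[cols]
    m_eff, n_eff = len(cols), len(rows)
    b = np.log(kr / (m_eff - kr))  # independence-ish start
    g = np.zeros(len(cols))

    def p_core(bv: np.ndarray, gv: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(bv[:, None] + gv[None, :])))

    pc = p_core(b, g)
    mix = 1.0
    last_resid = np.inf
    converged = False
    it = 0
    for it in range(1, int(max_iter) + 1):
        # r(x, y) = 1 / (exp(-y) + exp(x)); row update then column update (Jacobi)
        r_row = 1.0 / (np.exp(-g)[None, :] + np.exp(b)[:, None])
        b_new = np.log(kr) - np.log(r_row.sum(axis=1))
        r_col = 1.0 / (np.exp(-b)[:, None] + np.exp(g)[None, :])
        g_new = np.log(kc) - np.log(r_col.sum(axis=0))
        b = mix * b_new + (1 - mix) * b
        g = mix * g_new + (1 - mix) * g

        pc_new = p_core(b, g)
        delta = np.abs(pc_new - pc).max()
        pc = pc_new
        resid = max(
            np.abs(pc.sum(axis=1) - kr).max(), np.abs(pc.sum(axis=0) - kc).max()
        )
        if delta < tol:
            converged = True
            break
        if resid > last_resid * (1 + 1e-12) and mix > 0.5:
            mix = 0.5  # damp if the raw iteration oscillates
        last_resid = resid

    if not converged:
        raise RuntimeError(
            f"null model did not converge in {max_iter} iterations; "
            f"max degree residual {last_resid:.3e}"
        )
    beta[rows] = b
    gamma[cols] = g
    p[np.ix_(rows, cols)] = pc
    return NullModel(beta, gamma, p, converged, it)


def expected_freq(null: NullModel) -> np.ndarray:
    """Null-expected co-occurrence <f> = p.T p / N."""
    p = null.p
    return p.T @ p / p.shape[0]


def sigma_freq(null: NullModel) -> np.ndarray:
    """Error-propagated SE of f under independent Bernoulli cells.

    f_munu is a mean of N independent Bernoulli products with success
    probabilities p_am * p_an, so
    sigma^2 = sum_a p_am p_an (1 - p_am p_an) / N^2.
    """
    p = null.p
    N = p.shape[0]
    first = p.T @ p  # sum_a p_am p_an
    second = (p * p).T @ (p * p)  # sum_a (p_am p_an)^2
    var = (first - second) / N**2
    return np.sqrt(np.clip(var, 0.0, None))


def z_scores(
    f: np.ndarray, f_null: np.ndarray, sigma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(f - <f>) / sigma; cells with sigma == 0 are flagged and set to 0."""
    undefined = sigma == 0
    z = np.zeros_like(f, dtype=float)
    np.divide(f - f_null, sigma, out=z, where=~undefined)
    return z, undefined


def compute_stats(A: np.ndarray, null: NullModel | None = None) -> CooccurrenceStats:
    """Full observed-vs-null pipeline for an occurrence matrix A."""
    f = cooccurrence_freq(A)
    if null is None:
        null = fit_null(A)
    f_null = expected_freq(null)
    sigma = sigma_freq(null)
    z, undefined = z_scores(f, f_null, sigma)
    return CooccurrenceStats(
        f=f, f_null=f_null, sigma=sigma, z=z, n_rows=np.asarray(A).shape[0],
        undefined=undefined,
    )


def qq_points(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal QQ points for the off-diagonal z values.

    Returns (theoretical, observed) with plotting positions (i - 0.5) / n;
    used to pick the z threshold by inspection.
    """
    from scipy.stats import norm

    z = np.asarray(z, dtype=float)
    if z.ndim == 2:
        iu = np.triu_indices_from(z, k=1)
        vals = z[iu]
    else:
        vals = z
    vals = np.sort(vals[np.isfinite(vals)])
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 finite z values")
    theo = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, vals


def build_graph(
    z: np.ndarray,
    threshold: float,
    labels: list[str],
    response_correlations: np.ndarray | None = None,
    signs: list[str] | None = None,
) -> nx.Graph:
    """Co-occurrence graph: edges where z exceeds the threshold (strict).

    Nodes are the perturbations involved in at least one significant pair;
    edges carry the z value and (if given) the response-profile correlation,
    nodes carry sign and degree attributes.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    z = np.asarray(z, dtype=float)
    P = z.shape[0]
    G = nx.Graph()
    for mu in range(P):
        for nu in range(mu + 1, P):
            if z[mu, nu] > threshold:
                G.add_edge(
                    labels[mu],
                    labels[nu],
                    z=float(z[mu, nu]),
                    correlation=(
                        float(response_correlations[mu, nu])
                        if response_correlations is not None
                        else float("nan")
                    ),
                )
    for idx, lab in enumerate(labels):
        if lab in G:
            if signs is not None:
                G.nodes[lab]["sign"] = signs[idx]
            G.nodes[lab]["degree"] = G.degree(lab)
    return G


def sample_null(null: NullModel, rng: np.random.Generator) -> np.ndarray:
    """Draw one binary matrix from the fitted null (independent Bernoulli)."""
    return (rng.random(null.p.shape) < null.p).astype(int)
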