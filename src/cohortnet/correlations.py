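"""The four association estimators run on a filtered OTU table.

* :func:`pearson_matrix` — Pearson correlation of relative abundances with
  Benjamini-Hochberg adjusted two-sided p-values.
* :func:`sparcc` — compositionally aware basis correlations estimated from
  log-ratio variances (Dirichlet-smoothed fractions, linear basis solve,
  iterative strongly-correlated-pair exclusion), with
  :func:`sparcc_pvalues` producing two-sided bootstrap pseudo p-values.
* :func:`dice_sorensen` — presence/absence co-occurrence index.
* :func:`mb_network` — sparse neighborhood selection (lasso regressions on
  CLR-transformed counts) with StARS stability selection of the penalty.

Coefficient matrices are symmetric with the diagonal never treated as an
edge.  Undefined entries (zero-variance OTUs, empty presence vectors) are
NaN and excluded from multiple-testing counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path
from statsmodels.stats.multitest import multipletests

from .otu_table import InvalidArgumentError, OtuTable

logger = logging.getLogger("cohortnet")


@dataclass
class CorrelationResult:
    """Per-method symmetric coefficient/support matrices.

    ``coef``/``p_raw``/``p_adj`` are OTU x OTU DataFrames (absent where the
    method does not produce them); ``support`` and ``sign`` are produced by
    the mb graph method (boolean adjacency and -1/0/+1 edge signs).
    """

    method: str
    otus: list
    coef: pd.DataFrame | None = None
    p_raw: pd.DataFrame | None = None
    p_adj: pd.DataFrame | None = None
    support: pd.DataFrame | None = None
    sign: pd.DataFrame | None = None

    def to_long(self) -> pd.DataFrame:
        """Long-format upper-triangle edge table (one row per OTU pair)."""
        ids = self.otus
        iu, ju = np.triu_indices(len(ids), k=1)
        rows = dict(
            otu_i=[ids[a] for a in iu], otu_j=[ids[b] for b in ju],
            method=self.method)
        for name in ("coef", "p_raw", "p_adj"):
            m = getattr(self, name)
            rows[name] = m.to_numpy()[iu, ju] if m is not None else np.nan
        rows["sign"] = (self.sign.to_numpy()[iu, ju]
                        if self.sign is not None else np.nan)
        rows["support"] = (self.support.to_numpy()[iu, ju]
                           if self.support is not None else np.nan)
        return pd.DataFrame(rows)


def _sym_df(arr: np.ndarray, ids) -> pd.DataFrame:
    return pd.DataFrame(arr, index=list(ids), columns=list(ids))


def bh_adjust_matrix(p: np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """BH (or BY) step-up adjustment over the upper triangle of ``p``.

    NaN entries are excluded from the number of tests.  Returns a symmetric
    matrix with NaN preserved.
    """
    d = p.shape[0]
    iu, ju = np.triu_indices(d, k=1)
    raw = p[iu, ju]
    adj = np.full_like(raw, np.nan, dtype=float)
    ok = ~np.isnan(raw)
    if ok.any():
        adj[ok] = multipletests(raw[ok], method=method)[1]
    out = np.full_like(p, np.nan, dtype=float)
    out[iu, ju] = adj
    out[ju, iu] = adj
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------


def pearson_matrix(table: OtuTable, adjust: str = "fdr_bh") -> CorrelationResult:
    """Pairwise Pearson r of relative abundances with adjusted p-values.

    Zero-variance OTUs get NaN coefficients and are excluded from the
    multiple-testing count.
    """
    n = table.n_samples
    if n < 3:
        raise InvalidArgumentError("Pearson needs at least 3 samples")
    x = table.proportions.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    good = sd > 0
    z = np.where(good, xc / np.where(sd > 0, sd, 1.0), np.nan)
    r = (z.T @ z) / n
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, 0.0)
    ids = list(table.counts.columns)
    return CorrelationResult("pearson", ids, coef=_sym_df(r, ids),
                             p_raw=_sym_df(p, ids),
                             p_adj=_sym_df(bh_adjust_matrix(p, adjust), ids))


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------


def clr_transform(table: OtuTable | pd.DataFrame | np.ndarray,
                  pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform: log(count + pc) minus the row mean log."""
    if pseudocount <= 0:
        raise InvalidArgumentError("pseudocount must be > 0")
    if isinstance(table, OtuTable):
        arr = table.counts.to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    logx = np.log(arr + pseudocount)
    return logx - logx.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------


@dataclass
class SparccState:
    """Intermediates of the SparCC basis solve."""

    T: np.ndarray                  # log-ratio variance matrix t_ij
    omega: np.ndarray              # basis variances
    rho: np.ndarray                # basis correlations, clipped to [-1, 1]
    excluded_pairs: set = field(default_factory=set)
    iterations_used: int = 0
    floored_components: list = field(default_factory=list)


def estimate_variation_matrix(counts: np.ndarray, max_iter: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Mean log-ratio variance matrix over ``max_iter`` Dirichlet draws.

    Per draw, fractions are sampled from Dirichlet(counts + 1) per sample and
    t_ij = Var_s(log(x_is / x_js)) computed via the log-covariance identity
    t_ij = v_i + v_j - 2 c_ij.
    """
    n, d = counts.shape
    acc = np.zeros((d, d))
    for _ in range(max_iter):
        g = rng.gamma(counts + 1.0)
        fracs = g / g.sum(axis=1, keepdims=True)
        logf = np.log(fracs)
        c = np.cov(logf, rowvar=False)
        v = np.diag(c)
        acc += v[:, None] + v[None, :] - 2.0 * c
    t = acc / max_iter
    np.fill_diagonal(t, 0.0)
    return t


def basis_correlations(T: np.ndarray, th: float = 0.1, exiter: int = 10,
                       omega_floor: float = 1e-10) -> SparccState:
    """Solve basis variances and correlations from a variation matrix.

    Under the sparsity approximation t_ij ~ omega_i + omega_j the basis
    variances solve the linear system ``M omega = rowsum(T)`` with
    ``M = diag(degree) + A`` over currently included pairs.  Basis
    correlations follow as ``rho_ij = (omega_i + omega_j - t_ij) /
    (2 sqrt(omega_i omega_j))``.  Up to ``exiter`` exclusion rounds remove
    the most strongly correlated pair while ``max |rho| > th``; negative
    solved variances are floored and flagged.
    """
    T = np.asarray(T, dtype=float)
    d = T.shape[0]
    if d < 3:
        raise InvalidArgumentError("basis solve needs at least 3 components")
    include = np.ones((d, d), dtype=bool)
    np.fill_diagonal(include, False)
    excluded: set = set()
    floored: list = []
    rho = np.zeros((d, d))
    omega = np.zeros(d)
    rounds = 0
    for rounds in range(exiter + 1):
        deg = include.sum(axis=1).astype(float)
        M = include.astype(float)
        np.fill_diagonal(M, np.maximum(deg, 1.0))
        trow = (T * include).sum(axis=1)
        omega = np.linalg.solve(M, trow)
        bad = omega <= 0
        if bad.any():
            floored = list(np.where(bad)[0])
            omega = np.where(bad, omega_floor, omega)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = np.clip((omega[:, None] + omega[None, :] - T) / denom, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)

        if rounds == exiter:
            break
        cand = np.abs(np.where(include, rho, 0.0))
        np.fill_diagonal(cand, 0.0)
        mx = cand.max()
        if mx <= th:
            break
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        include[i, j] = include[j, i] = False
        excluded.add((min(i, j), max(i, j)))
    return SparccState(T=T, omega=omega, rho=rho, excluded_pairs=excluded,
                       iterations_used=rounds, floored_components=floored)


def sparcc(table: OtuTable, max_iter: int = 100, th: float = 0.1,
           exiter: int = 10, seed: int = 0) -> tuple[CorrelationResult, SparccState]:
    """SparCC basis correlations for an OTU count table."""
    if table.n_otus < 4:
        raise InvalidArgumentError("SparCC needs at least 4 OTUs")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy(dtype=float)
    T = estimate_variation_matrix(counts, max_iter, rng)
    state = basis_correlations(T, th=th, exiter=exiter)
    ids = list(table.counts.columns)
    return CorrelationResult("sparcc", ids, coef=_sym_df(state.rho, ids)), state


def sparcc_pvalues(table: OtuTable, n_boot: int = 100, seed: int = 0,
                   max_iter: int = 100, th: float = 0.1, exiter: int = 10,
                   observed: np.ndarray | None = None,
                   adjust: str = "fdr_bh") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided bootstrap pseudo p-values for SparCC correlations.

    Bootstrap tables resample each OTU's counts independently across samples,
    destroying cross-OTU association while keeping marginals; the pseudo
    p-value is the two-sided exceedance fraction with the +1/(n_boot+1)
    continuity correction, so the smallest attainable value is 1/(n_boot+1).
    """
    if n_boot < 1:
        raise InvalidArgumentError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy(dtype=float)
    n, d = counts.shape
    if observed is None:
        T = estimate_variation_matrix(counts, max_iter, rng)
        observed = basis_correlations(T, th=th, exiter=exiter).rho
    exceed = np.zeros((d, d))
    for _ in range(n_boot):
        boot = np.empty_like(counts)
        for k in range(d):
            boot[:, k] = counts[rng.integers(0, n, n), k]
        Tb = estimate_variation_matrix(boot, max_iter, rng)
        rho_b = basis_correlations(Tb, th=th, exiter=exiter).rho
        exceed += np.abs(rho_b) >= np.abs(observed)
    p = (exceed + 1.0) / (n_boot + 1.0)
    np.fill_diagonal(p, 0.0)
    ids = list(table.counts.columns)
    return _sym_df(p, ids), _sym_df(bh_adjust_matrix(p, adjust), ids)


def sparcc_with_pvalues(table: OtuTable, max_iter: int = 100, th: float = 0.1,
                        exiter: int = 10, n_boot: int = 100, seed: int = 0,
                        ) -> tuple[CorrelationResult, SparccState]:
    """SparCC coefficients plus bootstrap pseudo p-values in one result."""
    res, state = sparcc(table, max_iter=max_iter, th=th, exiter=exiter, seed=seed)
    p_raw, p_adj = sparcc_pvalues(table, n_boot=n_boot, seed=seed + 1,
                                  max_iter=max_iter, th=th, exiter=exiter,
                                  observed=state.rho)
    res.p_raw, res.p_adj = p_raw, p_adj
    return res, state


# ---------------------------------------------------------------------------
# Dice-Sorensen
# ---------------------------------------------------------------------------


def dice_sorensen(table: OtuTable) -> CorrelationResult:
    """Dice-Sorensen index on the binarized (count > 0) table.

    ``coef = 2|a & b| / (|a| + |b|)`` for presence sets a, b; pairs involving
    an OTU absent from every sample are NaN (undefined).
    """
    b = (table.counts.to_numpy() > 0).astype(float)
    inter = b.T @ b
    sizes = b.sum(axis=0)
    denom = sizes[:, None] + sizes[None, :]
    defined = (sizes[:, None] > 0) & (sizes[None, :] > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.where(defined, 2.0 * inter / np.maximum(denom, 1), np.nan)
    coef[np.diag_indices_from(coef)] = np.where(sizes > 0, 1.0, np.nan)
    ids = list(table.counts.columns)
    return CorrelationResult("dice", ids, coef=_sym_df(coef, ids))


# ---------------------------------------------------------------------------
# neighborhood selection (mb) with StARS
# ---------------------------------------------------------------------------


@dataclass
class StarsState:
    """StARS selection path: penalties, instabilities, and the chosen one."""

    lambda_path: np.ndarray        # strictly decreasing
    instability: np.ndarray        # mean edge instability per lambda
    monotone_instability: np.ndarray
    beta: float
    selected_lambda: float
    selected_index: int
    subsample_size: int
    n_reps: int


def _neighborhood_adjacency(X: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Boolean (nlambda, d, d) neighborhood indicators from per-node lassos."""
    n, d = X.shape
    nl = len(alphas)
    adj = np.zeros((nl, d, d), dtype=bool)
    cols = np.arange(d)
    for i in range(d):
        others = cols[cols != i]
        alphas_out, coefs, _ = lasso_path(X[:, others], X[:, i], alphas=alphas)
        order = np.argsort(-alphas_out)        # ensure descending-lambda order
        coefs = coefs[:, order]
        nz = coefs != 0                        # (d-1, nlambda)
        for l in range(nl):
            adj[l, i, others] = nz[:, l]
    return adj


def _neighborhood_coefs(X: np.ndarray, alpha: float) -> np.ndarray:
    """Full (d, d) lasso coefficient matrix B at a single penalty."""
    n, d = X.shape
    B = np.zeros((d, d))
    cols = np.arange(d)
    for i in range(d):
        others = cols[cols != i]
        _, coefs, _ = lasso_path(X[:, others], X[:, i], alphas=[alpha])
        B[i, others] = coefs[:, 0]
    return B


def mb_network(table: OtuTable, nlambda: int = 20,
               lambda_min_ratio: float = 1e-2, n_reps: int = 50,
               beta: float = 0.05, seed: int = 0, pseudocount: float = 1.0,
               symmetrize: str = "or") -> tuple[CorrelationResult, StarsState]:
    """Sparse neighborhood-selection graph with StARS penalty selection.

    CLR-transform the counts, then for each OTU run an L1-penalized
    regression on all others over a geometric penalty path of ``nlambda``
    values from the smallest penalty giving empty neighborhoods down by
    ``lambda_min_ratio``.  StARS draws ``n_reps`` subsamples of size
    ``min(floor(10 sqrt(n)), floor(0.8 n))``, measures per-penalty mean edge
    instability ``2 theta (1 - theta)`` over subsample edge frequencies
    ``theta``, and selects the densest penalty whose running-supremum
    instability stays at or below ``beta``.  The final graph refits on the
    full data at the selected penalty; neighborhoods are OR-combined (AND
    via ``symmetrize="and"``) and each edge's sign is the sign of the mean
    of its two regression coefficients.
    """
    if nlambda < 2:
        raise InvalidArgumentError("nlambda must be >= 2")
    if symmetrize not in ("or", "and"):
        raise InvalidArgumentError("symmetrize must be 'or' or 'and'")
    rng = np.random.default_rng(seed)
    X = clr_transform(table, pseudocount=pseudocount)
    X = X - X.mean(axis=0)
    n, d = X.shape

    lam_max = 0.0
    cols = np.arange(d)
    for i in range(d):
        others = cols[cols != i]
        lam_max = max(lam_max, np.abs(X[:, others].T @ X[:, i]).max() / n)
    if lam_max == 0.0:
        lam_max = 1.0
    path = lam_max * lambda_min_ratio ** (np.arange(nlambda) / (nlambda - 1))

    b = min(int(np.floor(10.0 * np.sqrt(n))), int(np.floor(0.8 * n)))
    if b < 3:
        b = max(3, int(np.floor(0.8 * n)))
        logger.warning("mb_network: n=%d too small for StARS subsampling; "
                       "using subsample size %d", n, b)

    freq = np.zeros((nlambda, d, d))
    for _ in range(n_reps):
        idx = rng.choice(n, size=b, replace=False)
        Xs = X[idx] - X[idx].mean(axis=0)
        adj = _neighborhood_adjacency(Xs, path)
        adj = adj | np.transpose(adj, (0, 2, 1))
        freq += adj
    theta = freq / n_reps
    xi = 2.0 * theta * (1.0 - theta)
    iu, ju = np.triu_indices(d, k=1)
    instability = xi[:, iu, ju].mean(axis=1)
    monotone = np.maximum.accumulate(instability)
    ok = np.where(monotone <= beta)[0]
    sel = int(ok[-1]) if len(ok) else 0

    B = _neighborhood_coefs(X, path[sel])
    support = (B != 0) | (B.T != 0) if symmetrize == "or" else (B != 0) & (B.T != 0)
    np.fill_diagonal(support, False)
    sign = np.where(support, np.sign(B + B.T), 0).astype(int)

    ids = list(table.counts.columns)
    state = StarsState(lambda_path=path, instability=instability,
                       monotone_instability=monotone, beta=beta,
                       selected_lambda=float(path[sel]), selected_index=sel,
                       subsample_size=b, n_reps=n_reps)
    res = CorrelationResult("mb", ids, support=_sym_df(support, ids),
                            sign=_sym_df(sign, ids))
    return res, state
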