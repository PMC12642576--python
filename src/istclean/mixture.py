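"""Per-cell two-component Poisson mixture and the denoising filter.

Each cell's gene counts are modelled as a mixture of two Poisson components:
an *endogenous* component for genes the cell truly expresses and a
*contamination* component for genes observed only through segmentation
spillover or ambient signal.  Both component means are tied to the cell's
spatial context ``x⁺`` (neighbour sums plus global background, see
:mod:`istclean.spatial`):

* ``multiplicative`` (default): mean = ``(x⁺_j + 1) · λ`` (one molecule of
  pseudo-context), so ``λ_c`` is the fraction of the surrounding signal
  that leaks into the cell and is expected to be ~0 without contamination;
* ``additive``: mean = ``x⁺_j + λ``, the literal offset form; with
  ``x⁺ ≡ 0`` this reduces exactly to a plain two-component Poisson mixture.

The latent indicator ``Z_ij`` (gene endogenously expressed) has prior
``π_i``; EM with multiple restarts yields MLEs, the posterior
``α_ij = P(Z_ij = 1 | x)`` is computed per gene, and counts with
``α_ij ≤ cutoff`` (default 0.75, inclusive) are set to zero.  The output is
therefore integer-valued: every count is kept whole or removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, special

from ._errors import ValidationError
from .config import RunConfig
from . import spatial

logger = logging.getLogger(__name__)

#: Smallest admissible Poisson rate parameter; prevents zero-mean degeneracy.
LAMBDA_FLOOR: float = 1e-6
#: Pseudo-context (molecules) added to x⁺ in multiplicative mode.  It keeps
#: the likelihood well defined and informative for zero-context genes (a
#: zero count then has probability e^{-λ} exactly as in the additive model),
#: which makes the component labels identifiable for isolated cells.
OFFSET_PSEUDO: float = 1.0
#: π is kept inside this open interval so both components stay alive.
PI_MIN: float = 1e-4
PI_MAX: float = 1.0 - 1e-4

DEFAULT_ALPHA_CUTOFF: float = 0.75
#: Largest multiplicative contamination rate still interpretable as leakage.
#: λ_c is the fraction of the total surrounding signal (neighbour sum plus
#: background) that reappears inside the cell; per-neighbour spill
#: probabilities observed with poor segmentation stay well below ~0.25 of
#: the whole neighbourhood, whereas fits with λ_c beyond it invariably mean
#: the second component has absorbed expression variability instead of
#: contamination.  Cells with such fits pass through unfiltered.
LAMBDA_C_MAX: float = 0.25
#: In additive mode the analogous degeneracy is a fit with effectively
#: coincident rates (often both at the floor), where α equals the prior π;
#: cells whose rates differ by less than this ratio pass through.
ADDITIVE_SEPARATION_RATIO: float = 0.95
DEFAULT_N_RESTARTS: int = 10
DEFAULT_OFFSET_MODE: str = "multiplicative"
EM_TOL: float = 1e-6
EM_MAX_ITER: int = 200


@dataclass
class CellMixtureParams:
    """Per-cell mixture parameters with the identifiability ordering
    ``λ_e ≥ λ_c ≥ λ_floor`` enforced at construction."""

    pi: float
    lam_e: float
    lam_c: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pi < 1.0):
            raise ValidationError(f"pi must be in (0, 1), got {self.pi}")
        if not (self.lam_e >= self.lam_c >= LAMBDA_FLOOR):
            raise ValidationError(
                f"need lam_e >= lam_c >= {LAMBDA_FLOOR}, got "
                f"lam_e={self.lam_e}, lam_c={self.lam_c}"
            )
        for v in (self.pi, self.lam_e, self.lam_c):
            if not math.isfinite(v):
                raise ValidationError("non-finite mixture parameter")


@dataclass
class CellMixtureFit:
    params: CellMixtureParams | None
    log_likelihood: float
    n_iter: int
    converged: bool
    restart_index: int
    skipped: bool = False
    skip_reason: str | None = None


@dataclass
class DenoiseResult:
    """Output bundle of :func:`denoise`.

    ``adjusted`` holds integer counts with contamination zeroed; every entry
    equals the raw count or zero.  ``posterior`` is dense ``α`` with NaN
    rows for skipped cells.  ``fits`` is one row per cell.
    """

    adjusted: sparse.csr_matrix
    posterior: np.ndarray
    fits: pd.DataFrame
    report: dict
    cell_ids: list[str] = field(default_factory=list)
    gene_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# likelihood machinery (vectorised over restarts internally)
# ---------------------------------------------------------------------------

def _component_means(xplus: np.ndarray, lam: np.ndarray, mode: str) -> np.ndarray:
    """Component mean per gene; ``lam`` broadcasts over leading axes."""
    if mode == "additive":
        return xplus + lam
    if mode == "multiplicative":
        return (xplus + OFFSET_PSEUDO) * lam
    raise ValidationError(f"unknown offset_mode {mode!r}")


def _e_step_arrays(
    x: np.ndarray,
    xplus: np.ndarray,
    pi: np.ndarray,
    lam_e: np.ndarray,
    lam_c: np.ndarray,
    mode: str,
    log_fact: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior and log-likelihood for R parameter sets at once.

    ``pi, lam_e, lam_c`` are (R,), ``x, xplus, log_fact`` are (G,); returns
    ``alpha`` (R, G) and ``ll`` (R,).
    """
    me = _component_means(xplus[None, :], lam_e[:, None], mode)
    mc = _component_means(xplus[None, :], lam_c[:, None], mode)
    if np.any(me <= 0) or np.any(mc <= 0):
        raise ValidationError("non-positive Poisson mean; parameter floor violated")
    log_a = np.log(pi)[:, None] + x[None, :] * np.log(me) - me
    log_b = np.log1p(-pi)[:, None] + x[None, :] * np.log(mc) - mc
    m = np.maximum(log_a, log_b)
    lse = m + np.log(np.exp(log_a - m) + np.exp(log_b - m))
    alpha = np.exp(log_a - lse)
    ll = (lse - log_fact[None, :]).sum(axis=1)
    return alpha, ll


def _additive_rate_root(
    x: np.ndarray, xplus: np.ndarray, w: np.ndarray
) -> float:
    """Solve ``Σ_j w_j·[x_j/(x⁺_j+λ) − 1] = 0`` for λ on [floor, max(x)+1].

    The score is strictly decreasing in λ, so a sign check at the floor
    decides whether the bracketed root exists.
    """
    wsum = w.sum()
    if wsum <= 1e-12:
        logger.debug("all-zero component weights; rate set to floor")
        return LAMBDA_FLOOR

    def score(lam: float) -> float:
        return float((w * x / (xplus + lam)).sum() - wsum)

    if score(LAMBDA_FLOOR) <= 0.0:
        return LAMBDA_FLOOR
    hi = float(x.max()) + 1.0
    return float(optimize.brentq(score, LAMBDA_FLOOR, hi, xtol=1e-10, rtol=1e-12))


def _m_step_arrays(
    x: np.ndarray,
    xplus: np.ndarray,
    alpha: np.ndarray,
    mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximise the expected complete-data log-likelihood; (R, G) alpha in,
    (R,) parameter vectors out, re-ordered so ``lam_e >= lam_c``."""
    pi = np.clip(alpha.mean(axis=1), PI_MIN, PI_MAX)
    if mode == "multiplicative":
        xf = xplus + OFFSET_PSEUDO
        num_e = (alpha * x[None, :]).sum(axis=1)
        den_e = (alpha * xf[None, :]).sum(axis=1)
        num_c = x.sum() - num_e
        den_c = xf.sum() - den_e
        with np.errstate(divide="ignore", invalid="ignore"):
            lam_e = np.where(den_e > 1e-12, num_e / np.maximum(den_e, 1e-300), LAMBDA_FLOOR)
            lam_c = np.where(den_c > 1e-12, num_c / np.maximum(den_c, 1e-300), LAMBDA_FLOOR)
        lam_e = np.maximum(lam_e, LAMBDA_FLOOR)
        lam_c = np.maximum(lam_c, LAMBDA_FLOOR)
    else:
        R = alpha.shape[0]
        lam_e = np.empty(R)
        lam_c = np.empty(R)
        for r in range(R):
            lam_e[r] = _additive_rate_root(x, xplus, alpha[r])
            lam_c[r] = _additive_rate_root(x, xplus, 1.0 - alpha[r])
    flip = lam_c > lam_e
    if flip.any():
        lam_e2 = np.where(flip, lam_c, lam_e)
        lam_c2 = np.where(flip, lam_e, lam_c)
        pi = np.where(flip, 1.0 - pi, pi)
        lam_e, lam_c = lam_e2, lam_c2
    return pi, lam_e, lam_c


# ---------------------------------------------------------------------------
# public single-parameter-set operations
# ---------------------------------------------------------------------------

def _check_vectors(x, xplus) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    xplus = np.asarray(xplus, dtype=float).ravel()
    if x.shape != xplus.shape:
        raise ValidationError(
            f"count vector has {x.size} genes but offset vector {xplus.size}"
        )
    if (xplus < 0).any():
        raise ValidationError("offsets must be non-negative")
    return x, xplus


def cell_log_likelihood(
    x, xplus, params: CellMixtureParams, offset_mode: str = DEFAULT_OFFSET_MODE
) -> float:
    """Mixture log-likelihood of one cell's counts, log-sum-exp stabilised."""
    x, xplus = _check_vectors(x, xplus)
    log_fact = special.gammaln(x + 1.0)
    _, ll = _e_step_arrays(
        x, xplus,
        np.array([params.pi]), np.array([params.lam_e]), np.array([params.lam_c]),
        offset_mode, log_fact,
    )
    return float(ll[0])


def e_step(
    x, xplus, params: CellMixtureParams, offset_mode: str = DEFAULT_OFFSET_MODE
) -> tuple[np.ndarray, float]:
    """Posterior ``α_j = P(Z_j = 1 | x_j)`` and the current log-likelihood."""
    x, xplus = _check_vectors(x, xplus)
    log_fact = special.gammaln(x + 1.0)
    alpha, ll = _e_step_arrays(
        x, xplus,
        np.array([params.pi]), np.array([params.lam_e]), np.array([params.lam_c]),
        offset_mode, log_fact,
    )
    return alpha[0], float(ll[0])


def m_step(
    x, xplus, alpha, offset_mode: str = DEFAULT_OFFSET_MODE
) -> CellMixtureParams:
    """Update ``(π, λ_e, λ_c)`` from the posterior responsibilities.

    ``π`` is the mean responsibility (clamped open); each rate maximises the
    weighted Poisson likelihood — closed form in multiplicative mode,
    bracketed 1-D root finding in additive mode.
    """
    x, xplus = _check_vectors(x, xplus)
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.shape != x.shape:
        raise ValidationError("alpha and x must have equal length")
    if ((alpha < 0) | (alpha > 1)).any():
        raise ValidationError("alpha must lie in [0, 1]")
    pi, lam_e, lam_c = _m_step_arrays(x, xplus, alpha[None, :], offset_mode)
    return CellMixtureParams(pi=float(pi[0]), lam_e=float(lam_e[0]), lam_c=float(lam_c[0]))


def contamination_evidence(params: CellMixtureParams, offset_mode: str) -> bool:
    """Whether a fitted mixture supports filtering at all.

    A two-component fit on a cell without contamination still splits the
    sampling noise of expression, but the resulting "contamination"
    component is not contamination-like: in multiplicative mode its rate
    λ_c lands far above any plausible leakage fraction
    (:data:`LAMBDA_C_MAX`), and in additive mode the two rates coincide
    (α degenerates to the prior π).  In either case filtering would act on
    noise, so the caller passes the cell through unchanged.
    """
    if offset_mode == "multiplicative":
        return params.lam_c <= LAMBDA_C_MAX
    return params.lam_c < ADDITIVE_SEPARATION_RATIO * params.lam_e


# ---------------------------------------------------------------------------
# restart-based fit
# ---------------------------------------------------------------------------

def _init_rates(
    x: np.ndarray, xplus: np.ndarray, pi0: float, mode: str
) -> tuple[float, float]:
    """Seed the rates from π₀: genes most in excess of their context seed the
    endogenous rate, the rest the contamination rate."""
    G = len(x)
    k = max(1, min(G - 1, int(math.ceil(pi0 * G))))
    if mode == "additive":
        resid = x - xplus
        order = np.argsort(-resid, kind="stable")
        top, rest = order[:k], order[k:]
        lam_e = max(float(resid[top].mean()), 1.0)
        lam_c = max(float(resid[rest].mean()), LAMBDA_FLOOR)
    else:
        xf = xplus + OFFSET_PSEUDO
        ratio = x / xf
        order = np.argsort(-ratio, kind="stable")
        top, rest = order[:k], order[k:]
        lam_e = max(float(x[top].sum() / xf[top].sum()), 10 * LAMBDA_FLOOR)
        lam_c = max(float(x[rest].sum() / xf[rest].sum()), LAMBDA_FLOOR)
    if lam_c > lam_e:
        lam_e, lam_c = lam_c, lam_e
    return lam_e, lam_c


def fit_cell_mixture(
    x,
    xplus,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed=0,
    offset_mode: str = DEFAULT_OFFSET_MODE,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> tuple[CellMixtureFit, np.ndarray]:
    """EM fit of one cell with multiple restarts.

    Each restart draws ``π₀ ~ Unif(0, 0.5)``, seeds the rates from it and
    iterates E/M until the relative log-likelihood change falls below
    ``tol`` or ``max_iter`` is reached.  The restart with the highest final
    log-likelihood wins (ties break toward the lower restart index), making
    the result independent of restart execution order.  ``seed`` may be an
    integer or anything :func:`numpy.random.default_rng` accepts.
    """
    x, xplus = _check_vectors(x, xplus)
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    pi0s = rng.uniform(0.0, 0.5, size=n_restarts)
    pi0s = np.clip(pi0s, PI_MIN, PI_MAX)
    log_fact = special.gammaln(x + 1.0)

    lam_e = np.empty(n_restarts)
    lam_c = np.empty(n_restarts)
    for r, p0 in enumerate(pi0s):
        lam_e[r], lam_c[r] = _init_rates(x, xplus, float(p0), offset_mode)
    pi = pi0s.copy()

    alpha, ll_prev = _e_step_arrays(x, xplus, pi, lam_e, lam_c, offset_mode, log_fact)
    converged = np.zeros(n_restarts, dtype=bool)
    n_iter = np.full(n_restarts, 0, dtype=int)
    for it in range(1, max_iter + 1):
        pi, lam_e, lam_c = _m_step_arrays(x, xplus, alpha, offset_mode)
        alpha, ll = _e_step_arrays(x, xplus, pi, lam_e, lam_c, offset_mode, log_fact)
        rel = np.abs(ll - ll_prev) / (np.abs(ll) + 1e-300)
        newly = (~converged) & (rel < tol)
        n_iter[newly] = it
        converged |= newly
        ll_prev = ll
        if converged.all():
            break
    n_iter[~converged] = max_iter

    best = int(np.argmax(ll))
    if not converged[best]:
        logger.debug("best restart did not converge within %d iterations", max_iter)
    params = CellMixtureParams(
        pi=float(pi[best]), lam_e=float(lam_e[best]), lam_c=float(lam_c[best])
    )
    alpha_best, ll_best = _e_step_arrays(
        x, xplus,
        np.array([params.pi]), np.array([params.lam_e]), np.array([params.lam_c]),
        offset_mode, log_fact,
    )
    fit = CellMixtureFit(
        params=params,
        log_likelihood=float(ll_best[0]),
        n_iter=int(n_iter[best]),
        converged=bool(converged[best]),
        restart_index=best,
    )
    return fit, alpha_best[0]


def filter_cell(x, alpha, cutoff: float = DEFAULT_ALPHA_CUTOFF) -> np.ndarray:
    """Zero every count whose posterior is ``<= cutoff`` (inclusive)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValidationError(f"cutoff must be in [0, 1], got {cutoff}")
    x = np.asarray(x)
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.shape != x.shape:
        raise ValidationError("alpha and x must have equal length")
    return np.where(alpha <= cutoff, np.zeros_like(x), x)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def denoise(
    counts,
    cells: pd.DataFrame,
    tx: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    gene_names: list[str] | None = None,
) -> DenoiseResult:
    """Full denoising pass: spatial context, per-cell fits, filtering.

    Parameters
    ----------
    counts
        Cells × genes integer matrix (dense or sparse), rows aligned with
        ``cells``.
    cells
        Cell table with ``cell_id``, ``x``, ``y`` (μm).
    tx
        Optional transcript table (``x``, ``y``, ``gene``) for the global
        background estimate; without it the global offset is zero.
    config
        :class:`~istclean.config.RunConfig`; defaults apply when omitted.

    Cells with fewer than ``config.min_nonzero_genes`` expressed genes are
    passed through unchanged (``skipped=True``, posterior row NaN).  Cells
    whose best fit carries no contamination-like component (see
    :func:`contamination_evidence`) also pass through; their count is
    reported as ``n_no_separation``.  Each
    cell's restarts use an RNG stream derived from the master seed and the
    cell index, so results do not depend on evaluation order.
    """
    cfg = config or RunConfig()
    spatial.validate_cell_table(cells)
    X = counts.toarray() if sparse.issparse(counts) else np.asarray(counts)
    if X.ndim != 2 or X.shape[0] != len(cells):
        raise ValidationError(
            f"count matrix shape {X.shape} does not match {len(cells)} cells"
        )
    n, g = X.shape
    if n < 1 or g < 2:
        raise ValidationError("need at least 1 cell and 2 genes")
    if not np.issubdtype(X.dtype, np.integer):
        if not np.allclose(X, np.round(X)):
            raise ValidationError("count matrix must be integer-valued")
        X = np.round(X).astype(np.int64)
    if (X < 0).any():
        raise ValidationError("count matrix must be non-negative")
    if gene_names is None:
        gene_names = [f"gene_{j}" for j in range(g)]

    warnings_log: list[str] = []
    nbrs = spatial.build_neighborhood_index(cells, d=cfg.radius_um)
    bg = None
    bg_info: dict = {"used": False}
    if tx is not None:
        grid = spatial.hexbin_transcripts(tx, cfg.n_hexbins, gene_names=gene_names)
        gmm = spatial.fit_background_gmm(grid.bin_totals, seed=cfg.seed)
        bg = spatial.compute_background_profile(grid, gmm, d=cfg.radius_um)
        bg_info = {
            "used": True,
            "n_bins": grid.n_bins,
            "n_background_bins": int(len(gmm.background_bins)),
            "background_weight": gmm.background_weight,
            "background_mean_total": float(gmm.means[gmm.background_component]),
        }
    else:
        warnings_log.append("no transcript table; global background disabled")
    xplus = spatial.compute_offsets(X, nbrs, bg, gene_names=gene_names)

    adjusted = X.copy()
    posterior = np.full((n, g), np.nan)
    rows = []
    n_skipped = 0
    n_no_separation = 0
    for i in range(n):
        xi = X[i].astype(float)
        nz = int((xi > 0).sum())
        cid = str(cells["cell_id"].iloc[i])
        if nz < cfg.min_nonzero_genes:
            n_skipped += 1
            rows.append(
                dict(cell_id=cid, pi=np.nan, lambda_e=np.nan, lambda_c=np.nan,
                     loglik=np.nan, n_iter=0, converged=False, skipped=True)
            )
            continue
        fit, alpha = fit_cell_mixture(
            xi, xplus[i],
            n_restarts=cfg.n_restarts,
            seed=[cfg.seed, i],
            offset_mode=cfg.offset_mode,
        )
        posterior[i] = alpha
        if contamination_evidence(fit.params, cfg.offset_mode):
            adjusted[i] = filter_cell(X[i], alpha, cutoff=cfg.alpha_cutoff)
        else:
            n_no_separation += 1  # no evidence of contamination: keep counts
        rows.append(
            dict(cell_id=cid, pi=fit.params.pi, lambda_e=fit.params.lam_e,
                 lambda_c=fit.params.lam_c, loglik=fit.log_likelihood,
                 n_iter=fit.n_iter, converged=fit.converged, skipped=False)
        )
    fits = pd.DataFrame(rows)
    report = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "n_cells": n,
        "n_genes": g,
        "n_skipped": n_skipped,
        "n_no_separation": n_no_separation,
        "background": bg_info,
        "warnings": warnings_log,
        "total_counts_raw": int(X.sum()),
        "total_counts_adjusted": int(adjusted.sum()),
    }
    return DenoiseResult(
        adjusted=sparse.csr_matrix(adjusted),
        posterior=posterior,
        fits=fits,
        report=report,
        cell_ids=[str(c) for c in cells["cell_id"]],
        gene_names=list(gene_names),
    )
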