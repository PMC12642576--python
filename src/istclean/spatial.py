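"""Spatial context for contamination modelling.

A cell's contamination risk at a gene is driven by how much of that gene is
present *around* the cell.  This module builds that context in two parts:

* **local** — for each cell, the summed counts of every gene over all
  neighbouring cells whose centroids lie within a radius ``d`` (default
  50 μm, inclusive boundary);
* **global** — a per-gene ambient background level estimated by binning the
  decoded transcript molecules into a regular hexagonal lattice, splitting
  the bins into "background" and "tissue" with a two-component Gaussian
  mixture on the bin totals, and averaging each gene over the background
  bins.  The average is rescaled by ``π·d²/A`` (disc area over hexbin area
  ``A``) so it is expressed per neighbourhood-sized area and can be added
  directly to the local sums.

The result is the offset matrix ``x_plus`` (cells × genes) consumed by
:mod:`istclean.mixture`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from ._errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

#: Neighbourhood radius in μm used when none is given.
DEFAULT_RADIUS_UM: float = 50.0
#: Target number of hexagonal bins used when none is given.
DEFAULT_N_HEXBINS: int = 200

_SQRT3 = math.sqrt(3.0)


# ---------------------------------------------------------------------------
# cell table validation
# ---------------------------------------------------------------------------

def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check a cell table (columns ``cell_id``, ``x``, ``y`` in μm).

    Raises :class:`ValidationError` naming the offending cell on non-finite
    coordinates or duplicated ids.
    """
    for col in ("cell_id", "x", "y"):
        if col not in cells.columns:
            raise ValidationError(f"cell table is missing required column {col!r}")
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"duplicate cell_id {dup!r} in cell table")
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        offender = cells["cell_id"].iloc[int(np.flatnonzero(bad)[0])]
        raise ValidationError(
            f"non-finite coordinates for cell_id {offender!r}"
        )
    return cells


# ---------------------------------------------------------------------------
# neighbourhoods
# ---------------------------------------------------------------------------

@dataclass
class NeighborhoodIndex:
    """Per-cell neighbour lists within a fixed radius (self excluded).

    ``neighbors[i]`` holds the integer indices of all cells whose centroid
    is within ``radius`` μm (inclusive) of cell ``i``.  The relation is
    symmetric by construction.
    """

    radius: float
    neighbors: list[np.ndarray]

    @property
    def n_cells(self) -> int:
        return len(self.neighbors)

    def adjacency(self) -> sparse.csr_matrix:
        """Boolean adjacency matrix (no self loops), CSR."""
        n = self.n_cells
        indptr = np.zeros(n + 1, dtype=np.int64)
        indptr[1:] = np.cumsum([len(a) for a in self.neighbors])
        indices = (
            np.concatenate(self.neighbors)
            if n and indptr[-1]
            else np.empty(0, dtype=np.int64)
        )
        data = np.ones(len(indices), dtype=np.int64)
        return sparse.csr_matrix((data, indices, indptr), shape=(n, n))


def build_neighborhood_index(
    cells: pd.DataFrame, d: float = DEFAULT_RADIUS_UM
) -> NeighborhoodIndex:
    """Find, for every cell, all other cells within ``d`` μm of its centroid.

    Distances are Euclidean on the (x, y) centroids; the boundary is
    inclusive, so a pair at exactly ``d`` μm counts as neighbours.
    """
    if d <= 0:
        raise ValidationError(f"neighbourhood radius must be positive, got {d}")
    validate_cell_table(cells)
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    if len(xy) == 0:
        raise ValidationError("cell table is empty")
    tree = cKDTree(xy)
    raw = tree.query_ball_point(xy, r=d)
    neighbors = []
    for i, lst in enumerate(raw):
        arr = np.asarray([t for t in lst if t != i], dtype=np.int64)
        arr.sort()
        neighbors.append(arr)
    return NeighborhoodIndex(radius=float(d), neighbors=neighbors)


# ---------------------------------------------------------------------------
# hexagonal binning
# ---------------------------------------------------------------------------

@dataclass
class HexbinGrid:
    """Regular flat-top hexagonal lattice with per-bin transcript counts.

    The lattice is anchored so one hex centre sits at the bounding-box min
    corner.  ``area`` is the exact area of a single hexagon,
    ``(3√3/2)·r²`` for circumradius ``r``.
    """

    circumradius: float
    origin: tuple[float, float]
    centers: np.ndarray            # (n_bins, 2) hex centre coordinates, μm
    bin_totals: np.ndarray         # (n_bins,) total transcripts per bin
    gene_counts: sparse.csr_matrix  # (n_bins, n_genes)
    gene_names: list[str]

    @property
    def area(self) -> float:
        return 1.5 * _SQRT3 * self.circumradius**2

    @property
    def n_bins(self) -> int:
        return len(self.bin_totals)


def _axial_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Round fractional axial hex coordinates to the nearest hex (cube rounding)."""
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q[fix_q] = -r[fix_q] - s[fix_q]
    r[fix_r] = -q[fix_r] - s[fix_r]
    return q.astype(np.int64), r.astype(np.int64)


def _xy_to_axial(x: np.ndarray, y: np.ndarray, r: float) -> tuple[np.ndarray, np.ndarray]:
    qf = (2.0 / 3.0) * x / r
    rf = (-x / 3.0 + _SQRT3 / 3.0 * y) / r
    return _axial_round(qf, rf)


def _axial_to_xy(q: np.ndarray, r_ax: np.ndarray, r: float) -> tuple[np.ndarray, np.ndarray]:
    x = r * 1.5 * q
    y = r * _SQRT3 * (r_ax + q / 2.0)
    return x, y


def hexbin_transcripts(
    tx: pd.DataFrame,
    n_bins_target: int = DEFAULT_N_HEXBINS,
    gene_names: list[str] | None = None,
) -> HexbinGrid:
    """Bin transcript molecules into a regular hexagonal lattice.

    Parameters
    ----------
    tx
        Transcript table with columns ``x``, ``y`` (μm) and ``gene``.
    n_bins_target
        Desired bin count; the circumradius is chosen as
        ``r = sqrt(2·bbox_area / (3√3·n_bins_target))`` so the realised
        number of hexes covering the bounding box approximates the target.
    gene_names
        Gene panel fixing the column order of the per-bin gene counts.
        Defaults to the sorted set of genes present.  Transcripts whose gene
        is outside the panel raise a :class:`ValidationError`.
    """
    if n_bins_target < 2:
        raise ValidationError(f"n_bins_target must be >= 2, got {n_bins_target}")
    for col in ("x", "y", "gene"):
        if col not in tx.columns:
            raise ValidationError(f"transcript table is missing column {col!r}")
    if len(tx) == 0:
        raise ValidationError("transcript table is empty")
    x = tx["x"].to_numpy(dtype=float)
    y = tx["y"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite transcript coordinates")

    xmin, xmax = float(x.min()), float(x.max())
    ymin, ymax = float(y.min()), float(y.max())
    bbox_area = (xmax - xmin) * (ymax - ymin)
    if bbox_area <= 0:
        raise DegenerateInputError(
            "all transcripts fall on a single point or line; a hexagonal grid "
            "cannot be formed — disable the global background estimate"
        )
    r = math.sqrt(2.0 * bbox_area / (3.0 * _SQRT3 * n_bins_target))

    if gene_names is None:
        gene_names = sorted(tx["gene"].astype(str).unique().tolist())
    gene_index = {g: i for i, g in enumerate(gene_names)}
    genes = tx["gene"].astype(str).map(gene_index)
    if genes.isna().any():
        missing = tx.loc[genes.isna(), "gene"].iloc[0]
        raise ValidationError(f"transcript gene {missing!r} not in the gene panel")
    gidx = genes.to_numpy(dtype=np.int64)

    # hexes covering the bounding box (centres inside, tiny tolerance), plus
    # any hex a transcript actually falls in — conservation is exact
    q_tx, r_tx = _xy_to_axial(x - xmin, y - ymin, r)
    keys = set(zip(q_tx.tolist(), r_tx.tolist()))
    qmax = int(math.ceil((xmax - xmin) / (1.5 * r))) + 1
    rmax = int(math.ceil((ymax - ymin) / (_SQRT3 * r))) + 1
    qq, rr = np.meshgrid(np.arange(-1, qmax + 1), np.arange(-rmax, rmax + 1))
    qq = qq.ravel()
    rr = rr.ravel()
    cx, cy = _axial_to_xy(qq.astype(float), rr.astype(float), r)
    eps = 1e-9 * max(xmax - xmin, ymax - ymin)
    inside = (
        (cx >= -eps)
        & (cx <= xmax - xmin + eps)
        & (cy >= -eps)
        & (cy <= ymax - ymin + eps)
    )
    keys.update(zip(qq[inside].tolist(), rr[inside].tolist()))
    key_list = sorted(keys)
    key_to_bin = {k: i for i, k in enumerate(key_list)}
    n_bins = len(key_list)

    bin_of_tx = np.fromiter(
        (key_to_bin[(int(q), int(rr_))] for q, rr_ in zip(q_tx, r_tx)),
        dtype=np.int64,
        count=len(q_tx),
    )
    bin_totals = np.bincount(bin_of_tx, minlength=n_bins).astype(np.int64)
    gene_counts = sparse.coo_matrix(
        (np.ones(len(gidx), dtype=np.int64), (bin_of_tx, gidx)),
        shape=(n_bins, len(gene_names)),
    ).tocsr()

    ks = np.asarray(key_list, dtype=float)
    cxs, cys = _axial_to_xy(ks[:, 0], ks[:, 1], r)
    centers = np.column_stack([cxs + xmin, cys + ymin])
    return HexbinGrid(
        circumradius=r,
        origin=(xmin, ymin),
        centers=centers,
        bin_totals=bin_totals,
        gene_counts=gene_counts,
        gene_names=list(gene_names),
    )


# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------

@dataclass
class BackgroundGMM:
    """Two-component univariate Gaussian mixture over hexbin totals.

    The lower-mean component is designated as background; each bin is
    hard-assigned to the component with the larger posterior responsibility.
    """

    weights: np.ndarray            # (2,) mixing proportions
    means: np.ndarray              # (2,)
    variances: np.ndarray          # (2,)
    responsibilities: np.ndarray   # (n_bins, 2), rows sum to 1
    log_likelihood: float
    n_iter: int
    converged: bool
    background_component: int = field(init=False)
    background_bins: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.background_component = int(np.argmin(self.means))
        hard = np.argmax(self.responsibilities, axis=1)
        self.background_bins = np.flatnonzero(hard == self.background_component)

    @property
    def background_weight(self) -> float:
        return float(self.weights[self.background_component])


def fit_background_gmm(
    bin_totals: np.ndarray,
    seed: int = 0,
    max_iter: int = 500,
    rtol: float = 1e-8,
) -> BackgroundGMM:
    """EM fit of a two-component Gaussian mixture to hexbin totals.

    Initialisation is deterministic (split at the median, component moments
    from each half), so the fit is reproducible regardless of ``seed``; the
    seed argument is kept for interface stability.  Variances are floored at
    ``1e-6 · var(totals)`` to prevent collapse onto a single bin.
    """
    c = np.asarray(bin_totals, dtype=float).ravel()
    if len(c) < 4:
        raise ValidationError(f"need at least 4 bins to fit a mixture, got {len(c)}")
    total_var = float(np.var(c))
    if total_var <= 0:
        raise ValidationError("bin totals have zero variance; cannot separate background")
    var_floor = 1e-6 * total_var

    med = np.median(c)
    lo = c[c <= med]
    hi = c[c > med]
    if len(hi) == 0:  # >half the data at the median
        lo, hi = c[c < med], c[c >= med]
    w = np.array([len(lo), len(hi)], dtype=float) / len(c)
    mu = np.array([lo.mean(), hi.mean()])
    var = np.maximum(np.array([lo.var(), hi.var()]), var_floor)

    def _log_norm(x: np.ndarray, m: float, v: float) -> np.ndarray:
        return -0.5 * (np.log(2 * np.pi * v) + (x - m) ** 2 / v)

    ll_prev = -np.inf
    converged = False
    resp = np.full((len(c), 2), 0.5)
    n_done = 0
    for n_done in range(1, max_iter + 1):
        logp = np.column_stack(
            [np.log(w[k]) + _log_norm(c, mu[k], var[k]) for k in range(2)]
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        resp = np.exp(logp - lse[:, None])
        ll = float(lse.sum())
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= rtol * (abs(ll) + 1e-300):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / len(c)
        mu = (resp * c[:, None]).sum(axis=0) / nk
        var = (resp * (c[:, None] - mu) ** 2).sum(axis=0) / nk
        if (var < var_floor).any():
            logger.warning("background GMM variance collapsed; floor applied")
            var = np.maximum(var, var_floor)
    return BackgroundGMM(
        weights=w,
        means=mu,
        variances=var,
        responsibilities=resp,
        log_likelihood=ll_prev,
        n_iter=n_done,
        converged=converged,
    )


@dataclass
class BackgroundProfile:
    """Per-gene expected ambient count within a radius-``d`` disc."""

    values: np.ndarray        # (n_genes,) x_b per gene, >= 0
    gene_names: list[str]
    background_bins: np.ndarray
    radius: float


def compute_background_profile(
    grid: HexbinGrid, gmm: BackgroundGMM, d: float = DEFAULT_RADIUS_UM
) -> BackgroundProfile:
    """Average each gene over the background bins and scale to disc area.

    The per-gene background level is ``(π·d²/A) · mean_{k∈B} counts[k, j]``
    where ``B`` is the set of background bins and ``A`` the hexbin area, so
    choosing ``A = π·d²`` returns the raw background-bin mean unchanged.
    """
    bins = gmm.background_bins
    if len(bins) == 0:
        raise DegenerateInputError(
            "no hexbin was assigned to the background component; disable the "
            "global background estimate"
        )
    mean_counts = np.asarray(
        grid.gene_counts[bins].mean(axis=0)
    ).ravel().astype(float)
    scale = math.pi * d * d / grid.area
    return BackgroundProfile(
        values=scale * mean_counts,
        gene_names=list(grid.gene_names),
        background_bins=bins,
        radius=float(d),
    )


# ---------------------------------------------------------------------------
# offsets
# ---------------------------------------------------------------------------

def compute_offsets(
    counts,
    nbrs: NeighborhoodIndex,
    bg: BackgroundProfile | None = None,
    gene_names: list[str] | None = None,
) -> np.ndarray:
    """Assemble the offset matrix ``x_plus[i, j] = x_b[j] + Σ_{t∈T_i} x[t, j]``.

    ``counts`` is the raw cells × genes matrix (dense or sparse).  With no
    background profile the global term is zero and a warning is logged.
    """
    X = sparse.csr_matrix(counts) if not sparse.issparse(counts) else counts.tocsr()
    n, g = X.shape
    if nbrs.n_cells != n:
        raise ValidationError(
            f"neighbourhood index covers {nbrs.n_cells} cells but the count "
            f"matrix has {n} rows"
        )
    local = np.asarray((nbrs.adjacency() @ X).todense(), dtype=float)
    if bg is None:
        logger.warning("no background profile supplied; global offset set to 0")
        return local
    if gene_names is not None:
        if list(bg.gene_names) != list(gene_names):
            idx = {gn: k for k, gn in enumerate(bg.gene_names)}
            try:
                order = [idx[gn] for gn in gene_names]
            except KeyError as e:
                raise ValidationError(
                    f"gene {e.args[0]!r} missing from the background profile"
                ) from None
            return local + bg.values[order][None, :]
    if len(bg.values) != g:
        raise ValidationError(
            f"background profile has {len(bg.values)} genes, count matrix {g}"
        )
    return local + bg.values[None, :]
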