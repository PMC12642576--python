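"""Evaluation statistics for contamination removal.

Two complementary views of denoising quality:

* **MECR** (mutually exclusive co-expression rate) — for a gene pair that
  biology says should never be co-expressed in one cell, the fraction of
  cells expressing *both* among cells expressing *either*.  High values
  indicate spillover (a false-positive proxy); a good denoiser drives it
  toward zero.
* **PMP** (positive marker purity) — the fraction of a cell's total counts
  falling in its own cell type's marker set (a true-positive proxy); a good
  denoiser raises it without destroying marker signal.

Mutually exclusive pairs and marker sets are derived from a labelled
reference count matrix: per cell type, genes are kept when they rank in the
top fraction by mean pairwise AUC, are detected in at least half of the
type's cells, and in at most 5% of all other cells; every cross-type
combination of the surviving type-specific genes forms a pair.

Real-valued inputs (from tools emitting fractional counts) are rounded
half-up before MECR, so 0.5 counts as expressed and 0.49 does not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse, stats

from ._errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FRAC_AUC: float = 0.30
DEFAULT_MIN_IN: float = 0.50
DEFAULT_MAX_OUT: float = 0.05


@dataclass
class GenePairSet:
    """Unordered, de-duplicated mutually exclusive gene pairs."""

    pairs: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        canon = []
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"pair ({a!r}, {b!r}) repeats one gene")
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                canon.append(key)
        self.pairs = canon

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class MarkerSets:
    """Per-cell-type marker gene sets plus the per-gene statistics that
    produced them (mean AUC, in-type and out-of-type detection rates)."""

    markers: dict[str, list[str]]
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for ct, genes in self.markers.items():
            if len(genes) == 0:
                raise ValidationError(f"marker set for type {ct!r} is empty")


def _as_dense(counts) -> np.ndarray:
    X = counts.toarray() if sparse.issparse(counts) else np.asarray(counts)
    if X.ndim != 2:
        raise ValidationError(f"count matrix must be 2-D, got shape {X.shape}")
    if (X < 0).any():
        raise ValidationError("count matrix must be non-negative")
    return np.asarray(X, dtype=float)


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round non-negative values half-up: 0.49 → 0, 0.5 → 1."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


# ---------------------------------------------------------------------------
# MECR
# ---------------------------------------------------------------------------

def mecr(
    counts,
    gene_names: list[str],
    pairs: GenePairSet | list[tuple[str, str]],
) -> pd.DataFrame:
    """Mutually exclusive co-expression rate per gene pair.

    Counts are rounded half-up first; a cell is positive for a gene when the
    rounded count exceeds zero.  Pairs where no cell expresses either gene
    get ``NaN`` (0/0) with a logged warning.

    Returns a data frame with columns ``gene_a, gene_b, mecr, n_either``.
    """
    X = round_half_up(_as_dense(counts))
    idx = {g: j for j, g in enumerate(gene_names)}
    if isinstance(pairs, GenePairSet):
        pair_list = pairs.pairs
    else:
        pair_list = GenePairSet(list(pairs)).pairs
    rows = []
    pos = X > 0
    n_undefined = 0
    for a, b in pair_list:
        if a not in idx or b not in idx:
            missing = a if a not in idx else b
            raise ValidationError(f"pair gene {missing!r} not in the gene panel")
        pa, pb = pos[:, idx[a]], pos[:, idx[b]]
        either = int((pa | pb).sum())
        both = int((pa & pb).sum())
        if either == 0:  # 0/0 — no cell expresses either gene
            n_undefined += 1
            rate = np.nan
        else:
            rate = both / either
        rows.append(dict(gene_a=a, gene_b=b, mecr=rate, n_either=either))
    if n_undefined:
        logger.warning(
            "MECR undefined (no expressing cell) for %d of %d pairs; reported as NaN",
            n_undefined, len(pair_list),
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "mecr", "n_either"])


# ---------------------------------------------------------------------------
# reference-based derivation of pairs and markers
# ---------------------------------------------------------------------------

def _pairwise_auc(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Column-wise rank-sum AUC of group a vs group b (mid-ranks for ties)."""
    na, nb = len(values_a), len(values_b)
    combined = np.vstack([values_a, values_b])
    ranks = stats.rankdata(combined, axis=0)
    r_a = ranks[:na].sum(axis=0)
    return (r_a - na * (na + 1) / 2.0) / (na * nb)


def derive_exclusive_pairs(
    ref_counts,
    gene_names: list[str],
    labels,
    frac_auc: float = DEFAULT_FRAC_AUC,
    min_in: float = DEFAULT_MIN_IN,
    max_out: float = DEFAULT_MAX_OUT,
) -> tuple[GenePairSet, MarkerSets]:
    """Derive type-specific genes and their mutually exclusive cross pairs.

    Per cell type, a gene qualifies when it is (1) detected in at least
    ``min_in`` of the type's cells, (2) detected in at most ``max_out`` of
    all other cells, and (3) within the top ``frac_auc`` fraction of the
    qualifying genes by mean pairwise AUC (focal type vs each other type,
    averaged; ceil rounding, ties broken by panel order).  Pairs are all
    cross-type combinations of the surviving genes.
    """
    if not (0 < frac_auc <= 1):
        raise ValidationError(f"frac_auc must be in (0, 1], got {frac_auc}")
    X = _as_dense(ref_counts)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValidationError(
            f"{len(labels)} labels for {X.shape[0]} reference cells"
        )
    types = sorted(pd.unique(labels).tolist())
    if len(types) < 2:
        logger.warning("fewer than 2 cell types; no cross-type pairs exist")
        return GenePairSet([], provenance="derived"), MarkerSets(markers={})
    groups = {t: np.flatnonzero(labels == t) for t in types}
    for t, g in groups.items():
        if len(g) < 2:
            raise ValidationError(f"cell type {t!r} has fewer than 2 reference cells")

    detected = X > 0
    stat_rows = []
    specific: dict[str, list[str]] = {}
    for t in types:
        in_idx = groups[t]
        out_mask = np.ones(X.shape[0], dtype=bool)
        out_mask[in_idx] = False
        det_in = detected[in_idx].mean(axis=0)
        det_out = detected[out_mask].mean(axis=0)
        aucs = np.mean(
            [_pairwise_auc(X[in_idx], X[groups[u]]) for u in types if u != t],
            axis=0,
        )
        passing = np.flatnonzero((det_in >= min_in) & (det_out <= max_out))
        k = int(math.ceil(frac_auc * len(passing)))
        order = passing[np.argsort(-aucs[passing], kind="stable")][:k]
        kept = set(order.tolist())
        specific[t] = [gene_names[j] for j in sorted(kept)]
        for j in passing:
            stat_rows.append(
                dict(cell_type=t, gene=gene_names[j], mean_auc=float(aucs[j]),
                     det_in=float(det_in[j]), det_out=float(det_out[j]),
                     selected=bool(j in kept))
            )

    retained = {t: genes for t, genes in specific.items() if genes}
    pair_list: list[tuple[str, str]] = []
    for t, u in combinations(sorted(retained), 2):
        for a in retained[t]:
            for b in retained[u]:
                if a != b:
                    pair_list.append((a, b))
    if not pair_list:
        logger.warning("no gene passed the specificity filters for >= 2 types")
    stats_df = pd.DataFrame(
        stat_rows,
        columns=["cell_type", "gene", "mean_auc", "det_in", "det_out", "selected"],
    )
    return (
        GenePairSet(pair_list, provenance="derived"),
        MarkerSets(markers=retained, stats=stats_df),
    )


# ---------------------------------------------------------------------------
# PMP
# ---------------------------------------------------------------------------

def pmp(
    counts,
    gene_names: list[str],
    markers: MarkerSets | dict[str, list[str]],
    labels,
) -> tuple[pd.Series, float]:
    """Positive marker purity per cell and its type-balanced mean.

    Per cell: the fraction of total counts in the cell type's marker set.
    The summary is the unweighted mean over cell types of the within-type
    mean, so small types weigh as much as large ones.  Cells with zero
    total count are excluded (NaN) with a logged warning.
    """
    X = _as_dense(counts)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValidationError(f"{len(labels)} labels for {X.shape[0]} cells")
    marker_map = markers.markers if isinstance(markers, MarkerSets) else markers
    types = pd.unique(labels).tolist()
    missing = [t for t in types if t not in marker_map]
    if missing:
        raise ValidationError(
            f"no marker set for cell type(s) {sorted(map(str, missing))}"
        )
    idx = {g: j for j, g in enumerate(gene_names)}
    marker_cols = {}
    for t in types:
        cols = []
        for g in marker_map[t]:
            if g not in idx:
                raise ValidationError(f"marker gene {g!r} not in the gene panel")
            cols.append(idx[g])
        marker_cols[t] = np.asarray(cols, dtype=int)

    totals = X.sum(axis=1)
    per_cell = np.full(X.shape[0], np.nan)
    for t in types:
        rows = np.flatnonzero(labels == t)
        mk = X[np.ix_(rows, marker_cols[t])].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_cell[rows] = np.where(totals[rows] > 0, mk / totals[rows], np.nan)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("%d cells with zero total count excluded from PMP", n_zero)

    type_means = []
    for t in types:
        vals = per_cell[labels == t]
        vals = vals[~np.isnan(vals)]
        if len(vals):
            type_means.append(vals.mean())
    mean_pmp = float(np.mean(type_means)) if type_means else float("nan")
    return pd.Series(per_cell, name="pmp"), mean_pmp
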