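"""Correlation, soft thresholding, adjacency and topological overlap.

The weighted network pipeline: a pairwise feature correlation matrix is
raised to a soft power beta to give an adjacency in [0, 1], and the
topological overlap matrix (TOM) then blends direct adjacency with
shared-neighbour structure,

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu.
1 - TOM is the dissimilarity handed to hierarchical clustering.

The soft power is chosen so that the network approximates scale-free
topology: for each candidate beta, connectivities k are binned into
equal-occupancy bins and log10(frequency) is regressed on log10(mean k
per bin); the model fit R^2, signed by the slope, should be high and
the slope negative. The smallest beta reaching the fit cutoff is taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from coexnet.core_data import ExpressionDataset

logger = logging.getLogger(__name__)

NetworkType = Literal["unsigned", "signed", "signed-hybrid"]
TomType = Literal["unsigned", "signed"]
CorrMethod = Literal["pearson", "bicor"]

DEFAULT_POWERS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)

_SYM_TOL = 1e-10


@dataclass
class SoftThresholdReport:
    """Scale-free fit statistics per candidate power, and the choice made."""

    table: pd.DataFrame  # power, scale_free_fit_R2, mean/median/max connectivity
    chosen_power: float
    fit_cutoff: float
    reached_cutoff: bool


@dataclass
class CoexpressionNetwork:
    """Correlation / adjacency / TOM matrices with their parameters."""

    feature_ids: list[str]
    correlation: np.ndarray
    adjacency: np.ndarray
    tom: np.ndarray
    power: float
    network_type: NetworkType
    tom_type: TomType
    soft_threshold: SoftThresholdReport | None = field(default=None, repr=False)

    @property
    def tom_dissimilarity(self) -> np.ndarray:
        return tom_dissimilarity(self.tom)


def _check_square_symmetric(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=_SYM_TOL, rtol=0.0):
        raise ValueError(f"{name} must be symmetric (tolerance {_SYM_TOL})")
    return m


def _bicor(X: np.ndarray) -> np.ndarray:
    """Biweight midcorrelation of the columns of X.

    Robust alternative to Pearson: observations are weighted by Tukey's
    biweight around the column median, with the usual MAD scaling
    (9 * MAD defines the zero-weight boundary). Columns whose MAD is
    zero fall back to mean/SD weights for that column, which reduces to
    Pearson behaviour there.
    """
    n, p = X.shape
    med = np.median(X, axis=0)
    dev = X - med
    mad = np.median(np.abs(dev), axis=0)
    u = np.zeros_like(X)
    ok = mad > 0
    u[:, ok] = dev[:, ok] / (9.0 * mad[ok])
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    # zero-MAD columns: fall back to standardized deviations (Pearson-like)
    if (~ok).any():
        sd = X[:, ~ok].std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = np.flatnonzero(~ok)[sd == 0]
            raise ValueError(f"zero-variance feature at column index {bad.tolist()}")
        w[:, ~ok] = 1.0
    xw = dev * w
    norm = np.sqrt((xw**2).sum(axis=0))
    if np.any(norm == 0):
        bad = np.flatnonzero(norm == 0)
        raise ValueError(f"degenerate biweight normalization at column index {bad.tolist()}")
    xn = xw / norm
    c = xn.T @ xn
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return c


def pairwise_correlation(ds: ExpressionDataset, method: CorrMethod = "pearson") -> np.ndarray:
    """Feature x feature correlation matrix (Pearson or biweight mid-cor).

    Requires a complete matrix, >= 3 samples, and nonzero variance in
    every feature (a zero-variance feature is named in the error).
    """
    ds.require_complete("pairwise correlation")
    if ds.n_samples < 3:
        raise ValueError(f"need >= 3 samples for correlation, have {ds.n_samples}")
    X = ds.values
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        names = [ds.feature_ids[i] for i in np.flatnonzero(sd == 0)[:10]]
        raise ValueError(f"zero-variance features: {names}")
    if method == "pearson":
        c = np.corrcoef(X, rowvar=False)
        np.clip(c, -1.0, 1.0, out=c)
        np.fill_diagonal(c, 1.0)
        return c
    if method == "bicor":
        return _bicor(X)
    raise ValueError(f"unknown correlation method {method!r}")


def adjacency_from_correlation(
    corr: np.ndarray,
    power: float,
    network_type: NetworkType = "signed",
) -> np.ndarray:
    """Soft-threshold a correlation matrix into an adjacency in [0, 1].

    unsigned: |r|^beta; signed: ((1 + r)/2)^beta; signed-hybrid: r^beta
    for r > 0, else 0. The diagonal is set to 1.
    """
    if power <= 0:
        raise ValueError(f"power must be > 0, got {power}")
    corr = _check_square_symmetric(corr, "correlation")
    if network_type == "unsigned":
        adj = np.abs(corr) ** power
    elif network_type == "signed":
        adj = ((1.0 + corr) / 2.0) ** power
    elif network_type == "signed-hybrid":
        adj = np.where(corr > 0, corr, 0.0) ** power
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.clip(adj, 0.0, 1.0, out=adj)
    np.fill_diagonal(adj, 1.0)
    return adj


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    adj = _check_square_symmetric(adj, "adjacency")
    return adj.sum(axis=1) - np.diag(adj)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of the log-log degree-distribution fit.

    Connectivities are split into ``n_bins`` equal-width bins over
    [min(k), max(k)]; empty bins and bins with non-positive mean k are
    dropped, and log10(frequency) is regressed on log10(mean k per
    bin). (Equal-width binning is required: equal-occupancy bins have
    constant frequency by construction, which degenerates the fit.)
    The R^2 is signed by the slope so a scale-free (decreasing) fit is
    positive.
    """
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        raise ValueError(
            "all connectivities are identical; the degree distribution is "
            "degenerate and a scale-free fit is undefined"
        )
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    log_k, log_f = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_f.append(np.log10(mask.sum() / len(k)))
    if len(log_k) < 3:
        raise ValueError("fewer than 3 usable bins for the scale-free fit")
    fit = stats.linregress(log_k, log_f)
    r2 = float(fit.rvalue**2)
    if not np.isfinite(r2):  # constant log-frequency across bins
        return 0.0, float(fit.slope) if np.isfinite(fit.slope) else 0.0
    return r2 * float(np.sign(fit.slope)), float(fit.slope)


def pick_soft_threshold(
    ds: ExpressionDataset,
    candidate_powers: tuple[float, ...] | list[float] = DEFAULT_POWERS,
    network_type: NetworkType = "signed",
    fit_cutoff: float = 0.9,
    corr_method: CorrMethod = "pearson",
    corr: np.ndarray | None = None,
) -> SoftThresholdReport:
    """Evaluate candidate soft powers and choose one by scale-free fit.

    The chosen power is the smallest candidate whose signed R^2 reaches
    ``fit_cutoff``; if none does, the power maximizing signed R^2 is
    used and a warning is logged. A precomputed correlation matrix can
    be passed to avoid recomputation.
    """
    powers = list(candidate_powers)
    if not powers:
        raise ValueError("candidate_powers must be non-empty")
    if any(p <= 0 for p in powers):
        raise ValueError("all candidate powers must be > 0")
    if corr is None:
        corr = pairwise_correlation(ds, method=corr_method)
    rows = []
    for p in powers:
        adj = adjacency_from_correlation(corr, p, network_type)
        k = connectivity(adj)
        r2, slope = scale_free_fit(k)
        rows.append(
            {
                "power": p,
                "scale_free_fit_R2": r2,
                "slope": slope,
                "mean_connectivity": float(k.mean()),
                "median_connectivity": float(np.median(k)),
                "max_connectivity": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    passing = table[table["scale_free_fit_R2"] >= fit_cutoff]
    if len(passing):
        chosen = float(passing["power"].iloc[0])
        reached = True
    else:
        chosen = float(table.loc[table["scale_free_fit_R2"].idxmax(), "power"])
        reached = False
        logger.warning(
            "no candidate power reached fit_cutoff=%.2f; using power=%g with "
            "best signed R^2=%.3f", fit_cutoff, chosen,
            float(table["scale_free_fit_R2"].max()),
        )
    return SoftThresholdReport(table=table, chosen_power=chosen, fit_cutoff=fit_cutoff, reached_cutoff=reached)


def default_power(n_samples: int, network_type: NetworkType = "signed") -> int:
    """Sample-size-based default soft power, used when no candidate
    reaches the scale-free fit cutoff (the standard practitioner
    recommendation: more samples support smaller powers; signed
    networks need roughly double the unsigned power)."""
    if n_samples < 20:
        unsigned = 9
    elif n_samples < 30:
        unsigned = 8
    elif n_samples < 40:
        unsigned = 7
    else:
        unsigned = 6
    return unsigned * 2 if network_type == "signed" else unsigned


def tom_similarity(
    adj: np.ndarray,
    tom_type: TomType = "signed",
    block_size: int | None = None,
) -> np.ndarray:
    """Topological overlap matrix of a [0, 1] adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu;
    the diagonal is 1. For non-negative adjacencies the unsigned and
    signed variants coincide (the signed variant takes absolute values
    in L and k, which changes nothing when a >= 0).

    ``block_size`` computes the shared-neighbour product L in row
    blocks, trading peak memory for a little speed on large matrices;
    the result is identical.
    """
    adj = _check_square_symmetric(adj, "adjacency")
    if np.any(adj < 0) or np.any(adj > 1):
        raise ValueError("adjacency entries must lie in [0, 1]")
    if tom_type not in ("unsigned", "signed"):
        raise ValueError(f"unknown tom_type {tom_type!r}")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    if block_size is None or block_size >= n:
        L = a @ a
    else:
        L = np.empty_like(a)
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            L[start:stop] = a[start:stop] @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.clip(tom, 0.0, 1.0, out=tom)
    np.fill_diagonal(tom, 1.0)
    # enforce exact symmetry against float round-off in the matmul
    tom = (tom + tom.T) / 2.0
    return tom


def tom_dissimilarity(tom: np.ndarray) -> np.ndarray:
    """1 - TOM elementwise, with an exactly zero diagonal."""
    tom = _check_square_symmetric(tom, "TOM")
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 1.0, out=d)
    return d


def build_network(
    ds: ExpressionDataset,
    power: float | None = None,
    network_type: NetworkType = "signed",
    tom_type: TomType = "signed",
    corr_method: CorrMethod = "pearson",
    candidate_powers: tuple[float, ...] | list[float] = DEFAULT_POWERS,
    fit_cutoff: float = 0.9,
    block_size: int | None = None,
) -> CoexpressionNetwork:
    """Run correlation -> (power selection) -> adjacency -> TOM."""
    corr = pairwise_correlation(ds, method=corr_method)
    report = None
    if power is None:
        report = pick_soft_threshold(
            ds, candidate_powers, network_type, fit_cutoff, corr_method, corr=corr
        )
        if report.reached_cutoff:
            power = report.chosen_power
        else:
            # the scale-free fit is uninformative on this data; the
            # max-R^2 power is unstable, so fall back to the
            # sample-size-based default instead
            power = float(default_power(ds.n_samples, network_type))
            logger.warning(
                "scale-free cutoff not reached; using sample-size default power=%g", power
            )
    adj = adjacency_from_correlation(corr, power, network_type)
    tom = tom_similarity(adj, tom_type, block_size=block_size)
    return CoexpressionNetwork(
        feature_ids=ds.feature_ids,
        correlation=corr,
        adjacency=adj,
        tom=tom,
        power=float(power),
        network_type=network_type,
        tom_type=tom_type,
        soft_threshold=report,
    )
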