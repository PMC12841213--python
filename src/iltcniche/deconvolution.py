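"""Per-spot cell-type fraction estimation by nonnegative least squares.

Each Visium spot mixes a handful of cells; its depth-normalised expression is
modelled as a nonnegative combination of reference cell-type profiles, and
the NNLS coefficients, rescaled to sum to one, are read as transcript
proportions. Counts are depth-normalised but *not* log-transformed before
fitting: the mixture model is additive on the linear scale and a log
transform would break that additivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp

from .errors import ValidationError
from .reference import ReferenceProfile

log = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_ZERO = "zero_spot"
FLAG_DEGENERATE = "degenerate"


@dataclass
class FractionTable:
    """Per-spot NNLS output: raw coefficients, proportions, residual, flag."""

    coefficients: pd.DataFrame  # spot x cell type, raw NNLS scale
    proportions: pd.DataFrame   # rows sum to 1, or all-zero for zero spots
    residual: pd.Series
    flag: pd.Series

    @property
    def cell_types(self) -> list[str]:
        return list(self.proportions.columns)

    def t_fraction(self, t_cell_types) -> pd.Series:
        cols = [c for c in t_cell_types if c in self.proportions.columns]
        return self.proportions[cols].sum(axis=1)


def _collapse_duplicate_columns(design: np.ndarray):
    """Group exactly-collinear columns (equal after L2 scaling).

    Returns (reduced design, groups) where each group lists original column
    indices sharing one reduced column. Zero columns form their own groups
    and are excluded from the fit.
    """
    n_cols = design.shape[1]
    norms = np.linalg.norm(design, axis=0)
    keys: dict[bytes, list[int]] = {}
    zero_cols: list[int] = []
    order: list[bytes] = []
    for j in range(n_cols):
        if norms[j] == 0:
            zero_cols.append(j)
            continue
        key = (design[:, j] / norms[j]).tobytes()
        if key not in keys:
            keys[key] = []
            order.append(key)
        keys[key].append(j)
    groups = [keys[k] for k in order]
    reduced = np.column_stack([design[:, g[0]] for g in groups]) \
        if groups else np.empty((design.shape[0], 0))
    return reduced, groups, zero_cols


def nnls_fit(design: np.ndarray, y: np.ndarray):
    """Solve min ||design @ x - y||_2 s.t. x >= 0 (Lawson-Hanson active set).

    Exactly duplicate columns (equal after scaling to unit norm) are
    collapsed before the fit and the coefficient is split equally among
    them afterwards; all-zero columns get coefficient 0. Either situation
    flags the fit ``degenerate``. Deterministic for fixed inputs.

    Returns
    -------
    x : ndarray of coefficients, one per design column
    residual : float, ||design @ x - y||_2
    flag : str, "ok" or "degenerate"
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if design.ndim != 2 or design.shape[1] < 1:
        raise ValidationError("design must be 2-D with >= 1 column")
    if y.shape[0] != design.shape[0]:
        raise ValidationError(
            f"y has length {y.shape[0]}, design has {design.shape[0]} rows"
        )
    if np.isnan(design).any() or np.isnan(y).any():
        raise ValidationError("NaN in NNLS inputs")
    if (design < 0).any() or (y < 0).any():
        raise ValidationError("NNLS inputs must be nonnegative")

    reduced, groups, zero_cols = _collapse_duplicate_columns(design)
    flag = FLAG_OK
    if zero_cols or any(len(g) > 1 for g in groups):
        flag = FLAG_DEGENERATE
    x = np.zeros(design.shape[1])
    if reduced.shape[1] == 0:
        return x, float(np.linalg.norm(y)), flag
    coef, residual = scipy.optimize.nnls(reduced, y)
    for g, c in zip(groups, coef):
        x[g] = c / len(g)
    return x, float(residual), flag


def estimate_dispersion(counts_fit_mu: np.ndarray, counts_obs: np.ndarray,
                        scale_factors: np.ndarray) -> float:
    """Pooled method-of-moments negative-binomial size estimate.

    Solves E[(y - mu)^2] = s*mu + mu^2/theta over all spot/gene cells, where
    ``counts_fit_mu`` and ``counts_obs`` are on the normalised scale and
    ``scale_factors`` (per spot) map counts to that scale. Clamped to
    [1e-2, 1e6]; near-Poisson data hits the upper clamp.
    """
    resid2 = (counts_obs - counts_fit_mu) ** 2
    excess = resid2 - scale_factors[:, None] * counts_fit_mu
    denom = max(float(np.nansum(excess)), 1e-12)
    theta = float(np.nansum(counts_fit_mu ** 2)) / denom
    return float(np.clip(theta, 1e-2, 1e6))


def deconvolve_spots(adata, ref: ReferenceProfile, scale: float = 1e4,
                     min_gene_overlap: int = 50, weighting: str = "nb",
                     n_iter: int = 6) -> FractionTable:
    """NNLS-deconvolve every spot against the reference.

    Counts are normalised to counts-per-``scale`` (linear, no log) and the
    design columns are normalised to sum to one over the shared genes, so
    coefficients are comparable across cell types and proportions read as
    transcript fractions. Shared genes are taken in dataset order, making
    the result invariant to gene order in the reference.

    With ``weighting="nb"`` (default) the fit is iteratively reweighted:
    gene variances are modelled as s*mu + mu^2/theta (negative-binomial
    mean-variance), with mu from the previous pass and a pooled
    method-of-moments theta, and each NNLS solves the rescaled system.
    UMI counts are strongly overdispersed at Visium depths and an
    unweighted fit lets the high-abundance genes' noise dominate the
    stromal split; the reweighted fit tracks the oracle (known-variance)
    accuracy. ``weighting="none"`` restores the plain unweighted fit.
    """
    ref_df = ref.to_frame()
    common = [g for g in adata.var_names if g in ref_df.index]
    if len(common) < min_gene_overlap:
        raise ValidationError(
            f"only {len(common)} genes shared between dataset "
            f"({adata.n_vars}) and reference ({len(ref.genes)}); "
            f"floor is {min_gene_overlap}"
        )
    design = ref_df.loc[common].to_numpy(float)
    col_sums = design.sum(axis=0)
    design = np.divide(design, np.where(col_sums > 0, col_sums, 1.0))

    X = sp.csr_matrix(adata[:, common].X).astype(float)
    totals = np.asarray(sp.csr_matrix(adata.X).sum(axis=1)).ravel()

    n_spots, n_types = adata.n_obs, len(ref.cell_types)
    coefs = np.zeros((n_spots, n_types))
    props = np.zeros((n_spots, n_types))
    residuals = np.zeros(n_spots)
    flags = np.full(n_spots, FLAG_OK, dtype=object)
    if weighting not in ("nb", "none"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    dense = np.asarray(X.todense())
    nonzero = totals > 0
    flags[~nonzero] = FLAG_ZERO
    sf = np.where(nonzero, scale / np.maximum(totals, 1.0), 0.0)
    Y = dense * sf[:, None]
    for i in np.flatnonzero(nonzero):
        x, res, flag = nnls_fit(design, Y[i])
        coefs[i], residuals[i], flags[i] = x, res, flag
    if weighting == "nb":
        idx = np.flatnonzero(nonzero)
        for _ in range(n_iter):
            fit = coefs[idx] @ design.T
            theta = estimate_dispersion(fit, Y[idx], sf[idx])
            for j, i in enumerate(idx):
                var = sf[i] * fit[j] + fit[j] ** 2 / theta
                w = 1.0 / np.sqrt(np.maximum(var, 1e-12))
                x, res, flag = nnls_fit(design * w[:, None], Y[i] * w)
                coefs[i], flags[i] = x, flag
                residuals[i] = float(
                    np.linalg.norm(design @ x - Y[i]))
    for i in np.flatnonzero(nonzero):
        s = coefs[i].sum()
        if s > 0:
            props[i] = coefs[i] / s
    index = adata.obs_names
    return FractionTable(
        coefficients=pd.DataFrame(coefs, index=index, columns=ref.cell_types),
        proportions=pd.DataFrame(props, index=index, columns=ref.cell_types),
        residual=pd.Series(residuals, index=index, name="residual"),
        flag=pd.Series(flags, index=index, name="flag"),
    )
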