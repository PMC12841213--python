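"""Spatial statistics: kNN spatial weights, Moran's I with permutation
inference, the γδT–MAIT imbalance index and rank correlations with severity.

Moran's I on a field x over weights w:

    I = (N / W) * Σ_ij w_ij (x_i - x̄)(x_j - x̄) / Σ_i (x_i - x̄)²

with W = Σ_ij w_ij and null expectation E[I] = -1/(N-1). Weights default to
a binary 6-nearest-neighbour graph symmetrised by union, the natural scheme
on the hexagonal Visium lattice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .errors import ParameterError, ValidationError

log = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_CONSTANT = "constant_field"


@dataclass
class SpatialWeights:
    ids: np.ndarray
    w: sp.csr_matrix  # symmetric, zero diagonal unless row-standardised
    k: int
    row_standardised: bool = False

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def total(self) -> float:
        return float(self.w.sum())


def build_spatial_weights(coords, k: int = 6, ids=None,
                          row_standardise: bool = False) -> SpatialWeights:
    """Binary kNN graph on 2-D coordinates, symmetrised by union.

    Neighbour ranking is by Euclidean distance with ties broken by spot
    index order (deterministic for duplicated coordinates); no self-edges.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < k + 1:
        raise ParameterError(
            f"{n} spots cannot support k={k}; reduce k to at most {n - 1}"
        )
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    rows, cols = [], []
    order_idx = np.arange(n)
    for i in range(n):
        cand = np.delete(order_idx, i)
        dist = d[i, cand]
        sel = cand[np.lexsort((cand, dist))[:k]]
        rows.extend([i] * k)
        cols.extend(sel.tolist())
    w = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    w = w.maximum(w.T)  # union symmetrisation, binary
    if row_standardise:
        inv = 1.0 / np.asarray(w.sum(axis=1)).ravel()
        w = sp.diags(inv) @ w
    if ids is None:
        ids = np.arange(n)
    return SpatialWeights(np.asarray(ids), sp.csr_matrix(w), k,
                          row_standardise)


def morans_i(values, weights: SpatialWeights) -> dict:
    """Global Moran's I; constant fields yield NaN with a flag, no raise."""
    x = np.asarray(values, dtype=float)
    if x.shape[0] != weights.n:
        raise ValidationError("values not aligned to weights")
    n = x.shape[0]
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        return {"I": np.nan, "N": n, "expected": -1.0 / (n - 1),
                "p": np.nan, "n_perm": 0, "flag": FLAG_CONSTANT}
    W = weights.total
    num = float(z @ (weights.w @ z))
    return {"I": (n / W) * num / denom, "N": n,
            "expected": -1.0 / (n - 1), "p": np.nan, "n_perm": 0,
            "flag": FLAG_OK}


def morans_permutation(values, weights: SpatialWeights, n_perm: int = 199,
                       seed: int = 0) -> dict:
    """Moran's I with a two-sided permutation p-value.

    p = (1 + #{|I_perm - E[I]| >= |I_obs - E[I]|}) / (n_perm + 1), with the
    +1/+1 correction guaranteeing p in (0, 1]. Spot labels are permuted with
    a seeded generator; deterministic for a fixed seed.
    """
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    res = morans_i(values, weights)
    if res["flag"] == FLAG_CONSTANT:
        res["p"] = 1.0
        res["n_perm"] = n_perm
        return res
    x = np.asarray(values, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    z = x - x.mean()
    denom = float(z @ z)
    W = weights.total
    perms = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)
    # row-wise quadratic form z' W z, vectorised over permutations
    nums = np.einsum("ij,ij->i", perms, perms @ weights.w.T.toarray()
                     if n <= 2048 else (weights.w @ perms.T).T)
    i_perm = (n / W) * nums / denom
    e_i = res["expected"]
    extreme = np.abs(i_perm - e_i) >= abs(res["I"] - e_i) - 1e-12
    res["p"] = float((1 + extreme.sum()) / (n_perm + 1))
    res["n_perm"] = n_perm
    return res


def imbalance_index(summary: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """γδT–MAIT imbalance per lesional sample.

    index = z(epidermal MAIT %) - z(dermal γδT %), z-scored across the
    lesional samples (sd with the n-1 denominator). Requires >= 3 lesional
    samples carrying both components; a zero-variance component makes the
    index undefined and raises.
    """
    les = summary[summary["group"] == "L"]
    derm = les[les["layer"] == "dermis"].set_index("sample")["pct_gdT"]
    epid = les[les["layer"] == "epidermis"].set_index("sample")["pct_MAIT"]
    common = derm.index.intersection(epid.index)
    if len(common) < 3:
        raise ValidationError(
            f"imbalance index needs >= 3 lesional samples with both "
            f"components; found {len(common)}"
        )
    derm, epid = derm.loc[common], epid.loc[common]
    sd_d, sd_e = derm.std(ddof=ddof), epid.std(ddof=ddof)
    if sd_d == 0 or sd_e == 0:
        raise ValidationError("zero variance in an imbalance component")
    z_d = (derm - derm.mean()) / sd_d
    z_e = (epid - epid.mean()) / sd_e
    out = pd.DataFrame({
        "sample": common,
        "z_epid_MAIT": z_e.to_numpy(),
        "z_derm_gdT": z_d.to_numpy(),
    })
    out["index"] = out["z_epid_MAIT"] - out["z_derm_gdT"]
    return out.reset_index(drop=True)


def severity_correlation(x, pasi) -> dict:
    """Spearman rank correlation of a niche feature with PASI.

    Average ranks for ties; p from the large-sample t approximation.
    Pairs with missing PASI (or missing x) are dropped and counted. With
    fewer than 4 complete pairs rho is reported without a p-value.
    """
    x = np.asarray(x, dtype=float)
    pasi = np.asarray(pasi, dtype=float)
    if x.shape != pasi.shape:
        raise ValidationError("x and pasi must be paired")
    ok = ~(np.isnan(x) | np.isnan(pasi))
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("severity_correlation: dropped %d incomplete pairs",
                 n_dropped)
    x, pasi = x[ok], pasi[ok]
    n = x.size
    if n < 2 or np.ptp(x) == 0 or np.ptp(pasi) == 0:
        return {"rho": np.nan, "p": np.nan, "n": n, "flag": "undefined"}
    rho, p = scipy.stats.spearmanr(x, pasi)
    if n < 4:
        return {"rho": float(rho), "p": np.nan, "n": n, "flag": "small_n"}
    return {"rho": float(rho), "p": float(p), "n": n, "flag": FLAG_OK}
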