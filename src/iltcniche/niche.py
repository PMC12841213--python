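"""Niche calling: signature scoring, adaptive T-cell gating and
dominance-based assignment of γδT / MAIT / iNKT labels to spots.

A spot is eligible for a niche label only if its deconvolved pan-T fraction
clears a per-sample adaptive threshold (quantile with a floor), which absorbs
sample-to-sample variation in immune-cell density. Among eligible spots the
label is the subset whose within-sample z-scored signature dominates, and
only if that z-score is positive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .deconvolution import FractionTable
from .errors import ParameterError, ValidationError
from .io import SignatureSet
from .reference import T_CELL_TYPES

log = logging.getLogger(__name__)

NICHE_LABELS = ("gdT", "MAIT", "iNKT")
LABEL_NONE = "none"

#: niche label -> reference cell type carrying its deconvolved fraction
SUBSET_CELL_TYPE = {"gdT": "T_gdT", "MAIT": "T_MAIT", "iNKT": "T_iNKT"}

#: niche label -> conventional signature-set name in the GMT
SUBSET_SIGNATURE = {"gdT": "gdT", "MAIT": "MAIT", "iNKT": "iNKT"}


def score_signature(log_expr, genes, gene_set, mode: str = "plain_mean",
                    seed: int = 0, n_bins: int = 25,
                    n_control: int = 50) -> np.ndarray:
    """Per-spot module score over a gene set.

    plain_mean: mean log-normalised expression over the set's genes present
    in the data. control_corrected: subtracts the mean over a size-matched
    control pool drawn (seeded) from ``n_bins`` expression bins, ``n_control``
    control genes per signature gene, matching on mean expression.
    """
    log_expr = np.asarray(log_expr, dtype=float)
    genes = pd.Index(genes)
    present = [g for g in gene_set if g in genes]
    if not present:
        raise ValidationError(
            f"no signature gene present in the data (set of "
            f"{len(list(gene_set))} genes)"
        )
    cols = genes.get_indexer(present)
    sig_score = log_expr[:, cols].mean(axis=1)
    if mode == "plain_mean":
        return sig_score
    if mode != "control_corrected":
        raise ParameterError(f"unknown scoring mode {mode!r}")
    rng = np.random.default_rng(seed)
    gene_means = log_expr.mean(axis=0)
    n_bins = min(n_bins, len(genes))
    bins = pd.qcut(pd.Series(gene_means, index=genes), n_bins,
                   labels=False, duplicates="drop")
    ctrl_idx: list[int] = []
    for g in present:
        pool = np.flatnonzero(bins.to_numpy() == bins[g])
        take = rng.choice(pool, size=min(n_control, pool.size),
                          replace=False)
        ctrl_idx.extend(take.tolist())
    ctrl_score = log_expr[:, ctrl_idx].mean(axis=1)
    return sig_score - ctrl_score


def score_all_signatures(log_expr, genes, signatures: SignatureSet,
                         mode: str = "plain_mean", seed: int = 0,
                         n_bins: int = 25, n_control: int = 50,
                         index=None) -> pd.DataFrame:
    """Score every set in a SignatureSet; one column per set."""
    out = {}
    for i, (name, gene_list) in enumerate(signatures.items()):
        out[name] = score_signature(log_expr, genes, gene_list, mode=mode,
                                    seed=seed + i, n_bins=n_bins,
                                    n_control=n_control)
    return pd.DataFrame(out, index=index)


def adaptive_threshold(values, quantile: float = 0.8, floor: float = 0.05,
                       min_spots: int = 10) -> float:
    """Per-sample T gate: max(linear-interpolation quantile, floor).

    Samples with fewer than ``min_spots`` spots fall back to the floor.
    """
    if not 0 < quantile < 1:
        raise ParameterError("quantile must lie in (0, 1)")
    values = np.asarray(values, dtype=float)
    if values.size < min_spots:
        log.warning("adaptive_threshold: only %d spots; using floor %.3g",
                    values.size, floor)
        return float(floor)
    return float(max(np.quantile(values, quantile), floor))


def call_niches(fractions: FractionTable, subset_scores: pd.DataFrame,
                samples: pd.Series, t_gate_quantile: float = 0.8,
                t_gate_floor: float = 0.05,
                t_cell_types=T_CELL_TYPES) -> pd.DataFrame:
    """Assign one niche label per spot.

    Rules, in order: (1) a spot passes the T gate iff its pan-T deconvolved
    fraction >= its sample's adaptive threshold (inclusive); (2) among
    passing spots the label is the subset with the largest within-sample
    z-scored signature, provided that z-score is > 0; (3) ties break by the
    larger corresponding deconvolved subset fraction, then by the fixed
    order gdT > MAIT > iNKT. Requested subsets without a signature column
    are skipped with a warning (e.g. datasets where iNKT could not be
    assessed).
    """
    subsets = [s for s in NICHE_LABELS if s in subset_scores.columns]
    missing = [s for s in NICHE_LABELS if s not in subset_scores.columns]
    if missing:
        log.warning("subsets without signature scores skipped: %s", missing)
    if not subsets:
        raise ValidationError("no subset signature scores provided")
    if not subset_scores.index.equals(fractions.proportions.index):
        raise ValidationError("fractions and scores not aligned on spots")

    t_frac = fractions.t_fraction(t_cell_types)
    samples = samples.loc[t_frac.index]

    thresholds = {
        s: adaptive_threshold(t_frac[samples == s],
                              quantile=t_gate_quantile, floor=t_gate_floor)
        for s in samples.unique()
    }
    thr = samples.map(thresholds).astype(float)
    passes = t_frac >= thr

    # within-sample z-scores per subset (sd with n-1; constant -> z = 0)
    z = {}
    for sub in subsets:
        col = subset_scores[sub]
        mu = col.groupby(samples).transform("mean")
        sd = col.groupby(samples).transform(lambda v: v.std(ddof=1))
        z[sub] = ((col - mu) / sd.replace(0, np.nan)).fillna(0.0)
    zdf = pd.DataFrame(z)

    labels = pd.Series(LABEL_NONE, index=t_frac.index, dtype=object)
    pass_idx = t_frac.index[passes.to_numpy()]
    if len(pass_idx):
        zp = zdf.loc[pass_idx]
        zmax = zp.max(axis=1)
        eligible = zmax > 0
        for spot in pass_idx[eligible.to_numpy()]:
            row = zp.loc[spot]
            best = row[row == row.max()].index.tolist()
            if len(best) > 1:
                fr = fractions.proportions.loc[spot]
                sub_fr = {s: fr.get(SUBSET_CELL_TYPE[s], 0.0) for s in best}
                top = max(sub_fr.values())
                best = [s for s in best if sub_fr[s] == top]
                best.sort(key=lambda s: NICHE_LABELS.index(s))
            labels[spot] = best[0]

    out = pd.DataFrame({
        "sample": samples,
        "T_fraction": t_frac,
        "threshold": thr,
        "passes_gate": passes,
        "label": labels,
    })
    for sub in subsets:
        out[f"score_{sub}"] = subset_scores[sub]
        out[f"z_{sub}"] = zdf[sub]
    return out


def niche_frequencies(calls: pd.DataFrame, obs: pd.DataFrame,
                      min_spots: int = 20) -> pd.DataFrame:
    """Per sample x layer niche percentages.

    pct_X = 100 * #spots labelled X / #spots in that sample and layer.
    Layers with zero spots simply yield no row; cells with fewer than
    ``min_spots`` spots are flagged low_n.
    """
    meta = obs[["sample", "layer", "group"]].copy()
    if "pasi" in obs.columns:
        meta["pasi"] = obs["pasi"]
    else:
        meta["pasi"] = np.nan
    df = meta.join(calls[["label"]], how="inner")
    rows = []
    for (sample, layer), sub in df.groupby(["sample", "layer"],
                                           observed=True):
        n = len(sub)
        row = {
            "sample": sample,
            "layer": layer,
            "group": sub["group"].iloc[0],
            "pasi": sub["pasi"].iloc[0],
            "n_spots": n,
            "low_n": n < min_spots,
        }
        for lab in NICHE_LABELS:
            row[f"pct_{lab}"] = 100.0 * (sub["label"] == lab).sum() / n
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["sample", "layer"]).reset_index(drop=True)
    return out


def lesion_ratio(summary: pd.DataFrame, donors: pd.Series | None = None
                 ) -> pd.DataFrame:
    """Per-donor lesional : non-lesional niche-percentage ratios by layer.

    Donors default to the sample-name convention "<donor>_L" / "<donor>_NL".
    A zero non-lesional percentage is replaced by the pseudo-frequency
    100/(n_spots + 1) and the row flagged. Unpaired samples are excluded
    and logged.
    """
    df = summary.copy()
    if donors is not None:
        df["donor"] = df["sample"].map(donors)
    else:
        def _strip(s: str):
            for suf in ("_L", "_NL"):
                if s.endswith(suf):
                    return s[: -len(suf)]
            return None
        df["donor"] = df["sample"].map(_strip)
    df = df[df["group"].isin(["L", "NL"])]
    rows = []
    for (donor, layer), sub in df.groupby(["donor", "layer"], observed=True,
                                          dropna=True):
        les = sub[sub["group"] == "L"]
        non = sub[sub["group"] == "NL"]
        if len(les) != 1 or len(non) != 1:
            log.info("lesion_ratio: donor %s layer %s unpaired; excluded",
                     donor, layer)
            continue
        for lab in NICHE_LABELS:
            pct_l = float(les[f"pct_{lab}"].iloc[0])
            pct_nl = float(non[f"pct_{lab}"].iloc[0])
            pseudo = False
            if pct_nl == 0.0:
                pct_nl = 100.0 / (float(non["n_spots"].iloc[0]) + 1.0)
                pseudo = True
            rows.append({
                "donor": donor, "layer": layer, "subset": lab,
                "ratio": pct_l / pct_nl, "pseudo_denominator": pseudo,
            })
    return pd.DataFrame(rows)
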