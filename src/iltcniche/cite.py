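"""CITE-seq companion stage: CLR normalisation of antibody-derived tag (ADT)
counts, hierarchical programmatic gating of innate-like T-cell subsets,
per-donor subset frequencies, and RNA–protein concordance.

Gating thresholds are computed once on the full cohort (fixed CLR cutoff or
cohort quantile among parent-positive cells) and applied identically to all
donors, replacing interactive gating with an explicit, reproducible rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .spatial import severity_correlation

log = logging.getLogger(__name__)


def clr_transform(adt: pd.DataFrame, margin: str = "per_cell") -> pd.DataFrame:
    """Centred log-ratio transform with a +1 pseudo-count.

    per_cell (classical compositional definition): for each cell,
    clr(x_i) = ln(x_i + 1) - mean_j ln(x_j + 1) over that cell's markers.
    per_feature: the same centring across cells of one marker.
    """
    if (adt.to_numpy() < 0).any():
        raise ValidationError("ADT counts must be nonnegative")
    lx = np.log1p(adt.astype(float))
    if margin == "per_cell":
        if adt.shape[1] == 1:
            log.warning("single-marker panel: per-cell CLR is identically 0")
        return lx.sub(lx.mean(axis=1), axis=0)
    if margin == "per_feature":
        return lx.sub(lx.mean(axis=0), axis=1)
    raise ParameterError(f"unknown CLR margin {margin!r}")


@dataclass
class GateSpec:
    """One gate: positivity on ``marker`` above a threshold, within parent.

    rule: ("fixed", cutoff) or ("quantile", q) — quantile thresholds are
    computed once over the CLR values of the full cohort, so every donor is
    gated against the same cutoffs; the hierarchy acts only through the
    AND with the parent gate.
    """

    name: str
    marker: str
    rule: tuple[str, float]
    parent: str | None = None  # None = root (applied to all cells)


#: editable defaults; each quantile is set so the threshold falls in the
#: valley below the shifted positive cloud rather than inside it — for a
#: two-marker AND gate (MAIT) the per-cell CLR couples the markers (two
#: elevated markers raise the cell mean and drag both CLR values down), so
#: those quantiles sit a little lower than 1 minus the expected frequency
DEFAULT_GATES = [
    # root: leukocytes (CD45 is high on essentially all PBMC events)
    GateSpec("CD45pos", "CD45", ("quantile", 0.05)),
    GateSpec("gdT", "TCRgd", ("quantile", 0.95), parent="CD45pos"),
    GateSpec("MAIT_CD161", "CD161", ("quantile", 0.90), parent="CD45pos"),
    GateSpec("MAIT", "TCRVa7_2", ("quantile", 0.92), parent="MAIT_CD161"),
    GateSpec("iNKT", "Va24Ja18", ("quantile", 0.985), parent="CD45pos"),
]


def gate_positive(clr: pd.DataFrame, gate_specs: list[GateSpec]
                  ) -> pd.DataFrame:
    """Evaluate a gating hierarchy; returns cell x gate booleans.

    A cell is positive for a gate iff its CLR value exceeds the threshold
    (strict >) AND it is positive for the parent gate. Thresholds are
    resolved once on the full cohort. Gates must be listed parents-first.
    """
    gates = pd.DataFrame(index=clr.index)
    for spec in gate_specs:
        if spec.marker not in clr.columns:
            raise ValidationError(f"unknown marker {spec.marker!r} in gate "
                                  f"{spec.name!r}")
        if spec.parent is None:
            parent_mask = pd.Series(True, index=clr.index)
        else:
            if spec.parent not in gates.columns:
                raise ValidationError(
                    f"gate {spec.name!r} references undefined parent "
                    f"{spec.parent!r} (gates must be listed parents-first)"
                )
            parent_mask = gates[spec.parent]
        kind, value = spec.rule
        vals = clr[spec.marker]
        if kind == "fixed":
            thr = float(value)
        elif kind == "quantile":
            thr = float(np.quantile(vals.to_numpy(), value))
        else:
            raise ParameterError(f"unknown gate rule {kind!r}")
        gates[spec.name] = (vals > thr) & parent_mask
    return gates


def subset_frequencies(gates: pd.DataFrame, meta: pd.DataFrame,
                       root: str = "CD45pos",
                       subset_gates=("gdT", "MAIT", "iNKT"),
                       phenotype_gates=(), min_root: int = 50
                       ) -> pd.DataFrame:
    """Per-donor subset frequencies as % of root-positive cells.

    Phenotype gates (children of a subset gate) are summarised as the
    marker-positive % within that subset; a subset with zero cells reports
    a missing percentage and is flagged. Donors with fewer than ``min_root``
    root-positive cells are flagged low_n.
    """
    if root not in gates.columns:
        raise ValidationError(f"root gate {root!r} missing")
    df = gates.join(meta[["donor", "group"]])
    rows = []
    for donor, sub in df.groupby("donor", observed=True):
        n_root = int(sub[root].sum())
        row = {"donor": donor, "group": sub["group"].iloc[0],
               "n_root": n_root, "low_n": n_root < min_root}
        for g in subset_gates:
            if g not in sub.columns:
                continue
            n_sub = int(sub[g].sum())
            row[f"pct_{g}"] = 100.0 * n_sub / n_root if n_root else np.nan
            for ph in phenotype_gates:
                pg, parent = (ph if isinstance(ph, tuple) else (ph, g))
                if parent != g or pg not in sub.columns:
                    continue
                if n_sub == 0:
                    row[f"pct_{pg}_of_{g}"] = np.nan
                    row[f"flag_{pg}_of_{g}"] = "empty_subset"
                else:
                    row[f"pct_{pg}_of_{g}"] = \
                        100.0 * int(sub[pg].sum()) / n_sub
        rows.append(row)
    return pd.DataFrame(rows).sort_values("donor").reset_index(drop=True)


def rna_protein_concordance(rna_scores: pd.Series, adt_freqs: pd.Series
                            ) -> dict:
    """Spearman concordance between per-donor mean RNA gene-set score and
    the ADT-defined subset frequency (same statistic as the severity
    correlations)."""
    common = rna_scores.index.intersection(adt_freqs.index)
    return severity_correlation(rna_scores.loc[common].to_numpy(),
                                adt_freqs.loc[common].to_numpy())
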