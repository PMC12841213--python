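"""End-to-end orchestration: simulate/load a cohort, call niches, and write
the CSV reports. All stages are seeded through RunConfig, so a run is
deterministic: the same seed and config produce byte-identical reports.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import cite as cite_mod
from . import expression, niche, spatial
from .config import RunConfig
from .deconvolution import deconvolve_spots
from .errors import IltcError, ValidationError
from .io import (SignatureSet, read_gmt, read_spot_dataset, qc_filter,
                 write_gmt, write_spot_dataset)
from .reference import ReferenceProfile, read_reference, write_reference
from .synthetic import Cohort

log = logging.getLogger(__name__)

CSV_FLOAT = "%.10g"

REPORTS = ("niche_calls.csv", "sample_summary.csv", "severity_stats.csv",
           "de_table.csv", "enrichment.csv", "cite_summary.csv")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a simulated cohort as MTX+TSV per section plus reference,
    signature GMT, and ground-truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truths = []
    for adata, truth in cohort.sections:
        write_spot_dataset(adata, out_dir, prefix=truth.sample)
        t = truth.labels.to_frame()
        t.insert(0, "sample", truth.sample)
        truths.append(t.reset_index())
    if truths:
        pd.concat(truths).to_csv(out_dir / "ground_truth.csv", index=False)
    cohort.samples.to_csv(out_dir / "sample_table.csv", index=False,
                          float_format=CSV_FLOAT)
    if cohort.reference is not None:
        write_reference(cohort.reference, out_dir / "reference.csv")
    if cohort.signatures is not None:
        write_gmt(cohort.signatures, out_dir / "signatures.gmt")


def load_cohort_dir(data_dir: str | Path) -> ad.AnnData:
    """Concatenate every <sample>.counts.mtx (+sidecars) in a directory."""
    data_dir = Path(data_dir)
    mtx_files = sorted(data_dir.glob("*.counts.mtx"))
    if not mtx_files:
        raise ValidationError(f"no *.counts.mtx files in {data_dir}")
    parts = []
    for mtx in mtx_files:
        prefix = mtx.name[: -len(".counts.mtx")]
        parts.append(read_spot_dataset(
            mtx, data_dir / f"{prefix}.spots.tsv",
            data_dir / f"{prefix}.genes.tsv"))
    return ad.concat(parts, merge="same") if len(parts) > 1 else parts[0]


def _severity_stats(summary: pd.DataFrame, imb: pd.DataFrame | None,
                    moran: pd.DataFrame) -> pd.DataFrame:
    """Rank correlations of niche features (and Moran's I) with PASI over
    lesional samples."""
    rows = []
    les = summary[summary["group"] == "L"]
    for layer in ("dermis", "epidermis"):
        sub = les[les["layer"] == layer]
        for lab in niche.NICHE_LABELS:
            r = spatial.severity_correlation(sub[f"pct_{lab}"].to_numpy(),
                                             sub["pasi"].to_numpy())
            rows.append({"feature": f"pct_{lab}", "layer": layer, **r})
    if imb is not None and len(imb):
        pasi = les.drop_duplicates("sample").set_index("sample")["pasi"]
        common = imb.set_index("sample")["index"]
        r = spatial.severity_correlation(
            common.to_numpy(), pasi.loc[common.index].to_numpy())
        rows.append({"feature": "imbalance_index", "layer": "", **r})
    if len(moran):
        m = moran.merge(les[["sample", "pasi"]].drop_duplicates("sample"),
                        on="sample", how="inner")
        for (layer, subset), sub in m.groupby(["layer", "subset"]):
            r = spatial.severity_correlation(sub["I"].to_numpy(),
                                             sub["pasi"].to_numpy())
            rows.append({"feature": f"moran_{subset}", "layer": layer, **r})
    cols = ["feature", "layer", "rho", "p", "n", "flag"]
    return pd.DataFrame(rows, columns=cols)


def _moran_table(calls: pd.DataFrame, obs: pd.DataFrame,
                 config: RunConfig) -> pd.DataFrame:
    """Moran's I of each subset's niche-indicator field per sample x layer."""
    rows = []
    df = obs[["sample", "layer", "x", "y"]].join(calls[["label"]],
                                                 how="inner")
    for gi, ((sample, layer), sub) in enumerate(
            df.groupby(["sample", "layer"], observed=True)):
        if len(sub) < config.knn_k + 1:
            continue
        weights = spatial.build_spatial_weights(
            sub[["x", "y"]].to_numpy(), k=config.knn_k)
        for li, lab in enumerate(niche.NICHE_LABELS):
            field = (sub["label"] == lab).to_numpy(float)
            res = spatial.morans_permutation(
                field, weights, n_perm=config.moran_n_perm,
                seed=config.seed * 100000 + gi * 10 + li)
            rows.append({"sample": sample, "layer": layer, "subset": lab,
                         "I": res["I"], "p": res["p"],
                         "n_perm": res["n_perm"], "n": res["N"],
                         "flag": res["flag"]})
    return pd.DataFrame(rows, columns=["sample", "layer", "subset", "I",
                                       "p", "n_perm", "n", "flag"])


def run_pipeline(config: RunConfig, data_dir: str | Path,
                 ref_path: str | Path | None = None,
                 gmt_path: str | Path | None = None,
                 out_dir: str | Path | None = None,
                 adt_path: str | Path | None = None,
                 adt_meta_path: str | Path | None = None,
                 rna_scores_path: str | Path | None = None) -> dict:
    """Run the full niche-mapping pipeline on a cohort directory.

    Writes niche_calls.csv, sample_summary.csv, severity_stats.csv,
    de_table.csv and enrichment.csv (plus fractions.csv, moran.csv and
    imbalance.csv); cite_summary.csv is written when ADT inputs are given.
    Returns the dict of written paths. Any stage failure raises; the CLI
    removes partial outputs in that case.
    """
    data_dir = Path(data_dir)
    out_dir = Path(out_dir or config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = read_reference(ref_path or data_dir / "reference.csv")
    sigs = read_gmt(gmt_path or data_dir / "signatures.gmt")

    adata = load_cohort_dir(data_dir)
    adata = qc_filter(adata, config.min_genes_per_spot,
                      config.max_mito_fraction, config.mito_prefix)

    fractions = deconvolve_spots(adata, ref, scale=config.norm_scale,
                                 min_gene_overlap=config.min_gene_overlap)
    log_expr = expression.log_normalize(adata.X, scale=config.norm_scale)
    scores = niche.score_all_signatures(
        log_expr, adata.var_names, sigs, mode=config.signature_mode,
        seed=config.seed, n_bins=config.n_expression_bins,
        n_control=config.n_control_genes, index=adata.obs_names)

    subset_cols = [s for s in niche.NICHE_LABELS if s in scores.columns]
    calls = niche.call_niches(fractions, scores[subset_cols],
                              adata.obs["sample"],
                              t_gate_quantile=config.t_gate_quantile,
                              t_gate_floor=config.t_gate_floor)
    summary = niche.niche_frequencies(calls, adata.obs)

    # per sample x layer module-score means over all spots
    module_cols = [c for c in scores.columns if c not in subset_cols]
    if module_cols and len(summary):
        mod = scores[module_cols].join(adata.obs[["sample", "layer"]])
        means = mod.groupby(["sample", "layer"], observed=True).mean()
        means.columns = [f"mod_{c}" for c in means.columns]
        summary = summary.merge(means.reset_index(),
                                on=["sample", "layer"], how="left")

    moran = _moran_table(calls, adata.obs, config)
    try:
        imb = spatial.imbalance_index(summary)
    except IltcError as exc:
        log.warning("imbalance index unavailable: %s", exc)
        imb = pd.DataFrame(columns=["sample", "z_epid_MAIT", "z_derm_gdT",
                                    "index"])
    les = summary[summary["group"] == "L"]
    if len(les) == 0 or les["pasi"].isna().all():
        log.warning("no lesional PASI available; severity stats empty")
        severity = pd.DataFrame(columns=["feature", "layer", "rho", "p",
                                         "n", "flag"])
    else:
        severity = _severity_stats(summary, imb, moran)

    # DE between γδT- and MAIT-labelled lesional spots, then enrichment
    lesional = adata.obs["group"] == "L"
    lab = calls["label"]
    de_mask = lesional & lab.isin(["gdT", "MAIT"])
    de_records, enr_rows = [], []
    if (lab[de_mask] == "gdT").sum() >= 3 and \
            (lab[de_mask] == "MAIT").sum() >= 3:
        sub_idx = np.flatnonzero(de_mask.to_numpy())
        de_records = expression.wilcoxon_de(
            log_expr[sub_idx], adata.var_names,
            (lab[de_mask] == "gdT").to_numpy())
        up, down = expression.filter_de(de_records, config.lfc_min,
                                        config.alpha)
        universe = [r.gene for r in de_records]
        for direction, recs in (("gdT_up", up), ("MAIT_up", down)):
            if not recs:
                continue
            for e in expression.hypergeom_enrich(
                    [r.gene for r in recs], sigs, universe):
                enr_rows.append({"direction": direction,
                                 "set_name": e.set_name, "overlap": e.overlap,
                                 "set_size": e.set_size,
                                 "query_size": e.query_size,
                                 "universe_size": e.universe_size,
                                 "gene_ratio": e.gene_ratio, "p": e.p,
                                 "p_adj": e.p_adj})
    else:
        log.warning("too few γδT/MAIT lesional spots for DE; tables empty")

    de_table = pd.DataFrame(
        [vars(r) for r in de_records],
        columns=["gene", "log_fc", "p", "p_adj", "pct_a", "pct_b"])
    enrichment = pd.DataFrame(
        enr_rows, columns=["direction", "set_name", "overlap", "set_size",
                           "query_size", "universe_size", "gene_ratio",
                           "p", "p_adj"])

    paths = {}

    def _write(name: str, df: pd.DataFrame, index=False):
        p = out_dir / name
        df.to_csv(p, index=index, float_format=CSV_FLOAT)
        paths[name] = p

    calls_out = calls.copy()
    calls_out.insert(0, "spot", calls_out.index)
    _write("niche_calls.csv", calls_out.reset_index(drop=True))
    fr = fractions.proportions.copy()
    fr.insert(0, "spot", fr.index)
    fr["residual"] = fractions.residual
    fr["flag"] = fractions.flag
    _write("fractions.csv", fr.reset_index(drop=True))
    _write("sample_summary.csv", summary)
    _write("severity_stats.csv", severity)
    _write("moran.csv", moran)
    _write("imbalance.csv", imb)
    _write("de_table.csv", de_table)
    _write("enrichment.csv", enrichment)

    if adt_path is not None:
        cite_summary = run_cite_stage(config, adt_path, adt_meta_path,
                                      rna_scores_path, out_dir)
        paths.update(cite_summary)
    return paths


def run_cite_stage(config: RunConfig, adt_path, adt_meta_path,
                   rna_scores_path=None,
                   out_dir: str | Path = ".") -> dict:
    """CLR-normalise ADT counts, gate subsets, summarise per donor, and
    (when RNA scores are supplied) test RNA-protein concordance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    adt = pd.read_csv(adt_path, index_col=0)
    meta = pd.read_csv(adt_meta_path, sep="\t", index_col=0)
    clr = cite_mod.clr_transform(adt, margin=config.clr_margin)
    gates = cite_mod.gate_positive(clr, cite_mod.DEFAULT_GATES)
    freqs = cite_mod.subset_frequencies(gates, meta)
    paths = {}
    freqs.to_csv(out_dir / "cite_summary.csv", index=False,
                 float_format=CSV_FLOAT)
    paths["cite_summary.csv"] = out_dir / "cite_summary.csv"
    if rna_scores_path is not None:
        rna = pd.read_csv(rna_scores_path, index_col=0)
        cd45 = gates["CD45pos"]
        rows = []
        for sub in ("gdT", "MAIT", "iNKT"):
            if sub not in rna.columns or f"pct_{sub}" not in freqs.columns:
                continue
            donor_means = rna.loc[cd45].join(meta["donor"]) \
                .groupby("donor")[sub].mean()
            r = cite_mod.rna_protein_concordance(
                donor_means, freqs.set_index("donor")[f"pct_{sub}"])
            rows.append({"subset": sub, **r})
        conc = pd.DataFrame(rows, columns=["subset", "rho", "p", "n",
                                           "flag"])
        conc.to_csv(out_dir / "cite_concordance.csv", index=False,
                    float_format=CSV_FLOAT)
        paths["cite_concordance.csv"] = out_dir / "cite_concordance.csv"
    return paths
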