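"""Readers/writers for the on-disk formats the pipeline touches.

Spot datasets are MatrixMarket ("coordinate integer general", genes as rows,
matching common Visium exports) plus two TSV sidecars; gene-set collections
are standard GMT. In memory a spot dataset is an AnnData with spots as
observations and genes as variables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

VALID_LAYERS = ("epidermis", "dermis")
VALID_GROUPS = ("HC", "NL", "L")

OBS_COLUMNS = ("x", "y", "layer", "sample", "group", "pasi")


class SignatureSet:
    """Ordered, named gene sets (GMT contents).

    Genes within a set are de-duplicated preserving first occurrence.
    """

    def __init__(self, sets: dict[str, list[str]] | None = None,
                 descriptions: dict[str, str] | None = None):
        self._sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = descriptions or {}
        for name, genes in (sets or {}).items():
            self.add(name, genes)

    def add(self, name: str, genes: list[str], description: str = "") -> None:
        if not genes:
            raise ValidationError(f"gene set {name!r} is empty")
        if name in self._sets:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(g, None)
        self._sets[name] = list(seen)
        if description:
            self.descriptions[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def names(self) -> list[str]:
        return list(self._sets)

    def items(self):
        return ((k, list(v)) for k, v in self._sets.items())


def read_gmt(path: str | Path) -> SignatureSet:
    """Parse a GMT file: name <tab> description <tab> gene1 [<tab> gene2...]."""
    sigs = SignatureSet()
    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected name, description and at least one gene"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} empty")
            sigs.add(name, genes, desc)
    if n_lines == 0:
        log.warning("GMT file %s is empty", path)
    return sigs


def write_gmt(sigs: SignatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sigs.items():
            desc = sigs.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _validate_obs(spots: pd.DataFrame, path) -> None:
    required = ["barcode", "x", "y", "layer", "sample", "group"]
    missing = [c for c in required if c not in spots.columns]
    if missing:
        raise FormatError(f"{path}: spots table missing columns {missing}")
    dup = spots["barcode"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate barcodes: "
            f"{spots.loc[dup, 'barcode'].tolist()[:5]}"
        )
    for col, valid in (("layer", VALID_LAYERS), ("group", VALID_GROUPS)):
        bad = ~spots[col].isin(valid)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: row {row + 1}: invalid {col} "
                f"{spots[col].iloc[row]!r}; allowed: {valid}"
            )


def read_spot_dataset(counts_path: str | Path, spots_path: str | Path,
                      genes_path: str | Path) -> ad.AnnData:
    """Load a gene x spot MTX with TSV sidecars into an AnnData (spots x genes).

    Missing PASI is encoded as an empty field and becomes NaN (0 is a valid
    PASI and is never used as a missing marker).
    """
    try:
        _, _, _, _, field, _ = scipy.io.mminfo(counts_path)
    except ValueError as exc:
        raise FormatError(f"{counts_path}: not MatrixMarket: {exc}") from exc
    if field != "integer":
        raise FormatError(
            f"{counts_path}: expected 'coordinate integer' MatrixMarket "
            f"counts, found field {field!r}"
        )
    counts = sp.csr_matrix(scipy.io.mmread(counts_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    spots = pd.read_csv(spots_path, sep="\t", dtype={"barcode": str,
                                                     "sample": str})
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"{counts_path}: {counts.shape[0]} gene rows but "
            f"{len(genes)} symbols in {genes_path}"
        )
    if counts.shape[1] != len(spots):
        raise FormatError(
            f"{counts_path}: {counts.shape[1]} spot columns but "
            f"{len(spots)} rows in {spots_path}"
        )
    if genes.duplicated().any():
        raise ValidationError(f"{genes_path}: duplicate gene symbols")
    _validate_obs(spots, spots_path)
    obs = spots.set_index("barcode")
    if "pasi" not in obs.columns:
        obs["pasi"] = np.nan
    obs["pasi"] = pd.to_numeric(obs["pasi"], errors="coerce")
    obs = obs[list(OBS_COLUMNS)]
    adata = ad.AnnData(
        X=counts.T.tocsr().astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata


def write_spot_dataset(adata: ad.AnnData, out_dir: str | Path,
                       prefix: str = "section") -> dict[str, Path]:
    """Write counts.mtx + spots.tsv + genes.tsv for one dataset/section."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / f"{prefix}.counts.mtx",
        "spots": out_dir / f"{prefix}.spots.tsv",
        "genes": out_dir / f"{prefix}.genes.tsv",
    }
    X = sp.coo_matrix(adata.X).T.astype(np.int64)  # genes x spots on disk
    scipy.io.mmwrite(str(paths["counts"]), X, field="integer")
    obs = adata.obs.reset_index(names="barcode")[["barcode", *OBS_COLUMNS]]
    obs.to_csv(paths["spots"], sep="\t", index=False, na_rep="")
    pd.Series(adata.var_names).to_csv(paths["genes"], sep="\t", index=False,
                                      header=False)
    return paths


def qc_filter(adata: ad.AnnData, min_genes_per_spot: int = 20,
              max_mito_fraction: float = 0.2,
              mito_prefix: str = "MT-") -> ad.AnnData:
    """Drop spots with too few detected genes or too high a mito fraction.

    Filtering is idempotent; retention is logged per sample and samples
    losing every spot trigger a warning (they vanish from all downstream
    frequency tables).
    """
    X = sp.csr_matrix(adata.X)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_mask = np.array([g.startswith(mito_prefix)
                          for g in adata.var_names])
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel().astype(float) \
        if mito_mask.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1.0), 0.0)
    keep = (detected >= min_genes_per_spot) & (mito_frac <= max_mito_fraction)
    for sample, idx in adata.obs.groupby("sample", observed=True).indices.items():
        n_before, n_after = len(idx), int(keep[idx].sum())
        log.info("QC %s: %d -> %d spots", sample, n_before, n_after)
        if n_after == 0:
            log.warning("QC removed every spot of sample %s; sample dropped",
                        sample)
    return adata[keep].copy()
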