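"""Synthetic Visium-like cohorts and CITE-seq-like matrices with known
ground truth.

The generator emulates the structure of the real study inputs: hexagonal
spot lattices split into an epidermal band and dermal remainder, spot counts
drawn negative-binomial around a mixture of reference cell-type profiles,
planted γδT/MAIT/iNKT-enriched spots with layer-biased placement, a
per-sample PASI covariate with monotone links to niche proportions
(dermal γδT decreasing, epidermal MAIT increasing), and a paired ADT+RNA
matrix with planted subset frequencies. Every downstream stage therefore
has a parameter-recovery oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ParameterError
from .io import SignatureSet
from .reference import CORE_CELL_TYPES, T_CELL_TYPES, ReferenceProfile

log = logging.getLogger(__name__)

NICHE_SUBSETS = ("gdT", "MAIT", "iNKT")
SUBSET_TO_TYPE = {"gdT": "T_gdT", "MAIT": "T_MAIT", "iNKT": "T_iNKT"}

#: study conditions: planted subset fraction in a niche spot vs the total
#: background T fraction spread over all T lineages
NICHE_T_FRACTION = 0.25
BACKGROUND_T_FRACTION = 0.05

#: PASI range sampled for lesional donors and the linear severity links
PASI_RANGE = (2.0, 30.0)
DEFAULT_SEVERITY_LINK = {
    "dermal_gdT": (0.16, -0.005),    # intercept, slope per PASI unit
    "epidermal_MAIT": (0.02, 0.005),
}
#: background niche-spot proportion in HC / non-lesional skin (free
#: parameter of the generator; not derived from any published cohort)
BACKGROUND_NICHE_PROP = 0.02
#: lesional niche proportions without a severity link
LESIONAL_FIXED = {("epidermis", "gdT"): 0.08, ("dermis", "MAIT"): 0.05}


def _child_rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic per-stage/per-section child generator."""
    return np.random.default_rng([int(seed), *map(int, stream)])


def make_reference(n_genes: int = 300, cell_types=CORE_CELL_TYPES,
                   markers_per_type: int = 20, marker_fold: float = 8.0,
                   seed: int = 0) -> ReferenceProfile:
    """Reference with exclusive marker blocks over a log-normal baseline.

    Each cell type receives ``markers_per_type`` exclusive genes expressed
    at ``marker_fold`` times baseline in that type only.
    """
    cell_types = list(cell_types)
    n_types = len(cell_types)
    if n_genes < n_types * markers_per_type:
        raise ParameterError(
            f"{n_genes} genes cannot host {n_types} x {markers_per_type} "
            "exclusive markers"
        )
    if marker_fold <= 1:
        log.warning("marker_fold <= 1: cell types are not distinguishable; "
                    "downstream recovery is not expected to work")
    rng = _child_rng(seed, 0)
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    expr = np.tile(baseline[:, None], (1, n_types))
    genes: list[str] = []
    markers: dict[str, list[str]] = {ct: [] for ct in cell_types}
    g = 0
    for t, ct in enumerate(cell_types):
        for j in range(markers_per_type):
            name = f"{ct}.m{j:02d}"
            genes.append(name)
            markers[ct].append(name)
            expr[g, t] = baseline[g] * marker_fold
            g += 1
    genes.extend(f"gene{i:04d}" for i in range(n_genes - g))
    return ReferenceProfile(genes, cell_types, expr, markers)


def reference_signatures(ref: ReferenceProfile) -> SignatureSet:
    """Signature sets matching the reference's planted markers."""
    sigs = SignatureSet()
    for sub in NICHE_SUBSETS:
        sigs.add(sub, ref.markers[SUBSET_TO_TYPE[sub]],
                 f"{sub} niche markers")
    sigs.add("panT", ref.markers["T_conv"], "pan-T markers")
    sigs.add("fibroblast", ref.markers["fibroblast"], "fibroblast markers")
    sigs.add("keratinocyte", ref.markers["keratinocyte"],
             "keratinocyte markers")
    half = len(ref.markers["T_MAIT"]) // 2
    sigs.add("residency",
             ref.markers["T_MAIT"][:half] + ref.markers["T_conv"][:half],
             "tissue-residency programme (synthetic stand-in)")
    return sigs


def hex_lattice(n_spots: int) -> np.ndarray:
    """Unit-spacing hexagonal lattice with offset rows (Visium-like)."""
    n_cols = int(np.ceil(np.sqrt(n_spots)))
    coords = []
    row = 0
    while len(coords) < n_spots:
        for col in range(n_cols):
            coords.append((col + 0.5 * (row % 2), row * np.sqrt(3) / 2))
            if len(coords) == n_spots:
                break
        row += 1
    return np.asarray(coords)


@dataclass
class GroundTruth:
    """Per-spot truth for one section plus its planted summary."""

    fractions: pd.DataFrame        # spot x cell type, rows sum to 1
    labels: pd.Series              # gdT | MAIT | iNKT | none
    layer_proportions: pd.DataFrame  # layer x subset planted proportions
    sample: str
    pasi: float


def _spot_fractions(label: str, layer: str, cell_types,
                    niche_t: float, background_t: float) -> np.ndarray:
    t_types = [ct for ct in T_CELL_TYPES if ct in cell_types]
    per_t = background_t / len(t_types)
    frac = {ct: 0.0 for ct in cell_types}
    for ct in t_types:
        frac[ct] = per_t
    if label != "none":
        frac[SUBSET_TO_TYPE[label]] = niche_t
    remainder = 1.0 - sum(frac.values())
    major, minor = (("keratinocyte", "fibroblast") if layer == "epidermis"
                    else ("fibroblast", "keratinocyte"))
    frac[major] += 0.75 * remainder
    frac[minor] += 0.25 * remainder
    return np.array([frac[ct] for ct in cell_types])


def simulate_section(ref: ReferenceProfile, n_spots: int = 400,
                     epidermis_fraction: float = 0.3,
                     niche_spec: dict | None = None,
                     depth: float = 5000.0, dispersion: float | None = 0.5,
                     seed: int = 0, sample: str = "S1", group: str = "L",
                     pasi: float = np.nan,
                     niche_t: float = NICHE_T_FRACTION,
                     background_t: float = BACKGROUND_T_FRACTION,
                     ) -> tuple[ad.AnnData, GroundTruth]:
    """One Visium-like section with planted niche spots.

    ``niche_spec`` maps layer -> {subset: target spot proportion}; per-layer
    proportions must sum to <= 1. Counts are negative-binomial with mean
    depth x (reference mixture) and the given dispersion in the GLM
    (variance-inflation) convention: var = mu + dispersion * mu^2.
    ``dispersion=None`` (or 0) selects the Poisson limit.
    """
    niche_spec = niche_spec or {}
    for layer, props in niche_spec.items():
        if sum(props.values()) > 1.0 + 1e-9:
            raise ParameterError(
                f"niche proportions for {layer} sum above 1: {props}"
            )
    rng = _child_rng(seed, 1)
    coords = hex_lattice(n_spots)
    # epidermal band: top fraction of spots by y (rounded)
    n_epi = int(round(epidermis_fraction * n_spots))
    order = np.lexsort((np.arange(n_spots), -coords[:, 1]))
    layers = np.full(n_spots, "dermis", dtype=object)
    layers[order[:n_epi]] = "epidermis"

    labels = np.full(n_spots, "none", dtype=object)
    for layer in ("epidermis", "dermis"):
        idx = np.flatnonzero(layers == layer)
        props = niche_spec.get(layer, {})
        pool = rng.permutation(idx)
        start = 0
        for sub in NICHE_SUBSETS:
            n_sub = int(round(props.get(sub, 0.0) * idx.size))
            labels[pool[start:start + n_sub]] = sub
            start += n_sub

    fractions = np.vstack([
        _spot_fractions(labels[i], layers[i], ref.cell_types,
                        niche_t, background_t)
        for i in range(n_spots)
    ])

    col_sums = ref.mean_expr.sum(axis=0)
    r_norm = ref.mean_expr / col_sums  # columns sum to 1
    mu = depth * fractions @ r_norm.T
    if dispersion is None or dispersion == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        counts = rng.poisson(lam)

    barcodes = [f"{sample}-{i:05d}" for i in range(n_spots)]
    obs = pd.DataFrame({
        "x": coords[:, 0], "y": coords[:, 1], "layer": layers,
        "sample": sample, "group": group, "pasi": pasi,
    }, index=pd.Index(barcodes, name="barcode"))
    adata = ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs,
                       var=pd.DataFrame(index=pd.Index(ref.genes,
                                                       name="gene")))
    planted = pd.DataFrame(
        {sub: [float(np.mean(labels[layers == lay] == sub))
               if (layers == lay).any() else 0.0
               for lay in ("epidermis", "dermis")]
         for sub in NICHE_SUBSETS},
        index=pd.Index(["epidermis", "dermis"], name="layer"),
    )
    truth = GroundTruth(
        fractions=pd.DataFrame(fractions, index=obs.index,
                               columns=ref.cell_types),
        labels=pd.Series(labels, index=obs.index, name="label"),
        layer_proportions=planted,
        sample=sample, pasi=pasi,
    )
    return adata, truth


@dataclass
class Cohort:
    """A simulated multi-sample study."""

    samples: pd.DataFrame  # sample, donor, group, pasi + planted proportions
    sections: list = field(default_factory=list)   # (AnnData, GroundTruth)
    reference: ReferenceProfile | None = None
    signatures: SignatureSet | None = None


def planted_sample_table(n_lesional: int = 12, n_hc: int = 6,
                         severity_link=None, jitter: float = 0.02,
                         seed: int = 0) -> pd.DataFrame:
    """Planted per-sample, per-layer niche-spot proportions.

    Lesional donors receive PASI ~ Uniform(2, 30); dermal γδT and epidermal
    MAIT proportions follow the linear severity links plus Gaussian jitter;
    HC and paired non-lesional samples sit at background. Negative values
    are clipped at 0 with a warning.
    """
    link = dict(DEFAULT_SEVERITY_LINK)
    if severity_link:
        link.update(severity_link)
    rng = _child_rng(seed, 2)
    pasi = rng.uniform(*PASI_RANGE, size=n_lesional)
    rows = []

    def _jit():
        return rng.normal(0.0, jitter) if jitter > 0 else 0.0

    for d in range(n_lesional):
        donor = f"D{d + 1:02d}"
        for layer in ("epidermis", "dermis"):
            row = {"sample": f"{donor}_L", "donor": donor, "group": "L",
                   "pasi": pasi[d], "layer": layer}
            for sub in NICHE_SUBSETS:
                if layer == "dermis" and sub == "gdT":
                    a, b = link["dermal_gdT"]
                    p = a + b * pasi[d]
                elif layer == "epidermis" and sub == "MAIT":
                    a, b = link["epidermal_MAIT"]
                    p = a + b * pasi[d]
                else:
                    p = LESIONAL_FIXED.get((layer, sub),
                                           BACKGROUND_NICHE_PROP)
                row[f"prop_{sub}"] = p + _jit()
            rows.append(row)
        for layer in ("epidermis", "dermis"):
            row = {"sample": f"{donor}_NL", "donor": donor, "group": "NL",
                   "pasi": pasi[d], "layer": layer}
            for sub in NICHE_SUBSETS:
                row[f"prop_{sub}"] = BACKGROUND_NICHE_PROP + _jit()
            rows.append(row)
    for h in range(n_hc):
        donor = f"H{h + 1:02d}"
        for layer in ("epidermis", "dermis"):
            row = {"sample": donor, "donor": donor, "group": "HC",
                   "pasi": np.nan, "layer": layer}
            for sub in NICHE_SUBSETS:
                row[f"prop_{sub}"] = BACKGROUND_NICHE_PROP + _jit()
            rows.append(row)
    table = pd.DataFrame(rows)
    prop_cols = [f"prop_{s}" for s in NICHE_SUBSETS]
    n_clip = int((table[prop_cols] < 0).to_numpy().sum())
    if n_clip:
        log.warning("clipped %d negative planted proportions at 0", n_clip)
    table[prop_cols] = table[prop_cols].clip(lower=0.0)
    return table


def simulate_cohort(n_lesional: int = 12, n_hc: int = 6,
                    severity_link=None, jitter: float = 0.02, seed: int = 0,
                    spots_per_section: int = 400,
                    epidermis_fraction: float = 0.3, depth: float = 5000.0,
                    dispersion: float | None = 0.5,
                    ref: ReferenceProfile | None = None,
                    generate_counts: bool = True) -> Cohort:
    """Full synthetic study: planted sample table plus (optionally) one
    counts section per sample.

    With ``generate_counts=False`` only the planted per-sample proportions
    are produced, which is what sample-level statistics need and is orders
    of magnitude cheaper than drawing counts.
    """
    table = planted_sample_table(n_lesional, n_hc, severity_link, jitter,
                                 seed)
    ref = ref or make_reference(seed=seed)
    cohort = Cohort(samples=table, reference=ref,
                    signatures=reference_signatures(ref))
    if not generate_counts:
        return cohort
    for i, (sample, sub) in enumerate(table.groupby("sample", sort=True)):
        spec = {
            layer: {s: float(r[f"prop_{s}"]) for s in NICHE_SUBSETS}
            for layer, r in sub.set_index("layer").iterrows()
        }
        row = sub.iloc[0]
        adata, truth = simulate_section(
            ref, n_spots=spots_per_section,
            epidermis_fraction=epidermis_fraction, niche_spec=spec,
            depth=depth, dispersion=dispersion, seed=seed * 1000 + i,
            sample=sample, group=row["group"], pasi=float(row["pasi"]),
        )
        cohort.sections.append((adata, truth))
    return cohort


# ---------------------------------------------------------------------------
# CITE-seq-like generator

DEFAULT_SUBSET_FREQS = {"gdT": 0.05, "MAIT": 0.04, "iNKT": 0.01,
                        "other": 0.90}
DEFAULT_MARKER_PANEL = {
    "gdT": ["TCRgd"],
    "MAIT": ["CD161", "TCRVa7_2"],
    "iNKT": ["Va24Ja18"],
}
ALL_MARKERS = ["CD45", "TCRgd", "CD161", "TCRVa7_2", "Va24Ja18",
               "CD27", "OX40", "2B4", "KLRG1", "CCR4", "CXCR6"]
#: disease-group multipliers on subset frequencies (systemic pattern:
#: γδT reduced in psoriatic disease, MAIT increased in PsA)
DEFAULT_GROUP_EFFECTS = {
    "HC": {}, "PsO": {"gdT": 0.6}, "PsA": {"gdT": 0.6, "MAIT": 1.6},
}


@dataclass
class CiteData:
    adt: pd.DataFrame          # cell x marker counts
    meta: pd.DataFrame         # donor, group, label per cell
    rna_scores: pd.DataFrame   # cell x subset RNA gene-set scores
    donor_truth: pd.DataFrame  # planted per-donor subset frequencies


def simulate_citeseq(n_cells: int = 24000, subset_freqs=None,
                     marker_panel=None, effect: float = 8.0, seed: int = 0,
                     n_donors: int = 12, donor_freq_sd: float = 0.5,
                     concordance_rho: float = 0.9,
                     group_effects=None, baseline_mean: float = 5.0,
                     cd45_mean: float = 100.0, adt_dispersion: float = 0.1,
                     rna_member_effect: float = 0.5,
                     rna_cell_sd: float = 1.0) -> CiteData:
    """Paired ADT + RNA-score matrix with planted subset structure.

    Cells of a subset have ``effect``-fold elevated counts on that subset's
    positive markers; per-donor subset frequencies vary log-normally around
    the group-adjusted base rates; per-donor mean RNA scores are planted to
    correlate with the true frequencies at ``concordance_rho``. ADT counts
    are negative-binomial in the variance-inflation convention
    (var = mu + adt_dispersion * mu^2).
    """
    freqs = dict(subset_freqs or DEFAULT_SUBSET_FREQS)
    if abs(sum(freqs.values()) - 1.0) > 1e-6:
        raise ParameterError(f"subset frequencies must sum to 1: {freqs}")
    panel = dict(marker_panel or DEFAULT_MARKER_PANEL)
    group_effects = group_effects or DEFAULT_GROUP_EFFECTS
    if effect <= 1:
        log.warning("effect <= 1: gating recovery will be at chance")
    rng = _child_rng(seed, 3)
    subsets = [s for s in freqs if s != "other"]
    groups = sorted(group_effects)
    cells_per_donor = n_cells // n_donors

    donor_rows = []
    cell_rows = []
    for d in range(n_donors):
        donor = f"C{d + 1:02d}"
        group = groups[d % len(groups)]
        f = {}
        for s in subsets:
            base = freqs[s] * group_effects[group].get(s, 1.0)
            f[s] = base * float(np.exp(rng.normal(0.0, donor_freq_sd)))
        f_other = max(1.0 - sum(f.values()), 0.0)
        probs = np.array([*[f[s] for s in subsets], f_other])
        probs = probs / probs.sum()
        draws = rng.multinomial(cells_per_donor, probs)
        labels = np.repeat([*subsets, "other"], draws)
        rng.shuffle(labels)
        donor_rows.append({"donor": donor, "group": group,
                           **{f"freq_{s}": f[s] for s in subsets}})
        for lab in labels:
            cell_rows.append((donor, group, lab))
    meta = pd.DataFrame(cell_rows, columns=["donor", "group", "label"])
    meta.index = pd.Index([f"cell{i:06d}" for i in range(len(meta))],
                          name="cell")
    donor_truth = pd.DataFrame(donor_rows).set_index("donor")

    n = len(meta)
    mu = np.full((n, len(ALL_MARKERS)), baseline_mean)
    mu[:, ALL_MARKERS.index("CD45")] = cd45_mean
    for s in subsets:
        member = (meta["label"] == s).to_numpy()
        for m in panel.get(s, []):
            mu[member, ALL_MARKERS.index(m)] = baseline_mean * effect
    lam = rng.gamma(shape=1.0 / adt_dispersion, scale=adt_dispersion * mu)
    adt = pd.DataFrame(rng.poisson(lam).astype(np.int64), index=meta.index,
                       columns=ALL_MARKERS)

    # planted RNA-protein concordance at the donor level
    scores = {}
    for s in subsets:
        # plant on the log scale, where donor frequencies are Gaussian
        fvals = np.log(donor_truth[f"freq_{s}"].clip(lower=1e-6))

        def _z(v):
            sd = v.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                return v * 0.0
            return (v - v.mean()) / sd

        zf = _z(fvals)
        eps = _z(pd.Series(rng.normal(size=len(zf)), index=zf.index))
        base = (concordance_rho * zf
                + np.sqrt(max(1 - concordance_rho ** 2, 0.0)) * eps)
        per_cell = meta["donor"].map(base).to_numpy(dtype=float)
        per_cell = per_cell + rna_member_effect * (meta["label"] == s)
        per_cell = per_cell + rng.normal(0.0, rna_cell_sd, size=n)
        scores[s] = per_cell
    rna_scores = pd.DataFrame(scores, index=meta.index)
    return CiteData(adt=adt, meta=meta, rna_scores=rna_scores,
                    donor_truth=donor_truth)
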