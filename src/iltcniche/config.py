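"""Run configuration: QC cutoffs, gating parameters and reproducibility knobs.

Defaults are deliberately conservative and every threshold is exposed, since
published spot-level QC cutoffs vary by dataset and platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ParameterError

SIGNATURE_MODES = ("plain_mean", "control_corrected")
CLR_MARGINS = ("per_cell", "per_feature")


@dataclass
class RunConfig:
    """Parameters steering a full niche-mapping run.

    Attributes
    ----------
    seed
        Top-level RNG seed; fans out to per-stage child seeds.
    min_genes_per_spot
        Spots with fewer detected genes are discarded during QC.
    max_mito_fraction
        Spots with a higher mitochondrial count fraction are discarded.
    mito_prefix
        Gene-symbol prefix identifying mitochondrial transcripts.
    knn_k
        Neighbour count for the spatial weights graph; 6 matches the
        hexagonal packing of Visium spots.
    t_gate_quantile, t_gate_floor
        Per-sample adaptive threshold on the deconvolved pan-T fraction:
        max(quantile, floor).
    signature_mode
        "plain_mean" or "control_corrected" module scoring.
    clr_margin
        Margin of the centred log-ratio transform for ADT counts.
    """

    seed: int = 0
    min_genes_per_spot: int = 20
    max_mito_fraction: float = 0.2
    mito_prefix: str = "MT-"
    knn_k: int = 6
    t_gate_quantile: float = 0.8
    t_gate_floor: float = 0.05
    signature_mode: str = "plain_mean"
    clr_margin: str = "per_cell"
    norm_scale: float = 1e4
    min_gene_overlap: int = 50
    moran_n_perm: int = 199
    n_expression_bins: int = 25
    n_control_genes: int = 50
    lfc_min: float = 0.25
    alpha: float = 0.05
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")
        if self.knn_k < 1:
            raise ParameterError("knn_k must be >= 1")
        for name in ("max_mito_fraction", "t_gate_quantile", "t_gate_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.signature_mode not in SIGNATURE_MODES:
            raise ParameterError(
                f"signature_mode must be one of {SIGNATURE_MODES}"
            )
        if self.clr_margin not in CLR_MARGINS:
            raise ParameterError(f"clr_margin must be one of {CLR_MARGINS}")
        if self.norm_scale <= 0:
            raise ParameterError("norm_scale must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
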