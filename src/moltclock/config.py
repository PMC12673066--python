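"""Run configuration: every tunable stage parameter with its default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "read_config"]


@dataclass
class RunConfig:
    """Stage parameters, seeds and paths for a reproducible run.

    Defaults mirror the analysis conventions: log2 pseudocount 8 (32 in
    perturbation mode), amplitude/graded classification cutoffs 0.25,
    promoter window 2000 bp upstream / 500 bp into the gene, 750-UMI cell
    filter, 0.05% gene filter, embedding KDE bandwidth 0.15 on an 800-grid,
    100-cell cluster minimum, spline spar 0.9, ChIP input cutoff 11 with
    mode-centering bandwidth 0.04, seven enrichment bins, four motif bins,
    k = 100 enrichment clusters, k = 20 differential clusters, and a
    differential cutoff of 0.25.
    """

    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    # normalization / fitting
    pseudocount: float = 8.0
    pseudocount_perturbation: float = 32.0
    amp_cut: float = 0.25
    graded_cut: float = 0.25
    upstream_bp: int = 2000
    into_gene_bp: int = 500
    # timing
    molt_exit_angle: float = 125.8
    loess_span: float = 0.75
    # single cell
    min_umis: int = 750
    min_gene_frac: float = 0.0005
    kde_bandwidth: float = 0.15
    kde_grid: int = 800
    min_cluster_cells: int = 100
    outlier_fold: float = 1.5
    n_hvg: int = 2000
    spar: float = 0.9
    ring_cv_cut: float = 0.4
    ring_coverage_cut: float = 300.0
    reference_sd_deg: float = 45.0
    # chip features
    chip_input_cut: float = 11.0
    chip_mode_bandwidth: float = 0.04
    min_occupancy_hits: int = 10
    n_enrichment_bins: int = 7
    n_motif_bins: int = 4
    motif_base_cutoff_frac: float = 0.6
    # models
    fisher_log10p_cut: float = -10.0
    n_peak_clusters: int = 100
    n_diff_clusters: int = 20
    diff_cut: float = 0.25
    spline_components: int = 6
    train_frac: float = 0.10
    # synthetic world
    noise_sd: float = 0.1
    n_tfs: int = 9
    n_peaks: int = 2000
    cobind_blocks: int = 20
    n_samples: int = 16
    rna_delay_deg: float = 15.0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
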