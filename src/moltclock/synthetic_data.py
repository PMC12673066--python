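"""Synthetic molting-clock worlds with known ground truth.

Every input the analysis pipeline consumes can be generated here with a
known answer: oscillatory log2 ATAC/RNA time courses driven by additive TF
phase vectors, ChIP IP/input counts whose normalized enrichment recovers the
true binding matrix, ring-structured single-cell counts, and two-condition
(vehicle vs auxin) time courses in which one TF's activity collapses after
treatment onset.

The generative model is exactly the model the fitting code assumes: peak g
has Cartesian phase coordinates ``(x_g, y_g) = sum_f C_{g,f} (x'_f, y'_f)``
over TF activity vectors, and its log2 signal at sample phase ``phi_s`` is

    z_{g,s} = mu_g + x_g cos(phi_s) + y_g sin(phi_s) + gamma_g lambda_s + noise

so round-trip recovery is exact at zero noise.  Binding is organised into
co-binding blocks: peaks within a block share a TF-combination profile up to
lognormal jitter, mirroring the block structure of real ChIP enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rhythm_fit import SampleTiming, classify

__all__ = [
    "GroundTruth",
    "SyntheticWorld",
    "DepletionSpec",
    "make_tf_system",
    "make_timecourse",
    "make_sc_ring",
    "graded_covariate",
]


def graded_covariate(timing: SampleTiming) -> np.ndarray:
    """The trend covariate lambda_s used by generator and fits alike.

    Scaled to [0, 1] over the time course so the graded coefficient is
    directly comparable to the oscillation amplitude in the classification.
    """
    t = timing.unwrapped
    return (t - t[0]) / (t[-1] - t[0])


@dataclass
class GroundTruth:
    """True generative parameters of a synthetic world.

    tf_vectors: per-TF activity vector (columns x, y), log2 units per unit
    enrichment.  peak_enrichment: nonnegative peaks x TFs matrix.  The true
    phase coordinates of every peak are the enrichment-weighted vector sum of
    the TF vectors; class labels follow the amplitude/graded cutoffs used by
    the fitting stage.
    """

    tf_vectors: pd.DataFrame
    peak_enrichment: pd.DataFrame
    graded_coef: pd.Series
    peak_mean: pd.Series
    sample_unwrapped: np.ndarray
    noise_sd: float = 0.1
    seed: int = 0
    stage_span: float = 360.0
    amp_cut: float = 0.25
    graded_cut: float = 0.25

    def __post_init__(self) -> None:
        if list(self.peak_enrichment.columns) != list(self.tf_vectors.index):
            raise ValueError("enrichment columns must match TF vector index")
        if (self.peak_enrichment.to_numpy() < 0).any():
            raise ValueError("enrichment must be nonnegative")
        self.sample_unwrapped = np.asarray(self.sample_unwrapped, dtype=float)
        if np.any(np.diff(self.sample_unwrapped) <= 0):
            raise ValueError("sample phases must strictly increase (unwrapped)")

    @property
    def peaks(self) -> pd.Index:
        return self.peak_enrichment.index

    @property
    def peak_xy(self) -> pd.DataFrame:
        """True (x, y) per peak: enrichment-weighted sum of TF vectors."""
        xy = self.peak_enrichment.to_numpy() @ self.tf_vectors[["x", "y"]].to_numpy()
        return pd.DataFrame(xy, index=self.peaks, columns=["x", "y"])

    @property
    def amplitude(self) -> pd.Series:
        xy = self.peak_xy
        return pd.Series(np.hypot(xy["x"], xy["y"]), index=self.peaks, name="amplitude")

    @property
    def phase(self) -> pd.Series:
        xy = self.peak_xy
        phi = np.mod(np.rad2deg(np.arctan2(xy["y"], xy["x"])), 360.0)
        return pd.Series(phi, index=self.peaks, name="phase")

    @property
    def peak_class(self) -> pd.Series:
        labels = classify(
            self.amplitude.to_numpy(),
            self.graded_coef.to_numpy(),
            amp_cut=self.amp_cut,
            graded_cut=self.graded_cut,
        )
        return pd.Series(labels, index=self.peaks, name="class")

    @property
    def tissue_specific_flat(self) -> pd.Index:
        """Bound-but-flat peaks (nonzero enrichment whose vector sum cancels)."""
        bound = self.peak_enrichment.sum(axis=1) > 0
        return self.peaks[bound & (self.peak_class == "flat")]


@dataclass
class DepletionSpec:
    """Auxin-style depletion of one TF from a given sample index onward.

    The depleted TF's contribution is multiplied by ``exp(-(s - onset)/tau)``
    (tau in sampling intervals), collapsing to near zero within one sample.
    """

    tf: str
    onset: int
    tau: float = 0.5


@dataclass
class SyntheticWorld:
    """A bundle of generated input data plus its :class:`GroundTruth`."""

    truth: GroundTruth
    timing: SampleTiming
    atac: pd.DataFrame
    rna: pd.DataFrame
    tss_table: pd.DataFrame
    peak_bed: pd.DataFrame
    links: pd.DataFrame
    reference_phases: pd.Series
    chip_ip: pd.DataFrame
    chip_input: pd.DataFrame
    atac_treated: pd.DataFrame | None = None
    rna_treated: pd.DataFrame | None = None
    depletion: DepletionSpec | None = None
    rna_delay_deg: float = 15.0
    molt_entry_angle: float = 42.5
    molt_exit_angle: float = 125.8


def make_tf_system(
    n_tfs: int,
    n_peaks: int,
    cobind_blocks: int = 20,
    seed: int = 0,
    frac_flat: float = 0.15,
    frac_graded: float = 0.10,
    n_samples: int = 16,
    span_degrees: float = 675.0,
    noise_sd: float = 0.1,
    vector_length: tuple[float, float] = (0.15, 0.45),
    angle_jitter_deg: float = 15.0,
    enrichment_jitter_sd: float = 0.25,
    tf_vectors: pd.DataFrame | None = None,
) -> GroundTruth:
    """Draw a random TF system with block co-binding structure.

    TF activity-vector angles are spread over the circle (equal spacing plus
    jitter); lengths are uniform in ``vector_length``.  Peaks are grouped into
    ``cobind_blocks`` blocks sharing a TF-combination profile with lognormal
    jitter; a ``frac_flat`` fraction is unbound (all-zero vector sum) and a
    ``frac_graded`` fraction unbound with a graded drift coefficient.
    Pass ``tf_vectors`` to fix the activity vectors explicitly.
    """
    if n_tfs < 2:
        raise ValueError("n_tfs must be >= 2")
    if n_peaks < n_tfs:
        raise ValueError("n_peaks must be >= n_tfs")
    if cobind_blocks < 1:
        raise ValueError("cobind_blocks must be positive")
    rng = np.random.default_rng(seed)
    tf_names = [f"tf{i:02d}" for i in range(n_tfs)]
    if tf_vectors is None:
        angles = np.arange(n_tfs) * 360.0 / n_tfs
        angles = angles + rng.uniform(-angle_jitter_deg, angle_jitter_deg, n_tfs)
        lengths = rng.uniform(*vector_length, n_tfs)
        tf_vectors = pd.DataFrame(
            {
                "x": lengths * np.cos(np.deg2rad(angles)),
                "y": lengths * np.sin(np.deg2rad(angles)),
            },
            index=tf_names,
        )
    else:
        tf_names = list(tf_vectors.index)
        n_tfs = len(tf_names)

    peaks = pd.Index([f"peak{i:05d}" for i in range(n_peaks)], name="peak")
    n_flat = int(round(frac_flat * n_peaks))
    n_graded = int(round(frac_graded * n_peaks))
    n_bound = n_peaks - n_flat - n_graded

    # block profiles: which TFs co-bind, and how strongly
    block_profiles = np.zeros((cobind_blocks, n_tfs))
    for b in range(cobind_blocks):
        k = int(rng.integers(1, min(3, n_tfs) + 1))
        members = rng.choice(n_tfs, size=k, replace=False)
        block_profiles[b, members] = rng.uniform(0.5, 2.0, size=k)
    block_of_peak = rng.integers(0, cobind_blocks, size=n_bound)
    enrichment = np.zeros((n_peaks, n_tfs))
    jitter = rng.lognormal(mean=0.0, sigma=enrichment_jitter_sd, size=(n_bound, n_tfs))
    enrichment[:n_bound] = block_profiles[block_of_peak] * jitter

    gamma = np.zeros(n_peaks)
    graded_slice = slice(n_bound, n_bound + n_graded)
    gamma[graded_slice] = rng.uniform(0.3, 0.7, n_graded) * rng.choice([-1, 1], n_graded)

    mu = rng.uniform(4.0, 10.0, n_peaks)
    # default 16 samples at 45 degree spacing (~2 larval stages sampled
    # hourly): the wrapped phases tile the circle uniformly, so harmonic
    # predictors are orthogonal to the constant and gene-mean centering
    # introduces no phase-dependent bias
    unwrapped = np.linspace(0.0, span_degrees, n_samples)
    return GroundTruth(
        tf_vectors=tf_vectors,
        peak_enrichment=pd.DataFrame(enrichment, index=peaks, columns=tf_names),
        graded_coef=pd.Series(gamma, index=peaks, name="gamma"),
        peak_mean=pd.Series(mu, index=peaks, name="mu"),
        sample_unwrapped=unwrapped,
        noise_sd=noise_sd,
        seed=seed,
    )


def _depletion_factor(n_samples: int, spec: DepletionSpec) -> np.ndarray:
    if not 0 <= spec.onset < n_samples:
        raise ValueError("depletion onset outside the sampled range")
    s = np.arange(n_samples, dtype=float)
    factor = np.ones(n_samples)
    after = s >= spec.onset
    factor[after] = np.exp(-(s[after] - spec.onset) / spec.tau)
    return factor


def _signal_matrix(
    truth: GroundTruth,
    unwrapped: np.ndarray,
    lam: np.ndarray,
    depletion: DepletionSpec | None,
) -> np.ndarray:
    phi = np.deg2rad(unwrapped)
    xy = truth.peak_xy.to_numpy()
    base = truth.peak_mean.to_numpy()[:, None] + truth.graded_coef.to_numpy()[:, None] * lam[None, :]
    full = base + xy[:, [0]] * np.cos(phi)[None, :] + xy[:, [1]] * np.sin(phi)[None, :]
    if depletion is None:
        return full
    # subtract the depleted TF's lost contribution; exactly zero pre-onset,
    # so vehicle and treated matrices are identical before treatment
    vec = truth.tf_vectors.loc[depletion.tf, ["x", "y"]].to_numpy(dtype=float)
    c_dep = truth.peak_enrichment[depletion.tf].to_numpy()
    xy_dep = np.outer(c_dep, vec)
    factor = _depletion_factor(unwrapped.size, depletion)
    osc_dep = xy_dep[:, [0]] * np.cos(phi)[None, :] + xy_dep[:, [1]] * np.sin(phi)[None, :]
    return full - osc_dep * (1.0 - factor)[None, :]


def make_timecourse(
    truth: GroundTruth,
    n_samples: int | None = None,
    conditions: str | DepletionSpec = "wildtype",
    seed: int = 0,
    rna_delay_deg: float = 15.0,
    rna_amp_scale: float = 1.3,
    chip_input_depth: tuple[float, float] = (50.0, 200.0),
    gene_spacing: int = 5000,
    peak_width: int = 400,
    n_reference_genes: int = 400,
    reference_amp: float = 0.5,
) -> SyntheticWorld:
    """Generate a full time-course world from a :class:`GroundTruth`.

    In wild-type mode a single condition is produced.  With a
    :class:`DepletionSpec`, matched vehicle and auxin matrices share the same
    noise realization and differ only in the depleted TF's decaying
    contribution, so pre-onset columns are identical.

    RNA is generated for one linked gene per peak, with the gene oscillation
    delayed by ``rna_delay_deg`` relative to its promoter peak; the peak BED
    and TSS tables place each peak inside its gene's promoter window.
    """
    rng = np.random.default_rng(seed)
    if n_samples is None:
        unwrapped = truth.sample_unwrapped
    else:
        unwrapped = np.linspace(
            truth.sample_unwrapped[0], truth.sample_unwrapped[-1], n_samples
        )
        truth = replace(truth, sample_unwrapped=unwrapped)
    n_s = unwrapped.size
    samples = [f"s{i:02d}" for i in range(n_s)]
    timing = SampleTiming(samples=samples, unwrapped=unwrapped)
    lam = (unwrapped - unwrapped[0]) / (unwrapped[-1] - unwrapped[0])

    peaks = truth.peaks
    n_peaks = peaks.size
    noise = rng.normal(0.0, truth.noise_sd, size=(n_peaks, n_s))

    depletion = conditions if isinstance(conditions, DepletionSpec) else None
    atac_veh = _signal_matrix(truth, unwrapped, lam, None) + noise
    atac = pd.DataFrame(atac_veh, index=peaks, columns=samples)
    atac_treated = None
    if depletion is not None:
        atac_aux = _signal_matrix(truth, unwrapped, lam, depletion) + noise
        atac_treated = pd.DataFrame(atac_aux, index=peaks, columns=samples)

    # one gene per peak, phase-delayed, amplitude rescaled
    genes = pd.Index([f"gene{i:05d}" for i in range(n_peaks)], name="gene")
    xy = truth.peak_xy.to_numpy()
    delay = np.deg2rad(rna_delay_deg)
    # delaying the peak by +d degrees rotates the phase angle by +d
    gx = rna_amp_scale * (xy[:, 0] * np.cos(delay) - xy[:, 1] * np.sin(delay))
    gy = rna_amp_scale * (xy[:, 0] * np.sin(delay) + xy[:, 1] * np.cos(delay))
    phi = np.deg2rad(unwrapped)
    gmu = rng.uniform(4.0, 10.0, n_peaks)
    rna_noise = rng.normal(0.0, truth.noise_sd, size=(n_peaks, n_s))
    rna_clean = gmu[:, None] + np.outer(gx, np.cos(phi)) + np.outer(gy, np.sin(phi))
    rna = pd.DataFrame(rna_clean + rna_noise, index=genes, columns=samples)
    rna_treated = None
    if depletion is not None:
        vec = truth.tf_vectors.loc[depletion.tf, ["x", "y"]].to_numpy(dtype=float)
        c_dep = truth.peak_enrichment[depletion.tf].to_numpy()
        dep_x = rna_amp_scale * c_dep * (vec[0] * np.cos(delay) - vec[1] * np.sin(delay))
        dep_y = rna_amp_scale * c_dep * (vec[0] * np.sin(delay) + vec[1] * np.cos(delay))
        factor = _depletion_factor(n_s, depletion)
        dep_term = np.outer(dep_x, np.cos(phi)) + np.outer(dep_y, np.sin(phi))
        rna_aux = rna_clean - dep_term * (1.0 - factor[None, :]) + rna_noise
        rna_treated = pd.DataFrame(rna_aux, index=genes, columns=samples)

    # genome layout: peak i inside gene i's promoter window (+ strand)
    starts = np.arange(n_peaks) * gene_spacing + 1000
    peak_bed = pd.DataFrame(
        {"chrom": "chrI", "start": starts, "end": starts + peak_width, "name": peaks}
    )
    tss = starts + peak_width + 300  # peak within [tss-2000, tss+500)
    tss_table = pd.DataFrame(
        {"gene": genes, "chrom": "chrI", "start": tss, "end": tss + 1500, "strand": "+"}
    )
    links = pd.DataFrame({"peak": peaks, "gene": genes})

    # phase-annotated reference gene set: clock-driven oscillators with
    # phases spread over the whole circle, appended to the RNA matrix
    # (unaffected by depletion, consistent with coupling off by default)
    ref_names = pd.Index([f"refgene{i:04d}" for i in range(n_reference_genes)])
    ref_phase = rng.uniform(0.0, 360.0, n_reference_genes)
    ref_mu = rng.uniform(4.0, 10.0, n_reference_genes)
    rel = np.deg2rad(unwrapped[None, :] - ref_phase[:, None])
    ref_z = (
        ref_mu[:, None]
        + reference_amp * np.cos(rel)
        + rng.normal(0.0, truth.noise_sd, size=(n_reference_genes, n_s))
    )
    ref_df = pd.DataFrame(ref_z, index=ref_names, columns=samples)
    rna = pd.concat([rna, ref_df])
    if rna_treated is not None:
        rna_treated = pd.concat([rna_treated, ref_df])
    reference_phases = pd.Series(ref_phase, index=ref_names, name="phase")

    # ChIP counts: input Poisson at a per-peak depth; IP at depth * 2^enrichment
    input_mean = rng.uniform(*chip_input_depth, size=n_peaks)
    tf_names = list(truth.tf_vectors.index)
    enr = truth.peak_enrichment.to_numpy()
    ip_mean = input_mean[:, None] * np.power(2.0, enr)
    chip_input = pd.DataFrame(
        rng.poisson(np.repeat(input_mean[:, None], len(tf_names), axis=1)).astype(float),
        index=peaks,
        columns=tf_names,
    )
    chip_ip = pd.DataFrame(rng.poisson(ip_mean).astype(float), index=peaks, columns=tf_names)

    return SyntheticWorld(
        truth=truth,
        timing=timing,
        atac=atac,
        rna=rna,
        tss_table=tss_table,
        peak_bed=peak_bed,
        links=links,
        reference_phases=reference_phases,
        chip_ip=chip_ip,
        chip_input=chip_input,
        atac_treated=atac_treated,
        rna_treated=rna_treated,
        depletion=depletion,
        rna_delay_deg=rna_delay_deg,
    )


def make_sc_ring(
    n_cells: int,
    gene_phases: np.ndarray | pd.Series,
    depth: float = 2000.0,
    seed: int = 0,
    amp: float | np.ndarray = 0.6,
    noise: str = "poisson",
    nb_dispersion: float = 2.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Single-cell counts from cells on a developmental ring.

    Cells sit at angles uniform on [0, 360); gene g's linear-space mean is
    ``baseline_g * (1 + a_g * cos(angle - phase_g))`` with 0 <= a_g < 1,
    scaled so a cell's expected library is ``depth`` UMIs; counts are Poisson
    (or negative binomial).  Returns (cells x genes counts, true angles).
    """
    if n_cells < 100:
        raise ValueError("n_cells must be >= 100")
    phases = np.asarray(pd.Series(gene_phases), dtype=float)
    n_genes = phases.size
    a = np.broadcast_to(np.asarray(amp, dtype=float), (n_genes,)).copy()
    if np.any(a >= 1.0) or np.any(a < 0.0):
        raise ValueError("oscillation fraction a must be in [0, 1)")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 360.0, n_cells)
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    rel = np.deg2rad(angles[:, None] - phases[None, :])
    mean = baseline[None, :] * (1.0 + a[None, :] * np.cos(rel))
    mean = mean / mean.sum(axis=1, keepdims=True) * depth
    if noise == "poisson":
        counts = rng.poisson(mean)
    elif noise == "nb":
        shape = nb_dispersion
        counts = rng.poisson(rng.gamma(shape, mean / shape))
    else:
        raise ValueError("noise must be 'poisson' or 'nb'")
    if isinstance(gene_phases, pd.Series):
        gene_index = gene_phases.index
    else:
        gene_index = pd.Index([f"g{i:04d}" for i in range(n_genes)])
    cells = pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell")
    return pd.DataFrame(counts, index=cells, columns=gene_index), angles
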