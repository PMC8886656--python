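"""Synthetic generators with known ground truth for every pipeline stage.

The generators produce (a) coupled phase-oscillator dynamics whose coupling
strength K controls true synchronization and metastability, (b) two-group
cohorts of simulated BOLD series with an injected coupling difference and a
cognitive score constructed from each subject's realized metastability,
(c) mediation triads x -> m -> y with known path coefficients, and (d)
low-rank-plus-noise structural-connectivity matrices.  Everything is
deterministic given its seed; cohort subjects draw independent child seeds
from one root ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phase import BoldTimeSeries, PhaseMatrix, RSN_NAMES, order_parameter, sync_metrics, wrap_phase
from .stats import ConnectivityTable

__all__ = [
    "OscillatorConfig",
    "MediationConfig",
    "CovariateSpec",
    "CohortSpec",
    "simulate_kuramoto",
    "phases_to_bold",
    "generate_cohort",
    "generate_parcellation",
    "generate_mediation_triad",
    "generate_connectivity",
]


@dataclass(frozen=True)
class OscillatorConfig:
    """Parameters of the stochastic Kuramoto simulation.

    The oscillators obey the Euler–Maruyama update

    .. math::
        \\theta_i \\mathrel{+}= \\Big[2\\pi f_i
            + \\frac{K}{n}\\sum_j \\sin(\\theta_j-\\theta_i)\\Big]\\,dt
            + \\sigma\\sqrt{dt}\\,\\xi_i,

    with natural frequencies ``f_i ~ N(freq_mean, freq_sd)`` in Hz and
    independent standard-normal increments ``xi_i``.  ``noise_sd`` (sigma) is
    the phase-noise intensity in rad/sqrt(s); with the default 1.5 the
    incoherent-to-coherent transition sits near K ~ 2-3, between the probed
    couplings K=1 and K=5.  ``burn_in`` seconds are simulated and discarded
    before sampling so the output reflects the stationary regime rather than
    the relaxation from random initial phases.  Output phases are sampled
    every ``tr`` seconds for ``duration`` seconds.
    """

    n_oscillators: int = 100
    coupling: float = 1.0
    freq_mean: float = 0.05
    freq_sd: float = 0.01
    noise_sd: float = 1.5
    dt: float = 0.2
    duration: float = 410.0
    tr: float = 2.0
    burn_in: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        scalars = {
            "coupling": self.coupling,
            "freq_mean": self.freq_mean,
            "freq_sd": self.freq_sd,
            "noise_sd": self.noise_sd,
            "dt": self.dt,
            "duration": self.duration,
            "tr": self.tr,
            "burn_in": self.burn_in,
        }
        for name, value in scalars.items():
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")
        if self.n_oscillators < 2:
            raise ValueError("need at least 2 oscillators")
        if self.coupling < 0:
            raise ValueError("coupling K must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.freq_sd < 0:
            raise ValueError("freq_sd must be >= 0")
        if self.dt <= 0 or self.tr <= 0:
            raise ValueError("dt and tr must be positive")
        if self.dt > self.tr:
            raise ValueError("integration step dt must not exceed output interval tr")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.duration / self.tr < 20:
            raise ValueError("duration must cover at least 20 output samples")


@dataclass(frozen=True)
class MediationConfig:
    """Ground-truth path model x -> m -> y for mediation tests.

    ``m = a*x + e_m`` and ``y = b*m + c'*x + e_y`` with Gaussian noise;
    x is a balanced binary 0/1 group label, mirroring a control-vs-patient
    contrast.  Optional nuisance covariates are independent standard
    normals that do not enter m or y (so adjusted estimates stay unbiased).
    """

    n_samples: int = 200
    path_a: float = 0.6
    path_b: float = 0.5
    path_c_prime: float = 0.2
    noise_m: float = 1.0
    noise_y: float = 1.0
    n_covariates: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.noise_m < 0 or self.noise_y < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_covariates < 0:
            raise ValueError("n_covariates must be >= 0")


@dataclass(frozen=True)
class CovariateSpec:
    """Per-group sampling model for one phenotype covariate."""

    name: str
    mean0: float
    sd0: float
    mean1: float
    sd1: float
    binary: bool = False  # if True, means are Bernoulli probabilities


def default_covariates() -> tuple[CovariateSpec, ...]:
    """Covariate models loosely matched to an elderly clinical cohort."""
    return (
        CovariateSpec("age", 60.0, 11.0, 61.5, 9.0),
        CovariateSpec("gender", 0.45, 0.0, 0.40, 0.0, binary=True),
        CovariateSpec("handedness", 0.95, 0.0, 0.95, 0.0, binary=True),
        CovariateSpec("education", 11.5, 3.5, 10.0, 4.0),
        CovariateSpec("fd", 0.10, 0.04, 0.13, 0.05),
        CovariateSpec("tiv", 1450.0, 120.0, 1440.0, 125.0),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with an injected coupling difference.

    Group 0 subjects are simulated at coupling ``coupling_group0``, group 1
    at ``coupling_group1``, each perturbed per subject by Gaussian jitter of
    SD ``coupling_jitter_sd`` (truncated at 0).  The jitter models
    between-subject heterogeneity; without it the mediator has almost no
    within-group variance and the mediator->score path degenerates to a
    regression on measurement noise.  The phenotype table carries a synthetic cognitive
    score built as ``score_intercept + score_slope * metastability + noise``
    from each subject's *realized* global metastability, so a
    group -> metastability -> score mediation chain is present by
    construction whenever the couplings differ.
    """

    n_per_group: int = 20
    coupling_group0: float = 3.0
    coupling_group1: float = 0.5
    coupling_jitter_sd: float = 0.5
    oscillator: OscillatorConfig = field(
        default_factory=lambda: OscillatorConfig(n_oscillators=60)
    )
    covariates: tuple[CovariateSpec, ...] = field(default_factory=default_covariates)
    score_intercept: float = 24.0
    score_slope: float = 40.0
    score_noise_sd: float = 0.5
    amplitude_sd: float = 0.1
    obs_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.coupling_group0 < 0 or self.coupling_group1 < 0:
            raise ValueError("couplings must be >= 0")
        if self.coupling_jitter_sd < 0:
            raise ValueError("coupling_jitter_sd must be >= 0")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")


def simulate_kuramoto(config: OscillatorConfig) -> PhaseMatrix:
    """Integrate the stochastic Kuramoto model and sample phases on the tr grid.

    The all-to-all coupling term ``(K/n) sum_j sin(theta_j - theta_i)`` is
    evaluated through the exact mean-field identity
    ``K * r(t) * sin(psi(t) - theta_i)`` where ``r e^{i psi}`` is the complex
    order parameter, which reduces the per-step cost from O(n^2) to O(n).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_oscillators
    omega = 2 * np.pi * rng.normal(config.freq_mean, config.freq_sd, size=n)
    theta = rng.uniform(-np.pi, np.pi, size=n)

    n_out = int(round(config.duration / config.tr))
    # explicit Euler needs K*dt well below 1 or the locked state overshoots;
    # refine the step beyond the configured dt whenever coupling demands it
    dt_stable = 0.2 / max(config.coupling, 1e-9)
    steps_per_sample = max(
        1,
        int(round(config.tr / config.dt)),
        int(np.ceil(config.tr / dt_stable)),
    )
    dt = config.tr / steps_per_sample
    burn_steps = int(round(config.burn_in / dt))
    sqrt_dt = np.sqrt(dt)

    out = np.empty((n, n_out))

    def step() -> None:
        nonlocal theta
        z = np.exp(1j * theta).mean()
        drift = omega + config.coupling * np.abs(z) * np.sin(np.angle(z) - theta)
        theta = theta + drift * dt
        if config.noise_sd > 0:
            theta = theta + config.noise_sd * sqrt_dt * rng.standard_normal(n)

    for _ in range(burn_steps):
        step()
    for k in range(n_out):
        out[:, k] = theta
        for _ in range(steps_per_sample):
            step()

    return PhaseMatrix(phases=wrap_phase(out), tr=config.tr)


def phases_to_bold(
    phases: PhaseMatrix,
    amplitude_sd: float = 0.0,
    obs_noise_sd: float = 0.0,
    seed: int = 0,
) -> BoldTimeSeries:
    """Turn oscillator phases into a BOLD-like signal matrix.

    ``s_i(t) = A_i cos(theta_i(t)) + eps_i(t)`` with per-region amplitudes
    ``A_i = |N(1, amplitude_sd)|`` and i.i.d. Gaussian observation noise.
    """
    if amplitude_sd < 0 or obs_noise_sd < 0:
        raise ValueError("amplitude_sd and obs_noise_sd must be >= 0")
    if phases.n_timepoints == 0 or phases.n_regions == 0:
        raise ValueError("empty phase matrix")
    rng = np.random.default_rng(seed)
    n, L = phases.phases.shape
    amplitudes = np.abs(rng.normal(1.0, amplitude_sd, size=(n, 1)))
    signal = amplitudes * np.cos(phases.phases)
    if obs_noise_sd > 0:
        signal = signal + rng.normal(0.0, obs_noise_sd, size=(n, L))
    return BoldTimeSeries(values=signal, tr=phases.tr, region_ids=phases.region_ids)


def generate_parcellation(region_ids) -> dict[str, str]:
    """Assign parcels round-robin to the seven canonical resting-state networks."""
    return {rid: RSN_NAMES[i % len(RSN_NAMES)] for i, rid in enumerate(region_ids)}


def generate_cohort(spec: CohortSpec) -> tuple[list[BoldTimeSeries], pd.DataFrame]:
    """Simulate a two-group cohort of BOLD series plus its phenotype table.

    Returns one time series per subject (group 0 first) and a phenotype
    DataFrame with columns ``subject_id, group, score`` plus one column per
    covariate.  The score is a stated linear function of each subject's
    realized global metastability (computed from the noiseless oscillator
    phases) plus Gaussian noise.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 * spec.n_per_group + 1)
    pheno_rng = np.random.default_rng(children[-1])

    series: list[BoldTimeSeries] = []
    rows: list[dict] = []
    for i in range(2 * spec.n_per_group):
        group = 0 if i < spec.n_per_group else 1
        base_coupling = spec.coupling_group0 if group == 0 else spec.coupling_group1
        coupling = max(
            0.0, float(pheno_rng.normal(base_coupling, spec.coupling_jitter_sd))
        )
        child = children[i]
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        osc = OscillatorConfig(
            n_oscillators=spec.oscillator.n_oscillators,
            coupling=coupling,
            freq_mean=spec.oscillator.freq_mean,
            freq_sd=spec.oscillator.freq_sd,
            noise_sd=spec.oscillator.noise_sd,
            dt=spec.oscillator.dt,
            duration=spec.oscillator.duration,
            tr=spec.oscillator.tr,
            burn_in=spec.oscillator.burn_in,
            seed=sub_seed,
        )
        phases = simulate_kuramoto(osc)
        bold = phases_to_bold(
            phases,
            amplitude_sd=spec.amplitude_sd,
            obs_noise_sd=spec.obs_noise_sd,
            seed=sub_seed + 1,
        )
        series.append(bold)

        truth = sync_metrics(order_parameter(phases), "global")
        row: dict = {
            "subject_id": f"sub-{i:03d}",
            "group": group,
            "coupling": coupling,
            "true_synchronization": truth.synchronization,
            "true_metastability": truth.metastability,
        }
        for cov in spec.covariates:
            mean = cov.mean0 if group == 0 else cov.mean1
            sd = cov.sd0 if group == 0 else cov.sd1
            if cov.binary:
                row[cov.name] = int(pheno_rng.random() < mean)
            else:
                row[cov.name] = float(pheno_rng.normal(mean, sd))
        row["score"] = float(
            spec.score_intercept
            + spec.score_slope * truth.metastability
            + pheno_rng.normal(0.0, spec.score_noise_sd)
        )
        rows.append(row)

    return series, pd.DataFrame(rows)


def generate_mediation_triad(config: MediationConfig) -> pd.DataFrame:
    """Generate a mediation triad table with known path coefficients.

    Columns: ``x`` (balanced binary 0/1), ``m``, ``y`` and, if requested,
    ``cov1..covK`` nuisance covariates.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    x = np.zeros(n)
    x[n // 2 :] = 1.0
    rng.shuffle(x)
    m = config.path_a * x + rng.normal(0.0, config.noise_m, size=n)
    y = config.path_b * m + config.path_c_prime * x + rng.normal(0.0, config.noise_y, size=n)
    data = {"x": x, "m": m, "y": y}
    for k in range(config.n_covariates):
        data[f"cov{k + 1}"] = rng.standard_normal(n)
    return pd.DataFrame(data)


def generate_connectivity(
    n_subjects: int,
    n_edges: int,
    latent_dim: int = 1,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ConnectivityTable:
    """Low-rank-plus-noise non-negative subject-by-edge fiber-count matrix.

    The matrix is ``baseline + sum_k u_k v_k^T + noise`` with non-negative
    loadings ``v_k`` and a baseline large enough that negative entries are
    rare; any residual negatives are clipped to zero.  The first latent
    score vector ``u_1`` is stored on the returned table
    (``latent_scores``) for recovery tests.  With unit-SD latent scores the
    signal-to-noise ratio of the first factor is ``1 / noise_sd``.
    """
    if latent_dim < 1 or latent_dim >= min(n_subjects, n_edges):
        raise ValueError(
            f"latent_dim must be in [1, min(n_subjects, n_edges)), got {latent_dim}"
        )
    if n_subjects < 2 or n_edges < 2:
        raise ValueError("need at least 2 subjects and 2 edges")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    scores = rng.standard_normal((n_subjects, latent_dim))
    # decreasing factor strengths so the first factor dominates
    strengths = 1.0 / (1.0 + np.arange(latent_dim))
    loadings = np.abs(rng.standard_normal((latent_dim, n_edges)))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    baseline = 5.0
    matrix = baseline + (scores * strengths) @ loadings
    if noise_sd > 0:
        matrix = matrix + rng.normal(0.0, noise_sd / np.sqrt(n_edges), size=matrix.shape)
    matrix = np.clip(matrix, 0.0, None)

    seeds = ("thalamus", "putamen", "caudate", "pallidum")
    edge_labels = tuple(
        (seeds[j % len(seeds)], f"ctx{j:04d}") for j in range(n_edges)
    )
    return ConnectivityTable(
        matrix=matrix,
        edge_labels=edge_labels,
        subject_ids=tuple(f"sub-{i:03d}" for i in range(n_subjects)),
        normalized=False,
        latent_scores=scores[:, 0].copy(),
    )
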