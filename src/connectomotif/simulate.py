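"""Synthetic connectome cohorts with planted network motifs.

The generator emulates the statistical structure the motif analysis
assumes, so every pipeline stage is testable without real data:

* a shared heavy-tailed (log-normal) base connectome, mimicking the skewed
  dynamic range of probabilistic-tractography streamline counts;
* sparse, mutually orthogonal planted motifs (disjoint region-pair
  supports, ~2% of pairs each) whose per-subject weights vary across the
  cohort;
* behavior coupled to the weights: day-1 double-embedding performance
  tracks one motif's scan-a weight at a configurable Spearman correlation,
  and the day-4 minus day-1 performance change tracks another motif's
  scan-b minus scan-a weight change (white-matter plasticity);
* entrywise Gaussian scan noise, clipping at zero and rounding to integer
  counts, as in real streamline data.

Corpus-callosum parcels (the last five regions when there are more than
ten) are target-only: their source rows are all zero and motif supports
avoid them, matching seed-to-seed tractography run per hemisphere with the
callosal parcels as extra targets.

Everything is reproducible from the seed; the returned
:class:`GroundTruth` is the oracle for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .behavior import AnswerCounts, BehavioralTable, write_behavior
from .exceptions import ConfigError
from .io import (
    ConnectivityMatrix,
    ConnectomeCohort,
    Parcellation,
    hcp_mmp_labels,
    n_features,
    unvectorize,
    write_cohort_files,
)


@dataclass(frozen=True)
class SimulationParams:
    """Study-shaped defaults: 28 subjects, 185 regions, scans a/b/c.

    ``weight_sd`` (planted-weight spread across subjects) and ``noise_sd``
    (per-entry scan noise) jointly set the spectral signal-to-noise ratio
    — the planted component's singular value over the noise bulk edge,
    sigma_w * sqrt(n) / (sigma_n * (sqrt(F) + sqrt(n))) — about 5.9 at the
    defaults, comfortably above the recovery threshold.

    ``behavior_rho`` / ``plasticity_rho`` are target Spearman correlations
    between planted weights and behavior; internally converted to the
    latent Pearson scale via rho_P = 2 sin(pi rho_S / 6).
    """

    n_subjects: int = 28
    n_regions: int = 185
    scans: tuple[str, ...] = ("a", "b", "c")
    hemisphere: str = "left"
    n_planted_motifs: int = 2
    motif_sparsity: float = 0.02
    base_log_mean: float = 6.0
    base_log_sigma: float = 1.2
    weight_sd: float = 600.0
    weight_decay: float = 0.5
    noise_sd: float = 4.0
    behavior_coupled_motif: int | None = 0
    behavior_rho: float = 0.7
    plastic_motif: int | None = 1
    plasticity_sd: float = 300.0
    plasticity_rho: float = 0.7
    scan_jitter_sd: float = 50.0
    retention_sd: float = 50.0
    double_range: tuple[float, float] = (0.58, 0.91)
    single_range: tuple[float, float] = (0.67, 1.00)
    gain_mean: float = 0.08
    gain_sd: float = 0.06
    trials_per_type: int = 33
    integer_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_sd < 0 or self.noise_sd < 0 or self.plasticity_sd < 0:
            raise ConfigError("standard deviations must be nonnegative")
        for m, name in (
            (self.behavior_coupled_motif, "behavior_coupled_motif"),
            (self.plastic_motif, "plastic_motif"),
        ):
            if m is not None and not 0 <= m < self.n_planted_motifs:
                raise ConfigError(
                    f"{name}={m} references a motif outside the "
                    f"{self.n_planted_motifs} planted motifs"
                )
        for lo, hi in (self.double_range, self.single_range):
            if not (0.0 <= lo < hi <= 1.0):
                raise ConfigError("performance ranges must be within [0, 1]")

    @property
    def spectral_snr(self) -> float:
        """Planted singular value over the noise bulk edge (infinite if noiseless)."""
        F = n_features(self.n_regions, "symmetric")
        n = self.n_subjects
        if self.noise_sd == 0:
            return float("inf")
        return float(
            self.weight_sd * np.sqrt(n)
            / (self.noise_sd * (np.sqrt(F) + np.sqrt(n)))
        )


@dataclass
class GroundTruth:
    """Planted structure: the oracle for recovery and coupling tests."""

    motifs: np.ndarray  # (n_features, n_planted) orthonormal, symmetric mode
    weights: np.ndarray  # (n_subjects, n_scans, n_planted)
    subjects: list[str]
    scans: list[str]
    index_map: list[tuple[str, str]]
    behavior_coupled_motif: int | None
    plastic_motif: int | None
    behavior_rho: float
    plasticity_rho: float

    def weight_vector(self, scan: str, motif: int) -> np.ndarray:
        return self.weights[:, self.scans.index(scan), motif]

    def weight_change_vector(
        self, motif: int, scans: tuple[str, str] = ("a", "b")
    ) -> np.ndarray:
        a, b = (self.scans.index(s) for s in scans)
        return self.weights[:, b, motif] - self.weights[:, a, motif]


def _spearman_to_pearson(rho_s: float) -> float:
    """Latent-normal Pearson correlation yielding a target Spearman value."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _make_parcellation(params: SimulationParams) -> tuple[Parcellation, np.ndarray]:
    """Labels plus a boolean mask of callosal (target-only) regions."""
    d = params.n_regions
    if d > 10:
        labels = hcp_mmp_labels(d - 5, 5)
        cc_mask = np.zeros(d, dtype=bool)
        cc_mask[-5:] = True
    else:
        labels = tuple(f"R{i:03d}" for i in range(1, d + 1))
        cc_mask = np.zeros(d, dtype=bool)
    return Parcellation(labels=labels, hemisphere=params.hemisphere), cc_mask


def _plant_motifs(
    rng: np.random.Generator, params: SimulationParams, cc_mask: np.ndarray
) -> np.ndarray:
    """Orthonormal sparse motifs with disjoint cortical region-pair supports."""
    d = params.n_regions
    F = n_features(d, "symmetric")
    iu, ju = np.triu_indices(d, k=1)
    cortical_pairs = np.flatnonzero(~cc_mask[iu] & ~cc_mask[ju])
    support_size = max(2, int(round(params.motif_sparsity * F)))
    k = params.n_planted_motifs
    if k * support_size > len(cortical_pairs):
        raise ConfigError("motif supports exceed available cortical region pairs")
    order = rng.permutation(cortical_pairs)
    motifs = np.zeros((F, k))
    for m in range(k):
        sup = order[m * support_size : (m + 1) * support_size]
        v = rng.standard_normal(support_size)
        v /= np.linalg.norm(v)
        motifs[sup, m] = v
        # sign convention: largest-|entry| positive, matching the decomposition
        imax = int(np.argmax(np.abs(motifs[:, m])))
        if motifs[imax, m] < 0:
            motifs[:, m] = -motifs[:, m]
    return motifs


def _coupled_latent(
    rng: np.random.Generator, z: np.ndarray, rho_s: float
) -> np.ndarray:
    """Standard-normal latent with Pearson corr 2 sin(pi rho_s/6) to z."""
    rho_p = _spearman_to_pearson(rho_s)
    return rho_p * z + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(len(z))


def _counts_from_performance(
    rng: np.random.Generator, p: float, n_trials: int
) -> tuple[int, int, int]:
    n_correct = int(np.clip(round(p * n_trials), 0, n_trials))
    remaining = n_trials - n_correct
    n_incorrect = int(rng.binomial(remaining, 0.7)) if remaining else 0
    return n_correct, n_incorrect, remaining - n_incorrect


def _generate(
    params: SimulationParams, couple: bool
) -> tuple[ConnectomeCohort, BehavioralTable, GroundTruth]:
    rng = np.random.default_rng(params.seed)
    d = params.n_regions
    n = params.n_subjects
    k = params.n_planted_motifs
    scans = list(params.scans)
    subjects = [f"S{i:02d}" for i in range(1, n + 1)]
    parc, cc_mask = _make_parcellation(params)

    # shared base connectome: heavy-tailed counts, callosal rows target-only
    base = rng.lognormal(params.base_log_mean, params.base_log_sigma, size=(d, d))
    np.fill_diagonal(base, 0.0)
    base[cc_mask, :] = 0.0

    motifs = _plant_motifs(rng, params, cc_mask)
    motif_mats = np.stack([unvectorize(motifs[:, m], d, "symmetric") for m in range(k)])

    # per-subject, per-scan planted weights; per-motif scales decay
    # geometrically so planted motifs have distinct explained variance and
    # are identifiable (equal scales leave them defined only up to rotation)
    motif_sds = params.weight_sd * params.weight_decay ** np.arange(k)
    weights = np.zeros((n, len(scans), k))
    # baseline weights are drawn Gaussian, then made exactly sample-orthogonal
    # to each other and to the constant (base-connectome) direction: finite
    # cohorts otherwise carry chance weight correlations that rotate the
    # recovered motifs within the planted subspace
    if n < k + 2:
        raise ConfigError("need at least n_planted_motifs + 2 subjects")
    raw = rng.standard_normal((n, k))
    basis = [np.ones(n) / np.sqrt(n)]
    cols = []
    for m in range(k):
        v = raw[:, m]
        for b in basis:
            v = v - (v @ b) * b
        v = v / np.linalg.norm(v)
        basis.append(v)
        cols.append(v * motif_sds[m] * np.sqrt(n - 1))
    w_a = np.column_stack(cols)
    weights[:, 0, :] = w_a
    delta = np.zeros(n)
    for si in range(1, len(scans)):
        jitter = rng.normal(0.0, params.scan_jitter_sd, size=(n, k))
        if si == 1:
            weights[:, 1, :] = w_a + jitter
            if couple and params.plastic_motif is not None and params.plasticity_sd > 0:
                delta = rng.normal(0.0, params.plasticity_sd, size=n)
                weights[:, 1, params.plastic_motif] = w_a[:, params.plastic_motif] + delta
        else:
            weights[:, si, :] = weights[:, si - 1, :] + rng.normal(
                0.0, params.retention_sd, size=(n, k)
            )

    # connectivity matrices
    matrices: dict[tuple[str, str], ConnectivityMatrix] = {}
    for si, scan in enumerate(scans):
        for sj, subj in enumerate(subjects):
            values = base + np.tensordot(weights[sj, si, :], motif_mats, axes=1)
            if params.noise_sd > 0:
                noise = rng.normal(0.0, params.noise_sd, size=(d, d))
                noise[cc_mask, :] = 0.0
                values = values + noise
            values = np.clip(values, 0.0, None)
            if params.integer_counts:
                values = np.round(values)
            np.fill_diagonal(values, 0.0)
            matrices[(subj, scan)] = ConnectivityMatrix(
                values=values, subject=subj, scan=scan, hemisphere=params.hemisphere
            )
    cohort = ConnectomeCohort(
        parcellation=parc, matrices=matrices, subjects=subjects, scans=scans
    )

    # behavior: day-1 double performance coupled to the scan-a weight of one
    # motif; day-4 minus day-1 gain coupled to the b-a weight change of the
    # plastic motif.  Monotone (logistic) mapping into the printed ranges.
    if couple and params.behavior_coupled_motif is not None:
        z1 = w_a[:, params.behavior_coupled_motif] / max(
            motif_sds[params.behavior_coupled_motif], 1e-12
        )
        latent1 = _coupled_latent(rng, z1, params.behavior_rho)
    else:
        latent1 = rng.standard_normal(n)
    if couple and params.plastic_motif is not None and params.plasticity_sd > 0:
        zd = delta / max(params.plasticity_sd, 1e-12)
        latent_gain = _coupled_latent(rng, zd, params.plasticity_rho)
    else:
        latent_gain = rng.standard_normal(n)

    lo_d, hi_d = params.double_range
    lo_s, hi_s = params.single_range
    p1_double = lo_d + (hi_d - lo_d) * expit(1.7 * latent1)
    gain = params.gain_mean + params.gain_sd * latent_gain
    p4_double = np.clip(p1_double + gain, 0.0, 1.0)
    z_single = rng.standard_normal(n)
    p_single_base = lo_s + (hi_s - lo_s) * expit(1.0 * (z_single + 0.8))

    records: list[AnswerCounts] = []
    for sj, subj in enumerate(subjects):
        for day in range(1, 5):
            frac = (day - 1) / 3.0
            p_dbl = float(p1_double[sj] + frac * (p4_double[sj] - p1_double[sj]))
            p_sgl = float(np.clip(p_single_base[sj] + 0.02 * frac, 0.0, 1.0))
            for stype, p in (("double", p_dbl), ("single", p_sgl)):
                c, i, m = _counts_from_performance(rng, p, params.trials_per_type)
                records.append(
                    AnswerCounts(subject=subj, day=day, sentence_type=stype,
                                 n_correct=c, n_incorrect=i, n_missed=m)
                )
    # spans: reading span loosely tracks single-embedding ability, digit span free
    spans = {
        subj: {
            "reading_span": float(np.clip(3.5 + 0.8 * z_single[sj]
                                          + 0.8 * rng.standard_normal(), 2.0, 7.0)),
            "digit_span": float(np.clip(6.0 + 1.5 * rng.standard_normal(), 3.0, 10.0)),
        }
        for sj, subj in enumerate(subjects)
    }
    behavior = BehavioralTable.from_records(records, spans)

    iu, ju = np.triu_indices(d, k=1)
    index_map = [(parc.labels[i], parc.labels[j]) for i, j in zip(iu, ju)]
    truth = GroundTruth(
        motifs=motifs,
        weights=weights,
        subjects=subjects,
        scans=scans,
        index_map=index_map,
        behavior_coupled_motif=params.behavior_coupled_motif if couple else None,
        plastic_motif=params.plastic_motif if couple else None,
        behavior_rho=params.behavior_rho if couple else 0.0,
        plasticity_rho=params.plasticity_rho if couple else 0.0,
    )
    return cohort, behavior, truth


def generate_cohort(
    params: SimulationParams,
) -> tuple[ConnectomeCohort, BehavioralTable, GroundTruth]:
    """Cohort with planted motif-behavior and plasticity couplings."""
    return _generate(params, couple=True)


def generate_null_cohort(
    params: SimulationParams,
) -> tuple[ConnectomeCohort, BehavioralTable]:
    """Cohort whose behavior is independent of all planted weights.

    Planted motifs still vary across subjects (the connectomes have the
    same low-rank-plus-noise structure) but behavior latents are fresh
    noise and no plasticity shift is planted — the null for type-I-error
    studies.
    """
    cohort, behavior, _ = _generate(params, couple=False)
    return cohort, behavior


def write_cohort(
    cohort: ConnectomeCohort,
    behavior: BehavioralTable,
    directory: str | Path,
) -> Path:
    """Write matrices, manifest, parcellation and behavior tables; return manifest path."""
    directory = Path(directory)
    manifest = write_cohort_files(cohort, directory)
    write_behavior(behavior, directory / "behavior.tsv", directory / "spans.tsv")
    return manifest
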