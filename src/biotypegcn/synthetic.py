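"""Synthetic cohorts with planted biotype structure.

Real discovery/validation cohorts for this kind of study are access
restricted, so every downstream stage is exercised on simulated cohorts
that reproduce the statistical structure the model assumes:

* each subject has an FNC feature vector (upper-triangle Pearson
  correlations over C components grouped into 7 networks);
* patients belong to one of K_true hidden subtypes, each expressed as a
  standardized mean shift on the edges of a few network-by-network blocks;
* age, gender, site and mean framewise displacement leave small linear
  traces on the edges;
* treated patients carry longitudinal symptom scores whose recovery slope
  depends on (biotype, medication arm).

Determinism contract: a ``CohortSpec`` plus its seed fully determines every
generated number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    IllConditionedSampleError,
    InfeasibleCohortError,
    MissingAssignmentError,
)
from .fnc import NetworkPartition, edge_index, n_edges, unvectorize_fnc

#: Default per-subtype affected network blocks: subtype 1 shifts
#: cognitive-control/default-mode and sensorimotor/visual coupling, subtype 2
#: shifts within-default-mode and cognitive-control/cerebellar coupling.
DEFAULT_AFFECTED_BLOCKS = (
    (("CC", "DM"), ("SM", "VI")),
    (("DM", "DM"), ("CC", "CB")),
)


@dataclass(frozen=True)
class CovariateModel:
    """Linear nuisance structure on edges.

    Loadings are drawn once per edge from centered normals with the given
    standard deviations, so covariate effects are diffuse and an order of
    magnitude smaller than the planted subtype separation at defaults.
    """

    age_load_sd: float = 5e-4   # per month of age (centered)
    gender_load_sd: float = 5e-3
    site_offset_sd: float = 5e-3
    fd_load_sd: float = 5e-2    # per mm of mean FD (centered)
    n_sites: int = 4


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description for one synthetic cohort."""

    n_hc: int = 200
    n_patients: int = 400
    subtype_props: tuple[float, ...] = (0.5, 0.5)
    n_components: int = 53
    network_sizes: tuple[int, ...] = (5, 2, 9, 9, 17, 7, 4)
    effect_size: float = 0.8
    affected_blocks: tuple = DEFAULT_AFFECTED_BLOCKS
    noise_sd: float = 0.1
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    timepoints: int | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.subtype_props) - 1.0) > 1e-9:
            raise ConfigurationError("subtype_props must sum to 1")
        if any(p < 0 for p in self.subtype_props):
            raise ConfigurationError("subtype_props must be non-negative")
        if sum(self.network_sizes) != self.n_components:
            raise ConfigurationError(
                f"network_sizes sum {sum(self.network_sizes)} != n_components {self.n_components}"
            )
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_patients < self.k_true:
            raise InfeasibleCohortError(
                f"{self.n_patients} patients cannot realize {self.k_true} subtypes"
            )
        if len(self.affected_blocks) != self.k_true:
            raise ConfigurationError("need one affected-block list per subtype")

    @property
    def k_true(self) -> int:
        return len(self.subtype_props)

    @property
    def partition(self) -> NetworkPartition:
        return NetworkPartition(tuple(self.network_sizes))

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_components)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectRecord:
    """One subject's phenotype row; ``true_subtype`` is hidden ground truth."""

    id: str
    diagnosis: str  # "patient" | "control"
    true_subtype: int | None
    age: float      # months
    gender: str     # "M" | "F"
    site: str
    mean_fd: float  # mm
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if (self.diagnosis == "patient") != (self.true_subtype is not None):
            raise ConfigurationError("true_subtype present iff diagnosis is patient")
        if self.age <= 0 or self.mean_fd < 0:
            raise ConfigurationError("age must be positive and mean_fd non-negative")


def block_edge_indices(spec: CohortSpec, blocks) -> np.ndarray:
    """Canonical edge positions whose endpoints fall in the given network pairs."""
    part = spec.partition
    nets = part.component_networks
    wanted = {frozenset(b) for b in blocks}
    idx = [
        k
        for k, (i, j) in enumerate(edge_index(spec.n_components))
        if frozenset((nets[i], nets[j])) in wanted
    ]
    return np.asarray(idx, dtype=int)


def _base_pattern(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Population-mean edge values: higher within-network than between."""
    nets = spec.partition.component_networks
    base = np.empty(spec.n_edges)
    for k, (i, j) in enumerate(edge_index(spec.n_components)):
        base[k] = 0.45 if nets[i] == nets[j] else 0.15
    return base + rng.normal(0.0, 0.05, size=spec.n_edges)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], np.ndarray]:
    """Draw a cohort and its FNC feature matrix (subjects x edges).

    Patients receive the base connectivity pattern plus their subtype's
    block shift of ``effect_size * noise_sd`` per affected edge, plus
    covariate effects and N(0, noise_sd) edge noise; controls receive the
    same without the subtype shift. Edge values are clipped to (-1, 1).
    """
    rng = np.random.default_rng(spec.seed)
    cov = spec.covariate_model
    d = spec.n_edges

    base = _base_pattern(spec, rng)
    age_load = rng.normal(0.0, cov.age_load_sd, size=d)
    gender_load = rng.normal(0.0, cov.gender_load_sd, size=d)
    site_offsets = rng.normal(0.0, cov.site_offset_sd, size=(cov.n_sites, d))
    fd_load = rng.normal(0.0, cov.fd_load_sd, size=d)

    shift = spec.effect_size * spec.noise_sd
    subtype_shift = np.zeros((spec.k_true, d))
    for s, blocks in enumerate(spec.affected_blocks):
        subtype_shift[s, block_edge_indices(spec, blocks)] = shift

    n = spec.n_hc + spec.n_patients
    # largest-remainder allocation of patients to subtypes
    raw = np.asarray(spec.subtype_props) * spec.n_patients
    counts = np.floor(raw).astype(int)
    remainder = spec.n_patients - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    subtype_of = np.repeat(np.arange(spec.k_true), counts)

    subjects: list[SubjectRecord] = []
    fncs = np.empty((n, d))
    for i in range(n):
        is_patient = i >= spec.n_hc
        subtype = int(subtype_of[i - spec.n_hc]) if is_patient else None
        age = rng.uniform(108.0, 132.0)
        gender = "M" if rng.random() < 0.5 else "F"
        site_idx = int(rng.integers(cov.n_sites))
        mean_fd = float(abs(rng.normal(0.15, 0.05)))
        edges = base.copy()
        if is_patient:
            edges += subtype_shift[subtype]
        edges += (age - 120.0) * age_load
        edges += (1.0 if gender == "M" else 0.0) * gender_load
        edges += site_offsets[site_idx]
        edges += (mean_fd - 0.15) * fd_load
        edges += rng.normal(0.0, spec.noise_sd, size=d)
        fncs[i] = np.clip(edges, -0.999, 0.999)

        cognition = 100.0 + rng.normal(0.0, 12.0)
        if is_patient:
            cognition -= 5.0 + 4.0 * subtype  # subtype 2 lower, as in severity ordering
        subjects.append(
            SubjectRecord(
                id=f"S{i + 1:04d}",
                diagnosis="patient" if is_patient else "control",
                true_subtype=None if subtype is None else subtype + 1,
                age=float(age),
                gender=gender,
                site=f"site{site_idx + 1}",
                mean_fd=mean_fd,
                scores={"total_cognition": float(cognition)},
            )
        )
    return subjects, fncs


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "id": s.id,
            "diagnosis": s.diagnosis,
            "true_subtype": s.true_subtype,
            "age": s.age,
            "gender": s.gender,
            "site": s.site,
            "mean_fd": s.mean_fd,
        }
        row.update(s.scores)
        rows.append(row)
    return pd.DataFrame(rows)


def nearest_psd_correlation(matrix: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-floored, unit-diagonal-rescaled repair of a correlation matrix."""
    m = np.asarray(matrix, dtype=float)
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    w = np.maximum(w, floor)
    repaired = (v * w) @ v.T
    scale = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(scale, scale)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def generate_timecourses(
    spec: CohortSpec,
    target_fnc: np.ndarray,
    seed: int | None = None,
) -> np.ndarray:
    """Sample a C x T time-course matrix whose empirical correlation
    converges to ``target_fnc`` as T grows.

    ``target_fnc`` may be an edge vector or a full C x C matrix. Rows of the
    output are exactly zero mean and unit variance (standardization does not
    change Pearson correlations).
    """
    target = np.asarray(target_fnc, dtype=float)
    if target.ndim == 1:
        target = unvectorize_fnc(target)
    c = target.shape[0]
    t = spec.timepoints if spec.timepoints is not None else 4 * c
    if t < c:
        raise IllConditionedSampleError(f"need T >= C, got T={t}, C={c}")
    corr = nearest_psd_correlation(target)
    w, v = np.linalg.eigh(corr)
    root = (v * np.sqrt(np.maximum(w, 0.0))) @ v.T
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    samples = root @ rng.standard_normal((c, t))
    samples -= samples.mean(axis=1, keepdims=True)
    samples /= samples.std(axis=1, keepdims=True)
    return samples


DEFAULT_WEEKS = (0, 1, 2, 3, 4, 8)
#: Default per-(biotype, arm) plateau reductions (score points at full
#: response). Biotype 1 responds strongly to MPH; other cells moderately.
DEFAULT_EFFECT_PLAN = {
    (1, "MPH"): 24.0,
    (1, "ATX"): 10.0,
    (2, "MPH"): 10.0,
    (2, "ATX"): 10.0,
}


def response_curve(week, tau: float = 1.5):
    """Monotone fraction of full medication response attained by ``week``.

    Stimulant and non-stimulant ADHD medication effects set in within days
    and then plateau, so the response fraction is 1 - exp(-week / tau);
    tau = 1.5 weeks puts ~75% of the full effect before week 2 and leaves
    the curve still rising slightly at week 8.
    """
    return 1.0 - np.exp(-np.asarray(week, dtype=float) / tau)


def generate_longitudinal(
    subjects: list[SubjectRecord],
    weeks=DEFAULT_WEEKS,
    arms=("MPH", "ATX"),
    effect_plan=None,
    seed: int = 0,
    scale: str = "RS-Total",
    baseline_mean: float = 40.0,
    baseline_sd: float = 5.0,
    noise_sd: float = 2.0,
    rand_intercept_sd: float = 2.0,
    rand_slope_sd: float = 3.0,
    tau: float = 1.5,
) -> pd.DataFrame:
    """Simulate per-week symptom scores for treated patients.

    score(t) = baseline - effect(biotype, arm) * g(t) + b0_i + b1_i * g(t)
    + noise, floored at 0, with g the monotone saturating response curve
    (:func:`response_curve`), effect the (biotype, arm) plateau reduction,
    and (b0_i, b1_i) subject-level random intercept and response-magnitude
    deviation. ``arms`` is either a mapping id -> arm or a sequence of arm
    names to sample uniformly. Patients must carry a biotype
    (``true_subtype``).
    """
    if effect_plan is None:
        effect_plan = DEFAULT_EFFECT_PLAN
    weeks = list(weeks)
    if 0 not in weeks:
        raise ConfigurationError("weeks must include the baseline week 0")
    rng = np.random.default_rng(seed)
    rows = []
    for s in subjects:  # every subject passed is a medicated subject
        if s.true_subtype is None:
            raise MissingAssignmentError(f"subject {s.id} has no biotype assignment")
        biotype = int(s.true_subtype)
        if isinstance(arms, dict):
            arm = arms[s.id]
        else:
            arm = str(arms[int(rng.integers(len(arms)))])
        key = (biotype, arm)
        if key not in effect_plan:
            raise ConfigurationError(f"effect_plan missing effect for {key}")
        effect = effect_plan[key]
        baseline = rng.normal(baseline_mean, baseline_sd)
        b0 = rng.normal(0.0, rand_intercept_sd) if rand_intercept_sd > 0 else 0.0
        b1 = rng.normal(0.0, rand_slope_sd) if rand_slope_sd > 0 else 0.0
        for week in weeks:
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            g = float(response_curve(week, tau))
            score = baseline - effect * g + b0 + b1 * g + eps
            rows.append(
                {
                    "id": s.id,
                    "biotype": biotype,
                    "med": arm,
                    "week": week,
                    "scale": scale,
                    "score": max(0.0, float(score)),
                }
            )
    return pd.DataFrame(rows)
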