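"""Seeded simulator of drug cascades over a latent disease network.

The generative model mirrors the analysis assumptions: drugs are born as a
homogeneous Poisson process over a span of years, each seeded in a single
disease; once a disease has adopted a drug it "sends" it to every disease
that has not yet adopted it, with an exponential delay governed by a latent
per-year rate matrix ``lambda[i, j]``; a disease's adoption time is the
minimum arrival over all senders, and arrivals after the last observation
time are censored (no record).  Per-drug study histories are drawn from an
inhomogeneous Poisson process whose expected cumulative count at age ``t``
is ``alpha * t**beta``, the power-law form that empirical accumulation
curves follow.

The latent rates and per-drug growth parameters are returned as ground
truth so that every downstream stage (power-law fitting, taxonomy, network
inference) can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events_io import (
    AdoptionRecord,
    DEFAULT_WINDOW,
    EventTable,
    ObservationWindow,
    StudyRecord,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_rate_matrix",
    "simulate_cascades",
    "simulate_studies",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of the cascade + study-history simulator.

    Defaults emulate a mid-sized clinical corpus: a couple of decades of
    drug births, tens of drugs per year, disease-to-disease communication
    rates spanning an order of magnitude (0.05-0.5 per year, i.e. mean
    propagation delays of 2-20 years), and per-drug growth exponents beta
    in [0.7, 1.6], the range spanned by observed accumulation quintiles.
    """

    n_diseases: int = 10
    edge_density: float = 0.3
    lambda_low: float = 0.05
    lambda_high: float = 0.5
    rate_matrix: np.ndarray | None = None  # explicit override of the above
    drugs_per_year: float = 50.0
    year_span: tuple[float, float] = (1990.0, 2010.0)
    seed_disease_weights: np.ndarray | None = None  # uniform when None
    alpha_range: tuple[float, float] = (0.5, 4.0)  # log-uniform
    beta_range: tuple[float, float] = (0.7, 1.6)  # uniform
    window: ObservationWindow = field(default_factory=lambda: DEFAULT_WINDOW)
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValueError("edge_density must be in [0, 1]")
        if self.rate_matrix is None and self.lambda_low <= 0:
            raise ValueError("lambda_low must be > 0")
        if self.lambda_high < self.lambda_low:
            raise ValueError("lambda_high must be >= lambda_low")
        if self.beta_range[0] <= 0:
            raise ValueError("beta range must be positive")
        if self.year_span[0] >= self.year_span[1]:
            raise ValueError("year_span must be increasing")
        if self.seed_disease_weights is not None:
            w = np.asarray(self.seed_disease_weights, dtype=float)
            if w.shape != (self.n_diseases,) or not np.isclose(w.sum(), 1.0):
                raise ValueError("seed_disease_weights must be a probability vector of length n_diseases")

    @property
    def disease_ids(self) -> list[str]:
        width = max(2, len(str(self.n_diseases - 1)))
        return [f"D{i:0{width}d}" for i in range(self.n_diseases)]


@dataclass
class GroundTruth:
    """Latent parameters of one simulated dataset."""

    lambda_true: np.ndarray  # disease x disease per-year rates, 0 = no edge
    disease_ids: list[str]
    alpha_true: dict[str, float]
    beta_true: dict[str, float]
    seed_assignments: dict[str, str]  # drug -> seeding disease
    birth_times: dict[str, float]

    def __post_init__(self):
        lam = np.asarray(self.lambda_true, dtype=float)
        if lam.ndim != 2 or lam.shape[0] != lam.shape[1]:
            raise ValueError("lambda_true must be square")
        if np.any(np.diag(lam) != 0):
            raise ValueError("lambda_true diagonal must be 0")
        if lam.shape[0] != len(self.disease_ids):
            raise ValueError("dimension mismatch with disease_ids")

    def rate(self, i: str, j: str) -> float:
        ii = self.disease_ids.index(i)
        jj = self.disease_ids.index(j)
        return float(self.lambda_true[ii, jj])


def generate_rate_matrix(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the latent rate matrix: each off-diagonal entry is nonzero with
    probability ``edge_density``, with rate log-uniform in
    [lambda_low, lambda_high]."""
    if config.rate_matrix is not None:
        lam = np.asarray(config.rate_matrix, dtype=float)
        if lam.shape != (config.n_diseases, config.n_diseases):
            raise ValueError("explicit rate_matrix has wrong shape")
        return lam
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0]))
    n = config.n_diseases
    present = rng.random((n, n)) < config.edge_density
    log_lo, log_hi = np.log(config.lambda_low), np.log(config.lambda_high)
    rates = np.exp(rng.uniform(log_lo, log_hi, size=(n, n)))
    lam = np.where(present, rates, 0.0)
    np.fill_diagonal(lam, 0.0)
    return lam


def _simulate_one_cascade(
    lam: np.ndarray,
    seed_idx: int,
    t_birth: float,
    t_max: float,
    rng: np.random.Generator,
) -> dict[int, float]:
    """Event-driven cascade for one drug: returns {disease index -> time}."""
    n = lam.shape[0]
    adopted: dict[int, float] = {seed_idx: t_birth}
    arrival = np.full(n, np.inf)
    arrival[seed_idx] = -np.inf  # sentinel: already adopted

    def send_from(i: int, t_i: float) -> None:
        for j in range(n):
            if arrival[j] == -np.inf or lam[i, j] <= 0:
                continue
            cand = t_i + rng.exponential(1.0 / lam[i, j])
            if cand < arrival[j]:
                arrival[j] = cand

    send_from(seed_idx, t_birth)
    while True:
        j = int(np.argmin(np.where(arrival == -np.inf, np.inf, arrival)))
        t_j = arrival[j]
        if not np.isfinite(t_j) or t_j > t_max:
            break
        adopted[j] = t_j
        arrival[j] = -np.inf
        send_from(j, t_j)
    return adopted


def simulate_cascades(
    lambda_true: np.ndarray, config: SimulationConfig
) -> tuple[tuple[AdoptionRecord, ...], GroundTruth]:
    """Simulate drug births and their propagation across diseases.

    Births follow a homogeneous Poisson process over ``year_span``; each
    drug is seeded in one disease drawn from ``seed_disease_weights``.
    Arrivals after ``window.t_max`` leave no record (right censoring).
    Deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    n = config.n_diseases
    lam = np.asarray(lambda_true, dtype=float)
    ids = config.disease_ids
    t0, t1 = config.year_span
    n_drugs = rng.poisson(config.drugs_per_year * (t1 - t0))
    births = np.sort(rng.uniform(t0, t1, size=n_drugs))
    weights = (
        np.full(n, 1.0 / n)
        if config.seed_disease_weights is None
        else np.asarray(config.seed_disease_weights, dtype=float)
    )
    seeds = rng.choice(n, size=n_drugs, p=weights)
    a_lo, a_hi = config.alpha_range
    alphas = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi), size=n_drugs)) if a_lo > 0 else np.full(n_drugs, a_lo)
    betas = rng.uniform(config.beta_range[0], config.beta_range[1], size=n_drugs)

    width = max(4, len(str(max(n_drugs - 1, 0))))
    records: list[AdoptionRecord] = []
    alpha_true: dict[str, float] = {}
    beta_true: dict[str, float] = {}
    seed_assignments: dict[str, str] = {}
    birth_map: dict[str, float] = {}
    for k in range(n_drugs):
        drug = f"drug{k:0{width}d}"
        adopted = _simulate_one_cascade(lam, int(seeds[k]), float(births[k]), config.window.t_max, rng)
        for j, t in adopted.items():
            records.append(AdoptionRecord(time=float(t), drug_id=drug, disease_id=ids[j]))
        alpha_true[drug] = float(alphas[k])
        beta_true[drug] = float(betas[k])
        seed_assignments[drug] = ids[int(seeds[k])]
        birth_map[drug] = float(births[k])

    truth = GroundTruth(
        lambda_true=lam,
        disease_ids=ids,
        alpha_true=alpha_true,
        beta_true=beta_true,
        seed_assignments=seed_assignments,
        birth_times=birth_map,
    )
    adoptions = tuple(sorted(records, key=lambda a: (a.time, a.drug_id, a.disease_id)))
    return adoptions, truth


def simulate_studies(
    adoptions: tuple[AdoptionRecord, ...],
    truth: GroundTruth,
    config: SimulationConfig,
) -> EventTable:
    """Generate per-drug study histories by time-rescaling.

    Study ages for a drug follow an inhomogeneous Poisson process with
    cumulative intensity ``Lambda(t) = alpha * t**beta`` (so the expected
    cumulative study count at age ``t`` is exactly ``alpha * t**beta``),
    truncated at the observation end.  Every drug additionally has a birth
    study at age 0.  Each study is annotated with the diseases the drug has
    adopted by the study's time (at least the seed disease).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    by_drug: dict[str, list[AdoptionRecord]] = {}
    for a in adoptions:
        by_drug.setdefault(a.drug_id, []).append(a)

    records: list[StudyRecord] = []
    t_max = config.window.t_max
    for drug in sorted(by_drug):
        alpha = truth.alpha_true[drug]
        beta = truth.beta_true[drug]
        t_birth = truth.birth_times[drug]
        span = t_max - t_birth
        ages = [0.0]
        if alpha > 0 and span > 0:
            total = alpha * span**beta
            n_events = rng.poisson(total)
            if n_events > 0:
                # order statistics of the rescaled process
                u = np.sort(rng.uniform(0.0, total, size=n_events))
                ages.extend(((u / alpha) ** (1.0 / beta)).tolist())
        disease_times = sorted((a.time, a.disease_id) for a in by_drug[drug])
        for s_idx, age in enumerate(ages):
            t = t_birth + age
            diseases = frozenset(d for (td, d) in disease_times if td <= t)
            if not diseases:  # the seed adoption happens exactly at birth
                diseases = frozenset({disease_times[0][1]})
            records.append(
                StudyRecord(time=t, drug_id=drug, study_id=f"{drug}_s{s_idx:04d}", diseases=diseases)
            )
    return EventTable(records)


def simulate_dataset(config: SimulationConfig) -> tuple[EventTable, tuple[AdoptionRecord, ...], GroundTruth]:
    """Convenience wrapper: rate matrix -> cascades -> study histories."""
    lam = generate_rate_matrix(config)
    adoptions, truth = simulate_cascades(lam, config)
    events = simulate_studies(adoptions, truth, config)
    return events, adoptions, truth
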