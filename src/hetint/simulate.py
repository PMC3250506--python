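"""Synthetic data with known ground truth for every pipeline stage.

Two generators are provided:

* :func:`simulate_coculture` draws monoculture baselines log-normally,
  builds the co-culture expression *exactly* by the blend model
  ``e_co = (a*e_A + (1-a)*e_B) * I`` with a sparse set of planted
  interaction factors, and applies independent multiplicative noise per
  replicate.  Gamma noise (mean 1, CV ``noise_cv``) matches the Gamma-error
  assumption of the fitting model so that recovery and oracle-equivalence
  checks are well posed; a log-normal mode exercises robustness to
  misspecification.

* :func:`simulate_cohort` builds an NKI-style tumor cohort: patients fall
  into a high/low signature-expression group (50/50), signature genes are
  shifted between groups, and survival times are exponential with a
  proportional-hazards effect of the signature score.  The score is
  standardized so the two planted group means sit one unit apart, making
  ``log_hr_per_score_sd`` the true between-group log hazard ratio while the
  hazard still varies continuously with the score.  Censoring times are
  exponential with the rate calibrated so the expected censored fraction
  matches ``censor_rate``.

Both return the matrices/records in exactly the containers and dialects the
analysis modules consume, together with a JSON-serializable truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io import ExperimentDesign
from .signatures import GeneSignature
from .survival import ClinicalRecord

__all__ = [
    "CoCultureSimSpec",
    "CohortSimSpec",
    "CoCultureSim",
    "CohortSim",
    "simulate_coculture",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CoCultureSimSpec:
    """Study conditions for one simulated monoculture/co-culture triplet.

    Defaults mirror the profiling experiments being emulated: ~2000 genes
    passing filters, two biological replicates per condition, an equal-cell
    mixture (a=0.5), and multiplicative noise with a 10% CV.
    """

    n_genes: int = 2000
    a_true: float = 0.5
    induced_sets: tuple[tuple[tuple[int, ...], float], ...] = ()
    noise_cv: float = 0.1
    n_replicates: int = 2
    baseline_log2_sd: float = 1.5
    noise: str = "gamma"  # or "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.a_true < 1:
            raise ValueError("a_true must be in (0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise not in ("gamma", "lognormal"):
            raise ValueError("noise must be 'gamma' or 'lognormal'")
        for idx, fold in self.induced_sets:
            if fold <= 0:
                raise ValueError("interaction folds must be > 0")
            if any(i < 0 or i >= self.n_genes for i in idx):
                raise ValueError("induced gene index out of range")


class CoCultureSim(NamedTuple):
    matrix: pd.DataFrame  # log2 ratios, genes x samples
    design: ExperimentDesign
    truth: dict


def _multiplicative_noise(rng: np.random.Generator, cv: float, size, kind: str) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    if kind == "gamma":
        shape = 1.0 / cv**2
        return rng.gamma(shape, 1.0 / shape, size=size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-(sigma**2) / 2, sigma, size=size)


def simulate_coculture(spec: CoCultureSimSpec) -> CoCultureSim:
    """Generate a log2 expression matrix for one blend-model experiment."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    mono_a = np.exp2(rng.normal(0.0, spec.baseline_log2_sd, n))
    mono_b = np.exp2(rng.normal(0.0, spec.baseline_log2_sd, n))
    interaction = np.ones(n)
    for idx, fold in spec.induced_sets:
        interaction[list(idx)] = fold
    co = (spec.a_true * mono_a + (1 - spec.a_true) * mono_b) * interaction

    columns, data, roles = [], [], {}
    for role, truth_vec, tag in (
        ("monoculture_A", mono_a, "monoA"),
        ("monoculture_B", mono_b, "monoB"),
        ("coculture", co, "co"),
    ):
        for rep in range(1, spec.n_replicates + 1):
            noise = _multiplicative_noise(rng, spec.noise_cv, n, spec.noise)
            sample = f"{tag}_r{rep}"
            columns.append(sample)
            data.append(np.log2(truth_vec * noise))
            roles[sample] = (role, rep)

    matrix = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=columns)
    truth = {
        "a_true": spec.a_true,
        "interaction_factors": {
            str(gene_ids[i]): float(interaction[i])
            for i in range(n)
            if interaction[i] != 1.0
        },
        "induced_genes": sorted(
            str(gene_ids[i]) for idx, _ in spec.induced_sets for i in idx
        ),
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
    }
    return CoCultureSim(matrix, ExperimentDesign(roles), truth)


@dataclass(frozen=True)
class CohortSimSpec:
    """Study conditions for a simulated tumor cohort with survival follow-up.

    Defaults emulate an early-stage breast-cancer cohort: ~300 patients, a
    clear two-group signature structure (between-group shift twice the
    within-group SD), a hazard ratio of 2 per group for the signature
    effect, a baseline hazard of 0.05 events/year (median survival ~14
    years in the low group) and ~30% censoring.
    """

    signature: GeneSignature
    n_patients: int = 300
    n_background_genes: int = 200
    group_shift: float = 2.0
    within_sd: float = 1.0
    log_hr_per_score_sd: float = float(np.log(2))
    baseline_hazard: float = 0.05
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


class CohortSim(NamedTuple):
    matrix: pd.DataFrame  # log2 ratios, genes (signature + background) x patients
    records: list[ClinicalRecord]
    truth: dict


def _calibrate_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Censoring hazard mu with sum(mu/(mu+lam)) / n == target (exponential races)."""
    if target == 0:
        return 0.0

    def frac(mu: float) -> float:
        return float(np.mean(mu / (mu + hazards)))

    lo, hi = 1e-12, float(hazards.max())
    while frac(hi) < target:
        hi *= 2
    return float(optimize.brentq(lambda m: frac(m) - target, lo, hi))


def simulate_cohort(spec: CohortSimSpec) -> CohortSim:
    """Generate an NKI-style cohort: expression matrix + clinical records."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    patients = [f"p{i:04d}" for i in range(n)]
    high = np.zeros(n, dtype=bool)
    high[rng.permutation(n)[: n // 2]] = True

    sig_genes = [g for g, _ in spec.signature.members]
    dirs = np.array([d for _, d in spec.signature.members], dtype=float)
    m = len(sig_genes)
    # signature genes: +-shift/2 between groups (along each gene's direction)
    centers = np.where(high, spec.group_shift / 2.0, -spec.group_shift / 2.0)
    sig_values = dirs[:, None] * centers[None, :] + rng.normal(
        0.0, spec.within_sd, (m, n)
    )
    bg_genes = [f"bg{i:04d}" for i in range(spec.n_background_genes)]
    bg_values = rng.normal(0.0, spec.within_sd, (spec.n_background_genes, n))
    matrix = pd.DataFrame(
        np.vstack([sig_values, bg_values]),
        index=pd.Index(sig_genes + bg_genes, name="gene_id"),
        columns=patients,
    )

    raw_score = (dirs[:, None] * sig_values).sum(axis=0)
    mean_high, mean_low = raw_score[high].mean(), raw_score[~high].mean()
    sep = mean_high - mean_low
    if abs(sep) > 1e-12:
        z = (raw_score - raw_score.mean()) / sep  # group means one unit apart
    else:
        sd = raw_score.std(ddof=0)
        z = (raw_score - raw_score.mean()) / (sd if sd > 0 else 1.0)

    hazards = spec.baseline_hazard * np.exp(spec.log_hr_per_score_sd * z)
    event_times = rng.exponential(1.0 / hazards)
    mu = _calibrate_censor_rate(hazards, spec.censor_rate)
    censor_times = (
        rng.exponential(1.0 / mu, n) if mu > 0 else np.full(n, np.inf)
    )
    observed = np.minimum(event_times, censor_times)
    died = event_times <= censor_times

    records = []
    for i, pid in enumerate(patients):
        events = [("death", float(observed[i]))] if died[i] else []
        records.append(ClinicalRecord(pid, events, float(observed[i])))

    truth = {
        "group": {p: ("high" if h else "low") for p, h in zip(patients, high)},
        "log_hr_per_score_sd": spec.log_hr_per_score_sd,
        "standardized_score": {p: float(v) for p, v in zip(patients, z)},
        "censor_hazard": mu,
        "n_events": int(died.sum()),
        "seed": spec.seed,
    }
    return CohortSim(matrix, records, truth)
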