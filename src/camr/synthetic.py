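"""Synthetic three-modality cohorts with known shared/private latent structure.

Each patient carries a shared latent factor (information common to all three
modalities) and one private factor per modality. Observed feature blocks are
linear images of these factors through per-seed orthonormal loading matrices,
plus an additive per-modality offset (the controllable "modality gap") and
Gaussian noise. Event times follow a proportional-hazards model with
log-linear risk in the latent factors; censoring times are independent
exponentials whose rate is calibrated to hit a target censored fraction.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import MODALITIES, ModalityBlock, MultimodalCohort, SurvivalLabels


@dataclasses.dataclass
class SimulationConfig:
    """Generator settings. Defaults give a moderately informative cohort.

    `beta_shared` acts on the shared factor; `beta_private` acts on each
    modality's private factor (same vector for all three). `modality_shift`
    is the additive offset per modality creating the distributional gap the
    alignment network is meant to remove.
    """

    n_patients: int = 300
    feature_count: int = 80
    shared_dim: int = 5
    private_dim: int = 3
    beta_shared: Sequence[float] = (0.8, 0.6, 0.5, 0.4, 0.3)
    beta_private: Sequence[float] = (0.3, 0.2, 0.1)
    noise_sd: float = 0.5
    censor_rate_target: float = 0.3
    baseline_hazard: float = 1e-3
    modality_shift: Sequence[float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        if self.feature_count < self.shared_dim + self.private_dim:
            raise ValueError("feature_count must be >= shared_dim + private_dim")
        if not 0 <= self.censor_rate_target < 1:
            raise ValueError("censor_rate_target must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if len(self.beta_shared) != self.shared_dim:
            raise ValueError("beta_shared length must equal shared_dim")
        if len(self.beta_private) != self.private_dim:
            raise ValueError("beta_private length must equal private_dim")
        if len(self.modality_shift) != 3:
            raise ValueError("modality_shift needs one offset per modality (3)")


@dataclasses.dataclass
class SimulatedTruth:
    """Ground truth of a simulated cohort, for oracle evaluations."""

    latent_shared: np.ndarray
    latent_private: dict[str, np.ndarray]
    true_risk: np.ndarray
    loading_matrices: dict[str, np.ndarray]
    censoring_rate_realized: float


def _orthonormal_loadings(rng: np.random.Generator, n_features: int,
                          n_factors: int) -> np.ndarray:
    """Random loading matrix with orthonormal columns (shared and private
    signal directions do not overlap in feature space)."""
    a = rng.standard_normal((n_features, n_factors))
    q, _ = np.linalg.qr(a)
    return q[:, :n_factors]


def _calibrate_censor_rate(event_rates: np.ndarray, target: float) -> float:
    """Bisection for the exponential censoring rate c with
    mean_i c/(c + lambda_i) = target (competing independent exponentials)."""
    if target <= 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + event_rates)))

    lo, hi = 1e-12, float(event_rates.max())
    while frac(hi) < target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig) -> tuple[MultimodalCohort, SimulatedTruth]:
    """Draw a cohort and its ground truth; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k, q = config.n_patients, config.shared_dim, config.private_dim

    z = rng.standard_normal((n, k))
    private = {m: rng.standard_normal((n, q)) for m in MODALITIES}

    loadings = {
        m: _orthonormal_loadings(rng, config.feature_count, k + q)
        for m in MODALITIES
    }

    blocks = {}
    scale = np.sqrt(config.feature_count)  # keep per-feature signal O(1)
    for m, shift in zip(MODALITIES, config.modality_shift):
        latent = np.hstack([z, private[m]])
        x = scale * latent @ loadings[m].T + shift
        x += config.noise_sd * rng.standard_normal(x.shape)
        names = [f"{m}_feat_{j + 1}" for j in range(config.feature_count)]
        blocks[m] = ModalityBlock(m, x, names)

    beta_s = np.asarray(config.beta_shared, dtype=float)
    beta_p = np.asarray(config.beta_private, dtype=float)
    true_risk = z @ beta_s + sum(private[m] @ beta_p for m in MODALITIES)

    event_rates = config.baseline_hazard * np.exp(true_risk)
    t_event = rng.exponential(1.0 / event_rates)
    c_rate = _calibrate_censor_rate(event_rates, config.censor_rate_target)
    if c_rate > 0:
        t_censor = rng.exponential(1.0 / c_rate, size=n)
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-9)

    ids = [f"PT{i + 1:05d}" for i in range(n)]
    labels = SurvivalLabels(time, event, ids)
    truth = SimulatedTruth(
        latent_shared=z,
        latent_private=private,
        true_risk=true_risk,
        loading_matrices=loadings,
        censoring_rate_realized=float(1.0 - event.mean()),
    )
    return MultimodalCohort(blocks, labels), truth


def oracle_cindex(truth: SimulatedTruth, labels: SurvivalLabels) -> float:
    """Concordance of the true linear predictor — the ceiling any learned
    risk score can approach on this cohort."""
    from .evaluation import concordance_index

    c, _ = concordance_index(truth.true_risk, labels)
    return c


def write_truth(truth: SimulatedTruth, config: SimulationConfig,
                path: str | Path) -> None:
    payload = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "beta_shared": list(config.beta_shared),
        "beta_private": list(config.beta_private),
        "modality_shift": list(config.modality_shift),
        "censor_rate_target": config.censor_rate_target,
        "censoring_rate_realized": truth.censoring_rate_realized,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
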