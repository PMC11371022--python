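"""Seeded generators for every external input of the prediction chain.

The toxicity literature behind the NTCP fit, the depth-dose curves of the
dosimetry utilities, and small analytically solvable reaction networks are
all emulated here so the full pipeline runs and is testable offline.  All
generators are pure functions of (design, seed).

The default toxicity design mirrors the scale of the published fit:
thirteen groups at 10 Gy, dose rates log-spaced from 1e-2 to 1e7 Gy/s
(conventional through FLASH), 50 subjects per group, binomial outcomes
drawn from the model itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosimetry import DoseCurve
from .ntcp_model import (
    NTCPParameters,
    ToxicityObservation,
    ntcp_from_exposure,
)
from .radiolysis_kinetics import (
    Reaction,
    ReactionNetwork,
    Species,
    SurrogateModel,
    normalized_exposure,
)

__all__ = [
    "SyntheticDesign",
    "default_surrogate",
    "generate_toxicity_dataset",
    "generate_toy_network",
    "generate_depth_dose",
]


def default_surrogate() -> SurrogateModel:
    """A fixed reference exposure surrogate for synthetic designs.

    Constant-in-dose FLASH amplitude 0.94 (high-dose-rate exposure floor
    ~0.06), transition midpoint near 3 Gy/s and width ~0.6 decades — the
    shape of the canonical network's fitted surface at 10 Gy.  Synthetic
    reference, not refitted per run: designs that need the freshly fitted
    surface pass their own surrogate.
    """
    return SurrogateModel(
        a_coefficients=np.array([0.94]),
        b_coefficients=np.array([0.45]),
        width=0.59,
        max_residual=0.0,
    )


@dataclass(frozen=True)
class SyntheticDesign:
    """Design of a synthetic toxicity study."""

    seed: int = 0
    n_groups: int = 13
    dose_range: tuple = (10.0, 10.0)  # Gy; degenerate = fixed dose
    dose_rate_range: tuple = (1e-2, 1e7)  # Gy/s, log-spaced groups
    subjects_per_group: int = 50
    true_parameters: NTCPParameters = field(default_factory=NTCPParameters)
    surrogate: SurrogateModel = field(default_factory=default_surrogate)

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be at least 1")
        if self.subjects_per_group < 1:
            raise ValueError("subjects_per_group must be at least 1")
        if self.dose_range[0] <= 0 or self.dose_rate_range[0] <= 0:
            raise ValueError("dose and dose-rate ranges must be positive")
        if self.dose_range[1] < self.dose_range[0]:
            raise ValueError("dose_range must be (lo, hi) with hi >= lo")
        if self.dose_rate_range[1] < self.dose_rate_range[0]:
            raise ValueError("dose_rate_range must be (lo, hi) with hi >= lo")


def generate_toxicity_dataset(design: SyntheticDesign) -> list:
    """Binomial toxicity groups drawn from the composed model.

    Doses are evenly spaced across ``dose_range`` and dose rates
    log-spaced across ``dose_rate_range`` (both deterministic); the only
    randomness is the seeded binomial outcome draw with probability
    NTCP(N(D, Dr)).
    """
    rng = np.random.default_rng(design.seed)
    doses = np.linspace(
        design.dose_range[0], design.dose_range[1], design.n_groups
    )
    if design.dose_rate_range[0] == design.dose_rate_range[1]:
        rates = np.full(design.n_groups, design.dose_rate_range[0])
    else:
        rates = np.geomspace(
            design.dose_rate_range[0], design.dose_rate_range[1], design.n_groups
        )
    observations = []
    for i, (d, r) in enumerate(zip(doses, rates)):
        exposure = normalized_exposure(design.surrogate, d, r)
        p = ntcp_from_exposure(design.true_parameters, exposure)
        responders = int(rng.binomial(design.subjects_per_group, p))
        observations.append(
            ToxicityObservation(
                dose=float(d),
                dose_rate=float(r),
                responders=responders,
                total_subjects=design.subjects_per_group,
                source_label=f"synthetic-group-{i + 1}",
            )
        )
    return observations


def generate_toy_network(kind: str) -> tuple:
    """Small reaction networks with known closed-form solutions.

    Returns ``(network, info)`` where ``info`` holds the parameters the
    analytic solution needs.  Kinds:

    * ``production-decay`` — S produced at g*Dr while the beam is on,
      first-order decay k; [S](t) = (p/k)(1 - exp(-k t)) during
      irradiation, and the total AUC over [0, inf) is p*T/k.
    * ``linear-chain`` — A -> B -> C, conserving total mass.
    * ``oxygen-capture`` — R + O2 -> ROO with O2 in large excess, so R
      decays pseudo-first-order with k' = k [O2]0.
    """
    if kind == "production-decay":
        network = ReactionNetwork(
            species=(
                Species("S", "produced at g*Dr, decays first-order", 0.0, 0.5),
            ),
            reactions=(Reaction.from_equation("S ->", 2.0),),
            name="toy-production-decay",
            readout="S",
        )
        info = {"g_value": 0.5, "k": 2.0}
        return network, info
    if kind == "linear-chain":
        network = ReactionNetwork(
            species=(
                Species("A", "", 1e-6, 0.0),
                Species("B", "", 0.0, 0.0),
                Species("C", "", 0.0, 0.0),
            ),
            reactions=(
                Reaction.from_equation("A -> B", 3.0),
                Reaction.from_equation("B -> C", 1.0),
            ),
            name="toy-linear-chain",
            readout="B",
        )
        info = {"a0": 1e-6, "k1": 3.0, "k2": 1.0}
        return network, info
    if kind == "oxygen-capture":
        network = ReactionNetwork(
            species=(
                Species("R", "carbon radical", 1e-7, 0.0),
                Species("O2", "oxygen in excess", 1e-3, 0.0),
                Species("ROO", "peroxyl product", 0.0, 0.0),
            ),
            reactions=(Reaction.from_equation("R + O2 -> ROO", 4.9e8),),
            name="toy-oxygen-capture",
            readout="ROO",
        )
        info = {"r0": 1e-7, "o2": 1e-3, "k": 4.9e8}
        return network, info
    raise ValueError(f"unknown toy network kind {kind!r}")


def generate_depth_dose(
    profile_kind: str,
    n_points: int = 101,
    peak_mm: float = 10.0,
    span_mm: float = 20.0,
    buildup_mm: float = 2.0,
    attenuation_per_mm: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseCurve:
    """Deterministic analytic depth-dose fixtures.

    * ``triangle`` — linear rise to 1 at ``peak_mm``, linear fall to 0 at
      ``span_mm``.
    * ``flat`` — uniform dose 1 across the span.
    * ``buildup-exponential`` — (1 - exp(-z / buildup)) * exp(-mu z),
      the qualitative shape of a photon PDD.

    ``noise_sd > 0`` adds seeded Gaussian noise, clipped at zero.
    """
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    z = np.linspace(0.0, span_mm, n_points)
    if profile_kind == "triangle":
        up = z / peak_mm
        down = (span_mm - z) / (span_mm - peak_mm)
        dose = np.clip(np.minimum(up, down), 0.0, None)
    elif profile_kind == "flat":
        dose = np.ones_like(z)
    elif profile_kind == "buildup-exponential":
        dose = (1.0 - np.exp(-z / buildup_mm)) * np.exp(-attenuation_per_mm * z)
    else:
        raise ValueError(f"unknown profile kind {profile_kind!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dose = np.clip(dose + rng.normal(0.0, noise_sd, dose.size), 0.0, None)
    return DoseCurve(z, dose)
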