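"""Default study conditions for the synthetic multi-target experiment.

One place defines what the simulated study looks like: 18 independent
targets whose PAM-distal junction accuracy is drawn around the HEK 293T
mean (74.18%), whose PAM-proximal accuracy declines with the target's
insertion fraction (the mechanism behind the negative
insertion-vs-accuracy correlation), and dual-guide deletion pools whose
precise-ligation probability is the product of the two retained ends'
single-end accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nhejacc.synthetic_data import (
    DEFAULT_TAG,
    SimulationConfig,
    make_synthetic_target,
)
from nhejacc.target_model import GenomeTarget

N_TARGETS = 18
MEAN_DISTAL = 0.7418
MEAN_PROXIMAL = 0.3862
DISTAL_SD = 0.15
PROXIMAL_SLOPE = 0.55  # accuracy lost per unit insertion fraction
PROXIMAL_NOISE_SD = 0.08

#: independent-end model for dual-guide precise ligation
DUAL_P_PRECISE = {
    "PAM_in": MEAN_DISTAL**2,
    "PAM_out": MEAN_PROXIMAL**2,
    "PAM_in_out": MEAN_DISTAL * MEAN_PROXIMAL,
}


@dataclass(frozen=True)
class TargetCondition:
    """Ground-truth parameters for one simulated target."""

    target: GenomeTarget
    p_acc_distal: float
    p_acc_proximal: float
    mut_insertion_fraction: float


def child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


def draw_study_conditions(
    rng: np.random.Generator, n_targets: int = N_TARGETS
) -> list[TargetCondition]:
    """Draw per-target conditions for the multi-target study."""
    ins_fracs = rng.uniform(0.05, 0.95, size=n_targets)
    p_prox = np.clip(
        MEAN_PROXIMAL
        + PROXIMAL_SLOPE * (0.5 - ins_fracs)
        + rng.normal(0, PROXIMAL_NOISE_SD, n_targets),
        0.02, 0.98,
    )
    m, s = MEAN_DISTAL, DISTAL_SD
    nu = m * (1 - m) / s**2 - 1
    p_dist = np.clip(rng.beta(m * nu, (1 - m) * nu, n_targets), 0.02, 0.98)
    return [
        TargetCondition(
            target=make_synthetic_target(
                np.random.default_rng(child_seed(rng)), name=f"target_{i:02d}"
            ),
            p_acc_distal=float(p_dist[i]),
            p_acc_proximal=float(p_prox[i]),
            mut_insertion_fraction=float(ins_fracs[i]),
        )
        for i in range(n_targets)
    ]


def accuracy_config(
    cond: TargetCondition, seed: int, n_reads: int = 20_000
) -> SimulationConfig:
    """The dsODN-capture pool for one target."""
    return SimulationConfig(
        target=cond.target, tag=DEFAULT_TAG, n_reads=n_reads,
        p_acc_distal=cond.p_acc_distal, p_acc_proximal=cond.p_acc_proximal,
        mut_insertion_fraction=cond.mut_insertion_fraction, seed=seed,
    )


def profiling_config(
    cond: TargetCondition, seed: int, n_reads: int = 8_000
) -> SimulationConfig:
    """The matched dsODN-free pool used for mutation-type assessment."""
    return SimulationConfig(
        target=cond.target, tag=DEFAULT_TAG, n_reads=n_reads,
        f_wt=0.55, f_dsodn=0.0, f_mut=0.45,
        mut_insertion_fraction=cond.mut_insertion_fraction, seed=seed,
    )
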