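"""Two-proportion sample-size and power machinery for the trial design.

The protocol assumed a 55% response rate on tocilizumab and 20% on
rituximab in the B-cell-poor stratum, 90% power at two-sided alpha
0.05, a recruited mix of 60% B-cell poor / 35% rich / 5% germinal
centre positive, 10% ungradable biopsies and 5% dropout. The exact
formula behind the protocol's 82 B-cell-poor patients is not published;
this module reports the uncorrected pooled normal-approximation n, the
continuity-corrected (Fleiss) n and a simulation-calibrated n side by
side rather than forcing agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "DesignAssumptions",
    "n_per_group",
    "power_sim",
    "recruitment_chain",
]


@dataclass
class DesignAssumptions:
    """Protocol planning assumptions for the primary comparison."""

    p_ref: float = 0.20
    p_alt: float = 0.55
    power: float = 0.90
    alpha: float = 0.05
    prop_poor: float = 0.60
    prop_rich: float = 0.35
    prop_gc: float = 0.05
    ungradable_rate: float = 0.10
    dropout_rate: float = 0.05

    def __post_init__(self) -> None:
        probs = [
            self.p_ref, self.p_alt, self.prop_poor, self.prop_rich,
            self.prop_gc, self.ungradable_rate, self.dropout_rate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be strictly between 0 and 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be strictly between 0 and 1")
        if abs(self.prop_poor + self.prop_rich + self.prop_gc - 1.0) > 1e-9:
            raise ValueError("pathotype proportions must sum to 1")


def n_per_group(
    assumptions: DesignAssumptions,
    simulate: bool = False,
    reps: int = 2000,
    seed: int = 0,
) -> Dict[str, int]:
    """Per-group sample size for the two-proportion comparison.

    Returns the pooled normal-approximation n (rounded up), the Fleiss
    continuity-corrected n, and — when ``simulate`` is set — the
    smallest n on a unit grid whose simulated chi-square power reaches
    the target.
    """
    p1, p2 = assumptions.p_ref, assumptions.p_alt
    if p1 == p2:
        raise ValueError("p_ref and p_alt must differ")
    delta = abs(p2 - p1)
    pbar = (p1 + p2) / 2
    z_a = stats.norm.ppf(1 - assumptions.alpha / 2)
    z_b = stats.norm.ppf(assumptions.power)
    n_formula = (
        z_a * math.sqrt(2 * pbar * (1 - pbar))
        + z_b * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))
    ) ** 2 / delta**2
    out = {
        "formula": math.ceil(n_formula - 1e-12),
        "fleiss": math.ceil(n_formula + 2 / delta - 1e-12),
    }
    if simulate:
        n = max(2, out["formula"] - 6)
        while True:
            power, _ = power_sim(n, assumptions, reps=reps, seed=seed)
            if power >= assumptions.power:
                out["simulated"] = n
                break
            n += 1
    return out


def power_sim(
    n_per_arm: int,
    assumptions: DesignAssumptions,
    reps: int = 10_000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Simulated power of the uncorrected two-sided chi-square test.

    Draws ``reps`` two-arm trials with ``n_per_arm`` patients per group
    and the assumed response rates, applies the uncorrected Pearson
    chi-square at the assumed alpha, and returns the rejection fraction
    with its binomial Monte-Carlo standard error.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n_per_arm, assumptions.p_ref, size=reps)
    x2 = rng.binomial(n_per_arm, assumptions.p_alt, size=reps)
    # vectorised uncorrected Pearson chi-square on [[x1, n-x1], [x2, n-x2]]
    n = n_per_arm
    total = 2 * n
    col1 = x1 + x2
    col2 = total - col1
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (
            total * (x1 * (n - x2) - x2 * (n - x1)) ** 2
            / (n * n * col1 * col2)
        )
    chi2 = np.where((col1 == 0) | (col2 == 0), 0.0, chi2)
    crit = stats.chi2.ppf(1 - assumptions.alpha, 1)
    power = float(np.mean(chi2 > crit))
    mc_se = math.sqrt(power * (1 - power) / reps)
    return power, mc_se


def recruitment_chain(
    n_poor_required: int, assumptions: DesignAssumptions
) -> int:
    """Total recruitment needed to yield the required B-cell-poor n.

    Inflates sequentially for the poor fraction, ungradable biopsies
    and dropout, rounding to the nearest integer at the end:
    n_poor / (prop_poor * (1 - ungradable) * (1 - dropout)).
    """
    if assumptions.prop_poor <= 0:
        raise ValueError("prop_poor must be positive")
    if assumptions.ungradable_rate >= 1 or assumptions.dropout_rate >= 1:
        raise ValueError("attrition rates must be < 1")
    total = n_poor_required / (
        assumptions.prop_poor
        * (1 - assumptions.ungradable_rate)
        * (1 - assumptions.dropout_rate)
    )
    return int(math.floor(total + 0.5))
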