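"""Monte-Carlo power simulation for the pre-registered context effect.

The design question: with n subjects measured in two correlated conditions
(raw-scale standardized mean difference d, common SD, between-condition
correlation rho), how often does the paired test of the context main effect
(equivalent to the 2-level repeated-measures F) reach significance?  The
closed-form check uses the noncentral-t distribution with
dz = d / sqrt(2 (1 - rho)).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml
from scipy import stats as sps


@dataclass(frozen=True)
class PowerSimConfig:
    n_subjects: int = 50
    effect_d: float = 0.30  # standardized mean difference on the raw scale
    sd: float = 1.4
    rho: float = 0.80
    reps: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be below 1")
        if self.reps < 1:
            raise ValueError("reps must be at least 1")

    @classmethod
    def from_yaml(cls, path) -> "PowerSimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PowerSimResult:
    proportion: float
    se: float
    n_significant: int
    config: PowerSimConfig

    def to_dict(self) -> dict:
        return {
            "proportion": self.proportion,
            "se": self.se,
            "n_significant": self.n_significant,
            "config": self.config.to_dict(),
        }


def simulate_power(config: PowerSimConfig) -> PowerSimResult:
    """Fraction of simulated paired tests significant at the alpha level.

    Each replicate draws ``n_subjects`` bivariate-normal condition pairs
    with means (0, d * sd), common sd and correlation rho, and applies a
    two-sided paired t-test.  The binomial standard error of the fraction
    is returned alongside.
    """
    rng = np.random.default_rng(config.seed)
    n, reps = config.n_subjects, config.reps
    delta = config.effect_d * config.sd
    sd_diff = config.sd * np.sqrt(2.0 * (1.0 - config.rho))
    diffs = rng.normal(delta, sd_diff, size=(reps, n))
    t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(n))
    t_crit = sps.t.ppf(1.0 - config.alpha / 2.0, n - 1)
    n_sig = int((np.abs(t) > t_crit).sum())
    prop = n_sig / reps
    se = float(np.sqrt(prop * (1.0 - prop) / reps))
    return PowerSimResult(prop, se, n_sig, config)


def analytic_power(config: PowerSimConfig) -> float:
    """Closed-form two-sided paired-t power for the same generative model."""
    n = config.n_subjects
    dz = config.effect_d / np.sqrt(2.0 * (1.0 - config.rho))
    ncp = dz * np.sqrt(n)
    t_crit = sps.t.ppf(1.0 - config.alpha / 2.0, n - 1)
    return float(
        sps.nct.sf(t_crit, n - 1, ncp) + sps.nct.cdf(-t_crit, n - 1, ncp)
    )
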