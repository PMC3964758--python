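"""Monte-Carlo power for the kinship mixed-model variant test.

One power run fixes a family-structured pedigree, then repeatedly gene-drops
the variant, simulates the truncated MET-hour phenotype with the configured
variance fractions, fits the ML mixed model (intercept + variant, additive
relationship random effect — deliberately without sex/age, which makes the
estimates conservative), and records the Wald p-value of the variant. Power
is the fraction of replicates rejecting at the Bonferroni-corrected alpha,
reported with a 95% normal-approximation binomial confidence interval.

The pedigree is held fixed across replicates within a run (family
composition is a nuisance parameter; genotypes and phenotypes are
re-sampled), so the relationship-matrix eigendecomposition is computed once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import KinshipTransform, fit_rotated
from .pedigree import relationship_blocks
from .simulate import (ConfigurationError, PhenotypeSimulator, SimulationConfig,
                       gene_drop, generate_families)

DEFAULT_ALPHA = 0.05 / 11  # Bonferroni for the 11 variant tests


@dataclass
class PowerConfig:
    sim: SimulationConfig
    n_reps: int = 1000
    alpha: float = DEFAULT_ALPHA
    master_seed: int = 0
    max_failure_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be at least 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")


@dataclass
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_reps: int
    n_failed: int
    config: PowerConfig
    p_values: Optional[np.ndarray] = None
    valid: bool = True

    def as_row(self) -> dict:
        sim = self.config.sim
        return {
            "n_individuals": sim.n_individuals,
            "maf": sim.maf,
            "effect_r2": sim.effect_r2,
            "heritability_h2": sim.heritability_h2,
            "n_reps": self.n_reps,
            "alpha": self.config.alpha,
            "power": self.power,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_failed": self.n_failed,
        }


def binomial_ci(successes: int, n: int, level: float = 0.95,
                method: str = "wald") -> tuple[float, float]:
    """Binomial proportion confidence interval, clipped to [0, 1].

    Default is the normal (Wald) approximation p +/- z * sqrt(p(1-p)/n);
    ``method="wilson"`` gives the Wilson score interval.
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("require 0 <= successes <= n and n >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = successes / n
    if method == "wald":
        half = z * np.sqrt(p * (1.0 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        denom = 1.0 + z ** 2 / n
        center = (p + z ** 2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1.0 - p) / n + z ** 2 / (4 * n ** 2)) / denom
        lo, hi = center - half, center + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return (float(max(0.0, lo)), float(min(1.0, hi)))


def simulate_pvalues(config: PowerConfig,
                     progress: bool = False) -> tuple[np.ndarray, int]:
    """Replicate p-values of the variant Wald test under the configured model.

    Seed discipline: the master seed is expanded with ``numpy``'s
    SeedSequence; child stream 0 generates the pedigree, child stream k >= 1
    drives replicate k, so any replicate is independently reproducible.
    """
    sim = config.sim
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(config.n_reps + 1)
    ped_rng = np.random.default_rng(children[0])
    pedigree = generate_families(sim, rng=ped_rng)
    phen = PhenotypeSimulator(pedigree)
    transform = KinshipTransform(relationship_blocks(pedigree, phen.ids), phen.n)
    ones_t = transform.rotate(np.ones(phen.n))
    mask = pedigree.arrays()["in_analysis"]
    pvals = np.full(config.n_reps, np.nan)
    n_failed = 0
    for k in range(config.n_reps):
        rng = np.random.default_rng(children[k + 1])
        codes = gene_drop(pedigree, sim.maf, rng)
        y = phen.simulate(codes, sim, rng)
        g = codes[mask].astype(float)
        if g.std() == 0.0:
            n_failed += 1
            continue
        Xt = np.column_stack([ones_t, transform.rotate(g)])
        try:
            fit = fit_rotated(transform.rotate(y), Xt, transform.d,
                              names=["intercept", "variant"])
        except Exception:
            n_failed += 1
            continue
        b, se = fit.coef("variant")
        pvals[k] = stats.chi2.sf((b / se) ** 2, df=1)
    return pvals, n_failed


def estimate_power(config: PowerConfig, keep_pvalues: bool = False,
                   ci_method: str = "wald") -> PowerResult:
    """Monte-Carlo rejection rate of the variant test at ``config.alpha``."""
    pvals, n_failed = simulate_pvalues(config)
    ok = ~np.isnan(pvals)
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise ConfigurationError("every replicate failed to fit")
    rejections = int((pvals[ok] < config.alpha).sum())
    power = rejections / n_ok
    lo, hi = binomial_ci(rejections, n_ok, 0.95, method=ci_method)
    valid = n_failed <= config.max_failure_fraction * config.n_reps
    return PowerResult(power=float(power), ci_low=lo, ci_high=hi,
                       n_reps=n_ok, n_failed=n_failed, config=config,
                       p_values=pvals if keep_pvalues else None, valid=valid)


def power_table(configs: Sequence[PowerConfig], **kwargs) -> pd.DataFrame:
    """One row of power and CI per configuration; deterministic given seeds."""
    if not configs:
        raise ValueError("power_table requires at least one configuration")
    return pd.DataFrame([estimate_power(c, **kwargs).as_row() for c in configs])


def analytic_power_unrelated(n: int, effect_r2: float, alpha: float) -> float:
    """Closed-form power for unrelated individuals, no truncation.

    Limit-case oracle: the Wald statistic for a variant explaining a fraction
    R^2 of the variance is approximately noncentral chi-square(1) with
    noncentrality N * R^2 / (1 - R^2).
    """
    ncp = n * effect_r2 / (1.0 - effect_r2)
    crit = stats.chi2.isf(alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))
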