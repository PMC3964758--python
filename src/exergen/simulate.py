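"""Synthetic twin-family cohorts: pedigrees, gene dropping, and phenotypes.

The generator emulates a twin-register sample: families drawn from a mixture
of small templates (MZ pairs, DZ pairs, DZ pairs with an extra sibling,
singletons), biallelic variants dropped through the pedigree with founders in
Hardy-Weinberg equilibrium, and a right-skewed weekly MET-hour phenotype
built from a latent Gaussian with additive-genetic familial covariance, a
variant effect expressed as a fraction of phenotypic variance, a floor at
zero and a cap at 120 MET hours.

Twin parents are generated as founder allele sources but flagged
``in_analysis=False``: the analysis sample consists of the survey
participants, not their full ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pedigree import FEMALE, MALE, Individual, Pedigree, relationship_blocks


class ConfigurationError(ValueError):
    """Infeasible or inconsistent simulation settings."""


#: Default family-template mixture. Twin-pair dominated; configurable because
#: the true register composition is not public.
DEFAULT_FAMILY_MIXTURE = {
    "mz_pair": 0.40,
    "dz_pair": 0.40,
    "dz_pair_sib": 0.15,
    "single": 0.05,
}

#: Number of analysis participants contributed by each template.
TEMPLATE_SIZES = {"mz_pair": 2, "dz_pair": 2, "dz_pair_sib": 3, "single": 1}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``effect_r2`` is the fraction of (latent, pre-truncation) phenotypic
    variance explained by the variant; ``heritability_h2`` the fraction from
    the additive polygenic background. The latent Gaussian is affine-mapped
    to ``phenotype_mean`` / ``phenotype_sd`` (MET hours/week), floored at
    ``phenotype_floor`` and capped at ``truncation_cap``.
    """

    n_individuals: Optional[int] = None
    n_families: Optional[int] = None
    family_composition: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_MIXTURE))
    maf: float = 0.19
    effect_r2: float = 0.005
    heritability_h2: float = 0.55
    phenotype_mean: float = 13.0
    phenotype_sd: float = 18.0
    phenotype_floor: Optional[float] = 0.0
    truncation_cap: Optional[float] = 120.0
    p_female: float = 0.62
    age_range: tuple[float, float] = (18.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals is None and self.n_families is None:
            raise ConfigurationError("one of n_individuals or n_families is required")
        if self.n_individuals is not None and self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be positive")
        if not self.family_composition:
            raise ConfigurationError("family_composition is empty")
        unknown = set(self.family_composition) - set(TEMPLATE_SIZES)
        if unknown:
            raise ConfigurationError(f"unknown family templates: {sorted(unknown)}")
        total = sum(self.family_composition.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError(f"mixture weights sum to {total}, not 1")
        if not 0.0 <= self.maf <= 1.0:
            raise ConfigurationError("maf must lie in [0, 1]")
        if self.effect_r2 < 0 or self.heritability_h2 < 0:
            raise ConfigurationError("variance fractions must be nonnegative")
        if self.effect_r2 + self.heritability_h2 >= 1.0:
            raise ConfigurationError("effect_r2 + heritability_h2 must be < 1")
        if self.truncation_cap is not None and self.truncation_cap <= 0:
            raise ConfigurationError("truncation_cap must be positive")


# ----------------------------------------------------------------------
# Pedigree generation
# ----------------------------------------------------------------------

def _build_family(template: str, fam: str, rng: np.random.Generator,
                  p_female: float, age_range: tuple[float, float]) -> list[Individual]:
    def age() -> float:
        return float(np.round(rng.uniform(*age_range), 1))

    def sex() -> str:
        return FEMALE if rng.random() < p_female else MALE

    if template == "single":
        return [Individual(f"{fam}-1", fam, sex=sex(), age=age())]
    father = Individual(f"{fam}-F", fam, sex=MALE, in_analysis=False)
    mother = Individual(f"{fam}-M", fam, sex=FEMALE, in_analysis=False)
    members = [father, mother]
    if template == "mz_pair":
        s = sex()
        for k in (1, 2):
            members.append(
                Individual(f"{fam}-T{k}", fam, father.individual_id,
                           mother.individual_id, sex=s, zygosity="MZ", age=age())
            )
    elif template in ("dz_pair", "dz_pair_sib"):
        for k in (1, 2):
            members.append(
                Individual(f"{fam}-T{k}", fam, father.individual_id,
                           mother.individual_id, sex=sex(), zygosity="DZ", age=age())
            )
        if template == "dz_pair_sib":
            members.append(
                Individual(f"{fam}-S1", fam, father.individual_id,
                           mother.individual_id, sex=sex(), age=age())
            )
    else:  # pragma: no cover - guarded by SimulationConfig
        raise ConfigurationError(f"unknown template {template!r}")
    return members


def generate_families(config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None) -> Pedigree:
    """Draw a pedigree from the family-template mixture.

    If ``n_individuals`` is set, families are drawn until the analysis-sample
    size reaches it (final total within one template size of the target);
    otherwise exactly ``n_families`` families are drawn. Deterministic given
    ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = sorted(config.family_composition)
    weights = np.array([config.family_composition[t] for t in names])
    weights = weights / weights.sum()
    if config.n_individuals is not None:
        positive = [TEMPLATE_SIZES[t] for t, w in zip(names, weights) if w > 0]
        if config.n_individuals < min(positive):
            raise ConfigurationError(
                f"n_individuals={config.n_individuals} smaller than the smallest template"
            )
    individuals: list[Individual] = []
    n_sampled = 0
    fam_count = 0
    while True:
        if config.n_individuals is not None:
            if n_sampled >= config.n_individuals:
                break
        elif fam_count >= int(config.n_families):
            break
        template = names[int(rng.choice(len(names), p=weights))]
        fam_count += 1
        members = _build_family(template, f"F{fam_count:05d}", rng,
                                config.p_female, config.age_range)
        individuals.extend(members)
        n_sampled += sum(m.in_analysis for m in members)
    return Pedigree(individuals)


# ----------------------------------------------------------------------
# Gene dropping
# ----------------------------------------------------------------------

def gene_drop(pedigree: Pedigree, maf: float,
              rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Drop a biallelic variant through the pedigree.

    Founders receive two alleles i.i.d. Bernoulli(maf) (Hardy-Weinberg);
    each non-founder receives one uniformly chosen allele from each parent;
    MZ co-twins copy their representative's genotype. Returns the per-
    individual count of the minor allele (0/1/2), in pedigree order.
    """
    if not 0.0 <= maf <= 1.0:
        raise ConfigurationError("maf must lie in [0, 1]")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    arr = pedigree.arrays()
    father, mother, mz_rep, level = (
        arr["father"], arr["mother"], arr["mz_rep"], arr["level"],
    )
    n = len(pedigree)
    alleles = np.zeros((n, 2), dtype=np.int8)
    founders = father < 0
    alleles[founders] = rng.random((int(founders.sum()), 2)) < maf
    founder_copies = np.flatnonzero(founders & (mz_rep != np.arange(n)))
    alleles[founder_copies] = alleles[mz_rep[founder_copies]]
    for lev in range(1, int(level.max()) + 1 if n else 0):
        sel = np.flatnonzero(level == lev)
        if sel.size == 0:
            continue
        missing = (father[sel] < 0) | (mother[sel] < 0)
        if missing.any():
            bad = pedigree.individuals[sel[missing][0]].individual_id
            raise ConfigurationError(f"non-founder {bad} lacks parent records")
        pick_f = rng.integers(0, 2, size=sel.size)
        pick_m = rng.integers(0, 2, size=sel.size)
        alleles[sel, 0] = alleles[father[sel], pick_f]
        alleles[sel, 1] = alleles[mother[sel], pick_m]
        # MZ co-twins inherit the representative's realized transmission
        copies = sel[mz_rep[sel] != sel]
        alleles[copies] = alleles[mz_rep[copies]]
    return alleles.sum(axis=1).astype(np.int8)


# ----------------------------------------------------------------------
# Phenotype simulation
# ----------------------------------------------------------------------

class PhenotypeSimulator:
    """Reusable phenotype sampler for a fixed pedigree.

    Pre-factorizes the per-family additive-relationship blocks so repeated
    draws (as in the power engine) cost only Gaussian sampling. Families with
    identical relationship blocks are grouped and sampled in one vectorized
    call.
    """

    def __init__(self, pedigree: Pedigree):
        self.pedigree = pedigree
        self.ids = pedigree.analysis_ids()
        self.n = len(self.ids)
        self._groups: list[tuple[np.ndarray, np.ndarray]] = []
        by_key: dict[bytes, list[np.ndarray]] = {}
        factors: dict[bytes, np.ndarray] = {}
        for positions, A in relationship_blocks(pedigree, self.ids):
            key = np.round(A, 10).tobytes() + bytes([len(positions)])
            if key not in factors:
                w, U = np.linalg.eigh(A)
                factors[key] = U * np.sqrt(np.clip(w, 0.0, None))
            by_key.setdefault(key, []).append(positions)
        for key, pos_list in by_key.items():
            self._groups.append((np.vstack(pos_list), factors[key]))

    def genetic_deviates(self, rng: np.random.Generator) -> np.ndarray:
        """One draw of a ~ N(0, A) over the analysis sample (unit variance)."""
        a = np.empty(self.n)
        for positions, L in self._groups:
            z = rng.standard_normal(positions.shape)
            a[positions] = z @ L.T
        return a

    def simulate(self, genotype_codes: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator | int | None = None) -> np.ndarray:
        """Phenotypes for the analysis sample given full-pedigree genotypes."""
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        mask = self.pedigree.arrays()["in_analysis"]
        g = np.asarray(genotype_codes, dtype=float)
        if g.shape[0] == len(self.pedigree):
            g = g[mask]
        if g.shape[0] != self.n:
            raise ConfigurationError("genotype length does not match the pedigree")
        r2, h2 = config.effect_r2, config.heritability_h2
        if r2 + h2 >= 1.0:
            raise ConfigurationError("effect_r2 + heritability_h2 must be < 1")
        var_g = 2.0 * config.maf * (1.0 - config.maf)
        if r2 > 0 and var_g == 0:
            raise ConfigurationError("monomorphic variant cannot explain variance")
        beta = np.sqrt(r2 / var_g) if r2 > 0 else 0.0
        latent = beta * (g - 2.0 * config.maf)
        if h2 > 0:
            latent = latent + np.sqrt(h2) * self.genetic_deviates(rng)
        latent = latent + np.sqrt(1.0 - r2 - h2) * rng.standard_normal(self.n)
        y = config.phenotype_mean + config.phenotype_sd * latent
        lo = -np.inf if config.phenotype_floor is None else config.phenotype_floor
        hi = np.inf if config.truncation_cap is None else config.truncation_cap
        return np.clip(y, lo, hi)


def simulate_phenotype(pedigree: Pedigree, genotype_codes: np.ndarray,
                       config: SimulationConfig,
                       rng: np.random.Generator | int | None = None) -> np.ndarray:
    """One-shot phenotype draw; see :class:`PhenotypeSimulator`."""
    return PhenotypeSimulator(pedigree).simulate(genotype_codes, config, rng)
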