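"""Genotype coding, allele-frequency and Hardy-Weinberg statistics, and QC.

SNPs are coded additively as the number of copies of a designated counted
allele (0/1/2); multi-allelic VNTRs are collapsed to the count of a single
focal repeat (e.g. the DRD4 7-repeat). QC applies the usual candidate-gene
filters: minor allele frequency, Hardy-Weinberg equilibrium, Mendelian error
rate, call rate, concordance between genotyping platforms, and allele
frequency difference against a reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

ABSENCE = "absence-of-focal"


class DataError(ValueError):
    """Alleles or codes inconsistent with the variant specification."""


class UndefinedValueError(ValueError):
    """Statistic undefined for the given data (e.g. all genotypes missing)."""


@dataclass(frozen=True)
class VariantSpec:
    variant_id: str
    kind: str  # "snp" | "vntr"
    allele_labels: tuple[str, ...]
    counted_allele: str  # allele whose copies give the 0/1/2 code
    minor_allele: Optional[str] = None
    effect_allele: Optional[str] = None  # dopamine-increasing allele, or ABSENCE
    gene: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "vntr"):
            raise DataError(f"{self.variant_id}: kind must be 'snp' or 'vntr'")
        if self.kind == "snp" and len(self.allele_labels) != 2:
            raise DataError(f"{self.variant_id}: a SNP has exactly two alleles")
        if self.counted_allele not in self.allele_labels:
            raise DataError(f"{self.variant_id}: counted allele not in labels")
        if self.minor_allele is not None and self.minor_allele not in self.allele_labels:
            raise DataError(f"{self.variant_id}: minor allele not in labels")
        if self.effect_allele is not None and self.effect_allele != ABSENCE \
                and self.effect_allele not in self.allele_labels:
            raise DataError(f"{self.variant_id}: effect allele not in labels")

    @property
    def focal_allele(self) -> str:
        return self.counted_allele


@dataclass
class GenotypeVector:
    """Per-individual additive codes for one variant.

    ``codes`` holds 0/1/2 hard calls or [0, 2] dosages; missing values are
    NaN. Hard-call-only statistics (HWE, Mendelian checks) refuse dosage
    vectors.
    """

    variant: VariantSpec
    codes: np.ndarray
    dosage: bool = False

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        obs = self.codes[~np.isnan(self.codes)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise DataError(f"{self.variant.variant_id}: codes outside [0, 2]")
        if not self.dosage and obs.size and not np.all(obs == np.round(obs)):
            raise DataError(
                f"{self.variant.variant_id}: non-integer codes in hard-call mode"
            )

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def n_nonmissing(self) -> int:
        return int((~np.isnan(self.codes)).sum())

    def genotype_counts(self) -> tuple[int, int, int]:
        if self.dosage:
            raise DataError("genotype counts require hard calls, not dosages")
        obs = self.codes[~np.isnan(self.codes)].astype(int)
        return (int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum()))


@dataclass
class QCThresholds:
    hwe_p_min: float = 1e-5
    maf_min: float = 0.01
    mendel_rate_max: float = 0.02
    call_rate_min: float = 0.95
    freq_diff_max: float = 0.20
    concordance_min: float = 0.95

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise DataError(f"threshold {name}={v} outside [0, 1]")


# ----------------------------------------------------------------------
# Coding
# ----------------------------------------------------------------------

def _code_pairs(pairs: Sequence, spec: VariantSpec, focal: str) -> GenotypeVector:
    codes = np.full(len(pairs), np.nan)
    labels = set(spec.allele_labels)
    for i, pair in enumerate(pairs):
        if pair is None:
            continue
        a, b = (str(x) for x in pair)
        if a in ("NA", "") or b in ("NA", ""):
            continue
        if a not in labels or b not in labels:
            raise DataError(
                f"{spec.variant_id}: allele pair ({a}, {b}) not in {spec.allele_labels}"
            )
        codes[i] = (a == focal) + (b == focal)
    return GenotypeVector(spec, codes)


def code_snp(allele_pairs: Sequence, spec: VariantSpec) -> GenotypeVector:
    """0/1/2 count of the counted allele from called allele pairs."""
    if spec.kind != "snp":
        raise DataError(f"{spec.variant_id}: code_snp requires a SNP spec")
    return _code_pairs(allele_pairs, spec, spec.counted_allele)


def code_vntr(repeat_pairs: Sequence, spec: VariantSpec) -> GenotypeVector:
    """0/1/2 count of the focal repeat allele (all other repeats pooled)."""
    if spec.kind != "vntr":
        raise DataError(f"{spec.variant_id}: code_vntr requires a VNTR spec")
    return _code_pairs(repeat_pairs, spec, spec.focal_allele)


# ----------------------------------------------------------------------
# Frequency and Hardy-Weinberg statistics
# ----------------------------------------------------------------------

def counted_allele_freq(genotypes: GenotypeVector) -> float:
    """Frequency of the counted allele (mean code / 2; accepts dosages)."""
    obs = genotypes.codes[~np.isnan(genotypes.codes)]
    if obs.size == 0:
        raise UndefinedValueError("all genotypes missing")
    return float(obs.sum() / (2.0 * obs.size))


def maf(genotypes: GenotypeVector) -> float:
    """Minor allele frequency, folded into [0, 0.5]."""
    f = counted_allele_freq(genotypes)
    return min(f, 1.0 - f)


def hwe_test(genotype_counts: tuple[int, int, int], method: str = "chisq") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts (n0, n1, n2).

    Default is the 1-df Pearson chi-square of observed vs HWE-expected counts
    at the sample allele frequency, without continuity correction;
    ``method="exact"`` gives the standard exact conditional test. A
    monomorphic sample is in perfect equilibrium by convention (p = 1).
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise DataError("genotype counts must be nonnegative")
    n = n0 + n1 + n2
    if n < 1:
        raise UndefinedValueError("empty genotype table")
    p = (2 * n2 + n1) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    if method == "chisq":
        expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        observed = np.array([n0, n1, n2], dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(n0, n1, n2)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n0: int, n1: int, n2: int) -> float:
    """Exact HWE test: sum of conditional probabilities <= that observed."""
    n = n0 + n1 + n2
    n_minor = min(2 * n0 + n1, 2 * n2 + n1)
    het_values = np.arange(n_minor % 2, n_minor + 1, 2)
    from scipy.special import gammaln

    def log_prob(het: int) -> float:
        # log P(n_het | n, n_minor) under random mating, up to normalization
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        return (het * np.log(2) + gammaln(n + 1)
                - gammaln(het + 1) - gammaln(hom_minor + 1) - gammaln(hom_major + 1)
                - (gammaln(2 * n + 1) - gammaln(n_minor + 1)
                   - gammaln(2 * n - n_minor + 1)))

    logp = np.array([log_prob(int(h)) for h in het_values])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed_het = n1
    p_obs = probs[het_values == observed_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ----------------------------------------------------------------------
# Mendelian consistency and concordance
# ----------------------------------------------------------------------

def _transmittable(code: int) -> tuple[int, int]:
    # (min, max) copies of the counted allele a parent with this code can pass
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}[code]


def mendel_check(pedigree: Pedigree, genotypes: GenotypeVector | np.ndarray
                 ) -> tuple[int, int, float]:
    """Count Mendelian inconsistencies over parent-offspring trios and duos.

    Returns ``(errors, informative_transmissions, rate)`` where each
    available parent-offspring link counts as one transmission (a full trio
    contributes two) and a trio/duo whose child genotype is impossible under
    biallelic inheritance counts as one error. Requires hard calls.
    """
    codes = genotypes.codes if isinstance(genotypes, GenotypeVector) else np.asarray(
        genotypes, dtype=float)
    if isinstance(genotypes, GenotypeVector) and genotypes.dosage:
        raise DataError("Mendelian checks require hard calls, not dosages")
    if codes.shape[0] != len(pedigree):
        raise DataError("genotype length does not match the pedigree")
    arr = pedigree.arrays()
    father, mother = arr["father"], arr["mother"]
    errors = 0
    transmissions = 0
    for i in range(len(pedigree)):
        parents = [p for p in (father[i], mother[i]) if p >= 0]
        if not parents or np.isnan(codes[i]):
            continue
        child = int(codes[i])
        known = [int(codes[p]) for p in parents if not np.isnan(codes[p])]
        if not known:
            continue
        transmissions += len(known)
        if len(known) == 2:
            lo = sum(_transmittable(c)[0] for c in known)
            hi = sum(_transmittable(c)[1] for c in known)
            if not lo <= child <= hi:
                errors += 1
        else:
            lo, hi = _transmittable(known[0])
            if child < lo or child > hi + 1:
                errors += 1
    rate = errors / transmissions if transmissions else 0.0
    return errors, transmissions, rate


def concordance(a: GenotypeVector, b: GenotypeVector) -> float:
    """Fraction of identical hard calls among jointly non-missing individuals."""
    if len(a) != len(b):
        raise DataError("vectors differ in length")
    both = ~np.isnan(a.codes) & ~np.isnan(b.codes)
    if not both.any():
        raise UndefinedValueError("no jointly non-missing individuals")
    return float((a.codes[both] == b.codes[both]).mean())


# ----------------------------------------------------------------------
# QC report
# ----------------------------------------------------------------------

def apply_qc(
    genotypes: Mapping[str, GenotypeVector],
    pedigree: Optional[Pedigree] = None,
    reference_freqs: Optional[Mapping[str, float]] = None,
    thresholds: Optional[QCThresholds] = None,
    duplicates: Optional[Mapping[str, GenotypeVector]] = None,
) -> pd.DataFrame:
    """Evaluate each variant against the QC thresholds.

    Returns one row per (variant, metric) with the computed value, the
    threshold, and the verdict; a variant passes iff every computable metric
    passes. Metrics whose inputs are absent (no pedigree, no reference
    frequency, no duplicate platform) are skipped, not failed.
    """
    thresholds = thresholds or QCThresholds()
    rows = []
    for vid, gv in genotypes.items():
        checks: list[tuple[str, float, str, float, bool]] = []
        f_maf = maf(gv)
        checks.append(("maf", f_maf, ">", thresholds.maf_min, f_maf > thresholds.maf_min))
        call_rate = gv.n_nonmissing / len(gv) if len(gv) else 0.0
        checks.append(("call_rate", call_rate, ">", thresholds.call_rate_min,
                       call_rate > thresholds.call_rate_min))
        if not gv.dosage:
            p_hwe = hwe_test(gv.genotype_counts())
            checks.append(("hwe_p", p_hwe, ">", thresholds.hwe_p_min,
                           p_hwe > thresholds.hwe_p_min))
        if pedigree is not None and not gv.dosage:
            _, _, rate = mendel_check(pedigree, gv)
            checks.append(("mendel_rate", rate, "<", thresholds.mendel_rate_max,
                           rate < thresholds.mendel_rate_max))
        if reference_freqs is not None and vid in reference_freqs:
            diff = abs(f_maf - reference_freqs[vid])
            checks.append(("freq_diff", diff, "<", thresholds.freq_diff_max,
                           diff < thresholds.freq_diff_max))
        if duplicates is not None and vid in duplicates:
            conc = concordance(gv, duplicates[vid])
            checks.append(("concordance", conc, ">", thresholds.concordance_min,
                           conc > thresholds.concordance_min))
        variant_pass = all(ok for *_, ok in checks)
        for metric, value, op, thr, ok in checks:
            rows.append({"variant": vid, "metric": metric, "value": value,
                         "comparison": op, "threshold": thr,
                         "metric_pass": ok, "variant_pass": variant_pass})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Polygenic risk score
# ----------------------------------------------------------------------

def effect_allele_copies(gv: GenotypeVector) -> np.ndarray:
    """Copies of the variant's dopamine-increasing effect allele per individual."""
    spec = gv.variant
    if spec.effect_allele is None:
        raise ConfigurationMissing(spec.variant_id)
    if spec.effect_allele == spec.counted_allele:
        return gv.codes
    if spec.effect_allele == ABSENCE or spec.effect_allele in spec.allele_labels:
        return 2.0 - gv.codes
    raise ConfigurationMissing(spec.variant_id)  # pragma: no cover


class ConfigurationMissing(KeyError):
    """A variant lacks an effect-allele mapping for the risk score."""

    def __init__(self, variant_id: str):
        super().__init__(f"no effect-allele mapping for variant {variant_id!r}")


def risk_score(genotype_set: Mapping[str, GenotypeVector] | Iterable[GenotypeVector],
               ) -> np.ndarray:
    """Polygenic risk score: summed effect-allele copies across variants.

    Complete-case: individuals missing a hard call on any included variant
    get a missing (NaN) score. Bounded by [0, 2 x number of variants].
    """
    vectors = list(genotype_set.values()) if isinstance(genotype_set, Mapping) \
        else list(genotype_set)
    if not vectors:
        raise ValueError("risk_score requires at least one variant")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise DataError("genotype vectors differ in length")
    score = np.zeros(lengths.pop())
    for gv in vectors:
        score = score + effect_allele_copies(gv)
    return score
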