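"""Kinship mixed-model association analysis of the simulated cohort.

For each of the eleven panel variants, fits the maximum-likelihood mixed
model (fixed effects: intercept, sex, z-scored age, sex x age, variant;
random effect: additive genetic relatedness) and Wald-tests the variant at
the Bonferroni-corrected alpha = .05/11. Then fits the joint model with all
eleven variants (likelihood-ratio test, 11 df) and the polygenic
dopamine-risk-score model. The cohort was generated with a true 0.5%
variance effect at rs1800497 and no effect elsewhere, so rs1800497 is the
only variant expected to show signal beyond chance.

Requires results/ from 01_simulate_cohort.py.
Run:  python analysis/04_association.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from exergen import bonferroni_alpha, fit, joint_test, risk_score, test_variant
from exergen.io import read_genotypes, read_pedigree, write_report
from exergen.panel import PANEL_BY_ID

RESULTS = Path(__file__).resolve().parent.parent / "results"
ALPHA = bonferroni_alpha(0.05, 11)


def main() -> None:
    data = pd.read_csv(RESULTS / "cohort_analysis.tsv", sep="\t", comment="#")
    pedigree = read_pedigree(RESULTS / "cohort.fam")
    variant_ids = list(PANEL_BY_ID)

    rows = []
    for vid in variant_ids:
        res = fit(data, pedigree, variants=[vid])
        tr = test_variant(res, vid, alpha=ALPHA)
        b, se = res.coef(vid)
        rows.append({"term": vid, "kind": "wald", "n_used": res.n_used,
                     "estimate": b, "se": se, "statistic": tr.statistic,
                     "df": tr.df, "p_value": tr.p_value,
                     "significant": tr.significant,
                     "h2_hat": res.heritability})
    single = pd.DataFrame(rows)
    print(f"single-variant Wald tests at alpha = {ALPHA:.4f} "
          f"(n = {single.n_used.iloc[0]}):")
    print(single[["term", "estimate", "p_value", "significant"]]
          .to_string(index=False))

    full = fit(data, pedigree, variants=variant_ids)
    null = fit(data, pedigree, variants=[])
    lrt = joint_test(full, null, alpha=ALPHA)
    print(f"\njoint test of all 11 variants: chi2 = {lrt.statistic:.2f}, "
          f"df = {lrt.df}, p = {lrt.p_value:.4f}")
    rows.append({"term": "joint_11_variants", "kind": "lrt",
                 "n_used": full.n_used, "estimate": np.nan, "se": np.nan,
                 "statistic": lrt.statistic, "df": lrt.df,
                 "p_value": lrt.p_value, "significant": lrt.significant,
                 "h2_hat": full.heritability})

    genotypes = read_genotypes(RESULTS / "cohort_genotypes.tsv",
                               {vid: pv.spec for vid, pv in PANEL_BY_ID.items()})
    geno_ids = pd.read_csv(RESULTS / "cohort_genotypes.tsv", sep="\t",
                           comment="#", usecols=["individual_id"])
    scores = pd.Series(risk_score(genotypes), index=geno_ids.individual_id)
    data["risk_score"] = data.individual_id.map(scores)
    rs_fit = fit(data, pedigree, variants=["risk_score"])
    tr = test_variant(rs_fit, "risk_score", alpha=ALPHA)
    b, se = rs_fit.coef("risk_score")
    print(f"dopamine risk score: beta = {b:.3f} (se {se:.3f}), p = {tr.p_value:.4f}")
    rows.append({"term": "risk_score", "kind": "wald", "n_used": rs_fit.n_used,
                 "estimate": b, "se": se, "statistic": tr.statistic,
                 "df": tr.df, "p_value": tr.p_value,
                 "significant": tr.significant, "h2_hat": rs_fit.heritability})

    write_report(RESULTS / "association.tsv", pd.DataFrame(rows))
    print(f"\nwrote {RESULTS}/association.tsv")


if __name__ == "__main__":
    main()
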