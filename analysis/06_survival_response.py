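"""Survival and immunotherapy-response stratification by called subtype.

Joins the discovered subtype calls onto the discovery cohort's clinical
table and quantifies the MUT1/MUT2 contrast: Kaplan-Meier medians,
log-rank test, univariate and covariate-adjusted Cox hazard ratios
(MUT2 vs MUT1; adjusted for age, sex, smoking), and the chi-square test
of responder rates.
"""

import json
from pathlib import Path

import pandas as pd

from sigsubtype.clinical_stats import (
    chi_square_test,
    cox_fit,
    km_estimate,
    logrank_test,
    response_table,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    clinical = pd.read_csv(RESULTS / "cohorts" / "discovery.clinical.tsv", sep="\t")
    calls = pd.read_csv(RESULTS / "discovery.subtypes.tsv", sep="\t", index_col=0)["subtype"]
    clinical["subtype"] = clinical["sample_id"].map(calls)

    g1 = clinical[clinical.subtype == "MUT1"]
    g2 = clinical[clinical.subtype == "MUT2"]
    km1, km2 = km_estimate(g1), km_estimate(g2)
    km1.to_frame().to_csv(RESULTS / "km_MUT1.tsv", sep="\t", index=False)
    km2.to_frame().to_csv(RESULTS / "km_MUT2.tsv", sep="\t", index=False)
    lr = logrank_test(g2, g1)
    cox_uni = cox_fit(clinical, ["subtype"])["subtype_MUT2"]
    cox_adj = cox_fit(clinical, ["subtype", "age", "sex", "smoking"])["subtype_MUT2"]
    table = response_table(clinical)
    chi2, _, p_resp = chi_square_test(table)
    r1, r2 = table[0, 0] / table[0].sum(), table[1, 0] / table[1].sum()

    summary = {
        "n": {"MUT1": len(g1), "MUT2": len(g2)},
        "median_os_months": {"MUT1": km1.median_survival, "MUT2": km2.median_survival},
        "logrank": {"chi_square": round(lr.chi_square, 3), "p_value": float(f"{lr.p_value:.3g}")},
        "cox_univariate_hr": {
            "hr": round(cox_uni.hazard_ratio, 3),
            "ci": [round(cox_uni.ci_lower, 3), round(cox_uni.ci_upper, 3)],
            "p": float(f"{cox_uni.p_value:.3g}"),
        },
        "cox_adjusted_hr": {
            "hr": round(cox_adj.hazard_ratio, 3),
            "ci": [round(cox_adj.ci_lower, 3), round(cox_adj.ci_upper, 3)],
            "p": float(f"{cox_adj.p_value:.3g}"),
        },
        "response": {
            "rate_MUT1": round(float(r1), 3),
            "rate_MUT2": round(float(r2), 3),
            "chi_square": round(chi2, 3),
            "p_value": float(f"{p_resp:.3g}"),
        },
    }
    (RESULTS / "survival_response.json").write_text(json.dumps(summary, indent=1))
    print(
        f"median OS: MUT1 {km1.median_survival:.1f} vs MUT2 {km2.median_survival:.1f} months; "
        f"log-rank p = {lr.p_value:.2g}"
    )
    print(
        f"Cox HR (MUT2 vs MUT1): univariate {cox_uni.hazard_ratio:.2f} "
        f"[{cox_uni.ci_lower:.2f}, {cox_uni.ci_upper:.2f}], "
        f"adjusted {cox_adj.hazard_ratio:.2f}"
    )
    print(f"response rates: MUT1 {r1:.1%} vs MUT2 {r2:.1%} (chi-square p = {p_resp:.2g})")


if __name__ == "__main__":
    main()
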