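"""Pool the published per-cohort demographics into one summary table.

Aggregates the packaged count tables of the six published urothelial
carcinoma cohorts (IMvigor210, UC-GENOME, TCGA, MSK2022, MSK2015,
Tongji; 2229 patients) and recomputes every pooled count and percentage
from the per-cohort counts.
"""

from pathlib import Path

from sigsubtype.clinical_stats import cohort_summary, load_published_demographics

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    summary = cohort_summary(load_published_demographics())
    summary.to_csv(RESULTS / "pooled_demographics.tsv", sep="\t", index=False)

    def cell(char, cat):
        row = summary[(summary.characteristic == char) & (summary.category == cat)].iloc[0]
        return int(row.pooled_count), row.pooled_percent

    n = summary.attrs["total_n"]
    print(f"pooled n = {n} across {len(summary.attrs['cohort_sizes'])} cohorts")
    for label, (char, cat) in {
        "men": ("sex", "male"),
        "OS events": ("os", "event"),
        "current smokers": ("smoking", "current"),
        "former smokers": ("smoking", "former"),
        "never smokers": ("smoking", "never"),
    }.items():
        count, pct = cell(char, cat)
        print(f"  {label}: {count} ({pct}%)")


if __name__ == "__main__":
    main()
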