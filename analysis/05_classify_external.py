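"""Train the shrunken-centroid classifier and transfer it to the external cohort.

Fits the nearest-shrunken-centroid model on the discovery cohort's
retained-signature CS features with the discovered MUT1/MUT2 labels
(shrinkage chosen by 10-fold cross-validation, one-SE rule), then
classifies the independently simulated external cohort and scores the
calls against its ground truth.
"""

from pathlib import Path

import pandas as pd

from sigsubtype.nsc_classifier import nsc_fit, nsc_predict, roc_auc

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 20260105) -> None:
    cs = pd.read_csv(RESULTS / "cohorts" / "discovery.cs_matrix.tsv", sep="\t", index_col=0)
    report = pd.read_csv(RESULTS / "retained_signatures.tsv", sep="\t", index_col=0)
    retained = list(report.index[report["retained"]])
    labels = pd.read_csv(RESULTS / "discovery.subtypes.tsv", sep="\t", index_col=0)["subtype"]

    model = nsc_fit(cs.loc[labels.index, retained], labels.to_numpy(), seed=seed)
    model.to_json(RESULTS / "nsc_model.json")
    print(
        f"fitted NSC: delta = {model.delta:.3f}, "
        f"{model.n_surviving_features()}/{len(retained)} features survive shrinkage"
    )

    cs_ext = pd.read_csv(RESULTS / "cohorts" / "external.cs_matrix.tsv", sep="\t", index_col=0)
    preds = nsc_predict(model, cs_ext[retained])
    preds.rename_axis("sample").to_csv(RESULTS / "external.predictions.tsv", sep="\t")

    truth = pd.read_csv(RESULTS / "cohorts" / "external.truth.tsv", sep="\t", index_col=0)
    agree = (preds.loc[truth.index, "predicted"] == truth["true_subtype"]).mean()
    auc = roc_auc(
        preds.loc[truth.index, "posterior_MUT2"].to_numpy(),
        (truth["true_subtype"] == "MUT2").astype(int).to_numpy(),
    )
    print(f"external transfer: accuracy = {agree:.3f}, posterior AUC = {auc:.3f}")


if __name__ == "__main__":
    main()
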