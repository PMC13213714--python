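"""Place each tumor in cosine-similarity space and filter the signature set.

Computes the samples x signatures cosine-similarity (CS) matrix for both
cohorts against the shared reference set, then applies the retention
filter on the discovery cohort: a signature is kept only if at least 10%
of samples reach CS >= 0.24 against it.
"""

from pathlib import Path

import pandas as pd

from sigsubtype.signature_space import (
    ReferenceSignatureSet,
    build_cs_matrix,
    filter_signatures,
)
from sigsubtype.spectra import read_spectrum_matrix

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    signatures = ReferenceSignatureSet.from_tsv(RESULTS / "cohorts" / "signatures.tsv")
    for name in ("discovery", "external"):
        spectra = read_spectrum_matrix(RESULTS / "cohorts" / f"{name}.spectra.tsv")
        cs = build_cs_matrix(spectra, signatures)
        cs.to_csv(RESULTS / "cohorts" / f"{name}.cs_matrix.tsv", sep="\t")

    cs_disc = pd.read_csv(RESULTS / "cohorts" / "discovery.cs_matrix.tsv", sep="\t", index_col=0)
    retained = filter_signatures(cs_disc)
    retained.report().to_csv(RESULTS / "retained_signatures.tsv", sep="\t")
    print(
        f"retained {len(retained.retained)} of {signatures.n_signatures} signatures "
        f"(CS >= {retained.cs_threshold} in >= {retained.min_prevalence:.0%} of samples): "
        f"{retained.retained}"
    )


if __name__ == "__main__":
    main()
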