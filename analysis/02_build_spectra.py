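"""Build 96-channel mutational spectra from the simulated MAF files.

Parses each cohort's MAF (both strands are represented; purine-referenced
rows are collapsed to the pyrimidine channels), reports how many rows were
accepted, and writes the samples x 96 spectrum matrices.
"""

from pathlib import Path

from sigsubtype.spectra import build_spectrum_matrix, read_maf, write_spectrum_matrix

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for name in ("discovery", "external"):
        maf = RESULTS / "cohorts" / f"{name}.maf.tsv"
        records, report = read_maf(maf, deduplicate=False)
        matrix = build_spectrum_matrix(records)
        write_spectrum_matrix(matrix, RESULTS / "cohorts" / f"{name}.spectra.tsv")
        print(
            f"{name}: {report.n_accepted} SNVs across {matrix.shape[0]} samples "
            f"(median burden {int(matrix.sum(axis=1).median())})"
        )


if __name__ == "__main__":
    main()
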