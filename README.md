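# sigsubtype

Mutational-signature subtyping of urothelial carcinoma from somatic SNV
catalogs.

Transcriptome-based subtyping schemes for bladder and upper-tract urothelial
carcinoma are well established, but a unified classification built on the
*genomic* mutation catalog is not. This package implements a subtyping
pipeline that works directly on somatic single-nucleotide variants:

1. **Spectra** — per-tumor SNVs (MAF or VCF) are binned into the 96
   pyrimidine-referenced trinucleotide channels
   (6 substitution classes × 16 flank pairs, COSMIC channel order).
2. **Signature space** — each tumor's spectrum *v* is compared against every
   reference single-base-substitution (SBS) signature *s_j* by cosine
   similarity, CS(v, s_j) = v·s_j / (‖v‖‖s_j‖) ∈ [0, 1]. Signatures with
   CS ≥ 0.24 in fewer than 10% of samples are excluded.
3. **Subtype discovery** — non-negative matrix factorization (Frobenius loss,
   Lee–Seung multiplicative updates) of the filtered samples × signatures CS
   matrix, V ≈ WH, with consensus clustering over seeded restarts and the
   cophenetic correlation as the stability diagnostic; k = 2 is the subtype
   model. The cluster enriched for the APOBEC signatures SBS2/SBS13 is
   labeled **MUT1**; the cluster enriched for the clock-like/mismatch-repair
   signatures SBS1/SBS6/SBS15/SBS87 is **MUT2**.
4. **Transfer** — a from-scratch nearest-shrunken-centroid (PAM) classifier,
   with shrinkage Δ chosen by stratified cross-validation (one-SE rule),
   assigns MUT1/MUT2 to external cohorts.
5. **Clinical contrast** — Kaplan–Meier curves, the two-group log-rank test,
   Cox proportional-hazards models (MUT1 as reference; Efron ties; optional
   adjustment for age, sex, smoking), the chi-square test of responder
   rates, and a pooled multi-cohort demographic summarizer.

A synthetic-cohort generator provides ground truth for every stage: subtype-
specific Dirichlet-multinomial spectra realized as concrete MAF rows,
exponential survival with a configurable subtype hazard ratio (default 1.74,
MUT2 vs MUT1), and Bernoulli response (defaults 31.8% vs 13.1%).

## Worked example

```python
from sigsubtype import *
from sigsubtype.synthetic_cohort import SimulationConfig, simulate_cohort
from sigsubtype.subtype_discovery import discover_subtypes

cohort = simulate_cohort(SimulationConfig(n_samples=100, seed=7))
cs = build_cs_matrix(cohort.spectra, cohort.signatures)
retained = filter_signatures(cs)          # CS >= 0.24 in >= 10% of samples
assignment, results, _ = discover_subtypes(
    cs, retained=retained.retained, k=2, n_runs=20, seed=1
)
print(retained.retained)
print(results[0].cophenetic_coefficient)
print(assignment.labels.value_counts().to_dict())
```

prints

```
['SBS1', 'SBS2', 'SBS5', 'SBS6', 'SBS13', 'SBS15', 'SBS87', 'SBS3', 'SBS7a', 'SBS10a']
0.9998513104757132
{'MUT1': 63, 'MUT2': 37}
```

— ten signatures pass the prevalence filter, the two-cluster consensus is
essentially perfectly stable (cophenetic ≈ 1), and the 63/37 MUT1/MUT2 split
recovers the simulated 60/40 subtype mix exactly (adjusted Rand index 1.0
against the generator's truth).

The same stages are scripted as a narrative analysis under `analysis/`
(`01_simulate_cohorts.py` → `07_pooled_demographics.py`; each prints what it
found and writes its tables under `results/`) and as `sigsubtype`
subcommands (`simulate`, `spectra`, `cs`, `filter`, `discover`, `classify`,
`survive`, `summarize`, `report`), every artifact carrying a provenance
JSON with input checksums, parameters and seeds.

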