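"""Synthetic cohorts with known subtype ground truth.

The generator emulates the statistical structure the subtyping analysis
assumes, providing ground truth for every pipeline stage:

* each tumor belongs to a latent subtype (MUT1, APOBEC-dominant, drawing
  mainly on SBS2/SBS13; MUT2, clock-like/MMR-dominant, on
  SBS1/SBS6/SBS15/SBS87);
* its signature exposure is a Dirichlet draw around the subtype mean, its
  mutation count log-normal (WES-like, median ~100), and its 96-channel
  spectrum a multinomial draw from the exposure-mixed signature matrix;
* every mutation is realized as a concrete MAF row whose trinucleotide
  context is consistent with its channel (random strand, chromosome and
  position — no reference genome needed);
* survival is exponential with a subtype hazard ratio (default 1.74,
  MUT2 vs MUT1) under uniform censoring tuned to a target event
  fraction, and immunotherapy response is Bernoulli per subtype
  (defaults 31.8% vs 13.1%). Covariates (age, sex, smoking) follow
  cohort-like marginals and are independent of subtype by default so
  univariate effect recovery is clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from sigsubtype.errors import ConfigError
from sigsubtype.signature_space import ReferenceSignatureSet
from sigsubtype.spectra import CHANNEL_LABELS, PYRIMIDINE_SUBS, reverse_complement

SUBTYPES = ("MUT1", "MUT2")

#: Invented default exposure presets anchored to the qualitative signature
#: composition of each subtype; fully configurable, never estimates of any
#: real cohort.
DEFAULT_EXPOSURE_MEANS = {
    "MUT1": {"SBS2": 0.35, "SBS13": 0.35, "SBS5": 0.20, "SBS1": 0.10},
    "MUT2": {"SBS1": 0.30, "SBS6": 0.25, "SBS15": 0.20, "SBS87": 0.15, "SBS5": 0.10},
}

DEFAULT_SIGNATURE_NAMES = [
    "SBS1", "SBS2", "SBS5", "SBS6", "SBS13", "SBS15", "SBS87",
    "SBS3", "SBS4", "SBS7a", "SBS10a", "SBS40",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_samples: int = 300
    subtype_proportions: tuple[float, float] = (0.6, 0.4)  # (MUT1, MUT2)
    exposure_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EXPOSURE_MEANS.items()})
    exposure_concentration: float = 50.0
    mutation_count_median: float = 100.0
    mutation_count_sigma: float = 0.8
    mutation_count_min: int = 1
    baseline_median_os_months: float = 15.0  # MUT1 median OS
    hazard_ratio: float = 1.74  # MUT2 vs MUT1
    target_event_fraction: float = 0.39
    response_rates: tuple[float, float] = (0.318, 0.131)  # (MUT1, MUT2)
    age_mean: float = 66.0
    age_sd: float = 11.0
    male_fraction: float = 0.758
    smoking_probs: dict = field(
        default_factory=lambda: {"former": 0.536, "never": 0.328, "current": 0.136}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ConfigError("subtype proportions must sum to 1")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard ratio must be positive")
        if not 0 < self.target_event_fraction < 1:
            raise ConfigError("target event fraction must lie in (0, 1)")
        for p in (*self.response_rates, self.male_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        for st, means in self.exposure_means.items():
            if st not in SUBTYPES:
                raise ConfigError(f"unknown subtype {st!r} in exposure means")
            total = sum(means.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"{st} exposure means sum to {total}, expected 1")


@dataclass
class SimulatedCohort:
    truth: pd.DataFrame  # sample, true_subtype, n_mutations
    exposures: pd.DataFrame  # samples x signatures (true Dirichlet draws)
    spectra: pd.DataFrame  # samples x 96 channel counts
    maf: pd.DataFrame  # one row per simulated mutation, MAF dialect
    clinical: pd.DataFrame  # clinical-table schema
    signatures: ReferenceSignatureSet
    config: SimulationConfig


def make_synthetic_signatures(
    n_channels: int = 96,
    n_signatures: int = 12,
    sparsity: float = 0.10,
    seed: int = 0,
    names: list[str] | None = None,
    max_pairwise_cosine: float = 0.7,
) -> ReferenceSignatureSet:
    """Sparse synthetic reference signatures with canonical SBS-style names.

    Each column puts Dirichlet mass on a small random channel support
    (about ``sparsity`` of the 96 channels), so distinct signatures are
    nearly disjoint; columns are redrawn until every pairwise cosine is
    below ``max_pairwise_cosine``. The default names include SBS2/SBS13
    (APOBEC) and SBS1/SBS6/SBS15/SBS87 so labeling logic is exercised.
    """
    if n_signatures < 2:
        raise ConfigError("need at least 2 signatures")
    if n_channels != 96:
        raise ConfigError("signature space is fixed at the 96 canonical channels")
    if names is None:
        names = list(DEFAULT_SIGNATURE_NAMES[:n_signatures])
        names += [f"SBS_SYN{i}" for i in range(len(names), n_signatures)]
    if len(names) != n_signatures:
        raise ConfigError("names length must equal n_signatures")
    rng = np.random.default_rng(seed)
    support_size = max(3, int(round(sparsity * n_channels)))

    def draw_column() -> np.ndarray:
        col = np.zeros(n_channels)
        support = rng.choice(n_channels, size=support_size, replace=False)
        col[support] = rng.dirichlet(np.ones(support_size))
        return col

    cols: list[np.ndarray] = []
    for _ in range(n_signatures):
        for _attempt in range(200):
            cand = draw_column()
            ok = all(
                float(cand @ c / (np.linalg.norm(cand) * np.linalg.norm(c)))
                < max_pairwise_cosine
                for c in cols
            )
            if ok:
                cols.append(cand)
                break
        else:
            raise ConfigError("could not draw sufficiently distinct signatures")
    matrix = pd.DataFrame(np.column_stack(cols), index=CHANNEL_LABELS, columns=names)
    return ReferenceSignatureSet(matrix)


def _channel_components(idx: int) -> tuple[str, str, str, str]:
    sub_idx, rem = divmod(idx, 16)
    five, three = divmod(rem, 4)
    ref, alt = PYRIMIDINE_SUBS[sub_idx]
    bases = "ACGT"
    return bases[five], ref, alt, bases[three]


def _maf_rows_for_sample(sample: str, channel_counts: np.ndarray, rng) -> list[tuple]:
    rows = []
    for idx in np.flatnonzero(channel_counts):
        five, ref, alt, three = _channel_components(idx)
        ctx = five + ref + three
        for _ in range(int(channel_counts[idx])):
            chrom = str(rng.integers(1, 23))
            pos = int(rng.integers(10_000, 100_000_000))
            if rng.random() < 0.5:  # emit on the purine strand
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                rows.append(
                    (sample, chrom, pos, comp[ref], comp[alt], reverse_complement(ctx))
                )
            else:
                rows.append((sample, chrom, pos, ref, alt, ctx))
    return rows


def simulate_spectra(
    config: SimulationConfig,
    signatures: ReferenceSignatureSet,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw subtypes, exposures, mutation counts, spectra, and MAF rows."""
    for st, means in config.exposure_means.items():
        unknown = [s for s in means if s not in signatures.signature_names]
        if unknown:
            raise ConfigError(f"exposure means for {st} reference unknown signature(s) {unknown}")

    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    subtype_idx = rng.choice(2, size=n, p=list(config.subtype_proportions))
    subtypes = np.array(SUBTYPES)[subtype_idx]

    sig_names = signatures.signature_names
    S = signatures.matrix.to_numpy()  # 96 x S
    exposures = np.zeros((n, len(sig_names)))
    counts = np.zeros((n, 96), dtype=np.int64)
    n_mut = np.maximum(
        config.mutation_count_min,
        np.round(
            np.exp(rng.normal(np.log(config.mutation_count_median), config.mutation_count_sigma, size=n))
        ).astype(int),
    )
    maf_rows: list[tuple] = []
    for i in range(n):
        means = config.exposure_means[subtypes[i]]
        active = [sig_names.index(s) for s in means]
        alpha = np.array([means[sig_names[j]] for j in active]) * config.exposure_concentration
        expo = rng.dirichlet(alpha)
        exposures[i, active] = expo
        p = S @ exposures[i]
        p = p / p.sum()
        counts[i] = rng.multinomial(n_mut[i], p)
        maf_rows.extend(_maf_rows_for_sample(samples[i], counts[i], rng))

    truth = pd.DataFrame(
        {"sample": samples, "true_subtype": subtypes, "n_mutations": n_mut}
    ).set_index("sample")
    exposures_df = pd.DataFrame(exposures, index=truth.index, columns=sig_names)
    spectra = pd.DataFrame(counts, index=truth.index, columns=CHANNEL_LABELS)
    maf = pd.DataFrame(
        maf_rows,
        columns=[
            "Tumor_Sample_Barcode",
            "Chromosome",
            "Start_Position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "ref_context",
        ],
    )
    return truth, exposures_df, spectra, maf


def _uniform_censoring_window(rates: np.ndarray, weights: np.ndarray, target: float) -> float:
    """Solve for C so that P(T < U), U~Unif(0,C), hits the target event fraction."""

    def event_fraction(C: float) -> float:
        x = rates * C
        return float(weights @ (1.0 - (1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e7
    if event_fraction(hi) < target:
        raise ConfigError(f"target event fraction {target} unreachable")
    return brentq(lambda C: event_fraction(C) - target, lo, hi, xtol=1e-9)


def simulate_clinical(
    config: SimulationConfig,
    true_subtypes,
    rng: np.random.Generator,
    sample_ids=None,
) -> pd.DataFrame:
    """Exponential survival, Bernoulli response, and cohort-like covariates.

    OS ~ Exp(rate_MUT1 * HR^{1[MUT2]}) with rate_MUT1 = ln 2 / baseline
    median; censoring times are Uniform(0, C) with C solved so the
    expected event fraction equals the configured target.
    """
    subtypes = np.asarray(true_subtypes)
    n = len(subtypes)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    is_mut2 = (subtypes == "MUT2").astype(int)
    rate1 = np.log(2.0) / config.baseline_median_os_months
    rates = rate1 * config.hazard_ratio**is_mut2
    t_true = rng.exponential(1.0 / rates)
    C = _uniform_censoring_window(
        np.array([rate1, rate1 * config.hazard_ratio]),
        np.array(config.subtype_proportions),
        config.target_event_fraction,
    )
    u = rng.uniform(0.0, C, size=n)
    os_months = np.minimum(t_true, u)
    os_event = (t_true <= u).astype(int)

    resp_p = np.where(is_mut2 == 1, config.response_rates[1], config.response_rates[0])
    responder = rng.random(n) < resp_p
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 25.0, 95.0)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    smoking_cats = list(config.smoking_probs)
    smoking = rng.choice(
        smoking_cats, size=n, p=[config.smoking_probs[c] for c in smoking_cats]
    )
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": "simulated",
            "os_months": np.round(os_months, 4),
            "os_event": os_event,
            "response": np.where(responder, "responder", "nonresponder"),
            "age": np.round(age, 1),
            "sex": sex,
            "smoking": smoking,
            "subtype": subtypes,
        }
    )


def simulate_cohort(
    config: SimulationConfig | None = None,
    signatures: ReferenceSignatureSet | None = None,
) -> SimulatedCohort:
    """Full synthetic cohort: spectra + MAF + clinical, seeded from config."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    if signatures is None:
        signatures = make_synthetic_signatures(seed=int(rng.integers(2**31)))
    truth, exposures, spectra, maf = simulate_spectra(config, signatures, rng)
    clinical = simulate_clinical(
        config, truth["true_subtype"].to_numpy(), rng, sample_ids=list(truth.index)
    )
    return SimulatedCohort(truth, exposures, spectra, maf, clinical, signatures, config)


def config_provenance(config: SimulationConfig) -> dict:
    return asdict(config)
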