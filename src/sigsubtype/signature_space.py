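"""Reference SBS signature space: cosine similarities and the retention filter.

Each reference signature is a probability vector over the 96 channels
(COSMIC-style TSV: first column channel label, one column per signature).
A tumor's position in signature space is its vector of cosine similarities
(CS) against every reference signature; because both spectra and
signatures are nonnegative, every CS lies in [0, 1] and is invariant to
scaling (raw counts and normalized frequencies give identical values).

Signatures that never resemble the cohort are removed before clustering:
signature j is retained iff the fraction of samples with CS >= cs_threshold
(default 0.24) is at least min_prevalence (default 10%), both boundaries
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sigsubtype.errors import AlignmentError, EmptyFilterError, FormatError, UndefinedSimilarityError
from sigsubtype.spectra import CHANNEL_LABELS

logger = logging.getLogger(__name__)

DEFAULT_CS_THRESHOLD = 0.24
DEFAULT_MIN_PREVALENCE = 0.10


@dataclass
class ReferenceSignatureSet:
    """A 96 x S matrix of reference signatures, columns summing to 1."""

    matrix: pd.DataFrame  # index = channel labels, columns = signature names

    def __post_init__(self) -> None:
        if list(self.matrix.index) != CHANNEL_LABELS:
            # align by label, never by position
            missing = [c for c in CHANNEL_LABELS if c not in self.matrix.index]
            if missing:
                raise AlignmentError(
                    f"signature set lacks channel label(s) {missing[:5]}..."
                )
            self.matrix = self.matrix.loc[CHANNEL_LABELS]
        if self.matrix.shape[1] < 2:
            raise FormatError("a signature set needs at least 2 signatures")
        if self.matrix.columns.duplicated().any():
            raise FormatError("duplicate signature names")
        if (self.matrix.values < 0).any():
            raise FormatError("signature matrix has negative entries")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            logger.warning(
                "renormalizing %d signature column(s) whose sums deviate from 1",
                int((~np.isclose(sums, 1.0, atol=1e-6)).sum()),
            )
            self.matrix = self.matrix / sums

    @property
    def signature_names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[1]

    def subset(self, names: list[str]) -> "ReferenceSignatureSet":
        return ReferenceSignatureSet(self.matrix[names].copy())

    @classmethod
    def from_tsv(cls, path) -> "ReferenceSignatureSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        out = self.matrix.copy()
        out.index.name = "Type"
        out.to_csv(path, sep="\t")


def cosine_similarity(a, b) -> float:
    """Cosine similarity a.b / (|a| |b|) of two nonnegative 96-vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError(f"shape mismatch {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def build_cs_matrix(
    spectra: pd.DataFrame,
    signatures: ReferenceSignatureSet,
) -> pd.DataFrame:
    """Samples x signatures cosine-similarity matrix.

    Spectra columns are aligned to the signature channel labels by name.
    Zero-count samples have no defined direction; their rows are NaN and
    the caller decides whether to drop them (the pipeline does, with a
    logged list).
    """
    missing = [c for c in CHANNEL_LABELS if c not in spectra.columns]
    if missing:
        raise AlignmentError(f"spectra lack channel label(s) {missing[:5]}...")
    X = spectra[CHANNEL_LABELS].to_numpy(dtype=float)
    S = signatures.matrix.to_numpy(dtype=float)
    xn = np.linalg.norm(X, axis=1, keepdims=True)
    sn = np.linalg.norm(S, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = (X @ S) / (xn * sn)
    zero = (xn[:, 0] == 0.0)
    if zero.any():
        logger.warning(
            "%d zero-count sample(s) flagged undefined in the CS matrix: %s",
            int(zero.sum()),
            list(spectra.index[zero][:10]),
        )
        cs[zero, :] = np.nan
    return pd.DataFrame(cs, index=spectra.index, columns=signatures.signature_names)


@dataclass
class RetainedSignatureSet:
    """The filter's audit trail: which signatures survive and why."""

    retained: list[str]
    prevalence: pd.Series  # per-signature fraction of samples with CS >= threshold
    cs_threshold: float
    min_prevalence: float

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prevalence": self.prevalence,
                "retained": [name in set(self.retained) for name in self.prevalence.index],
            }
        ).rename_axis("signature")


def filter_signatures(
    cs: pd.DataFrame,
    cs_threshold: float = DEFAULT_CS_THRESHOLD,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
) -> RetainedSignatureSet:
    """Drop signatures resembling fewer than ``min_prevalence`` of samples.

    Rows that are entirely NaN (zero-count samples) are excluded from the
    prevalence denominator. Both comparisons are inclusive: a signature at
    exactly the prevalence boundary is retained.
    """
    if cs.shape[0] == 0 or cs.shape[1] == 0:
        raise EmptyFilterError("empty CS matrix")
    defined = cs.dropna(axis=0, how="all")
    n = defined.shape[0]
    if n == 0:
        raise EmptyFilterError("no samples with a defined spectrum direction")
    prevalence = (defined >= cs_threshold).sum(axis=0) / n
    retained = [name for name in cs.columns if prevalence[name] >= min_prevalence]
    if not retained:
        raise EmptyFilterError(
            f"no signature reaches prevalence {min_prevalence} at CS >= {cs_threshold}; "
            "review the thresholds"
        )
    logger.info("retained %d of %d signatures", len(retained), cs.shape[1])
    return RetainedSignatureSet(retained, prevalence, cs_threshold, min_prevalence)
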