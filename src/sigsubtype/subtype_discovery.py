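"""Subtype discovery: NMF consensus clustering of the CS matrix.

Samples (rows of the filtered cosine-similarity matrix) are factorized as
V ~ W H with nonnegative factors by Lee-Seung multiplicative updates on
the Frobenius loss. A sample's hard cluster is the arg-max of its W row.
Stability over random restarts is summarized by the consensus matrix
(average co-clustering indicator) and its cophenetic correlation; the
pipeline defaults to k = 2, the rank the subtyping model asserts, while
reporting the stability diagnostic across a rank range.

The two clusters are mapped to biological labels by their APOBEC signal:
the cluster with the higher mean cosine similarity to the APOBEC
signatures SBS2/SBS13 is MUT1, the other (clock-like/MMR-enriched
SBS1/SBS6/SBS15/SBS87) is MUT2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from sigsubtype.errors import DegenerateClusteringError, RankError, SigsubtypeError

logger = logging.getLogger(__name__)

_EPS = 1e-12

APOBEC_SIGNATURES = ("SBS2", "SBS13")
MMR_CLOCK_SIGNATURES = ("SBS1", "SBS6", "SBS15", "SBS87")


@dataclass
class NMFModel:
    W: np.ndarray  # samples x k
    H: np.ndarray  # k x features
    k: int
    objective_trace: np.ndarray  # Frobenius loss per recorded iteration
    seed: int
    n_iter: int
    converged: bool

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H

    def relative_error(self, V: np.ndarray) -> float:
        return float(np.linalg.norm(V - self.reconstruction()) / np.linalg.norm(V))

    def hard_clusters(self) -> np.ndarray:
        """Arg-max cluster per sample; ties break to the lower index."""
        return np.argmax(self.W, axis=1)


def nmf_factorize(
    V: np.ndarray,
    k: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMFModel:
    """Multiplicative-update NMF of a nonnegative matrix.

    W and H start from seeded uniform random draws scaled to the data;
    iteration stops when the relative change of the Frobenius objective
    drops below ``tol`` or at ``max_iter``. The objective trace is
    non-increasing by construction of the updates.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise SigsubtypeError("NMF input contains non-finite entries")
    if (V < 0).any():
        raise SigsubtypeError("NMF input must be nonnegative")
    n, m = V.shape
    if k < 1 or k >= min(n, m):
        raise RankError(f"rank k={k} must satisfy 1 <= k < min{V.shape}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(0.0, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.0, 1.0, size=(k, m)) * scale
    trace = [float(np.linalg.norm(V - W @ H) ** 2)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(V - W @ H) ** 2)
        prev = trace[-1]
        trace.append(obj)
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break
    return NMFModel(W, H, k, np.array(trace), seed, it, converged)


@dataclass
class ConsensusResult:
    k: int
    consensus_matrix: np.ndarray  # samples x samples, symmetric, unit diagonal
    cophenetic_coefficient: float
    n_runs: int
    n_degenerate: int
    labels: np.ndarray  # hard clusters from the consensus matrix itself


def _consensus_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cut the average-linkage tree of (1 - consensus) at k clusters."""
    from scipy.cluster.hierarchy import fcluster

    dist = squareform(1.0 - consensus, checks=False)
    tree = average(dist)
    return fcluster(tree, t=k, criterion="maxclust") - 1


def consensus_cluster(
    V: np.ndarray,
    k_range=range(2, 7),
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[list[ConsensusResult], int]:
    """Consensus NMF over random restarts for each candidate rank.

    For each k, ``n_runs`` factorizations from distinct seeds produce hard
    clusterings; their connectivity matrices are averaged into a consensus
    matrix, whose cophenetic correlation (between 1 - consensus distances
    and the average-linkage cophenetic distances) scores stability. Runs
    that collapse all samples into one cluster are discarded with a
    warning. Returns the per-k results and the arg-max-cophenetic k.
    """
    V = np.asarray(V, dtype=float)
    n = V.shape[0]
    if n_runs < 2:
        raise SigsubtypeError("consensus clustering needs n_runs >= 2")
    results: list[ConsensusResult] = []
    ss = np.random.SeedSequence(seed)
    for k in k_range:
        run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]
        connectivity_sum = np.zeros((n, n))
        used = 0
        degenerate = 0
        for rs in run_seeds:
            model = nmf_factorize(V, k, max_iter=max_iter, tol=tol, seed=rs)
            labels = model.hard_clusters()
            if len(np.unique(labels)) < 2:
                degenerate += 1
                continue
            connectivity_sum += (labels[:, None] == labels[None, :]).astype(float)
            used += 1
        if used == 0:
            raise DegenerateClusteringError(
                f"all {n_runs} runs at k={k} assigned every sample to one cluster"
            )
        if degenerate:
            logger.warning("k=%d: discarded %d degenerate run(s)", k, degenerate)
        consensus = connectivity_sum / used
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        dist = squareform(1.0 - consensus, checks=False)
        tree = average(dist)
        coph, _ = cophenet(tree, dist)
        labels = _consensus_labels(consensus, k)
        results.append(ConsensusResult(k, consensus, float(coph), used, degenerate, labels))
    selected = max(results, key=lambda r: r.cophenetic_coefficient).k
    return results, selected


@dataclass
class SubtypeAssignment:
    """Per-sample MUT1/MUT2 call with cluster-confidence metadata."""

    labels: pd.Series  # sample -> "MUT1"/"MUT2"
    cluster_index: pd.Series  # sample -> raw cluster index
    membership_strength: pd.Series  # max-normalized W row entry (or consensus share)
    anchor_used: str = "APOBEC"
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subtype": self.labels,
                "cluster_index": self.cluster_index,
                "membership_strength": self.membership_strength,
            }
        ).rename_axis("sample")


def assign_subtype_labels(
    clusters: np.ndarray,
    cs: pd.DataFrame,
    apobec_signatures=APOBEC_SIGNATURES,
    membership_strength: np.ndarray | None = None,
) -> SubtypeAssignment:
    """Label the two clusters MUT1/MUT2 by their mean APOBEC similarity.

    The cluster with the higher mean CS over ``apobec_signatures`` becomes
    MUT1. If no APOBEC signature survived filtering, the labeling falls
    back to the inverted clock-like/MMR anchor (higher SBS1/SBS6/SBS15/
    SBS87 similarity -> MUT2) with a loud warning.
    """
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    if len(uniq) != 2:
        raise SigsubtypeError(f"expected exactly 2 clusters, got {len(uniq)}")
    if len(clusters) != cs.shape[0]:
        raise SigsubtypeError("cluster vector and CS matrix row counts differ")

    anchors = [s for s in apobec_signatures if s in cs.columns]
    anchor_used = "APOBEC"
    invert = False
    if not anchors:
        anchors = [s for s in MMR_CLOCK_SIGNATURES if s in cs.columns]
        anchor_used = "MMR/clock-like (inverted)"
        invert = True
        logger.warning(
            "no APOBEC signature among retained columns; falling back to the "
            "inverted %s anchor — verify subtype orientation manually",
            anchors,
        )
        if not anchors:
            raise SigsubtypeError("neither APOBEC nor fallback anchor signatures present")

    means = {c: float(cs.loc[clusters == c, anchors].to_numpy().mean()) for c in uniq}
    high = max(sorted(uniq), key=lambda c: means[c])
    mut1 = ({c for c in uniq} - {high}).pop() if invert else high
    label_map = {c: ("MUT1" if c == mut1 else "MUT2") for c in uniq}
    labels = pd.Series([label_map[c] for c in clusters], index=cs.index, name="subtype")
    if membership_strength is None:
        membership_strength = np.ones(len(clusters))
    return SubtypeAssignment(
        labels=labels,
        cluster_index=pd.Series(clusters, index=cs.index, name="cluster_index"),
        membership_strength=pd.Series(membership_strength, index=cs.index, name="membership_strength"),
        anchor_used=anchor_used,
        notes={"anchor_means": {int(c): means[c] for c in uniq}},
    )


def discover_subtypes(
    cs: pd.DataFrame,
    retained: list[str] | None = None,
    k: int = 2,
    n_runs: int = 50,
    seed: int = 0,
    k_range=None,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[SubtypeAssignment, list[ConsensusResult], int]:
    """End-to-end discovery: consensus NMF on the (filtered) CS matrix.

    ``k`` forces the pipeline rank (default 2, the subtype model); the
    stability diagnostic over ``k_range`` (default: just {k}) is returned
    alongside. Membership strength is the sample's consensus-derived W row
    maximum, normalized, from a final factorization at the forced rank.
    """
    cols = retained if retained is not None else list(cs.columns)
    V_df = cs[cols].dropna(axis=0, how="any")
    dropped = cs.index.difference(V_df.index)
    if len(dropped):
        logger.warning("dropping %d sample(s) with undefined CS rows", len(dropped))
    V = V_df.to_numpy(dtype=float)
    if k_range is None:
        k_range = [k]
    results, best_k = consensus_cluster(
        V, k_range=k_range, n_runs=n_runs, seed=seed, max_iter=max_iter, tol=tol
    )
    chosen = next(r for r in results if r.k == k)
    clusters = chosen.labels
    if len(np.unique(clusters)) < 2:
        raise DegenerateClusteringError("consensus clustering produced a single cluster")
    # membership strength: per-sample mean consensus with its own cluster
    strength = np.array(
        [chosen.consensus_matrix[i, clusters == clusters[i]].mean() for i in range(len(clusters))]
    )
    assignment = assign_subtype_labels(
        clusters, V_df, membership_strength=strength
    )
    return assignment, results, best_k
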