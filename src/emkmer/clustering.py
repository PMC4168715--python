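"""Epigenetic contig clustering for metagenomes.

Detection on a pooled contig set only finds motifs whose signal survives
averaging over every genome in the mixture.  Each contig is therefore
summarised by a vector over the pooled significant motif set O — entry j is
the mean, over that motif's occurrences in the contig, of the per-position
native/WGA median-IPD ratio (~1 when unmodified, elevated when the contig's
genome methylates that motif).  K-means on these vectors bins contigs by
epigenetic profile, and rerunning the full detector inside each bin recovers
genome-specific motifs that the pooled run diluted away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .detect import DetectionConfig, DetectionResult, detect_motifs
from .io import ReferenceSet, SampleKinetics
from .kmers import MotifKey, collect_all_stats, scan_occurrences
from .scoring import assign_significance, fit_all_nulls, scores_from_stats

__all__ = [
    "ClusterAssignment",
    "build_contig_vectors",
    "cluster_contigs",
    "refine_per_cluster",
    "pca_diagnostics",
    "score_and_detect",
]

NULL_RATIO = 1.0  # imputation value: the no-modification native/WGA ratio


def score_and_detect(
    ref: ReferenceSet,
    native: SampleKinetics,
    wga: SampleKinetics,
    cfg: DetectionConfig | None = None,
) -> tuple[pd.DataFrame, dict, DetectionResult]:
    """Full scoring + detection pass over one contig set: collect per-motif
    observation statistics, score LLRs, fit the per-k gamma nulls, correct,
    and run the two-phase detector.  Returns (scores, nulls, result)."""
    cfg = cfg or DetectionConfig()
    stats = collect_all_stats(ref, native, wga, cfg.kmin, cfg.kmax)
    scores = scores_from_stats(stats, min_obs=cfg.min_obs)
    nulls = fit_all_nulls(scores, min_fit_points=cfg.min_fit_points)
    scores = assign_significance(scores, nulls)
    return scores, nulls, detect_motifs(scores, cfg)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # contig_id -> cluster label in 0..K-1
    centroids: np.ndarray
    k: int

    def contigs_in(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def build_contig_vectors(
    ref: ReferenceSet,
    native: SampleKinetics,
    wga: SampleKinetics,
    motifs: list[MotifKey],
    min_contig_len: int = 10_000,
) -> pd.DataFrame:
    """Per-contig native/WGA kinetic ratio over the motif set.

    One row per contig of length >= ``min_contig_len``, one column per motif
    (named ``SEQ:offset``).  Entry j is the ratio of the contig's mean
    native median IPD to its mean WGA median IPD across motif j's
    occurrences (each side averaged over the occurrences where it is
    present) — ~1 for an unmodified motif, elevated when the contig's genome
    modifies it.  Averaging each side before taking the ratio keeps the
    entry stable at low coverage, where dividing by individual per-position
    WGA medians would be dominated by their sampling noise.  An entry is NaN
    (masked) when either side has no value in the contig; strands are
    pooled.
    """
    if not motifs:
        raise ValueError("no motif features; run detection first")
    contigs = [c for c in ref.contig_ids if ref.length(c) >= min_contig_len]
    cols = [f"{m.seq}:{m.offset}" for m in motifs]
    mat = np.full((len(contigs), len(motifs)), np.nan)
    cidx = {c: i for i, c in enumerate(contigs)}
    for j, key in enumerate(motifs):
        nat_vals: dict[str, list[float]] = {}
        wga_vals: dict[str, list[float]] = {}
        for cid, strand, pos in scan_occurrences(ref, key):
            if cid not in cidx:
                continue
            nmed, _ = native.track(ref, cid, strand)
            wmed, _ = wga.track(ref, cid, strand)
            if np.isfinite(nmed[pos]):
                nat_vals.setdefault(cid, []).append(nmed[pos])
            if np.isfinite(wmed[pos]):
                wga_vals.setdefault(cid, []).append(wmed[pos])
        for cid in set(nat_vals) & set(wga_vals):
            denom = float(np.mean(wga_vals[cid]))
            if denom > 0:
                mat[cidx[cid], j] = float(np.mean(nat_vals[cid])) / denom
    return pd.DataFrame(mat, index=pd.Index(contigs, name="contig"), columns=cols)


def cluster_contigs(
    vectors: pd.DataFrame, k: int = 3, seed: int = 0
) -> ClusterAssignment:
    """K-means (Euclidean) on the contig vectors; masked entries are imputed
    with the null ratio 1.0 first.  Seeded k-means++ with 10 restarts, so the
    assignment is deterministic per seed.  Labels are arbitrary up to
    permutation — compare partitions, not raw labels."""
    if len(vectors) < k:
        raise ValueError(f"{len(vectors)} contig vectors < K={k}")
    X = vectors.to_numpy(dtype=float)
    X = np.where(np.isfinite(X), X, NULL_RATIO)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterAssignment(
        labels=pd.Series(labels, index=vectors.index, name="cluster"),
        centroids=km.cluster_centers_,
        k=k,
    )


def refine_per_cluster(
    assignment: ClusterAssignment,
    ref: ReferenceSet,
    native: SampleKinetics,
    wga: SampleKinetics,
    cfg: DetectionConfig | None = None,
) -> dict[int, DetectionResult]:
    """Rerun the full scoring + detection pipeline restricted to each
    cluster's contigs.  Clusters where nothing is scorable yield an empty
    result."""
    cfg = cfg or DetectionConfig()
    out: dict[int, DetectionResult] = {}
    for label in range(assignment.k):
        cids = assignment.contigs_in(label)
        if not cids:
            out[label] = DetectionResult(
                table=pd.DataFrame(columns=["rank", "seq", "offset", "k", "phase",
                                            "llr", "gamma_corr", "z", "normal_prob", "anchor"])
            )
            continue
        sub = ref.subset(cids)
        _, _, result = score_and_detect(sub, native, wga, cfg)
        out[label] = result
    return out


def pca_diagnostics(vectors: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """First two principal-component coordinates of the (imputed) contig
    vectors, for plotting only.  Returns (coords, explained variance
    fractions)."""
    if len(vectors) < 2:
        raise ValueError("need >= 2 vectors")
    X = vectors.to_numpy(dtype=float)
    X = np.where(np.isfinite(X), X, NULL_RATIO)
    n_comp = min(2, X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    if n_comp < 2:  # pad so callers always get PC1/PC2
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - n_comp))])
    df = pd.DataFrame(coords[:, :2], index=vectors.index, columns=["PC1", "PC2"])
    evr = np.zeros(2)
    evr[: len(pca.explained_variance_ratio_)] = pca.explained_variance_ratio_
    return df, evr
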