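"""Model/Results interface over the motif-detection pipeline.

:class:`MotifModel` is built from a reference plus paired native/WGA
kinetics (per-read records or pre-aggregated per-position medians); its
``fit()`` runs median aggregation, kmer observation collection, LLR scoring,
gamma-null calibration and the two-phase detector, and returns a
:class:`MotifResults` carrying the score table, the fitted nulls, the
detected motifs and a ``summary()``.  :class:`MetagenomeModel` adds the
contig-vector / K-means / per-cluster refinement loop and reports pre- and
post-clustering results side by side.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .clustering import (
    ClusterAssignment,
    build_contig_vectors,
    cluster_contigs,
    refine_per_cluster,
    score_and_detect,
)
from .detect import DetectionConfig, DetectionResult
from .io import (
    ReferenceSet,
    SampleKinetics,
    aggregate_medians,
    load_ipd_table,
    load_median_table,
    load_reference,
)
from .kmers import MotifKey

__all__ = ["MotifModel", "MotifResults", "MetagenomeModel", "MetagenomeResults"]


def _as_kinetics(data, role: str, min_depth: int) -> SampleKinetics:
    if isinstance(data, SampleKinetics):
        return data
    if isinstance(data, pd.DataFrame):
        return aggregate_medians(data, role=role, min_depth=min_depth)
    raise TypeError(f"{role}: expected SampleKinetics or a record DataFrame")


class MotifModel:
    """Single-sample (or pooled) epigenetic motif model.

    Parameters
    ----------
    ref : ReferenceSet
        Contigs the kinetics are indexed on.
    native, wga : DataFrame of per-read IPD records, or SampleKinetics
        The native sample and its whole-genome-amplified (modification-free)
        control.  Record frames are aggregated to per-position medians with
        ``min_depth``.
    config : DetectionConfig, optional
        Thresholds; defaults are t_gamma=1e-6, t_n=10 SD, k in 4..7.
    """

    def __init__(self, ref: ReferenceSet, native, wga,
                 config: DetectionConfig | None = None, min_depth: int = 1):
        self.ref = ref
        self.config = config or DetectionConfig()
        self.min_depth = min_depth
        self.native = _as_kinetics(native, "native", min_depth)
        self.wga = _as_kinetics(wga, "wga", min_depth)

    @classmethod
    def from_files(cls, ref_fasta, native_path, wga_path,
                   config: DetectionConfig | None = None, min_depth: int = 1,
                   aggregated: bool = False) -> "MotifModel":
        """Build from FASTA + kinetics TSVs (per-read by default; set
        ``aggregated=True`` for the per-position median dialect)."""
        ref = load_reference(ref_fasta)
        if aggregated:
            native = load_median_table(native_path, "native")
            wga = load_median_table(wga_path, "wga")
        else:
            native = load_ipd_table(native_path)
            wga = load_ipd_table(wga_path)
        return cls(ref, native, wga, config=config, min_depth=min_depth)

    def fit(self) -> "MotifResults":
        scores, nulls, detection = score_and_detect(
            self.ref, self.native, self.wga, self.config
        )
        return MotifResults(self, scores, nulls, detection)


class MotifResults:
    """Fit output: per-motif scores, per-k gamma nulls, detected motifs."""

    def __init__(self, model: MotifModel, scores: pd.DataFrame, nulls: dict,
                 detection: DetectionResult):
        self.model = model
        self.scores = scores
        self.nulls = nulls
        self.detection = detection

    @property
    def motifs(self) -> list[MotifKey]:
        return self.detection.motifs

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Epigenetic motif detection results (emkmer %s)" % _version,
            "=" * 58,
            f"contigs: {len(self.model.ref)}   total length: {self.model.ref.total_length()} bp",
            f"k range: {cfg.kmin}..{cfg.kmax}   t_gamma: {cfg.t_gamma:g}   t_n: {cfg.t_n:g} SD",
            f"motifs scored: {int(self.scores['scorable'].sum())} / {len(self.scores)} observed",
        ]
        for k in sorted(self.nulls):
            n = self.nulls[k]
            lines.append(
                f"  gamma null k={k}: shape={n.shape:.3g} scale={n.scale:.3g} "
                f"(n_fit={n.n_fit}, cutoff={n.fit_cutoff_llr:.3g})"
            )
        lines.append(f"detected motifs: {len(self.detection)}")
        if len(self.detection):
            tbl = self.detection.table
            lines.append(
                tbl.to_string(
                    index=False,
                    columns=["rank", "seq", "offset", "phase", "llr", "gamma_corr"],
                    float_format=lambda v: f"{v:.4g}",
                )
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path, seed: int | None = None) -> None:
        """Write score and result tables plus a small provenance record."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .scoring import write_score_table

        write_score_table(self.scores, outdir / "scores.tsv")
        self.detection.to_tsv(outdir / "motifs.tsv")
        info = {"version": _version, "config": asdict(self.model.config),
                "min_depth": self.model.min_depth}
        if seed is not None:
            info["seed"] = seed
        (outdir / "run_info.json").write_text(json.dumps(info, indent=2))


class MetagenomeModel:
    """Metagenomic extension: pooled detection, contig clustering by
    epigenetic profile, and per-cluster re-detection."""

    def __init__(self, ref: ReferenceSet, native, wga,
                 config: DetectionConfig | None = None, min_depth: int = 1,
                 k_clusters: int = 3, min_contig_len: int = 10_000,
                 seed: int = 0):
        self.base = MotifModel(ref, native, wga, config=config, min_depth=min_depth)
        self.k_clusters = k_clusters
        self.min_contig_len = min_contig_len
        self.seed = seed

    def fit(self, iterate: int = 1) -> "MetagenomeResults":
        """Run pooled detection, then ``iterate`` rounds of
        build-vectors -> cluster -> refine (one round by default;
        extra rounds reuse the refined motif union as features)."""
        if iterate < 1:
            raise ValueError("iterate must be >= 1")
        pooled = self.base.fit()
        features = pooled.motifs
        vectors = assignment = per_cluster = None
        for _ in range(iterate):
            if not features:
                break
            vectors = build_contig_vectors(
                self.base.ref, self.base.native, self.base.wga,
                features, self.min_contig_len,
            )
            assignment = cluster_contigs(vectors, self.k_clusters, self.seed)
            per_cluster = refine_per_cluster(
                assignment, self.base.ref, self.base.native, self.base.wga,
                self.base.config,
            )
            union: list[MotifKey] = []
            for label in sorted(per_cluster):
                for m in per_cluster[label].motifs:
                    if m not in union:
                        union.append(m)
            features = union or features
        return MetagenomeResults(self, pooled, vectors, assignment, per_cluster)


class MetagenomeResults:
    def __init__(self, model: MetagenomeModel, pooled: MotifResults,
                 vectors: pd.DataFrame | None,
                 assignment: ClusterAssignment | None,
                 per_cluster: dict[int, DetectionResult] | None):
        self.model = model
        self.pooled = pooled
        self.vectors = vectors
        self.assignment = assignment
        self.per_cluster = per_cluster or {}

    @property
    def pre_clustering_motifs(self) -> list[MotifKey]:
        return self.pooled.motifs

    @property
    def post_clustering_motifs(self) -> list[MotifKey]:
        out: list[MotifKey] = []
        for label in sorted(self.per_cluster):
            for m in self.per_cluster[label].motifs:
                if m not in out:
                    out.append(m)
        return out

    def summary(self) -> str:
        lines = [
            "Metagenomic motif detection (emkmer %s)" % _version,
            "=" * 58,
            f"pre-clustering motifs:  {[str(m) for m in self.pre_clustering_motifs]}",
        ]
        if self.assignment is not None:
            sizes = self.assignment.labels.value_counts().sort_index()
            lines.append(
                "clusters (K=%d): %s" % (
                    self.model.k_clusters,
                    ", ".join(f"{i}: {n} contigs" for i, n in sizes.items()),
                )
            )
            for label in sorted(self.per_cluster):
                ms = [str(m) for m in self.per_cluster[label].motifs]
                lines.append(f"  cluster {label}: {ms}")
        lines.append(
            f"post-clustering motifs: {[str(m) for m in self.post_clustering_motifs]}"
        )
        return "\n".join(lines)
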