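"""Two-phase neighborhood-aware motif detection.

A motif's parents and children share occurrences with it, so thresholding
corrected gamma probabilities alone would report whole families around every
true motif.  Phase 1 walks motifs in decreasing LLR order, accepts a motif
only when it is gamma-significant *and* out-scores all of its parents, and
suppresses the accepted motif's neighbors from further Phase-1 consideration.
Phase 2 then revisits the suppressed neighborhood: a neighbor is rescued when
its LLR is an extreme outlier (``t_n`` standard deviations by default)
within the same-length neighbor set of its anchor motif *and* it passes the
gamma cutoff in its own right — this is what recovers nested motif families
such as GATC -> GGATC/GATCC -> GGATCC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kmers import (
    MotifKey,
    children as children_of,
    detection_neighborhood,
    parents,
    shift_families,
)

__all__ = [
    "DetectionConfig",
    "NeighborScore",
    "DetectionResult",
    "detect_phase1",
    "neighbor_stats",
    "detect_phase2",
    "detect_motifs",
]

RESULT_COLUMNS = [
    "rank",
    "seq",
    "offset",
    "k",
    "phase",
    "llr",
    "gamma_corr",
    "z",
    "normal_prob",
    "anchor",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Detector thresholds.

    t_gamma: corrected gamma-probability cutoff (smaller = more stringent).
    t_n: Phase-2 neighborhood deviation cutoff. By default a z-score gate
        (a neighbor passes when its LLR sits >= t_n scale units above its
        same-length neighborhood location); with ``t_n_is_z=False`` it is
        read as an upper bound on the normal tail probability instead.
    robust_neighbor_stats: standardise neighborhoods by median/MAD (default)
        rather than mean/SD, so nested true motifs do not mask each other.
    kmin/kmax: motif length range of the search space.
    min_obs: observations required on each side before a motif is scorable;
        calibrated so the WGA variance MLE cannot collapse often enough,
        across the whole motif table, to beat t_gamma by chance.
    """

    t_gamma: float = 1e-6
    t_n: float = 10.0
    kmin: int = 4
    kmax: int = 7
    t_n_is_z: bool = True
    robust_neighbor_stats: bool = True
    min_obs: int = 25
    min_fit_points: int = 20

    def __post_init__(self):
        if not 0 < self.t_gamma < 1:
            raise ValueError("t_gamma must be in (0, 1)")
        if self.t_n <= 0:
            raise ValueError("t_n must be > 0")
        if not 1 <= self.kmin <= self.kmax:
            raise ValueError("need 1 <= kmin <= kmax")


@dataclass(frozen=True)
class NeighborScore:
    key: MotifKey
    anchor: MotifKey
    llr: float
    gamma_corr: float
    z: float
    normal_prob: float


@dataclass
class DetectionResult:
    """Accepted motifs in acceptance order (Phase 1 before Phase 2)."""

    table: pd.DataFrame

    @property
    def motifs(self) -> list[MotifKey]:
        return [
            MotifKey(s, int(o))
            for s, o in zip(self.table["seq"], self.table["offset"])
        ]

    def phase(self, phase: int) -> list[MotifKey]:
        sub = self.table[self.table["phase"] == phase]
        return [MotifKey(s, int(o)) for s, o in zip(sub["seq"], sub["offset"])]

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.rename(columns={"seq": "motif"})
        out.to_csv(path, sep="\t", index=False)


def _score_maps(scores: pd.DataFrame):
    """(llr, gamma_corr) lookup for scorable motifs with a finite corrected
    probability."""
    sc = scores[scores["scorable"] & np.isfinite(scores["gamma_corr"])]
    llr = {}
    corr = {}
    for seq, off, l, g in zip(sc["seq"], sc["offset"], sc["llr"], sc["gamma_corr"]):
        key = MotifKey(seq, int(off))
        llr[key] = float(l)
        corr[key] = float(g)
    return llr, corr


def detect_phase1(
    scores: pd.DataFrame, cfg: DetectionConfig
) -> list[MotifKey]:
    """Greedy selection of independent gamma-significant motifs.

    Repeatedly takes the highest-LLR candidate (ties broken lexicographically
    by (seq, offset)); terminates as soon as that candidate fails the
    corrected gamma cutoff; otherwise accepts it iff its LLR exceeds every
    scorable parent's LLR, and on acceptance removes its neighborhood
    (parents, children and same-length shifts — all motifs whose observation
    sets can report the accepted motif's modified bases) from the candidate
    pool.  The examined motif itself always leaves the pool.
    """
    llr, corr = _score_maps(scores)
    order = sorted(llr, key=lambda m: (-llr[m], m.seq, m.offset))
    removed: set[MotifKey] = set()
    accepted: list[MotifKey] = []
    for key in order:
        if key in removed:
            continue
        if not corr[key] < cfg.t_gamma:
            break  # most significant remaining motif fails the gate
        parent_max = max(
            (llr[p] for p in parents(key) if p in llr), default=-np.inf
        )
        if llr[key] > parent_max:
            accepted.append(key)
            removed |= detection_neighborhood(key, cfg.kmin, cfg.kmax)
        removed.add(key)
    return accepted


def neighbor_stats(
    accepted: Iterable[MotifKey],
    scores: pd.DataFrame,
    cfg: DetectionConfig | None = None,
) -> list[NeighborScore]:
    """Neighborhood z-statistics for Phase 2.

    For each Phase-1 motif, its suppressed neighborhood is split into
    structural comparison classes — parents, children, and shift families at
    each alignment distance |d| — because a member's relation to the anchor
    fixes how much of the anchor's signal it inherits (children see all of
    it, a shift at distance d a fraction ~4^-d), so only members of the same
    class are exchangeable under "no additional modification".  Each
    member's LLR is standardised against its class and converted to an upper
    normal tail probability.  By default the class location/scale are the
    median and 1.4826*MAD: a class can legitimately contain several truly
    modified motifs (nested families such as GGATC/GATCC among the children
    of GATC), and a mean/SD standardisation is masked by them — the robust
    version lets up to half the class stand out.  With
    ``cfg.robust_neighbor_stats=False`` the plain mean/SD is used.  Members
    already accepted are excluded; classes with fewer than 3 scorable
    members or no spread are unscored; a motif adjacent to several anchors
    keeps its most extreme (largest z) standing.
    """
    cfg = cfg or DetectionConfig()
    llr, corr = _score_maps(scores)
    accepted = list(accepted)
    in_O = set(accepted)
    best: dict[MotifKey, NeighborScore] = {}
    for anchor in accepted:
        classes: list[set[MotifKey]] = [parents(anchor), children_of(anchor)]
        classes.extend(shift_families(anchor).values())
        for members in classes:
            group = [n for n in members if n in llr and n not in in_O]
            if len(group) < 3:
                continue
            vals = np.array([llr[n] for n in group])
            if cfg.robust_neighbor_stats:
                mu = float(np.median(vals))
                sigma = 1.4826 * float(np.median(np.abs(vals - mu)))
            else:
                mu = float(vals.mean())
                sigma = float(vals.std(ddof=1))
            if sigma <= 0 and np.allclose(vals, mu):
                continue  # degenerate class: identical LLRs carry no ranking
            for n in group:
                dev = llr[n] - mu
                if sigma > 0:
                    z = dev / sigma
                elif dev > 0:
                    z = np.inf  # zero robust spread, genuine deviation
                else:
                    z = 0.0
                ns = NeighborScore(
                    key=n,
                    anchor=anchor,
                    llr=llr[n],
                    gamma_corr=corr[n],
                    z=float(z),
                    normal_prob=float(sps.norm.sf(z)),
                )
                prev = best.get(n)
                if prev is None or ns.z > prev.z:
                    best[n] = ns
    return sorted(best.values(), key=lambda s: (-s.z, s.key.seq, s.key.offset))


def detect_phase2(
    neighbor_scores: Iterable[NeighborScore],
    cfg: DetectionConfig,
    accepted: list[MotifKey],
) -> tuple[list[MotifKey], list[NeighborScore]]:
    """Rescue neighborhood outliers.

    Neighbors are visited by decreasing deviation; the loop stops at the
    first one failing the ``t_n`` gate.  A passing neighbor is accepted iff
    it also clears the corrected gamma cutoff; either way the walk continues.
    Returns (full accepted list, the Phase-2 acceptances with provenance).
    """
    out = list(accepted)
    rescued: list[NeighborScore] = []
    ranked = sorted(
        neighbor_scores, key=lambda s: (s.normal_prob, s.key.seq, s.key.offset)
    )
    for ns in ranked:
        passes = ns.z >= cfg.t_n if cfg.t_n_is_z else ns.normal_prob < cfg.t_n
        if not passes:
            break
        if ns.gamma_corr < cfg.t_gamma:
            out.append(ns.key)
            rescued.append(ns)
    return out, rescued


def detect_motifs(scores: pd.DataFrame, cfg: DetectionConfig | None = None) -> DetectionResult:
    """Run both phases and assemble the ranked result table."""
    cfg = cfg or DetectionConfig()
    phase1 = detect_phase1(scores, cfg)
    nstats = neighbor_stats(phase1, scores, cfg)
    _, rescued = detect_phase2(nstats, cfg, phase1)
    llr, corr = _score_maps(scores)
    rows = []
    for rank, key in enumerate(phase1, start=1):
        rows.append(
            (rank, key.seq, key.offset, key.k, 1, llr[key], corr[key], np.nan, np.nan, "")
        )
    for i, ns in enumerate(rescued, start=len(phase1) + 1):
        rows.append(
            (
                i,
                ns.key.seq,
                ns.key.offset,
                ns.key.k,
                2,
                ns.llr,
                ns.gamma_corr,
                ns.z,
                ns.normal_prob,
                str(ns.anchor.seq) + ":" + str(ns.anchor.offset),
            )
        )
    return DetectionResult(table=pd.DataFrame(rows, columns=RESULT_COLUMNS))
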