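"""Per-motif log-likelihood ratios and the per-k gamma null.

For each motif the set of native median IPDs is contrasted with the matched
WGA (modification-free) set.  ln median IPDs are modelled as normal with a
common (pooled) spread; the LLR is the summed log-density ratio of the
native observations under their own MLE mean versus the WGA MLE mean:

    llr = sum_i [ ln phi(y_i; mu_y, s_p) - ln phi(y_i; mu_z, s_p) ]
        = n_y (mu_y - mu_z)^2 / (2 s_p^2)

with y = ln(native medians), z = ln(WGA medians), plug-in MLE means, and
s_p^2 the observation-weighted pool of the two MLE variances.  Pooling makes
the statistic a mean-shift test (its null is ~chi-square with one degree of
freedom, comfortably inside the gamma family used for calibration) and
deliberately does *not* reward variance inflation: a motif whose native
set is a mixture of modified and unmodified contexts gains nothing from the
mixture's inflated spread, so a pure sub-motif out-scores its diluted
parent, which is what lets nested motif families resolve correctly.
LLRs are nonnegative by construction.  Because motifs of one length share
occurrences (substrings, overlaps), significance is calibrated *empirically
and separately per kmer length*: a gamma distribution is fitted to the bulk
of that length's LLRs (motifs whose WGA IPDs exceed the native ones are
noise and bound the fit, together with a 99th-percentile trim), and each
motif's survival probability is Bonferroni-corrected by the size of its
length class, k*4^k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kmers import KmerStats, MotifKey, MotifObservations

__all__ = [
    "GammaNull",
    "SD_FLOOR",
    "compute_llr",
    "score_all",
    "scores_from_stats",
    "fit_gamma_null",
    "fit_all_nulls",
    "assign_significance",
    "write_score_table",
    "read_score_table",
]

SD_FLOOR = 1e-3  # ln-IPD units; guards against degenerate (tied) median sets

SCORE_COLUMNS = [
    "seq",
    "offset",
    "k",
    "n_occ",
    "n_native",
    "n_wga",
    "llr",
    "direction",
    "scorable",
    "p_gamma",
    "gamma_corr",
]


@dataclass(frozen=True)
class GammaNull:
    """Gamma null for the LLRs of one kmer length (location fixed at 0)."""

    k: int
    shape: float
    scale: float
    n_fit: int
    fit_cutoff_llr: float

    def sf(self, llr) -> np.ndarray | float:
        return sps.gamma.sf(llr, self.shape, scale=self.scale)


def compute_llr(
    native_medians: np.ndarray, wga_medians: np.ndarray
) -> tuple[float, str]:
    """LLR of one motif's native median IPDs against its WGA null.

    Computed as the term-by-term sum of normal log-density ratios over the
    native ln medians, with the native MLE mean as the alternative, the WGA
    MLE mean as the null, and the pooled MLE spread shared by both (see the
    module docstring for why the spread is pooled).  Both sides need at
    least two strictly positive values.  Returns (llr, direction) with
    direction ``"native_higher"`` iff the mean ln native IPD exceeds the
    mean ln WGA IPD (ties break to ``"wga_higher"``, the conservative noise
    label).
    """
    y = np.log(np.asarray(native_medians, dtype=float))
    z = np.log(np.asarray(wga_medians, dtype=float))
    if y.size < 2 or z.size < 2:
        raise ValueError("need >= 2 observations on each side")
    if not (np.isfinite(y).all() and np.isfinite(z).all()):
        raise ValueError("median IPDs must be positive and finite")
    mu_y = float(np.mean(y))
    mu_z = float(np.mean(z))
    var_y = float(np.mean((y - mu_y) ** 2))
    var_z = float(np.mean((z - mu_z) ** 2))
    sd_p = max(
        np.sqrt((y.size * var_y + z.size * var_z) / (y.size + z.size)), SD_FLOOR
    )
    ll_alt = -np.sum((y - mu_y) ** 2) / (2 * sd_p**2)
    ll_null = -np.sum((y - mu_z) ** 2) / (2 * sd_p**2)
    llr = float(ll_alt - ll_null)
    direction = "native_higher" if mu_y > mu_z else "wga_higher"
    # MLE dominance makes the LLR nonnegative up to rounding; clip the dust.
    return max(llr, 0.0), direction


def score_all(
    observations: Iterable[MotifObservations], min_obs: int = 25
) -> pd.DataFrame:
    """Apply :func:`compute_llr` to a collection of per-motif observation
    sets; motifs with fewer than ``min_obs`` values on either side are
    carried through flagged unscorable."""
    rows = []
    for obs in observations:
        n_nat, n_wga = len(obs.native_medians), len(obs.wga_medians)
        scorable = n_nat >= min_obs and n_wga >= min_obs
        if scorable:
            llr, direction = compute_llr(obs.native_medians, obs.wga_medians)
        else:
            llr, direction = np.nan, ""
        rows.append(
            (
                obs.key.seq,
                obs.key.offset,
                obs.key.k,
                obs.n_occurrences,
                n_nat,
                n_wga,
                llr,
                direction,
                scorable,
                np.nan,
                np.nan,
            )
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def scores_from_stats(
    stats: Mapping[int, KmerStats], min_obs: int = 25
) -> pd.DataFrame:
    """Vectorised scoring of the whole motif space from sufficient statistics.

    Algebraically identical to :func:`compute_llr` (same MLEs, same variance
    floor) but computed from per-motif (n, sum, sum-of-squares) of the ln
    medians, so the full 4..7-mer table scores in one pass.  Only motifs with
    at least one occurrence are returned.
    """
    frames = []
    for k, st in sorted(stats.items()):
        present = np.flatnonzero(st.n_occ > 0)
        if present.size == 0:
            continue
        n_y = st.n_native[present].astype(float)
        n_z = st.n_wga[present].astype(float)
        scorable = (n_y >= max(min_obs, 2)) & (n_z >= max(min_obs, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            mu_y = st.sum_native[present] / n_y
            var_y = np.maximum(st.ssq_native[present] / n_y - mu_y**2, 0.0)
            mu_z = st.sum_wga[present] / n_z
            var_z = np.maximum(st.ssq_wga[present] / n_z - mu_z**2, 0.0)
            var_p = (n_y * var_y + n_z * var_z) / (n_y + n_z)
        sd_p = np.maximum(np.sqrt(var_p), SD_FLOOR)
        llr = n_y * (mu_y - mu_z) ** 2 / (2 * sd_p**2)
        llr = np.where(scorable, np.maximum(llr, 0.0), np.nan)
        direction = np.where(
            scorable, np.where(mu_y > mu_z, "native_higher", "wga_higher"), ""
        )
        seqs = [st.key_of(int(i)).seq for i in present]
        frames.append(
            pd.DataFrame(
                {
                    "seq": seqs,
                    "offset": (present % k).astype(int),
                    "k": k,
                    "n_occ": st.n_occ[present],
                    "n_native": st.n_native[present],
                    "n_wga": st.n_wga[present],
                    "llr": llr,
                    "direction": direction,
                    "scorable": scorable,
                    "p_gamma": np.nan,
                    "gamma_corr": np.nan,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SCORE_COLUMNS]


def fit_gamma_null(
    llrs: np.ndarray,
    directions: np.ndarray,
    k: int,
    min_fit_points: int = 20,
) -> GammaNull:
    """Fit the gamma null to one length class's LLRs.

    Motifs where the WGA IPDs exceed the native ones cannot be driven by a
    modification, so the largest such LLR bounds the noise; the fit set is
    all LLRs strictly below max(that bound, the class's 99th percentile),
    which keeps genuine outliers out of the null while tolerating classes
    where many motifs are perturbed by a shared strong signal.  Maximum
    likelihood with location fixed at 0; method-of-moments fallback on
    non-convergence.
    """
    llrs = np.asarray(llrs, dtype=float)
    directions = np.asarray(directions)
    if llrs.size < min_fit_points:
        raise ValueError(
            f"k={k}: {llrs.size} LLRs < min_fit_points={min_fit_points}"
        )
    noise = llrs[directions == "wga_higher"]
    noise_max = float(noise.max()) if noise.size else -np.inf
    q99 = float(np.quantile(llrs, 0.99))
    cutoff = max(noise_max, q99)
    fit_set = llrs[(llrs < cutoff) & (llrs > 0)]
    if fit_set.size < min_fit_points:
        raise ValueError(f"k={k}: only {fit_set.size} positive LLRs below cutoff")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape, loc, scale = sps.gamma.fit(fit_set, floc=0)
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
            raise RuntimeError("degenerate MLE")
    except Exception:  # pragma: no cover - exercised only on pathological data
        warnings.warn(f"k={k}: gamma MLE failed, using method of moments")
        m, v = float(fit_set.mean()), float(fit_set.var())
        v = max(v, 1e-12)
        shape, scale = m * m / v, v / m
    return GammaNull(
        k=k,
        shape=float(shape),
        scale=float(scale),
        n_fit=int(fit_set.size),
        fit_cutoff_llr=float(cutoff),
    )


def fit_all_nulls(
    scores: pd.DataFrame, min_fit_points: int = 20
) -> dict[int, GammaNull]:
    """Per-k gamma nulls over the scorable motifs; length classes with too
    few points are skipped (their motifs stay unscored)."""
    nulls: dict[int, GammaNull] = {}
    sc = scores[scores["scorable"]]
    for k, sub in sc.groupby("k"):
        try:
            nulls[int(k)] = fit_gamma_null(
                sub["llr"].to_numpy(),
                sub["direction"].to_numpy(),
                int(k),
                min_fit_points,
            )
        except ValueError as exc:
            warnings.warn(f"no gamma null for k={k}: {exc}")
    return nulls


def assign_significance(
    scores: pd.DataFrame, nulls: Mapping[int, GammaNull]
) -> pd.DataFrame:
    """Attach p_gamma (gamma survival at the LLR) and gamma_corr
    (p_gamma * k*4^k, the Bonferroni-corrected value) to a score table.

    Motifs with WGA IPDs above native get p_gamma = 1 — modifications slow
    the polymerase, so that direction is noise by definition.  gamma_corr
    values above 1 are legal; they simply fail every cutoff.
    """
    out = scores.copy()
    p = np.full(len(out), np.nan)
    for k, null in nulls.items():
        mask = (out["k"].to_numpy() == k) & out["scorable"].to_numpy()
        if mask.any():
            p[mask] = null.sf(out.loc[mask, "llr"].to_numpy())
    noise = out["direction"].to_numpy() == "wga_higher"
    p[noise & out["scorable"].to_numpy()] = 1.0
    kk = out["k"].to_numpy(dtype=float)
    out["p_gamma"] = p
    out["gamma_corr"] = p * kk * 4.0**kk
    return out


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    cols = ["seq", "offset", "k", "n_native", "n_wga", "llr", "direction", "p_gamma", "gamma_corr"]
    scores.rename(columns={"seq": "motif"}).to_csv(
        path, sep="\t", index=False,
        columns=["motif"] + cols[1:],
    )


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").rename(columns={"motif": "seq"})
    df["scorable"] = np.isfinite(df["llr"].to_numpy(dtype=float))
    if "n_occ" not in df.columns:
        df["n_occ"] = np.maximum(df["n_native"], df["n_wga"])
    return df[SCORE_COLUMNS]
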