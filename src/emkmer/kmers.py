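"""Motif space enumeration, occurrence scanning and observation collection.

A candidate motif is a *(kmer, offset)* pair: the kmer sequence together with
the position of its putatively modified base, e.g. G(m6A)TC = ("GATC", 1).
For lengths kmin..kmax the space therefore holds sum_k k*4^k keys.  Motifs of
length k-1 / k+1 that preserve the modified base are the motif's *parents* /
*children*; parents and children together form its *neighbors*.

Scanning is strand-symmetric: the reverse strand is scanned as the reverse
complement in its own 5'->3' coordinates, so kinetics collected on either
strand line up with the template base the polymerase actually read.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .io import ReferenceSet, SampleKinetics

__all__ = [
    "MotifKey",
    "MotifObservations",
    "KmerStats",
    "enumerate_motif_space",
    "motif_space_size",
    "scan_occurrences",
    "collect_observations",
    "collect_all_stats",
    "parents",
    "children",
    "neighbors",
    "shifts",
    "shift_families",
    "detection_neighborhood",
    "occurrences_to_bed",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


class MotifKey(NamedTuple):
    """A kmer plus the offset of its putatively modified base."""

    seq: str
    offset: int

    def validate(self) -> "MotifKey":
        if not self.seq or set(self.seq) - set(_BASES):
            raise ValueError(f"motif sequence must be non-empty ACGT, got {self.seq!r}")
        if not 0 <= self.offset < len(self.seq):
            raise ValueError(f"offset {self.offset} outside kmer {self.seq!r}")
        return self

    @property
    def k(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:  # G[A]TC style
        return f"{self.seq[: self.offset]}[{self.seq[self.offset]}]{self.seq[self.offset + 1 :]}"


@dataclass
class MotifObservations:
    """Paired native/WGA median-IPD observation sets for one motif."""

    key: MotifKey
    native_medians: np.ndarray
    wga_medians: np.ndarray
    n_occurrences: int

    @property
    def scorable(self) -> bool:
        return len(self.native_medians) >= 2 and len(self.wga_medians) >= 2


def motif_space_size(kmin: int, kmax: int) -> int:
    return sum(k * 4**k for k in range(kmin, kmax + 1))


def enumerate_motif_space(kmin: int, kmax: int) -> list[MotifKey]:
    """All (kmer, offset) keys for lengths kmin..kmax, in (k, seq, offset)
    order; exactly sum_k k*4^k keys."""
    if not 1 <= kmin <= kmax:
        raise ValueError(f"need 1 <= kmin <= kmax, got ({kmin}, {kmax})")
    keys: list[MotifKey] = []
    for k in range(kmin, kmax + 1):
        for code in range(4**k):
            seq = _decode(code, k)
            keys.extend(MotifKey(seq, off) for off in range(k))
    return keys


def _decode(code: int, k: int) -> str:
    out = []
    for i in range(k - 1, -1, -1):
        out.append(_BASES[(code >> (2 * i)) & 3])
    return "".join(out)


def _encode_seq(seq: str) -> np.ndarray:
    """ACGTN string -> int8 codes, N (and anything else) -> 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int64)
    for b, c in _CODE.items():
        codes[arr == ord(b)] = c
    return codes


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial codes of all k-windows and a validity mask (no N)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    wc = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        wc = wc * 4 + np.where(c == 4, 0, c)
        valid &= c != 4
    return wc, valid


def scan_occurrences(ref: ReferenceSet, key: MotifKey) -> list[tuple[str, str, int]]:
    """Exact occurrences of ``key.seq`` on both strands.

    Returns (contig_id, strand, position) triples where ``position`` is the
    coordinate of the modified base on that strand's own template (reverse
    strand counts from the reverse-complement 5' end).  Windows containing N
    never match.
    """
    key.validate()
    hits: list[tuple[str, str, int]] = []
    k = key.k
    target = 0
    for b in key.seq:
        target = target * 4 + _CODE[b]
    for cid in ref.contig_ids:
        for strand in "+-":
            codes = _encode_seq(ref.strand_sequence(cid, strand))
            wc, valid = _window_codes(codes, k)
            starts = np.flatnonzero((wc == target) & valid)
            hits.extend((cid, strand, int(s) + key.offset) for s in starts)
    return hits


def collect_observations(
    ref: ReferenceSet,
    native: SampleKinetics,
    wga: SampleKinetics,
    key: MotifKey,
) -> MotifObservations:
    """The native and WGA median-IPD sets at the modified base of every
    occurrence of ``key`` (each side independently; missing medians skipped)."""
    occ = scan_occurrences(ref, key)
    nat, wg = [], []
    for cid, strand, pos in occ:
        m, _ = native.track(ref, cid, strand)
        if np.isfinite(m[pos]):
            nat.append(m[pos])
        m, _ = wga.track(ref, cid, strand)
        if np.isfinite(m[pos]):
            wg.append(m[pos])
    return MotifObservations(
        key=key,
        native_medians=np.asarray(nat, dtype=float),
        wga_medians=np.asarray(wg, dtype=float),
        n_occurrences=len(occ),
    )


@dataclass
class KmerStats:
    """Vectorised per-motif observation statistics for one kmer length.

    Arrays are indexed by motif id ``code * k + offset`` (size k*4^k) and hold
    occurrence counts plus the count / sum / sum-of-squares of ln median IPDs
    on each side — the sufficient statistics for the normal-model LLR.
    """

    k: int
    n_occ: np.ndarray
    n_native: np.ndarray
    sum_native: np.ndarray
    ssq_native: np.ndarray
    n_wga: np.ndarray
    sum_wga: np.ndarray
    ssq_wga: np.ndarray

    def key_of(self, motif_id: int) -> MotifKey:
        return MotifKey(_decode(motif_id // self.k, self.k), motif_id % self.k)

    @staticmethod
    def motif_id(key: MotifKey) -> int:
        code = 0
        for b in key.seq:
            code = code * 4 + _CODE[b]
        return code * key.k + key.offset


def collect_all_stats(
    ref: ReferenceSet,
    native: SampleKinetics,
    wga: SampleKinetics,
    kmin: int = 4,
    kmax: int = 7,
) -> dict[int, KmerStats]:
    """Sweep every contig once per (k, strand) and accumulate, for every
    (kmer, offset) key, the sufficient statistics of its ln median-IPD
    observation sets.  This is the batch counterpart of
    :func:`collect_observations` and scales to the full 4..7-mer space."""
    out: dict[int, KmerStats] = {}
    for k in range(kmin, kmax + 1):
        size = k * 4**k
        st = KmerStats(
            k=k,
            n_occ=np.zeros(size, dtype=np.int64),
            n_native=np.zeros(size, dtype=np.int64),
            sum_native=np.zeros(size),
            ssq_native=np.zeros(size),
            n_wga=np.zeros(size, dtype=np.int64),
            sum_wga=np.zeros(size),
            ssq_wga=np.zeros(size),
        )
        out[k] = st
    for cid in ref.contig_ids:
        for strand in "+-":
            seq_codes = _encode_seq(ref.strand_sequence(cid, strand))
            nat_med, _ = native.track(ref, cid, strand)
            wga_med, _ = wga.track(ref, cid, strand)
            ln_nat = np.log(nat_med)  # NaN propagates through log
            ln_wga = np.log(wga_med)
            for k in range(kmin, kmax + 1):
                st = out[k]
                wc, valid = _window_codes(seq_codes, k)
                if wc.size == 0:
                    continue
                starts = np.flatnonzero(valid)
                base_ids = wc[starts] * k
                for off in range(k):
                    ids = base_ids + off
                    np.add.at(st.n_occ, ids, 1)
                    pos = starts + off
                    for ln_vals, n_a, s_a, q_a in (
                        (ln_nat, st.n_native, st.sum_native, st.ssq_native),
                        (ln_wga, st.n_wga, st.sum_wga, st.ssq_wga),
                    ):
                        v = ln_vals[pos]
                        ok = np.isfinite(v)
                        if ok.any():
                            iid = ids[ok]
                            vv = v[ok]
                            np.add.at(n_a, iid, 1)
                            np.add.at(s_a, iid, vv)
                            np.add.at(q_a, iid, vv * vv)
    return out


def parents(key: MotifKey) -> set[MotifKey]:
    """The (k-1)-mers obtained by trimming one flanking base while keeping
    the modified base; at most two."""
    out: set[MotifKey] = set()
    if key.offset >= 1:  # trim the first base
        out.add(MotifKey(key.seq[1:], key.offset - 1))
    if key.offset <= key.k - 2:  # trim the last base
        out.add(MotifKey(key.seq[:-1], key.offset))
    return out


def children(key: MotifKey, ref: ReferenceSet | None = None) -> set[MotifKey]:
    """The 8 (k+1)-mers obtained by prepending or appending one base.

    When ``ref`` is given, children whose sequence never occurs on either
    strand of the reference are dropped.
    """
    out: set[MotifKey] = set()
    for b in _BASES:
        out.add(MotifKey(b + key.seq, key.offset + 1))
        out.add(MotifKey(key.seq + b, key.offset))
    if ref is not None:
        out = {c for c in out if scan_occurrences(ref, c)}
    return out


def neighbors(key: MotifKey, ref: ReferenceSet | None = None) -> set[MotifKey]:
    return parents(key) | children(key, ref)


def shift_families(key: MotifKey) -> dict[int, set[MotifKey]]:
    """Same-length motifs that can report the same physical modified base,
    grouped by alignment distance |d|.

    A key q of the same length is a *shift* of ``key`` when some nonzero
    alignment offset d places q's window over an occurrence of ``key`` such
    that the two kmers agree on the overlap and q's modified offset lands on
    ``key``'s modified base (q.offset = key.offset + d).  The positions of q
    outside the overlap are free, so each d contributes a family of 4^|d|
    motifs, each seeing the key's kinetic signal diluted by ~4^-|d| (the
    chance that an occurrence of q extends to an occurrence of the key).
    Because expected dilution is a function of |d|, the detector treats each
    |d| family as its own comparison class.  A motif compatible at several
    distances is kept at the smallest |d|.
    """
    k = key.k
    fams: dict[int, set[MotifKey]] = {}
    seen: set[MotifKey] = {key}
    for dist in range(1, k):
        fam: set[MotifKey] = set()
        for d in (dist, -dist):
            off = key.offset + d
            if not 0 <= off < k:
                continue
            fixed: dict[int, str] = {}
            for i in range(k):
                j = i - d
                if 0 <= j < k:
                    fixed[i] = key.seq[j]
            free = [i for i in range(k) if i not in fixed]
            for combo in product(_BASES, repeat=len(free)):
                chars = ["N"] * k
                for i, b in fixed.items():
                    chars[i] = b
                for i, b in zip(free, combo):
                    chars[i] = b
                q = MotifKey("".join(chars), off)
                if q not in seen:
                    fam.add(q)
        if fam:
            fams[dist] = fam
            seen |= fam
    return fams


def shifts(key: MotifKey) -> set[MotifKey]:
    """Union of all shift families of the key (see :func:`shift_families`)."""
    out: set[MotifKey] = set()
    for fam in shift_families(key).values():
        out |= fam
    return out


def detection_neighborhood(
    key: MotifKey,
    kmin: int = 4,
    kmax: int = 7,
    max_uncovered: int = 2,
) -> set[MotifKey]:
    """The key's co-observation family: every motif whose observation set
    reports the key's modified bases at non-trivial rate.

    A motif q of any length in [kmin, kmax] belongs when some alignment of
    q's window over an occurrence of the key (a) keeps q's modified offset on
    the key's modified base, (b) agrees with the key on the overlap, and (c)
    leaves at most ``max_uncovered`` of the key's bases outside q's window —
    i.e. the expected fraction of q's occurrences that extend to the key
    (hence inherit its kinetic signal) is at least 4**-max_uncovered.
    Parents, children and one-step shifts are special cases.  Used by
    Phase 1 to suppress the family of an accepted motif, whose elevated LLRs
    the accepted motif already explains.
    """
    ka = key.k
    out: set[MotifKey] = set()
    for kq in range(kmin, kmax + 1):
        # s: start of q's window relative to the key's window start
        for s in range(-(kq - 1), ka):
            off = key.offset - s
            if not 0 <= off < kq:
                continue
            overlap_lo, overlap_hi = max(0, s), min(ka, s + kq)
            if ka - (overlap_hi - overlap_lo) > max_uncovered:
                continue
            fixed = {i - s: key.seq[i] for i in range(overlap_lo, overlap_hi)}
            free = [i for i in range(kq) if i not in fixed]
            for combo in product(_BASES, repeat=len(free)):
                chars = ["N"] * kq
                for i, b in fixed.items():
                    chars[i] = b
                for i, b in zip(free, combo):
                    chars[i] = b
                q = MotifKey("".join(chars), off)
                if q != key:
                    out.add(q)
    return out


def occurrences_to_bed(
    ref: ReferenceSet, keys: Iterable[MotifKey], path: str | Path
) -> None:
    """Dump occurrences as a BED-like TSV (0-based half-open kmer interval on
    the occurrence's own strand, plus the modified-base offset)."""
    rows = []
    for key in keys:
        for cid, strand, pos in scan_occurrences(ref, key):
            start = pos - key.offset
            rows.append((cid, start, start + key.k, key.seq, key.offset, strand))
    pd.DataFrame(
        rows, columns=["contig", "start", "end", "motif", "offset", "strand"]
    ).to_csv(path, sep="\t", index=False)
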