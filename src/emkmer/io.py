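"""Reference and kinetics input/output.

SMRT sequencing reports an inter-pulse duration (IPD) for every incorporated
base of every read.  This module reads references (FASTA) and per-read IPD
tables, collapses them to the per-position *median* IPD that the rest of the
pipeline consumes, and provides the read-level downsampling and
WGA-contamination mixing operations used in the simulation experiments.

Coordinates are 0-based and strand-specific: a position on the ``-`` strand
counts from the 5' end of the reverse-complement template, so position ``p``
on ``-`` corresponds to forward coordinate ``L - 1 - p``.  IPDs must be
strictly positive (the scoring stage works in ln-IPD space); units are
arbitrary but must be consistent within a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ReferenceSet",
    "SampleKinetics",
    "IPD_COLUMNS",
    "MEDIAN_COLUMNS",
    "load_reference",
    "load_ipd_table",
    "write_ipd_table",
    "load_median_table",
    "write_median_table",
    "aggregate_medians",
    "downsample_to_coverage",
    "mix_contamination",
]

IPD_COLUMNS = ["contig", "position", "strand", "read_id", "ipd"]
MEDIAN_COLUMNS = ["contig", "position", "strand", "median_ipd", "depth"]

_VALID = set("ACGTN")


class ReferenceSet:
    """An ordered collection of contigs over the alphabet ACGTN.

    Sequences are uppercased on construction; characters outside ACGTN are
    mapped to N.  Contig ids must be unique and sequences non-empty.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        self._seqs: dict[str, str] = {}
        for contig_id, seq in records:
            if contig_id in self._seqs:
                raise ValueError(f"duplicate contig id: {contig_id!r}")
            s = str(seq).upper()
            if not s:
                raise ValueError(f"empty sequence for contig {contig_id!r}")
            if not set(s) <= _VALID:
                s = "".join(c if c in _VALID else "N" for c in s)
            self._seqs[contig_id] = s
        if not self._seqs:
            raise ValueError("no sequences")
        self._rc: dict[str, str] = {}

    @property
    def contig_ids(self) -> list[str]:
        return list(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._seqs

    def __getitem__(self, contig_id: str) -> str:
        return self._seqs[contig_id]

    def items(self):
        return self._seqs.items()

    def length(self, contig_id: str) -> int:
        return len(self._seqs[contig_id])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def revcomp(self, contig_id: str) -> str:
        """Reverse complement of a contig (cached); N maps to N."""
        rc = self._rc.get(contig_id)
        if rc is None:
            rc = str(Seq(self._seqs[contig_id]).reverse_complement())
            self._rc[contig_id] = rc
        return rc

    def strand_sequence(self, contig_id: str, strand: str) -> str:
        if strand == "+":
            return self._seqs[contig_id]
        if strand == "-":
            return self.revcomp(contig_id)
        raise ValueError(f"unknown strand {strand!r}")

    def subset(self, contig_ids: Iterable[str]) -> "ReferenceSet":
        ids = list(contig_ids)
        missing = [c for c in ids if c not in self._seqs]
        if missing:
            raise KeyError(f"unknown contigs: {missing}")
        return ReferenceSet((c, self._seqs[c]) for c in ids)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for cid, seq in self._seqs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


@dataclass
class SampleKinetics:
    """Per-position median IPDs for one sample role (native or WGA).

    ``table`` has columns contig, position, strand, median_ipd, depth; the
    median is NaN wherever depth < min_depth.  ``tracks`` lazily exposes the
    same data as dense per-strand numpy arrays for fast kmer collection.
    """

    role: str
    table: pd.DataFrame
    _tracks: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self):
        if self.role not in ("native", "wga"):
            raise ValueError(f"role must be 'native' or 'wga', got {self.role!r}")
        missing = [c for c in MEDIAN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"kinetics table missing columns {missing}")

    def track(self, ref: ReferenceSet, contig_id: str, strand: str):
        """(median array, depth array) over a contig on one strand.

        Median entries are NaN where no value is available.  Positions are
        validated against the contig length.
        """
        key = (contig_id, strand)
        cached = self._tracks.get(key)
        if cached is not None:
            return cached
        n = ref.length(contig_id)
        med = np.full(n, np.nan)
        dep = np.zeros(n, dtype=np.int64)
        sub = self.table
        sel = (sub["contig"].to_numpy() == contig_id) & (
            sub["strand"].to_numpy() == strand
        )
        if sel.any():
            pos = sub.loc[sel, "position"].to_numpy(dtype=np.int64)
            if pos.min() < 0 or pos.max() >= n:
                raise ValueError(
                    f"position out of range for contig {contig_id!r} (len {n})"
                )
            med[pos] = sub.loc[sel, "median_ipd"].to_numpy(dtype=float)
            dep[pos] = sub.loc[sel, "depth"].to_numpy(dtype=np.int64)
        self._tracks[key] = (med, dep)
        return med, dep


def load_reference(path: str | Path) -> ReferenceSet:
    """Read a FASTA file into a :class:`ReferenceSet`.

    Lowercase (masked) bases are uppercased; IUPAC ambiguity codes become N.
    Raises on an empty file or duplicate ids.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return ReferenceSet(records)


def _validate_ipd_frame(df: pd.DataFrame, source: str, max_bad_lines: int) -> pd.DataFrame:
    bad: list[str] = []
    strand_ok = df["strand"].isin(["+", "-"]).to_numpy()
    ipd = pd.to_numeric(df["ipd"], errors="coerce").to_numpy()
    pos = pd.to_numeric(df["position"], errors="coerce").to_numpy()
    ok = strand_ok & np.isfinite(ipd) & (ipd > 0) & np.isfinite(pos) & (pos >= 0)
    if not ok.all():
        # +2: header line plus 1-based numbering
        for idx in np.flatnonzero(~ok)[: max_bad_lines + 1]:
            row = df.iloc[idx]
            bad.append(
                f"{source}:{idx + 2}: invalid record "
                f"(strand={row['strand']!r}, ipd={row['ipd']!r})"
            )
        if len(bad) > max_bad_lines:
            raise ValueError(
                f"more than {max_bad_lines} bad lines in {source}; first: {bad[0]}"
            )
        raise ValueError("; ".join(bad))
    out = df.copy()
    out["position"] = pos.astype(np.int64)
    out["ipd"] = ipd.astype(float)
    return out


def load_ipd_table(path: str | Path, max_bad_lines: int = 0) -> pd.DataFrame:
    """Read a per-read kinetics TSV (columns contig, position, strand,
    read_id, ipd) into a validated DataFrame.

    Lines with an unknown strand symbol or a non-positive/non-numeric IPD are
    reported with their line number; more than ``max_bad_lines`` such lines
    aborts the load.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "read_id": str})
    missing = [c for c in IPD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return _validate_ipd_frame(df[IPD_COLUMNS], str(path), max_bad_lines)


def write_ipd_table(records: pd.DataFrame, path: str | Path) -> None:
    records[IPD_COLUMNS].to_csv(path, sep="\t", index=False)


def load_median_table(path: str | Path, role: str) -> SampleKinetics:
    """Read the pre-aggregated per-position dialect
    (contig, position, strand, median_ipd, depth)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = [c for c in MEDIAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: unknown strand symbol")
    return SampleKinetics(role=role, table=df[MEDIAN_COLUMNS].copy())


def write_median_table(kin: SampleKinetics, path: str | Path) -> None:
    kin.table[MEDIAN_COLUMNS].to_csv(path, sep="\t", index=False)


def _grouped_medians(keys: np.ndarray, values: np.ndarray):
    """Median and count of ``values`` within each run of equal ``keys``.

    Sorts by (key, value); within each group the values are then ordered, so
    the median is read off the middle order statistic(s).  Returns
    (unique keys, medians, counts).
    """
    order = np.lexsort((values, keys))
    k = keys[order]
    v = values[order]
    boundaries = np.flatnonzero(np.diff(k)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(k)]))
    counts = ends - starts
    lo = starts + (counts - 1) // 2
    hi = starts + counts // 2
    medians = 0.5 * (v[lo] + v[hi])
    return k[starts], medians, counts


def aggregate_medians(
    records: pd.DataFrame, role: str, min_depth: int = 1
) -> SampleKinetics:
    """Collapse per-read IPDs to the per-position median.

    The median (rather than the mean) is kept because it is robust to the
    heavy-tailed per-read IPD distribution, and using one value per position
    weights every occurrence of a motif equally regardless of local coverage.
    Positions with fewer than ``min_depth`` reads keep their depth but have a
    missing (NaN) median.  Even-sized groups use the mean of the two middle
    order statistics.
    """
    if records.empty:
        return SampleKinetics(role=role, table=pd.DataFrame(columns=MEDIAN_COLUMNS))
    contigs, contig_codes = np.unique(records["contig"].to_numpy(), return_inverse=True)
    strand_codes = (records["strand"].to_numpy() == "-").astype(np.int64)
    pos = records["position"].to_numpy(dtype=np.int64)
    span = int(pos.max()) + 1
    keys = (contig_codes * 2 + strand_codes) * span + pos
    uk, med, cnt = _grouped_medians(keys, records["ipd"].to_numpy(dtype=float))
    med = med.copy()
    med[cnt < min_depth] = np.nan
    table = pd.DataFrame(
        {
            "contig": contigs[uk // (2 * span)],
            "position": uk % span,
            "strand": np.where((uk // span) % 2 == 1, "-", "+"),
            "median_ipd": med,
            "depth": cnt,
        }
    )
    return SampleKinetics(role=role, table=table)


def downsample_to_coverage(
    records: pd.DataFrame,
    target_coverage: float,
    genome_length: int,
    seed: int,
) -> pd.DataFrame:
    """Subsample whole reads (by read_id, without replacement) to a target
    mean coverage.

    Coverage is total bases retained divided by ``genome_length``.  Sampling
    whole reads preserves within-read correlation of IPDs.  Deterministic for
    a given seed.
    """
    if target_coverage < 0:
        raise ValueError("target_coverage must be >= 0")
    if target_coverage == 0 or records.empty:
        return records.iloc[0:0].copy()
    achieved = len(records) / genome_length
    if target_coverage > achieved * (1 + 1e-9):
        raise ValueError(
            f"target coverage {target_coverage:g}X exceeds available "
            f"{achieved:g}X"
        )
    read_ids = records["read_id"].to_numpy()
    unique_ids = pd.unique(read_ids)
    n_keep = int(round(len(unique_ids) * target_coverage / achieved))
    n_keep = min(max(n_keep, 1), len(unique_ids))
    if n_keep == len(unique_ids):
        return records.copy()
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(unique_ids, size=n_keep, replace=False))
    return records[records["read_id"].isin(keep)].reset_index(drop=True)


def mix_contamination(
    native_records: pd.DataFrame,
    wga_records: pd.DataFrame,
    noise_fraction: float,
    seed: int,
    total_reads: int | None = None,
) -> pd.DataFrame:
    """Build a simulated "native" dataset containing ``noise_fraction`` WGA
    reads and ``1 - noise_fraction`` true native reads (by read count).

    WGA reads carry no modification signal, so mixing them in emulates
    contamination by unmodified (or foreign) DNA.  The kept WGA reads are
    relabeled with a ``wga:`` read-id prefix but are otherwise
    indistinguishable from native reads downstream.  Deterministic per seed.
    """
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError(f"noise_fraction must be in [0, 1], got {noise_fraction}")
    native_ids = pd.unique(native_records["read_id"].to_numpy()) if len(native_records) else np.array([], dtype=object)
    wga_ids = pd.unique(wga_records["read_id"].to_numpy()) if len(wga_records) else np.array([], dtype=object)
    if total_reads is None:
        total_reads = len(native_ids)
    n_wga = int(round(total_reads * noise_fraction))
    n_native = total_reads - n_wga
    if n_native > len(native_ids):
        raise ValueError(f"need {n_native} native reads, have {len(native_ids)}")
    if n_wga > len(wga_ids):
        raise ValueError(f"need {n_wga} WGA reads, have {len(wga_ids)}")
    rng = np.random.default_rng(seed)
    parts = []
    if n_native:
        keep = set(rng.choice(native_ids, size=n_native, replace=False))
        parts.append(native_records[native_records["read_id"].isin(keep)])
    if n_wga:
        keep = set(rng.choice(wga_ids, size=n_wga, replace=False))
        sub = wga_records[wga_records["read_id"].isin(keep)].copy()
        sub["read_id"] = "wga:" + sub["read_id"].astype(str)
        parts.append(sub)
    if not parts:
        return native_records.iloc[0:0].copy()
    return pd.concat(parts, ignore_index=True)
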