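"""Methylation-call I/O, read QC, CpG enumeration and per-site aggregation.

This module owns the per-read 5mC call table (the output of a signal-level
methylation caller) and everything computed directly from it: the read-level
quality filter, enumeration and panel numbering of CpG sites, aggregation of
per-read log-likelihood-ratio (LLR) calls into per-site methylation
frequencies with the clinical filters (ambiguous calls with ``|LLR| <
llr_cutoff`` discarded, sites with fewer than ``min_reads`` qualifying calls
dropped), window means over panel-index ranges, and the three-category
clinical binning of a methylation fraction.

Coordinates are 0-based half-open internally; CpG sites are reported at the
forward-strand C. Minus-strand calls are collapsed onto the plus-strand C
coordinate (a CpG is palindromic, both strands measure one site).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Column order of the per-read methylation-call TSV dialect.
METH_CALL_COLUMNS = [
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "log_lik_methylated",
    "log_lik_unmethylated",
    "num_calling_strands",
    "num_motifs",
    "sequence",
]

#: Column order of the per-site methylation-frequency TSV dialect.
METH_FREQ_COLUMNS = [
    "chromosome",
    "start",
    "end",
    "num_motifs_in_group",
    "called_sites",
    "called_sites_methylated",
    "methylated_frequency",
    "group_sequence",
]

METHYLATION_CATEGORIES = ("not_detected", "low", "detected")


class FormatError(ValueError):
    """A call/frequency table violates its dialect (bad header or row)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DomainError(ValueError):
    """A value fell outside its mathematical domain (e.g. a fraction)."""


@dataclass(frozen=True)
class MethFilterParams:
    """Per-call LLR magnitude cutoff and per-site minimum qualifying depth.

    A call is *qualifying* iff ``|llr| >= llr_cutoff`` and counted methylated
    iff ``llr >= +llr_cutoff``; a site is reported iff it accumulates at
    least ``min_reads`` qualifying calls.
    """

    llr_cutoff: float = 2.5
    min_reads: int = 10

    def __post_init__(self):
        if self.llr_cutoff <= 0:
            raise ValueError("llr_cutoff must be > 0")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


@dataclass(frozen=True)
class QCParams:
    """Read-level QC: both thresholds are strict ('higher than' / 'longer than')."""

    min_mean_q: float = 8.0
    min_length: int = 200

    def __post_init__(self):
        if self.min_mean_q < 0 or self.min_length < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass(frozen=True)
class ReadRecord:
    read_name: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_name}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )


@dataclass
class QCCounts:
    total: int = 0
    passed: int = 0
    failed_length: int = 0
    failed_quality: int = 0


@dataclass(frozen=True)
class RegionWindow:
    """An inclusive range of panel CpG indices (e.g. DMR2 = CpGs 70-81)."""

    name: str
    lo: int
    hi: int

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"window {self.name}: lo {self.lo} > hi {self.hi}")

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1


@dataclass(frozen=True)
class RegionMean:
    """Mean methylation over a window; ``mean is None`` when no site was usable."""

    mean: float | None
    n_sites_used: int

    @property
    def defined(self) -> bool:
        return self.mean is not None


@dataclass(frozen=True)
class MethylationBins:
    """Boundaries of the clinical 3-category readout.

    Defaults follow the 'not detected < 10%, low 10-30%, detected > 30%'
    convention with both boundary values in the 'low' band (the middle band
    is printed inclusively, the outer bands strictly).
    """

    low: float = 0.10
    high: float = 0.30
    low_inclusive: bool = True
    high_inclusive: bool = True


# ---------------------------------------------------------------------------
# read QC


def mean_read_quality(qualities: Sequence[int]) -> float:
    """Mean Phred quality of a read: -10*log10(mean per-base error probability)."""
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        return 0.0
    err = np.power(10.0, -q / 10.0)
    return float(-10.0 * math.log10(float(err.mean())))


def qc_filter_reads(
    reads: Iterable[ReadRecord], params: QCParams = QCParams()
) -> tuple[list[ReadRecord], QCCounts]:
    """Keep reads with mean quality > min_mean_q AND length > min_length.

    Both inequalities are strict. Returns the passing reads and counts of the
    rejection reasons (a read failing both is counted under length).
    """
    counts = QCCounts()
    passing: list[ReadRecord] = []
    for read in reads:
        counts.total += 1
        if len(read.sequence) <= params.min_length:
            counts.failed_length += 1
            continue
        if mean_read_quality(read.qualities) <= params.min_mean_q:
            counts.failed_quality += 1
            continue
        counts.passed += 1
        passing.append(read)
    return passing, counts


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file as ReadRecords (Biopython parser underneath)."""
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        try:
            yield ReadRecord(
                read_name=rec.id,
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
        except (KeyError, ValueError) as exc:  # pragma: no cover - defensive
            raise FormatError(f"malformed FASTQ record #{i}: {exc}") from exc


def qc_filter_fastq(
    path: str | Path, params: QCParams = QCParams()
) -> tuple[list[ReadRecord], QCCounts]:
    return qc_filter_reads(read_fastq(path), params)


# ---------------------------------------------------------------------------
# CpG enumeration


def enumerate_cpgs(
    sequence: str,
    interval: tuple[int, int] | None = None,
    chrom: str = "region",
    subregions: Sequence[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Enumerate forward-strand CG dinucleotides in a captured interval.

    Sites are numbered 1..N from the 5' end of the interval (``panel_index``)
    and reported 0-based at the C. Matching is case-insensitive; ambiguity
    codes (including N) never match. ``subregions`` optionally labels sites
    with (label, start, end) half-open intervals.

    Returns a DataFrame with columns chrom, start, panel_index[, subregion].
    """
    lo, hi = (0, len(sequence)) if interval is None else interval
    if lo < 0 or hi > len(sequence) or lo > hi:
        raise ValueError(f"interval [{lo},{hi}) outside sequence bounds")
    seq = sequence.upper()
    starts = [i for i in range(lo, hi - 1) if seq[i] == "C" and seq[i + 1] == "G"]
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": pd.array(starts, dtype=int),
            "panel_index": pd.array(range(1, len(starts) + 1), dtype=int),
        }
    )
    if subregions is not None:
        labels = pd.Series([pd.NA] * len(df), dtype="object")
        for name, s, e in subregions:
            labels[(df["start"] >= s) & (df["start"] < e)] = name
        df["subregion"] = labels
    return df


# ---------------------------------------------------------------------------
# aggregation


def _expand_motif_groups(calls: pd.DataFrame) -> pd.DataFrame:
    """Expand calls covering a group of num_motifs CpGs into one row per motif.

    Each motif in the group inherits the call's LLR (the caller emits one
    statistic for the whole group). Motif positions are recovered from the CG
    offsets inside the ``sequence`` context column.
    """
    single = calls[calls["num_motifs"] <= 1]
    multi = calls[calls["num_motifs"] > 1]
    if multi.empty:
        return calls
    rows = []
    for _, row in multi.iterrows():
        seq = str(row["sequence"]).upper()
        offsets = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
        if len(offsets) < int(row["num_motifs"]):
            raise FormatError(
                f"call at {row['chromosome']}:{row['start']} declares "
                f"{row['num_motifs']} motifs but its sequence context shows "
                f"{len(offsets)} CG occurrences"
            )
        offsets = offsets[: int(row["num_motifs"])]
        for off in offsets:
            new = row.copy()
            new["start"] = int(row["start"]) + (off - offsets[0])
            new["end"] = new["start"]
            new["num_motifs"] = 1
            rows.append(new)
    expanded = pd.DataFrame(rows, columns=calls.columns)
    return pd.concat([single, expanded], ignore_index=True)


def aggregate_site_frequency(
    calls: pd.DataFrame,
    params: MethFilterParams = MethFilterParams(),
    split_groups: bool = True,
) -> pd.DataFrame:
    """Aggregate per-read LLR calls into per-site methylation frequencies.

    A call qualifies iff ``|llr| >= llr_cutoff`` and is methylated iff
    ``llr >= +llr_cutoff``; ambiguous calls are excluded from numerator and
    denominator. A site is reported only when it has at least ``min_reads``
    qualifying calls. Calls grouping several motifs contribute the same state
    to every motif in the group when ``split_groups`` is set.

    Returns a frequency table in the METH_FREQ_COLUMNS dialect, sorted by
    (chromosome, start).
    """
    if calls.empty:
        return pd.DataFrame(columns=METH_FREQ_COLUMNS)
    calls = calls.copy()
    if split_groups:
        calls = _expand_motif_groups(calls)
    llr = calls["log_lik_ratio"].astype(float)
    qualifying = llr.abs() >= params.llr_cutoff
    q = calls[qualifying].copy()
    if q.empty:
        return pd.DataFrame(columns=METH_FREQ_COLUMNS)
    q["is_meth"] = (q["log_lik_ratio"].astype(float) >= params.llr_cutoff).astype(int)
    grouped = (
        q.groupby(["chromosome", "start"], sort=True)
        .agg(
            called_sites=("is_meth", "size"),
            called_sites_methylated=("is_meth", "sum"),
            group_sequence=("sequence", "first"),
        )
        .reset_index()
    )
    grouped = grouped[grouped["called_sites"] >= params.min_reads].copy()
    grouped["methylated_frequency"] = (
        grouped["called_sites_methylated"] / grouped["called_sites"]
    )
    grouped["end"] = grouped["start"]
    grouped["num_motifs_in_group"] = 1
    return grouped[METH_FREQ_COLUMNS].reset_index(drop=True)


def annotate_panel_index(freq: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Attach panel_index (and subregion, if present) to a frequency table.

    Joins on (chromosome, start) against an enumerate_cpgs table; frequency
    rows at positions absent from the site list are dropped.
    """
    cols = ["chrom", "start", "panel_index"] + (
        ["subregion"] if "subregion" in sites.columns else []
    )
    merged = freq.merge(
        sites[cols].rename(columns={"chrom": "chromosome"}),
        on=["chromosome", "start"],
        how="inner",
    )
    return merged.sort_values("panel_index").reset_index(drop=True)


def region_mean(freq: pd.DataFrame, window: RegionWindow) -> RegionMean:
    """Unweighted mean methylated_frequency over reported sites in a window.

    ``freq`` must carry a ``panel_index`` column (see annotate_panel_index).
    Zero usable sites yields an explicitly undefined mean, distinct from 0.
    """
    if "panel_index" not in freq.columns:
        raise ValueError("frequency table lacks panel_index; annotate it first")
    sel = freq[
        (freq["panel_index"] >= window.lo) & (freq["panel_index"] <= window.hi)
    ]
    sel = sel[sel["methylated_frequency"].notna()]
    if sel.empty:
        return RegionMean(mean=None, n_sites_used=0)
    return RegionMean(
        mean=float(sel["methylated_frequency"].mean()), n_sites_used=len(sel)
    )


def classify_methylation_level(
    freq: float, bins: MethylationBins = MethylationBins()
) -> str:
    """Bin a methylation fraction into not_detected / low / detected."""
    if not (0.0 <= freq <= 1.0) or not math.isfinite(freq):
        raise DomainError(f"methylation fraction {freq!r} outside [0, 1]")
    above_low = freq >= bins.low if bins.low_inclusive else freq > bins.low
    below_high = freq <= bins.high if bins.high_inclusive else freq < bins.high
    if not above_low:
        return "not_detected"
    if below_high:
        return "low"
    return "detected"


# ---------------------------------------------------------------------------
# TSV dialects


def _read_tsv(
    path: str | Path, columns: list[str], strict: bool, numeric: dict[str, type]
) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, missing header")
    header = lines[0].split("\t")
    if header != columns:
        raise FormatError(f"{path}: bad header {header!r}, expected {columns!r}", line=1)
    rows, skipped = [], 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(columns):
            if strict:
                raise FormatError(
                    f"{path}: expected {len(columns)} columns, found {len(fields)}",
                    line=lineno,
                )
            skipped += 1
            logger.warning("%s: skipping malformed line %d", path, lineno)
            continue
        rows.append(fields)
    df = pd.DataFrame(rows, columns=columns)
    for col, typ in numeric.items():
        df[col] = df[col].astype(typ)
    if skipped:
        logger.info("%s: %d malformed lines skipped", path, skipped)
    return df


_CALL_TYPES = {
    "start": int,
    "end": int,
    "log_lik_ratio": float,
    "log_lik_methylated": float,
    "log_lik_unmethylated": float,
    "num_calling_strands": int,
    "num_motifs": int,
}

_FREQ_TYPES = {
    "start": int,
    "end": int,
    "num_motifs_in_group": int,
    "called_sites": int,
    "called_sites_methylated": int,
    "methylated_frequency": float,
}


def read_meth_calls(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a per-read methylation-call TSV (strict: fail at first bad row)."""
    return _read_tsv(path, METH_CALL_COLUMNS, strict, _CALL_TYPES)


def write_meth_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, columns=METH_CALL_COLUMNS)


def read_meth_freq(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a per-site methylation-frequency TSV."""
    return _read_tsv(path, METH_FREQ_COLUMNS, strict, _FREQ_TYPES)


def write_meth_freq(freq: pd.DataFrame, path: str | Path) -> None:
    freq.to_csv(path, sep="\t", index=False, columns=METH_FREQ_COLUMNS)


def write_bed(sites: pd.DataFrame, path: str | Path) -> None:
    """Write CpG sites as 6-column BED (0-based half-open, score = panel index)."""
    with open(path, "w") as fh:
        for _, row in sites.iterrows():
            name = row.get("subregion", "cpg")
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['start'] + 2}\t"
                f"{name}\t{row['panel_index']}\t+\n"
            )
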