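"""Diploid SNV calling from base-count pileups at target loci.

The caller mirrors the gate settings of the long-read assay it re-implements
(candidate alt-allele frequency >= 0.15, candidate depth >= 10, ploidy 2,
CpG-aware candidate selection) but replaces signal-level re-evaluation with
a binomial genotype likelihood over {ref/ref, ref/alt, alt/alt} with
expected alt fractions {e, 1/2, 1-e}, where e = error_rate / 3 is the share
of substitution error directed at the alt base.

Also here: the advisory homopolymer-context flag (a 6-G run near one MGMT
locus makes its genotypes unreliable on older pore chemistry), tumor/normal
somatic classification, the cross-platform allele-frequency chi-squared
comparison, and a minimal VCF 4.2 writer/reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPES = ("ref/ref", "ref/alt", "alt/alt")
SOMATIC_STATUSES = ("somatic", "germline", "absent", "inconsistent")


class UndefinedTestError(ValueError):
    """A contingency-table margin is zero; the test statistic is undefined."""


@dataclass(frozen=True)
class VariantParams:
    min_candidate_frequency: float = 0.15
    min_candidate_depth: int = 10
    ploidy: int = 2
    error_rate: float = 0.05

    def __post_init__(self):
        if self.min_candidate_frequency <= 0 or self.min_candidate_depth <= 0:
            raise ValueError("candidate thresholds must be positive")
        if self.ploidy != 2:
            raise ValueError("only diploid calling (ploidy=2) is supported")
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")


@dataclass(frozen=True)
class GenotypeCall:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str | None
    genotype: str  # ref/ref, ref/alt, alt/alt, no_call
    allele_frequency: float
    depth: int
    quality: float  # log-likelihood margin best vs second-best genotype
    homopolymer_flag: bool = False
    no_call_reason: str | None = None

    @property
    def is_variant(self) -> bool:
        return self.genotype in ("ref/alt", "alt/alt")


def _counts_from_column(col) -> tuple[str, int, str, dict[str, int]]:
    """Accept a pileup DataFrame row (or mapping) and pull out the fields."""
    counts = {b: int(col[b]) for b in "ACGT"}
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative base count")
    return str(col["chrom"]), int(col["pos"]), str(col["ref"]).upper(), counts


def genotype_log_likelihoods(
    alt_count: int, depth: int, error_rate: float
) -> np.ndarray:
    """Binomial log-likelihoods of {ref/ref, ref/alt, alt/alt}.

    Expected alt fraction per genotype: e, 1/2, 1-e with e = error_rate/3.
    """
    e = error_rate / 3.0
    probs = np.array([e, 0.5, 1.0 - e])
    return stats.binom.logpmf(alt_count, depth, probs)


def call_genotype(
    column,
    params: VariantParams = VariantParams(),
    cpg_positions: Sequence[int] | set[int] | None = None,
) -> GenotypeCall:
    """Call a diploid genotype at one pileup column.

    Gates: no_call below min_candidate_depth; the candidate alt is the most
    frequent non-reference base and is only considered when its frequency
    reaches min_candidate_frequency. When the position is a known panel CpG,
    C->T (and G->A, the minus-strand image) candidates are excluded as
    methylation-context artifacts before the most frequent alt is chosen.
    """
    chrom, pos, ref, counts = _counts_from_column(column)
    depth = sum(counts.values())
    if depth < params.min_candidate_depth:
        return GenotypeCall(
            chrom, pos, ref, None, "no_call", 0.0, depth, 0.0,
            no_call_reason="insufficient_depth",
        )
    excluded: set[str] = set()
    if cpg_positions is not None and pos in set(cpg_positions):
        if ref == "C":
            excluded.add("T")
        elif ref == "G":
            excluded.add("A")
    candidates = [
        b for b in "ACGT" if b != ref and b not in excluded and counts[b] > 0
    ]
    if not candidates:
        return GenotypeCall(chrom, pos, ref, None, "ref/ref", 0.0, depth, np.inf)
    alt = max(candidates, key=lambda b: (counts[b], -"ACGT".index(b)))
    af = counts[alt] / depth
    if af < params.min_candidate_frequency:
        return GenotypeCall(chrom, pos, ref, alt, "ref/ref", af, depth, np.inf)
    ll = genotype_log_likelihoods(counts[alt], depth, params.error_rate)
    order = np.argsort(ll)[::-1]
    best = int(order[0])
    quality = float(ll[order[0]] - ll[order[1]])
    return GenotypeCall(
        chrom, pos, ref, alt, GENOTYPES[best], af, depth, quality
    )


def flag_homopolymer(reference: str, pos: int, min_run: int = 5) -> bool:
    """True iff pos lies within or immediately adjacent to a base run >= min_run."""
    if pos < 0 or pos >= len(reference):
        raise ValueError(f"position {pos} outside reference of length {len(reference)}")
    seq = reference.upper()
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run and (i - 1) <= pos <= j:
            return True
        i = j
    return False


def call_region(
    pileup: pd.DataFrame,
    reference: str,
    params: VariantParams = VariantParams(),
    cpg_positions: Sequence[int] | set[int] | None = None,
    hp_min_run: int = 5,
) -> list[GenotypeCall]:
    """Scan every pileup column; return variant calls (genotype != ref/ref).

    Each emitted call carries the advisory homopolymer-context flag; the
    flag never suppresses a call.
    """
    if len(pileup) and int(pileup["pos"].max()) >= len(reference):
        raise ValueError("pileup extends past the reference sequence")
    positions = pileup["pos"].to_numpy()
    if len(positions) > 1 and (np.diff(positions) < 0).any():
        raise ValueError("pileup columns must be sorted by position")
    ref_upper = reference.upper()
    variants: list[GenotypeCall] = []
    cpg_set = set(cpg_positions) if cpg_positions is not None else None
    for row in pileup.itertuples(index=False):
        d = row._asdict()
        if ref_upper[int(d["pos"])] != str(d["ref"]).upper():
            raise ValueError(
                f"pileup ref {d['ref']!r} at {d['pos']} disagrees with reference"
            )
        call = call_genotype(d, params, cpg_set)
        if call.is_variant:
            variants.append(
                GenotypeCall(
                    **{
                        **call.__dict__,
                        "homopolymer_flag": flag_homopolymer(
                            reference, call.pos, hp_min_run
                        ),
                    }
                )
            )
    return variants


def classify_somatic(tumor: GenotypeCall, normal: GenotypeCall) -> str:
    """Somatic = variant in tumor, absent from the matched normal.

    Both variant -> germline; tumor reference -> absent; any no_call ->
    inconsistent (the pair cannot be interpreted).
    """
    if (tumor.chrom, tumor.pos) != (normal.chrom, normal.pos):
        raise ValueError(
            f"locus mismatch: tumor {tumor.chrom}:{tumor.pos} vs "
            f"normal {normal.chrom}:{normal.pos}"
        )
    if tumor.genotype == "no_call" or normal.genotype == "no_call":
        return "inconsistent"
    if tumor.is_variant and not normal.is_variant:
        return "somatic"
    if tumor.is_variant and normal.is_variant:
        return "germline"
    return "absent"


@dataclass(frozen=True)
class AFComparison:
    statistic: float
    p_value: float
    delta_af: float


def compare_allele_frequencies(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> AFComparison:
    """Pearson chi-squared (no continuity correction) on a 2x2 ref/alt table.

    Also reports the absolute difference in alt-allele frequency between the
    two platforms. Identical tables give statistic 0, p = 1.
    """
    table = np.array([counts_a, counts_b], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedTestError("a margin of the 2x2 table is zero")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    af_a = counts_a[1] / sum(counts_a)
    af_b = counts_b[1] / sum(counts_b)
    return AFComparison(
        statistic=float(stat), p_value=float(p), delta_af=abs(af_a - af_b)
    )


# ---------------------------------------------------------------------------
# minimal VCF 4.2

_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##FILTER=<ID=PASS,Description="All filters passed">',
    '##FILTER=<ID=homopolymer,Description="Within or adjacent to a homopolymer run">',
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele frequency">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]

_GT_CODE = {"ref/ref": "0/0", "ref/alt": "0/1", "alt/alt": "1/1"}
_GT_DECODE = {v: k for k, v in _GT_CODE.items()}


def write_vcf(
    calls: Iterable[GenotypeCall], path: str | Path, sample: str = "SAMPLE"
) -> None:
    """Write variant calls as minimal VCF 4.2 (POS is 1-based)."""
    with open(path, "w") as fh:
        for line in _VCF_HEADER:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for c in calls:
            filt = "homopolymer" if c.homopolymer_flag else "PASS"
            qual = f"{c.quality:.2f}" if np.isfinite(c.quality) else "."
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt or '.'}\t{qual}\t"
                f"{filt}\tAF={c.allele_frequency:.6g};DP={c.depth}\tGT\t"
                f"{_GT_CODE.get(c.genotype, './.')}\n"
            )


def read_vcf(path: str | Path) -> list[GenotypeCall]:
    """Read back the module's own minimal VCF dialect."""
    calls: list[GenotypeCall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alt, qual, filt, info, _fmt, gt = fields[:10]
            info_d = dict(kv.split("=") for kv in info.split(";"))
            calls.append(
                GenotypeCall(
                    chrom=chrom,
                    pos=int(pos) - 1,
                    ref=ref,
                    alt=None if alt == "." else alt,
                    genotype=_GT_DECODE.get(gt, "no_call"),
                    allele_frequency=float(info_d["AF"]),
                    depth=int(info_d["DP"]),
                    quality=np.inf if qual == "." else float(qual),
                    homopolymer_flag=(filt == "homopolymer"),
                )
            )
    return calls
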