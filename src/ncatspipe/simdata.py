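"""Seeded synthetic inputs for the targeted methylation + genotyping pipeline.

Everything downstream of alignment is emulated here: the two linear
methylation standards (an 897-bp molecule carrying 52 CpGs, sequenced at
~100% and ~0% methylation), the three-locus capture panel (MGMT
promoter/exon 1 with 98 CpGs and a 5' portion of intron 1 with 121 CpGs,
plus IDH1 and IDH2 exon 4 amplicons), per-read CpG log-likelihood-ratio
(LLR) calls, noisy base pileups with homopolymer-inflated substitution
error, and a sample cohort in which exon-1 methylation suppresses and
intron-1 methylation raises MGMT expression.

All generators are deterministic for a fixed spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .methio import METH_CALL_COLUMNS, enumerate_cpgs

BASES = np.array(["A", "C", "G", "T"])


class InfeasibleSpecError(ValueError):
    """The requested sequence geometry cannot be realised."""


class ConsistencyError(ValueError):
    """A variant plan disagrees with the reference it is planted in."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class StandardSpec:
    """A linear methylation-standard molecule."""

    length_bp: int = 897
    n_cpg: int = 52
    true_meth_level: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.length_bp < 1 or self.n_cpg < 0:
            raise ValueError("length_bp must be >= 1 and n_cpg >= 0")
        if not 0.0 <= self.true_meth_level <= 1.0:
            raise ValueError("true_meth_level must be in [0, 1]")


@dataclass(frozen=True)
class LlrModel:
    """Signed-Gaussian model of per-read LLR calls.

    A truly methylated call draws +|N(mu_meth, sigma)|, an unmethylated call
    -|N(mu_unmeth, sigma)|; the sign is then flipped with probability
    miscall_rate. Positive LLR is evidence for 5mC, so the downstream 2.5
    magnitude cutoff separates confident from ambiguous calls.
    """

    mu_meth: float = 4.0
    mu_unmeth: float = 4.0
    sigma: float = 1.5
    miscall_rate: float = 0.03

    def __post_init__(self):
        if min(self.mu_meth, self.mu_unmeth, self.sigma) <= 0:
            raise ValueError("mu_meth, mu_unmeth and sigma must be > 0")
        if not 0.0 <= self.miscall_rate < 0.5:
            raise ValueError("miscall_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class ErrorProfile:
    """Nanopore-like base error rates; substitutions inflate in homopolymers."""

    sub_rate: float = 0.05
    ins_rate: float = 0.03
    del_rate: float = 0.03
    homopolymer_sub_multiplier: float = 2.0
    homopolymer_min_run: int = 5

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ValueError("sub + ins + del rates must sum below 1")
        if self.homopolymer_sub_multiplier < 1.0:
            raise ValueError("homopolymer multiplier must be >= 1")


@dataclass(frozen=True)
class SubregionSpec:
    label: str
    length_bp: int
    n_cpg: int


@dataclass(frozen=True)
class VariantSpec:
    region: str
    offset: int  # 0-based within the region
    ref_base: str
    alt_base: str
    allele_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError("allele_fraction must be in [0, 1]")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")


@dataclass(frozen=True)
class RegionSpec:
    name: str
    subregions: tuple[SubregionSpec, ...]
    # motifs forced verbatim into the reference, e.g. a mutation hotspot codon
    forced_motifs: tuple[tuple[int, str], ...] = ()

    @property
    def length_bp(self) -> int:
        return sum(s.length_bp for s in self.subregions)


@dataclass(frozen=True)
class PanelSpec:
    regions: tuple[RegionSpec, ...]
    variant_plan: tuple[VariantSpec, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """A cohort with exon-methylation-repressed, intron-methylation-boosted expression.

    Per sample a latent exon-1 methylation mean is drawn uniformly; the
    intron-1 mean mirrors it (``1 - exon_mean``), reproducing the
    anti-correlated exon/intron block structure seen across samples in the
    assay this emulates. Each CpG scatters around its sample-level block
    mean; log2 relative expression is ``intercept + exon_effect * exon_mean
    + intron_effect * intron_mean + N(0, noise_sd)``. Truth is recorded for
    recovery tests.
    """

    n_samples: int = 8
    n_exon_cpgs: int = 12
    n_intron_cpgs: int = 34
    exon_effect: float = -1.0
    intron_effect: float = 1.0
    noise_sd: float = 0.3
    cpg_sd: float = 0.05
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4 for meaningful correlation")
        if self.noise_sd < 0 or self.cpg_sd < 0:
            raise ValueError("noise_sd and cpg_sd must be >= 0")


# ---------------------------------------------------------------------------
# sequence generation


def _place_disjoint_cpgs(length: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly sample n disjoint CG start positions in a length-bp sequence.

    Bijection with n distinct values from range(length - n): p_i = w_i + i.
    """
    if 2 * n > length:
        raise InfeasibleSpecError(
            f"{n} disjoint CpGs cannot fit in {length} bp (need >= {2 * n})"
        )
    if n == 0:
        return np.array([], dtype=int)
    w = np.sort(rng.choice(length - n, size=n, replace=False))
    return w + np.arange(n)


def _fill_and_fix(seq: np.ndarray, free: np.ndarray, rng: np.random.Generator) -> None:
    """Fill free positions with random bases, then break accidental CGs.

    The C of any CG not created deliberately is rewritten to A (which can
    never create a new CG), so a single left-to-right pass suffices.
    """
    seq[free] = rng.choice(BASES, size=int(free.sum()))
    protected = ~free
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            if protected[i] and protected[i + 1]:
                continue
            if not protected[i]:
                seq[i] = "A"
            else:
                seq[i + 1] = "T"


def random_sequence_with_cpgs(
    length: int,
    n_cpg: int,
    rng: np.random.Generator,
    forced_motifs: Sequence[tuple[int, str]] = (),
    max_attempts: int = 1000,
) -> tuple[str, np.ndarray]:
    """Random sequence with *exactly* n_cpg forward-strand CG dinucleotides.

    ``forced_motifs`` are substrings written verbatim at fixed offsets (for
    planting mutation-hotspot codons); CGs inside forced motifs count toward
    n_cpg. Returns (sequence, sorted CpG start positions, 0-based).
    """
    forced = np.zeros(length, dtype=bool)
    template = np.full(length, "", dtype="<U1")
    for off, motif in forced_motifs:
        if off < 0 or off + len(motif) > length:
            raise InfeasibleSpecError(f"forced motif at {off} outside sequence")
        for j, b in enumerate(motif.upper()):
            template[off + j] = b
            forced[off + j] = True
    forced_cg = [
        i
        for i in range(length - 1)
        if forced[i] and forced[i + 1] and template[i] == "C" and template[i + 1] == "G"
    ]
    n_free_cpg = n_cpg - len(forced_cg)
    if n_free_cpg < 0:
        raise InfeasibleSpecError(
            f"forced motifs already contain {len(forced_cg)} CpGs > n_cpg={n_cpg}"
        )

    if not forced_motifs:
        starts = _place_disjoint_cpgs(length, n_cpg, rng)
        seq = np.full(length, "", dtype="<U1")
        designated = np.zeros(length, dtype=bool)
        seq[starts] = "C"
        seq[starts + 1] = "G"
        designated[starts] = True
        designated[starts + 1] = True
        free = ~designated
        _fill_and_fix(seq, free, rng)
        return "".join(seq), starts

    # with forced motifs: rejection-sample the free CpG placement
    for _ in range(max_attempts):
        seq = template.copy()
        designated = forced.copy()
        slots = [
            i
            for i in range(length - 1)
            if not designated[i] and not designated[i + 1]
        ]
        chosen: list[int] = []
        slots_arr = np.array(slots, dtype=int)
        order = rng.permutation(len(slots_arr))
        taken = np.zeros(length, dtype=bool)
        for idx in order:
            if len(chosen) == n_free_cpg:
                break
            p = int(slots_arr[idx])
            if taken[p] or taken[p + 1]:
                continue
            chosen.append(p)
            taken[p] = taken[p + 1] = True
        if len(chosen) < n_free_cpg:
            continue
        starts = np.sort(np.array(chosen, dtype=int))
        seq[starts] = "C"
        seq[starts + 1] = "G"
        designated[starts] = True
        designated[starts + 1] = True
        _fill_and_fix(seq, ~designated, rng)
        s = "".join(seq)
        all_starts = sorted(set(starts.tolist()) | set(forced_cg))
        # verify exactness (forced/filler junctions can in principle clash)
        observed = [i for i in range(length - 1) if s[i : i + 2] == "CG"]
        if observed == list(all_starts) and len(observed) == n_cpg:
            return s, np.array(all_starts, dtype=int)
    raise InfeasibleSpecError(
        f"could not place {n_cpg} CpGs in {length} bp around forced motifs"
    )


@dataclass(frozen=True)
class Standard:
    sequence: str
    cpg_starts: np.ndarray
    truth: np.ndarray  # per-CpG true methylation fraction
    name: str = "standard"


def generate_standard(spec: StandardSpec, name: str = "standard") -> Standard:
    """Generate a methylation-standard molecule with exact CpG geometry."""
    rng = np.random.default_rng(spec.seed)
    seq, starts = random_sequence_with_cpgs(spec.length_bp, spec.n_cpg, rng)
    truth = np.full(len(starts), spec.true_meth_level, dtype=float)
    return Standard(sequence=seq, cpg_starts=starts, truth=truth, name=name)


# ---------------------------------------------------------------------------
# per-read methylation calls


def simulate_meth_calls(
    sites: Sequence[int] | np.ndarray,
    truth: Sequence[float] | np.ndarray | float,
    depth: int,
    model: LlrModel = LlrModel(),
    seed: int = 0,
    chrom: str = "region",
    sequence: str | None = None,
    read_prefix: str = "read",
) -> pd.DataFrame:
    """Simulate `depth` per-read LLR calls at each CpG site.

    Each simulated molecule (read) covers every site of the region; its true
    state at a site is Bernoulli(truth[site]); the emitted LLR is the signed
    Gaussian draw of ``model`` with its sign flipped at miscall_rate. Output
    is a DataFrame in the per-read call TSV dialect.
    """
    sites = np.asarray(sites, dtype=int)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if sites.size == 0:
        return pd.DataFrame(columns=METH_CALL_COLUMNS)
    truth = np.broadcast_to(np.asarray(truth, dtype=float), sites.shape)
    if truth.min() < 0 or truth.max() > 1:
        raise ValueError("truth values must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sites = sites.size
    state = rng.random((depth, n_sites)) < truth  # True = methylated
    mu = np.where(state, model.mu_meth, model.mu_unmeth)
    magnitude = np.abs(rng.normal(mu, model.sigma))
    sign = np.where(state, 1.0, -1.0)
    flip = rng.random((depth, n_sites)) < model.miscall_rate
    sign = np.where(flip, -sign, sign)
    llr = sign * magnitude

    if sequence is not None:
        contexts = [
            sequence[max(0, s - 5) : s + 7] for s in sites
        ]
    else:
        contexts = ["NNNNNCGNNNNN"] * n_sites
    read_names = np.array([f"{read_prefix}_{i:06d}" for i in range(depth)])
    df = pd.DataFrame(
        {
            "chromosome": chrom,
            "strand": "+",
            "start": np.tile(sites, depth),
            "end": np.tile(sites, depth),
            "read_name": np.repeat(read_names, n_sites),
            "log_lik_ratio": llr.ravel(),
            "log_lik_methylated": llr.ravel() / 2.0,
            "log_lik_unmethylated": -llr.ravel() / 2.0,
            "num_calling_strands": 1,
            "num_motifs": 1,
            "sequence": np.tile(np.array(contexts, dtype=object), depth),
        }
    )
    return df[METH_CALL_COLUMNS]


# ---------------------------------------------------------------------------
# pileups


def homopolymer_run_lengths(sequence: str) -> np.ndarray:
    """Per-position length of the maximal single-base run containing it."""
    n = len(sequence)
    runs = np.zeros(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        runs[i:j] = j - i
        i = j
    return runs


def simulate_pileup(
    sequence: str,
    variant_plan: Sequence[VariantSpec],
    depth: int,
    profile: ErrorProfile = ErrorProfile(),
    seed: int = 0,
    chrom: str = "region",
) -> pd.DataFrame:
    """Simulate a per-position base-count pileup over a region.

    Per read and position: the true base is the planted alt with probability
    allele_fraction (else reference); the read then drops the base with
    del_rate or substitutes it (uniformly to the 3 other bases) with
    sub_rate, inflated by the homopolymer multiplier inside runs of length
    >= homopolymer_min_run. Insertions do not alter column counts.

    Returns a DataFrame with columns chrom, pos, ref, A, C, G, T, depth.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    variants = {}
    for v in variant_plan:
        if v.offset < 0 or v.offset >= n:
            raise ConsistencyError(f"variant offset {v.offset} outside region")
        if seq[v.offset] != v.ref_base.upper():
            raise ConsistencyError(
                f"variant at offset {v.offset}: plan ref {v.ref_base!r} != "
                f"reference base {seq[v.offset]!r}"
            )
        variants[v.offset] = v
    rng = np.random.default_rng(seed)
    runs = homopolymer_run_lengths(seq)
    base_index = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros((n, 4), dtype=int)
    for pos in range(n):
        ref_i = base_index[seq[pos]]
        true = np.full(depth, ref_i, dtype=int)
        if pos in variants:
            v = variants[pos]
            alt_i = base_index[v.alt_base.upper()]
            true[rng.random(depth) < v.allele_fraction] = alt_i
        kept = rng.random(depth) >= profile.del_rate
        true = true[kept]
        sub_p = profile.sub_rate
        if runs[pos] >= profile.homopolymer_min_run:
            sub_p = min(0.75, sub_p * profile.homopolymer_sub_multiplier)
        sub = rng.random(true.size) < sub_p
        if sub.any():
            # uniform among the 3 other bases
            shift = rng.integers(1, 4, size=int(sub.sum()))
            true[sub] = (true[sub] + shift) % 4
        counts[pos] = np.bincount(true, minlength=4)
    df = pd.DataFrame(counts, columns=["A", "C", "G", "T"])
    df.insert(0, "ref", list(seq))
    df.insert(0, "pos", np.arange(n))
    df.insert(0, "chrom", chrom)
    df["depth"] = df[["A", "C", "G", "T"]].sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# panel


#: IDH hotspot codons planted into the synthetic exon-4 amplicons.
IDH1_CODON132 = "CGT"  # R132; G>A... the assayed mutant is CGT -> GGT
IDH2_CODON172 = "AGG"  # R172; the assayed mutant is AGG -> AAG
IDH1_CODON132_OFFSET = 150
IDH2_CODON172_OFFSET = 150


def mgmt_panel_spec(seed: int = 0, variant_plan: Sequence[VariantSpec] = ()) -> PanelSpec:
    """Default three-locus capture panel.

    The MGMT region carries 98 CpGs in the promoter/exon-1 subregion and 121
    in the 5' portion of intron 1 (the study's capture geometry); IDH1/IDH2
    exon-4 amplicons carry their wild-type hotspot codons at a fixed offset.
    Lengths are synthetic choices giving realistic CpG density.
    """
    regions = (
        RegionSpec(
            name="MGMT",
            subregions=(
                SubregionSpec("promoter_exon1", 1000, 98),
                SubregionSpec("intron1", 1400, 121),
            ),
        ),
        RegionSpec(
            name="IDH1",
            subregions=(SubregionSpec("idh1", 400, 1),),
            forced_motifs=((IDH1_CODON132_OFFSET, IDH1_CODON132),),
        ),
        RegionSpec(
            name="IDH2",
            subregions=(SubregionSpec("idh2", 400, 0),),
            forced_motifs=((IDH2_CODON172_OFFSET, IDH2_CODON172),),
        ),
    )
    return PanelSpec(regions=regions, variant_plan=tuple(variant_plan), seed=seed)


@dataclass(frozen=True)
class PanelReference:
    sequences: dict[str, str]
    subregions: pd.DataFrame  # chrom, start, end, label
    cpg_sites: pd.DataFrame  # chrom, start, panel_index, subregion
    variant_plan: tuple[VariantSpec, ...]


def generate_panel(spec: PanelSpec) -> PanelReference:
    """Generate panel reference sequences honoring subregion CpG counts exactly."""
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    sub_rows = []
    site_frames = []
    for region in spec.regions:
        parts = []
        offset = 0
        boundaries = []
        for sub in region.subregions:
            boundaries.append((sub.label, offset, offset + sub.length_bp))
            forced = [
                (f_off - offset, motif)
                for f_off, motif in region.forced_motifs
                if offset <= f_off < offset + sub.length_bp
            ]
            sub_seq, _ = random_sequence_with_cpgs(
                sub.length_bp, sub.n_cpg, rng, forced_motifs=forced
            )
            parts.append(sub_seq)
            offset += sub.length_bp
        seq = "".join(parts)
        # a junction can create a spurious CG (filler C | filler G): break it
        chars = np.array(list(seq))
        pos = 0
        for sub in region.subregions[:-1]:
            pos += sub.length_bp
            if chars[pos - 1] == "C" and chars[pos] == "G":
                chars[pos - 1] = "A"
        seq = "".join(chars)
        sequences[region.name] = seq
        for label, s, e in boundaries:
            sub_rows.append({"chrom": region.name, "start": s, "end": e, "label": label})
        sites = enumerate_cpgs(seq, chrom=region.name, subregions=boundaries)
        site_frames.append(sites)
        for sub in region.subregions:
            got = int((sites["subregion"] == sub.label).sum())
            if got != sub.n_cpg:  # pragma: no cover - generator contract
                raise InfeasibleSpecError(
                    f"{region.name}/{sub.label}: generated {got} CpGs, "
                    f"spec demands {sub.n_cpg}"
                )
    for v in spec.variant_plan:
        if v.region not in sequences:
            raise ConsistencyError(f"variant region {v.region!r} not in panel")
        if sequences[v.region][v.offset] != v.ref_base.upper():
            raise ConsistencyError(
                f"{v.region}:{v.offset}: plan ref {v.ref_base!r} != reference "
                f"{sequences[v.region][v.offset]!r}"
            )
    return PanelReference(
        sequences=sequences,
        subregions=pd.DataFrame(sub_rows),
        cpg_sites=pd.concat(site_frames, ignore_index=True),
        variant_plan=spec.variant_plan,
    )


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class Cohort:
    """Samples x CpGs methylation matrix with expression and labels."""

    meth: pd.DataFrame  # rows: sample_id; columns: cpg_### fractions
    expression: pd.Series  # relative expression (linear scale, > 0)
    labels: pd.DataFrame  # sample_type, tmz_status
    cpg_info: pd.DataFrame  # column, panel_index, subregion
    truth: dict


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a methylation-expression-coupled cohort (see CohortSpec)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    exon_mean = rng.uniform(0.1, 0.9, size=n)
    intron_mean = 1.0 - exon_mean
    exon = np.clip(
        rng.normal(exon_mean[:, None], spec.cpg_sd, size=(n, spec.n_exon_cpgs)), 0, 1
    )
    intron = np.clip(
        rng.normal(intron_mean[:, None], spec.cpg_sd, size=(n, spec.n_intron_cpgs)),
        0,
        1,
    )
    log2_expr = (
        spec.intercept
        + spec.exon_effect * exon_mean
        + spec.intron_effect * intron_mean
        + rng.normal(0.0, spec.noise_sd, size=n)
    )
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    # exon CpGs use the clinically relevant DMR2 indices 70..81; intron CpGs
    # continue the panel numbering from 99 upward
    exon_idx = list(range(70, 70 + spec.n_exon_cpgs))
    intron_idx = list(range(99, 99 + spec.n_intron_cpgs))
    columns = [f"cpg{i:03d}" for i in exon_idx + intron_idx]
    meth = pd.DataFrame(
        np.hstack([exon, intron]), index=sample_ids, columns=columns
    )
    meth.index.name = "sample_id"
    expression = pd.Series(
        np.power(2.0, log2_expr), index=sample_ids, name="relative_expression"
    )
    labels = pd.DataFrame(
        {
            "sample_type": ["cell_line" if i < n // 2 else "tumor" for i in range(n)],
            "tmz_status": ["unknown"] * n,
        },
        index=sample_ids,
    )
    cpg_info = pd.DataFrame(
        {
            "column": columns,
            "panel_index": exon_idx + intron_idx,
            "subregion": ["promoter_exon1"] * spec.n_exon_cpgs
            + ["intron1"] * spec.n_intron_cpgs,
        }
    )
    truth = {
        "exon_mean": exon_mean,
        "intron_mean": intron_mean,
        "exon_effect": spec.exon_effect,
        "intron_effect": spec.intron_effect,
        "log2_expression": log2_expr,
    }
    return Cohort(
        meth=meth, expression=expression, labels=labels, cpg_info=cpg_info, truth=truth
    )
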