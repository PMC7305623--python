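"""Limit-of-detection by read subsampling: in-silico methylation mixtures.

Re-creates the depth-titration experiment: reads are drawn without
replacement from a fully methylated and a fully unmethylated call pool to
build mixtures at intermediate methylation levels, each mixture is
aggregated with the clinical filters, and replicate dispersion (CV) plus
pairwise Welch t-tests with Bonferroni correction decide the smallest depth
at which the canonical levels {0, 25, 50, 75, 100}% separate — the
theoretical limit of detection (20X in the source assay).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import methio
from .methio import MethFilterParams
from .simdata import LlrModel, Standard, simulate_meth_calls


class PoolShortfallError(ValueError):
    """A pool holds fewer calls than the requested subsampling depth."""


@dataclass(frozen=True)
class MixtureScenario:
    """Design of the titration: levels x depths grid, replicated."""

    levels: tuple[float, ...] = (0.0, 0.10, 0.25, 0.50, 0.75, 1.0)
    depths: tuple[int, ...] = (5, 10, 15, 20, 25, 50)
    n_replicates: int = 100
    alpha: float = 0.05
    seed: int = 0
    #: levels entering the pairwise distinguishability claim (the 10% mixture
    #: is titrated but excluded from the 5-level separation statement)
    test_levels: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75, 1.0)

    def __post_init__(self):
        if any(not 0.0 <= p <= 1.0 for p in self.levels):
            raise ValueError("levels must be in [0, 1]")
        if any(d < 1 for d in self.depths):
            raise ValueError("depths must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not set(self.test_levels) <= set(self.levels):
            raise ValueError("test_levels must be a subset of levels")


@dataclass
class LODResult:
    """Outcome of the titration.

    ``replicates``: one row per (level, depth, replicate) with the replicate
    statistic (mean frequency across reported CpGs). ``cells``: per-cell
    mean, SD and CV (CV missing when the mean is 0). ``pairwise``: per depth,
    Welch t-tests between all test-level pairs with Bonferroni-adjusted
    p-values. ``lod_depth``: smallest depth at which every pair separates at
    alpha (None if no depth does).
    """

    replicates: pd.DataFrame
    cells: pd.DataFrame
    pairwise: pd.DataFrame
    lod_depth: int | None
    scenario: MixtureScenario = field(repr=False, default=None)


def _pool_arrays(pool: pd.DataFrame) -> dict[tuple[str, int], np.ndarray]:
    """Index a call-pool DataFrame by site -> array of LLRs."""
    out: dict[tuple[str, int], np.ndarray] = {}
    for (chrom, start), grp in pool.groupby(["chromosome", "start"], sort=True):
        out[(chrom, start)] = grp["log_lik_ratio"].to_numpy(dtype=float)
    return out


def make_mixture(
    pool0: pd.DataFrame,
    pool100: pd.DataFrame,
    p: float,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a mixture call table at methylation level p and a given depth.

    Per site, round(p * depth) calls are sampled without replacement from
    the 100%-methylated pool and the remainder from the 0% pool.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    k100 = int(round(p * depth))
    k0 = depth - k100
    a0 = pool0 if isinstance(pool0, dict) else _pool_arrays(pool0)
    a100 = pool100 if isinstance(pool100, dict) else _pool_arrays(pool100)
    sites = sorted(set(a0) | set(a100))
    rows_chrom, rows_start, rows_llr, rows_read = [], [], [], []
    for site in sites:
        llr0 = a0.get(site, np.empty(0))
        llr100 = a100.get(site, np.empty(0))
        if len(llr0) < k0:
            raise PoolShortfallError(
                f"site {site[0]}:{site[1]}: 0% pool has {len(llr0)} calls, "
                f"need {k0}"
            )
        if len(llr100) < k100:
            raise PoolShortfallError(
                f"site {site[0]}:{site[1]}: 100% pool has {len(llr100)} calls, "
                f"need {k100}"
            )
        pick0 = rng.choice(len(llr0), size=k0, replace=False) if k0 else []
        pick100 = rng.choice(len(llr100), size=k100, replace=False) if k100 else []
        llrs = np.concatenate([llr0[pick0], llr100[pick100]])
        rows_chrom.extend([site[0]] * depth)
        rows_start.extend([site[1]] * depth)
        rows_llr.extend(llrs.tolist())
        rows_read.extend(
            [f"p0_{i}" for i in np.atleast_1d(pick0)]
            + [f"p100_{i}" for i in np.atleast_1d(pick100)]
        )
    llr_arr = np.asarray(rows_llr, dtype=float)
    df = pd.DataFrame(
        {
            "chromosome": rows_chrom,
            "strand": "+",
            "start": rows_start,
            "end": rows_start,
            "read_name": rows_read,
            "log_lik_ratio": llr_arr,
            "log_lik_methylated": llr_arr / 2.0,
            "log_lik_unmethylated": -llr_arr / 2.0,
            "num_calling_strands": 1,
            "num_motifs": 1,
            "sequence": "NNNNNCGNNNNN",
        }
    )
    return df[methio.METH_CALL_COLUMNS]


def simulate_pools(
    standard: Standard,
    model: LlrModel = LlrModel(),
    pool_depth: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the 0% and 100% methylated call pools of a standard."""
    ss = np.random.SeedSequence(seed)
    s0, s100 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    pool0 = simulate_meth_calls(
        standard.cpg_starts, 0.0, pool_depth, model, seed=s0,
        chrom=standard.name, sequence=standard.sequence,
    )
    pool100 = simulate_meth_calls(
        standard.cpg_starts, 1.0, pool_depth, model, seed=s100,
        chrom=standard.name, sequence=standard.sequence,
    )
    return pool0, pool100


def bonferroni(p_raw: np.ndarray | float, n_tests: int) -> np.ndarray | float:
    """Bonferroni adjustment: min(1, p * n_tests); never below the raw p."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * n_tests)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test, guarded for the zero-variance degenerate case."""
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return (np.inf, 0.0) if np.mean(a) != np.mean(b) else (0.0, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def binomial_cv_oracle(p_obs: float, depth: float, n_sites: float) -> float:
    """Closed-form CV of the replicate statistic under pure binomial sampling.

    The replicate statistic averages n_sites independent per-site frequencies
    each estimated from ~depth calls: CV = sqrt((1-p)/(p * depth * n_sites)).
    """
    if p_obs <= 0:
        return np.nan
    return float(np.sqrt((1.0 - p_obs) / (p_obs * depth * n_sites)))


def titrate(
    scenario: MixtureScenario,
    pool0: pd.DataFrame,
    pool100: pd.DataFrame,
    params: MethFilterParams = MethFilterParams(),
) -> LODResult:
    """Run the full mixture/depth titration.

    Each (level, depth) cell runs n_replicates independent mixtures (child
    RNG streams fanned out from the master seed); each mixture is aggregated
    with the clinical filters and summarised by its mean frequency across
    reported CpGs. Replicates with every site filtered out are recorded as
    unusable rather than silently skipped.
    """
    master = np.random.SeedSequence(scenario.seed)
    children = iter(master.spawn(len(scenario.levels) * len(scenario.depths)))
    idx0, idx100 = _pool_arrays(pool0), _pool_arrays(pool100)
    rep_rows = []
    for level in scenario.levels:
        for depth in scenario.depths:
            cell_ss = next(children)
            streams = cell_ss.spawn(scenario.n_replicates)
            for rep, child in enumerate(streams):
                rng = np.random.default_rng(child)
                mix = make_mixture(idx0, idx100, level, depth, seed=rng)
                freq = methio.aggregate_site_frequency(mix, params)
                usable = not freq.empty
                stat = (
                    float(freq["methylated_frequency"].mean()) if usable else np.nan
                )
                rep_rows.append(
                    {
                        "level": level,
                        "depth": depth,
                        "replicate": rep,
                        "mean_frequency": stat,
                        "n_sites": len(freq),
                        "usable": usable,
                    }
                )
    replicates = pd.DataFrame(rep_rows)

    cell_rows = []
    for (level, depth), grp in replicates.groupby(["level", "depth"]):
        ok = grp[grp["usable"]]
        usable_cell = len(ok) >= 2
        mean = float(ok["mean_frequency"].mean()) if usable_cell else np.nan
        sd = float(ok["mean_frequency"].std(ddof=1)) if usable_cell else np.nan
        cv = sd / mean if usable_cell and mean > 0 else np.nan
        cell_rows.append(
            {
                "level": level,
                "depth": depth,
                "n_usable": len(ok),
                "usable": usable_cell,
                "mean": mean,
                "sd": sd,
                "cv": cv,
            }
        )
    cells = pd.DataFrame(cell_rows)

    pair_rows = []
    tl = sorted(scenario.test_levels)
    pairs = [(a, b) for i, a in enumerate(tl) for b in tl[i + 1 :]]
    for depth in scenario.depths:
        sub = replicates[(replicates["depth"] == depth) & replicates["usable"]]
        groups: Mapping[float, np.ndarray] = {
            lvl: sub[sub["level"] == lvl]["mean_frequency"].to_numpy()
            for lvl in tl
        }
        for a, b in pairs:
            xa, xb = groups[a], groups[b]
            if len(xa) < 2 or len(xb) < 2:
                t, p_raw = np.nan, np.nan
            else:
                t, p_raw = _welch(xa, xb)
            pair_rows.append(
                {
                    "depth": depth,
                    "level_a": a,
                    "level_b": b,
                    "t": t,
                    "p_raw": p_raw,
                    "p_adj": float(bonferroni(p_raw, len(pairs)))
                    if np.isfinite(p_raw)
                    else np.nan,
                }
            )
    pairwise = pd.DataFrame(pair_rows)

    lod_depth = None
    for depth in sorted(scenario.depths):
        sub = pairwise[pairwise["depth"] == depth]
        if len(sub) == len(pairs) and sub["p_adj"].notna().all() and (
            sub["p_adj"] < scenario.alpha
        ).all():
            lod_depth = int(depth)
            break
    return LODResult(
        replicates=replicates,
        cells=cells,
        pairwise=pairwise,
        lod_depth=lod_depth,
        scenario=scenario,
    )
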