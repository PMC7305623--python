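"""End-to-end pipeline: simulate -> aggregate -> genotype -> report.

One YAML config drives the whole run: the panel geometry, every module's
parameter block (all defaulting to the assay's stated settings) and a master
seed fanned out into per-stage, per-sample child streams, so any stage can
be re-run independently yet reproducibly. Each sample yields a clinical-style
report (IDH1/2 genotype + allele frequency + somatic status, MGMT exon-1 and
intron-1 methylation means with the 3-category readout) in JSON and rendered
text, plus a run manifest recording every effective parameter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import assoc, genotype, methio, simdata
from .genotype import VariantParams
from .methio import MethFilterParams, MethylationBins, QCParams, RegionWindow
from .simdata import ErrorProfile, LlrModel, VariantSpec, mgmt_panel_spec

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration (carries the key path)."""


#: named variants available to sample specs (region, offset, ref, alt)
KNOWN_VARIANTS = {
    "idh1_r132": ("IDH1", simdata.IDH1_CODON132_OFFSET, "C", "G"),
    "idh2_r172": ("IDH2", simdata.IDH2_CODON172_OFFSET + 1, "G", "A"),
}


@dataclass
class SampleConfig:
    sample_id: str
    exon_meth: float = 0.5
    intron_meth: float = 0.5
    meth_depth: int = 50
    pileup_depth: int = 200
    variants: list[dict] = field(default_factory=list)
    matched_normal: bool = False
    germline_variants: list[dict] = field(default_factory=list)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "run"
    qc: QCParams = field(default_factory=QCParams)
    meth_filter: MethFilterParams = field(default_factory=MethFilterParams)
    llr_model: LlrModel = field(default_factory=LlrModel)
    error_profile: ErrorProfile = field(default_factory=ErrorProfile)
    variant_params: VariantParams = field(default_factory=VariantParams)
    bins: MethylationBins = field(default_factory=MethylationBins)
    dmr2: RegionWindow = field(default_factory=lambda: RegionWindow("DMR2", 70, 81))
    panel_seed: int = 0
    samples: list[SampleConfig] = field(default_factory=list)


_SECTION_TYPES = {
    "qc": QCParams,
    "meth_filter": MethFilterParams,
    "llr_model": LlrModel,
    "error_profile": ErrorProfile,
    "variant_params": VariantParams,
    "bins": MethylationBins,
}


def _build_section(cls, block: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    for key in block:
        if key not in names:
            raise ConfigError(f"{path}.{key}: unknown key")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline YAML config (fails fast on unknown keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    cfg = PipelineConfig()
    known = {
        "seed", "out_dir", "panel_seed", "samples", "dmr2",
        *_SECTION_TYPES.keys(),
    }
    for key in raw:
        if key not in known:
            raise ConfigError(f"{key}: unknown config key")
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.panel_seed = int(raw.get("panel_seed", cfg.panel_seed))
    cfg.out_dir = str(raw.get("out_dir", cfg.out_dir))
    for key, cls in _SECTION_TYPES.items():
        if key in raw:
            setattr(cfg, key, _build_section(cls, raw[key] or {}, key))
    if "dmr2" in raw:
        block = raw["dmr2"]
        try:
            cfg.dmr2 = RegionWindow("DMR2", int(block["lo"]), int(block["hi"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"dmr2: {exc}") from exc
    for i, sample in enumerate(raw.get("samples", [])):
        path = f"samples[{i}]"
        if "sample_id" not in sample:
            raise ConfigError(f"{path}.sample_id: required")
        names = {f.name for f in dataclasses.fields(SampleConfig)}
        for key in sample:
            if key not in names:
                raise ConfigError(f"{path}.{key}: unknown key")
        cfg.samples.append(SampleConfig(**sample))
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    out: dict[str, Any] = {
        "seed": cfg.seed,
        "panel_seed": cfg.panel_seed,
        "out_dir": cfg.out_dir,
        "dmr2": {"lo": cfg.dmr2.lo, "hi": cfg.dmr2.hi},
    }
    for key, _ in _SECTION_TYPES.items():
        out[key] = dataclasses.asdict(getattr(cfg, key))
    out["samples"] = [dataclasses.asdict(s) for s in cfg.samples]
    return out


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def _resolve_variants(entries: list[dict], path: str) -> list[VariantSpec]:
    specs = []
    for j, entry in enumerate(entries):
        if "name" in entry:
            if entry["name"] not in KNOWN_VARIANTS:
                raise ConfigError(f"{path}[{j}].name: unknown variant {entry['name']!r}")
            region, off, ref, alt = KNOWN_VARIANTS[entry["name"]]
            af = float(entry.get("allele_fraction", 0.5))
            specs.append(VariantSpec(region, off, ref, alt, af))
        else:
            try:
                specs.append(
                    VariantSpec(
                        region=entry["region"],
                        offset=int(entry["offset"]),
                        ref_base=entry["ref_base"],
                        alt_base=entry["alt_base"],
                        allele_fraction=float(entry.get("allele_fraction", 0.5)),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"{path}[{j}]: {exc}") from exc
    return specs


def _child_seed(master: int, *tags: str) -> int:
    """Stable per-stage, per-sample seed below 2**31 (process-independent)."""
    digest = hashlib.sha256("|".join(tags).encode()).digest()
    h = np.random.SeedSequence(
        [master, int.from_bytes(digest[:4], "little")]
    )
    return int(h.generate_state(1)[0] % (2**31))


def _sample_report(
    cfg: PipelineConfig,
    panel: simdata.PanelReference,
    sample: SampleConfig,
    out_dir: Path,
) -> dict:
    """Simulate, aggregate and genotype one sample; return its report dict."""
    report: dict[str, Any] = {"sample_id": sample.sample_id}
    mgmt_sites = panel.cpg_sites[panel.cpg_sites["chrom"] == "MGMT"]
    truth = np.where(
        mgmt_sites["subregion"] == "promoter_exon1",
        sample.exon_meth,
        sample.intron_meth,
    )
    calls = simdata.simulate_meth_calls(
        mgmt_sites["start"].to_numpy(),
        truth,
        sample.meth_depth,
        cfg.llr_model,
        seed=_child_seed(cfg.seed, "meth", sample.sample_id),
        chrom="MGMT",
        sequence=panel.sequences["MGMT"],
    )
    calls_path = out_dir / f"{sample.sample_id}.calls.tsv"
    methio.write_meth_calls(calls, calls_path)
    freq = methio.aggregate_site_frequency(calls, cfg.meth_filter)
    freq_path = out_dir / f"{sample.sample_id}.methfreq.tsv"
    methio.write_meth_freq(freq, freq_path)
    annotated = methio.annotate_panel_index(freq, panel.cpg_sites)
    logger.info(
        "sample=%s stage=methfreq calls_in=%d sites_reported=%d sites_filtered=%d",
        sample.sample_id, len(calls), len(freq),
        len(mgmt_sites) - len(freq),
    )

    exon_window = cfg.dmr2
    n_mgmt = int(len(mgmt_sites))
    n_prom = int((mgmt_sites["subregion"] == "promoter_exon1").sum())
    intron_window = RegionWindow("intron1", n_prom + 1, n_mgmt)
    exon_mean = methio.region_mean(annotated, exon_window)
    intron_mean = methio.region_mean(annotated, intron_window)
    report["mgmt"] = {
        "exon1_dmr2_mean": exon_mean.mean,
        "exon1_dmr2_n_sites": exon_mean.n_sites_used,
        "exon1_dmr2_category": (
            methio.classify_methylation_level(exon_mean.mean, cfg.bins)
            if exon_mean.defined
            else "unusable"
        ),
        "intron1_mean": intron_mean.mean,
        "intron1_n_sites": intron_mean.n_sites_used,
        "sites_reported": int(len(freq)),
        "usable": exon_mean.defined,
    }

    variant_specs = _resolve_variants(sample.variants, f"{sample.sample_id}.variants")
    germline_specs = _resolve_variants(
        sample.germline_variants, f"{sample.sample_id}.germline_variants"
    )
    report["genotype"] = {}
    all_tumor_calls: list[genotype.GenotypeCall] = []
    for region_name in ("IDH1", "IDH2"):
        seq = panel.sequences[region_name]
        plan = [
            v for v in variant_specs + germline_specs if v.region == region_name
        ]
        pileup = simdata.simulate_pileup(
            seq,
            plan,
            sample.pileup_depth,
            cfg.error_profile,
            seed=_child_seed(cfg.seed, "pileup", sample.sample_id, region_name),
            chrom=region_name,
        )
        cpg_pos = panel.cpg_sites[panel.cpg_sites["chrom"] == region_name][
            "start"
        ].tolist()
        variants = genotype.call_region(
            pileup, seq, cfg.variant_params, cpg_positions=cpg_pos
        )
        all_tumor_calls.extend(variants)
        logger.info(
            "sample=%s stage=genotype region=%s columns=%d variants=%d",
            sample.sample_id, region_name, len(pileup), len(variants),
        )
        somatic_status = {}
        if sample.matched_normal:
            normal_plan = [v for v in germline_specs if v.region == region_name]
            normal_pileup = simdata.simulate_pileup(
                seq,
                normal_plan,
                sample.pileup_depth,
                cfg.error_profile,
                seed=_child_seed(cfg.seed, "normal", sample.sample_id, region_name),
                chrom=region_name,
            )
            for v in variants:
                ncall = genotype.call_genotype(
                    normal_pileup.iloc[v.pos].to_dict(), cfg.variant_params
                )
                somatic_status[f"{region_name}:{v.pos}"] = genotype.classify_somatic(
                    v, ncall
                )
        report["genotype"][region_name] = {
            "variants": [
                {
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "genotype": v.genotype,
                    "allele_frequency": round(v.allele_frequency, 4),
                    "homopolymer_flag": v.homopolymer_flag,
                    "somatic_status": somatic_status.get(f"{region_name}:{v.pos}"),
                }
                for v in variants
            ]
        }
    genotype.write_vcf(
        all_tumor_calls, out_dir / f"{sample.sample_id}.vcf", sample.sample_id
    )
    report["qc"] = {
        "meth_depth": sample.meth_depth,
        "pileup_depth": sample.pileup_depth,
    }
    return report


def render_report(report: dict) -> str:
    """Human-readable one-sample summary."""
    lines = [f"Sample {report['sample_id']}"]
    m = report["mgmt"]
    if m["usable"]:
        lines.append(
            f"  MGMT exon-1 (DMR2) methylation: {m['exon1_dmr2_mean'] * 100:.1f}% "
            f"({m['exon1_dmr2_category']}, {m['exon1_dmr2_n_sites']} CpGs)"
        )
        intron = m["intron1_mean"]
        lines.append(
            "  MGMT intron-1 methylation: "
            + (f"{intron * 100:.1f}%" if intron is not None else "unusable")
            + f" ({m['intron1_n_sites']} CpGs)"
        )
    else:
        lines.append("  MGMT methylation: unusable (all CpGs filtered)")
    for region, block in report["genotype"].items():
        if not block["variants"]:
            lines.append(f"  {region}: wild type")
        for v in block["variants"]:
            flag = " [homopolymer]" if v["homopolymer_flag"] else ""
            som = f", {v['somatic_status']}" if v.get("somatic_status") else ""
            lines.append(
                f"  {region} {v['ref']}>{v['alt']} at offset {v['pos']}: "
                f"{v['genotype']}, AF {v['allele_frequency']:.2f}{som}{flag}"
            )
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline; returns the run manifest.

    Per-sample failures are logged and recorded without aborting the other
    samples. Outputs: per-sample call/frequency TSVs, VCF, report JSON and
    text, plus manifest.json.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = simdata.generate_panel(mgmt_panel_spec(seed=cfg.panel_seed))
    simdata.write_fasta(panel.sequences, out / "panel.fasta")
    methio.write_bed(panel.cpg_sites, out / "cpg_sites.bed")
    reports, failures = [], []
    for sample in cfg.samples:
        try:
            report = _sample_report(cfg, panel, sample, out)
            reports.append(report)
            with open(out / f"{sample.sample_id}.report.json", "w") as fh:
                json.dump(report, fh, indent=2)
            with open(out / f"{sample.sample_id}.report.txt", "w") as fh:
                fh.write(render_report(report))
        except Exception as exc:  # noqa: BLE001 - isolate per-sample failure
            logger.error("sample=%s failed: %s", sample.sample_id, exc)
            failures.append({"sample_id": sample.sample_id, "error": str(exc)})
    manifest = {
        "config": config_to_dict(cfg),
        "n_samples": len(cfg.samples),
        "n_completed": len(reports),
        "failures": failures,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
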