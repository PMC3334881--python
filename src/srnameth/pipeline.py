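"""End-to-end orchestration: generate -> treat -> map/classify -> enrich
-> trim/tail -> target scan, with a YAML config, a run manifest and a
plain-text report.

All randomness derives from a single top-level seed, fanned out with
fixed per-stage offsets so stages can be re-run in isolation. Identical
config and seed give byte-identical outputs. The report only formats
numbers already present in the stage tables; it recomputes nothing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd
import yaml

from . import __version__, abundance, io, mapping, pairing, simulate, tailing
from .model import ReferenceSet

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: per-stage seed offsets (all randomness flows from config seed + offset)
SEED_OFFSETS = {"reference": 0, "library": 1, "beta_elimination": 2}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "reference": {},          # ReferenceSpec field overrides, or {"fasta":..., "gff3":...}
    "library": {
        "n_species": 50,
        "copy_mean": 20.0,
        "size_min": 18,
        "size_max": 28,
        "classes": {},        # per-class ClassSim field overrides
    },
    "beta_elimination": {"p_meth": 1.0, "p_unmeth": 0.1},
    "classify": {"min_prefix": 15},
    "enrich": {"threshold": 0.0},
    "scan": {"min_complementarity": 0.69, "max_bulges": 0},
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base and path == "":
            raise ConfigError(f"unknown config section {key!r}")
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            out[key] = _merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def validate_config(config: Optional[dict]) -> dict:
    """Fill defaults and sanity-check a config mapping."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if not isinstance(cfg["seed"], int) or cfg["seed"] < 0:
        raise ConfigError("seed must be a non-negative integer")
    be = cfg["beta_elimination"]
    if not 0.0 <= be["p_unmeth"] <= be["p_meth"] <= 1.0:
        raise ConfigError("beta_elimination requires 0 <= p_unmeth <= p_meth <= 1")
    ref = cfg["reference"]
    if "fasta" in ref:
        if not Path(ref["fasta"]).exists():
            raise ConfigError(f"reference fasta not found: {ref['fasta']}")
        if "gff3" in ref and not Path(ref["gff3"]).exists():
            raise ConfigError(f"reference gff3 not found: {ref['gff3']}")
    else:
        valid = {f.name for f in dataclasses.fields(simulate.ReferenceSpec)}
        unknown = set(ref) - valid
        if unknown:
            raise ConfigError(f"unknown reference spec fields: {sorted(unknown)}")
    if cfg["classify"]["min_prefix"] < 15:
        raise ConfigError("classify.min_prefix must be >= 15")
    return cfg


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _library_config(cfg: dict) -> simulate.LibraryConfig:
    lib = cfg["library"]
    classes = simulate.default_class_sims(
        n_species=lib["n_species"], copy_mean=lib["copy_mean"]
    )
    for cls, overrides in lib["classes"].items():
        if cls not in classes:
            raise ConfigError(f"unknown read class in library.classes: {cls!r}")
        classes[cls] = dataclasses.replace(classes[cls], **overrides)
    return simulate.LibraryConfig(
        classes=classes,
        size_min=lib["size_min"],
        size_max=lib["size_max"],
        p_meth=cfg["beta_elimination"]["p_meth"],
        p_unmeth=cfg["beta_elimination"]["p_unmeth"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_reference(cfg: dict) -> ReferenceSet:
    ref_cfg = cfg["reference"]
    if "fasta" in ref_cfg:
        return io.read_reference(ref_cfg["fasta"], ref_cfg.get("gff3"))
    spec = simulate.ReferenceSpec(**ref_cfg)
    return simulate.build_reference(spec, seed=cfg["seed"] + SEED_OFFSETS["reference"])


def run_pipeline(config: Union[dict, PathLike], outdir: PathLike) -> Path:
    """Run every stage and write tables, report and manifest to ``outdir``."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    logger.info("stage reference")
    ref = make_reference(cfg)
    io.write_reference_fasta(ref, out / "reference.fa")
    io.write_gff3(ref, out / "features.gff3")
    io.write_bed(ref, out / "features.bed")
    counts["features"] = len(ref.features)

    logger.info("stage simulate")
    lib_cfg = _library_config(cfg)
    untreated = simulate.simulate_library(
        ref, lib_cfg, seed=cfg["seed"] + SEED_OFFSETS["library"]
    )
    io.write_library(untreated, out / "untreated.fa")
    io.write_truth(untreated, out / "untreated.truth.tsv")
    counts["untreated_species"] = len(untreated)
    counts["untreated_copies"] = sum(r.count for r in untreated)

    logger.info("stage beta-elimination")
    be = cfg["beta_elimination"]
    treated = simulate.apply_beta_elimination(
        untreated,
        p_meth=be["p_meth"],
        p_unmeth=be["p_unmeth"],
        seed=cfg["seed"] + SEED_OFFSETS["beta_elimination"],
    )
    io.write_library(treated, out / "treated.fa")
    counts["treated_species"] = len(treated)
    counts["treated_copies"] = sum(r.count for r in treated)

    logger.info("stage map/classify")
    min_prefix = cfg["classify"]["min_prefix"]
    asg_u, aln_u = mapping.classify_library(untreated, ref, min_prefix=min_prefix)
    asg_t, _ = mapping.classify_library(treated, ref, min_prefix=min_prefix)
    pd.DataFrame(
        {"read_id": list(asg_u), "class": list(asg_u.values())}
    ).to_csv(out / "class_untreated.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"read_id": list(asg_t), "class": list(asg_t.values())}
    ).to_csv(out / "class_treated.tsv", sep="\t", index=False)
    profile = mapping.size_firstnt_profile(
        untreated, size_min=cfg["library"]["size_min"], size_max=cfg["library"]["size_max"]
    )
    profile.to_csv(out / "size_profile.tsv", sep="\t")
    xfeats = ref.features_of_class("xcluster_locus")
    if xfeats:
        feat = xfeats[0]
        all_alns = [a for alns in aln_u.values() for a in alns]
        track = mapping.coverage_track(
            all_alns, feat, {r.read_id: r.count for r in untreated}
        )
        with open(out / "xcluster_coverage.bedgraph", "w") as fh:
            for i, value in enumerate(track):
                if value:
                    fh.write(
                        f"{feat.contig}\t{feat.start + i}\t{feat.start + i + 1}\t{value}\n"
                    )

    logger.info("stage enrichment")
    table = abundance.class_ratio_table(
        treated, untreated, asg_t, asg_u, threshold=cfg["enrich"]["threshold"]
    )
    table.to_csv(out / "class_ratio.tsv", sep="\t")
    fc_u = abundance.feature_copy_counts(untreated, aln_u, ref.features)
    asg_t_alns = mapping.classify_library(treated, ref, min_prefix=min_prefix)[1]
    fc_t = abundance.feature_copy_counts(treated, asg_t_alns, ref.features)
    enr = abundance.feature_enrichment(
        fc_t,
        fc_u,
        total_treated=max(abundance.mapped_total(treated, asg_t), 1),
        total_untreated=max(abundance.mapped_total(untreated, asg_u), 1),
        threshold=cfg["enrich"]["threshold"],
    )
    pd.DataFrame([dataclasses.asdict(e) for e in enr]).to_csv(
        out / "feature_enrichment.tsv", sep="\t", index=False
    )

    logger.info("stage trim/tail")
    calls, unplaced = tailing.call_library(untreated, ref, min_prefix=min_prefix)
    counts["unplaced_reads"] = len(unplaced)
    pd.DataFrame(
        [dataclasses.asdict(c) for c in calls.values()]
    ).to_csv(out / "tail_calls.tsv", sep="\t", index=False)
    tailing.tail_table(calls, untreated, asg_u).to_csv(
        out / "tail_proportions.tsv", sep="\t"
    )
    tailing.tail_composition(calls, untreated).to_csv(
        out / "tail_composition.tsv", sep="\t"
    )

    logger.info("stage target scan")
    scan_rows = []
    if xfeats and ref.features_of_class("trigger_locus"):
        guide = simulate.trigger_guide(ref)
        transcript = simulate.xcluster_transcript(ref)
        sites = pairing.scan_transcript(
            guide,
            transcript,
            min_complementarity=cfg["scan"]["min_complementarity"],
            max_bulges=cfg["scan"]["max_bulges"],
            guide_id="trigger-26g",
            target_id="xcluster",
        )
        for site in sites:
            scan_rows.append(
                {
                    "guide_id": site.guide_id,
                    "target_id": site.target_id,
                    "window_start": site.window_start,
                    "window_end": site.window_end,
                    "states": site.state_string,
                    "complementarity": site.complementarity,
                    "complementarity_wc_only": site.complementarity_wc,
                    "predicted_call": site.predicted_call,
                }
            )
    pd.DataFrame(
        scan_rows,
        columns=[
            "guide_id",
            "target_id",
            "window_start",
            "window_end",
            "states",
            "complementarity",
            "complementarity_wc_only",
            "predicted_call",
        ],
    ).to_csv(out / "target_sites.tsv", sep="\t", index=False)
    counts["target_sites"] = len(scan_rows)

    manifest = {
        "version": __version__,
        "config": cfg,
        "seeds": {stage: cfg["seed"] + off for stage, off in SEED_OFFSETS.items()},
        "counts": counts,
        "digests": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix != ".json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    (out / "report.txt").write_text(summarize(out))
    return out


def summarize(outdir: PathLike) -> str:
    """Format a human-readable report from the stage tables.

    Every number is read back from a stage TSV; nothing is recomputed.
    """
    out = Path(outdir)
    lines = ["small RNA methylation-enrichment run summary", "=" * 44, ""]

    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"package version {manifest['version']}, seed {manifest['config']['seed']}")
        for key, value in sorted(manifest["counts"].items()):
            lines.append(f"  {key}: {value}")
        lines.append("")

    ratio_path = out / "class_ratio.tsv"
    if ratio_path.exists():
        table = pd.read_csv(ratio_path, sep="\t", index_col=0)
        if not table.empty:
            lines.append("beta-elimination class enrichment (treated/untreated RPM):")
            for cls, row in table.iterrows():
                lines.append(
                    f"  {cls:<18} ratio {row['ratio']:8.3f}  log2 {row['log2_ratio']:+7.3f}"
                    f"  {row['status']}"
                )
            lines.append("")

    tail_path = out / "tail_proportions.tsv"
    if tail_path.exists():
        table = pd.read_csv(tail_path, sep="\t", index_col=0)
        if not table.empty:
            lines.append("3' untemplated tailing by class (placed copies):")
            for cls, row in table.iterrows():
                lines.append(
                    f"  {cls:<18} tailed {row['tailed_proportion']:6.3f}"
                    f"  trimmed {row['trimmed_proportion']:6.3f}"
                )
            lines.append("")

    sites_path = out / "target_sites.tsv"
    if sites_path.exists():
        table = pd.read_csv(sites_path, sep="\t")
        lines.append(f"trigger-guide target sites on the X-cluster: {len(table)}")
        for _, row in table.iterrows():
            lines.append(
                f"  {row['window_start']:>6}-{row['window_end']:<6}"
                f" complementarity {row['complementarity']:.3f} ({row['predicted_call']})"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
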