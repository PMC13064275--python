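"""End-to-end orchestration: generate/ingest -> decontaminate -> normalize ->
diversity -> core/Venn -> assembly -> networks -> report.

All numeric outputs are written as TSV with fixed float formatting so that
identical configurations yield byte-identical files. A single global seed
is expanded into per-stage seeds by a fixed counter scheme
(``stage_seed = (seed * 97 + stage_index) mod (2^31 - 1)``) so stages can
be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import core_venn as cv
from . import diversity as dv
from . import io_preprocess as iop
from . import networks as nw
from .synthetic_cohort import SimConfig, simulate_cohort

_FLOAT_FMT = "%.10g"

_THRESHOLD_RANGES = {
    "core_prevalence": (0, 1),
    "network_prevalence": (0, 1),
    "r_threshold": (0, 1),
    "rc_threshold": (0, 1),
    "css_quantile": (0, 1),
    "blank_prevalence_min": (0, 1),
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Thresholds follow the emulated study design: core genus prevalence
    0.8, network core ASV prevalence 0.5, |r| 0.3, |betaNTI| 2,
    |RCbray| 0.95."""

    sim: SimConfig | None = None
    table: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    core_prevalence: float = 0.8
    network_prevalence: float = 0.5
    r_threshold: float = 0.3
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    blank_prevalence_min: float = 0.5
    ratio_min: float = 1.0
    css_quantile: float = 0.5
    n_null: int = 999
    n_perm: int = 999
    network_sites: tuple[str, ...] = ("oropharynx", "BAL")
    seed: int = 1
    out_dir: str = "results/pipeline"

    def validate(self) -> None:
        has_paths = any([self.table, self.metadata, self.taxonomy, self.tree])
        if self.sim is not None and has_paths:
            raise ConfigError("config must give either input paths or a sim block, not both")
        if self.sim is None and not has_paths:
            raise ConfigError("config must give input paths or a sim block")
        for key, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ConfigError(f"{key} = {v} outside permitted range [{lo}, {hi}]")
        if self.bnti_threshold <= 0:
            raise ConfigError("bnti_threshold must be positive")

    def stage_seed(self, stage_index: int) -> int:
        return (self.seed * 97 + stage_index) % (2**31 - 1)


def validate_config(path) -> PipelineConfig:
    """Load a YAML config, injecting defaults and rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "sim" in raw and raw["sim"] is not None:
        sim_raw = raw["sim"]
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown sim config keys: {sorted(sim_unknown)}")
        if "sites" in sim_raw:
            sim_raw["sites"] = tuple(sim_raw["sites"])
        raw["sim"] = SimConfig(**sim_raw)
    if "network_sites" in raw:
        raw["network_sites"] = tuple(raw["network_sites"])
    cfg = PipelineConfig(**raw)
    try:
        cfg.validate()
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    dropped_samples: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)

    def add_stage(self, name: str, n_rows: int, files: list[str],
                  warnings: list[str] | None = None, skipped: bool = False) -> None:
        self.stages.append({
            "stage": name, "rows": int(n_rows), "files": files,
            "warnings": warnings or [], "skipped": skipped,
        })
        self.files.extend(files)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> str:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)
    return path.name


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run every analysis stage; identical configs give byte-identical outputs."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(params={
        k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
        for k, v in dataclasses.asdict(cfg).items()
    })

    # -- stage 0: inputs ----------------------------------------------------
    try:
        if cfg.sim is not None:
            counts, meta, tree, taxonomy, truth = simulate_cohort(cfg.sim)
        else:
            counts = iop.read_feature_table(cfg.table)
            meta = iop.read_metadata(cfg.metadata)
            taxonomy = iop.read_taxonomy(cfg.taxonomy)
            import skbio
            tree = skbio.TreeNode.read(str(cfg.tree), convert_underscores=False)
            truth = None
        meta = meta.loc[counts.index]
        files = [_write(counts.T.rename_axis("ASV_ID"), out / "counts_raw.tsv")]
        report.add_stage("input", len(counts), files)
    except Exception as exc:  # noqa: BLE001
        raise StageError("input", exc) from exc

    # -- stage 1: decontamination ------------------------------------------
    blank_ids = list(meta.index[meta["group"] == "blank"])
    try:
        if blank_ids:
            cleaned, rep = iop.remove_contaminants(
                counts, blank_ids,
                blank_prevalence_min=cfg.blank_prevalence_min,
                ratio_min=cfg.ratio_min,
            )
            for b in blank_ids:
                report.dropped_samples.append({"sample_id": b, "reason": "blank control"})
            files = [_write(rep.evidence.rename_axis("taxon_id"), out / "contaminant_report.tsv")]
            (out / "contaminants.json").write_text(
                json.dumps({"removed": rep.removed_taxon_ids, "rule": rep.rule}, indent=2))
            files.append("contaminants.json")
            report.add_stage("decontaminate", len(cleaned), files)
        else:
            cleaned = counts
            report.add_stage("decontaminate", len(cleaned), [], skipped=True,
                            warnings=["no blank samples: decontamination skipped"])
        meta_bio = meta.loc[cleaned.index]
    except Exception as exc:  # noqa: BLE001
        raise StageError("decontaminate", exc) from exc

    # -- stage 2: normalization + genus aggregation -------------------------
    try:
        empty = cleaned.index[cleaned.sum(axis=1) == 0]
        for s in empty:
            report.dropped_samples.append({"sample_id": s, "reason": "zero total count"})
        cleaned = cleaned.drop(index=empty)
        meta_bio = meta_bio.loc[cleaned.index]
        norm = iop.css_normalize(cleaned, quantile_l=cfg.css_quantile)
        genus_counts = iop.aggregate_genus(cleaned, taxonomy)
        genus_norm = iop.css_normalize(genus_counts, quantile_l=cfg.css_quantile)
        files = [
            _write(norm.values.T.rename_axis("ASV_ID"), out / "css_normalized.tsv"),
            _write(norm.scaling_factors.to_frame().rename_axis("sample_id"),
                   out / "css_scaling_factors.tsv"),
            _write(genus_counts.T.rename_axis("genus"), out / "genus_counts.tsv"),
        ]
        report.add_stage("normalize", len(norm.values), files)
    except Exception as exc:  # noqa: BLE001
        raise StageError("normalize", exc) from exc

    # -- stage 3: diversity --------------------------------------------------
    try:
        warnings: list[str] = []
        alpha = pd.DataFrame({
            "observed_richness": cleaned.apply(dv.observed_richness, axis=1),
            "pielou_evenness": cleaned.apply(dv.pielou_evenness, axis=1),
        }).join(meta_bio[["subject_id", "site", "group"]])
        bc = dv.bray_curtis(norm.values)
        wu = dv.weighted_unifrac(cleaned, tree, normalized=True)
        perm_site = dv.permanova(
            wu, meta_bio["site"].values, strata=meta_bio["subject_id"].values,
            n_perm=cfg.n_perm, seed=cfg.stage_seed(3))
        perm_rows = [{"factor": "site", "strata": "subject_id",
                      **dataclasses.asdict(perm_site)}]
        for site, sub in meta_bio.groupby("site"):
            if sub["group"].nunique() < 2:
                continue
            subwu = wu.filter(list(sub.index))
            try:
                pr = dv.permanova(subwu, sub["group"].values, strata=None,
                                  n_perm=cfg.n_perm, seed=cfg.stage_seed(3))
                perm_rows.append({"factor": f"group@{site}", "strata": None,
                                  **dataclasses.asdict(pr)})
            except ValueError as e:
                warnings.append(f"permanova group@{site}: {e}")
        indiv, w1 = dv.individuality(wu, meta_bio)
        recov, w2 = dv.recovery_trajectory(bc, meta_bio, baseline_group="NS")
        spd, spd_info = dv.site_pair_distance(wu, meta_bio, "oropharynx", "BAL")
        lfc = dv.logfold_to_baseline(genus_norm.values, meta_bio, baseline_group="NS")
        warnings += w1 + w2
        files = [
            _write(alpha.rename_axis("sample_id"), out / "alpha_diversity.tsv"),
            _write(pd.DataFrame(bc.data, index=bc.ids, columns=bc.ids).rename_axis("sample_id"),
                   out / "bray_curtis.tsv"),
            _write(pd.DataFrame(wu.data, index=wu.ids, columns=wu.ids).rename_axis("sample_id"),
                   out / "weighted_unifrac.tsv"),
            _write(pd.DataFrame(perm_rows), out / "permanova.tsv", index=False),
            _write(indiv, out / "individuality.tsv", index=False),
            _write(recov, out / "recovery_trajectory.tsv", index=False),
            _write(spd, out / "site_pair_distance.tsv", index=False),
            _write(lfc.rename_axis("sample_id"), out / "logfold_to_baseline.tsv"),
        ]
        report.add_stage("diversity", len(alpha), files, warnings=warnings)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("diversity", exc) from exc

    # -- stage 4: core microbiome / Venn -------------------------------------
    try:
        strata = meta_bio[["group", "site"]].drop_duplicates()
        cores: dict[str, dict[str, set]] = {}
        core_rows = []
        for _, (group, site) in strata.iterrows():
            prev = iop.prevalence_by_subject(genus_counts, meta_bio, group, site)
            cs = cv.core_taxa(prev, threshold=cfg.core_prevalence,
                              stratum=f"{group}|{site}")
            cores.setdefault(site, {})[group] = set(cs.members)
            core_rows.append({"group": group, "site": site,
                              "n_core": len(cs.members),
                              "members": ";".join(sorted(cs.members))})
        overlap = cv.core_overlap_table({s: g for s, g in cores.items() if len(g) >= 2})
        files = [
            _write(pd.DataFrame(core_rows), out / "core_sets.tsv", index=False),
            _write(overlap, out / "core_overlap.tsv", index=False),
        ]
        report.add_stage("core_venn", len(core_rows), files)
    except Exception as exc:  # noqa: BLE001
        raise StageError("core_venn", exc) from exc

    # -- stage 5: community assembly -----------------------------------------
    try:
        pairs = asm.assembly_pairs(cleaned, tree, meta_bio,
                                   n_null=cfg.n_null, seed=cfg.stage_seed(5))
        fractions = asm.process_fractions(pairs)
        files = [
            _write(pairs, out / "assembly_pairs.tsv", index=False),
            _write(fractions, out / "assembly_fractions.tsv", index=False),
        ]
        report.add_stage("assembly", len(pairs), files)
    except Exception as exc:  # noqa: BLE001
        raise StageError("assembly", exc) from exc

    # -- stage 6: co-occurrence networks ---------------------------------------
    try:
        warnings = []
        records: dict[str, nw.TopologyRecord] = {}
        hubs: dict[str, set[str]] = {}
        edge_frames = []
        for site in cfg.network_sites:
            for group in sorted(meta_bio.loc[meta_bio["site"] == site, "group"].unique()):
                key = f"{group}|{site}"
                try:
                    core_tab = nw.core_asv_filter(cleaned, meta_bio, group, site,
                                                  threshold=cfg.network_prevalence)
                    g = nw.build_network(norm.values.loc[core_tab.index, core_tab.columns],
                                         r_threshold=cfg.r_threshold)
                except ValueError as e:
                    warnings.append(f"network {key}: {e}")
                    continue
                records[key] = nw.topology(g, seed=cfg.stage_seed(6))
                hubs[key] = nw.detect_hubs(g)
                ef = nw.edge_list(g)
                ef.insert(0, "stratum", key)
                edge_frames.append(ef)
        files = []
        if len(records) >= 2:
            metrics, jac = nw.compare_networks(records, hubs)
            files.append(_write(metrics.rename_axis("metric"), out / "network_topology.tsv"))
            files.append(_write(jac.rename_axis("stratum"), out / "hub_jaccard.tsv"))
            hub_rows = pd.DataFrame(
                [{"stratum": k, "hubs": ";".join(sorted(v))} for k, v in hubs.items()])
            files.append(_write(hub_rows, out / "hub_taxa.tsv", index=False))
        if edge_frames:
            files.append(_write(pd.concat(edge_frames, ignore_index=True),
                                out / "network_edges.tsv", index=False))
        report.add_stage("networks", len(records), files, warnings=warnings)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("networks", exc) from exc

    (out / "run_report.json").write_text(report.to_json())
    return report


def desk_scale_sim(seed: int = 1, **overrides) -> SimConfig:
    """A reduced-size cohort for fast end-to-end runs: same design (sites,
    groups, longitudinal structure, blanks), smaller taxon pool and depth."""
    defaults = dict(n_taxa_pool=120, depth_mean=3000.0,
                    contaminant_fraction=0.1, seed=seed)
    defaults.update(overrides)
    return SimConfig(**defaults)
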