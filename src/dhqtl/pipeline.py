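"""End-to-end orchestration: simulate -> score -> ANOVA -> segregation -> QTL scan.

A :class:`RunConfig` (plain YAML on disk) drives a deterministic run:
every stage writes tab-delimited outputs carrying the seed and a config
hash, and a rerun with the same config and seed reproduces them
bit-for-bit.  Partial runs resume from existing intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .linkage import map_summary
from .qtl import QtlScan, ScanOptions, name_and_report
from .scoring import score_lines
from .segregation import MixedInheritanceModel
from .simulate import SimConfig, simulate_split_measurements, simulate_study
from .stats import anova_block_in_rep, assign_blocks, describe, line_means

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "STAGES"]

log = logging.getLogger("dhqtl")

STAGES = ("simulate", "score", "describe", "segregate", "mapstats", "scan")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "dhqtl_run"
    seed: int = 0
    stages: tuple = STAGES
    n_blocks: int = 14
    sim: dict = field(default_factory=dict)       # SimConfig overrides
    scan: dict = field(default_factory=dict)      # ScanOptions overrides
    scan_methods: tuple = ("icim", "mqm")
    permutations: int = 0  # 0 = use the configured lod_threshold as-is
    sigma_e2: float | None = None  # None = take the ANOVA error MS
    trait: str = "Hsr"
    resume: bool = True

    def sim_config(self) -> SimConfig:
        return replace(SimConfig(seed=self.seed), **self.sim)

    def scan_options(self) -> ScanOptions:
        return replace(ScanOptions(seed=self.seed), **self.scan)

    def hash(self) -> str:
        """Hash of the analytic settings (output location excluded)."""
        raw = dataclasses.asdict(self)
        raw.pop("outdir")
        blob = json.dumps(raw, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("stages", "scan_methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["stages"] = list(raw["stages"])
        raw["scan_methods"] = list(raw["scan_methods"])
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def _provenance(config: RunConfig) -> list[str]:
    return [f"seed: {config.seed}", f"config: {config.hash()}"]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a run report (also written to ``run_report.json``): per
    stage, the files written and headline numbers.  With ``resume``,
    stages whose outputs already exist are loaded rather than rerun; a
    missing upstream intermediate raises an error naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": config.hash(), "stages": {}}
    prov = _provenance(config)

    paths = {
        "map": out / "map.tsv",
        "genotypes": out / "genotypes.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
        "scores": out / "scores.tsv",
        "summary": out / "trait_summary.tsv",
        "anova": out / "anova.tsv",
        "segregation": out / "segregation_aic.tsv",
        "architecture": out / "genetic_parameters.tsv",
        "mapstats": out / "map_summary.tsv",
    }

    study = None

    def need_study():
        nonlocal study
        if study is None:
            for key in ("map", "genotypes", "phenotypes"):
                if not paths[key].exists():
                    raise FileNotFoundError(
                        f"missing intermediate {paths[key]}: run the 'simulate' "
                        "stage first"
                    )
            from .simulate import DhStudy
            study = DhStudy(
                dio.read_map(paths["map"]),
                dio.read_genotypes(paths["genotypes"]),
                dio.read_phenotypes(paths["phenotypes"]),
                dio.read_truth(paths["truth"]) if paths["truth"].exists()
                else config.sim_config(),
            )
        return study

    # ------------------------------------------------------- simulate
    if "simulate" in config.stages:
        if config.resume and all(
            paths[k].exists() for k in ("map", "genotypes", "phenotypes", "truth")
        ):
            log.info("simulate: reusing existing intermediates")
            study = need_study()
        else:
            sim = config.sim_config()
            study = simulate_study(sim)
            dio.write_map(study.gmap, paths["map"], seed=config.seed)
            dio.write_genotypes(study.genotypes, paths["genotypes"], seed=config.seed)
            dio.write_phenotypes(study.phenotypes, paths["phenotypes"], seed=config.seed)
            dio.write_truth(study.truth, paths["truth"])
        report["stages"]["simulate"] = {
            "n_lines": study.genotypes.shape[0],
            "n_markers": study.genotypes.shape[1],
            "files": [str(paths[k]) for k in ("map", "genotypes", "phenotypes", "truth")],
        }

    # ---------------------------------------------------------- score
    if "score" in config.stages:
        study = need_study()
        lm = study.line_means().clip(0.0, 100.0)
        rng = np.random.default_rng(config.seed + 17)
        frames = []
        for line, mean_idx in lm.items():
            meas = simulate_split_measurements(float(mean_idx), n_plants=10, seed=rng)
            meas.insert(0, "line", line)
            frames.append(meas)
        measurements = pd.concat(frames, ignore_index=True)
        scores = score_lines(measurements)
        dio.write_table(scores, paths["scores"], prov)
        report["stages"]["score"] = {
            "n_lines": len(scores),
            "mean_index": float(scores["index"].mean()),
            "files": [str(paths["scores"])],
        }

    # ------------------------------------------------------- describe
    sigma_e2 = config.sigma_e2
    if "describe" in config.stages:
        study = need_study()
        lm = study.line_means()
        summ = describe(lm.to_numpy()).as_series().to_frame("value")
        dio.write_table(summ.reset_index(names="statistic"), paths["summary"], prov)
        records = study.phenotypes.copy()
        blocks = assign_blocks(sorted(set(records["line"])), config.n_blocks,
                               seed=config.seed)
        records["block"] = records["line"].map(blocks)
        anova = anova_block_in_rep(records)
        dio.write_table(anova.table.reset_index(), paths["anova"], prov)
        if sigma_e2 is None:
            sigma_e2 = anova.sigma2_hat
        report["stages"]["describe"] = {
            "mean": float(lm.mean()),
            "error_ms": anova.sigma2_hat,
            "files": [str(paths["summary"]), str(paths["anova"])],
        }

    # ------------------------------------------------------ segregate
    if "segregate" in config.stages:
        study = need_study()
        if sigma_e2 is None:
            sigma_e2 = study.truth.env_variance
        lm = study.line_means()
        sel = MixedInheritanceModel(lm.to_numpy(), sigma_e2).fit_catalog(
            seed=config.seed
        )
        dio.write_table(sel.table, paths["segregation"], prov)
        arch = sel.best.genetic_params().as_series().to_frame("estimate")
        dio.write_table(arch.reset_index(names="parameter"), paths["architecture"], prov)
        report["stages"]["segregate"] = {
            "selected": sel.best.spec.label,
            "aic": sel.best.aic,
            "h_mg2": sel.best.genetic_params().h_mg2,
            "files": [str(paths["segregation"]), str(paths["architecture"])],
        }

    # ------------------------------------------------------- mapstats
    if "mapstats" in config.stages:
        study = need_study()
        summ = map_summary(study.gmap)
        per_group = summ.pop("per_group")
        dio.write_table(per_group, paths["mapstats"],
                        prov + [f"{k}: {v}" for k, v in summ.items()])
        report["stages"]["mapstats"] = {
            "total_length_cm": summ["total_length_cm"],
            "mean_interval_per_marker": summ["mean_interval_per_marker"],
            "files": [str(paths["mapstats"])],
        }

    # ----------------------------------------------------------- scan
    if "scan" in config.stages:
        study = need_study()
        lm = study.line_means()
        opts = config.scan_options()
        scan = QtlScan(lm, study.genotypes, study.gmap, opts)
        if config.permutations:
            threshold = scan.permutation_threshold(
                n_permutations=config.permutations
            )
            scan.options = replace(opts, lod_threshold=threshold)
            report["stages"]["permutation_threshold"] = threshold
        hits_by_key = {}
        scan_report: dict = {"files": []}
        for method in config.scan_methods:
            res = scan.fit(method=method, trait=config.trait)
            ppath = out / f"profile_{method}.tsv"
            hpath = out / f"hits_{method}.tsv"
            dio.write_table(res.profile, ppath, prov)
            dio.write_table(res.hits, hpath, prov)
            hits_by_key[method.upper()] = res.hits
            scan_report[method] = {
                "max_lod": res.max_lod,
                "n_hits": int(len(res.hits)),
                "total_pve": res.total_pve,
            }
            scan_report["files"] += [str(ppath), str(hpath)]
        combined = name_and_report(hits_by_key, trait=config.trait)
        rpath = out / "qtl_report.tsv"
        dio.write_table(combined, rpath, prov)
        scan_report["files"].append(str(rpath))
        report["stages"]["scan"] = scan_report

    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
    return report


def validate_inputs(paths: dict) -> pd.DataFrame:
    """Schema checks on genotype/map/phenotype files (report-only).

    ``paths`` maps any of 'genotypes', 'map', 'phenotypes' to file
    paths.  Returns a DataFrame of issues (empty when clean).
    """
    issues = []

    def add(file, problem):
        issues.append({"file": str(file), "problem": problem})

    gmap = None
    if "map" in paths:
        try:
            df = dio.read_table(paths["map"])
            if not {"marker", "group", "cm"}.issubset(df.columns):
                add(paths["map"], "missing required columns marker/group/cm")
            else:
                for grp, sub in df.groupby("group"):
                    if np.any(np.diff(sub["cm"].to_numpy(float)) < 0):
                        add(paths["map"], f"decreasing positions in group {grp}")
                if df["marker"].duplicated().any():
                    add(paths["map"], "duplicate marker names")
                gmap = df
        except Exception as exc:  # pragma: no cover - defensive
            add(paths["map"], f"unreadable: {exc}")

    geno = None
    if "genotypes" in paths:
        try:
            df = pd.read_csv(paths["genotypes"], sep="\t", comment="#",
                             index_col=0, dtype=str)
            codes = set(df.to_numpy(str).ravel())
            bad = codes - {"a", "b", "-"}
            if bad:
                add(paths["genotypes"],
                    f"illegal codes for DH data: {sorted(bad)}")
            geno = df
            if gmap is not None and list(df.columns) != list(gmap["marker"]):
                add(paths["genotypes"], "marker columns do not match the map")
        except Exception as exc:  # pragma: no cover
            add(paths["genotypes"], f"unreadable: {exc}")

    if "phenotypes" in paths:
        try:
            df = dio.read_phenotypes(paths["phenotypes"])
            needed = {"line", "rep", "plant", "value"}
            if not needed.issubset(df.columns):
                add(paths["phenotypes"], f"missing columns {sorted(needed - set(df.columns))}")
            elif geno is not None:
                orphan = set(df["line"]) - set(geno.index)
                if orphan:
                    add(paths["phenotypes"],
                        f"{len(orphan)} lines absent from the genotype file")
        except Exception as exc:  # pragma: no cover
            add(paths["phenotypes"], f"unreadable: {exc}")

    return pd.DataFrame(issues, columns=["file", "problem"])
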