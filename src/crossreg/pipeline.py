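"""End-to-end orchestration: simulate -> preprocess -> DE -> TF scan -> motif
nulls -> specificity -> enrichment, with a JSON manifest per run."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .de import calibrate_permutation_fdr, consistent_de, effect_size, test_differential
from .motif import DEFAULT_THRESHOLDS
from .synthetic import ScenarioConfig, generate_regulatory_scenario
from .tfreg import (
    correlation_of_correlations,
    permute_regulon_labels,
    scan_tf_regulators,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Expand the global seed into an independent per-stage seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass
class RunConfig:
    """Thresholds and sizes for an end-to-end run."""

    seed: int = 0
    out_dir: str = "run"
    contrast: tuple = ("g1", "g2")
    fdr: float = 0.10
    es_cutoff: float = 0.8
    tf_alpha: float = 0.01
    n_perm_fdr: int = 200
    n_perm_regulon: int = 200
    gc_floor: float = 0.79
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    scenario: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if not 0 < self.tf_alpha < 1:
            raise ValueError("tf_alpha must be in (0, 1)")
        if self.es_cutoff < 0:
            raise ValueError("es_cutoff must be >= 0")
        if not 0 <= self.gc_floor <= 1:
            raise ValueError("gc_floor must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the synthetic-scenario pipeline end to end; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "fdr": config.fdr,
            "es_cutoff": config.es_cutoff,
            "tf_alpha": config.tf_alpha,
            "gc_floor": config.gc_floor,
            **config.thresholds,
        },
        "stages": {},
        "outputs": {},
    }

    scen_kwargs = dict(config.scenario)
    scen_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
    if "driver_tfs" in scen_kwargs:
        scen_kwargs["driver_tfs"] = tuple(scen_kwargs["driver_tfs"])
    if isinstance(scen_kwargs.get("targets_per_tf"), list):
        scen_kwargs["targets_per_tf"] = tuple(scen_kwargs["targets_per_tf"])
    scenario = generate_regulatory_scenario(ScenarioConfig(**scen_kwargs))
    cio.write_study(scenario.cohort_a, out / "cohort_a.tsv", out / "cohort_a.meta.tsv")
    cio.write_study(scenario.cohort_b, out / "cohort_b.tsv", out / "cohort_b.meta.tsv")
    cio.write_regulons(scenario.regulons, out / "regulons.tsv")
    scenario.truth.to_csv(out / "truth.tsv", sep="\t")
    manifest["stages"]["simulate"] = {
        "n_genes": scenario.cohort_a.n_genes,
        "n_regulons": len(scenario.regulons),
        "seed": scen_kwargs["seed"],
    }

    results = {}
    for name, study in (("a", scenario.cohort_a), ("b", scenario.cohort_b)):
        cal = calibrate_permutation_fdr(
            study,
            config.contrast,
            n_perm=config.n_perm_fdr,
            target_fdr=config.fdr,
            seed=stage_seed(config.seed, f"fdr_{name}"),
        )
        effects = test_differential(study, config.contrast)
        d = effect_size(study, *config.contrast)
        df = pd.DataFrame(
            {
                "gene": [e.gene for e in effects],
                "p": [e.p for e in effects],
                "d": [e.d for e in effects],
                "direction": [e.direction for e in effects],
                "significant": [e.p <= cal.cutoff_p for e in effects],
            }
        )
        df.to_csv(out / f"de_{name}.tsv", sep="\t", index=False)
        results[name] = {"study": study, "cal": cal, "effects": effects, "d": d}
        manifest["stages"][f"de_{name}"] = {
            "cutoff_p": cal.cutoff_p,
            "n_significant": cal.n_observed,
            "n_tested": study.n_genes,
            "attained": cal.attained,
        }

    consistent = consistent_de(
        results["a"]["effects"],
        results["b"]["effects"],
        rule="es_both",
        cutoffs={"es": config.es_cutoff},
    )
    manifest["stages"]["consistent_de"] = {"n_genes": len(consistent)}

    tf_stage: dict = {}
    candidates: dict[str, list] = {}
    for name in ("a", "b"):
        study, d = results[name]["study"], results[name]["d"]
        scan = scan_tf_regulators(
            study,
            scenario.regulons,
            d,
            es_cutoff=config.es_cutoff,
            alpha=config.tf_alpha,
        )
        rows = [
            {
                "tf": r.tf,
                "motif": r.motif,
                "p": r.p,
                "direction": r.direction,
                "n_targets": r.n_targets_tested,
                "n_nontargets": r.n_nontargets,
                "passes": r.passes(config.tf_alpha),
            }
            for r in scan
        ]
        pd.DataFrame(rows).to_csv(out / f"tf_scan_{name}.tsv", sep="\t", index=False)
        candidates[name] = [r for r in scan if r.passes(config.tf_alpha)]
        stage = {"n_tested": len(scan), "n_pass": len(candidates[name])}
        if len(scan) >= 2:
            gp, expected, _ = permute_regulon_labels(
                study,
                scenario.regulons,
                d,
                n_perm=config.n_perm_regulon,
                seed=stage_seed(config.seed, f"regperm_{name}"),
                es_cutoff=config.es_cutoff,
                alpha=config.tf_alpha,
            )
            stage["global_p"] = gp
            stage["expected_pass"] = expected
        tf_stage[name] = stage
    manifest["stages"]["tf_scan"] = tf_stage

    eligible = {
        name: set(
            results[name]["d"].index[
                np.abs(results[name]["d"].fillna(0.0)) > config.es_cutoff
            ]
        )
        for name in ("a", "b")
    }
    coc_rows = []
    seen_tfs = {r.tf for r in candidates["a"] + candidates["b"]}
    for reg in scenario.regulons:
        if reg.tf not in seen_tfs:
            continue
        coc = correlation_of_correlations(
            scenario.cohort_a, scenario.cohort_b, reg, eligible["a"], eligible["b"]
        )
        coc_rows.append(
            {
                "tf": coc.tf,
                "motif": reg.motif,
                "rho": coc.rho,
                "p": coc.p,
                "n_shared_targets": coc.n_shared_targets,
                "testable": coc.testable,
            }
        )
    pd.DataFrame(
        coc_rows,
        columns=["tf", "motif", "rho", "p", "n_shared_targets", "testable"],
    ).to_csv(out / "coc.tsv", sep="\t", index=False)
    manifest["stages"]["coc"] = {"n_candidate_tfs": len(coc_rows)}

    truth_drivers = set(scenario.tf_truth.index[scenario.tf_truth["driver"]])
    found = {r.tf for r in candidates["a"]} | {r.tf for r in candidates["b"]}
    manifest["stages"]["recovery"] = {
        "planted_drivers": sorted(truth_drivers),
        "candidates": sorted(found),
        "drivers_recovered": sorted(truth_drivers & found),
    }

    for f in sorted(out.glob("*.tsv")):
        manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def validate_inputs(paths: dict) -> list[str]:
    """Cross-check input files; returns a list of violation messages."""
    violations: list[str] = []
    study = None
    if "expr" in paths and "meta" in paths:
        try:
            values = cio.read_expression(paths["expr"])
            meta = cio.read_metadata(paths["meta"])
            extra = set(meta.index) - set(values.columns)
            missing = set(values.columns) - set(meta.index)
            for s in sorted(extra):
                violations.append(f"metadata sample {s!r} missing from matrix")
            for s in sorted(missing):
                violations.append(f"matrix sample {s!r} missing from metadata")
            if not missing:
                study = True
        except Exception as exc:  # surface parse failures as violations
            violations.append(f"expression/metadata unreadable: {exc}")
    promoters = None
    if "promoters" in paths:
        try:
            promoters = cio.read_promoters(
                paths["promoters"], paths.get("conservation")
            )
        except Exception as exc:
            violations.append(f"promoters unreadable: {exc}")
    if promoters and "dnase" in paths:
        try:
            lengths = {p.gene: len(p) for p in promoters}
            for iv in cio.read_bed(paths["dnase"]):
                if iv.chrom not in lengths:
                    violations.append(f"BED interval on unknown gene {iv.chrom!r}")
                elif iv.end > lengths[iv.chrom]:
                    violations.append(
                        f"BED interval {iv.chrom}:{iv.start}-{iv.end} beyond "
                        f"promoter length {lengths[iv.chrom]}"
                    )
        except Exception as exc:
            violations.append(f"BED unreadable: {exc}")
    if "regulons" in paths:
        try:
            regulons = cio.read_regulons(paths["regulons"])
            if study and "expr" in paths:
                genes = set(cio.read_expression(paths["expr"]).index)
                for reg in regulons:
                    if reg.tf not in genes:
                        violations.append(f"regulon TF {reg.tf!r} not in matrix")
        except Exception as exc:
            violations.append(f"regulons unreadable: {exc}")
    return violations
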