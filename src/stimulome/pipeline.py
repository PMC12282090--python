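"""End-to-end pipeline: simulate → center → decompose → test → cluster.

One YAML config drives a hermetic run: every input path, seed and cutoff
is declared in the config, all stage outputs land in one run directory
with a provenance record, and rerunning the same config reproduces the
result files byte-for-byte. Stage timings go to ``run.log``, which is
the only non-deterministic file in the run directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .datasets import BlockSpec, PlantedShift, SyntheticDesign, simulate_dataset
from .deg_coverage import coverage, gene_differential
from .diff_activity import (
    fit_replicate_null,
    select_high_density_components,
    test_contrast,
)
from .expression import ExpressionMatrix, SampleContrast, center_to_reference
from .ica import RobustICA
from .stimulon import activity_spearman, build_stimulon_graph

RESULT_FILES = [
    "expression.tsv",
    "metadata.tsv",
    "truth.json",
    "model_weights.tsv",
    "model_members.json",
    "activities.tsv",
    "high_density.json",
    "stimulon_edges.tsv",
    "stimulon_clusters.json",
    "coverage.json",
    "provenance.json",
]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    seed: int
    synthetic: dict = field(default_factory=dict)
    expression_paths: dict | None = None
    ica: dict = field(default_factory=dict)
    diff_activity: dict = field(default_factory=dict)
    deg: dict = field(default_factory=dict)
    stimulon: dict = field(default_factory=dict)
    reference: dict = field(default_factory=lambda: {"phase": "batch"})
    contrasts: list = field(default_factory=list)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config requires a seed")
        if not self.contrasts:
            raise ValueError("config requires at least one contrast")
        for c in self.contrasts:
            for key in ("label", "group_a", "group_b"):
                if key not in c:
                    raise ValueError(f"contrast missing {key!r}: {c}")
        for name, section, lo, hi in (
            ("diff_activity.fdr_cutoff", self.diff_activity.get("fdr_cutoff"), 0, 1),
            ("stimulon.rho_threshold", self.stimulon.get("rho_threshold"), 0, 1),
            ("stimulon.p_cutoff", self.stimulon.get("p_cutoff"), 0, 1),
            ("ica.min_occurrence", self.ica.get("min_occurrence"), 0, 1),
        ):
            if section is not None and not lo <= section <= hi:
                raise ValueError(f"{name} out of range [{lo}, {hi}]")
        if self.expression_paths is None and not self.synthetic:
            raise ValueError("config needs either expression paths or a synthetic section")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return cls(
            seed=raw.get("seed"),
            synthetic=raw.get("synthetic", {}) or {},
            expression_paths=raw.get("expression"),
            ica=raw.get("ica", {}) or {},
            diff_activity=raw.get("diff_activity", {}) or {},
            deg=raw.get("deg", {}) or {},
            stimulon=raw.get("stimulon", {}) or {},
            reference=raw.get("reference", {"phase": "batch"}),
            contrasts=raw.get("contrasts", []) or [],
        )

    def canonical(self) -> dict:
        return {
            "seed": self.seed,
            "synthetic": self.synthetic,
            "expression": self.expression_paths,
            "ica": self.ica,
            "diff_activity": self.diff_activity,
            "deg": self.deg,
            "stimulon": self.stimulon,
            "reference": self.reference,
            "contrasts": self.contrasts,
        }

    def hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def design_from_config(cfg: dict) -> SyntheticDesign:
    cfg = dict(cfg)
    shifts = tuple(PlantedShift(**s) for s in cfg.pop("shifts", []))
    blocks = tuple(
        BlockSpec(
            components=tuple(b["components"]),
            target_abs_rho=b.get("target_abs_rho", 0.9),
            signs=tuple(b["signs"]) if b.get("signs") else None,
        )
        for b in cfg.pop("blocks", [])
    )
    return SyntheticDesign(shifts=shifts, blocks=blocks, **cfg)


def _contrast_from_spec(X: ExpressionMatrix, spec: dict) -> SampleContrast:
    ga = X.samples_where(**spec["group_a"])
    gb = X.samples_where(**spec["group_b"])
    return SampleContrast(frozenset(ga), frozenset(gb), label=spec["label"])


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute every stage and write all outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def stage(name):
        t0 = time.perf_counter()

        def done():
            log_lines.append(f"{name}: {time.perf_counter() - t0:.2f}s")

        return done

    # -- data ------------------------------------------------------------
    finish = stage("data")
    if config.expression_paths is not None:
        X = ExpressionMatrix.from_tsv(
            config.expression_paths["values"], config.expression_paths["metadata"]
        )
        truth = None
    else:
        design = design_from_config(config.synthetic)
        X, truth = simulate_dataset(design, config.seed)
    X.to_tsv(out / "expression.tsv", out / "metadata.tsv")
    if truth is not None:
        truth.write_json(out / "truth.json")
    else:
        (out / "truth.json").write_text("{}\n")
    finish()

    # -- preprocess: center to reference ---------------------------------
    finish = stage("preprocess")
    reference = X.samples_where(**config.reference)
    Xc = center_to_reference(X, reference) if reference else X
    finish()

    # -- decomposition ----------------------------------------------------
    finish = stage("ica")
    ica_cfg = dict(config.ica)
    dimensionality = ica_cfg.pop(
        "dimensionality",
        truth.n_components if truth is not None else min(Xc.shape) // 2,
    )
    results = RobustICA(Xc, dimensionality=dimensionality, **ica_cfg).fit(config.seed)
    results.components.write(out / "model_weights.tsv", out / "model_members.json")
    results.activities.to_tsv(out / "activities.tsv")
    finish()

    # -- differential activity --------------------------------------------
    finish = stage("diff_activity")
    pairs = X.replicate_pairs()
    null = fit_replicate_null(results.activities, pairs)
    da_cfg = config.diff_activity
    contrast_results = []
    contrasts = [_contrast_from_spec(X, spec) for spec in config.contrasts]
    for contrast in contrasts:
        res = test_contrast(
            results.activities,
            contrast,
            null,
            delta_cutoff=da_cfg.get("delta_cutoff", 5.0),
            fdr_cutoff=da_cfg.get("fdr_cutoff", 0.1),
        )
        res.rename_axis("component").to_csv(
            out / f"diffact_{contrast.label}.tsv", sep="\t", float_format="%.10g"
        )
        contrast_results.append(res)
    selected = select_high_density_components(contrast_results)
    with open(out / "high_density.json", "w") as fh:
        json.dump({"components": sorted(selected)}, fh, sort_keys=True, indent=1)
    finish()

    # -- stimulons ---------------------------------------------------------
    finish = stage("stimulon")
    st_cfg = config.stimulon
    nodes = sorted(selected) if len(selected) >= 2 else results.components.names
    graph = None
    if len(nodes) >= 2:
        corr, pmat = activity_spearman(results.activities, components=nodes)
        graph = build_stimulon_graph(
            corr,
            pmat,
            member_sizes=results.components.member_sizes(),
            rho_threshold=st_cfg.get("rho_threshold", 0.7),
            p_cutoff=st_cfg.get("p_cutoff", 0.05),
        )
        graph.to_files(out / "stimulon_edges.tsv", out / "stimulon_clusters.json")
    else:
        (out / "stimulon_edges.tsv").write_text("node_i\tnode_j\trho\tp\n")
        (out / "stimulon_clusters.json").write_text('{"clusters": []}\n')
    finish()

    # -- DEG coverage ------------------------------------------------------
    finish = stage("coverage")
    deg_cfg = config.deg
    cov = {}
    for contrast in contrasts:
        deg = gene_differential(
            Xc,
            contrast,
            delta_cutoff=deg_cfg.get("delta_cutoff", 2.0),
            fdr_cutoff=deg_cfg.get("fdr_cutoff", 0.1),
        )
        cov[contrast.label] = {
            k: (None if v != v else round(v, 10))
            for k, v in coverage(deg, results.components).items()
        }
    with open(out / "coverage.json", "w") as fh:
        json.dump(cov, fh, sort_keys=True, indent=1)
    finish()

    # -- provenance & log --------------------------------------------------
    provenance = {
        "config_hash": config.hash(),
        "config": config.canonical(),
        "seed": config.seed,
        "package_version": __version__,
        "n_robust_components": results.components.n_components,
        "n_converged_restarts": results.n_converged_restarts,
        "n_high_density": len(selected),
        "n_stimulon_clusters": len(graph.clusters) if graph is not None else 0,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, sort_keys=True, indent=1)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
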