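"""Canned simulation studies validating the pipeline end to end.

Each study fixes one synthetic design — the conditions under which the
package's behaviour is characterised — runs the relevant stages from
scratch, and returns summary statistics. They are used by the test
suite and the reproduction script alike, so the numbers reported there
are always recomputed, never stored.

Problem sizes (2000 genes / 10 components / 60 samples for recovery,
500 and 200 replicate simulations for calibration and power) are chosen
so each study characterises the method at a desk-scale workload.
"""

from __future__ import annotations

import numpy as np

from ._rng import child_ints, stage_seed_sequence
from .datasets import (
    BlockSpec,
    PlantedShift,
    SyntheticDesign,
    generate_activities,
    simulate_dataset,
)
from .deg_coverage import coverage, gene_differential
from .diff_activity import fit_replicate_null, test_contrast
from .expression import SampleContrast, center_to_reference
from .ica import ActivityMatrix, RobustICA, match_components
from .stimulon import activity_spearman, build_stimulon_graph


def _study_seeds(seed: int, n: int) -> list[int]:
    return child_ints(stage_seed_sequence(seed, "simulation"), n)


def recovery_design() -> SyntheticDesign:
    """The component-recovery workload: 2000 genes, 10 planted
    components, 15 conditions in paired duplicates (60 samples),
    expression noise at 5% of the signal RMS."""
    return SyntheticDesign(
        n_genes=2000,
        n_components=10,
        n_conditions=15,
        n_batch_conditions=5,
        replicates_per_condition=4,
        expression_noise_fraction=0.05,
    )


def component_recovery_study(seed: int, n_restarts: int = 20) -> dict:
    """Fit robust ICA on planted data and score recovery.

    Returns the worst-case |Pearson| between each planted gene-weight
    column and its Hungarian-matched robust component, and the
    worst-case Jaccard index between planted and recovered member sets.
    """
    design = recovery_design()
    X, truth = simulate_dataset(design, seed)
    reference = X.samples_where(phase="batch")
    Xc = center_to_reference(X, reference)
    results = RobustICA(
        Xc, dimensionality=design.n_components, n_restarts=n_restarts
    ).fit(seed)
    matching = match_components(results.components.weights, truth.source_weights)
    jaccards = []
    for i, name in enumerate(truth.source_weights.columns):
        planted = truth.member_sets[i]
        recovered = results.components.member_sets[matching.loc[name, "matched"]]
        jaccards.append(len(planted & recovered) / len(planted | recovered))
    return {
        "n_planted": design.n_components,
        "n_recovered": results.components.n_components,
        "min_abs_pearson": float(matching["abs_pearson"].min()),
        "min_member_jaccard": float(min(jaccards)),
    }


def _null_power_design(shifted: tuple = ()) -> SyntheticDesign:
    # 15 conditions x 2 pairs = 30 replicate pairs; condition baselines
    # flat so the only between-sample variation is replicate noise (plus
    # the planted shifts, if any).
    return SyntheticDesign(
        n_genes=400,  # unused by activity-level studies; must stay valid
        n_components=12,
        member_genes_per_component=10,
        n_conditions=15,
        n_batch_conditions=5,
        replicates_per_condition=4,
        condition_sd=0.0,
        replicate_noise_sd=1.0,
        shifts=tuple(PlantedShift(component=c, delta=10.0) for c in shifted),
    )


def _six_vs_six(metadata) -> SampleContrast:
    batch = sorted(metadata.index[metadata["phase"] == "batch"])[:6]
    fed = sorted(metadata.index[metadata["phase"] == "fedbatch"])[:6]
    return SampleContrast(frozenset(batch), frozenset(fed), label="batch_vs_fedbatch")


def _pairs_from_metadata(metadata) -> list[tuple]:
    pairs = []
    for _, grp in metadata.groupby("replicate_pair", sort=True):
        ids = sorted(grp.index)
        if len(ids) == 2:
            pairs.append(tuple(ids))
    return pairs


def null_calibration_study(seed: int, n_sims: int = 500) -> dict:
    """False-flag rate of the differential-activity test under the null.

    Simulates datasets with no planted shifts and no condition-level
    variation (replicate noise sd 1), fits the replicate null from 30
    pairs, tests a 6-vs-6 contrast, and reports the fraction of
    component tests with q < 0.1. The binomial Monte-Carlo standard
    error at the nominal 0.1 level is included.
    """
    design = _null_power_design()
    n_flagged = 0
    n_total = 0
    for s in _study_seeds(seed, n_sims):
        A, meta = generate_activities(design, s)
        activities = ActivityMatrix(A)
        null = fit_replicate_null(activities, _pairs_from_metadata(meta))
        res = test_contrast(activities, _six_vs_six(meta), null)
        n_flagged += int((res["qvalue"] < 0.1).sum())
        n_total += len(res)
    mc_se = float(np.sqrt(0.1 * 0.9 / n_total))
    return {
        "n_sims": n_sims,
        "n_tests": n_total,
        "flag_fraction": n_flagged / n_total,
        "mc_se": mc_se,
        "bound": 0.1 + 3 * mc_se,
    }


POWER_SHIFTED_COMPONENTS = (0, 2, 5, 7, 9)


def power_study(seed: int, n_sims: int = 200) -> dict:
    """Detection power for planted ΔA = 10 at replicate noise sd 1.

    Five of twelve components carry a batch→fed-batch shift of 10
    activity units; each simulation tests a 6-vs-6 contrast against a
    30-pair replicate null. Power is the fraction of shifted components
    flagged (|ΔA| > 5, q < 0.1); the null flag rate over the unshifted
    components is reported alongside.
    """
    design = _null_power_design(shifted=POWER_SHIFTED_COMPONENTS)
    shifted_names = {f"comp{c:02d}" for c in POWER_SHIFTED_COMPONENTS}
    hits = misses = null_flags = null_total = 0
    for s in _study_seeds(seed, n_sims):
        A, meta = generate_activities(design, s)
        activities = ActivityMatrix(A)
        null = fit_replicate_null(activities, _pairs_from_metadata(meta))
        res = test_contrast(activities, _six_vs_six(meta), null)
        flagged = set(res.index[res["high_activity"]])
        hits += len(flagged & shifted_names)
        misses += len(shifted_names - flagged)
        null_flags += len(flagged - shifted_names)
        null_total += len(res) - len(shifted_names)
    return {
        "n_sims": n_sims,
        "power": hits / (hits + misses),
        "null_flag_fraction": null_flags / null_total,
    }


STIMULON_BLOCKS = (
    BlockSpec(components=(0, 1, 2), target_abs_rho=0.9, signs=(1, -1, 1)),
    BlockSpec(components=(3, 4, 5), target_abs_rho=0.9),
    BlockSpec(components=(6, 7), target_abs_rho=0.9),
)


def stimulon_recovery_study(seed: int) -> dict:
    """Recover three planted correlation blocks as stimulon clusters.

    Ten components, three blocks at within-block |ρ| ≈ 0.9 (one block
    mixes signs, exercising negative edges); the two remaining
    components are unplanted and must stay unclustered. Cluster naming
    is checked for determinism by rebuilding the graph.
    """
    design = SyntheticDesign(
        n_genes=300,
        n_components=10,
        n_conditions=50,
        n_batch_conditions=15,
        replicates_per_condition=2,
        condition_sd=3.0,
        replicate_noise_sd=0.5,
        blocks=STIMULON_BLOCKS,
    )
    A, _ = generate_activities(design, seed)
    activities = ActivityMatrix(A)
    corr, pmat = activity_spearman(activities)
    sizes = {name: 20 for name in activities.component_names}

    def build():
        return build_stimulon_graph(corr, pmat, member_sizes=sizes)

    graph = build()
    planted = sorted(
        frozenset(f"comp{c:02d}" for c in b.components) for b in STIMULON_BLOCKS
    )
    recovered = sorted(graph.clusters)
    rebuilt = build()
    return {
        "n_planted_blocks": len(STIMULON_BLOCKS),
        "n_clusters": len(graph.clusters),
        "partition_matches": recovered == planted,
        "naming_deterministic": rebuilt.names == graph.names
        and sorted(rebuilt.clusters) == recovered,
    }


COVERAGE_SHIFTED_COMPONENTS = (0, 1, 2)


def deg_coverage_study(seed: int, n_restarts: int = 10) -> dict:
    """End-to-end DEG coverage on planted data.

    Three of eight components carry strong batch→fed-batch shifts
    (ΔA = 25, i.e. per-member-gene shifts of ≈ 5 log-TPM units), so the
    significantly regulated genes are exactly driven by component
    members; coverage of the fitted member sets should approach 1.
    """
    design = SyntheticDesign(
        n_genes=1000,
        n_components=8,
        n_conditions=10,
        n_batch_conditions=4,
        replicates_per_condition=4,
        shifts=tuple(
            PlantedShift(component=c, delta=25.0) for c in COVERAGE_SHIFTED_COMPONENTS
        ),
    )
    X, truth = simulate_dataset(design, seed)
    Xc = center_to_reference(X, X.samples_where(phase="batch"))
    results = RobustICA(
        Xc, dimensionality=design.n_components, n_restarts=n_restarts
    ).fit(seed)
    contrast = SampleContrast(
        frozenset(X.samples_where(phase="batch")),
        frozenset(X.samples_where(phase="fedbatch")),
        label="batch_vs_fedbatch",
    )
    deg = gene_differential(Xc, contrast)
    cov = coverage(deg, results.components)
    n_up = int((deg["direction"] == 1).sum())
    n_down = int((deg["direction"] == -1).sum())
    return {
        "n_significant_up": n_up,
        "n_significant_down": n_down,
        "coverage_up": cov["up"],
        "coverage_down": cov["down"],
    }


def evaluate_demo_run(run_dir) -> dict:
    """Score a demo pipeline run directory against its planted truth.

    Maps each planted component to the fitted component with the most
    similar member set (Jaccard), then checks that the planted shifted
    components are exactly the flagged ones and that each planted block
    lies inside a single recovered stimulon cluster.
    """
    import json
    from pathlib import Path

    run_dir = Path(run_dir)
    truth = json.loads((run_dir / "truth.json").read_text())
    members = json.loads((run_dir / "model_members.json").read_text())["member_sets"]
    fitted = {name: set(genes) for name, genes in members.items()}

    def best_match(planted_genes):
        planted_genes = set(planted_genes)
        return max(
            fitted,
            key=lambda n: len(planted_genes & fitted[n])
            / max(len(planted_genes | fitted[n]), 1),
        )

    mapped = {
        i: best_match(genes) for i, genes in enumerate(truth["member_sets"])
    }
    shifted = {mapped[s["component"]] for s in truth["planted_shifts"]}
    flagged = set(
        json.loads((run_dir / "high_density.json").read_text())["components"]
    )
    clusters = [
        frozenset(c["members"])
        for c in json.loads((run_dir / "stimulon_clusters.json").read_text())[
            "clusters"
        ]
    ]
    blocks_contained = all(
        any({mapped[c] for c in b["components"]} <= cl for cl in clusters)
        for b in truth["planted_blocks"]
    )
    return {
        "flagged_matches_planted": flagged == shifted,
        "n_flagged": len(flagged),
        "n_planted_shifts": len(truth["planted_shifts"]),
        "blocks_contained": blocks_contained,
        "n_clusters": len(clusters),
    }


def demo_pipeline_config(seed: int) -> dict:
    """The default synthetic demo: 2000 genes, 10 components, 60
    samples, planted shifts on three components and two correlated
    blocks — the config used for the end-to-end determinism check."""
    return {
        "seed": seed,
        "synthetic": {
            "n_genes": 2000,
            "n_components": 10,
            "n_conditions": 15,
            "n_batch_conditions": 5,
            "replicates_per_condition": 4,
            "shifts": [
                {"component": 0, "delta": 10.0},
                {"component": 1, "delta": -10.0},
                {"component": 2, "delta": 15.0},
                {"component": 3, "delta": 12.0},
                {"component": 4, "delta": 12.0},
            ],
            "blocks": [
                {"components": [0, 1, 2], "target_abs_rho": 0.9, "signs": [1, -1, 1]},
                {"components": [3, 4], "target_abs_rho": 0.9},
            ],
        },
        "ica": {"n_restarts": 10},
        "contrasts": [
            {
                "label": "batch_vs_fedbatch",
                "group_a": {"phase": "batch"},
                "group_b": {"phase": "fedbatch"},
            }
        ],
    }
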