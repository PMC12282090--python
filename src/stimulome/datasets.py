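"""Synthetic expression data with planted, fully known structure.

Every downstream stage of the package (decomposition, differential
activity, stimulon detection, DEG coverage) is validated against data
generated here, where the latent gene-weight matrix S, the activity
matrix A, the member gene sets, the planted activity shifts and the
planted correlated blocks are all known exactly.

The forward model is the one the decomposition inverts::

    X = S · A + E

with S sparse and heavy-tailed in the gene dimension (a small member set
per component carries large weights over a near-zero background), A built
from condition-block means plus paired-replicate noise on the log-TPM
scale, and E i.i.d. Gaussian measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .expression import ExpressionMatrix
from .process import OD_TO_CDW_FACTOR, ProcessTimeSeries, feed_rate

BATCH = "batch"
FEDBATCH = "fedbatch"

#: mol CO2 per hour per gram CDW in the synthetic off-gas profile, chosen
#: to put a 0.25 L culture at ~50 g/L CDW near 0.04 mol/h.
CO2_PER_GRAM_CDW = 0.003


@dataclass(frozen=True)
class PlantedShift:
    """A planted activity difference: component's mean activity in
    ``phase_b`` conditions exceeds ``phase_a`` conditions by ``delta``."""

    component: int
    phase_a: str = BATCH
    phase_b: str = FEDBATCH
    delta: float = 10.0


@dataclass(frozen=True)
class BlockSpec:
    """Components sharing a latent condition factor, so their activities
    correlate at roughly ``target_abs_rho`` across conditions. ``signs``
    (±1 per component) sets the loading sign; default all +1."""

    components: tuple
    target_abs_rho: float = 0.9
    signs: tuple | None = None

    def sign_vector(self) -> np.ndarray:
        if self.signs is None:
            return np.ones(len(self.components))
        return np.asarray(self.signs, dtype=float)


@dataclass
class SyntheticDesign:
    """Sizes, noise levels, and planted structure of a synthetic dataset.

    Defaults describe the scale at which the pipeline is exercised:
    2000 genes, 10 components with 20 member genes each at unit weight
    scale over a 0.05-SD background; 15 conditions (5 batch, 10 fed-batch)
    sampled in paired biological duplicates (4 replicates = 2 pairs per
    condition, 60 samples); replicate noise of 1 activity unit, matching
    the scale on which a |ΔA| > 5 cutoff is meaningful; condition-to-
    condition baseline SD of 3; expression noise at 5% of the signal RMS.
    """

    n_genes: int = 2000
    n_components: int = 10
    n_conditions: int = 15
    n_batch_conditions: int = 5
    replicates_per_condition: int = 4
    member_genes_per_component: int = 20
    member_weight_scale: float = 1.0
    background_sd: float = 0.05
    condition_sd: float = 3.0
    replicate_noise_sd: float = 1.0
    expression_noise_fraction: float = 0.05
    shifts: tuple = ()
    blocks: tuple = ()

    @property
    def n_samples(self) -> int:
        return self.n_conditions * self.replicates_per_condition

    def validate(self) -> None:
        if self.n_components >= min(self.n_genes, self.n_samples):
            raise ValueError("n_components must be < min(n_genes, n_samples)")
        if self.member_genes_per_component * self.n_components >= self.n_genes:
            raise ValueError("member genes exhaust the genome (invalid design)")
        if self.replicates_per_condition < 2 or self.replicates_per_condition % 2:
            raise ValueError("replicates_per_condition must be even and ≥ 2")
        if not 0 < self.n_batch_conditions < self.n_conditions:
            raise ValueError("need at least one batch and one fed-batch condition")
        for sd in (
            self.background_sd,
            self.condition_sd,
            self.replicate_noise_sd,
            self.expression_noise_fraction,
        ):
            if sd < 0:
                raise ValueError("noise scales must be non-negative")
        for s in self.shifts:
            if not 0 <= s.component < self.n_components:
                raise ValueError(f"shift references unknown component {s.component}")
        for b in self.blocks:
            for c in b.components:
                if not 0 <= c < self.n_components:
                    raise ValueError(f"block references unknown component {c}")
            if b.signs is not None and len(b.signs) != len(b.components):
                raise ValueError("block signs length mismatch")


@dataclass
class PlantedTruth:
    """Ground truth of one synthetic dataset: the latent S and A of
    X ≈ S·A, plus member sets, planted shifts/blocks and the seed."""

    source_weights: pd.DataFrame  # genes × k
    activity_profile: pd.DataFrame  # k × samples
    member_sets: list  # list of frozenset of gene ids
    planted_shifts: tuple
    planted_blocks: tuple
    seed: int
    sample_metadata: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.source_weights.shape[1]

    @property
    def signal_rms(self) -> float:
        sa = self.source_weights.to_numpy() @ self.activity_profile.to_numpy()
        return float(np.sqrt(np.mean(sa**2)))

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "component_names": list(self.source_weights.columns),
            "member_sets": [sorted(s) for s in self.member_sets],
            "planted_shifts": [asdict(s) for s in self.planted_shifts],
            "planted_blocks": [
                {
                    "components": list(b.components),
                    "target_abs_rho": b.target_abs_rho,
                    "signs": None if b.signs is None else list(b.signs),
                }
                for b in self.planted_blocks
            ],
            "source_weights": {
                c: [round(v, 12) for v in self.source_weights[c]]
                for c in self.source_weights.columns
            },
            "activity_profile": {
                s: [round(v, 12) for v in self.activity_profile[s]]
                for s in self.activity_profile.columns
            },
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _component_names(k: int) -> list[str]:
    return [f"comp{i:02d}" for i in range(k)]


def generate_sources(design: SyntheticDesign, seed: int):
    """Sparse heavy-tailed gene-weight matrix (genes × k) and member sets.

    Each component gets ``member_genes_per_component`` disjoint member
    genes with weight sign·(scale + |N(0, 0.1·scale)|); all other weights
    are N(0, background_sd). Columns are scaled to unit norm, so members
    stand well clear of the background whenever scale ≫ background_sd.
    """
    design.validate()
    rng = stage_rng(seed, "sources")
    n, k, m = design.n_genes, design.n_components, design.member_genes_per_component
    genes = _gene_ids(n)
    W = rng.normal(0.0, design.background_sd, size=(n, k))
    perm = rng.permutation(n)
    member_sets = []
    for j in range(k):
        idx = perm[j * m : (j + 1) * m]
        signs = rng.choice([-1.0, 1.0], size=m)
        magnitudes = design.member_weight_scale + np.abs(
            rng.normal(0.0, 0.1 * design.member_weight_scale, size=m)
        )
        W[idx, j] = signs * magnitudes
        member_sets.append(frozenset(genes[i] for i in idx))
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    S = pd.DataFrame(W, index=genes, columns=_component_names(k))
    return S, member_sets


def _condition_table(design: SyntheticDesign) -> pd.DataFrame:
    phases = [
        BATCH if c < design.n_batch_conditions else FEDBATCH
        for c in range(design.n_conditions)
    ]
    return pd.DataFrame(
        {
            "condition": [f"c{c:02d}" for c in range(design.n_conditions)],
            "phase": phases,
            "time_h": [2.0 * c for c in range(design.n_conditions)],
        }
    )


def generate_activities(design: SyntheticDesign, seed: int):
    """Activity matrix (k × samples) with condition-block structure.

    Per component, condition baselines are N(0, condition_sd). Components
    in a planted block share a latent per-condition factor z so their
    baselines correlate at ≈ target_abs_rho (sign per ``signs``). Planted
    shifts add ``delta`` to the baselines of the shifted phase. Samples
    within a condition share its baseline and differ only by replicate
    noise; consecutive replicates form biological pairs recorded in the
    metadata, never inferred from names.
    """
    design.validate()
    rng = stage_rng(seed, "activities")
    k, n_cond, reps = design.n_components, design.n_conditions, design.replicates_per_condition
    conditions = _condition_table(design)

    raw = rng.normal(0.0, 1.0, size=(k, n_cond))
    mixed = raw.copy()
    for block in design.blocks:
        z = rng.normal(0.0, 1.0, size=n_cond)
        rho = block.target_abs_rho
        signs = block.sign_vector()
        for s, comp in zip(signs, block.components):
            mixed[comp] = s * (np.sqrt(rho) * z + np.sqrt(1.0 - rho) * raw[comp])
    baseline = design.condition_sd * mixed
    for shift in design.shifts:
        mask = (conditions["phase"] == shift.phase_b).to_numpy()
        baseline[shift.component, mask] += shift.delta

    sample_ids, meta_rows = [], []
    for c in range(n_cond):
        row = conditions.iloc[c]
        for r in range(reps):
            sid = f"{row.condition}r{r}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "strain": "SYN",
                    "phase": row.phase,
                    "medium": "low_metal",
                    "time_h": row.time_h,
                    "replicate_pair": f"{row.condition}p{r // 2}",
                    "od600": 5.0 * np.exp(0.11 * row.time_h),
                }
            )
    A = np.repeat(baseline, reps, axis=1) + rng.normal(
        0.0, design.replicate_noise_sd, size=(k, len(sample_ids))
    )
    activities = pd.DataFrame(A, index=_component_names(k), columns=sample_ids)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    return activities, metadata


def synthesize_expression(
    truth: PlantedTruth, noise_sd: float, seed: int
) -> ExpressionMatrix:
    """Forward model X = S·A + E with E i.i.d. N(0, noise_sd)."""
    S = truth.source_weights.to_numpy()
    A = truth.activity_profile.to_numpy()
    if S.shape[1] != A.shape[0]:
        raise ValueError("source and activity shapes are not conformable")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = stage_rng(seed, "expression_noise")
    X = S @ A + rng.normal(0.0, noise_sd, size=(S.shape[0], A.shape[1]))
    values = pd.DataFrame(
        X, index=truth.source_weights.index, columns=truth.activity_profile.columns
    )
    return ExpressionMatrix(values, truth.sample_metadata)


def simulate_dataset(design: SyntheticDesign, seed: int):
    """Full generator: (ExpressionMatrix, PlantedTruth) from one design
    and one seed, with expression noise at
    ``expression_noise_fraction × RMS(S·A)``."""
    S, member_sets = generate_sources(design, seed)
    A, metadata = generate_activities(design, seed)
    truth = PlantedTruth(
        source_weights=S,
        activity_profile=A,
        member_sets=member_sets,
        planted_shifts=tuple(design.shifts),
        planted_blocks=tuple(design.blocks),
        seed=seed,
        sample_metadata=metadata,
    )
    noise_sd = design.expression_noise_fraction * truth.signal_rms
    X = synthesize_expression(truth, noise_sd, seed)
    return X, truth


def generate_process_profile(
    F0: float = 0.535,
    mu_set: float = 0.11,
    t_grid=None,
    X0: float = 8.0,
    volume_l: float = 0.25,
) -> ProcessTimeSeries:
    """Idealised fed-batch time series under exponential feeding.

    Feed follows F(t) = F0·exp(μ_set·t) exactly, biomass grows at μ_set
    from X0 g/L CDW, OD600 = CDW / 0.34, and the CO2 formation rate is
    proportional to total biomass (CO2_PER_GRAM_CDW mol/h per g).
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 30.0 + 1e-9, 0.5)
    t = np.asarray(t_grid, dtype=float)
    if (t < 0).any():
        raise ValueError("process times must be non-negative")
    if not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    cdw = X0 * np.exp(mu_set * t)
    data = pd.DataFrame(
        {
            "time_h": t,
            "feed_mL_h": feed_rate(t, F0=F0, mu_set=mu_set),
            "cdw_g_L": cdw,
            "od600": cdw / OD_TO_CDW_FACTOR,
            "co2_mol_h": CO2_PER_GRAM_CDW * cdw * volume_l,
        }
    )
    return ProcessTimeSeries(data, volume_l=volume_l)
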