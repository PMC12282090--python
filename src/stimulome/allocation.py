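"""Proteome-allocation summaries from genome-scale model solutions.

This module consumes solution tables exported from a metabolism-and-
expression (ME) model with oxidative-damage reactions; it does not build
or solve the model. Two mass-flux ratios are computed:

    % proteome(pathway) = 100 · Σ_{i∈pathway} mw_i · V_i,translation
                                / Σ_j mw_j · V_j,translation

    % damaged proteome  = 100 · Σ_k mw_k · V_k,ComplexFormation
                                / Σ_j mw_j · V_j,translation

where mw is molecular weight, V_translation the protein translation
flux, and the k sum runs over the protein-damaging reactions (ids with
the ``damage_`` prefix). Both are ratios, so any consistent unit system
(e.g. g/mmol and mmol/gDW/h) cancels.

Intracellular ROS concentrations scale with the rate of ROS formation,
which tracks respiration: a strain's basal superoxide and hydrogen
peroxide levels are scaled by its oxygen uptake rate relative to a
reference (wild-type) strain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

DAMAGE_PREFIX = "damage_"

#: Basal intracellular ROS levels of a wild-type E. coli reference.
WT_BASAL_SUPEROXIDE_NMOL_L = 0.2
WT_BASAL_H2O2_NMOL_L = 50.0


@dataclass(frozen=True)
class RosState:
    """Intracellular ROS concentrations (nmol/L) at a given oxygen
    uptake rate (mmol/gDW/h)."""

    superoxide: float = WT_BASAL_SUPEROXIDE_NMOL_L
    hydrogen_peroxide: float = WT_BASAL_H2O2_NMOL_L
    oxygen_uptake_rate: float = 0.0

    def __post_init__(self):
        if min(self.superoxide, self.hydrogen_peroxide, self.oxygen_uptake_rate) < 0:
            raise ValueError("ROS state values must be non-negative")


@dataclass
class ModelSolution:
    """ME-model solution tables.

    ``proteins``: columns id, mw, v_translation, pathway.
    ``damage_reactions``: columns id (``damage_``-prefixed), mw,
    v_complex_formation.
    """

    proteins: pd.DataFrame
    damage_reactions: pd.DataFrame

    def __post_init__(self):
        prot = self.proteins
        for col in ("id", "mw", "v_translation", "pathway"):
            if col not in prot.columns:
                raise ValueError(f"proteins table missing column {col!r}")
        if (prot["mw"] <= 0).any():
            raise ValueError("molecular weights must be positive")
        if (prot["v_translation"] < 0).any():
            raise ValueError("translation fluxes must be non-negative")
        dmg = self.damage_reactions
        for col in ("id", "mw", "v_complex_formation"):
            if col not in dmg.columns:
                raise ValueError(f"damage table missing column {col!r}")
        if len(dmg):
            if (dmg["mw"] <= 0).any():
                raise ValueError("molecular weights must be positive")
            if (dmg["v_complex_formation"] < 0).any():
                raise ValueError("damage fluxes must be non-negative")
            bad = dmg.loc[~dmg["id"].str.startswith(DAMAGE_PREFIX), "id"]
            if len(bad):
                raise ValueError(
                    f"damage reaction ids must carry the {DAMAGE_PREFIX!r} prefix: "
                    f"{sorted(bad)}"
                )

    @classmethod
    def from_tsv(cls, proteins_path, damage_path) -> "ModelSolution":
        return cls(
            proteins=pd.read_csv(proteins_path, sep="\t"),
            damage_reactions=pd.read_csv(damage_path, sep="\t"),
        )

    def total_translation_mass_flux(self) -> float:
        return float((self.proteins["mw"] * self.proteins["v_translation"]).sum())


def percent_proteome(solution: ModelSolution, pathway: str) -> float:
    """Percent of total proteome mass flux translated for one pathway."""
    total = solution.total_translation_mass_flux()
    if total <= 0:
        raise ValueError("total translation mass flux is zero")
    sel = solution.proteins[solution.proteins["pathway"] == pathway]
    part = float((sel["mw"] * sel["v_translation"]).sum())
    return 100.0 * part / total


def percent_damaged_proteome(solution: ModelSolution) -> float:
    """Percent of proteome mass flux lost to damaging reactions."""
    total = solution.total_translation_mass_flux()
    if total <= 0:
        raise ValueError("total translation mass flux is zero")
    dmg = solution.damage_reactions
    part = float((dmg["mw"] * dmg["v_complex_formation"]).sum()) if len(dmg) else 0.0
    return 100.0 * part / total


def allocation_summary(solution: ModelSolution) -> pd.DataFrame:
    """Percent proteome per pathway plus the damaged-proteome percent."""
    pathways = sorted(solution.proteins["pathway"].unique())
    rows = [
        {"pathway": p, "percent_proteome": percent_proteome(solution, p)}
        for p in pathways
    ]
    rows.append(
        {"pathway": "damaged", "percent_proteome": percent_damaged_proteome(solution)}
    )
    return pd.DataFrame(rows)


def scale_ros(base: RosState, strain_our: float, wt_our: float) -> RosState:
    """Scale basal ROS concentrations by the strain's oxygen uptake rate
    relative to the wild-type reference."""
    if wt_our <= 0:
        raise ValueError("reference oxygen uptake rate must be positive")
    if strain_our < 0:
        raise ValueError("strain oxygen uptake rate must be non-negative")
    ratio = strain_our / wt_our
    return RosState(
        superoxide=base.superoxide * ratio,
        hydrogen_peroxide=base.hydrogen_peroxide * ratio,
        oxygen_uptake_rate=strain_our,
    )
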