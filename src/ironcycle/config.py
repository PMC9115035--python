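"""World configuration: every tunable of the simulator in one flat record.

Iron amounts are carried internally in "iron units" of ``unit_scale`` atoms
(default 1e5 atoms per unit), so that the literature per-cell-per-minute rates
become small per-tick numbers that interact sensibly with the fitted adsorbed-Fe2+
tolerance of 300.  One tick corresponds to one minute and one patch edge to 2 um.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Any

ADHESION_MODES = ("electrostatic", "biofilm")
ENCRUSTATION_MODES = ("shedding", "low_ph")

#: atoms of Fe3+ reduced per cell per minute including the electron-shuttle share
LITERATURE_PER_CELL_REDUCTION = 5.0e7
#: fraction of Shewanella-mediated reduction that runs through electron shuttles
SHUTTLE_SHARE = 0.8
#: atoms of Fe2+ oxidized per FeOB cell per minute (maximum biological rate)
LITERATURE_PER_CELL_OXIDATION = 3.6e7


def derive_contact_reduction_rate(
    per_cell_rate: float = LITERATURE_PER_CELL_REDUCTION,
    shuttle_share: float = SHUTTLE_SHARE,
    unit_scale: float = 1.0,
) -> float:
    """Contact-only reduction rate from a total per-cell rate.

    The measured whole-cell rate includes the shuttle-mediated share; the
    direct-contact rate is the remainder, ``per_cell_rate * (1 - shuttle_share)``.
    With the defaults this is 1e7 atoms/(cell*min).  Passing ``unit_scale``
    converts to internal iron units per tick.
    """
    return per_cell_rate * (1.0 - shuttle_share) / unit_scale


@dataclass
class WorldConfig:
    # --- world setup ---
    grid_side: int = 21
    fe_patch_percentage: float = 10.0
    fe_clustering: float = 0.8
    initial_number_fe3reducer: int = 50
    initial_number_fe2oxidizer: int = 50
    initial_number_nanoparticle: int = 0
    start_medium_fe2: float = 0.0
    max_ticks: int = 2880
    unit_scale: float = 1.0e5          # atoms per internal iron unit
    bulk_fe3_per_patch: float = 2.0e6  # iron units of Fe3+ per bulk patch

    # --- movement ---
    speed_fe2_oxidizer: float = 2.0    # patches / tick
    speed_fe3_reducer: float = 5.0     # patches / tick (doubled under chemotaxis)
    tumble_probability: float = 0.3    # per tick; tripled under chemotaxis
    chemo_persistence: int = 30        # ticks the chemotactic mode persists

    # --- nanoparticle characteristics ---
    iron_per_cubicnm: float = 5000.0   # model atoms per nm^3 of particle volume
    cell_surface_area: float = 3.5e6   # nm^2, rod 2 um x 0.5 um

    # --- process rates (iron units / tick unless stated) ---
    mineral_aggregation_probability: float = 100.0  # percent per contact
    contact_reduction_rate: float = 100.0           # 1e7 atoms/min at unit_scale 1e5
    fe2_ads_tolerance: float = 300.0                # iron units on a patch surface
    np_mineral_reduction_ratio: float = 100.0
    abiotic_oxidation_ratio: float = 0.01           # fraction of each Fe2+ pool per tick
    np_attachment_threshold: float = 50.0           # percent Fe3+ of total particle iron
    np_dissociation_threshold: float = 0.7          # fraction Fe2+ of total particle iron
    shedding_diameter: float = 10.0                 # nm
    shedding_sd: float = 2.0                        # nm, spread of the release draw
    fe2_equilibrium_rate: float = 0.02              # fraction of the deviation per tick
    e_shuttle_range: float = 10.0                   # patch lengths (20 um)
    fe2_solid_ineq: float = 0.9                     # equilibrium share adsorbed to solids
    contact_oxidation_rate: float = 360.0           # 3.6e7 atoms/min at unit_scale 1e5
    np_loss_percentage: float = 0.2                 # percent of free particles per tick

    # --- modes of action ---
    adhesion_mode: str = "electrostatic"
    encrustation_mode: str = "shedding"

    # biofilm detachment constants: p0 * 2^(-t/tau) / (1 + n_near) * (m_ox if oxic)
    detach_p0: float = 0.2
    detach_tau: float = 60.0
    detach_oxic_multiplier: float = 2.0

    # --- secondary-mineral aging ---
    aging_enabled: bool = False
    aging_lag: int = 200       # minutes without reduction before decay starts
    aging_rate: float = 0.003  # susceptibility lost per minute past the lag

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        c = self
        if c.grid_side < 3:
            raise ValueError("grid_side must be >= 3")
        for name in (
            "fe_patch_percentage",
            "mineral_aggregation_probability",
            "np_attachment_threshold",
            "np_loss_percentage",
        ):
            v = getattr(c, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        for name in ("fe_clustering", "abiotic_oxidation_ratio",
                     "np_dissociation_threshold", "fe2_equilibrium_rate",
                     "fe2_solid_ineq", "tumble_probability"):
            v = getattr(c, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("initial_number_fe3reducer", "initial_number_fe2oxidizer",
                     "initial_number_nanoparticle", "max_ticks", "chemo_persistence",
                     "aging_lag"):
            v = getattr(c, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        for name in ("start_medium_fe2", "bulk_fe3_per_patch", "speed_fe2_oxidizer",
                     "speed_fe3_reducer", "contact_reduction_rate", "fe2_ads_tolerance",
                     "np_mineral_reduction_ratio", "shedding_diameter", "shedding_sd",
                     "e_shuttle_range", "contact_oxidation_rate", "detach_p0",
                     "detach_tau", "aging_rate"):
            if getattr(c, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("unit_scale", "iron_per_cubicnm", "cell_surface_area",
                     "np_mineral_reduction_ratio", "detach_oxic_multiplier"):
            if getattr(c, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if c.adhesion_mode not in ADHESION_MODES:
            raise ValueError(f"adhesion_mode must be one of {ADHESION_MODES}")
        if c.encrustation_mode not in ENCRUSTATION_MODES:
            raise ValueError(f"encrustation_mode must be one of {ENCRUSTATION_MODES}")
        if self.tumble_probability * 3.0 > 1.0:
            raise ValueError("tumble_probability must be <= 1/3 so the tripled "
                             "chemotactic tumble rate remains a probability")

    # ------------------------------------------------------------------
    def with_overrides(self, **overrides: Any) -> "WorldConfig":
        """Return a validated copy with the given fields replaced."""
        return replace(self, **overrides)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


def default_config(**overrides: Any) -> WorldConfig:
    return WorldConfig(**overrides)
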