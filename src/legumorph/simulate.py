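"""Deterministic forward simulator of potential shoot development.

The framework treats vegetative morphogenesis as a set of rules that are
linear in thermal time (TT):

* each axis produces phytomers at a constant rate (one per phyllochron);
* every phytomer on the main or a primary axis carries an axillary bud that
  bursts exactly ``ram_dist`` bearer phyllochrons after the phytomer appears
  (sylleptic branching with probability 1 in the absence of stress);
* primary axes spawn from the collar at regular ``br1`` main-phyllochron
  intervals; secondary axes spawn at each budburst; secondary axes do not
  branch further;
* every organ of a phytomer expands along a logistic in phyllochronic time,
  towards a final dimension set by a rank profile and the species maxima.

All event times are computed in closed form; a reporting TT grid only decides
where snapshots are taken, never the architecture itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import leaf_area  # noqa: F401  (re-exported: part of the model surface)
from .errors import ConfigurationError, SimulationAborted
from .kinetics import logistic_fraction
from .species import SpeciesConfig


@dataclass
class Organ:
    """One organ of a phytomer with its expansion kinetics.

    ``l_max`` is a length in cm (for the leaflet organ: the central leaflet);
    the leaflet organ additionally carries the whole-leaf final area (cm^2)
    and the leaflet count.
    """

    organ_type: str
    l_max: float
    s: float
    t50: float
    n_leaflets: int | None = None
    area_max: float | None = None


@dataclass
class Phytomer:
    rank: int                      # 1-based from the axis base
    tt_appear: float               # degree-days
    organs: list = field(default_factory=list)
    bud_burst_tt: float | None = None   # None on secondary axes (no branching)


@dataclass
class Axis:
    axis_id: str
    category: str                  # "main" | "primary" | "secondary"
    parent_axis: str | None        # None = borne at the collar
    parent_rank: int | None
    tt_start: float                # degree-days
    phyllochron: float             # degree-days per phytomer
    phytomers: list = field(default_factory=list)


@dataclass
class PlantArchitecture:
    """Simulated state: hierarchical axes plus the species configuration."""

    config: SpeciesConfig
    horizon_tt: float
    axes: list = field(default_factory=list)

    def axis(self, axis_id: str) -> Axis:
        for ax in self.axes:
            if ax.axis_id == axis_id:
                return ax
        raise KeyError(axis_id)

    def summary(self, tt: float) -> dict:
        return plant_summaries(self, tt)

    def snapshots(self, tt_grid) -> pd.DataFrame:
        return pd.DataFrame([self.summary(tt) for tt in np.asarray(tt_grid, dtype=float)])

    def to_long_frame(self, tt_grid) -> pd.DataFrame:
        """Long-format organ table: one row per (snapshot, axis, phytomer, organ)."""
        rows = []
        for tt in np.asarray(tt_grid, dtype=float):
            for ax in self.axes:
                for ph in ax.phytomers:
                    if ph.tt_appear > tt:
                        continue
                    tau = (tt - ph.tt_appear) / ax.phyllochron
                    for organ in ph.organs:
                        frac = organ_relative_length(organ, tau)
                        rows.append({
                            "snapshot_tt": tt,
                            "axis_id": ax.axis_id,
                            "category": ax.category,
                            "parent_axis": ax.parent_axis if ax.parent_axis else "collar",
                            "parent_rank": ax.parent_rank,
                            "phytomer_rank": ph.rank,
                            "organ_type": organ.organ_type,
                            "current_length_cm": organ.l_max * frac,
                            "final_length_cm": organ.l_max,
                            "leaf_area_cm2": (organ.area_max * frac ** 2
                                              if organ.area_max is not None else np.nan),
                        })
        return pd.DataFrame(rows)


# -- elementary rules ---------------------------------------------------------

def phytomer_stage(axis: Axis, tt: float) -> float:
    """Decimal phytomer count of an axis at TT (0 before the axis starts)."""
    return max(0.0, (tt - axis.tt_start) / axis.phyllochron)


def appearance_tt(axis: Axis, rank: int) -> float:
    """TT at which phytomer ``rank`` appears on an axis (arithmetic progression)."""
    return axis.tt_start + rank * axis.phyllochron


def branch_burst_tt(phytomer: Phytomer, bearer: Axis, config: SpeciesConfig) -> float:
    """Budburst TT of a phytomer's axillary bud on a main or primary axis."""
    return phytomer.tt_appear + config.ram_dist * bearer.phyllochron


def organ_relative_length(organ: Organ, tau: float):
    """Fraction of the final dimension reached ``tau`` phyllochrons after appearance."""
    return logistic_fraction(tau, organ.s, organ.t50)


def organ_final_dimension(config: SpeciesConfig, organ_type: str, rank: int):
    """Final dimension of an organ type at a rank (cm; cm^2 for 'leaf')."""
    return config.final_dimension(organ_type, rank)


# -- architecture construction ------------------------------------------------

def _build_organs(config: SpeciesConfig, rank: int) -> list:
    organs = []
    for organ_type in config.organ_types():
        s, t50 = config.kinetic(organ_type)
        if organ_type == "leaflet":
            organs.append(Organ("leaflet", config.leaflet_length_max(rank), s, t50,
                                n_leaflets=config.n_leaflets(rank),
                                area_max=config.final_dimension("leaf", rank)))
        else:
            organs.append(Organ(organ_type, config.final_dimension(organ_type, rank), s, t50))
    return organs


def _fill_phytomers(axis: Axis, horizon_tt: float, config: SpeciesConfig,
                    build_organs: bool) -> None:
    n = int(np.floor((horizon_tt - axis.tt_start) / axis.phyllochron + 1e-9))
    if n > config.max_phytomers_per_axis:
        raise SimulationAborted(
            f"axis {axis.axis_id}: {n} phytomers exceeds guard "
            f"max_phytomers_per_axis={config.max_phytomers_per_axis}")
    for rank in range(1, n + 1):
        organs = _build_organs(config, rank) if build_organs else []
        axis.phytomers.append(Phytomer(rank, appearance_tt(axis, rank), organs))


def simulate_development(config: SpeciesConfig, tt_grid=None, horizon_tt: float | None = None,
                         build_organs: bool = True, allow_secondary: bool = True
                         ) -> PlantArchitecture:
    """Simulate potential development up to a TT horizon.

    ``tt_grid`` (increasing from 0) is a reporting schedule; the architecture
    depends only on its last value (equivalently pass ``horizon_tt`` directly).
    ``allow_secondary=False`` suppresses the outgrowth of axillary buds into
    secondary axes (budburst times are still recorded on each phytomer).
    """
    if tt_grid is not None:
        grid = np.asarray(tt_grid, dtype=float)
        if grid.size == 0 or grid[0] < 0 or np.any(np.diff(grid) <= 0) and grid.size > 1:
            raise ConfigurationError("tt_grid must be non-empty and strictly increasing from >= 0")
        horizon_tt = float(grid[-1])
    if horizon_tt is None or horizon_tt < 0:
        raise ConfigurationError("a non-negative TT horizon is required")

    main = Axis("main", "main", None, None, 0.0, config.phy0)
    axes = [main]
    _fill_phytomers(main, horizon_tt, config, build_organs)

    # Primary axes spawn from the collar at regular intervals of br1 main
    # phyllochrons, the first after a configurable collar lag.
    i = 0
    while True:
        t_spawn = (config.collar_lag + i * config.br1) * config.phy0
        if t_spawn > horizon_tt:
            break
        ax = Axis(f"P{i + 1}", "primary", None, None, t_spawn, config.primary_phyllochron)
        _fill_phytomers(ax, horizon_tt, config, build_organs)
        axes.append(ax)
        i += 1
        if len(axes) > config.n_axes_max:
            raise SimulationAborted(
                f"axis count exceeds guard n_axes_max={config.n_axes_max} "
                f"while spawning primary axes at TT={t_spawn:.1f}")

    # Every main/primary phytomer branches ram_dist bearer phyllochrons after
    # it appears; the bud grows into a secondary axis.  No tertiary branching.
    for bearer in list(axes):
        if bearer.category == "secondary":
            continue
        for ph in bearer.phytomers:
            ph.bud_burst_tt = branch_burst_tt(ph, bearer, config)
            if not allow_secondary or ph.bud_burst_tt > horizon_tt:
                continue
            sec = Axis(f"S.{bearer.axis_id}.{ph.rank}", "secondary",
                       bearer.axis_id, ph.rank, ph.bud_burst_tt,
                       config.secondary_phyllochron)
            _fill_phytomers(sec, horizon_tt, config, build_organs)
            axes.append(sec)
            if len(axes) > config.n_axes_max:
                raise SimulationAborted(
                    f"axis count exceeds guard n_axes_max={config.n_axes_max} "
                    f"while spawning secondary axes (TT horizon {horizon_tt:.1f})")

    return PlantArchitecture(config=config, horizon_tt=horizon_tt, axes=axes)


# -- plant-level summaries ----------------------------------------------------

def plant_summaries(arch: PlantArchitecture, tt: float) -> dict:
    """Recompute plant-level summaries from the axes at a given TT.

    Total leaf area treats the instantaneous area of a leaf as the final area
    times the squared relative leaflet length (area scales with length x
    width, both following the leaflet kinetic).  Height is the summed current
    internode length along the main axis.
    """
    if tt < 0 or tt > arch.horizon_tt + 1e-9:
        raise ConfigurationError(f"TT {tt} outside simulated horizon {arch.horizon_tt}")
    counts = {"main": 0, "primary": 0, "secondary": 0}
    n_phytomers = {"main": 0, "primary": 0, "secondary": 0}
    total_area = 0.0
    height = 0.0
    for ax in arch.axes:
        if ax.tt_start > tt:
            continue
        counts[ax.category] += 1
        for ph in ax.phytomers:
            if ph.tt_appear > tt:
                continue
            n_phytomers[ax.category] += 1
            tau = (tt - ph.tt_appear) / ax.phyllochron
            for organ in ph.organs:
                frac = float(organ_relative_length(organ, tau))
                if organ.organ_type == "leaflet" and organ.area_max is not None:
                    total_area += organ.area_max * frac ** 2
                if organ.organ_type == "internode" and ax.category == "main":
                    height += organ.l_max * frac
    return {
        "tt": float(tt),
        "n_axes_main": counts["main"],
        "n_axes_primary": counts["primary"],
        "n_axes_secondary": counts["secondary"],
        "n_phytomers_main": n_phytomers["main"],
        "n_phytomers_total": sum(n_phytomers.values()),
        "main_axis_stage": phytomer_stage(arch.axis("main"), tt),
        "total_leaf_area_cm2": total_area,
        "height_cm": height,
    }
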