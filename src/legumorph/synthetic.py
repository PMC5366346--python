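"""Synthetic observation datasets emulating the greenhouse protocol.

The generator runs the deterministic forward model and samples it the way the
plants were measured: weekly axis/phytomer censuses on a decimal scale, daily
organ-length series on fixed phytomer ranks (5-7 and 11-13 of the main axis,
3-5 of a primary axis), leaf scans of mature leaves, and budburst records.
Measurement noise is additive Gaussian on the observations only; the
generative rules themselves stay deterministic, so one seed fully determines
a dataset and the ground-truth trait record is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataValidationError
from .estimate import ObservationDataset, TRAIT_COLUMNS
from .simulate import organ_relative_length, simulate_development
from .species import SpeciesConfig
from .thermal import TemperatureSeries, cumulative_thermal_time


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise.

    ``length_sd`` and ``area_sd`` are fractions of the organ's final dimension;
    ``stage_sd`` is in phytomers on the decimal census counts (noisy counts are
    floored at the previous observation so censuses stay monotone).
    """

    length_sd: float = 0.05
    stage_sd: float = 0.2
    area_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.length_sd, self.stage_sd, self.area_sd) < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, seed)


@dataclass(frozen=True)
class SamplingSchedule:
    """When and where the virtual plants are measured."""

    census_interval_days: float = 7.0
    length_interval_days: float = 1.0
    main_ranks: tuple = (5, 6, 7, 11, 12, 13)
    primary_ranks: tuple = (3, 4, 5)
    horizon_days: float = 80.0

    def __post_init__(self) -> None:
        if self.census_interval_days <= 0 or self.length_interval_days <= 0:
            raise ConfigurationError("sampling intervals must be positive")
        if self.horizon_days <= 0:
            raise ConfigurationError("horizon must be positive")
        if min(self.main_ranks + self.primary_ranks, default=1) < 1:
            raise ConfigurationError("monitored ranks must be >= 1")


def generate_temperature_series(mean: float, diurnal_amplitude: float, days: float,
                                step_minutes: float = 15.0) -> TemperatureSeries:
    """Deterministic sinusoidal diurnal temperature trace (deg C).

    ``T(t) = mean - amplitude * cos(2*pi*t)`` with t in days, sampled every
    ``step_minutes`` (the greenhouse logger recorded 15-min means).
    """
    if step_minutes <= 0:
        raise ConfigurationError("step must be positive")
    n = int(round(days * 24 * 60 / step_minutes))
    t = np.linspace(0.0, days, n + 1)
    return TemperatureSeries(t, mean - diurnal_amplitude * np.cos(2 * np.pi * t))


def _tt_lookup(temperature: TemperatureSeries, config: SpeciesConfig):
    ctt = cumulative_thermal_time(temperature, config.beta)

    def tt_at(day):
        return np.interp(day, temperature.days, ctt)

    return tt_at


def _check_ranks_reachable(config, schedule, horizon_tt, axes):
    """Every monitored rank must appear *and* finish expanding in the horizon."""
    _, end = config.expansion_window()
    monitored = []
    for ax in axes:
        if ax.category == "main":
            monitored.append((ax, schedule.main_ranks))
        elif ax.axis_id == "P1":
            monitored.append((ax, schedule.primary_ranks))
    for ax, ranks in monitored:
        for rank in sorted(ranks):
            finish = ax.tt_start + (rank + max(end, 0.0)) * ax.phyllochron
            if finish > horizon_tt + 1e-9:
                raise DataValidationError(
                    f"horizon too short: rank {rank} on axis {ax.axis_id} only completes "
                    f"expansion at TT {finish:.0f} > horizon {horizon_tt:.0f}")


def generate_observations(config: SpeciesConfig, schedule: SamplingSchedule | None = None,
                          noise: NoiseModel | None = None,
                          temperature: TemperatureSeries | None = None,
                          n_plants: int = 4,
                          tables: tuple = ("census", "lengths", "scans", "branching"),
                          ) -> tuple[ObservationDataset, dict]:
    """Generate an observation dataset plus its ground-truth trait record.

    The forward model is simulated once (potential development is
    deterministic, so replicate plants share the same architecture) and
    sampled per plant with independent measurement noise.  Returns
    ``(dataset, truth)`` where ``truth`` holds the 12 trait-matrix values.
    """
    schedule = schedule or SamplingSchedule()
    noise = noise or NoiseModel()
    if n_plants < 1:
        raise ConfigurationError("n_plants must be >= 1")
    rng = np.random.default_rng(noise.seed)
    if temperature is None:
        temperature = generate_temperature_series(config.beta.t_ref, 0.0,
                                                  schedule.horizon_days)
    if temperature.span[1] < schedule.horizon_days - 1e-9:
        raise DataValidationError("temperature series shorter than the sampling horizon")
    tt_at = _tt_lookup(temperature, config)
    horizon_tt = float(tt_at(schedule.horizon_days))
    arch = simulate_development(config, horizon_tt=horizon_tt,
                                build_organs="lengths" in tables)
    if "lengths" in tables:
        _check_ranks_reachable(config, schedule, horizon_tt, arch.axes)
    plants = [f"plant{i + 1}" for i in range(n_plants)]

    census_rows, length_rows, scan_rows, branch_rows = [], [], [], []

    if "census" in tables:
        days = np.arange(0.0, schedule.horizon_days + 1e-9, schedule.census_interval_days)
        tts = np.asarray(tt_at(days), dtype=float)
        for plant in plants:
            for ax in arch.axes:
                last = 0.0
                for day, tt in zip(days, tts):
                    if tt < ax.tt_start:
                        continue
                    stage = (tt - ax.tt_start) / ax.phyllochron
                    if noise.stage_sd > 0:
                        stage = max(last, max(0.0, stage + rng.normal(0.0, noise.stage_sd)))
                    last = stage
                    census_rows.append({"plant_id": plant, "axis_id": ax.axis_id,
                                        "category": ax.category, "species": config.name,
                                        "day": day, "tt": tt, "decimal_count": stage})

    if "lengths" in tables:
        days = np.arange(0.0, schedule.horizon_days + 1e-9, schedule.length_interval_days)
        tts = np.asarray(tt_at(days), dtype=float)
        monitored = []
        for ax in arch.axes:
            ranks = (schedule.main_ranks if ax.category == "main"
                     else schedule.primary_ranks if ax.axis_id == "P1" else ())
            for rank in ranks:
                if rank <= len(ax.phytomers):
                    monitored.append((ax, ax.phytomers[rank - 1]))
        for plant in plants:
            for ax, ph in monitored:
                for organ in ph.organs:
                    sd = noise.length_sd * organ.l_max
                    for day, tt in zip(days, tts):
                        if tt < ph.tt_appear:
                            continue
                        tau = (tt - ph.tt_appear) / ax.phyllochron
                        value = organ.l_max * float(organ_relative_length(organ, tau))
                        if sd > 0:
                            value = max(0.0, value + rng.normal(0.0, sd))
                        length_rows.append({"plant_id": plant, "axis_id": ax.axis_id,
                                            "category": ax.category,
                                            "phytomer_rank": ph.rank,
                                            "organ_type": organ.organ_type,
                                            "day": day, "tt": tt, "length_cm": value})

    if "scans" in tables:
        # Leaves scanned at the end of the experiment: main-axis ranks whose
        # leaf has effectively completed expansion (>= 95 %) by the horizon.
        main = arch.axis("main")
        s_lf, t50_lf = config.kinetic("leaflet")
        tau_95 = t50_lf + config.d95["leaflet"] / 2.0
        for plant in plants:
            for ph in main.phytomers:
                if ph.tt_appear + tau_95 * main.phyllochron > horizon_tt:
                    break
                rank = ph.rank
                length = config.leaflet_length_max(rank)
                width = config.leaflet_width_ratio * length
                n = config.n_leaflets(rank)
                area = config.final_dimension("leaf", rank)
                if noise.area_sd > 0:
                    area = max(0.0, area * (1.0 + rng.normal(0.0, noise.area_sd)))
                scan_rows.append({"plant_id": plant, "rank": rank,
                                  "leaflet_length_cm": length,
                                  "leaflet_width_cm": width,
                                  "n_leaflets": n, "area_cm2": area})

    if "branching" in tables:
        for plant in plants:
            for ax in arch.axes:
                if ax.category == "secondary":
                    continue
                for ph in ax.phytomers:
                    observed = ph.bud_burst_tt is not None and ph.bud_burst_tt <= horizon_tt
                    branch_rows.append({"plant_id": plant, "axis_id": ax.axis_id,
                                        "category": ax.category,
                                        "phytomer_rank": ph.rank,
                                        "burst_observed": observed,
                                        "tt": ph.bud_burst_tt if observed else np.nan})

    dataset = ObservationDataset(
        census=pd.DataFrame(census_rows),
        lengths=pd.DataFrame(length_rows),
        scans=pd.DataFrame(scan_rows),
        branching=pd.DataFrame(branch_rows),
    )
    truth = {col: config.trait_values()[col] for col in TRAIT_COLUMNS}
    return dataset, truth
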