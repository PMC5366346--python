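"""Species configuration: the morphogenetic trait set of one forage legume.

A :class:`SpeciesConfig` bundles everything the simulator and the synthetic
generator need for one species: phyllochrons of the three axis categories,
branching parameters, organ-expansion kinetics (d95/t50 per organ type),
final organ dimensions with their rank profiles, and the leaflet-count rule.

Six configurations are packaged (alfalfa A, white clover WC, red clover RC,
sainfoin SF, birdsfoot trefoil BT, kura clover KC).  Printed reference values
anchor them; entries marked ``interpolated`` in the YAML are plausible
placeholders chosen to respect the published orderings between species and
are overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .allometry import ALLOMETRY_COEFFICIENT
from .errors import ConfigurationError
from .kinetics import s_from_d95
from .thermal import BetaThermalParams

ORGAN_TYPES = ("leaflet", "petiole", "internode", "stipule")


@dataclass(frozen=True)
class OrganProfile:
    """Relative final-dimension profile along an axis.

    Linear rise from ``f0`` (relative size at rank 1) to 1 at ``r_peak``, then
    a plateau, declining by ``decline`` per rank (floored at 0) if non-zero.
    """

    f0: float = 0.4
    r_peak: int = 8
    decline: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.f0 <= 1):
            raise ConfigurationError(f"profile f0 must be in (0, 1], got {self.f0}")
        if self.r_peak < 1:
            raise ConfigurationError(f"profile r_peak must be >= 1, got {self.r_peak}")
        if self.decline < 0:
            raise ConfigurationError(f"profile decline must be >= 0, got {self.decline}")

    def value(self, rank: int) -> float:
        if rank < 1:
            raise ConfigurationError(f"phytomer rank must be >= 1, got {rank}")
        if rank < self.r_peak:
            if self.r_peak == 1:
                return 1.0
            return self.f0 + (1.0 - self.f0) * (rank - 1) / (self.r_peak - 1)
        return max(0.0, 1.0 - self.decline * (rank - self.r_peak))


@dataclass(frozen=True)
class LeafletRule:
    """Leaflet count per leaf: fixed (trifoliolate) or rising with rank.

    The ``rank_linear`` form (sainfoin) rises linearly from ``base`` leaflets
    at rank 1 to ``cap`` at ``cap_rank``, rounded to the nearest odd integer
    (compound leaves carry a terminal leaflet plus pairs).
    """

    kind: str = "fixed"
    count: int = 3
    base: int = 5
    cap: int = 25
    cap_rank: int = 12

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "rank_linear"):
            raise ConfigurationError(f"unknown leaflet rule kind {self.kind!r}")
        if min(self.count, self.base, self.cap) < 1 or self.cap_rank < 1:
            raise ConfigurationError("leaflet counts and cap_rank must be >= 1")

    def count_at(self, rank: int) -> int:
        if self.kind == "fixed":
            return self.count
        frac = min(1.0, (rank - 1) / max(1, self.cap_rank - 1))
        n = self.base + (self.cap - self.base) * frac
        odd = 2 * round((n - 1) / 2) + 1
        return int(min(max(odd, 1), self.cap))


_POSITIVE_FIELDS = ("phy0", "br1", "phy1", "phy2", "max_pet", "max_in", "max_lf")


@dataclass(frozen=True)
class SpeciesConfig:
    """Full morphogenetic parameter set of one species.

    Phyllochron semantics: ``phy0`` is the main-axis phyllochron in degree-days
    per phytomer; ``phy1`` and ``phy2`` are *relative development rates*
    (phytomer per phytomer) of primary and secondary axes with respect to the
    main axis, so a primary axis has phyllochron ``phy0 / phy1``.

    Kinetics: ``d95_*`` are 5-95 % expansion durations and ``t50_*`` are
    half-expansion delays, both in phyllochrons of the bearing axis, referenced
    to the appearance of the bearer leaf (leaflet t50 is 0 by convention; a
    negative ``t50_in`` means internodes expand before leaflets, as in white
    clover).
    """

    name: str
    code: str
    phy0: float
    br1: float
    phy1: float
    phy2: float
    ram_dist: float
    d95: dict = field(default_factory=dict)      # organ type -> phyllochrons
    t50: dict = field(default_factory=dict)      # organ type -> phyllochrons
    max_pet: float = 1.0                         # cm
    max_in: float = 1.0                          # cm
    max_lf: float = 1.0                          # cm^2 (whole-leaf area)
    max_stip: float = 1.0                        # cm
    has_stipule: bool = False
    leaflet_rule: LeafletRule = field(default_factory=LeafletRule)
    leaflet_width_ratio: float = 0.6             # central leaflet width / length
    profiles: dict = field(default_factory=dict)  # "leaf"/"petiole"/"internode"
    beta: BetaThermalParams = field(default_factory=BetaThermalParams)
    first_branch_lag: float | None = None        # phyllochrons; default br1
    n_axes_max: int = 2000
    max_phytomers_per_axis: int = 500
    interpolated: tuple = ()

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.ram_dist < 0:
            raise ConfigurationError(f"ram_dist must be >= 0, got {self.ram_dist}")
        if not (0 < self.leaflet_width_ratio <= 1):
            raise ConfigurationError("leaflet_width_ratio must be in (0, 1]")
        for organ in self.organ_types():
            if organ not in self.d95 or self.d95[organ] <= 0:
                raise ConfigurationError(f"d95 missing or non-positive for {organ!r}")
        for organ in ("petiole", "internode"):
            if organ not in self.t50:
                raise ConfigurationError(f"t50 offset missing for {organ!r}")
        if self.first_branch_lag is not None and self.first_branch_lag < 0:
            raise ConfigurationError("first_branch_lag must be >= 0")
        for key in ("leaf", "petiole", "internode"):
            if key not in self.profiles:
                raise ConfigurationError(f"profile missing for {key!r}")

    # -- axis-level parameters ------------------------------------------------

    @property
    def primary_phyllochron(self) -> float:
        return self.phy0 / self.phy1

    @property
    def secondary_phyllochron(self) -> float:
        return self.phy0 / self.phy2

    @property
    def collar_lag(self) -> float:
        """Phyllochrons before the first primary axis spawns (default br1)."""
        return self.br1 if self.first_branch_lag is None else self.first_branch_lag

    # -- organ-level parameters ----------------------------------------------

    def organ_types(self) -> tuple:
        return ORGAN_TYPES if self.has_stipule else ORGAN_TYPES[:3]

    def kinetic(self, organ_type: str) -> tuple[float, float]:
        """(steepness s, t50) of the expansion logistic for one organ type."""
        if organ_type not in self.organ_types():
            raise ConfigurationError(f"unknown organ type {organ_type!r} for {self.name}")
        t50 = 0.0 if organ_type == "leaflet" else float(self.t50.get(organ_type, 0.0))
        return s_from_d95(self.d95[organ_type]), t50

    def expansion_window(self) -> tuple[float, float]:
        """Phyllochronic span (first organ 5 %, last organ 95 %) of a phytomer."""
        starts, ends = [], []
        for organ in self.organ_types():
            s, t50 = self.kinetic(organ)
            half = self.d95[organ] / 2.0
            starts.append(t50 - half)
            ends.append(t50 + half)
        return min(starts), max(ends)

    def final_dimension(self, organ_type: str, rank: int):
        """Final organ dimension at a rank: cm, or cm^2 for the whole leaf."""
        if organ_type == "leaf":
            return self.max_lf * self.profiles["leaf"].value(rank)
        if organ_type == "leaflet":
            return self.leaflet_length_max(rank)
        if organ_type == "petiole":
            return self.max_pet * self.profiles["petiole"].value(rank)
        if organ_type == "internode":
            return self.max_in * self.profiles["internode"].value(rank)
        if organ_type == "stipule":
            return self.max_stip * self.profiles.get("stipule", self.profiles["leaf"]).value(rank)
        raise ConfigurationError(f"unknown organ type {organ_type!r}")

    def n_leaflets(self, rank: int) -> int:
        return self.leaflet_rule.count_at(rank)

    def leaflet_length_max(self, rank: int) -> float:
        """Central leaflet length (cm) consistent with the leaf-area allometry."""
        area = self.final_dimension("leaf", rank)
        n = self.n_leaflets(rank)
        return math.sqrt(area / (ALLOMETRY_COEFFICIENT * self.leaflet_width_ratio * n))

    # -- trait-matrix view ----------------------------------------------------

    def trait_values(self) -> dict:
        """The species' values for the 12 trait-matrix columns."""
        return {
            "phy0": self.phy0,
            "br1": self.br1,
            "phy1": self.phy1,
            "ram_dist": self.ram_dist,
            "d95_in": self.d95["internode"],
            "d95_pet": self.d95["petiole"],
            "d95_lf": self.d95["leaflet"],
            "t50_pet": self.t50["petiole"],
            "t50_in": self.t50["internode"],
            "max_pet": self.max_pet,
            "max_in": self.max_in,
            "max_lf": self.max_lf,
        }


# -- loading ------------------------------------------------------------------

def _profile(entry) -> OrganProfile:
    if entry is None:
        return OrganProfile()
    return OrganProfile(f0=float(entry.get("f0", 0.4)),
                        r_peak=int(entry.get("r_peak", 8)),
                        decline=float(entry.get("decline", 0.0)))


def config_from_dict(raw: dict) -> SpeciesConfig:
    """Build a :class:`SpeciesConfig` from a plain mapping (YAML schema)."""
    try:
        d95 = {"leaflet": float(raw["d95_lf"]),
               "petiole": float(raw["d95_pet"]),
               "internode": float(raw["d95_in"])}
        t50 = {"leaflet": 0.0,
               "petiole": float(raw["t50_pet"]),
               "internode": float(raw["t50_in"])}
        has_stipule = bool(raw.get("has_stipule", False))
        if has_stipule:
            d95["stipule"] = float(raw.get("d95_stip", raw["d95_lf"]))
            t50["stipule"] = float(raw.get("t50_stip", 0.0))
        leaflets = raw.get("leaflets", {}) or {}
        rule = LeafletRule(kind=leaflets.get("kind", "fixed"),
                           count=int(leaflets.get("count", 3)),
                           base=int(leaflets.get("base", 5)),
                           cap=int(leaflets.get("cap", 25)),
                           cap_rank=int(leaflets.get("cap_rank", 12)))
        profiles_raw = raw.get("profiles", {}) or {}
        profiles = {key: _profile(profiles_raw.get(key))
                    for key in ("leaf", "petiole", "internode")}
        if "stipule" in profiles_raw:
            profiles["stipule"] = _profile(profiles_raw["stipule"])
        beta_raw = raw.get("beta", {}) or {}
        beta = BetaThermalParams(t_min=float(beta_raw.get("t_min", 0.0)),
                                 t_max=float(beta_raw.get("t_max", 40.0)),
                                 q=float(beta_raw.get("q", 1.5)))
        return SpeciesConfig(
            name=str(raw["name"]),
            code=str(raw.get("code", raw["name"])),
            phy0=float(raw["phy0"]),
            br1=float(raw["br1"]),
            phy1=float(raw["phy1"]),
            phy2=float(raw.get("phy2", 0.6)),
            ram_dist=float(raw["ram_dist"]),
            d95=d95,
            t50=t50,
            max_pet=float(raw["max_pet"]),
            max_in=float(raw["max_in"]),
            max_lf=float(raw["max_lf"]),
            max_stip=float(raw.get("max_stip", 1.0)),
            has_stipule=has_stipule,
            leaflet_rule=rule,
            leaflet_width_ratio=float(raw.get("leaflet_width_ratio", 0.6)),
            profiles=profiles,
            beta=beta,
            first_branch_lag=(None if raw.get("first_branch_lag") is None
                              else float(raw["first_branch_lag"])),
            n_axes_max=int(raw.get("n_axes_max", 2000)),
            max_phytomers_per_axis=int(raw.get("max_phytomers_per_axis", 500)),
            interpolated=tuple(raw.get("interpolated", ())),
        )
    except KeyError as exc:
        raise ConfigurationError(f"species config missing required key {exc.args[0]!r}") from exc


def load_species_config(path) -> SpeciesConfig:
    """Load a species configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return config_from_dict(raw)


def packaged_species() -> tuple:
    """Names of the species configurations shipped with the package."""
    return ("alfalfa", "white_clover", "red_clover", "sainfoin",
            "birdsfoot_trefoil", "kura_clover")


def get_species(name: str) -> SpeciesConfig:
    """Load a packaged species configuration by name (see packaged_species)."""
    if name not in packaged_species():
        raise ConfigurationError(
            f"unknown packaged species {name!r}; choose from {packaged_species()}")
    ref = resources.files("legumorph.data").joinpath(f"{name}.yaml")
    with resources.as_file(ref) as path:
        return load_species_config(path)
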