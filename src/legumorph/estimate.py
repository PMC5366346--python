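"""Inverse pipeline: recover morphogenetic traits from observation tables.

The estimators mirror how the traits are defined:

* phyllochrons from ordinary least squares of the decimal phytomer count on
  thermal time, restricted to censuses with at least three unfolded leaves;
  the phyllochron is the reciprocal slope and the x-intercept dates the axis;
* organ kinetics from a three-parameter logistic in phyllochronic time, with
  the 5-95 % duration d95 = 2*ln(19)/s; phytomer replicates are pooled per
  organ type through a joint fit sharing (s, t50) across series;
* branching from per-position budburst probabilities and the appearance-to-
  burst delay in bearer phyllochrons;
* the leaf-area allometry by regression through the origin of area on
  length x width x leaflet count;
* a trait matrix (individuals x 12 traits) feeding a correlation-matrix PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA

from .errors import (DataValidationError, DegenerateFitError, InsufficientDataError)
from .kinetics import d95_from_s, logistic_fraction, s_from_d95  # noqa: F401 (d95/s re-exported)

#: Trait-matrix columns, in the canonical order.
TRAIT_COLUMNS = ("phy0", "br1", "phy1", "ram_dist", "d95_in", "d95_pet", "d95_lf",
                 "t50_pet", "t50_in", "max_pet", "max_in", "max_lf")

_CENSUS_COLS = {"plant_id", "axis_id", "category", "tt", "decimal_count"}
_LENGTH_COLS = {"plant_id", "axis_id", "category", "phytomer_rank", "organ_type",
                "tt", "length_cm"}
_SCAN_COLS = {"plant_id", "rank", "leaflet_length_cm", "leaflet_width_cm",
              "n_leaflets", "area_cm2"}
_BRANCH_COLS = {"plant_id", "axis_id", "category", "phytomer_rank",
                "burst_observed", "tt"}


@dataclass
class ObservationDataset:
    """Tidy observation tables: censuses, length series, leaf scans, branching."""

    census: pd.DataFrame
    lengths: pd.DataFrame
    scans: pd.DataFrame
    branching: pd.DataFrame

    def validate(self) -> "ObservationDataset":
        for frame, cols, name in ((self.census, _CENSUS_COLS, "census"),
                                  (self.lengths, _LENGTH_COLS, "lengths"),
                                  (self.scans, _SCAN_COLS, "scans"),
                                  (self.branching, _BRANCH_COLS, "branching")):
            if frame.empty:
                continue
            missing = cols - set(frame.columns)
            if missing:
                raise DataValidationError(f"{name} table missing columns {sorted(missing)}")
        if len(self.lengths) and (self.lengths["length_cm"] < 0).any():
            raise DataValidationError("lengths table contains negative lengths")
        if len(self.census):
            for (_, _), grp in self.census.groupby(["plant_id", "axis_id"]):
                counts = grp.sort_values("tt")["decimal_count"].to_numpy()
                if np.any(np.diff(counts) < -1e-9):
                    raise DataValidationError("decimal counts must be non-decreasing per axis")
        return self


# -- leaf appearance ----------------------------------------------------------

@dataclass(frozen=True)
class LeafAppearanceFit:
    rate: float          # phytomer per degree-day
    phyllochron: float   # degree-days per phytomer
    r2: float
    intercept: float
    tt_start: float      # x-intercept: TT at which the axis started
    n_used: int


def fit_leaf_appearance(tt, decimal_count, min_count: float = 3.0) -> LeafAppearanceFit:
    """OLS of decimal phytomer count on TT for one axis.

    Only censuses with at least ``min_count`` unfolded leaves enter the fit
    (axes are characterized once they carry three or more unfolded leaves).
    """
    tt = np.asarray(tt, dtype=float)
    count = np.asarray(decimal_count, dtype=float)
    mask = count >= min_count
    if mask.sum() < 2 or np.unique(tt[mask]).size < 2:
        raise InsufficientDataError(
            f"need >= 2 censuses with count >= {min_count} at distinct TT, have {int(mask.sum())}")
    res = stats.linregress(tt[mask], count[mask])
    if res.slope <= 0:
        raise DegenerateFitError(f"non-positive leaf appearance rate ({res.slope:.3g})")
    return LeafAppearanceFit(rate=float(res.slope), phyllochron=float(1.0 / res.slope),
                             r2=float(res.rvalue ** 2), intercept=float(res.intercept),
                             tt_start=float(-res.intercept / res.slope),
                             n_used=int(mask.sum()))


# -- logistic organ growth ----------------------------------------------------

@dataclass
class KineticFit:
    """A fitted expansion logistic; d95 always equals 2*ln(19)/s."""

    organ_type: str
    l_max: float
    s: float
    t50: float
    d95: float
    rss: float
    n_points: int
    converged: bool = True


def truncate_after_growth_stops(tau, length, n_flat: int = 4):
    """Drop the tail of a series once ``n_flat`` consecutive values are unchanged.

    Mirrors the measurement protocol (daily measurements stop after four
    consecutive identical readings); series without ties pass through intact.
    """
    tau = np.asarray(tau, dtype=float)
    length = np.asarray(length, dtype=float)
    order = np.argsort(tau)
    tau, length = tau[order], length[order]
    run = 1
    for i in range(1, len(length)):
        run = run + 1 if length[i] == length[i - 1] else 1
        if run >= n_flat:
            keep = i - (n_flat - 1) + 1  # keep the first of the flat run
            return tau[:keep], length[:keep]
    return tau, length


def _logistic_model(tau, l_max, s, t50):
    return l_max * logistic_fraction(tau, max(s, 1e-9), t50)


def _init_logistic(tau, length):
    l0 = 1.05 * float(np.max(length))
    frac = np.asarray(length) / l0
    t50_0 = _crossing(tau, frac, 0.5)
    t25 = _crossing(tau, frac, 0.25)
    t75 = _crossing(tau, frac, 0.75)
    if t25 is not None and t75 is not None and t75 > t25:
        s0 = 2.0 * np.log(3.0) / (t75 - t25)
    else:
        s0 = 2.0
    if t50_0 is None:
        t50_0 = float(tau[0])
    return l0, float(s0), float(t50_0)


def _crossing(tau, frac, level):
    above = frac >= level
    if not above.any() or above.all():
        return None
    idx = int(np.argmax(above))
    if idx == 0:
        return float(tau[0])
    x0, x1 = tau[idx - 1], tau[idx]
    y0, y1 = frac[idx - 1], frac[idx]
    if y1 == y0:
        return float(x1)
    return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))


def fit_logistic_growth(tau, length, organ_type: str = "organ",
                        fix_lmax: float | None = None) -> KineticFit:
    """Nonlinear least-squares fit of the expansion logistic to one series.

    Parameters are (l_max, s, t50); with ``fix_lmax`` the final dimension is
    constrained and only (s, t50) are estimated.  Three deterministic
    multi-start perturbations are tried before flagging non-convergence.
    """
    tau = np.asarray(tau, dtype=float)
    length = np.asarray(length, dtype=float)
    if tau.size < 4:
        raise InsufficientDataError(f"need >= 4 points for a logistic fit, have {tau.size}")
    if np.max(length) <= 0 or np.ptp(length) == 0:
        raise DegenerateFitError("length series is flat or non-positive")
    order = np.argsort(tau)
    tau, length = tau[order], length[order]
    l0, s0, t50_0 = _init_logistic(tau, length)
    span = max(np.ptp(tau), 1.0)
    attempts = [(l0, s0, t50_0),
                (l0, 0.5 * s0, t50_0 + 0.25 * span),
                (l0, 2.0 * s0, t50_0 - 0.25 * span),
                (1.2 * l0, s0, t50_0)]
    best = None
    for lm, s_ini, t_ini in attempts:
        try:
            if fix_lmax is None:
                popt, _ = optimize.curve_fit(
                    _logistic_model, tau, length, p0=[lm, s_ini, t_ini],
                    bounds=([1e-9, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=20000)
                l_max, s, t50 = popt
            else:
                popt, _ = optimize.curve_fit(
                    lambda x, s, t50: _logistic_model(x, fix_lmax, s, t50),
                    tau, length, p0=[s_ini, t_ini],
                    bounds=([1e-6, -np.inf], [np.inf, np.inf]), maxfev=20000)
                l_max, (s, t50) = fix_lmax, popt
        except RuntimeError:
            continue
        rss = float(np.sum((length - _logistic_model(tau, l_max, s, t50)) ** 2))
        if best is None or rss < best.rss:
            best = KineticFit(organ_type, float(l_max), float(s), float(t50),
                              d95_from_s(float(s)), rss, int(tau.size))
        if best.rss <= 1e-12 * max(1.0, float(np.sum(length ** 2))):
            break
    if best is None:
        return KineticFit(organ_type, np.nan, np.nan, np.nan, np.nan, np.inf,
                          int(tau.size), converged=False)
    return best


@dataclass
class SharedKineticFit:
    """Joint fit over phytomer replicates: shared (s, t50), per-series l_max."""

    organ_type: str
    s: float
    t50: float
    d95: float
    l_max: np.ndarray
    rss: float
    n_points: int
    n_series: int
    converged: bool = True


def fit_shared_logistic(series, organ_type: str = "organ") -> SharedKineticFit:
    """Fit one logistic (shared s and t50) to several (tau, length) series."""
    series = [(np.asarray(t, dtype=float), np.asarray(y, dtype=float)) for t, y in series]
    series = [s for s in series if s[0].size >= 2 and np.max(s[1]) > 0]
    if not series or sum(t.size for t, _ in series) < 4:
        raise InsufficientDataError("too few points for a pooled logistic fit")
    tau_all = np.concatenate([t for t, _ in series])
    y_all = np.concatenate([y for _, y in series])
    l0 = np.array([1.05 * float(np.max(y)) for _, y in series])
    frac = np.concatenate([y / (1.05 * np.max(y)) for _, y in series])
    order = np.argsort(tau_all)
    _, s0, t50_0 = _init_logistic(tau_all[order],
                                  (frac * 1.0)[order] * 1.0)  # fractions as pseudo-lengths

    def residuals(x):
        s, t50 = x[0], x[1]
        lmaxes = x[2:]
        out = []
        for (t, y), lm in zip(series, lmaxes):
            out.append(lm * logistic_fraction(t, max(s, 1e-9), t50) - y)
        return np.concatenate(out)

    span = max(np.ptp(tau_all), 1.0)
    best = None
    for s_ini, t_ini in ((s0, t50_0), (0.5 * s0, t50_0 + 0.25 * span),
                         (2.0 * s0, t50_0 - 0.25 * span)):
        x0 = np.concatenate(([s_ini, t_ini], l0))
        lb = np.concatenate(([1e-6, -np.inf], np.full(len(series), 1e-9)))
        ub = np.full(2 + len(series), np.inf)
        sol = optimize.least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-14,
                                     ftol=1e-14, gtol=1e-14, max_nfev=20000)
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best.rss:
            best = SharedKineticFit(organ_type, float(sol.x[0]), float(sol.x[1]),
                                    d95_from_s(float(sol.x[0])), sol.x[2:].copy(),
                                    rss, int(tau_all.size), len(series))
        if best.rss <= 1e-12 * max(1.0, float(np.sum(y_all ** 2))):
            break
    return best


# -- branching ----------------------------------------------------------------

@dataclass
class BranchingProbabilityResult:
    table: pd.DataFrame            # position, probability, n_plants
    asymptote: float | None
    s: float | None
    x50: float | None
    flag: str = "ok"               # "ok" | "flat" | "fit_failed"


def branching_probability(branching: pd.DataFrame, at_tt: float,
                          axis_id: str = "main", convention: str = "base",
                          top_rank: int | None = None) -> BranchingProbabilityResult:
    """Per-position budburst probabilities at a date, plus a logistic-in-position fit.

    The probability at a position is the fraction of plants whose axillary bud
    at that position has burst by ``at_tt``.  Positions are base-ranked by
    default; ``convention='apex'`` re-expresses them as (top_rank - rank + 1),
    requiring ``top_rank``.
    """
    if branching.empty:
        raise InsufficientDataError("branching table is empty")
    sub = branching[branching["axis_id"] == axis_id]
    plants = sub["plant_id"].unique()
    if plants.size == 0:
        raise InsufficientDataError("branching table has no plants for this axis")
    rows = []
    for rank, grp in sub.groupby("phytomer_rank"):
        burst = grp[grp["burst_observed"] & (grp["tt"] <= at_tt)]["plant_id"].nunique()
        rows.append({"position": int(rank), "probability": burst / plants.size,
                     "n_plants": plants.size})
    table = pd.DataFrame(rows).sort_values("position").reset_index(drop=True)
    if convention == "apex":
        if top_rank is None:
            raise DataValidationError("apex convention requires top_rank")
        table["position"] = top_rank - table["position"] + 1
        table = table.sort_values("position").reset_index(drop=True)
    elif convention != "base":
        raise DataValidationError(f"unknown position convention {convention!r}")

    probs = table["probability"].to_numpy()
    if np.allclose(probs, 0.0):
        return BranchingProbabilityResult(table, None, None, None, flag="flat")
    x = table["position"].to_numpy(dtype=float)
    try:
        popt, _ = optimize.curve_fit(
            lambda p, a, s, x50: a * logistic_fraction(p, max(s, 1e-9), x50),
            x, probs, p0=[min(1.0, probs.max()), 1.0, float(np.median(x))],
            bounds=([1e-6, 1e-6, -np.inf], [1.0, 100.0, np.inf]), maxfev=20000)
        return BranchingProbabilityResult(table, float(popt[0]), float(popt[1]),
                                          float(popt[2]))
    except RuntimeError:
        return BranchingProbabilityResult(table, None, None, None, flag="fit_failed")


# -- allometry and profiles ---------------------------------------------------

@dataclass(frozen=True)
class AllometryFit:
    coefficient: float
    r2: float
    n: int


def fit_allometry(scans: pd.DataFrame) -> AllometryFit:
    """Regression through the origin of leaf area on length x width x leaflet count."""
    needed = {"leaflet_length_cm", "leaflet_width_cm", "n_leaflets", "area_cm2"}
    missing = needed - set(scans.columns)
    if missing:
        raise DataValidationError(f"leaf-scan table missing columns {sorted(missing)}")
    x = (scans["leaflet_length_cm"] * scans["leaflet_width_cm"]
         * scans["n_leaflets"]).to_numpy(dtype=float)
    y = scans["area_cm2"].to_numpy(dtype=float)
    ok = x > 0
    if ok.sum() < 3:
        raise InsufficientDataError("need >= 3 scans with positive length x width x n")
    x, y = x[ok], y[ok]
    denom = float(np.sum(x * x))
    if denom == 0:
        raise DegenerateFitError("degenerate predictor in allometry fit")
    coef = float(np.sum(x * y) / denom)
    rss = float(np.sum((y - coef * x) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    return AllometryFit(coef, r2, int(x.size))


def relative_profile(ranks, values):
    """Per-rank dimensions divided by the value at the reference rank.

    The reference is the first rank attaining the maximum, so the output peaks
    at exactly 1 there.  Returns ``(relative_values, reference_rank)``.
    """
    ranks = np.asarray(ranks)
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.nanmax(values) <= 0:
        raise DegenerateFitError("profile needs at least one positive dimension")
    ref_idx = int(np.nanargmax(values))
    return values / values[ref_idx], ranks[ref_idx]


# -- trait matrix and PCA -----------------------------------------------------

@dataclass
class TraitMatrix:
    values: pd.DataFrame           # individuals x traits
    imputed: pd.DataFrame          # boolean mask of imputed cells
    excluded: list = field(default_factory=list)


def assemble_trait_matrix(records, trait_columns=TRAIT_COLUMNS,
                          max_missing_fraction: float = 0.5) -> TraitMatrix:
    """Assemble the individuals x traits matrix, imputing by species mean.

    ``records`` is a DataFrame (or list of dicts) with one row per individual,
    the trait columns, and optionally a ``species`` column used for imputation
    groups.  Individuals missing more than half the traits are excluded with a
    warning; every imputed cell is flagged in the returned mask.
    """
    frame = pd.DataFrame(records)
    if frame.empty:
        empty = pd.DataFrame(columns=list(trait_columns))
        return TraitMatrix(empty, empty.astype(bool))
    for col in trait_columns:
        if col not in frame.columns:
            frame[col] = np.nan
    values = frame[list(trait_columns)].astype(float)
    missing_frac = values.isna().mean(axis=1)
    excluded = list(frame.index[missing_frac > max_missing_fraction])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} individual(s) missing more than "
                      f"{max_missing_fraction:.0%} of traits", stacklevel=2)
        values = values.drop(index=excluded)
        frame = frame.drop(index=excluded)
    imputed = values.isna()
    if imputed.to_numpy().any():
        if "species" in frame.columns:
            filled = values.groupby(frame["species"]).transform(lambda c: c.fillna(c.mean()))
        else:
            filled = values.fillna(values.mean())
        warnings.warn(f"imputed {int(imputed.to_numpy().sum())} missing trait cell(s) "
                      "by species mean", stacklevel=2)
        values = filled
    return TraitMatrix(values, imputed, excluded)


@dataclass
class PcaResult:
    loadings: pd.DataFrame         # traits x components (orthonormal columns)
    scores: pd.DataFrame           # individuals x components
    variance_fraction: np.ndarray
    dropped: list = field(default_factory=list)


def pca_traits(matrix: pd.DataFrame) -> PcaResult:
    """Correlation-matrix PCA of a trait table.

    Columns are standardized (zero mean, unit sample variance) because the
    traits carry heterogeneous units; zero-variance columns are dropped with a
    warning.  Component signs are fixed so the largest-magnitude loading of
    each component is positive.
    """
    values = pd.DataFrame(matrix).astype(float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise InsufficientDataError("PCA needs at least 2 individuals and 2 traits")
    if not np.isfinite(values.to_numpy()).all():
        raise DataValidationError("trait matrix contains non-finite values")
    stds = values.std(ddof=1)
    dropped = list(stds.index[stds == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance trait column(s) {dropped}", stacklevel=2)
        values = values.drop(columns=dropped)
    if values.shape[1] < 2:
        raise InsufficientDataError("fewer than 2 traits left after dropping constants")
    z = (values - values.mean()) / values.std(ddof=1)
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=values.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=values.index, columns=comp_names),
        variance_fraction=pca.explained_variance_ratio_.copy(),
        dropped=dropped,
    )


# -- full pipeline ------------------------------------------------------------

def estimate_traits(dataset: ObservationDataset, min_count: float = 3.0,
                    min_primary_axes: int = 2):
    """Recover the 12 trait-matrix columns for every plant in a dataset.

    Returns ``(traits, diagnostics)``: a DataFrame indexed by plant with the
    trait columns (plus ``species`` if present in the census table), and a
    long diagnostics table with per-fit quality measures.
    """
    dataset.validate()
    trait_rows = []
    diag_rows = []
    species_col = "species" if "species" in dataset.census.columns else None
    for plant, cen in dataset.census.groupby("plant_id"):
        row: dict = {"plant_id": plant}
        if species_col:
            row["species"] = cen[species_col].iloc[0]
        axis_fits: dict[str, LeafAppearanceFit] = {}

        main = cen[cen["axis_id"] == "main"]
        try:
            fit0 = fit_leaf_appearance(main["tt"], main["decimal_count"], min_count)
            axis_fits["main"] = fit0
            row["phy0"] = fit0.phyllochron
            diag_rows.append({"plant_id": plant, "quantity": "phy0", "r2": fit0.r2,
                              "n": fit0.n_used, "converged": True})
        except (InsufficientDataError, DegenerateFitError) as exc:
            diag_rows.append({"plant_id": plant, "quantity": "phy0", "r2": np.nan,
                              "n": 0, "converged": False, "note": str(exc)})
            fit0 = None

        primary_fits = []
        for axis_id, grp in cen[cen["category"] == "primary"].groupby("axis_id"):
            try:
                fit_p = fit_leaf_appearance(grp["tt"], grp["decimal_count"], min_count)
            except (InsufficientDataError, DegenerateFitError):
                continue
            axis_fits[axis_id] = fit_p
            primary_fits.append(fit_p)
        if fit0 is not None and primary_fits:
            row["phy1"] = float(np.mean([fit0.phyllochron / f.phyllochron
                                         for f in primary_fits]))
            starts = np.sort([f.tt_start for f in primary_fits])
            if starts.size >= min_primary_axes:
                row["br1"] = float(np.mean(np.diff(starts)) / fit0.phyllochron)
            diag_rows.append({"plant_id": plant, "quantity": "phy1",
                              "n": len(primary_fits), "converged": True})

        if fit0 is not None and len(dataset.branching):
            br = dataset.branching
            br = br[(br["plant_id"] == plant) & (br["axis_id"] == "main")
                    & (br["burst_observed"].astype(bool))]
            if len(br):
                appear = fit0.tt_start + br["phytomer_rank"].to_numpy() * fit0.phyllochron
                lags = (br["tt"].to_numpy() - appear) / fit0.phyllochron
                row["ram_dist"] = float(np.mean(lags))
                diag_rows.append({"plant_id": plant, "quantity": "ram_dist",
                                  "n": int(len(br)), "converged": True})

        ln = (dataset.lengths[dataset.lengths["plant_id"] == plant]
              if len(dataset.lengths) else dataset.lengths)
        organ_fits: dict[str, SharedKineticFit] = {}
        for organ_type, grp in (ln.groupby("organ_type") if len(ln) else ()):
            series = []
            for (axis_id, rank), sub in grp.groupby(["axis_id", "phytomer_rank"]):
                fit_a = axis_fits.get(axis_id)
                if fit_a is None:
                    continue
                appear = fit_a.tt_start + rank * fit_a.phyllochron
                tau = (sub["tt"].to_numpy(dtype=float) - appear) / fit_a.phyllochron
                tau, length = truncate_after_growth_stops(tau, sub["length_cm"].to_numpy())
                series.append((tau, length))
            if not series:
                continue
            try:
                organ_fits[organ_type] = fit_shared_logistic(series, organ_type)
            except InsufficientDataError as exc:
                diag_rows.append({"plant_id": plant, "quantity": f"kinetics_{organ_type}",
                                  "converged": False, "note": str(exc)})
        if "leaflet" in organ_fits:
            ref_t50 = organ_fits["leaflet"].t50
            mapping = {"leaflet": "lf", "petiole": "pet", "internode": "in"}
            for organ_type, short in mapping.items():
                fit_o = organ_fits.get(organ_type)
                if fit_o is None:
                    continue
                row[f"d95_{short}"] = fit_o.d95
                if organ_type != "leaflet":
                    row[f"t50_{short}"] = fit_o.t50 - ref_t50
                diag_rows.append({"plant_id": plant, "quantity": f"kinetics_{organ_type}",
                                  "rss": fit_o.rss, "n": fit_o.n_points,
                                  "converged": fit_o.converged})
            if "petiole" in organ_fits:
                row["max_pet"] = float(np.max(organ_fits["petiole"].l_max))
            if "internode" in organ_fits:
                row["max_in"] = float(np.max(organ_fits["internode"].l_max))

        scans = (dataset.scans[dataset.scans["plant_id"] == plant]
                 if len(dataset.scans) else dataset.scans)
        if len(scans):
            row["max_lf"] = float(scans["area_cm2"].max())

        trait_rows.append(row)

    traits = pd.DataFrame(trait_rows).set_index("plant_id") if trait_rows else pd.DataFrame()
    diagnostics = pd.DataFrame(diag_rows)
    return traits, diagnostics
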