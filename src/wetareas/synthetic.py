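"""Synthetic boreal landscapes and bryophyte communities with known truth.

Two generators live here. ``generate_dem`` builds a mild-relief DEM (a
tilted plane plus Gaussian hills and one incised meandering channel) with
known hydrology, emulating a boreal upland: flat areas interspersed with
elevated blocks and incised valleys. ``simulate_community`` populates
plots with bryophyte percent-cover data whose plot-level responses
(cover, richness, inverse-Simpson diversity) follow known mixed-model
relationships with the depth-to-water (DTW) covariate, so downstream
model fits can be checked against the generating parameters.

The community generator has two modes:

* ``"glmm"`` (default): plot-level responses are drawn directly from the
  generating mixed models — richness from a Poisson log-link model,
  total cover on the square-root scale, diversity on its fitting scale —
  and species identities/abundances are then allocated to match. This
  gives exact control of the generating coefficients for
  parameter-recovery experiments, while Gaussian moisture niches still
  decide *which* species occur where (so indicator-species structure
  along the wet/moist/dry gradient emerges).
* ``"niche"``: the classical species-level model — presence is Bernoulli
  with a Gaussian niche-weighted probability and cover is the niche mean
  times lognormal noise, capped at the species maximum. Responses then
  emerge bottom-up rather than being controlled.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import DEMGrid
from .hydrology import DTWGrid

__all__ = [
    "LandscapeParams", "CommunityParams", "generate_dem",
    "default_species_pool", "assign_forest_types", "place_plots",
    "simulate_community", "SimulatedCommunity", "FOREST_TYPES",
    "PAPER_PLOT_DESIGN",
]

FOREST_TYPES = ("broadleaf", "mixed", "conifer")

# Plots per compartment per forest type replicating the field design:
# three ~10 ha compartments per type, 8-14 plots each, 111 plots total
# (34 broadleaf, 38 mixed, 39 conifer).
PAPER_PLOT_DESIGN = {
    "broadleaf": (11, 11, 12),
    "mixed": (12, 13, 13),
    "conifer": (13, 13, 13),
}


@dataclass
class LandscapeParams:
    """Controls of the synthetic DEM generator.

    The default extent (180 x 180 cells at 10 m) covers 324 ha so that
    even the largest flow-initiation threshold (16 ha) yields sources.
    base_slope tilts the plane downhill toward the east; hills are
    Gaussian bumps whose amplitude/width are drawn uniformly from the
    given ranges; one meandering channel is incised along the tilt so the
    surface has a realistic stream with adjacent wet floor.
    """

    n_rows: int = 180
    n_cols: int = 180
    cell_size: float = 10.0
    base_elevation: float = 700.0
    base_slope: float = 0.010
    n_hills: int = 12
    hill_amplitude: tuple[float, float] = (2.0, 8.0)
    hill_width: tuple[float, float] = (80.0, 250.0)
    channel_incision_depth: float = 2.0
    channel_width: float = 30.0
    channel_meander_amplitude: float = 250.0
    channel_meander_wavelength: float = 1200.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if min(self.hill_amplitude) < 0 or self.channel_incision_depth < 0:
            raise ValueError("amplitudes must be >= 0")


def generate_dem(params: LandscapeParams | None = None) -> DEMGrid:
    """Deterministic synthetic DEM: tilted plane + hills + incised channel."""
    p = params or LandscapeParams()
    rng = np.random.default_rng(p.seed)
    xs = (np.arange(p.n_cols) + 0.5) * p.cell_size
    ys = -(np.arange(p.n_rows) + 0.5) * p.cell_size   # row 0 = north
    X, Y = np.meshgrid(xs, ys)
    z = p.base_elevation - p.base_slope * X

    # Channel centerline meanders west->east across the middle.
    y_mid = ys.mean()
    yc = y_mid + p.channel_meander_amplitude * np.sin(
        2 * np.pi * xs / p.channel_meander_wavelength)
    dist_ch = np.abs(Y - yc[None, :])
    # Hills avoid the channel corridor so the incised valley stays open.
    hill_gate = 1.0 - np.exp(-dist_ch ** 2 / (2 * (3 * p.channel_width) ** 2))
    hills = np.zeros_like(z)
    for _ in range(p.n_hills):
        cx = rng.uniform(xs.min(), xs.max())
        cy = rng.uniform(ys.min(), ys.max())
        amp = rng.uniform(*p.hill_amplitude)
        width = rng.uniform(*p.hill_width)
        hills += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * width ** 2))
    z = z + hills * hill_gate
    z = z - p.channel_incision_depth * np.exp(-dist_ch ** 2 / (2 * p.channel_width ** 2))
    return DEMGrid(z, p.cell_size, origin=(0.0, 0.0))


def assign_forest_types(dtw: DTWGrid, breaks: tuple[float, float] = (1.2, 2.5)
                        ) -> np.ndarray:
    """Map DTW cells to forest types by wetness position.

    Conifer stands occupy the wettest cells (DTW <= break1), mixed stands
    the intermediate band (break1, break2], broadleaf the driest cells —
    mirroring the drier-to-wetter ordering of boreal cover types.
    """
    b1, b2 = breaks
    if not b1 < b2:
        raise ValueError("breaks must be strictly increasing")
    d = dtw.dtw
    out = np.full(d.shape, "", dtype="U9")
    out[np.isfinite(d) & (d <= b1)] = "conifer"
    out[np.isfinite(d) & (d > b1) & (d <= b2)] = "mixed"
    out[np.isfinite(d) & (d > b2)] = "broadleaf"
    return out


def place_plots(type_map: np.ndarray, dtw: DTWGrid,
                n_compartments_per_type: int = 3,
                plots_per_compartment=None,
                seed: int = 0) -> pd.DataFrame:
    """Stratified plot placement within spatial compartments.

    Each forest type's cells are split into ``n_compartments_per_type``
    contiguous east-west blocks (compartments); within a compartment,
    plots sit at evenly spaced DTW quantiles (a single plot lands on the
    median-DTW cell), capturing the moisture gradient the way the field
    sampling did. ``plots_per_compartment`` may be an int applied
    everywhere or None for the field design (8-14 per compartment,
    111 plots total).
    """
    d = dtw.dtw
    rows, cols = np.indices(d.shape)
    records = []
    comp_idx = 0
    for ftype in FOREST_TYPES:
        sel = (type_map == ftype) & np.isfinite(d)
        if plots_per_compartment is None:
            counts = PAPER_PLOT_DESIGN[ftype][:n_compartments_per_type]
            if n_compartments_per_type != 3:
                raise ValueError("the default field design assumes 3 "
                                 "compartments per type; pass an explicit "
                                 "plots_per_compartment otherwise")
        else:
            counts = (int(plots_per_compartment),) * n_compartments_per_type
        cs = cols[sel]
        if cs.size < sum(counts):
            raise ValueError(f"forest type {ftype!r} occupies too few cells "
                             f"({cs.size}) for {sum(counts)} plots")
        # Compartments: east-west blocks by column quantile of the type's cells.
        edges = np.quantile(cs, np.linspace(0, 1, n_compartments_per_type + 1))
        for k, n_plots in enumerate(counts):
            lo, hi = edges[k], edges[k + 1]
            in_block = sel & (cols >= lo) & (cols <= hi if k == n_compartments_per_type - 1 else cols < hi)
            rr, cc = rows[in_block], cols[in_block]
            vals = d[in_block]
            if vals.size < n_plots:
                raise ValueError(f"compartment {comp_idx} has too few cells "
                                 f"({vals.size}) for {n_plots} plots")
            order = np.argsort(vals, kind="stable")
            m = vals.size
            for i in range(n_plots):
                q = (i + 0.5) / n_plots if n_plots > 1 else 0.5
                j = order[int(round(q * (m - 1)))]
                r, c = int(rr[j]), int(cc[j])
                x = dtw.origin[0] + (c + 0.5) * dtw.cell_size
                y = dtw.origin[1] - (r + 0.5) * dtw.cell_size
                records.append({
                    "plot_id": f"p{len(records):03d}",
                    "compartment": f"c{comp_idx}",
                    "forest_type": ftype,
                    "x": x, "y": y, "row": r, "col": c,
                    "dtw": float(d[r, c]),
                })
            comp_idx += 1
    return pd.DataFrame.from_records(records)


def default_species_pool(n_species: int = 30, seed: int = 12345) -> pd.DataFrame:
    """A bryophyte species pool spanning the moisture gradient.

    Columns: name, moisture_optimum (m DTW), tolerance (m), max_cover (%),
    baseline_presence_prob, affinity_broadleaf / _mixed / _conifer.
    The first few species form a feathermoss guild (wet/moist optima,
    high maximum cover, conifer affinity) that dominates wet conifer
    floors the way Hylocomium- and Pleurozium-type mats do; the rest
    spread their optima over 0-5 m DTW with drier species leaning toward
    broadleaf stands.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_feather = max(3, n_species // 10)
    for i in range(n_species):
        if i < n_feather:
            name = f"feathermoss_{i:02d}"
            opt = rng.uniform(0.0, 1.2)
            tol = rng.uniform(0.8, 1.5)
            max_cover = rng.uniform(70, 95)
            aff = (0.2, 0.7, 1.0)
        else:
            name = f"bryophyte_{i:02d}"
            opt = rng.uniform(0.0, 5.0)
            tol = rng.uniform(0.4, 1.6)
            max_cover = rng.uniform(5, 50)
            dry = opt / 5.0   # drier optima lean broadleaf
            aff = (0.3 + 0.7 * dry, 0.8, 1.0 - 0.7 * dry)
        rows.append({
            "name": name, "moisture_optimum": opt, "tolerance": tol,
            "max_cover": max_cover,
            "baseline_presence_prob": rng.uniform(0.3, 0.9),
            "affinity_broadleaf": aff[0], "affinity_mixed": aff[1],
            "affinity_conifer": aff[2],
        })
    return pd.DataFrame(rows)


def _per_type(value, default) -> dict:
    if value is None:
        return dict(default)
    if isinstance(value, dict):
        return {t: float(value[t]) for t in FOREST_TYPES}
    return {t: float(value) for t in FOREST_TYPES}


@dataclass
class CommunityParams:
    """Generating coefficients of the plot-level community model.

    All slopes are per meter of DTW on the model's fitting scale:
    richness on the log link, cover on the square-root(percent) scale,
    diversity on the scale named by ``diversity_transform`` per forest
    type ('none' or 'log'). Defaults reproduce the fitted field
    relationships (e.g. richness slope 0.07, conifer cover slope -0.54).
    compartment_sd is the SD of the compartment random intercept (applied
    independently per response on its fitting scale); residual SDs apply
    to the Gaussian responses; overdispersion is a lognormal SD on the
    Poisson mean (0 = pure Poisson).
    """

    richness_intercept: dict | float | None = None
    richness_dtw_slope: dict | float | None = None
    cover_intercept: dict | float | None = None
    cover_dtw_slope: dict | float | None = None
    diversity_intercept: dict | float | None = None
    diversity_dtw_slope: dict | float | None = None
    diversity_transform: dict | str | None = None
    compartment_sd: float = 0.15
    cover_residual_sd: float = 1.5
    diversity_residual_sd: float = 0.7
    overdispersion: float = 0.0
    niche_cover_noise_sd: float = 0.6
    mode: str = "glmm"
    seed: int = 0

    def __post_init__(self):
        self.richness_intercept = _per_type(
            self.richness_intercept,
            {"broadleaf": 2.17, "mixed": 2.43, "conifer": 2.24})
        self.richness_dtw_slope = _per_type(
            self.richness_dtw_slope,
            {"broadleaf": 0.07, "mixed": 0.07, "conifer": 0.22})
        self.cover_intercept = _per_type(
            self.cover_intercept,
            {"broadleaf": 1.45, "mixed": 4.04, "conifer": 6.23})
        self.cover_dtw_slope = _per_type(
            self.cover_dtw_slope,
            {"broadleaf": 0.02, "mixed": -0.08, "conifer": -0.54})
        self.diversity_intercept = _per_type(
            self.diversity_intercept,
            {"broadleaf": 4.39, "mixed": 0.88, "conifer": 0.64})
        self.diversity_dtw_slope = _per_type(
            self.diversity_dtw_slope,
            {"broadleaf": 0.52, "mixed": 0.10, "conifer": 0.25})
        if self.diversity_transform is None:
            self.diversity_transform = {"broadleaf": "none", "mixed": "log",
                                        "conifer": "log"}
        elif isinstance(self.diversity_transform, str):
            self.diversity_transform = {t: self.diversity_transform
                                        for t in FOREST_TYPES}
        if self.compartment_sd < 0 or self.cover_residual_sd < 0 \
                or self.diversity_residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.mode not in ("glmm", "niche"):
            raise ValueError("mode must be 'glmm' or 'niche'")


@dataclass
class SimulatedCommunity:
    """Generated plot table plus the generating truth for recovery tests."""

    table: pd.DataFrame          # plots x (metadata + species covers)
    species: list
    truth: dict


def _evenness_theta(d_target: float, richness: int) -> np.ndarray:
    """Geometric-series proportions with inverse Simpson == d_target.

    Returns proportions p_i (descending) over ``richness`` species such
    that 1 / sum(p_i^2) equals d_target (clamped to [1, richness]).
    """
    from scipy.optimize import brentq

    r = richness
    if r == 1:
        return np.array([1.0])
    d = min(max(d_target, 1.0), float(r))

    def inv_simpson(theta):
        w = theta ** np.arange(r)
        p = w / w.sum()
        return 1.0 / np.sum(p ** 2)

    if d >= r - 1e-9:
        return np.full(r, 1.0 / r)
    if d <= 1 + 1e-9:
        theta = 1e-12
    else:
        theta = brentq(lambda t: inv_simpson(t) - d, 1e-12, 1 - 1e-12,
                       xtol=1e-12)
    w = theta ** np.arange(r)
    return w / w.sum()


_MIN_TOTAL_COVER = 0.1   # trace total cover when present species exist


def simulate_community(plots: pd.DataFrame, pool: pd.DataFrame | None = None,
                       cparams: CommunityParams | None = None
                       ) -> SimulatedCommunity:
    """Simulate species percent cover per plot along the DTW gradient.

    ``plots`` needs columns plot_id, compartment, forest_type, dtw.
    Returns the wide plot table (metadata + one column per species) and
    the generating truth (coefficients, compartment effects, latent
    responses, clamp counts).
    """
    cp = cparams or CommunityParams()
    if pool is None:
        pool = default_species_pool()
    if plots.empty:
        raise ValueError("plots table is empty")
    required = {"plot_id", "compartment", "forest_type", "dtw"}
    missing = required - set(plots.columns)
    if missing:
        raise ValueError(f"plots table lacks columns: {sorted(missing)}")
    bad = ~plots["forest_type"].isin(FOREST_TYPES)
    if bad.any():
        raise ValueError("unknown forest types: "
                         f"{sorted(plots.loc[bad, 'forest_type'].unique())}")
    probs = pool["baseline_presence_prob"].to_numpy()
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("baseline_presence_prob must lie in [0, 1]")

    rng = np.random.default_rng(cp.seed)
    comps = sorted(plots["compartment"].unique())
    b = {resp: dict(zip(comps, rng.normal(0, cp.compartment_sd, len(comps))))
         for resp in ("richness", "cover", "diversity")}

    n_sp = len(pool)
    names = pool["name"].tolist()
    opt = pool["moisture_optimum"].to_numpy()
    tol = pool["tolerance"].to_numpy()
    maxc = pool["max_cover"].to_numpy()
    base_p = pool["baseline_presence_prob"].to_numpy()

    covers = np.zeros((len(plots), n_sp))
    latent = {"richness_mu": [], "cover_sqrt": [], "diversity_target": []}
    clamps = {"diversity_low": 0, "diversity_high": 0, "richness_pool": 0,
              "cover_censored": 0, "max_cover_capped": 0}

    for i, rec in enumerate(plots.itertuples(index=False)):
        ft = rec.forest_type
        dtw = float(rec.dtw)
        aff = pool[f"affinity_{ft}"].to_numpy()
        niche = np.exp(-((dtw - opt) ** 2) / (2 * tol ** 2))
        weight = base_p * niche * aff

        if cp.mode == "niche":
            # presence from the niche alone; forest-type affinity scales
            # abundance, so a plot at a species' optimum (baseline 1) is
            # occupied with certainty
            present = rng.random(n_sp) < np.clip(base_p * niche, 0, 1)
            mean_cover = maxc * niche * aff
            noise = rng.lognormal(-cp.niche_cover_noise_sd ** 2 / 2,
                                  cp.niche_cover_noise_sd, n_sp)
            cov = np.where(present, np.minimum(mean_cover * noise, maxc), 0.0)
            covers[i] = cov
            continue

        # --- glmm mode: controlled plot-level responses ---
        eta_r = (cp.richness_intercept[ft] + cp.richness_dtw_slope[ft] * dtw
                 + b["richness"][rec.compartment])
        mu_r = np.exp(eta_r)
        if cp.overdispersion > 0:
            mu_r *= rng.lognormal(-cp.overdispersion ** 2 / 2, cp.overdispersion)
        richness = int(rng.poisson(mu_r))
        if richness > n_sp:
            richness = n_sp
            clamps["richness_pool"] += 1
        latent["richness_mu"].append(mu_r)

        s = (cp.cover_intercept[ft] + cp.cover_dtw_slope[ft] * dtw
             + b["cover"][rec.compartment]
             + rng.normal(0, cp.cover_residual_sd))
        if s < 0:
            clamps["cover_censored"] += 1
        total = max(s, 0.0) ** 2
        latent["cover_sqrt"].append(s)

        t = (cp.diversity_intercept[ft] + cp.diversity_dtw_slope[ft] * dtw
             + b["diversity"][rec.compartment]
             + rng.normal(0, cp.diversity_residual_sd))
        d_target = t if cp.diversity_transform[ft] == "none" else np.exp(t)
        latent["diversity_target"].append(d_target)
        if richness == 0:
            continue
        if d_target < 1:
            clamps["diversity_low"] += 1
        if d_target > richness:
            clamps["diversity_high"] += 1

        # Which species: niche-weighted sampling without replacement, the
        # best-suited species taking the largest abundance share.
        w = weight + 1e-12
        chosen = rng.choice(n_sp, size=richness, replace=False, p=w / w.sum())
        chosen = chosen[np.argsort(-w[chosen], kind="stable")]
        p = _evenness_theta(d_target, richness)
        # flooring the *total* keeps proportions (hence diversity and
        # richness) intact even when the latent cover is censored at zero
        cov = max(total, _MIN_TOTAL_COVER) * p
        capped = cov > maxc[chosen]
        clamps["max_cover_capped"] += int(capped.sum())
        covers[i, chosen] = np.minimum(cov, maxc[chosen])

    table = plots.reset_index(drop=True).copy()
    table[names] = covers
    truth = {
        "params": cp,
        "compartment_effects": b,
        "latent": {k: np.asarray(v) for k, v in latent.items()},
        "clamps": clamps,
        "species_pool": pool,
    }
    return SimulatedCommunity(table, names, truth)
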