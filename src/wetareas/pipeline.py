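"""Configuration-driven end-to-end runs.

A run reproduces the full workflow on either user-supplied or simulated
inputs: DEM -> DTW rasters across flow-initiation thresholds -> plot DTW
covariates -> diversity summaries -> per-threshold mixed-model fits and
AICc selection -> (at the selected threshold) indicator species
analysis, PERMANOVA and NMDS per forest type. Every intermediate
artifact is written so each stage can be re-run independently, and the
JSON report carries every seed, so identical configurations yield
byte-identical reports.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as cm
from . import hydrology as hy
from . import inference as inf
from . import synthetic as syn
from .raster import read_ascii_grid, write_ascii_grid

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_METADATA_COLS = ("plot_id", "compartment", "forest_type", "x", "y",
                  "row", "col", "dtw")


@dataclass
class RunConfig:
    """One pipeline run. Exactly one terrain source (``dem_path`` or
    ``landscape``) and one plot source (``plots_path`` or ``community``)
    must be given; a master seed is mandatory."""

    seed: int
    outdir: str
    dem_path: str | None = None
    landscape: dict | None = None
    plots_path: str | None = None
    community: dict | None = None
    thresholds: tuple = hy.DEFAULT_THRESHOLDS_HA
    diagonal_factor: str | float = "sqrt2"
    step_cost_mode: str = "rise_only"
    forest_type_breaks: tuple[float, float] = (1.2, 2.5)
    generating_lambda: float = 4.0
    n_perm: int = 999
    nmds_k: int = 2
    nmds_restarts: int = 20
    run_fits: bool = True
    run_isa: bool = True
    run_permanova: bool = True
    run_nmds: bool = True

    def __post_init__(self):
        if (self.dem_path is None) == (self.landscape is None):
            raise ValueError("exactly one of dem_path / landscape required")
        if (self.plots_path is None) == (self.community is None):
            raise ValueError("exactly one of plots_path / community required")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def dtw_params(self) -> hy.DTWParams:
        a = np.sqrt(2) if self.diagonal_factor in ("sqrt2", "sqrt(2)") \
            else float(self.diagonal_factor)
        return hy.DTWParams(diagonal_factor=a,
                            step_cost_mode=self.step_cost_mode)


def _child_seed(master: int, name: str) -> int:
    """Stable per-stage seed derived from the master seed and stage name."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


_RESPONSES = {
    # response column -> (family, transform per forest type)
    "total_cover": ("gaussian",
                    {"broadleaf": "sqrt", "mixed": "sqrt", "conifer": "sqrt"}),
    "richness": ("poisson-log",
                 {"broadleaf": "none", "mixed": "none", "conifer": "none"}),
    "inverse_simpson": ("gaussian",
                        {"broadleaf": "none", "mixed": "log",
                         "conifer": "log"}),
}


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                    from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the report (also written to
    ``outdir/report.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s "
                                      "%(message)s"))
    root = logging.getLogger("wetareas")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    cfg_dump = dataclasses.asdict(config)
    cfg_dump.pop("outdir", None)   # keep the report body location-independent
    report: dict = {"config": _jsonable(cfg_dump), "seeds": {}, "stages": {}}

    def seed_for(name):
        s = _child_seed(config.seed, name)
        report["seeds"][name] = s
        return s

    try:
        # ---- terrain
        if config.dem_path:
            dem = _stage("read_dem")(read_ascii_grid)(config.dem_path)
        else:
            lp = syn.LandscapeParams(**{**(config.landscape or {}),
                                        "seed": seed_for("landscape")})
            dem = _stage("generate_dem")(syn.generate_dem)(lp)
        write_ascii_grid(dem, out / "dem.asc")

        # ---- hydrology / DTW suite
        suite = _stage("dtw_suite")(hy.dtw_suite)(
            dem, config.thresholds, config.dtw_params())
        for lam, grid in suite.dtw_by_lambda.items():
            g = dem.with_elevations(np.where(np.isfinite(grid.dtw),
                                             grid.dtw, np.nan))
            write_ascii_grid(g, out / f"dtw_{lam:g}ha.asc")
        suite.correlation.to_csv(out / "dtw_correlation.csv")
        report["stages"]["dtw_suite"] = {
            "thresholds": list(map(float, config.thresholds)),
            "skipped": suite.skipped,
            "min_pairwise_correlation":
                float(np.nanmin(suite.correlation.to_numpy())),
        }

        # ---- plots
        lam0 = float(config.generating_lambda)
        if lam0 not in suite.dtw_by_lambda:
            raise RuntimeError(f"generating threshold {lam0} ha missing from "
                               "the DTW suite")
        if config.plots_path:
            table = pd.read_csv(config.plots_path)
            species = [c for c in table.columns if c not in _METADATA_COLS]
        else:
            tmap = _stage("assign_forest_types")(syn.assign_forest_types)(
                suite.dtw_by_lambda[lam0], config.forest_type_breaks)
            plots = _stage("place_plots")(syn.place_plots)(
                tmap, suite.dtw_by_lambda[lam0], seed=seed_for("plots"))
            cp = syn.CommunityParams(**{**(config.community or {}),
                                        "seed": seed_for("community")})
            sim = _stage("simulate_community")(syn.simulate_community)(
                plots, cparams=cp)
            table, species = sim.table, sim.species

        # per-threshold DTW covariates at the plots
        pts = list(zip(table["x"], table["y"]))
        for lam, grid in sorted(suite.dtw_by_lambda.items()):
            table[f"dtw_{lam:g}ha"] = hy.sample_dtw_at_points(grid, pts)
        table.to_csv(out / "plots.csv", index=False)

        summaries = cm.summarize_plots(table, species)
        summaries.to_csv(out / "summaries.csv", index=False)

        # ---- per-threshold fits and AICc selection
        selected_lambda = lam0
        if config.run_fits:
            fit_rows, selections = [], {}
            for ftype in syn.FOREST_TYPES:
                sub = summaries[summaries["forest_type"] == ftype]
                if sub["compartment"].nunique() < 2:
                    continue
                for resp, (family, transforms) in _RESPONSES.items():
                    fits = {}
                    for lam in sorted(suite.dtw_by_lambda):
                        col = f"dtw_{lam:g}ha"
                        try:
                            fits[lam] = inf.fit_dtw_model(
                                sub[resp], sub[col], sub["compartment"],
                                family=family,
                                transform=transforms[ftype],
                                response=resp)
                        except ValueError as exc:
                            logger.warning("fit %s/%s at %s ha failed: %s",
                                           ftype, resp, lam, exc)
                    if len(fits) < 2:
                        continue
                    sel = inf.select_threshold(fits)
                    selections[(ftype, resp)] = sel
                    for lam, f in fits.items():
                        fit_rows.append({
                            "forest_type": ftype, "response": resp,
                            "lambda_ha": lam, **{
                                k: getattr(f, k) for k in (
                                    "intercept", "dtw_coef", "dtw_se",
                                    "dtw_stat", "dtw_p", "var_compartment",
                                    "var_residual", "loglik", "aicc",
                                    "marginal_r2", "conditional_r2", "n",
                                    "n_excluded", "converged")}})
            fits_df = pd.DataFrame(fit_rows)
            fits_df.to_csv(out / "fits.csv", index=False)
            # overall selection: the threshold supported (Delta < 2) for the
            # most (forest type, response) pairs; ties to the smallest lambda
            counts: dict = {}
            for sel in selections.values():
                for lam in sel.supported:
                    counts[lam] = counts.get(lam, 0) + 1
            if counts:
                best = max(counts.values())
                selected_lambda = min(l for l, c in counts.items()
                                      if c == best)
            report["stages"]["fits"] = {
                "selected_lambda_ha": float(selected_lambda),
                "support_counts": {f"{l:g}": c for l, c in sorted(counts.items())},
                "selection": {
                    f"{ft}/{resp}": {
                        "best_lambda": sel.best_lambda,
                        "supported": sel.supported,
                        "delta": dict(zip(map(str, sel.table["lambda_ha"]),
                                          sel.table["delta"])),
                    } for (ft, resp), sel in sorted(selections.items())},
            }
            pd.DataFrame(
                [{"forest_type": ft, "response": resp,
                  "best_lambda": sel.best_lambda,
                  "supported": " ".join(f"{l:g}" for l in sel.supported)}
                 for (ft, resp), sel in sorted(selections.items())]
            ).to_csv(out / "selection.csv", index=False)

        sel_col = f"dtw_{selected_lambda:g}ha"

        # ---- composition analyses at the selected threshold
        if config.run_isa:
            isa_out = {}
            for ftype in syn.FOREST_TYPES:
                sub = table[table["forest_type"] == ftype]
                if sub.empty:
                    continue
                classes = cm.classify_wetness(sub[sel_col].to_numpy())
                if len(np.unique(classes)) < 2 or not sub[species].to_numpy().sum():
                    isa_out[ftype] = "skipped: fewer than 2 wetness classes"
                    continue
                res = cm.indicator_value_analysis(
                    sub, species, classes, n_perm=config.n_perm,
                    seed=seed_for(f"isa_{ftype}"))
                res = res.sort_values("p_value").reset_index(drop=True)
                res.to_csv(out / f"isa_{ftype}.csv", index=False)
                sig = res[res["p_value"] <= 0.05]
                isa_out[ftype] = {
                    "n_species": int(len(res)),
                    "n_significant": int(len(sig)),
                    "top": res.iloc[0][["species", "group",
                                        "indicator_value",
                                        "p_value"]].to_dict(),
                }
            report["stages"]["isa"] = _jsonable(isa_out)

        if config.run_permanova or config.run_nmds:
            comp_out: dict = {}
            for ftype in syn.FOREST_TYPES:
                sub = table[table["forest_type"] == ftype]
                if len(sub) < 4:
                    continue
                try:
                    D, excluded = inf.bray_curtis(sub, species)
                except ValueError as exc:
                    comp_out[ftype] = {"skipped": str(exc)}
                    continue
                entry: dict = {"n_plots": int(D.shape[0]),
                               "n_excluded_zero_cover": len(excluded)}
                kept = sub.set_index("plot_id").loc[D.index]
                if config.run_permanova:
                    pm = inf.permanova(D, kept[sel_col].to_numpy(),
                                       n_perm=config.n_perm,
                                       seed=seed_for(f"permanova_{ftype}"))
                    entry["permanova"] = _jsonable(pm)
                if config.run_nmds:
                    om = inf.nmds(D, k=config.nmds_k,
                                  n_restarts=config.nmds_restarts,
                                  seed=seed_for(f"nmds_{ftype}"))
                    coords = pd.DataFrame(
                        om.coordinates, index=D.index,
                        columns=[f"nmds{i + 1}" for i in range(config.nmds_k)])
                    coords.to_csv(out / f"nmds_{ftype}.csv")
                    entry["nmds"] = {"stress": om.stress,
                                     "converged": om.converged}
                comp_out[ftype] = entry
            report["stages"]["composition"] = comp_out

        report["status"] = "ok"
    finally:
        root.removeHandler(fh)
        fh.close()

    with open(out / "report.json", "w") as f:
        json.dump(_jsonable(report), f, indent=2, sort_keys=True)
    return report
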