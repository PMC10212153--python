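"""End-to-end orchestration: detections in, per-species model results out.

Stages (each also exposed as a CLI subcommand) hand off through plain-text
files so any stage can be run and tested in isolation:

1. events      — independence-filter wildlife (30 min) and human (1 min)
                 detection records into events.
2. covariates  — per species, one model-table row per event: nocturnality
                 response plus raw human-presence, infrastructure and
                 environmental covariates.
3. scale-select— BIC-Bayes-factor choice among daily/weekly/monthly human
                 presence, against the intercept-only null.
4. fit         — flat-prior Bayesian linear model per species with z-scaled
                 predictors, credible intervals and evidence tiers.
5. diagnose    — Moran's I permutation test on per-station mean nocturnality.
6. activity    — circular kernel densities of diel activity per species and
                 for humans.

All randomness flows from one root seed split per stage; re-running a config
reproduces every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import circular_kde
from .bayeslm import (NocturnalityLM, collinearity_screen, scale_analysis)
from .covariates import assemble_model_table, station_covariates
from .events import filter_independent_events
from .io import read_detections, read_effort, read_lines, read_stations
from .spatial import build_weights, morans_i

__all__ = ["PipelineConfig", "run_pipeline", "load_inputs", "report"]

logger = logging.getLogger(__name__)

INFRASTRUCTURE_PREDICTORS = (
    "trail_density", "road_density", "dist_boundary", "lunar_fraction", "crown_closure",
)


@dataclass
class PipelineConfig:
    """Configuration with the analysis constants as defaults."""

    data_dir: str = "."
    out_dir: str = "results"
    species: Optional[Sequence[str]] = None  # None = every non-human species
    wildlife_threshold_min: float = 30.0
    human_threshold_min: float = 1.0
    buffer_radius_m: float = 500.0
    ci_levels: Tuple[float, float] = (0.90, 0.95)
    collinearity_threshold: float = 0.7
    method: str = "analytic"  # or "sampling"
    chains: int = 4
    iterations: int = 100_000
    burn_in: int = 5_000
    thinning: int = 1
    moran_permutations: int = 999
    moran_scheme: str = "inverse_distance"
    utc_offset_hours: float = -8.0
    per_station_solar: bool = True
    recompute_geometry: bool = True
    min_events: int = 10
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.wildlife_threshold_min <= 0 or self.human_threshold_min <= 0:
            raise ValueError("independence thresholds must be > 0")
        for level in self.ci_levels:
            if not 0 < level < 1:
                raise ValueError("CI levels must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ci_levels" in data:
            data["ci_levels"] = tuple(data["ci_levels"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = list(self.species) if self.species is not None else None
        d["ci_levels"] = list(self.ci_levels)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries stage and species context."""

    def __init__(self, stage: str, species: Optional[str], cause: BaseException):
        self.stage, self.species = stage, species
        where = f"stage {stage!r}" + (f", species {species!r}" if species else "")
        super().__init__(f"{where}: {cause}")
        self.__cause__ = cause


def load_inputs(config: PipelineConfig) -> dict:
    """Read detections, effort, stations and (optionally) line layers."""
    data = Path(config.data_dir)
    detections = read_detections(data / "detections.csv")
    # normalise any fixed-offset suffix to naive local clock time
    if getattr(detections["timestamp"].dtype, "tz", None) is not None:
        detections["timestamp"] = detections["timestamp"].dt.tz_localize(None)
    effort = read_effort(data / "effort.csv")
    stations = read_stations(data / "stations.csv")
    layers = {}
    for name in ("trails", "roads", "boundary"):
        fp = data / f"{name}.geojson"
        layers[name] = read_lines(fp) if fp.exists() else None
    if config.recompute_geometry and layers["boundary"]:
        stations = station_covariates(
            stations, layers["trails"], layers["roads"], layers["boundary"],
            radius_m=config.buffer_radius_m)
    return {"detections": detections, "effort": effort, "stations": stations,
            "layers": layers}


def _wildlife_species(detections: pd.DataFrame, config: PipelineConfig):
    if config.species is not None:
        return list(config.species)
    return sorted(s for s in detections["species"].unique() if s != "human")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle under ``config.out_dir``.

    Returns a dict with the in-memory objects (events, model tables, scale
    selections, fit results, Moran results, activity densities, manifest).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config)
    detections, effort, stations = (
        inputs["detections"], inputs["effort"], inputs["stations"])

    species_list = _wildlife_species(detections, config)
    rng_root = np.random.SeedSequence(config.seed)
    moran_seed, fit_seed = [int(s.generate_state(1)[0] % (2**31))
                            for s in rng_root.spawn(2)]

    # --- events ----------------------------------------------------------
    human_records = detections[detections["species"] == "human"]
    wildlife_records = detections[detections["species"] != "human"]
    human_events = filter_independent_events(human_records, config.human_threshold_min) \
        if len(human_records) else pd.DataFrame(
            columns=["station_id", "species", "start_timestamp", "n_records"])
    wildlife_events = filter_independent_events(
        wildlife_records, config.wildlife_threshold_min) if len(wildlife_records) else \
        pd.DataFrame(columns=["station_id", "species", "start_timestamp", "n_records"])
    all_events = pd.concat([wildlife_events, human_events], ignore_index=True)
    all_events.to_csv(out / "events.csv", index=False)
    logger.info("events: %d wildlife, %d human (%.1fs)",
                len(wildlife_events), len(human_events), time.time() - t0)

    tables: Dict[str, pd.DataFrame] = {}
    selections: Dict[str, object] = {}
    fits: Dict[str, object] = {}
    morans: Dict[str, object] = {}
    densities: Dict[str, object] = {}
    screens: Dict[str, pd.DataFrame] = {}
    skipped = []

    for species in species_list:
        sp_events = wildlife_events[wildlife_events["species"] == species]
        if len(sp_events) < config.min_events:
            logger.warning("skipping %s: %d events (< %d)", species, len(sp_events),
                           config.min_events)
            skipped.append(species)
            continue

        try:
            table = assemble_model_table(
                sp_events, stations, human_events, effort,
                utc_offset_hours=config.utc_offset_hours,
                per_station_solar=config.per_station_solar)
        except Exception as exc:
            raise StageError("covariates", species, exc) from exc
        tables[species] = table
        table.to_csv(out / f"model_table_{species}.csv", index=False)

        try:
            pred_cols = [c for c in table.columns
                         if c not in ("species", "station_id", "start_timestamp",
                                      "nocturnality")]
            screens[species] = collinearity_screen(
                table[pred_cols], threshold=config.collinearity_threshold)
            selections[species] = scale_analysis(table)
        except Exception as exc:
            raise StageError("scale-select", species, exc) from exc

        try:
            sel = selections[species]
            predictors = ([sel.chosen_column] if sel.chosen != "none" else []) + \
                list(INFRASTRUCTURE_PREDICTORS)
            model = NocturnalityLM.from_dataframe(
                table, predictors=predictors, species=species)
            fits[species] = model.fit(
                method=config.method, chains=config.chains,
                iterations=config.iterations, burn_in=config.burn_in,
                thinning=config.thinning, seed=fit_seed)
        except Exception as exc:
            raise StageError("fit", species, exc) from exc

        try:
            means = table.groupby("station_id")["nocturnality"].mean()
            sub = stations[stations["station_id"].isin(means.index)].reset_index(drop=True)
            if len(sub) >= 3 and means.loc[sub["station_id"]].std() > 0:
                w = build_weights(sub, scheme=config.moran_scheme)
                morans[species] = morans_i(
                    means.loc[sub["station_id"]].to_numpy(), w,
                    n_permutations=config.moran_permutations, seed=moran_seed)
            else:
                logger.warning("%s: too few distinct stations for Moran's I", species)
        except Exception as exc:
            raise StageError("diagnose", species, exc) from exc

        try:
            hours = pd.DatetimeIndex(sp_events["start_timestamp"])
            clock = hours.hour + hours.minute / 60.0 + hours.second / 3600.0
            densities[species] = circular_kde(clock)
        except Exception as exc:
            raise StageError("activity", species, exc) from exc

    if len(human_events) >= 2:
        hh = pd.DatetimeIndex(human_events["start_timestamp"])
        densities["human"] = circular_kde(hh.hour + hh.minute / 60.0 + hh.second / 3600.0)

    _write_outputs(out, config, tables, selections, fits, morans, densities, screens,
                   wildlife_events)
    if config.make_plots:
        _plot_activity(out, densities)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "species_processed": sorted(tables),
        "species_skipped": skipped,
        "n_wildlife_events": int(len(wildlife_events)),
        "n_human_events": int(len(human_events)),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"events": all_events, "tables": tables, "selections": selections,
            "fits": fits, "morans": morans, "densities": densities,
            "screens": screens, "manifest": manifest}


def _write_outputs(out, config, tables, selections, fits, morans, densities,
                   screens, wildlife_events):
    (out / "scale_selection.json").write_text(json.dumps({
        sp: {"bayes_factors": sel.bayes_factors, "chosen": sel.chosen}
        for sp, sel in selections.items()}, indent=1))
    (out / "collinearity.json").write_text(json.dumps({
        sp: scr.to_dict(orient="records") for sp, scr in screens.items()}, indent=1))
    (out / "fits.json").write_text(json.dumps({
        sp: {
            "method": res.method,
            "n_obs": int(res.n_obs),
            "df_resid": int(res.df_resid),
            "residual_sd_posterior_mean": res.sigma,
            "converged": res.converged(),
            "rhat": None if res.rhat is None else res.rhat.round(5).to_dict(),
            "coefficients": json.loads(
                res.to_frame().drop(columns="species").to_json(orient="index")),
        } for sp, res in fits.items()}, indent=1))
    frames = [res.to_frame().reset_index(names="parameter") for res in fits.values()]
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(out / "results.csv", index=False)
    (out / "moran.json").write_text(json.dumps({
        sp: {"I": m.I, "expected_I": m.expected_I, "p_value": m.p_value,
             "n_permutations": m.n_permutations, "scheme": m.scheme, "seed": m.seed}
        for sp, m in morans.items()}, indent=1))
    for name, dens in densities.items():
        pd.DataFrame({"time": dens.grid, "density": dens.density}).to_csv(
            out / f"activity_{name}.csv", index=False)
    # event summary shaped like the detections table of the study
    if len(wildlife_events):
        rows = []
        for sp, grp in wildlife_events.groupby("species"):
            tab = tables.get(sp)
            noct = tab["nocturnality"] if tab is not None else None
            rows.append({
                "species": sp,
                "n_events": int(len(grp)),
                "mean_nocturnality": None if noct is None else round(float(noct.mean()), 2),
                "min_nocturnality": None if noct is None else round(float(noct.min()), 2),
                "max_nocturnality": None if noct is None else round(float(noct.max()), 2),
            })
        pd.DataFrame(rows).to_csv(out / "event_summary.csv", index=False)


def _plot_activity(out, densities):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    species = [s for s in densities if s != "human"]
    if not species:
        return
    ncol = 2
    nrow = int(np.ceil(len(species) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(9, 3 * nrow), squeeze=False)
    for ax, sp in zip(axes.ravel(), species):
        d = densities[sp]
        ax.plot(d.grid, d.density, "k-", label=sp)
        if "human" in densities:
            h = densities["human"]
            ax.plot(h.grid, h.density, "r-", alpha=0.7, label="human")
        ax.set_xlim(0, 24)
        ax.set_xlabel("time of day (h)")
        ax.set_ylabel("density")
        ax.legend(frameon=False, fontsize=8)
    for ax in axes.ravel()[len(species):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(Path(out) / "activity.png", dpi=120)
    plt.close(fig)


def report(out_dir) -> str:
    """Render a plain-text summary of a completed run's output files."""
    out = Path(out_dir)
    lines = ["diel-activity analysis report", "=" * 32]
    summary = out / "event_summary.csv"
    if summary.exists():
        lines += ["", "Independent detection events and nocturnality:",
                  pd.read_csv(summary).to_string(index=False)]
    sel_file = out / "scale_selection.json"
    if sel_file.exists():
        sel = json.loads(sel_file.read_text())
        lines += ["", "Temporal-scale selection (BIC Bayes factors vs null):"]
        for sp, entry in sel.items():
            bfs = ", ".join(f"{k}={v:.3g}" for k, v in entry["bayes_factors"].items())
            lines.append(f"  {sp}: {bfs} -> chosen: {entry['chosen']}")
    res_file = out / "results.csv"
    if res_file.exists():
        res = pd.read_csv(res_file)
        lines += ["", "Posterior estimates (z-scaled predictors):",
                  res.to_string(index=False, float_format=lambda v: f"{v: .3f}")]
    moran_file = out / "moran.json"
    if moran_file.exists():
        moran = json.loads(moran_file.read_text())
        lines += ["", "Spatial autocorrelation (Moran's I on station mean nocturnality):"]
        for sp, m in moran.items():
            lines.append(f"  {sp}: I={m['I']:.3f} (E[I]={m['expected_I']:.3f}), "
                         f"p={m['p_value']:.3f} [{m['scheme']}]")
    return "\n".join(lines)
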