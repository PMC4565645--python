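"""End-to-end orchestration: fits, tables, plots, maps, and a manifest.

``run_full_pipeline`` chains every stage — allometric fits, scale-adjusted
metrics, baseline groups, per-capita and group summaries, memory fits with
diagnostics, cross-indicator models, the next-census forecast, and the
geographic change map — writing one artifact per stage plus a manifest with
a content hash for each file.  Every numeric output carries the config hash
and seed in a comment header, and a fixed seed reproduces every artifact
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, forecast, io, memory, sami
from .synthetic import default_config, generate_panel

logger = logging.getLogger("urbansami")

__all__ = ["PipelineConfig", "run_full_pipeline", "render_change_map"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    With ``panel_path=None`` the reference synthetic scenario is simulated
    (seeded) and analyzed; otherwise the panel (and optionally coordinates)
    are read from disk.  ``baseline_year`` defaults to the earliest census;
    ``horizon_year`` to one census step past the last.
    """

    out_dir: str = "urbansami_output"
    panel_path: str | None = None
    coords_path: str | None = None
    baseline_year: int | None = None
    horizon_year: int | None = None
    seed: int = 0
    n_boot_se: int = 1000
    n_boot_ci: int = 10_000
    variance_ratio: float = 1.0
    zero_policy: str = "drop"
    robust_se: bool = False
    n_cities: int = 1605
    map_indicator: str = "homicides"

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis re-run elsewhere gets the same hash)."""
        d = dataclasses.asdict(self)
        for key in ("out_dir", "panel_path", "coords_path"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    A stage failure is recorded in the manifest and does not discard the
    artifacts already completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    manifest: dict = {"config": dataclasses.asdict(config), "metadata": meta,
                      "artifacts": {}, "failures": {}}
    state: dict = {}

    def artifact(name, path):
        manifest["artifacts"][name] = {"path": str(path.name), "sha256": _sha256(path)}

    def stage(name):
        def wrap(fn):
            try:
                logger.info("stage %s", name)
                fn()
            except Exception as err:  # keep completed artifacts, record failure
                logger.error("stage %s failed: %s", name, err)
                manifest["failures"][name] = f"{type(err).__name__}: {err}"
        return wrap

    @stage("input")
    def _input():
        if config.panel_path is None:
            cfg = default_config(seed=config.seed, n_cities=config.n_cities)
            panel, truth, coords = generate_panel(cfg)
            io.write_census_panel(panel, out / "panel.csv", meta)
            io.write_coordinates(coords, out / "coordinates.csv", meta)
            artifact("panel", out / "panel.csv")
            artifact("coordinates", out / "coordinates.csv")
            state["panel"], state["coords"] = panel, coords
        else:
            state["panel"] = io.read_census_panel(config.panel_path).complete_subset()
            if config.coords_path:
                state["coords"] = io.read_coordinates(config.coords_path)

    @stage("allometry")
    def _allometry():
        panel = state["panel"]
        fits = allometry.fit_all_allometries(
            panel, seed=config.seed, n_boot=config.n_boot_se,
            variance_ratio=config.variance_ratio, zero_policy=config.zero_policy,
        )
        state["fits"] = fits
        io._write_frame(allometry.fits_to_frame(fits), out / "allometry.csv", meta)
        artifact("allometry", out / "allometry.csv")

    @stage("per_capita")
    def _per_capita():
        panel = state["panel"]
        frames = [
            allometry.per_capita_group_means(panel, year, n_boot=config.n_boot_ci,
                                             seed=config.seed + year)
            for year in panel.years
        ]
        io._write_frame(pd.concat(frames, ignore_index=True),
                        out / "per_capita.csv", meta)
        artifact("per_capita", out / "per_capita.csv")

    @stage("sami")
    def _sami():
        panel, fits = state["panel"], state["fits"]
        table = sami.compute_sami(panel, fits, zero_policy=config.zero_policy)
        baseline = config.baseline_year or min(panel.years)
        table = sami.label_baseline_groups(table, baseline)
        state["table"], state["baseline"] = table, baseline
        io.write_sami_table(table, out / "sami.csv", meta)
        artifact("sami", out / "sami.csv")

    @stage("groups")
    def _groups():
        summary = sami.group_summaries(state["table"], n_boot=config.n_boot_ci,
                                       seed=config.seed)
        state["group_summary"] = summary
        io._write_frame(summary, out / "group_summary.csv", meta)
        artifact("group_summary", out / "group_summary.csv")

    @stage("memory")
    def _memory():
        table = state["table"]
        fits = memory.fit_all_memory(table)
        state["memory_fits"] = fits
        io._write_frame(memory.memory_fits_to_frame(fits), out / "memory.csv", meta)
        artifact("memory", out / "memory.csv")
        rows = []
        for (ind, pair), f in fits.items():
            diag = memory.residual_diagnostics(f, table)
            for w in range(len(diag.window_sd)):
                rows.append({
                    "indicator": ind, "year_from": pair[0], "year_to": pair[1],
                    "cvm_statistic": diag.cvm_statistic, "cvm_p": diag.cvm_p,
                    "window": w, "window_center": diag.window_centers[w],
                    "window_sd": diag.window_sd[w],
                    "window_n": diag.window_counts[w],
                })
        io._write_frame(pd.DataFrame(rows), out / "diagnostics.csv", meta)
        artifact("diagnostics", out / "diagnostics.csv")

    @stage("forecast")
    def _forecast():
        table = state["table"]
        models = forecast.fit_all_cross_models(table, robust=config.robust_se)
        state["models"] = models
        io._write_frame(forecast.models_to_frame(models), out / "models.csv", meta)
        artifact("models", out / "models.csv")
        years = table.years
        averaged = {
            ind: forecast.average_models(
                [models[(ind, (t0, t1))] for t0, t1 in zip(years[:-1], years[1:])]
            )
            for ind in table.indicators
        }
        state["averaged"] = averaged
        io._write_frame(forecast.models_to_frame(
            {(ind, None): m for ind, m in averaged.items()}),
            out / "models_averaged.csv", meta)
        artifact("models_averaged", out / "models_averaged.csv")

    @stage("predict")
    def _predict():
        table = state["table"]
        years = table.years
        step = years[-1] - years[-2]
        horizon = config.horizon_year or years[-1] + step
        predicted, n_skipped = forecast.predict_next(
            table, state["averaged"], from_year=years[-1],
            horizon_year=horizon, census_step=step,
        )
        state["predicted"], state["horizon"] = predicted, horizon
        logger.info("forecast skipped %d cities with incomplete predictors", n_skipped)
        io.write_sami_table(predicted, out / "predictions.csv", meta)
        artifact("predictions", out / "predictions.csv")
        # in-sample check: predict the last census from the one before
        insample, _ = forecast.predict_next(
            table, state["averaged"], from_year=years[-2],
            horizon_year=years[-1], census_step=step,
        )
        report = forecast.compare_predicted_empirical(
            insample, table, n_boot=config.n_boot_ci, seed=config.seed)
        io._write_frame(report.group_means, out / "comparison_group_means.csv", meta)
        io._write_frame(report.cdf_distance, out / "comparison_cdf.csv", meta)
        artifact("comparison_group_means", out / "comparison_group_means.csv")
        artifact("comparison_cdf", out / "comparison_cdf.csv")

    @stage("plots")
    def _plots():
        _plot_group_means(state["group_summary"], out / "group_means.png")
        _plot_memory_scatter(state["table"], state["memory_fits"],
                             out / "memory_scatter.png")
        _plot_cdf_overlay(state["table"], state["predicted"], state["horizon"],
                          out / "cdf_overlay.png")
        for name in ("group_means", "memory_scatter", "cdf_overlay"):
            artifact(name, out / f"{name}.png")

    @stage("map")
    def _map():
        if "coords" not in state or "predicted" not in state:
            raise RuntimeError("map stage needs coordinates and predictions")
        table, predicted = state["table"], state["predicted"]
        last = table.years[-1]
        ind = config.map_indicator
        changes = (predicted.series(ind, state["horizon"])
                   - table.series(ind, last)).dropna()
        skipped = io.write_change_geojson(changes, state["coords"],
                                          out / "changes.geojson", scale=1.0)
        if skipped:
            logger.warning("map skipped %d cities without coordinates", len(skipped))
        render_change_map(changes, state["coords"], out / "change_map.png",
                          title=f"Predicted change in D ({ind})")
        artifact("changes_geojson", out / "changes.geojson")
        artifact("change_map", out / "change_map.png")

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


# -- plotting -----------------------------------------------------------


def _plot_group_means(summary: pd.DataFrame, path) -> None:
    import matplotlib.pyplot as plt

    indicators = sorted(summary["indicator"].unique())
    fig, axes = plt.subplots(2, (len(indicators) + 1) // 2,
                             figsize=(3 * ((len(indicators) + 1) // 2), 6),
                             squeeze=False)
    for ax, ind in zip(axes.ravel(), indicators):
        sub = summary[summary["indicator"] == ind]
        for group, color in (("above", "tab:red"), ("below", "tab:blue")):
            g = sub[sub["group"] == group].sort_values("year")
            ax.errorbar(g["year"], g["mean"],
                        yerr=[g["mean"] - g["ci_low"], g["ci_high"] - g["mean"]],
                        marker="o", label=group, color=color)
        ax.axhline(0.0, color="gray", lw=0.5)
        ax.set_title(ind, fontsize=8)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_memory_scatter(table, fits: dict, path) -> None:
    import matplotlib.pyplot as plt

    pairs = sorted({pair for (_, pair) in fits})
    pair = pairs[-1]
    indicators = sorted({ind for (ind, p) in fits if p == pair})
    fig, axes = plt.subplots(2, (len(indicators) + 1) // 2,
                             figsize=(3 * ((len(indicators) + 1) // 2), 6),
                             squeeze=False)
    for ax, ind in zip(axes.ravel(), indicators):
        f = fits[(ind, pair)]
        d0 = table.series(ind, pair[0])
        d1 = table.series(ind, pair[1])
        common = d0.index.intersection(d1.index)
        x, y = d0.loc[common], d1.loc[common]
        ax.plot(x, y, ".", ms=2, alpha=0.4, color="purple")
        grid = np.linspace(x.min(), x.max(), 10)
        ax.plot(grid, f.intercept + f.slope * grid, "--", color="black",
                label=f"alpha={f.slope:.2f}")
        ax.set_title(ind, fontsize=8)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_cdf_overlay(table, predicted, horizon: int, path) -> None:
    import matplotlib.pyplot as plt

    indicators = predicted.indicators
    fig, axes = plt.subplots(2, (len(indicators) + 1) // 2,
                             figsize=(3 * ((len(indicators) + 1) // 2), 6),
                             squeeze=False)
    last = table.years[-1]
    for ax, ind in zip(axes.ravel(), indicators):
        for label, series in (("empirical " + str(last), table.series(ind, last)),
                              ("predicted " + str(horizon),
                               predicted.series(ind, horizon))):
            vals = np.sort(series.to_numpy())
            ax.step(vals, np.arange(1, vals.size + 1) / vals.size, label=label)
        ax.set_title(ind, fontsize=8)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_change_map(changes, coords, path, scale: float | None = None,
                      title: str = "") -> None:
    """Bubble map of per-city changes: radius ~ |delta|, diverging hues.

    Increases are drawn in shades of red, decreases in shades of azure, with
    darker shades for larger absolute changes.  With all deltas zero the
    radii are zero and the color scale degenerates gracefully.
    """
    import matplotlib
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    if isinstance(changes, dict):
        changes = pd.Series(changes)
    lookup = coords.lookup()
    rows = [(lookup[str(c)][1], lookup[str(c)][0], float(d))
            for c, d in changes.items() if str(c) in lookup]
    lon, lat, delta = (np.array(v) for v in zip(*rows)) if rows else (
        np.array([]), np.array([]), np.array([]))
    dmax = np.abs(delta).max() if delta.size else 0.0
    if scale is None:
        scale = 40.0 / dmax if dmax > 0 else 1.0
    norm = colors.Normalize(vmin=-dmax if dmax > 0 else -1.0,
                            vmax=dmax if dmax > 0 else 1.0)
    cmap = matplotlib.colormaps["RdBu_r"]  # red = increase, azure = decrease
    fig, ax = plt.subplots(figsize=(6, 6))
    sizes = (scale * np.abs(delta)) ** 2
    ax.scatter(lon, lat, s=sizes, c=delta, cmap=cmap, norm=norm,
               alpha=0.7, linewidths=0)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(title)
    fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, label="delta D")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
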