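"""End-to-end orchestration: cohort -> preprocessing -> PLV networks ->
efficiency statistics -> classification, with reproducible artifacts.

Conventions: samples are 0-based, intervals are half-open [start, stop); all
randomness flows from one pipeline seed through ``numpy.random.SeedSequence``
children (simulation first, classifier second), so a rerun with the same
config and seed reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .preprocess import (BROADBAND, DEFAULT_BANDS, BandSpec, EEGEpoch,
                         average_reference, bandpass, select_gfp_block)
from .connectivity import band_plv_batch, windowed_band_plv
from .netmetrics import DEFAULT_THRESHOLDS, efficiency_sweep
from .groupstats import build_stats_table, render_markdown
from .classify import DEFAULT_TOP_N, train_and_evaluate, vectorize_features
from .simulate import LabelledCohort, SimulationConfig, read_cohort, simulate_cohort
from .regions import validate_region_map

__all__ = ["PipelineConfig", "run_pipeline", "preprocess_cohort",
           "efficiency_observations", "cohort_feature_set"]

log = logging.getLogger("menet")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; serialisable to/from JSON or YAML."""

    simulation: SimulationConfig | None = None
    cohort_path: str | None = None
    bands: tuple[str, ...] = ("alpha", "beta", "gamma")
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    block_dur: float = 1.0
    window: float = 0.4
    overlap: float = 0.5
    broadband: tuple[float, float] = BROADBAND
    filter_per_band: bool = True
    alpha_level: float = 0.05
    kernel: str = "rbf"
    n_trees: int = 500
    top_n: tuple[int, ...] = DEFAULT_TOP_N
    group_split: bool = False
    out_dir: str = "menet_out"
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None and self.cohort_path is None:
            raise ConfigurationError("config needs a simulation block or a cohort_path")
        if not all(0.0 < t < 1.0 for t in self.thresholds):
            raise ConfigurationError("thresholds must lie in (0, 1)")
        known = {b.name for b in DEFAULT_BANDS}
        unknown = set(self.bands) - known
        if unknown:
            raise ConfigurationError(f"unknown bands: {sorted(unknown)}")
        if not (0 < self.alpha_level < 1):
            raise ConfigurationError("alpha_level must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if raw.get("simulation") is not None:
            sim = dict(raw["simulation"])
            if "bands" in sim:
                sim["bands"] = tuple(BandSpec(**b) for b in sim["bands"])
            if "coupled_regions" in sim:
                sim["coupled_regions"] = tuple(sim["coupled_regions"])
            raw["simulation"] = SimulationConfig(**sim)
        for key in ("bands", "thresholds", "top_n", "broadband"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["bands"] = [dataclasses.asdict(b) for b in self.simulation.bands]
            d["simulation"] = sim
        return d


def _bands_by_name(names) -> list[BandSpec]:
    lookup = {b.name: b for b in DEFAULT_BANDS}
    return [lookup[n] for n in names]


def preprocess_cohort(cohort: LabelledCohort, broadband=BROADBAND,
                      block_dur: float = 1.0) -> list[EEGEpoch]:
    """Broadband filter, average reference and GFP block selection per epoch."""
    blocks = []
    for ep in cohort.epochs:
        ep = bandpass(ep, broadband[0], broadband[1])
        ep = average_reference(ep)
        blocks.append(select_gfp_block(ep, block_dur))
    return blocks


def efficiency_observations(blocks: list[EEGEpoch], labels: list[str],
                            region_map: dict[str, str], bands: list[BandSpec],
                            thresholds=DEFAULT_THRESHOLDS,
                            filter_per_band: bool = True) -> pd.DataFrame:
    """Tidy per-epoch efficiency table: (epoch_id, band, threshold, scope, group, value)."""
    rows = []
    for band in bands:
        if filter_per_band:
            band_blocks = [bandpass(b, band.f_lo, band.f_hi) for b in blocks]
        else:
            band_blocks = blocks
        conns = band_plv_batch(band_blocks, band)
        for eid, (conn, group) in enumerate(zip(conns, labels)):
            for res in efficiency_sweep(conn, thresholds, region_map):
                rows.append((eid, band.name, res.threshold, "global", group, res.e_global))
                for region, val in res.e_regional.items():
                    rows.append((eid, band.name, res.threshold, f"region:{region}",
                                 group, val))
    return pd.DataFrame(rows, columns=["epoch_id", "band", "threshold",
                                       "scope", "group", "value"])


def cohort_feature_set(blocks: list[EEGEpoch], labels: list[str], band: BandSpec,
                       window: float = 0.4, overlap: float = 0.5,
                       filter_per_band: bool = True):
    """Windowed PLV feature set for one band (one sample per window)."""
    conns, y, groups = [], [], []
    for eid, (block, group) in enumerate(zip(blocks, labels)):
        if filter_per_band:
            block = bandpass(block, band.f_lo, band.f_hi)
        for conn in windowed_band_plv(block, band, win=window, overlap=overlap):
            conns.append(conn)
            y.append(group)
            groups.append(eid)
    return vectorize_features(conns, y, groups)


def _mean_plv(blocks, labels, band, filter_per_band):
    if filter_per_band:
        blocks = [bandpass(b, band.f_lo, band.f_hi) for b in blocks]
    conns = band_plv_batch(blocks, band)
    stack = np.stack([c.values for c in conns])
    return pd.DataFrame(stack.mean(axis=0), index=conns[0].node_ids,
                        columns=conns[0].node_ids)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact directory.

    Artifacts: efficiency.csv, stats_table.csv, stats_tables.md,
    mean_plv_<band>.csv, report.json, roc_<band>.csv,
    feature_importance_<band>.csv, manifest.json and run.log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        ss = np.random.SeedSequence(config.seed)
        sim_seed, clf_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

        t0 = time.perf_counter()
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=sim_seed)
            log.info("stage=simulate config=%s", sim)
            cohort = simulate_cohort(sim)
        else:
            log.info("stage=load cohort_path=%s", config.cohort_path)
            cohort = read_cohort(config.cohort_path)
        region_map = validate_region_map(cohort.region_map)
        labels = cohort.labels
        log.info("stage=simulate done n_epochs=%d elapsed=%.1fs",
                 len(cohort.epochs), time.perf_counter() - t0)

        t0 = time.perf_counter()
        blocks = preprocess_cohort(cohort, config.broadband, config.block_dur)
        log.info("stage=preprocess done elapsed=%.1fs", time.perf_counter() - t0)

        bands = _bands_by_name(config.bands)
        t0 = time.perf_counter()
        obs = efficiency_observations(blocks, labels, region_map, bands,
                                      config.thresholds, config.filter_per_band)
        obs.to_csv(out / "efficiency.csv", index=False)
        for band in bands:
            _mean_plv(blocks, labels, band, config.filter_per_band).to_csv(
                out / f"mean_plv_{band.name}.csv")
        log.info("stage=connectivity+efficiency done elapsed=%.1fs",
                 time.perf_counter() - t0)

        table = build_stats_table(obs, alpha=config.alpha_level)
        table.to_csv(out / "stats_table.csv", index=False)
        md = []
        for band in bands:
            md.append(f"## Global efficiency, {band.name} band\n")
            md.append(render_markdown(table, band.name, regional=False))
            md.append(f"\n## Regional efficiency, {band.name} band\n")
            md.append(render_markdown(table, band.name, regional=True))
            md.append("\n")
        (out / "stats_tables.md").write_text("".join(md))
        log.info("stage=stats done")

        t0 = time.perf_counter()
        report_all: dict[str, dict] = {}
        for band in bands:
            fs = cohort_feature_set(blocks, labels, band, config.window,
                                    config.overlap, config.filter_per_band)
            ranking, report = train_and_evaluate(
                fs, seed=clf_seed, n_list=config.top_n, kernel=config.kernel,
                n_trees=config.n_trees, group_split=config.group_split)
            report_all[band.name] = {
                "results": report.results,
                "seed": report.seed, "kernel": report.kernel,
                "n_train": report.n_train, "n_test": report.n_test,
                "cv_folds": report.cv_folds, "group_split": report.group_split,
            }
            rocs = []
            for n, res in report.results.items():
                for fpr, tpr in zip(res["roc_fpr"], res["roc_tpr"]):
                    rocs.append((n, fpr, tpr))
            pd.DataFrame(rocs, columns=["top_n", "fpr", "tpr"]).to_csv(
                out / f"roc_{band.name}.csv", index=False)
            imp = pd.DataFrame({
                "node_i": [f[0] for f in ranking.feature_ids],
                "node_j": [f[1] for f in ranking.feature_ids],
                "band": [f[2] for f in ranking.feature_ids],
                "gini": ranking.gini,
            }).sort_values(["gini", "node_i", "node_j"],
                           ascending=[False, True, True], kind="mergesort")
            imp.to_csv(out / f"feature_importance_{band.name}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report_all, fh, indent=2, sort_keys=True)
        log.info("stage=classify done elapsed=%.1fs", time.perf_counter() - t0)

        cfg_json = json.dumps(config.to_jsonable(), sort_keys=True)
        manifest = {
            "config": json.loads(cfg_json),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "menet_version": __version__,
            "versions": _library_versions(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("run complete out=%s", out)
    except Exception:
        log.exception("pipeline aborted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _library_versions() -> dict[str, str]:
    import scipy
    import sklearn
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "sklearn": sklearn.__version__}
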