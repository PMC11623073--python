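"""End-to-end orchestration: simulate → fuse → augment → run → evaluate →
carbon, with per-stage artifacts and JSON run-metadata sidecars.

Every stage writes its artifact plus a ``<stage>.meta.json`` sidecar holding
the seed, row counts and duration, so the bookkeeping (rows read / dropped /
positive / negative) is auditable.  All randomness flows from the single
top-level seed; file outputs contain no wall-clock values, so a re-run with
the same seed reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .augment import assemble_dataset, attack_calendar, generate_negatives
from .carbon import PhaseTimer, PowerModel, ledger_report
from .containers import GladDataset, RegionAtlas, events_from_csv, events_to_csv
from .errors import LocustLensError
from .fusion import build_positive_rows, read_climate
from .knn import KnnConfig
from .metrics import evaluate
from .model import LocustLens
from .simulate import SimulationConfig, make_atlas, make_climate, simulate_events

log = logging.getLogger("locustlens")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    folds: int = 5
    span: tuple[int, int] | None = None
    track_carbon: bool = True
    region: str = "US"
    resume: bool = False


class StageError(LocustLensError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sidecar(path: Path, stage: str, seed: int, **extra) -> None:
    meta = {
        "stage": stage,
        "seed": seed,
        "locustlens_version": __version__,
        "python": platform.python_version(),
        **extra,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2)
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage, returning the artifact paths.  A failing stage raises
    :class:`StageError` naming it."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    if sim.seed != config.seed:
        # single top-level seed governs everything
        sim = SimulationConfig(
            **{**sim.__dict__, "seed": config.seed}
        )
    timer = PhaseTimer()
    paths = {
        "atlas": out / "atlas.csv",
        "events": out / "events.csv",
        "climate": out / "climate.nc",
        "positives": out / "glad_pos.csv",
        "dataset": out / "glad42.csv",
        "predictions": out / "predictions.csv",
        "baseline_predictions": out / "predictions_baseline.csv",
        "report": out / "report.json",
        "carbon": out / "carbon.json",
    }

    def fresh(*keys: str) -> bool:
        return not (config.resume and all(paths[k].exists() for k in keys))

    stage = "simulate"
    try:
        if fresh("atlas", "events", "climate"):
            with timer.phase(stage):
                atlas = make_atlas(sim)
                grid = make_climate(sim, atlas)
                events = simulate_events(sim, atlas, grid)
                atlas.to_csv(paths["atlas"])
                grid.to_netcdf(paths["climate"])
                events_to_csv(events, paths["events"])
            _sidecar(paths["events"], stage, config.seed, n_events=len(events))
            log.info("simulate: %d events over %d region-months",
                     len(events), len(atlas) * len(grid.time_axis))

        stage = "fuse"
        with timer.phase(stage):
            atlas = RegionAtlas.from_csv(paths["atlas"])
            grid = read_climate(paths["climate"])
            events = events_from_csv(paths["events"])
            positives = build_positive_rows(events, grid, atlas)
            positives.to_csv(paths["positives"])
        _sidecar(paths["positives"], stage, config.seed, **positives.counters())
        log.info("fuse: %s", positives.counters())

        stage = "augment"
        with timer.phase(stage):
            span = config.span or sim.year_span
            calendar = attack_calendar(positives)
            negatives = generate_negatives(calendar, atlas, grid, span)
            dataset = assemble_dataset(positives, negatives)
            dataset.to_csv(paths["dataset"])
        _sidecar(paths["dataset"], stage, config.seed, **dataset.counters())
        log.info("augment: %s", dataset.counters())

        stage = "run"
        with timer.phase(stage):
            results = LocustLens(
                dataset, config.knn, n_splits=config.folds, seed=config.seed
            ).fit()
            results.predictions_frame().to_csv(paths["predictions"], index=False)
            baseline = LocustLens(
                dataset, config.knn, n_splits=config.folds, seed=config.seed,
                mode="global",
            ).fit()
            baseline.predictions_frame().to_csv(
                paths["baseline_predictions"], index=False
            )
        _sidecar(
            paths["predictions"], stage, config.seed,
            mean_fit_s=results.report.mean_fit_s,
            mean_predict_s=results.report.mean_predict_s,
        )

        stage = "evaluate"
        with timer.phase(stage):
            # score the deterministic prediction columns so report.json is
            # byte-reproducible; timings live in the run-metadata sidecar
            report = {
                "locustlens": evaluate(
                    results.predictions_frame(), per_country=True
                ).to_dict(),
                "global_baseline": evaluate(
                    baseline.predictions_frame(), per_country=True
                ).to_dict(),
            }
            paths["report"].write_text(json.dumps(report, indent=2))
        log.info(
            "evaluate: locustlens acc=%.4f, baseline acc=%.4f",
            results.accuracy, baseline.accuracy,
        )

        stage = "carbon"
        if config.track_carbon:
            ledger = ledger_report(
                timer.durations, PowerModel(), region=config.region
            )
            paths["carbon"].write_text(ledger.to_json())
            log.info("carbon: %.4f gCO2eq total", ledger.total_emissions_g)
        else:
            paths.pop("carbon")
    except LocustLensError as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    except (OSError, KeyError, ValueError) as exc:
        raise StageError(stage, exc) from exc
    return paths
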