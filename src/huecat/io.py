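"""Run configuration, seeding, persistence and the experiment pipelines.

A single global seed fans out to per-component seeds through
``numpy.random.SeedSequence([seed, *keys])``, so every sub-experiment is
independently reproducible.  Each pipeline writes its artifacts (CSV /
JSON) plus a manifest recording the configuration, its hash and the
seed; re-running with the same configuration reproduces identical
outputs on deterministic paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import borders as _borders
from . import evolution as _evolution
from . import experiments as _experiments
from . import probes as _probes

__all__ = ["RunConfig", "PRESETS", "run_pipeline", "load_manifest"]

#: planted borders used by all synthetic drivers when none are supplied;
#: 7 unevenly spaced positions (minimum gap 0.10 of the circle)
DEFAULT_PLANTED = (0.03, 0.16, 0.30, 0.45, 0.60, 0.75, 0.90)


PRESETS = {
    # the study-scale design
    "paper": {
        "class_counts": (4, 5, 6, 7, 8, 9),
        "n_shifts": 150,
        "n_train_per_class": 500,
        "n_val_per_class": 50,
        "samples_per_bin": 60,
        "pop_size": 100,
        "n_generations": 40,
        "n_replicates": 12,
        "n_boot": 100_000,
    },
    # reduced counts (never altered formulas or thresholds) so every
    # experiment finishes in minutes on one CPU
    "desk": {
        "class_counts": (5, 6, 7),
        "n_shifts": 50,
        "n_train_per_class": 100,
        "n_val_per_class": 20,
        "samples_per_bin": 20,
        "pop_size": 40,
        "n_generations": 15,
        "n_replicates": 2,
        "n_boot": 2_000,
    },
}

EXPERIMENTS = ("invariant", "evolution", "within-category", "objects", "psychophysics")


@dataclass(frozen=True)
class RunConfig:
    experiment: str
    seed: int = 0
    preset: str = "desk"
    extractor: str = "responder:categorical"  # or fg-mean-rgb | downsample | scratch
    outdir: str = "results"
    planted_borders: tuple = DEFAULT_PLANTED
    label_noise: float = 0.05
    overrides: tuple = ()  # ((key, value), ...) applied over the preset

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose from {EXPERIMENTS}")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    def params(self) -> dict:
        p = dict(PRESETS[self.preset])
        p.update(dict(self.overrides))
        return p

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["planted_borders"] = tuple(d.get("planted_borders", DEFAULT_PLANTED))
        d["overrides"] = tuple(tuple(kv) for kv in d.get("overrides", ()))
        return cls(**d)


def _resolve_extractor(cfg: RunConfig):
    """Extractor or responder named in the config."""
    spec = cfg.extractor
    planted = np.array(cfg.planted_borders)
    if spec == "responder:categorical":
        return _probes.ResponderModel("categorical", planted, cfg.label_noise)
    if spec == "responder:continuous":
        return _probes.ResponderModel("continuous", label_noise=cfg.label_noise)
    if spec == "fg-mean-rgb":
        return _probes.ForegroundMeanColor()
    if spec == "downsample":
        return _probes.DownsampleExtractor()
    if spec == "scratch":
        return _probes.make_scratch_category_backbone(planted, seed=cfg.seed)
    raise ValueError(f"unknown extractor spec {cfg.extractor!r}")


def _write_manifest(outdir: Path, cfg: RunConfig, artifacts: dict) -> None:
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_manifest(outdir) -> tuple:
    """Re-create the RunConfig (and artifact index) from a manifest."""
    manifest = json.loads((Path(outdir) / "manifest.json").read_text())
    return RunConfig.from_dict(manifest["config"]), manifest["artifacts"]


def _run_invariant(cfg: RunConfig, outdir: Path, log: list) -> dict:
    p = cfg.params()
    source = _resolve_extractor(cfg)
    grid = _probes.EvalGrid(100, p["samples_per_bin"])
    tc_cfg = _probes.TrainConfig(n_train_per_class=p["n_train_per_class"],
                                 n_val_per_class=p["n_val_per_class"], epochs=5)
    kwargs = {}
    if isinstance(source, _probes.ResponderModel):
        kwargs["responder"] = source
        extractor = None
    else:
        extractor = source
    rows = _probes.run_invariant_experiment(
        extractor, class_counts=p["class_counts"], n_shifts=p["n_shifts"],
        cfg=tc_cfg, grid=grid, seed=cfg.seed, **kwargs,
    )
    failed = sum(r is None for r in rows)
    if failed:
        log.append(f"excluded {failed} failed training rows")
    ok = [r for r in rows if r is not None]
    tc = _borders.accumulate_transition_counts(ok)
    est = _borders.detect_peaks(tc)
    protos = _borders.compute_prototypes(est, tc) if est.n_borders >= 2 else None
    pd.DataFrame({
        "edge_index": np.arange(tc.n_bins),
        "edge_hue": np.arange(tc.n_bins) / tc.n_bins,
        "raw": tc.raw,
        "smoothed": tc.smoothed,
    }).to_csv(outdir / "transition_count.csv", index=False)
    mode_rows = pd.DataFrame([r.mode_row for r in ok])
    mode_rows.insert(0, "n_classes", [r.meta.get("n_classes") for r in ok])
    mode_rows.insert(1, "shift", [r.meta.get("shift") for r in ok])
    mode_rows.to_csv(outdir / "mode_rows.csv", index=False)
    # full per-sample grids; indices align with the mode_rows CSV rows
    np.savez_compressed(outdir / "row_samples.npz",
                        **{f"row{idx}": r.samples for idx, r in enumerate(ok)})
    summary = {
        "n_rows": len(ok),
        "n_failed": failed,
        "borders": list(map(float, est.positions)),
    }
    if protos is not None:
        summary["prototypes"] = list(map(float, protos.prototype))
    (outdir / "borders.json").write_text(json.dumps(summary, indent=2))
    return {"transition_count": "transition_count.csv",
            "mode_rows": "mode_rows.csv", "row_samples": "row_samples.npz",
            "borders": "borders.json"}


def _run_evolution(cfg: RunConfig, outdir: Path, log: list) -> dict:
    p = cfg.params()
    planted = np.array(cfg.planted_borders)
    if cfg.extractor.startswith("responder"):
        fitness = _evolution.OracleFitness(planted)
    else:
        fitness = _evolution.ProbeFitness(_resolve_extractor(cfg), seed=cfg.seed)
    ecfg = _evolution.EvolutionConfig(
        pop_size=p["pop_size"],
        n_elite=max(1, p["pop_size"] // 10),
        n_generations=p["n_generations"],
        mutation_off_after=max(1, int(p["n_generations"] * 0.75)),
        n_replicates=p["n_replicates"],
    )
    pooled = []
    rows = []
    for rep in range(p["n_replicates"]):
        res = _evolution.run_evolution(fitness, ecfg, seed=cfg.seed * 1000 + rep)
        pooled.extend(res.top(ecfg.pop_size // 10))
        for rec in res.records:
            for member, (bs, fit) in enumerate(zip(rec.population, rec.fitness)):
                rows.append({"replicate": rep, "generation": rec.generation,
                             "member": member, "fitness": fit,
                             **{f"b{i}": v for i, v in enumerate(bs.positions)}})
    pd.DataFrame(rows).to_csv(outdir / "generations.csv", index=False)
    summ = _evolution.summarize_replicates(pooled)
    out = {
        "median": list(map(float, summ["median"])),
        "sd": list(map(float, summ["sd"])),
        "n_solutions": summ["n_solutions"],
    }
    (outdir / "evolution_summary.json").write_text(json.dumps(out, indent=2))
    return {"generations": "generations.csv", "summary": "evolution_summary.json"}


def _run_within_category(cfg: RunConfig, outdir: Path, log: list) -> dict:
    source = _resolve_extractor(cfg)
    p = cfg.params()
    reps = 3 if cfg.preset == "desk" else 15
    curve = _experiments.within_category_error_curve(
        source, np.array(cfg.planted_borders), n_repetitions=reps,
        samples_per_bin=p["samples_per_bin"], seed=cfg.seed,
    )
    frames = []
    for cls in range(curve.errors.shape[0]):
        frames.append(pd.DataFrame({
            "category": cls,
            "step_frac": curve.positions,
            "mean_error": curve.mean[cls],
            "sd": curve.sd[cls],
        }))
    pd.concat(frames).to_csv(outdir / "error_curve.csv", index=False)
    return {"error_curve": "error_curve.csv"}


def _run_objects(cfg: RunConfig, outdir: Path, log: list) -> dict:
    source = _resolve_extractor(cfg)
    if isinstance(source, _probes.ResponderModel):
        raise ValueError("the objects experiment needs a feature extractor")
    p = cfg.params()
    desk = cfg.preset == "desk"
    res = _experiments.object_color_experiment(
        source, np.array(cfg.planted_borders),
        n_permutations=3 if desk else 100,
        n_train_per_class=40 if desk else 500,
        n_val_per_class=10 if desk else 50,
        n_eval_outlines=8 if desk else 80,
        n_bins=25 if desk else 100,
        seed=cfg.seed,
    )
    med = res.median
    frames = []
    for cls in range(med.shape[0]):
        frames.append(pd.DataFrame({
            "band": cls,
            "band_center": res.bands[cls].center,
            "bin": np.arange(med.shape[1]),
            "median_accuracy": med[cls],
            "sd": res.sd[cls],
        }))
    pd.concat(frames).to_csv(outdir / "object_accuracy.csv", index=False)
    return {"object_accuracy": "object_accuracy.csv"}


def _run_psychophysics(cfg: RunConfig, outdir: Path, log: list) -> dict:
    p = cfg.params()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9A]))
    tables = [
        _experiments.simulate_observer(
            np.array(cfg.planted_borders), rng, lapse_rate=cfg.label_noise,
            border_jitter_sd=0.01, observer_id=f"sim{i}",
        )
        for i in range(10)
    ]
    for tb in tables:
        tb.to_frame().to_csv(outdir / f"observer_{tb.observer_id}.csv", index=False)
    tc, est, protos = _experiments.observer_transition_analysis(tables)
    boot = _experiments.bootstrap_correlation_test(tables, n_boot=p["n_boot"], rng=rng)
    out = {
        "transition_count": list(map(int, tc.raw)),
        "borders": list(map(float, est.positions)),
        "prototypes": list(map(float, protos.prototype)) if protos else None,
        "mean_pairwise_correlation": boot["statistic"],
        "bootstrap_p": boot["p_value"],
        "n_boot": boot["n_boot"],
    }
    (outdir / "psychophysics.json").write_text(json.dumps(out, indent=2))
    return {"psychophysics": "psychophysics.json"}


_RUNNERS = {
    "invariant": _run_invariant,
    "evolution": _run_evolution,
    "within-category": _run_within_category,
    "objects": _run_objects,
    "psychophysics": _run_psychophysics,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the named experiment and persist its artifact bundle.

    Returns the output directory containing the artifacts, a run log
    and a manifest with the config hash and seed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list = []
    artifacts = _RUNNERS[cfg.experiment](cfg, outdir, log)
    (outdir / "run.log").write_text("\n".join(log) + ("\n" if log else ""))
    _write_manifest(outdir, cfg, artifacts)
    return outdir
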