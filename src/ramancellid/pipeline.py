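"""End-to-end orchestration: config -> simulate (or load) -> condition ->
classify -> reports, with structured logging and a single fanned-out seed.

A run is fully described by a :class:`RunConfig` (parsed from YAML).  The
full analysis conditions every spectrum (despike, order-5 polynomial
baseline, Savitzky-Golay smoothing), crops to the fingerprint window,
splits off every fourth spectrum for validation, selects the PLS-DA
complexity by venetian-blinds cross-validation, and writes classification
reports at spectrum and/or cell level together with VIP scores and
provenance.  All randomness derives from one global seed fanned out into
named per-stage streams, so reruns are byte-identical.
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
import yaml

from . import __version__
from .chemometrics import (
    classification_report,
    fit_plsda,
    predict,
    select_n_lv,
    split_every_fourth,
    venetian_cv,
    vip_scores,
)
from .hyperspectral import (
    kmeans_manhattan,
    subtract_background_cluster,
    sum_filter,
)
from .preprocess import PLSDA_RECIPE, PreprocessRecipe, Step, apply_recipe
from .spectral_data import crop_axis, read_dataset, read_map, write_dataset
from .synthetic_data import (
    SimulationConfig,
    default_templates,
    simulate_dataset,
    simulate_map,
)

__all__ = ["ConfigError", "RunConfig", "run_full_analysis", "run_map_analysis"]

log = logging.getLogger("ramancellid")


class ConfigError(ValueError):
    pass


#: Per-spectrum conditioning applied before any multivariate analysis.
CONDITIONING_RECIPE = PreprocessRecipe(
    (
        Step("despike"),
        Step("baseline", {"order": 5}),
        Step("savgol", {"width": 11, "polyorder": 3}),
    )
)


def _stage_seed(seed: int, stage: int) -> int:
    """Independent per-stage integer seed derived from the global one."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated run configuration (see ``from_dict`` for the YAML schema)."""

    seed: int = 0
    output_dir: str = "ramancellid_out"
    level: str = "both"  # spectrum | cell | both
    simulate: dict | None = None
    input_paths: dict | None = None
    conditioning: PreprocessRecipe = CONDITIONING_RECIPE
    plsda_recipe: PreprocessRecipe = PLSDA_RECIPE
    crop: tuple[float, float] = (600.0, 1800.0)
    target_error: float = 0.05
    n_lv_max: int = 10
    n_splits: int = 10
    map_section: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        simulate = cfg.get("simulate")
        input_paths = cfg.get("input")
        if (simulate is None) == (input_paths is None):
            raise ConfigError("exactly one of 'simulate' and 'input' must be given")
        level = cfg.get("level", "both")
        if level not in ("spectrum", "cell", "both"):
            raise ConfigError(f"level must be spectrum/cell/both, got {level!r}")
        recipes = cfg.get("recipes", {})
        conditioning = (
            PreprocessRecipe.from_config(recipes["conditioning"])
            if "conditioning" in recipes
            else CONDITIONING_RECIPE
        )
        plsda_recipe = (
            PreprocessRecipe.from_config(recipes["plsda"])
            if "plsda" in recipes
            else PLSDA_RECIPE
        )
        sel = cfg.get("model_selection", {})
        return cls(
            seed=int(cfg.get("seed", 0)),
            output_dir=str(cfg.get("output_dir", "ramancellid_out")),
            level=level,
            simulate=simulate,
            input_paths=input_paths,
            conditioning=conditioning,
            plsda_recipe=plsda_recipe,
            crop=tuple(cfg.get("crop", (600.0, 1800.0))),
            target_error=float(sel.get("target_error", 0.05)),
            n_lv_max=int(sel.get("n_lv_max", 10)),
            n_splits=int(sel.get("n_splits", 10)),
            map_section=cfg.get("map", {}),
            raw=cfg,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if not isinstance(cfg, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(cfg)


def _provenance(cfg: RunConfig) -> dict:
    digest = hashlib.sha256(
        json.dumps(cfg.raw, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {
        "config_sha256": digest,
        "seed": cfg.seed,
        "ramancellid_version": __version__,
        "numpy_version": np.__version__,
    }


class _RunDir:
    """Tracks files written during a run so failures leave no partial bundle."""

    def __init__(self, out: Path):
        self.out = out
        self.out.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.out / name
        self.files.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.files:
            p.unlink(missing_ok=True)


def _load_or_simulate(cfg: RunConfig):
    if cfg.simulate is not None:
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        params = {k: v for k, v in cfg.simulate.items() if k in sim_fields}
        unknown = set(cfg.simulate) - sim_fields
        if unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
        params.setdefault("seed", _stage_seed(cfg.seed, 0))
        sim = SimulationConfig(**params)
        dataset, truth = simulate_dataset(sim)
        return dataset, truth
    d = read_dataset(cfg.input_paths["matrix"], cfg.input_paths["meta"])
    return d, None


def run_full_analysis(cfg: RunConfig) -> dict[str, str]:
    """Execute the full identification pipeline; returns artifact paths."""
    out = _RunDir(Path(cfg.output_dir))
    t0 = time.time()
    stage = "setup"
    try:
        stage = "simulate/load"
        dataset, truth = _load_or_simulate(cfg)
        log.info("stage=%s n_spectra=%d", stage, dataset.n_spectra)

        stage = "conditioning"
        conditioned = apply_recipe(dataset, cfg.conditioning)
        log.info("stage=%s steps=%s", stage, list(cfg.conditioning.names))

        stage = "crop"
        conditioned = crop_axis(conditioned, *cfg.crop)
        log.info("stage=%s window=%s n_points=%d", stage, cfg.crop, len(conditioned.axis))

        stage = "split"
        calibration, validation = split_every_fourth(conditioned)
        log.info(
            "stage=%s calibration=%d validation=%d",
            stage, calibration.n_spectra, validation.n_spectra,
        )

        stage = "venetian_cv"
        curves = venetian_cv(
            calibration, cfg.n_lv_max, cfg.n_splits, cfg.plsda_recipe
        )
        n_lv, met = select_n_lv(curves, cfg.target_error)
        log.info("stage=%s selected_n_lv=%d met_target=%s", stage, n_lv, met)

        stage = "fit_plsda"
        model = fit_plsda(calibration, n_lv, cfg.plsda_recipe)
        pmodel = out.path("model.json")
        pmodel.write_text(model.to_json())

        stage = "reports"
        levels = ["spectrum", "cell"] if cfg.level == "both" else [cfg.level]
        artifacts: dict[str, str] = {}
        for level in levels:
            rep = classification_report(model, calibration, validation, curves, level)
            p = out.path(f"report_{level}.csv")
            rep.per_class.to_csv(p)
            artifacts[f"report_{level}"] = str(p)
            pc = out.path(f"confusion_{level}.csv")
            rep.confusion_matrix.to_csv(pc)
            artifacts[f"confusion_{level}"] = str(pc)
            log.info(
                "stage=reports level=%s avg_sens=%.4f avg_spec=%.4f",
                level, rep.average_sensitivity, rep.average_specificity,
            )

        stage = "vip"
        vip = vip_scores(model)
        pv = out.path("vip.csv")
        np.savetxt(
            pv,
            np.column_stack([vip.axis.values, vip.vip]),
            delimiter=",",
            header="wavenumber_cm1,vip",
            comments="",
        )
        artifacts["vip"] = str(pv)

        stage = "curves"
        pcur = out.path("error_curves.csv")
        np.savetxt(
            pcur,
            np.column_stack(
                [curves.n_lv, curves.calibration_error, curves.cv_error]
            ),
            delimiter=",",
            header="n_lv,calibration_error,cv_error",
            comments="",
        )
        artifacts["error_curves"] = str(pcur)

        stage = "dataset"
        pd_, pm = out.path("dataset.csv"), out.path("dataset_meta.csv")
        write_dataset(dataset, pd_, pm)
        artifacts["dataset"] = str(pd_)

        stage = "provenance"
        prov = _provenance(cfg)
        prov["selected_n_lv"] = n_lv
        prov["met_target"] = bool(met)
        prov["runtime_s"] = round(time.time() - t0, 3)
        pp = out.path("provenance.json")
        pp.write_text(json.dumps(prov, indent=2, sort_keys=True))
        artifacts["provenance"] = str(pp)
        return artifacts
    except Exception as exc:
        out.cleanup()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def evaluate_identification(
    sim: SimulationConfig | None = None,
    n_lv_max: int = 10,
    n_splits: int = 10,
    target_error: float = 0.05,
    crop: tuple[float, float] = (600.0, 1800.0),
):
    """Run the identification study in memory and return its objects.

    Convenience used by scripted evaluations: simulate the default
    five-class line-scan study, condition the spectra, select the PLS-DA
    complexity by venetian-blinds CV, and report at both levels.

    Returns a dict with keys ``dataset``, ``truth``, ``curves``,
    ``n_lv``, ``met_target``, ``model``, ``report_spectrum``,
    ``report_cell``, ``vip``.
    """
    from .chemometrics import classification_report

    if sim is None:
        sim = SimulationConfig()
    dataset, truth = simulate_dataset(sim)
    conditioned = crop_axis(apply_recipe(dataset, CONDITIONING_RECIPE), *crop)
    calibration, validation = split_every_fourth(conditioned)
    curves = venetian_cv(calibration, n_lv_max, n_splits, PLSDA_RECIPE)
    n_lv, met = select_n_lv(curves, target_error)
    model = fit_plsda(calibration, n_lv, PLSDA_RECIPE)
    return {
        "dataset": dataset,
        "truth": truth,
        "curves": curves,
        "n_lv": n_lv,
        "met_target": met,
        "model": model,
        "report_spectrum": classification_report(
            model, calibration, validation, curves, "spectrum"
        ),
        "report_cell": classification_report(
            model, calibration, validation, curves, "cell"
        ),
        "vip": vip_scores(model),
    }


def run_map_analysis(cfg: RunConfig) -> dict[str, str]:
    """Area-scan analysis: sum filters, k-medians segmentation, cluster spectra."""
    out = _RunDir(Path(cfg.output_dir))
    section = cfg.map_section or {}
    stage = "setup"
    try:
        stage = "simulate/load map"
        if "matrix" in section:
            hmap = read_map(section["matrix"], section["meta"])
        else:
            sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
            params = {k: v for k, v in section.items() if k in sim_fields}
            params.setdefault("seed", _stage_seed(cfg.seed, 1))
            sim = SimulationConfig(**params)
            template = default_templates()[0]
            hmap, _ = simulate_map(
                template,
                tuple(section.get("grid_shape", (24, 24))),
                float(section.get("step_um", 0.5)),
                cfg=sim,
            )
        log.info("stage=%s pixels=%d", stage, hmap.n_pixels)

        artifacts: dict[str, str] = {}
        stage = "sum filters"
        for lo, hi in section.get("sum_filters", [(1420, 1460)]):
            img = sum_filter(hmap, lo, hi)
            p = out.path(f"sum_filter_{int(lo)}_{int(hi)}.csv")
            np.savetxt(p, img.image(), delimiter=",")
            artifacts[f"sum_filter_{int(lo)}_{int(hi)}"] = str(p)

        stage = "kmedians"
        k = int(section.get("k", 4))
        result = kmeans_manhattan(
            hmap, k, seed=_stage_seed(cfg.seed, 2),
            n_restarts=int(section.get("n_restarts", 10)),
        )
        p = out.path("cluster_labels.csv")
        np.savetxt(p, hmap.image(result.pixel_labels), delimiter=",", fmt="%d")
        artifacts["cluster_labels"] = str(p)
        p = out.path("cluster_spectra.csv")
        np.savetxt(
            p,
            np.vstack([hmap.axis.values, result.cluster_spectra]),
            delimiter=",",
        )
        artifacts["cluster_spectra"] = str(p)

        stage = "background subtraction"
        diffs = subtract_background_cluster(result, hmap, bg_label=1)
        p = out.path("cluster_spectra_bg_subtracted.csv")
        rows = [hmap.axis.values] + [diffs[j] for j in sorted(diffs)]
        np.savetxt(p, np.vstack(rows), delimiter=",")
        artifacts["cluster_spectra_bg_subtracted"] = str(p)
        return artifacts
    except Exception as exc:
        out.cleanup()
        raise RuntimeError(f"map analysis failed at stage {stage!r}: {exc}") from exc
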