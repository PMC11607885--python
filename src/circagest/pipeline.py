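"""End-to-end orchestration: simulate/ingest -> preprocess -> onset -> fit ->
peaks -> report, with a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import generate_cohort, inject_truth_log, read_cohort, write_cohort
from .model import ModelSpec, curves_to_report, fit_acclimation, fit_behaviour_model
from .onset import acclimation_threshold, onset_group_model, onsets_by_night, validate_acclimation
from .peaks import peak_table
from .preprocess import aggregate, filter_food_events, to_five_min
from .profiles import BEHAVIOURS, CohortConfig
from .samplers import FULL, REDUCED, TINY, SamplerSettings

logger = logging.getLogger(__name__)

PRESETS: Dict[str, SamplerSettings] = {"full": FULL, "reduced": REDUCED, "tiny": TINY}


@dataclass
class RunConfig:
    """Pipeline run configuration; the seed is mandatory."""

    seed: int
    outdir: Path
    input_csv: Optional[Path] = None       # None -> synthetic mode
    behaviours: Sequence[str] = BEHAVIOURS
    preset: str = "reduced"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    make_figures: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.outdir = Path(self.outdir)
        unknown = set(self.behaviours) - set(BEHAVIOURS)
        if unknown:
            raise ValueError(f"unknown behaviours: {sorted(unknown)}")
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {sorted(PRESETS)}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "input": str(self.input_csv),
                "behaviours": list(self.behaviours),
                "preset": self.preset,
                "cohort": str(self.cohort),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(cfg: RunConfig) -> Dict[str, object]:
    """Run the full analysis; writes all artefacts under ``cfg.outdir`` and
    returns them in memory as well.  Any stage failure raises with a
    stage-tagged message."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    t0 = time.time()
    artefacts: Dict[str, object] = {}

    def fail(stage, exc):
        raise RuntimeError(f"[stage:{stage}] {exc}") from exc

    # --- ingest / simulate -------------------------------------------------
    try:
        _stage("ingest")
        if cfg.input_csv is None:
            cohort_cfg = cfg.cohort
            if cohort_cfg.random_seed is None:
                cohort_cfg.random_seed = cfg.seed
            records = generate_cohort(cohort_cfg)
            write_cohort(records, out / "raw_records.csv")
            truth = inject_truth_log(cohort_cfg)
            truth.to_csv(out / "truth.csv", index=False)
            artefacts["truth"] = truth
        else:
            records = read_cohort(cfg.input_csv)
        missing = set(cfg.behaviours) - set(records["behaviour"].unique())
        if missing:
            raise ValueError(f"behaviours absent from input: {sorted(missing)}")
    except Exception as e:  # noqa: BLE001
        fail("ingest", e)

    # --- preprocess --------------------------------------------------------
    try:
        _stage("preprocess")
        n0 = len(records)
        records = filter_food_events(records)
        logger.info("records after food-event filter: %d (of %d)", len(records), n0)
        blocks = to_five_min(records)
        hourly = aggregate(records)
        hourly.to_csv(out / "hourly.csv", index=False)
        artefacts["hourly"] = hourly
    except Exception as e:  # noqa: BLE001
        fail("preprocess", e)

    # --- onset -------------------------------------------------------------
    try:
        _stage("onset")
        thresholds = acclimation_threshold(blocks)
        onsets = onsets_by_night(blocks, thresholds)
        onsets.to_csv(out / "onsets.csv", index=False)
        validation = validate_acclimation(onsets[onsets["phase"] == "acclimation"])
        om = onset_group_model(onsets)
        om.per_day.to_csv(out / "onset_effects.csv", index=False)
        artefacts.update(onsets=onsets, onset_model=om, onset_validation=validation)
    except Exception as e:  # noqa: BLE001
        fail("onset", e)

    # --- fit + peaks -------------------------------------------------------
    settings = PRESETS[cfg.preset]
    all_curves, all_peaks = {}, []
    for behaviour in cfg.behaviours:
        try:
            _stage(f"fit:{behaviour}")
            profiles = fit_acclimation(hourly, behaviour, settings=settings, seed=cfg.seed)
            spec = ModelSpec(behaviour, settings=settings, seed=cfg.seed)
            curves = fit_behaviour_model(hourly, profiles, spec)
            rep = curves_to_report(curves)
            rep.insert(0, "config_hash", chash)
            rep.to_csv(out / f"curves_{behaviour}.csv", index=False)
            all_curves[behaviour] = curves
        except Exception as e:  # noqa: BLE001
            fail(f"fit:{behaviour}", e)
        try:
            _stage(f"peaks:{behaviour}")
            pt = peak_table(curves, force=True)
            pt.insert(0, "config_hash", chash)
            pt.to_csv(out / f"peaks_{behaviour}.csv", index=False)
            all_peaks.append(pt)
        except Exception as e:  # noqa: BLE001
            fail(f"peaks:{behaviour}", e)
    artefacts["curves"] = all_curves
    if all_peaks:
        peaks = pd.concat(all_peaks, ignore_index=True)
        peaks.to_csv(out / "peak_tables.csv", index=False)
        artefacts["peaks"] = peaks

    # --- figures -----------------------------------------------------------
    if cfg.make_figures and all_curves:
        try:
            _stage("report")
            from .figures import behaviour_figure

            for behaviour, curves in all_curves.items():
                behaviour_figure(hourly, curves, out / f"fig_{behaviour}.png")
        except Exception as e:  # noqa: BLE001
            fail("report", e)

    manifest = {
        "package": "circagest",
        "version": __version__,
        "seed": cfg.seed,
        "preset": cfg.preset,
        "config_hash": chash,
        "behaviours": list(cfg.behaviours),
        "runtime_s": round(time.time() - t0, 1),
        "onset_validation": artefacts.get("onset_validation"),
        "rhat_max": {b: float(c.rhat_max) for b, c in all_curves.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    artefacts["manifest"] = manifest
    return artefacts
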