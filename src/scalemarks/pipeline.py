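"""End-to-end orchestration: simulate (or load) -> screen -> fit -> diagnose
-> summarize -> recover, with a run manifest recording seeds and versions.

The pipeline is a pure function of (config, seed): identical inputs produce
identical outputs, including the draws table. Mixed-species inputs are split
and fitted one model per species.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .design import build_design, extract_counts
from .diagnostics import diagnose
from .effects import effect_summary, interaction_surface, recovery_report
from .model import ModelConfig, draws_to_frame, fit_model
from .records import ScaleDataset, filter_readable, load_scale_table, split_by_species, write_scale_table
from .screening import kruskal_wallis, length_correlation, marks_by_locality, status_percentage_table
from .simulate import SimulationBundle, simulate_dataset, SyntheticTruth, truth_to_toml

log = logging.getLogger("scalemarks")


class PipelineConfigError(ValueError):
    """The pipeline configuration is inconsistent."""


@dataclass
class PipelineConfig:
    """Inputs, outputs and model settings for a full run.

    Exactly one of ``input_csv`` (observed data) or ``truth`` (synthetic mode)
    must be given.
    """

    out_dir: Path
    input_csv: Optional[Path] = None
    truth: Optional[SyntheticTruth] = None
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    per_scale_screen: bool = False
    full_draws: bool = False

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.truth is None):
            raise PipelineConfigError(
                "provide exactly one of input_csv (observed mode) or truth "
                "(synthetic mode)"
            )
        self.out_dir = Path(self.out_dir)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write its artifacts under ``config.out_dir``.

    Returns a report bundle (dict of in-memory stage results). On a stage
    failure the exception propagates; artifacts of completed stages remain on
    disk and the manifest records the failing stage.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "scalemarks_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "stages": [],
    }
    report: dict = {}

    def checkpoint(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        log.info("stage %s done: %s", stage, info)

    try:
        # --- data ------------------------------------------------------
        bundle: Optional[SimulationBundle] = None
        if config.truth is not None:
            bundle = simulate_dataset(config.truth, seed=config.seed)
            dataset = bundle.dataset
            write_scale_table(dataset, out / "dataset.csv")
            (out / "truth.toml").write_text(truth_to_toml(config.truth))
        else:
            dataset = load_scale_table(config.input_csv)
        checkpoint("data", records=len(dataset), specimens=len(dataset.specimen_ids))

        by_species = split_by_species(dataset)
        report["species"] = {}
        for species, ds in sorted(by_species.items()):
            rep: dict = {}
            tag = f"{species}"

            # --- screening ----------------------------------------------
            table = status_percentage_table(ds)
            table.to_frame().to_csv(out / f"{tag}_status_table.csv")
            readable = filter_readable(ds)
            values, groups = marks_by_locality(ds, per_scale=config.per_scale_screen)
            screen: dict = {"n_total": len(ds), "n_readable": len(readable)}
            if len(set(groups)) >= 2:
                kw = kruskal_wallis(values, groups)
                screen["kruskal_wallis"] = {
                    "H": kw.H,
                    "df": kw.df,
                    "p_value": kw.p_value,
                    "tie_correction": kw.tie_correction,
                }
            screen["length_correlation"] = length_correlation(ds)
            with open(out / f"{tag}_screen.json", "w") as fh:
                json.dump(screen, fh, indent=2)
            rep["screen"] = screen
            checkpoint(f"screen[{species}]", **{k: v for k, v in screen.items() if not isinstance(v, dict)})

            # --- model --------------------------------------------------
            design = build_design(readable, centre="auto")
            counts = extract_counts(readable)
            draws = fit_model(design, counts, config.model)
            draws_to_frame(draws, full=config.full_draws).to_csv(
                out / f"{tag}_draws.csv", index=False
            )
            rep["draws"] = draws
            checkpoint(
                f"fit[{species}]",
                rows=design.n_rows,
                individuals=design.n_individuals,
                attempts=draws.meta["attempts"],
            )

            # --- diagnostics ---------------------------------------------
            ppc_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
            )
            diag = diagnose(
                draws,
                design,
                counts,
                ess_threshold=config.model.ess_threshold,
                ppc_rng=ppc_rng,
            )
            with open(out / f"{tag}_diagnostics.json", "w") as fh:
                json.dump(diag.to_dict(), fh, indent=2, default=float)
            rep["diagnostics"] = diag
            checkpoint(f"diagnose[{species}]", converged=diag.converged, n_divergent=diag.n_divergent)

            # --- summaries -----------------------------------------------
            summary = effect_summary(draws)
            summary.to_frame().to_csv(out / f"{tag}_effects.csv", index=False)
            surface = interaction_surface(draws, sex="F")
            surface.to_frame().to_csv(out / f"{tag}_interaction.csv", index=False)
            rep["effects"] = summary
            rep["surface"] = surface
            checkpoint(f"summarize[{species}]")

            # --- recovery (synthetic mode) -------------------------------
            if bundle is not None and species == bundle.truth.species:
                rec = recovery_report(bundle.truth, summary)
                rec.to_frame().to_csv(out / f"{tag}_recovery.csv", index=False)
                rep["recovery"] = rec
                checkpoint(f"recover[{species}]", coverage=rec.coverage_fraction)

            report["species"][species] = rep

        report["manifest"] = manifest
        return report
    except Exception as exc:
        manifest["failed"] = repr(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
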