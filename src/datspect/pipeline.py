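"""End-to-end pipeline: cohort -> (volumes ->) panels -> SVM -> report.

Two modes: ``image`` renders phantom volumes and computes all six indices
per subject; ``tabular`` draws the panels directly from the calibrated
per-class distributions.  A run directory receives the panels CSV, the two
SVM model JSONs, the report CSV, the comparison JSON and a log; reruns with
the same config are bit-identical apart from float formatting.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import DEFAULT_C_GRID
from .evaluate import build_report, evaluate_svm_schemes
from .geometry import load_template
from .indices import FDConfig, IndexConfig, compute_panel
from .io import write_json, write_panels
from .panel import panels_to_frame
from .phantom import CohortSpec, make_striatal_phantom, sample_cohort, tabular_cohort
from .voi import build_fitted_vois, build_pentagonal_vois
from .volume import save_volume


@dataclass
class PipelineConfig:
    n_ps: int = 71
    n_nps: int = 40
    cohort_seed: int = 0
    split_seed: int = 0
    svm_seed: int = 0
    mode: str = "tabular"  # "tabular" | "image"
    template_path: str | None = None
    test_fraction: float = 0.25
    c_grid: tuple = DEFAULT_C_GRID
    k_folds: int = 10
    fd_threshold_fractions: tuple = (0.35, 0.40, 0.45, 0.50, 0.55)
    striatal_volume_ml: float = 11.2
    save_volumes: bool = False
    out_dir: str = "datspect_run"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in d.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = unknown
        if cfg.mode not in ("tabular", "image"):
            raise ValueError("mode must be 'tabular' or 'image'")
        return cfg


def run_pipeline(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    try:
        cohort = CohortSpec(n_ps=config.n_ps, n_nps=config.n_nps, seed=config.cohort_seed)
        if config.mode == "tabular":
            panels = tabular_cohort(cohort)
        else:
            panels = _image_route(cohort, config, out)
        write_panels(panels, out / "panels.csv")
        df = panels_to_frame(panels)

        svm_results = evaluate_svm_schemes(
            df,
            split_seed=config.split_seed,
            svm_seed=config.svm_seed,
            test_fraction=config.test_fraction,
            c_grid=config.c_grid,
            k_folds=config.k_folds,
        )
        for name, ev in svm_results.items():
            ev.model.save(out / f"model_{name}.json")

        report, meta = build_report(df, svm_results)
        report.to_csv(out / "report.csv", index=False, float_format="%.6g")
        write_json(meta, out / "comparisons.json")
        write_json(
            {
                "datspect_version": __version__,
                "python": sys.version.split()[0],
                "config": {k: v for k, v in vars(config).items() if k != "extra"},
                "split": {
                    "train_ids": svm_results["svm_q"].split.train_ids,
                    "test_ids": svm_results["svm_q"].split.test_ids,
                },
            },
            out / "log.json",
        )
        if marker.exists():
            marker.unlink()
        return out
    except Exception:
        marker.write_text("pipeline failed; see traceback on stderr\n")
        raise


def _image_route(cohort: CohortSpec, config: PipelineConfig, out: Path):
    template = load_template(config.template_path)
    fitted = build_fitted_vois(template)
    pentagonal = build_pentagonal_vois(template)
    index_config = IndexConfig(
        fd=FDConfig(threshold_fractions=tuple(config.fd_threshold_fractions)),
        striatal_volume_ml=config.striatal_volume_ml,
    )
    vol_dir = out / "volumes"
    if config.save_volumes:
        vol_dir.mkdir(exist_ok=True)
    panels = []
    counts = {"PS": 0, "NPS": 0}
    for spec, label in sample_cohort(cohort):
        counts[label] += 1
        subject_id = f"{label}{counts[label]:04d}"
        volume, _ = make_striatal_phantom(spec, template)
        if config.save_volumes:
            save_volume(volume, vol_dir / f"{subject_id}.nii.gz")
        panels.append(
            compute_panel(
                volume, fitted, pentagonal, index_config, subject_id=subject_id, label=label
            )
        )
    return panels


def report_from_panels(df: pd.DataFrame, config: PipelineConfig):
    """Evaluation only (panels already computed elsewhere)."""
    svm_results = evaluate_svm_schemes(
        df,
        split_seed=config.split_seed,
        svm_seed=config.svm_seed,
        test_fraction=config.test_fraction,
        c_grid=config.c_grid,
        k_folds=config.k_folds,
    )
    return build_report(df, svm_results)
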