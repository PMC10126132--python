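"""End-to-end orchestration: score wells, build the call matrix, optionally
test airway topography, then run the discrimination analyses, writing one
auditable JSON report plus per-stage outputs."""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .config import RunConfig
from .discrimination import lr_results_frame, resampled_roc_comparison, run_panel_lr
from .io import (
    read_cohort_csv,
    read_profiles_csv,
    read_reference_tm_csv,
    read_wells_csv,
    write_call_matrix_csv,
)
from .qpcr import MirCallMatrix, MissingReferenceTmError, build_call_matrix, call_sample
from .topography import permutation_test

logger = logging.getLogger(__name__)

__all__ = ["score_wells_file", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def score_wells_file(wells_path, ref_tm_path, config: RunConfig) -> MirCallMatrix:
    """Score a well export into a sample x panel call matrix."""
    wells = read_wells_csv(wells_path)
    ref_tm = read_reference_tm_csv(ref_tm_path)
    groups: dict[tuple[str, str], list] = defaultdict(list)
    for w in wells:
        if not w.is_positive_control:
            groups[(w.sample_id, w.mir_id)].append(w)
    calls = []
    for (sample, mir), grp in groups.items():
        if mir not in ref_tm:
            raise MissingReferenceTmError(mir)
        calls.append(call_sample(grp, ref_tm[mir], config.scoring))
    panel = [m for m in config.panel if any(c.mir_id == m for c in calls)] or list(config.panel)
    return build_call_matrix(calls, panel)


def run_pipeline(
    config: RunConfig,
    *,
    wells: str | None = None,
    ref_tm: str | None = None,
    profiles: str | None = None,
    tissue_pairs: Sequence[tuple[str, str]] = (("EBC", "BAL"), ("EBC", "MW")),
    cohort: str | None = None,
) -> dict:
    """Execute the staged analysis on whichever inputs are given.

    Stages: score -> call matrix (wells + ref_tm), topography permutation
    tests (profiles), logistic panel + random-forest comparison (cohort).
    Writes per-stage outputs and a MANIFEST/report into ``config.out_dir``;
    raises ``PipelineError`` labeled with the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_echo = config.to_dict()
    config_echo.pop("out_dir", None)  # analysis parameters only; paths are environment
    report: dict = {
        "mirpipe_version": __version__,
        "config": config_echo,
        "stages": {},
    }
    manifest: list[dict] = []

    def done(stage: str, files: list[str]) -> None:
        manifest.append({"stage": stage, "status": "complete", "files": files})
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    if wells is not None:
        try:
            matrix = score_wells_file(wells, ref_tm, config)
            write_call_matrix_csv(matrix, out / "calls.csv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("score", str(exc)) from exc
        report["stages"]["score"] = {
            "n_samples": len(matrix.samples),
            "n_mirs": len(matrix.mirs),
        }
        done("score", ["calls.csv"])

    if profiles is not None:
        try:
            pset = read_profiles_csv(profiles)
            topo_rows = []
            for a, b in tissue_pairs:
                res = permutation_test(
                    pset, a, b, n_permutations=config.n_permutations, seed=config.seed
                )
                topo_rows.append(
                    {
                        "tissue_a": a,
                        "tissue_b": b,
                        "observed_sh": res.observed_sh,
                        "p_value": res.p_value,
                        "n_permutations": res.n_permutations,
                        "exhaustive": res.exhaustive,
                        "seed": res.seed,
                    }
                )
            pd.DataFrame(topo_rows).to_csv(out / "topography.csv", index=False)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("topography", str(exc)) from exc
        report["stages"]["topography"] = topo_rows
        done("topography", ["topography.csv"])

    if cohort is not None:
        try:
            df = read_cohort_csv(cohort, panel=list(config.panel))
        except Exception as exc:
            raise PipelineError("cohort-parse", str(exc)) from exc
        try:
            lr = run_panel_lr(df, panel=list(config.panel))
            lr_results_frame(lr).to_csv(out / "lr_table.csv", index=False, na_rep="NA")
            comparison = resampled_roc_comparison(
                df,
                "clinical",
                "combined",
                n_splits=config.n_splits,
                seed=config.seed,
                panel=list(config.panel),
                n_trees=config.n_trees,
            )
            (out / "comparison.json").write_text(json.dumps(comparison.to_dict(), indent=2))
        except Exception as exc:
            raise PipelineError("discrimination", str(exc)) from exc
        report["stages"]["discrimination"] = {
            "n_subjects": int(len(df)),
            "lr_significant_adjusted": [
                r.mir_id for r in lr if r.p_adjusted is not None and r.p_adjusted < 0.05
            ],
            "mean_auc_clinical": comparison.mean_auc_a,
            "mean_auc_combined": comparison.mean_auc_b,
            "auc_difference_pct": comparison.auc_difference_pct,
            "welch_p": comparison.welch_p,
        }
        done("discrimination", ["lr_table.csv", "comparison.json"])

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
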