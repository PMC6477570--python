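"""End-to-end composition: simulate -> extract -> label -> cross-validate.

This is the plumbing the examples, CLI and acceptance checks share.  Every
stage is deterministic given the cohort seed, so two runs of ``run_study``
with identical arguments produce bit-identical reports.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import CvReport, ModelSpec, loso_cv
from .labeling import assign_labels
from .ppg_bvp import PpgConfig, extract_ppg
from .signals import MeasurementWindow
from .synthetic import CohortConfig, CohortWindow, generate_cohort
from .thermal_nose import extract_thermal

__all__ = ["ExtractedCohort", "process_window", "extract_cohort", "run_study"]


def process_window(cw: CohortWindow,
                   ppg_config: PpgConfig = PpgConfig()) -> MeasurementWindow:
    """Run both extraction pipelines on one window's raw inputs."""
    _, pp = extract_ppg(cw.frames, ppg_config)
    tv = extract_thermal(cw.thermal)
    return MeasurementWindow(cw.participant_id, cw.session_id, pp=pp, tv=tv,
                             vas=cw.vas,
                             meta={"latent_stress": cw.latent_stress,
                                   "true_label": cw.true_label})


@dataclass
class ExtractedCohort:
    """Windows after signal extraction, plus the session score table."""

    windows: list[MeasurementWindow]
    scores: pd.DataFrame


def extract_cohort(config: CohortConfig,
                   ppg_config: PpgConfig = PpgConfig()) -> ExtractedCohort:
    """Generate and extract a full synthetic cohort (streaming)."""
    windows = []
    rows = []
    for cw in generate_cohort(config):
        windows.append(process_window(cw, ppg_config))
        rows.append({"participant_id": cw.participant_id,
                     "session_id": cw.session_id, "vas": cw.vas})
    return ExtractedCohort(windows, pd.DataFrame(rows))


def label_windows(cohort: ExtractedCohort, strategy: str = "L1"
                  ) -> list[MeasurementWindow]:
    """Attach binary labels from the chosen strategy to the windows."""
    labels = assign_labels(cohort.scores, strategy)
    lookup = {(r.participant_id, r.session_id): r.label
              for r in labels.itertuples()}
    for w in cohort.windows:
        w.label = int(lookup[(w.participant_id, w.session_id)] == "Stress")
    return cohort.windows


def run_study(config: CohortConfig, model_spec: ModelSpec = ModelSpec(),
              modality: str = "multimodal", strategy: str = "L1",
              seed: int = 0, exclude_sessions: tuple[str, ...] = (),
              permute_labels: bool = False) -> CvReport:
    """Full study: simulate a cohort, extract, label, and run LOSO.

    ``permute_labels`` shuffles the binary labels across windows (with
    ``seed``) after labeling — the chance-level control.
    """
    cohort = extract_cohort(config)
    windows = label_windows(cohort, strategy)
    if permute_labels:
        rng = np.random.default_rng(seed)
        labels = [w.label for w in windows]
        for w, lab in zip(windows, rng.permutation(labels)):
            w.label = int(lab)
    return loso_cv(windows, model_spec, modality=modality, seed=seed,
                   exclude_sessions=exclude_sessions)
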