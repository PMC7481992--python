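"""Stage orchestration: from recordings to asymmetry profiles and statistics.

This module glues the stages together for both the CLI and scripts:

1. condition the EEG and regress out the EOG;
2. multitaper band power -> area power -> power-EEG AI;
3. Pearson connectomes (broadband "time-EEG" and fMRI) -> contralateral
   degree -> FC AI;
4. cohort statistics and the randomized-network null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .asymmetry import NO_BAND, WHOLE, AsymmetryProfile, fc_asymmetry, power_asymmetry
from .connectome import ConnectivityMatrix, contralateral_degree, pearson_fc
from .io import PipelineConfig
from .montage import AREAS
from .nulls import NullEnsemble, null_ensemble
from .spectral import (
    area_band_power,
    condition_eeg,
    multitaper_band_power,
    regress_out_eog,
)
from .stats import CohortStats, run_cohort_analysis
from .synthetic import SubjectRecording

__all__ = [
    "SubjectResult",
    "process_subject",
    "process_cohort",
    "analyze_cohort",
    "cohort_nulls",
    "recover_cross_modal_r",
]


@dataclass
class SubjectResult:
    """Per-subject intermediates and the final asymmetry profile."""

    profile: AsymmetryProfile
    eeg_fc: ConnectivityMatrix
    fmri_fc: ConnectivityMatrix
    band_power: pd.DataFrame  # tidy per-channel table
    area_power: pd.DataFrame


def process_subject(rec: SubjectRecording, config: Optional[PipelineConfig] = None) -> SubjectResult:
    """Run the full single-subject pipeline."""
    config = config or PipelineConfig()
    bands = config.band_definitions()

    eeg = condition_eeg(rec.eeg, rec.fs)
    eog = condition_eeg(rec.eog, rec.fs)
    eeg = regress_out_eog(eeg, eog)

    table = multitaper_band_power(
        eeg,
        fs=500.0,
        bands=bands,
        nw=config.multitaper_nw,
        n_tapers=config.multitaper_tapers,
    )
    area_power = area_band_power(table, rec.eeg_scheme)

    eeg_fc = pearson_fc(eeg, rec.eeg_scheme)
    fmri_fc = pearson_fc(rec.fmri, rec.mri_scheme)

    profile = AsymmetryProfile(subject_id=rec.subject_id)
    profile.update(power_asymmetry(area_power))
    profile.update(
        fc_asymmetry(contralateral_degree(eeg_fc, abs_edges=config.abs_edges), "FC-EEG")
    )
    profile.update(
        fc_asymmetry(contralateral_degree(fmri_fc, abs_edges=config.abs_edges), "FC-fMRI")
    )

    return SubjectResult(
        profile=profile,
        eeg_fc=eeg_fc,
        fmri_fc=fmri_fc,
        band_power=table.to_frame(rec.eeg_scheme.labels).assign(subject=rec.subject_id),
        area_power=area_power,
    )


def process_cohort(
    recordings: Sequence[SubjectRecording], config: Optional[PipelineConfig] = None
) -> list[SubjectResult]:
    config = config or PipelineConfig()
    return [process_subject(rec, config) for rec in recordings]


def analyze_cohort(
    results: Sequence[SubjectResult],
    groups: Optional[dict[str, str]] = None,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> CohortStats:
    config = config or PipelineConfig()
    profiles = [r.profile for r in results]
    groups = groups or {}
    return run_cohort_analysis(
        profiles,
        groups,
        n_perm=config.n_perm,
        seed=seed,
        include_fc_eeg=config.include_fc_eeg,
    )


def cohort_nulls(
    results: Sequence[SubjectResult],
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
    n_realizations: Optional[int] = None,
) -> NullEnsemble:
    config = config or PipelineConfig()
    return null_ensemble(
        fmri_fcs=[r.fmri_fc for r in results],
        eeg_fcs=[r.eeg_fc for r in results],
        power_profiles=[r.profile for r in results],
        n_realizations=n_realizations or config.null_realizations,
        seed=seed,
        swaps_per_edge=config.null_swaps_per_edge,
        mode=config.null_mode,
        sparsity=config.null_sparsity,
    )


def recover_cross_modal_r(
    profiles: Sequence[AsymmetryProfile], band: str = "alpha"
) -> float:
    """Cross-subject correlation between composite fMRI and EEG asymmetry.

    The fMRI side is each subject's FC-fMRI AI averaged over the five areas
    (whole-hemisphere FC AI is identically zero, see
    :mod:`hemiconn.asymmetry`); the EEG side is the whole-brain power AI of
    ``band``.  Averaging over areas pools the independent estimation noise of
    the area AIs, so this composite is the natural estimator of the latent
    cross-modal coupling.
    """
    x = np.array(
        [
            np.mean([p.entries[("FC-fMRI", NO_BAND, a)] for a in AREAS])
            for p in profiles
        ]
    )
    y = np.array([p.entries[("powerEEG", band, WHOLE)] for p in profiles])
    return float(sps.pearsonr(x, y).statistic)
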