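"""Synthetic multimodal cohorts with controllable hemispheric asymmetry.

The generator produces, per subject, band-structured EEG (band-limited
filtered-noise oscillations plus 1/f background and a low-frequency ocular
artifact mixed into frontal channels) and slow, correlated fMRI-like parcel
signals drawn from a latent-factor model.  A single subject-level latent
asymmetry couples the two modalities:

* ``a_i ~ Normal(0, latent_sd²)`` is the shared latent;
* the EEG asymmetry is driven by ``a_eeg = a_i`` and the fMRI asymmetry by
  ``a_fmri = r·a_i + sqrt(1-r²)·b_i`` with an independent ``b_i``, so the
  population correlation between the two induced asymmetries equals the
  requested ``cross_modal_r``.

EEG band amplitudes on right/left channels scale as ``1 ± gain·a/2``
(rightward power asymmetry for positive latents).  fMRI parcels load on a
global factor, an area factor (homotopic coupling) and a homologue-pair
factor; the global loading of *area-labeled* parcels is modulated by
``1 ± gain·a/2`` per hemisphere while the unlabeled (subcortical/insula)
parcels stay symmetric — that symmetry break is what shifts right vs. left
contralateral degree (a hemisphere-signed modulation of *every* node cancels
exactly in cross-hemisphere correlations, since each interhemispheric edge
joins one up- and one down-weighted node).

Everything is reproducible: subject ``i`` is generated from the deterministic
substream ``(seed, i)``, independent of cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .exceptions import ConfigError, DataError
from .montage import AREAS, NodeScheme, default_eeg_scheme, default_mri_scheme
from .spectral import DEFAULT_BANDS

__all__ = [
    "SimulationParams",
    "SubjectRecording",
    "simulate_subject",
    "simulate_cohort",
    "GROUP_SIZES",
    "gain_for",
]

#: Subgroup sizes of the cohort the generator emulates.
GROUP_SIZES: dict[str, int] = {"inattention": 19, "motion": 11, "mixed": 32}

GainKey = tuple[str, Optional[str], Optional[str]]  # (metric, band, area)

DEFAULT_BAND_AMP: dict[str, float] = {"delta": 1.0, "theta": 0.8, "alpha": 1.2, "beta": 0.5}

#: Default asymmetry injection: rightward alpha-power asymmetry in every
#: area, plus connectivity asymmetry of the fMRI connectome; FC-EEG neutral.
DEFAULT_ASYM_GAIN: dict[GainKey, float] = {
    ("powerEEG", "alpha", None): 0.3,
    ("FC-fMRI", None, None): 0.8,
}


def gain_for(
    gains: Mapping[GainKey, float], metric: str, band: Optional[str], area: Optional[str]
) -> float:
    """Resolve an asymmetry gain; ``None`` entries in keys act as wildcards."""
    for key in ((metric, band, area), (metric, band, None), (metric, None, area), (metric, None, None)):
        if key in gains:
            return float(gains[key])
    return 0.0


@dataclass
class SimulationParams:
    """Cohort-level generator settings.

    The defaults encode the study conditions the analysis assumes: 500 Hz
    EEG for five minutes, fMRI at TR 1.45 s (248 volumes ≈ 6 min), 19
    subjects (inattention-profile group size), alpha-dominant resting-state
    band amplitudes, and a cross-modal asymmetry correlation of 0.6.
    """

    n_subjects: int = GROUP_SIZES["inattention"]
    group: str = "inattention"
    eeg_fs: float = 500.0
    eeg_duration: float = 300.0
    fmri_tr: float = 1.45
    fmri_volumes: int = 248
    band_amp: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_AMP))
    asym_gain: dict[GainKey, float] = field(default_factory=lambda: dict(DEFAULT_ASYM_GAIN))
    latent_sd: float = 1.0
    noise_1f_exponent: float = 1.0
    noise_1f_scale: float = 0.4
    eeg_shared_mix: float = 0.5
    eog_amp: float = 1.5
    eog_gains: tuple[float, float] = (0.4, 0.25)
    fmri_global_loading: float = 0.6
    fmri_area_loading: float = 0.5
    fmri_pair_loading: float = 0.3
    fmri_noise_sd: float = 0.6
    cross_modal_r: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be positive")
        if self.eeg_fs <= 0 or self.eeg_duration <= 0 or self.fmri_tr <= 0:
            raise ConfigError("sampling rate, duration and TR must be positive")
        if self.fmri_volumes < 4:
            raise ConfigError("need at least 4 fMRI volumes")
        if abs(self.cross_modal_r) > 1:
            raise ConfigError(f"|cross_modal_r| must be <= 1, got {self.cross_modal_r}")
        if any(v < 0 for v in self.band_amp.values()):
            raise ConfigError("band amplitudes must be non-negative")
        if self.latent_sd < 0 or self.noise_1f_scale < 0 or self.fmri_noise_sd < 0:
            raise ConfigError("scale parameters must be non-negative")
        if not 0 <= self.eeg_shared_mix < 1:
            raise ConfigError("eeg_shared_mix must lie in [0, 1)")
        for v in (
            self.eeg_fs, self.eeg_duration, self.latent_sd, self.cross_modal_r,
            self.noise_1f_scale, self.noise_1f_exponent, *self.band_amp.values(),
            *self.asym_gain.values(),
        ):
            if not math.isfinite(v):
                raise ConfigError("simulation parameters must be finite")


@dataclass
class SubjectRecording:
    """One subject's raw synthetic data plus ground-truth latents."""

    subject_id: str
    group: str
    eeg: np.ndarray  # (channels, samples)
    eog: np.ndarray  # (2, samples)
    fmri: np.ndarray  # (parcels, volumes)
    eeg_scheme: NodeScheme
    mri_scheme: NodeScheme
    fs: float
    tr: float
    latent_asym: float
    latent_eeg: float = 0.0
    latent_fmri: float = 0.0

    def __post_init__(self) -> None:
        if self.eeg.shape[0] != len(self.eeg_scheme):
            raise DataError(
                f"{self.subject_id}: EEG has {self.eeg.shape[0]} rows, "
                f"scheme expects {len(self.eeg_scheme)}"
            )
        if self.fmri.shape[0] != len(self.mri_scheme):
            raise DataError(
                f"{self.subject_id}: fMRI has {self.fmri.shape[0]} rows, "
                f"scheme expects {len(self.mri_scheme)}"
            )
        if self.eog.shape[1] != self.eeg.shape[1]:
            raise DataError(f"{self.subject_id}: EOG/EEG sample counts differ")
        for name, arr in (("EEG", self.eeg), ("EOG", self.eog), ("fMRI", self.fmri)):
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{self.subject_id}: {name} contains non-finite values")


def _complex_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)


def _simulate_eeg(
    params: SimulationParams, scheme: NodeScheme, rng: np.random.Generator, a_eeg: float
) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(params.eeg_duration * params.eeg_fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / params.eeg_fs)
    nf = freqs.size
    n_ch = len(scheme)
    sign = np.where(scheme.hemisphere_mask("R"), 1.0, -1.0)
    area_idx = np.array([AREAS.index(node.area) for node in scheme.nodes])

    z_chan = _complex_noise(rng, (n_ch, nf))
    z_area = _complex_noise(rng, (len(AREAS), nf))
    z_back = _complex_noise(rng, (n_ch, nf))
    z_eog = _complex_noise(rng, (2, nf))

    m0 = params.eeg_shared_mix
    coef = np.zeros((n_ch, nf), dtype=complex)
    for band in DEFAULT_BANDS:
        amp0 = params.band_amp.get(band.name, 0.0)
        if amp0 == 0.0:
            continue
        mask = (freqs >= band.lo) & (freqs < band.hi)
        g_pow = np.array(
            [gain_for(params.asym_gain, "powerEEG", band.name, node.area) for node in scheme.nodes]
        )
        g_fc = np.array(
            [gain_for(params.asym_gain, "FC-EEG", band.name, node.area) for node in scheme.nodes]
        )
        amp = np.clip(amp0 * (1.0 + sign * g_pow * a_eeg / 2.0), 0.0, None)
        mix = np.clip(m0 * (1.0 + sign * g_fc * a_eeg / 2.0), 0.0, 0.99)
        shared = z_area[area_idx]
        band_coef = np.sqrt(1.0 - mix**2)[:, None] * z_chan + mix[:, None] * shared
        coef += mask[None, :] * amp[:, None] * band_coef

    if params.noise_1f_scale > 0:
        with np.errstate(divide="ignore"):
            slope = np.where(freqs > 0, freqs, np.inf) ** (-params.noise_1f_exponent / 2.0)
        coef += params.noise_1f_scale * slope[None, :] * z_back

    scale = np.sqrt(n)
    eeg = np.fft.irfft(coef, n=n, axis=1) * scale

    eog_mask = (freqs > 0) & (freqs < 4.0)
    eog = np.fft.irfft(params.eog_amp * eog_mask[None, :] * z_eog, n=n, axis=1) * scale
    frontal = scheme.area_mask("L", "frontal") | scheme.area_mask("R", "frontal")
    g1, g2 = params.eog_gains
    eeg[frontal] += g1 * eog[0] + g2 * eog[1]
    return eeg, eog


def _simulate_fmri(
    params: SimulationParams, scheme: NodeScheme, rng: np.random.Generator, a_fmri: float
) -> np.ndarray:
    t = params.fmri_volumes
    n_nodes = len(scheme)
    sign = np.where(scheme.hemisphere_mask("R"), 1.0, -1.0)

    global_f = rng.standard_normal(t)
    area_f = rng.standard_normal((len(AREAS), t))
    # one factor per homologue pair (shared by the two partners)
    pair_id: dict[frozenset[str], int] = {}
    pair_idx = np.empty(n_nodes, dtype=int)
    for i, node in enumerate(scheme.nodes):
        key = frozenset((node.label, node.homologue))
        pair_idx[i] = pair_id.setdefault(key, len(pair_id))
    pair_f = rng.standard_normal((len(pair_id), t))
    noise = rng.standard_normal((n_nodes, t))

    w0 = params.fmri_global_loading
    loading = np.full(n_nodes, w0)
    for i, node in enumerate(scheme.nodes):
        if node.area is not None:
            g = gain_for(params.asym_gain, "FC-fMRI", None, node.area)
            loading[i] = max(w0 * (1.0 + sign[i] * g * a_fmri / 2.0), 0.05 * w0)

    y = loading[:, None] * global_f[None, :]
    for i, node in enumerate(scheme.nodes):
        if node.area is not None:
            y[i] += params.fmri_area_loading * area_f[AREAS.index(node.area)]
    y += params.fmri_pair_loading * pair_f[pair_idx]
    y += params.fmri_noise_sd * noise
    return y


def simulate_subject(
    params: SimulationParams,
    subject_index: int,
    eeg_scheme: Optional[NodeScheme] = None,
    mri_scheme: Optional[NodeScheme] = None,
) -> SubjectRecording:
    """Generate one subject from the deterministic substream (seed, index)."""
    eeg_scheme = eeg_scheme or default_eeg_scheme()
    mri_scheme = mri_scheme or default_mri_scheme()
    rng = np.random.default_rng([params.seed, subject_index])

    a = rng.normal(0.0, params.latent_sd)
    b = rng.normal(0.0, params.latent_sd)
    r = params.cross_modal_r
    a_eeg = a
    a_fmri = r * a + math.sqrt(max(0.0, 1.0 - r * r)) * b

    eeg, eog = _simulate_eeg(params, eeg_scheme, rng, a_eeg)
    fmri = _simulate_fmri(params, mri_scheme, rng, a_fmri)
    return SubjectRecording(
        subject_id=f"sub-{subject_index:03d}",
        group=params.group,
        eeg=eeg,
        eog=eog,
        fmri=fmri,
        eeg_scheme=eeg_scheme,
        mri_scheme=mri_scheme,
        fs=params.eeg_fs,
        tr=params.fmri_tr,
        latent_asym=a,
        latent_eeg=a_eeg,
        latent_fmri=a_fmri,
    )


def simulate_cohort(
    params: SimulationParams,
    eeg_scheme: Optional[NodeScheme] = None,
    mri_scheme: Optional[NodeScheme] = None,
) -> list[SubjectRecording]:
    """Generate ``params.n_subjects`` recordings (reproducible from seed)."""
    eeg_scheme = eeg_scheme or default_eeg_scheme()
    mri_scheme = mri_scheme or default_mri_scheme()
    return [
        simulate_subject(params, i, eeg_scheme=eeg_scheme, mri_scheme=mri_scheme)
        for i in range(params.n_subjects)
    ]
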