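"""Hemispheric asymmetry index (AI) for connectome degree and band power.

The asymmetry index of a hemispheric quantity X is

    AI(X) = 100 * (|X(R)| - |X(L)|) / N

with N the number of nodes per hemisphere entering X.  AI is bounded in
[-100, 100]; positive values indicate rightward, negative values leftward
hemispheric dominance.

For connectome metrics, X is built from each node's *mean* contralateral
correlation (contralateral degree divided by the number of contralateral
nodes, hence in [-1, 1] per node); this normalization is what keeps AI inside
the printed ±100 range at every level.  Note that at whole-hemisphere level
the signed sums over left and right are identical by construction (every
interhemispheric edge contributes to both hemispheres), so whole-hemisphere
FC AI is exactly 0; the informative connectome asymmetry is the area-level
AI, where the source nodes are restricted to one area but the targets remain
all contralateral nodes.

For band power, X is the area-mean relative power (already in [0, 1]), used
with N = 1; the whole-brain power AI of a band is the unweighted mean of its
five area AIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .connectome import DegreeProfile
from .exceptions import ConfigError, DataError
from .montage import AREAS

__all__ = [
    "asymmetry_index",
    "fc_asymmetry",
    "power_asymmetry",
    "AsymmetryProfile",
    "METRICS",
    "WHOLE",
]

METRICS: tuple[str, ...] = ("FC-fMRI", "FC-EEG", "powerEEG")
NO_BAND = "none"
WHOLE = "whole"


def asymmetry_index(xr: float, xl: float, n: int) -> float:
    """AI(X) = 100 * (|X(R)| - |X(L)|) / N.

    Parameters
    ----------
    xr, xl
        Right- and left-hemisphere values of the metric.
    n
        Number of nodes per hemisphere entering X (must be >= 1).
    """
    if n < 1:
        raise ConfigError(f"N must be a positive integer, got {n}")
    return 100.0 * (abs(xr) - abs(xl)) / n


@dataclass
class AsymmetryProfile:
    """One subject's AI values keyed by (metric, band, area).

    ``band`` is ``"none"`` for the two connectome metrics; ``area`` is one of
    the five areas or ``"whole"``.
    """

    subject_id: str
    entries: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def update(self, other: Mapping[tuple[str, str, str], float]) -> "AsymmetryProfile":
        self.entries.update(other)
        return self

    def __getitem__(self, key: tuple[str, str, str]) -> float:
        return self.entries[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": self.subject_id, "metric": m, "band": b, "area": a, "ai": v}
            for (m, b, a), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, subject_id: str) -> "AsymmetryProfile":
        sub = frame[frame["subject"] == subject_id]
        entries = {
            (r.metric, r.band, r.area): float(r.ai) for r in sub.itertuples(index=False)
        }
        return cls(subject_id=subject_id, entries=entries)


def fc_asymmetry(
    profile: DegreeProfile,
    metric: str,
    level: str = "both",
) -> dict[tuple[str, str, str], float]:
    """Connectome AI at whole-hemisphere and/or area level.

    X is accumulated from per-node mean contralateral correlation
    (degree / n_contralateral).  Whole-hemisphere AI uses
    N = nodes-per-hemisphere; area AI restricts X to the area's source nodes
    and uses N = that area's per-hemisphere node count.  Areas without
    labeled nodes are skipped with a warning.
    """
    if metric not in ("FC-fMRI", "FC-EEG"):
        raise ConfigError(f"unknown FC metric {metric!r}")
    if level not in ("whole", "area", "both"):
        raise ConfigError(f"level must be whole, area or both, got {level!r}")
    scheme = profile.scheme
    xnorm = profile.degrees / profile.n_contralateral

    out: dict[tuple[str, str, str], float] = {}
    if level in ("whole", "both"):
        xr = float(xnorm[scheme.hemisphere_mask("R")].sum())
        xl = float(xnorm[scheme.hemisphere_mask("L")].sum())
        out[(metric, NO_BAND, WHOLE)] = asymmetry_index(xr, xl, scheme.n_per_hemisphere)
    if level in ("area", "both"):
        for area in AREAS:
            n_area = scheme.n_in_area(area)
            if n_area == 0:
                warnings.warn(
                    f"scheme {scheme.name!r}: no nodes labeled {area!r}; area AI skipped",
                    stacklevel=2,
                )
                continue
            xr = float(xnorm[scheme.area_mask("R", area)].sum())
            xl = float(xnorm[scheme.area_mask("L", area)].sum())
            out[(metric, NO_BAND, area)] = asymmetry_index(xr, xl, n_area)
    return out


def power_asymmetry(area_power: pd.DataFrame) -> dict[tuple[str, str, str], float]:
    """Band-power AI per band and area, plus the whole-brain mean per band.

    ``area_power`` is the output of :func:`hemiconn.spectral.area_band_power`:
    rows indexed by (hemisphere, area), one column per band, values being
    area-mean relative power in [0, 1].  Per cell,
    AI = 100 * (|P_R| - |P_L|) (N = 1, the quantity is already an area mean);
    the whole-brain AI of a band is the unweighted mean over the five areas.
    """
    values = area_power.to_numpy(dtype=float)
    if np.any(values < -1e-9) or np.any(values > 1 + 1e-9):
        raise DataError("relative power must lie in [0, 1]")
    out: dict[tuple[str, str, str], float] = {}
    areas = area_power.index.get_level_values("area").unique()
    for band in area_power.columns:
        area_ais = []
        for area in areas:
            p_r = float(area_power.loc[("R", area), band])
            p_l = float(area_power.loc[("L", area), band])
            ai = asymmetry_index(p_r, p_l, 1)
            out[("powerEEG", band, area)] = ai
            area_ais.append(ai)
        out[("powerEEG", band, WHOLE)] = float(np.mean(area_ais))
    return out
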