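"""Degree-preserving network randomization and null distributions of AI.

Correlation connectomes are fully dense, where classical Maslov–Sneppen
topological rewiring is a no-op (every double-edge swap recreates existing
edges).  The default randomization therefore permutes edge *weights* over the
fixed dense topology by repeated pairwise swaps of edge slots: every node's
edge count is trivially preserved and the off-diagonal weight multiset is
conserved exactly — the state weighted degree-preserving randomization of a
dense graph converges to.  An optional sparsify-then-rewire mode thresholds
the connectome (top fraction of |r|), performs classical weight-carrying
double-edge swaps on the surviving edges, and keeps per-node edge counts
exactly.

A :class:`NullEnsemble` rewires every subject's connectomes per realization,
recomputes asymmetry profiles and cross-modal correlations, and reports
empirical two-sided p-values with the (k+1)/(n+1) correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .asymmetry import NO_BAND, WHOLE, AsymmetryProfile, fc_asymmetry
from .connectome import ConnectivityMatrix, contralateral_degree
from .exceptions import RewireError
from .montage import AREAS

__all__ = ["maslov_rewire", "NullEnsemble", "null_ensemble", "empirical_p"]


def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def maslov_rewire(
    fc: ConnectivityMatrix,
    swaps_per_edge: int = 100,
    seed: int | np.random.Generator = 0,
    mode: str = "weight_permute",
    sparsity: float = 0.2,
) -> ConnectivityMatrix:
    """Randomize a connectome while preserving every node's degree.

    Parameters
    ----------
    fc
        Input connectome (>= 4 nodes).
    swaps_per_edge
        Accepted swaps performed per edge (default 100).
    seed
        Integer seed or a Generator.
    mode
        ``"weight_permute"`` (default, dense): swap weights between randomly
        chosen off-diagonal edge slots; topology untouched, degrees trivially
        preserved, weight multiset conserved.
        ``"sparsify"``: keep the top ``sparsity`` fraction of edges by |r|,
        then perform weight-carrying double-edge swaps (a,b),(c,d) ->
        (a,d),(c,b), rejecting self-loops and duplicate edges; per-node edge
        counts are preserved exactly and removed slots are set to 0.
    """
    n = fc.n_nodes
    if n < 4:
        raise RewireError(f"need at least 4 nodes to rewire, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if swaps_per_edge < 1:
        raise RewireError("swaps_per_edge must be a positive integer")

    if mode == "weight_permute":
        iu, ju = _triu_indices(n)
        weights = fc.weights[iu, ju].copy()
        n_edges = weights.size
        n_swaps = swaps_per_edge * n_edges
        pairs = rng.integers(0, n_edges, size=(n_swaps, 2))
        for a, b in pairs:
            weights[a], weights[b] = weights[b], weights[a]
        out = np.eye(n)
        out[iu, ju] = weights
        out[ju, iu] = weights
        return ConnectivityMatrix(out, fc.scheme)

    if mode != "sparsify":
        raise RewireError(f"unknown rewiring mode {mode!r}")

    iu, ju = _triu_indices(n)
    w = fc.weights[iu, ju]
    n_keep = max(int(round(sparsity * w.size)), 2)
    order = np.argsort(-np.abs(w), kind="stable")[:n_keep]
    edges = [(int(iu[k]), int(ju[k]), float(w[k])) for k in order]
    if len(edges) < 2:
        raise RewireError("too few edges after sparsification to swap")

    edge_set = {frozenset((a, b)) for a, b, _ in edges}
    n_target = swaps_per_edge * len(edges)
    accepted = 0
    attempts = 0
    max_attempts = 100 * n_target
    while accepted < n_target and attempts < max_attempts:
        attempts += 1
        k1, k2 = rng.integers(0, len(edges), size=2)
        if k1 == k2:
            continue
        a, b, w1 = edges[k1]
        c, d, w2 = edges[k2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,d) and (c,b)
        if len({a, b, c, d}) < 4:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[k1] = (a, d, w1)
        edges[k2] = (c, b, w2)
        accepted += 1

    out = np.eye(n)
    for a, b, wv in edges:
        out[a, b] = wv
        out[b, a] = wv
    return ConnectivityMatrix(out, fc.scheme)


def empirical_p(real: float, null_values: np.ndarray) -> float:
    """Two-sided empirical p-value with the (k+1)/(n+1) correction."""
    null_values = np.asarray(null_values, dtype=float)
    n = null_values.size
    center = float(np.median(null_values))
    k = int(np.sum(np.abs(null_values - center) >= abs(real - center)))
    return (k + 1) / (n + 1)


@dataclass
class NullEnsemble:
    """Null distributions of AI and cross-modal correlation under rewiring.

    Attributes
    ----------
    ai_summary
        One row per (metric, band, area): null mean/SD/quantiles of the
        cohort-mean AI and the empirical p of the real cohort-mean AI.
    corr_summary
        One row per cross-modal (band, area) cell: null mean/quantiles of the
        cross-subject correlation and the empirical p of the real r.
    ai_null
        ``(n_realizations, cells)`` cohort-mean AI per realization.
    corr_null
        ``(n_realizations, cells)`` cross-modal r per realization.
    """

    n_realizations: int
    ai_cells: list[tuple[str, str, str]]
    ai_null: np.ndarray
    ai_real: np.ndarray
    corr_cells: list[tuple[str, str]]
    corr_null: np.ndarray
    corr_real: np.ndarray

    @property
    def ai_summary(self) -> pd.DataFrame:
        rows = []
        for j, (metric, band, area) in enumerate(self.ai_cells):
            null = self.ai_null[:, j]
            rows.append(
                {
                    "metric": metric,
                    "band": band,
                    "area": area,
                    "real": self.ai_real[j],
                    "null_mean": null.mean(),
                    "null_sd": null.std(ddof=1) if null.size > 1 else 0.0,
                    "q025": np.quantile(null, 0.025),
                    "q975": np.quantile(null, 0.975),
                    "empirical_p": empirical_p(self.ai_real[j], null),
                }
            )
        return pd.DataFrame(rows)

    @property
    def corr_summary(self) -> pd.DataFrame:
        rows = []
        for j, (band, area) in enumerate(self.corr_cells):
            null = self.corr_null[:, j]
            rows.append(
                {
                    "metric_pair": "FC-fMRI~powerEEG",
                    "band": band,
                    "area": area,
                    "real_r": self.corr_real[j],
                    "null_mean": null.mean(),
                    "q025": np.quantile(null, 0.025),
                    "q975": np.quantile(null, 0.975),
                    "empirical_p": empirical_p(self.corr_real[j], null),
                }
            )
        return pd.DataFrame(rows)


def _cohort_mean_ai(
    profiles: Sequence[Mapping[tuple[str, str, str], float]],
    cells: Sequence[tuple[str, str, str]],
) -> np.ndarray:
    return np.array([np.mean([p[c] for p in profiles]) for c in cells])


def null_ensemble(
    fmri_fcs: Sequence[ConnectivityMatrix],
    eeg_fcs: Sequence[ConnectivityMatrix],
    power_profiles: Sequence[AsymmetryProfile],
    n_realizations: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
    mode: str = "weight_permute",
    sparsity: float = 0.2,
) -> NullEnsemble:
    """Build the randomized-network null for a cohort.

    Per realization, every subject's FC-fMRI and FC-EEG connectome is rewired
    with an independent substream; AI profiles are recomputed and, for each
    (band, area) cell, the cross-subject correlation between the *rewired*
    FC-fMRI area AI and the (fixed — band power has no network to rewire)
    power-EEG AI is recorded.  The real statistics are evaluated against the
    ensemble with two-sided empirical p-values.
    """
    n_subj = len(fmri_fcs)
    if not (n_subj == len(eeg_fcs) == len(power_profiles)):
        raise RewireError("fMRI, EEG and power inputs must cover the same subjects")

    mri_scheme = fmri_fcs[0].scheme
    fc_areas = [WHOLE] + mri_scheme.areas_present()
    eeg_areas = [WHOLE] + eeg_fcs[0].scheme.areas_present()
    ai_cells = [("FC-fMRI", NO_BAND, a) for a in fc_areas]
    ai_cells += [("FC-EEG", NO_BAND, a) for a in eeg_areas]

    bands = sorted({b for (_, b, _) in power_profiles[0].entries if b != NO_BAND})
    corr_areas = [a for a in AREAS if a in mri_scheme.areas_present()]
    corr_cells = [(b, a) for b in bands for a in corr_areas]

    def fc_profiles(fmri_list, eeg_list):
        out = []
        for fm, ee in zip(fmri_list, eeg_list):
            entries: dict[tuple[str, str, str], float] = {}
            entries.update(fc_asymmetry(contralateral_degree(fm), "FC-fMRI"))
            entries.update(fc_asymmetry(contralateral_degree(ee), "FC-EEG"))
            out.append(entries)
        return out

    def cross_modal_r(fc_entry_list):
        vals = []
        for band, area in corr_cells:
            x = np.array([e[("FC-fMRI", NO_BAND, area)] for e in fc_entry_list])
            y = np.array([p.entries[("powerEEG", band, area)] for p in power_profiles])
            if x.std() == 0 or y.std() == 0:
                vals.append(0.0)
            else:
                vals.append(float(sps.pearsonr(x, y).statistic))
        return np.array(vals)

    real_entries = fc_profiles(fmri_fcs, eeg_fcs)
    ai_real = _cohort_mean_ai(real_entries, ai_cells)
    corr_real = cross_modal_r(real_entries)

    ai_null = np.empty((n_realizations, len(ai_cells)))
    corr_null = np.empty((n_realizations, len(corr_cells)))
    for r in range(n_realizations):
        rng = np.random.default_rng([seed, r])
        fm_null = [
            maslov_rewire(fc, swaps_per_edge=swaps_per_edge, seed=rng, mode=mode, sparsity=sparsity)
            for fc in fmri_fcs
        ]
        ee_null = [
            maslov_rewire(fc, swaps_per_edge=swaps_per_edge, seed=rng, mode=mode, sparsity=sparsity)
            for fc in eeg_fcs
        ]
        entries = fc_profiles(fm_null, ee_null)
        ai_null[r] = _cohort_mean_ai(entries, ai_cells)
        corr_null[r] = cross_modal_r(entries)

    return NullEnsemble(
        n_realizations=n_realizations,
        ai_cells=ai_cells,
        ai_null=ai_null,
        ai_real=ai_real,
        corr_cells=corr_cells,
        corr_null=corr_null,
        corr_real=corr_real,
    )
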