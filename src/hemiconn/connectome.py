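"""Functional connectomes and contralateral degree of centrality.

The connectome of a modality is the node × node matrix of Pearson
correlations between regional (fMRI parcel) or channel (broadband "time-EEG")
time courses.  For each node the contralateral degree of centrality is the
sum of its connectivity strengths to every node of the opposite hemisphere;
hemisphere- and area-level summaries feed the asymmetry index.

Degree sums are signed by default (edge weights enter as Pearson r); taking
absolute values of edges first is available as a sensitivity variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .montage import AREAS, NodeScheme

__all__ = ["ConnectivityMatrix", "DegreeProfile", "pearson_fc", "contralateral_degree"]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson-correlation connectome over a node scheme."""

    weights: np.ndarray
    scheme: NodeScheme

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.scheme)
        if w.shape != (n, n):
            raise DataError(f"weights must be {n}×{n} for scheme {self.scheme.name!r}, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise DataError("connectivity matrix contains non-finite entries")
        if not np.allclose(w, w.T, atol=1e-10):
            raise DataError("connectivity matrix must be symmetric")
        if np.abs(w).max() > 1 + 1e-8:
            raise DataError("connectivity entries must lie in [-1, 1]")
        if not np.allclose(np.diag(w), 1.0, atol=1e-8):
            raise DataError("connectivity diagonal must equal 1")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.scheme)


def pearson_fc(series: np.ndarray, scheme: NodeScheme) -> ConnectivityMatrix:
    """Pairwise Pearson correlation connectome of node time courses.

    Parameters
    ----------
    series
        ``(nodes, timepoints)`` array, rows ordered as the scheme's nodes;
        at least 3 timepoints and nonzero variance per node.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] != len(scheme):
        raise DataError(
            f"series has {series.shape[0]} rows but scheme {scheme.name!r} "
            f"has {len(scheme)} nodes"
        )
    if series.shape[1] < 3:
        raise DataError(f"need at least 3 timepoints, got {series.shape[1]}")
    if not np.all(np.isfinite(series)):
        raise DataError("time series contain non-finite values")
    sd = series.std(axis=1)
    tol = 1e-12 * (1.0 + np.abs(series.mean(axis=1)))
    if np.any(sd <= tol):
        bad = scheme.labels[int(np.argmin(sd - tol))]
        raise DataError(f"zero-variance time course at node {bad!r}")
    w = np.corrcoef(series)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(w, scheme)


@dataclass
class DegreeProfile:
    """Per-node contralateral degree (signed sum of edge weights).

    ``degrees[i]`` is the sum of ``w[i, j]`` over all nodes j in the opposite
    hemisphere; hemisphere and area totals are sums of their nodes' degrees
    (area restriction applies to the source node only — targets are always
    all contralateral nodes).
    """

    degrees: np.ndarray
    scheme: NodeScheme

    def hemisphere_total(self, hemisphere: str) -> float:
        return float(self.degrees[self.scheme.hemisphere_mask(hemisphere)].sum())

    def area_total(self, hemisphere: str, area: str) -> float:
        return float(self.degrees[self.scheme.area_mask(hemisphere, area)].sum())

    @property
    def n_contralateral(self) -> int:
        """Number of contralateral target nodes (nodes per hemisphere)."""
        return self.scheme.n_per_hemisphere


def contralateral_degree(fc: ConnectivityMatrix, abs_edges: bool = False) -> DegreeProfile:
    """Contralateral degree of centrality for every node.

    Parameters
    ----------
    fc
        Connectome over a scheme with hemisphere labels.
    abs_edges
        If true, sum ``|r|`` instead of signed r (sensitivity variant; the
        default follows the asymmetry-index formula, which applies absolute
        values only at the hemisphere/area level).
    """
    w = np.abs(fc.weights) if abs_edges else fc.weights
    left = fc.scheme.hemisphere_mask("L")
    right = fc.scheme.hemisphere_mask("R")
    degrees = np.empty(len(fc.scheme))
    degrees[left] = w[np.ix_(left, right)].sum(axis=1)
    degrees[right] = w[np.ix_(right, left)].sum(axis=1)
    return DegreeProfile(degrees, fc.scheme)
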