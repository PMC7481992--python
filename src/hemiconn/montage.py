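"""Node schemes: EEG montages and MRI parcellations with hemisphere/area structure.

A :class:`NodeScheme` is the backbone of every downstream stage.  It lists the
nodes (EEG channels or MRI parcels) of both hemispheres, assigns each node to
one of five scalp/lobe areas (frontal, central, temporal, parietal,
occipital — or no area), and pairs every node with its contralateral
homologue.  Asymmetry indices only depend on this structure, never on label
strings.

Two built-in schemes are provided:

* a 30-channel EEG scheme (15 per hemisphere, 3 channels per area per
  hemisphere), with positional homologue pairing within each area;
* an 84-parcel MRI scheme (42 per hemisphere) based on the Desikan–Killiany
  cortical parcels plus subcortical structures; 33 cortical parcels per
  hemisphere carry an area label, the remaining 9 (insula + subcortical)
  carry no area and participate only in whole-hemisphere metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import SchemeError

__all__ = [
    "AREAS",
    "Node",
    "NodeScheme",
    "default_eeg_scheme",
    "default_mri_scheme",
    "load_scheme",
    "save_scheme",
    "EEG_DISPLAY_ALIASES",
]

#: Canonical area order used everywhere (tables, aggregation, AI profiles).
AREAS: tuple[str, ...] = ("frontal", "central", "temporal", "parietal", "occipital")

HEMISPHERES: tuple[str, str] = ("L", "R")


@dataclass(frozen=True)
class Node:
    """One EEG channel or MRI parcel."""

    label: str
    hemisphere: str  # "L" or "R"
    area: Optional[str]  # one of AREAS, or None (whole-hemisphere only)
    homologue: str  # label of the contralateral partner


class NodeScheme:
    """Ordered node set of both hemispheres with homologue pairing.

    Parameters
    ----------
    nodes
        Node records; order defines the row order of every data matrix.

    Raises
    ------
    SchemeError
        If hemispheres are unbalanced, labels collide, the homologue map is
        not a hemisphere-swapping involution, or homologues disagree on area.
    """

    def __init__(self, nodes: Sequence[Node], name: str = "custom") -> None:
        self.nodes: tuple[Node, ...] = tuple(nodes)
        self.name = name
        self._index = {n.label: i for i, n in enumerate(self.nodes)}
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        if len(self._index) != len(self.nodes):
            seen: set[str] = set()
            for n in self.nodes:
                if n.label in seen:
                    raise SchemeError(f"duplicate node label {n.label!r}")
                seen.add(n.label)
        n_l = sum(1 for n in self.nodes if n.hemisphere == "L")
        n_r = sum(1 for n in self.nodes if n.hemisphere == "R")
        if n_l != n_r or n_l == 0:
            raise SchemeError(
                f"hemispheres must hold equal, nonzero node counts (L={n_l}, R={n_r})"
            )
        for n in self.nodes:
            if n.hemisphere not in HEMISPHERES:
                raise SchemeError(f"node {n.label!r}: hemisphere must be L or R")
            if n.area is not None and n.area not in AREAS:
                raise SchemeError(f"node {n.label!r}: unknown area {n.area!r}")
            if n.homologue not in self._index:
                raise SchemeError(f"node {n.label!r}: homologue {n.homologue!r} not in scheme")
            mate = self.nodes[self._index[n.homologue]]
            if mate.hemisphere == n.hemisphere:
                raise SchemeError(
                    f"node {n.label!r}: homologue {mate.label!r} lies in the same hemisphere"
                )
            if mate.homologue != n.label:
                raise SchemeError(
                    f"node {n.label!r}: homologue map is not an involution via {mate.label!r}"
                )
            if mate.area != n.area:
                raise SchemeError(
                    f"node {n.label!r} (area {n.area}) paired with {mate.label!r} "
                    f"(area {mate.area}): homologues must share the area"
                )

    # -- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_per_hemisphere(self) -> int:
        """N in the asymmetry-index formula: nodes per hemisphere."""
        return len(self.nodes) // 2

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise SchemeError(f"unknown node label {label!r}") from None

    def area_of(self, label: str) -> Optional[str]:
        return self.nodes[self.index(label)].area

    def homologue(self, label: str) -> str:
        return self.nodes[self.index(label)].homologue

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        """Boolean mask over node order selecting one hemisphere."""
        if hemisphere not in HEMISPHERES:
            raise SchemeError(f"hemisphere must be L or R, got {hemisphere!r}")
        return np.array([n.hemisphere == hemisphere for n in self.nodes])

    def area_mask(self, hemisphere: str, area: str) -> np.ndarray:
        if area not in AREAS:
            raise SchemeError(f"unknown area {area!r}")
        return np.array(
            [n.hemisphere == hemisphere and n.area == area for n in self.nodes]
        )

    def areas_present(self) -> list[str]:
        """Labeled areas, in canonical order, that have at least one node."""
        present = {n.area for n in self.nodes if n.area is not None}
        return [a for a in AREAS if a in present]

    def nodes_in(self, hemisphere: str, area: Optional[str] = None) -> list[Node]:
        out = [n for n in self.nodes if n.hemisphere == hemisphere]
        if area is not None:
            out = [n for n in out if n.area == area]
        return out

    def n_in_area(self, area: str) -> int:
        """Labeled nodes per hemisphere in ``area`` (equal for L and R)."""
        return int(self.area_mask("L", area).sum())

    # -- serialization ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        save_scheme(self, path)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NodeScheme) and self.nodes == other.nodes

    def __repr__(self) -> str:
        return (
            f"NodeScheme({self.name!r}, {len(self)} nodes, "
            f"{self.n_per_hemisphere} per hemisphere)"
        )


# ---------------------------------------------------------------------------
# Built-in schemes
# ---------------------------------------------------------------------------

_AREA_CODE = {"frontal": "F", "central": "C", "temporal": "T", "parietal": "P", "occipital": "O"}

#: Display aliases mapping abstract channel labels to conventional 10-20 style
#: names (odd index = left, even index = right).  Cosmetic only: the analysis
#: depends exclusively on hemisphere/area structure.
EEG_DISPLAY_ALIASES: dict[str, str] = {
    "FL1": "F3", "FL2": "F7", "FL3": "F9", "FR1": "F4", "FR2": "F8", "FR3": "F6",
    "CL1": "C1", "CL2": "C3", "CL3": "C5", "CR1": "C2", "CR2": "C4", "CR3": "C6",
    "TL1": "T5", "TL2": "T9", "TL3": "T11", "TR1": "T6", "TR2": "T8", "TR3": "T10",
    "PL1": "P1", "PL2": "P3", "PL3": "P9", "PR1": "P2", "PR2": "P8", "PR3": "P10",
    "OL1": "O1", "OL2": "PO3", "OL3": "PO7", "OR1": "O2", "OR2": "PO4", "OR3": "PO8",
}


def default_eeg_scheme() -> NodeScheme:
    """30-channel EEG scheme: 15 per hemisphere, 3 per area per hemisphere.

    Homologues are paired positionally within each area (k-th left channel of
    an area with the k-th right channel of that area).
    """
    nodes: list[Node] = []
    for area in AREAS:
        code = _AREA_CODE[area]
        for hemi in HEMISPHERES:
            for k in (1, 2, 3):
                other = "R" if hemi == "L" else "L"
                nodes.append(
                    Node(
                        label=f"{code}{hemi}{k}",
                        hemisphere=hemi,
                        area=area,
                        homologue=f"{code}{other}{k}",
                    )
                )
    return NodeScheme(nodes, name="eeg30")


# Desikan-Killiany cortical parcels grouped into the five lobar areas
# (33 labeled per hemisphere).
_MRI_AREA_PARCELS: dict[str, tuple[str, ...]] = {
    "frontal": (
        "caudal-anterior-cingulate",
        "caudal-middle-frontal",
        "lateral-orbitofrontal",
        "medial-orbitofrontal",
        "pars-opercularis",
        "pars-orbitalis",
        "pars-triangularis",
        "rostral-anterior-cingulate",
        "rostral-middle-frontal",
        "superior-frontal",
        "frontal-pole",
    ),
    "central": ("paracentral", "postcentral", "precentral"),
    "temporal": (
        "bankssts",
        "entorhinal",
        "fusiform",
        "inferior-temporal",
        "middle-temporal",
        "parahippocampal",
        "superior-temporal",
        "temporal-pole",
        "transverse-temporal",
    ),
    "parietal": (
        "inferior-parietal",
        "isthmus-cingulate",
        "posterior-cingulate",
        "precuneus",
        "superior-parietal",
        "supramarginal",
    ),
    "occipital": ("cuneus", "lateral-occipital", "lingual", "pericalcarine"),
}

# Parcels completing the 42 per hemisphere; no area label (whole-hemisphere
# metrics only): insula plus subcortical structures.
_MRI_UNLABELED_PARCELS: tuple[str, ...] = (
    "insula",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
    "ventral-diencephalon",
)


def default_mri_scheme() -> NodeScheme:
    """84-parcel MRI scheme: 42 per hemisphere, 33 of them area-labeled.

    Labels are ``<parcel>-L`` / ``<parcel>-R``; homologues are the same parcel
    in the opposite hemisphere.
    """
    nodes: list[Node] = []

    def add(parcel: str, area: Optional[str]) -> None:
        for hemi in HEMISPHERES:
            other = "R" if hemi == "L" else "L"
            nodes.append(
                Node(
                    label=f"{parcel}-{hemi}",
                    hemisphere=hemi,
                    area=area,
                    homologue=f"{parcel}-{other}",
                )
            )

    for area in AREAS:
        for parcel in _MRI_AREA_PARCELS[area]:
            add(parcel, area)
    for parcel in _MRI_UNLABELED_PARCELS:
        add(parcel, None)
    return NodeScheme(nodes, name="mri84")


BUILTIN_SCHEMES = {"eeg30": default_eeg_scheme, "mri84": default_mri_scheme}


# ---------------------------------------------------------------------------
# Montage file I/O (TSV: label, hemisphere, area, homologue)
# ---------------------------------------------------------------------------

_HEADER = ("label", "hemisphere", "area", "homologue")


def save_scheme(scheme: NodeScheme, path: str | Path) -> None:
    """Write a scheme as the documented TSV montage format."""
    lines = ["\t".join(_HEADER)]
    for n in scheme.nodes:
        lines.append(
            "\t".join([n.label, n.hemisphere, n.area if n.area else "none", n.homologue])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_scheme(path: str | Path) -> NodeScheme:
    """Read and validate a montage TSV file.

    The file must carry a header row ``label hemisphere area homologue``
    (tab-separated); ``#`` starts a comment line; area ``none`` means no area
    label.  All :class:`NodeScheme` invariants are checked on load.
    """
    path = Path(path)
    nodes: list[Node] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if not header_seen:
            if tuple(f.lower() for f in fields) != _HEADER:
                raise SchemeError(
                    f"{path}:{lineno}: expected header {' '.join(_HEADER)!r}, got {raw!r}"
                )
            header_seen = True
            continue
        if len(fields) != 4:
            raise SchemeError(f"{path}:{lineno}: expected 4 tab-separated fields, got {raw!r}")
        label, hemi, area, homologue = fields
        nodes.append(
            Node(
                label=label,
                hemisphere=hemi,
                area=None if area.lower() in ("none", "") else area,
                homologue=homologue,
            )
        )
    if not header_seen:
        raise SchemeError(f"{path}: empty montage file (no header)")
    return NodeScheme(nodes, name=path.stem)
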