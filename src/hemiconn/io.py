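"""File formats, configuration and provenance.

Subject layout (one directory per subject)::

    <subject_id>/
        eeg.tsv    channels × samples, channel label in the first column
        eog.tsv    2 × samples
        fmri.tsv   parcels × volumes, parcel label in the first column
        meta.json  {"subject_id", "fs_hz", "tr_s", "group", "latent_asym"}

Cohort manifest: JSON listing subject ids, group labels, seed and the
ground-truth latent asymmetries.  Result tables are CSV with provenance
comment lines (``#``) carrying the package version, config hash and seed —
deliberately no timestamp, so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError, DataError
from .montage import BUILTIN_SCHEMES, NodeScheme, load_scheme
from .spectral import DEFAULT_BANDS, BandDefinition
from .synthetic import SimulationParams, SubjectRecording

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_subject",
    "write_subject",
    "write_manifest",
    "read_manifest",
    "write_table",
    "read_table",
]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs besides the seed.

    ``eeg_scheme``/``mri_scheme`` name a builtin scheme (``eeg30``,
    ``mri84``) or point at a montage TSV file.  ``simulation`` holds keyword
    overrides for :class:`hemiconn.synthetic.SimulationParams`.
    """

    eeg_scheme: str = "eeg30"
    mri_scheme: str = "mri84"
    bands: list[dict[str, Any]] = field(
        default_factory=lambda: [
            {"name": b.name, "lo": b.lo, "hi": b.hi} for b in DEFAULT_BANDS
        ]
    )
    multitaper_nw: float = 4.0
    multitaper_tapers: int = 7
    abs_edges: bool = False
    null_mode: str = "weight_permute"
    null_swaps_per_edge: int = 10
    null_realizations: int = 100
    null_sparsity: float = 0.2
    n_perm: int = 1000
    include_fc_eeg: bool = False
    simulation: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(BandDefinition(b["name"], float(b["lo"]), float(b["hi"])) for b in self.bands)

    def resolve_scheme(self, which: str) -> NodeScheme:
        name = getattr(self, f"{which}_scheme")
        if name in BUILTIN_SCHEMES:
            return BUILTIN_SCHEMES[name]()
        path = Path(name)
        if not path.exists():
            raise ConfigError(f"{which}_scheme {name!r} is neither builtin nor an existing file")
        return load_scheme(path)

    def simulation_params(self, seed: Optional[int] = None) -> SimulationParams:
        kwargs = dict(self.simulation)
        if "asym_gain" in kwargs:
            kwargs["asym_gain"] = {
                _parse_gain_key(k): float(v) for k, v in kwargs["asym_gain"].items()
            }
        kwargs.setdefault("seed", self.seed)
        if seed is not None:
            kwargs["seed"] = seed
        try:
            return SimulationParams(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"invalid simulation settings: {exc}") from exc

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if "asym_gain" in d.get("simulation", {}):
            d["simulation"] = dict(d["simulation"])
            d["simulation"]["asym_gain"] = {
                "|".join("*" if p is None else str(p) for p in k) if isinstance(k, tuple) else k: v
                for k, v in d["simulation"]["asym_gain"].items()
            }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _parse_gain_key(key: str | tuple) -> tuple[str, Optional[str], Optional[str]]:
    if isinstance(key, tuple):
        return key  # already parsed
    parts = [p.strip() for p in str(key).split("|")]
    if len(parts) != 3:
        raise ConfigError(
            f"asym_gain key must be 'metric|band|area' ('*' as wildcard), got {key!r}"
        )
    metric, band, area = parts
    return (metric, None if band == "*" else band, None if area == "*" else area)


def load_config(path: Optional[str | Path] = None, **overrides: Any) -> PipelineConfig:
    """Load a YAML config file (all keys optional) and apply overrides."""
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# Subject and manifest I/O
# ---------------------------------------------------------------------------


def _write_matrix_tsv(path: Path, labels: list[str], data: np.ndarray) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for label, row in zip(labels, data):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _read_matrix_tsv(path: Path) -> tuple[list[str], np.ndarray]:
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        labels.append(parts[0])
        try:
            rows.append(np.array(parts[1:], dtype=float))
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: non-numeric sample ({exc})") from exc
    if not rows:
        raise DataError(f"{path}: empty matrix file")
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise DataError(f"{path}: ragged rows (lengths {sorted(lengths)})")
    return labels, np.vstack(rows)


def write_subject(dirpath: str | Path, rec: SubjectRecording) -> Path:
    """Persist one subject under ``dirpath/<subject_id>/``."""
    out = Path(dirpath) / rec.subject_id
    out.mkdir(parents=True, exist_ok=True)
    _write_matrix_tsv(out / "eeg.tsv", rec.eeg_scheme.labels, rec.eeg)
    _write_matrix_tsv(out / "eog.tsv", ["EOG1", "EOG2"], rec.eog)
    _write_matrix_tsv(out / "fmri.tsv", rec.mri_scheme.labels, rec.fmri)
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs_hz": rec.fs,
        "tr_s": rec.tr,
        "latent_asym": rec.latent_asym,
        "latent_eeg": rec.latent_eeg,
        "latent_fmri": rec.latent_fmri,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8")
    return out


def read_subject(
    dirpath: str | Path, eeg_scheme: NodeScheme, mri_scheme: NodeScheme
) -> SubjectRecording:
    """Load and validate one subject directory."""
    d = Path(dirpath)
    for fname in ("eeg.tsv", "eog.tsv", "fmri.tsv", "meta.json"):
        if not (d / fname).exists():
            raise DataError(f"{d}: missing {fname}")
    meta = json.loads((d / "meta.json").read_text(encoding="utf-8"))
    for key in ("fs_hz", "tr_s"):
        if key not in meta:
            raise DataError(f"{d}/meta.json: missing required key {key!r}")
    eeg_labels, eeg = _read_matrix_tsv(d / "eeg.tsv")
    _, eog = _read_matrix_tsv(d / "eog.tsv")
    fmri_labels, fmri = _read_matrix_tsv(d / "fmri.tsv")
    if eeg_labels != eeg_scheme.labels:
        raise DataError(
            f"{d}/eeg.tsv: channel labels do not match scheme {eeg_scheme.name!r} "
            f"({len(eeg_labels)} rows vs {len(eeg_scheme)} nodes)"
        )
    if fmri_labels != mri_scheme.labels:
        raise DataError(
            f"{d}/fmri.tsv: parcel labels do not match scheme {mri_scheme.name!r} "
            f"({len(fmri_labels)} rows vs {len(mri_scheme)} nodes)"
        )
    return SubjectRecording(
        subject_id=str(meta.get("subject_id", d.name)),
        group=str(meta.get("group", "unknown")),
        eeg=eeg,
        eog=eog,
        fmri=fmri,
        eeg_scheme=eeg_scheme,
        mri_scheme=mri_scheme,
        fs=float(meta["fs_hz"]),
        tr=float(meta["tr_s"]),
        latent_asym=float(meta.get("latent_asym", 0.0)),
        latent_eeg=float(meta.get("latent_eeg", 0.0)),
        latent_fmri=float(meta.get("latent_fmri", 0.0)),
    )


def write_manifest(path: str | Path, recordings, config: PipelineConfig, seed: int) -> None:
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": seed,
        "subjects": [
            {"subject_id": r.subject_id, "group": r.group, "latent_asym": r.latent_asym}
            for r in recordings
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")


def read_manifest(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Result tables with provenance headers
# ---------------------------------------------------------------------------


def provenance_header(config: PipelineConfig, seed: int) -> str:
    return (
        f"# hemiconn={__version__}\n"
        f"# config_hash={config.config_hash()}\n"
        f"# seed={seed}\n"
    )


def write_table(df: pd.DataFrame, path: str | Path, config: PipelineConfig, seed: int) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
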