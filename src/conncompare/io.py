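"""Core data model and file I/O for connectome analysis.

Connectomes are square, symmetric, nonnegative weighted adjacency matrices
over a fixed, ordered set of brain regions. Matrices travel as plain
delimited text (comma or tab, no header) with region labels in a sidecar
file (one label per line); cohorts are described by a YAML manifest mapping
subject ids to group labels and per-modality matrix files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("conncompare")

#: symmetry tolerance for validated Connectome matrices
SYMMETRY_TOL = 1e-10
#: asymmetry beyond this on file read is an error, below it we average
READ_ASYMMETRY_TOL = 1e-8

MODALITIES = ("functional", "structural")


class ValidationError(ValueError):
    """Raised when an input violates the data-model invariants."""


def _default_labels(n: int) -> list[str]:
    return [f"region{i:02d}" for i in range(n)]


@dataclass
class Connectome:
    """A weighted, undirected brain network.

    Parameters
    ----------
    matrix
        N x N real matrix; symmetric (tol 1e-10), zero diagonal, entries >= 0.
    labels
        Ordered region names, length N. Region order is identity: it is
        never sorted and must align across subjects.
    modality
        ``"functional"`` or ``"structural"``.
    weighted
        False if the matrix is binary (entries in {0, 1}).
    """

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)
    modality: str = "structural"
    weighted: bool = True
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(f"matrix must be square, got shape {m.shape}")
        if not self.labels:
            self.labels = _default_labels(m.shape[0])
        if len(self.labels) != m.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for {m.shape[0]} nodes"
            )
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if np.isnan(m).any():
            raise ValidationError("matrix contains non-numeric (NaN) entries")
        if (m < 0).any():
            raise ValidationError("matrix contains negative entries")
        if np.abs(m - m.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValidationError("matrix is not symmetric within 1e-10")
        if np.abs(np.diag(m)).max(initial=0.0) != 0.0:
            raise ValidationError("diagonal must be exactly zero")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of nonzero upper-triangle entries (present edges E)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.matrix[iu]))

    @property
    def density(self) -> float:
        """Fraction of present edges, D = E / (N(N-1)/2)."""
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def copy(self) -> "Connectome":
        return Connectome(
            self.matrix.copy(), list(self.labels), self.modality,
            self.weighted, self.subject_id,
        )


@dataclass
class MetricCurve:
    """A graph metric sampled on an ordered density grid for one subject."""

    metric: str
    grid: np.ndarray
    values: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ValidationError("density grid must be strictly increasing")
        if self.grid[0] <= 0 or self.grid[-1] > 1:
            raise ValidationError("density grid must lie in (0, 1]")
        if self.values.shape != self.grid.shape:
            raise ValidationError("values must align 1:1 with the grid")


@dataclass(frozen=True)
class DensityWindow:
    """A closed density interval [d_lo, d_hi] used for AUC integration."""

    d_lo: float
    d_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.d_lo < self.d_hi <= 1):
            raise ValidationError(
                f"require 0 < d_lo < d_hi <= 1, got [{self.d_lo}, {self.d_hi}]"
            )


@dataclass
class SubjectRecord:
    id: str
    group: str
    paths: dict[str, Path] = field(default_factory=dict)


@dataclass
class CohortManifest:
    """Subjects of a two-group cohort and where their matrices live."""

    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        if len(self.groups) != 2:
            raise ValidationError(
                f"manifest must define exactly two groups, got {self.groups}"
            )

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    @property
    def group_sizes(self) -> dict[str, int]:
        return {g: sum(1 for s in self.subjects if s.group == g)
                for g in self.groups}

    def subjects_in(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]


def read_matrix(
    path: str | Path,
    labels_path: str | Path | None = None,
    modality: str = "structural",
    weighted: bool = True,
    subject_id: str | None = None,
) -> Connectome:
    """Read a delimited N x N matrix (comma or whitespace, no header).

    Mild asymmetry (max |A - A.T| <= 1e-8, e.g. from printed precision) is
    repaired by averaging; anything larger — typically a transposed or
    truncated file — is an error.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        m = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric entry ({exc})") from exc
    if m.shape[0] != m.shape[1]:
        raise ValidationError(f"{path}: non-square matrix {m.shape}")
    if np.isnan(m).any():
        raise ValidationError(f"{path}: non-numeric entry (NaN)")
    asym = np.abs(m - m.T).max(initial=0.0)
    if asym > READ_ASYMMETRY_TOL:
        raise ValidationError(
            f"{path}: matrix asymmetric (max |A - A.T| = {asym:.3g} > "
            f"{READ_ASYMMETRY_TOL:g}); refusing to symmetrize"
        )
    if asym > 0:
        m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    labels: list[str] = []
    if labels_path is not None:
        labels = [ln.strip() for ln in Path(labels_path).read_text().splitlines()
                  if ln.strip()]
        if len(labels) != m.shape[0]:
            raise ValidationError(
                f"{labels_path}: {len(labels)} labels for {m.shape[0]} nodes"
            )
    return Connectome(m, labels, modality, weighted, subject_id)


def write_matrix(conn: Connectome, path: str | Path,
                 labels_path: str | Path | None = None) -> None:
    """Write a connectome as comma-delimited text (full round-trip precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, conn.matrix, delimiter=",", fmt="%.17g")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(conn.labels) + "\n")


def load_manifest(path: str | Path, check_files: bool = True) -> CohortManifest:
    """Load a YAML cohort manifest.

    Expected layout::

        subjects:
          - id: NTG1
            group: NTG
            functional: func/NTG1.csv
            structural: struct/NTG1.csv

    Relative paths are resolved against the manifest's directory. Missing
    files are reported (logged; error when ``check_files``).
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "subjects" not in doc:
        raise ValidationError(f"{path}: manifest must contain a 'subjects' list")
    records = []
    for entry in doc["subjects"]:
        paths = {
            m: (path.parent / entry[m]).resolve()
            for m in MODALITIES if m in entry
        }
        records.append(SubjectRecord(str(entry["id"]), str(entry["group"]), paths))
    manifest = CohortManifest(records)
    missing = [
        f"{s.id}:{m}" for s in manifest.subjects
        for m, p in s.paths.items() if not p.exists()
    ]
    if missing:
        msg = f"{path}: missing matrix files for {missing}"
        if check_files:
            raise ValidationError(msg)
        logger.warning(msg)
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    doc = {"subjects": [
        {"id": s.id, "group": s.group,
         **{m: str(Path(p).relative_to(path.parent) if Path(p).is_relative_to(path.parent) else p)
            for m, p in s.paths.items()}}
        for s in manifest.subjects
    ]}
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def density_grid(d_min: float, d_max: float, step: float = 0.01) -> np.ndarray:
    """Ordered density grid from d_min to d_max inclusive (rounded to step)."""
    n = int(round((d_max - d_min) / step))
    grid = d_min + step * np.arange(n + 1)
    return np.round(grid, 10)
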