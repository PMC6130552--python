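"""Construct functional and structural connectomes from raw tables.

Functional edges are Fisher r-to-z transformed Pearson correlations between
regional time series, with negative edges zeroed (negative-correlation
networks behave differently from positive ones and are excluded here).
Structural edges are mean streamline fractional anisotropy (FA), kept only
where at least ``min_streamlines`` tractography streamlines connect the
region pair, then scaled to (0, 1] by the maximum weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Connectome, ValidationError, _default_labels

logger = logging.getLogger("conncompare")

#: |r| is clipped here before atanh so duplicated signals stay finite
FISHER_R_CAP = 1.0 - 1e-7


@dataclass
class TimeSeriesMatrix:
    """Regional BOLD-like signals: N regions x T timepoints."""

    data: np.ndarray
    subject_id: str | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time series must be a 2-D regions x time array")
        if self.data.shape[1] < 3:
            raise ValidationError("need at least 3 timepoints per region")
        if np.isnan(self.data).any():
            raise ValidationError("time series contain NaN")
        if self.labels is None:
            self.labels = _default_labels(self.data.shape[0])
        zero = np.where(np.all(self.data == 0, axis=1))[0]
        if zero.size:
            logger.warning("constant-zero region rows: %s", zero.tolist())


@dataclass
class StreamlineTable:
    """Pairwise streamline counts and mean FA from deterministic tractography."""

    counts: np.ndarray
    mean_fa: np.ndarray
    subject_id: str | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mean_fa = np.asarray(self.mean_fa, dtype=float)
        c, f = self.counts, self.mean_fa
        if c.shape != f.shape or c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValidationError("counts and mean_fa must be matching square matrices")
        if (c < 0).any() or not np.array_equal(c, c.T):
            raise ValidationError("counts must be symmetric and nonnegative")
        if not np.allclose(f, f.T):
            raise ValidationError("mean_fa must be symmetric")
        if (f < 0).any() or (f > 1).any():
            raise ValidationError("FA values must lie in [0, 1]")
        if np.any(np.diag(c)) or np.any(np.diag(f)):
            raise ValidationError("diagonals must be zero")
        if np.any((c > 0) & (f <= 0)):
            raise ValidationError("FA must be positive wherever streamlines exist")
        if self.labels is None:
            self.labels = _default_labels(c.shape[0])


def build_functional_connectome(ts: TimeSeriesMatrix) -> Connectome:
    """Fisher-z correlation connectome with negative edges zeroed.

    edge(i, j) = atanh(r_ij) if r_ij > 0 else 0, with |r| capped at
    1 - 1e-7 so perfectly correlated (duplicated) signals remain finite.
    """
    data = ts.data
    sd = data.std(axis=1)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = [ts.labels[i] for i in dead]
        raise ValidationError(
            f"zero-variance region(s) {names}: correlation undefined"
        )
    r = np.corrcoef(data)
    r = np.clip(r, -FISHER_R_CAP, FISHER_R_CAP)
    z = np.arctanh(r)
    z[z < 0] = 0.0
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return Connectome(z, list(ts.labels), "functional", True, ts.subject_id)


def build_structural_connectome(
    st: StreamlineTable,
    min_streamlines: int = 3,
    scale_max: float | None = None,
) -> Connectome:
    """FA-weighted structural connectome with a streamline-count threshold.

    Edges with fewer than ``min_streamlines`` streamlines are removed as
    likely false positives; surviving edges carry mean FA, divided by the
    maximum surviving weight (max-scaling) so weights lie in (0, 1] and zero
    still means "no edge". Pass ``scale_max`` to divide by a cohort-wide
    maximum instead of the per-subject one.
    """
    keep = st.counts >= min_streamlines
    w = np.where(keep, st.mean_fa, 0.0).astype(float)
    np.fill_diagonal(w, 0.0)
    top = w.max()
    if top == 0:
        raise ValidationError(
            "empty structural network: no edge reaches the streamline threshold"
        )
    w = w / (scale_max if scale_max is not None else top)
    return Connectome(w, list(st.labels), "structural", True, st.subject_id)
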