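"""Structure-function coupling via communication measures.

Communication measures describe how signals could travel over the
structural connectome without global knowledge of its topology: weighted
shortest path length (SPL), search information (SI; bits a memoryless
random walker needs to follow the shortest path), path transitivity (PT;
density of local detours along the shortest path, via the matching index),
column-wise z-scored mean first passage time (MFPT) of a random walk,
neighborhood overlap (NO; Jaccard overlap of neighbor sets) and matching
index (MI; weighted similarity of connection profiles).

Per subject, the measures over node pairs are the predictors of a multiple
linear regression whose response is the observed functional connectivity of
the same pairs; the fitted values form the predicted functional matrix, and
structure-function coupling is the Pearson correlation between predicted
and observed values. The "default" subset is {SPL, SI}; "all" adds PT,
MFPT(z), NO and MI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .io import ValidationError
from .metrics import strengths, weight_to_length
from .stats import two_sample_t

logger = logging.getLogger("conncompare")

DEFAULT_MEASURES = ("SPL", "SI")
ALL_MEASURES = ("SPL", "SI", "PT", "MFPTz", "NO", "MI")


def _shortest_path_data(matrix: np.ndarray):
    lengths = csr_matrix(weight_to_length(matrix))
    dist, pred = _csgraph_sp(lengths, method="D", directed=False,
                             return_predecessors=True)
    return dist, pred


def _reconstruct_path(pred: np.ndarray, s: int, t: int) -> list[int]:
    """Node sequence of the shortest path s -> t from the predecessor matrix."""
    path = [t]
    while path[-1] != s:
        prev = pred[s, path[-1]]
        if prev < 0:
            return []
        path.append(int(prev))
    return path[::-1]


def search_information(matrix: np.ndarray) -> np.ndarray:
    """Bits needed by a memoryless random walker to follow each shortest path.

    SI(s -> t) = -log2 prod over path steps of w_step / strength(current
    node). Asymmetric in general; inf for disconnected pairs.
    """
    n = matrix.shape[0]
    dist, pred = _shortest_path_data(matrix)
    s_node = strengths(matrix)
    si = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            if not np.isfinite(dist[s, t]):
                si[s, t] = np.inf
                continue
            path = _reconstruct_path(pred, s, t)
            logp = 0.0
            for a, b in zip(path[:-1], path[1:]):
                logp += np.log2(matrix[a, b] / s_node[a])
            si[s, t] = -logp
    return si


def matching_index(matrix: np.ndarray) -> np.ndarray:
    """Weighted similarity of two nodes' connection profiles.

    MI(i, j) = sum over shared neighbors k (excluding i, j) of
    (w_ik + w_jk), divided by the same sum over the union of neighbors.
    1 for identical neighborhoods, 0 for disjoint ones.
    """
    n = matrix.shape[0]
    a = matrix != 0
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = np.ones(n, dtype=bool)
            keep[[i, j]] = False
            wi, wj = matrix[i] * keep, matrix[j] * keep
            both = a[i] & a[j] & keep
            either = (a[i] | a[j]) & keep
            den = wi[either].sum() + wj[either].sum()
            if den > 0:
                num = wi[both].sum() + wj[both].sum()
                mi[i, j] = mi[j, i] = num / den
    return mi


def neighborhood_overlap(matrix: np.ndarray) -> np.ndarray:
    """Jaccard overlap of binarized neighbor sets (endpoints excluded)."""
    n = matrix.shape[0]
    a = matrix != 0
    no = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = np.ones(n, dtype=bool)
            keep[[i, j]] = False
            inter = np.count_nonzero(a[i] & a[j] & keep)
            union = np.count_nonzero((a[i] | a[j]) & keep)
            if union:
                no[i, j] = no[j, i] = inter / union
    return no


def path_transitivity(matrix: np.ndarray) -> np.ndarray:
    """Mean matching index among node pairs along each shortest path.

    PT(s, t) = (2 / (Omega(Omega-1))) * sum over pairs (i < j) of path
    nodes of MI(pi_i, pi_j), where Omega is the path's node count. For
    adjacent pairs (Omega = 2) this reduces to MI(s, t). Symmetric.
    """
    n = matrix.shape[0]
    dist, pred = _shortest_path_data(matrix)
    mi = matching_index(matrix)
    pt = np.zeros((n, n))
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]):
                pt[s, t] = pt[t, s] = np.inf
                continue
            path = _reconstruct_path(pred, s, t)
            omega = len(path)
            total = 0.0
            for ii in range(omega):
                for jj in range(ii + 1, omega):
                    total += mi[path[ii], path[jj]]
            pt[s, t] = pt[t, s] = 2.0 * total / (omega * (omega - 1))
    return pt


def mean_first_passage_time(matrix: np.ndarray) -> np.ndarray:
    """Expected random-walk steps to first reach each target node (raw MFPT).

    Transition probabilities P(i, j) = w_ij / strength_i; solved through the
    fundamental matrix Z = (I - P + 1 pi)^-1 with stationary distribution
    pi proportional to node strength: MFPT(i, j) = (Z_jj - Z_ij) / pi_j.
    """
    s = strengths(matrix)
    if (s == 0).any():
        raise ValidationError("isolated node: random walk undefined")
    p = matrix / s[:, None]
    n = matrix.shape[0]
    pi = s / s.sum()
    z = np.linalg.inv(np.eye(n) - p + np.outer(np.ones(n), pi))
    mfpt = (np.diag(z)[None, :] - z) / pi[None, :]
    np.fill_diagonal(mfpt, 0.0)
    return mfpt


def columnwise_zscore(matrix: np.ndarray) -> np.ndarray:
    """Z-score each column over its off-diagonal entries (diagonal stays 0).

    Degenerate single-entry columns (N = 2) z-score to 0.
    """
    n = matrix.shape[0]
    out = np.zeros_like(matrix, dtype=float)
    off = ~np.eye(n, dtype=bool)
    for j in range(n):
        col = matrix[off[:, j], j]
        sd = col.std()
        if col.size < 2 or sd == 0:
            continue
        out[off[:, j], j] = (col - col.mean()) / sd
    return out


@dataclass
class CommMeasureSet:
    """Per-pair communication-measure matrices for one structural connectome."""

    spl: np.ndarray
    si: np.ndarray
    pt: np.ndarray | None = None
    mfptz: np.ndarray | None = None
    no: np.ndarray | None = None
    mi: np.ndarray | None = None
    subset: str = "default"

    def predictor_matrices(self) -> dict[str, np.ndarray]:
        """Symmetrized predictor matrices in a fixed order."""
        out = {"SPL": self.spl, "SI": (self.si + self.si.T) / 2.0}
        if self.subset == "all":
            out["PT"] = self.pt
            out["MFPTz"] = (self.mfptz + self.mfptz.T) / 2.0
            out["NO"] = self.no
            out["MI"] = self.mi
        return out


def comm_measures(matrix: np.ndarray, subset: str = "default") -> CommMeasureSet:
    if subset not in ("default", "all"):
        raise ValidationError(f"measure subset must be default|all, got {subset!r}")
    dist, _ = _shortest_path_data(matrix)
    np.fill_diagonal(dist, 0.0)
    si = search_information(matrix)
    if subset == "default":
        return CommMeasureSet(dist, si)
    return CommMeasureSet(
        dist, si,
        pt=path_transitivity(matrix),
        mfptz=columnwise_zscore(mean_first_passage_time(matrix)),
        no=neighborhood_overlap(matrix),
        mi=matching_index(matrix),
        subset="all",
    )


@dataclass
class CouplingResult:
    """Predicted-vs-observed functional connectivity coupling for one subject."""

    r: float
    p_value: float
    params: np.ndarray = field(repr=False)
    measures: tuple[str, ...] = DEFAULT_MEASURES
    n_pairs: int = 0
    subject_id: str | None = None
    predicted: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        return (f"coupling r = {self.r:.3f} (p = {self.p_value:.4g}, "
                f"{self.n_pairs} pairs, measures: {', '.join(self.measures)})")


def predict_fc(
    sc_matrix: np.ndarray,
    fc_matrix: np.ndarray,
    subset: str = "default",
    include_zero_fc: bool = True,
    subject_id: str | None = None,
) -> CouplingResult:
    """Regress observed FC on structural communication measures per node pair.

    Node pairs with no structural path are excluded (the measures are
    undefined there); collinear predictors are dropped with a warning.
    When ``include_zero_fc`` is False, pairs whose observed functional edge
    is zero (zeroed negative correlations) are excluded from the regression.
    """
    if sc_matrix.shape != fc_matrix.shape:
        raise ValidationError("SC and FC must share the node set")
    n = sc_matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    cms = comm_measures(sc_matrix, subset)
    preds = cms.predictor_matrices()
    y_all = fc_matrix[iu, ju]
    cols = {name: m[iu, ju] for name, m in preds.items()}
    mask = np.ones(iu.size, dtype=bool)
    for v in cols.values():
        mask &= np.isfinite(v)
    n_drop = int(np.count_nonzero(~mask))
    if n_drop:
        logger.info("excluding %d structurally disconnected pairs", n_drop)
    if not include_zero_fc:
        mask &= y_all != 0
    y = y_all[mask]
    kept_names: list[str] = []
    x_cols: list[np.ndarray] = []
    for name, v in cols.items():
        candidate = np.column_stack([np.ones(y.size)] + x_cols + [v[mask]])
        if np.linalg.matrix_rank(candidate) == candidate.shape[1]:
            kept_names.append(name)
            x_cols.append(v[mask])
        else:
            logger.warning("dropping collinear predictor %s", name)
    if not x_cols:
        raise ValidationError("no usable predictors (all collinear/degenerate)")
    x = sm.add_constant(np.column_stack(x_cols), has_constant="add")
    fit = sm.OLS(y, x).fit()
    r, p = sps.pearsonr(fit.fittedvalues, y)
    predicted = np.zeros((n, n))
    predicted[iu[mask], ju[mask]] = fit.fittedvalues
    predicted[ju[mask], iu[mask]] = fit.fittedvalues
    return CouplingResult(float(r), float(p), fit.params, tuple(kept_names),
                          int(y.size), subject_id, predicted)


def compare_coupling(
    rs_a: np.ndarray, rs_b: np.ndarray, fisher: bool = True
) -> tuple[float, float]:
    """Two-sample t test on per-subject coupling correlations.

    Correlations are Fisher-z transformed by default so they live on an
    unbounded, approximately normal scale.
    """
    rs_a = np.asarray(rs_a, dtype=float)
    rs_b = np.asarray(rs_b, dtype=float)
    if fisher:
        rs_a, rs_b = np.arctanh(rs_a), np.arctanh(rs_b)
    return two_sample_t(rs_a, rs_b)
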