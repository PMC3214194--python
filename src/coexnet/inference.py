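"""Co-expression network inference from expression matrices.

The pipeline mirrors the classical MINET/Infotheo workflow for microarray
data: equal-frequency discretization of each probeset's expression profile,
plug-in (empirical) mutual information between all probeset pairs, MRNET
edge scoring (maximum of the two directed MRMR forward-selection scores),
optional normalization of the weights to [0, 1], and conversion of the
resulting adjacency matrix to an undirected weighted graph.

All mutual-information values are in nats (natural logarithm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import entropy as _entropy
from sklearn.metrics import mutual_info_score

from .errors import InvalidDataError, InvalidSpecError

__all__ = [
    "ExpressionMatrix",
    "DiscretizationSpec",
    "DiscretizedMatrix",
    "MIMatrix",
    "MrnetResult",
    "discretize_equalfreq",
    "mutual_information",
    "mi_matrix",
    "mrnet",
    "normalize_weights",
    "matrix_to_network",
]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise InvalidDataError(f"{what} must be unique")


@dataclass
class ExpressionMatrix:
    """Labeled samples x probesets matrix of (preprocessed) expression values.

    Rows are samples, columns are probesets — the transposed orientation
    used when discretizing expression profiles, so that each *column* is
    one probeset measured across all samples.
    """

    sample_ids: list[str]
    probeset_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidDataError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.probeset_ids):
            raise InvalidDataError("id lists must match matrix dimensions")
        if n < 2 or p < 2:
            raise InvalidDataError("need at least 2 samples and 2 probesets")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.probeset_ids, "probeset ids")
        if not np.isfinite(self.values).all():
            raise InvalidDataError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probesets(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tsv(cls, path, transposed: bool = False) -> "ExpressionMatrix":
        """Read a TSV/CSV matrix: first row probeset ids, first column sample ids.

        With ``transposed=True`` the file is probesets x samples and is
        transposed on load.
        """
        import pandas as pd

        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if transposed:
            df = df.T
        return cls(
            sample_ids=[str(i) for i in df.index],
            probeset_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.probeset_ids
        ).to_csv(path, sep="\t")


@dataclass
class DiscretizationSpec:
    """Equal-frequency binning parameters.

    The default bin count is floor(sqrt(n_samples)), the usual heuristic for
    plug-in MI estimation on small sample sizes.
    """

    nbins: int
    method: str = "equalfreq"

    def __post_init__(self) -> None:
        if self.method != "equalfreq":
            raise InvalidSpecError(f"unsupported discretization method {self.method!r}")
        if int(self.nbins) != self.nbins or self.nbins < 2:
            raise InvalidSpecError("nbins must be an integer >= 2")
        self.nbins = int(self.nbins)

    @classmethod
    def default_for(cls, n_samples: int) -> "DiscretizationSpec":
        return cls(nbins=int(math.floor(math.sqrt(n_samples))))


@dataclass
class DiscretizedMatrix:
    """Integer bin labels (0 .. nbins-1) with the same layout as the source matrix."""

    sample_ids: list[str]
    probeset_ids: list[str]
    values: np.ndarray
    nbins: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) >= self.nbins:
            raise InvalidDataError("bin labels must lie in {0, ..., nbins-1}")


@dataclass
class MIMatrix:
    """Symmetric pairwise mutual-information matrix (nats).

    The diagonal stores each column's plug-in entropy; MRNET ignores it.
    """

    probeset_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.probeset_ids)
        if self.values.shape != (n, n):
            raise InvalidDataError("MI matrix shape must match probeset ids")


@dataclass
class MrnetResult:
    """MRNET output: undirected weights plus the raw directed MRMR scores.

    ``directed_scores[i, j]`` is the MRMR forward-selection score of
    predictor i for target j (may be negative); ``weights`` is the
    clamped symmetric max of both directions with a zero diagonal.
    """

    probeset_ids: list[str]
    weights: np.ndarray
    directed_scores: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize_equalfreq(
    x: ExpressionMatrix, spec: DiscretizationSpec | None = None
) -> DiscretizedMatrix:
    """Column-wise rank-based equal-frequency binning.

    Each column is stably sorted (ties keep original sample order) and split
    into ``nbins`` consecutive blocks of as-equal-as-possible size; the first
    ``n mod nbins`` blocks receive the extra element.  A run of tied values
    may therefore straddle a bin boundary — the rule is deterministic.
    """
    if spec is None:
        spec = DiscretizationSpec.default_for(x.n_samples)
    n = x.n_samples
    if spec.nbins > n:
        raise InvalidSpecError(f"nbins={spec.nbins} exceeds n_samples={n}")
    base, extra = divmod(n, spec.nbins)
    block_sizes = np.full(spec.nbins, base, dtype=np.int64)
    block_sizes[:extra] += 1
    bin_of_rank = np.repeat(np.arange(spec.nbins), block_sizes)

    out = np.empty_like(x.values, dtype=np.int64)
    for j in range(x.n_probesets):
        order = np.argsort(x.values[:, j], kind="stable")
        out[order, j] = bin_of_rank
    return DiscretizedMatrix(
        sample_ids=list(x.sample_ids),
        probeset_ids=list(x.probeset_ids),
        values=out,
        nbins=spec.nbins,
    )


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def mutual_information(a, b) -> float:
    """Plug-in mutual information between two discrete vectors, in nats.

    I = sum_{x,y} p(x,y) ln[ p(x,y) / (p(x) p(y)) ] over occupied joint cells.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidDataError("inputs must be 1-D vectors of equal length")
    if a.size == 0:
        raise InvalidDataError("inputs must have length >= 1")
    if a.size == 1:
        return 0.0
    return float(mutual_info_score(a, b))


def column_entropy(a) -> float:
    """Plug-in entropy of a discrete vector, in nats."""
    _, counts = np.unique(np.asarray(a), return_counts=True)
    return float(_entropy(counts))


def mi_matrix(d: DiscretizedMatrix) -> MIMatrix:
    """All pairwise plug-in MI values; each unordered pair computed once.

    Diagonal entries hold the per-column entropies.
    """
    p = d.values.shape[1]
    if p < 2:
        raise InvalidDataError("need at least 2 columns for an MI matrix")
    m = np.zeros((p, p))
    for i in range(p):
        m[i, i] = column_entropy(d.values[:, i])
        for j in range(i + 1, p):
            mij = mutual_information(d.values[:, i], d.values[:, j])
            m[i, j] = m[j, i] = mij
    return MIMatrix(probeset_ids=list(d.probeset_ids), values=m)


# ---------------------------------------------------------------------------
# MRNET
# ---------------------------------------------------------------------------

def mrnet(mim: MIMatrix) -> MrnetResult:
    """MRNET edge scoring from a mutual-information matrix.

    For each target variable Y, an MRMR forward selection ranks every other
    variable: the first predictor is the one of maximal relevance I(X;Y),
    with score I(X;Y); each subsequent pick maximizes
    ``u_j = I(X_j;Y) - mean_{X_k in S} I(X_j;X_k)`` over the unselected
    candidates (S = already-selected set) and receives that u_j as its
    score.  Selection runs to exhaustion, so every ordered pair (i, j) gets
    a directed score.  The undirected weight is
    ``w_ij = max(0, max(s_{i->j}, s_{j->i}))``.  Arg-max ties break on the
    lowest column index.
    """
    m = mim.values
    p = m.shape[0]
    if not np.allclose(m, m.T, atol=1e-9):
        raise InvalidDataError("MI matrix must be symmetric")
    off = m[~np.eye(p, dtype=bool)]
    if off.size and off.min() < 0:
        raise InvalidDataError("MI matrix off-diagonal entries must be >= 0")

    scores = np.zeros((p, p))
    for t in range(p):
        relevance = m[:, t].copy()
        remaining = np.ones(p, dtype=bool)
        remaining[t] = False
        redundancy_sum = np.zeros(p)
        n_selected = 0
        while remaining.any():
            if n_selected == 0:
                u = relevance.copy()
            else:
                u = relevance - redundancy_sum / n_selected
            u[~remaining] = -np.inf
            pick = int(np.argmax(u))  # first occurrence = lowest index
            scores[pick, t] = u[pick]
            remaining[pick] = False
            redundancy_sum += m[:, pick]
            n_selected += 1

    weights = np.maximum(scores, scores.T)
    weights = np.maximum(weights, 0.0)
    np.fill_diagonal(weights, 0.0)
    return MrnetResult(
        probeset_ids=list(mim.probeset_ids),
        weights=weights,
        directed_scores=scores,
    )


def normalize_weights(r: MrnetResult) -> MrnetResult:
    """Scale weights so the global maximum is exactly 1; all-zero input unchanged."""
    w = np.asarray(r.weights, dtype=float)
    if (w < 0).any():
        raise InvalidDataError("weights must be nonnegative")
    top = w.max(initial=0.0)
    if top > 0:
        w = w / top
    return MrnetResult(
        probeset_ids=list(r.probeset_ids),
        weights=w,
        directed_scores=r.directed_scores,
    )


def matrix_to_network(r: MrnetResult) -> nx.Graph:
    """Adjacency matrix -> undirected graph: one node per probeset, one edge
    per strictly positive weight; isolated nodes retained."""
    g = nx.Graph()
    g.add_nodes_from(r.probeset_ids)
    w = r.weights
    p = len(r.probeset_ids)
    for i in range(p):
        for j in range(i + 1, p):
            if w[i, j] > 0:
                g.add_edge(r.probeset_ids[i], r.probeset_ids[j], weight=float(w[i, j]))
    return g


def infer_network(
    x: ExpressionMatrix,
    nbins: int | None = None,
    normalize: bool = False,
) -> nx.Graph:
    """Full pipeline: discretize -> MI matrix -> MRNET [-> normalize] -> graph."""
    spec = (
        DiscretizationSpec(nbins=nbins)
        if nbins is not None
        else DiscretizationSpec.default_for(x.n_samples)
    )
    result = mrnet(mi_matrix(discretize_equalfreq(x, spec)))
    if normalize:
        result = normalize_weights(result)
    return matrix_to_network(result)
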