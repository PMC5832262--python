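"""Dyadic association matrices from proximity-collar encounter logs.

Proximity collars log encounters twice — once per collar in the dyad — and
UHF signal-strength variation means the two views rarely agree exactly.  The
raw product of a deployment is therefore an *asymmetric* n x n count matrix
in which entry (i, j) is what collar i logged about collar j.  This module
aggregates encounter records into such matrices, quantifies the asymmetry
via the correlation between the matrix triangles, and removes per-collar
detection bias by iteratively rescaling the most deviant collar until the
triangle correlation stops improving, then symmetrizing.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EncounterRecord",
    "AssociationMatrix",
    "aggregate_encounters",
    "triangle_correlation",
    "correct_collar_bias",
    "read_encounters_csv",
    "write_encounters_csv",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass(frozen=True)
class EncounterRecord:
    """One dyadic logging event: collar_a logged `count` encounters with
    collar_b on `day`, totalling `duration_s` seconds."""

    collar_a: str
    collar_b: str
    day: int
    count: int
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.collar_a == self.collar_b:
            raise ValueError("encounter record requires two distinct collars")
        if self.count < 0:
            raise ValueError("encounter count must be nonnegative")
        if self.duration_s < 0:
            raise ValueError("encounter duration must be nonnegative")


@dataclass
class AssociationMatrix:
    """n x n dyadic weights for one sex x density-treatment x replicate.

    ``weights[i][j]`` is what collar ``ids[i]`` logged about ``ids[j]``
    (raw, possibly asymmetric) or the corrected symmetric dyadic weight.
    """

    ids: list[str]
    weights: np.ndarray
    symmetric: bool = False
    sex: str | None = None
    density: float | None = None
    replicate: int | None = None
    days_included: tuple[int, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.ids)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights must be {n}x{n}, got {self.weights.shape}")
        if np.any(self.weights < 0):
            raise ValueError("association weights must be nonnegative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal of an association matrix must be zero")
        if self.symmetric and not np.array_equal(self.weights, self.weights.T):
            raise ValueError("matrix flagged symmetric but weights differ across the diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def copy(self) -> "AssociationMatrix":
        return replace(self, ids=list(self.ids), weights=self.weights.copy(),
                       days_included=tuple(self.days_included), meta=dict(self.meta))


def aggregate_encounters(
    records: Iterable[EncounterRecord],
    ids: Sequence[str] | None = None,
    exclude_days: Iterable[int] = (),
    **meta,
) -> AssociationMatrix:
    """Sum encounter counts into a raw (asymmetric) association matrix.

    Each record contributes ``count`` to entry (collar_a, collar_b) only:
    the mirrored log from the partner collar arrives as its own record.
    Days in *exclude_days* (e.g. handling days when herds were collared or
    moved among corrals) are dropped before summation.  Duplicate records
    for the same dyad-day are summed.

    Parameters
    ----------
    ids
        Collar roster defining matrix order.  If omitted, the sorted set of
        collars appearing in the records is used.  Records naming a collar
        outside an explicit roster raise ``KeyError``.
    """
    records = list(records)
    excluded = set(exclude_days)
    if ids is None:
        ids = sorted({r.collar_a for r in records} | {r.collar_b for r in records})
    ids = list(ids)
    index = {c: k for k, c in enumerate(ids)}
    n = len(ids)
    W = np.zeros((n, n))
    days: set[int] = set()
    for r in records:
        if r.day in excluded:
            continue
        try:
            i, j = index[r.collar_a], index[r.collar_b]
        except KeyError as exc:
            raise KeyError(f"unknown collar id {exc.args[0]!r}") from None
        W[i, j] += r.count
        days.add(r.day)
    return AssociationMatrix(ids=ids, weights=W, symmetric=False,
                             days_included=tuple(sorted(days)), **meta)


def _triangles(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(W.shape[0], k=1)
    return W[iu, ju], W[ju, iu]


def triangle_correlation(m: AssociationMatrix | np.ndarray) -> float:
    """Pearson correlation between the upper and lower matrix triangles.

    Pairs entry (i, j) with (j, i) over all dyads i < j; 1.0 means the two
    collars of every dyad agree up to a perfect linear relation.  Returns
    ``nan`` when either triangle has zero variance (undefined correlation).
    """
    W = m.weights if isinstance(m, AssociationMatrix) else np.asarray(m, dtype=float)
    if W.shape[0] < 3:
        raise ValueError("triangle correlation needs at least 3 individuals")
    upper, lower = _triangles(W)
    if upper.std() == 0 or lower.std() == 0:
        return float("nan")
    return float(np.corrcoef(upper, lower)[0, 1])


def _collar_deviance(W: np.ndarray) -> np.ndarray:
    """Per-collar mean percent pairwise difference vs what others logged.

    D_i = mean over partners j of |W[i,j] - W[j,i]| / ((W[i,j] + W[j,i]) / 2),
    skipping dyads where both directions logged zero (treated as true zeros,
    which carry no information about relative collar efficiency).
    """
    n = W.shape[0]
    D = np.zeros(n)
    for i in range(n):
        num = den = 0.0
        cnt = 0
        for j in range(n):
            if j == i:
                continue
            s = W[i, j] + W[j, i]
            if s == 0:
                continue
            D[i] += abs(W[i, j] - W[j, i]) / (s / 2.0)
            cnt += 1
        if cnt:
            D[i] /= cnt
    return D


def correct_collar_bias(
    raw: AssociationMatrix,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[AssociationMatrix, np.ndarray]:
    """Remove per-collar detection bias and symmetrize.

    Iteratively: (1) find the collar whose logs deviate most, in mean
    percent pairwise difference, from what every other collar logged about
    it (ties broken toward the lower index); (2) rescale that collar's row
    so its mean logged count equals the mean of what others logged about it;
    (3) recompute the triangle correlation and stop once the improvement
    falls below *tol*, the correlation would decrease, or *max_iter* is
    reached.  The corrected matrix is the entrywise mean of the rescaled
    matrix and its transpose, so its triangle correlation is exactly 1.

    Returns the corrected symmetric matrix and the per-collar cumulative
    scale factors (a collar that under-logged by half gets factor ~2).
    """
    W = raw.weights.copy()
    n = raw.n
    factors = np.ones(n)
    if not np.any(W):
        warnings.warn("all-zero association matrix: returned unchanged with unit factors")
        out = raw.copy()
        out.symmetric = True
        return out, factors
    corr = triangle_correlation(W)
    for _ in range(max_iter):
        D = _collar_deviance(W)
        if np.nanmax(D) <= 0:
            break  # already symmetric
        k = int(np.argmax(D))  # argmax returns the lowest index on ties
        off = np.arange(n) != k
        mean_out = W[k, off].mean()
        mean_in = W[off, k].mean()
        if mean_out == 0:
            break
        f = mean_in / mean_out
        if f == 1.0:
            break
        W_new = W.copy()
        W_new[k, :] *= f
        new_corr = triangle_correlation(W_new)
        # nan correlation (degenerate triangle) is treated as no improvement
        if not np.isnan(new_corr) and (np.isnan(corr) or new_corr >= corr):
            W = W_new
            factors[k] *= f
            if not np.isnan(corr) and new_corr - corr < tol:
                corr = new_corr
                break
            corr = new_corr
        else:
            break  # a step that lowers the correlation is rejected
    sym = (W + W.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    out = raw.copy()
    out.weights = sym
    out.symmetric = True
    return out, factors


# ---------------------------------------------------------------------------
# I/O: encounter CSV and matrix TSV round-trips
# ---------------------------------------------------------------------------

_ENCOUNTER_COLS = ["collar_a", "collar_b", "day", "count", "duration_s"]


def write_encounters_csv(records: Iterable[EncounterRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ENCOUNTER_COLS)
        for r in records:
            w.writerow([r.collar_a, r.collar_b, r.day, r.count, repr(float(r.duration_s))])


def read_encounters_csv(path) -> list[EncounterRecord]:
    df = pd.read_csv(path, dtype={"collar_a": str, "collar_b": str},
                     float_precision="round_trip")
    return [
        EncounterRecord(row.collar_a, row.collar_b, int(row.day), int(row.count),
                        float(row.duration_s))
        for row in df.itertuples(index=False)
    ]


def write_matrix_tsv(m: AssociationMatrix, path) -> None:
    """TSV with a header row and leading column of collar ids; full decimal
    precision (``repr``) so corrected matrices round-trip bit-exactly."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow([""] + list(m.ids))
        for i, cid in enumerate(m.ids):
            w.writerow([cid] + [repr(float(x)) for x in m.weights[i]])


def read_matrix_tsv(path, symmetric: bool | None = None, **meta) -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ids = [str(c) for c in df.columns]
    W = df.to_numpy(dtype=float)
    if symmetric is None:
        symmetric = bool(np.array_equal(W, W.T))
    return AssociationMatrix(ids=ids, weights=W, symmetric=symmetric, **meta)
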