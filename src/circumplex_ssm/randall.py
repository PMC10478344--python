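"""Randomization test of hypothesized circumplex order relations.

A circumplex of k equally spaced variables predicts that the correlation
between two variables decreases with their angular distance. Every
unordered pair of off-diagonal correlation cells whose angular-distance
classes differ yields one order prediction: the cell in the closer class
is predicted to be larger. For k = 8 the distance classes (45, 90, 135,
180 degrees) hold 8, 8, 8 and 4 cells, giving 288 predictions.

The correspondence index is (met - violated) / predictions, with exact
ties (within a small tolerance) counting toward neither the numerator nor
removed from the denominator (the Hubert-Arabie convention). The p-value
is the proportion of relabelings of the variable order — including the
observed one — whose correspondence index is at least the observed index.
Because the index is invariant under rotations and reflections of the
order, enumerating the (k-1)! relabelings with the first variable fixed
gives the same p as enumerating all k! permutations or the k!/(2k)
distinct circular orders; for a strictly perfect circumplex at k = 8 only
the observed order and its reflection attain the maximum, so
p = 2/5040 = 1/2520 ~= .0004.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RandallResult",
    "randall_predictions",
    "n_randall_predictions",
    "randall_test",
]

_TIE_TOL = 1e-10


@dataclass
class RandallResult:
    """Outcome of the order-relations randomization test."""

    n_predictions: int
    n_met: int
    n_violated: int
    n_tied: int
    correspondence_index: float
    p_value: float
    n_relabelings: int
    exhaustive: bool

    def __post_init__(self) -> None:
        if self.n_met + self.n_violated + self.n_tied != self.n_predictions:
            raise ValueError("met + violated + tied must equal predictions")
        if not (-1.0 - 1e-12 <= self.correspondence_index <= 1.0 + 1e-12):
            raise ValueError("correspondence index outside [-1, 1]")


def _cells_and_classes(k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Off-diagonal cells (i<j) of a k-variable circulant and their
    angular-distance classes (in steps of the common spacing)."""
    iu = np.triu_indices(k, 1)
    steps = iu[1] - iu[0]
    classes = np.minimum(steps, k - steps)
    return iu[0], iu[1], classes


def randall_predictions(k: int) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All order predictions for k equally spaced circumplex variables.

    Each prediction is a pair of correlation cells ((i, j), (l, m)) with
    the first cell in the strictly closer distance class, hence predicted
    to hold the larger correlation.
    """
    if k < 3:
        raise ValueError("need at least 3 variables")
    ci, cj, classes = _cells_and_classes(k)
    preds = []
    n_cells = len(classes)
    for a, b in itertools.combinations(range(n_cells), 2):
        if classes[a] == classes[b]:
            continue
        closer, farther = (a, b) if classes[a] < classes[b] else (b, a)
        preds.append(((int(ci[closer]), int(cj[closer])),
                      (int(ci[farther]), int(cj[farther]))))
    return preds


def n_randall_predictions(k: int) -> int:
    return len(randall_predictions(k))


def _prediction_index_pairs(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Cell-index pairs (closer, farther) into the flattened upper triangle."""
    _, _, classes = _cells_and_classes(k)
    n_cells = len(classes)
    a, b = np.triu_indices(n_cells, 1)
    differ = classes[a] != classes[b]
    a, b = a[differ], b[differ]
    swap = classes[a] > classes[b]
    closer = np.where(swap, b, a)
    farther = np.where(swap, a, b)
    return closer, farther


def _scores_for_perms(values: np.ndarray, perms: np.ndarray, k: int,
                      tie_tol: float) -> np.ndarray:
    """Correspondence index per relabeling.

    values: the full k x k correlation matrix; perms: (P, k) variable
    indices placed at circle positions 0..k-1.
    """
    iu0, iu1, _ = _cells_and_classes(k)
    closer, farther = _prediction_index_pairs(k)
    cells = values[perms[:, iu0], perms[:, iu1]]  # (P, n_cells)
    diff = cells[:, closer] - cells[:, farther]  # (P, n_predictions)
    met = (diff > tie_tol).sum(axis=1)
    violated = (diff < -tie_tol).sum(axis=1)
    return (met - violated) / diff.shape[1]


def randall_test(
    matrix: np.ndarray,
    mode: str = "exhaustive",
    *,
    n_samples: int = 10000,
    seed: int | None = None,
    tie_tol: float = _TIE_TOL,
) -> RandallResult:
    """Randomization test of circumplex order relations on a correlation
    matrix whose variables are in circle-position order.

    ``mode='exhaustive'`` enumerates all relabelings with the first
    variable fixed ((k-1)! of them, feasible up to k = 8);
    ``mode='sampled'`` draws ``n_samples`` random relabelings and adds the
    observed one.
    """
    R = np.asarray(matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("matrix must be square")
    k = R.shape[0]
    if k < 3:
        raise ValueError("need at least 3 variables")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("matrix must have a unit diagonal")

    iu0, iu1, _ = _cells_and_classes(k)
    closer, farther = _prediction_index_pairs(k)
    n_pred = len(closer)
    cells = R[iu0, iu1]
    diff = cells[closer] - cells[farther]
    n_met = int((diff > tie_tol).sum())
    n_violated = int((diff < -tie_tol).sum())
    n_tied = n_pred - n_met - n_violated
    observed = (n_met - n_violated) / n_pred if n_pred else 0.0

    if n_pred == 0:
        return RandallResult(0, 0, 0, 0, 0.0, 1.0, 0, mode == "exhaustive")

    if mode == "exhaustive":
        if math.factorial(k - 1) > 500_000:
            raise ValueError("exhaustive mode is infeasible beyond k = 9; use mode='sampled'")
        rest = np.array(list(itertools.permutations(range(1, k))), dtype=np.intp)
        perms = np.concatenate(
            [np.zeros((rest.shape[0], 1), dtype=np.intp), rest], axis=1
        )
        scores = _scores_for_perms(R, perms, k, tie_tol)
        p = float(np.mean(scores >= observed - 1e-12))
        n_relab = perms.shape[0]
        exhaustive = True
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(k) for _ in range(n_samples)], dtype=np.intp)
        scores = _scores_for_perms(R, perms, k, tie_tol)
        p = (1.0 + float(np.sum(scores >= observed - 1e-12))) / (1.0 + n_samples)
        n_relab = n_samples
        exhaustive = False
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return RandallResult(
        n_predictions=n_pred,
        n_met=n_met,
        n_violated=n_violated,
        n_tied=n_tied,
        correspondence_index=float(observed),
        p_value=p,
        n_relabelings=n_relab,
        exhaustive=exhaustive,
    )
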