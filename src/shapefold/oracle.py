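"""Exhaustive enumeration oracle, accuracy metrics and beta grid search.

The enumerator lists *every* pseudoknot-free, triple-free structure over
allowed pairs (hairpin gap > theta) for short sequences, and the brute-force
ensemble evaluates the weighted Boltzmann distribution directly from the
definition — the ground truth against which the dynamic-programming engine is
validated.  Accuracy scoring uses exact pair matching (no +-1 slippage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .energy import EnergyParams
from .fold import score_structure
from .metrics import structure_distance
from .structures import ALLOWED_PAIRS, SecondaryStructure

ENUM_LIMIT = 20


def enumerate_structures(
    seq: str, params: EnergyParams, limit: int = ENUM_LIMIT
) -> list[SecondaryStructure]:
    """All secondary structures of *seq*, each exactly once.

    Recursive interval decomposition: position i is unpaired, or pairs with
    some k (allowed pair, k - i > theta), splitting the interval.
    """
    n = len(seq)
    if n > limit:
        raise ValueError(f"sequence length {n} exceeds enumeration limit {limit}")
    theta = params.theta

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> tuple[frozenset, ...]:
        if i > j:
            return (frozenset(),)
        out = list(enum(i + 1, j))
        for k in range(i + theta + 1, j + 1):
            if seq[i] + seq[k] in ALLOWED_PAIRS:
                for inner in enum(i + 1, k - 1):
                    for rest in enum(k + 1, j):
                        out.append(inner | rest | {(i, k)})
        return tuple(out)

    result = [
        SecondaryStructure(
            n=n, pairs=tuple(s), theta=theta, sequence=seq, severity="reject"
        )
        for s in enum(0, n - 1)
    ]
    enum.cache_clear()
    return result


def count_structures(seq: str, theta: int) -> int:
    """Independent structure count by the standard counting recursion."""

    @lru_cache(maxsize=None)
    def count(i: int, j: int) -> int:
        if j - i < theta + 1:
            return 1
        total = count(i + 1, j)
        for k in range(i + theta + 1, j + 1):
            if seq[i] + seq[k] in ALLOWED_PAIRS:
                total += count(i + 1, k - 1) * count(k + 1, j)
        return total

    return count(0, len(seq) - 1)


@dataclass
class BruteForceEnsemble:
    """Ground-truth weighted ensemble from exhaustive enumeration."""

    structures: list[SecondaryStructure]
    energies: np.ndarray  # E(S), kcal/mol
    distances: np.ndarray  # d(S, q)
    prob_unweighted: np.ndarray  # P(S)
    prob_weighted: np.ndarray  # P'(S)
    Z: float
    Z_weighted: float
    p_unweighted: np.ndarray  # pair-probability matrices (symmetric)
    p_weighted: np.ndarray
    expected_distance_unweighted: float
    expected_distance_weighted: float
    mfe_score: float  # min over S of E(S) + beta*d(S, q)
    mfe_index: int


def brute_force_ensemble(
    seq: str,
    q: np.ndarray | None,
    beta: float,
    params: EnergyParams,
    *,
    stack_bonus: np.ndarray | None = None,
    limit: int = ENUM_LIMIT,
) -> BruteForceEnsemble:
    """Evaluate the weighted Boltzmann ensemble directly from the definition.

    w(S) = exp(-beta*d(S,q)/RT); Z' = sum_S exp(-E(S)/RT) w(S); the marginals
    and expected distances follow by direct summation.  ``stack_bonus``
    switches the per-structure energies to the Deigan stacking rule (q and
    beta are then typically None/0).
    """
    n = len(seq)
    RT = params.RT
    structures = enumerate_structures(seq, params, limit=limit)
    q_arr = None if q is None else np.asarray(q, dtype=float)
    energies = np.array(
        [score_structure(seq, s, params, stack_bonus=stack_bonus) for s in structures]
    )
    if q_arr is None:
        distances = np.zeros(len(structures))
    else:
        distances = np.array([structure_distance(s, q_arr) for s in structures])
    boltz = np.exp(-energies / RT)
    wboltz = boltz * np.exp(-beta * distances / RT)
    Z = float(boltz.sum())
    Zw = float(wboltz.sum())
    P = boltz / Z
    Pw = wboltz / Zw
    p0 = np.zeros((n, n))
    pw = np.zeros((n, n))
    for s, pr, prw in zip(structures, P, Pw):
        for i, j in s.pairs:
            p0[i, j] += pr
            p0[j, i] += pr
            pw[i, j] += prw
            pw[j, i] += prw
    mfe_objective = energies + beta * distances
    mfe_index = int(np.argmin(mfe_objective))
    return BruteForceEnsemble(
        structures=structures,
        energies=energies,
        distances=distances,
        prob_unweighted=P,
        prob_weighted=Pw,
        Z=Z,
        Z_weighted=Zw,
        p_unweighted=p0,
        p_weighted=pw,
        expected_distance_unweighted=float((P * distances).sum()),
        expected_distance_weighted=float((Pw * distances).sum()),
        mfe_score=float(mfe_objective[mfe_index]),
        mfe_index=mfe_index,
    )


# ----------------------------------------------------------------------
# accuracy


@dataclass(frozen=True)
class AccuracyResult:
    """Exact-pair-matching accuracy; undefined ratios (0/0) are None."""

    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    ppv: float | None


def accuracy(
    predicted: SecondaryStructure, reference: SecondaryStructure
) -> AccuracyResult:
    """Sensitivity and PPV of *predicted* against *reference*, no slippage."""
    if predicted.n != reference.n:
        raise ValueError("predicted and reference structures differ in length")
    pred = set(predicted.pairs)
    ref = set(reference.pairs)
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    sens = tp / (tp + fn) if (tp + fn) else None
    ppv = tp / (tp + fp) if (tp + fp) else None
    return AccuracyResult(tp=tp, fp=fp, fn=fn, sensitivity=sens, ppv=ppv)


def discrepancy_positions(
    q: np.ndarray,
    reference: SecondaryStructure,
    threshold: float = 0.5,
) -> tuple[list[int], float]:
    """Positions where probing data and a reference structure disagree.

    A position is a discrepancy when |q_i - x_i| > threshold (x from the
    reference).  Missing (NaN) data positions are excluded from both the
    flagged set and the denominator of the returned rate.
    """
    q = np.asarray(q, dtype=float)
    if q.size != reference.n:
        raise ValueError("length mismatch between q and reference structure")
    x = reference.x
    observed = ~np.isnan(q)
    flagged = observed & (np.abs(q - x) > threshold)
    n_obs = int(observed.sum())
    rate = float(flagged.sum() / n_obs) if n_obs else 0.0
    return list(np.flatnonzero(flagged)), rate


# ----------------------------------------------------------------------
# beta grid search


def beta_grid_search(
    seq: str,
    q: np.ndarray,
    reference: SecondaryStructure,
    params: EnergyParams,
    grid: np.ndarray | None = None,
    objective: str = "sum",
) -> tuple[float, list[dict]]:
    """Pick beta maximizing prediction accuracy against a reference.

    For each beta on the grid the weighted MFE is computed and scored
    (sensitivity, PPV).  ``objective`` combines them as ``sum`` (default),
    ``product`` or ``min``; None ratios count as 0.  Ties break toward the
    smallest beta.  Returns (best_beta, per-beta profile rows).
    """
    from .fold import weighted_mfe  # deferred: avoids cycle at import time

    if grid is None:
        grid = np.round(np.arange(0.0, 3.0 + 1e-9, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty beta grid")
    combine = {
        "sum": lambda s, p: s + p,
        "product": lambda s, p: s * p,
        "min": min,
    }[objective]
    profile = []
    best_beta, best_val = None, -math.inf
    for beta in grid:
        result = weighted_mfe(seq, q, float(beta), params)
        acc = accuracy(result.structure, reference)
        s = acc.sensitivity or 0.0
        p = acc.ppv or 0.0
        val = combine(s, p)
        profile.append(
            {
                "beta": float(beta),
                "sensitivity": acc.sensitivity,
                "ppv": acc.ppv,
                "objective": val,
                "score": result.score,
            }
        )
        if val > best_val + 1e-12:
            best_val = val
            best_beta = float(beta)
    return best_beta, profile
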