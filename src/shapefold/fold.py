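"""Soft-constraint folding engine: weighted partition function, base-pair
probabilities, weighted MFE, and the stacking pseudo-energy comparison mode.

The model: probing data gives each position i a probability ``q[i]`` of being
unpaired.  Every structure S has an indicator vector x (x[i]=1 iff unpaired)
and an L1 distance d(S,q) = sum_i |x[i] - q[i]|.  Each position contributes a
Boltzmann position weight

    omega(i, x) = exp(-beta * |x - q[i]| / RT),

so the weight of a whole structure factorizes as exp(-beta*d(S,q)/RT) and the
weighted partition function is

    Z' = sum_S exp(-E(S)/RT) * exp(-beta*d(S,q)/RT),

computed by a McCaskill-style inside recursion in which every position
contributes exactly one weight factor (paired or unpaired).  An inside-outside
pass yields weighted pair probabilities p'_ij; a min-sum transform of the same
recursion yields the weighted MFE, the structure minimizing E(S) + beta*d(S,q).

Numeric safety: because of the one-weight-per-position factorization, dividing
both omega(i,0) and omega(i,1) by a per-nucleotide scale s rescales every
structure's term by s^-n uniformly; probabilities are invariant and
log Z' = log(Z'_scaled) + n*log(s).  The scale is chosen automatically from
the weighted MFE for long sequences (no overflow for n <= 5000 at 37 C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import EnergyParams, hairpin_energy, internal_energy
from .structures import ALLOWED_PAIRS, SecondaryStructure

INF = math.inf

#: Default Deigan et al. slope/intercept for the comparison mode (kcal/mol).
DEIGAN_SLOPE = 1.8
DEIGAN_INTERCEPT = -0.8

_AUTOSCALE_ABOVE = 60  # below this, scale 1 keeps small cases bit-transparent
_SFACT = 1.07  # safety factor on the MFE-based scale estimate


# ----------------------------------------------------------------------
# weights


@dataclass(frozen=True)
class WeightSet:
    """Per-position Boltzmann weights omega(i, unpaired) and omega(i, paired)."""

    unpaired: np.ndarray  # omega(i, 1)
    paired: np.ndarray  # omega(i, 0)
    beta: float
    RT: float


def build_weights(q: np.ndarray, beta: float, RT: float) -> WeightSet:
    """Weights omega(i,x) = exp(-beta*|x - q_i|/RT); x=1 means unpaired."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    q = np.asarray(q, dtype=float)
    if np.isnan(q).any():
        raise ValueError("q contains missing values; resolve them first")
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q values must lie in [0, 1]")
    return WeightSet(
        unpaired=np.exp(-beta * (1.0 - q) / RT),
        paired=np.exp(-beta * q / RT),
        beta=beta,
        RT=RT,
    )


def loop_weight(i: int, j: int, weights: WeightSet) -> float:
    """Omega(i, j): product of unpaired weights over [i..j]; empty -> 1."""
    if i > j:
        return 1.0
    return float(np.prod(weights.unpaired[i : j + 1]))


def uniform_weights(n: int, RT: float) -> WeightSet:
    """All-ones weights (plain, unweighted folding)."""
    return WeightSet(unpaired=np.ones(n), paired=np.ones(n), beta=0.0, RT=RT)


# ----------------------------------------------------------------------
# loop energies bound to one sequence (with optional Deigan stack bonus)


class _Loops:
    """Caches Boltzmann-ready loop energies for one (sequence, params) pair.

    ``stack_bonus`` is a per-position pseudo energy added to helix stack terms
    only (all four positions of each stack), which is the Deigan comparison
    mode; ``None`` for soft/plain modes.
    """

    def __init__(self, seq: str, params: EnergyParams, stack_bonus=None):
        self.seq = seq
        self.params = params
        self.bonus = None if stack_bonus is None else np.asarray(stack_bonus, float)

    def hairpin(self, i: int, j: int) -> float:
        return hairpin_energy(self.seq, i, j, self.params)

    def internal(self, i: int, j: int, k: int, l: int) -> float:
        e = internal_energy(self.seq, i, j, k, l, self.params)
        if self.bonus is not None and k == i + 1 and l == j - 1 and e < INF:
            e += self.bonus[i] + self.bonus[j] + self.bonus[k] + self.bonus[l]
        return e


def _candidates(seq: str, theta: int) -> np.ndarray:
    n = len(seq)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + theta + 1, n):
            if seq[i] + seq[j] in ALLOWED_PAIRS:
                ok[i, j] = True
    return ok


# ----------------------------------------------------------------------
# inside


@dataclass
class PartitionTables:
    """Inside tables of the weighted partition function (scaled representation).

    Entries over interval [i..j] are stored divided by ``exp(log_scale)`` per
    position; ``log_Z`` undoes the scaling.  The scaled per-position weights
    actually used are kept so the outside pass is consistent by construction.
    """

    n: int
    Z: np.ndarray
    ZB: np.ndarray
    ZM: np.ndarray
    ZM1: np.ndarray
    wu: np.ndarray  # scaled omega(i,1)
    wp: np.ndarray  # scaled omega(i,0)
    log_scale: float  # ln(s) per nucleotide

    @property
    def log_Z(self) -> float:
        return math.log(self.Z[0, self.n - 1]) + self.n * self.log_scale

    def total(self) -> float:
        """Z' as a plain float (may overflow for very long sequences)."""
        return math.exp(self.log_Z)

    def z(self, i: int, j: int) -> float:
        return 1.0 if i > j else float(self.Z[i, j])


def _auto_log_scale(seq, weights, params, stack_bonus) -> float:
    n = len(seq)
    if n <= _AUTOSCALE_ABOVE:
        return 0.0
    pseudo_u = -params.RT * np.log(weights.unpaired)
    pseudo_p = -params.RT * np.log(weights.paired)
    score = _mfe_tables(seq, params, pseudo_u, pseudo_p, stack_bonus)[0]
    return max(0.0, -_SFACT * score / (n * params.RT))


def inside(
    seq: str,
    weights: WeightSet,
    params: EnergyParams,
    *,
    stack_bonus: np.ndarray | None = None,
    log_scale: float | None = None,
) -> PartitionTables:
    """Weighted inside recursion over all pseudoknot-free structures.

    Z(i,j) splits on the rightmost position being unpaired or paired; ZB(i,j)
    sums hairpin, internal-loop and multiloop closings of pair (i,j); ZM/ZM1
    are the multiloop helpers (at-least-one / exactly-one component).  Every
    position contributes exactly one weight factor in every term.
    """
    n = len(seq)
    theta, RT = params.theta, params.RT
    loops = _Loops(seq, params, stack_bonus)
    if log_scale is None:
        log_scale = _auto_log_scale(seq, weights, params, stack_bonus)
    s = math.exp(log_scale)
    wu = weights.unpaired / s
    wp = weights.paired / s
    # prefix logs for O(1) loop-weight products over arbitrary spans
    lwu = np.concatenate(([0.0], np.cumsum(np.log(wu))))
    lg = np.concatenate(([0.0], np.cumsum(np.log(wu) - params.ml_c / RT)))

    def om(a: int, b: int) -> float:  # product of wu over [a..b]
        return 1.0 if a > b else math.exp(lwu[b + 1] - lwu[a])

    def gm(a: int, b: int) -> float:  # wu * e^{-c/RT} product (multiloop gaps)
        return 1.0 if a > b else math.exp(lg[b + 1] - lg[a])

    ok = _candidates(seq, theta)
    Z = np.zeros((n, n))
    ZB = np.zeros((n, n))
    ZM = np.zeros((n, n))
    ZM1 = np.zeros((n, n))
    eb = math.exp(-params.ml_b / RT)
    eab = math.exp(-(params.ml_a + params.ml_b) / RT)
    max_loop = params.max_loop

    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            # --- ZB ---
            if ok[i, j]:
                eh = loops.hairpin(i, j)
                acc = math.exp(-eh / RT) * om(i + 1, j - 1) if eh < INF else 0.0
                for k in range(i + 1, min(i + 2 + max_loop, j - 1)):
                    n1 = k - i - 1
                    lmin = max(k + theta + 1, j - 1 - (max_loop - n1))
                    for l in range(lmin, j):
                        if ZB[k, l] > 0.0:
                            ei = loops.internal(i, j, k, l)
                            if ei < INF:
                                acc += (
                                    math.exp(-ei / RT)
                                    * om(i + 1, k - 1)
                                    * om(l + 1, j - 1)
                                    * ZB[k, l]
                                )
                mm = 0.0
                for h in range(i + 2, j):
                    if ZM[i + 1, h - 1] > 0.0 and ZM1[h, j - 1] > 0.0:
                        mm += ZM[i + 1, h - 1] * ZM1[h, j - 1]
                acc += eab * mm
                ZB[i, j] = wp[i] * wp[j] * acc
            # --- ZM1 ---
            acc = 0.0
            for l in range(i + theta + 1, j + 1):
                if ZB[i, l] > 0.0:
                    acc += ZB[i, l] * eb * gm(l + 1, j)
            ZM1[i, j] = acc
            # --- ZM ---
            acc = 0.0
            for k in range(i, j - theta):
                if ZM1[k, j] > 0.0:
                    left = gm(i, k - 1) + (ZM[i, k - 1] if k - 1 >= i else 0.0)
                    acc += left * ZM1[k, j]
            ZM[i, j] = acc
            # --- Z ---
            acc = (Z[i, j - 1] if j - 1 >= i else 1.0) * wu[j]
            for k in range(i, j - theta):
                if ZB[k, j] > 0.0:
                    acc += (Z[i, k - 1] if k - 1 >= i else 1.0) * ZB[k, j]
            Z[i, j] = acc
    if not np.isfinite(Z[0, n - 1]) or Z[0, n - 1] <= 0.0:
        raise FloatingPointError(
            "partition function overflow/underflow; supply a log_scale"
        )
    return PartitionTables(
        n=n, Z=Z, ZB=ZB, ZM=ZM, ZM1=ZM1, wu=wu, wp=wp, log_scale=log_scale
    )


# ----------------------------------------------------------------------
# outside / base-pair probabilities


@dataclass
class BasePairProbMatrix:
    """Symmetric matrix of pair probabilities and derived unpaired vector."""

    p: np.ndarray

    @property
    def unpaired(self) -> np.ndarray:
        return 1.0 - self.p.sum(axis=1)

    @property
    def n(self) -> int:
        return self.p.shape[0]


def pair_probabilities(
    tables: PartitionTables,
    seq: str,
    params: EnergyParams,
    *,
    stack_bonus: np.ndarray | None = None,
) -> BasePairProbMatrix:
    """Inside-outside pass: p'_ij for every candidate pair.

    The outside value Qout(i,j) sums, over all contexts of pair (i,j), the
    weight of everything outside [i..j]: exterior placement, enclosure in an
    internal loop, or membership in a multiloop (as last component next to
    ZM, or with other components on either side).  p'_ij = Qout*ZB/Z'.
    """
    n, theta, RT = tables.n, params.theta, params.RT
    Z, ZB, ZM = tables.Z, tables.ZB, tables.ZM
    wu, wp = tables.wu, tables.wp
    loops = _Loops(seq, params, stack_bonus)
    lwu = np.concatenate(([0.0], np.cumsum(np.log(wu))))
    lg = np.concatenate(([0.0], np.cumsum(np.log(wu) - params.ml_c / RT)))

    def om(a, b):
        return 1.0 if a > b else math.exp(lwu[b + 1] - lwu[a])

    def gm_vec(a, bs):  # vectorized gm(a, b) over array of b
        out = np.exp(lg[bs + 1] - lg[a])
        out[bs < a] = 1.0
        return out

    eabb = math.exp(-(params.ml_a + 2 * params.ml_b) / RT)
    max_loop = params.max_loop
    ztot = Z[0, n - 1]
    qout = np.zeros((n, n))
    p = np.zeros((n, n))
    cand = [(i, j) for i in range(n) for j in range(i + 1, n) if ZB[i, j] > 0.0]
    cand.sort(key=lambda ij: ij[0] - ij[1])  # decreasing span

    for i, j in cand:
        acc = tables.z(0, i - 1) * tables.z(j + 1, n - 1)
        # enclosed in an internal loop by (k, l)
        for k in range(max(0, i - 1 - max_loop), i):
            n1 = i - k - 1
            for l in range(j + 1, min(n, j + 2 + (max_loop - n1))):
                if ZB[k, l] > 0.0 and qout[k, l] > 0.0:
                    ei = loops.internal(k, l, i, j)
                    if ei < INF:
                        acc += (
                            qout[k, l]
                            * wp[k]
                            * wp[l]
                            * math.exp(-ei / RT)
                            * om(k + 1, i - 1)
                            * om(j + 1, l - 1)
                        )
        # component of a multiloop closed by (k, l), k < i, l > j
        if i >= 1 and j <= n - 2:
            ks = np.arange(0, i)
            ls = np.arange(j + 1, n)
            Q = qout[0:i, j + 1 : n] * wp[0:i, None] * wp[None, j + 1 : n]
            if Q.any():
                ul = np.exp(lg[i] - lg[ks + 1])  # gm(k+1, i-1)
                zml = np.zeros(i)
                sel = ks + 1 <= i - 1
                zml[sel] = ZM[ks[sel] + 1, i - 1]
                ur = gm_vec(j + 1, ls - 1)
                zmr = np.zeros(ls.size)
                sel = j + 1 <= ls - 1
                zmr[sel] = ZM[j + 1, ls[sel] - 1]
                t_zml = zml @ Q
                acc += eabb * (t_zml @ ur + (ul @ Q) @ zmr + t_zml @ zmr)
        qout[i, j] = acc
        p[i, j] = acc * ZB[i, j] / ztot

    np.clip(p, 0.0, 1.0, out=p)
    return BasePairProbMatrix(p=p + p.T)


# ----------------------------------------------------------------------
# weighted MFE (min-sum transform)


@dataclass(frozen=True)
class MfeResult:
    """Optimal structure under the objective E(S) + beta*d(S,q)."""

    structure: SecondaryStructure
    score: float  # minimized objective (kcal/mol)
    energy: float  # Turner-energy component E(S) of the reported structure

    @property
    def data_term(self) -> float:
        """beta * d(S, q) of the reported structure."""
        return self.score - self.energy


def _mfe_tables(seq, params, pseudo_u, pseudo_p, stack_bonus):
    """Min-sum DP; returns (score, tables...) for traceback."""
    n = len(seq)
    theta, max_loop = params.theta, params.max_loop
    loops = _Loops(seq, params, stack_bonus)
    ok = _candidates(seq, theta)
    cu = np.concatenate(([0.0], np.cumsum(pseudo_u)))
    cg = np.concatenate(([0.0], np.cumsum(pseudo_u + params.ml_c)))

    def U(a, b):  # unpaired pseudo-energy over [a..b]
        return 0.0 if a > b else cu[b + 1] - cu[a]

    def Um(a, b):  # unpaired-in-multiloop (adds c per base)
        return 0.0 if a > b else cg[b + 1] - cg[a]

    F = np.zeros((n, n))
    FB = np.full((n, n), INF)
    FM = np.full((n, n), INF)
    FM1 = np.full((n, n), INF)

    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if ok[i, j]:
                best = loops.hairpin(i, j) + U(i + 1, j - 1)
                for k in range(i + 1, min(i + 2 + max_loop, j - 1)):
                    n1 = k - i - 1
                    lmin = max(k + theta + 1, j - 1 - (max_loop - n1))
                    for l in range(lmin, j):
                        if FB[k, l] < INF:
                            ei = loops.internal(i, j, k, l)
                            if ei < INF:
                                cand = ei + U(i + 1, k - 1) + U(l + 1, j - 1) + FB[k, l]
                                if cand < best:
                                    best = cand
                for h in range(i + 2, j):
                    if FM[i + 1, h - 1] < INF and FM1[h, j - 1] < INF:
                        cand = (
                            params.ml_a
                            + params.ml_b
                            + FM[i + 1, h - 1]
                            + FM1[h, j - 1]
                        )
                        if cand < best:
                            best = cand
                FB[i, j] = pseudo_p[i] + pseudo_p[j] + best
            best = INF
            for l in range(i + theta + 1, j + 1):
                if FB[i, l] < INF:
                    cand = FB[i, l] + params.ml_b + Um(l + 1, j)
                    if cand < best:
                        best = cand
            FM1[i, j] = best
            best = INF
            for k in range(i, j - theta):
                if FM1[k, j] < INF:
                    left = Um(i, k - 1)
                    if k - 1 >= i and FM[i, k - 1] < left:
                        left = FM[i, k - 1]
                    cand = left + FM1[k, j]
                    if cand < best:
                        best = cand
            FM[i, j] = best
            best = (F[i, j - 1] if j - 1 >= i else 0.0) + pseudo_u[j]
            for k in range(i, j - theta):
                if FB[k, j] < INF:
                    cand = (F[i, k - 1] if k - 1 >= i else 0.0) + FB[k, j]
                    if cand < best:
                        best = cand
            F[i, j] = best
    score = F[0, n - 1] if n > 0 else 0.0
    return score, F, FB, FM, FM1, U, Um, loops


_TRACE_TOL = 1e-6


def _traceback(seq, params, pseudo_u, pseudo_p, tabs) -> list[tuple[int, int]]:
    """Deterministic traceback (smallest split index wins on ties)."""
    n = len(seq)
    theta, max_loop = params.theta, params.max_loop
    score, F, FB, FM, FM1, U, Um, loops = tabs
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[int, int, str]] = [(0, n - 1, "F")] if n else []

    def close(a, b):
        return abs(a - b) <= _TRACE_TOL * (1.0 + abs(b))

    while stack:
        i, j, which = stack.pop()
        if i > j:
            continue
        if which == "F":
            target = F[i, j]
            found = False
            for k in range(i, j - theta):
                if FB[k, j] < INF:
                    left = F[i, k - 1] if k - 1 >= i else 0.0
                    if close(left + FB[k, j], target):
                        stack.append((i, k - 1, "F"))
                        stack.append((k, j, "B"))
                        found = True
                        break
            if not found:
                prev = (F[i, j - 1] if j - 1 >= i else 0.0) + pseudo_u[j]
                assert close(prev, target), "traceback failed in F"
                stack.append((i, j - 1, "F"))
        elif which == "B":
            pairs.append((i, j))
            target = FB[i, j] - pseudo_p[i] - pseudo_p[j]
            eh = loops.hairpin(i, j)
            if eh < INF and close(eh + U(i + 1, j - 1), target):
                continue
            found = False
            for k in range(i + 1, min(i + 2 + max_loop, j - 1)):
                n1 = k - i - 1
                lmin = max(k + theta + 1, j - 1 - (max_loop - n1))
                for l in range(lmin, j):
                    if FB[k, l] < INF:
                        ei = loops.internal(i, j, k, l)
                        if ei < INF and close(
                            ei + U(i + 1, k - 1) + U(l + 1, j - 1) + FB[k, l], target
                        ):
                            stack.append((k, l, "B"))
                            found = True
                            break
                if found:
                    break
            if found:
                continue
            for h in range(i + 2, j):
                if FM[i + 1, h - 1] < INF and FM1[h, j - 1] < INF:
                    cand = params.ml_a + params.ml_b + FM[i + 1, h - 1] + FM1[h, j - 1]
                    if close(cand, target):
                        stack.append((i + 1, h - 1, "M"))
                        stack.append((h, j - 1, "M1"))
                        found = True
                        break
            assert found, "traceback failed in B"
        elif which == "M1":
            target = FM1[i, j]
            for l in range(i + theta + 1, j + 1):
                if FB[i, l] < INF and close(
                    FB[i, l] + params.ml_b + Um(l + 1, j), target
                ):
                    stack.append((i, l, "B"))
                    break
            else:
                raise AssertionError("traceback failed in M1")
        else:  # M
            target = FM[i, j]
            found = False
            for k in range(i, j - theta):
                if FM1[k, j] < INF:
                    if close(Um(i, k - 1) + FM1[k, j], target):
                        stack.append((k, j, "M1"))
                        found = True
                        break
                    if k - 1 >= i and FM[i, k - 1] < INF and close(
                        FM[i, k - 1] + FM1[k, j], target
                    ):
                        stack.append((i, k - 1, "M"))
                        stack.append((k, j, "M1"))
                        found = True
                        break
            assert found, "traceback failed in M"
    return pairs


def weighted_mfe(
    seq: str,
    q: np.ndarray | None,
    beta: float,
    params: EnergyParams,
    *,
    stack_bonus: np.ndarray | None = None,
) -> MfeResult:
    """Structure minimizing E(S) + beta*d(S, q) (plain MFE when beta=0).

    The reported ``score`` is the minimized objective; ``energy`` is the
    Turner-energy component of the returned structure (for Deigan mode the
    score already contains the stack pseudo-energies and ``energy`` is the
    unmodified Turner part).
    """
    n = len(seq)
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if q is None or beta == 0.0:
        pseudo_u = np.zeros(n)
        pseudo_p = np.zeros(n)
    else:
        q = np.asarray(q, dtype=float)
        if np.isnan(q).any():
            raise ValueError("q contains missing values; resolve them first")
        pseudo_u = beta * (1.0 - q)
        pseudo_p = beta * q
    tabs = _mfe_tables(seq, params, pseudo_u, pseudo_p, stack_bonus)
    pairs = _traceback(seq, params, pseudo_u, pseudo_p, tabs)
    structure = SecondaryStructure(
        n=n, pairs=tuple(pairs), theta=params.theta, sequence=seq, severity="reject"
    )
    energy = score_structure(seq, structure, params)
    return MfeResult(structure=structure, score=float(tabs[0]), energy=energy)


# ----------------------------------------------------------------------
# per-structure scoring (loop decomposition; shared with the test oracle)


def score_structure(
    seq: str,
    structure: SecondaryStructure,
    params: EnergyParams,
    *,
    stack_bonus: np.ndarray | None = None,
) -> float:
    """Free energy E(S) of one structure under the loop model.

    Decomposes S into hairpin, internal/bulge/stack and multiloop terms,
    exactly mirroring the folding grammar.  With ``stack_bonus``, each helix
    stack additionally contributes the bonus of its four positions, so the
    positions interior to a helix are counted twice and isolated pairs
    contribute nothing — the Deigan stacking rule.
    """
    loops = _Loops(seq, params, stack_bonus)
    table = structure.pair_table
    total = 0.0
    for i, j in structure.pairs:
        children: list[tuple[int, int]] = []
        unpaired = 0
        k = i + 1
        while k < j:
            if table[k] > k:
                children.append((k, int(table[k])))
                k = int(table[k]) + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            total += hairpin_energy(seq, i, j, params)
        elif len(children) == 1:
            total += loops.internal(i, j, *children[0])
        else:
            total += params.ml_a + params.ml_b * (1 + len(children)) + params.ml_c * unpaired
    return total


# ----------------------------------------------------------------------
# Deigan comparison mode


def deigan_pseudo_energy(
    raw: np.ndarray | float,
    m: float = DEIGAN_SLOPE,
    b: float = DEIGAN_INTERCEPT,
) -> np.ndarray | float:
    """Stacking pseudo free energy m*ln(raw + 1) + b; missing (NaN) -> 0."""
    arr = np.asarray(raw, dtype=float)
    out = np.where(
        np.isnan(arr), 0.0, m * np.log1p(np.clip(arr, 0.0, None)) + b
    )
    return float(out) if np.isscalar(raw) else out


def fold_deigan(
    seq: str,
    raw: np.ndarray,
    params: EnergyParams,
    m: float = DEIGAN_SLOPE,
    b: float = DEIGAN_INTERCEPT,
) -> tuple[MfeResult, PartitionTables]:
    """MFE and partition function with the stacking pseudo-energy model.

    Takes *unnormalized* reactivities; each helix stack term acquires the
    pseudo energies of its four positions (interior helix positions thus
    count twice).  All position weights are 1: the tilt acts through the
    energy model only.
    """
    n = len(seq)
    bonus = deigan_pseudo_energy(np.asarray(raw, dtype=float), m, b)
    mfe = weighted_mfe(seq, None, 0.0, params, stack_bonus=bonus)
    tables = inside(
        seq, uniform_weights(n, params.RT), params, stack_bonus=bonus
    )
    return mfe, tables
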