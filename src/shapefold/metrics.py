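"""Diagnostics over the (weighted) Boltzmann ensemble.

These quantities summarize how well the ensemble agrees with probing data and
how variable it is:

* ``structure_distance`` d(S,q) = sum_i |x_i - q_i| — L1 disagreement between
  one structure's unpaired indicator and the data (a sum over positions, so
  values are of order n).
* ``expected_distance`` ED = E[d(S,q)] over the ensemble, computed in
  quadratic time from the unpaired probabilities:
  ED = sum_i [u_i (1-q_i) + (1-u_i) q_i].
* ``critical_distance`` d* = (RT/beta) ln(Z/Z'): structures closer to the data
  than d* gain probability under the soft-constraint tilt, farther ones lose.
* pointwise entropy (full partner distribution or binary paired/unpaired) and
  Morgan-Higgs structural diversity (expected base-pair distance between two
  independent draws from the ensemble).

Entropies are in nats (natural logarithm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fold import BasePairProbMatrix
from .structures import SecondaryStructure


def structure_distance(structure: SecondaryStructure, q: np.ndarray) -> float:
    """d(S, q) = sum_i |x_i - q_i| with x_i = 1 iff position i is unpaired."""
    q = np.asarray(q, dtype=float)
    if len(structure) != q.size:
        raise ValueError(
            f"structure has {len(structure)} positions but q has {q.size}"
        )
    return float(np.abs(structure.x - q).sum())


def _unpaired_vector(bpp) -> np.ndarray:
    if isinstance(bpp, BasePairProbMatrix):
        return bpp.unpaired
    arr = np.asarray(bpp, dtype=float)
    if arr.ndim == 2:
        return 1.0 - arr.sum(axis=1)
    return arr  # already an unpaired-probability vector


def expected_distance(bpp, q: np.ndarray) -> float:
    """Ensemble expectation of d(S, q), in O(n) from unpaired probabilities.

    ``bpp`` may be a :class:`BasePairProbMatrix`, a symmetric probability
    matrix, or directly the unpaired-probability vector (weighted or
    unweighted).  The same formula serves the unnormalized-reactivity
    variant: pass raw reactivities in place of ``q`` (missing entries NaN
    are skipped).
    """
    u = _unpaired_vector(bpp)
    q = np.asarray(q, dtype=float)
    if u.size != q.size:
        raise ValueError("length mismatch between ensemble and data")
    terms = u * (1.0 - q) + (1.0 - u) * q
    return float(np.nansum(terms))


def critical_distance(
    log_z: float,
    log_z_weighted: float,
    beta: float,
    RT: float,
    *,
    ed_unweighted: float | None = None,
) -> float:
    """d* = (RT/beta) ln(Z / Z').

    Satisfies the sign property P'(S) > P(S) iff d(S,q) < d*.  At beta = 0
    the expression is 0/0; its limit is the unweighted expected distance,
    returned if the caller supplies it.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0.0:
        if ed_unweighted is None:
            raise ValueError(
                "d* is undefined at beta=0; its limit equals the unweighted "
                "expected distance (pass ed_unweighted to obtain it)"
            )
        return float(ed_unweighted)
    return RT / beta * (log_z - log_z_weighted)


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    mask = p > 0.0
    out[mask] = p[mask] * np.log(p[mask])
    return out


def pointwise_entropy(
    bpp: BasePairProbMatrix, mode: str = "full"
) -> tuple[np.ndarray, float]:
    """Per-position Shannon entropy (nats) and its average.

    ``full``: outcomes of position i are its possible partners plus
    "unpaired".  ``binary``: outcomes are paired vs unpaired only.
    """
    p = bpp.p
    u = np.clip(bpp.unpaired, 0.0, 1.0)
    if mode == "full":
        h = -(_xlogx(p).sum(axis=1) + _xlogx(u))
    elif mode == "binary":
        h = -(_xlogx(u) + _xlogx(1.0 - u))
    else:
        raise ValueError(f"unknown entropy mode {mode!r}")
    h = np.maximum(h, 0.0)
    return h, float(h.mean())


def morgan_higgs_diversity(bpp: BasePairProbMatrix | np.ndarray) -> float:
    """Expected base-pair distance between two independent ensemble draws.

    D = 2 * sum_{i<j} p_ij (1 - p_ij); zero exactly when every pair
    probability is 0 or 1 (a deterministic ensemble).
    """
    p = bpp.p if isinstance(bpp, BasePairProbMatrix) else np.asarray(bpp, float)
    iu = np.triu_indices(p.shape[0], k=1)
    pij = p[iu]
    return float(2.0 * np.sum(pij * (1.0 - pij)))


@dataclass
class EnsembleReport:
    """Bundle of ensemble diagnostics for one folding run."""

    ed_weighted: float
    ed_unweighted: float
    d_star: float | None
    avg_entropy_full: float
    avg_entropy_binary: float
    avg_entropy_full_unweighted: float
    avg_entropy_binary_unweighted: float
    diversity: float
    diversity_unweighted: float
    log_z: float
    log_z_weighted: float
    entropy_full: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    entropy_binary: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    unpaired_weighted: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    unpaired_unweighted: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self, include_vectors: bool = True) -> dict:
        d = {
            "ED_weighted": self.ed_weighted,
            "ED_unweighted": self.ed_unweighted,
            "d_star": self.d_star,
            "avg_entropy_full": self.avg_entropy_full,
            "avg_entropy_binary": self.avg_entropy_binary,
            "avg_entropy_full_unweighted": self.avg_entropy_full_unweighted,
            "avg_entropy_binary_unweighted": self.avg_entropy_binary_unweighted,
            "diversity": self.diversity,
            "diversity_unweighted": self.diversity_unweighted,
            "logZ": self.log_z,
            "logZ_weighted": self.log_z_weighted,
        }
        if include_vectors:
            d["entropy_full"] = self.entropy_full
            d["entropy_binary"] = self.entropy_binary
            d["unpaired_weighted"] = self.unpaired_weighted
            d["unpaired_unweighted"] = self.unpaired_unweighted
        return d


def ensemble_report(
    bpp_weighted: BasePairProbMatrix,
    bpp_unweighted: BasePairProbMatrix,
    q: np.ndarray,
    log_z: float,
    log_z_weighted: float,
    beta: float,
    RT: float,
) -> EnsembleReport:
    """Assemble all diagnostics from weighted and unweighted ensembles."""
    ed_u = expected_distance(bpp_unweighted, q)
    ed_w = expected_distance(bpp_weighted, q)
    d_star = critical_distance(
        log_z, log_z_weighted, beta, RT, ed_unweighted=ed_u if beta == 0 else None
    )
    hf, hf_avg = pointwise_entropy(bpp_weighted, "full")
    hb, hb_avg = pointwise_entropy(bpp_weighted, "binary")
    _, hf0_avg = pointwise_entropy(bpp_unweighted, "full")
    _, hb0_avg = pointwise_entropy(bpp_unweighted, "binary")
    return EnsembleReport(
        ed_weighted=ed_w,
        ed_unweighted=ed_u,
        d_star=d_star,
        avg_entropy_full=hf_avg,
        avg_entropy_binary=hb_avg,
        avg_entropy_full_unweighted=hf0_avg,
        avg_entropy_binary_unweighted=hb0_avg,
        diversity=morgan_higgs_diversity(bpp_weighted),
        diversity_unweighted=morgan_higgs_diversity(bpp_unweighted),
        log_z=log_z,
        log_z_weighted=log_z_weighted,
        entropy_full=hf,
        entropy_binary=hb,
        unpaired_weighted=bpp_weighted.unpaired,
        unpaired_unweighted=bpp_unweighted.unpaired,
    )
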