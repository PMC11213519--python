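r"""Entropy Sorting mathematics for feature pairs.

Entropy Sorting treats a pair of minority-oriented features (a reference
feature RF and a query feature QF, where the QF is the one with the
larger minority cardinality) as a sortable arrangement.  The conditional
entropy of the QF given the RF, as a function of the overlap ``x``
between the two minority states, traces a concave curve (the "ES
parabola") that is maximised at the independence overlap

    x_me = m_rf * m_qf / n.

Two scalars summarise a pair:

* **ESS** (Entropy Sort Score) — a signed correlation in [-1, 1] built
  from the entropy gap ``G(x) = H(x_me) - H(x)``: it is 0 at
  independence, +1 when the overlap reaches its upper bound
  ``x_max = m_rf`` and -1 at the lower bound
  ``x_min = max(0, m_rf + m_qf - n)``.
* **EP** (Error Potential) — the exceedance of the observed deviation
  ``|x - x_me|`` over ``z`` standard deviations of the overlap under the
  independence (hypergeometric/permutation) null.  EP > 0 flags a pair
  whose co-occurrence is stronger than random chance explains.

Continuous activities in [0, 1] plug into the same formulas through
fractional cardinalities (column sums) and a product-t-norm overlap
``x = sum_i a_i * b_i``, whose permutation-null expectation is exactly
``m_rf * m_qf / n`` — so the discrete independence point is preserved.
On 0/1 vectors every quantity reduces exactly to the count-based binary
form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ActivityMatrix, ESMatrices
from .config import RunConfig

__all__ = [
    "PairConfiguration",
    "make_pair",
    "binary_entropy",
    "conditional_entropy",
    "ess",
    "error_potential",
    "null_overlap_sd",
    "classify_error_scenario",
    "pairwise_matrices",
    "RULE_TABLE",
]

_DEGENERATE_TOL = 1e-12
_BOUND_TOL = 1e-9


class DegeneratePairError(ValueError):
    """A pair with a zero minority cardinality cannot be entropy-sorted."""


@dataclass(frozen=True)
class PairConfiguration:
    """One feature pair's Entropy Sorting state.

    Cardinalities may be fractional (continuous activities); on binary
    vectors they are the minority-state counts.

    ``x_min``/``x_max`` are the structural overlap bounds of the
    underlying discrete problem; ``x_lo``/``x_hi`` are the bounds the
    product overlap can actually attain for the given value
    distributions — the rearrangement bounds ``sum(sorted(a) *
    sorted(b))`` and ``sum(sorted(a) * reversed(sorted(b)))``.  On 0/1
    vectors the attainable bounds coincide exactly with the structural
    ones; they are what the ESS is normalised against so that perfectly
    aligned continuous features score +1.
    """

    n: float
    m_rf: float
    m_qf: float
    x: float
    rf_index: int
    qf_index: int
    x_lo: float | None = None
    x_hi: float | None = None

    def __post_init__(self) -> None:
        if self.x_hi is None:
            object.__setattr__(self, "x_hi", self.x_max)
        if self.x_lo is None:
            object.__setattr__(self, "x_lo", self.x_min)

    @property
    def x_min(self) -> float:
        return max(0.0, self.m_rf + self.m_qf - self.n)

    @property
    def x_max(self) -> float:
        return self.m_rf

    @property
    def x_me(self) -> float:
        return self.m_rf * self.m_qf / self.n


def make_pair(
    a: np.ndarray,
    b: np.ndarray,
    index_a: int = 0,
    index_b: int = 1,
    overlap_operator: str = "product",
) -> PairConfiguration:
    """Build the :class:`PairConfiguration` for two activity vectors.

    The reference feature (RF) is the vector with the smaller minority
    cardinality; ties go to the lower gene index.  The overlap is the
    product t-norm ``sum(a * b)`` (default) or the fuzzy minimum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("activity vectors must be 1-D and of equal length")
    n = float(a.size)
    m_a, m_b = float(a.sum()), float(b.sum())
    if m_a <= 0 or m_b <= 0:
        raise DegeneratePairError("zero-cardinality activity vector")
    sa, sb = np.sort(a), np.sort(b)
    if overlap_operator == "product":
        x = float(a @ b)
        x_hi = float(sa @ sb)
        x_lo = float(sa @ sb[::-1])
    elif overlap_operator == "minimum":
        x = float(np.minimum(a, b).sum())
        x_hi = float(np.minimum(sa, sb).sum())
        x_lo = float(np.minimum(sa, sb[::-1]).sum())
    else:
        raise ValueError(f"unknown overlap operator {overlap_operator!r}")
    if m_a < m_b or (m_a == m_b and index_a <= index_b):
        m_rf, m_qf, rf, qf = m_a, m_b, index_a, index_b
    else:
        m_rf, m_qf, rf, qf = m_b, m_a, index_b, index_a
    return PairConfiguration(
        n=n, m_rf=m_rf, m_qf=m_qf, x=x, rf_index=rf, qf_index=qf,
        x_lo=x_lo, x_hi=x_hi,
    )


def binary_entropy(q) -> np.ndarray | float:
    """Shannon entropy of a Bernoulli(q) variable in bits; h(0)=h(1)=0."""
    q = np.asarray(q, dtype=float)
    q = np.clip(q, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.where(q > 0, q * np.log2(q), 0.0) - np.where(
            q < 1, (1 - q) * np.log2(1 - q), 0.0
        )
    return out if out.ndim else float(out)


def conditional_entropy(pc: PairConfiguration, x: float | None = None) -> float:
    """H(QF | RF) in bits at overlap ``x`` (defaults to the observed one).

    H(x) = (m_rf/n) h(x/m_rf) + ((n-m_rf)/n) h((m_qf-x)/(n-m_rf)).
    """
    if x is None:
        x = pc.x
    if x < pc.x_min - _BOUND_TOL or x > pc.x_max + _BOUND_TOL:
        raise ValueError(
            f"overlap {x} outside [{pc.x_min}, {pc.x_max}]"
        )
    x = min(max(x, pc.x_min), pc.x_max)
    n, m_rf, m_qf = pc.n, pc.m_rf, pc.m_qf
    h_in = binary_entropy(x / m_rf)
    rest = n - m_rf
    h_out = binary_entropy((m_qf - x) / rest) if rest > 0 else 0.0
    return (m_rf / n) * h_in + (rest / n) * h_out


def ess(pc: PairConfiguration) -> float:
    """Entropy Sort Score in [-1, 1].

    The entropy gap G(x) = H(x_me) - H(x) is normalised by its value at
    the attainable overlap bound on the observed side: +G(x)/G(x_hi)
    when x >= x_me, -G(x)/G(x_lo) otherwise.  On binary features the
    attainable bounds equal the structural ones (x_max, x_min), giving
    the count-based discrete score exactly.
    """
    h_me = conditional_entropy(pc, pc.x_me)
    x = min(max(pc.x, pc.x_min), pc.x_max)
    gap = h_me - conditional_entropy(pc, x)
    if x >= pc.x_me:
        norm = h_me - conditional_entropy(pc, pc.x_hi)
        sign = 1.0
    else:
        norm = h_me - conditional_entropy(pc, pc.x_lo)
        sign = -1.0
    if abs(norm) < _DEGENERATE_TOL:
        import warnings

        warnings.warn("degenerate ESS normaliser; returning 0", stacklevel=2)
        return 0.0
    return sign * min(max(gap, 0.0) / norm, 1.0)


def null_overlap_sd(n: float, m_rf: float, m_qf: float) -> float:
    """SD of the overlap under the independence (permutation) null.

    The closed-form hypergeometric SD, valid for fractional
    cardinalities: sqrt(m_rf m_qf (n-m_rf)(n-m_qf) / (n^2 (n-1))).
    """
    if n < 2:
        raise ValueError("need at least 2 samples for a null SD")
    return float(
        np.sqrt(m_rf * m_qf * (n - m_rf) * (n - m_qf) / (n * n * (n - 1)))
    )


def error_potential(pc: PairConfiguration, z: float = 1.0) -> float:
    """EP = |x - x_me| - z * sigma_0; positive iff the deviation from
    independence exceeds ``z`` null standard deviations."""
    sigma0 = null_overlap_sd(pc.n, pc.m_rf, pc.m_qf)
    return abs(pc.x - pc.x_me) - z * sigma0


# Scenario rule table.  2x2 contingency cells of a pair:
#   a = x (RF-minority & QF-minority overlap)
#   b = m_rf - x (RF-minority outside QF-minority)
#   c = m_qf - x (QF-minority outside RF-minority; RF-majority overlap)
#   d = n - m_rf - m_qf + x
# Divergence direction follows sign(x - x_me); the error cell is the
# off-diagonal cell whose samples would have to be mislabelled for the
# pair to reach a perfect sort.  Scenario 5 is the false-negative case:
# x above independence while RF-majority states still overlap the QF
# minority state (c > 0).
RULE_TABLE = {
    0: "nothing to repair: x = x_me, or both off-diagonal cells empty",
    1: "toward_min_sort, putative FPs in cell b (b < c)",
    2: "toward_min_sort, putative FPs in cell c (c <= b)",
    3: "toward_max_sort, putative FPs in cell b (c = 0, b < x)",
    4: "toward_max_sort, putative FPs in cell b (c = 0, b >= x)",
    5: "toward_max_sort, putative FNs in cell c (c > 0)",
}


def classify_error_scenario(pc: PairConfiguration, tol: float = 1e-9) -> dict:
    """Classify the pair's divergence into one of the five ES error
    scenarios (informational; EP is not modulated by the scenario).

    Returns ``{"id", "direction", "error_cell"}``; id 0 is the
    nothing-to-repair sentinel (at independence, or when the pair is
    already perfectly sorted so both off-diagonal cells are empty).
    """
    b = pc.m_rf - pc.x
    c = pc.m_qf - pc.x
    dev = pc.x - pc.x_me
    if abs(dev) <= tol:
        return {"id": 0, "direction": None, "error_cell": None}
    if dev > 0:
        if c > tol:
            return {"id": 5, "direction": "toward_max_sort", "error_cell": "c"}
        if b <= tol:  # perfectly sorted: no populated cell to repair
            return {"id": 0, "direction": "toward_max_sort", "error_cell": None}
        sid = 3 if b < pc.x else 4
        return {"id": sid, "direction": "toward_max_sort", "error_cell": "b"}
    if b < c:
        return {"id": 1, "direction": "toward_min_sort", "error_cell": "b"}
    return {"id": 2, "direction": "toward_min_sort", "error_cell": "c"}


# ---------------------------------------------------------------------------
# vectorised all-pairs computation


def _entropy_curve(x, n, m_rf, m_qf):
    """Vectorised H(x) for broadcastable arrays of configurations."""
    rest = n - m_rf
    h_in = binary_entropy(np.divide(x, m_rf, out=np.zeros_like(x), where=m_rf > 0))
    frac_out = np.divide(m_qf - x, rest, out=np.zeros_like(x), where=rest > 0)
    h_out = binary_entropy(frac_out)
    return (m_rf / n) * h_in + (rest / n) * h_out


def _pair_block(A: np.ndarray, B: np.ndarray, As: np.ndarray, Bs: np.ndarray, z: float):
    """ESS and EP for every (column of A) x (column of B) pair.

    A is cells x p, B is cells x q; ``As``/``Bs`` are the same matrices
    with each column sorted ascending (for the rearrangement overlap
    bounds).  Returns (p x q, p x q) arrays.
    """
    n = float(A.shape[0])
    m_a = A.sum(axis=0)[:, None]
    m_b = B.sum(axis=0)[None, :]
    x = A.T @ B
    x_hi = As.T @ Bs
    x_lo = As.T @ Bs[::-1]
    m_rf = np.minimum(m_a, m_b)
    m_qf = np.maximum(m_a, m_b)
    x_min = np.maximum(0.0, m_rf + m_qf - n)
    x_max = m_rf
    x_me = m_rf * m_qf / n
    x = np.clip(x, x_min, x_max)
    x_hi = np.clip(x_hi, x_me, x_max)
    x_lo = np.clip(x_lo, x_min, x_me)

    h_me = _entropy_curve(x_me, n, m_rf, m_qf)
    gap = h_me - _entropy_curve(x, n, m_rf, m_qf)
    gap = np.maximum(gap, 0.0)
    up = x >= x_me
    norm_up = h_me - _entropy_curve(x_hi, n, m_rf, m_qf)
    norm_dn = h_me - _entropy_curve(x_lo, n, m_rf, m_qf)
    norm = np.where(up, norm_up, norm_dn)
    sign = np.where(up, 1.0, -1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ess_block = np.where(
            np.abs(norm) < _DEGENERATE_TOL, 0.0, sign * np.minimum(gap / norm, 1.0)
        )

    sigma0 = np.sqrt(m_rf * m_qf * (n - m_rf) * (n - m_qf) / (n * n * (n - 1)))
    ep_block = np.abs(x - x_me) - z * sigma0
    return ess_block, ep_block


def pairwise_matrices(act: ActivityMatrix, config: RunConfig | None = None) -> ESMatrices:
    """Compute the full gene x gene ESS and EP matrices from M_m.

    Work proceeds in fixed-size column chunks so peak memory stays
    O(j * chunk); the result is independent of the chunking.  All genes
    must have a strictly positive cardinality (guaranteed by activity
    normalisation with ``min_cells_expressing >= 1``).
    """
    if config is None:
        config = RunConfig()
    V = act.values.to_numpy(dtype=float)
    j = V.shape[1]
    if j < 2:
        raise ValueError("need at least 2 genes for pairwise matrices")
    est_gb = 3 * j * j * 8 / 1e9
    if est_gb > config.memory_cap_gb:
        raise MemoryError(
            f"{j} genes would need ~{est_gb:.1f} GB for ESS/EP/dEPs matrices "
            f"(cap {config.memory_cap_gb} GB); pre-filter genes (e.g. by "
            "variance or min_cells_expressing) or raise memory_cap_gb"
        )
    if config.overlap_operator != "product":
        return _pairwise_scalar(act, config)
    Vs = np.sort(V, axis=0)
    ess_m = np.empty((j, j))
    ep_m = np.empty((j, j))
    step = max(1, int(config.chunk_size))
    for start in range(0, j, step):
        stop = min(start + step, j)
        e_blk, p_blk = _pair_block(
            V[:, start:stop], V, Vs[:, start:stop], Vs, config.ep_z
        )
        ess_m[start:stop, :] = e_blk
        ep_m[start:stop, :] = p_blk
    # exact symmetry regardless of floating-point summation order
    ess_m = (ess_m + ess_m.T) / 2.0
    ep_m = (ep_m + ep_m.T) / 2.0
    np.fill_diagonal(ess_m, 1.0)
    deps = np.maximum(ep_m, 0.0)
    np.fill_diagonal(deps, 0.0)
    genes = act.gene_ids
    return ESMatrices(
        ess=pd.DataFrame(ess_m, index=genes, columns=genes),
        ep=pd.DataFrame(ep_m, index=genes, columns=genes),
        deps=pd.DataFrame(deps, index=genes, columns=genes),
    )


def _pairwise_scalar(act: ActivityMatrix, config: RunConfig) -> ESMatrices:
    """Scalar fallback used for the non-default overlap operator."""
    V = act.values.to_numpy(dtype=float)
    j = V.shape[1]
    ess_m = np.eye(j)
    ep_m = np.zeros((j, j))
    for i in range(j):
        for k in range(i + 1, j):
            pc = make_pair(V[:, i], V[:, k], i, k, config.overlap_operator)
            ess_m[i, k] = ess_m[k, i] = ess(pc)
            ep_m[i, k] = ep_m[k, i] = error_potential(pc, config.ep_z)
    deps = np.maximum(ep_m, 0.0)
    np.fill_diagonal(deps, 0.0)
    genes = act.gene_ids
    return ESMatrices(
        ess=pd.DataFrame(ess_m, index=genes, columns=genes),
        ep=pd.DataFrame(ep_m, index=genes, columns=genes),
        deps=pd.DataFrame(deps, index=genes, columns=genes),
    )
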