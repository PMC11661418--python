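"""Per-stratum optimal matching of treated and untreated patients.

Within each prognostic stratum the smaller treatment arm is labelled A and
the larger B, distances are root-sum-square differences of covariates
normalized over the pooled stratum members, and one of three exact
formulations selects which pairs (and hence which patients) enter the
matched training set:

``equalized``
    minimize total distance, each patient used at most once, exactly
    ``alpha`` pairs per stratum — every stratum contributes the same
    number of patients per arm.
``exact_one_to_one``
    every A-patient matched to exactly one distinct B-patient (used when
    the stratum is too small to afford discarding A-patients).
``relaxed``
    each patient may be used up to twice (matching with replacement),
    exactly ``alpha`` pairs — trades duplicate rows for smaller total
    distance.

All three are solved to *global* optimality: the capacity-1 problems via
the rectangular assignment algorithm (with zero-profit dummy columns
enforcing the pair quota), the relaxed problem as a bipartite-flow LP
whose basic optima are integral. A brute-force enumerator provides the
independent optimum for small instances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linear_sum_assignment, linprog, milp
from scipy.spatial.distance import cdist

from .cohort import Cohort, EncodedCohort, encode

logger = logging.getLogger(__name__)

FORMULATIONS = ("equalized", "exact_one_to_one", "relaxed")
_LEXI_LIMIT = 64  # apply lexicographic tie-break perturbation up to this |A|*|B|


class MatchingError(ValueError):
    """Infeasible or malformed matching instance."""


@dataclass
class MatchingInstance:
    """One stratum's bipartite distance problem (A = smaller arm)."""

    stratum_index: int
    A_ids: np.ndarray
    B_ids: np.ndarray
    D: np.ndarray
    alpha: int

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        self.A_ids = np.asarray(self.A_ids)
        self.B_ids = np.asarray(self.B_ids)
        if self.D.shape != (len(self.A_ids), len(self.B_ids)):
            raise MatchingError("distance matrix shape mismatch")
        if self.m > self.n_B:
            raise MatchingError("A must be the smaller (or equal) arm")
        if not np.isfinite(self.D).all() or (self.D < 0).any():
            raise MatchingError("distances must be finite and nonnegative")

    @property
    def m(self) -> int:
        return len(self.A_ids)

    @property
    def n_B(self) -> int:
        return len(self.B_ids)


@dataclass
class MatchSolution:
    """Selected pair multiset for one stratum."""

    pairs: list  # (i in A, j in B) index pairs, each with multiplicity 1
    formulation: str
    total_distance: float
    a_counts: np.ndarray  # per-A-patient match counts
    b_counts: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class MatchedCohorts:
    """Matched untreated/treated row multisets with per-stratum provenance."""

    untreated: Cohort
    treated: Cohort
    provenance: pd.DataFrame  # columns: stratum, untreated_id, treated_id, distance

    @property
    def n_pairs(self) -> int:
        return len(self.provenance)


def normalize_covariates(members: EncodedCohort | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Standardize columns over the pooled stratum members.

    Uses the sample SD (denominator n-1); zero-variance columns map to 0 so
    they contribute nothing to any distance.
    """
    if isinstance(members, EncodedCohort):
        Z = members.Z.to_numpy(dtype=float)
    else:
        Z = np.asarray(members, dtype=float)
    if Z.shape[0] < 2:
        raise MatchingError("need >= 2 stratum members to normalize")
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    out = np.zeros_like(Z)
    ok = sd > 0
    out[:, ok] = (Z[:, ok] - mean[ok]) / sd[ok]
    return out


def compute_distance_matrix(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between normalized covariate vectors."""
    norm_a, norm_b = np.atleast_2d(norm_a), np.atleast_2d(norm_b)
    if norm_a.shape[1] != norm_b.shape[1]:
        raise MatchingError("covariate dimension mismatch between arms")
    return cdist(norm_a, norm_b, metric="euclidean")


def _lexi_costs(D: np.ndarray) -> np.ndarray:
    """Subtract a geometric reward so earlier (i, j) pairs win exact ties.

    Applied only on small instances where the total reward is provably
    below any nonzero optimality gap of interest; large instances rely on
    the deterministic solver instead.
    """
    m, n = D.shape
    if m * n > _LEXI_LIMIT:
        return D
    scale = max(D.max(), 1.0)
    ranks = (np.arange(m)[:, None] * n + np.arange(n)).astype(float)
    return D - 1e-9 * scale * np.power(0.5, ranks)


def _solution_from_pairs(inst: MatchingInstance, pairs, formulation: str) -> MatchSolution:
    pairs = sorted(pairs)
    a_counts = np.zeros(inst.m, dtype=int)
    b_counts = np.zeros(inst.n_B, dtype=int)
    total = 0.0
    for i, j in pairs:
        a_counts[i] += 1
        b_counts[j] += 1
        total += inst.D[i, j]
    return MatchSolution(
        pairs=pairs,
        formulation=formulation,
        total_distance=float(total),
        a_counts=a_counts,
        b_counts=b_counts,
    )


def solve_equalized_matching(inst: MatchingInstance) -> MatchSolution:
    """Minimum-distance matching with exactly ``alpha`` pairs, capacities 1.

    Because distances are nonnegative, the optimum of the >= alpha
    formulation selects exactly alpha pairs; the quota is enforced by
    augmenting the cost matrix with ``m - alpha`` strictly profitable dummy
    columns that absorb the unmatched A-patients.
    """
    alpha = inst.alpha
    if alpha < 0:
        raise MatchingError("alpha must be nonnegative")
    if alpha == 0:
        return _solution_from_pairs(inst, [], "equalized")
    if inst.m < alpha or inst.n_B < alpha:
        raise MatchingError(
            f"equalized matching infeasible: need alpha={alpha} patients per arm "
            f"(have {inst.m}, {inst.n_B}); use exact_one_to_one for small strata"
        )
    C = _lexi_costs(inst.D)
    n_dummy = inst.m - alpha
    if n_dummy:
        # dummy cost below any real cost => all dummies used => alpha real pairs
        dummy = np.full((inst.m, n_dummy), C.min() - 1.0)
        C = np.hstack([C, dummy])
    rows, cols = linear_sum_assignment(C)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if j < inst.n_B]
    assert len(pairs) == alpha
    return _solution_from_pairs(inst, pairs, "equalized")


def solve_exact_one_to_one(inst: MatchingInstance) -> MatchSolution:
    """Match every A-patient to exactly one distinct B-patient, minimum total."""
    if inst.m > inst.n_B:
        raise MatchingError("exact 1-1 matching needs |A| <= |B|")
    if inst.m == 0:
        return _solution_from_pairs(inst, [], "exact_one_to_one")
    rows, cols = linear_sum_assignment(_lexi_costs(inst.D))
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols)]
    return _solution_from_pairs(inst, pairs, "exact_one_to_one")


def solve_relaxed_matching(inst: MatchingInstance) -> MatchSolution:
    """Minimum-distance selection of exactly ``alpha`` pairs, capacities 2.

    Solved as an LP over the bipartite-flow polytope (row/column sums <= 2,
    cardinality row = alpha, variables in [0,1]); basic optima of this
    polytope are integral, which is asserted, with an exact MILP fallback.
    """
    alpha = inst.alpha
    if alpha < 0:
        raise MatchingError("alpha must be nonnegative")
    if alpha == 0:
        return _solution_from_pairs(inst, [], "relaxed")
    if 2 * min(inst.m, inst.n_B) < alpha:
        raise MatchingError(
            f"relaxed matching infeasible: capacity 2*min(m, n)={2*min(inst.m, inst.n_B)}"
            f" < alpha={alpha}"
        )
    m, n = inst.m, inst.n_B
    c = _lexi_costs(inst.D).ravel()
    row_caps = sp.kron(sp.eye(m, format="csr"), sp.csr_matrix(np.ones((1, n))), format="csr")
    col_caps = sp.kron(sp.csr_matrix(np.ones((1, m))), sp.eye(n, format="csr"), format="csr")
    A_ub = sp.vstack([row_caps, col_caps], format="csr")
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.full(m + n, 2.0),
        A_eq=sp.csr_matrix(np.ones((1, m * n))),
        b_eq=[float(alpha)],
        bounds=(0.0, 1.0),
        method="highs-ds",
    )
    if res.status != 0:
        raise MatchingError(f"relaxed matching LP failed: {res.message}")
    z = res.x
    if np.abs(z - np.round(z)).max() > 1e-6:  # non-basic/fractional vertex
        z = _relaxed_milp(c, A_ub, m, n, alpha)
    z = np.round(z).astype(int).reshape(m, n)
    pairs = [(int(i), int(j)) for i, j in zip(*np.nonzero(z))]
    assert len(pairs) == alpha
    return _solution_from_pairs(inst, pairs, "relaxed")


def _relaxed_milp(c, A_ub, m, n, alpha):
    cons = [
        LinearConstraint(A_ub, -np.inf, np.full(m + n, 2.0)),
        LinearConstraint(sp.csr_matrix(np.ones((1, m * n))), alpha, alpha),
    ]
    res = milp(c, constraints=cons, bounds=Bounds(0, 1), integrality=np.ones(m * n))
    if res.status != 0:
        raise MatchingError(f"relaxed matching MILP failed: {res.message}")
    return res.x


_SOLVERS = {
    "equalized": solve_equalized_matching,
    "exact_one_to_one": solve_exact_one_to_one,
    "relaxed": solve_relaxed_matching,
}


def solve(inst: MatchingInstance, formulation: str) -> MatchSolution:
    if formulation not in _SOLVERS:
        raise MatchingError(f"unknown formulation {formulation!r}")
    return _SOLVERS[formulation](inst)


def brute_force_matching_oracle(inst: MatchingInstance, formulation: str) -> MatchSolution:
    """Exhaustive global optimum for small instances (test oracle).

    Enumerates every feasible 0/1 pair-selection respecting the
    formulation's capacities and cardinality; independent of the solvers.
    """
    if inst.m * inst.n_B > 36:
        raise MatchingError("oracle limited to |A|*|B| <= 36")
    if formulation == "exact_one_to_one":
        cardinality, cap = inst.m, 1
    elif formulation == "equalized":
        if inst.m < inst.alpha or inst.n_B < inst.alpha:
            raise MatchingError("equalized oracle infeasible")
        cardinality, cap = inst.alpha, 1
    elif formulation == "relaxed":
        if 2 * min(inst.m, inst.n_B) < inst.alpha:
            raise MatchingError("relaxed oracle infeasible")
        cardinality, cap = inst.alpha, 2
    else:
        raise MatchingError(f"unknown formulation {formulation!r}")
    if cardinality == 0:
        return _solution_from_pairs(inst, [], formulation)
    m, n = inst.m, inst.n_B
    d = inst.D.ravel()
    best, best_total = None, np.inf
    combo_iter = itertools.combinations(range(m * n), cardinality)
    while True:
        chunk = list(itertools.islice(combo_iter, 500_000))
        if not chunk:
            break
        combos = np.asarray(chunk, dtype=np.int64)
        rows = combos // n  # nondecreasing along axis 1 (lexicographic combos)
        cols = np.sort(combos % n, axis=1)
        feasible = np.ones(len(combos), dtype=bool)
        # a value occurring > cap times in a sorted row <=> equal entries cap apart
        for mat in (rows, cols):
            for k in range(cardinality - cap):
                feasible &= mat[:, k] != mat[:, k + cap]
        if not feasible.any():
            continue
        totals = d[combos].sum(axis=1)
        totals[~feasible] = np.inf
        k = int(np.argmin(totals))
        if totals[k] < best_total:
            best, best_total = combos[k], totals[k]
    if best is None:
        raise MatchingError("no feasible selection found")
    return _solution_from_pairs(
        inst, [(int(p) // n, int(p) % n) for p in best], formulation
    )


def build_matching_instance(
    cohort: Cohort,
    stratum_members: np.ndarray,
    stratum_index: int,
    alpha: int,
    encoded: EncodedCohort = None,
) -> Optional[MatchingInstance]:
    """Assemble one stratum's instance: arm split, pooled normalization, distances.

    Returns ``None`` (with a warning) when one arm of the stratum is empty —
    such strata yield no matched pairs.
    """
    if encoded is None:
        encoded = encode(cohort)
    members = np.asarray(stratum_members, dtype=int)
    a = cohort.a[members]
    untreated = members[a == 0]
    treated = members[a == 1]
    if len(untreated) == 0 or len(treated) == 0:
        logger.warning(
            "stratum %d has an empty arm (untreated=%d, treated=%d); no pairs",
            stratum_index,
            len(untreated),
            len(treated),
        )
        return None
    norm = np.zeros((cohort.n, encoded.K))
    norm[members] = normalize_covariates(encoded.Z.to_numpy(dtype=float)[members])
    # A = smaller arm; ties go to the untreated side for determinism
    if len(untreated) <= len(treated):
        A_rows, B_rows = untreated, treated
    else:
        A_rows, B_rows = treated, untreated
    D = compute_distance_matrix(norm[A_rows], norm[B_rows])
    return MatchingInstance(
        stratum_index=stratum_index, A_ids=A_rows, B_ids=B_rows, D=D, alpha=alpha
    )


def match_stratified_cohort(
    cohort: Cohort,
    assignment,
    variant: str = "equalized",
    encoded: EncodedCohort = None,
) -> MatchedCohorts:
    """Run the per-stratum dispatch and assemble the matched cohorts.

    Strata whose smaller arm holds at most ``alpha`` patients are matched
    exactly 1-1 (no discarding from the minority); larger strata use the
    configured ``variant`` with the global quota ``alpha``. Both endpoints
    of every selected pair enter the matched training multisets.
    """
    if variant not in ("equalized", "relaxed"):
        raise MatchingError("variant must be 'equalized' or 'relaxed'")
    if encoded is None:
        encoded = encode(cohort)
    alpha = assignment.alpha
    strata = np.asarray(assignment.stratum)
    untreated_rows, treated_rows, records = [], [], []
    for s in range(1, assignment.n_strata + 1):
        members = np.flatnonzero(strata == s)
        if len(members) == 0:
            continue
        inst = build_matching_instance(cohort, members, s, alpha, encoded)
        if inst is None:
            continue
        formulation = "exact_one_to_one" if inst.m <= alpha else variant
        try:
            sol = solve(inst, formulation)
        except MatchingError as exc:
            raise MatchingError(f"stratum {s}: {exc}") from exc
        logger.info(
            "stratum %d: m=%d, n=%d -> %s, %d pairs",
            s,
            inst.m,
            inst.n_B,
            formulation,
            sol.n_pairs,
        )
        for i, j in sol.pairs:
            row_a, row_b = int(inst.A_ids[i]), int(inst.B_ids[j])
            row_u, row_t = (
                (row_a, row_b) if cohort.a[row_a] == 0 else (row_b, row_a)
            )
            untreated_rows.append(row_u)
            treated_rows.append(row_t)
            records.append(
                {
                    "stratum": s,
                    "formulation": formulation,
                    "untreated_id": cohort.ids[row_u],
                    "treated_id": cohort.ids[row_t],
                    "distance": inst.D[i, j],
                }
            )
    provenance = pd.DataFrame(
        records, columns=["stratum", "formulation", "untreated_id", "treated_id", "distance"]
    )
    return MatchedCohorts(
        untreated=cohort.take(untreated_rows),
        treated=cohort.take(treated_rows),
        provenance=provenance,
    )


def oversample(matched: MatchedCohorts, factor: int) -> MatchedCohorts:
    """Replicate every matched row ``factor`` times (distinct census unchanged)."""
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise MatchingError("oversampling factor must be an integer >= 1")
    if factor == 1:
        return matched
    idx_u = np.repeat(np.arange(matched.untreated.n), factor)
    idx_t = np.repeat(np.arange(matched.treated.n), factor)
    prov = matched.provenance.loc[
        np.repeat(matched.provenance.index.to_numpy(), factor)
    ].reset_index(drop=True)
    return MatchedCohorts(
        untreated=matched.untreated.take(idx_u),
        treated=matched.treated.take(idx_t),
        provenance=prov,
    )
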