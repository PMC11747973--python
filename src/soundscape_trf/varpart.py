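"""Variance partitioning of encoding-model performance.

Prediction correlations are converted to explained variance R^2 (signed
square, so anti-correlated predictions cannot masquerade as explained
variance) and decomposed set-theoretically: the intersection of two models is
A + B - (A u B), extended by inclusion-exclusion to three models. Because
the R^2 terms are estimates, the raw decomposition can go negative; a
post-hoc bias estimator restores the set-theoretic constraint that every
partition term is at least zero, by the smallest uniform subtraction from
the (overfitting-inflated) union-model terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def r2_from_score(r: float) -> float:
    """Signed square: R^2 = sign(r) * r^2."""
    r = np.asarray(r, float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlation must lie in [-1, 1]")
    out = np.sign(r) * r**2
    return float(out) if out.ndim == 0 else out


def partition_two(r2_a: float, r2_b: float, r2_ab: float) -> tuple[float, float, float]:
    """Two-set decomposition: (unique_A, unique_B, shared_AB).

    shared = A + B - (A u B); unique_A = (A u B) - B; unique_B = (A u B) - A.
    The three terms sum to A u B exactly. Negative terms are allowed here and
    handled by ``bias_correct``.
    """
    shared = r2_a + r2_b - r2_ab
    unique_a = r2_ab - r2_b
    unique_b = r2_ab - r2_a
    return unique_a, unique_b, shared


@dataclass
class PartitionTable:
    """Full three-set decomposition (R^2 units) with the bias term."""

    totals: dict  # model -> total R^2 (A, B, C)
    unions: dict  # "AB", "AC", "BC", "ABC" -> R^2 of the joint models
    uniques: dict  # model -> unique R^2
    pairwise: dict  # "AB", "AC", "BC" -> intersection R^2
    triple: float
    bias: float = 0.0

    def terms(self) -> dict:
        out = {f"unique_{k}": v for k, v in self.uniques.items()}
        out.update({f"shared_{k}": v for k, v in self.pairwise.items()})
        out["shared_ABC"] = self.triple
        return out


def partition_three(
    r2_singles: tuple[float, float, float],
    r2_pair_unions: tuple[float, float, float],
    r2_full_union: float,
) -> PartitionTable:
    """Three-set decomposition from single and joint model R^2 values.

    Arguments follow (A, B, C), (A u B, A u C, B u C), A u B u C. The triple
    intersection is A u B u C + A + B + C - (A u B) - (B u C) - (A u C);
    pairwise intersections are A + B - (A u B) etc.; uniques follow
    inclusion-exclusion, e.g. unique_A = A - (A n B) - (A n C) + (A n B n C).
    """
    a, b, c = (float(v) for v in r2_singles)
    uab, uac, ubc = (float(v) for v in r2_pair_unions)
    uabc = float(r2_full_union)
    triple = uabc + a + b + c - uab - ubc - uac
    iab = a + b - uab
    iac = a + c - uac
    ibc = b + c - ubc
    uniques = {
        "A": a - iab - iac + triple,
        "B": b - iab - ibc + triple,
        "C": c - iac - ibc + triple,
    }
    return PartitionTable(
        totals={"A": a, "B": b, "C": c},
        unions={"AB": uab, "AC": uac, "BC": ubc, "ABC": uabc},
        uniques=uniques,
        pairwise={"AB": iab, "AC": iac, "BC": ibc},
        triple=triple,
    )


def bias_correct(partition) -> "PartitionTable | tuple":
    """Restore nonnegativity by the smallest-magnitude uniform subtraction b
    from every union-model R^2 (the overfitting-inflated terms).

    For a two-set partition pass (r2_a, r2_b, r2_ab); a corrected
    (unique_A, unique_B, shared, b) tuple is returned. For a three-set
    ``PartitionTable`` a corrected table with its ``bias`` is returned.
    b = 0 whenever the raw partition is already nonnegative; infeasible
    constraint systems raise with the binding constraint named.
    """
    if isinstance(partition, PartitionTable):
        return _bias_correct_three(partition)
    r2_a, r2_b, r2_ab = partition
    # terms as functions of b: shared(b) = A+B-(AuB-b), unique_A(b) = (AuB-b)-B
    ua0, ub0, sh0 = partition_two(r2_a, r2_b, r2_ab)
    lo = -sh0  # shared >= 0 needs b >= -shared
    hi = min(ua0, ub0)  # uniques >= 0 cap b from above
    if lo > hi + 1e-12:
        raise ValueError(
            f"no feasible bias: shared needs b >= {lo:.4g} but "
            f"unique terms cap b at {hi:.4g}"
        )
    # smallest magnitude adjustment; b < 0 (adding back to the union) occurs
    # when the joint model underfits and a unique term goes negative
    b = float(np.clip(0.0, lo, hi))
    ua, ub, sh = partition_two(r2_a, r2_b, r2_ab - b)
    return ua, ub, sh, b


def _bias_correct_three(table: PartitionTable) -> PartitionTable:
    # Uniform subtraction of b from each union term (AB, AC, BC, ABC):
    # pairwise intersections gain +b, the triple gains +2b (three pairwise
    # subtractions against one full-union subtraction), uniques are invariant.
    neg_unique = {k: v for k, v in table.uniques.items() if v < -1e-12}
    if neg_unique:
        k = min(neg_unique, key=neg_unique.get)
        raise ValueError(
            f"no feasible bias: unique_{k} = {neg_unique[k]:.4g} is negative "
            "and invariant under uniform union subtraction"
        )
    b = max(
        0.0,
        -min(table.pairwise.values()),
        -table.triple / 2.0,
    )
    corrected = partition_three(
        tuple(table.totals[k] for k in ("A", "B", "C")),
        tuple(table.unions[k] - b for k in ("AB", "AC", "BC")),
        table.unions["ABC"] - b,
    )
    corrected.bias = float(b)
    return corrected


def reconstruct_union(table: PartitionTable, models=("A", "B", "C")) -> float:
    """Inclusion-exclusion reconstruction of a union from partition terms
    (guards the identities; exact to floating-point round-off)."""
    models = set(models)
    # Venn regions: uniques, exclusive pairwise (pairwise - triple), triple.
    # A region belongs to the union iff its label set intersects `models`.
    total = sum(v for k, v in table.uniques.items() if k in models)
    for key, v in table.pairwise.items():
        if models & set(key):
            total += v - table.triple
    total += table.triple
    return total
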