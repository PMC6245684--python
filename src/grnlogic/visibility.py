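"""Exhaustive visibility statistics over the non-degenerate search space.

All probabilities are computed with exact integer arithmetic (fractions) and
exposed as floats; the exact values are kept on the result object.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from grnlogic.boolean_space import enumerate_search_space
from grnlogic.spsd import (
    Integration,
    Regime,
    fully_visible_matrix,
    visible_out_degree_matrix,
)

__all__ = [
    "VisibilityResult",
    "visibility_probability",
    "full_visibility_by_state",
    "full_visibility_probability",
    "visibility_result",
]


def _degree_matrix(
    k: int,
    regime: Regime | str,
    integration: Integration | str,
    indices: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    if indices is None:
        indices = enumerate_search_space(k).index_array()
    return visible_out_degree_matrix(k, indices, regime, integration), len(indices)


def visibility_probability(
    k: int,
    regime: Regime | str,
    integration: Integration | str,
    indices: np.ndarray | None = None,
) -> Fraction:
    """Average fraction of visible transition edges over functions and states.

    The per-function fraction divides the visible out-degrees summed over all
    states by the total edge count k' * 2**k (k' = k/2 under knock-down only,
    k under both perturbations); the result averages this over the search
    space. Restricting ``indices`` (e.g. to a single function) yields the
    per-function diagnostic instead of the population value.
    """
    regime = Regime.parse(regime)
    degrees, n_funcs = _degree_matrix(k, regime, integration, indices)
    total_edges = (k << k) // (2 if regime is Regime.D else 1)  # k' * 2**k
    return Fraction(int(degrees.sum()), n_funcs * total_edges)


def full_visibility_by_state(
    k: int,
    regime: Regime | str,
    integration: Integration | str,
    indices: np.ndarray | None = None,
) -> dict[int, Fraction]:
    """P_fv,s: fraction of functions whose state ``s`` is fully visible.

    Full visibility means every regulator's effect is evidenced: k visible
    perturbation edges under transcriptome-only or +PPI integration, and
    unconditionally under full cis-element (+PPI) knowledge.
    """
    if indices is None:
        indices = enumerate_search_space(k).index_array()
    fully = fully_visible_matrix(k, indices, regime, integration)
    counts = fully.sum(axis=0)
    return {s: Fraction(int(counts[s]), len(indices)) for s in range(1 << k)}


def full_visibility_probability(
    k: int,
    regime: Regime | str,
    integration: Integration | str,
    indices: np.ndarray | None = None,
) -> Fraction:
    """P_fv: mean of P_fv,s over all 2**k states."""
    by_state = full_visibility_by_state(k, regime, integration, indices)
    return sum(by_state.values(), Fraction(0)) / (1 << k)


@dataclass(frozen=True)
class VisibilityResult:
    k: int
    regime: Regime
    integration: Integration
    P_v: float
    P_fv: float
    P_fv_by_state: dict[int, float]
    exact_P_v: Fraction
    exact_P_fv: Fraction

    def to_record(self) -> dict:
        return {
            "k": self.k,
            "regime": self.regime.value,
            "integration": self.integration.value,
            "P_v": self.P_v,
            "P_fv": self.P_fv,
            "P_fv_by_state": {str(s): v for s, v in self.P_fv_by_state.items()},
        }


def visibility_result(
    k: int, regime: Regime | str, integration: Integration | str
) -> VisibilityResult:
    """Bundle P_v, P_fv and the per-state table for one analysis setting."""
    regime = Regime.parse(regime)
    integration = Integration.parse(integration)
    p_v = visibility_probability(k, regime, integration)
    by_state = full_visibility_by_state(k, regime, integration)
    p_fv = sum(by_state.values(), Fraction(0)) / (1 << k)
    return VisibilityResult(
        k=k,
        regime=regime,
        integration=integration,
        P_v=float(p_v),
        P_fv=float(p_fv),
        P_fv_by_state={s: float(v) for s, v in by_state.items()},
        exact_P_v=p_v,
        exact_P_fv=p_fv,
    )
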