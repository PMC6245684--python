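"""Ambiguity of Boolean-function identification from perturbation experiments.

A perturbation step applied at an initial state observes the target output at
that state and at every state reachable by a single available perturbation.
The functions of the search space agreeing with all observed (state, output)
pairs are the candidates; their number ``N_cmn`` measures the ambiguity and
1/N_cmn the chance of picking the true function. Averaging 1/N_cmn over all
functions and all fully visible initial states gives the unambiguity
probability ``P_ua``; multi-step experiments extend the observations along a
path of initial states and the analysis optimistically takes the
least-ambiguous path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from itertools import combinations

import numpy as np

from grnlogic.boolean_space import (
    BooleanFunction,
    SearchSpace,
    enumerate_search_space,
    input_bit_mask,
)
from grnlogic.spsd import (
    Integration,
    Regime,
    _edge_targets,
    fully_visible_matrix,
)

__all__ = [
    "ObservationSet",
    "PerturbationPath",
    "StepResult",
    "AmbiguityResult",
    "observations_from_step",
    "consistent_count",
    "consistent_indices",
    "min_common_counts",
    "unambiguity_probability",
    "mean_common_count",
    "ratio_tables",
]


class InconsistentObservationError(ValueError):
    """Two observations assign different outputs to the same input state."""


@dataclass(frozen=True)
class ObservationSet:
    """A partial truth assignment: observed input states and their outputs."""

    k: int
    observed: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_states = 1 << self.k
        for s, v in self.observed.items():
            if not 0 <= s < n_states:
                raise ValueError(f"state {s} out of range for k={self.k}")
            if v not in (0, 1):
                raise ValueError(f"output at state {s} must be 0 or 1, got {v!r}")

    def merge(self, other: "ObservationSet") -> "ObservationSet":
        if other.k != self.k:
            raise ValueError("cannot merge observation sets with different k")
        merged = dict(self.observed)
        for s, v in other.observed.items():
            if merged.get(s, v) != v:
                raise InconsistentObservationError(
                    f"conflicting outputs at state {s}: {merged[s]} vs {v}"
                )
            merged[s] = v
        return ObservationSet(self.k, merged)

    def is_consistent_with(self, f: BooleanFunction) -> bool:
        return all(f.outputs[s] == v for s, v in self.observed.items())

    @property
    def state_mask(self) -> int:
        """Bitmask over state numbers (bit s set iff s observed)."""
        mask = 0
        for s in self.observed:
            mask |= 1 << s
        return mask

    def __len__(self) -> int:
        return len(self.observed)


@dataclass(frozen=True)
class PerturbationPath:
    """Ordered initial states of a multi-step experiment."""

    k: int
    regime: Regime
    initials: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regime", Regime.parse(self.regime))
        if len(self.initials) < 1:
            raise ValueError("a perturbation path needs at least one step")
        if self.regime is Regime.D and len(self.initials) > self.k:
            raise ValueError(
                f"knock-down-only paths exhaust after at most k={self.k} steps"
            )
        for prev, nxt in zip(self.initials, self.initials[1:]):
            dests = {d for _, d, _ in _edge_targets(prev, self.k, self.regime)}
            if nxt not in dests:
                raise ValueError(
                    f"state {nxt} is not reachable from {prev} by a single "
                    f"perturbation under regime {self.regime.value}"
                )

    @property
    def n_p(self) -> int:
        return len(self.initials)


@dataclass(frozen=True)
class StepResult:
    observations: ObservationSet
    destinations: tuple[int, ...]
    visible_out_degree: int | None  # only set for the first step
    fully_visible: bool | None = None  # eligibility of the state as step 1


def observations_from_step(
    f: BooleanFunction,
    s: int,
    regime: Regime | str,
    first_step: bool = True,
    integration: Integration | str = Integration.TX_CIS_PPI,
) -> StepResult:
    """Observe one perturbation step of ``f`` at initial state ``s``.

    All available perturbations are performed; the output is recorded at the
    initial state and at every destination (duplicates deduplicate through
    the mapping). On the first step the visible out-degree under the given
    integration is also reported so callers can apply the full-visibility
    indicator; later steps ignore visibility entirely.
    """
    regime = Regime.parse(regime)
    integration = Integration.parse(integration)
    k = f.k
    if not 0 <= s < (1 << k):
        raise ValueError(f"state {s} out of range for k={k}")
    targets = _edge_targets(s, k, regime)
    observed = {s: f.outputs[s]}
    for _i, dest, _kind in targets:
        observed[dest] = f.outputs[dest]
    n_visible = fully = None
    if first_step:
        n_visible = _visible_out_degree(f, s, targets, integration)
        fully = (
            True if integration is Integration.TX_CIS_PPI else n_visible == k
        )
    return StepResult(
        observations=ObservationSet(k, observed),
        destinations=tuple(d for _, d, _ in targets),
        visible_out_degree=n_visible,
        fully_visible=fully,
    )


def _visible_out_degree(f, s, targets, integration) -> int:
    k = f.k
    if integration is Integration.TX_CIS_PPI:
        return len(targets)
    count = 0
    for i, dest, _ in targets:
        if f.outputs[s] != f.outputs[dest]:
            count += 1
        elif integration is Integration.TX_PPI and any(
            j != i
            and (s & input_bit_mask(k, j))
            and f.outputs[s] != f.outputs[s ^ input_bit_mask(k, j)]
            for j, _d, _ in targets
        ):
            count += 1
    return count


# ---------------------------------------------------------------------------
# Counting functions consistent with observations
# ---------------------------------------------------------------------------


def consistent_indices(obs: ObservationSet, space: SearchSpace) -> tuple[int, ...]:
    """Sorted indices of the search-space functions agreeing with ``obs``."""
    if obs.k != space.k:
        raise ValueError("observation set and search space disagree on k")
    n_states = 1 << space.k
    keep = []
    for b in space.indices:
        if all(((b >> (n_states - 1 - s)) & 1) == v for s, v in obs.observed.items()):
            keep.append(b)
    return tuple(keep)


def consistent_count(
    obs: ObservationSet,
    space: SearchSpace,
    method: str = "filter",
) -> int:
    """Number of search-space functions agreeing with every observation.

    ``method='filter'`` scans the enumerated space directly;
    ``method='completion'`` counts non-degenerate completions of the partial
    assignment by inclusion-exclusion over ignored-input sets without
    touching the enumeration. The two routes agree by construction and are
    cross-checked in the test suite.
    """
    if method == "filter":
        return len(consistent_indices(obs, space))
    if method == "completion":
        return _completion_count(obs)
    raise ValueError(f"unknown method {method!r}; use 'filter' or 'completion'")


def _completion_count(obs: ObservationSet) -> int:
    """Inclusion-exclusion over subsets of ignored inputs.

    A function ignoring input set J is constant on each orbit of states
    under flipping the bits of J; it is consistent with the observations iff
    no orbit carries both a 0 and a 1, and then there are 2**(#unconstrained
    orbits) such functions.
    """
    k = obs.k
    total = 0
    for r in range(k + 1):
        for J in combinations(range(1, k + 1), r):
            flip = 0
            for i in J:
                flip |= input_bit_mask(k, i)
            n = _constant_on_orbits_count(obs, flip)
            total += (-1) ** r * n
    return total


def _constant_on_orbits_count(obs: ObservationSet, flip_mask: int) -> int:
    k = obs.k
    free = 0
    visited: set[int] = set()
    for s in range(1 << k):
        orbit = _orbit(s, flip_mask, k)
        rep = min(orbit)
        if rep in visited:
            continue
        visited.add(rep)
        values = {obs.observed[t] for t in orbit if t in obs.observed}
        if len(values) > 1:
            return 0
        if not values:
            free += 1
    return 1 << free


@lru_cache(maxsize=None)
def _orbit(s: int, flip_mask: int, k: int) -> frozenset[int]:
    out = {s}
    frontier = [s]
    bits = [1 << p for p in range(k) if flip_mask & (1 << p)]
    while frontier:
        cur = frontier.pop()
        for bit in bits:
            nxt = cur ^ bit
            if nxt not in out:
                out.add(nxt)
                frontier.append(nxt)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Exhaustive sweeps (vectorized over the whole search space)
# ---------------------------------------------------------------------------


def _step_mask(s: int, k: int, regime: Regime) -> int:
    """State-set bitmask observed by one full perturbation step at ``s``."""
    mask = 1 << s
    for _, d, _ in _edge_targets(s, k, regime):
        mask |= 1 << d
    return mask


@lru_cache(maxsize=None)
def _path_masks(k: int, regime: Regime, s: int, n_p: int) -> frozenset[int]:
    """Observed-state bitmasks of all length-``n_p`` paths starting at ``s``.

    Paths that exhaust early (knock-down at state 0) keep what they have
    observed. The masks do not depend on the Boolean function: the SPSD
    topology is function-independent.
    """
    base = _step_mask(s, k, regime)
    if n_p == 1:
        return frozenset({base})
    dests = [d for _, d, _ in _edge_targets(s, k, regime)]
    if not dests:
        return frozenset({base})
    out = set()
    for d in dests:
        for rest in _path_masks(k, regime, d, n_p - 1):
            out.add(base | rest)
    return frozenset(out)


_group_count_cache: dict[tuple[int, int], np.ndarray] = {}


def _counts_for_mask(
    k: int, state_mask: int, indices: np.ndarray, cacheable: bool
) -> np.ndarray:
    """Per-function count of search-space functions agreeing on the masked states."""
    key = (k, state_mask)
    if cacheable:
        cached = _group_count_cache.get(key)
        if cached is not None:
            return cached
    n_states = 1 << k
    bits_mask = 0
    for s in range(n_states):
        if state_mask & (1 << s):
            bits_mask |= 1 << (n_states - 1 - s)
    keys = indices & np.int64(bits_mask)
    _, inverse, counts = np.unique(keys, return_inverse=True, return_counts=True)
    result = counts[inverse].astype(np.int32)
    if cacheable:
        _group_count_cache[key] = result
    return result


def min_common_counts(
    k: int,
    regime: Regime | str,
    n_p: int = 1,
    space: SearchSpace | None = None,
) -> np.ndarray:
    """Minimal N_cmn over all length-``n_p`` paths, per (function, state).

    Returns an array of shape (N_B(k), 2**k); entry (j, s) is the smallest
    candidate count achievable by any path of ``n_p`` steps whose first
    initial state is ``s``, for the function ``space.indices[j]``.
    """
    regime = Regime.parse(regime)
    _validate_np(k, regime, n_p)
    if space is None:
        space = enumerate_search_space(k)
    cacheable = space is enumerate_search_space(k)  # enumerate() is memoized
    indices = space.index_array()
    n_states = 1 << k
    result = np.empty((indices.shape[0], n_states), dtype=np.int32)
    for s in range(n_states):
        best: np.ndarray | None = None
        for state_mask in sorted(_path_masks(k, regime, s, n_p)):
            counts = _counts_for_mask(k, state_mask, indices, cacheable)
            best = counts if best is None else np.minimum(best, counts)
        result[:, s] = best
    return result


def _validate_np(k: int, regime: Regime, n_p: int) -> None:
    if n_p < 1:
        raise ValueError("the number of perturbation steps n_p must be >= 1")
    if regime is Regime.D and n_p > k:
        raise ValueError(
            f"knock-down-only experiments exhaust at state 0 after k={k} steps; "
            f"n_p={n_p} is undefined for regime D"
        )


@dataclass(frozen=True)
class AmbiguityResult:
    k: int
    regime: Regime
    integration: Integration
    n_p: int
    P_ua: float
    mean_Ncmn: float
    exact_P_ua: Fraction

    def to_record(self) -> dict:
        return {
            "k": self.k,
            "regime": self.regime.value,
            "integration": self.integration.value,
            "n_p": self.n_p,
            "P_ua": self.P_ua,
            "mean_Ncmn": self.mean_Ncmn,
        }


def unambiguity_probability(
    k: int,
    regime: Regime | str,
    integration: Integration | str,
    n_p: int = 1,
) -> AmbiguityResult:
    """P_ua over the whole search space, exactly.

    P_ua = (1 / (2**k * N_B(k))) * sum over functions b and states s of
    I(state s fully visible for b) / minN_cmn(b, s, n_p). With n_p = 1 the
    minimisation is vacuous and the single-step definition is recovered.
    """
    regime = Regime.parse(regime)
    integration = Integration.parse(integration)
    space = enumerate_search_space(k)
    indices = space.index_array()
    eligible = fully_visible_matrix(k, indices, regime, integration)
    mins = min_common_counts(k, regime, n_p, space)
    vals = mins[eligible]
    # exact rational sum of 1/N over eligible entries, tallied by value
    tally = np.bincount(vals)
    total = Fraction(0)
    for value, count in enumerate(tally):
        if value and count:
            total += Fraction(int(count), int(value))
    p_ua = total / ((1 << k) * space.size)
    mean_ncmn = float(vals.mean()) if vals.size else float("nan")
    return AmbiguityResult(
        k=k,
        regime=regime,
        integration=integration,
        n_p=n_p,
        P_ua=float(p_ua),
        mean_Ncmn=mean_ncmn,
        exact_P_ua=p_ua,
    )


def mean_common_count(
    k: int,
    regime: Regime | str,
    integration: Integration | str,
    restrict_visible: bool = True,
) -> float:
    """Average single-step N_cmn over the reporting set.

    Knock-down-only regimes average over the top state (the only one that can
    be fully visible) across all functions; DO regimes average over the
    (function, state) pairs whose initial state is fully visible under the
    integration, or over all pairs when ``restrict_visible`` is False.
    """
    regime = Regime.parse(regime)
    integration = Integration.parse(integration)
    space = enumerate_search_space(k)
    counts = min_common_counts(k, regime, 1, space)
    if regime is Regime.D:
        return float(counts[:, (1 << k) - 1].mean())
    if not restrict_visible:
        return float(counts.mean())
    eligible = fully_visible_matrix(k, space.index_array(), regime, integration)
    vals = counts[eligible]
    return float(vals.mean()) if vals.size else float("nan")


def ratio_tables(k_list=(2, 3, 4), n_p_max: int = 4, exhausted: str = "clamp") -> dict:
    """Unambiguity-ratio tables across integration modes and regimes.

    ``integration_gain`` (rows D/DO, columns per k and integration): mean
    over n_p = 1..``n_p_max`` of P_ua(regime+X, n_p) / P_ua(regime+TX, n_p).
    ``do_over_d`` (rows n_p, columns per k and integration):
    P_ua(DO+X, n_p) / P_ua(D+X, n_p).

    Knock-down-only paths exhaust at state 0 after k steps, so P_ua(D, n_p)
    is undefined beyond n_p = k. With ``exhausted='clamp'`` (default) the
    saturated value P_ua(D, k) is used there — further steps cannot add
    observations, so the probability genuinely stops changing; affected
    ``do_over_d`` entries carry ``d_clamped: true``. With
    ``exhausted='omit'`` those entries are None and the averages run over
    the feasible step counts only.
    """
    if exhausted not in ("clamp", "omit"):
        raise ValueError("exhausted must be 'clamp' or 'omit'")
    k_list = list(k_list)
    cache: dict[tuple, Fraction] = {}

    def p_ua(k, regime, integ, n_p) -> Fraction | None:
        if regime is Regime.D and n_p > k:
            if exhausted == "omit":
                return None
            n_p = k  # saturation: no transitions remain past state 0
        key = (k, regime, integ, n_p)
        if key not in cache:
            cache[key] = unambiguity_probability(k, regime, integ, n_p).exact_P_ua
        return cache[key]

    integration_gain: dict[str, dict] = {}
    for regime in (Regime.D, Regime.DO):
        row: dict[str, dict[str, float]] = {}
        for k in k_list:
            entry = {}
            for integ in (Integration.TX_PPI, Integration.TX_CIS_PPI):
                ratios = []
                for n in range(1, n_p_max + 1):
                    num = p_ua(k, regime, integ, n)
                    den = p_ua(k, regime, Integration.TX, n)
                    if num is not None and den is not None:
                        ratios.append(num / den)
                entry[integ.value] = float(sum(ratios) / len(ratios))
            row[f"k={k}"] = entry
        integration_gain[regime.value] = row

    do_over_d: dict[str, dict] = {}
    for n_p in range(1, n_p_max + 1):
        row = {}
        for k in k_list:
            entry: dict[str, float | bool | None] = {}
            for integ in (Integration.TX, Integration.TX_PPI, Integration.TX_CIS_PPI):
                num = p_ua(k, Regime.DO, integ, n_p)
                den = p_ua(k, Regime.D, integ, n_p)
                entry[integ.value] = None if den is None else float(num / den)
            entry["d_clamped"] = n_p > k and exhausted == "clamp"
            row[f"k={k}"] = entry
        do_over_d[f"n_p={n_p}"] = row

    return {"integration_gain": integration_gain, "do_over_d": do_over_d}
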