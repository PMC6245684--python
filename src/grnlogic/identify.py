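"""Boolean-function identification from real perturbation records.

Interprets wild-type plus knock-down/over-expression outcomes together with
cis-element and PPI evidence: the cis-elements name the directly bound
regulators, PPI edges optimistically add indirectly bound (putative) ones,
and the perturbation records pin down the truth table. Unlike the exhaustive
sweeps, identification searches *all* truth tables, degenerate ones
included, because a real candidate-regulator set may be over-complete; a
degenerate winner is reported through its essential-input reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from grnlogic.ambiguity import InconsistentObservationError, ObservationSet
from grnlogic.boolean_space import (
    BooleanFunction,
    effective_inputs,
    reduce_to_essential,
)
from grnlogic.spsd import Regime, _edge_targets

__all__ = [
    "PerturbationRecord",
    "RegulatorEvidence",
    "Candidate",
    "IdentificationResult",
    "candidate_regulators",
    "identify_function",
    "simulate_experiment",
    "records_from_table",
]


@dataclass(frozen=True)
class PerturbationRecord:
    """One observed (regulator states -> target state) row of an experiment."""

    regulator_states: tuple[int, ...]
    target_state: int
    label: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.regulator_states):
            raise ValueError("regulator states must be 0/1 bits")
        if self.target_state not in (0, 1):
            raise ValueError("target state must be a 0/1 bit")

    @property
    def state_number(self) -> int:
        s = 0
        for bit in self.regulator_states:
            s = (s << 1) | bit
        return s


@dataclass(frozen=True)
class RegulatorEvidence:
    """Cis-element and PPI evidence about the regulators of one target."""

    target: str
    cis_regulators: frozenset[str] = frozenset()
    ppi_edges: frozenset[frozenset[str]] = frozenset()

    @staticmethod
    def build(
        target: str,
        cis_regulators: Iterable[str] = (),
        ppi_edges: Iterable[tuple[str, str]] = (),
    ) -> "RegulatorEvidence":
        return RegulatorEvidence(
            target=target,
            cis_regulators=frozenset(cis_regulators),
            ppi_edges=frozenset(frozenset(pair) for pair in ppi_edges),
        )


@dataclass(frozen=True)
class Candidate:
    name: str
    provenance: str  # "direct(cis)" or "indirect(ppi)"


def candidate_regulators(evidence: RegulatorEvidence) -> list[Candidate]:
    """Ordered candidate regulators with provenance.

    Cis-element regulators are direct anchors; the PPI graph is then expanded
    to a fixpoint, adding any protein linked to an already-included regulator
    as an indirect, putative candidate. PPI edges with no anchor contribute
    nothing: a physical interaction alone is not regulatory evidence.
    """
    out = [Candidate(name, "direct(cis)") for name in sorted(evidence.cis_regulators)]
    included = set(evidence.cis_regulators)
    frontier = list(out)
    adjacency: dict[str, set[str]] = {}
    for pair in evidence.ppi_edges:
        members = sorted(pair)
        if len(members) == 1:  # self-interaction carries no new candidate
            continue
        a, b = members
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    while frontier:
        current = frontier.pop(0)
        for neighbor in sorted(adjacency.get(current.name, ())):
            if neighbor not in included:
                included.add(neighbor)
                cand = Candidate(neighbor, "indirect(ppi)")
                out.append(cand)
                frontier.append(cand)
    return out


@dataclass(frozen=True)
class IdentificationResult:
    k: int
    count: int
    consistent_indices: tuple[int, ...]
    function: BooleanFunction | None
    effective_inputs: tuple[int, ...] | None
    reduced: BooleanFunction | None

    @property
    def unique(self) -> bool:
        return self.count == 1

    def to_record(self) -> dict:
        return {
            "k": self.k,
            "count": self.count,
            "consistent_indices": list(self.consistent_indices),
            "function": self.function.to_record() if self.function else None,
            "effective_inputs": list(self.effective_inputs or ()),
            "reduced": self.reduced.to_record() if self.reduced else None,
        }


def _observation_set(records: Sequence[PerturbationRecord], k: int) -> ObservationSet:
    observed: dict[int, int] = {}
    for idx, rec in enumerate(records):
        if len(rec.regulator_states) != k:
            raise ValueError(
                f"record {idx} has {len(rec.regulator_states)} regulator states, "
                f"expected {k}"
            )
        s = rec.state_number
        if observed.get(s, rec.target_state) != rec.target_state:
            raise InconsistentObservationError(
                f"record {idx} ({rec.label or 'unlabelled'}) assigns target state "
                f"{rec.target_state} to input state {s}, conflicting with an "
                f"earlier record that observed {observed[s]}"
            )
        observed[s] = rec.target_state
    return ObservationSet(k, observed)


def identify_function(
    records: Sequence[PerturbationRecord], k: int
) -> IdentificationResult:
    """All truth tables consistent with the records; unique hit is decoded.

    Records must share one regulator ordering (and, by convention, one
    experimental condition — filter before calling). Conflicting records
    raise :class:`InconsistentObservationError` naming the clashing rows.
    """
    conditions = {rec.condition for rec in records}
    if len(conditions) > 1:
        raise ValueError(
            f"records span multiple conditions {sorted(conditions)}; "
            "identify one condition at a time"
        )
    obs = _observation_set(records, k)
    n_states = 1 << k
    all_b = np.arange(1 << n_states, dtype=np.int64)
    keep = np.ones(all_b.shape[0], dtype=bool)
    for s, v in obs.observed.items():
        keep &= ((all_b >> (n_states - 1 - s)) & 1) == v
    consistent = tuple(int(b) for b in all_b[keep])
    function = effective = reduced = None
    if len(consistent) == 1:
        function = BooleanFunction(k=k, b=consistent[0])
        effective = tuple(sorted(effective_inputs(function)))
        reduced = reduce_to_essential(function) if effective else None
    return IdentificationResult(
        k=k,
        count=len(consistent),
        consistent_indices=consistent,
        function=function,
        effective_inputs=effective,
        reduced=reduced,
    )


def simulate_experiment(
    hidden_f: BooleanFunction,
    wild_type: int,
    regime: Regime | str,
    n_p: int,
    seed: int,
    dropout: float = 0.0,
) -> list[PerturbationRecord]:
    """Seeded multi-step experiment on a hidden function.

    Each step performs every available perturbation from the current initial
    state and records the outcome; the next initial state is drawn uniformly
    from the destinations. The wild-type record is always kept; every other
    record is independently dropped with probability ``dropout``.
    """
    regime = Regime.parse(regime)
    k = hidden_f.k
    if not 0 <= wild_type < (1 << k):
        raise ValueError(f"wild-type state {wild_type} out of range for k={k}")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    if regime is Regime.D and wild_type == 0:
        raise ValueError(
            "no knock-down is possible from the all-zero wild type; "
            "use the DO regime or another wild type"
        )
    rng = np.random.default_rng(seed)
    from grnlogic.boolean_space import state_bits  # local to avoid cycle at import

    records = [
        PerturbationRecord(
            regulator_states=state_bits(wild_type, k),
            target_state=hidden_f.outputs[wild_type],
            label="wild-type",
            condition="simulated",
        )
    ]
    current = wild_type
    for step in range(1, n_p + 1):
        targets = _edge_targets(current, k, regime)
        if not targets:
            break  # knock-down path exhausted at state 0
        for i, dest, kind in targets:
            if dropout > 0.0 and rng.random() < dropout:
                continue
            records.append(
                PerturbationRecord(
                    regulator_states=state_bits(dest, k),
                    target_state=hidden_f.outputs[dest],
                    label=f"step{step}:{kind}{i}@{current}",
                    condition="simulated",
                )
            )
        current = int(
            targets[rng.integers(len(targets))][1]
        )  # uniform next initial state
    return records


def records_from_table(
    rows: Iterable[Sequence[str]], k: int, condition: str | None = None
) -> list[PerturbationRecord]:
    """Records from parsed TSV rows ``RF1..RFk, target, label, condition``."""
    out = []
    for row in rows:
        if len(row) < k + 1:
            raise ValueError(f"row too short for k={k}: {row!r}")
        states = tuple(int(x) for x in row[:k])
        target = int(row[k])
        label = str(row[k + 1]) if len(row) > k + 1 else ""
        cond = str(row[k + 2]) if len(row) > k + 2 else ""
        if condition is not None and cond != condition:
            continue
        out.append(
            PerturbationRecord(
                regulator_states=states,
                target_state=target,
                label=label,
                condition=cond,
            )
        )
    return out
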