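"""Enumeration and classification of k-input Boolean functions.

Conventions used project-wide:

* An input state number ``s`` (0 .. 2**k - 1) encodes the regulator tuple
  ``RF1 RF2 ... RFk`` with RF1 as the most significant bit, so for k=2 the
  state number 2 is the regulator configuration ``10``.
* A function index ``b`` (0 .. 2**(2**k) - 1) is the decimal value of the
  2**k output bits read with state 0 as the most significant bit; e.g. for
  k=2 the index 8 is the truth table ``1000`` (output 1 only at state 00).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "BooleanFunction",
    "SearchSpace",
    "decode_index",
    "encode_outputs",
    "effective_inputs",
    "enumerate_search_space",
    "reduce_to_essential",
    "search_space_size_closed_form",
]

#: largest k analysed in full; enumeration beyond this is allowed but costly
MAX_ANALYZED_K = 4


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"number of inputs k must be a positive integer, got {k!r}")


def input_bit_mask(k: int, i: int) -> int:
    """State-number bit mask of the 1-based input index ``i`` (RF1 = MSB)."""
    if not 1 <= i <= k:
        raise ValueError(f"input index must be in 1..{k}, got {i}")
    return 1 << (k - i)


def state_bits(s: int, k: int) -> tuple[int, ...]:
    """Regulator tuple (RF1, ..., RFk) of state number ``s``."""
    return tuple((s >> (k - i)) & 1 for i in range(1, k + 1))


@dataclass(frozen=True)
class BooleanFunction:
    """A k-input Boolean truth table with its decimal index ``b``.

    ``outputs[s]`` is the function value at input state number ``s``.
    """

    k: int
    b: int
    outputs: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        _check_k(self.k)
        n_states = 1 << self.k
        if not 0 <= self.b < (1 << n_states):
            raise ValueError(
                f"function index b={self.b} out of range for k={self.k}; "
                f"valid range is 0..{(1 << n_states) - 1}"
            )
        if not self.outputs:
            object.__setattr__(self, "outputs", _outputs_from_index(self.b, self.k))
        elif len(self.outputs) != n_states or encode_outputs(self.outputs) != self.b:
            raise ValueError("outputs do not match the function index b")

    @property
    def n_states(self) -> int:
        return 1 << self.k

    def __call__(self, *inputs: int) -> int:
        if len(inputs) != self.k:
            raise ValueError(f"expected {self.k} inputs, got {len(inputs)}")
        s = 0
        for bit in inputs:
            s = (s << 1) | (1 if bit else 0)
        return self.outputs[s]

    def value_at(self, s: int) -> int:
        """Output at state number ``s``."""
        return self.outputs[s]

    @property
    def effective_inputs(self) -> frozenset[int]:
        return frozenset(effective_inputs(self))

    @property
    def is_constant(self) -> bool:
        return len(set(self.outputs)) == 1

    @property
    def is_degenerate(self) -> bool:
        """True when at least one input never influences the output."""
        return len(effective_inputs(self)) < self.k

    def to_record(self) -> dict:
        return {
            "k": self.k,
            "b": self.b,
            "outputs": list(self.outputs),
            "effective_inputs": sorted(effective_inputs(self)),
        }

    def minterm_expression(self, names: Sequence[str] | None = None) -> str:
        """Canonical sum-of-products string over inputs RF1..RFk."""
        if names is None:
            names = [f"RF{i}" for i in range(1, self.k + 1)]
        if len(names) != self.k:
            raise ValueError("need one name per input")
        terms = []
        for s in range(self.n_states):
            if self.outputs[s]:
                bits = state_bits(s, self.k)
                lits = [n if bit else f"~{n}" for n, bit in zip(names, bits)]
                terms.append("&".join(lits))
        if not terms:
            return "0"
        if len(terms) == self.n_states:
            return "1"
        return " | ".join(terms)

    def __repr__(self) -> str:  # noqa: D105
        return f"F_{self.b}^{self.k}"


def _outputs_from_index(b: int, k: int) -> tuple[int, ...]:
    n_states = 1 << k
    return tuple((b >> (n_states - 1 - s)) & 1 for s in range(n_states))


def decode_index(b: int, k: int) -> BooleanFunction:
    """Truth table of the function with index ``b`` on ``k`` inputs.

    The bit of ``b`` at position ``2**k - 1 - s`` is the output at state
    ``s`` (state 0 is the most significant bit).
    """
    _check_k(k)
    n_states = 1 << k
    if not 0 <= b < (1 << n_states):
        raise ValueError(
            f"function index b={b} out of range for k={k}; "
            f"valid range is 0..{(1 << n_states) - 1}"
        )
    return BooleanFunction(k=k, b=b)


def encode_outputs(outputs: Sequence[int]) -> int:
    """Decimal index of an output sequence (state 0 first / MSB)."""
    b = 0
    for bit in outputs:
        b = (b << 1) | (1 if bit else 0)
    return b


@lru_cache(maxsize=None)
def _effective_inputs_cached(k: int, b: int) -> frozenset[int]:
    outputs = _outputs_from_index(b, k)
    eff = set()
    for i in range(1, k + 1):
        mask = input_bit_mask(k, i)
        for s in range(1 << k):
            if outputs[s] != outputs[s ^ mask]:
                eff.add(i)
                break
    return frozenset(eff)


def effective_inputs(f: BooleanFunction) -> set[int]:
    """1-based indices of inputs whose flip changes the output somewhere."""
    return set(_effective_inputs_cached(f.k, f.b))


def reduce_to_essential(f: BooleanFunction) -> BooleanFunction:
    """Equivalent function over only the effective inputs (order preserved).

    A constant function is returned as the 1-input constant with a warning;
    callers can detect it through ``is_constant``.
    """
    eff = sorted(effective_inputs(f))
    if not eff:
        warnings.warn(
            f"{f!r} is constant; returning a 1-input constant form", stacklevel=2
        )
        return BooleanFunction(k=1, b=0 if f.outputs[0] == 0 else 3)
    if len(eff) == f.k:
        return f
    k2 = len(eff)
    outputs = []
    for s2 in range(1 << k2):
        # embed the reduced state into a full state with ineffective inputs at 0
        s = 0
        for pos, i in enumerate(eff):
            if (s2 >> (k2 - 1 - pos)) & 1:
                s |= input_bit_mask(f.k, i)
        outputs.append(f.outputs[s])
    return BooleanFunction(k=k2, b=encode_outputs(outputs))


def search_space_size_closed_form(k: int) -> int:
    """Inclusion-exclusion count of k-input functions with all inputs effective."""
    _check_k(k)
    return sum(
        (-1) ** j * math.comb(k, j) * (1 << (1 << (k - j))) for j in range(k + 1)
    )


@dataclass(frozen=True)
class SearchSpace:
    """All function indices on ``k`` inputs in which every input is effective."""

    k: int
    indices: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.indices)

    def __contains__(self, b: int) -> bool:
        return b in self._index_set

    def __iter__(self) -> Iterator[int]:
        return iter(self.indices)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def _index_set(self) -> frozenset[int]:
        return _index_set_cached(self.k, self.indices)

    def functions(self) -> Iterator[BooleanFunction]:
        for b in self.indices:
            yield BooleanFunction(k=self.k, b=b)

    def filtered(self, keep) -> "SearchSpace":
        """Restriction to indices accepted by the predicate ``keep(b)``."""
        return SearchSpace(self.k, tuple(b for b in self.indices if keep(b)))

    def index_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=np.int64)


@lru_cache(maxsize=None)
def _index_set_cached(k: int, indices: tuple[int, ...]) -> frozenset[int]:
    return frozenset(indices)


def output_matrix(k: int, indices: np.ndarray) -> np.ndarray:
    """Boolean matrix ``O[j, s]`` = output of function ``indices[j]`` at state s."""
    n_states = 1 << k
    shifts = np.arange(n_states - 1, -1, -1, dtype=np.int64)
    return ((indices[:, None] >> shifts[None, :]) & 1).astype(bool)


@lru_cache(maxsize=8)
def enumerate_search_space(k: int) -> SearchSpace:
    """Enumerate, in increasing index order, every non-degenerate function.

    For ``k`` above 4 the enumeration is still exact but its cost doubles in
    the exponent; a warning is emitted.
    """
    _check_k(k)
    if k > MAX_ANALYZED_K:
        warnings.warn(
            f"enumerating the search space for k={k} requires scanning "
            f"2**{1 << k} truth tables; this may be very slow",
            stacklevel=2,
        )
    n_states = 1 << k
    all_b = np.arange(1 << n_states, dtype=np.int64)
    out = output_matrix(k, all_b)  # (2**2**k, 2**k)
    keep = np.ones(all_b.shape[0], dtype=bool)
    states = np.arange(n_states)
    for i in range(1, k + 1):
        mask = input_bit_mask(k, i)
        keep &= (out != out[:, states ^ mask]).any(axis=1)
    return SearchSpace(k, tuple(int(b) for b in all_b[keep]))
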