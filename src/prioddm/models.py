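"""The eight theory-driven DDM parameterizations.

The experiment crosses four prioritization conditions (no item
prioritized, or the first / middle / last list item prioritized) with
three probed serial positions.  Two theoretical families describe what
prioritization does to the probed item's memory evidence:

* **Attentional Boost** — prioritizing an item improves it with no cost
  to the other items.  A probed item is either ``prioritized`` (the
  prioritized position was the one probed) or at ``baseline``.
* **Resource Tradeoff** — the benefit to the prioritized item comes at
  the expense of the others.  A probed item is at ``baseline`` (control
  condition), ``prioritized``, or ``diminished`` (some *other* item was
  prioritized).

Each family comes in two recency variants.  In the *differ* variant the
most recent item (serial position 3) behaves like any other position; in
the *equivalent* variant recency and prioritization are the same
mechanism, so serial position 3 collapses: the boost family estimates a
single state for it, while the tradeoff family distinguishes only
whether the focus of attention is held ``foa_alone`` (control, or the
last item itself prioritized) or ``foa_shared`` (an earlier item
prioritized).

Finally each of the four structures is fit with or without a
speed-accuracy tradeoff: with one, boundary separation varies over the
four prioritization conditions (it cannot depend on the probed position,
which is unknown until after the decision); without, a single boundary
is shared.  Drift rate and non-decision time always carry one free
parameter per distinct (probe position, attention state) pair.  The
resulting per-participant free-parameter counts are

    ========  =========  ========  ===  ===========
    model id  family     recency   SAT  (v, a, t)
    ========  =========  ========  ===  ===========
    1         boost      differ    yes  (6, 4, 6)
    2         boost      equiv     yes  (5, 4, 5)
    3         boost      differ    no   (6, 1, 6)
    4         boost      equiv     no   (5, 1, 5)
    5         tradeoff   differ    yes  (9, 4, 9)
    6         tradeoff   equiv     yes  (8, 4, 8)
    7         tradeoff   differ    no   (9, 1, 9)
    8         tradeoff   equiv     no   (8, 1, 8)
    ========  =========  ========  ===  ===========
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, ParameterError
from .wiener import DDMParams

__all__ = [
    "PRIORITIZATIONS",
    "PROBE_POSITIONS",
    "ALL_CONDITIONS",
    "TrialCondition",
    "attention_state",
    "ModelSpec",
    "build_spec",
    "resolve_params",
]

PRIORITIZATIONS = ("control", "first", "middle", "last")
PROBE_POSITIONS = (1, 2, 3)

#: position name matching each probe position, used by the state rules
_PRIO_OF_PROBE = {1: "first", 2: "middle", 3: "last"}

#: canonical ordering of attention-state labels for index numbering
STATE_ORDER = ("baseline", "prioritized", "diminished", "foa_alone", "foa_shared")

_MODEL_TABLE = {
    1: ("boost", "differ", True),
    2: ("boost", "equivalent", True),
    3: ("boost", "differ", False),
    4: ("boost", "equivalent", False),
    5: ("tradeoff", "differ", True),
    6: ("tradeoff", "equivalent", True),
    7: ("tradeoff", "differ", False),
    8: ("tradeoff", "equivalent", False),
}


class TrialCondition(NamedTuple):
    """One cell of the 4 (prioritization) x 3 (probe position) design."""

    prioritization: str
    probe_position: int


ALL_CONDITIONS = tuple(
    TrialCondition(p, q) for p in PRIORITIZATIONS for q in PROBE_POSITIONS
)


def _validate_condition(cond: TrialCondition) -> None:
    if cond.prioritization not in PRIORITIZATIONS:
        raise ParameterError(
            f"prioritization must be one of {PRIORITIZATIONS}, got {cond.prioritization!r}"
        )
    if cond.probe_position not in PROBE_POSITIONS:
        raise ParameterError(
            f"probe_position must be one of {PROBE_POSITIONS}, got {cond.probe_position!r}"
        )


def attention_state(cond: TrialCondition, theory: str, recency: str) -> str:
    """Attention state of the probed item under one theoretical family.

    Total over all 12 conditions.  The boost family only ever returns
    ``baseline`` / ``prioritized``; ``diminished`` and the two
    focus-of-attention states arise only in the tradeoff family.
    """
    cond = TrialCondition(*cond)
    _validate_condition(cond)
    if theory not in ("boost", "tradeoff"):
        raise ParameterError(f"theory must be 'boost' or 'tradeoff', got {theory!r}")
    if recency not in ("differ", "equivalent"):
        raise ParameterError(f"recency must be 'differ' or 'equivalent', got {recency!r}")
    match = cond.prioritization == _PRIO_OF_PROBE[cond.probe_position]
    if theory == "boost":
        if recency == "equivalent" and cond.probe_position == 3:
            # the recency item is already in the FOA: one state only
            return "baseline"
        return "prioritized" if match else "baseline"
    # tradeoff family
    if recency == "equivalent" and cond.probe_position == 3:
        if cond.prioritization in ("control", "last"):
            return "foa_alone"
        return "foa_shared"
    if cond.prioritization == "control":
        return "baseline"
    return "prioritized" if match else "diminished"


@dataclass(frozen=True)
class ModelSpec:
    """One model's mapping from design cell to parameter indices.

    ``v_index`` / ``t_index`` map each of the 12 conditions to a drift /
    non-decision-time slot numbered by probe position then attention
    state (order: baseline, prioritized, diminished, foa_alone,
    foa_shared); ``a_index`` maps to a boundary slot numbered by
    prioritization order when a speed-accuracy tradeoff is modelled, or
    to a single shared slot otherwise.  A flat parameter vector is laid
    out as ``[v_0..v_{n_v-1}, a_0..a_{n_a-1}, t_0..t_{n_t-1}]``.
    """

    model_id: int
    theory: str
    recency: str
    sat: bool
    v_index: dict[TrialCondition, int]
    a_index: dict[TrialCondition, int]
    t_index: dict[TrialCondition, int]
    n_v: int
    n_a: int
    n_t: int

    @property
    def n_params(self) -> int:
        return self.n_v + self.n_a + self.n_t

    @property
    def description(self) -> str:
        fam = "Attentional Boost" if self.theory == "boost" else "Resource Tradeoff"
        rec = (
            "prioritization and recency differ"
            if self.recency == "differ"
            else "prioritization and recency are equivalent"
        )
        sat = "speed-accuracy tradeoff" if self.sat else "no speed-accuracy tradeoff"
        return f"{fam}, {rec}, {sat}"

    @property
    def state_labels(self) -> list[str]:
        """Label ``sp<q>:<state>`` for each v/t slot, in index order."""
        seen: dict[int, str] = {}
        for cond in ALL_CONDITIONS:
            j = self.v_index[cond]
            if j not in seen:
                state = attention_state(cond, self.theory, self.recency)
                seen[j] = f"sp{cond.probe_position}:{state}"
        return [seen[j] for j in range(self.n_v)]

    @property
    def boundary_labels(self) -> list[str]:
        if self.sat:
            return [f"a[{p}]" for p in PRIORITIZATIONS]
        return ["a"]

    @property
    def param_labels(self) -> list[str]:
        """Names of all ``n_params`` slots in flat-vector order."""
        return (
            [f"v[{s}]" for s in self.state_labels]
            + self.boundary_labels
            + [f"t[{s}]" for s in self.state_labels]
        )

    def flat_indices(self, cond: TrialCondition) -> tuple[int, int, int]:
        """(v, a, t) positions of one condition in the flat vector."""
        cond = TrialCondition(*cond)
        return (
            self.v_index[cond],
            self.n_v + self.a_index[cond],
            self.n_v + self.n_a + self.t_index[cond],
        )

    def resolve(self, cond: TrialCondition, values: Sequence[float]) -> DDMParams:
        """Assemble the trial's DDM parameters from a flat value vector."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_params,):
            raise ConfigurationError(
                f"model {self.model_id} needs {self.n_params} values, got shape {values.shape}"
            )
        iv, ia, it = self.flat_indices(cond)
        return DDMParams(v=float(values[iv]), a=float(values[ia]), t0=float(values[it]))

    # -- plain-text round trip -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "theory": self.theory,
            "recency": self.recency,
            "sat": self.sat,
            "n_v": self.n_v,
            "n_a": self.n_a,
            "n_t": self.n_t,
            "v_index": {f"{c.prioritization}/{c.probe_position}": i for c, i in self.v_index.items()},
            "a_index": {f"{c.prioritization}/{c.probe_position}": i for c, i in self.a_index.items()},
            "t_index": {f"{c.prioritization}/{c.probe_position}": i for c, i in self.t_index.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        def parse(m: dict) -> dict[TrialCondition, int]:
            out = {}
            for key, i in m.items():
                p, q = key.split("/")
                out[TrialCondition(p, int(q))] = int(i)
            return out

        return cls(
            model_id=int(d["model_id"]),
            theory=d["theory"],
            recency=d["recency"],
            sat=bool(d["sat"]),
            v_index=parse(d["v_index"]),
            a_index=parse(d["a_index"]),
            t_index=parse(d["t_index"]),
            n_v=int(d["n_v"]),
            n_a=int(d["n_a"]),
            n_t=int(d["n_t"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))


def build_spec(model_id: int) -> ModelSpec:
    """Build the parameter-index mapping for one of the eight models."""
    if model_id not in _MODEL_TABLE:
        raise ParameterError(f"model_id must be in 1..8, got {model_id!r}")
    theory, recency, sat = _MODEL_TABLE[model_id]

    # number v/t slots by (probe position, state), probe-major
    pairs: list[tuple[int, str]] = []
    for cond in ALL_CONDITIONS:
        state = attention_state(cond, theory, recency)
        pair = (cond.probe_position, state)
        if pair not in pairs:
            pairs.append(pair)
    pairs.sort(key=lambda pq: (pq[0], STATE_ORDER.index(pq[1])))
    slot = {pair: i for i, pair in enumerate(pairs)}

    v_index = {
        cond: slot[(cond.probe_position, attention_state(cond, theory, recency))]
        for cond in ALL_CONDITIONS
    }
    t_index = dict(v_index)
    if sat:
        a_index = {cond: PRIORITIZATIONS.index(cond.prioritization) for cond in ALL_CONDITIONS}
        n_a = 4
    else:
        a_index = {cond: 0 for cond in ALL_CONDITIONS}
        n_a = 1
    return ModelSpec(
        model_id=model_id,
        theory=theory,
        recency=recency,
        sat=sat,
        v_index=v_index,
        a_index=a_index,
        t_index=t_index,
        n_v=len(pairs),
        n_a=n_a,
        n_t=len(pairs),
    )


def resolve_params(spec: ModelSpec, cond: TrialCondition, values: Sequence[float]) -> DDMParams:
    """Module-level alias for :meth:`ModelSpec.resolve`."""
    return spec.resolve(cond, values)
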