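"""Ten-state cyclic kinetic scheme of P2X3 receptor activation and desensitization.

The receptor is modelled as a continuous-time Markov chain with a resting
branch (R, AR, A2R, A3R plus the open state A3Ro reached by gating of the
fully occupied receptor) and a desensitized branch (D, AD, A2D, A3D plus the
rapidly desensitizing state A3Df).  Agonist binding steps are second order:
their propensity is the rate constant (mM^-1 s^-1) multiplied by the agonist
concentration (mM).  All other steps are first order (s^-1).

The occupancy dynamics are linear mass-action ODEs ``dp/dt = Q(c) p`` where
``Q(c)`` is the concentration-dependent generator matrix assembled by
:func:`build_generator`.  ``Q`` follows the column convention: entry
``(j, i)`` is the propensity of the ``i -> j`` transition and each diagonal
entry is minus its column's off-diagonal sum, so columns sum to zero and
total occupancy is conserved.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "STATE_NAMES",
    "RATE_NAMES",
    "LIGAND_DEPENDENT",
    "UNIT_FIRST_ORDER",
    "UNIT_BINDING",
    "SchemeValidationError",
    "RateSetError",
    "Transition",
    "KineticScheme",
    "RateSet",
    "StateVector",
    "load_scheme",
    "load_rate_set",
    "build_generator",
    "steady_state",
]

STATE_NAMES = ("R", "AR", "A2R", "A3R", "A3Ro", "D", "AD", "A2D", "A3D", "A3Df")

RATE_NAMES = tuple(
    f"{prefix}{i}"
    for prefix, count in (("k", 4), ("l", 4), ("m", 4), ("n", 4), ("d", 5), ("r", 5))
    for i in range(1, count + 1)
)

#: binding steps whose propensity scales with agonist concentration
LIGAND_DEPENDENT = frozenset({"k1", "k2", "k3", "m1", "m2", "m3"})

UNIT_FIRST_ORDER = "s^-1"
UNIT_BINDING = "mM^-1 s^-1"


class SchemeValidationError(ValueError):
    """A kinetic scheme violates its structural invariants."""


class RateSetError(ValueError):
    """A rate-constant document is incomplete or inconsistent."""


def _packaged(name: str) -> dict:
    text = importlib.resources.files("p2x3kin.data").joinpath(name).read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class Transition:
    """One directed edge of the scheme.

    ``ligand_order`` is 1 for agonist-binding steps (propensity multiplied by
    concentration) and 0 otherwise.
    """

    source: str
    target: str
    rate: str
    ligand_order: int = 0


@dataclass(frozen=True)
class KineticScheme:
    """States and directed transitions of the receptor model."""

    states: tuple[str, ...] = STATE_NAMES
    transitions: tuple[Transition, ...] = ()

    def __post_init__(self):
        self.validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def default(cls) -> "KineticScheme":
        """The canonical cyclic ten-state wiring, from the packaged document."""
        return cls.from_dict(_packaged("scheme.yaml"))

    @classmethod
    def from_dict(cls, doc: Mapping) -> "KineticScheme":
        transitions = tuple(
            Transition(t["source"], t["target"], t["rate"], int(t.get("ligand_order", 0)))
            for t in doc["transitions"]
        )
        return cls(states=tuple(doc["states"]), transitions=transitions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KineticScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "transitions": [
                {
                    "source": t.source,
                    "target": t.target,
                    "rate": t.rate,
                    "ligand_order": t.ligand_order,
                }
                for t in self.transitions
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- queries -----------------------------------------------------------
    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def n_states(self) -> int:
        return len(self.states)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if len(self.states) != 10:
            raise SchemeValidationError(
                f"expected 10 states, got {len(self.states)}"
            )
        if len(set(self.states)) != len(self.states):
            raise SchemeValidationError("duplicate state names")
        if len(self.transitions) != 26:
            raise SchemeValidationError(
                f"expected 26 transitions, got {len(self.transitions)}"
            )
        names = [t.rate for t in self.transitions]
        if len(set(names)) != 26:
            raise SchemeValidationError("rate-constant names are not unique")
        unknown = set(names) - set(RATE_NAMES)
        if unknown:
            raise SchemeValidationError(f"unknown rate names: {sorted(unknown)}")
        for t in self.transitions:
            if t.source not in self.states or t.target not in self.states:
                raise SchemeValidationError(
                    f"transition {t.rate} references unknown state"
                )
            expected = 1 if t.rate in LIGAND_DEPENDENT else 0
            if t.ligand_order != expected:
                raise SchemeValidationError(
                    f"{t.rate}: ligand_order {t.ligand_order}, expected {expected}"
                )
        # reversibility: each edge must have a partner in the opposite direction
        pairs = {(t.source, t.target) for t in self.transitions}
        missing = [(s, d) for s, d in pairs if (d, s) not in pairs]
        if missing:
            raise SchemeValidationError(f"non-reversible edges: {missing}")
        # connectivity and degree
        out_deg = {s: 0 for s in self.states}
        in_deg = {s: 0 for s in self.states}
        for t in self.transitions:
            out_deg[t.source] += 1
            in_deg[t.target] += 1
        if min(out_deg.values()) < 1 or min(in_deg.values()) < 1:
            raise SchemeValidationError("every state needs in- and out-edges")
        seen = {self.states[0]}
        frontier = [self.states[0]]
        adjacency: dict[str, list[str]] = {s: [] for s in self.states}
        for t in self.transitions:
            adjacency[t.source].append(t.target)
        while frontier:
            nxt = frontier.pop()
            for neighbour in adjacency[nxt]:
                if neighbour not in seen:
                    seen.add(neighbour)
                    frontier.append(neighbour)
        if seen != set(self.states):
            raise SchemeValidationError("scheme graph is not connected")


@dataclass(frozen=True)
class RateSet:
    """Named rate-constant values for one experimental condition."""

    values: Mapping[str, float]
    label: str = ""

    def __post_init__(self):
        missing = [n for n in RATE_NAMES if n not in self.values]
        if missing:
            raise RateSetError(f"missing rate constants: {missing}")
        unknown = sorted(set(self.values) - set(RATE_NAMES))
        if unknown:
            raise RateSetError(f"unknown rate constants: {unknown}")
        negative = [n for n in RATE_NAMES if self.values[n] < 0]
        if negative:
            raise RateSetError(f"negative rate constants: {negative}")
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @staticmethod
    def units(name: str) -> str:
        return UNIT_BINDING if name in LIGAND_DEPENDENT else UNIT_FIRST_ORDER

    def replace(self, label: str | None = None, **changes: float) -> "RateSet":
        """A copy with some constants changed (values in model units)."""
        unknown = sorted(set(changes) - set(RATE_NAMES))
        if unknown:
            raise RateSetError(f"unknown rate constants: {unknown}")
        values = dict(self.values)
        values.update(changes)
        return RateSet(values, label if label is not None else self.label)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RateSet":
        entries = doc.get("rates", doc)
        values: dict[str, float] = {}
        for name, entry in entries.items():
            if name == "label":
                continue
            if isinstance(entry, Mapping):
                value = float(entry["value"])
                units = entry.get("units")
                if units is not None and name in RATE_NAMES:
                    expected = cls.units(name)
                    if units.replace("·", " ").replace("*", " ") != expected:
                        raise RateSetError(
                            f"{name}: units '{units}' but expected '{expected}'"
                        )
            else:
                value = float(entry)
            values[name] = value
        return cls(values, str(doc.get("label", "")))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RateSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "rates": {
                n: {"value": self.values[n], "units": self.units(n)}
                for n in RATE_NAMES
            },
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


#: aliases accepted for the two packaged conditions
_PACKAGED_RATE_FILES = {
    "control": "control.yaml",
    "mbcd": "mbcd.yaml",
}


def load_rate_set(source: str | Path | Mapping) -> RateSet:
    """Load and validate a rate set.

    ``source`` may be one of the packaged condition names (``"control"`` or
    ``"MbCD"``, case-insensitive), a path to a YAML/JSON document, or a
    mapping with the same structure.
    """
    if isinstance(source, Mapping):
        return RateSet.from_dict(source)
    key = str(source).lower()
    if key in _PACKAGED_RATE_FILES:
        return RateSet.from_dict(_packaged(_PACKAGED_RATE_FILES[key]))
    path = Path(source)
    if not path.exists():
        raise RateSetError(
            f"unknown rate set {source!r}: not a packaged condition "
            f"({sorted(_PACKAGED_RATE_FILES)}) and no such file"
        )
    return RateSet.from_yaml(path)


def load_scheme(source: str | Path | Mapping | None = None) -> KineticScheme:
    """Load the packaged scheme (default) or a user-supplied variant."""
    if source is None:
        return KineticScheme.default()
    if isinstance(source, Mapping):
        return KineticScheme.from_dict(source)
    return KineticScheme.from_yaml(source)


@dataclass(frozen=True)
class StateVector:
    """Occupancy of each scheme state at one time point."""

    occupancies: np.ndarray
    states: tuple[str, ...] = STATE_NAMES
    time: float = 0.0

    def __post_init__(self):
        occ = np.asarray(self.occupancies, dtype=float)
        object.__setattr__(self, "occupancies", occ)
        if occ.shape != (len(self.states),):
            raise ValueError("occupancy vector length does not match states")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupancies sum to {occ.sum():.12f}, not 1")
        if occ.min() < -1e-12:
            raise ValueError(f"negative occupancy {occ.min():.3e}")

    def __getitem__(self, state: str) -> float:
        return float(self.occupancies[self.states.index(state)])

    def as_dict(self) -> dict[str, float]:
        # tiny negative round-off is clamped for reporting
        return {s: max(float(v), 0.0) for s, v in zip(self.states, self.occupancies)}


def build_generator(
    scheme: KineticScheme, rates: RateSet, concentration: float
) -> np.ndarray:
    """Assemble the concentration-dependent generator matrix Q(c).

    Off-diagonal entry ``(target, source)`` is the transition's rate value
    multiplied by ``concentration ** ligand_order``; diagonals make each
    column sum to zero.
    """
    if concentration < 0:
        raise ValueError(f"negative agonist concentration {concentration}")
    n = scheme.n_states
    q = np.zeros((n, n))
    for t in scheme.transitions:
        propensity = rates[t.rate] * (concentration if t.ligand_order else 1.0)
        i, j = scheme.index(t.source), scheme.index(t.target)
        q[j, i] += propensity
        q[i, i] -= propensity
    return q


def steady_state(
    scheme: KineticScheme, rates: RateSet, concentration: float
) -> StateVector:
    """Stationary occupancy distribution of Q(c).

    Solves ``Q v = 0`` with the normalization ``sum(v) = 1`` by replacing one
    balance equation with the normalization row.  At zero agonist the chain
    is reducible and the unique stationary distribution lives on the
    reachable resting/desensitized pair, split by the balance
    ``d1 * p(R) = r1 * p(D)``.
    """
    q = build_generator(scheme, rates, concentration)
    n = scheme.n_states
    a = q.copy()
    a[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    try:
        v = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"steady-state solve failed at c={concentration} mM "
            f"(generator condition number {np.linalg.cond(q):.3e})"
        ) from exc
    residual = float(np.abs(q @ v).max())
    scale = max(float(np.abs(q).max()), 1.0)
    if residual > 1e-8 * scale or v.min() < -1e-9:
        raise RuntimeError(
            f"steady-state solution unreliable at c={concentration} mM: "
            f"residual {residual:.3e}, min occupancy {v.min():.3e}"
        )
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    return StateVector(v, scheme.states, time=0.0)
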