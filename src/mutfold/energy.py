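"""Secondary-structure legality and structure energies.

The structure model is the standard pseudoknot-free one: a structure is a
set of base pairs in which every position pairs at most once, pairs never
cross (nested or disjoint only), hairpin loops contain at least
``MIN_HAIRPIN = 3`` unpaired nucleotides, and only canonical pairs
(Watson-Crick AU/GC plus the GU wobble) are allowed.

Three energy models ship, all deterministic and oracle-verifiable:

``toy-uniform``
    every pair contributes -1.0 kcal/mol, RT = 1.0 -- closed-form testable.
``toy-pairtype``
    per-pair-type energies (GC -3.0, AU -2.0, GU -1.0 kcal/mol, RT = 1.0).
``stacking``
    nearest-neighbour model: a per-pair baseline plus a stack term for
    every pair of directly adjacent pairs (i,j),(i+1,j-1), read from a
    shipped parameter file with Turner-2004-style values; RT = 0.6163
    kcal/mol (37 degrees C).

Dangling ends, coaxial stacking and special loop bonuses are deliberately
excluded; the open chain has energy exactly 0 under every model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "MIN_HAIRPIN",
    "SecondaryStructure",
    "EnergyModel",
    "EnergyModelError",
    "is_canonical",
    "structure_energy",
    "load_energy_parameters",
    "write_energy_parameters",
    "get_model",
]

#: Minimum number of unpaired nucleotides in a hairpin loop.
MIN_HAIRPIN = 3

_CANONICAL = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)

_PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")


class EnergyModelError(ValueError):
    """Raised for illegal structures or malformed parameter files."""


def is_canonical(a: str, b: str) -> bool:
    """True iff (a, b) can form a canonical (WC or GU wobble) pair."""
    return (a, b) in _CANONICAL


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs, 1-based, i < j."""

    pairs: frozenset

    def __init__(self, pairs):
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in pairs))
        self._validate()

    def _validate(self) -> None:
        seen = {}
        for (i, j) in self.pairs:
            if not (1 <= i < j):
                raise EnergyModelError(f"pair ({i},{j}) violates 1 <= i < j")
            if j - i < MIN_HAIRPIN + 1:
                raise EnergyModelError(
                    f"pair ({i},{j}) closes a hairpin loop shorter than {MIN_HAIRPIN}"
                )
            for p in (i, j):
                if p in seen:
                    raise EnergyModelError(f"position {p} occurs in two pairs")
                seen[p] = True
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i, j = plist[a]
            for b in range(a + 1, len(plist)):
                k, l = plist[b]
                if i < k <= j < l:
                    raise EnergyModelError(
                        f"crossing pairs ({i},{j}) and ({k},{l})"
                    )

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list:
        return sorted(self.pairs)


@dataclass(frozen=True)
class EnergyModel:
    """Energies (kcal/mol) for pairs and, optionally, stacked pair steps.

    ``pair_energies`` maps a pair type like ``"GC"`` (the 5' partner first)
    to its baseline energy.  ``stack_energies`` maps ``"XY/WZ"`` -- outer
    pair X.Y at (i,j), inner pair W.Z at (i+1,j-1) -- to the stack term;
    empty for the toy models.
    """

    model_id: str
    RT: float
    pair_energies: dict
    stack_energies: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.RT <= 0:
            raise EnergyModelError(f"RT must be positive, got {self.RT}")
        missing = [t for t in _PAIR_TYPES if t not in self.pair_energies]
        if missing:
            raise EnergyModelError(f"missing pair energies for {missing}")

    def pair_energy(self, a: str, b: str) -> float:
        if not is_canonical(a, b):
            raise EnergyModelError(f"non-canonical pair {a}-{b}")
        return self.pair_energies[a + b]

    def stack_energy(self, outer: str, inner: str) -> float:
        """Stack term for inner pair directly inside outer; 0 for toy models."""
        if not self.stack_energies:
            return 0.0
        key = f"{outer}/{inner}"
        if key not in self.stack_energies:
            raise EnergyModelError(f"missing stack energy for {key}")
        return self.stack_energies[key]

    @property
    def has_stacking(self) -> bool:
        return bool(self.stack_energies)


def structure_energy(seq, s: SecondaryStructure, m: EnergyModel) -> float:
    """Energy of a structure: pair baselines plus adjacent-pair stack terms."""
    residues = seq.residues if hasattr(seq, "residues") else str(seq)
    pairset = s.pairs
    total = 0.0
    for (i, j) in pairset:
        a, b = residues[i - 1], residues[j - 1]
        if not is_canonical(a, b):
            raise EnergyModelError(
                f"pair ({i},{j}) = {a}-{b} is non-canonical for this sequence"
            )
        total += m.pair_energy(a, b)
        if m.has_stacking and (i + 1, j - 1) in pairset:
            total += m.stack_energy(
                residues[i - 1] + residues[j - 1],
                residues[i] + residues[j - 2],
            )
    return total


# --- parameter files -------------------------------------------------------

_STACK_KEYS = [f"{o}/{i}" for o in _PAIR_TYPES for i in _PAIR_TYPES]


def load_energy_parameters(path) -> EnergyModel:
    """Load an :class:`EnergyModel` from a ``key = value`` parameter file.

    Lines starting with ``#`` are comments.  Required keys: ``model``,
    ``RT``, ``PAIR_<XY>`` for all six canonical pair types and, when
    ``model = stacking``, ``STACK_<XY>_<WZ>`` for all 36 outer/inner
    combinations.  Missing keys are reported together.
    """
    entries = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise EnergyModelError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = stripped.partition("=")
        entries[key.strip()] = value.strip()

    model_id = entries.pop("model", None)
    if model_id is None:
        raise EnergyModelError(f"{path}: missing 'model' key")

    def _num(key):
        raw = entries[key]
        try:
            return float(raw)
        except ValueError:
            raise EnergyModelError(f"{path}: non-numeric value {raw!r} for {key}")

    required = ["RT"] + [f"PAIR_{t}" for t in _PAIR_TYPES]
    if model_id == "stacking":
        required += [f"STACK_{k.replace('/', '_')}" for k in _STACK_KEYS]
    missing = [k for k in required if k not in entries]
    if missing:
        raise EnergyModelError(f"{path}: missing keys {missing}")
    known = set(required)
    unknown = [k for k in entries if k not in known]
    if unknown:
        raise EnergyModelError(f"{path}: unknown keys {unknown}")

    pair = {t: _num(f"PAIR_{t}") for t in _PAIR_TYPES}
    stack = {}
    if model_id == "stacking":
        stack = {k: _num(f"STACK_{k.replace('/', '_')}") for k in _STACK_KEYS}
    return EnergyModel(
        model_id=model_id, RT=_num("RT"), pair_energies=pair, stack_energies=stack
    )


def write_energy_parameters(model: EnergyModel, path) -> None:
    """Serialize a model so that :func:`load_energy_parameters` round-trips."""
    lines = [f"model = {model.model_id}", f"RT = {model.RT!r}"]
    for t in _PAIR_TYPES:
        lines.append(f"PAIR_{t} = {model.pair_energies[t]!r}")
    if model.has_stacking:
        for k in _STACK_KEYS:
            lines.append(f"STACK_{k.replace('/', '_')} = {model.stack_energies[k]!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _data_path(name: str):
    return resources.files("mutfold") / "data" / name


def get_model(model_id: str) -> EnergyModel:
    """Return one of the shipped models by id."""
    if model_id == "toy-uniform":
        return EnergyModel(
            model_id="toy-uniform",
            RT=1.0,
            pair_energies={t: -1.0 for t in _PAIR_TYPES},
        )
    if model_id == "toy-pairtype":
        return load_energy_parameters(_data_path("toy-pairtype.params"))
    if model_id == "stacking":
        return load_energy_parameters(_data_path("stacking.params"))
    raise EnergyModelError(
        f"unknown model {model_id!r}; choose toy-uniform, toy-pairtype or stacking"
    )
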