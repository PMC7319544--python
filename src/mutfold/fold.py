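"""Partition-function folding over the Boltzmann ensemble.

Two independent routes to the same quantities are kept side by side:

* :func:`enumerate_structures` / :func:`bruteforce_ensemble` -- exhaustive
  enumeration of every pseudoknot-free structure (guarded to n <= 25),
  used as the oracle in the test suite;
* :func:`pair_probabilities_global` -- inside/outside (McCaskill-style)
  dynamic programming in O(n^3) time, which must agree with the oracle to
  1e-9 and is what every downstream analysis consumes.

Local folding (:func:`pair_probabilities_local`) mirrors the windowed
averaging of RNAplfold at the contract level: a pair's probability is the
unweighted mean of its window-restricted global probability over all
length-W windows fully containing it, and pairs spanning more than the
max span L are dropped entirely.  Accessibility (unpaired probabilities,
per position and per u-mer stretch) comes from the same machinery, with
u-mer probabilities computed as constrained/unconstrained partition
function ratios.

Long sequences are handled by the usual per-nucleotide rescaling of the
partition function (Boltzmann weights are divided by sigma per position);
the scale is estimated from a max-weight prepass and adjusted on over- or
underflow, and all reported probabilities are scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .energy import (
    MIN_HAIRPIN,
    EnergyModel,
    EnergyModelError,
    SecondaryStructure,
    is_canonical,
    structure_energy,
)
from .sequences import RnaSequence

__all__ = [
    "FoldingParams",
    "BasePairMatrix",
    "AccessibilityProfile",
    "EnsembleFold",
    "enumerate_structures",
    "bruteforce_ensemble",
    "pair_probabilities_global",
    "pair_probabilities_local",
    "unpaired_region_probability",
    "accessibility_profile",
]

_ENUM_GUARD = 25


@dataclass(frozen=True)
class FoldingParams:
    """Local-folding parameters: window W, max base-pair span L, u-mer lengths.

    ``window=None`` / ``max_span=None`` mean "full sequence length", i.e.
    global folding.  Invariant: 1 <= L <= W after resolution against n.
    """

    window: int | None = None
    max_span: int | None = None
    u_lengths: tuple = (1,)

    def __post_init__(self) -> None:
        if self.window is not None and self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.max_span is not None:
            if self.max_span < 1:
                raise ValueError(f"max_span must be >= 1, got {self.max_span}")
            if self.window is not None and self.max_span > self.window:
                raise ValueError(
                    f"max_span ({self.max_span}) must not exceed window "
                    f"({self.window})"
                )
        if not self.u_lengths or any(u < 1 for u in self.u_lengths):
            raise ValueError("u_lengths must be non-empty with all u >= 1")
        object.__setattr__(self, "u_lengths", tuple(int(u) for u in self.u_lengths))

    def resolve(self, n: int) -> tuple[int, int]:
        """Effective (W, L) for a sequence of length n."""
        W = n if self.window is None else min(self.window, n)
        L = W if self.max_span is None else min(self.max_span, W)
        return W, L

    @classmethod
    def global_preset(cls, u_lengths=(1,)) -> "FoldingParams":
        return cls(window=None, max_span=None, u_lengths=u_lengths)

    @classmethod
    def local_preset(cls, u_lengths=(1,)) -> "FoldingParams":
        # typical RNAplfold practice for long RNAs
        return cls(window=200, max_span=150, u_lengths=u_lengths)

    def is_global(self, n: int) -> bool:
        W, L = self.resolve(n)
        return W >= n


@dataclass
class BasePairMatrix:
    """Symmetric n x n matrix of ensemble base-pair probabilities."""

    n: int
    P: np.ndarray
    params: FoldingParams
    model_id: str

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.n, self.n):
            raise ValueError(f"matrix shape {self.P.shape} != ({self.n},{self.n})")

    def row_sums(self) -> np.ndarray:
        return self.P.sum(axis=1)

    def value(self, i: int, j: int) -> float:
        """Pair probability at 1-based positions (i, j)."""
        return float(self.P[i - 1, j - 1])


@dataclass
class AccessibilityProfile:
    """Per-position (and per-u-mer) unpaired probabilities.

    ``pu`` has length n; ``pu_u[u]`` has length n-u+1 with entry k (0-based)
    the probability that positions k+1 .. k+u are simultaneously unpaired.
    """

    n: int
    pu: np.ndarray
    pu_u: dict
    params: FoldingParams
    model_id: str


def _allowed_matrix(residues: str, max_span: int | None) -> np.ndarray:
    n = len(residues)
    allowed = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            if max_span is not None and j - i > max_span:
                break
            allowed[i, j] = is_canonical(residues[i], residues[j])
    return allowed


# --- brute-force oracle ----------------------------------------------------

def enumerate_structures(
    seq: RnaSequence, model: EnergyModel | None = None, max_span: int | None = None
) -> list[SecondaryStructure]:
    """Every legal pseudoknot-free structure of ``seq``, open chain included.

    Exponential-time; guarded to n <= 25.  ``model`` is accepted for
    interface symmetry (legality is model-independent here: all three
    shipped models allow exactly the canonical pairs).
    """
    n = seq.n
    if n > _ENUM_GUARD:
        raise ValueError(f"enumeration is limited to n <= {_ENUM_GUARD}, got {n}")
    residues = seq.residues
    allowed = _allowed_matrix(residues, max_span)

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> tuple:
        # structures of the 0-based inclusive interval [i, j]
        if j - i < MIN_HAIRPIN + 1:
            return ((),)
        out = list(enum(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if not allowed[i, k]:
                continue
            rights = enum(k + 1, j) if k < j else ((),)
            for inner in enum(i + 1, k - 1):
                for right in rights:
                    out.append(((i + 1, k + 1),) + inner + right)
        return tuple(out)

    return [SecondaryStructure(pairs) for pairs in enum(0, n - 1)]


def bruteforce_ensemble(
    seq: RnaSequence, model: EnergyModel, max_span: int | None = None
):
    """Boltzmann sum Z and pair-probability matrix by direct enumeration."""
    structures = enumerate_structures(seq, model, max_span=max_span)
    n = seq.n
    weights = np.array(
        [np.exp(-structure_energy(seq, s, model) / model.RT) for s in structures]
    )
    Z = float(weights.sum())
    P = np.zeros((n, n))
    for s, w in zip(structures, weights):
        for (i, j) in s.pairs:
            P[i - 1, j - 1] += w
    P /= Z
    P = P + P.T
    params = FoldingParams(max_span=max_span, window=None)
    return Z, BasePairMatrix(n=n, P=P, params=params, model_id=model.model_id)


# --- McCaskill inside/outside ---------------------------------------------

class EnsembleFold:
    """One inside/outside pass over a sequence (optionally masked/span-capped).

    Exposes the partition function (``log_Z``), the pair-probability matrix
    (``P``), and the joint probability of directly stacked adjacent pairs
    (``P_stack``, needed for feature expectations in the relative-entropy
    computation).  ``allowed_mask`` further restricts which pairs may form
    (used for u-mer accessibility constraints and common-structure-space
    ensembles); energies always come from this object's own sequence.
    """

    def __init__(
        self,
        seq: RnaSequence,
        model: EnergyModel,
        max_span: int | None = None,
        allowed_mask: np.ndarray | None = None,
    ):
        self.seq = seq
        self.model = model
        self.n = seq.n
        n = self.n
        residues = seq.residues
        allowed = _allowed_matrix(residues, max_span)
        if allowed_mask is not None:
            allowed &= np.asarray(allowed_mask, dtype=bool)
        self.allowed = allowed

        lwb = np.full((n, n), -np.inf)
        ii, jj = np.nonzero(allowed)
        for i, j in zip(ii, jj):
            lwb[i, j] = -model.pair_energy(residues[i], residues[j]) / model.RT
        self._lwb = lwb

        lws = np.zeros((n, n))
        if model.has_stacking:
            for i, j in zip(ii, jj):
                if i + 1 < j - 1 and allowed[i + 1, j - 1]:
                    lws[i, j] = (
                        -model.stack_energy(
                            residues[i] + residues[j],
                            residues[i + 1] + residues[j - 1],
                        )
                        / model.RT
                    )
        self._lws = lws

        self._run()

    # -- scale estimation ---------------------------------------------------

    def _max_log_weight(self) -> float:
        """Max-plus analogue of the inside pass: the best structure's log weight."""
        n = self.n
        lwb, lws = self._lwb, self._lws
        G = np.zeros((n + 1, n))  # G[k, j]: interval [k, j]; row j+1 = 0 (empty)
        Gb = np.full((n, n), -np.inf)
        for i in range(n - 1, -1, -1):
            if i + MIN_HAIRPIN + 1 < n:
                inner = G[i + 1, : n - 1]  # G(i+1, j-1) at index j-1
                for j in range(i + MIN_HAIRPIN + 1, n):
                    if not self.allowed[i, j]:
                        continue
                    best_in = G[i + 1, j - 1]
                    if i + 1 < n and Gb[i + 1, j - 1] > -np.inf:
                        best_in = max(best_in, lws[i, j] + Gb[i + 1, j - 1])
                    Gb[i, j] = lwb[i, j] + best_in
            for j in range(i, n):
                best = G[i + 1, j] if i + 1 <= j else 0.0
                for k in range(i + MIN_HAIRPIN + 1, j + 1):
                    if Gb[i, k] > -np.inf:
                        rest = G[k + 1, j] if k + 1 <= j else 0.0
                        best = max(best, Gb[i, k] + rest)
                G[i, j] = best
        return float(G[0, n - 1])

    # -- inside -------------------------------------------------------------

    def _inside(self, log_sigma: float) -> str:
        n = self.n
        u = np.exp(-log_sigma)
        wb = np.exp(self._lwb - 2.0 * log_sigma)  # 0 where disallowed
        ws = np.exp(self._lws)

        Zex = np.zeros((n + 1, n))
        for j in range(n):
            Zex[j + 1, j] = 1.0  # empty interval
        Zb = np.zeros((n, n))

        for i in range(n - 1, -1, -1):
            if i + MIN_HAIRPIN + 1 < n:
                zin = np.zeros(n)
                zin[1:] = Zex[i + 1, : n - 1]  # Z(i+1, j-1)
                zbin = np.zeros(n)
                if i + 1 < n:
                    zbin[1:] = Zb[i + 1, : n - 1]  # Zb(i+1, j-1)
                Zb[i, :] = wb[i, :] * (zin + (ws[i, :] - 1.0) * zbin)
            T = Zb[i, :] @ Zex[1:, :]
            row = u * Zex[i + 1, :] + T
            Zex[i, i:] = row[i:]
            if not np.all(np.isfinite(Zex[i, i:])):
                return "overflow"
        if Zex[0, n - 1] <= 0.0:
            return "underflow"
        self._Zex = Zex
        self._Zb = Zb
        self._wb = wb
        self._ws = ws
        self._log_sigma = log_sigma
        return "ok"

    def _run(self) -> None:
        n = self.n
        log_sigma = 0.0
        if n > 250:
            log_sigma = max(0.0, self._max_log_weight()) / n + 0.1
        step = max(0.5, 400.0 / n)
        for _ in range(64):
            status = self._inside(log_sigma)
            if status == "ok":
                break
            log_sigma += step if status == "overflow" else -step
        else:
            raise FloatingPointError("partition function scaling did not converge")
        self._outside()

    # -- outside ------------------------------------------------------------

    def _outside(self) -> None:
        n = self.n
        Zex, Zb, wb, ws = self._Zex, self._Zb, self._wb, self._ws
        Ztot = Zex[0, n - 1]
        P = np.zeros((n, n))
        M = np.zeros((n, n))
        D = np.zeros((n, n))
        stacking = self.model.has_stacking

        for d in range(n - 1, MIN_HAIRPIN, -1):
            span_pairs = []
            for i in range(0, n - d):
                j = i + d
                if not self.allowed[i, j] or Zb[i, j] <= 0.0:
                    continue
                zpre = Zex[0, i - 1] if i >= 1 else 1.0
                zsuf = Zex[j + 1, n - 1] if j <= n - 2 else 1.0
                val = zpre * zsuf / Ztot
                if i >= 1 and j <= n - 2:
                    # innermost enclosing pair (k, l), k < i, l > j
                    val += Zex[1 : i + 1, i - 1] @ D[:i, j]
                    if stacking and self.allowed[i - 1, j + 1]:
                        val += (ws[i - 1, j + 1] - 1.0) * M[i - 1, j + 1]
                P[i, j] = Zb[i, j] * val
                M[i, j] = P[i, j] * wb[i, j] / Zb[i, j]
                span_pairs.append((i, j))
            for (i, j) in span_pairs:
                # register (i, j) as a potential enclosing pair for shorter spans
                D[i, i:j] += M[i, j] * Zex[i + 1 : j + 1, j - 1]

        np.clip(P, 0.0, 1.0, out=P)
        self._P_upper = P
        self.P = P + P.T

    # -- public quantities --------------------------------------------------

    @property
    def log_Z(self) -> float:
        """Natural log of the (unscaled) partition function."""
        return float(np.log(self._Zex[0, self.n - 1]) + self.n * self._log_sigma)

    @property
    def Z(self) -> float:
        return float(np.exp(self.log_Z))

    def pair_matrix(self, params: FoldingParams | None = None) -> BasePairMatrix:
        if params is None:
            params = FoldingParams()
        return BasePairMatrix(
            n=self.n, P=self.P.copy(), params=params, model_id=self.model.model_id
        )

    def unpaired(self) -> np.ndarray:
        return 1.0 - self._P_upper.sum(axis=1) - self._P_upper.sum(axis=0)

    @property
    def P_stack(self) -> np.ndarray:
        """Joint probability that (i,j) and (i+1,j-1) are both paired.

        Upper-triangular, indexed by the outer pair.
        """
        n = self.n
        out = np.zeros((n, n))
        Zb, wb, ws = self._Zb, self._wb, self._ws
        for i in range(n):
            for j in range(i + MIN_HAIRPIN + 3, n):
                if Zb[i, j] > 0.0 and Zb[i + 1, j - 1] > 0.0:
                    out[i, j] = (
                        self._P_upper[i, j]
                        * wb[i, j]
                        * ws[i, j]
                        * Zb[i + 1, j - 1]
                        / Zb[i, j]
                    )
        return out


def pair_probabilities_global(
    seq: RnaSequence,
    model: EnergyModel,
    max_span: int | None = None,
    allowed_mask: np.ndarray | None = None,
) -> BasePairMatrix:
    """Global McCaskill pair probabilities (optionally span-capped)."""
    fold = EnsembleFold(seq, model, max_span=max_span, allowed_mask=allowed_mask)
    return fold.pair_matrix(FoldingParams(max_span=max_span))


def unpaired_region_probability(
    seq: RnaSequence,
    model: EnergyModel,
    i: int,
    u: int,
    max_span: int | None = None,
) -> float:
    """Probability that the 1-based stretch i .. i+u-1 is entirely unpaired.

    Computed as the ratio of the partition function with all pairs touching
    the stretch forbidden over the unconstrained one.
    """
    n = seq.n
    if u < 1 or i < 1 or i + u - 1 > n:
        raise ValueError(f"region [{i}, {i + u - 1}] out of range 1..{n}")
    free = EnsembleFold(seq, model, max_span=max_span)
    mask = np.ones((n, n), dtype=bool)
    mask[i - 1 : i + u - 1, :] = False
    mask[:, i - 1 : i + u - 1] = False
    constrained = EnsembleFold(seq, model, max_span=max_span, allowed_mask=mask)
    return float(np.exp(constrained.log_Z - free.log_Z))


def _global_profile(
    seq: RnaSequence, model: EnergyModel, u_lengths, max_span: int | None
):
    """(pu, pu_u) on the full sequence, one fold plus constrained refolds."""
    fold = EnsembleFold(seq, model, max_span=max_span)
    pu = np.clip(fold.unpaired(), 0.0, 1.0)
    pu_u = {}
    for u in u_lengths:
        if u == 1:
            pu_u[1] = pu.copy()
        else:
            vals = np.array(
                [
                    unpaired_region_probability(seq, model, start, u, max_span)
                    for start in range(1, seq.n - u + 2)
                ]
            )
            pu_u[u] = np.clip(vals, 0.0, 1.0)
    return pu, pu_u


def accessibility_profile(
    seq: RnaSequence, model: EnergyModel, params: FoldingParams
) -> AccessibilityProfile:
    """Unpaired probabilities per position and per u-mer stretch.

    Global mode: pu(i) = 1 - sum_j P(i,j) exactly; u-mer probabilities from
    constrained partition-function ratios.  Local mode (W < n): each value
    is the unweighted mean of its window-restricted counterpart over all
    length-W windows fully containing the position (or stretch).
    """
    n = seq.n
    W, L = params.resolve(n)
    if any(u > W for u in params.u_lengths):
        raise ValueError(
            f"u-mer length exceeds window size {W}: {params.u_lengths}"
        )
    if W >= n:
        pu, pu_u = _global_profile(seq, model, params.u_lengths, L)
        return AccessibilityProfile(
            n=n, pu=pu, pu_u=pu_u, params=params, model_id=model.model_id
        )

    pu_acc = np.zeros(n)
    pu_cnt = np.zeros(n)
    pu_u_acc = {u: np.zeros(n - u + 1) for u in params.u_lengths}
    pu_u_cnt = {u: np.zeros(n - u + 1) for u in params.u_lengths}
    for a in range(0, n - W + 1):
        sub = RnaSequence(id=f"{seq.id}[{a + 1}..{a + W}]",
                          residues=seq.residues[a : a + W])
        w_pu, w_pu_u = _global_profile(sub, model, params.u_lengths, L)
        pu_acc[a : a + W] += w_pu
        pu_cnt[a : a + W] += 1.0
        for u in params.u_lengths:
            span = W - u + 1
            pu_u_acc[u][a : a + span] += w_pu_u[u]
            pu_u_cnt[u][a : a + span] += 1.0
    pu = pu_acc / pu_cnt
    pu_u = {u: pu_u_acc[u] / pu_u_cnt[u] for u in params.u_lengths}
    return AccessibilityProfile(
        n=n, pu=pu, pu_u=pu_u, params=params, model_id=model.model_id
    )


def pair_probabilities_local(
    seq: RnaSequence, model: EnergyModel, params: FoldingParams
) -> BasePairMatrix:
    """Windowed local pair probabilities, RNAplfold-style averaging.

    P(i,j) is the unweighted mean of the window-restricted global
    probability over all length-W windows fully containing [i, j]; edge
    pairs are covered by fewer windows, so each entry is divided by its own
    covering-window count.  Pairs with span > L are exactly zero.
    """
    n = seq.n
    W, L = params.resolve(n)
    if W >= n:
        fold = EnsembleFold(seq, model, max_span=L)
        return fold.pair_matrix(params)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for a in range(0, n - W + 1):
        sub = RnaSequence(id=f"{seq.id}[{a + 1}..{a + W}]",
                          residues=seq.residues[a : a + W])
        fold = EnsembleFold(sub, model, max_span=L)
        acc[a : a + W, a : a + W] += fold.P
        cnt[a : a + W, a : a + W] += 1.0
    P = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    return BasePairMatrix(n=n, P=P, params=params, model_id=model.model_id)
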