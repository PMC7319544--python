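"""Differential comparison of wildtype and mutant structure ensembles.

Sign conventions (both kept deliberately, with explicit axis labels in
every output):

* pair-level ``delta`` is mutant - WT, so red/positive means the mutation
  *increases* the pairing potential;
* ``acc_delta`` (accessibility) is WT - mutant, so *negative* values mark
  positions more likely unpaired in the mutant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fold import AccessibilityProfile, BasePairMatrix

__all__ = [
    "DiffResult",
    "diff_matrix",
    "split_weakened_strengthened",
    "combined_triangle_matrix",
    "accessibility_delta",
    "build_diff_result",
]


@dataclass
class DiffResult:
    """All differential structure representations for one WT/mutant pair."""

    delta: np.ndarray          # mutant - WT pairing probability
    weakened: np.ndarray       # max(0, -delta)
    strengthened: np.ndarray   # max(0, delta)
    combined: np.ndarray       # WT upper triangle, mutant lower triangle
    acc_delta: np.ndarray      # WT - mutant unpaired probability
    p_wt: np.ndarray
    p_mut: np.ndarray
    pu_wt: np.ndarray
    pu_mut: np.ndarray

    @property
    def n(self) -> int:
        return self.delta.shape[0]


def _check_compatible(wt: BasePairMatrix, mut: BasePairMatrix, check_params=True):
    if wt.n != mut.n:
        raise ValueError(f"length mismatch: WT n={wt.n}, mutant n={mut.n}")
    if check_params and wt.params != mut.params:
        raise ValueError(
            "folding parameters differ between WT and mutant matrices "
            f"({wt.params} vs {mut.params}); differences are only meaningful "
            "for identical parameters"
        )


def diff_matrix(wt: BasePairMatrix, mut: BasePairMatrix) -> np.ndarray:
    """delta(i,j) = P_mut(i,j) - P_wt(i,j); positive = strengthened by mutation."""
    _check_compatible(wt, mut)
    return mut.P - wt.P


def split_weakened_strengthened(delta: np.ndarray):
    """Non-negative decomposition: (weakened, strengthened), disjoint supports."""
    delta = np.asarray(delta, dtype=float)
    return np.maximum(0.0, -delta), np.maximum(0.0, delta)


def combined_triangle_matrix(wt: BasePairMatrix, mut: BasePairMatrix) -> np.ndarray:
    """WT probabilities in the upper (row < col) and mutant in the lower triangle."""
    _check_compatible(wt, mut, check_params=False)
    n = wt.n
    combined = np.zeros((n, n))
    upper = np.triu_indices(n, k=1)
    combined[upper] = wt.P[upper]
    lower = np.tril_indices(n, k=-1)
    combined[lower] = mut.P[lower]
    return combined


def accessibility_delta(
    wt: AccessibilityProfile, mut: AccessibilityProfile
) -> np.ndarray:
    """acc_delta(i) = pu_wt(i) - pu_mut(i); negative = more accessible mutant."""
    if wt.n != mut.n:
        raise ValueError(f"length mismatch: WT n={wt.n}, mutant n={mut.n}")
    if set(wt.pu_u) != set(mut.pu_u):
        raise ValueError("u-mer settings differ between WT and mutant profiles")
    return wt.pu - mut.pu


def build_diff_result(
    wt: BasePairMatrix,
    mut: BasePairMatrix,
    wt_acc: AccessibilityProfile,
    mut_acc: AccessibilityProfile,
) -> DiffResult:
    delta = diff_matrix(wt, mut)
    weakened, strengthened = split_weakened_strengthened(delta)
    return DiffResult(
        delta=delta,
        weakened=weakened,
        strengthened=strengthened,
        combined=combined_triangle_matrix(wt, mut),
        acc_delta=accessibility_delta(wt_acc, mut_acc),
        p_wt=wt.P.copy(),
        p_mut=mut.P.copy(),
        pu_wt=wt_acc.pu.copy(),
        pu_mut=mut_acc.pu.copy(),
    )
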