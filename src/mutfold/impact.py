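"""Quantifying mutation-induced structure aberration.

Two complementary scores, in the spirit of the established ensemble
comparison tools for riboSNitch assessment:

* :func:`ensemble_relative_entropy` -- the Kullback-Leibler divergence
  between the WT and mutant Boltzmann ensembles, computed by dynamic
  programming over the *common* structure space (structures legal for
  both sequences).  The strict KL divergence is infinite whenever the WT
  ensemble puts mass on structures the mutant cannot form, so the
  divergence of the renormalized (conditional) distributions is reported
  together with each ensemble's coverage of the common space and an
  ``infinite_flag``.
* :func:`region_distance_scan` -- a sliding-window scan for the region
  accommodating the largest change, scored by Euclidean distance and
  Pearson correlation of the window-restricted pair-probability matrices,
  with empirical p-values from the exhaustive background of all 3n
  single-nucleotide substitutions of the input sequence.

The relative entropy never requires enumeration: with pair/stack-additive
energies, D(q_wt || q_mut) over the common space equals
``<E_mut - E_wt>_{q_wt} / RT + ln(Z'_mut / Z'_wt)`` where primes denote
common-space-restricted partition functions and the energy expectation
decomposes over pair and stack feature probabilities of the restricted WT
ensemble.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .energy import MIN_HAIRPIN, EnergyModel, is_canonical
from .fold import (
    BasePairMatrix,
    EnsembleFold,
    FoldingParams,
    pair_probabilities_local,
)
from .sequences import MutationSpec, RnaSequence, apply_mutations

__all__ = [
    "RelativeEntropyResult",
    "RegionScanResult",
    "ImpactReport",
    "ScanConfig",
    "ensemble_relative_entropy",
    "region_distance_scan",
    "background_scores",
    "empirical_pvalue",
    "build_impact_report",
]

_COVERAGE_TOL = 1e-9


@dataclass
class RelativeEntropyResult:
    """KL divergence of WT vs mutant conditional ensembles (common space)."""

    d_common: float       # nats
    coverage_wt: float    # P(common space) under the full WT ensemble
    coverage_mut: float
    infinite_flag: bool   # strict (unconditional) KL divergence diverges

    @property
    def d_bits(self) -> float:
        return self.d_common / np.log(2.0)

    def to_dict(self) -> dict:
        return {
            "d_common_nats": self.d_common,
            "d_common_bits": self.d_bits,
            "coverage_wt": self.coverage_wt,
            "coverage_mut": self.coverage_mut,
            "infinite_flag": self.infinite_flag,
        }


@dataclass
class RegionScanResult:
    """Largest-change region by Euclidean distance / correlation scan."""

    best_d_interval: tuple   # 1-based closed interval [a, b]
    d_max: float
    best_r_interval: tuple
    r_min: float
    p_d: float | None = None
    p_r: float | None = None
    background_size: int | None = None

    def to_dict(self) -> dict:
        return {
            "best_d_interval": list(self.best_d_interval),
            "d_max": self.d_max,
            "best_r_interval": list(self.best_r_interval),
            "r_min": self.r_min,
            "p_d": self.p_d,
            "p_r": self.p_r,
            "background_size": self.background_size,
        }


@dataclass
class ScanConfig:
    """Everything needed to refold and rescan a sequence reproducibly."""

    model: EnergyModel
    params: FoldingParams = field(default_factory=FoldingParams)
    window_lengths: tuple = (50,)
    step: int = 5

    def fold(self, seq: RnaSequence) -> BasePairMatrix:
        return pair_probabilities_local(seq, self.model, self.params)


def _common_mask(wt: RnaSequence, mut: RnaSequence, max_span: int | None):
    n = wt.n
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            if max_span is not None and j - i > max_span:
                break
            mask[i, j] = is_canonical(wt.residues[i], wt.residues[j]) and is_canonical(
                mut.residues[i], mut.residues[j]
            )
    return mask | mask.T


def ensemble_relative_entropy(
    wt: RnaSequence,
    mut: RnaSequence,
    model: EnergyModel,
    max_span: int | None = None,
) -> RelativeEntropyResult:
    """KL divergence D(q_wt || q_mut) over the common structure space.

    q_wt / q_mut are the Boltzmann distributions renormalized over the
    structures legal for both sequences; coverages report how much of each
    full ensemble that space captures.  Computed without enumeration via
    restricted partition functions and feature-probability expectations.
    """
    if wt.n != mut.n:
        raise ValueError(f"length mismatch: WT n={wt.n}, mutant n={mut.n}")
    mask = _common_mask(wt, mut, max_span)

    wt_full = EnsembleFold(wt, model, max_span=max_span)
    mut_full = EnsembleFold(mut, model, max_span=max_span)
    wt_c = EnsembleFold(wt, model, max_span=max_span, allowed_mask=mask)
    mut_c = EnsembleFold(mut, model, max_span=max_span, allowed_mask=mask)

    coverage_wt = float(np.exp(wt_c.log_Z - wt_full.log_Z))
    coverage_mut = float(np.exp(mut_c.log_Z - mut_full.log_Z))

    # <E_mut - E_wt> under the restricted WT ensemble, by features
    n = wt.n
    delta_E = 0.0
    P_upper = wt_c._P_upper
    for i, j in zip(*np.nonzero(wt_c.allowed)):
        p = P_upper[i, j]
        if p <= 0.0:
            continue
        e_wt = model.pair_energy(wt.residues[i], wt.residues[j])
        e_mut = model.pair_energy(mut.residues[i], mut.residues[j])
        delta_E += p * (e_mut - e_wt)
    if model.has_stacking:
        P_stack = wt_c.P_stack
        for i, j in zip(*np.nonzero(P_stack)):
            s_wt = model.stack_energy(
                wt.residues[i] + wt.residues[j], wt.residues[i + 1] + wt.residues[j - 1]
            )
            s_mut = model.stack_energy(
                mut.residues[i] + mut.residues[j],
                mut.residues[i + 1] + mut.residues[j - 1],
            )
            delta_E += P_stack[i, j] * (s_mut - s_wt)

    d = delta_E / model.RT + (mut_c.log_Z - wt_c.log_Z)
    return RelativeEntropyResult(
        d_common=max(0.0, float(d)),
        coverage_wt=min(1.0, coverage_wt),
        coverage_mut=min(1.0, coverage_mut),
        infinite_flag=coverage_wt < 1.0 - _COVERAGE_TOL,
    )


# --- region scan -----------------------------------------------------------

def _window_vectors(P_wt, P_mut, a, b):
    """Flattened upper-triangle vectors over the 0-based window [a, b]."""
    iu = np.triu_indices(b - a + 1, k=1)
    return P_wt[a : b + 1, a : b + 1][iu], P_mut[a : b + 1, a : b + 1][iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with explicit degenerate-variance rules."""
    if np.array_equal(x, y):
        return 1.0
    x_flat = np.ptp(x) == 0.0
    y_flat = np.ptp(y) == 0.0
    if x_flat or y_flat:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def _scan_starts(n: int, length: int, step: int):
    last = n - length
    starts = list(range(0, last + 1, step))
    if starts[-1] != last:
        starts.append(last)  # always cover the 3' tail
    return starts


def region_distance_scan(
    wt: BasePairMatrix,
    mut: BasePairMatrix,
    window_lengths=(50,),
    step: int = 5,
) -> RegionScanResult:
    """Scan subsequence windows for the largest ensemble change.

    For every start (stride ``step``, plus the final start) and every
    length (clipped to n), the window's pair probabilities (both ends
    inside) are compared by Euclidean distance (maximized) and Pearson
    correlation (minimized).  Ties resolve toward the smallest start, then
    the smallest length.
    """
    if wt.n != mut.n:
        raise ValueError(f"length mismatch: WT n={wt.n}, mutant n={mut.n}")
    n = wt.n
    lengths = sorted({min(int(l), n) for l in window_lengths})
    if any(l < 4 for l in lengths):
        raise ValueError(f"window lengths must be >= 4 (no pair fits): {lengths}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")

    best_d = None  # (d, start, length)
    best_r = None  # (r, start, length)
    for length in lengths:
        for a in _scan_starts(n, length, step):
            x, y = _window_vectors(wt.P, mut.P, a, a + length - 1)
            d = float(np.sqrt(np.sum((x - y) ** 2)))
            r = _pearson(x, y)
            key = (a, length)
            if best_d is None or d > best_d[0] or (d == best_d[0] and key < best_d[1:]):
                best_d = (d, a, length)
            if best_r is None or r < best_r[0] or (r == best_r[0] and key < best_r[1:]):
                best_r = (r, a, length)

    return RegionScanResult(
        best_d_interval=(best_d[1] + 1, best_d[1] + best_d[2]),
        d_max=best_d[0],
        best_r_interval=(best_r[1] + 1, best_r[1] + best_r[2]),
        r_min=best_r[0],
    )


# --- empirical p-values ----------------------------------------------------

def _all_point_mutations(wt: RnaSequence):
    for pos in range(1, wt.n + 1):
        ref = wt.base(pos)
        for alt in "ACGU":
            if alt != ref:
                yield f"{ref}{pos}{alt}", pos, ref, alt


def background_scores(wt: RnaSequence, config: ScanConfig) -> dict:
    """Scores of all 3n single-nucleotide substitutions of the WT.

    Each mutant is refolded and rescanned under ``config``; returns a dict
    mutation-code -> (d_max, r_min).  Deterministic and exhaustive -- this
    replaces any precomputed background-mutation table.
    """
    from .sequences import PointEdit

    wt_matrix = config.fold(wt)
    out = {}
    for code, pos, ref, alt in _all_point_mutations(wt):
        spec = MutationSpec(edits=(PointEdit(pos, ref, alt),))
        mut_seq = apply_mutations(wt, spec)
        mut_matrix = config.fold(mut_seq)
        scan = region_distance_scan(
            wt_matrix, mut_matrix, config.window_lengths, config.step
        )
        out[code] = (scan.d_max, scan.r_min)
    return out


def empirical_pvalue(
    observed: float,
    wt: RnaSequence,
    config: ScanConfig,
    mode: str,
    exclude: str | None = None,
    background: dict | None = None,
):
    """Empirical p-value of a scan score against the 3n-mutation background.

    p = (1 + #{background scores at least as extreme}) / (1 + 3n), where
    "as extreme" means >= for mode ``"d"`` and <= for mode ``"r"``.  When
    the observed score belongs to a mutation that is itself part of the
    background, pass its code as ``exclude`` so it is not counted against
    itself (the denominator stays 3n + 1).  Returns (p, background_size).
    """
    if mode not in ("d", "r"):
        raise ValueError(f"mode must be 'd' or 'r', got {mode!r}")
    if background is None:
        background = background_scores(wt, config)
    idx = 0 if mode == "d" else 1
    count = 0
    for code, scores in background.items():
        if exclude is not None and code == exclude:
            continue
        s = scores[idx]
        if (mode == "d" and s >= observed) or (mode == "r" and s <= observed):
            count += 1
    size = len(background)
    return (1 + count) / (1 + size), size


# --- integrated report -----------------------------------------------------

@dataclass
class ImpactReport:
    """Joint relative-entropy and region-scan assessment of one mutation."""

    relent: RelativeEntropyResult | None
    scan: RegionScanResult
    mutation: MutationSpec
    params: FoldingParams
    model_id: str

    def to_dict(self) -> dict:
        W = self.params.window
        L = self.params.max_span
        return {
            "mutation": self.mutation.code(),
            "model_id": self.model_id,
            "params": {
                "window": W,
                "max_span": L,
                "u_lengths": list(self.params.u_lengths),
            },
            "relative_entropy": self.relent.to_dict() if self.relent else None,
            "region_scan": self.scan.to_dict(),
            "notes": {
                "delta_sign": "pair delta = mutant - WT; acc_delta = WT - mutant",
                "relative_entropy_space": (
                    "conditional distributions over the common structure space; "
                    "infinite_flag marks divergent strict KL"
                ),
                "background_model": (
                    "exhaustive on-the-fly background of all 3n single-nucleotide "
                    "substitutions of the input sequence"
                ),
            },
        }


def build_impact_report(
    wt: RnaSequence,
    spec: MutationSpec,
    model: EnergyModel,
    params: FoldingParams | None = None,
    window_lengths=(50,),
    step: int = 5,
    compute_pvalues: bool = True,
) -> ImpactReport:
    """Run both scorers on a WT sequence and a mutation spec.

    The relative entropy is computed on the global ensemble (span cap L
    applied identically to both sequences); the region scan and its
    p-values use the folding mode given by ``params``.
    """
    if params is None:
        params = FoldingParams()
    mut = apply_mutations(wt, spec)
    _, L = params.resolve(wt.n)
    relent = ensemble_relative_entropy(
        wt, mut, model, max_span=L if L < wt.n else None
    )

    config = ScanConfig(
        model=model, params=params,
        window_lengths=tuple(window_lengths), step=step,
    )
    wt_matrix = config.fold(wt)
    mut_matrix = config.fold(mut)
    scan = region_distance_scan(wt_matrix, mut_matrix, window_lengths, step)

    if compute_pvalues:
        background = background_scores(wt, config)
        exclude = None
        if len(spec.edits) == 1 and not spec.is_identity:
            exclude = spec.code()
        scan.p_d, scan.background_size = empirical_pvalue(
            scan.d_max, wt, config, "d", exclude=exclude, background=background
        )
        scan.p_r, _ = empirical_pvalue(
            scan.r_min, wt, config, "r", exclude=exclude, background=background
        )

    return ImpactReport(
        relent=relent, scan=scan, mutation=spec, params=params,
        model_id=model.model_id,
    )
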