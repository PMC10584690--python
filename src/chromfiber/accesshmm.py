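"""Two-state chain HMM for molecule-wide DNA accessibility decoding.

Each usable adenine along a molecule contributes two hidden states —
accessible or inaccessible to the methyltransferase — with Bernoulli
emissions on the observed binary methylation call.  Emission
probabilities come from control molecules: the accessible-state rate is
the fraction of fully methylated naked-DNA control molecules called
methylated at that adenine, the inaccessible-state rate the fraction of
unmethylated control molecules called methylated, each smoothed as
(k + 0.5) / (n + 0.5) so no rate is exactly zero.

Transitions follow a geometric run-length model: with expected state
run length L bp, the per-base switching hazard is 1/L, so the
probability of staying in the same state across an inter-adenine gap of
B bases is (1 - 1/L)^B.  The default L = 1000 bp deliberately demands a
high burden of evidence to switch states, minimizing spurious
switching.  Decoding is maximum a posteriori (Viterbi); the decoded
per-adenine path (accessible = 1, inaccessible = 0) is interpolated to
a per-base accessibility track.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .synthdata import MethylationCalls

INACCESSIBLE, ACCESSIBLE = 0, 1
DEFAULT_RUN_LENGTH = 1000.0


@dataclass(frozen=True)
class AccessibilityHMM:
    """Chain HMM over usable adenines of one template or molecule."""

    adenine_positions: np.ndarray
    p_meth_acc: np.ndarray  # P(methylation call | accessible), per adenine
    p_meth_inacc: np.ndarray  # P(methylation call | inaccessible), per adenine
    expected_run_length: float = DEFAULT_RUN_LENGTH
    initial_accessible: float = 0.5

    def __post_init__(self) -> None:
        pos = np.asarray(self.adenine_positions, dtype=int)
        pa = np.asarray(self.p_meth_acc, dtype=float)
        pi = np.asarray(self.p_meth_inacc, dtype=float)
        object.__setattr__(self, "adenine_positions", pos)
        object.__setattr__(self, "p_meth_acc", pa)
        object.__setattr__(self, "p_meth_inacc", pi)
        if len(pos) == 0:
            raise ValueError("HMM needs at least one usable adenine")
        if not (len(pos) == len(pa) == len(pi)):
            raise ValueError("positions and emission arrays must match in length")
        if len(pos) > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError("adenine positions must be strictly increasing")
        if np.any(pi <= 0) or np.any(pi > pa) or np.any(pa > 1):
            raise ValueError("emissions must satisfy 0 < p_inacc <= p_acc <= 1")
        if self.expected_run_length <= 1:
            raise ValueError("expected_run_length must exceed 1 bp")
        if not 0 < self.initial_accessible < 1:
            raise ValueError("initial_accessible must be in (0, 1)")

    @property
    def n_adenines(self) -> int:
        return len(self.adenine_positions)

    def stay_probabilities(self) -> np.ndarray:
        """(1 - 1/L)^B for each inter-adenine gap B (length n-1)."""
        gaps = np.diff(self.adenine_positions)
        return (1.0 - 1.0 / self.expected_run_length) ** gaps


@dataclass(frozen=True)
class StatePath:
    """A decoded state sequence with its joint log-probability."""

    states: np.ndarray  # per-adenine, ACCESSIBLE or INACCESSIBLE
    log_probability: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", np.asarray(self.states, dtype=int))


@dataclass(frozen=True)
class AccessibilityTrack:
    """Per-base accessibility values in [0, 1]."""

    template_length: int
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(vals) != self.template_length:
            raise ValueError("track length must equal template_length")
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("track values must lie in [0, 1]")


def emissions_from_controls(methylated_count, total_count) -> np.ndarray:
    """Smoothed per-adenine methylation fraction (k + 0.5) / (n + 0.5)."""
    k = np.asarray(methylated_count, dtype=float)
    n = np.asarray(total_count, dtype=float)
    if np.any(k < 0) or np.any(n < 1):
        raise ValueError("counts must satisfy n >= 1 and k >= 0")
    if np.any(k > n):
        raise ValueError("methylated_count cannot exceed total_count")
    return (k + 0.5) / (n + 0.5)


def build_hmm(
    adenine_positions,
    p_meth_acc,
    p_meth_inacc,
    expected_run_length: float = DEFAULT_RUN_LENGTH,
    usable_mask=None,
    initial_accessible: float = 0.5,
) -> AccessibilityHMM:
    """Assemble the chain HMM over usable adenines.

    In homogeneous mode the two emission vectors are control fractions
    shared by every molecule of an amplicon; in genomic mode they are
    per-molecule rate maps supplied by the caller.  Unusable adenines
    are dropped from the chain and their distances absorbed into the
    inter-adenine gaps.
    """
    pos = np.asarray(adenine_positions, dtype=int)
    pa = np.asarray(p_meth_acc, dtype=float)
    pi = np.asarray(p_meth_inacc, dtype=float)
    if usable_mask is not None:
        mask = np.asarray(usable_mask, dtype=bool)
        pos, pa, pi = pos[mask], pa[mask], pi[mask]
    if len(pos) == 0:
        raise ValueError("no usable adenines")
    return AccessibilityHMM(pos, pa, pi, expected_run_length, initial_accessible)


def _emission_logp(hmm: AccessibilityHMM, calls: np.ndarray) -> np.ndarray:
    """(2, n) emission log-probabilities; row 0 inaccessible, row 1 accessible."""
    with np.errstate(divide="ignore"):
        out = np.stack(
            [
                np.where(calls == 1, np.log(hmm.p_meth_inacc), np.log1p(-hmm.p_meth_inacc)),
                np.where(calls == 1, np.log(hmm.p_meth_acc), np.log1p(-hmm.p_meth_acc)),
            ]
        )
    return out


def _align_calls(hmm: AccessibilityHMM, calls) -> np.ndarray:
    if isinstance(calls, MethylationCalls):
        if len(calls.calls) == hmm.n_adenines and np.array_equal(
            calls.adenine_positions, hmm.adenine_positions
        ):
            obs = calls.calls
        else:
            # restrict molecule calls to the HMM's (usable) adenines
            idx = np.searchsorted(calls.adenine_positions, hmm.adenine_positions)
            if np.any(idx >= len(calls.adenine_positions)) or np.any(
                calls.adenine_positions[idx] != hmm.adenine_positions
            ):
                raise ValueError("molecule calls do not cover the HMM's adenines")
            obs = calls.calls[idx]
    else:
        obs = np.asarray(calls, dtype=int)
    if len(obs) != hmm.n_adenines:
        raise ValueError("observation length does not match the HMM")
    return obs


def viterbi_decode(hmm: AccessibilityHMM, calls) -> StatePath:
    """Most likely accessibility path given the binary methylation calls.

    Log-space dynamic program, linear in the number of adenines.  On an
    exact score tie the inaccessible state is preferred (conservative
    footprint calling).
    """
    obs = _align_calls(hmm, calls)
    n = hmm.n_adenines
    em = _emission_logp(hmm, obs)
    stay = hmm.stay_probabilities()
    with np.errstate(divide="ignore"):
        log_stay = np.log(stay)
        log_switch = np.log1p(-stay)
        init = np.array(
            [np.log(1.0 - hmm.initial_accessible), np.log(hmm.initial_accessible)]
        )

    score = init + em[:, 0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        # cand[j, i]: arriving in state i from state j
        cand = np.array(
            [
                [score[0] + log_stay[t - 1], score[0] + log_switch[t - 1]],
                [score[1] + log_switch[t - 1], score[1] + log_stay[t - 1]],
            ]
        )
        # argmax over predecessor j; ties broken toward inaccessible (j=0)
        back[t] = np.where(cand[1] > cand[0], 1, 0)
        score = cand.max(axis=0) + em[:, t]
    # final tie also resolved toward inaccessible
    last = int(score[1] > score[0])
    states = np.empty(n, dtype=int)
    states[-1] = last
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return StatePath(states=states, log_probability=float(score[last]))


def brute_force_decode(hmm: AccessibilityHMM, calls, max_adenines: int = 20) -> StatePath:
    """Exhaustive-enumeration decoder, usable as an independent oracle.

    Scores every one of the 2^n state paths directly; refuses more than
    ``max_adenines`` adenines.  Ties are broken toward the path that is
    lexicographically smaller (all-inaccessible first), matching the
    Viterbi preference.
    """
    obs = _align_calls(hmm, calls)
    n = hmm.n_adenines
    if n > max_adenines:
        raise ValueError(f"brute force limited to {max_adenines} adenines")
    em = _emission_logp(hmm, obs)
    stay = hmm.stay_probabilities()
    init = np.log([1.0 - hmm.initial_accessible, hmm.initial_accessible])
    best_lp, best_path = -np.inf, None
    for path in product((0, 1), repeat=n):
        lp = init[path[0]] + em[path[0], 0]
        for t in range(1, n):
            p_stay = stay[t - 1]
            lp += np.log(p_stay if path[t] == path[t - 1] else 1.0 - p_stay)
            lp += em[path[t], t]
        if lp > best_lp:
            best_lp, best_path = lp, path
    return StatePath(states=np.array(best_path), log_probability=float(best_lp))


def interpolate_track(
    path: StatePath,
    positions,
    template_length: int,
    method: str = "linear",
) -> AccessibilityTrack:
    """Expand a decoded per-adenine path to a per-base track.

    Decoded adenines take 1 (accessible) or 0 (inaccessible); bases
    between consecutive decoded adenines are linearly interpolated
    (``method='nearest'`` snaps to the closer adenine instead); bases
    before the first and after the last decoded adenine copy the
    nearest decoded value.
    """
    pos = np.asarray(positions, dtype=int)
    states = np.asarray(path.states, dtype=float)
    if len(pos) == 0:
        raise ValueError("cannot interpolate an empty path")
    if len(pos) != len(states):
        raise ValueError("positions and path lengths differ")
    if np.any(pos < 0) or np.any(pos >= template_length):
        raise ValueError("positions outside the template")
    base = np.arange(template_length)
    if method == "linear":
        values = np.interp(base, pos, states)
    elif method == "nearest":
        idx = np.clip(np.searchsorted(pos, base), 1, len(pos) - 1) if len(pos) > 1 else None
        if idx is None:
            values = np.full(template_length, states[0])
        else:
            left, right = pos[idx - 1], pos[idx]
            nearest = np.where(base - left <= right - base, idx - 1, idx)
            values = states[nearest]
            values[base <= pos[0]] = states[0]
            values[base >= pos[-1]] = states[-1]
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return AccessibilityTrack(template_length=template_length, values=values)


def decode_molecule(
    hmm: AccessibilityHMM,
    calls: MethylationCalls,
    template_length: int,
    method: str = "linear",
) -> AccessibilityTrack:
    """Viterbi-decode one molecule and interpolate to a per-base track."""
    path = viterbi_decode(hmm, calls)
    return interpolate_track(path, hmm.adenine_positions, template_length, method=method)
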