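"""Synthetic methylation-footprinting data with the structure the decoder assumes.

Generates per-adenine methylation efficiencies (a :class:`RateMap`),
per-molecule binary methylation calls for fibers carrying planted
nucleosome footprints, positive/negative control molecules (naked fully
methylated / unmethylated DNA), and two-component Student-t residual
samples for the mixture-threshold stage.

The forward model matches the decoder's generative assumptions: each
adenine is methylated with probability ``p_acc`` when the base is
accessible to the methyltransferase and ``p_inacc`` when protected by a
nucleosome.  An adenine occupies a template position on whichever strand
carries the A, so a single merged coordinate track holds at most one
adenine per position; the default inclusion fraction of 0.5 models A/T
content.  Default efficiencies (mean p_acc ~ 0.40, mean p_inacc ~ 0.02,
Beta-distributed across adenines) are fixture choices that make
nucleosome-scale footprints detectable; they are not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .arraysim import FiberTemplate

_EPS = 1e-9


@dataclass(frozen=True)
class RateMap:
    """Per-adenine methylation probabilities in the two accessibility states."""

    template_id: str
    template_length: int
    adenine_positions: np.ndarray  # strictly increasing ints
    p_acc: np.ndarray
    p_inacc: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.adenine_positions, dtype=int)
        pa = np.asarray(self.p_acc, dtype=float)
        pi = np.asarray(self.p_inacc, dtype=float)
        object.__setattr__(self, "adenine_positions", pos)
        object.__setattr__(self, "p_acc", pa)
        object.__setattr__(self, "p_inacc", pi)
        if not (len(pos) == len(pa) == len(pi)):
            raise ValueError("positions and rate arrays must have equal length")
        if len(pos) and (np.any(np.diff(pos) <= 0)):
            raise ValueError("adenine positions must be strictly increasing")
        if len(pos) and (pos[0] < 0 or pos[-1] >= self.template_length):
            raise ValueError("adenine positions outside the template")
        if np.any(pi <= 0) or np.any(pi >= pa) or np.any(pa > 1):
            raise ValueError("rates must satisfy 0 < p_inacc < p_acc <= 1")

    @property
    def n_adenines(self) -> int:
        return len(self.adenine_positions)


@dataclass(frozen=True)
class MethylationCalls:
    """Binary methylation observations for one molecule."""

    molecule_id: str
    template_id: str
    adenine_positions: np.ndarray
    calls: np.ndarray  # 1 = methylated
    usable: np.ndarray  # boolean mask

    def __post_init__(self) -> None:
        pos = np.asarray(self.adenine_positions, dtype=int)
        calls = np.asarray(self.calls, dtype=int)
        usable = np.asarray(self.usable, dtype=bool)
        object.__setattr__(self, "adenine_positions", pos)
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "usable", usable)
        if not (len(pos) == len(calls) == len(usable)):
            raise ValueError("positions/calls/usable must have equal length")
        if len(pos) and np.any(np.diff(pos) <= 0):
            raise ValueError("adenine positions must be strictly increasing")
        if not np.isin(calls, (0, 1)).all():
            raise ValueError("calls must be binary")


@dataclass(frozen=True)
class ResidualSample:
    """Log-IPD residuals, optionally with generating-component labels."""

    values: np.ndarray
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.isfinite(vals).all():
            raise ValueError("residual values must be finite")
        if self.truth is not None:
            truth = np.asarray(self.truth, dtype=int)
            object.__setattr__(self, "truth", truth)
            if len(truth) != len(vals):
                raise ValueError("truth labels must match values in length")


def make_rate_map(
    template_length: int,
    adenine_fraction: float = 0.5,
    acc_beta: tuple[float, float] = (8.0, 12.0),
    inacc_beta: tuple[float, float] = (2.0, 98.0),
    seed: int | None = None,
    template_id: str = "synth",
) -> RateMap:
    """Draw adenine positions and per-adenine state-dependent rates.

    Positions are included independently at ``adenine_fraction``; rates
    come from the two Beta laws (defaults mean 0.40 accessible, 0.02
    inaccessible) and are clipped into 0 < p_inacc < p_acc <= 1.
    """
    if not 0 < adenine_fraction <= 1:
        raise ValueError("adenine_fraction must be in (0, 1]")
    if min(acc_beta) <= 0 or min(inacc_beta) <= 0:
        raise ValueError("Beta shape parameters must be positive")
    rng = np.random.default_rng(seed)
    include = rng.random(template_length) < adenine_fraction
    positions = np.flatnonzero(include)
    n = len(positions)
    p_acc = np.clip(rng.beta(*acc_beta, size=n), _EPS, 1.0)
    p_inacc = np.clip(rng.beta(*inacc_beta, size=n), _EPS, 1.0)
    p_inacc = np.minimum(p_inacc, p_acc - _EPS)
    if np.any(p_inacc <= 0) or np.any(p_inacc >= p_acc):
        raise ValueError("could not produce valid rates; check Beta parameters")
    return RateMap(template_id, template_length, positions, p_acc, p_inacc)


def simulate_molecule(
    fiber: FiberTemplate, rates: RateMap, seed: int | None = None, molecule_id: str = "mol0"
) -> MethylationCalls:
    """Bernoulli calls: p_inacc inside planted footprints, p_acc outside."""
    if rates.template_length != fiber.template_length:
        raise ValueError(
            f"rate map length {rates.template_length} != fiber length {fiber.template_length}"
        )
    rng = np.random.default_rng(seed)
    inside = np.zeros(rates.template_length, dtype=bool)
    for start, end in fiber.footprints():
        inside[start:end] = True
    p = np.where(inside[rates.adenine_positions], rates.p_inacc, rates.p_acc)
    calls = (rng.random(rates.n_adenines) < p).astype(int)
    return MethylationCalls(
        molecule_id=molecule_id,
        template_id=rates.template_id,
        adenine_positions=rates.adenine_positions.copy(),
        calls=calls,
        usable=np.ones(rates.n_adenines, dtype=bool),
    )


def simulate_controls(
    rates: RateMap, n_molecules: int, kind: str, seed: int | None = None
) -> list[MethylationCalls]:
    """Control molecules: ``positive`` = fully methylated naked DNA
    (p_acc everywhere), ``negative`` = unmethylated (p_inacc everywhere)."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if kind == "positive":
        p = rates.p_acc
    elif kind == "negative":
        p = rates.p_inacc
    else:
        raise ValueError(f"unknown control kind {kind!r}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_molecules):
        calls = (rng.random(rates.n_adenines) < p).astype(int)
        out.append(
            MethylationCalls(
                molecule_id=f"{kind}{i}",
                template_id=rates.template_id,
                adenine_positions=rates.adenine_positions.copy(),
                calls=calls,
                usable=np.ones(rates.n_adenines, dtype=bool),
            )
        )
    return out


def control_counts(controls: Sequence[MethylationCalls]) -> tuple[np.ndarray, np.ndarray]:
    """Per-adenine (methylated_count, total_count) over control molecules."""
    if not controls:
        raise ValueError("need at least one control molecule")
    calls = np.vstack([c.calls for c in controls])
    return calls.sum(axis=0), np.full(calls.shape[1], len(controls))


def simulate_residuals(n: int, mixture, seed: int | None = None) -> ResidualSample:
    """Draw ``n`` residuals from a two-component Student-t mixture.

    ``mixture`` is a :class:`chromfiber.methylmix.TMixture`; truth labels
    record the generating component (0 = lower mean, 1 = upper mean).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.asarray(mixture.weights, dtype=float)
    comp = rng.choice(2, size=n, p=weights / weights.sum())
    values = np.empty(n)
    for j in range(2):
        idx = comp == j
        k = int(idx.sum())
        if k:
            values[idx] = mixture.means[j] + mixture.scales[j] * rng.standard_t(
                mixture.dfs[j], size=k
            )
    return ResidualSample(values=values, truth=comp)


def write_calls_tsv(calls_list: Iterable[MethylationCalls], path) -> None:
    """MethylationCalls as TSV: molecule_id, position, call, usable."""
    with open(path, "w") as fh:
        fh.write("molecule_id\tposition\tcall\tusable\n")
        for mc in calls_list:
            for pos, call, use in zip(mc.adenine_positions, mc.calls, mc.usable):
                fh.write(f"{mc.molecule_id}\t{pos}\t{call}\t{int(use)}\n")


def read_calls_tsv(path, template_id: str = "synth") -> list[MethylationCalls]:
    """Read molecules written by :func:`write_calls_tsv`."""
    per_mol: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            mol, pos, call, use = line.rstrip("\n").split("\t")
            per_mol.setdefault(mol, []).append((int(pos), int(call), int(use)))
    out = []
    for mol, rows in per_mol.items():
        rows.sort()
        pos, calls, use = zip(*rows)
        out.append(
            MethylationCalls(
                molecule_id=mol,
                template_id=template_id,
                adenine_positions=np.array(pos),
                calls=np.array(calls),
                usable=np.array(use, dtype=bool),
            )
        )
    return out


def write_rate_map_tsv(rates: RateMap, path) -> None:
    """RateMap as TSV: position, p_acc, p_inacc."""
    with open(path, "w") as fh:
        fh.write("position\tp_acc\tp_inacc\n")
        for pos, pa, pi in zip(rates.adenine_positions, rates.p_acc, rates.p_inacc):
            fh.write(f"{pos}\t{pa:.10g}\t{pi:.10g}\n")


def read_rate_map_tsv(path, template_length: int, template_id: str = "synth") -> RateMap:
    """Read a rate map written by :func:`write_rate_map_tsv`."""
    pos, pa, pi = [], [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            p, a, i = line.rstrip("\n").split("\t")
            pos.append(int(p))
            pa.append(float(a))
            pi.append(float(i))
    return RateMap(template_id, template_length, np.array(pos), np.array(pa), np.array(pi))
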