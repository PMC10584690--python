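"""Monte-Carlo nucleosome array simulation and in-silico remodeling.

Fibers are fixed-length DNA templates carrying non-overlapping 147-bp
nucleosome footprints.  Arrays are initialized by random sequential
adsorption (rejection sampling of uniform start positions), which is
subject to the Rényi car-parking limit at high density, and are then
remodeled by one of two idealized nucleosome-sliding processes:

``clamp``
    A "ruler" remodeler: in a single 5'→3' pass, any nucleosome whose
    linker to its 5' neighbor is within a visibility threshold is slid
    against that neighbor to a fixed (optionally jittered) ruler
    distance.  The 5' nucleosome always acts as the barrier.

``length_sensing``
    A flanking-DNA-sensing remodeler: over many sweeps, each nucleosome
    slides one step toward a flank only when that flank exceeds a
    sensing cutoff, with a fair coin when both flanks qualify.  Modeled
    as a step function of flank length.

Both processes only slide nucleosomes; they never evict or load them.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NUCLEOSOME_LENGTH = 147
DEFAULT_MIN_LINKER = 10
DEFAULT_VISIBILITY = 183


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place another nucleosome."""


class InvalidFiberError(ValueError):
    """Raised when a fiber violates the non-overlap/ordering invariants."""


@dataclass(frozen=True)
class FiberTemplate:
    """A template of ``template_length`` bp with sorted nucleosome starts.

    ``entries`` are 0-based start positions of ``nucleosome_length``-bp
    footprints; footprints must be pairwise disjoint and lie inside the
    template.
    """

    template_id: str
    template_length: int
    entries: tuple[int, ...] = ()
    nucleosome_length: int = NUCLEOSOME_LENGTH

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(int(e) for e in self.entries))
        self.validate()

    def validate(self) -> None:
        if self.template_length <= 0:
            raise InvalidFiberError("template_length must be positive")
        if self.nucleosome_length <= 0:
            raise InvalidFiberError("nucleosome_length must be positive")
        prev_exit = None
        for e in self.entries:
            if not 0 <= e <= self.template_length - self.nucleosome_length:
                raise InvalidFiberError(
                    f"entry {e} outside [0, {self.template_length - self.nucleosome_length}]"
                )
            if prev_exit is not None and e < prev_exit:
                raise InvalidFiberError("entries overlap or are unsorted")
            prev_exit = e + self.nucleosome_length

    @property
    def n_nucleosomes(self) -> int:
        return len(self.entries)

    @property
    def exits(self) -> tuple[int, ...]:
        return tuple(e + self.nucleosome_length for e in self.entries)

    def linkers(self) -> list[int]:
        """Internal linker lengths (next entry minus previous exit)."""
        return [
            self.entries[i + 1] - (self.entries[i] + self.nucleosome_length)
            for i in range(len(self.entries) - 1)
        ]

    def footprints(self) -> list[tuple[int, int]]:
        """Half-open (start, end) footprint intervals."""
        return [(e, e + self.nucleosome_length) for e in self.entries]


@dataclass(frozen=True)
class RemodelConfig:
    """Parameters for in-silico remodeling.

    ``ruler`` is the clamp target linker in nt (20 and 48 model the
    SNF2h and ACF sensing ranges); ``ruler_sd`` adds normal jitter,
    truncated at zero.  ``visibility`` is the maximal linker at which a
    3' nucleosome is seen by the clamp.  ``flank_cutoff`` is the
    length-sensing step-function gate; ``step`` the per-translocation
    shift and ``n_sweeps`` the number of 5'→3' passes.
    """

    mode: str = "clamp"  # {"clamp", "length_sensing"}
    ruler: int = 20
    ruler_sd: float = 0.0
    visibility: int = DEFAULT_VISIBILITY
    flank_cutoff: int = 48
    step: int = 1
    n_sweeps: int = 500
    slide_mode: str = "step"  # {"step", "until_blocked"} per visit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("clamp", "length_sensing"):
            raise ValueError(f"unknown remodeling mode {self.mode!r}")
        if self.slide_mode not in ("step", "until_blocked"):
            raise ValueError(f"unknown slide_mode {self.slide_mode!r}")
        if self.ruler < 0:
            raise ValueError("ruler must be >= 0")
        if self.ruler_sd < 0:
            raise ValueError("ruler_sd must be >= 0")
        if self.visibility <= 0:
            raise ValueError("visibility must be > 0")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.flank_cutoff < self.step:
            raise ValueError("flank_cutoff must be >= step")
        if self.n_sweeps <= 0:
            raise ValueError("n_sweeps must be positive")


def place_nucleosomes(
    template_length: int,
    n_nucleosomes: int,
    min_linker: int = DEFAULT_MIN_LINKER,
    max_attempts: int = 10_000,
    seed: int | None = None,
    template_id: str = "sim",
    nucleosome_length: int = NUCLEOSOME_LENGTH,
    max_restarts: int = 100,
) -> FiberTemplate:
    """Randomly place ``n_nucleosomes`` non-overlapping nucleosomes.

    Candidate starts are drawn uniformly on the template and accepted
    only when the new footprint keeps at least ``min_linker`` nt between
    adjacent entry/exit points.  Random sequential adsorption jams below
    the Rényi coverage limit, so after ``max_attempts`` consecutive
    rejections the partial configuration is discarded and placement
    restarts from an empty template; :class:`PackingError` is raised
    once ``max_restarts`` runs have all jammed (or immediately when the
    requested count cannot fit by length).
    """
    if n_nucleosomes < 0:
        raise ValueError("n_nucleosomes must be >= 0")
    if min_linker < 0:
        raise ValueError("min_linker must be >= 0")
    if template_length < n_nucleosomes * nucleosome_length:
        raise PackingError(
            f"{n_nucleosomes} nucleosomes of {nucleosome_length} bp cannot fit "
            f"on a {template_length}-bp template"
        )
    rng = np.random.default_rng(seed)
    max_start = template_length - nucleosome_length
    entries: list[int] = []
    restarts = 0
    rejections = 0
    while len(entries) < n_nucleosomes:
        cand = int(rng.integers(0, max_start + 1))
        # accept only if the footprint plus min_linker clears every placed one
        ok = all(
            cand + nucleosome_length + min_linker <= e
            or e + nucleosome_length + min_linker <= cand
            for e in entries
        )
        if ok:
            entries.append(cand)
            rejections = 0
        else:
            rejections += 1
            if rejections >= max_attempts:
                restarts += 1
                if restarts >= max_restarts:
                    raise PackingError(
                        f"gave up after {restarts} jammed placement runs of "
                        f"{max_attempts} consecutive rejections each at density "
                        f"{n_nucleosomes}"
                    )
                entries.clear()
                rejections = 0
    return FiberTemplate(
        template_id=template_id,
        template_length=template_length,
        entries=tuple(sorted(entries)),
        nucleosome_length=nucleosome_length,
    )


def remodel_clamp(
    fiber: FiberTemplate, config: RemodelConfig, seed: int | None = None
) -> FiberTemplate:
    """One 5'→3' clamping pass: visible nucleosomes snap to the ruler.

    Pair (i, i+1) is visible when the current linker (entry_{i+1} minus
    exit_i, with exit_i already updated by earlier moves in the pass) is
    at most ``config.visibility``; the 3' nucleosome is then placed at
    exit_i + d with d ~ Normal(ruler, ruler_sd) truncated at 0 and
    rounded to an integer, constrained so it never overlaps the next
    nucleosome downstream and never leaves the template.
    """
    fiber.validate()
    if config.mode != "clamp":
        raise ValueError("config.mode must be 'clamp'")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    L = fiber.nucleosome_length
    entries = list(fiber.entries)
    for i in range(len(entries) - 1):
        exit_i = entries[i] + L
        linker = entries[i + 1] - exit_i
        if linker > config.visibility:
            continue
        if config.ruler_sd > 0:
            d = max(0.0, rng.normal(config.ruler, config.ruler_sd))
        else:
            d = float(config.ruler)
        new_entry = exit_i + int(round(d))
        upper = fiber.template_length - L
        if i + 2 < len(entries):
            upper = min(upper, entries[i + 2] - L)
        entries[i + 1] = min(new_entry, upper)
    return replace(fiber, entries=tuple(entries))


def remodel_length_sensing(
    fiber: FiberTemplate, config: RemodelConfig, seed: int | None = None
) -> FiberTemplate:
    """Iterative flank-gated sliding, ``config.n_sweeps`` 5'→3' sweeps.

    Per nucleosome and sweep: the 5' flank is the gap to the 5'
    neighbor's exit (or to position 0) and the 3' flank the gap to the
    3' neighbor's entry (or to the template end).  The nucleosome moves
    ``config.step`` nt toward a flank only if that flank is at least
    ``config.flank_cutoff``; a fair coin decides when both qualify.
    With ``slide_mode='until_blocked'`` the direction is chosen once per
    visit and the nucleosome keeps stepping until that flank falls below
    the cutoff (the default single step preserves the density-dependent
    steady state that distinguishes the mechanisms).
    """
    fiber.validate()
    if config.mode != "length_sensing":
        raise ValueError("config.mode must be 'length_sensing'")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    L = fiber.nucleosome_length
    entries = list(fiber.entries)
    n = len(entries)
    cutoff, step = config.flank_cutoff, config.step
    until_blocked = config.slide_mode == "until_blocked"
    for _ in range(config.n_sweeps):
        for i in range(n):
            left_bound = entries[i - 1] + L if i > 0 else 0
            right_bound = entries[i + 1] if i < n - 1 else fiber.template_length
            flank5 = entries[i] - left_bound
            flank3 = right_bound - (entries[i] + L)
            go5 = flank5 >= cutoff
            go3 = flank3 >= cutoff
            if go5 and go3:
                direction = -1 if rng.random() < 0.5 else 1
            elif go5:
                direction = -1
            elif go3:
                direction = 1
            else:
                continue
            if until_blocked:
                flank = flank5 if direction < 0 else flank3
                moves = (flank - cutoff) // step + 1  # last step crosses the gate
                entries[i] += direction * step * int(moves)
            else:
                entries[i] += direction * step
    return replace(fiber, entries=tuple(entries))


def remodel(fiber: FiberTemplate, config: RemodelConfig, seed: int | None = None) -> FiberTemplate:
    """Dispatch to the configured remodeling mode."""
    if config.mode == "clamp":
        return remodel_clamp(fiber, config, seed)
    return remodel_length_sensing(fiber, config, seed)


def regular_array(
    template_length: int,
    nrl: int,
    phase: int = 0,
    n_nucleosomes: int | None = None,
    template_id: str = "regular",
    nucleosome_length: int = NUCLEOSOME_LENGTH,
) -> FiberTemplate:
    """An evenly spaced array with entry-to-entry spacing ``nrl``.

    Starts at ``phase`` and packs nucleosomes every ``nrl`` bp until the
    template ends (or ``n_nucleosomes`` is reached).  Useful as a
    ground-truth fixture for repeat-length estimation.
    """
    if nrl < nucleosome_length:
        raise ValueError("nrl must be at least the nucleosome length")
    entries = []
    e = phase
    while e <= template_length - nucleosome_length:
        entries.append(e)
        if n_nucleosomes is not None and len(entries) >= n_nucleosomes:
            break
        e += nrl
    return FiberTemplate(
        template_id=template_id,
        template_length=template_length,
        entries=tuple(entries),
        nucleosome_length=nucleosome_length,
    )


def jittered_regular_array(
    template_length: int,
    nrl: int,
    n_nucleosomes: int,
    jitter_sd: float = 10.0,
    seed: int | None = None,
    template_id: str = "regular",
    nucleosome_length: int = NUCLEOSOME_LENGTH,
) -> FiberTemplate:
    """A regular array with random phase and per-nucleosome jitter.

    The array of ``n_nucleosomes`` at spacing ``nrl`` is placed at a
    uniform random phase within the template, then every entry receives
    independent Normal(0, jitter_sd) displacement (rounded, clipped to
    keep footprints disjoint and on-template).  Emulates the positional
    noise of real phased fibers; used as the planted-population fixture
    for repeat-length and clustering analyses.
    """
    span = (n_nucleosomes - 1) * nrl + nucleosome_length
    if span > template_length:
        raise ValueError("array span exceeds template length")
    rng = np.random.default_rng(seed)
    phase = int(rng.integers(0, template_length - span + 1))
    entries: list[int] = []
    prev_exit = 0
    for i in range(n_nucleosomes):
        e = phase + i * nrl + int(round(rng.normal(0.0, jitter_sd)))
        e = min(max(e, prev_exit), template_length - nucleosome_length)
        entries.append(e)
        prev_exit = e + nucleosome_length
    return FiberTemplate(
        template_id=template_id,
        template_length=template_length,
        entries=tuple(entries),
        nucleosome_length=nucleosome_length,
    )


def occupancy_track(fiber: FiberTemplate) -> np.ndarray:
    """Per-base accessibility: 0 inside footprints, 1 elsewhere."""
    fiber.validate()
    track = np.ones(fiber.template_length, dtype=float)
    for start, end in fiber.footprints():
        track[start:end] = 0.0
    return track


def write_fiber_bed(fibers: list[FiberTemplate], path) -> None:
    """Write fibers as BED3+ text: molecule_id, start, end, template_id, template_length."""
    with open(path, "w") as fh:
        fh.write("#molecule_id\tstart\tend\ttemplate_id\ttemplate_length\n")
        for i, fib in enumerate(fibers):
            for start, end in fib.footprints():
                fh.write(
                    f"mol{i}\t{start}\t{end}\t{fib.template_id}\t{fib.template_length}\n"
                )


def read_fiber_bed(path) -> list[FiberTemplate]:
    """Read fibers written by :func:`write_fiber_bed`."""
    per_mol: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            mol, start, end, tid, tlen = line.rstrip("\n").split("\t")
            rec = per_mol.setdefault(mol, {"tid": tid, "tlen": int(tlen), "entries": []})
            rec["entries"].append(int(start))
    return [
        FiberTemplate(
            template_id=rec["tid"],
            template_length=rec["tlen"],
            entries=tuple(sorted(rec["entries"])),
        )
        for rec in per_mol.values()
    ]
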