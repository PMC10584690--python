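"""Inaccessible-region calling, nucleosome counting and fiber density.

Inaccessible regions are maximal runs of bases whose decoded
accessibility is at or below a threshold (default 0.5, inclusive).
Region lengths map to nucleosome counts through a configurable ladder
of length cutoffs: very short regions (< ``sub_max``) count zero —
subnucleosomal protections such as nonspecific histone-DNA contacts —
and successive boundaries separate the mono-, di-, tri-... nucleosome
classes, with an extrapolation increment past the last boundary.  The
default ladder (100 / 280 / 450 / 620 bp, +170 bp per extra
nucleosome) reflects the 147-bp nucleosome core plus typical observed
mono-nucleosome footprints of roughly 120-160 nt; real datasets
calibrate their own ladder from the footprint-length histogram
(:func:`suggest_cutoffs`).

Per-fiber nucleosome density is total nucleosomes x 1000 / template
length (nucleosomes per kbp); horizon plots are 2-D histograms of
footprint midpoint versus footprint length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmin

from .accesshmm import AccessibilityTrack

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class NucCountCutoffs:
    """Length ladder mapping footprint length to nucleosome count."""

    sub_max: int = 100
    boundaries: tuple[int, ...] = (280, 450, 620)
    extrapolation_increment: int = 170

    def __post_init__(self) -> None:
        ladder = (self.sub_max, *self.boundaries)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        if self.extrapolation_increment <= 0:
            raise ValueError("extrapolation_increment must be positive")

    def count_for_length(self, length: int) -> int:
        if length < self.sub_max:
            return 0
        for k, b in enumerate(self.boundaries, start=1):
            if length < b:
                return k
        extra = (length - self.boundaries[-1]) // self.extrapolation_increment
        return len(self.boundaries) + int(extra) + 1


@dataclass(frozen=True)
class FootprintSet:
    """Disjoint sorted inaccessible intervals for one molecule."""

    molecule_id: str
    regions: tuple[tuple[int, int], ...]
    nuc_count_per_region: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        regions = tuple((int(s), int(e)) for s, e in self.regions)
        object.__setattr__(self, "regions", regions)
        prev_end = -1
        for s, e in regions:
            if e <= s:
                raise ValueError("regions must have end > start")
            if s < prev_end:
                raise ValueError("regions must be sorted and disjoint")
            prev_end = e
        if self.nuc_count_per_region is not None:
            counts = tuple(int(c) for c in self.nuc_count_per_region)
            object.__setattr__(self, "nuc_count_per_region", counts)
            if len(counts) != len(regions):
                raise ValueError("one count per region required")
            if any(c < 0 for c in counts):
                raise ValueError("counts must be non-negative")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.regions], dtype=int)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(s + e) / 2.0 for s, e in self.regions])

    @property
    def total_nucleosomes(self) -> int:
        if self.nuc_count_per_region is None:
            raise ValueError("nucleosome counts not yet assigned")
        return int(sum(self.nuc_count_per_region))


def call_inaccessible_regions(
    track: AccessibilityTrack | np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    molecule_id: str = "mol0",
) -> FootprintSet:
    """Maximal runs with accessibility <= threshold, as half-open intervals."""
    values = track.values if isinstance(track, AccessibilityTrack) else np.asarray(track, float)
    below = values <= threshold
    if not below.any():
        return FootprintSet(molecule_id=molecule_id, regions=())
    padded = np.concatenate(([False], below, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return FootprintSet(molecule_id=molecule_id, regions=tuple(zip(starts, ends)))


def count_nucleosomes(fp: FootprintSet, cutoffs: NucCountCutoffs | None = None) -> FootprintSet:
    """Assign a nucleosome count to each region by the length ladder."""
    cutoffs = cutoffs or NucCountCutoffs()
    counts = tuple(cutoffs.count_for_length(e - s) for s, e in fp.regions)
    return FootprintSet(
        molecule_id=fp.molecule_id, regions=fp.regions, nuc_count_per_region=counts
    )


def fiber_density(fp: FootprintSet, template_length: int) -> float:
    """Nucleosomes per kbp: total count x 1000 / template_length."""
    if template_length <= 0:
        raise ValueError("template_length must be positive")
    return fp.total_nucleosomes * 1000.0 / template_length


def horizon_histogram(
    fps,
    template_length: int,
    length_bins=None,
    position_bins=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Footprint length x midpoint 2-D histogram over a set of molecules.

    Returns (counts, midpoint_edges, length_edges); counts sum to the
    total number of regions.
    """
    fps = list(fps)
    if not fps:
        raise ValueError("need at least one footprint set")
    mids = np.concatenate([fp.midpoints for fp in fps]) if fps else np.array([])
    lengths = np.concatenate([fp.lengths for fp in fps]).astype(float)
    if position_bins is None:
        position_bins = np.arange(0, template_length + 10, 10)
    if length_bins is None:
        length_bins = np.arange(0, max(float(lengths.max(initial=0)) + 10, 20), 10)
    counts, pos_edges, len_edges = np.histogram2d(mids, lengths, bins=[position_bins, length_bins])
    return counts, pos_edges, len_edges


def suggest_cutoffs(
    lengths, bin_width: int = 10, smooth_window: int = 5
) -> list[int]:
    """Locate valleys of the footprint-length histogram as candidate cutoffs.

    A helper for calibrating :class:`NucCountCutoffs` on real data; the
    returned valley positions separate the periodic mono/di/tri...
    peaks of the length histogram.
    """
    lengths = np.asarray(lengths, float)
    if len(lengths) == 0:
        return []
    edges = np.arange(0, lengths.max() + bin_width * 2, bin_width)
    hist, _ = np.histogram(lengths, bins=edges)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        hist = np.convolve(hist, kernel, mode="same")
    (minima,) = argrelmin(hist)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return [int(centers[i]) for i in minima]


def write_footprints_bed(fps, path) -> None:
    """Footprints as BED3+: molecule_id, start, end, length, nuc_count."""
    with open(path, "w") as fh:
        fh.write("#molecule_id\tstart\tend\tlength\tnuc_count\n")
        for fp in fps:
            counts = fp.nuc_count_per_region or [-1] * len(fp.regions)
            for (s, e), c in zip(fp.regions, counts):
                fh.write(f"{fp.molecule_id}\t{s}\t{e}\t{e - s}\t{c}\n")


def write_density_tsv(fps, template_length: int, path) -> None:
    """Per-fiber density table: molecule_id, n_nucs, density_per_kbp."""
    with open(path, "w") as fh:
        fh.write("molecule_id\tn_nucs\tdensity_per_kbp\n")
        for fp in fps:
            n = fp.total_nucleosomes
            fh.write(f"{fp.molecule_id}\t{n}\t{fiber_density(fp, template_length):.6g}\n")
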