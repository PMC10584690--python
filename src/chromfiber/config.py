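"""Run configuration, seeded substreams and end-to-end workflows.

A :class:`RunConfig` carries every tunable the pipelines use, with
defaults matching the values the method was established with (HMM run
length L = 1000 bp, accessibility threshold 0.5, Leiden resolution 0.4
with a 5% cumulative cluster-size filter, visibility 183 nt, ruler /
flank cutoffs of 20 and 48 nt, q < 0.05, mixture tolerance 1e-6).

Each stochastic stage draws its own child seed from the master seed via
``numpy.random.SeedSequence`` keyed by the stage name, so no two stages
share random state and any stage can be rerun in isolation.

Workflows:

``simulate_compare``
    Build random fiber ensembles across a density range, remodel with
    the clamping and the length-sensing process, and write per-density
    average-autocorrelogram peak tables plus their peak-vs-density
    correlations.

``decode``
    Generate (or load) synthetic molecules with planted footprints,
    build the control-calibrated chain HMM, Viterbi-decode every
    molecule, call footprints and densities, and write the
    autocorrelogram matrix.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import accesshmm, arraysim, fiberstats, footprints, synthdata

logger = logging.getLogger("chromfiber")

SPAWN_KEY_MOD = 2**31 - 1


@dataclass
class RunConfig:
    """Parameters for the end-to-end workflows (defaults are canonical)."""

    workflow: str = "simulate_compare"  # {decode, simulate_compare, enrich}
    seed: int = 0
    output_dir: str = "chromfiber_out"
    input_path: str = ""  # enrich workflow: TSV of molecule_id, cluster, domain
    # template / simulation
    template_length: int = 2712
    densities: tuple[int, ...] = tuple(range(5, 13))
    fibers_per_density: int = 200
    min_linker: int = 10
    # remodeling
    ruler: int = 20
    ruler_sd: float = 0.0
    visibility: int = 183
    flank_cutoff: int = 48
    step: int = 1
    n_sweeps: int = 500
    # synthetic data / decoding
    n_molecules: int = 200
    n_controls: int = 200
    adenine_fraction: float = 0.5
    expected_run_length: float = 1000.0
    accessibility_threshold: float = 0.5
    # mixture stage
    mixture_tol: float = 1e-6
    min_mean_gap: float = 0.2
    min_frac_above: float = 0.02
    # clustering / stats
    resolution: float = 0.4
    min_total_frac: float = 0.05
    q_cutoff: float = 0.05
    max_lag: int = 1000
    peak_window: tuple[int, int] = (100, 500)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed derived from the master seed."""
        key = int.from_bytes(stage.encode(), "little") % SPAWN_KEY_MOD
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % SPAWN_KEY_MOD)


def load_config(path) -> RunConfig:
    """Parse a flat key=value config file with module-prefixed keys.

    Lines look like ``arraysim.visibility = 183``; the prefix before
    the dot is dropped and the remainder must name a RunConfig field.
    ``#`` starts a comment.
    """
    cfg = RunConfig()
    valid = {f.name: f for f in dataclasses.fields(RunConfig)}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            key = key.split(".")[-1]
            if key not in valid:
                raise ValueError(f"{path}:{ln}: unknown parameter {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, tuple):
                parsed = tuple(int(v) for v in val.replace(",", " ").split())
            elif isinstance(current, bool):
                parsed = val.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                parsed = int(val)
            elif isinstance(current, float):
                parsed = float(val)
            else:
                parsed = val
            setattr(cfg, key, parsed)
    return cfg


def _manifest(config: RunConfig, outputs: dict, outdir: Path) -> dict:
    import chromfiber

    manifest = {
        "version": chromfiber.__version__,
        "workflow": config.workflow,
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def simulate_remodeled_ensemble(
    config: RunConfig, mode: str
) -> tuple[list[arraysim.FiberTemplate], list[int]]:
    """Fiber ensembles per density, remodeled by the requested process."""
    remodel_cfg = arraysim.RemodelConfig(
        mode=mode,
        ruler=config.ruler,
        ruler_sd=config.ruler_sd,
        visibility=config.visibility,
        flank_cutoff=config.flank_cutoff,
        step=config.step,
        n_sweeps=config.n_sweeps,
    )
    base = config.stage_seed(f"simulate:{mode}")
    fibers, densities = [], []
    counter = 0
    for d in config.densities:
        for _ in range(config.fibers_per_density):
            fib = arraysim.place_nucleosomes(
                config.template_length,
                d,
                min_linker=config.min_linker,
                max_attempts=100_000,
                seed=base + counter,
            )
            fib = arraysim.remodel(fib, remodel_cfg, seed=base + counter + 1)
            fibers.append(fib)
            densities.append(d)
            counter += 2
    return fibers, densities


def run_simulate_compare(config: RunConfig, outdir: Path) -> dict:
    outputs = {}
    results = {}
    for mode in ("clamp", "length_sensing"):
        logger.info("simulating and remodeling (%s)", mode)
        fibers, dens = simulate_remodeled_ensemble(config, mode)
        tracks = [arraysim.occupancy_track(f) for f in fibers]
        profiles = fiberstats.per_density_profiles(
            tracks, dens, window=config.peak_window, max_lag=config.max_lag
        )
        path = outdir / f"profiles_{mode}.tsv"
        fiberstats.write_profiles_tsv(profiles, path)
        outputs[f"profiles_{mode}"] = str(path)
        with_peaks = [p for p in profiles if p.peak_lag is not None]
        corr = (
            fiberstats.density_peak_correlation(with_peaks)
            if len(with_peaks) >= 3
            else None
        )
        results[mode] = {
            "peaks": {p.density: p.peak_lag for p in profiles},
            "correlation": corr,
        }
    with open(outdir / "peak_correlations.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    outputs["peak_correlations"] = str(outdir / "peak_correlations.json")
    return outputs


def run_decode(config: RunConfig, outdir: Path) -> dict:
    outputs = {}
    logger.info("generating synthetic molecules with planted footprints")
    rates = synthdata.make_rate_map(
        config.template_length,
        adenine_fraction=config.adenine_fraction,
        seed=config.stage_seed("rate_map"),
    )
    neg = synthdata.simulate_controls(
        rates, config.n_controls, "negative", seed=config.stage_seed("neg_controls")
    )
    pos = synthdata.simulate_controls(
        rates, config.n_controls, "positive", seed=config.stage_seed("pos_controls")
    )
    p_acc = accesshmm.emissions_from_controls(*synthdata.control_counts(pos))
    p_inacc = accesshmm.emissions_from_controls(*synthdata.control_counts(neg))
    p_inacc = np.minimum(p_inacc, p_acc)
    hmm = accesshmm.build_hmm(
        rates.adenine_positions, p_acc, p_inacc, config.expected_run_length
    )

    base = config.stage_seed("molecules")
    rng = np.random.default_rng(base)
    mol_calls, fibers = [], []
    for i in range(config.n_molecules):
        d = int(rng.choice(config.densities))
        fib = arraysim.place_nucleosomes(
            config.template_length,
            d,
            min_linker=config.min_linker,
            max_attempts=100_000,
            seed=base + 2 * i,
        )
        mc = synthdata.simulate_molecule(
            fib, rates, seed=base + 2 * i + 1, molecule_id=f"mol{i}"
        )
        fibers.append(fib)
        mol_calls.append(mc)
    synthdata.write_calls_tsv(mol_calls, outdir / "molecule_calls.tsv")
    outputs["molecule_calls"] = str(outdir / "molecule_calls.tsv")

    logger.info("decoding %d molecules", len(mol_calls))
    fps, tracks = [], []
    for mc in mol_calls:
        track = accesshmm.decode_molecule(hmm, mc, config.template_length)
        fp = footprints.call_inaccessible_regions(
            track, threshold=config.accessibility_threshold, molecule_id=mc.molecule_id
        )
        fps.append(footprints.count_nucleosomes(fp))
        tracks.append(track)
    footprints.write_footprints_bed(fps, outdir / "footprints.bed")
    footprints.write_density_tsv(fps, config.template_length, outdir / "density.tsv")
    matrix = fiberstats.autocorrelogram_matrix(tracks, max_lag=config.max_lag)
    fiberstats.write_autocorrelogram_tsv(
        matrix, [mc.molecule_id for mc in mol_calls], outdir / "autocorrelograms.tsv"
    )
    outputs.update(
        footprints=str(outdir / "footprints.bed"),
        density=str(outdir / "density.tsv"),
        autocorrelograms=str(outdir / "autocorrelograms.tsv"),
    )
    return outputs


def run_enrich(config: RunConfig, outdir: Path) -> dict:
    from . import enrichstats

    if not config.input_path:
        raise ValueError("enrich workflow requires input_path (TSV: molecule_id, cluster, domain)")
    import pandas as pd

    table = pd.read_csv(config.input_path, sep="\t")
    for col in ("cluster", "domain"):
        if col not in table.columns:
            raise ValueError(f"enrich input missing required column {col!r}")
    result = enrichstats.fisher_enrichment(table["cluster"].values, table["domain"].values)
    path = outdir / "enrichment.tsv"
    enrichstats.write_enrichment_tsv(result, path)
    return {"enrichment": str(path)}


def run_workflow(config: RunConfig) -> dict:
    """Execute the configured workflow; returns the run manifest."""
    runners = {
        "simulate_compare": run_simulate_compare,
        "decode": run_decode,
        "enrich": run_enrich,
    }
    if config.workflow not in runners:
        raise ValueError(
            f"unknown workflow {config.workflow!r} "
            "(expected decode, simulate_compare or enrich)"
        )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = runners[config.workflow](config, outdir)
    return _manifest(config, outputs, outdir)
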