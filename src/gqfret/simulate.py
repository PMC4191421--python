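"""Seeded synthetic smFRET trace generator.

Emulates the statistical structure of the assay's raw data so that every
analysis stage can be exercised without instrument movies: per-molecule
donor/acceptor intensity traces at fixed frame time, with

* a spectroscopic state drawn per molecule from the Langmuir occupancy model
  (static mode, the steady-state default) or alternating folded/unfolded
  classes with exponential dwells (qualitative dynamic mode);
* Gaussian-distributed E_FRET per frame around the state mean;
* per-molecule brightness with a lognormal molecule-to-molecule spread;
* additive Gaussian noise and constant background per channel;
* geometric single-step donor/acceptor photobleaching (acceptor bleaching
  moves the signal to the donor channel; donor bleaching kills both, since
  FRET requires an excited donor);
* optional contaminants: aggregates (two molecules in one spot) and
  donor-only molecules, flagged in ground truth for filter validation.

Reproducibility contract: every molecule draws from an independent stream
keyed by (seed, dataset_index, molecule_index), so any trace can be
regenerated bit-identically in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError
from .states import (
    CANONICAL_STATES,
    Condition,
    FretState,
    Nucleotide,
    OccupancySpec,
    StateName,
    occupancy_vector,
)
from .traces import Trace, TraceDataset, condition_to_dict, write_traces

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "simulate_trace", "simulate_contaminant",
           "simulate_dataset", "simulate_titration"]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study's steady-state setup.

    ``n_frames=30`` corresponds to the short movies used for population
    histograms; long movies are 1000-4000 frames.  ``total_intensity`` is the
    per-molecule signal budget in counts/frame and ``intensity_cv`` its
    lognormal molecule-to-molecule spread.  Bleach rates are per frame and
    chosen so that short movies rarely bleach while most long movies do.
    ``effector`` names the Condition field whose concentration drives the
    occupancy model.
    """

    condition: Condition
    occupancy: OccupancySpec
    n_molecules: int = 250
    n_frames: int = 30
    total_intensity: float = 500.0
    intensity_cv: float = 0.2
    noise_sigma: float = 30.0
    background_d: float = 20.0
    background_a: float = 15.0
    donor_bleach_rate: float = 7e-4
    acceptor_bleach_rate: float = 5e-4
    contaminant_fraction: float = 0.05
    dynamic_mode: bool = False
    dwell_folded: float = 20.0
    dwell_unfolded: float = 20.0
    effector: str = "protein_conc"
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules <= 0 or self.n_frames <= 0:
            raise ConfigurationError("n_molecules and n_frames must be positive")
        if self.total_intensity <= 0 or self.noise_sigma <= 0:
            raise ConfigurationError("total_intensity and noise_sigma must be positive")
        if self.intensity_cv < 0 or self.background_d < 0 or self.background_a < 0:
            raise ConfigurationError("intensity_cv and backgrounds must be non-negative")
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise ConfigurationError("bleach rates must be non-negative")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ConfigurationError("contaminant_fraction must be in [0, 1)")
        if self.dwell_folded <= 0 or self.dwell_unfolded <= 0:
            raise ConfigurationError("dwell times must be positive")
        if self.effector not in ("protein_conc", "nucleotide_conc"):
            raise ConfigurationError(f"unknown effector field {self.effector!r}")

    @property
    def effector_conc(self) -> float:
        return float(getattr(self.condition, self.effector))


def _rng(config: SimulationConfig, dataset_index: int, molecule_index: int, stream: int):
    ss = np.random.SeedSequence(
        [int(config.seed), int(dataset_index), int(molecule_index), stream]
    )
    return np.random.default_rng(ss)


def _brightness(config: SimulationConfig, rng) -> float:
    if config.intensity_cv == 0:
        return config.total_intensity
    s = np.sqrt(np.log1p(config.intensity_cv**2))
    return config.total_intensity * rng.lognormal(mean=-0.5 * s * s, sigma=s)


def _bleach_frame(rate: float, n_frames: int, rng) -> int | None:
    """First dark frame under per-frame bleaching probability ``rate``."""
    if rate <= 0:
        return None
    g = int(rng.geometric(rate))
    return g if g < n_frames else None


def _state_path(config: SimulationConfig, rng) -> list[tuple[FretState, int]]:
    """Sequence of (state, n_frames) segments covering the whole trace."""
    spec = config.occupancy
    probs = occupancy_vector(config.effector_conc, spec)
    states = list(probs)
    p = np.array([probs[s] for s in states])
    p = p / p.sum()
    if not config.dynamic_mode:
        state = states[rng.choice(len(states), p=p)]
        return [(state, config.n_frames)]

    # Dynamic mode (qualitative): alternate folded/unfolded classes with
    # exponential dwells; the initial class follows the steady-state
    # occupancy, the state within a class is redrawn per visit.
    low_states = [s for s, _ in spec.low_states]
    low_w = np.array([w for _, w in spec.low_states])
    folded_states = [s for s, _ in spec.folded_states]
    folded_w = np.array([w for _, w in spec.folded_states])
    p_low = sum(probs.get(s, 0.0) for s in low_states)
    in_low = rng.uniform() < p_low
    frame_time = config.condition.frame_time
    segments: list[tuple[FretState, int]] = []
    remaining = config.n_frames
    while remaining > 0:
        if in_low:
            pool, w, dwell = low_states, low_w, config.dwell_unfolded
        else:
            pool, w, dwell = folded_states, folded_w, config.dwell_folded
        state = pool[rng.choice(len(pool), p=w / w.sum())]
        n = max(1, int(np.ceil(rng.exponential(dwell / frame_time))))
        n = min(n, remaining)
        segments.append((state, n))
        remaining -= n
        in_low = not in_low
    return segments


def _render(
    config: SimulationConfig,
    rng,
    segments: list[tuple[FretState, int]],
    brightness: float,
    bleach_d: int | None,
    bleach_a: int | None,
):
    """Turn a state path into noisy two-channel intensities."""
    n = config.n_frames
    e = np.empty(n)
    names = np.empty(n, dtype=object)
    i = 0
    for state, length in segments:
        e[i : i + length] = rng.normal(state.e_mean, state.e_sigma, length)
        names[i : i + length] = state.name.value
        i += length
    assert i == n

    frames = np.arange(n)
    donor_alive = frames < (bleach_d if bleach_d is not None else n)
    acceptor_alive = frames < (bleach_a if bleach_a is not None else n)
    e_eff = np.where(acceptor_alive, e, 0.0)  # acceptor dark: all signal to donor
    sig_a = np.where(donor_alive, brightness * e_eff, 0.0)
    sig_d = np.where(donor_alive, brightness * (1.0 - e_eff), 0.0)
    i_a = sig_a + config.background_a + rng.normal(0.0, config.noise_sigma, n)
    i_d = sig_d + config.background_d + rng.normal(0.0, config.noise_sigma, n)
    return i_d, i_a, names


def simulate_trace(
    config: SimulationConfig, molecule_index: int, dataset_index: int = 0
) -> Trace:
    """Simulate one single-molecule trace.

    Deterministic under fixed (config.seed, dataset_index, molecule_index).
    """
    rng = _rng(config, dataset_index, molecule_index, stream=0)
    brightness = _brightness(config, rng)
    segments = _state_path(config, rng)
    bleach_d = _bleach_frame(config.donor_bleach_rate, config.n_frames, rng)
    bleach_a = _bleach_frame(config.acceptor_bleach_rate, config.n_frames, rng)
    i_d, i_a, names = _render(config, rng, segments, brightness, bleach_d, bleach_a)
    return Trace(
        molecule_id=molecule_index,
        i_donor=i_d,
        i_acceptor=i_a,
        true_state_path=names,
        bleach_frame_d=bleach_d,
        bleach_frame_a=bleach_a,
        category="single",
    )


def simulate_contaminant(
    config: SimulationConfig, molecule_index: int, dataset_index: int = 0
) -> Trace:
    """Simulate a non-single-molecule trace for the filter to reject.

    Either an aggregate (two independent molecules in one diffraction spot,
    ~2x brightness) or a donor-only molecule (no acceptor, apparent E ~ 0);
    the choice is a fair coin in the molecule's own stream.  Contaminants do
    not photobleach within these short traces.
    """
    rng = _rng(config, dataset_index, molecule_index, stream=1)
    n = config.n_frames
    if rng.uniform() < 0.5:  # aggregate
        parts_d = np.zeros(n)
        parts_a = np.zeros(n)
        for _ in range(2):
            b = _brightness(config, rng)
            segments = _state_path(config, rng)
            e = np.empty(n)
            i = 0
            for state, length in segments:
                e[i : i + length] = rng.normal(state.e_mean, state.e_sigma, length)
                i += length
            parts_a += b * e
            parts_d += b * (1.0 - e)
        i_a = parts_a + config.background_a + rng.normal(0.0, config.noise_sigma, n)
        i_d = parts_d + config.background_d + rng.normal(0.0, config.noise_sigma, n)
        category = "aggregate"
        names = np.full(n, "aggregate", dtype=object)
    else:  # donor-only
        b = _brightness(config, rng)
        state = CANONICAL_STATES[StateName.donor_only]
        e = rng.normal(state.e_mean, state.e_sigma, n)
        i_a = b * e + config.background_a + rng.normal(0.0, config.noise_sigma, n)
        i_d = b * (1.0 - e) + config.background_d + rng.normal(0.0, config.noise_sigma, n)
        category = "donor_only"
        names = np.full(n, state.name.value, dtype=object)
    return Trace(
        molecule_id=molecule_index,
        i_donor=i_d,
        i_acceptor=i_a,
        true_state_path=names,
        bleach_frame_d=None,
        bleach_frame_a=None,
        category=category,
    )


def simulate_dataset(config: SimulationConfig, dataset_index: int = 0) -> TraceDataset:
    """Simulate a full imaging field (one movie) under one condition.

    Each molecule is independently a contaminant with probability
    ``contaminant_fraction`` (decided in its own stream, so per-molecule
    determinism is preserved).  Ground truth (occupancy parameters, state
    table, per-molecule categories) is recorded for test harnesses.
    """
    traces = []
    for m in range(config.n_molecules):
        decide = _rng(config, dataset_index, m, stream=2)
        if config.contaminant_fraction > 0 and decide.uniform() < config.contaminant_fraction:
            traces.append(simulate_contaminant(config, m, dataset_index))
        else:
            traces.append(simulate_trace(config, m, dataset_index))

    spec = config.occupancy
    ground_truth = {
        "effector": config.effector,
        "effector_conc": config.effector_conc,
        "isotherm": {
            "alpha": spec.isotherm.alpha,
            "k_eq": spec.isotherm.k_eq,
            "units": spec.isotherm.units,
        },
        "baseline_low_percent": spec.baseline_low_percent,
        "bound_folded_fraction": spec.bound_folded_fraction,
        "states": {
            s.name.value: {"e_mean": s.e_mean, "e_sigma": s.e_sigma, "weight": w}
            for s, w in (*spec.folded_states, *spec.low_states)
        },
        "occupancy": {
            s.name.value: p
            for s, p in occupancy_vector(config.effector_conc, spec).items()
        },
    }
    provenance = {"seed": config.seed, "dataset_index": dataset_index}
    return TraceDataset(
        traces=traces,
        condition=config.condition,
        ground_truth=ground_truth,
        provenance=provenance,
    )


def _condition_at(config: SimulationConfig, x: float) -> Condition:
    """Condition metadata with the effector concentration set to ``x``."""
    if config.effector == "protein_conc":
        return replace(config.condition, protein_conc=x)
    if x == 0.0:
        return replace(config.condition, nucleotide=Nucleotide.nt_free, nucleotide_conc=0.0)
    return replace(config.condition, nucleotide_conc=x)


def simulate_titration(
    base_config: SimulationConfig,
    effector_concentrations,
    n_fields: int = 1,
    out_dir=None,
) -> list[TraceDataset]:
    """Datasets for a titration: ``n_fields`` imaging fields (independent
    movies) per effector concentration, occupancies from the shared Langmuir
    model evaluated at each concentration.

    Replicate fields emulate the practice of recording several short movies
    per condition, whose spread provides the error bars of the titration
    points.  The zero-concentration datasets are the subtraction reference; a
    warning is emitted if the grid omits zero.  When ``out_dir`` is given,
    each dataset is written to ``out_dir/conc_<i>_field_<f>`` and its
    manifest records the Condition and ground-truth parameters.
    """
    concs = [float(c) for c in effector_concentrations]
    if any(c < 0 for c in concs):
        raise ConfigurationError("effector concentrations must be non-negative")
    if n_fields < 1:
        raise ConfigurationError("n_fields must be >= 1")
    if 0.0 not in concs:
        warnings.warn(
            "titration has no zero-concentration dataset; reference subtraction "
            "will need an explicit reference",
            stacklevel=2,
        )
    datasets = []
    for i, x in enumerate(concs):
        config = replace(base_config, condition=_condition_at(base_config, x))
        for f in range(n_fields):
            ds = simulate_dataset(config, dataset_index=i * n_fields + f)
            ds.provenance["effector_conc"] = x
            ds.provenance["field"] = f
            if out_dir is not None:
                from pathlib import Path

                path = write_traces(ds, Path(out_dir) / f"conc_{i:02d}_field_{f:02d}")
                logger.debug("wrote dataset (x=%g, field %d) to %s", x, f, path)
            datasets.append(ds)
    return datasets
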