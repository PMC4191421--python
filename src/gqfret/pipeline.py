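"""Run configuration and orchestration: generation -> processing -> fits.

A run is fully reproducible from a single YAML config plus a seed.  The
stages mirror the analysis: ``cmd_simulate`` writes per-condition trace
files, ``cmd_analyze`` builds percent-normalized histograms, subtracts the
zero-effector reference and tabulates the cumulative positive area per
concentration, and ``cmd_fit`` performs the weighted Langmuir fit.  The same
machinery is importable for in-memory use (no files) via
:func:`process_dataset` and :func:`titration_series_from_datasets`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ManifestError
from .histograms import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_FRAMES_PER_MOLECULE,
    E_RANGE,
    FretHistogram,
    build_histogram,
    positive_area,
    subtract_reference,
    threshold_population,
    write_histogram,
)
from .isotherm import TitrationSeries, fit_langmuir, format_report, write_fit_result
from .simulate import SimulationConfig, simulate_titration
from .states import (
    FretState,
    IsothermParams,
    OccupancySpec,
    StateName,
)
from .traces import (
    FilterCriteria,
    TraceDataset,
    compute_fret,
    condition_from_dict,
    filter_single_molecules,
    read_traces,
    subtract_background,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessingOptions",
    "HistogramOptions",
    "RunConfig",
    "load_config",
    "process_dataset",
    "pooled_histogram",
    "titration_series_from_datasets",
    "cmd_simulate",
    "cmd_analyze",
    "cmd_fit",
    "cmd_report",
]


@dataclass(frozen=True)
class ProcessingOptions:
    background_method: str = "constant"
    background_d: float = 20.0
    background_a: float = 15.0
    criteria: FilterCriteria = field(default_factory=FilterCriteria)


@dataclass(frozen=True)
class HistogramOptions:
    bin_width: float = DEFAULT_BIN_WIDTH
    frames_per_molecule: int = DEFAULT_FRAMES_PER_MOLECULE
    e_range: tuple[float, float] = E_RANGE
    e_threshold: float | None = None


# ---------------------------------------------------------------------------
# In-memory pipeline pieces
# ---------------------------------------------------------------------------

def process_dataset(dataset: TraceDataset, proc: ProcessingOptions):
    """Background-subtract, filter to single molecules, compute E_FRET.

    Returns (fret_traces, filter_report)."""
    corrected = [
        subtract_background(
            t,
            method=proc.background_method,
            background=(proc.background_d, proc.background_a),
            step_frac=proc.criteria.step_frac,
        )
        for t in dataset.traces
    ]
    corrected_ds = TraceDataset(
        corrected, dataset.condition, dataset.ground_truth, dict(dataset.provenance)
    )
    accepted, report = filter_single_molecules(corrected_ds, proc.criteria)
    fret = [compute_fret(t, proc.criteria.min_total_frac) for t in accepted.traces]
    return fret, report


def pooled_histogram(
    datasets: list[TraceDataset], proc: ProcessingOptions, histo: HistogramOptions
) -> FretHistogram:
    """Histogram pooling the accepted molecules of several datasets."""
    fret_all = []
    for ds in datasets:
        fret, _ = process_dataset(ds, proc)
        fret_all.extend(fret)
    return build_histogram(
        fret_all,
        frames_per_molecule=histo.frames_per_molecule,
        bin_width=histo.bin_width,
        e_range=histo.e_range,
        condition=datasets[0].condition if datasets else None,
    )


def _effector_conc(ds: TraceDataset, effector: str) -> float:
    if "effector_conc" in ds.provenance:
        return float(ds.provenance["effector_conc"])
    return float(getattr(ds.condition, effector))


def _binomial_err(y_percent: float, n_molecules: int) -> float:
    p = min(max(y_percent / 100.0, 1.0 / max(n_molecules, 2)), 1.0 - 1.0 / max(n_molecules, 2))
    return 100.0 * float(np.sqrt(p * (1.0 - p) / max(n_molecules, 1)))


def titration_series_from_datasets(
    datasets: list[TraceDataset],
    proc: ProcessingOptions | None = None,
    histo: HistogramOptions | None = None,
    effector: str = "protein_conc",
    units: str = "nM",
    mode: str = "unfolding",
    reference_description: str = "",
) -> tuple[TitrationSeries, dict]:
    """Full subtraction analysis of a titration, in memory.

    All zero-concentration datasets are pooled into the reference histogram.
    For each non-zero concentration, the titration value is the cumulative
    positive area of the histogram pooling *all* replicate fields against the
    pooled reference (one histogram per condition, one subtraction, as the
    normalization to 100% of the whole molecule population implies); the
    error bar is the standard deviation of the per-field scores, or a
    binomial standard error when only one field exists.

    Returns the series plus a details dict (per-concentration histograms,
    filter reports, per-field scores).
    """
    proc = proc or ProcessingOptions()
    histo = histo or HistogramOptions()
    groups: dict[float, list[TraceDataset]] = {}
    for ds in datasets:
        groups.setdefault(_effector_conc(ds, effector), []).append(ds)
    if 0.0 not in groups:
        raise ManifestError("no zero-effector reference dataset in the titration")

    reference = pooled_histogram(groups[0.0], proc, histo)
    xs, ys, errs = [], [], []
    details: dict = {"reference": reference, "per_conc": {}}
    for x in sorted(groups):
        if x == 0.0:
            continue
        areas = []
        reports = []
        hists = []
        fret_pooled = []
        for ds in groups[x]:
            fret, report = process_dataset(ds, proc)
            fret_pooled.extend(fret)
            hist = build_histogram(
                fret,
                frames_per_molecule=histo.frames_per_molecule,
                bin_width=histo.bin_width,
                e_range=histo.e_range,
                condition=ds.condition,
            )
            diff = subtract_reference(hist, reference, sample_id=f"x={x}")
            areas.append(positive_area(diff))
            reports.append(report)
            hists.append(hist)
        pooled = build_histogram(
            fret_pooled,
            frames_per_molecule=histo.frames_per_molecule,
            bin_width=histo.bin_width,
            e_range=histo.e_range,
            condition=groups[x][0].condition,
        )
        y = positive_area(subtract_reference(pooled, reference, sample_id=f"x={x}"))
        if len(areas) >= 2:
            err = float(np.std(areas, ddof=1))
            err = max(err, 1e-3)  # guard against degenerate zero spread
        else:
            err = _binomial_err(y, hists[0].n_molecules)
        xs.append(x)
        ys.append(y)
        errs.append(err)
        details["per_conc"][x] = {
            "areas": areas,
            "histograms": hists,
            "filter_reports": reports,
        }
        logger.info("x=%g %s: positive area %.2f +/- %.2f %%", x, units, y, err)

    series = TitrationSeries(
        effector=effector,
        x=np.array([0.0, *xs]),
        y=np.array([0.0, *ys]),
        y_err=np.array([1.0, *errs]),  # zero point excluded from fit by default
        units=units,
        mode=mode,
        reference_description=reference_description,
    )
    return series, details


# ---------------------------------------------------------------------------
# Config document
# ---------------------------------------------------------------------------

_STATE_KEYS = {"name", "e_mean", "e_sigma", "weight"}


def _state_pairs(entries, key):
    pairs = []
    for entry in entries:
        unknown = set(entry) - _STATE_KEYS
        if unknown:
            raise ConfigurationError(f"unknown keys {sorted(unknown)} in {key}")
        try:
            name = StateName(entry["name"])
        except (KeyError, ValueError):
            raise ConfigurationError(
                f"invalid state name in {key}: {entry.get('name')!r} "
                f"(must be one of {[s.value for s in StateName]})"
            ) from None
        pairs.append(
            (
                FretState(name, float(entry["e_mean"]), float(entry["e_sigma"])),
                float(entry.get("weight", 1.0)),
            )
        )
    return tuple(pairs)


def occupancy_from_config(block: dict) -> OccupancySpec:
    iso = block.get("isotherm")
    if not isinstance(iso, dict):
        raise ConfigurationError("generator.occupancy.isotherm block is required")
    isotherm = IsothermParams(
        alpha=float(iso["alpha"]), k_eq=float(iso["k_eq"]), units=str(iso.get("units", "nM"))
    )
    kwargs = {}
    if "bound_folded_fraction" in block:
        kwargs["bound_folded_fraction"] = float(block["bound_folded_fraction"])
    if "baseline_low_percent" in block:
        kwargs["baseline_low_percent"] = float(block["baseline_low_percent"])
    if "bound_folded_state" in block:
        (pair,) = _state_pairs([block["bound_folded_state"]], "occupancy.bound_folded_state")
        kwargs["bound_folded_state"] = pair[0]
    return OccupancySpec(
        isotherm=isotherm,
        folded_states=_state_pairs(block.get("folded_states", []), "occupancy.folded_states"),
        low_states=_state_pairs(block.get("low_states", []), "occupancy.low_states"),
        **kwargs,
    )


@dataclass
class RunConfig:
    """Everything a run needs; serializable, hashable, seed-overridable."""

    run_dir: Path
    generator: SimulationConfig
    concentrations: list[float]
    n_fields: int
    processing: ProcessingOptions
    histogram: HistogramOptions
    fit_mode: str = "unfolding"
    include_zero: bool = False
    units: str = "nM"
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_GENERATOR_KEYS = {
    "condition", "occupancy", "n_molecules", "n_frames", "total_intensity",
    "intensity_cv", "noise_sigma", "background_d", "background_a",
    "donor_bleach_rate", "acceptor_bleach_rate", "contaminant_fraction",
    "dynamic_mode", "dwell_folded", "dwell_unfolded", "effector",
    "concentrations", "n_fields",
}


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Load and validate a YAML run config; errors name the offending key."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    for key in ("run_dir", "generator"):
        if key not in raw:
            raise ConfigurationError(f"config missing required key '{key}'")
    gen = raw["generator"]
    unknown = set(gen) - _GENERATOR_KEYS
    if unknown:
        raise ConfigurationError(f"unknown generator keys: {sorted(unknown)}")
    if "condition" not in gen or "occupancy" not in gen:
        raise ConfigurationError("generator.condition and generator.occupancy are required")
    try:
        condition = condition_from_dict(gen["condition"])
    except ManifestError as exc:
        raise ConfigurationError(f"generator.condition: {exc}") from exc
    occupancy = occupancy_from_config(gen["occupancy"])
    seed = int(raw.get("seed", 0)) if seed_override is None else int(seed_override)
    sim_kwargs = {
        k: gen[k]
        for k in _GENERATOR_KEYS - {"condition", "occupancy", "concentrations", "n_fields"}
        if k in gen
    }
    generator = SimulationConfig(condition=condition, occupancy=occupancy, seed=seed, **sim_kwargs)

    proc_block = raw.get("processing", {})
    crit_kwargs = {
        k: proc_block[k]
        for k in ("intensity_band_frac", "step_frac", "e_min", "min_total_frac")
        if k in proc_block
    }
    processing = ProcessingOptions(
        background_method=proc_block.get("background_method", "constant"),
        background_d=float(proc_block.get("background_d", 20.0)),
        background_a=float(proc_block.get("background_a", 15.0)),
        criteria=FilterCriteria(**crit_kwargs),
    )
    hist_block = raw.get("histogram", {})
    histogram = HistogramOptions(
        bin_width=float(hist_block.get("bin_width", DEFAULT_BIN_WIDTH)),
        frames_per_molecule=int(
            hist_block.get("frames_per_molecule", DEFAULT_FRAMES_PER_MOLECULE)
        ),
        e_threshold=hist_block.get("e_threshold"),
    )
    fit_block = raw.get("fit", {})
    mode = fit_block.get("mode", "unfolding")
    if mode not in ("unfolding", "folding"):
        raise ConfigurationError(f"fit.mode must be 'unfolding' or 'folding', got {mode!r}")

    return RunConfig(
        run_dir=Path(raw["run_dir"]),
        generator=generator,
        concentrations=[float(c) for c in gen.get("concentrations", [0.0])],
        n_fields=int(gen.get("n_fields", 1)),
        processing=processing,
        histogram=histogram,
        fit_mode=mode,
        include_zero=bool(fit_block.get("include_zero", False)),
        units=occupancy.isotherm.units,
        log_level=str(raw.get("log_level", "INFO")),
        raw=raw,
    )


def _setup_run_logging(config: RunConfig):
    config.run_dir.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("gqfret")
    root.setLevel(config.log_level.upper())
    log_path = config.run_dir / "run.log"
    if not any(
        isinstance(h, logging.FileHandler) and getattr(h, "baseFilename", "") == str(log_path)
        for h in root.handlers
    ):
        handler = logging.FileHandler(log_path)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(handler)


# ---------------------------------------------------------------------------
# CLI-facing commands
# ---------------------------------------------------------------------------

def cmd_simulate(config: RunConfig) -> Path:
    """Simulate the configured titration and write trace files + manifest."""
    _setup_run_logging(config)
    out = config.run_dir / "datasets"
    simulate_titration(
        config.generator, config.concentrations, n_fields=config.n_fields, out_dir=out
    )
    manifest = {
        "config_hash": config.config_hash,
        "seed": config.generator.seed,
        "concentrations": config.concentrations,
        "n_fields": config.n_fields,
        "effector": config.generator.effector,
        "units": config.units,
    }
    (config.run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("simulated %d datasets into %s", len(config.concentrations) * config.n_fields, out)
    return out


def _load_run_datasets(config: RunConfig) -> list[TraceDataset]:
    ds_dir = config.run_dir / "datasets"
    paths = sorted(p for p in ds_dir.iterdir() if p.is_dir())
    if not paths:
        raise ManifestError(f"no datasets under {ds_dir}")
    return [read_traces(p) for p in paths]


def cmd_analyze(config: RunConfig) -> Path:
    """Histograms, reference subtraction and the unfolded-percent table."""
    _setup_run_logging(config)
    datasets = _load_run_datasets(config)
    series, details = titration_series_from_datasets(
        datasets,
        proc=config.processing,
        histo=config.histogram,
        effector=config.generator.effector,
        units=config.units,
        mode=config.fit_mode,
    )
    hist_dir = config.run_dir / "histograms"
    write_histogram(details["reference"], hist_dir / "reference.csv")
    rows = []
    for x, info in details["per_conc"].items():
        for f, hist in enumerate(info["histograms"]):
            write_histogram(hist, hist_dir / f"conc_{x:g}_field_{f}.csv")
        diff = subtract_reference(
            pooled_hist_of(info["histograms"]), details["reference"], sample_id=f"x={x:g}"
        )
        pd.DataFrame(
            {
                "bin_left": diff.bin_edges[:-1],
                "bin_right": diff.bin_edges[1:],
                "delta_percent": diff.delta_percent,
            }
        ).to_csv(hist_dir / f"difference_{x:g}.csv", index=False)
        row = {"n_fields": len(info["areas"])}
        if config.histogram.e_threshold is not None:
            row["threshold_population"] = float(
                np.mean(
                    [
                        threshold_population(h, config.histogram.e_threshold)
                        for h in info["histograms"]
                    ]
                )
            )
        rows.append(row)
    table = pd.DataFrame(
        {
            "concentration": series.x,
            "percent": series.y,
            "percent_err": series.y_err,
        }
    )
    table.attrs["units"] = config.units
    table.to_csv(config.run_dir / "unfolded_percent.csv", index=False)
    meta = {
        "config_hash": config.config_hash,
        "seed": config.generator.seed,
        "units": config.units,
        "mode": config.fit_mode,
        "effector": config.generator.effector,
    }
    (config.run_dir / "unfolded_percent.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True)
    )
    return config.run_dir / "unfolded_percent.csv"


def pooled_hist_of(hists: list[FretHistogram]) -> FretHistogram:
    """Average replicate-field histograms (each sums to 100, so does the mean)."""
    counts = np.mean([h.counts_percent for h in hists], axis=0)
    return FretHistogram(
        hists[0].bin_edges.copy(),
        counts,
        n_molecules=sum(h.n_molecules for h in hists),
        condition=hists[0].condition,
    )


def cmd_fit(config: RunConfig) -> Path:
    """Weighted Langmuir fit of the tabulated titration."""
    _setup_run_logging(config)
    table_path = config.run_dir / "unfolded_percent.csv"
    if not table_path.exists():
        raise ManifestError(f"no unfolded-percent table at {table_path}; run analyze first")
    table = pd.read_csv(table_path)
    series = TitrationSeries(
        effector=config.generator.effector,
        x=table["concentration"].to_numpy(),
        y=table["percent"].to_numpy(),
        y_err=table["percent_err"].to_numpy(),
        units=config.units,
        mode=config.fit_mode,
    )
    params = fit_langmuir(series, include_zero=config.include_zero)
    fit_dir = config.run_dir / "fits"
    write_fit_result(params, series, fit_dir / "langmuir.json")
    report = format_report(params, series)
    (fit_dir / "report.txt").write_text(report + "\n")
    if series.x.max() < 3 * params.k_eq:
        logger.warning("saturation not reached: max x < 3*K_eq")
    logger.info(
        "fit: alpha=%.1f+/-%.1f %%, K_eq=%.3g+/-%.2g %s",
        params.alpha, params.alpha_err, params.k_eq, params.k_eq_err, params.units,
    )
    return fit_dir / "langmuir.json"


def cmd_report(config: RunConfig) -> str:
    """Return the text report of an already-fitted run."""
    fit_path = config.run_dir / "fits" / "report.txt"
    if not fit_path.exists():
        raise ManifestError(f"no fit report at {fit_path}; run fit first")
    return fit_path.read_text()
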