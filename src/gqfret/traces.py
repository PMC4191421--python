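"""Trace ingestion, background subtraction, single-molecule filtering and E_FRET.

This stage turns raw two-channel intensity time traces into per-molecule
FRET-efficiency time series.  Traces are screened so that only single
molecules enter the histograms: aggregates are caught by an intensity band
around the dataset median, multi-step photobleaching by step counting, and
donor-only molecules by their near-zero apparent FRET.  E_FRET is the
proximity ratio I_A / (I_A + I_D); no gamma or crosstalk correction is
applied, a convention shared with the synthetic generator so that state
levels are self-consistent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ManifestError, TraceParseError
from .states import Cation, Condition, Nucleotide, Protein

logger = logging.getLogger(__name__)

__all__ = [
    "Trace",
    "TraceDataset",
    "FretTrace",
    "FilterCriteria",
    "FilterReport",
    "read_traces",
    "write_traces",
    "subtract_background",
    "filter_single_molecules",
    "compute_fret",
    "condition_to_dict",
    "condition_from_dict",
]

# Manifest keys of the condition block (text interchange format).
_CONDITION_KEYS = (
    "construct",
    "protein",
    "protein_conc_nM",
    "nucleotide",
    "nucleotide_conc_uM",
    "cation",
    "cation_conc_mM",
    "frame_time_s",
)


@dataclass
class Trace:
    """Per-molecule donor/acceptor intensity time series.

    ``true_state_path``, ``bleach_frame_d/a`` and ``category`` are
    generator-only ground truth ("single", "aggregate" or "donor_only");
    they are ``None`` for traces read from instrument-style files.
    """

    molecule_id: int
    i_donor: np.ndarray
    i_acceptor: np.ndarray
    true_state_path: np.ndarray | None = None
    bleach_frame_d: int | None = None
    bleach_frame_a: int | None = None
    category: str | None = None

    def __post_init__(self):
        self.i_donor = np.asarray(self.i_donor, dtype=float)
        self.i_acceptor = np.asarray(self.i_acceptor, dtype=float)
        if self.i_donor.shape != self.i_acceptor.shape:
            raise ConfigurationError("donor and acceptor arrays must have equal length")

    @property
    def n_frames(self) -> int:
        return self.i_donor.size

    @property
    def total(self) -> np.ndarray:
        return self.i_donor + self.i_acceptor


@dataclass
class TraceDataset:
    """All traces of one movie/condition plus its metadata."""

    traces: list[Trace]
    condition: Condition
    ground_truth: dict | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {t.n_frames for t in self.traces}
        if len(lengths) > 1:
            raise ConfigurationError(
                f"all traces in a dataset must share n_frames, got {sorted(lengths)}"
            )

    @property
    def n_molecules(self) -> int:
        return len(self.traces)


@dataclass
class FretTrace:
    """E_FRET per frame; only the first ``usable_frames`` entries are valid."""

    molecule_id: int
    e: np.ndarray
    usable_frames: int

    def __post_init__(self):
        self.e = np.asarray(self.e, dtype=float)
        if not 0 <= self.usable_frames <= self.e.size:
            raise ConfigurationError("usable_frames must be in [0, len(e)]")


# ---------------------------------------------------------------------------
# File I/O: one CSV table per dataset + JSON manifest
# ---------------------------------------------------------------------------

def condition_to_dict(condition: Condition) -> dict:
    return {
        "construct": condition.construct,
        "protein": condition.protein.value,
        "protein_conc_nM": condition.protein_conc,
        "nucleotide": condition.nucleotide.value,
        "nucleotide_conc_uM": condition.nucleotide_conc,
        "cation": condition.cation.value,
        "cation_conc_mM": condition.cation_conc,
        "frame_time_s": condition.frame_time,
    }


def condition_from_dict(block: dict) -> Condition:
    missing = [k for k in _CONDITION_KEYS if k not in block]
    if missing:
        raise ManifestError(f"condition block missing required keys: {missing}")
    try:
        return Condition(
            construct=str(block["construct"]),
            protein=Protein(block["protein"]),
            protein_conc=float(block["protein_conc_nM"]),
            nucleotide=Nucleotide(block["nucleotide"]),
            nucleotide_conc=float(block["nucleotide_conc_uM"]),
            cation=Cation(block["cation"]),
            cation_conc=float(block["cation_conc_mM"]),
            frame_time=float(block["frame_time_s"]),
        )
    except ValueError as exc:
        raise ManifestError(f"invalid condition value: {exc}") from exc


def write_traces(dataset: TraceDataset, path: str | Path) -> Path:
    """Write ``traces.csv`` and ``manifest.json`` under directory ``path``.

    The round trip through :func:`read_traces` is lossless for intensities
    (full ``repr`` precision) and metadata; unknown manifest keys survive in
    ``provenance``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in dataset.traces:
        frames = np.arange(t.n_frames)
        rows.append(
            pd.DataFrame(
                {
                    "molecule_id": t.molecule_id,
                    "frame": frames,
                    "i_donor": t.i_donor,
                    "i_acceptor": t.i_acceptor,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    # shortest round-trip float formatting keeps the table lossless
    table.to_csv(path / "traces.csv", index=False, float_format=lambda v: repr(float(v)))

    manifest = dict(dataset.provenance)
    manifest["condition"] = condition_to_dict(dataset.condition)
    if dataset.ground_truth is not None:
        manifest["ground_truth"] = dataset.ground_truth
    per_mol = {}
    for t in dataset.traces:
        if t.category is not None:
            per_mol[str(t.molecule_id)] = {
                "category": t.category,
                "bleach_frame_d": t.bleach_frame_d,
                "bleach_frame_a": t.bleach_frame_a,
            }
    if per_mol:
        manifest["molecules"] = per_mol
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def read_traces(path: str | Path) -> TraceDataset:
    """Read a dataset written by :func:`write_traces`.

    Raises :class:`TraceParseError` for malformed tables (naming the molecule
    and line where possible) and :class:`ManifestError` for missing metadata.
    """
    path = Path(path)
    csv_path = path / "traces.csv"
    manifest_path = path / "manifest.json"
    if not csv_path.exists():
        raise TraceParseError(f"no trace table at {csv_path}")
    if csv_path.stat().st_size == 0:
        raise TraceParseError(f"empty trace table: {csv_path}")
    try:
        table = pd.read_csv(csv_path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceParseError(f"malformed trace table {csv_path}: {exc}") from exc
    required = {"molecule_id", "frame", "i_donor", "i_acceptor"}
    if not required.issubset(table.columns):
        raise TraceParseError(
            f"trace table {csv_path} must have columns {sorted(required)}"
        )
    if table.empty:
        raise TraceParseError(f"trace table {csv_path} contains no rows")
    for col in ("i_donor", "i_acceptor"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.isna().idxmax()) + 2  # header + 0-based index
            mol = table["molecule_id"].iloc[numeric.isna().idxmax()]
            raise TraceParseError(
                f"non-numeric {col} for molecule {mol} at line {line} of {csv_path}"
            )
        table[col] = numeric

    if not manifest_path.exists():
        raise ManifestError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if "condition" not in manifest:
        raise ManifestError(
            f"manifest {manifest_path} missing 'condition' block with keys "
            f"{list(_CONDITION_KEYS)}"
        )
    condition = condition_from_dict(manifest["condition"])
    per_mol = manifest.get("molecules", {})

    traces = []
    for mol_id, group in table.groupby("molecule_id", sort=True):
        meta = per_mol.get(str(mol_id), {})
        traces.append(
            Trace(
                molecule_id=int(mol_id),
                i_donor=group["i_donor"].to_numpy(),
                i_acceptor=group["i_acceptor"].to_numpy(),
                bleach_frame_d=meta.get("bleach_frame_d"),
                bleach_frame_a=meta.get("bleach_frame_a"),
                category=meta.get("category"),
            )
        )
    provenance = {
        k: v for k, v in manifest.items() if k not in ("condition", "ground_truth", "molecules")
    }
    return TraceDataset(
        traces=traces,
        condition=condition,
        ground_truth=manifest.get("ground_truth"),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Background subtraction
# ---------------------------------------------------------------------------

def _largest_step(total: np.ndarray, step_frac: float) -> int | None:
    """Frame index of the largest single-frame intensity drop, if it exceeds
    ``step_frac`` times the running mean before the drop; else None."""
    if total.size < 3:
        return None
    drops = total[:-1] - total[1:]
    k = int(np.argmax(drops))
    pre_mean = float(np.mean(total[: k + 1]))
    if pre_mean > 0 and drops[k] > step_frac * pre_mean:
        return k + 1  # first frame after the step
    return None


def subtract_background(
    trace: Trace,
    method: str = "constant",
    background: tuple[float, float] = (0.0, 0.0),
    step_frac: float = 0.5,
) -> Trace:
    """Return a copy of ``trace`` with per-channel background removed.

    ``method="constant"`` subtracts the given ``(donor, acceptor)`` values.
    ``method="post_bleach"`` estimates the background per channel as the mean
    over frames after the last detected bleach step (total-intensity drop);
    if no step is found it falls back to ``constant`` with a logged warning.
    Corrected intensities may go slightly negative; they are not clipped.
    """
    if method == "post_bleach":
        step = _largest_step(trace.total, step_frac)
        if step is None or step >= trace.n_frames - 1:
            logger.warning(
                "molecule %d: no bleach step detected, falling back to constant "
                "background subtraction", trace.molecule_id,
            )
            method = "constant"
        else:
            bd = float(np.mean(trace.i_donor[step:]))
            ba = float(np.mean(trace.i_acceptor[step:]))
            return replace(trace, i_donor=trace.i_donor - bd, i_acceptor=trace.i_acceptor - ba)
    if method == "constant":
        bd, ba = background
        return replace(trace, i_donor=trace.i_donor - bd, i_acceptor=trace.i_acceptor - ba)
    raise ConfigurationError(f"unknown background method {method!r}")


# ---------------------------------------------------------------------------
# Single-molecule filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the single-molecule screen (all config-exposed).

    ``intensity_band_frac``: accepted mean total intensity within
    median * (1 +/- frac) across the dataset (rejects aggregates and dim
    spots). ``step_frac``: a single-frame drop larger than this fraction of
    the pre-drop mean counts as a bleach step; more than one such donor step
    rejects the trace.  ``e_min``: minimum mean apparent FRET over usable
    frames (rejects donor-only molecules).  ``min_total_frac``: frames whose
    total falls below this fraction of the trace median are unusable.
    """

    intensity_band_frac: float = 0.4
    step_frac: float = 0.5
    e_min: float = 0.1
    min_total_frac: float = 0.25


@dataclass
class FilterReport:
    n_input: int
    n_accepted: int
    rejected_by_reason: dict[str, int]
    rejected_ids: dict[int, str]


def _count_steps(total: np.ndarray, step_frac: float) -> int:
    """Number of distinct large single-frame drops in the total intensity."""
    n_steps = 0
    remaining = total
    offset = 0
    while True:
        step = _largest_step(remaining, step_frac)
        if step is None:
            return n_steps
        n_steps += 1
        remaining = remaining[step:]
        offset += step
        if remaining.size < 3 or n_steps > 3:
            return n_steps


def _usable_frames(trace: Trace, criteria: FilterCriteria) -> int:
    total = trace.total
    med = float(np.median(total))
    floor = criteria.min_total_frac * max(med, 0.0)
    below = np.nonzero(total < floor)[0]
    return int(below[0]) if below.size else trace.n_frames


def filter_single_molecules(
    dataset: TraceDataset, criteria: FilterCriteria | None = None
) -> tuple[TraceDataset, FilterReport]:
    """Screen a dataset down to single molecules.

    A trace is accepted iff (a) its mean total intensity over usable frames
    lies inside the dataset intensity band, (b) it shows at most one bleach
    step and (c) it is not donor-only.  The report counts rejections per
    reason; accepted and rejected sets partition the input.
    """
    criteria = criteria or FilterCriteria()
    if not dataset.traces:
        logger.warning("filter_single_molecules: empty dataset")
        return (
            TraceDataset([], dataset.condition, dataset.ground_truth, dict(dataset.provenance)),
            FilterReport(0, 0, {}, {}),
        )

    usable = {t.molecule_id: _usable_frames(t, criteria) for t in dataset.traces}
    mean_totals = {}
    for t in dataset.traces:
        n = max(usable[t.molecule_id], 1)
        mean_totals[t.molecule_id] = float(np.mean(t.total[:n]))
    med = float(np.median(list(mean_totals.values())))
    lo = (1.0 - criteria.intensity_band_frac) * med
    hi = (1.0 + criteria.intensity_band_frac) * med

    accepted: list[Trace] = []
    rejected: dict[int, str] = {}
    for t in dataset.traces:
        n = usable[t.molecule_id]
        mean_total = mean_totals[t.molecule_id]
        if not lo <= mean_total <= hi:
            rejected[t.molecule_id] = "intensity_band"
            continue
        if _count_steps(t.total, criteria.step_frac) > 1:
            rejected[t.molecule_id] = "multi_step"
            continue
        if n == 0:
            rejected[t.molecule_id] = "no_usable_frames"
            continue
        total = t.total[:n]
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(total > 0, t.i_acceptor[:n] / np.where(total > 0, total, 1.0), 0.0)
        if float(np.mean(e)) <= criteria.e_min:
            rejected[t.molecule_id] = "no_acceptor"
            continue
        accepted.append(t)

    reasons: dict[str, int] = {}
    for r in rejected.values():
        reasons[r] = reasons.get(r, 0) + 1
    report = FilterReport(
        n_input=len(dataset.traces),
        n_accepted=len(accepted),
        rejected_by_reason=reasons,
        rejected_ids=rejected,
    )
    logger.info(
        "filter: %d in, %d accepted, rejected %s", report.n_input, report.n_accepted, reasons
    )
    out = TraceDataset(
        traces=accepted,
        condition=dataset.condition,
        ground_truth=dataset.ground_truth,
        provenance=dict(dataset.provenance),
    )
    return out, report


# ---------------------------------------------------------------------------
# FRET computation
# ---------------------------------------------------------------------------

def compute_fret(trace: Trace, min_total_frac: float = 0.25) -> FretTrace:
    """Proximity ratio e[t] = I_A / (I_A + I_D) on a background-subtracted trace.

    Frames whose total intensity falls below ``min_total_frac`` times the
    trace median total are unusable; ``usable_frames`` ends at the first such
    frame (donor photobleaching sends the total to ~0, so this also truncates
    at the first donor bleach).  Zero or negative totals yield e = 0 at that
    frame rather than NaN, and such frames are past the usable range anyway.
    The ratio is invariant to scaling both channels by a common factor.
    """
    total = trace.total
    med = float(np.median(total))
    floor = min_total_frac * max(med, 0.0)
    below = np.nonzero(total < floor)[0]
    usable = int(below[0]) if below.size else trace.n_frames
    safe = np.where(total > 0, total, 1.0)
    e = np.where(total > 0, trace.i_acceptor / safe, 0.0)
    return FretTrace(molecule_id=trace.molecule_id, e=e, usable_frames=usable)
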