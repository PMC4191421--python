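"""Percent-normalized E_FRET histograms, subtraction scoring and level fitting.

The central quantification: each condition's E_FRET values are binned into a
histogram normalized so the whole molecule population is 100%.  The
percent-normalized reference histogram (the state without the titrated
effector) is subtracted bin-by-bin; because both are normalized, positive and
negative lobes of the difference balance exactly, and the cumulative positive
area is the unfolded (or protein-bound) population in percent.  This
subtraction score is preferred over multi-Gaussian decomposition because
broad, overlapping peaks cannot be identified uniquely; Gaussian fitting is
still provided for calibrating the discrete FRET levels themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit.models import GaussianModel

from .exceptions import ConfigurationError, FitError
from .states import Condition
from .traces import FretTrace, condition_from_dict, condition_to_dict

__all__ = [
    "FretHistogram",
    "DifferenceHistogram",
    "GaussianComponent",
    "build_histogram",
    "subtract_reference",
    "positive_area",
    "threshold_population",
    "fit_gaussians",
    "write_histogram",
    "read_histogram",
]

E_RANGE = (-0.2, 1.2)
DEFAULT_BIN_WIDTH = 0.025
DEFAULT_FRAMES_PER_MOLECULE = 20


@dataclass
class FretHistogram:
    """Binned E_FRET distribution normalized to percent (sums to 100)."""

    bin_edges: np.ndarray
    counts_percent: np.ndarray
    n_molecules: int
    condition: Condition | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts_percent = np.asarray(self.counts_percent, dtype=float)
        if self.counts_percent.size != self.bin_edges.size - 1:
            raise ConfigurationError("counts must have len(bin_edges) - 1 entries")
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-9):
            raise ConfigurationError("bin_edges must be increasing and uniform")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class DifferenceHistogram:
    """Sample-minus-reference histogram; entries sum to zero by construction."""

    bin_edges: np.ndarray
    delta_percent: np.ndarray
    reference_id: str = "reference"
    sample_id: str = "sample"


@dataclass(frozen=True)
class GaussianComponent:
    center: float
    sigma: float
    area_percent: float


def build_histogram(
    fret_traces: list[FretTrace],
    frames_per_molecule: int = DEFAULT_FRAMES_PER_MOLECULE,
    bin_width: float = DEFAULT_BIN_WIDTH,
    e_range: tuple[float, float] = E_RANGE,
    condition: Condition | None = None,
) -> FretHistogram:
    """Pool the first ``min(frames_per_molecule, usable_frames)`` E values of
    each molecule and normalize the binned counts to percent.

    Capping the frames per molecule keeps long-lived bright molecules from
    dominating the population statistics.  Values outside ``e_range`` (rare
    noise excursions) are clamped into the edge bins so normalization to
    100% is exact.
    """
    if not fret_traces:
        raise ConfigurationError("cannot build a histogram from no traces")
    lo, hi = e_range
    n_bins = int(round((hi - lo) / bin_width))
    if not np.isclose(n_bins * bin_width, hi - lo, rtol=1e-9):
        raise ConfigurationError("bin_width must evenly divide the histogram range")
    edges = lo + bin_width * np.arange(n_bins + 1)

    pooled = []
    n_molecules = 0
    for ft in fret_traces:
        n = min(frames_per_molecule, ft.usable_frames)
        if n <= 0:
            continue
        pooled.append(ft.e[:n])
        n_molecules += 1
    if not pooled:
        raise ConfigurationError("no usable frames in any trace")
    e = np.concatenate(pooled)
    eps = 1e-12
    e = np.clip(e, lo + eps, hi - eps)
    counts, _ = np.histogram(e, bins=edges)
    percent = counts * (100.0 / counts.sum())
    return FretHistogram(edges, percent, n_molecules=n_molecules, condition=condition)


def subtract_reference(
    sample: FretHistogram, reference: FretHistogram,
    sample_id: str = "sample", reference_id: str = "reference",
) -> DifferenceHistogram:
    """Bin-by-bin sample minus reference.

    Requires identical binning (no silent rebinning).  Since both inputs sum
    to 100, the difference sums to 0 and its positive and negative lobes have
    equal area.
    """
    if sample.bin_edges.size != reference.bin_edges.size or not np.allclose(
        sample.bin_edges, reference.bin_edges, rtol=0, atol=1e-12
    ):
        raise ConfigurationError("sample and reference histograms have different binning")
    delta = sample.counts_percent - reference.counts_percent
    return DifferenceHistogram(
        bin_edges=sample.bin_edges.copy(),
        delta_percent=delta,
        sample_id=sample_id,
        reference_id=reference_id,
    )


def positive_area(diff: DifferenceHistogram, e_cut: float | None = None) -> float:
    """Cumulative positive area of a difference histogram, in percent.

    By default *all* positive bins contribute, matching the cumulative-score
    definition; by conservation this equals the magnitude of the negative
    lobe.  ``e_cut`` optionally restricts the sum to bins whose centers lie
    at or below a FRET cutoff (sensitivity analysis for population that may
    enter intermediate levels such as the protein-bound folded state).
    """
    delta = diff.delta_percent
    if e_cut is not None:
        centers = 0.5 * (diff.bin_edges[:-1] + diff.bin_edges[1:])
        delta = delta[centers <= e_cut]
    return float(np.sum(delta[delta > 0]))


def threshold_population(hist: FretHistogram, e_max: float) -> float:
    """Percent of the population with E_FRET <= ``e_max``.

    Whole bins below the threshold count fully; the bin straddling ``e_max``
    contributes pro-rata, which removes bin-edge aliasing.
    """
    lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
    if not lo <= e_max <= hi:
        raise ValueError(f"e_max must lie within the histogram range [{lo}, {hi}]")
    left = hist.bin_edges[:-1]
    right = hist.bin_edges[1:]
    frac = np.clip((e_max - left) / (right - left), 0.0, 1.0)
    return float(np.sum(hist.counts_percent * frac))


def _gaussian_init(hist: FretHistogram, n_components: int):
    """k-means-style split of occupied bins for the initial guesses."""
    centers = hist.bin_centers
    weights = hist.counts_percent
    occupied = weights > 0
    x, w = centers[occupied], weights[occupied]
    if n_components == 1:
        mu = [float(np.average(x, weights=w))]
        groups = [np.ones_like(x, dtype=bool)]
    else:
        # Two-means on bin centers, weighted by counts.
        mu = [float(x.min()), float(x.max())]
        for _ in range(50):
            assign = np.abs(x[:, None] - np.array(mu)[None, :]).argmin(axis=1)
            new_mu = []
            for k in range(2):
                sel = assign == k
                new_mu.append(float(np.average(x[sel], weights=w[sel])) if sel.any() else mu[k])
            if np.allclose(new_mu, mu):
                break
            mu = new_mu
        groups = [assign == 0, assign == 1]
    inits = []
    for k, sel in enumerate(groups):
        wk = w[sel]
        xk = x[sel]
        var = np.average((xk - mu[k]) ** 2, weights=wk) if xk.size else 0.01
        sigma = float(np.clip(np.sqrt(var), 0.02, 0.3))
        amplitude = float(wk.sum()) * hist.bin_width
        inits.append((mu[k], sigma, max(amplitude, 1e-3)))
    return inits


def fit_gaussians(hist: FretHistogram, n_components: int = 1) -> list[GaussianComponent]:
    """Least-squares fit of a sum of Gaussians to bin centers vs percent.

    Initialization splits the occupied bins into ``n_components`` clusters;
    sigma is bounded to [0.01, 0.3].  Components are returned sorted by
    center with areas in percent.  Raises :class:`FitError` (carrying the
    last iterate and residual) on non-convergence.
    """
    if n_components not in (1, 2):
        raise ConfigurationError("n_components must be 1 or 2")
    if int(np.sum(hist.counts_percent > 0)) < 5 * n_components:
        raise ConfigurationError(
            f"need at least {5 * n_components} occupied bins for {n_components} components"
        )
    model = None
    params = None
    for k, (mu, sigma, amp) in enumerate(_gaussian_init(hist, n_components)):
        comp = GaussianModel(prefix=f"g{k}_")
        model = comp if model is None else model + comp
        p = comp.make_params(center=mu, sigma=sigma, amplitude=amp)
        p[f"g{k}_sigma"].set(min=0.01, max=0.3)
        p[f"g{k}_center"].set(min=hist.bin_edges[0], max=hist.bin_edges[-1])
        p[f"g{k}_amplitude"].set(min=0.0)
        params = p if params is None else params.update(p) or params
    result = model.fit(hist.counts_percent, params, x=hist.bin_centers)
    if not result.success:
        raise FitError(
            f"Gaussian fit did not converge: {result.message}",
            last_params={name: float(par.value) for name, par in result.params.items()},
            residual=float(np.sum(result.residual**2)),
        )
    comps = []
    for k in range(n_components):
        comps.append(
            GaussianComponent(
                center=float(result.params[f"g{k}_center"].value),
                sigma=float(result.params[f"g{k}_sigma"].value),
                area_percent=float(result.params[f"g{k}_amplitude"].value) / hist.bin_width,
            )
        )
    return sorted(comps, key=lambda c: c.center)


# ---------------------------------------------------------------------------
# CSV export/import (bin_left, bin_right, percent) + JSON sidecar
# ---------------------------------------------------------------------------

def write_histogram(hist: FretHistogram, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "bin_left": hist.bin_edges[:-1],
            "bin_right": hist.bin_edges[1:],
            "percent": hist.counts_percent,
        }
    ).to_csv(path, index=False)
    sidecar = {"n_molecules": hist.n_molecules}
    if hist.condition is not None:
        sidecar["condition"] = condition_to_dict(hist.condition)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_histogram(path: str | Path) -> FretHistogram:
    path = Path(path)
    table = pd.read_csv(path)
    edges = np.append(table["bin_left"].to_numpy(), table["bin_right"].to_numpy()[-1])
    sidecar_path = path.with_suffix(".json")
    n_molecules = 0
    condition = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        n_molecules = int(sidecar.get("n_molecules", 0))
        if "condition" in sidecar:
            condition = condition_from_dict(sidecar["condition"])
    return FretHistogram(
        bin_edges=edges,
        counts_percent=table["percent"].to_numpy(),
        n_molecules=n_molecules,
        condition=condition,
    )
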