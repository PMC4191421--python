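"""Spectroscopic state model for smFRET assays of G-quadruplex (GQ) unfolding.

A surface-tethered partial-duplex DNA carrying an intramolecular GQ and a
single-stranded overhang reports its conformation through the FRET efficiency
(proximity ratio) between a donor on the free end and an acceptor on the stem.
The observed populations fall into a small set of spectroscopic states, each
well described by a Gaussian E_FRET distribution:

* folded GQ -- two conformers in K+ (E ~ 0.64 and 0.78), one in Na+;
* helicase bound to the overhang with the GQ still folded (E ~ 0.55);
* unfolded (coiled) DNA not bound by protein (E ~ 0.40);
* protein-bound unfolded DNA (E ~ 0.20);
* coiled single-stranded tail of a non-GQ construct (E ~ 0.85).

Steady-state occupancy of the low-FRET (unfolded) class as a function of the
effector concentration x (protein or nucleotide) follows a Langmuir binding
isotherm

    y(x) = alpha * x / (x + K_eq)      [percent of all molecules]

where alpha is the saturating unfolded population and K_eq the concentration
of half-saturation.  Both the synthetic-trace generator and the isotherm
fitter share the types and the occupancy law defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "StateName",
    "FretState",
    "Condition",
    "IsothermParams",
    "OccupancySpec",
    "CANONICAL_STATES",
    "isotherm_eval",
    "occupancy_vector",
    "folded_states_potassium",
    "folded_states_sodium",
    "default_low_states",
]


class StateName(str, Enum):
    """Names of the spectroscopic states observed in the assay."""

    folded_conf1 = "folded_conf1"
    folded_conf2 = "folded_conf2"
    blm_bound_folded = "blm_bound_folded"
    unfolded = "unfolded"
    blm_bound_unfolded = "blm_bound_unfolded"
    coiled = "coiled"
    donor_only = "donor_only"


@dataclass(frozen=True)
class FretState:
    """A named spectroscopic state with Gaussian-distributed E_FRET.

    ``e_mean`` must lie in [0, 1]; individual samples drawn from the state are
    *not* clipped to [0, 1], since proximity-ratio noise legitimately produces
    values slightly outside that interval.
    """

    name: StateName
    e_mean: float
    e_sigma: float
    weight_within_class: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.e_mean <= 1.0:
            raise ConfigurationError(f"e_mean must be in [0, 1], got {self.e_mean}")
        if self.e_sigma <= 0.0:
            raise ConfigurationError(f"e_sigma must be > 0, got {self.e_sigma}")
        if not 0.0 <= self.weight_within_class <= 1.0:
            raise ConfigurationError(
                f"weight_within_class must be in [0, 1], got {self.weight_within_class}"
            )


#: Canonical E_FRET levels (mean, sigma) for the pd-hGQ12T-style constructs.
CANONICAL_STATES: dict[StateName, FretState] = {
    StateName.folded_conf1: FretState(StateName.folded_conf1, 0.64, 0.07),
    StateName.folded_conf2: FretState(StateName.folded_conf2, 0.78, 0.05),
    StateName.blm_bound_folded: FretState(StateName.blm_bound_folded, 0.55, 0.07),
    StateName.unfolded: FretState(StateName.unfolded, 0.40, 0.06),
    StateName.blm_bound_unfolded: FretState(StateName.blm_bound_unfolded, 0.20, 0.08),
    StateName.coiled: FretState(StateName.coiled, 0.85, 0.06),
    StateName.donor_only: FretState(StateName.donor_only, 0.03, 0.03),
}


class Protein(str, Enum):
    BLM = "BLM"
    BLM_K695M = "BLM_K695M"
    WRN = "WRN"
    RecQ = "RecQ"
    RECQ5 = "RECQ5"
    none = "none"


class Nucleotide(str, Enum):
    nt_free = "nt_free"
    ATP = "ATP"
    ATPgammaS = "ATPgammaS"
    ADP = "ADP"
    AMP_PNP = "AMP_PNP"


class Cation(str, Enum):
    K = "K"
    Na = "Na"


@dataclass(frozen=True)
class Condition:
    """Experimental condition metadata attached to every dataset.

    Concentration units are carried explicitly and never converted silently:
    protein in nM, nucleotide in uM, monovalent cation in mM.
    """

    construct: str = "pd-hGQ12T"
    protein: Protein = Protein.none
    protein_conc: float = 0.0  # nM
    nucleotide: Nucleotide = Nucleotide.nt_free
    nucleotide_conc: float = 0.0  # uM
    cation: Cation = Cation.K
    cation_conc: float = 150.0  # mM
    frame_time: float = 0.040  # s

    def __post_init__(self):
        if self.protein_conc < 0 or self.nucleotide_conc < 0:
            raise ConfigurationError("concentrations must be non-negative")
        if self.cation_conc <= 0:
            raise ConfigurationError("cation_conc must be positive")
        if self.frame_time <= 0:
            raise ConfigurationError("frame_time must be positive")
        free = self.nucleotide is Nucleotide.nt_free
        if free != (self.nucleotide_conc == 0.0):
            raise ConfigurationError(
                "nucleotide must be nt_free exactly when nucleotide_conc is 0 "
                f"(got {self.nucleotide.value} at {self.nucleotide_conc} uM)"
            )


@dataclass(frozen=True)
class IsothermParams:
    """Parameters of the Langmuir law y = alpha*x/(x + k_eq).

    ``alpha`` is in percent (0-100]; ``k_eq`` carries the same concentration
    unit as the effector variable it is fitted against.
    """

    alpha: float
    k_eq: float
    alpha_err: float = 0.0
    k_eq_err: float = 0.0
    units: str = "nM"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 100.0:
            raise ConfigurationError(f"alpha must be in [0, 100], got {self.alpha}")
        if self.k_eq <= 0.0:
            raise ConfigurationError(f"k_eq must be > 0, got {self.k_eq}")
        if self.alpha_err < 0 or self.k_eq_err < 0:
            raise ConfigurationError("parameter errors must be non-negative")


def isotherm_eval(x, params: IsothermParams):
    """Evaluate the Langmuir isotherm, percent unfolded at effector concentration x.

    Accepts a scalar or array; raises ValueError for negative concentrations.
    Monotonically non-decreasing in x, bounded above by ``params.alpha``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("effector concentration must be non-negative")
    y = params.alpha * x / (x + params.k_eq)
    return float(y) if y.ndim == 0 else y


def _check_weights(pairs, label):
    if not pairs:
        raise ConfigurationError(f"{label} must contain at least one state")
    total = sum(w for _, w in pairs)
    if any(w < 0 for _, w in pairs):
        raise ConfigurationError(f"{label} weights must be non-negative")
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ConfigurationError(f"{label} weights must sum to 1, got {total}")


@dataclass(frozen=True)
class OccupancySpec:
    """Forward model tying Langmuir parameters to per-state probabilities.

    The low-FRET class (unfolded + protein-bound unfolded) carries
    ``baseline_low_percent + isotherm(x)`` percent of the molecules, split
    across ``low_states`` by weight.  The remainder is the folded class: a
    constant fraction ``bound_folded_fraction`` of it sits in
    ``bound_folded_state`` (protein bound, GQ still folded) and the rest is
    split across ``folded_states``.

    ``baseline_low_percent`` is the low-class occupancy of the reference state
    at x = 0; it is non-zero when the titrated effector is a nucleotide and
    the reference already contains protein-driven unfolding.
    """

    isotherm: IsothermParams
    folded_states: tuple[tuple[FretState, float], ...]
    low_states: tuple[tuple[FretState, float], ...]
    bound_folded_fraction: float = 0.0
    bound_folded_state: FretState = CANONICAL_STATES[StateName.blm_bound_folded]
    baseline_low_percent: float = 0.0

    def __post_init__(self):
        _check_weights(self.folded_states, "folded_states")
        _check_weights(self.low_states, "low_states")
        if not 0.0 <= self.bound_folded_fraction <= 1.0:
            raise ConfigurationError("bound_folded_fraction must be in [0, 1]")
        if not 0.0 <= self.baseline_low_percent <= 100.0:
            raise ConfigurationError("baseline_low_percent must be in [0, 100]")

    def with_isotherm(self, isotherm: IsothermParams) -> "OccupancySpec":
        return replace(self, isotherm=isotherm)


def occupancy_vector(x: float, spec: OccupancySpec) -> dict[FretState, float]:
    """Per-state probabilities at effector concentration ``x``.

    Returns a mapping from :class:`FretState` to probability; the values sum
    to 1.  At x = 0 (and zero baseline) all probability sits in the folded
    class; at saturation with alpha = 100 it all moves to the low class.
    """
    low_total = (spec.baseline_low_percent + isotherm_eval(x, spec.isotherm)) / 100.0
    low_total = min(low_total, 1.0)
    folded_total = 1.0 - low_total

    probs: dict[FretState, float] = {}
    for state, w in spec.low_states:
        probs[state] = probs.get(state, 0.0) + low_total * w
    bound = folded_total * spec.bound_folded_fraction
    if bound > 0.0:
        probs[spec.bound_folded_state] = probs.get(spec.bound_folded_state, 0.0) + bound
    for state, w in spec.folded_states:
        probs[state] = probs.get(state, 0.0) + (folded_total - bound) * w
    return probs


def folded_states_potassium(conf1_weight: float = 0.5) -> tuple[tuple[FretState, float], ...]:
    """Folded-class mixture in K+: two conformers at E ~ 0.64 and 0.78.

    The relative abundance of the conformers is not pinned down by the
    histograms; 50/50 is the default and is a free generator parameter.
    """
    return (
        (CANONICAL_STATES[StateName.folded_conf1], conf1_weight),
        (CANONICAL_STATES[StateName.folded_conf2], 1.0 - conf1_weight),
    )


def folded_states_sodium() -> tuple[tuple[FretState, float], ...]:
    """Folded class in Na+: a single conformer (one Gaussian peak)."""
    return ((FretState(StateName.folded_conf1, 0.70, 0.05), 1.0),)


def default_low_states(unfolded_weight: float = 0.5) -> tuple[tuple[FretState, float], ...]:
    """Low-FRET class: equilibrium of unfolded (0.40) and bound-unfolded (0.20).

    The 50/50 default reproduces the merged peak observed at E ~ 0.30.
    """
    return (
        (CANONICAL_STATES[StateName.unfolded], unfolded_weight),
        (CANONICAL_STATES[StateName.blm_bound_unfolded], 1.0 - unfolded_weight),
    )
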