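"""Telomere erosion under division: division indices and the length gap.

Each division removes on average ``epsilon`` base pairs of telomere, so
the mean telomere deficit of a compartment tracks its mean division index
mu (divisions accrued per cell).  With semiconservative DNA labeling
bookkeeping, each division event adds 2 to the compartment mean:

    dmu1/dt = 2 p1
    dmu2/dt = 2 p2 - mR (mu2 - mu1 - K)

``K`` is the telomere loss index at conversion — the divisions' worth of
erosion a CD57- cell incurs while acquiring CD57 (default 0, telomerase
being highly active during clonal expansion).  The gap d = mu2 - mu1
relaxes exponentially at rate mR towards 2 (p2 - p1)/mR + K, giving the
steady-state telomere-length difference

    Delta_C = epsilon (2 (p2 - p1) / mR + K)      [bp]

reported with the sign convention "CD57- mean minus CD57+ mean": a faster
dividing CD57+ compartment gives a positive Delta (shorter CD57+
telomeres).  Delta_C is the model quantity fitted against the observed
mean per-molecule telomere-length difference (STELA data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InsufficientDataError, NonEquilibriumWarning
from .kinetics import KineticParameters, _check_times

__all__ = [
    "TelomereSettings",
    "DivisionIndexState",
    "TelomereObservation",
    "division_index_trajectories",
    "telomere_difference",
    "steady_state_delta",
    "observed_mean_difference",
]

#: mR below this (per day) is treated as "no equilibrating conversion flux"
MR_FLOOR = 1e-6


@dataclass(frozen=True)
class TelomereSettings:
    """epsilon: bp lost per division (default 50); K: loss index at conversion."""

    epsilon: float = 50.0
    K: float = 0.0

    def __post_init__(self):
        if self.epsilon < 0:
            raise DomainError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.K < 0:
            raise DomainError(f"K must be >= 0, got {self.K}")


@dataclass(frozen=True)
class DivisionIndexState:
    """Mean divisions accrued per cell in each compartment."""

    mu1: float
    mu2: float

    def __post_init__(self):
        if self.mu1 < 0 or self.mu2 < 0:
            raise DomainError("division indices must be nonnegative")


@dataclass(frozen=True)
class TelomereObservation:
    """Per-molecule telomere lengths (bp) for one subset, or a precomputed mean."""

    subset: str
    lengths: np.ndarray | None = None
    mean_bp: float | None = None

    def __post_init__(self):
        if self.lengths is not None:
            arr = np.asarray(self.lengths, dtype=float)
            if arr.size == 0:
                raise InsufficientDataError(f"no telomere molecules for {self.subset}")
            if np.any(arr <= 0):
                raise DomainError("telomere lengths must be positive")
            object.__setattr__(self, "lengths", arr)
        elif self.mean_bp is None:
            raise InsufficientDataError(
                f"telomere observation for {self.subset} has neither lengths nor mean"
            )

    @property
    def mean(self) -> float:
        if self.lengths is not None:
            return float(np.mean(self.lengths))
        return float(self.mean_bp)

    @property
    def n_molecules(self) -> int:
        return int(self.lengths.size) if self.lengths is not None else 1


def division_index_trajectories(
    params: KineticParameters,
    settings: TelomereSettings,
    initial: DivisionIndexState,
    times,
) -> list[DivisionIndexState]:
    """Exact solution of the division-index pair on a time grid.

    mu1 grows linearly; the gap d = mu2 - mu1 obeys
    d' = 2 (p2 - p1) - mR (d - K), solved in closed form.
    """
    t = _check_times(times)
    mu1 = initial.mu1 + 2.0 * params.p1 * t
    d0 = initial.mu2 - initial.mu1
    drive = 2.0 * (params.p2 - params.p1)
    if params.mR > 0:
        d_ss = drive / params.mR + settings.K
        d = d_ss + (d0 - d_ss) * np.exp(-params.mR * t)
    else:
        d = d0 + drive * t
    mu2 = np.maximum(mu1 + d, 0.0)
    return [DivisionIndexState(mu1=float(a), mu2=float(b)) for a, b in zip(mu1, mu2)]


def telomere_difference(state: DivisionIndexState, settings: TelomereSettings) -> float:
    """Delta = (mu2 - mu1) * epsilon, in bp (positive: CD57+ shorter)."""
    return (state.mu2 - state.mu1) * settings.epsilon


def steady_state_delta(
    params: KineticParameters,
    settings: TelomereSettings,
    mr_floor: float = MR_FLOOR,
) -> float:
    """Closed-form steady-state telomere-length difference Delta_C (bp).

    Delta_C = epsilon (2 (p2 - p1)/mR + K).  For mR below ``mr_floor`` the
    gap never equilibrates; the value is computed at the floored mR and a
    NonEquilibriumWarning is emitted when p1 != p2 (the formula diverges).
    """
    mr = params.mR
    if mr < mr_floor:
        if params.p1 != params.p2:
            warnings.warn(
                f"mR = {mr:g} is below the equilibration floor {mr_floor:g}; "
                "Delta_C evaluated at the floor is not an equilibrium value",
                NonEquilibriumWarning,
            )
        mr = mr_floor
    return settings.epsilon * (2.0 * (params.p2 - params.p1) / mr + settings.K)


def observed_mean_difference(
    neg: TelomereObservation, pos: TelomereObservation
) -> float:
    """Observed Delta (bp): mean CD57- length minus mean CD57+ length."""
    return neg.mean - pos.mean
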