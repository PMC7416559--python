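"""Storage/loss-modulus crossover analysis of oscillatory frequency sweeps.

In a frequency sweep of a viscoelastic gel the storage modulus G' grows
relative to the loss modulus G'' as frequency rises; the angular
frequency where the two curves intersect indicates the degree of
cross-linking — a more weakly cross-linked (less solid) network crosses
over at a lower frequency.  For an ideal single-mode Maxwell element the
crossover sits exactly at ``omega = 1/tau``.

Crossovers are located as sign changes of ``log G' - log G''`` along the
grid and refined by log-linear interpolation, since moduli typically
span decades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RheologySweep", "CrossoverReport", "crossover_frequency", "compare_sweeps"]


@dataclass
class RheologySweep:
    """A frequency sweep: angular frequency (rad/s) with storage and loss
    moduli (Pa) on a strictly increasing grid."""

    angular_frequency: np.ndarray
    storage_modulus: np.ndarray
    loss_modulus: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.angular_frequency = np.asarray(self.angular_frequency, dtype=float)
        self.storage_modulus = np.asarray(self.storage_modulus, dtype=float)
        self.loss_modulus = np.asarray(self.loss_modulus, dtype=float)
        n = self.angular_frequency.size
        if n < 3 or self.storage_modulus.size != n or self.loss_modulus.size != n:
            raise ValueError("sweep needs three equal-length columns of length >= 3")
        if np.any(np.diff(self.angular_frequency) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.angular_frequency <= 0):
            raise ValueError("angular frequencies must be positive")
        if np.any(self.storage_modulus <= 0) or np.any(self.loss_modulus <= 0):
            raise ValueError("moduli must be positive")


@dataclass
class CrossoverReport:
    """All G'/G'' crossovers found in a sweep; the first is primary."""

    crossover_frequency: float | None
    all_crossovers: list[float] = field(default_factory=list)
    bracketing_indices: tuple[int, int] | None = None
    method: str = "log-linear interpolation"

    @property
    def found(self) -> bool:
        return self.crossover_frequency is not None


def crossover_frequency(sweep: RheologySweep) -> CrossoverReport:
    """Locate where the loss and storage moduli cross.

    Sign changes of ``log G' - log G''`` along the grid are interpolated
    log-linearly within the bracketing interval; an exact tie at a grid
    point reports that grid frequency.  If the curves never cross on the
    grid the report carries no crossover.
    """
    logw = np.log(sweep.angular_frequency)
    delta = np.log(sweep.storage_modulus) - np.log(sweep.loss_modulus)
    crossings: list[float] = []
    bracket: tuple[int, int] | None = None
    for i in range(delta.size):
        if delta[i] == 0.0:
            crossings.append(float(sweep.angular_frequency[i]))
            if bracket is None:
                bracket = (i, i)
        elif i + 1 < delta.size and delta[i] * delta[i + 1] < 0:
            frac = delta[i] / (delta[i] - delta[i + 1])
            crossings.append(float(np.exp(logw[i] + frac * (logw[i + 1] - logw[i]))))
            if bracket is None:
                bracket = (i, i + 1)
    if not crossings:
        return CrossoverReport(crossover_frequency=None)
    return CrossoverReport(
        crossover_frequency=crossings[0],
        all_crossovers=crossings,
        bracketing_indices=bracket,
    )


def compare_sweeps(a: RheologySweep, b: RheologySweep) -> dict:
    """Compare two sweeps: crossover frequencies, their ratio, and the
    per-frequency modulus ratios b/a on the common grid (log-log
    interpolated where the grids differ)."""
    lo = max(a.angular_frequency[0], b.angular_frequency[0])
    hi = min(a.angular_frequency[-1], b.angular_frequency[-1])
    if lo >= hi:
        raise ValueError("frequency ranges do not overlap")
    common = np.geomspace(lo, hi, 50)

    def interp(sweep: RheologySweep, col: np.ndarray) -> np.ndarray:
        return np.exp(
            np.interp(np.log(common), np.log(sweep.angular_frequency), np.log(col))
        )

    xa, xb = crossover_frequency(a), crossover_frequency(b)
    ratio = (
        xa.crossover_frequency / xb.crossover_frequency
        if xa.found and xb.found
        else None
    )
    return {
        "crossover_a": xa,
        "crossover_b": xb,
        "crossover_ratio_a_over_b": ratio,
        "common_frequency": common,
        "storage_ratio_b_over_a": interp(b, b.storage_modulus) / interp(a, a.storage_modulus),
        "loss_ratio_b_over_a": interp(b, b.loss_modulus) / interp(a, a.loss_modulus),
    }
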