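"""Ensemble statistics of tunneling decay factors.

Given per-snapshot best-pathway decay factors eps_tot, this module
computes the moments <eps>, sigma^2, <eps^2> = <eps>^2 + sigma^2, the
classical coherence ratio

    R_coh = <eps>^2 / <eps^2>

and absolute couplings H_if = H_if_contact * eps_tot.  R_coh near 1 means
tunneling is governed by the average coupling; near 0.5, by its
fluctuations.  R_coh is computed from (mean, variance) through the moment
identity rather than from an independently accumulated <eps^2>, so the
identity holds exactly as printed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from hemepath import PLANCK_EV_S

__all__ = [
    "CouplingStats",
    "ensemble_stats",
    "coherence_ratio",
    "contact_coupling_from_frequency",
    "coupling_from_decay",
    "decay_histogram",
]

DEFAULT_CONTACT_COUPLING_EV = 0.177829  # h * 4.3e13 Hz


@dataclass
class CouplingStats:
    """Moments of an ensemble of decay factors and derived quantities."""

    mean_epsilon: float
    variance: float  # population variance
    n_frames: int
    contact_coupling: float = DEFAULT_CONTACT_COUPLING_EV  # eV
    route_occupancy: dict[str, float] = field(default_factory=dict)  # percent
    route_stats: dict[str, "CouplingStats"] = field(default_factory=dict)

    @property
    def mean_square(self) -> float:
        """<eps^2> via the exact moment identity."""
        return self.mean_epsilon**2 + self.variance

    @property
    def r_coh(self) -> float:
        return coherence_ratio(self.mean_epsilon, self.variance)

    @property
    def mean_Hif(self) -> float:
        """Average absolute coupling <H_if> = H_contact * <eps>, eV."""
        return coupling_from_decay(self.mean_epsilon, self.contact_coupling)

    def as_dict(self) -> dict:
        out = {
            "n_frames": self.n_frames,
            "mean_epsilon": self.mean_epsilon,
            "variance": self.variance,
            "mean_square": self.mean_square,
            "R_coh": self.r_coh,
            "mean_Hif_eV": self.mean_Hif,
        }
        if self.route_occupancy:
            out["route_occupancy_percent"] = dict(self.route_occupancy)
            out["routes"] = {
                label: stats.as_dict()
                for label, stats in self.route_stats.items()
            }
        return out


def coherence_ratio(mean_epsilon: float, variance: float) -> float:
    """Classical coherence ratio <eps>^2 / (<eps>^2 + sigma^2)."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    m2 = mean_epsilon**2
    return m2 / (m2 + variance)


def contact_coupling_from_frequency(frequency: float) -> float:
    """Contact coupling h*nu in eV from a frequency in Hz."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    return PLANCK_EV_S * frequency


def coupling_from_decay(
    epsilon_tot: float, contact_coupling: float = DEFAULT_CONTACT_COUPLING_EV
) -> float:
    """Absolute coupling H_if = H_contact * eps_tot, eV."""
    if not (0.0 < epsilon_tot <= 1.0):
        raise ValueError("decay factor must lie in (0, 1]")
    return contact_coupling * epsilon_tot


def ensemble_stats(
    decays: Sequence[float],
    route_labels: Sequence[str] | None = None,
    contact_coupling: float = DEFAULT_CONTACT_COUPLING_EV,
) -> CouplingStats:
    """Population moments of decay factors, overall and per route.

    Route occupancies are percentages of frames carried by each route
    label; route-weighted means recombine exactly to the total mean.
    """
    eps = np.asarray(decays, dtype=float)
    if eps.size == 0:
        raise ValueError("empty decay ensemble")
    if np.any(eps <= 0) or np.any(eps > 1):
        raise ValueError("decay factors must lie in (0, 1]")
    stats = CouplingStats(
        mean_epsilon=float(np.mean(eps)),
        variance=float(np.var(eps)),
        n_frames=int(eps.size),
        contact_coupling=contact_coupling,
    )
    if route_labels is not None:
        if len(route_labels) != eps.size:
            raise ValueError("one route label per decay required")
        counts = Counter(route_labels)
        labels = np.asarray(route_labels)
        for label, count in counts.items():
            sub = eps[labels == label]
            stats.route_occupancy[label] = 100.0 * count / eps.size
            stats.route_stats[label] = CouplingStats(
                mean_epsilon=float(np.mean(sub)),
                variance=float(np.var(sub)),
                n_frames=int(sub.size),
                contact_coupling=contact_coupling,
            )
    return stats


def decay_histogram(
    decays: Sequence[float],
    route_labels: Sequence[str] | None = None,
    bins: int = 40,
    log_scale: bool = True,
) -> dict:
    """Normalized histograms of decay factors, optionally per route.

    With ``log_scale`` the binning is uniform in log10(eps), matching how
    decay distributions spanning decades are usually displayed.  Densities
    are normalized so each histogram integrates to 1 over its binning
    variable.
    """
    eps = np.asarray(decays, dtype=float)
    if eps.size == 0:
        raise ValueError("empty decay ensemble")
    x = np.log10(eps) if log_scale else eps
    edges = np.histogram_bin_edges(x, bins=bins)
    out = {"log10": log_scale, "bin_edges": edges.tolist(), "total": None,
           "routes": {}}
    density, _ = np.histogram(x, bins=edges, density=True)
    out["total"] = density.tolist()
    if route_labels is not None:
        labels = np.asarray(route_labels)
        for label in dict.fromkeys(route_labels):
            sub = x[labels == label]
            d, _ = np.histogram(sub, bins=edges, density=True)
            out["routes"][str(label)] = d.tolist()
    return out
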