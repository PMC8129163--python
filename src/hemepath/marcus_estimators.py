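"""Marcus/linear-response estimators from vertical energy-gap series.

The vertical energy gap is defined package-wide as ``dE = E_f - E_i``,
the potential-energy difference between the final and initial redox
charge distributions at a fixed nuclear configuration.  Under the linear
response approximation (LRA) the gap is Gaussian in both states with
equal curvature, and

    dA0        = ( <dE>_i + <dE>_f ) / 2         reaction free energy
    lambda_St  = ( <dE>_i - <dE>_f ) / 2         Stokes reorganization
    lambda_var = var(dE_x) / (2 kB T)            variance reorganization
    chi_G      = (lambda_var_i + lambda_var_f) / (2 lambda_St)

chi_G close to 1 indicates an ergodic, LRA-consistent system; slow
conformational switching (bimodal gaps) inflates the variance estimates
and drives chi_G above 1.

Estimates over independent trajectory segments are combined by block
analysis: the first 20 ns of each segment is discarded as equilibration,
per-segment estimates are averaged, and the reported uncertainty is twice
the standard error of the mean over segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hemepath import EV_TO_KCAL_MOL, KB_EV

__all__ = [
    "GapSeries",
    "ETParameters",
    "InnerSphereEnergies",
    "load_gap_series",
    "reaction_free_energy",
    "stokes_reorganization",
    "variance_reorganization",
    "ergodicity_factor",
    "estimate_parameters",
    "block_analysis",
    "decompose_gap",
    "inner_sphere_lambda",
    "total_reorganization",
    "running_average",
    "gap_histogram_report",
]

DEFAULT_TEMPERATURE = 310.0  # K, physiological simulation temperature
DEFAULT_EQUILIBRATION_PS = 20_000.0  # 20 ns discarded per segment

_COMPONENT_TOL = 1e-6  # eV, row-sum check for decompositions


@dataclass
class GapSeries:
    """Time series of vertical energy gaps for one redox state.

    ``components`` optionally decomposes each gap over molecular
    components (e.g. TM domain, DH domain, environment, cofactors); the
    row sums must match ``gaps`` within ``_COMPONENT_TOL`` eV.
    """

    times: np.ndarray  # ps, strictly increasing
    gaps: np.ndarray  # eV
    state: str  # "initial" or "final"
    components: pd.DataFrame | None = None
    temperature: float = DEFAULT_TEMPERATURE  # K
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gaps = np.asarray(self.gaps, dtype=float)
        if self.times.shape != self.gaps.shape:
            raise ValueError("times and gaps must have the same length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.state not in ("initial", "final"):
            raise ValueError("state must be 'initial' or 'final'")
        if self.components is not None:
            if len(self.components) != len(self.gaps):
                raise ValueError("component table length mismatch")
            resid = np.abs(self.components.sum(axis=1).to_numpy() - self.gaps)
            if np.max(resid, initial=0.0) > _COMPONENT_TOL:
                raise ValueError(
                    "component columns do not sum to the total gap; add a "
                    "residual column or check units"
                )

    def __len__(self) -> int:
        return len(self.gaps)

    def mean(self) -> float:
        return float(np.mean(self.gaps))

    def variance(self) -> float:
        """Population variance (divisor n) of the gap, eV^2."""
        return float(np.var(self.gaps))

    def discard_equilibration(self, discard_ps: float) -> "GapSeries":
        """Drop samples with time < first time + discard_ps."""
        if not len(self.times):
            raise ValueError("empty series")
        cut = self.times[0] + discard_ps
        mask = self.times >= cut
        if not mask.any():
            raise ValueError(
                f"segment shorter ({self.times[-1] - self.times[0]:.0f} ps) "
                f"than the equilibration discard ({discard_ps:.0f} ps)"
            )
        comp = self.components.loc[mask].reset_index(drop=True) \
            if self.components is not None else None
        return GapSeries(
            times=self.times[mask], gaps=self.gaps[mask], state=self.state,
            components=comp, temperature=self.temperature,
            metadata=dict(self.metadata),
        )


@dataclass
class ETParameters:
    """Electron-transfer thermodynamic parameters (eV) with uncertainties.

    ``uncertainties`` maps field name to 2x the standard error of the mean
    over blocks, the convention used for reported error bars.
    """

    delta_A0: float
    lambda_St: float
    lambda_var_initial: float
    lambda_var_final: float
    chi_G: float
    uncertainties: dict[str, float] = field(default_factory=dict)
    n_blocks: int = 1

    def as_dict(self) -> dict:
        return {
            "delta_A0_eV": self.delta_A0,
            "lambda_St_eV": self.lambda_St,
            "lambda_var_initial_eV": self.lambda_var_initial,
            "lambda_var_final_eV": self.lambda_var_final,
            "chi_G": self.chi_G,
            "uncertainties_eV": dict(self.uncertainties),
            "n_blocks": self.n_blocks,
        }


@dataclass(frozen=True)
class InnerSphereEnergies:
    """Cofactor energies entering the inner-sphere reorganization.

    ``e_gR_O`` is the energy of the oxidized state at the reduced state's
    equilibrium geometry, and so on.  Each state must be lowest at its own
    equilibrium geometry.
    """

    e_gR_O: float
    e_gR_R: float
    e_gO_R: float
    e_gO_O: float

    def __post_init__(self) -> None:
        if self.e_gR_O < self.e_gO_O or self.e_gO_R < self.e_gR_R:
            raise ValueError(
                "each redox state must have its minimum energy at its own "
                "equilibrium geometry"
            )


def load_gap_series(
    path: str | Path,
    units: str = "eV",
    state: str | None = None,
    time_column: str = "time",
    gap_column: str = "gap",
    temperature: float = DEFAULT_TEMPERATURE,
) -> GapSeries | dict[str, GapSeries]:
    """Load a gap series from CSV/TSV (delimiter sniffed).

    ``units`` is ``"eV"`` or ``"kcal/mol"`` (1 eV = 23.0605 kcal/mol).
    Extra numeric columns are treated as a component decomposition.  If the
    file has a ``state`` column and ``state`` is not given, a dict keyed by
    state is returned.
    """
    if units not in ("eV", "kcal/mol"):
        raise ValueError("units must be 'eV' or 'kcal/mol'")
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (time_column, gap_column):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    scale = 1.0 if units == "eV" else 1.0 / EV_TO_KCAL_MOL

    def build(sub: pd.DataFrame, st: str) -> GapSeries:
        extra = [
            c for c in sub.columns
            if c not in (time_column, gap_column, "state")
        ]
        comp = sub[extra].astype(float) * scale if extra else None
        if comp is not None:
            comp = comp.reset_index(drop=True)
        return GapSeries(
            times=sub[time_column].to_numpy(dtype=float),
            gaps=sub[gap_column].to_numpy(dtype=float) * scale,
            state=st,
            components=comp,
            temperature=temperature,
            metadata={"source": str(path), "units_in": units},
        )

    if "state" in df.columns and state is None:
        return {
            st: build(sub, st) for st, sub in df.groupby("state", sort=False)
        }
    if state is None:
        raise ValueError("file has no state column; pass state=")
    if "state" in df.columns:
        df = df[df["state"] == state]
    return build(df, state)


def reaction_free_energy(mean_gap_initial: float, mean_gap_final: float) -> float:
    """LRA reaction free energy dA0 = (<dE>_i + <dE>_f)/2, eV."""
    return 0.5 * (mean_gap_initial + mean_gap_final)


def stokes_reorganization(mean_gap_initial: float, mean_gap_final: float) -> float:
    """Stokes reorganization energy lambda_St = (<dE>_i - <dE>_f)/2, eV.

    Warns when negative, which signals a breakdown of the LRA picture (or
    mislabeled states)."""
    lam = 0.5 * (mean_gap_initial - mean_gap_final)
    if lam < 0:
        warnings.warn(
            "negative Stokes reorganization energy: LRA violated or "
            "initial/final states swapped",
            stacklevel=2,
        )
    return lam


def variance_reorganization(
    series: GapSeries, temperature: float | None = None
) -> float:
    """Variance reorganization energy var(dE)/(2 kB T), eV.

    Uses the population variance (divisor n); the distinction from the
    sample variance is negligible at trajectory sample counts but is fixed
    here for bit-reproducibility.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 samples")
    t = temperature if temperature is not None else series.temperature
    if t <= 0:
        raise ValueError("temperature must be positive")
    return series.variance() / (2.0 * KB_EV * t)


def ergodicity_factor(
    lambda_var_initial: float, lambda_var_final: float, lambda_St: float
) -> float:
    """Non-ergodicity measure chi_G = (lambda_i^var + lambda_f^var)/(2 lambda_St)."""
    if lambda_St <= 0:
        raise ValueError("lambda_St must be positive")
    return (lambda_var_initial + lambda_var_final) / (2.0 * lambda_St)


def estimate_parameters(
    initial: GapSeries, final: GapSeries, temperature: float | None = None
) -> ETParameters:
    """All LRA parameters from one (initial, final) pair of gap series."""
    if initial.state != "initial" or final.state != "final":
        raise ValueError("pass series in (initial, final) order")
    mi, mf = initial.mean(), final.mean()
    lam_st = stokes_reorganization(mi, mf)
    lam_i = variance_reorganization(initial, temperature)
    lam_f = variance_reorganization(final, temperature)
    return ETParameters(
        delta_A0=reaction_free_energy(mi, mf),
        lambda_St=lam_st,
        lambda_var_initial=lam_i,
        lambda_var_final=lam_f,
        chi_G=ergodicity_factor(lam_i, lam_f, lam_st),
    )


def block_analysis(
    segments: Sequence[tuple[GapSeries, GapSeries]],
    equilibration_discard: float = DEFAULT_EQUILIBRATION_PS,
    temperature: float | None = None,
) -> ETParameters:
    """Block analysis over independent (initial, final) segment pairs.

    Each segment's first ``equilibration_discard`` ps is dropped, LRA
    parameters are estimated per segment, and the block mean is reported
    with uncertainty = 2x the standard error of the mean over segments.
    """
    if len(segments) < 2:
        raise ValueError("block analysis needs at least 2 segments")
    per_block = []
    for initial, final in segments:
        ini = initial.discard_equilibration(equilibration_discard)
        fin = final.discard_equilibration(equilibration_discard)
        per_block.append(estimate_parameters(ini, fin, temperature))

    fields = (
        "delta_A0", "lambda_St", "lambda_var_initial", "lambda_var_final",
        "chi_G",
    )
    n = len(per_block)
    means, errors = {}, {}
    for name in fields:
        vals = np.array([getattr(p, name) for p in per_block])
        means[name] = float(np.mean(vals))
        errors[name] = float(2.0 * np.std(vals, ddof=1) / np.sqrt(n))
    return ETParameters(
        delta_A0=means["delta_A0"],
        lambda_St=means["lambda_St"],
        lambda_var_initial=means["lambda_var_initial"],
        lambda_var_final=means["lambda_var_final"],
        chi_G=means["chi_G"],
        uncertainties=errors,
        n_blocks=n,
    )


def decompose_gap(
    initial: GapSeries, final: GapSeries
) -> pd.DataFrame:
    """Per-component dA0 and lambda_St contributions.

    Applies the mean-gap estimators to each component column; additivity
    of the mean guarantees the contributions sum to the totals.  Returns a
    DataFrame indexed by component with columns ``delta_A0`` and
    ``lambda_St`` (eV), plus a ``total`` row.
    """
    if initial.components is None or final.components is None:
        raise ValueError("both series need component columns")
    ci = set(initial.components.columns)
    cf = set(final.components.columns)
    if ci != cf:
        raise ValueError(f"component sets differ: {sorted(ci ^ cf)}")
    rows = {}
    for name in initial.components.columns:
        mi = float(initial.components[name].mean())
        mf = float(final.components[name].mean())
        rows[name] = {
            "delta_A0": reaction_free_energy(mi, mf),
            "lambda_St": 0.5 * (mi - mf),
        }
    rows["total"] = {
        "delta_A0": reaction_free_energy(initial.mean(), final.mean()),
        "lambda_St": 0.5 * (initial.mean() - final.mean()),
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def inner_sphere_lambda(e: InnerSphereEnergies) -> float:
    """Inner-sphere reorganization energy from cofactor energies, eV.

    The sum of the two relaxation energies — oxidized state relaxing from
    the reduced geometry and vice versa — i.e. twice their average.
    """
    return (e.e_gR_O - e.e_gO_O) + (e.e_gO_R - e.e_gR_R)


def total_reorganization(lambda_is: float, lambda_os: float) -> float:
    """Total reorganization energy lambda = lambda_is + lambda_os, eV."""
    if lambda_is < 0 or lambda_os < 0:
        raise ValueError("reorganization energies must be nonnegative")
    return lambda_is + lambda_os


def running_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with truncated ends (length n - window + 1)."""
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(values):
        raise ValueError("window larger than series")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")


def gap_histogram_report(
    series: GapSeries, bins: int = 60
) -> dict:
    """Descriptive histogram + two-component Gaussian-mixture summary.

    Intended as a report of possible bimodality in the gap (slow
    conformational switching); no automatic mode assignment is made.
    """
    counts, edges = np.histogram(series.gaps, bins=bins, density=True)
    x = series.gaps
    report = {
        "bin_edges": edges.tolist(),
        "density": counts.tolist(),
        "mean": float(np.mean(x)),
        "variance": float(np.var(x)),
    }
    try:
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=2, random_state=0).fit(x.reshape(-1, 1))
        report["mixture"] = {
            "means": gm.means_.ravel().tolist(),
            "variances": gm.covariances_.ravel().tolist(),
            "weights": gm.weights_.tolist(),
        }
    except ImportError:  # descriptive extra only
        report["mixture"] = None
    return report
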