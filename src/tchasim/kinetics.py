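"""Temporal models of the tethered hairpin-assembly reaction.

Three time-domain behaviours matter for the assay:

* **Exponential decay** -- the fluorescence loss when docked emitters
  are either photobleached or stripped off by toehold-mediated strand
  displacement.  Fitting ``F(t) = A exp(-k t) + F0`` to the two regimes
  and taking the rate ratio quantifies how much faster displacement is
  than bleaching; the ratio of successive cycle amplitudes gives the
  recovery yield of the cyclic reaction.

* **Logistic saturation** -- the per-spot intensity rise while
  fluorophore-carrying hairpins dock onto the finite number of sites a
  tether can reach, ``F(t) = F_max / (1 + exp(-r (t - t50)))``.

* **Site occupancy** -- a minimal birth-death picture of docking: each
  of the ``capacity`` reachable sites fills at an effective pseudo-first
  order rate ``k_on * c`` and empties by bleaching at ``k_b``,

  .. math:: dn/dt = k_{on} c (C - n) - k_b n

  The multi-step strand-displacement cascade is collapsed into the
  single effective docking rate because the individual step constants
  are not separately identifiable from intensity data.  A Gillespie
  realisation of the same birth-death chain provides the stochastic
  mode used for per-spot heterogeneity.

Model/results classes follow the statsmodels convention: construct a
model from data, call ``fit()``, get a results object with estimates,
standard errors and a ``summary()``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FitError",
    "KineticTrace",
    "DecayFit",
    "LogisticFit",
    "OccupancyParams",
    "ExponentialDecayModel",
    "LogisticSaturationModel",
    "fit_decay",
    "fit_logistic",
    "fold_ratio",
    "recovery_yield",
    "simulate_occupancy",
    "occupancy_closed_form",
]


class FitError(RuntimeError):
    """Raised when a trace cannot support the requested fit."""


@dataclass
class KineticTrace:
    """A fluorescence-versus-time trace (times in s, intensities in cps)."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_csv(cls, path) -> "KineticTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["F_cps"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "F_cps": self.intensities}).to_csv(path, index=False)


def _summary_table(title: str, rows: list[tuple[str, float, float | None]]) -> str:
    buf = io.StringIO()
    buf.write(title + "\n" + "=" * len(title) + "\n")
    for name, val, se in rows:
        if se is None or not np.isfinite(se):
            buf.write(f"{name:>12}  {val: .6g}\n")
        else:
            buf.write(f"{name:>12}  {val: .6g}  (se {se:.3g})\n")
    return buf.getvalue()


@dataclass
class DecayFit:
    """Results of an exponential-decay fit ``A exp(-k t) + F0``."""

    rate: float  # 1/s
    amplitude: float  # cps
    offset: float  # cps
    rate_se: float = np.nan
    fold_vs_reference: float | None = None
    cov: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        rows = [
            ("rate 1/s", self.rate, self.rate_se),
            ("amplitude", self.amplitude, None),
            ("offset", self.offset, None),
        ]
        if self.fold_vs_reference is not None:
            rows.append(("fold vs ref", self.fold_vs_reference, None))
        return _summary_table("Exponential decay fit", rows)


@dataclass
class LogisticFit:
    """Results of a logistic saturation fit ``F_max / (1 + exp(-r (t - t50)))``."""

    plateau: float  # cps
    rate: float  # 1/s
    midpoint: float  # s
    cov: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        return _summary_table(
            "Logistic saturation fit",
            [("plateau", self.plateau, None), ("rate 1/s", self.rate, None), ("t50 s", self.midpoint, None)],
        )


class ExponentialDecayModel:
    """Exponential decay model for a decreasing fluorescence trace.

    ``fit()`` initialises from a log-linear regression of the
    offset-subtracted trace and refines by nonlinear least squares.
    """

    def __init__(self, trace: KineticTrace):
        if len(trace) < 4:
            raise FitError("need at least 4 points for a decay fit")
        self.trace = trace

    def fit(self) -> DecayFit:
        t, f = self.trace.times, self.trace.intensities
        if np.ptp(f) == 0:
            raise FitError("constant trace: no decay to fit")
        slope = np.polyfit(t, f, 1)[0]
        if slope >= 0:
            raise FitError("trace is not decreasing")
        offset0 = float(f.min())
        amp0 = float(f[0] - offset0)
        resid = f - offset0
        pos = resid > amp0 * 1e-6
        if pos.sum() >= 2:
            k0 = max(1e-12, -np.polyfit(t[pos], np.log(resid[pos]), 1)[0])
        else:  # nearly a step: fall back on the span of the trace
            k0 = 1.0 / max(t[-1] - t[0], 1e-12)
        model = lambda tt, amp, k, off: amp * np.exp(-k * tt) + off
        try:
            popt, pcov = curve_fit(
                model,
                t,
                f,
                p0=(amp0 if amp0 > 0 else np.ptp(f), k0, offset0),
                bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                xtol=1e-13,
                ftol=1e-13,
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitError(f"decay fit did not converge: {exc}") from exc
        rate_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
        return DecayFit(rate=float(popt[1]), amplitude=float(popt[0]), offset=float(popt[2]),
                        rate_se=rate_se, cov=pcov)


class LogisticSaturationModel:
    """Logistic model for a rising, saturating fluorescence trace."""

    def __init__(self, trace: KineticTrace):
        if len(trace) < 5:
            raise FitError("need at least 5 points for a logistic fit")
        self.trace = trace

    def fit(self) -> LogisticFit:
        t, f = self.trace.times, self.trace.intensities
        if np.ptp(f) == 0:
            raise FitError("flat trace: no saturation to fit")
        if np.polyfit(t, f, 1)[0] <= 0:
            raise FitError("trace is not increasing")
        fmax0 = float(f.max())
        t50_0 = float(t[np.argmin(np.abs(f - fmax0 / 2.0))])
        grad = np.gradient(f, t)
        rate0 = max(4.0 * float(grad.max()) / fmax0, 1e-9)
        model = lambda tt, fmax, rate, t50: fmax / (1.0 + np.exp(-rate * (tt - t50)))
        try:
            popt, pcov = curve_fit(
                model, t, f, p0=(fmax0, rate0, t50_0),
                bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                xtol=1e-13, ftol=1e-13, maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitError(f"logistic fit did not converge: {exc}") from exc
        return LogisticFit(plateau=float(popt[0]), rate=float(popt[1]), midpoint=float(popt[2]), cov=pcov)


def fit_decay(trace: KineticTrace) -> DecayFit:
    """Fit ``F(t) = A exp(-k t) + F0`` to a decreasing trace."""
    return ExponentialDecayModel(trace).fit()


def fit_logistic(trace: KineticTrace) -> LogisticFit:
    """Fit a logistic saturation curve to a rising trace."""
    return LogisticSaturationModel(trace).fit()


def fold_ratio(displacement: DecayFit, bleach: DecayFit) -> float:
    """How many times faster displacement empties spots than bleaching."""
    if bleach.rate <= 0:
        raise ValueError("bleach rate must be > 0")
    return displacement.rate / bleach.rate


def recovery_yield(cycle_amplitudes) -> np.ndarray:
    """Per-cycle recovery fractions ``A[i+1] / A[i]`` of the cyclic reaction."""
    amps = np.asarray(cycle_amplitudes, dtype=float)
    if amps.size < 2:
        raise ValueError("need at least 2 cycle amplitudes")
    if np.any(amps <= 0):
        raise ValueError("cycle amplitudes must be > 0")
    return amps[1:] / amps[:-1]


@dataclass(frozen=True)
class OccupancyParams:
    """Effective docking kinetics of one tether's reachable sites.

    ``k_on`` is the effective per-site docking rate constant (M^-1 s^-1)
    that lumps the strand-displacement cascade; ``c_ha`` the
    fluorophore-hairpin concentration; ``capacity`` the number of
    reachable docking sites; ``k_bleach`` the per-emitter loss rate.
    """

    k_on: float = 1e5
    c_ha_mol_l: float = 1e-8
    capacity: int = 178
    k_bleach: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k_on, self.c_ha_mol_l, self.k_bleach) < 0:
            raise ValueError("rates and concentration must be >= 0")
        if self.capacity < 0 or int(self.capacity) != self.capacity:
            raise ValueError("capacity must be a nonnegative integer")


def occupancy_closed_form(params: OccupancyParams, t_grid) -> np.ndarray:
    """Closed-form solution of the linear docking ODE on ``t_grid``."""
    t = np.asarray(t_grid, dtype=float)
    kon_c = params.k_on * params.c_ha_mol_l
    k_tot = kon_c + params.k_bleach
    if k_tot == 0.0:
        return np.zeros_like(t)
    n_ss = params.capacity * kon_c / k_tot
    return n_ss * (1.0 - np.exp(-k_tot * t))


def simulate_occupancy(params: OccupancyParams, t_grid, seed=None) -> np.ndarray:
    """Emitters docked per spot over time.

    Deterministic mode (``seed=None``) returns the mean-field ODE
    solution; with a seed, one Gillespie birth-death realisation is
    drawn (births ``k_on c (C - n)``, deaths ``k_b n``), sampled on the
    grid.  Occupancy stays within ``[0, capacity]`` in both modes.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_grid must be >= 0")
    if seed is None:
        return occupancy_closed_form(params, t)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kon_c = params.k_on * params.c_ha_mol_l
    out = np.zeros(t.shape, dtype=float)
    n = 0
    now = 0.0
    idx = 0
    order = np.argsort(t)
    t_sorted = t[order]
    while idx < len(t_sorted):
        birth = kon_c * (params.capacity - n)
        death = params.k_bleach * n
        total = birth + death
        dt = np.inf if total <= 0 else rng.exponential(1.0 / total)
        while idx < len(t_sorted) and t_sorted[idx] < now + dt:
            out[order[idx]] = n
            idx += 1
        if not np.isfinite(dt):
            break
        now += dt
        n += 1 if rng.random() < birth / total else -1
    return out
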