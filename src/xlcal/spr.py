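"""SPR 1:1 Langmuir kinetics: simulation, global fitting, blocking normalization.

The 1:1 (Langmuir) model for a sensorgram at analyte concentration C:

    association  (t <= t_a):  R(t) = Req (1 - exp(-(C ka + kd) t)),
                              Req  = C ka Rmax / (C ka + kd)
    dissociation (t >  t_a):  R(t) = R(t_a) exp(-kd (t - t_a))

with association rate ka (1/(M s)), dissociation rate kd (1/s), surface
capacity Rmax (RU) and equilibrium constant KD = kd/ka (M). Fitting is a
global nonlinear least squares over all curves sharing (ka, kd, Rmax);
parameters are optimised on a log scale, which enforces positivity without
active bounds. Initialisation follows instrument-software practice: kd from
the log-linear slope of the dissociation phase, Rmax from observed plateaus,
ka from the equilibrium relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "KineticParams",
    "KineticFit",
    "simulate_1to1",
    "fit_1to1",
    "normalize_blocking",
    "fold_change",
]


@dataclass
class Sensorgram:
    """One response-vs-time trace at a fixed analyte concentration."""

    time: np.ndarray  # s, strictly increasing
    response: np.ndarray  # RU
    analyte_conc: float  # M
    t_assoc_end: float  # s
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.time[0] <= self.t_assoc_end <= self.time[-1]):
            raise ValueError("t_assoc_end outside the time range")


@dataclass
class KineticParams:
    ka: float  # 1/(M s)
    kd: float  # 1/s
    rmax: float  # RU

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValueError("ka, kd and Rmax must all be positive")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant kd/ka, molar."""
        return self.kd / self.ka


@dataclass
class KineticFit:
    params: KineticParams
    residual_rms: list[float]  # per curve, RU
    converged: bool
    n_curves: int
    stderr: Optional[dict] = None  # asymptotic fit standard errors

    @property
    def KD(self) -> float:
        return self.params.KD


def _model_curve(t: np.ndarray, t_assoc_end: float, conc: float, ka: float, kd: float, rmax: float) -> np.ndarray:
    kobs = conc * ka + kd
    req = conc * ka * rmax / kobs
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc_end)))
    r_at_end = req * (1.0 - np.exp(-kobs * t_assoc_end))
    dissoc = r_at_end * np.exp(-kd * np.maximum(t - t_assoc_end, 0.0))
    return np.where(t <= t_assoc_end, assoc, dissoc)


def simulate_1to1(
    params: KineticParams,
    conc: float,
    t_assoc: float,
    t_dissoc: float,
    dt: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> Sensorgram:
    """Closed-form 1:1 sensorgram with optional seeded Gaussian noise."""
    if conc <= 0:
        raise ValueError("analyte concentration must be positive")
    if dt <= 0 or dt >= t_assoc + t_dissoc:
        raise ValueError("dt must be positive and smaller than the trace duration")
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = _model_curve(t, t_assoc, conc, params.ka, params.kd, params.rmax)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(time=t, response=r, analyte_conc=conc, t_assoc_end=t_assoc, label=label)


def _initial_guess(curves: Sequence[Sensorgram]) -> tuple[float, float, float]:
    # kd: log-linear slope of the dissociation tail of the strongest curve
    best = max(curves, key=lambda c: c.response.max())
    mask = (best.time > best.t_assoc_end) & (best.response > 1e-9)
    kd0 = 1e-3
    if mask.sum() >= 3:
        slope = np.polyfit(best.time[mask], np.log(best.response[mask]), 1)[0]
        if slope < 0:
            kd0 = -slope
    # Rmax: largest plateau is Rmax C/(C+KD) <= Rmax
    r_end = max(
        float(np.interp(c.t_assoc_end, c.time, c.response)) for c in curves
    )
    rmax0 = max(r_end * 1.5, 1e-6)
    # ka from the mid-concentration equilibrium relation, crude but in range
    c_mid = float(np.median([c.analyte_conc for c in curves]))
    ka0 = kd0 / c_mid
    return ka0, kd0, rmax0


def fit_1to1(curves: Sequence[Sensorgram], init: Optional[tuple[float, float, float]] = None) -> KineticFit:
    """Global 1:1 fit over >= 2 curves sharing ka, kd and Rmax.

    Log-scale optimisation keeps all parameters positive; a small multistart
    around the data-driven initial guess guards against shallow local minima.
    Non-convergence is flagged in the result, never silent.
    """
    if len(curves) < 2:
        raise ValueError("global fitting requires at least 2 curves")
    concs = [c.analyte_conc for c in curves]
    if len(set(concs)) < 2:
        raise ValueError("curves must span at least 2 distinct analyte concentrations")

    times = [c.time for c in curves]
    resp = np.concatenate([c.response for c in curves])

    def residuals(logp: np.ndarray) -> np.ndarray:
        ka, kd, rmax = np.exp(logp)
        pred = np.concatenate(
            [
                _model_curve(t, c.t_assoc_end, c.analyte_conc, ka, kd, rmax)
                for t, c in zip(times, curves)
            ]
        )
        return pred - resp

    ka0, kd0, rmax0 = init if init is not None else _initial_guess(curves)
    best = None
    for ka_mult in (1.0, 0.1, 10.0):
        x0 = np.log([ka0 * ka_mult, kd0, rmax0])
        sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=5000)
        if best is None or sol.cost < best.cost:
            best = sol
    ka, kd, rmax = np.exp(best.x)
    params = KineticParams(ka=ka, kd=kd, rmax=rmax)

    rms = []
    offset = 0
    final = residuals(best.x)
    for c in curves:
        n = len(c.time)
        rms.append(float(np.sqrt(np.mean(final[offset:offset + n] ** 2))))
        offset += n

    stderr = None
    try:
        dof = max(len(final) - 3, 1)
        s2 = float(best.cost * 2.0) / dof
        cov_log = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se_log = np.sqrt(np.diag(cov_log))
        # delta method back to linear scale
        stderr = {
            "ka": ka * se_log[0],
            "kd": kd * se_log[1],
            "rmax": rmax * se_log[2],
            "KD": params.KD * math.hypot(se_log[0], se_log[1]),
        }
    except np.linalg.LinAlgError:
        pass

    return KineticFit(
        params=params,
        residual_rms=rms,
        converged=bool(best.success),
        n_curves=len(curves),
        stderr=stderr,
    )


def normalize_blocking(
    test_signal: Sensorgram,
    control_signal: Sensorgram,
    floor: float = 1e-9,
) -> Sensorgram:
    """Pointwise test/control ratio on the test grid (blocking-assay normalization).

    The control is linearly interpolated onto the test grid; points where the
    control falls below ``floor`` are masked (NaN), never divided. The
    convention mirrors normalising each time point to a negative-control
    antibody signal.
    """
    control = np.interp(test_signal.time, control_signal.time, control_signal.response)
    masked = np.abs(control) < floor
    if masked.all():
        raise ValueError("control signal entirely below the floor; nothing to normalize to")
    ratio = np.where(masked, np.nan, test_signal.response / np.where(masked, 1.0, control))
    return Sensorgram(
        time=test_signal.time.copy(),
        response=ratio,
        analyte_conc=test_signal.analyte_conc,
        t_assoc_end=test_signal.t_assoc_end,
        label=f"{test_signal.label}/{control_signal.label}",
    )


def fold_change(kd_a: float, kd_b: float) -> tuple[float, str]:
    """Ratio kd_a/kd_b and the one-significant-figure fold as printed in tables."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("KD values must be positive")
    ratio = kd_a / kd_b
    rounded = float(f"{ratio:.1g}")
    fold = str(int(rounded)) if rounded >= 1 and rounded == int(rounded) else str(rounded)
    return ratio, fold
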