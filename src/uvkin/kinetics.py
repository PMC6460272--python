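"""First-order UV inactivation kinetics with an explicit fluence term.

The survival model is the classic first-order (Chick–Watson style) decay

    N_t = N0 * exp(-k * x(t))

where ``x(t)`` is either exposure time ``t`` in minutes ("time" mode,
``k`` in 1/min) or the total fluence delivered up to ``t`` ("fluence"
mode).  Total fluence is modelled as

    H(t) = T * b * H0 * t

with ``T`` the culture transmittance (fraction), ``b`` the lamp bandwidth
(nm) and ``H0`` the lamp intensity (W/m^2); the proportionality constant
is fixed at 1, so fluence carries units of W·m^-2·nm·min.  Because H is
linear in t the two modes are re-expressions of each other:
``k_time = k_fluence * T*b*H0``.

Estimation is ordinary least squares of ``ln(N_t / N0)`` against ``x``,
fitting both slope and intercept; ``k`` is minus the slope and R^2 is the
conventional coefficient of determination of that regression.  Zero
counts (log undefined) are excluded and recorded on the fit, not
substituted.

Some sources print the closed-form estimators in garbled form
("k=(H(e−t−1))−1lnNt/N0" and "t=lnN0/(1/kHInNt"); those expressions are
not dimensionally consistent with the decay law above and are not
implemented — the standard inversion (k = -ln(Nt/N0)/x pointwise,
t = ln(N0/Nt)/k) is used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import DomainError, InsufficientDataError, UsageError, ValidationError

__all__ = [
    "IrradianceConfig",
    "SurvivalSeries",
    "KineticsFit",
    "od_to_transmittance",
    "total_fluence",
    "predict_survival",
    "fit_survival",
    "half_life",
    "time_to_threshold",
]

#: Tolerance for agreement between a supplied transmittance and one
#: implied by a supplied OD600 (Beer–Lambert, T = 10^-OD).
_OD_T_TOL = 1e-9

_MODES = ("time", "fluence")


def od_to_transmittance(od600: float) -> float:
    """Convert an OD600 absorbance to a transmittance fraction.

    Uses the Beer–Lambert convention ``T = 10**(-OD)``; an OD600 of 1.2
    gives T ≈ 0.063 (6.3%).

    Parameters
    ----------
    od600 : float
        Nonnegative absorbance at 600 nm.

    Returns
    -------
    float
        Transmittance in (0, 1].
    """
    if not math.isfinite(od600) or od600 < 0:
        raise DomainError(f"od600 must be a finite nonnegative number, got {od600!r}")
    return 10.0 ** (-od600)


@dataclass(frozen=True)
class IrradianceConfig:
    """Lamp and culture parameters for a UV irradiance experiment.

    Attributes
    ----------
    wavelength_nm : float
        Lamp wavelength (nm). Default 302 nm (mid-UVB source).
    intensity_h0 : float
        Fluence rate H0 at the sample plane (W/m^2). Default 70.
    bandwidth_b : float
        Spectral bandwidth b of the lamp (nm). Default 10.
    od600 : float or None
        Culture absorbance at 600 nm; when given and ``transmittance_t``
        is not, transmittance is derived as 10^-OD.
    transmittance_t : float or None
        Fraction of incident light reaching the cell film, in (0, 1].
        Default 0.063 when neither OD nor transmittance is supplied.
        If both are supplied they must agree to within 1e-9.
    """

    wavelength_nm: float = 302.0
    intensity_h0: float = 70.0
    bandwidth_b: float = 10.0
    od600: float | None = None
    transmittance_t: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValidationError("wavelength_nm must be positive")
        if self.intensity_h0 <= 0:
            raise ValidationError("intensity_h0 must be positive")
        if self.bandwidth_b <= 0:
            raise ValidationError("bandwidth_b must be positive")
        t = self.transmittance_t
        if self.od600 is not None:
            implied = od_to_transmittance(self.od600)
            if t is None:
                t = implied
            elif abs(t - implied) > _OD_T_TOL:
                raise ValidationError(
                    f"transmittance_t={t} disagrees with 10^(-od600)={implied:.9g} "
                    f"beyond {_OD_T_TOL:g}"
                )
        if t is None:
            t = 0.063  # measured 6.3% for a stationary-phase broth culture
        if not 0 < t <= 1:
            raise ValidationError(f"transmittance must lie in (0, 1], got {t}")
        object.__setattr__(self, "transmittance_t", float(t))

    @property
    def fluence_rate(self) -> float:
        """T*b*H0, the fluence delivered per minute of exposure."""
        return self.transmittance_t * self.bandwidth_b * self.intensity_h0


@dataclass(frozen=True)
class SurvivalSeries:
    """Paired exposure times and plate counts with a control population.

    ``times`` are minutes of UV exposure, strictly increasing; ``counts``
    are the corresponding CFU observations.  ``n0`` is the unirradiated
    control population on the same counting scale as ``counts`` (i.e.
    after any dilution).  A leading t=0 point, when present, is an
    observation of ``n0`` and participates in fitting like any other.

    Counts are stored as reals: observed plate counts are integers
    (enforced at the CSV boundary) but exact model-generated series are
    not, and both fit the same way.
    """

    times: tuple[float, ...]
    counts: tuple[float, ...]
    n0: float
    count_ceiling: float | None = None

    def __init__(
        self,
        times,
        counts,
        n0: float,
        count_ceiling: float | None = None,
    ) -> None:
        times = tuple(float(t) for t in times)
        counts = tuple(float(c) for c in counts)
        if len(times) != len(counts):
            raise ValidationError(
                f"times ({len(times)}) and counts ({len(counts)}) differ in length"
            )
        if len(times) == 0:
            raise ValidationError("empty survival series")
        if any(t < 0 for t in times):
            raise ValidationError("exposure times must be nonnegative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("exposure times must be strictly increasing")
        if any(not math.isfinite(c) or c < 0 for c in counts):
            raise ValidationError("CFU counts must be finite and nonnegative")
        if count_ceiling is not None and any(c > count_ceiling for c in counts):
            bad = next(c for c in counts if c > count_ceiling)
            raise ValidationError(
                f"count {bad} exceeds plate-countability ceiling {count_ceiling}"
            )
        if not (n0 > 0 and math.isfinite(n0)):
            raise ValidationError(f"control population n0 must be positive, got {n0}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "n0", float(n0))
        object.__setattr__(self, "count_ceiling", count_ceiling)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class KineticsFit:
    """Result of a survival-constant fit.

    ``k`` is the survival constant on the scale of the fitting mode
    (1/min in time mode, per fluence unit in fluence mode); ``slope`` is
    always the per-minute slope of the log-linear regression, so
    ``k == -slope`` in time mode and ``k == -slope/(T*b*H0)`` in fluence
    mode.  ``half_life_min`` is ln2 over the per-minute rate and is
    +inf for a non-decaying fit.
    """

    k: float
    slope: float
    intercept: float
    r2: float
    half_life_min: float
    mode: str
    n_points_used: int
    excluded_zero_times: tuple[float, ...] = ()
    non_decaying: bool = False

    @property
    def half_life_hr(self) -> float:
        return self.half_life_min / 60.0

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "half_life_min": self.half_life_min,
            "half_life_hr": self.half_life_hr,
            "mode": self.mode,
            "n_points_used": self.n_points_used,
            "excluded_zero_times": list(self.excluded_zero_times),
            "non_decaying": self.non_decaying,
        }
        return d


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise UsageError(f"mode must be one of {_MODES}, got {mode!r}")


def _x_scale(config: IrradianceConfig | None, mode: str) -> float:
    """Multiplier turning minutes into the fitting abscissa."""
    if mode == "time":
        return 1.0
    if config is None:
        raise UsageError("fluence mode requires an IrradianceConfig")
    return config.fluence_rate


def total_fluence(config: IrradianceConfig, t: float) -> float:
    """Total fluence H = T*b*H0*t delivered after t minutes of exposure.

    Linear and monotone in t; zero at t=0. Units: W·m^-2·nm·min.
    """
    if not math.isfinite(t) or t < 0:
        raise DomainError(f"exposure time must be nonnegative, got {t!r}")
    return config.fluence_rate * t


def predict_survival(
    n0: float,
    k: float,
    t: float,
    config: IrradianceConfig | None = None,
    mode: str = "time",
) -> float:
    """Expected surviving population N0·exp(-k·x(t)) after t minutes."""
    _check_mode(mode)
    if n0 <= 0:
        raise DomainError(f"n0 must be positive, got {n0}")
    if k <= 0:
        raise DomainError(f"survival constant k must be positive, got {k}")
    if not math.isfinite(t) or t < 0:
        raise DomainError(f"exposure time must be nonnegative, got {t!r}")
    return n0 * math.exp(-k * _x_scale(config, mode) * t)


def fit_survival(
    series: SurvivalSeries,
    config: IrradianceConfig | None = None,
    mode: str = "time",
) -> KineticsFit:
    """Estimate the survival constant from a plate-count series.

    Performs OLS of ``y = ln(count/n0)`` on exposure time (time mode) or
    total fluence (fluence mode), with both slope and intercept free.
    Zero counts are excluded (their times are reported on the fit).  A
    nonnegative slope is reported with ``non_decaying=True`` rather than
    raised.

    Raises
    ------
    InsufficientDataError
        If fewer than two positive-count points at distinct times remain.
    """
    _check_mode(mode)
    scale = _x_scale(config, mode)
    t = np.asarray(series.times, dtype=float)
    c = np.asarray(series.counts, dtype=float)
    keep = c > 0
    excluded = tuple(t[~keep])
    t, c = t[keep], c[keep]
    if len(t) < 2 or np.unique(t).size < 2:
        raise InsufficientDataError(
            f"need >= 2 positive counts at distinct times, have {len(t)}"
        )
    x = t * scale
    y = np.log(c / series.n0)
    res = _sps.linregress(x, y)
    slope_x = float(res.slope)
    # On a constant y, linregress reports rvalue = nan; R^2 of a flat fit is 0.
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue) ** 2
    k = -slope_x
    slope_min = slope_x * scale if mode == "fluence" else slope_x
    k_per_min = -slope_min
    non_decaying = slope_x >= 0
    hl = math.inf if non_decaying else math.log(2.0) / k_per_min
    return KineticsFit(
        k=k,
        slope=slope_min,
        intercept=float(res.intercept),
        r2=r2,
        half_life_min=hl,
        mode=mode,
        n_points_used=int(len(t)),
        excluded_zero_times=excluded,
        non_decaying=non_decaying,
    )


def half_life(k: float) -> float:
    """Half-life ln2/k (minutes) of a per-minute survival constant."""
    if not (k > 0 and math.isfinite(k)):
        raise DomainError(f"survival constant k must be positive, got {k}")
    return math.log(2.0) / k


def time_to_threshold(
    k: float,
    n0: float,
    nt: float,
    config: IrradianceConfig | None = None,
    mode: str = "time",
) -> float:
    """Exposure time (minutes) at which the population reaches ``nt``.

    Inverts the decay law: ``t = ln(n0/nt) / (k * [T*b*H0])``.  The
    threshold must be strictly between 0 and n0 — the model never grows,
    and true extinction (nt = 0) takes infinite time under first-order
    decay, so callers wanting "time to die" should pass nt = 1 CFU.
    """
    _check_mode(mode)
    if k <= 0:
        raise DomainError(f"survival constant k must be positive, got {k}")
    if n0 <= 0:
        raise DomainError(f"n0 must be positive, got {n0}")
    if nt <= 0:
        raise DomainError(
            "threshold nt must be positive (extinction time is infinite; "
            "use a threshold of >= 1 CFU)"
        )
    if nt >= n0:
        raise DomainError(f"threshold nt={nt} must be below n0={n0}")
    return math.log(n0 / nt) / (k * _x_scale(config, mode))
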