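"""Track statistics: step speeds, weighted MSD with two-stage Fuerth fits,
and autocovariance-based persistence times.

The mean squared displacement of a persistent random walk follows Fuerth's
equation ``MSD(dt) = 4D (dt - P (1 - exp(-dt/P)))`` with diffusion
coefficient ``D`` and persistence time ``P``. Because a track of ``n`` steps
contains ``floor(n/dt)`` *independent* displacements of length ``dt`` (the
overlapping ones share data), each MSD point is weighted by that count when
fitting. Fitting proceeds in two stages: a rough fit on all lags yields
``(D0, P0)``; the final fit uses only lags ``dt >= P0`` — on a log scale,
fitting ``ln D`` — because lattice cells do not truly move at sub-persistence
timescales and those small-lag points are discretisation artefacts.

Persistence is independently estimated from the decay of the step-vector
autocovariance, ``c * exp(-dt/P)``, restricted to an informative lag window:
lags up to ``0.5 * P_msd`` are discarded (small-lag lattice artefacts), and
so are lags beyond three times the point where the autocovariance first
drops below 5% of its initial value (beyond which the data are noise around
zero). The fit parameterises ``P^2`` to keep the persistence positive.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .migration import Track

__all__ = [
    "MsdCurve",
    "FurthFit",
    "AutocovCurve",
    "AutocovFit",
    "GroupedEstimates",
    "step_speeds",
    "msd_curve",
    "furth_msd",
    "fit_furth",
    "autocov_curve",
    "first_lag_below_fraction",
    "fit_autocov",
    "grouped_estimates",
]


@dataclass
class MsdCurve:
    """Mean squared displacement per lag, with independent-displacement weights."""

    lag: np.ndarray  # time units (e.g. MCS)
    msd: np.ndarray  # pixels^2
    weight: np.ndarray  # number of independent (non-overlapping) displacements

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)


@dataclass
class FurthFit:
    D: float  # diffusion coefficient, pixels^2 per time unit
    P: float  # persistence time
    D0: float  # stage-1 (rough) estimates
    P0: float
    lag_window: tuple[float, float]
    converged: bool = True


@dataclass
class AutocovCurve:
    lag: np.ndarray
    autocov: np.ndarray
    n_pairs: np.ndarray


@dataclass
class AutocovFit:
    c: float
    P: float
    t5: float  # first lag below 5% of the initial autocovariance
    lag_window: tuple[float, float]
    converged: bool = True
    window_open: bool = False  # no decay below 5% observed


def _as_tracks(tracks) -> list[Track]:
    if isinstance(tracks, Track):
        return [tracks]
    return list(tracks)


def step_speeds(track: Track) -> np.ndarray:
    """Instantaneous step-based speeds: displacement per logging interval."""
    if len(track) < 2:
        raise ValueError("need at least two track points for speeds")
    d = np.hypot(np.diff(track.x), np.diff(track.y))
    return d / np.diff(track.t)


def msd_curve(tracks: Track | Sequence[Track]) -> MsdCurve:
    """Pooled MSD over all (overlapping) displacements of all tracks.

    The mean at each lag uses every displacement; the stored weight is the
    pooled count of independent ones, ``sum_tracks floor(n_track / k)`` for
    lag index ``k``.
    """
    tracks = _as_tracks(tracks)
    if not tracks:
        raise ValueError("need at least one track")
    dt = tracks[0].dt
    max_k = max(len(tr) - 1 for tr in tracks)
    sums = np.zeros(max_k + 1)
    counts = np.zeros(max_k + 1)
    weights = np.zeros(max_k + 1)
    for tr in tracks:
        if not np.isclose(tr.dt, dt):
            raise ValueError("all tracks must share the logging interval")
        n = len(tr) - 1
        pos = tr.positions()
        for k in range(1, n + 1):
            disp = pos[k:] - pos[:-k]
            sq = np.einsum("ij,ij->i", disp, disp)
            sums[k] += sq.sum()
            counts[k] += len(sq)
            weights[k] += n // k
    k = np.arange(1, max_k + 1)
    return MsdCurve(lag=k * dt, msd=sums[1:] / counts[1:], weight=weights[1:])


def furth_msd(lag: np.ndarray, D: float, P: float) -> np.ndarray:
    """Fuerth's persistent-random-walk MSD: ``4D (dt - P(1 - exp(-dt/P)))``."""
    lag = np.asarray(lag, dtype=float)
    return 4.0 * D * (lag - P * (1.0 - np.exp(-lag / P)))


def fit_furth(
    curve: MsdCurve, p0_lags: int = 10, max_lag_fraction: float | None = 0.25
) -> FurthFit:
    """Two-stage weighted Fuerth fit of an MSD curve.

    Stage 1 fits all lags starting from ``P0 = p0_lags`` logging intervals
    and ``D0 = MSD(max lag) / (4 max lag)``; stage 2 refits on the log scale
    using only lags ``dt >= P0`` (the stage-1 persistence). If fewer than 5
    lags survive the cut or the final fit fails, the stage-1 values are
    retained and the fit is flagged unconverged.

    Lags beyond ``max_lag_fraction`` of the largest lag are excluded from
    both stages (``None`` disables the cut): the MSD at lags comparable to
    the track length rests on a handful of strongly correlated
    displacements, and including that tail destabilises the persistence
    estimate.
    """
    lag, msd, w = curve.lag, curve.msd, curve.weight
    good = (msd > 0) & (w > 0)
    if max_lag_fraction is not None:
        good &= lag <= max_lag_fraction * lag.max()
    lag, msd, w = lag[good], msd[good], w[good]
    if len(lag) < 3:
        raise ValueError("too few positive MSD points to fit")
    dt = lag[0]
    sw = np.sqrt(w)
    d0_start = max(msd[-1] / (4.0 * lag[-1]), 1e-12)
    p0_start = p0_lags * dt

    def resid_linear(theta):
        log_d, p = theta
        return sw * (furth_msd(lag, np.exp(log_d), p) - msd)

    stage1 = least_squares(
        resid_linear,
        x0=[np.log(d0_start), p0_start],
        bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    d_0 = float(np.exp(stage1.x[0]))
    p_0 = float(stage1.x[1])

    keep = lag >= p_0
    if keep.sum() < 5:
        warnings.warn("fewer than 5 lags beyond P0; keeping stage-1 Fuerth fit")
        return FurthFit(D=d_0, P=p_0, D0=d_0, P0=p_0,
                        lag_window=(float(lag[0]), float(lag[-1])), converged=False)
    lag2, msd2, sw2 = lag[keep], msd[keep], np.sqrt(w[keep])

    def resid_log(theta):
        log_d, p = theta
        model = furth_msd(lag2, np.exp(log_d), p)
        model = np.maximum(model, 1e-300)
        return sw2 * (np.log(model) - np.log(msd2))

    stage2 = least_squares(
        resid_log,
        x0=[np.log(d_0), p_0],
        bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not stage2.success:
        warnings.warn("final Fuerth fit did not converge; keeping stage-1 values")
        return FurthFit(D=d_0, P=p_0, D0=d_0, P0=p_0,
                        lag_window=(float(lag2[0]), float(lag2[-1])), converged=False)
    return FurthFit(
        D=float(np.exp(stage2.x[0])),
        P=float(stage2.x[1]),
        D0=d_0,
        P0=p_0,
        lag_window=(float(lag2[0]), float(lag2[-1])),
        converged=True,
    )


def autocov_curve(tracks: Track | Sequence[Track]) -> AutocovCurve:
    """Mean dot product of step displacement vectors separated by each lag.

    Lag 0 is the mean squared step length; for a persistent random walk the
    curve decays exponentially with time constant P.
    """
    tracks = _as_tracks(tracks)
    if not tracks or any(len(tr) < 3 for tr in tracks):
        raise ValueError("need tracks with at least 3 points")
    dt = tracks[0].dt
    max_k = max(len(tr) - 2 for tr in tracks)
    sums = np.zeros(max_k + 1)
    counts = np.zeros(max_k + 1)
    for tr in tracks:
        steps = np.diff(tr.positions(), axis=0)
        n = len(steps)
        for k in range(0, n):
            dots = np.einsum("ij,ij->i", steps[k:], steps[: n - k])
            sums[k] += dots.sum()
            counts[k] += len(dots)
    k = np.arange(0, max_k + 1)
    return AutocovCurve(lag=k * dt, autocov=sums / counts, n_pairs=counts)


def first_lag_below_fraction(
    lag: np.ndarray,
    values: np.ndarray,
    fraction: float = 0.05,
    reference: float | None = None,
) -> float:
    """Smallest lag at which ``values`` drops below ``fraction * reference``.

    ``reference`` defaults to the value at the smallest lag present. Returns
    ``inf`` when no point falls below the threshold.
    """
    lag = np.asarray(lag, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(lag)
    lag, values = lag[order], values[order]
    if reference is None:
        reference = values[0]
    below = values < fraction * reference
    if not below.any():
        return float("inf")
    return float(lag[np.argmax(below)])


def fit_autocov(
    curve: AutocovCurve, p_msd: float, fraction: float = 0.05
) -> AutocovFit:
    """Exponential-decay fit of the autocovariance over its informative window.

    Keeps lags with ``dt > 0.5 * p_msd`` and ``dt < 3 * t5`` where ``t5`` is
    the first retained lag below 5% of the autocovariance at the smallest
    retained lag. Fits ``c * exp(-dt / sqrt(Psq))`` starting from
    ``(c=1, Psq=p_msd^2)`` and returns ``P = sqrt(Psq)``; an all-positive
    curve leaves the window open and is flagged.
    """
    if p_msd <= 0:
        raise ValueError("p_msd must be > 0")
    lag = np.asarray(curve.lag, dtype=float)
    ac = np.asarray(curve.autocov, dtype=float)
    retained = lag > 0.5 * p_msd
    if not retained.any():
        warnings.warn("autocovariance window empty after the 0.5*P_msd filter")
        return AutocovFit(np.nan, np.nan, np.nan, (np.nan, np.nan), converged=False)
    lag_r, ac_r = lag[retained], ac[retained]
    t5 = first_lag_below_fraction(lag_r, ac_r, fraction)
    window_open = not np.isfinite(t5)
    keep = lag_r < 3.0 * t5 if not window_open else np.ones_like(lag_r, dtype=bool)
    lag_k, ac_k = lag_r[keep], ac_r[keep]
    if len(lag_k) < 2:
        warnings.warn("autocovariance window too small to fit")
        return AutocovFit(np.nan, np.nan, t5, (np.nan, np.nan), converged=False,
                          window_open=window_open)

    def resid(theta):
        c, psq = theta
        return c * np.exp(-lag_k / np.sqrt(psq)) - ac_k

    fit = least_squares(
        resid,
        x0=[1.0, p_msd**2],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not fit.success:
        warnings.warn("autocovariance fit did not converge")
        return AutocovFit(np.nan, np.nan, t5, (float(lag_k[0]), float(lag_k[-1])),
                          converged=False, window_open=window_open)
    return AutocovFit(
        c=float(fit.x[0]),
        P=float(np.sqrt(fit.x[1])),
        t5=t5,
        lag_window=(float(lag_k[0]), float(lag_k[-1])),
        converged=True,
        window_open=window_open,
    )


@dataclass
class GroupedEstimates:
    """Mean +/- SD of speed and persistence over independent track groups."""

    per_group: "object"  # pandas DataFrame: group, mean_speed, P_msd, P_autocov
    mean_speed: float
    sd_speed: float
    mean_persistence_msd: float
    sd_persistence_msd: float
    mean_persistence_autocov: float
    sd_persistence_autocov: float


def grouped_estimates(
    tracks: Sequence[Track], n_groups: int = 6, group_size: int = 5
) -> GroupedEstimates:
    """Independent speed/persistence estimates from groups of tracks.

    Tracks are split into ``n_groups`` consecutive groups of ``group_size``
    (by simulation order). Each group yields a mean step speed, an MSD-fit
    persistence and an autocovariance persistence; the summary reports the
    mean and SD over groups (ignoring failed autocovariance fits).
    """
    import pandas as pd

    tracks = list(tracks)
    if len(tracks) != n_groups * group_size:
        raise ValueError(
            f"need exactly {n_groups * group_size} tracks "
            f"({n_groups} groups of {group_size}), got {len(tracks)}"
        )
    rows = []
    for g in range(n_groups):
        group = tracks[g * group_size : (g + 1) * group_size]
        speeds = np.concatenate([step_speeds(tr) for tr in group])
        furth = fit_furth(msd_curve(group))
        acov = fit_autocov(autocov_curve(group), p_msd=furth.P)
        rows.append(
            {
                "group": g,
                "mean_speed": float(speeds.mean()),
                "persistence_msd": furth.P,
                "persistence_autocov": acov.P if acov.converged else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return GroupedEstimates(
            per_group=df,
            mean_speed=float(df["mean_speed"].mean()),
            sd_speed=float(df["mean_speed"].std(ddof=1)),
            mean_persistence_msd=float(df["persistence_msd"].mean()),
            sd_persistence_msd=float(df["persistence_msd"].std(ddof=1)),
            mean_persistence_autocov=float(np.nanmean(df["persistence_autocov"])),
            sd_persistence_autocov=float(np.nanstd(df["persistence_autocov"], ddof=1)),
        )
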