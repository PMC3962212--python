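"""Cell motility statistics from trajectories.

The motility model is the persistent random walk: cell velocity decorrelates
exponentially with a characteristic *persistence time* P, and the velocity
autocovariance is ``phi(tau) = phi0 * exp(-tau/P)`` with amplitude ``phi0``
approximately the mean squared velocity (µm²/min²). Two estimation routes
are provided:

* velocity autocovariance + weighted exponential fit -> (P, phi0);
* mean squared displacement + extended Fürth fit
  ``MSD(tau) = 2*phi0*P*[tau - P*(1 - exp(-tau/P))] + 4*sigma_pos**2``
  -> (P, phi0, sigma_pos), where sigma_pos is the per-coordinate centroid
  measurement error that offsets the MSD by a constant.

Autocovariance points computed from one set of tracks are mutually
correlated and their naive standard errors are underestimates at long lags
(data redundancy). Fit errors are therefore corrected by a seeded
cell-level bootstrap; corrected errors are floored at the raw fit errors.

The module exposes both the individual estimators and a statsmodels-style
`MotilityModel` / `MotilityResults` pair wrapping them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .tracking import Track

__all__ = [
    "VelocitySeries",
    "AcovEstimate",
    "MsdEstimate",
    "MotilityFit",
    "track_velocities",
    "velocity_autocovariance",
    "fit_exponential_acov",
    "ensemble_msd",
    "fit_extended_furth",
    "correct_overdispersion",
    "pool_parameters",
    "MotilityModel",
    "MotilityResults",
]


@dataclass
class VelocitySeries:
    """Velocities of one gap-free track segment, µm/min; times in minutes."""

    times: np.ndarray
    velocities: np.ndarray


@dataclass
class AcovEstimate:
    """Velocity autocovariance phi(tau) per lag, with naive standard errors.

    The stderr at lag tau is (sample std of the contributing velocity dot
    products) / sqrt(n_pairs) — an underestimate at long lags because the
    products overlap in time; see `correct_overdispersion`.
    """

    lags: np.ndarray  # minutes
    values: np.ndarray  # µm²/min²
    stderrs: np.ndarray
    n_pairs: np.ndarray


@dataclass
class MsdEstimate:
    """Ensemble mean squared displacement per lag (µm²)."""

    lags: np.ndarray
    values: np.ndarray
    stderrs: np.ndarray
    n_pairs: np.ndarray


@dataclass
class MotilityFit:
    """Fitted motility parameters with raw and corrected 1σ errors.

    P in minutes, phi0 in µm²/min², sigma_pos in µm (MSD route only,
    NaN otherwise). `corrected_errors` is None until
    `correct_overdispersion` has been applied.
    """

    P: float
    phi0: float
    sigma_pos: float
    raw_errors: dict[str, float]
    covariance: np.ndarray
    method: str  # "acov" or "furth"
    corrected_errors: dict[str, float] | None = None
    valid: bool = True
    flags: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# velocities


def _segments(track: Track) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a track at frame gaps and excluded points; return (frames, pos)."""
    ok = ~track.flags
    frames = track.frames[ok]
    pos = track.positions[ok]
    if len(frames) == 0:
        return []
    breaks = np.nonzero(np.diff(frames) != 1)[0] + 1
    return [
        (f, p)
        for f, p in zip(np.split(frames, breaks), np.split(pos, breaks))
        if len(f) >= 2
    ]


def track_velocities(track: Track, dt: float, pixel_size: float) -> list[VelocitySeries]:
    """Forward-difference velocities, µm/min, one series per gap-free segment.

    ``v(t_i) = (r_{i+1} - r_i) / dt`` with positions converted px -> µm.
    Frame gaps (and excluded points) split the track; each returned segment
    is uniformly sampled at `dt` minutes.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0 minutes")
    out = []
    for frames, pos in _segments(track):
        r = pos * pixel_size
        v = np.diff(r, axis=0) / dt
        t = frames[:-1] * dt
        out.append(VelocitySeries(times=np.asarray(t, dtype=float), velocities=v))
    return out


# ---------------------------------------------------------------------------
# lag statistics: accumulate (n, sum, sumsq) per lag per track so the
# bootstrap can resample cells without recomputing products


def _acov_moments(tracks: list[Track], n_lags: int, dt: float, pixel_size: float) -> np.ndarray:
    """Per-track accumulators: array (n_tracks, n_lags, 3) of (n, sum, sumsq)."""
    acc = np.zeros((len(tracks), n_lags, 3))
    for ti, tr in enumerate(tracks):
        for seg in track_velocities(tr, dt, pixel_size):
            v = seg.velocities
            m = len(v)
            for k in range(min(n_lags, m)):
                prods = np.einsum("ij,ij->i", v[: m - k], v[k:])
                acc[ti, k, 0] += prods.size
                acc[ti, k, 1] += prods.sum()
                acc[ti, k, 2] += (prods**2).sum()
    return acc


def _msd_moments(tracks: list[Track], n_lags: int, dt: float, pixel_size: float) -> np.ndarray:
    acc = np.zeros((len(tracks), n_lags, 3))
    for ti, tr in enumerate(tracks):
        for frames, pos in _segments(tr):
            r = pos * pixel_size
            m = len(r)
            for k in range(1, min(n_lags, m)):
                d = r[k:] - r[: m - k]
                sq = (d**2).sum(axis=1)
                acc[ti, k, 0] += sq.size
                acc[ti, k, 1] += sq.sum()
                acc[ti, k, 2] += (sq**2).sum()
    return acc


def _moments_to_estimate(acc: np.ndarray, dt: float, kind: str):
    tot = acc.sum(axis=0)  # (n_lags, 3)
    n = tot[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = tot[:, 1] / n
        var = (tot[:, 2] - n * mean**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    stderr = np.sqrt(np.where(n > 1, var / n, np.nan))
    lags = np.arange(len(n)) * dt
    keep = n > 0
    if kind == "acov":
        return AcovEstimate(lags[keep], mean[keep], stderr[keep], n[keep].astype(int))
    est = MsdEstimate(lags[keep], mean[keep], stderr[keep], n[keep].astype(int))
    # MSD(0) = 0 by definition
    if est.lags[0] == 0:
        est.values[0] = 0.0
        est.stderrs[0] = 0.0
    return est


def velocity_autocovariance(
    tracks: list[Track], max_lag: float, dt: float, pixel_size: float
) -> AcovEstimate:
    """phi(tau): mean of v(t)·v(t+tau) over all cells and valid time pairs.

    phi(0) is exactly the ensemble mean squared velocity. Lags with no
    contributing pairs are omitted.
    """
    n_lags = int(np.floor(max_lag / dt)) + 1
    acc = _acov_moments(tracks, n_lags, dt, pixel_size)
    if acc[:, :, 0].sum() == 0:
        raise ValueError("no velocity pairs available (tracks too short?)")
    return _moments_to_estimate(acc, dt, "acov")


def ensemble_msd(
    tracks: list[Track], max_lag: float, dt: float, pixel_size: float
) -> MsdEstimate:
    """MSD(tau): mean of |r(t+tau) − r(t)|² over cells and time origins."""
    n_lags = int(np.floor(max_lag / dt)) + 1
    acc = _msd_moments(tracks, n_lags, dt, pixel_size)
    if acc[:, 1:, 0].sum() == 0:
        raise ValueError("no displacement pairs available")
    return _moments_to_estimate(acc, dt, "msd")


# ---------------------------------------------------------------------------
# fits


def _wls_sigma(stderrs: np.ndarray) -> np.ndarray:
    s = np.asarray(stderrs, dtype=float).copy()
    floor = 1e-12 if not np.any(s > 0) else 1e-6 * np.nanmax(s)
    s[~np.isfinite(s) | (s <= 0)] = max(floor, 1e-300)
    return s


def _exp_model(tau, phi0, P):
    # clipped exponent keeps curve_fit's excursions through tiny P finite
    return phi0 * np.exp(np.clip(-np.asarray(tau, dtype=float) / P, -700.0, 700.0))


def _initial_P(lags, values) -> float:
    """Log-linear slope estimate of the decay time over positive points."""
    pos = values > 0
    if pos.sum() >= 3 and np.ptp(lags[pos]) > 0:
        slope = np.polyfit(lags[pos], np.log(values[pos]), 1)[0]
        if slope < 0:
            return -1.0 / slope
    return max(np.ptp(lags) / 3.0, 1.0)


def fit_exponential_acov(
    acov: AcovEstimate,
    fit_range: tuple[float, float] | None = None,
    include_zero_lag: bool = False,
) -> MotilityFit:
    """Weighted least-squares fit of ``phi0 * exp(-tau/P)``.

    Weights are 1/stderr². By default the zero-lag point is excluded (it is
    inflated by positional noise) and the window is iterated once: lags up
    to 3× an initial log-linear estimate of P. Raw 1σ errors come from the
    fit covariance; they ignore the correlation between autocovariance
    points (use `correct_overdispersion`).
    """
    lags, vals, errs = acov.lags, acov.values, acov.stderrs
    ok = np.isfinite(vals) & (acov.n_pairs > 1)
    if not include_zero_lag:
        ok &= lags > 0
    if fit_range is not None:
        lo, hi = fit_range
        ok &= (lags >= lo) & (lags <= hi)
        window = (lo, hi)
    else:
        p_init = _initial_P(lags[ok], vals[ok])
        hi = 3.0 * p_init
        ok &= lags <= hi
        window = (float(lags[ok].min()) if ok.any() else 0.0, hi)
    if ok.sum() < 3:
        raise ValueError("need at least 3 lags in the fit window")
    x, y, s = lags[ok], vals[ok], _wls_sigma(errs[ok])
    p0 = (max(y[0], 1e-6), _initial_P(x, y))
    try:
        popt, pcov = curve_fit(
            _exp_model, x, y, p0=p0, sigma=s, absolute_sigma=True, maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"exponential autocovariance fit did not converge: {exc}; "
            f"window={window}, n={ok.sum()}"
        ) from exc
    phi0, P = popt
    perr = np.sqrt(np.diag(pcov))
    flags = [] if P > 0 else ["negative persistence time: fit invalid"]
    return MotilityFit(
        P=float(P),
        phi0=float(phi0),
        sigma_pos=float("nan"),
        raw_errors={"P": float(perr[1]), "phi0": float(perr[0])},
        covariance=pcov,
        method="acov",
        valid=P > 0,
        flags=flags,
        settings={"fit_range": window, "include_zero_lag": include_zero_lag},
    )


def furth_msd(tau, P, phi0, noise_offset):
    """Persistent-random-walk MSD plus constant positional-noise offset.

    ``2*phi0*P*(tau - P*(1 - exp(-tau/P))) + noise_offset`` where
    noise_offset = 4*sigma_pos²; ballistic ``phi0*tau²`` at short lags,
    diffusive ``2*phi0*P*tau`` at long lags.
    """
    tau = np.asarray(tau, dtype=float)
    decay = np.exp(np.clip(-tau / P, -700.0, 700.0))
    return 2.0 * phi0 * P * (tau - P * (1.0 - decay)) + noise_offset


def fit_extended_furth(
    msd: MsdEstimate, fit_range: tuple[float, float] | None = None
) -> MotilityFit:
    """Weighted least-squares fit of the extended Fürth MSD curve.

    Fits (P, phi0, 4*sigma_pos²) to MSD(tau) for tau > 0; the constant
    offset estimates the centroid positional measurement error sigma_pos.
    A negative fitted offset is clamped to sigma_pos = 0 and flagged.
    """
    lags, vals, errs = msd.lags, msd.values, msd.stderrs
    ok = (lags > 0) & np.isfinite(vals) & (msd.n_pairs > 1)
    if fit_range is not None:
        ok &= (lags >= fit_range[0]) & (lags <= fit_range[1])
    if ok.sum() < 4:
        raise ValueError("need at least 4 positive lags for the Fürth fit")
    x, y, s = lags[ok], vals[ok], _wls_sigma(errs[ok])
    # initial values: diffusive slope and short-lag curvature
    slope = max((y[-1] - y[0]) / (x[-1] - x[0]), 1e-9)
    phi0_0 = max(y[0] / x[0] ** 2, 1e-9)
    P0 = max(slope / (2.0 * phi0_0), x[1] - x[0])
    try:
        popt, pcov = curve_fit(
            furth_msd, x, y, p0=(P0, phi0_0, 0.0), sigma=s,
            absolute_sigma=True, maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise RuntimeError(f"extended Fürth fit did not converge: {exc}") from exc
    P, phi0, c = popt
    perr = np.sqrt(np.diag(pcov))
    flags = []
    if c >= 0:
        sigma_pos = float(np.sqrt(c) / 2.0)
        sig_err = float(perr[2] / (4.0 * np.sqrt(c))) if c > 0 else float("inf")
    else:
        sigma_pos, sig_err = 0.0, float("nan")
        flags.append("fitted noise offset negative; sigma_pos clamped to 0")
    if P <= 0:
        flags.append("negative persistence time: fit invalid")
    return MotilityFit(
        P=float(P),
        phi0=float(phi0),
        sigma_pos=sigma_pos,
        raw_errors={"P": float(perr[0]), "phi0": float(perr[1]), "sigma_pos": sig_err},
        covariance=pcov,
        method="furth",
        valid=P > 0,
        flags=flags,
        settings={"fit_range": fit_range},
    )


# ---------------------------------------------------------------------------
# overdispersion correction and pooling


def _fit_from_moments(acc_sum: np.ndarray, dt: float, method: str, settings: dict):
    if method == "acov":
        est = _moments_to_estimate(acc_sum[None, :, :], dt, "acov")
        return fit_exponential_acov(
            est,
            fit_range=settings.get("fit_range"),
            include_zero_lag=settings.get("include_zero_lag", False),
        )
    est = _moments_to_estimate(acc_sum[None, :, :], dt, "msd")
    return fit_extended_furth(est, fit_range=settings.get("fit_range"))


def correct_overdispersion(
    fit: MotilityFit,
    tracks: list[Track],
    n_boot: int,
    seed: int,
    dt: float,
    pixel_size: float,
    max_lag: float | None = None,
) -> MotilityFit:
    """Bootstrap-corrected parameter errors accounting for data redundancy.

    Autocovariance (and MSD) points from overlapping time pairs of the same
    cells are correlated, so the naive fit errors are too small. Cells are
    resampled with replacement `n_boot` times; the lag statistics and the
    fit are recomputed per replicate, and the corrected error of each
    parameter is the bootstrap standard deviation, floored at the raw error.
    Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable corrected errors")
    if len(tracks) < 3:
        raise ValueError(
            "overdispersion correction needs >= 3 tracks; "
            "a cell-level bootstrap over fewer cells is meaningless"
        )
    if max_lag is None:
        fr = fit.settings.get("fit_range")
        max_lag = fr[1] if fr else 3.0 * fit.P
    n_lags = int(np.floor(max_lag / dt)) + 1
    if fit.method == "acov":
        acc = _acov_moments(tracks, n_lags, dt, pixel_size)
    else:
        acc = _msd_moments(tracks, n_lags, dt, pixel_size)
    rng = np.random.default_rng(seed)
    names = list(fit.raw_errors)
    samples: dict[str, list[float]] = {k: [] for k in names}
    n = len(tracks)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            bfit = _fit_from_moments(acc[idx].sum(axis=0), dt, fit.method, fit.settings)
        except (RuntimeError, ValueError):
            continue  # rare non-convergent replicate
        if not bfit.valid:
            continue
        for k in names:
            samples[k].append(getattr(bfit, k if k != "phi0" else "phi0"))
    # small-sample factor: the bootstrap of n cells understates the sampling
    # sd of smooth statistics by ~sqrt((n-1)/n)
    inflate = np.sqrt(n / (n - 1.0))
    corrected = {}
    for k in names:
        vals = np.asarray(samples[k], dtype=float)
        vals = vals[np.isfinite(vals)]
        boot_sd = float(np.std(vals, ddof=1) * inflate) if len(vals) >= 10 else float("nan")
        raw = fit.raw_errors[k]
        corrected[k] = max(boot_sd, raw) if np.isfinite(boot_sd) else raw
    return MotilityFit(
        P=fit.P,
        phi0=fit.phi0,
        sigma_pos=fit.sigma_pos,
        raw_errors=dict(fit.raw_errors),
        covariance=fit.covariance,
        method=fit.method,
        corrected_errors=corrected,
        valid=fit.valid,
        flags=list(fit.flags),
        settings={**fit.settings, "n_boot": n_boot, "bootstrap_seed": seed},
    )


def pool_parameters(fits: list[MotilityFit]) -> MotilityFit:
    """Inverse-variance weighted mean of parameters across movies.

    Pooled value ``sum(x_i/s_i²)/sum(1/s_i²)``, pooled error
    ``sqrt(1/sum(1/s_i²))``, using corrected errors. Permutation invariant.
    """
    if len(fits) < 2:
        raise ValueError("pooling needs >= 2 fits")
    if any(f.corrected_errors is None for f in fits):
        raise ValueError("all fits must carry corrected errors before pooling")
    names = [k for k in ("P", "phi0", "sigma_pos") if all(
        k in f.corrected_errors and np.isfinite(getattr(f, k)) for f in fits
    )]
    values, errors = {}, {}
    for k in names:
        x = np.asarray([getattr(f, k) for f in fits], dtype=float)
        s = np.asarray([f.corrected_errors[k] for f in fits], dtype=float)
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ValueError(f"zero or non-finite variance for parameter {k}")
        w = 1.0 / s**2
        values[k] = float((w * x).sum() / w.sum())
        errors[k] = float(np.sqrt(1.0 / w.sum()))
    return MotilityFit(
        P=values.get("P", float("nan")),
        phi0=values.get("phi0", float("nan")),
        sigma_pos=values.get("sigma_pos", float("nan")),
        raw_errors=dict(errors),
        covariance=np.diag([errors[k] ** 2 for k in names]),
        method=f"pooled-{fits[0].method}",
        corrected_errors=dict(errors),
        valid=all(f.valid for f in fits),
        settings={"n_pooled": len(fits)},
    )


# ---------------------------------------------------------------------------
# statsmodels-style front end


class MotilityModel:
    """Persistent-random-walk motility model for a set of cell tracks.

    Parameters
    ----------
    tracks : list of Track
        Trajectories in pixel coordinates (uniform frame interval).
    dt : float
        Frame interval, minutes.
    pixel_size : float
        Pixel edge length, µm (0.977 µm for the reference microscope setup).
    max_lag : float, optional
        Longest lag (minutes) entering the lag statistics; default one third
        of the longest track duration.

    Examples
    --------
    >>> model = MotilityModel(tracks, dt=2.0, pixel_size=0.977)
    >>> res = model.fit(method="acov", n_boot=200, seed=7)
    >>> print(res.summary())
    """

    def __init__(
        self,
        tracks: list[Track],
        dt: float,
        pixel_size: float = 0.977,
        max_lag: float | None = None,
    ) -> None:
        if not tracks:
            raise ValueError("no tracks supplied")
        self.tracks = list(tracks)
        self.dt = float(dt)
        self.pixel_size = float(pixel_size)
        if max_lag is None:
            longest = max(len(t) for t in tracks)
            max_lag = (longest - 1) * self.dt / 3.0
        self.max_lag = float(max_lag)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dt: float,
        pixel_size: float = 0.977,
        **kwargs,
    ) -> "MotilityModel":
        """Build from a track table with columns track_id, frame, x_px, y_px."""
        from .io import tracks_from_dataframe

        return cls(tracks_from_dataframe(df), dt=dt, pixel_size=pixel_size, **kwargs)

    def acov(self) -> AcovEstimate:
        return velocity_autocovariance(self.tracks, self.max_lag, self.dt, self.pixel_size)

    def msd(self) -> MsdEstimate:
        return ensemble_msd(self.tracks, self.max_lag, self.dt, self.pixel_size)

    def fit(
        self,
        method: str = "acov",
        fit_range: tuple[float, float] | None = None,
        n_boot: int = 200,
        seed: int | None = None,
    ) -> "MotilityResults":
        """Fit the motility parameters.

        method "acov": exponential fit to the velocity autocovariance for
        (P, phi0). method "furth": extended Fürth fit to the MSD for
        (P, phi0, sigma_pos). If `seed` is given and there are >= 3 tracks,
        errors are bootstrap-corrected with `n_boot` replicates.
        """
        if method == "acov":
            estimate = self.acov()
            fit = fit_exponential_acov(estimate, fit_range=fit_range)
        elif method == "furth":
            estimate = self.msd()
            fit = fit_extended_furth(estimate, fit_range=fit_range)
        else:
            raise ValueError(f"unknown method {method!r}; use 'acov' or 'furth'")
        if seed is not None and len(self.tracks) >= 3:
            fit = correct_overdispersion(
                fit, self.tracks, n_boot=n_boot, seed=seed,
                dt=self.dt, pixel_size=self.pixel_size, max_lag=self.max_lag,
            )
        return MotilityResults(self, fit, estimate)


class MotilityResults:
    """Fit results: parameters, errors, diagnostics, summary table."""

    def __init__(self, model: MotilityModel, fit: MotilityFit, estimate) -> None:
        self.model = model
        self.fit = fit
        self.estimate = estimate
        names = [k for k in ("P", "phi0", "sigma_pos") if k in fit.raw_errors]
        self.params = pd.Series({k: getattr(fit, k) for k in names})
        self.bse = pd.Series({k: fit.raw_errors[k] for k in names})
        self.corrected_bse = (
            pd.Series(fit.corrected_errors) if fit.corrected_errors else None
        )

    @property
    def persistence_time(self) -> float:
        return self.fit.P

    @property
    def phi0(self) -> float:
        return self.fit.phi0

    @property
    def sigma_pos(self) -> float:
        return self.fit.sigma_pos

    def cov_params(self) -> np.ndarray:
        return self.fit.covariance

    def conf_int(self, nsigma: float = 1.0, corrected: bool = True) -> pd.DataFrame:
        err = self.corrected_bse if corrected and self.corrected_bse is not None else self.bse
        lo = self.params - nsigma * err
        hi = self.params + nsigma * err
        return pd.DataFrame({"lower": lo, "upper": hi})

    def simulate(self, n_cells: int, n_frames: int, seed: int) -> list[Track]:
        """Simulate tracks from the fitted parameters (OU velocity process)."""
        from .synthetic import MotilityGroundTruth, simulate_ou_tracks

        gt = MotilityGroundTruth(
            P_true=self.fit.P,
            phi0_true=self.fit.phi0,
            sigma_pos_true=0.0,
            dt=self.model.dt,
            n_cells=n_cells,
            n_frames=n_frames,
            seed=seed,
        )
        return simulate_ou_tracks(gt, pixel_size=self.model.pixel_size)

    def summary(self) -> str:
        units = {"P": "min", "phi0": "µm²/min²", "sigma_pos": "µm"}
        buf = io.StringIO()
        title = {
            "acov": "Velocity autocovariance exponential fit",
            "furth": "Extended Fürth MSD fit",
        }.get(self.fit.method, self.fit.method)
        buf.write(f"{title}\n")
        buf.write("=" * 64 + "\n")
        buf.write(
            f"n_tracks: {len(self.model.tracks)}   dt: {self.model.dt} min   "
            f"max_lag: {self.model.max_lag:.1f} min\n"
        )
        buf.write("-" * 64 + "\n")
        buf.write(f"{'param':>10} {'value':>12} {'raw 1σ':>12} {'corr 1σ':>12}  unit\n")
        for k in self.params.index:
            corr = (
                f"{self.corrected_bse[k]:12.4g}"
                if self.corrected_bse is not None and k in self.corrected_bse
                else f"{'—':>12}"
            )
            buf.write(
                f"{k:>10} {self.params[k]:12.4g} {self.bse[k]:12.4g} {corr}  {units[k]}\n"
            )
        for fl in self.fit.flags:
            buf.write(f"note: {fl}\n")
        buf.write("=" * 64 + "\n")
        return buf.getvalue()

    def plot(self, ax=None):
        """Plot the lag statistic and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        est = self.estimate
        ax.errorbar(est.lags, est.values, yerr=est.stderrs, fmt="o", ms=3, label="data")
        tau = np.linspace(est.lags[est.lags > 0].min(), est.lags.max(), 200)
        if self.fit.method == "acov":
            ax.plot(tau, _exp_model(tau, self.fit.phi0, self.fit.P), label="fit")
            ax.set_ylabel("φ(τ)  [µm²/min²]")
        else:
            off = 4.0 * self.fit.sigma_pos**2
            ax.plot(tau, furth_msd(tau, self.fit.P, self.fit.phi0, off), label="fit")
            ax.set_ylabel("MSD(τ)  [µm²]")
        ax.set_xlabel("lag τ  [min]")
        ax.legend()
        return ax
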