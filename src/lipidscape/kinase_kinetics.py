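"""Real-time PIP 5-kinase assay analysis.

Pipeline: raw NBD-fluorescence progress curves (Em 530 nm, one read per
second, t = 0 at ATP addition) are corrected by subtracting both the
pre-ATP baseline and a matched background curve recorded with 0 mol%
substrate liposomes,

    ΔEm530(t) = (raw(t) − raw baseline) − (bg(t) − bg baseline),

initial velocities are taken as the least-squares slope of the initial
portion of each corrected curve, and velocities across substrate levels are
fitted to the allosteric sigmoidal (Hill) model

    v(S) = Vmax · S^h / (Khalf^h + S^h)

to obtain the apparent Km (≡ Khalf, the half-saturation substrate mol%),
Vmax and the Hill coefficient h. A linear probe calibration (signal per
mol% product, valid 0.125–1 mol%) optionally converts signal/s to mol%/s,
and simple blank subtraction covers endpoint (luminescence / absorbance)
assays.

The Hill fit is exposed both as the sklearn-style :class:`HillRegressor`
estimator and the functional wrapper :func:`fit_allosteric_sigmoidal`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class ProgressCurve:
    """A fluorescence time series with its pre-ATP baseline."""

    time: np.ndarray  # s, ascending, t=0 at ATP addition
    signal: np.ndarray
    baseline: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.time) < 5:
            raise ValueError("progress curve needs at least 5 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class CorrectedCurve:
    time: np.ndarray
    delta: np.ndarray  # ΔEm530, signal units

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)


@dataclass
class CalibrationLine:
    slope: float  # signal per mol% product
    intercept: float
    slope_se: float
    intercept_se: float
    valid_range: tuple[float, float] = (0.125, 1.0)
    n_used: int = 0
    excluded: list = field(default_factory=list)

    def signal_to_mol_percent(self, corrected_signal: float) -> float:
        """Invert the line: (signal − intercept) / slope."""
        return (corrected_signal - self.intercept) / self.slope


@dataclass
class KineticFit:
    vmax: float
    khalf: float  # apparent Km, mol% substrate
    hill: float
    rss: float
    converged: bool
    se: tuple = (np.nan, np.nan, np.nan)
    ci: dict | None = None  # residual-bootstrap CIs, if requested

    def velocity(self, S):
        from .synthetic_data import hill_velocity

        return hill_velocity(S, self.vmax, self.khalf, self.hill)


def correct_progress_curve(raw: ProgressCurve, background: ProgressCurve) -> CorrectedCurve:
    """Baseline- and background-subtract a raw curve.

    The background is interpolated linearly onto the raw time grid when the
    grids differ; the grids must overlap. Negative values are retained.
    """
    t = raw.time
    if t[0] > background.time[-1] or t[-1] < background.time[0]:
        raise ValueError("raw and background time ranges do not overlap")
    bg = np.interp(t, background.time, background.signal)
    delta = (raw.signal - raw.baseline) - (bg - background.baseline)
    return CorrectedCurve(t, delta)


def fit_probe_calibration(
    standards, valid_range: tuple[float, float] = (0.125, 1.0)
) -> CalibrationLine:
    """OLS line through (mol% product, signal) standards.

    Standards outside ``valid_range`` are excluded from the fit and reported
    in the returned object.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (n, 2): mol%, signal")
    lo, hi = valid_range
    inside = (arr[:, 0] >= lo) & (arr[:, 0] <= hi)
    used, dropped = arr[inside], arr[~inside]
    if len(used) < 2 or len(np.unique(used[:, 0])) < 2:
        raise ValueError("need at least 2 usable standards at distinct concentrations")
    res = stats.linregress(used[:, 0], used[:, 1])
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        valid_range=valid_range,
        n_used=len(used),
        excluded=dropped.tolist(),
    )


def initial_velocity(
    curve: CorrectedCurve,
    plateau_fraction: float = 0.2,
    fallback_fraction: float = 0.1,
    min_points: int = 5,
) -> float:
    """Least-squares slope of the initial portion of a corrected curve.

    Default window policy: fit over [0, t_w] where t_w is the largest time
    at which the curve is still below ``plateau_fraction`` of its plateau
    (the mean of the final 10% of points). If no usable plateau exists the
    first ``fallback_fraction`` of points is used. Exact on linear curves.
    """
    t, y = curve.time, curve.delta
    n = len(t)
    if n < min_points:
        raise ValueError("initial window shorter than 5 samples")
    plateau = float(np.mean(y[n - max(n // 10, 1):]))
    # robust point-noise estimate from successive differences
    noise = 1.4826 * float(np.median(np.abs(np.diff(y)))) / np.sqrt(2.0) if n > 1 else 0.0
    stop = None
    if plateau > 0:
        # first up-crossing of the smoothed curve through the cut; the noise
        # floor keeps baseline wiggle from truncating the window on curves
        # that never approach their plateau
        w = max(min_points, n // 50)
        kernel = np.ones(w) / w
        smooth = np.convolve(y, kernel, mode="same")
        cut = max(plateau_fraction * plateau, 3.0 * noise)
        above = np.nonzero(smooth > cut)[0]
        stop = int(above[0]) if len(above) else n
    if stop is None or stop < min_points:
        stop = max(int(np.ceil(fallback_fraction * n)), min_points)
    tw, yw = t[:stop], y[:stop]
    if len(tw) < min_points:
        raise ValueError("initial window shorter than 5 samples")
    if np.allclose(yw, yw[0]):
        return 0.0
    return float(stats.linregress(tw, yw).slope)


class HillRegressor(RegressorMixin, BaseEstimator):
    """Allosteric sigmoidal (Hill) velocity model, sklearn-style.

    Fits v(S) = Vmax·S^h / (Khalf^h + S^h) to (substrate mol%, initial
    velocity) data by nonlinear least squares with multi-start
    initialization over the Hill coefficient.

    Parameters
    ----------
    h_starts : Hill-coefficient starting values tried in turn.
    h_bounds : bounds on the fitted Hill coefficient.
    n_bootstrap : residual-bootstrap replicates for CIs (0 disables).
    random_state : seed for the bootstrap.

    Attributes (after fit)
    ----------------------
    vmax_, khalf_, hill_ : fitted parameters (Khalf is the apparent Km).
    rss_ : residual sum of squares; converged_ : success flag;
    se_ : asymptotic standard errors; ci_ : bootstrap CIs or None.
    """

    def __init__(self, h_starts=(0.5, 1.0, 2.0, 4.0), h_bounds=(0.2, 10.0),
                 n_bootstrap=0, ci_level=0.95, random_state=None):
        self.h_starts = h_starts
        self.h_bounds = h_bounds
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.random_state = random_state

    @staticmethod
    def _model(S, vmax, khalf, h):
        return vmax * S ** h / (khalf ** h + S ** h)

    def _fit_once(self, S, v, p0, bounds):
        try:
            popt, pcov = optimize.curve_fit(
                self._model, S, v, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            return None
        rss = float(np.sum((v - self._model(S, *popt)) ** 2))
        return popt, pcov, rss

    def _fit_core(self, S, v):
        vmax0 = float(np.max(v))
        if vmax0 <= 0:
            raise ValueError("velocities must contain positive values")
        half = vmax0 / 2.0
        order = np.argsort(S)
        khalf0 = float(np.interp(half, np.maximum.accumulate(v[order]), S[order]))
        khalf0 = min(max(khalf0, S.min() / 2), S.max() * 2)
        eps = 1e-12
        bounds = ([eps, eps, self.h_bounds[0]],
                  [np.inf, np.inf, self.h_bounds[1]])
        best = None
        for h0 in self.h_starts:
            res = self._fit_once(S, v, [vmax0, khalf0, h0], bounds)
            if res is not None and (best is None or res[2] < best[2]):
                best = res
        if best is None:
            raise RuntimeError(
                "allosteric sigmoidal fit failed from all starts "
                f"(h starts {self.h_starts}, Vmax0={vmax0:.3g}, Khalf0={khalf0:.3g})"
            )
        return best

    def fit(self, X, y):
        S = np.asarray(X, dtype=float).reshape(-1)
        v = np.asarray(y, dtype=float).reshape(-1)
        if len(S) != len(v):
            raise ValueError("X and y lengths differ")
        if len(np.unique(S)) < 4:
            raise ValueError("need at least 4 distinct substrate levels")
        popt, pcov, rss = self._fit_core(S, v)
        self.vmax_, self.khalf_, self.hill_ = map(float, popt)
        self.rss_ = rss
        self.converged_ = True
        with np.errstate(invalid="ignore"):
            self.se_ = tuple(np.sqrt(np.diag(pcov)))
        self.ci_ = None
        if self.n_bootstrap:
            self.ci_ = self._bootstrap_ci(S, v, popt)
        self.n_features_in_ = 1
        return self

    def _bootstrap_ci(self, S, v, popt):
        rng = np.random.default_rng(self.random_state)
        fitted = self._model(S, *popt)
        resid = v - fitted
        draws = []
        for _ in range(self.n_bootstrap):
            vb = fitted + rng.choice(resid, size=len(resid), replace=True)
            try:
                pb, _, _ = self._fit_core(S, vb)
            except RuntimeError:
                continue
            draws.append(pb)
        if not draws:
            return None
        draws = np.asarray(draws)
        alpha = (1.0 - self.ci_level) / 2.0
        lo = np.quantile(draws, alpha, axis=0)
        hi = np.quantile(draws, 1 - alpha, axis=0)
        names = ("vmax", "khalf", "hill")
        return {n: (float(l), float(u)) for n, l, u in zip(names, lo, hi)}

    def predict(self, X):
        check_is_fitted(self, "vmax_")
        S = np.asarray(X, dtype=float).reshape(-1)
        return self._model(S, self.vmax_, self.khalf_, self.hill_)


def fit_allosteric_sigmoidal(points, n_bootstrap: int = 0, seed=None) -> KineticFit:
    """Fit the allosteric sigmoidal model to (S mol%, Vi) pairs."""
    pts = np.asarray(points, dtype=float)
    est = HillRegressor(n_bootstrap=n_bootstrap, random_state=seed)
    est.fit(pts[:, 0], pts[:, 1])
    return KineticFit(
        vmax=est.vmax_, khalf=est.khalf_, hill=est.hill_, rss=est.rss_,
        converged=est.converged_, se=est.se_, ci=est.ci_,
    )


def endpoint_subtract(signal: float, blank: float, calibration: CalibrationLine | None = None):
    """Blank-subtract an endpoint reading; optionally convert via a standard line.

    Used for luminescence (ADP-based) and absorbance (malachite green)
    endpoint assays; with a calibration line the corrected absorbance is
    converted to analyte concentration by inverting the line.
    """
    if not (np.isfinite(signal) and np.isfinite(blank)):
        raise ValueError("signal and blank must be finite")
    corrected = float(signal - blank)
    if calibration is None:
        return corrected
    return float(calibration.signal_to_mol_percent(corrected))


def analyze_assay_run(run, n_bootstrap: int = 0, seed=None):
    """Full pipeline on a generated or loaded assay run.

    Corrects every curve against the matched background, estimates initial
    velocities, and fits the allosteric sigmoidal model. Returns
    (KineticFit, list of (S, Vi)).
    """
    points = []
    for S, curve in run.curves:
        corrected = correct_progress_curve(curve, run.background)
        points.append((S, initial_velocity(corrected)))
    fit = fit_allosteric_sigmoidal(points, n_bootstrap=n_bootstrap, seed=seed)
    return fit, points
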