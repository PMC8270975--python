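"""Onset-latency estimation by 4-parameter sigmoid fitting.

Averaged z-score traces are fit by least squares with the sigmoid

    s(x) = A + B / (1 + exp(-(-x - C) * D))
         = A + B / (1 + exp((x + C) * D))

(A: baseline asymptote, B: span, C: shift, D: slope parameter).  The
parameterization is degenerate under (A, B, C, D) -> (A + B, -B, C, -D);
fits are canonicalized to B >= 0, under which a response rising in time
has D < 0.  Onset times are the times at which the fit crosses 10/25/50%
of its peak above baseline, solved in closed form from the sigmoid
inverse, and the rising slope is the D parameter itself.

Onset-from-fit is preferred over raw threshold crossings (e.g. time to 2
baseline SDs) because the latter are sensitive to the per-segment noise
level, while percent-of-fit-peak latencies are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .trials import MeanTrace

__all__ = [
    "sigmoid",
    "SigmoidOnsetModel",
    "SigmoidOnsetResults",
    "OnsetResult",
    "fit_sigmoid",
    "onset_times",
    "rising_slope",
    "UnidentifiableFitError",
]


class UnidentifiableFitError(ValueError):
    """Raised when a requested quantity is undefined for a degenerate fit."""


def sigmoid(x: np.ndarray, A: float, B: float, C: float, D: float) -> np.ndarray:
    """The 4-parameter sigmoid A + B/(1 + exp(-(-x - C) * D))."""
    x = np.asarray(x, dtype=float)
    u = np.clip((x + C) * D, -700.0, 700.0)
    return A + B / (1.0 + np.exp(u))


@dataclass
class OnsetResult:
    """Onset latencies derived from a sigmoid fit.

    Times are relative to stimulus onset when the model was given one,
    otherwise in trace time.  ``peak`` is the fit's upper asymptote above
    the baseline level; ``slope`` is the D parameter.
    """

    t10: float
    t25: float
    t50: float
    peak: float
    slope: float
    baseline_level: float
    flags: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return "non_rising" not in self.flags


class SigmoidOnsetModel:
    """Least-squares sigmoid model of a mean z-score trace.

    Parameters
    ----------
    time, z : arrays
        The averaged trace.  A ``MeanTrace`` may be passed positionally
        through :meth:`from_mean_trace`.
    fit_window : (float, float), optional
        Half-open window in trace time; defaults to the full trace.
    stim_onset : float, optional
        When given, onset times are reported relative to it.
    """

    #: multi-start grid for |D| (1/s)
    D_GRID = (0.5, 1.0, 2.0, 5.0)
    N_C_STARTS = 5

    def __init__(self, time, z, fit_window=None, stim_onset: float | None = None):
        time = np.asarray(time, dtype=float)
        z = np.asarray(z, dtype=float)
        good = np.isfinite(z)
        time, z = time[good], z[good]
        if fit_window is not None:
            lo, hi = fit_window
            m = (time >= lo - 1e-12) & (time <= hi + 1e-12)
            time, z = time[m], z[m]
        else:
            fit_window = (float(time[0]), float(time[-1])) if time.size else (0.0, 0.0)
        if time.size < 8:
            raise ValueError("fit window must contain at least 8 samples")
        self.time = time
        self.z = z
        self.fit_window = (float(fit_window[0]), float(fit_window[1]))
        self.stim_onset = stim_onset

    @classmethod
    def from_mean_trace(cls, trace: MeanTrace, fit_window=None, pad_s: float = 5.0):
        if fit_window is None:
            fit_window = (
                trace.baseline_window[0],
                trace.stim_onset + trace.stim_duration + pad_s,
            )
        return cls(trace.time, trace.z, fit_window=fit_window,
                   stim_onset=trace.stim_onset)

    def _starts(self) -> list[np.ndarray]:
        x, y = self.time, self.z
        a0 = float(np.mean(y[: max(2, y.size // 4)]))
        b0 = float(np.ptp(y)) or 1.0
        mids = np.quantile(x, np.linspace(0.2, 0.85, self.N_C_STARTS))
        starts = []
        for m in mids:
            for d in self.D_GRID:
                # D < 0 with B > 0 is a rising curve; D > 0 a falling one
                starts.append(np.array([a0, b0, -m, -d]))
                starts.append(np.array([a0, b0, -m, d]))
        return starts

    def fit(self) -> "SigmoidOnsetResults":
        """Multi-start least-squares fit; returns the minimum-RSS result."""
        x, y = self.time, self.z

        def resid(p):
            return sigmoid(x, *p) - y

        best = None
        best_rss = np.inf
        for p0 in self._starts():
            try:
                sol = least_squares(resid, p0, method="lm", max_nfev=2000)
            except Exception:
                continue
            rss = float(sol.fun @ sol.fun)
            if np.all(np.isfinite(sol.x)) and rss < best_rss:
                best, best_rss = sol.x, rss
        if best is None:
            raise RuntimeError(
                f"sigmoid fit failed to converge from all starts (best RSS {best_rss})"
            )
        A, B, C, D = (float(v) for v in best)
        if B < 0:  # canonicalize the (A,B,C,D) <-> (A+B,-B,C,-D) degeneracy
            A, B, D = A + B, -B, -D
        return SigmoidOnsetResults(
            model=self, A=A, B=B, C=C, D=D, rss=best_rss
        )


@dataclass
class SigmoidOnsetResults:
    """A canonicalized (B >= 0) sigmoid fit and its derived onset latencies."""

    model: SigmoidOnsetModel
    A: float
    B: float
    C: float
    D: float
    rss: float

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.A, self.B, self.C, self.D)

    @property
    def fit_window(self) -> tuple[float, float]:
        return self.model.fit_window

    @property
    def rising(self) -> bool:
        """True when the canonical fit increases with time (D < 0, B > 0)."""
        return self.B > 0 and self.D < 0

    @property
    def identifiable(self) -> bool:
        """False for near-flat fits where span (and hence D) is undetermined."""
        scale = float(np.std(self.model.z))
        return abs(self.B) > 1e-8 + 1e-3 * scale

    def predict(self, t) -> np.ndarray:
        return sigmoid(np.asarray(t, dtype=float), self.A, self.B, self.C, self.D)

    def onset_times(
        self,
        levels: Sequence[float] = (10.0, 25.0, 50.0),
        baseline_level: float | None = None,
    ) -> OnsetResult:
        """Closed-form times at which the fit crosses each %-of-peak level.

        ``baseline_level`` defaults to the fitted lower asymptote (A for a
        rising canonical fit); the empirical baseline mean may be passed
        instead.  Peak is the upper asymptote minus the baseline level.
        Times are relative to stimulus onset when the model has one.
        """
        flags: list[str] = []
        if not self.rising or not self.identifiable:
            flags.append("non_rising")
            nan = float("nan")
            return OnsetResult(nan, nan, nan, nan, self.D,
                               baseline_level if baseline_level is not None else self.A,
                               tuple(flags))
        lower, upper = self.A, self.A + self.B
        L = lower if baseline_level is None else float(baseline_level)
        peak = upper - L
        if peak <= 0:
            flags.append("non_rising")
            nan = float("nan")
            return OnsetResult(nan, nan, nan, nan, self.D, L, tuple(flags))
        shift = self.model.stim_onset or 0.0
        times = {}
        for lev in levels:
            target = L + (lev / 100.0) * peak
            # solve A + B/(1+e^{(t+C)D}) = target  =>  e^{(t+C)D} = B/(target-A) - 1
            g = self.B / (target - self.A) - 1.0
            if g <= 0:
                times[lev] = float("nan")
                flags.append(f"level_{lev:g}_unreachable")
            else:
                times[lev] = np.log(g) / self.D - self.C - shift
        return OnsetResult(
            t10=times.get(10.0, float("nan")),
            t25=times.get(25.0, float("nan")),
            t50=times.get(50.0, float("nan")),
            peak=peak,
            slope=self.D,
            baseline_level=L,
            flags=tuple(flags),
        )

    def rising_slope(self) -> float:
        """The D parameter (1/s).  Under the canonical B > 0 convention a
        rising response has D < 0; steeper responses have larger |D|."""
        if not self.identifiable:
            raise UnidentifiableFitError(
                "fit span is ~0; slope parameter D is unidentifiable"
            )
        return self.D

    def summary(self) -> str:
        onset = self.onset_times()
        lines = [
            "Sigmoid onset fit  s(x) = A + B/(1 + exp(-(-x - C) * D))",
            "--------------------------------------------------------",
            f"A (baseline, z) : {self.A:10.4f}",
            f"B (span, z)     : {self.B:10.4f}",
            f"C (shift, s)    : {self.C:10.4f}",
            f"D (slope, 1/s)  : {self.D:10.4f}   (rising responses: D < 0)",
            f"RSS             : {self.rss:10.4g}",
            f"fit window (s)  : [{self.fit_window[0]:.2f}, {self.fit_window[1]:.2f})",
            f"t10 / t25 / t50 : {onset.t10:8.3f} / {onset.t25:8.3f} / {onset.t50:8.3f} s",
            f"peak (z)        : {onset.peak:10.4f}",
        ]
        if onset.flags:
            lines.append(f"flags           : {', '.join(onset.flags)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_sigmoid(trace, fit_window=None) -> SigmoidOnsetResults:
    """Fit the 4-parameter sigmoid to a mean trace (or (time, z) pair)."""
    if isinstance(trace, MeanTrace):
        return SigmoidOnsetModel.from_mean_trace(trace, fit_window=fit_window).fit()
    time, z = trace
    return SigmoidOnsetModel(time, z, fit_window=fit_window).fit()


def onset_times(fit: SigmoidOnsetResults, baseline_level: float | None = None,
                levels=(10.0, 25.0, 50.0)) -> OnsetResult:
    return fit.onset_times(levels=levels, baseline_level=baseline_level)


def rising_slope(fit: SigmoidOnsetResults) -> float:
    return fit.rising_slope()
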