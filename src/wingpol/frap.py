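"""FRAP trace preprocessing, constrained exponential-association fitting and
nested-model comparison.

The acquisition protocol is the study's: 3 pre-bleach frames at 2 frames/s,
a 1 s bleach, then 5 frames at 5 s, 10 at 10 s and 26 at 15 s intervals
(41 post-bleach frames, the last 510 s after the first).  Preprocessing
subtracts laser-off background, corrects for acquisition bleaching with an
unbleached reference trace (double normalization) and scales so the mean of
the corrected pre-bleach values is exactly 1.

Recovery is modeled as exponential association,

    I(t) = Y0 + Σ_i A_i · (1 − exp(−k_i · t)),   i = 1 .. order,

with Y0 the post-bleach floor, amplitudes A_i ≥ 0 and rates k_i > 0
(k1 > k2 for the two-phase model).  One- vs two-phase preference and
genotype contrasts use the extra-sum-of-squares F test

    F = ((SS1 − SS2)/(p2 − p1)) / (SS2/(n − p2)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .errors import FitError, ProtocolError, SpecError
from .stats import TestResult

__all__ = [
    "FrapProtocol",
    "FrapTrace",
    "FrapFit",
    "preprocess_trace",
    "fit_recovery",
    "compare_nested_fits",
    "compare_genotypes",
    "recovery_model",
]

#: default multi-start rate grid bounds, s^-1
RATE_GRID_LO = 1.0 / 500.0
RATE_GRID_HI = 1.0


@dataclass(frozen=True)
class FrapProtocol:
    """Frame schedule of a FRAP acquisition."""

    n_prebleach: int = 3
    prebleach_interval_s: float = 0.5
    bleach_duration_s: float = 1.0
    post_schedule: tuple[tuple[int, float], ...] = ((5, 5.0), (10, 10.0), (26, 15.0))

    def __post_init__(self) -> None:
        if self.n_prebleach < 1 or any(n < 1 or dt <= 0 for n, dt in self.post_schedule):
            raise SpecError("invalid FRAP protocol")

    @property
    def n_post(self) -> int:
        return sum(n for n, _ in self.post_schedule)

    @property
    def n_frames(self) -> int:
        return self.n_prebleach + self.n_post

    def post_times_s(self) -> np.ndarray:
        """Post-bleach frame times with t = 0 at the first post-bleach frame.

        The first scheduled frame *is* the t = 0 frame, so the opening
        segment contributes n − 1 intervals; later segments contribute n
        each (their first frame sits one interval after the previous one).
        """
        times = [0.0]
        first = True
        for n, dt in self.post_schedule:
            for _ in range(n - 1 if first else n):
                times.append(times[-1] + dt)
            first = False
        return np.array(times)


@dataclass
class FrapTrace:
    """Preprocessed FRAP trace: normalized post-bleach recovery values."""

    times_s: np.ndarray
    normalized_intensity: np.ndarray
    prebleach_values: np.ndarray
    excluded: np.ndarray = field(default=None)  # boolean mask over post frames

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.normalized_intensity = np.asarray(self.normalized_intensity, dtype=np.float64)
        self.prebleach_values = np.asarray(self.prebleach_values, dtype=np.float64)
        if self.excluded is None:
            self.excluded = np.zeros(self.times_s.size, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if np.any(np.diff(self.times_s) <= 0):
            raise SpecError("times must be strictly increasing")

    def included(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.excluded
        return self.times_s[keep], self.normalized_intensity[keep]


@dataclass
class FrapFit:
    model_order: int
    y0: float
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    ss: float
    n_points: int
    n_params: int
    degenerate: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        return recovery_model(t, self.y0, self.amplitudes, self.rates)


def recovery_model(t: np.ndarray, y0: float, amplitudes, rates) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    out = np.full_like(t, y0)
    for a, k in zip(amplitudes, rates):
        out = out + a * (1.0 - np.exp(-k * t))
    return out


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_trace(
    raw: np.ndarray,
    reference: np.ndarray,
    laser_off_background: float,
    protocol: FrapProtocol = FrapProtocol(),
    excluded_frames: np.ndarray | None = None,
) -> FrapTrace:
    """Background-subtract, bleach-correct and prebleach-normalize a trace.

    ``raw`` and ``reference`` cover all frames (prebleach first).  The
    reference is an unbleached region carrying acquisition bleaching and
    background only.  Correction divides framewise by the reference's
    background-subtracted value rescaled to its own prebleach mean, then
    normalizes against the mean of the trace's own corrected prebleach
    values — which is therefore exactly 1.
    """
    raw = np.asarray(raw, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if raw.shape != ref.shape:
        raise ProtocolError("raw and reference traces differ in length")
    if raw.size != protocol.n_frames:
        raise ProtocolError(
            f"trace has {raw.size} frames, protocol expects {protocol.n_frames}")
    if laser_off_background >= raw.min():
        raise ProtocolError("laser-off background is not below the minimum raw value")
    ref_sub = ref - laser_off_background
    if np.any(ref_sub <= 0):
        raise ProtocolError("reference trace hits background level; cannot correct")
    npre = protocol.n_prebleach
    bleach_factor = ref_sub / ref_sub[:npre].mean()
    corrected = (raw - laser_off_background) / bleach_factor
    pre_mean = corrected[:npre].mean()
    if pre_mean <= 0:
        raise ProtocolError("non-positive prebleach signal after correction")
    corrected = corrected / pre_mean
    excl = (np.zeros(protocol.n_post, dtype=bool) if excluded_frames is None
            else np.asarray(excluded_frames, dtype=bool))
    return FrapTrace(
        times_s=protocol.post_times_s(),
        normalized_intensity=corrected[npre:],
        prebleach_values=corrected[:npre],
        excluded=excl,
    )


# ---------------------------------------------------------------------------
# fitting

def _fit_from_start(t, y, x0, order) -> optimize.OptimizeResult:
    lo = [0.0] + [0.0] * order + [1e-8] * order
    hi = [np.inf] * (1 + 2 * order)

    def resid(x):
        return recovery_model(t, x[0], x[1:1 + order], x[1 + order:]) - y

    return optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")


def _rate_grid(n: int = 4) -> np.ndarray:
    return np.geomspace(RATE_GRID_LO, RATE_GRID_HI, n)


def fit_recovery(trace: FrapTrace, order: int = 2,
                 seed_fit: FrapFit | None = None) -> FrapFit:
    """Constrained least-squares fit of the recovery model.

    Multi-start initialization over a geometric grid of rates spanning
    [1/500, 1] s⁻¹ guards against local minima; for order 2 the one-phase
    solution (A2 = 0) is always included as a start so the two-phase SS can
    never exceed the one-phase SS.  Rates are reported with k1 > k2; a
    near-degenerate pair (k1 ≈ k2) is flagged and refit at order 1.
    """
    if order not in (1, 2):
        raise SpecError("order must be 1 or 2")
    t, y = trace.included()
    n_params = 1 + 2 * order
    if t.size < n_params + 3:
        raise FitError(f"need >= {n_params + 3} points for order-{order} fit, got {t.size}")

    y0_guess = max(float(y[0]), 0.0)
    amp_total = max(float(y[-1]) - y0_guess, 1e-3)
    starts: list[np.ndarray] = []
    grid = _rate_grid()
    if order == 1:
        for k in grid:
            starts.append(np.array([y0_guess, amp_total, k]))
    else:
        for i, k1 in enumerate(grid):
            for k2 in grid[:i]:
                starts.append(np.array([y0_guess, amp_total / 2, amp_total / 2, k1, k2]))
        if seed_fit is not None and seed_fit.model_order == 1:
            # nested start: one-phase optimum with a null slow component
            a1, k1 = seed_fit.amplitudes[0], seed_fit.rates[0]
            starts.append(np.array([seed_fit.y0, a1, 0.0, k1, max(k1 / 10, 1e-6)]))

    best = None
    for x0 in starts:
        try:
            res = _fit_from_start(t, y, x0, order)
        except Exception:
            continue
        if res.x is None or not np.all(np.isfinite(res.x)):
            continue
        ss = float(2 * res.cost)
        if best is None or ss < best[0]:
            best = (ss, res.x)
    if best is None:
        raise FitError("recovery fit failed to converge from every start")
    ss, x = best
    y0 = float(x[0])
    amps = tuple(float(a) for a in x[1:1 + order])
    rates = tuple(float(k) for k in x[1 + order:])
    degenerate = False
    if order == 2:
        if rates[0] < rates[1]:  # enforce k1 > k2 by swapping components
            amps = (amps[1], amps[0])
            rates = (rates[1], rates[0])
        if abs(rates[0] - rates[1]) <= 1e-6 * rates[0]:
            degenerate = True
            warnings.warn("two-phase fit degenerate (k1 ≈ k2); falling back to one phase",
                          stacklevel=2)
            one = fit_recovery(trace, order=1)
            return FrapFit(1, one.y0, one.amplitudes, one.rates, one.ss,
                           one.n_points, one.n_params, degenerate=True)
    return FrapFit(order, y0, amps, rates, ss, int(t.size), n_params,
                   degenerate=degenerate)


def compare_nested_fits(fit_simple: FrapFit, fit_complex: FrapFit) -> TestResult:
    """Extra-sum-of-squares F test of nested curve fits on the same data."""
    if fit_simple.n_points != fit_complex.n_points:
        raise SpecError("nested fits must use the same data")
    p1, p2 = fit_simple.n_params, fit_complex.n_params
    if p2 <= p1:
        raise SpecError("complex model must have more parameters")
    n = fit_complex.n_points
    ss1, ss2 = fit_simple.ss, fit_complex.ss
    if ss2 > ss1 + 1e-12 * max(ss1, 1.0):
        raise SpecError("complex fit has larger SS than simple fit; fits are not nested optima")
    df = (p2 - p1, n - p2)
    if ss2 <= 0.0:
        return TestResult("extra-sum-of-squares F", float("inf"), df, 0.0,
                          n=n, flags=["perfect-complex-fit"])
    f = ((ss1 - ss2) / (p2 - p1)) / (ss2 / (n - p2))
    f = max(f, 0.0)
    p = float(sps.f.sf(f, *df))
    return TestResult("extra-sum-of-squares F", float(f), df, p, n=n)


def fit_and_select(trace: FrapTrace, alpha: float = 0.05) -> tuple[FrapFit, FrapFit, TestResult]:
    """Fit both model orders and test whether the two-phase fit is preferred."""
    one = fit_recovery(trace, order=1)
    two = fit_recovery(trace, order=2, seed_fit=one)
    if two.model_order == 1:  # degenerate fallback: no evidence for two phases
        return one, two, TestResult("extra-sum-of-squares F", 0.0,
                                    (2, one.n_points - 5), 1.0, n=one.n_points,
                                    flags=["degenerate-two-phase"])
    return one, two, compare_nested_fits(one, two)


# ---------------------------------------------------------------------------
# genotype comparison

_COMPONENT_SLOTS = {"fast": (1, 3), "slow": (2, 4), "all": None}
# parameter vector per genotype: (y0, a1, a2, k1, k2); slots give the shared indices


def _free_slots(shared_slots) -> list[int]:
    """Indices of genotype-B parameters NOT shared with genotype A.
    ``None`` means every parameter is shared (single pooled curve)."""
    if shared_slots is None:
        return []
    return [i for i in range(5) if i not in shared_slots]


def _joint_residuals(x, data_a, data_b, shared_slots):
    # x layout: genotype A params (5), then genotype B's free params
    pa = x[:5]
    pb = pa.copy()
    for j, i in enumerate(_free_slots(shared_slots)):
        pb[i] = x[5 + j]
    ta, ya = data_a
    tb, yb = data_b
    ra = recovery_model(ta, pa[0], pa[1:3], pa[3:5]) - ya
    rb = recovery_model(tb, pb[0], pb[1:3], pb[3:5]) - yb
    return np.concatenate([ra, rb])


def _pooled(traces: list[FrapTrace]) -> tuple[np.ndarray, np.ndarray]:
    ts, ys = [], []
    for tr in traces:
        t, y = tr.included()
        ts.append(t)
        ys.append(y)
    return np.concatenate(ts), np.concatenate(ys)


def _fit_shared(data_a, data_b, shared_slots, x0_a, x0_b) -> tuple[float, int]:
    """Least-squares fit with the given parameter slots shared across
    genotypes; returns (SS, n_params)."""
    free = _free_slots(shared_slots)
    x0 = np.concatenate([x0_a, [x0_b[i] for i in free]])
    lo = np.array([0.0, 0.0, 0.0, 1e-8, 1e-8])
    hi = np.array([np.inf] * 5)
    lo_full = np.concatenate([lo, lo[free]]) if free else lo
    hi_full = np.concatenate([hi, hi[free]]) if free else hi
    res = optimize.least_squares(
        _joint_residuals, np.clip(x0, lo_full, hi_full), bounds=(lo_full, hi_full),
        method="trf", args=(data_a, data_b, shared_slots))
    return float(2 * res.cost), int(x0.size)


def compare_genotypes(traces_a: list[FrapTrace], traces_b: list[FrapTrace],
                      component: str = "slow") -> TestResult:
    """Nested F test of whether a recovery component differs between genotypes.

    Pools each genotype's post-bleach points and compares a model in which
    the selected component's parameters — ``fast`` (A1, k1), ``slow``
    (A2, k2) or ``all`` (every parameter) — are shared across genotypes
    against the model in which every parameter is genotype-specific.
    """
    if component not in _COMPONENT_SLOTS:
        raise SpecError(f"component must be one of {sorted(_COMPONENT_SLOTS)}")
    data_a = _pooled(traces_a)
    data_b = _pooled(traces_b)
    xa = _best_two_phase(*data_a)
    xb = _best_two_phase(*data_b)

    # full model: independent parameters (shared set = empty -> all slots free)
    ss_full, p_full = _fit_shared(data_a, data_b, shared_slots=(), x0_a=xa, x0_b=xb)
    shared = _COMPONENT_SLOTS[component]
    ss_red, p_red = _fit_shared(data_a, data_b, shared_slots=shared, x0_a=xa, x0_b=xb)
    # reduced model is nested in full: guard against optimizer noise
    ss_red = max(ss_red, ss_full)

    n = data_a[0].size + data_b[0].size
    simple = FrapFit(2, 0, (), (), ss_red, n, p_red)
    complx = FrapFit(2, 0, (), (), min(ss_full, ss_red), n, p_full)
    res = compare_nested_fits(simple, complx)
    res.test_name = f"genotype comparison ({component} component)"
    return res


def _best_two_phase(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Multi-start two-phase fit on raw (t, y) arrays; returns the parameter
    vector (y0, a1, a2, k1, k2)."""
    y0_guess = max(float(np.min(y)), 0.0)
    amp = max(float(np.max(y)) - y0_guess, 1e-3)
    best = None
    grid = _rate_grid()
    for i, k1 in enumerate(grid):
        for k2 in grid[:i]:
            x0 = np.array([y0_guess, amp / 2, amp / 2, k1, k2])
            try:
                res = _fit_from_start(t, y, np.array([x0[0], x0[1], x0[2], x0[3], x0[4]]), 2)
            except Exception:
                continue
            ss = float(2 * res.cost)
            if best is None or ss < best[0]:
                best = (ss, res.x)
    if best is None:
        raise FitError("pooled two-phase fit failed")
    x = best[1]
    # canonical order k1 > k2
    if x[3] < x[4]:
        x = np.array([x[0], x[2], x[1], x[4], x[3]])
    return x
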