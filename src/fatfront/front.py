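"""Parametric reversed-sigmoid model of the intramuscular fat front.

Affected muscles show a fat fraction that is high at the distal end,
falls through a transition zone (the "fat front"), and levels off at a
spared proximal plateau.  We model the profile along relative muscle
length x in [0, 1] (distal -> proximal) as a reversed logistic,

    FF(x) = pi_base + (pi_top - pi_base) / (1 + exp((x - x0) / w))

with distal plateau ``pi_top``, proximal plateau ``pi_base``, front
position ``x0`` (the half-maximum point, allowed slightly outside [0, 1])
and front width ``w``.  Disease progression is emulated by advancing x0
proximally at a speed that peaks at intermediate whole-muscle fat
fractions, and by widening the front over time (the slope grows more
shallow at higher fat content).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .dixon import ValidationError
from .profiles import MuscleProfile

#: Parameter bounds: pi_top, pi_base in percent; x0, w in relative length.
DEFAULT_BOUNDS = ((0.0, 100.0), (0.0, 100.0), (-0.5, 1.5), (1e-3, 1.0))


@dataclass(frozen=True)
class FrontParams:
    """Reversed-sigmoid parameters for one muscle."""

    pi_top: float
    pi_base: float
    x0: float
    w: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_base <= self.pi_top <= 100.0):
            raise ValidationError(
                f"need 0 <= pi_base <= pi_top <= 100, got "
                f"({self.pi_base}, {self.pi_top})"
            )
        if self.w <= 0:
            raise ValidationError(f"front width must be > 0, got {self.w}")
        if not (-0.5 <= self.x0 <= 1.5):
            raise ValidationError(f"x0 must lie in [-0.5, 1.5], got {self.x0}")


@dataclass(frozen=True)
class FrontFit:
    params: FrontParams
    rmse: float
    converged: bool
    n_points: int


@dataclass(frozen=True)
class ProgressionConfig:
    """Phenomenological front-propagation law used for synthesis.

    The front speed v (relative length / year) follows a bell curve of the
    current whole-muscle fat fraction, peaking at ``mu_v`` percent — the
    fastest progression is seen in intermediately infiltrated muscles:

        v(FF) = v_max * exp(-((FF - mu_v) / s_v)^2)

    ``dw`` widens the front each year (the slope becomes more shallow as
    infiltration advances).  v_max = 0.065/yr gives, for typical plateaus
    (~80% over ~5%), a peak whole-muscle rate near 4.9 %/yr.
    """

    v_max: float = 0.065
    mu_v: float = 35.0
    s_v: float = 20.0
    dw: float = 0.02

    def speed(self, ff_whole: float) -> float:
        return self.v_max * float(np.exp(-(((ff_whole - self.mu_v) / self.s_v) ** 2)))


def eval_front(params: FrontParams, x) -> np.ndarray | float:
    """Evaluate FF(x) on relative positions x in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if x.size and (x.min() < -1e-9 or x.max() > 1 + 1e-9):
        raise ValidationError("x must lie in [0, 1]")
    z = (x - params.x0) / params.w
    val = params.pi_base + (params.pi_top - params.pi_base) * expit(-z)
    return float(val) if val.ndim == 0 else val


def mean_ff(params: FrontParams) -> float:
    """Whole-muscle mean of the model over [0, 1], in closed form.

    Integrating the logistic term gives
    int_0^1 1/(1+exp((x-x0)/w)) dx = [x - w*log(1+exp((x-x0)/w))]_0^1.
    """
    w, x0 = params.w, params.x0

    def antideriv(x: float) -> float:
        return x - w * float(np.logaddexp(0.0, (x - x0) / w))

    frac = antideriv(1.0) - antideriv(0.0)
    return params.pi_base + (params.pi_top - params.pi_base) * frac


def _residuals(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    top, base, x0, w = theta
    return base + (top - base) * expit(-(x - x0) / w) - y


def fit_front(
    profile: MuscleProfile,
    bounds=DEFAULT_BOUNDS,
    restarts: int = 10,
    seed: int = 0,
) -> FrontFit:
    """Fit the reversed sigmoid to a per-slice profile.

    Bounded nonlinear least squares with multi-start: one data-driven
    start plus ``restarts - 1`` seeded random draws within the bounds; the
    best-RMSE solution wins.  A (near-)constant profile cannot constrain
    the front and returns a plateau-only fit flagged ``converged=False``.
    """
    if profile.n_slices < 8:
        raise ValidationError(
            f"front fitting needs >= 8 slices, got {profile.n_slices}"
        )
    x = profile.relative_pos / 100.0
    y = profile.ff.astype(float)
    if np.ptp(y) < 1e-9:
        c = float(y[0])
        return FrontFit(
            params=FrontParams(pi_top=c, pi_base=c if c > 0 else 0.0, x0=0.5, w=0.1),
            rmse=0.0,
            converged=False,
            n_points=profile.n_slices,
        )
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(seed)
    # data-driven start: plateaus from the profile ends, front at the
    # steepest observed drop
    x0_guess = float(x[np.argmin(np.gradient(y, x))])
    starts = [np.array([max(y.max(), 1.0), max(y.min(), 0.0), x0_guess, 0.1])]
    for _ in range(max(restarts - 1, 0)):
        draw = lo + (hi - lo) * rng.random(4)
        if draw[0] < draw[1]:
            draw[0], draw[1] = draw[1], draw[0]
        starts.append(draw)
    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(
                _residuals, theta0, args=(x, y), bounds=(lo, hi),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer edge cases
            continue
        rmse = float(np.sqrt(np.mean(res.fun**2)))
        if best is None or rmse < best[1]:
            best = (res, rmse)
    res, rmse = best
    top, base, x0, w = res.x
    if top < base:  # degenerate flat solution; order the plateaus
        top = base = (top + base) / 2.0
        top += 1e-9
    params = FrontParams(
        pi_top=min(top, 100.0), pi_base=max(base, 0.0),
        x0=float(np.clip(x0, -0.5, 1.5)), w=max(w, 1e-3),
    )
    return FrontFit(
        params=params, rmse=rmse, converged=bool(res.success),
        n_points=profile.n_slices,
    )


def propagate_front(
    params: FrontParams, years: float, config: ProgressionConfig = ProgressionConfig()
) -> FrontParams:
    """Advance the front proximally by ``years`` of simulated progression.

    The speed is evaluated at the current whole-muscle FF (closed-form
    mean of the model), so heavily or barely infiltrated muscles move
    slowly and intermediately infiltrated ones fastest.  Widening is
    mean-neutral: after growing w the front position is re-solved so the
    whole-muscle FF is unchanged, then the v(FF)·years advance is applied
    — fat replacement never regresses, so mean FF is non-decreasing for
    v_max >= 0.
    """
    if years < 0:
        raise ValidationError("years must be >= 0")
    ff0 = mean_ff(params)
    v = config.speed(ff0)
    w = params.w + config.dw * years
    x0 = params.x0
    if config.dw != 0.0 and years > 0:
        widened = replace(params, w=w)
        x0 = _solve_x0_for_mean(widened, ff0)
    x0 = float(np.clip(x0 + v * years, -0.5, 1.5))
    out = replace(params, x0=x0, w=w)
    if mean_ff(out) < ff0 - 1e-12:
        # x0 hit its bound before the widening was compensated; keep the
        # old width so the advance alone governs the change
        out = replace(params, x0=float(np.clip(params.x0 + v * years, -0.5, 1.5)))
    return out


def _solve_x0_for_mean(params: FrontParams, target_ff: float) -> float:
    """Front position giving a target whole-muscle mean FF (w fixed).

    mean_ff is continuous and strictly increasing in x0; if the target is
    unreachable within the allowed x0 range the nearer bound is returned.
    """
    from scipy.optimize import brentq

    lo, hi = -0.5, 1.5
    if mean_ff(replace(params, x0=lo)) >= target_ff:
        return lo
    if mean_ff(replace(params, x0=hi)) <= target_ff:
        return hi
    return float(brentq(
        lambda x0: mean_ff(replace(params, x0=x0)) - target_ff, lo, hi, xtol=1e-12
    ))
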