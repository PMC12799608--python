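"""Contact-mechanics forward models and inverse fitting of AFM force curves.

Implements spherical Hertz contact with a multiplicative bottom-effect
correction (BEC) for finite sample thickness, power-law rheology (PLR)
relaxation, the Ting hereditary-integral force for an arbitrary indentation
history (approach *and* retraction), and least-squares fitting of single
force-distance curves to either model.

All quantities are SI internally (m, N, Pa, s). Convenience accessors on the
result objects report kPa / Pa.s / nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TipGeometry",
    "BECSpec",
    "PLRParameters",
    "ForceCurve",
    "IndentationTrajectory",
    "HertzResult",
    "TingFitResult",
    "ContactNotFoundError",
    "InsufficientDataError",
    "TingEvaluationError",
    "bec_factor",
    "hertz_force",
    "plr_relaxation",
    "ting_force",
    "detect_contact_point",
    "fit_hertz",
    "fit_plr",
    "apparent_modulus_linear_ramp",
]

#: Dimensionless polynomial coefficients of the bottom-effect correction for a
#: spherical indenter on a sample bonded to a rigid substrate, as a series in
#: chi = sqrt(R * delta) / h.
BEC_SPHERE_BONDED = (1.133, 1.497, 1.469, 0.755)


class ContactNotFoundError(ValueError):
    """Raised when no tip-sample contact can be located in a force curve."""


class InsufficientDataError(ValueError):
    """Raised when a curve has too few usable samples for the requested fit."""


class TingEvaluationError(RuntimeError):
    """Raised when the hereditary-integral evaluation fails numerically."""


@dataclass(frozen=True)
class TipGeometry:
    """Spherical probe geometry and cantilever calibration.

    Parameters
    ----------
    radius : float
        Tip radius R in metres. Default 70 nm, nominal for soft-cell
        paddle-shaped probes with pre-calibrated spring constants.
    spring_constant : float
        Cantilever spring constant k in N/m (default 0.1 N/m).
    poisson_ratio : float
        Poisson's ratio of the sample, assumed time-independent.
        Default 0.5 (incompressible).
    """

    radius: float = 70e-9
    spring_constant: float = 0.1
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"tip radius must be positive, got {self.radius}")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if not (0.0 <= self.poisson_ratio <= 0.5 + 1e-12):
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


@dataclass(frozen=True)
class BECSpec:
    """Bottom-effect correction for a sample of finite thickness.

    The correction multiplies the half-space contact force by
    ``1 + sum_i c_i * chi**(i+1)`` with ``chi = sqrt(R*delta)/h`` where ``h``
    is the local sample thickness. ``h = inf`` disables the correction.
    """

    thickness: float = np.inf
    coefficients: tuple[float, ...] = BEC_SPHERE_BONDED

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("sample thickness must be positive")


#: Correction disabled (semi-infinite sample).
NO_BEC = BECSpec(thickness=np.inf)


@dataclass(frozen=True)
class PLRParameters:
    """Power-law rheology parameters: springpot in parallel with a dashpot.

    Relaxation modulus ``E(t) = E0 * t**(-alpha) + eta * diracdelta(t)``.

    ``E0`` is the relaxation modulus at t = 1 s (Pa); ``alpha`` the power-law
    exponent (0 = solid-like, 1 = fluid-like); ``eta`` the Newtonian viscous
    term (Pa.s) entering as a Dirac contribution.
    """

    E0: float
    alpha: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


@dataclass
class ForceCurve:
    """A single force-distance curve (approach + retraction).

    ``z`` is the piezo coordinate increasing towards the sample; ``force``
    the cantilever force. Metadata record the acquisition: piezo speed,
    trigger force and vertical ramp size.
    """

    time: np.ndarray
    z: np.ndarray
    force: np.ndarray
    speed: float = 183e-6
    trigger_force: float = 1e-9
    ramp_size: float = 3e-6

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if not (self.z.size == n == self.force.size):
            raise ValueError("time, z and force must have equal length")
        if n < 16:
            raise ValueError(f"force curve needs >= 16 samples, got {n}")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if min(self.speed, self.trigger_force, self.ramp_size) <= 0:
            raise ValueError("acquisition metadata must be positive")

    @property
    def turnaround_index(self) -> int:
        """Index of the approach/retract turning point (max piezo extension)."""
        return int(np.argmax(self.z))


@dataclass
class IndentationTrajectory:
    """Indentation history ``delta(t)`` with t = 0 at contact.

    ``t_approach`` (the approach duration ``tm``) marks the turnaround; for a
    monotone ramp the indentation is maximal there.
    """

    time: np.ndarray
    indentation: np.ndarray
    t_approach: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.indentation = np.asarray(self.indentation, dtype=float)
        if self.time.size != self.indentation.size:
            raise ValueError("time and indentation must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.indentation < -1e-12):
            raise ValueError("indentation must be non-negative")
        if not 0 < self.t_approach <= self.time[-1] + 1e-15:
            raise ValueError("t_approach must lie inside the time window")


@dataclass
class HertzResult:
    """Apparent Young's modulus from a Hertz fit of the approach segment."""

    modulus: float            # Pa
    contact_point: float      # piezo z of contact, m
    contact_index: int
    residual_norm: float      # N
    n_points: int

    @property
    def modulus_kpa(self) -> float:
        return self.modulus * 1e-3


@dataclass
class TingFitResult:
    """Viscoelastic PLR parameters from a Ting-model fit of a full curve."""

    params: PLRParameters
    contact_point: float
    contact_index: int
    residual_norm: float
    converged: bool
    hertz: HertzResult | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def bec_factor(delta, spec: BECSpec, geom: TipGeometry):
    """Bottom-effect correction factor ``f_BEC(delta) >= 1``.

    Evaluates ``1 + sum_i c_i chi**(i+1)`` with ``chi = sqrt(R*delta)/h``.
    Returns a scalar for scalar input, an array otherwise.
    """
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation must be non-negative")
    if not np.isfinite(spec.thickness):
        out = np.ones_like(d)
        return float(out) if np.isscalar(delta) else out
    chi = np.sqrt(geom.radius * d) / spec.thickness
    out = np.ones_like(chi)
    p = np.ones_like(chi)
    for c in spec.coefficients:
        p = p * chi
        out = out + c * p
    return float(out) if np.isscalar(delta) else out


def hertz_force(delta, modulus: float, geom: TipGeometry, spec: BECSpec = NO_BEC):
    """Hertz contact force of a sphere, with bottom-effect correction.

    ``F = (4/3) * E/(1-nu^2) * sqrt(R) * delta^(3/2) * f_BEC(delta)``.
    """
    if modulus <= 0:
        raise ValueError("modulus must be positive")
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation must be non-negative")
    pref = 4.0 / 3.0 * modulus / (1.0 - geom.poisson_ratio**2) * np.sqrt(geom.radius)
    out = pref * d**1.5 * bec_factor(d, spec, geom)
    return float(out) if np.isscalar(delta) else out


def plr_relaxation(t, params: PLRParameters):
    """Power-law relaxation modulus ``E(t) = E0 * t**(-alpha)`` in Pa.

    The Newtonian (Dirac) term is *not* included here; it acts as an
    instantaneous-rate contribution inside :func:`ting_force`.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt <= 0):
        raise ValueError("t must be positive")
    out = params.E0 * tt ** (-params.alpha)
    return float(out) if np.isscalar(t) else out


def _powerlaw_weighted_integral(tq: float, xi: np.ndarray, w: np.ndarray,
                                alpha: float, lower: float, upper: float) -> float:
    """``int_lower^upper (tq - s)**(-alpha) * w(s) ds`` for interval weights.

    Product-integration rule: ``w[j]`` is the (constant) value of the
    integrand weight on ``[xi[j], xi[j+1]]`` — in practice the secant slope
    of a piecewise-linear primitive — and the singular kernel is integrated
    analytically over each sub-interval. Exact for alpha = 0 (telescopes to
    the primitive); handles the integrable singularity at s = tq (alpha < 1)
    without special-casing.
    """
    lower = max(lower, float(xi[0]))
    upper = min(upper, tq, float(xi[-1]))
    if upper <= lower:
        return 0.0
    a = np.clip(xi[:-1], lower, upper)
    b = np.clip(xi[1:], lower, upper)
    ua = np.maximum(tq - a, 0.0)
    ub = np.maximum(tq - b, 0.0)
    om = 1.0 - alpha
    return float(np.sum(w * (ua**om - ub**om)) / om)


def ting_force(traj: IndentationTrajectory, params: PLRParameters,
               geom: TipGeometry, spec: BECSpec = NO_BEC,
               return_t1: bool = False):
    """Force history of a viscoelastic (PLR) sample under spherical indentation.

    Evaluates the hereditary integral

    ``F(t) = 4 sqrt(R) / (3 (1 - nu^2)) *
    int_0^t1(t) f_BEC(delta) E(t - s) d(delta^(3/2))/ds ds``

    with ``E(t) = E0 t**-alpha``; the Newtonian dashpot enters as the
    instantaneous term ``f_BEC * eta * d(delta^(3/2))/dt`` during approach.
    On approach (t <= tm) the upper limit is t itself; during retraction the
    auxiliary time ``t1(t)`` solves

    ``int_t1^t E(t - s) d(delta)/ds ds = 0``

    (found by bisection on [0, tm] to a tolerance of 1e-6 * tm). The force is
    zero before contact and after full detachment (t1 -> 0).
    """
    t = traj.time
    d = np.maximum(traj.indentation, 0.0)
    tm = traj.t_approach
    nu = geom.poisson_ratio
    pref = 4.0 * np.sqrt(geom.radius) / (3.0 * (1.0 - nu**2))

    # derivatives taken one-sided per segment so the approach/retract kink at
    # tm does not contaminate the weights next to the kernel singularity
    it = int(np.searchsorted(t, tm, side="left"))
    it = min(max(it, 1), t.size - 1)
    g = d**1.5
    fb = bec_factor(d, spec, geom)

    def _interval_slopes(y: np.ndarray, seg: slice) -> np.ndarray:
        return np.diff(y[seg]) / np.diff(t[seg])

    app, ret = slice(0, it + 1), slice(it, None)
    fb_mid_app = 0.5 * (fb[:it] + fb[1 : it + 1])
    fb_mid_ret = 0.5 * (fb[it:-1] + fb[it + 1 :])
    wf_app = fb_mid_app * _interval_slopes(g, app)
    wf_ret = fb_mid_ret * _interval_slopes(g, ret)
    dp_app = _interval_slopes(d, app)
    dp_ret = _interval_slopes(d, ret)
    # pointwise rates for the instantaneous (dashpot) term
    gp_node = np.gradient(g[app], t[app])
    dp_node_ret = (np.gradient(d[ret], t[ret])
                   if t.size - it >= 2 else np.zeros(t.size - it))
    t_app, t_ret = t[app], t[ret]

    E0, alpha, eta = params.E0, params.alpha, params.eta

    def force_integral(tq: float, upper: float) -> float:
        val = _powerlaw_weighted_integral(tq, t_app, wf_app, alpha, 0.0,
                                          min(upper, tm))
        if upper > tm:
            val += _powerlaw_weighted_integral(tq, t_ret, wf_ret, alpha, tm, upper)
        return val

    om = 1.0 - alpha
    F = np.zeros_like(t)
    t1_out = np.where(t <= tm, np.minimum(t, tm), 0.0)
    tol = 1e-6 * tm
    detached = False
    t1_prev = tm

    for i, ti in enumerate(t):
        if ti <= 0 or (d[i] <= 0 and ti <= tm):
            continue
        if ti <= tm + 1e-15:
            F[i] = pref * (E0 * force_integral(ti, ti) + fb[i] * eta * gp_node[i])
            continue
        if detached:
            continue

        # t1 condition phi(s) = E0 * int_s^ti E-kernel * d'(xi) dxi + eta*d'(ti)
        # split at tm; suffix sums over approach intervals make each bisection
        # step O(1) after an O(n) setup per output time
        u_app = (ti - t_app) ** om
        contrib = dp_app * (u_app[:-1] - u_app[1:]) / om
        suffix = np.concatenate((np.cumsum(contrib[::-1])[::-1], [0.0]))
        tail = (
            _powerlaw_weighted_integral(ti, t_ret, dp_ret, alpha, tm, ti)
            + eta * dp_node_ret[i - it] / E0
        )
        if not np.isfinite(tail):
            raise TingEvaluationError(f"t1 bracketing failed at time index {i}")

        def condition(s: float) -> float:
            j = min(int(np.searchsorted(t_app, s, side="right")) - 1,
                    t_app.size - 2)
            part = suffix[j + 1] + dp_app[j] * ((ti - s) ** om - u_app[j + 1]) / om
            return part + tail

        hi = min(t1_prev, tm)
        if condition(0.0) <= 0.0:
            detached = True
            continue
        if condition(hi) >= 0.0:
            t1 = hi
        else:
            lo = 0.0
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if condition(mid) > 0.0:
                    lo = mid
                else:
                    hi = mid
            t1 = 0.5 * (lo + hi)
        t1_prev = t1
        t1_out[i] = t1
        F[i] = pref * E0 * force_integral(ti, t1)
    if return_t1:
        return F, t1_out
    return F


def apparent_modulus_linear_ramp(params: PLRParameters, ramp_time: float,
                                 include_eta: bool = True) -> float:
    """Closed-form apparent (Hertzian) modulus of a PLR sample.

    For a constant-rate indentation lasting ``ramp_time`` seconds the
    hereditary integral evaluates to a Hertz-like force with an effective
    modulus ``E_app = 1.5 * [E0 * B(3/2, 1-alpha) * t**-alpha + eta / t]``
    (Beta function B). Used as the rate-dependent ground truth for apparent
    stiffness in synthetic scenes.
    """
    from scipy.special import beta as beta_fn

    if ramp_time <= 0:
        raise ValueError("ramp_time must be positive")
    e = 1.5 * params.E0 * beta_fn(1.5, 1.0 - params.alpha) * ramp_time ** (-params.alpha)
    if include_eta:
        e += 1.5 * params.eta / ramp_time
    return float(e)


# ---------------------------------------------------------------------------
# inverse problem
# ---------------------------------------------------------------------------

def detect_contact_point(curve: ForceCurve, geom: TipGeometry | None = None,
                         min_baseline: int = 5) -> tuple[int, float]:
    """Locate the tip-sample contact on the approach segment.

    Scans candidate contact indices and scores each by the residual of a
    two-segment model: flat baseline before contact, Hertzian 3/2-power rise
    after. Returns ``(index, z_contact)`` of the best candidate.

    Raises
    ------
    ContactNotFoundError
        If the curve never rises meaningfully above its baseline noise.
    """
    turn = curve.turnaround_index
    z = curve.z[: turn + 1]
    f = curve.force[: turn + 1]
    n = z.size
    if n < min_baseline + 8:
        raise InsufficientDataError("approach segment too short")

    base0 = np.median(f[:min_baseline])
    noise = max(np.std(f[:min_baseline]), 1e-15)
    if np.max(f - base0) < 5 * noise and np.max(np.abs(f - base0)) < 1e-13:
        raise ContactNotFoundError("no contact found: force never leaves baseline")

    best = (np.inf, None)
    for i in range(min_baseline, n - 4):
        b = np.mean(f[:i])
        w = np.clip(z[i:] - z[i], 0.0, None) ** 1.5
        denom = float(w @ w)
        if denom == 0:
            continue
        a = float(w @ (f[i:] - b)) / denom
        if a < 0:
            a = 0.0
        r = float(np.sum((f[:i] - b) ** 2) + np.sum((f[i:] - b - a * w) ** 2))
        if r < best[0]:
            best = (r, i)
    if best[1] is None:
        raise ContactNotFoundError("no contact found")
    idx = best[1]
    return idx, float(z[idx])


def _approach_indentation(curve: ForceCurve, geom: TipGeometry, idx: int,
                          baseline: float) -> tuple[np.ndarray, np.ndarray]:
    """Post-contact approach indentation and baseline-corrected force."""
    turn = curve.turnaround_index
    zc = curve.z[idx]
    f = curve.force[idx : turn + 1] - baseline
    delta = (curve.z[idx : turn + 1] - zc) - f / geom.spring_constant
    return np.clip(delta, 0.0, None), f


def fit_hertz(curve: ForceCurve, geom: TipGeometry, spec: BECSpec = NO_BEC,
              contact: tuple[int, float] | None = None) -> HertzResult:
    """Fit the apparent Young's modulus to the approach segment.

    The contact point is detected (or supplied), the pre-contact baseline is
    subtracted, indentation is computed as piezo travel minus cantilever
    deflection, and the amplitude of the BEC-corrected 3/2-power law is
    solved in closed form (linear least squares).
    """
    if contact is None:
        idx, zc = detect_contact_point(curve, geom)
    else:
        idx, zc = contact
    baseline = float(np.mean(curve.force[:idx])) if idx > 0 else 0.0
    delta, f = _approach_indentation(curve, geom, idx, baseline)
    if delta.size < 8 or np.max(delta) <= 0:
        raise InsufficientDataError(
            f"only {delta.size} post-contact samples; need >= 8 with indentation"
        )
    basis = delta**1.5 * bec_factor(delta, spec, geom)
    denom = float(basis @ basis)
    if denom <= 0:
        raise InsufficientDataError("curve never indents")
    amp = float(basis @ f) / denom
    nu = geom.poisson_ratio
    modulus = amp * 3.0 * (1.0 - nu**2) / (4.0 * np.sqrt(geom.radius))
    if modulus <= 0:
        raise InsufficientDataError("non-positive modulus: no repulsive contact")
    resid = float(np.linalg.norm(f - amp * basis))
    return HertzResult(modulus=modulus, contact_point=zc, contact_index=idx,
                       residual_norm=resid, n_points=int(delta.size))


def fit_plr(curve: ForceCurve, geom: TipGeometry, spec: BECSpec = NO_BEC,
            contact: tuple[int, float] | None = None,
            x0: PLRParameters | None = None,
            max_nfev: int = 200) -> TingFitResult:
    """Fit power-law-rheology parameters with the Ting model.

    Nonlinear least squares of :func:`ting_force` against the measured force
    over approach + retraction. Initialised from the Hertz fit
    (``E0 <- E_hertz``, ``alpha <- 0.2``, ``eta <- 1 Pa.s``) with bounds
    ``E0 > 0``, ``alpha in [0, 0.99]``, ``eta >= 0``. The contact point is
    refined as a fourth free parameter around the detected position, which
    removes the bias a Hertz-shaped detector incurs on viscoelastic rises.
    Non-convergence is reported through the ``converged`` flag, not an
    exception.
    """
    if contact is None:
        idx, zc0 = detect_contact_point(curve, geom)
    else:
        idx, zc0 = contact
    turn = curve.turnaround_index
    if turn <= idx + 4 or curve.time.size - turn < 4:
        raise InsufficientDataError("approach and retraction must both be present")
    baseline = float(np.mean(curve.force[:idx])) if idx > 0 else 0.0
    hz = fit_hertz(curve, geom, spec, contact=(idx, zc0))

    # fixed fitting window opening well before the detected contact; the
    # Ting integral is invariant to leading zero-indentation samples, so the
    # contact position can move freely inside the window
    win = max(idx - 12, 1)
    t_w = curve.time[win:] - curve.time[win]
    z_w = curve.z[win:]
    f_w = curve.force[win:] - baseline
    tm = float(t_w[turn - win])
    k = geom.spring_constant
    scale_f = max(float(np.max(np.abs(f_w))), 1e-12)
    zspan = 0.5 * float(np.ptp(curve.z))

    def residuals(p: np.ndarray) -> np.ndarray:
        delta = np.clip((z_w - p[3]) - f_w / k, 0.0, None)
        traj = IndentationTrajectory(time=t_w, indentation=delta, t_approach=tm)
        model = ting_force(traj, PLRParameters(max(p[0], 1e-3), p[1], p[2]),
                           geom, spec)
        return (model - f_w) / scale_f

    p0 = np.array([hz.modulus if x0 is None else x0.E0,
                   0.2 if x0 is None else x0.alpha,
                   1.0 if x0 is None else x0.eta,
                   zc0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(
            residuals, p0,
            bounds=([1e-3, 0.0, 0.0, zc0 - zspan],
                    [np.inf, 0.99, np.inf, zc0 + zspan]),
            x_scale=[max(hz.modulus, 1.0), 0.1, 1.0, 50e-9],
            diff_step=1e-3,
            ftol=1e-12, xtol=1e-14, gtol=1e-14, max_nfev=max_nfev,
        )
    params = PLRParameters(float(sol.x[0]), float(sol.x[1]), float(sol.x[2]))
    return TingFitResult(
        params=params, contact_point=float(sol.x[3]), contact_index=idx,
        residual_norm=float(np.linalg.norm(sol.fun * scale_f)),
        converged=bool(sol.status > 0), hertz=hz,
    )
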