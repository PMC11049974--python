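"""Three-pool label-incorporation model and flux estimation.

The MEP pathway between newly fixed carbon and isoprene is modelled as a
linear cascade of three first-order pools — DXP (size ``A``), MEcDP (``B``)
and IDP+DMADP (``C``), all in pmol per mg dry weight — traversed by a single
steady-state flux ``J`` (pmol min^-1 mg^-1 DW).  When the feeding atmosphere
switches to 13CO2 at t=0, the fractional labeling of the terminal pool rises
toward a plateau ``m`` (the maximal fractional labeling, <1 because not all
Calvin-cycle carbon is labeled) following the closed form

    f(t) = m * [1 - A^2/((A-B)(A-C)) e^{-Jt/A}
                  - B^2/((B-A)(B-C)) e^{-Jt/B}
                  - C^2/((C-A)(C-B)) e^{-Jt/C}]

which is the analytic solution of the cascade ODEs

    da/dt = (J/A)(m - a),  db/dt = (J/B)(a - b),  dc/dt = (J/C)(b - c)

with a=b=c=0 at t=0, evaluated at the terminal pool c(t).  Pool sizes are
measured independently and entered as fixed parameters; only ``m`` and ``J``
are estimated from an observed labeling time course, by Levenberg-Marquardt
least squares.

The closed form degenerates when two pool sizes coincide (vanishing
denominators); in that case evaluation falls back to direct numerical
integration of the cascade, which is also retained as an independent oracle
for testing the algebra.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "PoolSizes",
    "LabelCurve",
    "FluxFit",
    "label_fraction",
    "cascade_ode_oracle",
    "fit_flux",
    "read_label_curve",
    "flux_fit_row",
]

#: relative tolerance below which two pool sizes are treated as equal and the
#: closed form is abandoned for the numerical path
DEGENERACY_RTOL = 1e-6

#: tolerance for clipping slightly out-of-range fractional labeling on ingestion
LABEL_EPS = 0.05


@dataclass(frozen=True)
class PoolSizes:
    """Pool sizes of the three measurable cascade intermediates.

    Attributes
    ----------
    A, B, C : float
        DXP, MEcDP and IDP+DMADP pool sizes, pmol mg^-1 DW.  All must be
        strictly positive.
    """

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "C"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"pool size {name} must be finite and > 0, got {v}")

    def is_distinct(self, rtol: float = DEGENERACY_RTOL) -> bool:
        """Whether all three pools are pairwise distinct at relative tolerance."""
        a, b, c = self.A, self.B, self.C
        scale = max(a, b, c)
        return (
            abs(a - b) > rtol * scale
            and abs(a - c) > rtol * scale
            and abs(b - c) > rtol * scale
        )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.A, self.B, self.C)


@dataclass(frozen=True)
class LabelCurve:
    """A fractional-labeling time course for one leaf run.

    ``times`` are minutes since the atmosphere switch (strictly increasing,
    non-negative); ``f`` are atom-weighted 13C fractions, clipped to [0, 1]
    on construction (values outside [-LABEL_EPS, 1+LABEL_EPS] are rejected
    as corrupt rather than clipped).
    """

    times: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if times.ndim != 1 or times.shape != f.shape:
            raise ValueError("times and f must be 1-D arrays of equal length")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(f)):
            raise ValueError("non-finite values in label curve")
        if times.size and times[0] < 0:
            raise ValueError("times must be non-negative (t=0 is the label switch)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f < -LABEL_EPS) or np.any(f > 1 + LABEL_EPS):
            raise ValueError("fractional labeling grossly outside [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "f", np.clip(f, 0.0, 1.0))

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FluxFit:
    """Result of fitting the label-incorporation model to one curve.

    ``J`` is the pathway flux (pmol min^-1 mg^-1 DW), ``m`` the plateau
    labeling; ``se_J``/``se_m`` are asymptotic standard errors (inf when the
    information matrix is singular, e.g. an unresolved transient), ``rss``
    the residual sum of squares and ``converged`` whether the optimizer
    reports success on an identifiable curve.
    """

    J: float
    m: float
    se_J: float
    se_m: float
    rss: float
    n_points: int
    converged: bool
    message: str = ""


def _coefficients(pools: PoolSizes) -> tuple[float, float, float]:
    """Partial-fraction coefficients of the cascade solution; they sum to 1."""
    a, b, c = pools.as_tuple()
    ca = a * a / ((a - b) * (a - c))
    cb = b * b / ((b - a) * (b - c))
    cc = c * c / ((c - a) * (c - b))
    return ca, cb, cc


def label_fraction(t, pools: PoolSizes, J: float, m: float):
    """Fractional labeling of the terminal (IDP+DMADP) pool at time ``t``.

    Parameters
    ----------
    t : float or array-like
        Minutes since the label switch, >= 0.
    pools : PoolSizes
        Fixed pool sizes; if two coincide within ``DEGENERACY_RTOL`` the
        closed form is undefined and the cascade is integrated numerically.
    J : float
        Pathway flux, > 0.
    m : float
        Plateau labeling in (0, 1].

    Returns
    -------
    float or ndarray
        f(t) in [0, m]; scalar for scalar ``t``.
    """
    if J <= 0:
        raise ValueError(f"flux J must be > 0, got {J}")
    if not 0 < m <= 1:
        raise ValueError(f"plateau m must be in (0, 1], got {m}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")

    if pools.is_distinct():
        ca, cb, cc = _coefficients(pools)
        a, b, c = pools.as_tuple()
        f = m * (
            1.0
            - ca * np.exp(-J * t_arr / a)
            - cb * np.exp(-J * t_arr / b)
            - cc * np.exp(-J * t_arr / c)
        )
        f = np.clip(f, 0.0, m)
    else:
        # degenerate pools: repeated eigenvalues, evaluate by integration
        order = np.argsort(t_arr)
        curve = cascade_ode_oracle(t_arr[order], pools, J, m)
        f = np.empty_like(t_arr)
        f[order] = curve.f

    return f[0] if np.isscalar(t) or np.ndim(t) == 0 else f


def cascade_ode_oracle(
    times, pools: PoolSizes, J: float, m: float, *, rtol: float = 1e-10, atol: float = 1e-12
) -> LabelCurve:
    """Integrate the three-pool cascade ODEs and return the terminal labeling.

    Serves two roles: an independent check of the closed form, and the
    evaluation path when pool sizes are (near-)degenerate.  Does not require
    distinct pools.  Raises ``RuntimeError`` if the integrator fails.
    """
    if J <= 0:
        raise ValueError(f"flux J must be > 0, got {J}")
    if not 0 < m <= 1:
        raise ValueError(f"plateau m must be in (0, 1], got {m}")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if t[0] < 0 or np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending and non-negative")

    a, b, c = pools.as_tuple()
    ka, kb, kc = J / a, J / b, J / c

    def rhs(_t, y):
        fa, fb, fc = y
        return [ka * (m - fa), kb * (fa - fb), kc * (fb - fc)]

    # stiff-capable integrator: time constants can differ by orders of magnitude
    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1]) if t[-1] > 0 else 1.0),
        [0.0, 0.0, 0.0],
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"cascade ODE integration failed: {sol.message}")
    f = np.clip(sol.y[2], 0.0, m)
    return LabelCurve(times=t, f=f)


def _default_init(curve: LabelCurve, pools: PoolSizes) -> tuple[float, float]:
    """Heuristic starting point: m from the observed plateau, J from the
    half-rise time of the terminal pool (t_half ~ C/J for the final step)."""
    m0 = float(np.max(curve.f))
    m0 = min(max(m0, 1e-3), 1.0)
    half = 0.5 * m0
    above = np.nonzero(curve.f >= half)[0]
    t_half = float(curve.times[above[0]]) if above.size and curve.times[above[0]] > 0 else 1.0
    J0 = pools.C / t_half
    return max(J0, 1e-6), m0


def fit_flux(
    curve: LabelCurve,
    pools: PoolSizes,
    init_J: float | None = None,
    init_m: float | None = None,
) -> FluxFit:
    """Estimate flux ``J`` and plateau ``m`` by Levenberg-Marquardt least
    squares, with pool sizes held fixed.

    Returns a :class:`FluxFit`; an unidentifiable curve (all-zero, or no
    resolved transient) yields ``converged=False`` with a diagnostic message
    rather than an exception.
    """
    n = len(curve)
    if n < 3:
        raise ValueError("need at least 3 points to fit 2 parameters")

    fmax = float(np.max(curve.f))
    if fmax <= 0:
        return FluxFit(np.nan, np.nan, np.nan, np.nan, 0.0, n, False, "all-zero curve")
    if float(np.min(curve.f)) > 0.9 * fmax:
        return FluxFit(
            np.nan, np.nan, np.nan, np.nan, 0.0, n, False,
            "no transient resolved: every observation is already near plateau",
        )

    if init_J is None or init_m is None:
        j0, m0 = _default_init(curve, pools)
        init_J = j0 if init_J is None else init_J
        init_m = m0 if init_m is None else init_m

    params = lmfit.Parameters()
    params.add("J", value=float(init_J), min=1e-9)
    params.add("m", value=float(min(max(init_m, 1e-6), 1.0)), min=1e-6, max=1.0)

    def residual(p):
        return label_fraction(curve.times, pools, p["J"].value, p["m"].value) - curve.f

    try:
        result = lmfit.minimize(residual, params, method="leastsq")
    except Exception as exc:  # optimizer blow-up is a diagnostic, not a crash
        return FluxFit(np.nan, np.nan, np.nan, np.nan, np.nan, n, False, str(exc))

    J_hat = float(result.params["J"].value)
    m_hat = float(result.params["m"].value)
    se_J = result.params["J"].stderr
    se_m = result.params["m"].stderr
    se_J = float(se_J) if se_J is not None and np.isfinite(se_J) else np.inf
    se_m = float(se_m) if se_m is not None and np.isfinite(se_m) else np.inf
    rss = float(np.sum(np.asarray(result.residual) ** 2))
    converged = bool(result.success) and J_hat > 0
    return FluxFit(J_hat, m_hat, se_J, se_m, rss, n, converged, str(result.message))


# ---------------------------------------------------------------------------
# I/O

def read_label_curve(path_or_buffer) -> LabelCurve:
    """Read a ``time_min,f_label`` CSV/TSV into a :class:`LabelCurve`."""
    df = pd.read_csv(path_or_buffer, sep=None, engine="python")
    missing = {"time_min", "f_label"} - set(df.columns)
    if missing:
        raise ValueError(f"label curve CSV missing columns: {sorted(missing)}")
    return LabelCurve(times=df["time_min"].to_numpy(), f=df["f_label"].to_numpy())


def flux_fit_row(sample_id: str, fit: FluxFit) -> str:
    """One TSV row ``sample_id,J,se_J,m,se_m,rss,n_points,converged``."""
    buf = io.StringIO()
    buf.write(
        f"{sample_id}\t{fit.J:.6g}\t{fit.se_J:.6g}\t{fit.m:.6g}\t{fit.se_m:.6g}"
        f"\t{fit.rss:.6g}\t{fit.n_points}\t{int(fit.converged)}"
    )
    return buf.getvalue()
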