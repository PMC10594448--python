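"""SPR sensorgram analysis: 1:1 Langmuir kinetics, double referencing,
global multi-cycle fitting, and Chi2 / Chi2% fit quality.

Model
-----
The 1:1 (Langmuir) interaction A + B <-> AB obeys

    dR/dt = ka * C * (Rmax - R) - kd * R

during analyte injection at concentration C, with closed-form solution

    R(t) = Req + (R_init - Req) * exp(-(ka*C + kd) * t),
    Req  = ka * C * Rmax / (ka * C + kd),

and pure exponential decay R(t) = R0 * exp(-kd * t) during dissociation.
KD = kd / ka.

Fitting
-------
Full kinetic fits share (ka, kd, Rmax) globally across a multi-cycle
concentration series; dissociation-only (off-rate screening) fits share
kd with one free amplitude R0 per cycle.  Parameters are fitted in
log-space to enforce positivity, with deterministic multi-start
initialization seeded from a terminal-slope linearization of the decay
and an equilibrium-response regression against concentration.

Fit quality is reported as Chi2 = SSR / (n - p) (residual mean square,
in RU^2) and as the percentage statistic Chi2% = Chi2 / Rmax * 100,
with values below 5% flagged as high-significance fits.  Note Chi2% as
defined divides RU^2 by RU; the statistic is used as defined, not
dimensionally corrected.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .types import KineticFit, SensorgramCycle, ValidationError

__all__ = [
    "model_association",
    "model_dissociation",
    "double_reference",
    "fit_dissociation",
    "fit_full_kinetics",
    "chi2",
    "chi2_percent",
    "Chi2Percent",
    "AlignmentError",
    "DegenerateFitError",
    "HIGH_SIGNIFICANCE_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Chi2% values strictly below this are "high significance" fits.
HIGH_SIGNIFICANCE_THRESHOLD = 5.0

#: Seconds excluded after each phase boundary to avoid bulk-shift
#: transients in fit windows.
DEFAULT_T_EXCLUDE = 2.0


class AlignmentError(ValueError):
    """Traces could not be aligned onto a common time grid."""


class DegenerateFitError(ValueError):
    """The data carry no signal to fit (e.g. all-zero traces)."""


def _check_positive(**params: float) -> None:
    for name, value in params.items():
        if value < 0 or (name in ("ka", "kd", "Rmax") and value == 0):
            raise ValidationError(f"{name}: must be positive, got {value}")


def model_association(t, ka: float, kd: float, C: float, Rmax: float,
                      R_init: float = 0.0):
    """1:1 model response during injection of analyte at concentration C.

    ``t`` is seconds since injection start (scalar or array); result in
    RU, bounded by max(R_init, Req).
    """
    _check_positive(ka=ka, kd=kd, Rmax=Rmax)
    if C < 0:
        raise ValidationError(f"C: must be >= 0, got {C}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t: must be >= 0")
    kobs = ka * C + kd
    req = ka * C * Rmax / kobs
    return req + (R_init - req) * np.exp(-kobs * t)


def model_dissociation(t, kd: float, R0: float):
    """1:1 model response after injection end: R0 * exp(-kd * t).

    ``t`` is seconds since dissociation start (re-zeroed).
    """
    _check_positive(kd=kd)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t: must be >= 0")
    return R0 * np.exp(-kd * t)


def _resample(t_ref: np.ndarray, t: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Linearly interpolate (t, r) onto t_ref; error on non-overlap."""
    if np.array_equal(t_ref, t):
        return r
    if t.size == 0 or t_ref.size == 0 or t_ref[0] < t[0] - 1e-9 or t_ref[-1] > t[-1] + 1e-9:
        raise AlignmentError(
            "trace time ranges do not overlap the active trace's grid"
        )
    return np.interp(t_ref, t, r)


def double_reference(
    active: SensorgramCycle,
    reference: SensorgramCycle,
    blank_active: SensorgramCycle,
    blank_reference: SensorgramCycle,
) -> SensorgramCycle:
    """Double-reference an active trace.

    corrected = (active - reference) - (blank_active - blank_reference),
    per phase and per time point; traces on different grids are
    resampled onto the active trace's grid by linear interpolation.
    The reference-cell subtraction removes bulk refractive-index and
    drift artefacts common to both flow cells; the blank-cycle
    subtraction removes systematic injection artefacts.
    """
    out = {}
    for tname, rname in (("t_assoc", "r_assoc"), ("t_dissoc", "r_dissoc")):
        t = getattr(active, tname)
        corr = (
            getattr(active, rname)
            - _resample(t, getattr(reference, tname), getattr(reference, rname))
            - _resample(t, getattr(blank_active, tname), getattr(blank_active, rname))
            + _resample(t, getattr(blank_reference, tname),
                        getattr(blank_reference, rname))
        )
        out[tname], out[rname] = t, corr
    return SensorgramCycle(
        active.cycle_id, active.concentration, "active",
        out["t_assoc"], out["r_assoc"], out["t_dissoc"], out["r_dissoc"],
        is_blank=active.is_blank,
    )


def double_reference_series(cycles: Sequence[SensorgramCycle]) -> List[SensorgramCycle]:
    """Double-reference every non-blank active cycle of a run.

    Pairs active/reference traces by cycle_id and uses the run's blank
    cycle pair; raises if any piece is missing.
    """
    by_key = {(c.cycle_id, c.role): c for c in cycles}
    blanks = {c.role: c for c in cycles if c.is_blank}
    if set(blanks) != {"active", "reference"}:
        raise AlignmentError("run must contain an active and a reference blank cycle")
    corrected = []
    for c in cycles:
        if c.is_blank or c.role != "active":
            continue
        try:
            ref = by_key[(c.cycle_id, "reference")]
        except KeyError:
            raise AlignmentError(f"cycle {c.cycle_id}: no reference trace") from None
        corrected.append(double_reference(c, ref, blanks["active"], blanks["reference"]))
    corrected.sort(key=lambda c: (c.concentration, c.cycle_id))
    return corrected


def chi2(residuals, n_points: int, n_params: int, normalize: bool = True) -> float:
    """Residual mean square SSR / (n - p) in RU^2 (or raw SSR)."""
    residuals = np.asarray(residuals, dtype=float)
    ssr = float(np.sum(residuals**2))
    if not normalize:
        return ssr
    if n_points <= n_params:
        raise ValidationError(
            f"n_points: need n_points > n_params, got {n_points} <= {n_params}"
        )
    return ssr / (n_points - n_params)


class Chi2Percent(NamedTuple):
    """Chi2% statistic with its high-significance flag (< 5%)."""

    percent: float
    high_significance: bool


def chi2_percent(chi2_value: float, Rmax: float) -> Chi2Percent:
    """Chi2 / Rmax * 100, flagged high-significance when below 5%."""
    if Rmax <= 0:
        raise ValidationError(f"Rmax: must be > 0, got {Rmax}")
    if chi2_value < 0:
        raise ValidationError(f"chi2: must be >= 0, got {chi2_value}")
    pct = chi2_value / Rmax * 100.0
    return Chi2Percent(pct, pct < HIGH_SIGNIFICANCE_THRESHOLD)


def _window_mask(t: np.ndarray, t_start: float, t_end: float) -> np.ndarray:
    return (t >= t_start - 1e-12) & (t <= t_end + 1e-12)


def _kd_init_from_slope(cycles: Sequence[SensorgramCycle],
                        masks: Sequence[np.ndarray]) -> float:
    """Estimate kd from the log-linear slope of the decay tails."""
    slopes = []
    for c, m in zip(cycles, masks):
        t, r = c.t_dissoc[m], c.r_dissoc[m]
        pos = r > max(1e-12, 1e-6 * np.max(np.abs(r), initial=0.0))
        if np.count_nonzero(pos) >= 3:
            slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
            if slope < 0:
                slopes.append(-slope)
    if not slopes:
        return 1e-3
    return float(np.median(slopes))


def fit_dissociation(
    cycles: Sequence[SensorgramCycle],
    window: Optional[Tuple[float, float]] = None,
    t_exclude: float = DEFAULT_T_EXCLUDE,
    rmax_for_chi2: Optional[float] = None,
    normalize_chi2: bool = True,
) -> KineticFit:
    """Off-rate screening: fit a global kd with one free R0 per cycle.

    Least-squares over the dissociation-phase windows of all cycles;
    kd and the R0 amplitudes are fitted in log-space.  ``window`` limits
    the fit to (t_start, t_end) seconds of the dissociation phase
    (default: from ``t_exclude`` to the end).  ``rmax_for_chi2``
    supplies a companion full-fit Rmax for the Chi2% statistic; without
    one the largest fitted R0 is used (flagged via ``rmax_source``).
    """
    if not cycles:
        raise ValidationError("cycles: need at least one cycle")
    masks = []
    for c in cycles:
        lo, hi = window if window is not None else (t_exclude, float(c.t_dissoc[-1]))
        if window is not None and (lo < c.t_dissoc[0] - 1e-9 or hi > c.t_dissoc[-1] + 1e-9):
            raise ValidationError("window: outside the dissociation data range")
        m = _window_mask(c.t_dissoc, lo, hi)
        if np.count_nonzero(m) < 2:
            raise ValidationError("window: fewer than 2 samples per cycle")
        masks.append(m)
    peak = max(float(np.max(np.abs(c.r_dissoc[m]))) for c, m in zip(cycles, masks))
    if peak <= 0:
        raise DegenerateFitError("all dissociation traces are zero")
    kd0 = _kd_init_from_slope(cycles, masks)
    r0_init = [max(float(c.r_dissoc[m][0]), 1e-6 * peak) for c, m in zip(cycles, masks)]
    x0 = np.log(np.concatenate([[kd0], r0_init]))

    def resid(x):
        kd = np.exp(x[0])
        out = []
        for i, (c, m) in enumerate(zip(cycles, masks)):
            r0 = np.exp(x[1 + i])
            out.append(c.r_dissoc[m] - r0 * np.exp(-kd * c.t_dissoc[m]))
        return np.concatenate(out)

    sol = least_squares(resid, x0, method="trf", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=500 * x0.size)
    kd = float(np.exp(sol.x[0]))
    r0 = {c.cycle_id: float(np.exp(v)) for c, v in zip(cycles, sol.x[1:])}
    n_points = int(sum(np.count_nonzero(m) for m in masks))
    n_params = 1 + len(cycles)
    c2 = chi2(sol.fun, n_points, n_params, normalize=normalize_chi2)
    if rmax_for_chi2 is not None:
        rmax, rmax_source = float(rmax_for_chi2), "global_fit"
    else:
        rmax, rmax_source = max(r0.values()), "max_R0"
    pct = chi2_percent(c2, rmax)
    converged = bool(sol.status > 0 and np.isfinite(sol.cost))
    if not converged:
        logger.warning("dissociation fit did not converge: %s", sol.message)
    return KineticFit(
        ka=float("nan"), kd=kd, KD=float("nan"), Rmax=rmax, r0=r0,
        chi2=c2, chi2_pct=pct.percent, high_significance=pct.high_significance,
        n_points=n_points, n_params=n_params, converged=converged,
        rmax_source=rmax_source, message=sol.message,
    )


def _equilibrium_init(cycles, t_assoc_end) -> Tuple[float, float]:
    """Crude (Rmax, KD) from the end-of-association response vs C.

    Linearizes Req = Rmax*C/(C+KD) as 1/Req = 1/Rmax + (KD/Rmax)*(1/C).
    """
    conc = np.array([c.concentration for c in cycles])
    req = np.array([float(np.interp(t_assoc_end, c.t_assoc, c.r_assoc))
                    for c in cycles])
    ok = req > 0
    if np.count_nonzero(ok) >= 2:
        coef = np.polyfit(1.0 / conc[ok], 1.0 / req[ok], 1)
        if coef[1] > 0 and coef[0] > 0:
            rmax = 1.0 / coef[1]
            kD = coef[0] * rmax
            return float(rmax), float(kD)
    rmax = float(np.max(req, initial=1.0)) * 1.5
    return max(rmax, 1e-6), float(np.median(conc))


def fit_full_kinetics(
    cycles: Sequence[SensorgramCycle],
    t_exclude: float = DEFAULT_T_EXCLUDE,
    normalize_chi2: bool = True,
) -> KineticFit:
    """Global 1:1 fit of (ka, kd, Rmax) over a multi-cycle series.

    Simultaneous least-squares over the association and dissociation
    phases of all (double-referenced) cycles, with ka, kd and Rmax
    shared globally and each cycle's dissociation amplitude tied to the
    model value at injection end.  Parameters are log-parameterized;
    initialization is a deterministic multi-start grid around a
    terminal-slope kd estimate and an equilibrium-response (Req vs C)
    regression; the best final cost wins, ties broken by lowest kd.
    """
    if not cycles:
        raise ValidationError("cycles: need at least one cycle")
    concs = {c.concentration for c in cycles}
    if len(concs) < 2:
        warnings.warn(
            "full kinetic fit with a single concentration is ill-posed; "
            "ka and kd may not be separable", stacklevel=2)
    t_end = float(cycles[0].t_assoc[-1])
    masks_a = [_window_mask(c.t_assoc, t_exclude, float(c.t_assoc[-1]))
               for c in cycles]
    masks_d = [_window_mask(c.t_dissoc, t_exclude, float(c.t_dissoc[-1]))
               for c in cycles]
    peak = max(float(np.max(np.abs(np.concatenate([c.r_assoc[ma], c.r_dissoc[md]]))))
               for c, ma, md in zip(cycles, masks_a, masks_d))
    if peak <= 0:
        raise DegenerateFitError("all traces are zero")

    def resid(x):
        ka, kd, rmax = np.exp(x)
        out = []
        for c, ma, md in zip(cycles, masks_a, masks_d):
            ra = model_association(c.t_assoc[ma], ka, kd, c.concentration, rmax)
            r0 = model_association(t_end, ka, kd, c.concentration, rmax)
            rd = model_dissociation(c.t_dissoc[md], kd, float(r0))
            out.append(c.r_assoc[ma] - ra)
            out.append(c.r_dissoc[md] - rd)
        return np.concatenate(out)

    kd0 = _kd_init_from_slope(cycles, masks_d)
    rmax0, kD0 = _equilibrium_init(cycles, t_end)
    ka0 = kd0 / max(kD0, 1e-15)
    starts = []
    for f_ka in (1.0, 0.1, 10.0):
        starts.append((ka0 * f_ka, kd0, rmax0))
    starts.append((kd0 / float(np.median([c.concentration for c in cycles])),
                   kd0, max(peak * 1.2, 1e-6)))
    best = None
    for ka_s, kd_s, rmax_s in starts:
        x0 = np.log([max(ka_s, 1e-12), max(kd_s, 1e-12), max(rmax_s, 1e-12)])
        sol = least_squares(resid, x0, method="trf", xtol=1e-15, ftol=1e-15,
                            gtol=1e-15, max_nfev=2000)
        key = (sol.cost, np.exp(sol.x[1]))
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]
    ka, kd, rmax = (float(v) for v in np.exp(sol.x))
    r0 = {c.cycle_id: float(model_association(t_end, ka, kd, c.concentration, rmax))
          for c in cycles}
    n_points = int(sum(np.count_nonzero(ma) + np.count_nonzero(md)
                       for ma, md in zip(masks_a, masks_d)))
    n_params = 3
    c2 = chi2(sol.fun, n_points, n_params, normalize=normalize_chi2)
    pct = chi2_percent(c2, rmax)
    converged = bool(sol.status > 0 and np.isfinite(sol.cost))
    if not converged:
        logger.warning("full kinetic fit did not converge: %s", sol.message)
    return KineticFit(
        ka=ka, kd=kd, KD=kd / ka, Rmax=rmax, r0=r0,
        chi2=c2, chi2_pct=pct.percent, high_significance=pct.high_significance,
        n_points=n_points, n_params=n_params, converged=converged,
        rmax_source="global_fit", message=sol.message,
    )
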