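"""Tm detection and Tm-shift KD fitting for nanoDSF titrations.

nanoDSF follows intrinsic tryptophan fluorescence while a protein sample is
heated; the melting temperature Tm is the midpoint of the unfolding
transition, located as the extremum of the first derivative of the 350 nm
trace.  A ligand that binds the folded state shifts Tm upward, and the
size of the shift across a ligand titration encodes the dissociation
constant.  The model here is the classic two-state, ligand-coupled
("Tm-shift") linkage:

    dGu(T) = dHu * (1 - T/Tm0) + dCp * ((T - Tm0) - T * ln(T/Tm0))
    Ku(T)  = exp(-dGu / (R T));     fu = Ku / (1 + Ku)

with 1:1 binding to the folded state.  At the observed midpoint half the
protein is unfolded, so the folded species sum to Pt/2 and the apparent
unfolding constant satisfies

    Ku(Tm) = 1 + Lfree / Kd

where Lfree accounts for ligand depletion by the Pt/2 of folded protein.
Fitting Tm(Lt) over a titration yields an apparent KD averaged over all
binding sites (the model assumes one-to-one binding), reported in µM with
a profile-likelihood CI95.

Units: Kelvin internally, Celsius at I/O boundaries; concentrations in µM;
enthalpies in kJ/mol with R = 8.314e-3 kJ/(mol K).  The binding enthalpy is
taken as zero, i.e. the KD is the apparent value in the melting-temperature
regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.signal import savgol_filter
from scipy.stats import f as f_dist

from .errors import DataError, FitError, ModelError, NoTransitionError

#: Gas constant, kJ/(mol K)
R_KJ = 8.314e-3

CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class ThermoModel:
    """Two-state unfolding thermodynamics (van't Hoff at the apo midpoint)."""

    tm0_K: float
    dhu_kJmol: float
    dcp_kJmolK: float = 0.0

    def __post_init__(self):
        if not self.tm0_K > 273.0:
            raise ModelError(f"Tm0 = {self.tm0_K} K must exceed 273 K")
        if not self.dhu_kJmol > 0:
            raise ModelError("unfolding enthalpy dHu must be positive")

    def delta_g(self, T_K):
        """Unfolding free energy dGu(T), kJ/mol (Gibbs-Helmholtz)."""
        T = np.asarray(T_K, dtype=float)
        dg = self.dhu_kJmol * (1.0 - T / self.tm0_K)
        if self.dcp_kJmolK != 0.0:
            dg = dg + self.dcp_kJmolK * ((T - self.tm0_K) - T * np.log(T / self.tm0_K))
        return dg

    def ku(self, T_K):
        """Unfolding equilibrium constant Ku(T)."""
        T = np.asarray(T_K, dtype=float)
        return np.exp(-self.delta_g(T) / (R_KJ * T))


def fraction_unfolded(T_K, model: ThermoModel):
    """fu(T) = Ku / (1 + Ku); equals 0.5 at Tm0 when dCp = 0."""
    ku = model.ku(T_K)
    return ku / (1.0 + ku)


@dataclass
class MeltingCurve:
    """One nanoDSF trace at one ligand concentration."""

    temperature_C: np.ndarray
    signal: np.ndarray
    ligand_total_uM: float
    protein_total_uM: float

    def __post_init__(self):
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature_C.size < 20:
            raise DataError(
                f"melting curve needs >= 20 points, got {self.temperature_C.size}"
            )
        if self.temperature_C.size != self.signal.size:
            raise DataError("temperature and signal lengths differ")
        if not np.all(np.diff(self.temperature_C) > 0):
            raise DataError("temperatures must be strictly increasing")
        if self.ligand_total_uM < 0 or not self.protein_total_uM > 0:
            raise DataError("need Lt >= 0 and Pt > 0")


@dataclass(frozen=True)
class TmDetection:
    """Detected midpoint with the derivative-extremum sign convention."""

    tm_K: float
    sign: str  # "max" if the derivative peak is positive, "min" if negative
    peak_derivative: float


def detect_tm(
    curve: MeltingCurve,
    smoothing_window: int = 9,
    polyorder: int = 3,
    noise_factor: float = 3.0,
) -> TmDetection:
    """Locate Tm as the extremum of the smoothed first derivative.

    The trace is Savitzky-Golay smoothed (default window 9, order 3) and
    differentiated on the temperature grid; the extremum of largest
    absolute value marks the midpoint, refined by a parabolic fit through
    the three points around the peak.  If the extremum does not stand out
    from the trace's overall derivative level (< ``noise_factor`` times the
    median absolute derivative) there is no detectable transition.
    """
    T = curve.temperature_C + CELSIUS_OFFSET
    window = min(smoothing_window, curve.signal.size)
    if window % 2 == 0:
        window -= 1
    if window > polyorder + 1:
        smooth = savgol_filter(curve.signal, window, polyorder)
    else:
        smooth = curve.signal
    deriv = np.gradient(smooth, T)
    abs_deriv = np.abs(deriv)
    peak = int(np.argmax(abs_deriv))
    floor = float(np.median(abs_deriv))
    if abs_deriv[peak] < noise_factor * floor:
        raise NoTransitionError(
            f"derivative extremum {abs_deriv[peak]:.3g} below "
            f"{noise_factor:g} x median |dS/dT| = {noise_factor * floor:.3g}"
        )
    tm = T[peak]
    if 0 < peak < T.size - 1:
        # parabola through the three points bracketing the extremum
        coeffs = np.polyfit(T[peak - 1 : peak + 2], deriv[peak - 1 : peak + 2], 2)
        if coeffs[0] != 0:
            vertex = -coeffs[1] / (2 * coeffs[0])
            if T[peak - 1] <= vertex <= T[peak + 1]:
                tm = vertex
    return TmDetection(
        tm_K=float(tm),
        sign="max" if deriv[peak] > 0 else "min",
        peak_derivative=float(deriv[peak]),
    )


def free_ligand_at_tm(kd_uM: float, lt_uM: float, pt_uM: float) -> float:
    """Free ligand at the midpoint, where the folded protein totals Pt/2.

    Solves Lfree = Lt - (Pt/2) * Lfree / (Kd + Lfree): the positive root of
    Lfree^2 + (Kd + Pt/2 - Lt) * Lfree - Kd * Lt = 0.
    """
    if kd_uM <= 0:
        raise ModelError("Kd must be positive")
    if lt_uM < 0 or pt_uM < 0:
        raise ModelError("concentrations must be non-negative")
    if lt_uM == 0:
        return 0.0
    b = kd_uM + pt_uM / 2.0 - lt_uM
    disc = b * b + 4.0 * kd_uM * lt_uM
    return float((-b + np.sqrt(disc)) / 2.0)


def predict_tm(
    model: ThermoModel,
    kd_uM: float,
    lt_uM: float,
    pt_uM: float,
    bracket_K: float = 60.0,
) -> float:
    """Midpoint temperature under the Tm-shift condition Ku(Tm) = 1 + Lfree/Kd.

    Returns Tm0 exactly at Lt = 0; otherwise the unique root above Tm0
    within ``bracket_K`` Kelvin.
    """
    if kd_uM <= 0:
        raise ModelError("Kd must be positive")
    if lt_uM == 0:
        return model.tm0_K
    lfree = free_ligand_at_tm(kd_uM, lt_uM, pt_uM)
    target = 1.0 + lfree / kd_uM

    def g(T):
        return model.ku(T) - target

    lo, hi = model.tm0_K, model.tm0_K + bracket_K
    if g(hi) < 0:
        raise ModelError(
            f"no midpoint bracket within [{lo:.1f}, {hi:.1f}] K "
            f"(Kd={kd_uM:g} uM, Lt={lt_uM:g} uM)"
        )
    return float(brentq(g, lo, hi, xtol=1e-10))


@dataclass
class ThermoFitResult:
    """Apparent KD from a Tm-shift titration fit."""

    kd_app_uM: float
    ci95_uM: tuple[float, float]
    tm_observed_K: list[float]
    tm_predicted_K: list[float]
    residual_norm: float
    model: ThermoModel
    ci_upper_unbounded: bool = False
    lt_uM: list[float] = field(default_factory=list)


_LOG10_KD_BOUNDS = (-2.0, 5.0)
_MULTISTART_KD_UM = (1.0, 10.0, 100.0, 1000.0)


def _fit_at(log10_kd, lts, tms, pt_uM, dhu0, tm00, dcp, fix_kd):
    """Least-squares over (dHu, Tm0) and optionally log10 Kd."""

    def residuals(theta):
        if fix_kd:
            dhu, tm0 = theta
            lkd = log10_kd
        else:
            lkd, dhu, tm0 = theta
        model = ThermoModel(tm0_K=tm0, dhu_kJmol=dhu, dcp_kJmolK=dcp)
        kd = 10.0 ** lkd
        out = np.empty_like(lts)
        for i, (lt, tm) in enumerate(zip(lts, tms)):
            try:
                out[i] = predict_tm(model, kd, lt, pt_uM, bracket_K=100.0) - tm
            except ModelError:
                out[i] = 50.0  # push the optimizer away from unreachable regimes
        return out

    if fix_kd:
        x0 = [dhu0, tm00]
        bounds = ([30.0, 273.15], [3000.0, 450.0])
    else:
        x0 = [log10_kd, dhu0, tm00]
        bounds = (
            [_LOG10_KD_BOUNDS[0], 30.0, 273.15],
            [_LOG10_KD_BOUNDS[1], 3000.0, 450.0],
        )
    sol = least_squares(residuals, x0, bounds=bounds, xtol=1e-12, ftol=1e-12)
    return sol


def fit_kd_tmshift(
    tm_observations: list[tuple[float, float]],
    pt_uM: float,
    model_init: ThermoModel | None = None,
    dcp_kJmolK: float = 0.0,
    profile_ci: bool = True,
) -> ThermoFitResult:
    """Fit (log10 Kd, dHu, Tm0) to (Lt, Tm) pairs by least squares.

    ``tm_observations`` are ``(ligand_total_uM, Tm_K)`` pairs, ideally
    including an apo (Lt = 0) point that anchors Tm0.  The fit is run in
    log10 Kd space with multistart over {1, 10, 100, 1000} µM; the CI95 is
    a profile scan over log10 Kd using an F-based threshold on the residual
    sum of squares (one parameter, 95%), which reproduces the asymmetric
    intervals typical of Tm-shift data.  An upper limit that never crosses
    the threshold before the Kd bound is flagged as an open interval.
    """
    obs = sorted(tm_observations, key=lambda p: p[0])
    if len(obs) < 4:
        raise FitError(f"need >= 4 titration points, got {len(obs)}")
    lts = np.array([p[0] for p in obs], dtype=float)
    tms = np.array([p[1] for p in obs], dtype=float)
    if lts[0] > 0:
        warnings.warn("no Lt=0 (apo) point; Tm0 is extrapolated", stacklevel=2)
    if np.any(np.diff(tms) < -1.0):
        warnings.warn("Tm not monotone non-decreasing in Lt", stacklevel=2)

    dhu0 = model_init.dhu_kJmol if model_init else 400.0
    tm00 = model_init.tm0_K if model_init else float(tms[0])

    best = None
    for kd0 in _MULTISTART_KD_UM:
        sol = _fit_at(np.log10(kd0), lts, tms, pt_uM, dhu0, tm00, dcp_kJmolK, False)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("Tm-shift fit did not converge")

    lkd_hat, dhu_hat, tm0_hat = best.x
    kd_hat = 10.0 ** lkd_hat
    model = ThermoModel(tm0_K=tm0_hat, dhu_kJmol=dhu_hat, dcp_kJmolK=dcp_kJmolK)
    tm_pred = [predict_tm(model, kd_hat, lt, pt_uM, bracket_K=100.0) for lt in lts]
    ssr_min = float(2 * best.cost)

    ci_lo, ci_hi, unbounded = kd_hat, kd_hat, False
    if profile_ci:
        ci_lo, ci_hi, unbounded = _profile_ci(
            lkd_hat, ssr_min, lts, tms, pt_uM, dhu_hat, tm0_hat, dcp_kJmolK
        )

    return ThermoFitResult(
        kd_app_uM=float(kd_hat),
        ci95_uM=(float(ci_lo), float(ci_hi)),
        tm_observed_K=[float(t) for t in tms],
        tm_predicted_K=[float(t) for t in tm_pred],
        residual_norm=float(np.sqrt(ssr_min)),
        model=model,
        ci_upper_unbounded=unbounded,
        lt_uM=[float(lt) for lt in lts],
    )


def _profile_ci(lkd_hat, ssr_min, lts, tms, pt_uM, dhu_hat, tm0_hat, dcp):
    """Profile-likelihood CI on Kd: SSR threshold from F(1, n-3) at 95%."""
    n = lts.size
    dof = max(n - 3, 1)
    if ssr_min <= 0:
        ssr_min = 1e-12  # noiseless data: interval collapses onto the estimate
    threshold = ssr_min * (1.0 + f_dist.ppf(0.95, 1, dof) / dof)

    def profile_ssr(lkd):
        sol = _fit_at(lkd, lts, tms, pt_uM, dhu_hat, tm0_hat, dcp, True)
        return float(2 * sol.cost)

    def crossing(lo, hi):
        return brentq(lambda l: profile_ssr(l) - threshold, lo, hi, xtol=1e-4)

    step = 0.25
    # lower limit
    ci_lo_l = lkd_hat
    l = lkd_hat - step
    while l >= _LOG10_KD_BOUNDS[0] - 1e-9:
        if profile_ssr(l) > threshold:
            ci_lo_l = crossing(l, min(l + step, lkd_hat))
            break
        l -= step
    else:
        ci_lo_l = _LOG10_KD_BOUNDS[0]
    # upper limit
    unbounded = False
    ci_hi_l = lkd_hat
    l = lkd_hat + step
    while l <= _LOG10_KD_BOUNDS[1] + 1e-9:
        if profile_ssr(l) > threshold:
            ci_hi_l = crossing(max(l - step, lkd_hat), l)
            break
        l += step
    else:
        ci_hi_l = _LOG10_KD_BOUNDS[1]
        unbounded = True
    hi = np.inf if unbounded else 10.0 ** ci_hi_l
    return 10.0 ** ci_lo_l, hi, unbounded
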