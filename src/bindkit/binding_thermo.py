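"""Quantitative binding models: fluorescence quenching, ITC, DSC and IC50.

The forward models here (`stern_volmer_fluorescence`, `itc_model_heats`,
`dsc_model_cp`, `four_param_logistic`) are the single source of truth for the
synthetic-data generators, so noise-free generated data round-trips through
the fitters exactly.

Model summary
-------------
* Stern-Volmer quenching: F0/F = 1 + K_sv [L]; K_q = K_sv / tau.  A K_q above
  the diffusion limit (~1e10 M^-1 s^-1) indicates static (ground-state
  complex) quenching.
* Quenching-derived K_d: double-log regression of log10((F0-F)/F) on
  log10(L_free) gives log10(Ka) (intercept) and the site exponent n (slope);
  L_free is refined iteratively as L_total - n * ((F0-F)/F0) * P_total.
* ITC: Wiseman one-set-of-sites isotherm with displacement-cell dilution
  factors; per-injection heats from differences of cumulative heat with the
  half-displaced-volume correction.
* DSC: sum of independent two-state transitions, each with separate
  calorimetric and van't Hoff enthalpies (non-two-state), on a linear
  baseline.
* Dose-response: 4-parameter logistic on log-concentration; CI by residual
  bootstrap.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from scipy.stats import t as t_dist

from .constants import R_KCAL, KCAL_TO_UCAL, TRP_LIFETIME_S
from .datatypes import (
    DoseResponse,
    DSCFit,
    DSCTransition,
    IC50Fit,
    ITCExperiment,
    ITCFit,
    ITCGeometry,
    ITCParams,
    QuenchBindingFit,
    SternVolmerFit,
    Thermogram,
    TitrationSeries,
)

__all__ = [
    "stern_volmer_fluorescence",
    "fit_stern_volmer",
    "estimate_kd_quench",
    "itc_model_heats",
    "bound_fraction",
    "fit_itc_one_site",
    "decompose_thermo",
    "dsc_model_cp",
    "fit_dsc",
    "four_param_logistic",
    "fit_ic50",
]


# ---------------------------------------------------------------------------
# fluorescence quenching
# ---------------------------------------------------------------------------

def stern_volmer_fluorescence(F0: float, K_sv: float, ligand_conc: np.ndarray) -> np.ndarray:
    """Noise-free fluorescence under Stern-Volmer quenching: F = F0 / (1 + K_sv L)."""
    L = np.asarray(ligand_conc, dtype=float)
    return F0 / (1.0 + K_sv * L)


def fit_stern_volmer(series: TitrationSeries, tau: float = TRP_LIFETIME_S) -> SternVolmerFit:
    """Ordinary least squares of F0/F on [L] with a free intercept.

    The intercept is left free as a quality check (it should be ~1); K_q is
    derived as K_sv / tau.  A non-monotone F0/F series beyond 1% tolerance
    sets ``monotone_warning`` instead of raising.
    """
    L = series.ligand_conc
    F = series.fluorescence
    if L.size < 4:
        raise ValueError("need at least 4 titration points")
    F0 = F[0]
    y = F0 / F

    dips = np.diff(y) < -0.01 * np.abs(y[:-1])
    monotone_warning = bool(np.any(dips))
    if monotone_warning:
        warnings.warn("F0/F decreases along the titration beyond noise tolerance",
                      stacklevel=2)

    X = np.column_stack([L, np.ones_like(L)])
    beta, res_ss, _, _ = np.linalg.lstsq(X, y, rcond=None)
    slope, intercept = float(beta[0]), float(beta[1])
    fitted = X @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - fitted) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(L.size - 2, 1)
    sxx = float(np.sum((L - L.mean()) ** 2))
    slope_se = float(np.sqrt(ss_res / dof / sxx)) if sxx > 0 else np.inf

    return SternVolmerFit(
        K_sv=slope,
        K_sv_se=slope_se,
        K_q=slope / tau,
        intercept=intercept,
        r_squared=max(0.0, min(1.0, r_squared)),
        monotone_warning=monotone_warning,
    )


def estimate_kd_quench(series: TitrationSeries, tol: float = 1e-6,
                       max_iter: int = 50) -> QuenchBindingFit:
    """Dissociation constant from quenching via iterative double-log regression.

    Each pass regresses log10((F0-F)/F) on log10(L_free): the intercept is
    log10(Ka) and the slope the binding-site exponent n.  L_free is then
    updated as L_total - n * ((F0-F)/F0) * P_total (floored at a small
    positive value) and the cycle repeats until the relative change in
    K_d = 1/Ka falls below ``tol``.
    """
    L_tot = series.ligand_conc
    F = series.fluorescence
    F0 = F[0]
    mask = (L_tot > 0) & (F < F0)
    if np.count_nonzero(mask) < 5:
        raise ValueError("need at least 5 nonzero-ligand points with F < F0")
    L_tot = L_tot[mask]
    Fq = F[mask]
    ratio = (F0 - Fq) / Fq          # = Ka * L_free^n in the binding model
    bound_frac = (F0 - Fq) / F0

    floor = 1e-3 * L_tot.min()
    L_free = L_tot.copy()
    K_d_prev = np.inf
    n_sites = 1.0
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        X = np.column_stack([np.log10(L_free), np.ones_like(L_free)])
        beta, *_ = np.linalg.lstsq(X, np.log10(ratio), rcond=None)
        n_sites, log_ka = float(beta[0]), float(beta[1])
        K_d = 10.0 ** (-log_ka)
        if np.isfinite(K_d_prev) and abs(K_d - K_d_prev) / K_d < tol:
            converged = True
            break
        K_d_prev = K_d
        if series.protein_conc == 0:
            converged = True  # no free-ligand correction: single pass suffices
            break
        L_free = np.maximum(L_tot - n_sites * bound_frac * series.protein_conc, floor)

    return QuenchBindingFit(K_d=K_d, n_sites=n_sites,
                            iterations=iterations, converged=converged)


# ---------------------------------------------------------------------------
# isothermal titration calorimetry
# ---------------------------------------------------------------------------

def _itc_concentrations(geom: ITCGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Cell macromolecule and ligand concentrations after each injection.

    Displacement-cell dilution: with cumulative injected volume v, the
    macromolecule is diluted by (1 - v/2V0)/(1 + v/2V0) and the titrant
    reaches X_syr * (v/V0) / (1 + v/2V0).
    """
    v = np.cumsum(geom.injection_volumes)
    V0 = geom.cell_volume
    M = geom.cell_conc * (1.0 - v / (2 * V0)) / (1.0 + v / (2 * V0))
    X = geom.syringe_conc * (v / V0) / (1.0 + v / (2 * V0))
    return M, X


def itc_model_heats(params: ITCParams, geom: ITCGeometry) -> np.ndarray:
    """Per-injection heats (µcal) of the one-set-of-sites (Wiseman) isotherm.

    The bound fraction after injection i is the physical (smaller) root of
    Theta^2 - Theta [1 + X/(nM) + 1/(n Ka M)] + X/(nM) = 0; cumulative heat
    Q_i = n Theta_i M_i dH V0, and the injection heat corrects for the half
    displaced volume: dQ_i = Q_i - Q_{i-1} + (dV_i/V0)(Q_i + Q_{i-1})/2.
    """
    M, X = _itc_concentrations(geom)
    n, Ka, dH = params.n, params.Ka, params.dH
    r = X / (n * M)
    b = 1.0 + r + 1.0 / (n * Ka * M)
    disc = b * b - 4.0 * r
    if np.any(disc < 0):
        raise ValueError("negative discriminant in the binding quadratic")
    theta = (b - np.sqrt(disc)) / 2.0
    V0 = geom.cell_volume
    Q = n * theta * M * dH * V0 * KCAL_TO_UCAL
    Q_prev = np.concatenate([[0.0], Q[:-1]])
    dV = np.asarray(geom.injection_volumes)
    return Q - Q_prev + (dV / V0) * (Q + Q_prev) / 2.0


def bound_fraction(params: ITCParams, geom: ITCGeometry) -> np.ndarray:
    """Theta_i after each injection (diagnostic; in [0, 1] and increasing)."""
    M, X = _itc_concentrations(geom)
    r = X / (params.n * M)
    b = 1.0 + r + 1.0 / (params.n * params.Ka * M)
    return (b - np.sqrt(b * b - 4.0 * r)) / 2.0


def decompose_thermo(K_d: float, dH: float, T: float = 298.15) -> tuple[float, float]:
    """Split binding thermodynamics: dG = RT ln K_d (1 M standard state), TdS = dH - dG."""
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    dG = R_KCAL * T * np.log(K_d)
    return dG, dH - dG


def fit_itc_one_site(exp: ITCExperiment) -> ITCFit:
    """Nonlinear least squares of the one-set-of-sites isotherm.

    If a blank dilution series is supplied it is subtracted point-wise;
    otherwise a constant per-injection offset is co-fitted.  Ka is fitted on
    a log scale.  Reports K_d = 1/Ka, dG = RT ln K_d and TdS = dH - dG at the
    geometry's temperature.
    """
    geom = exp.geometry
    heats = exp.heats.copy()
    if exp.dilution_heats is not None:
        heats = heats - exp.dilution_heats
        fit_offset = False
    else:
        fit_offset = True

    if geom.n_injections < 10:
        raise ValueError("need at least 10 injections for a stable fit")
    span = float(heats.max() - heats.min())
    if span < 1e-9 or not np.any(np.abs(heats - heats.mean()) > 1e-9):
        raise ValueError("flat isotherm: dH is unidentifiable")

    # initial guesses: n=1, Ka from the inflection of the cumulative heat,
    # dH from the saturation heat estimate
    M0, V0 = geom.cell_conc, geom.cell_volume
    Q_sat = float(np.sum(heats[np.abs(heats) > 0.05 * np.abs(heats).max()]))
    dH0 = Q_sat / (M0 * V0 * KCAL_TO_UCAL)
    if dH0 == 0:
        dH0 = -1.0
    x0 = np.array([1.0, np.log(1e6), dH0] + ([0.0] if fit_offset else []))

    def residual(p):
        n, log_ka, dH = p[0], p[1], p[2]
        offset = p[3] if fit_offset else 0.0
        if n <= 0:
            return np.full_like(heats, 1e6)
        model = itc_model_heats(ITCParams(n=n, K_d=float(np.exp(-log_ka)), dH=dH), geom)
        return model + offset - heats

    sol = least_squares(residual, x0, method="lm", max_nfev=20000)
    n_fit, log_ka, dH_fit = sol.x[0], sol.x[1], sol.x[2]
    offset = float(sol.x[3]) if fit_offset else 0.0
    Ka = float(np.exp(log_ka))
    K_d = 1.0 / Ka

    # linearized 95% CI for K_d from the Jacobian (log-Ka scale, so the
    # interval is asymmetric in K_d and always positive); t-quantile for the
    # small number of injections
    dof = max(heats.size - sol.x.size, 1)
    s2 = float(np.sum(sol.fun ** 2)) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se_log_ka = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_log_ka = np.nan
    if np.isfinite(se_log_ka):
        tq = float(t_dist.ppf(0.975, dof))
        ci = (float(np.exp(-(log_ka + tq * se_log_ka))),
              float(np.exp(-(log_ka - tq * se_log_ka))))
    else:
        ci = (float("nan"), float("nan"))
    c_value = n_fit * Ka * M0
    if not (1.0 <= c_value <= 1000.0):
        warnings.warn(f"c-value {c_value:.3g} outside the reliable [1, 1000] window",
                      stacklevel=2)
    dG, TdS = decompose_thermo(K_d, float(dH_fit), geom.temperature)
    return ITCFit(n=float(n_fit), K_d=K_d, dH=float(dH_fit), dG=float(dG),
                  TdS=float(TdS), dilution_offset=offset,
                  residual_norm=float(np.linalg.norm(sol.fun)),
                  c_value=float(c_value), K_d_ci95=ci)


# ---------------------------------------------------------------------------
# differential scanning calorimetry
# ---------------------------------------------------------------------------

def dsc_model_cp(transitions, T: np.ndarray, baseline=(0.0, 0.0)) -> np.ndarray:
    """Excess heat capacity (kcal mol^-1 K^-1) of independent two-state peaks.

    Each transition contributes dH_cal * (dH_vH / (R T^2)) * K/(1+K)^2 with
    K = exp[(dH_vH/R)(1/T_m - 1/T)], so at T = T_m (K = 1) the peak height is
    dH_cal dH_vH / (4 R T_m^2).  A linear baseline a + b(T - T_mean) is added.
    """
    T = np.asarray(T, dtype=float)
    a, b = baseline
    cp = a + b * (T - T.mean())
    for tr in transitions:
        K = np.exp((tr.dH_vH / R_KCAL) * (1.0 / tr.T_m - 1.0 / T))
        cp = cp + tr.dH_cal * (tr.dH_vH / (R_KCAL * T ** 2)) * K / (1.0 + K) ** 2
    return cp


def _initial_peaks(thermogram: Thermogram, n: int):
    """Candidate (T_m, height) pairs from local maxima of the smoothed trace."""
    cp = thermogram.excess_cp
    T = thermogram.temperature
    window = min(11, (len(cp) // 2) * 2 - 1)
    smooth = savgol_filter(cp, window, 3) if window >= 5 else cp
    interior = np.arange(1, len(cp) - 1)
    is_max = (smooth[interior] > smooth[interior - 1]) & (smooth[interior] >= smooth[interior + 1])
    peaks = interior[is_max]
    if len(peaks) < n:
        raise ValueError(
            f"only {len(peaks)} local maxima detected; try n_transitions <= {max(len(peaks), 1)}"
        )
    order = np.argsort(smooth[peaks])[::-1][:n]
    chosen = np.sort(peaks[order])
    return [(float(T[i]), float(smooth[i])) for i in chosen]


def fit_dsc(thermogram: Thermogram, n_transitions: int = 2) -> DSCFit:
    """Deconvolve a thermogram into ``n_transitions`` non-two-state peaks.

    Nonlinear least squares of `dsc_model_cp` plus a linear baseline,
    initialised from the highest local maxima of the smoothed signal.
    Fitted transitions are returned sorted by T_m.
    """
    if n_transitions < 1:
        raise ValueError("n_transitions must be >= 1")
    T = thermogram.temperature
    cp = thermogram.excess_cp
    peaks = _initial_peaks(thermogram, n_transitions)

    # parameters per transition: (T_m, dH_cal, dH_vH); then baseline (a, b)
    x0 = []
    for T_m, height in peaks:
        dH_vH0 = 100.0
        dH_cal0 = max(height, 1e-6) * 4.0 * R_KCAL * T_m ** 2 / dH_vH0
        x0.extend([T_m, dH_cal0, dH_vH0])
    x0.extend([float(np.percentile(cp, 5)), 0.0])
    x0 = np.array(x0)

    def unpack(p):
        trs = []
        for i in range(n_transitions):
            T_m, dH_cal, dH_vH = p[3 * i: 3 * i + 3]
            trs.append((T_m, abs(dH_cal) + 1e-12, abs(dH_vH) + 1e-12))
        return trs, (p[-2], p[-1])

    def residual(p):
        trs, base = unpack(p)
        model = base[0] + base[1] * (T - T.mean())
        for T_m, dH_cal, dH_vH in trs:
            K = np.exp(np.clip((dH_vH / R_KCAL) * (1.0 / T_m - 1.0 / T), -500, 500))
            model = model + dH_cal * (dH_vH / (R_KCAL * T ** 2)) * K / (1.0 + K) ** 2
        return model - cp

    sol = least_squares(residual, x0, method="lm", max_nfev=40000)
    trs, base = unpack(sol.x)
    transitions = tuple(
        DSCTransition(T_m=float(tm), dH_cal=float(hc), dH_vH=float(hv))
        for tm, hc, hv in sorted(trs)
    )
    for tr in transitions:
        if not (T[0] <= tr.T_m <= T[-1]):
            raise ValueError(f"fitted T_m {tr.T_m:.2f} K outside the data range")
    return DSCFit(transitions=transitions, baseline=(float(base[0]), float(base[1])),
                  residual_norm=float(np.linalg.norm(sol.fun)))


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def four_param_logistic(conc: np.ndarray, ic50: float, hill: float,
                        top: float, bottom: float) -> np.ndarray:
    """4PL inhibition curve: bottom + (top - bottom) / (1 + (c/ic50)^hill)."""
    c = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def _fit_4pl_core(log_c: np.ndarray, activity: np.ndarray) -> np.ndarray:
    top0 = float(activity.max())
    bot0 = float(activity.min())
    mid = (top0 + bot0) / 2.0
    log_ic50_0 = float(log_c[np.argmin(np.abs(activity - mid))])

    def residual(p):
        log_ic50, hill, top, bottom = p
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_c - log_ic50))) - activity

    sol = least_squares(residual, np.array([log_ic50_0, 1.0, top0, bot0]),
                        method="lm", max_nfev=10000)
    return sol.x


def fit_ic50(dr: DoseResponse, n_boot: int = 1000, seed: int = 0) -> IC50Fit:
    """4PL fit on log10 concentration with a residual-bootstrap 95% CI.

    Bootstrap: refit on fitted values plus resampled residuals ``n_boot``
    times, with residuals inflated by sqrt(n/(n-p)) to restore the degrees
    of freedom absorbed by the fit; the CI is the basic (reflected)
    bootstrap interval on the log10-IC50 scale, which corrects first-order
    estimator bias that the raw percentile interval ignores.
    """
    if dr.conc.size < 6:
        raise ValueError("need at least 6 concentrations spanning the inflection")
    span = float(dr.activity.max() - dr.activity.min())
    if span < 1e-12 * max(1.0, abs(float(dr.activity.mean()))):
        raise ValueError("activity is constant: no inflection to fit")
    log_c = np.log10(dr.conc)
    p = _fit_4pl_core(log_c, dr.activity)
    log_ic50, hill, top, bottom = p
    fitted = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_c - log_ic50)))
    resid = dr.activity - fitted
    # raw residuals understate the noise by the lost degrees of freedom
    n_pts = resid.size
    resid = resid * np.sqrt(n_pts / max(n_pts - 4, 1))

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        y = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            pb = _fit_4pl_core(log_c, y)
        except Exception:
            continue
        boot.append(pb[0])
    if boot:
        q_lo, q_hi = np.percentile(boot, [2.5, 97.5])
        lo, hi = 2 * log_ic50 - q_hi, 2 * log_ic50 - q_lo
        ci = (float(10.0 ** lo), float(10.0 ** hi))
    else:
        ci = (float(10.0 ** log_ic50), float(10.0 ** log_ic50))
    ic50 = float(10.0 ** log_ic50)
    ci = (min(ci[0], ic50), max(ci[1], ic50))  # CI always brackets the point estimate
    return IC50Fit(ic50=ic50, hill=float(hill), top=float(top),
                   bottom=float(bottom), ci95=ci, n_boot=n_boot)
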