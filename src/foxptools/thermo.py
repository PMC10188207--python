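"""Equilibrium binding and chemical-unfolding thermodynamics.

Binding follows the hyperbolic two-state isotherm

    r_obs = offset + r_max * [P] / (Kd + [P])

with an exact monomer-dimer (quadratic) isotherm available as an alternative
model.  Unfolding follows the linear extrapolation model

    dG_U(D) = dG_H2O + m * D        (m signed; destabilization => m < 0)

with four mechanisms:

    mono2   N = U
    mono3   N = I = U
    dimer2  N2 = 2U
    dimer3  N2 = 2I = U

Dimer equilibrium constants are expressed in total-monomer concentration
units: for N2 = 2U, K_U = 2*P_t*f_U^2/f_N with P_t the total protein in
monomer units, so the native fraction at a given denaturant concentration is
the positive root of a quadratic in f_U (or f_I for the three-state dimer).
The observed signal is the fraction-weighted sum of per-state signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .constants import NM_TO_M, R_KCAL, T_UNFOLDING_K
from .curves import TitrationCurve, UnfoldingCurve

MECHANISMS = ("mono2", "mono3", "dimer2", "dimer3")

_N_TRANSITIONS = {"mono2": 1, "mono3": 2, "dimer2": 1, "dimer3": 2}
_N_STATES = {"mono2": 2, "mono3": 3, "dimer2": 2, "dimer3": 3}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BindingModel:
    """Two-state binding isotherm parameters (Kd in nM)."""

    kd_nm: float
    r_max: float
    signal_offset: float = 0.0

    def __post_init__(self):
        if self.kd_nm <= 0:
            raise ValueError("kd_nm must be positive")


@dataclass
class UnfoldingMechanism:
    """Unfolding mechanism with one (dG0, m) pair per transition.

    ``state_signals`` lists the intrinsic signal of each state in unfolding
    order (N, [I,] U).  ``baseline_slopes``, when given, adds a linear
    denaturant dependence to each state signal (off by default; signals are
    normally normalized to the folded state).
    """

    kind: str
    transitions: list[tuple[float, float]]
    p_total_nm: float | None = None
    state_signals: tuple[float, ...] | None = None
    baseline_slopes: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.kind!r}")
        if len(self.transitions) != _N_TRANSITIONS[self.kind]:
            raise ValueError(
                f"{self.kind} requires {_N_TRANSITIONS[self.kind]} "
                f"(dG0, m) pairs, got {len(self.transitions)}"
            )
        if self.kind.startswith("dimer"):
            if not self.p_total_nm or self.p_total_nm <= 0:
                raise ValueError("dimer mechanisms require p_total_nm > 0")
        if self.state_signals is not None:
            if len(self.state_signals) != _N_STATES[self.kind]:
                raise ValueError(
                    f"{self.kind} requires {_N_STATES[self.kind]} state signals"
                )


@dataclass
class StateFractions:
    """Native / intermediate / unfolded populations along a denaturant axis."""

    f_n: np.ndarray
    f_i: np.ndarray
    f_u: np.ndarray

    def __post_init__(self):
        total = self.f_n + self.f_i + self.f_u
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("state fractions must sum to 1")


@dataclass
class ThermoFit:
    """Fit result with point estimates, uncertainties and diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float]
    residuals: np.ndarray
    redchi: float
    model: str
    covar: np.ndarray | None = None
    var_names: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)
    bootstrap: dict[str, np.ndarray] | None = None

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def se(self, name: str) -> float:
        return self.stderr.get(name, np.nan)

    def summary(self) -> str:
        lines = [f"model: {self.model}"]
        for name, value in self.params.items():
            se = self.stderr.get(name)
            se_txt = f" +/- {se:.4g}" if se is not None and np.isfinite(se) else ""
            lines.append(f"  {name} = {value:.6g}{se_txt}")
        lines.append(f"  reduced chi-square = {self.redchi:.4g}")
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "stderr": self.stderr,
            "redchi": self.redchi,
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# binding
# ---------------------------------------------------------------------------

def binding_signal(p_nm, model: BindingModel):
    """Hyperbolic two-state binding signal at total protein ``p_nm``."""
    p = np.asarray(p_nm, dtype=float)
    if np.any(p < 0):
        raise ValueError("protein concentration must be non-negative")
    return model.signal_offset + model.r_max * p / (model.kd_nm + p)


def dimer_fraction_exact(p_nm, kd_nm):
    """Exact monomer-dimer mass-action dimer fraction at total monomer p_nm.

    Solves Kd = [M]^2/[D2] with conservation [M] + 2[D2] = P; f is the
    fraction of monomer units in the dimer.
    """
    p = np.asarray(p_nm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = 2.0 * p + kd_nm / 2.0
        f = np.where(
            p > 0,
            (b - np.sqrt(np.maximum(b * b - 4.0 * p * p, 0.0))) / (2.0 * p),
            0.0,
        )
    return f


def _binding_curve(p, kd, r_max, offset, model="hyperbolic"):
    if model == "hyperbolic":
        return offset + r_max * p / (kd + p)
    if model == "quadratic":
        return offset + r_max * dimer_fraction_exact(p, kd)
    raise ValueError(f"unknown binding model {model!r}")


def fit_binding(
    curve: TitrationCurve,
    model: str = "hyperbolic",
    n_starts: int = 5,
    seed: int = 0,
) -> ThermoFit:
    """Fit a titration curve; returns Kd (nM), amplitude and offset with SEs.

    ``model='hyperbolic'`` treats [P] as the total protein, exactly as the
    two-state isotherm does; ``model='quadratic'`` uses the exact
    monomer-dimer mass-action isotherm and is labeled as such in the output.
    """
    x, y = curve.conc_nm, curve.signal
    if len(curve) < 5:
        raise ValueError("need at least 5 titration points")
    span = float(y.max() - y.min())
    offset0 = float(y[np.argmin(x)])
    half = offset0 + 0.5 * (float(y[np.argmax(x)]) - offset0)
    order = np.argsort(x)
    kd0 = float(np.interp(half, y[order], x[order]))
    kd0 = min(max(kd0, 1e-2), float(x.max()) or 1.0)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        params = lmfit.Parameters()
        jitter = 1.0 if start == 0 else float(rng.lognormal(0.0, 0.5))
        params.add("kd", value=kd0 * jitter, min=1e-4, max=1e7)
        params.add("r_max", value=(span or 1e-3) * (1 if start == 0 else jitter))
        params.add("offset", value=offset0)

        def _resid(pars):
            return _binding_curve(
                x, pars["kd"].value, pars["r_max"].value, pars["offset"].value, model
            ) - y

        try:
            result = lmfit.minimize(_resid, params, method="leastsq")
        except Exception:
            continue
        if best is None or result.chisqr < best.chisqr:
            best = result
    if best is None:
        raise RuntimeError("binding fit failed to converge from any start")

    params = {name: float(best.params[name].value) for name in best.params}
    stderr = {
        name: float(best.params[name].stderr)
        if best.params[name].stderr is not None
        else np.nan
        for name in best.params
    }
    flags = []
    if not best.success:
        flags.append("non_convergence")
    kd, kd_se = params["kd"], stderr["kd"]
    if not np.isfinite(kd_se) or kd_se > kd:
        flags.append("non_informative")
    if kd < 1e-3 or kd > 0.99e7:
        flags.append("kd_at_bounds")

    fitted = _binding_curve(x, params["kd"], params["r_max"], params["offset"], model)
    with np.errstate(divide="ignore", invalid="ignore"):
        dimer_frac = np.clip((y - params["offset"]) / params["r_max"], -0.5, 1.5)
    return ThermoFit(
        params=params,
        stderr=stderr,
        residuals=np.asarray(best.residual),
        redchi=float(best.redchi),
        model=f"binding-{model}",
        covar=getattr(best, "covar", None),
        var_names=list(best.var_names),
        flags=flags,
        extras={"fitted": fitted, "dimer_fraction": dimer_frac},
    )


# ---------------------------------------------------------------------------
# unfolding
# ---------------------------------------------------------------------------

def delta_g(dg0: float, m: float, d) -> np.ndarray | float:
    """Linear extrapolation free energy dG0 + m*D (kcal/mol, m signed)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("denaturant concentration must be non-negative")
    out = dg0 + m * d
    return float(out) if out.ndim == 0 else out


def _equilibrium_constants(mech: UnfoldingMechanism, d, temperature_k):
    rt = R_KCAL * temperature_k
    return [np.exp(-delta_g(dg0, m, d) / rt) for dg0, m in mech.transitions]


def fractions(
    mech: UnfoldingMechanism, d, temperature_k: float = T_UNFOLDING_K
) -> StateFractions:
    """State populations at denaturant concentration(s) ``d`` (molar).

    Monomer mechanisms are closed-form in the equilibrium constants; dimer
    mechanisms solve the mass-conservation quadratic in total-monomer units
    (numerically stable root form).
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    ks = _equilibrium_constants(mech, d, temperature_k)
    zeros = np.zeros_like(d)

    if mech.kind == "mono2":
        k1 = ks[0]
        f_n = 1.0 / (1.0 + k1)
        return StateFractions(f_n=f_n, f_i=zeros, f_u=1.0 - f_n)

    if mech.kind == "mono3":
        k1, k2 = ks
        denom = 1.0 + k1 + k1 * k2
        f_n = 1.0 / denom
        f_i = k1 / denom
        return StateFractions(f_n=f_n, f_i=f_i, f_u=1.0 - f_n - f_i)

    p_total = mech.p_total_nm * NM_TO_M
    if mech.kind == "dimer2":
        # 2*Pt*fU^2 + K*fU - K = 0; both roots in cancellation-free form
        k_u = ks[0]
        x = 8.0 * p_total / k_u
        s = np.sqrt(1.0 + x)
        f_u = 2.0 / (1.0 + s)
        f_n = x / (1.0 + s) ** 2  # (s-1)/(s+1) via s^2-1 = x, no cancellation
        return StateFractions(f_n=f_n, f_i=zeros, f_u=f_u)

    # dimer3: (2*Pt/K1)*fI^2 + (1+K2)*fI - 1 = 0
    k1, k2 = ks
    a = 2.0 * p_total / k1
    b = 1.0 + k2
    s = np.sqrt(b * b + 4.0 * a)
    f_i = 2.0 / (b + s)
    f_u = k2 * f_i
    f_n = 4.0 * a / (s + b) ** 2  # = (s-b)/(s+b) via s^2-b^2 = 4a
    return StateFractions(f_n=f_n, f_i=f_i, f_u=f_u)


def observed_signal(
    mech: UnfoldingMechanism, d, temperature_k: float = T_UNFOLDING_K
):
    """Fraction-weighted observable along the denaturant axis."""
    if mech.state_signals is None:
        raise ValueError("mechanism has no state_signals")
    d = np.atleast_1d(np.asarray(d, dtype=float))
    fr = fractions(mech, d, temperature_k)
    signals = list(mech.state_signals)
    if mech.baseline_slopes is not None:
        signals = [s + k * d for s, k in zip(signals, mech.baseline_slopes)]
    if abs(float(np.mean(np.atleast_1d(signals[0])))
           - float(np.mean(np.atleast_1d(signals[-1])))) < 1e-12:
        warnings.warn(
            "native and unfolded signals are equal: curve is flat and the "
            "stability is unidentifiable",
            stacklevel=2,
        )
    if len(signals) == 2:
        return signals[0] * fr.f_n + signals[1] * fr.f_u
    return signals[0] * fr.f_n + signals[1] * fr.f_i + signals[2] * fr.f_u


def _midpoint_guess(x, y_norm, level):
    """First denaturant concentration where the normalized signal crosses level."""
    below = np.nonzero(y_norm <= level)[0]
    if below.size == 0:
        return float(x[-1])
    j = below[0]
    if j == 0:
        return float(x[0]) or float(x[1]) / 2
    x0, x1 = x[j - 1], x[j]
    y0, y1 = y_norm[j - 1], y_norm[j]
    if y1 == y0:
        return float(x1)
    return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))


def _initial_unfolding_params(curve, kind, temperature_k):
    x, y = curve.denaturant_m, curve.signal
    rt = R_KCAL * temperature_k
    s_n, s_u = float(y[0]), float(y[-1])
    span = s_u - s_n
    y_norm = (y - s_u) / (s_n - s_u) if span != 0 else np.ones_like(y)

    # offset of the standard-state term for dimer dissociation steps
    if kind.startswith("dimer"):
        p_total = curve.p_total_nm * NM_TO_M
        dg_offset = -rt * np.log(p_total)
    else:
        dg_offset = 0.0

    m0 = -4.0 if kind.startswith("dimer") else -1.5
    if kind in ("mono2", "dimer2"):
        d_half = _midpoint_guess(x, y_norm, 0.5)
        dg0 = dg_offset - m0 * d_half
        return {"dg1": max(dg0, 1.0), "m1": m0, "s_n": s_n, "s_u": s_u}

    d1 = _midpoint_guess(x, y_norm, 0.75)
    d2 = _midpoint_guess(x, y_norm, 0.25)
    if d2 <= d1:
        d2 = d1 + max(0.5, 0.2 * float(x[-1] - x[0]))
    s_i = float(np.interp((d1 + d2) / 2.0, x, y))
    m2 = -1.5
    dg1 = dg_offset - m0 * d1
    dg2 = -m2 * d2
    return {
        "dg1": max(dg1, 1.0),
        "m1": m0,
        "dg2": max(dg2, 0.5),
        "m2": m2,
        "s_n": s_n,
        "s_i": s_i,
        "s_u": s_u,
    }


def _mech_from_params(pars, kind, p_total_nm):
    vals = {k: pars[k].value if hasattr(pars[k], "value") else pars[k] for k in pars}
    if kind in ("mono2", "dimer2"):
        transitions = [(vals["dg1"], vals["m1"])]
        signals = (vals["s_n"], vals["s_u"])
    else:
        transitions = [(vals["dg1"], vals["m1"]), (vals["dg2"], vals["m2"])]
        signals = (vals["s_n"], vals["s_i"], vals["s_u"])
    return UnfoldingMechanism(
        kind=kind,
        transitions=transitions,
        p_total_nm=p_total_nm,
        state_signals=signals,
    )


def _n_params_at_bounds(result) -> int:
    n = 0
    for par in result.params.values():
        if not par.vary:
            continue
        scale = max(abs(par.value), 1.0)
        if par.min is not None and np.isfinite(par.min):
            if par.value - par.min < 0.01 * scale:
                n += 1
                continue
        if par.max is not None and np.isfinite(par.max):
            if par.max - par.value < 0.01 * scale:
                n += 1
    return n


def fit_unfolding(
    curve: UnfoldingCurve,
    mech_kind: str | None = None,
    temperature_k: float = T_UNFOLDING_K,
    n_starts: int = 5,
    n_boot: int = 0,
    seed: int = 0,
    fix_baselines: bool = False,
    m_bounds: tuple[float, float] = (-10.0, -0.02),
) -> ThermoFit:
    """Fit an unfolding curve under the requested mechanism.

    Returns dG0 and m per transition plus the state signals, with standard
    errors from the linearized covariance; three-state fits also report the
    summed stability (``total_dg``) with its propagated SE.  An optional
    residual bootstrap refines the uncertainties.

    ``fix_baselines`` pins the native and unfolded signals to the first and
    last data points — appropriate for curves already normalized to folded
    fraction, where it removes the baseline/stability degeneracy that makes
    overlapping three-state transitions unidentifiable.  Three-state fits
    start from several structured splits of an effective two-state prefit in
    addition to the jittered heuristic starts; among starts whose residuals
    are statistically indistinguishable, interior solutions are preferred
    over ones pinned at parameter bounds (a bound-pinned transition signals
    a flat likelihood direction, not information).
    """
    kind = mech_kind or curve.mechanism
    if kind not in MECHANISMS:
        raise ValueError(f"unknown mechanism {kind!r}")
    if kind.startswith("dimer") and not curve.p_total_nm:
        raise ValueError("p_total_nm required for dimer mechanisms")
    x, y = curve.denaturant_m, curve.signal
    init = _initial_unfolding_params(curve, kind, temperature_k)
    rng = np.random.default_rng(seed)
    span = abs(float(y.max() - y.min())) or 1.0

    def _resid_factory(kind):
        def _resid(pars):
            mech = _mech_from_params(pars, kind, curve.p_total_nm)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return observed_signal(mech, x, temperature_k) - y
        return _resid

    _resid = _resid_factory(kind)

    inits = [init]
    three_state = kind in ("mono3", "dimer3")
    if three_state:
        # structured starts: split an effective two-state prefit
        try:
            two_kind = "mono2" if kind == "mono3" else "dimer2"
            prefit = fit_unfolding(
                curve, two_kind, temperature_k, n_starts=2,
                fix_baselines=fix_baselines, m_bounds=m_bounds,
            )
            dg_eff, m_eff = prefit["dg1"], prefit["m1"]
            s_n, s_u = prefit["s_n"], prefit["s_u"]
            for frac in (0.4, 0.5, 0.6):
                for si_frac in (0.3, 0.5, 0.8):
                    inits.append(
                        {
                            "dg1": max(frac * dg_eff * 1.2, 0.3),
                            "m1": m_eff / 2.0,
                            "dg2": max((1.0 - frac) * dg_eff * 1.2, 0.3),
                            "m2": m_eff / 2.0,
                            "s_n": s_n,
                            "s_i": s_u + si_frac * (s_n - s_u),
                            "s_u": s_u,
                        }
                    )
        except (RuntimeError, ValueError):
            pass

    candidates = []
    for start in range(max(1, n_starts) + len(inits) - 1):
        base = inits[start] if start < len(inits) else inits[0]
        jitter = start >= len(inits)
        params = lmfit.Parameters()
        for name, value in base.items():
            jit = float(rng.lognormal(0.0, 0.3)) if jitter else 1.0
            if name.startswith("dg"):
                params.add(name, value=min(value * jit, 39.0), min=0.05, max=40.0)
            elif name.startswith("m"):
                mval = min(max(value * jit, m_bounds[0] + 0.05), m_bounds[1])
                params.add(name, value=mval, min=m_bounds[0], max=m_bounds[1])
            elif name == "s_i" and fix_baselines:
                # for normalized curves the intermediate signal must lie
                # between the pinned baselines; degenerate solutions that
                # hide a transition park s_i on a baseline and are then
                # deprioritized by the at-bounds tie-break
                lo = min(base["s_n"], base["s_u"])
                hi = max(base["s_n"], base["s_u"])
                params.add(name, value=min(max(value, lo), hi), min=lo, max=hi)
            else:
                shift = float(rng.normal(0.0, 0.05 * span)) if jitter else 0.0
                vary = not (fix_baselines and name in ("s_n", "s_u"))
                params.add(name, value=value + shift if vary else value,
                           vary=vary)
        try:
            candidates.append(lmfit.minimize(_resid, params, method="leastsq"))
        except Exception:
            continue
    if not candidates:
        raise RuntimeError("unfolding fit failed to converge from any start")
    chi_min = min(c.chisqr for c in candidates)
    # two starts are statistically tied when their residual ratio is within
    # the F-distribution 95% band for this dof; flat (bound-pinned)
    # directions then lose to interior optima
    dof = max(x.size - candidates[0].nvarys, 1)
    tie_ratio = float(stats.f.ppf(0.95, dof, dof))
    tied = [c for c in candidates if c.chisqr <= chi_min * tie_ratio + 1e-300]
    tied.sort(key=lambda c: (_n_params_at_bounds(c), c.chisqr))
    best = tied[0]

    params = {name: float(best.params[name].value) for name in best.params}
    stderr = {
        name: float(best.params[name].stderr)
        if best.params[name].stderr is not None
        else np.nan
        for name in best.params
    }
    flags = []
    if not best.success:
        flags.append("non_convergence")
    covar = getattr(best, "covar", None)
    if covar is not None:
        sd = np.sqrt(np.diag(covar))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = covar / np.outer(sd, sd)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        if off.size and np.nanmax(np.abs(off)) > 0.99:
            flags.append("high_parameter_correlation")

    extras = {"abs_m1": abs(params["m1"])}
    if "m2" in params:
        extras["abs_m2"] = abs(params["m2"])
    if "dg2" in params:
        total = params["dg1"] + params["dg2"]
        var = np.nan
        if covar is not None:
            names = list(best.var_names)
            try:
                i, j = names.index("dg1"), names.index("dg2")
                var = covar[i, i] + covar[j, j] + 2.0 * covar[i, j]
            except ValueError:
                pass
        extras["total_dg"] = total
        extras["total_dg_se"] = float(np.sqrt(var)) if np.isfinite(var) else np.nan

    boot = None
    if n_boot > 0:
        mech = _mech_from_params(best.params, kind, curve.p_total_nm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = observed_signal(mech, x, temperature_k)
        resid = y - fitted
        samples = {name: [] for name in params}
        for _ in range(n_boot):
            y_b = fitted + rng.choice(resid, size=resid.size, replace=True)
            curve_b = UnfoldingCurve(
                denaturant_m=x, signal=y_b, mechanism=kind,
                p_total_nm=curve.p_total_nm,
            )
            try:
                fit_b = fit_unfolding(
                    curve_b, kind, temperature_k, n_starts=1, seed=0,
                    fix_baselines=fix_baselines, m_bounds=m_bounds,
                )
            except RuntimeError:
                continue
            for name in samples:
                samples[name].append(fit_b.params[name])
        boot = {name: np.asarray(v) for name, v in samples.items()}

    mech = _mech_from_params(best.params, kind, curve.p_total_nm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        extras["fitted"] = observed_signal(mech, x, temperature_k)
        extras["fractions"] = fractions(mech, x, temperature_k)
    return ThermoFit(
        params=params,
        stderr=stderr,
        residuals=np.asarray(best.residual),
        redchi=float(best.redchi),
        model=f"unfolding-{kind}",
        covar=covar,
        var_names=list(best.var_names),
        flags=flags,
        extras=extras,
        bootstrap=boot,
    )


def total_stability_profile(
    curve: UnfoldingCurve,
    mech_kind: str | None = None,
    temperature_k: float = T_UNFOLDING_K,
    totals=None,
    n_starts_per_total: int = 2,
    tie_ratio: float = 1.10,
    m_total_max: float = 4.0,
) -> ThermoFit:
    """Profile-likelihood estimate of the summed stability of a 3-state fit.

    When the two transitions of a three-state mechanism overlap, the free
    (unconstrained) fit has a nearly flat likelihood ridge toward large total
    stabilities: a transition can sharpen without limit (dG0 and |m| growing
    together at fixed midpoint) until it hides between data points, or hide
    behind a baseline, and its dG0 drifts without penalty.  The total
    dG0 = dG1 + dG2 is then better characterized by its likelihood profile:
    the residual sum of squares is minimized over all remaining parameters at
    each fixed total, and the estimate is the smallest-total local optimum
    statistically tied with the global one (the high-total ridge carries no
    information).  Baselines are pinned to the curve endpoints, appropriate
    for folded-fraction-normalized data.

    Because the total m-value scales with the buried surface area of the
    whole molecule and the two transitions partition it, the fit
    parameterizes (m_total, split fraction) and bounds |m1| + |m2| by
    ``m_total_max`` (default 4 kcal/(mol*M), generous for small, partly
    disordered helical constructs).  Raise it for large or dimeric systems.

    The 1-sigma uncertainty is read off where the profile crosses
    chi2_min + s2 (s2 the residual variance), following the standard
    profile-likelihood construction.
    """
    kind = mech_kind or curve.mechanism
    if kind not in ("mono3", "dimer3"):
        raise ValueError("total-stability profiling applies to 3-state fits")
    x, y = curve.denaturant_m, curve.signal
    totals = (
        np.asarray(totals, dtype=float)
        if totals is not None
        else np.geomspace(1.4, 20.0, 16)
    )
    s_n, s_u = float(y[0]), float(y[-1])
    lo, hi = min(s_n, s_u), max(s_n, s_u)
    fracs = np.linspace(0.35, 0.65, max(n_starts_per_total, 1))

    def _chi_at(tot: float) -> float:
        best = np.inf
        for frac in fracs:
            params = lmfit.Parameters()
            params.add("dg1", value=frac * tot, min=0.05, max=tot - 0.05)
            params.add("m_tot", value=-3.0, min=-m_total_max, max=-0.04)
            params.add("fm", value=0.5, min=0.02, max=0.98)
            params.add("s_i", value=(lo + hi) / 2.0, min=lo, max=hi)

            def _resid(p):
                m1 = p["fm"].value * p["m_tot"].value
                m2 = p["m_tot"].value - m1
                mech = UnfoldingMechanism(
                    kind,
                    [
                        (p["dg1"].value, m1),
                        (tot - p["dg1"].value, m2),
                    ],
                    p_total_nm=curve.p_total_nm,
                    state_signals=(s_n, p["s_i"].value, s_u),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return observed_signal(mech, x, temperature_k) - y

            try:
                result = lmfit.minimize(_resid, params, method="leastsq")
            except Exception:
                continue
            best = min(best, result.chisqr)
        return best

    chis = np.array([_chi_at(t) for t in totals])
    chi_min = float(np.nanmin(chis))
    pick = int(np.nanargmin(chis))
    for k in range(totals.size):
        left = chis[k - 1] if k > 0 else np.inf
        right = chis[k + 1] if k + 1 < totals.size else np.inf
        if chis[k] <= min(left, right) and chis[k] <= tie_ratio * chi_min:
            pick = k
            break
    total = float(totals[pick])

    # 1-sigma from the chi2_min + s2 crossing around the picked optimum
    dof = max(x.size - 5, 1)
    s2 = chis[pick] / dof
    level = chis[pick] + s2
    hi_edge = totals[-1]
    for k in range(pick, totals.size):
        if chis[k] > level:
            hi_edge = np.interp(level, chis[pick:k + 1], totals[pick:k + 1])
            break
    lo_edge = totals[0]
    for k in range(pick, -1, -1):
        if chis[k] > level:
            seg = slice(k, pick + 1)
            hi_c = chis[seg][::-1]
            hi_t = totals[seg][::-1]
            lo_edge = np.interp(level, hi_c, hi_t)
            break
    se = float(max(hi_edge - total, total - lo_edge))

    return ThermoFit(
        params={"total_dg": total},
        stderr={"total_dg": se},
        residuals=np.array([]),
        redchi=float(chis[pick] / dof),
        model=f"profile-total-{kind}",
        extras={"totals": totals, "profile_chisqr": chis},
    )
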