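"""Time-resolved fluorescence decay and anisotropy analysis.

The fluorescence decay is a multi-exponential,

    F(t) = sum_i x_i exp(-t / tau_i),        sum_i x_i = 1,

convolved with the instrument response (either a measured histogram or an
analytic Gaussian, for which the reconvolution is closed-form).  Rotational
depolarization follows

    r(t) = r0 * sum_j b_j exp(-t / rho_j),   sum_j b_j = 1,

whose steady-state (Perrin) form is r_S = r0 * sum_j b_j / (1 + tau/rho_j).
Polarized decays are modeled jointly as

    F_p(t) ~ F(t) * (1 + 2 r(t)) / 3,
    F_s(t) ~ F(t) * (1 - r(t)) / (3 G),

which keeps every term a pure exponential, so Gaussian-IRF reconvolution
stays analytic.  Fits maximize the Poisson likelihood; the reduced
chi-square uses Neyman weights so nested fits can be compared with an
F-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DecayHistogram:
    """Binned photon arrival-time (microtime) histogram."""

    bin_edges: np.ndarray
    counts: np.ndarray
    channel: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts must have len(bin_edges) - 1 entries")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_microtimes(
        cls, microtimes_ns, bin_width_ns: float, t_max_ns: float, channel=""
    ) -> "DecayHistogram":
        edges = np.arange(0.0, t_max_ns + bin_width_ns / 2, bin_width_ns)
        counts, _ = np.histogram(microtimes_ns, bins=edges)
        return cls(bin_edges=edges, counts=counts.astype(float), channel=channel)

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame({"time_ns": self.centers, "counts": self.counts})
        Path(path).write_text(
            f"# channel\t{self.channel}\n# bin_width_ns\t{self.bin_width}\n"
            + frame.to_csv(sep="\t", index=False, lineterminator="\n")
        )


@dataclass
class GaussianIRF:
    """Analytic Gaussian instrument response (ns)."""

    sigma_ns: float
    mean_ns: float = 0.0


@dataclass
class LifetimeModel:
    """Multi-exponential decay: components are (x_i, tau_i ns), x sum to 1."""

    components: tuple
    irf_shift_ns: float = 0.0
    background: float = 0.0

    def __post_init__(self):
        comps = sorted(self.components, key=lambda c: -c[1])
        xs = np.array([x for x, _ in comps])
        if not np.isclose(xs.sum(), 1.0):
            raise ValueError("lifetime fractions must sum to 1")
        if any(t <= 0 for _, t in comps):
            raise ValueError("lifetimes must be positive")
        self.components = tuple(comps)

    def mean_tau_f(self) -> float:
        """Fluorescence-weighted mean lifetime sum(x*tau^2)/sum(x*tau)."""
        xs = np.array([x for x, _ in self.components])
        taus = np.array([t for _, t in self.components])
        return float(np.sum(xs * taus**2) / np.sum(xs * taus))


@dataclass
class AnisotropyModel:
    """Depolarization model: r0 and rotational components (b_j, rho_j ns)."""

    r0: float
    components: tuple
    g_factor: float = 1.0

    def __post_init__(self):
        bs = np.array([b for b, _ in self.components])
        if not np.isclose(bs.sum(), 1.0):
            raise ValueError("rotational fractions must sum to 1")
        if any(r <= 0 for _, r in self.components):
            raise ValueError("rotational correlation times must be positive")
        if abs(self.r0) > 0.4:
            raise ValueError("|r0| must be <= 0.4")

    def r_of_t(self, t_ns) -> np.ndarray:
        t = np.asarray(t_ns, dtype=float)
        out = np.zeros_like(t)
        for b, rho in self.components:
            out = out + b * np.exp(-t / rho)
        return self.r0 * out


@dataclass
class FitResult:
    """Common fit container usable in F-test model comparison."""

    params: dict[str, float]
    stderr: dict[str, float]
    chisqr: float
    redchi: float
    ndata: int
    nvarys: int
    model: str
    success: bool = True
    flags: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def dof(self) -> int:
        return self.ndata - self.nvarys

    def se(self, name: str) -> float:
        return self.stderr.get(name, np.nan)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "stderr": self.stderr,
            "chisqr": self.chisqr,
            "redchi": self.redchi,
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def _exp_gauss(t, rate, mu, sigma):
    """Convolution of exp(-rate*t)*heaviside(t) with a Gaussian IRF."""
    if sigma <= 0:
        dt = t - mu
        return np.where(dt >= 0, np.exp(-rate * np.maximum(dt, 0.0)), 0.0)
    arg = (sigma * sigma * rate - (t - mu)) / (np.sqrt(2.0) * sigma)
    # log-space to avoid overflow of exp * erfc for large rates
    log_pre = 0.5 * sigma * sigma * rate * rate - rate * (t - mu)
    return 0.5 * np.exp(log_pre + np.log(np.maximum(special.erfc(arg), 1e-300)))


def decay_model(
    t_ns,
    model: LifetimeModel,
    irf: DecayHistogram | GaussianIRF | None = None,
) -> np.ndarray:
    """Expected (relative) decay intensity on the time grid ``t_ns``.

    With a histogram IRF the convolution is discrete and the grid must match
    the IRF binning; a Gaussian IRF uses the closed-form reconvolution; no
    IRF returns the bare multi-exponential.
    """
    t = np.asarray(t_ns, dtype=float)
    if irf is None or isinstance(irf, GaussianIRF):
        mu = model.irf_shift_ns + (irf.mean_ns if irf else 0.0)
        sigma = irf.sigma_ns if irf else 0.0
        out = np.zeros_like(t)
        for x, tau in model.components:
            out = out + x * _exp_gauss(t, 1.0 / tau, mu, sigma)
        return out + model.background
    # measured-IRF branch: discrete linear convolution on the shared grid
    centers = irf.centers
    if centers.size != t.size or not np.allclose(centers, t):
        raise ValueError("time grid must match the IRF binning")
    kernel = irf.counts / irf.counts.sum()
    bare = np.zeros_like(t)
    t0 = t - t[0] + model.irf_shift_ns
    for x, tau in model.components:
        bare = bare + x * np.where(t0 >= 0, np.exp(-np.maximum(t0, 0) / tau), 0.0)
    conv = np.convolve(kernel, bare)[: t.size]
    return conv + model.background


def _neyman_chisq(counts, expected):
    return float(np.sum((counts - expected) ** 2 / np.maximum(counts, 1.0)))


def _poisson_nll(counts, expected):
    mu = np.maximum(expected, 1e-12)
    return float(np.sum(mu - counts * np.log(mu)))


def _mle_minimize(objective, p0, bounds):
    result = optimize.minimize(
        objective, p0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    # covariance from a finite-difference Hessian of the NLL
    cov = None
    try:
        h_steps = np.maximum(1e-4 * np.abs(result.x), 1e-7)
        n = result.x.size
        hess = np.zeros((n, n))
        f0 = result.fun
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h_steps[i]
                ej = np.zeros(n); ej[j] = h_steps[j]
                fpp = objective(result.x + ei + ej)
                fpm = objective(result.x + ei - ej)
                fmp = objective(result.x - ei + ej)
                fmm = objective(result.x - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                    4.0 * h_steps[i] * h_steps[j]
                )
        cov = np.linalg.inv(hess)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            cov = None
        _ = f0
    except (np.linalg.LinAlgError, ValueError):
        cov = None
    return result, cov


def fit_decay(
    hist: DecayHistogram,
    irf: DecayHistogram | GaussianIRF | None = None,
    n_components: int = 1,
    compute_se: bool = True,
) -> FitResult:
    """Poisson-MLE multi-exponential fit of a decay histogram.

    Returns lifetimes, fractions, amplitude and background with standard
    errors, the Neyman reduced chi-square, and the fluorescence-weighted
    mean lifetime ``mean_tau_f``.
    """
    if hist.total < 1000:
        raise ValueError("need >= 1000 photons for a stable decay fit")
    counts = hist.counts
    t = hist.centers
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")

    mu_irf = irf.mean_ns if isinstance(irf, GaussianIRF) else float(
        np.average(irf.centers, weights=np.maximum(irf.counts, 1e-12))
    ) if isinstance(irf, DecayHistogram) else 0.0
    tau0 = max(float(np.average(t, weights=counts)) - mu_irf, 0.3)
    amp0 = hist.total * hist.bin_width / tau0
    bg0 = max(float(np.median(counts[counts <= np.percentile(counts, 10)])), 1e-3)

    def _model(theta):
        if n_components == 1:
            amp, tau, bg = theta
            model = LifetimeModel(components=((1.0, tau),), background=0.0)
        else:
            amp, x1, tau1, tau2, bg = theta
            model = LifetimeModel(
                components=((x1, tau1), (1.0 - x1, tau2)), background=0.0
            )
        return amp * decay_model(t, model, irf) + bg

    def _objective(theta):
        return _poisson_nll(counts, _model(theta))

    if n_components == 1:
        p0 = [amp0, tau0, bg0]
        bounds = [(1e-6, None), (1e-3, 1e3), (0.0, None)]
        names = ["amplitude", "tau1", "background"]
    else:
        p0 = [amp0, 0.5, tau0 * 1.5, tau0 * 0.5, bg0]
        bounds = [(1e-6, None), (1e-3, 1.0 - 1e-3), (1e-3, 1e3), (1e-3, 1e3),
                  (0.0, None)]
        names = ["amplitude", "x1", "tau1", "tau2", "background"]

    if compute_se:
        result, cov = _mle_minimize(_objective, p0, bounds)
    else:
        result = optimize.minimize(
            _objective, p0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12},
        )
        cov = None
    params = dict(zip(names, result.x.tolist()))
    stderr = {
        name: float(np.sqrt(cov[i, i])) if cov is not None else np.nan
        for i, name in enumerate(names)
    }
    flags = [] if result.success else ["non_convergence"]

    if n_components == 2:
        # canonical order: tau1 is the longer lifetime
        if params["tau1"] < params["tau2"]:
            params["tau1"], params["tau2"] = params["tau2"], params["tau1"]
            params["x1"] = 1.0 - params["x1"]
            stderr["tau1"], stderr["tau2"] = stderr["tau2"], stderr["tau1"]
        if abs(params["tau1"] - params["tau2"]) < 0.05 * params["tau1"]:
            flags.append("tau_collapse")
        comps = ((params["x1"], params["tau1"]),
                 (1.0 - params["x1"], params["tau2"]))
    else:
        comps = ((1.0, params["tau1"]),)
    lifetime = LifetimeModel(components=comps, background=params["background"])

    expected = _model(result.x)
    chisqr = _neyman_chisq(counts, expected)
    nvarys = len(names)
    return FitResult(
        params=params,
        stderr=stderr,
        chisqr=chisqr,
        redchi=chisqr / max(counts.size - nvarys, 1),
        ndata=counts.size,
        nvarys=nvarys,
        model=f"decay-{n_components}exp",
        success=bool(result.success),
        flags=flags,
        extras={
            "mean_tau_f": lifetime.mean_tau_f(),
            "lifetime_model": lifetime,
            "fitted": expected,
        },
    )


def ftest_select(fit1: FitResult, fit2: FitResult, alpha: float = 0.05):
    """Choose between nested fits (fit2 has more parameters) by F-test.

    Returns ``(chosen_fit, p_value)``; the richer model is kept only when
    p < alpha.
    """
    if fit2.nvarys <= fit1.nvarys:
        raise ValueError("fit2 must have more free parameters than fit1")
    ddf = fit2.nvarys - fit1.nvarys
    if fit2.chisqr > fit1.chisqr:
        warnings.warn(
            "richer model fits worse than the simpler one; keeping simpler"
        )
        return fit1, 1.0
    if fit1.chisqr == fit2.chisqr:
        return fit1, 1.0
    f_stat = ((fit1.chisqr - fit2.chisqr) / ddf) / (fit2.chisqr / fit2.dof)
    p = float(stats.f.sf(f_stat, ddf, fit2.dof))
    return (fit2 if p < alpha else fit1), p


# ---------------------------------------------------------------------------
# anisotropy
# ---------------------------------------------------------------------------

def steady_state_anisotropy(fp, fs, g: float = 1.0, dialect: str = "as-printed"):
    """Steady-state anisotropy from integrated polarized intensities.

    ``as-printed`` uses r = (Fp - Fs)/(Fp + 2*G*Fs); ``conventional`` applies
    G in the numerator as well, r = (Fp - G*Fs)/(Fp + 2*G*Fs).  The two agree
    for G = 1.
    """
    fp = np.asarray(fp, dtype=float)
    fs = np.asarray(fs, dtype=float)
    denom = fp + 2.0 * g * fs
    if np.any(np.asarray(fp + fs) <= 0):
        raise ValueError("total intensity must be positive")
    if dialect == "as-printed":
        num = fp - fs
    elif dialect == "conventional":
        num = fp - g * fs
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out = num / denom
    return float(out) if out.ndim == 0 else out


def perrin_rs(model: AnisotropyModel, tau_ns):
    """Steady-state anisotropy of the model at lifetime(s) ``tau_ns``.

    Vectorized over tau, which makes it directly usable to draw iso-rho
    Perrin lines over the mean-lifetime axis of 2D burst histograms.
    """
    tau = np.asarray(tau_ns, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    out = np.zeros_like(tau)
    for b, rho in model.components:
        out = out + b / (1.0 + tau / rho)
    out = model.r0 * out
    return float(out) if out.ndim == 0 else out


def perrin_line(r0: float, rho_ns: float, tau_grid_ns) -> np.ndarray:
    """Single-rho Perrin iso-line r(tau) = r0 / (1 + tau/rho)."""
    return perrin_rs(
        AnisotropyModel(r0=r0, components=((1.0, rho_ns),)), tau_grid_ns
    )


def fit_polarized_decays(
    hist_p: DecayHistogram,
    hist_s: DecayHistogram,
    irf: GaussianIRF | None = None,
    g: float = 1.0,
    n_rho: int = 1,
    n_tau: int = 2,
    r0: float = 0.38,
    fit_r0: bool = False,
) -> FitResult:
    """Joint Poisson-MLE fit of parallel/perpendicular decay histograms.

    The decay F(t) (``n_tau`` exponentials) and the depolarization r(t)
    (``n_rho`` rotational components at fundamental anisotropy ``r0``) are
    fitted simultaneously to F_p ~ F*(1+2r)/3 and F_s ~ F*(1-r)/(3G).
    Returns the rotational fractions b_j, correlation times rho_j, the
    per-component steady-state (Perrin) anisotropies evaluated at the fitted
    fluorescence-weighted mean lifetime, and the lifetime parameters.
    """
    if hist_p.total + hist_s.total < 1e4:
        raise ValueError("need >= 1e4 pooled photons for a sub-ensemble fit")
    if hist_p.counts.size != hist_s.counts.size or not np.allclose(
        hist_p.bin_edges, hist_s.bin_edges
    ):
        raise ValueError("parallel and perpendicular binning must match")
    if n_rho not in (1, 2) or n_tau not in (1, 2):
        raise ValueError("n_rho and n_tau must be 1 or 2")
    t = hist_p.centers
    counts = np.concatenate([hist_p.counts, hist_s.counts])
    mu = irf.mean_ns if irf is not None else 0.0
    sigma = irf.sigma_ns if irf is not None else 0.0

    tot = hist_p.counts + 2.0 * g * hist_s.counts
    tau0 = max(float(np.average(t, weights=np.maximum(tot, 1e-12))) - mu, 0.5)

    # parameter vector layout (always allocate, fix unused by bounds)
    names = ["amplitude"]
    if n_tau == 2:
        names += ["x1", "tau1", "tau2"]
    else:
        names += ["tau1"]
    if n_rho == 2:
        names += ["b1", "rho1", "rho2"]
    else:
        names += ["rho1"]
    if fit_r0:
        names += ["r0"]
    names += ["bg_p", "bg_s"]

    def _unpack(theta):
        vals = dict(zip(names, theta))
        if n_tau == 2:
            comps = ((vals["x1"], vals["tau1"]), (1.0 - vals["x1"], vals["tau2"]))
        else:
            comps = ((1.0, vals["tau1"]),)
        if n_rho == 2:
            rots = ((vals["b1"], vals["rho1"]), (1.0 - vals["b1"], vals["rho2"]))
        else:
            rots = ((1.0, vals["rho1"]),)
        return vals, comps, rots, vals.get("r0", r0)

    def _model(theta):
        vals, comps, rots, r0v = _unpack(theta)
        iso = np.zeros_like(t)
        aniso = np.zeros_like(t)
        for x, tau in comps:
            iso = iso + x * _exp_gauss(t, 1.0 / tau, mu, sigma)
            for b, rho in rots:
                aniso = aniso + x * b * _exp_gauss(
                    t, 1.0 / tau + 1.0 / rho, mu, sigma
                )
        amp = vals["amplitude"]
        model_p = amp * (iso + 2.0 * r0v * aniso) / 3.0 + vals["bg_p"]
        model_s = amp * (iso - r0v * aniso) / (3.0 * g) + vals["bg_s"]
        return np.concatenate([model_p, model_s])

    def _objective(theta):
        return _poisson_nll(counts, _model(theta))

    amp0 = float(tot.sum()) * hist_p.bin_width / tau0
    bg0 = max(float(np.percentile(hist_p.counts, 5)), 1e-3)
    p0 = [amp0]
    bounds = [(1e-9, None)]
    if n_tau == 2:
        p0 += [0.7, tau0 * 1.2, tau0 * 0.4]
        bounds += [(1e-3, 1 - 1e-3), (0.05, 500.0), (0.05, 500.0)]
    else:
        p0 += [tau0]
        bounds += [(0.05, 500.0)]
    if n_rho == 2:
        p0 += [0.5, 0.5, 30.0]
        bounds += [(1e-3, 1 - 1e-3), (0.01, 20.0), (1.0, 5000.0)]
    else:
        p0 += [5.0]
        bounds += [(0.01, 5000.0)]
    if fit_r0:
        p0 += [r0]
        bounds += [(0.05, 0.4)]
    p0 += [bg0, bg0]
    bounds += [(0.0, None), (0.0, None)]

    result, cov = _mle_minimize(_objective, p0, bounds)
    vals, comps, rots, r0v = _unpack(result.x)
    params = dict(zip(names, result.x.tolist()))
    stderr = {
        name: float(np.sqrt(cov[i, i])) if cov is not None else np.nan
        for i, name in enumerate(names)
    }
    flags = [] if result.success else ["non_convergence"]

    # canonical rotational order: component 1 is the fast one
    if n_rho == 2 and params["rho1"] > params["rho2"]:
        params["rho1"], params["rho2"] = params["rho2"], params["rho1"]
        params["b1"] = 1.0 - params["b1"]
        stderr["rho1"], stderr["rho2"] = stderr["rho2"], stderr["rho1"]
        rots = ((params["b1"], params["rho1"]),
                (1.0 - params["b1"], params["rho2"]))

    lifetime = LifetimeModel(components=comps)
    mean_tau = lifetime.mean_tau_f()
    rho_max = params.get("rho2", params["rho1"])
    if rho_max > 50.0 * mean_tau:
        flags.append("rho_lower_bound")

    aniso_model = AnisotropyModel(r0=r0v, components=rots, g_factor=g)
    r_components = {
        f"r_state{j + 1}": r0v / (1.0 + mean_tau / rho)
        for j, (_, rho) in enumerate(rots)
    }
    expected = _model(result.x)
    chisqr = _neyman_chisq(counts, expected)
    nvarys = len(names)
    return FitResult(
        params=params,
        stderr=stderr,
        chisqr=chisqr,
        redchi=chisqr / max(counts.size - nvarys, 1),
        ndata=counts.size,
        nvarys=nvarys,
        model=f"polarized-{n_tau}tau-{n_rho}rho",
        success=bool(result.success),
        flags=flags,
        extras={
            "lifetime_model": lifetime,
            "anisotropy_model": aniso_model,
            "mean_tau_f": mean_tau,
            "rotational_fractions": tuple(b for b, _ in rots),
            **r_components,
        },
    )
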