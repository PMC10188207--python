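"""Single-molecule burst pipeline.

Bursts are found with the all-photon sliding-window criterion (a photon is
"in burst" when at least ``m`` photons fall within a time window centered on
it; contiguous in-burst runs of at least ``L`` photons become bursts).  Each
burst yields background-corrected polarized intensities and from them the
steady-state anisotropy r_G, the fast mean-microtime lifetime estimate, and
the FRET efficiency / stoichiometry pair

    E = F_A / (F_A + gamma * F_D),
    S = (gamma * F_D + F_A) / (gamma * F_D + F_A + F_A^Aex),

with acceptor-excitation photons identified PIE-style in the second half of
the microtime period.  Intensity fluctuations are autocorrelated with a
multi-tau scheme (16 linear base bins, 8 points per octave) and fitted with
the 3D-Gaussian-volume diffusion model

    G(t) = (1/N) (1+t/t_diff)^-1 (1+(w/z)^2 t/t_diff)^-1/2
           (1 - d + d exp(-t/t_pho)) + B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

from .fluortime import DecayHistogram, steady_state_anisotropy
from .photons import (  # noqa: F401  (re-exported module surface)
    CHANNEL_CODE,
    CHANNELS,
    PhotonStream,
    StreamSchemaError,
    read_stream,
    write_stream,
)

GREEN_CHANNELS = ("Dp", "Ds")
RED_CHANNELS = ("Ap", "As")


@dataclass
class Burst:
    """One detected single-molecule transit and its observables."""

    start: int
    stop: int  # exclusive
    start_ns: float
    stop_ns: float
    counts: dict = field(default_factory=dict)
    r_g: float = np.nan
    mean_tau_ns: float = np.nan
    e_fret: float = np.nan
    stoichiometry: float = np.nan

    @property
    def n_photons(self) -> int:
        return self.stop - self.start

    @property
    def duration_ms(self) -> float:
        return (self.stop_ns - self.start_ns) / 1e6


@dataclass
class CorrelationCurve:
    """Normalized intensity autocorrelation on a quasi-log lag grid."""

    lag_s: np.ndarray
    g: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("correlation values must be finite")

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame({"lag_s": self.lag_s, "G": self.g})
        Path(path).write_text(
            frame.to_csv(sep="\t", index=False, lineterminator="\n")
        )

    @classmethod
    def from_tsv(cls, path) -> "CorrelationCurve":
        frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        return cls(lag_s=frame["lag_s"].to_numpy(), g=frame["G"].to_numpy())


# ---------------------------------------------------------------------------
# burst search
# ---------------------------------------------------------------------------

def detect_bursts(
    stream: PhotonStream,
    window_photons: int = 10,
    window_ns: float = 500_000.0,
    min_photons: int = 50,
) -> list[Burst]:
    """All-photon sliding-window burst search.

    A photon is in-burst when >= ``window_photons`` photons (itself included)
    fall within ``window_ns`` centered on it; runs of in-burst photons with
    at least ``min_photons`` members become bursts.
    """
    t = stream.macrotime_ns
    if t.size == 0:
        return []
    half = window_ns / 2.0
    left = np.searchsorted(t, t - half, side="left")
    right = np.searchsorted(t, t + half, side="right")
    in_burst = (right - left) >= window_photons

    # a run also breaks across gaps wider than the window: photons that far
    # apart cannot share a sliding window, so they belong to separate bursts
    run_id = np.zeros(t.size, dtype=np.int64)
    if t.size > 1:
        breaks = (~in_burst[:-1]) | (~in_burst[1:]) | (np.diff(t) > window_ns)
        run_id[1:] = np.cumsum(breaks)

    bursts = []
    starts_list, stops_list = [], []
    if in_burst.any():
        idx = np.nonzero(in_burst)[0]
        run_edges = np.nonzero(np.diff(run_id[idx]))[0]
        starts_arr = np.concatenate([[idx[0]], idx[run_edges + 1]])
        stops_arr = np.concatenate([idx[run_edges] + 1, [idx[-1] + 1]])
        starts_list, stops_list = starts_arr.tolist(), stops_arr.tolist()
    for i0, i1 in zip(starts_list, stops_list):
        if i1 - i0 >= min_photons:
            bursts.append(
                Burst(
                    start=int(i0),
                    stop=int(i1),
                    start_ns=float(t[i0]),
                    stop_ns=float(t[i1 - 1]),
                )
            )
    return bursts


# ---------------------------------------------------------------------------
# per-burst observables
# ---------------------------------------------------------------------------

def burst_observables(
    burst: Burst,
    stream: PhotonStream,
    irf_mean_ns: float | None = None,
    g: float | None = None,
    corrections: dict | None = None,
    dialect: str = "as-printed",
) -> Burst:
    """Populate a burst with r_G, mean lifetime, E and S.

    ``corrections`` may carry ``gamma`` (detection/quantum-yield ratio),
    ``alpha`` (donor leakage), ``delta`` (direct acceptor excitation) and
    ``background_rates_hz`` per channel; defaults are gamma=1, alpha=delta=0,
    zero background.
    """
    corrections = corrections or {}
    gamma = corrections.get("gamma", 1.0)
    alpha = corrections.get("alpha", 0.0)
    delta = corrections.get("delta", 0.0)
    bg_rates = corrections.get("background_rates_hz", {})
    g = g if g is not None else stream.g_factor
    if irf_mean_ns is None:
        irf_mean_ns = float(stream.meta.get("irf_mean_ns", 0.0))
    period = stream.excitation_period_ns
    alex = bool(stream.meta.get("alex", False))
    dex_window = period / 2.0 if alex else period

    sl = slice(burst.start, burst.stop)
    channel = stream.channel[sl]
    micro = stream.microtime_ns[sl]
    duration_s = max(burst.stop_ns - burst.start_ns, 0.0) / 1e9

    raw = {}
    for label, code in CHANNEL_CODE.items():
        mask = channel == code
        if alex and label in RED_CHANNELS:
            raw[label] = int((mask & (micro < dex_window)).sum())
            raw[label + "_aex"] = int((mask & (micro >= dex_window)).sum())
        else:
            raw[label] = int(mask.sum())
    counts = {}
    for key, value in raw.items():
        base = key.replace("_aex", "")
        rate = bg_rates.get(base, 0.0)
        counts[key] = max(value - rate * duration_s, 0.0)
    burst.counts = counts

    fp, fs = counts["Dp"], counts["Ds"]
    if fp + fs > 0:
        burst.r_g = steady_state_anisotropy(fp, fs, g=g, dialect=dialect)
        green = stream.channel_mask(GREEN_CHANNELS)[sl] & (micro < dex_window)
        if green.any():
            burst.mean_tau_ns = float(micro[green].mean()) - irf_mean_ns

    f_d = fp + fs
    f_a_raw = counts["Ap"] + counts["As"]
    f_aex = counts.get("Ap_aex", 0.0) + counts.get("As_aex", 0.0)
    f_a = f_a_raw - alpha * f_d - delta * f_aex
    if f_a + gamma * f_d > 0:
        burst.e_fret = f_a / (f_a + gamma * f_d)
    if alex:
        denom = gamma * f_d + f_a + f_aex
        if denom > 0:
            burst.stoichiometry = (gamma * f_d + f_a) / denom
    return burst


def analyze_bursts(
    stream: PhotonStream,
    window_photons: int = 10,
    window_ns: float = 500_000.0,
    min_photons: int = 50,
    corrections: dict | None = None,
    dialect: str = "as-printed",
) -> list[Burst]:
    """Burst search plus per-burst observables in one call."""
    bursts = detect_bursts(stream, window_photons, window_ns, min_photons)
    return [
        burst_observables(b, stream, corrections=corrections, dialect=dialect)
        for b in bursts
    ]


def bursts_to_frame(bursts: list[Burst]) -> pd.DataFrame:
    rows = []
    for b in bursts:
        rows.append(
            {
                "start_ns": b.start_ns,
                "stop_ns": b.stop_ns,
                "n_photons": b.n_photons,
                "duration_ms": b.duration_ms,
                "r_g": b.r_g,
                "mean_tau_ns": b.mean_tau_ns,
                "E": b.e_fret,
                "S": b.stoichiometry,
            }
        )
    return pd.DataFrame(rows)


def sub_ensemble_histograms(
    stream: PhotonStream,
    bursts: list[Burst],
    bin_width_ns: float | None = None,
    channels=GREEN_CHANNELS,
) -> tuple[DecayHistogram, DecayHistogram]:
    """Pool burst photons into parallel/perpendicular decay histograms."""
    period = stream.excitation_period_ns
    alex = bool(stream.meta.get("alex", False))
    t_max = period / 2.0 if alex else period
    bw = bin_width_ns or float(stream.meta.get("microtime_resolution_ns", 0.064))
    mask = np.zeros(len(stream), dtype=bool)
    for b in bursts:
        mask[b.start : b.stop] = True
    par = mask & (stream.channel == CHANNEL_CODE[channels[0]])
    per = mask & (stream.channel == CHANNEL_CODE[channels[1]])
    hist_p = DecayHistogram.from_microtimes(
        stream.microtime_ns[par], bw, t_max, channel=channels[0]
    )
    hist_s = DecayHistogram.from_microtimes(
        stream.microtime_ns[per], bw, t_max, channel=channels[1]
    )
    return hist_p, hist_s


# ---------------------------------------------------------------------------
# 2D histograms
# ---------------------------------------------------------------------------

BURST_FIELDS = {
    "r_g": lambda b: b.r_g,
    "mean_tau": lambda b: b.mean_tau_ns,
    "E": lambda b: b.e_fret,
    "S": lambda b: b.stoichiometry,
    "duration_ms": lambda b: b.duration_ms,
    "n_photons": lambda b: float(b.n_photons),
}


def hist2d(bursts: list[Burst], x: str, y: str, bins=41, ranges=None):
    """2D frequency histogram of two burst observables plus its marginals.

    Returns ``(counts, x_edges, y_edges, x_marginal, y_marginal)``.
    """
    if not bursts:
        raise ValueError("need at least one burst")
    if x not in BURST_FIELDS or y not in BURST_FIELDS:
        raise KeyError(f"unknown burst field; choose from {sorted(BURST_FIELDS)}")
    xv = np.array([BURST_FIELDS[x](b) for b in bursts])
    yv = np.array([BURST_FIELDS[y](b) for b in bursts])
    ok = np.isfinite(xv) & np.isfinite(yv)
    counts, xe, ye = np.histogram2d(xv[ok], yv[ok], bins=bins, range=ranges)
    return counts, xe, ye, counts.sum(axis=1), counts.sum(axis=0)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _correlate_at_lags(trace: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Normalized fluctuation autocorrelation of a binned trace.

    G(k) = <I_t I_{t+k}> / (mean_left * mean_right) - 1 with the symmetric
    segment normalization that keeps the estimator unbiased for stationary
    traces.
    """
    n = trace.size
    out = np.empty(lags.size)
    for i, k in enumerate(lags):
        a = trace[: n - k]
        b = trace[k:]
        ma, mb = a.mean(), b.mean()
        if ma <= 0 or mb <= 0:
            out[i] = 0.0
            continue
        out[i] = float(np.dot(a, b) / a.size / (ma * mb) - 1.0)
    return out


def autocorrelate(
    stream: PhotonStream,
    channels=GREEN_CHANNELS,
    bin_ns: float = 1000.0,
    n_base: int = 16,
    points_per_octave: int = 8,
    max_lag_s: float | None = None,
) -> CorrelationCurve:
    """Multi-tau autocorrelation of the photon stream's binned intensity.

    Base level: ``n_base`` linear lags at ``bin_ns`` resolution; each further
    octave halves the time resolution (coarsening the trace by 2) and keeps
    ``points_per_octave`` lags, producing the usual quasi-logarithmic grid.
    """
    mask = stream.channel_mask(channels)
    times = stream.macrotime_ns[mask]
    duration = stream.duration_ns()
    if times.size < 2 or duration <= 0:
        raise ValueError("stream too short to correlate")
    n_bins = int(np.ceil(duration / bin_ns))
    trace = np.bincount(
        np.minimum((times / bin_ns).astype(np.int64), n_bins - 1),
        minlength=n_bins,
    ).astype(float)

    max_lag_ns = (max_lag_s or duration / 10.0 / 1e9) * 1e9
    lag_list, g_list = [], []
    level = 0
    current = trace
    width = bin_ns
    while True:
        if level == 0:
            lags = np.arange(1, n_base + 1)
        else:
            lags = np.arange(points_per_octave + 1, 2 * points_per_octave + 1)
        lags = lags[lags < current.size // 2]
        if lags.size == 0:
            break
        lag_ns = lags * width
        keep = lag_ns <= max_lag_ns
        if not keep.any():
            break
        g = _correlate_at_lags(current, lags[keep])
        lag_list.append(lag_ns[keep])
        g_list.append(g)
        if not keep.all():
            break
        current = (
            current[: 2 * (current.size // 2)].reshape(-1, 2).sum(axis=1)
        )
        width *= 2.0
        level += 1
        if current.size < 4 * points_per_octave:
            break
    lag_s = np.concatenate(lag_list) / 1e9
    g = np.concatenate(g_list)
    order = np.argsort(lag_s)
    lag_s, g = lag_s[order], g[order]
    uniq = np.concatenate([[True], np.diff(lag_s) > 0])
    return CorrelationCurve(
        lag_s=lag_s[uniq],
        g=g[uniq],
        meta={"bin_ns": bin_ns, "channels": list(channels)},
    )


def fcs_model(t_s, n, t_diff_s, aspect, d, t_pho_s, b):
    """3D-Gaussian confocal diffusion correlation with a photophysics term."""
    t = np.asarray(t_s, dtype=float)
    diff = (1.0 / n) / (1.0 + t / t_diff_s) / np.sqrt(
        1.0 + aspect**2 * t / t_diff_s
    )
    pho = 1.0 - d + d * np.exp(-t / np.maximum(t_pho_s, 1e-12))
    return diff * pho + b


def fit_fcs(
    curve: CorrelationCurve,
    fix_aspect: float | None = None,
    fit_photophysics: bool = True,
) -> dict:
    """Fit a correlation curve with the 3D-Gaussian diffusion model.

    Returns the parameter estimates and standard errors; ``fix_aspect``
    clamps omega/z (useful for global analysis across curves); the
    photophysics amplitude d is constrained to [0, 1).
    """
    if curve.lag_s.size < 20:
        raise ValueError("need >= 20 lag points spanning t_diff")
    g = curve.g
    amp0 = max(float(np.mean(g[:3])), 1e-3)
    half = amp0 / 2.0
    below = np.nonzero(g <= half)[0]
    td0 = float(curve.lag_s[below[0]]) if below.size else float(
        np.median(curve.lag_s)
    )

    params = lmfit.Parameters()
    params.add("n", value=1.0 / amp0, min=1e-6)
    params.add("t_diff", value=td0, min=curve.lag_s[0] / 10.0,
               max=curve.lag_s[-1] * 10.0)
    if fix_aspect is not None:
        params.add("aspect", value=fix_aspect, vary=False)
    else:
        params.add("aspect", value=0.2, min=0.0, max=1.0)
    if fit_photophysics:
        params.add("d", value=0.05, min=0.0, max=1.0 - 1e-6)
        params.add("t_pho", value=max(curve.lag_s[0] * 2, 1e-6), min=1e-9,
                   max=td0)
    else:
        params.add("d", value=0.0, vary=False)
        params.add("t_pho", value=1e-6, vary=False)
    params.add("b", value=0.0, min=-0.5, max=0.5)

    def _resid(pars):
        return (
            fcs_model(
                curve.lag_s,
                pars["n"].value,
                pars["t_diff"].value,
                pars["aspect"].value,
                pars["d"].value,
                pars["t_pho"].value,
                pars["b"].value,
            )
            - g
        )

    result = lmfit.minimize(_resid, params, method="leastsq")
    out = {name: float(result.params[name].value) for name in result.params}
    out_se = {
        name: float(result.params[name].stderr)
        if result.params[name].stderr is not None
        else np.nan
        for name in result.params
    }
    return {
        "params": out,
        "stderr": out_se,
        "redchi": float(result.redchi),
        "success": bool(result.success),
        "fitted": fcs_model(
            curve.lag_s, out["n"], out["t_diff"], out["aspect"], out["d"],
            out["t_pho"], out["b"],
        ),
    }


def fit_fcs_global(curves: list[CorrelationCurve], aspect_grid=None) -> list[dict]:
    """Global FCS analysis: share omega/z across curves, free t_diff each.

    The shared aspect ratio is profiled on a grid (default 0.05-0.5) by
    total squared residual, then each curve is refitted at the optimum.
    """
    grid = aspect_grid if aspect_grid is not None else np.linspace(0.05, 0.5, 10)
    best_aspect, best_cost = grid[0], np.inf
    for aspect in grid:
        cost = 0.0
        for curve in curves:
            fit = fit_fcs(curve, fix_aspect=float(aspect))
            cost += float(np.sum((fit["fitted"] - curve.g) ** 2))
        if cost < best_cost:
            best_aspect, best_cost = float(aspect), cost
    return [fit_fcs(curve, fix_aspect=best_aspect) for curve in curves]
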