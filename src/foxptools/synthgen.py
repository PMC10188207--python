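"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate, with the statistical structure the analysis assumes:

* hyperbolic anisotropy titrations with homoscedastic Gaussian noise;
* denaturant unfolding isotherms for all four mechanisms (the noiseless
  signal is produced by the :mod:`.thermo` fraction solver, so the generator
  and the fitter share no code path beyond the model definition itself);
* time-tagged photon streams: Poisson burst arrivals, top-hat transits whose
  duration distribution reproduces the 3D-Gaussian FCS decay, per-photon
  multi-exponential lifetimes convolved with a Gaussian IRF, polarization
  channels drawn from the time-dependent anisotropy
  r(t) = r0 * sum_i b_i exp(-t/rho_i), and uniform uncorrelated background;
* multi-basin (Rg, helicity) reaction-coordinate series from a Gaussian
  mixture, plus an ideal-geometry peptide-backbone builder for structural
  fixtures.

Identical (spec, seed) always yields byte-identical output, including photon
ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import thermo
from .constants import T_BINDING_K, T_UNFOLDING_K
from .curves import TitrationCurve, UnfoldingCurve
from .landscape import FrameCoords, ReactionCoordSeries
from .photons import CHANNEL_CODE, PhotonStream

DEFAULT_TITRATION_MAX_NM = 5000.0
DEFAULT_P_TOTAL_NM = 200.0


@dataclass
class GeneratorConfig:
    """Seed, experimental conditions and sampling grid for one generator run."""

    seed: int = 0
    construct_label: str = ""
    temperature_k: float | None = None
    noise_sd: float = 0.0
    grid: np.ndarray | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)
            if self.grid.size == 0:
                raise ValueError("grid must not be empty")
            if self.grid.size > 1 and np.any(np.diff(self.grid) <= 0):
                raise ValueError("grid must be strictly increasing")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_titration_grid(
    max_nm: float = DEFAULT_TITRATION_MAX_NM, n: int = 12
) -> np.ndarray:
    """Zero plus a log-spaced ladder up to ``max_nm`` (default 0-5000 nM)."""
    return np.concatenate([[0.0], np.geomspace(max_nm / 1000.0, max_nm, n - 1)])


def gen_titration(
    kd_nm: float,
    r_mono: float,
    r_dimer: float,
    cfg: GeneratorConfig,
) -> TitrationCurve:
    """Synthetic anisotropy titration under the two-state isotherm.

    The noiseless signal at [P] = Kd is exactly the midpoint between the
    monomer and dimer anisotropies.
    """
    if kd_nm <= 0:
        raise ValueError("kd_nm must be positive")
    grid = cfg.grid if cfg.grid is not None else default_titration_grid()
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    model = thermo.BindingModel(
        kd_nm=kd_nm, r_max=r_dimer - r_mono, signal_offset=r_mono
    )
    signal = thermo.binding_signal(grid, model)
    rng = cfg.rng()
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=grid.size)
    return TitrationCurve(
        conc_nm=grid,
        signal=signal,
        sd=np.full(grid.size, cfg.noise_sd) if cfg.noise_sd > 0 else None,
        construct=cfg.construct_label,
        temperature_k=cfg.temperature_k or T_BINDING_K,
        meta={
            "seed": cfg.seed,
            "kd_true_nM": kd_nm,
            "r_mono": r_mono,
            "r_dimer": r_dimer,
            "noise_sd": cfg.noise_sd,
        },
    )


def gen_unfolding(
    mechanism: str,
    dg0,
    m,
    baselines,
    cfg: GeneratorConfig,
    p_total_nm: float | None = DEFAULT_P_TOTAL_NM,
) -> UnfoldingCurve:
    """Synthetic denaturant unfolding curve for any of the four mechanisms.

    ``dg0`` and ``m`` are scalars (two-state) or length-2 sequences
    (three-state), in kcal/mol and kcal/(mol*M) with signed m; ``baselines``
    lists the per-state signals in unfolding order.
    """
    dg0 = np.atleast_1d(np.asarray(dg0, dtype=float))
    m_arr = np.atleast_1d(np.asarray(m, dtype=float))
    if dg0.size != m_arr.size:
        raise ValueError("dg0 and m must have one value per transition")
    mech = thermo.UnfoldingMechanism(
        kind=mechanism,
        transitions=list(zip(dg0.tolist(), m_arr.tolist())),
        p_total_nm=p_total_nm if mechanism.startswith("dimer") else None,
        state_signals=tuple(baselines),
    )
    grid = cfg.grid if cfg.grid is not None else np.linspace(0.0, 5.0, 20)
    temperature = cfg.temperature_k or T_UNFOLDING_K
    signal = thermo.observed_signal(mech, grid, temperature)
    rng = cfg.rng()
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=grid.size)
    return UnfoldingCurve(
        denaturant_m=grid,
        signal=signal,
        mechanism=mechanism,
        p_total_nm=mech.p_total_nm,
        sd=np.full(grid.size, cfg.noise_sd) if cfg.noise_sd > 0 else None,
        construct=cfg.construct_label,
        temperature_k=temperature,
        meta={
            "seed": cfg.seed,
            "dg0_true": dg0.tolist(),
            "m_true": m_arr.tolist(),
            "baselines": list(baselines),
            "noise_sd": cfg.noise_sd,
        },
    )


# ---------------------------------------------------------------------------
# photon streams
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """One diffusing species: lifetime mixture, rotational depolarization.

    ``lifetimes`` is a list of (x_i, tau_i ns) with sum(x_i) = 1;
    ``rotations`` a list of (b_i, rho_i ns) with sum(b_i) = 1.  ``fret_e``
    (when set) sends donor-excitation photons to the acceptor channel with
    that probability; ``aex_ratio`` adds acceptor-excitation photons
    (PIE-style, second half-period) in that proportion to the burst size.
    """

    fraction: float
    lifetimes: tuple = ((1.0, 4.35),)
    r0: float = 0.38
    rotations: tuple = ((1.0, 60.0),)
    fret_e: float | None = None
    aex_ratio: float = 0.0
    tau_acceptor_ns: float = 3.5

    def __post_init__(self):
        xs = np.array([x for x, _ in self.lifetimes])
        bs = np.array([b for b, _ in self.rotations])
        if not np.isclose(xs.sum(), 1.0):
            raise ValueError("lifetime fractions must sum to 1")
        if not np.isclose(bs.sum(), 1.0):
            raise ValueError("rotational fractions must sum to 1")
        if any(t <= 0 for _, t in self.lifetimes):
            raise ValueError("lifetimes must be positive")
        if any(r <= 0 for _, r in self.rotations):
            raise ValueError("rotational times must be positive")
        if abs(self.r0) > 0.4:
            raise ValueError("|r0| must be <= 0.4")

    def anisotropy_at(self, t_ns) -> np.ndarray:
        t = np.asarray(t_ns, dtype=float)
        r = np.zeros_like(t)
        for b, rho in self.rotations:
            r = r + b * np.exp(-t / rho)
        return self.r0 * r


@dataclass
class PhotonStreamSpec:
    """Acquisition-level description of a synthetic photon stream."""

    duration_s: float = 60.0
    background_rate_hz: float = 1000.0
    burst_rate_hz: float = 20.0
    molecular_brightness_hz: float = 100_000.0
    t_diff_ms: float = 1.0
    species: tuple = (SpeciesSpec(fraction=1.0),)
    irf_sigma_ns: float = 0.25
    irf_mean_ns: float = 2.0
    microtime_resolution_ns: float = 0.064
    g_factor: float = 1.0
    excitation_period_ns: float = 50.0
    aspect: float = 0.2  # omega/z of the confocal volume

    def __post_init__(self):
        fr = np.array([sp.fraction for sp in self.species])
        if not np.isclose(fr.sum(), 1.0):
            raise ValueError("species fractions must sum to 1")
        for name in (
            "duration_s", "burst_rate_hz", "molecular_brightness_hz",
            "t_diff_ms", "microtime_resolution_ns", "excitation_period_ns",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_rate_hz < 0:
            raise ValueError("background_rate_hz must be non-negative")

    @property
    def alex(self) -> bool:
        return any(sp.aex_ratio > 0 for sp in self.species)


def _transit_sampler(t_diff_ms: float, aspect: float):
    """Inverse-survival sampler of top-hat transit durations (in ms).

    The survival function is chosen so that E[(T - tau)+] is proportional to
    the 3D-Gaussian diffusion correlation curve; the burst-averaged intensity
    autocorrelation then decays exactly like the FCS model it will be fitted
    with.
    """
    td, a2 = t_diff_ms, aspect**2
    t = np.concatenate([[0.0], np.geomspace(1e-4 * td, 200.0 * td, 4000)])
    u = t / td
    g1 = 1.0 / (1.0 + u)
    g2 = 1.0 / np.sqrt(1.0 + a2 * u)
    # -g'(t) for g = g1*g2, up to the 1/td factor
    neg_dg = g1**2 * g2 + 0.5 * a2 * g1 * g2**3
    survival = neg_dg / neg_dg[0]

    def sample(rng, size):
        uu = rng.uniform(0.0, survival[0], size=size)
        return np.interp(uu, survival[::-1], t[::-1])

    return sample


def gen_photon_stream(spec: PhotonStreamSpec, cfg: GeneratorConfig) -> PhotonStream:
    """Simulate a time-tagged photon stream under ``spec``.

    Bursts arrive as a Poisson process; each burst has a top-hat intensity
    profile over a transit time drawn so the ensemble intensity ACF matches
    the 3D-Gaussian diffusion curve with decay time ``t_diff_ms``.  Photon
    microtimes follow the species' multi-exponential decay convolved with a
    Gaussian IRF; polarization channels are drawn with probabilities
    proportional to (1+2r(t))/3 and (1-r(t))/(3G); background photons are
    uniform in macro- and microtime.
    """
    rng = cfg.rng()
    duration_ns = spec.duration_s * 1e9
    period = spec.excitation_period_ns
    window = period / 2.0 if spec.alex else period

    n_bursts = int(rng.poisson(spec.burst_rate_hz * spec.duration_s))
    sample_transit = _transit_sampler(spec.t_diff_ms, spec.aspect)
    starts_ns = np.sort(rng.uniform(0.0, duration_ns, size=n_bursts))
    transits_ms = sample_transit(rng, n_bursts)
    counts = rng.poisson(spec.molecular_brightness_hz * transits_ms * 1e-3)
    fractions = np.array([sp.fraction for sp in spec.species])
    burst_species = rng.choice(len(spec.species), size=n_bursts, p=fractions)

    total = int(counts.sum())
    if total == 0 and spec.background_rate_hz == 0:
        warnings.warn("duration too short: stream contains no photons")

    burst_id = np.repeat(np.arange(n_bursts), counts)
    macro = np.repeat(starts_ns, counts) + rng.uniform(
        0.0, 1.0, size=total
    ) * np.repeat(transits_ms * 1e6, counts)
    photon_species = burst_species[burst_id] if total else np.array([], int)

    micro = np.zeros(total)
    channel = np.zeros(total, dtype=np.int8)
    keep = np.ones(total, dtype=bool)
    for s_idx, sp in enumerate(spec.species):
        mask = photon_species == s_idx
        n = int(mask.sum())
        if n == 0:
            continue
        is_aex = (
            rng.uniform(size=n) < sp.aex_ratio / (1.0 + sp.aex_ratio)
            if sp.aex_ratio > 0
            else np.zeros(n, dtype=bool)
        )
        is_acceptor = is_aex.copy()
        if sp.fret_e is not None:
            dex = ~is_aex
            sens = rng.uniform(size=n) < sp.fret_e
            is_acceptor |= dex & sens

        xs = np.array([x for x, _ in sp.lifetimes])
        taus = np.array([t for _, t in sp.lifetimes])
        comp = rng.choice(len(xs), size=n, p=xs)
        t_emit = rng.exponential(taus[comp])
        t_emit[is_acceptor] = rng.exponential(
            sp.tau_acceptor_ns, size=int(is_acceptor.sum())
        )

        # the summed p+s detection probability varies with r(t); thin the
        # emission-time draw so the joint (time, channel) law is exact
        # (Poisson statistics survive the thinning)
        r_t = sp.anisotropy_at(t_emit)
        w_p = (1.0 + 2.0 * r_t) / 3.0
        w_s = (1.0 - r_t) / (3.0 * spec.g_factor)
        w_tot = w_p + w_s
        r_lo, r_hi = min(0.0, sp.r0), max(0.0, sp.r0)
        w_max = max(
            (1.0 + 2.0 * r_lo) / 3.0 + (1.0 - r_lo) / (3.0 * spec.g_factor),
            (1.0 + 2.0 * r_hi) / 3.0 + (1.0 - r_hi) / (3.0 * spec.g_factor),
        )
        keep[mask] = rng.uniform(size=n) < w_tot / w_max
        perp = rng.uniform(size=n) < w_s / w_tot

        jitter = rng.normal(0.0, spec.irf_sigma_ns, size=n)
        m_t = np.mod(spec.irf_mean_ns + t_emit + jitter, window)
        m_t = m_t + np.where(is_aex, window, 0.0)

        code = np.where(
            is_acceptor,
            np.where(perp, CHANNEL_CODE["As"], CHANNEL_CODE["Ap"]),
            np.where(perp, CHANNEL_CODE["Ds"], CHANNEL_CODE["Dp"]),
        )
        micro[mask] = m_t
        channel[mask] = code

    macro = macro[keep]
    micro = micro[keep]
    channel = channel[keep]

    # uncorrelated background, uniform in macro- and microtime, per channel
    bg_parts = []
    for ch in range(4):
        n_bg = int(rng.poisson(spec.background_rate_hz * spec.duration_s))
        if n_bg == 0:
            continue
        bg_parts.append(
            (
                rng.uniform(0.0, duration_ns, size=n_bg),
                rng.uniform(0.0, period, size=n_bg),
                np.full(n_bg, ch, dtype=np.int8),
            )
        )
    if bg_parts:
        macro = np.concatenate([macro] + [p[0] for p in bg_parts])
        micro = np.concatenate([micro] + [p[1] for p in bg_parts])
        channel = np.concatenate([channel] + [p[2] for p in bg_parts])

    # TCSPC-style quantization: floor into the channel [k*res, (k+1)*res)
    res = spec.microtime_resolution_ns
    micro = np.minimum(np.floor(micro / res) * res, period - res)
    order = np.argsort(macro, kind="stable")
    return PhotonStream(
        macrotime_ns=macro[order],
        microtime_ns=micro[order],
        channel=channel[order],
        meta={
            "seed": cfg.seed,
            "construct": cfg.construct_label,
            "g_factor": spec.g_factor,
            "excitation_period_ns": period,
            "microtime_resolution_ns": res,
            "irf_sigma_ns": spec.irf_sigma_ns,
            "irf_mean_ns": spec.irf_mean_ns,
            "duration_ns": duration_ns,
            "t_diff_ms": spec.t_diff_ms,
            "alex": spec.alex,
            "background_rate_hz": spec.background_rate_hz,
        },
    )


# ---------------------------------------------------------------------------
# reaction coordinates and structures
# ---------------------------------------------------------------------------

def replica_temperature_ladder(
    n_replicas: int = 18, t_min_k: float = 280.0, t_max_k: float = 370.0
) -> np.ndarray:
    """Equally spaced replica-exchange temperature ladder (default 280-370 K)."""
    return np.linspace(t_min_k, t_max_k, n_replicas)


def gen_reaction_coords(
    basins,
    n_frames: int,
    frame_dt_ns: float,
    cfg: GeneratorConfig,
) -> ReactionCoordSeries:
    """Sample (Rg, helicity) frames from a Gaussian mixture of basins.

    ``basins`` is a list of (weight, mean_rg Å, mean_helicity, cov) where cov
    is a 2x2 covariance (a scalar is promoted to cov*I; zero is allowed and
    gives a point mass).  Helicity is clipped to [0, 1].
    """
    weights = np.array([b[0] for b in basins], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("basin weights must sum to 1")
    if any(not (0.0 <= b[2] <= 1.0) for b in basins):
        raise ValueError("helicity means must lie in [0, 1]")
    rng = cfg.rng()
    choice = rng.choice(len(basins), size=n_frames, p=weights)
    out = np.zeros((n_frames, 2))
    for k, (_, mu_rg, mu_fa, cov) in enumerate(basins):
        mask = choice == k
        n = int(mask.sum())
        if n == 0:
            continue
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 0:
            cov = np.eye(2) * float(cov)
        if np.allclose(cov, 0.0):
            out[mask] = [mu_rg, mu_fa]
            continue
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular (non-PSD) basin covariance") from exc
        out[mask] = np.array([mu_rg, mu_fa]) + rng.normal(
            size=(n, 2)
        ) @ chol.T
    idx = np.arange(n_frames)
    return ReactionCoordSeries(
        frame=idx,
        time_ns=(idx + 1) * frame_dt_ns,
        rg_a=out[:, 0],
        f_alpha=np.clip(out[:, 1], 0.0, 1.0),
        temperature_k=cfg.temperature_k or 300.0,
        meta={"seed": cfg.seed, "construct": cfg.construct_label},
    )


# ideal backbone geometry (Å / degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom D from A-B-C with given internal coordinates."""
    angle = np.radians(angle_deg)
    torsion = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            -bond * np.sin(angle) * np.cos(torsion),
            -bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(
    phi_deg, psi_deg, omega_deg: float = 180.0
) -> FrameCoords:
    """Ideal-geometry backbone (N, CA, C per residue) from (phi, psi) lists.

    phi of the first residue and psi of the last are not used (they are
    undefined on a finite chain).
    """
    phi = np.atleast_1d(np.asarray(phi_deg, dtype=float))
    psi = np.atleast_1d(np.asarray(psi_deg, dtype=float))
    if phi.size != psi.size:
        raise ValueError("phi and psi must have equal length")
    n_res = phi.size
    coords = [
        np.array([0.0, 0.0, 0.0]),
        np.array([_BOND_N_CA, 0.0, 0.0]),
    ]
    ang = np.radians(_ANG_N_CA_C)
    coords.append(
        coords[1]
        + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    )
    for i in range(1, n_res):
        n_i = _place_atom(
            coords[-3], coords[-2], coords[-1],
            _BOND_C_N, _ANG_CA_C_N, psi[i - 1],
        )
        ca_i = _place_atom(
            coords[-2], coords[-1], n_i, _BOND_N_CA, _ANG_C_N_CA, omega_deg
        )
        c_i = _place_atom(
            coords[-1], n_i, ca_i, _BOND_CA_C, _ANG_N_CA_C, phi[i]
        )
        coords.extend([n_i, ca_i, c_i])
    atom_names = ["N", "CA", "C"] * n_res
    res_ids = np.repeat(np.arange(1, n_res + 1), 3)
    return FrameCoords(
        coords=np.array(coords), atom_names=atom_names, res_ids=res_ids
    )


def write_pdb(frames, path) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL records)."""
    if isinstance(frames, FrameCoords):
        frames = [frames]
    lines = []
    for model_no, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {model_no:>4d}")
        serial = 1
        for name, rid, (x, y, z) in zip(
            frame.atom_names, frame.res_ids, frame.coords
        ):
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:>5d} {pad_name} ALA A{int(rid):>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{name[0]:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
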