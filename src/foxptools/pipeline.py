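"""Declarative multi-stage runs and acceptance-fixture generation.

A run configuration (YAML or dict) names a global seed, an output directory
and an ordered stage list; stages execute in order, each writing its
artifacts (TSV data, JSON fit reports, PNG figures) under the output
directory, and all metrics are consolidated into ``metrics.json`` stamped
with the configuration hash and seed.  Sub-seeds derive deterministically
from the global seed so a rerun of the same configuration reproduces
identical metrics.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import fluortime, landscape, plots, reference, smburst, synthgen, thermo

STAGE_KINDS = ("titration", "unfolding", "photons", "fcs", "landscape")


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    """Pre-flight validation; raises ConfigError before any stage runs."""
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    for key in ("seed", "stages"):
        if key not in config:
            raise ConfigError(f"missing required key {key!r}")
    produced = set()
    for i, stage in enumerate(config["stages"]):
        kind = stage.get("kind")
        if kind not in STAGE_KINDS:
            raise ConfigError(f"stage {i}: unknown kind {kind!r}")
        if "name" not in stage:
            raise ConfigError(f"stage {i}: missing name")
        inp = stage.get("input")
        if inp is not None and inp not in produced and not Path(inp).exists():
            raise ConfigError(
                f"stage {i} ({stage['name']}): input {inp!r} does not exist "
                "and is not produced by an earlier stage"
            )
        produced.add(stage["name"])


def _sub_seed(seed: int, index: int) -> int:
    return (int(seed) * 1000 + index) % (2**31 - 1)


def _run_titration(stage, seed, outdir, figures):
    cfg = synthgen.GeneratorConfig(
        seed=seed,
        construct_label=stage.get("construct", ""),
        noise_sd=stage.get("noise_sd", 0.001),
        grid=synthgen.default_titration_grid(
            stage.get("max_nm", 5000.0), stage.get("n_points", 12)
        ),
    )
    if stage.get("input"):
        from .curves import TitrationCurve

        curve = TitrationCurve.from_tsv(stage["input"])
    else:
        curve = synthgen.gen_titration(
            stage["kd_nm"], stage.get("r_mono", 0.12),
            stage.get("r_dimer", 0.22), cfg,
        )
    curve.to_tsv(outdir / f"{stage['name']}.tsv")
    fit = thermo.fit_binding(curve, model=stage.get("model", "hyperbolic"))
    if figures:
        plots.plot_titration(curve, fit, outdir / f"{stage['name']}.png")
    return {
        "kd_nM": fit["kd"],
        "kd_se_nM": fit.se("kd"),
        "r_max": fit["r_max"],
        "offset": fit["offset"],
        "flags": fit.flags,
    }


def _run_unfolding(stage, seed, outdir, figures):
    mechanism = stage.get("mechanism", "dimer2")
    cfg = synthgen.GeneratorConfig(
        seed=seed,
        construct_label=stage.get("construct", ""),
        noise_sd=stage.get("noise_sd", 0.02),
        grid=np.linspace(
            stage.get("d_min", 0.0), stage.get("d_max", 5.0),
            stage.get("n_points", 20),
        ),
    )
    if stage.get("input"):
        from .curves import UnfoldingCurve

        curve = UnfoldingCurve.from_tsv(stage["input"])
    else:
        curve = synthgen.gen_unfolding(
            mechanism, stage["dg0"], stage["m"], stage["baselines"], cfg,
            p_total_nm=stage.get("p_total_nm", 200.0),
        )
    curve.to_tsv(outdir / f"{stage['name']}.tsv")
    fit = thermo.fit_unfolding(
        curve, mechanism, fix_baselines=stage.get("fix_baselines", False)
    )
    if figures:
        plots.plot_unfolding(curve, fit, outdir / f"{stage['name']}.png")
    metrics = {
        "dg1_kcal": fit["dg1"],
        "dg1_se_kcal": fit.se("dg1"),
        "abs_m1": fit.extras["abs_m1"],
        "flags": fit.flags,
    }
    if "dg2" in fit.params:
        metrics.update(
            dg2_kcal=fit["dg2"], dg2_se_kcal=fit.se("dg2"),
            total_dg_kcal=fit.extras["total_dg"],
        )
    return metrics


def _stream_spec(stage) -> synthgen.PhotonStreamSpec:
    species = []
    for sp in stage.get("species", [{}]):
        species.append(
            synthgen.SpeciesSpec(
                fraction=sp.get("fraction", 1.0),
                lifetimes=tuple(
                    tuple(c) for c in sp.get("lifetimes", [(1.0, 4.35)])
                ),
                r0=sp.get("r0", 0.38),
                rotations=tuple(
                    tuple(c) for c in sp.get("rotations", [(1.0, 60.0)])
                ),
                fret_e=sp.get("fret_e"),
                aex_ratio=sp.get("aex_ratio", 0.0),
            )
        )
    return synthgen.PhotonStreamSpec(
        duration_s=stage.get("duration_s", 30.0),
        background_rate_hz=stage.get("background_rate_hz", 500.0),
        burst_rate_hz=stage.get("burst_rate_hz", 50.0),
        molecular_brightness_hz=stage.get("molecular_brightness_hz", 5e4),
        t_diff_ms=stage.get("t_diff_ms", 1.0),
        species=tuple(species),
        g_factor=stage.get("g_factor", 1.0),
    )


def _run_photons(stage, seed, outdir, figures, artifacts):
    if stage.get("input"):
        stream = (
            artifacts[stage["input"]]
            if stage["input"] in artifacts
            else smburst.read_stream(stage["input"])
        )
    else:
        spec = _stream_spec(stage)
        stream = synthgen.gen_photon_stream(
            spec, synthgen.GeneratorConfig(seed=seed)
        )
        if stage.get("write_stream", False):
            smburst.write_stream(stream, outdir / f"{stage['name']}.h5")
    bursts = smburst.analyze_bursts(
        stream,
        window_photons=stage.get("window_photons", 10),
        window_ns=stage.get("window_ns", 500_000.0),
        min_photons=stage.get("min_photons", 50),
    )
    metrics = {"n_photons": len(stream), "n_bursts": len(bursts)}
    table = smburst.bursts_to_frame(bursts)
    if len(table):
        table.to_csv(outdir / f"{stage['name']}_bursts.tsv", sep="\t",
                     index=False)
        metrics["median_r_g"] = float(np.nanmedian(table["r_g"]))
        metrics["median_mean_tau_ns"] = float(
            np.nanmedian(table["mean_tau_ns"])
        )
    if stage.get("fit_anisotropy", True) and bursts:
        hist_p, hist_s = smburst.sub_ensemble_histograms(stream, bursts)
        irf = fluortime.GaussianIRF(
            sigma_ns=float(stream.meta.get("irf_sigma_ns", 0.25)),
            mean_ns=float(stream.meta.get("irf_mean_ns", 2.0)),
        )
        try:
            fit = fluortime.fit_polarized_decays(
                hist_p, hist_s, irf, g=stream.g_factor,
                n_rho=stage.get("n_rho", 2), n_tau=stage.get("n_tau", 2),
            )
            metrics.update(
                rho_fast_ns=fit.params["rho1"],
                rho_slow_ns=fit.params.get("rho2", np.nan),
                fast_fraction=fit.params.get("b1", 1.0),
                mean_tau_f_ns=fit.extras["mean_tau_f"],
            )
        except ValueError as exc:
            metrics["anisotropy_fit_error"] = str(exc)
    if figures and len(table) > 3:
        counts, xe, ye, _, _ = smburst.hist2d(
            bursts, "mean_tau", "r_g",
            bins=31,
            ranges=((0.0, 10.0), (-0.1, 0.45)),
        )
        tau_grid = np.linspace(0.5, 10.0, 50)
        lines = [
            (tau_grid, fluortime.perrin_line(0.38, rho, tau_grid),
             f"rho={rho} ns")
            for rho in (0.2, 60.0)
        ]
        plots.plot_hist2d(
            counts, xe, ye, outdir / f"{stage['name']}_hist2d.png",
            xlabel="mean tau (ns)", ylabel="r_G", perrin_lines=lines,
        )
    artifacts[stage["name"]] = stream
    return metrics


def _run_fcs(stage, seed, outdir, figures, artifacts):
    if stage.get("input") and stage["input"] in artifacts:
        stream = artifacts[stage["input"]]
    elif stage.get("input"):
        stream = smburst.read_stream(stage["input"])
    else:
        stream = synthgen.gen_photon_stream(
            _stream_spec(stage), synthgen.GeneratorConfig(seed=seed)
        )
    curve = smburst.autocorrelate(
        stream, bin_ns=stage.get("bin_ns", 5000.0),
        max_lag_s=stage.get("max_lag_s", 0.05),
    )
    curve.to_tsv(outdir / f"{stage['name']}_fcs.tsv")
    fit = smburst.fit_fcs(
        curve,
        fix_aspect=stage.get("fix_aspect", 0.2),
        fit_photophysics=stage.get("fit_photophysics", False),
    )
    if figures:
        plots.plot_fcs(curve, fit["fitted"], outdir / f"{stage['name']}_fcs.png",
                       t_diff_s=fit["params"]["t_diff"])
    return {
        "t_diff_ms": fit["params"]["t_diff"] * 1e3,
        "n_particles": fit["params"]["n"],
        "success": fit["success"],
    }


def _run_landscape(stage, seed, outdir, figures):
    if stage.get("input"):
        path = Path(stage["input"])
        if path.suffix == ".pdb":
            frames = landscape.load_pdb(path)
            series = landscape.series_from_frames(
                frames, stage.get("frame_dt_ns", 0.5)
            )
        else:
            series = landscape.ReactionCoordSeries.from_tsv(path)
    else:
        basins_spec = [
            (b["weight"], b["rg"], b["f_alpha"],
             np.diag([b.get("sd_rg", 0.5) ** 2, b.get("sd_fa", 0.02) ** 2]))
            for b in stage["basins"]
        ]
        series = synthgen.gen_reaction_coords(
            basins_spec, stage.get("n_frames", 20000),
            stage.get("frame_dt_ns", 0.5),
            synthgen.GeneratorConfig(seed=seed),
        )
    series.to_tsv(outdir / f"{stage['name']}_coords.tsv")
    surface = landscape.pmf2d(
        series, bins=stage.get("bins", 50),
        temperature_k=stage.get("temperature_k", 300.0),
    )
    basins = landscape.find_basins(
        surface, depth_threshold=stage.get("depth_threshold", 3.0)
    )
    surface.to_tsv(outdir / f"{stage['name']}_pmf.tsv")
    report = []
    for basin in basins:
        reps = landscape.select_representatives(
            series, basin,
            min_history=stage.get("min_history", 100),
        )
        report.append(
            {
                "label": basin.label,
                "min_pmf_kcal": basin.min_pmf,
                "mean_rg_A": basin.mean_rg,
                "mean_f_alpha": basin.mean_f_alpha,
                "n_representatives": int(len(reps)),
            }
        )
    (outdir / f"{stage['name']}_basins.json").write_text(
        json.dumps(report, indent=2)
    )
    if figures:
        plots.plot_pmf(surface, outdir / f"{stage['name']}_pmf.png")
    return {"n_basins": len(basins), "basins": report}


def run(config: dict | str | Path, figures: bool = True) -> dict:
    """Execute a run configuration; returns the consolidated metrics dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    outdir = Path(config.get("outdir", "runs/out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    metrics = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
    }
    artifacts: dict = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, stage in enumerate(config["stages"]):
            sub = _sub_seed(seed, i)
            kind = stage["kind"]
            if kind == "titration":
                out = _run_titration(stage, sub, outdir, figures)
            elif kind == "unfolding":
                out = _run_unfolding(stage, sub, outdir, figures)
            elif kind == "photons":
                out = _run_photons(stage, sub, outdir, figures, artifacts)
            elif kind == "fcs":
                out = _run_fcs(stage, sub, outdir, figures, artifacts)
            else:
                out = _run_landscape(stage, sub, outdir, figures)
            out["seed"] = sub
            metrics["stages"][stage["name"]] = out
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return metrics


# ---------------------------------------------------------------------------
# acceptance fixtures
# ---------------------------------------------------------------------------

def fixture_manifest() -> dict:
    """Generating truths for the full acceptance-fixture suite.

    Values are the published equilibrium parameters of the FoxP1 constructs
    (see :mod:`.reference`); everything else (noise levels, grids,
    intermediate signals) follows the documented study conditions.
    """
    r = reference
    return {
        "titrations": {
            "zip_lin": {
                "kd_nm": r.KD_NM["ZIP-lin"], "max_nm": 5000.0,
                "noise_sd": 0.001, "r_mono": 0.12, "r_dimer": 0.22,
            },
            "zip_lin_fkh": {
                "kd_nm": r.KD_NM["ZIP-lin-FKH"], "max_nm": 200.0,
                "noise_sd": 0.001, "r_mono": 0.12, "r_dimer": 0.22,
            },
            "dna_binding": {
                "kd_nm": r.KD_NM["ZIP-lin-FKH:DNA"], "max_nm": 500.0,
                "noise_sd": 0.001, "r_mono": 0.12, "r_dimer": 0.22,
            },
            "dimerization_with_dna": {
                "kd_nm": r.KD_NM["ZIP-lin-FKH+DNA"], "max_nm": 200.0,
                "noise_sd": 0.001, "r_mono": 0.12, "r_dimer": 0.22,
            },
        },
        "unfolding": {
            "zip_lin_dimer2": {
                "mechanism": "dimer2", "dg0": [r.DG_KCAL["ZIP-lin dimer"]],
                "m": [r.M_DIMER], "baselines": [1.0, 0.0],
                "p_total_nm": r.UNFOLDING_PTOTAL_NM,
                "noise_sd": 0.02, "d_max": 3.0, "n_points": 20,
            },
            "zip_in_tether_dimer2": {
                "mechanism": "dimer2",
                "dg0": [r.DG_KCAL["ZIP in ZIP-lin-FKH dimer"]],
                "m": [r.M_DIMER], "baselines": [1.0, 0.0],
                "p_total_nm": r.UNFOLDING_PTOTAL_NM,
                "noise_sd": 0.02, "d_max": 3.0, "n_points": 20,
            },
            "fkh_dimer3": {
                "mechanism": "dimer3",
                "dg0": [r.DG_KCAL["FKH step1 (N2=2I)"],
                        r.DG_KCAL["FKH step2 (I=U)"]],
                "m": [r.M_DIMER, r.M_MONOMER], "baselines": [1.0, 0.85, 0.0],
                "p_total_nm": r.UNFOLDING_PTOTAL_NM,
                "noise_sd": 0.02, "d_max": 5.0, "n_points": 20,
            },
            "zip_lin_mono3": {
                "mechanism": "mono3",
                "dg0": [0.4 * r.DG_KCAL["ZIP-lin monomer total"],
                        0.6 * r.DG_KCAL["ZIP-lin monomer total"]],
                "m": [r.M_MONOMER, r.M_MONOMER], "baselines": [1.0, 0.6, 0.0],
                "p_total_nm": None,
                "noise_sd": 0.03, "d_max": 5.0, "n_points": 20,
            },
            "zip_lin_fkh_mono2": {
                "mechanism": "mono2",
                "dg0": [r.DG_KCAL["ZIP-lin-FKH monomer"]],
                "m": [r.M_MONOMER], "baselines": [1.0, 0.0],
                "p_total_nm": None,
                "noise_sd": 0.03, "d_max": 5.0, "n_points": 20,
            },
        },
        "photon_streams": {
            "free": {
                "fast_fraction": r.FAST_RHO_FRACTION,
                "rho_fast_ns": r.RHO_FAST_NS, "rho_slow_ns": r.RHO_SLOW_NS,
                "r0": r.R0_FUNDAMENTAL, "tau_ns": r.TAU_BODIPY_NS,
            },
            "dna_bound": {
                "fast_fraction": 0.35,
                "rho_fast_ns": r.RHO_FAST_NS, "rho_slow_ns": 170.0,
                "r0": r.R0_FUNDAMENTAL, "tau_ns": r.TAU_BODIPY_NS,
            },
        },
        "reaction_coords": {
            "three_basin": {
                "basins": [
                    {"weight": 0.5, "rg": 12.0, "f_alpha": 0.85},
                    {"weight": 0.3, "rg": 14.0, "f_alpha": 0.55},
                    {"weight": 0.2, "rg": 22.0, "f_alpha": 0.25},
                ]
            }
        },
        "references": {
            "fkh_3dds_dimer_dg_kcal": r.DG_KCAL["FKH-3DDS dimer"],
            "fkh_3dds_kd_nm": r.KD_NM["FKH-3DDS"],
        },
    }


def make_fixtures(out_dir, seed: int = 1, photons: bool = False) -> dict:
    """Generate the synthetic fixture suite with a manifest of truths.

    Photon streams are large and off by default; the manifest always carries
    their generating parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = fixture_manifest()
    manifest["seed"] = int(seed)

    for i, (name, spec) in enumerate(manifest["titrations"].items()):
        cfg = synthgen.GeneratorConfig(
            seed=_sub_seed(seed, i), construct_label=name,
            noise_sd=spec["noise_sd"],
            grid=synthgen.default_titration_grid(spec["max_nm"], 12),
        )
        synthgen.gen_titration(
            spec["kd_nm"], spec["r_mono"], spec["r_dimer"], cfg
        ).to_tsv(out_dir / f"titration_{name}.tsv")

    for i, (name, spec) in enumerate(manifest["unfolding"].items()):
        cfg = synthgen.GeneratorConfig(
            seed=_sub_seed(seed, 100 + i), construct_label=name,
            noise_sd=spec["noise_sd"],
            grid=np.linspace(0.0, spec["d_max"], spec["n_points"]),
        )
        synthgen.gen_unfolding(
            spec["mechanism"], spec["dg0"], spec["m"], spec["baselines"],
            cfg, p_total_nm=spec["p_total_nm"],
        ).to_tsv(out_dir / f"unfolding_{name}.tsv")

    if photons:
        for i, (name, spec) in enumerate(manifest["photon_streams"].items()):
            stream = synthgen.gen_photon_stream(
                photon_spec_from_manifest(spec, n_photons=200_000),
                synthgen.GeneratorConfig(seed=_sub_seed(seed, 200 + i)),
            )
            smburst.write_stream(stream, out_dir / f"photons_{name}.h5")

    for i, (name, spec) in enumerate(manifest["reaction_coords"].items()):
        basins = [
            (b["weight"], b["rg"], b["f_alpha"],
             np.diag([0.5**2, 0.02**2]))
            for b in spec["basins"]
        ]
        synthgen.gen_reaction_coords(
            basins, 20000, 0.5,
            synthgen.GeneratorConfig(seed=_sub_seed(seed, 300 + i)),
        ).to_tsv(out_dir / f"coords_{name}.tsv")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def photon_spec_from_manifest(
    spec: dict, n_photons: int = 1_000_000
) -> synthgen.PhotonStreamSpec:
    """Stream spec for a sub-ensemble anisotropy fixture.

    One species with two rotational components; burst rate and duration are
    sized so the stream carries about ``n_photons`` photons.
    """
    species = synthgen.SpeciesSpec(
        fraction=1.0,
        lifetimes=((1.0, spec["tau_ns"]),),
        r0=spec["r0"],
        rotations=(
            (spec["fast_fraction"], spec["rho_fast_ns"]),
            (1.0 - spec["fast_fraction"], spec["rho_slow_ns"]),
        ),
    )
    duration_s = 60.0
    brightness = 5e4
    t_diff_ms = 1.0
    mean_transit_s = t_diff_ms * 1e-3 / (1.0 + 0.2**2 / 2.0)
    burst_rate = n_photons / (brightness * mean_transit_s) / duration_s
    return synthgen.PhotonStreamSpec(
        duration_s=duration_s,
        background_rate_hz=0.0,
        burst_rate_hz=burst_rate,
        molecular_brightness_hz=brightness,
        t_diff_ms=t_diff_ms,
        species=(species,),
    )
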