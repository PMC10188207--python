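"""Figure helpers for pipeline reports (headless Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_titration(curve, fit, path):
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.semilogx(
        np.maximum(curve.conc_nm, curve.conc_nm[curve.conc_nm > 0].min() / 3),
        curve.signal, "o", ms=4, label="data",
    )
    if fit is not None:
        ax.semilogx(
            np.maximum(curve.conc_nm, curve.conc_nm[curve.conc_nm > 0].min() / 3),
            fit.extras["fitted"], "-",
            label=f"Kd = {fit['kd']:.3g} nM",
        )
    ax.set_xlabel("[titrant] (nM)")
    ax.set_ylabel("anisotropy")
    ax.set_title(curve.construct or "titration")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_unfolding(curve, fit, path):
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.plot(curve.denaturant_m, curve.signal, "o", ms=4, label="data")
    if fit is not None:
        ax.plot(curve.denaturant_m, fit.extras["fitted"], "-",
                label=f"dG1 = {fit['dg1']:.3g} kcal/mol")
    ax.set_xlabel("[GdmCl] (M)")
    ax.set_ylabel("normalized signal")
    ax.set_title(f"{curve.construct or 'unfolding'} ({curve.mechanism})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_hist2d(counts, x_edges, y_edges, path, xlabel="", ylabel="",
                perrin_lines=None):
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    ax.pcolormesh(x_edges, y_edges, counts.T, cmap="viridis")
    if perrin_lines:
        for tau_grid, r_line, label in perrin_lines:
            ax.plot(tau_grid, r_line, "--", lw=1, label=label)
        ax.legend(frameon=False, fontsize=7)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fcs(curve, fitted, path, t_diff_s=None):
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.semilogx(curve.lag_s, curve.g, "o", ms=3, label="data")
    if fitted is not None:
        label = "fit"
        if t_diff_s is not None:
            label = f"t_diff = {t_diff_s * 1e3:.3g} ms"
        ax.semilogx(curve.lag_s, fitted, "-", label=label)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("G")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pmf(surface, path):
    fig, ax = plt.subplots(figsize=(4.4, 3.6))
    pmf = np.ma.masked_invalid(surface.pmf)
    mesh = ax.pcolormesh(
        surface.rg_edges, surface.fa_edges, pmf.T, cmap="viridis_r"
    )
    fig.colorbar(mesh, ax=ax, label="PMF (kcal/mol)")
    for basin in surface.basins:
        ax.plot(basin.mean_rg, basin.mean_f_alpha, "r*", ms=10)
        ax.annotate(basin.label, (basin.mean_rg, basin.mean_f_alpha),
                    color="red", fontsize=8)
    ax.set_xlabel("Rg (Å)")
    ax.set_ylabel("α-helical fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
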