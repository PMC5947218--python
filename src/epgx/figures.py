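"""Regeneration of the package's illustrative figures at desk scale.

Each figure writes the underlying numbers as CSV next to a PNG so results
can be inspected without the plot. Figures:

* ``fig_spgr_transient``  -- approach of RF-spoiled gradient echo to the
  ideally-spoiled steady state for single-pool / MT / exchange tissue;
* ``fig_bssfp_profiles``  -- bSSFP off-resonance profiles, steady-state
  solver vs converged transient reconstruction;
* ``fig_cpmg_bias``       -- CPMG echo train, its NNLS T2 spectrum, and the
  apparent myelin-water fraction vs exchange rate;
* ``fig_mrf_mt``          -- variable-flip transient signal: MT tissue vs
  the single-pool tissue with matched apparent T1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .models import SinglePoolModel, TwoPoolMTModel, t1_observed
from .presets import get_preset
from .relaxometry import bias_surface, nnls_t2_spectrum
from .sequences import (
    bssfp_transient_profile,
    mrf_train,
    simulate_cpmg,
    simulate_train,
    spgr_sequence,
)
from .steady_state import bssfp_ss, spgr_ideal_spoiled_ss

__all__ = ["regenerate_figure", "FIGURES"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def fig_spgr_transient(outdir: Path) -> list:
    plt = _mpl()
    tr, alpha, phi0 = 5.0, np.deg2rad(10), np.deg2rad(117)
    n = 1000
    frames = {}
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in ("single_wm", "wm_mt", "myelin_bm"):
        model = get_preset(name)
        ser = simulate_train(model, spgr_sequence(tr, alpha, phi0, n))
        ss = spgr_ideal_spoiled_ss(model, tr, alpha)
        ax.plot(np.arange(n), np.abs(ser.signal), label=name)
        ax.axhline(ss.magnitude, ls=":", lw=0.8)
        frames[name] = np.abs(ser.signal)
        frames[name + "_ss"] = np.full(n, ss.magnitude)
    ax.set_xlabel("pulse index")
    ax.set_ylabel("|signal| / M0")
    ax.set_title(f"SPGR TR={tr} ms, flip 10\N{DEGREE SIGN}, \N{GREEK CAPITAL LETTER PHI}0=117\N{DEGREE SIGN}")
    ax.legend()
    csv = outdir / "spgr_transient.csv"
    png = outdir / "spgr_transient.png"
    pd.DataFrame(frames).to_csv(csv, index=False)
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return [csv, png]


def fig_bssfp_profiles(outdir: Path) -> list:
    plt = _mpl()
    from dataclasses import replace

    tr, alpha = 5.0, np.deg2rad(10)
    psi = np.linspace(-np.pi, np.pi, 64)
    panels = {
        "single_wm": get_preset("single_wm"),
        "wm_mt": get_preset("wm_mt"),
        "myelin_bm_db0": get_preset("myelin_bm"),
        "myelin_bm_db12.8": replace(get_preset("myelin_bm"), delta_b=12.8),
    }
    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True)
    rows = {"psi": psi}
    for ax, (name, model) in zip(axes.ravel(), panels.items()):
        direct = np.array([abs(bssfp_ss(model, tr, alpha, p).signal) for p in psi])
        trans = np.abs(bssfp_transient_profile(model, tr, alpha, psi))
        ax.plot(psi, direct, label="steady-state solver")
        ax.plot(psi, trans, "--", label="transient + iFFT")
        ax.set_title(name)
        rows[name + "_direct"] = direct
        rows[name + "_transient"] = trans
    axes[0, 0].legend(fontsize=7)
    for ax in axes[1]:
        ax.set_xlabel(r"$\psi$ (rad/TR)")
    csv = outdir / "bssfp_profiles.csv"
    png = outdir / "bssfp_profiles.png"
    pd.DataFrame(rows).to_csv(csv, index=False)
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return [csv, png]


def fig_cpmg_bias(outdir: Path, ka_grid=None) -> list:
    plt = _mpl()
    model = get_preset("myelin_bm")
    echoes = simulate_cpmg(model, n_echoes=50, esp=5.0, b1_scale=1.1)
    spec = nnls_t2_spectrum(echoes.total, echoes.times)
    if ka_grid is None:
        ka_grid = np.linspace(0.0, 2.5, 6)
    f_hat, t2b_hat = bias_surface(model, ka_grid, b1_values=[1.0])
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    axes[0].semilogy(echoes.times, echoes.total, "o-")
    axes[0].set_xlabel("time (ms)")
    axes[0].set_title("CPMG echoes (ka=2, B1 x1.1)")
    axes[1].plot(spec.t2_grid, spec.amplitudes)
    axes[1].set_xscale("log")
    axes[1].set_xlabel("T2 (ms)")
    axes[1].set_title(f"NNLS spectrum: f={spec.f_hat:.3f}, T2b={spec.t2b_hat:.1f} ms")
    axes[2].plot(ka_grid, f_hat[:, 0, 0], "o-")
    axes[2].axhline(model.f, ls=":")
    axes[2].set_xlabel("ka (s$^{-1}$)")
    axes[2].set_title("apparent myelin-water fraction")
    fig.tight_layout()
    pd.DataFrame({"time_ms": echoes.times, "echo": echoes.total}).to_csv(
        outdir / "cpmg_echoes.csv", index=False
    )
    pd.DataFrame({"t2_ms": spec.t2_grid, "amplitude": spec.amplitudes}).to_csv(
        outdir / "cpmg_spectrum.csv", index=False
    )
    pd.DataFrame({"ka": ka_grid, "f_hat": f_hat[:, 0, 0], "t2b_hat": t2b_hat[:, 0, 0]}).to_csv(
        outdir / "cpmg_bias.csv", index=False
    )
    png = outdir / "cpmg_bias.png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return [outdir / "cpmg_echoes.csv", outdir / "cpmg_spectrum.csv", outdir / "cpmg_bias.csv", png]


def fig_mrf_mt(outdir: Path) -> list:
    plt = _mpl()
    wm = get_preset("wm_mt")
    sp = SinglePoolModel(t1=t1_observed(wm), t2=wm.t2a)
    train = mrf_train()
    mt = simulate_train(wm, train, record_z=True)
    single = simulate_train(sp, train, record_z=True)
    norm = 1.0 / (1.0 - wm.f)  # pool b is invisible
    fig, axes = plt.subplots(3, 1, figsize=(7, 7), sharex=True)
    axes[0].plot(np.rad2deg(train.flips))
    axes[0].set_ylabel("flip (deg)")
    axes[1].plot(np.abs(mt.signal) * norm, label="two-pool MT (/(1-f))")
    axes[1].plot(np.abs(single.signal), label="single pool, T1obs")
    axes[1].set_ylabel("|signal|")
    axes[1].legend(fontsize=8)
    axes[2].plot(mt.z0_a * norm, label="Z0a /(1-f)")
    axes[2].plot(mt.z0_b / wm.f, label="Z0b /f")
    axes[2].plot(single.z0_a, label="single pool Z0")
    axes[2].set_ylabel("Z0")
    axes[2].set_xlabel("pulse index")
    axes[2].legend(fontsize=8)
    pd.DataFrame(
        {
            "flip_deg": np.rad2deg(train.flips),
            "mt_signal": np.abs(mt.signal) * norm,
            "single_signal": np.abs(single.signal),
            "mt_z0a": mt.z0_a,
            "mt_z0b": mt.z0_b,
            "single_z0": single.z0_a,
        }
    ).to_csv(outdir / "mrf_mt.csv", index=False)
    png = outdir / "mrf_mt.png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return [outdir / "mrf_mt.csv", png]


FIGURES = {
    "fig_spgr_transient": fig_spgr_transient,
    "fig_bssfp_profiles": fig_bssfp_profiles,
    "fig_cpmg_bias": fig_cpmg_bias,
    "fig_mrf_mt": fig_mrf_mt,
}

# short aliases in sequence-number order
_ALIASES = {
    "fig2": "fig_spgr_transient",
    "fig3": "fig_bssfp_profiles",
    "fig4": "fig_cpmg_bias",
    "fig5": "fig_mrf_mt",
}


def regenerate_figure(name: str, outdir) -> list:
    """Recompute one named figure; returns the list of files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    key = _ALIASES.get(name, name)
    if key not in FIGURES:
        raise KeyError(
            f"unknown figure {name!r}; available: {sorted(FIGURES) + sorted(_ALIASES)}"
        )
    return FIGURES[key](outdir)
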