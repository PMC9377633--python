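"""Seeded sweep driver reproducing the figure-level experiments as tables.

Each preset names one of the parameter sweeps studied with these models
(imaginary-diameter and feedforward-norm sweeps, the regime map over
spectrum/feedforward norms, the norm-split sweep, the zero-trace outlier
sweep, the I/E sweeps on Dalean networks, the inhibition switch, and the
E-to-I/E-to-E ratio sweep).  ``run_sweep`` executes a grid x realisations
design, emits one row per realisation plus seed-averaged summaries, and
can write everything as CSV/JSON.

Every realisation derives its generator from ``numpy.random.SeedSequence
(seed, point_index, realisation_index)``, so single rows are reproducible
in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dale as _dale
from . import triangular as _tri
from .amplification import (
    evoked_energy_operator,
    max_norms_per_condition,
    optimal_basis,
    percent_amplified,
)
from .dynamics import NetworkModel, simulate, transient_duration
from .geometry import effective_rank, eigvec_angles, overlap_fraction

__all__ = ["SweepConfig", "PRESETS", "preset_config", "run_sweep", "make_fixtures"]


@dataclass(frozen=True)
class SweepConfig:
    """A sweep: one varying parameter (or parameter tuple) on a grid."""

    experiment: str
    parameter: str
    grid: tuple
    realisations: int = 20
    seed: int = 0
    n: int = 200
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("grid must be non-empty")
        if self.realisations < 1:
            raise ValueError("realisations must be >= 1")


#: Figure-level presets.  Defaults follow the study conditions; pass
#: overrides to :func:`preset_config` for desk-scale runs.
PRESETS: dict[str, dict] = {
    # amplification and eigenvector angles vs imaginary diameter at fixed
    # feedforward norm 75
    "fig3A": dict(parameter="d_im", grid=(1.0, 5.0, 10.0, 20.0, 50.0, 100.0),
                  options=dict(ff_norm=75.0, real_kind="uniform_with_small_outlier")),
    # same metrics vs feedforward norm at single-valued (0) real parts
    "fig3B": dict(parameter="ff_norm", grid=(10.0, 25.0, 50.0, 75.0, 150.0, 300.0),
                  options=dict(d_im=20.0, real_kind="single_value")),
    # effective ranks vs imaginary diameter (uniform real distribution)
    "fig4A": dict(parameter="d_im", grid=(1.0, 5.0, 10.0, 20.0, 50.0, 100.0),
                  options=dict(ff_norm=75.0, real_kind="uniform_with_small_outlier",
                               with_erank_P=True)),
    "fig4B": dict(parameter="ff_norm", grid=(10.0, 25.0, 50.0, 75.0, 150.0, 300.0),
                  options=dict(d_im=20.0, real_kind="uniform_with_small_outlier",
                               with_erank_P=True)),
    # nonlinear transient-duration map over (feedforward, spectrum) norms
    "fig5B": dict(parameter="ff_lam_norms",
                  grid=tuple((f, l) for f in (50.0, 100.0, 300.0, 500.0, 700.0)
                             for l in (50.0, 100.0, 300.0, 500.0, 700.0)),
                  options=dict()),
    # norm split between spectrum and feedforward at fixed total norm
    "fig5C": dict(parameter="percent_to_spectrum",
                  grid=(0.0, 25.0, 50.0, 75.0, 90.0, 100.0),
                  options=dict(total_norm=700.0)),
    # amplification vs imaginary diameter for zero-trace spectra with a
    # negative real outlier
    "fig6": dict(parameter="d_im", grid=(1.0, 5.0, 10.0, 20.0, 50.0, 100.0),
                 options=dict(ff_norm=75.0, outlier=-10.0)),
    # empirical outlier of an I/E = 40 circuit rescaled to smaller ratios
    "fig6D": dict(parameter="ie_ratio", grid=(3.0, 5.0, 10.0, 20.0, 30.0, 40.0),
                  options=dict(build_ie=40.0)),
    # Dalean spectra and amplification vs I/E at fixed Frobenius norm 100
    "fig7": dict(parameter="ie_ratio", grid=(3.0, 10.0, 40.0),
                 options=dict(frobenius_norm=100.0)),
    # inhibition switch: I/E = 40 circuit versus the same scaled to I/E = 1
    "fig8": dict(parameter="ie_ratio", grid=(40.0, 1.0),
                 options=dict(build_ie=40.0)),
    # imaginary diameter and Schur norms vs the E-to-I / E-to-E ratio
    "fig9C": dict(parameter="wie_over_wee",
                  grid=(0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8),
                  options=dict(ie_ratio=3.0)),
}


def preset_config(name: str, **overrides) -> SweepConfig:
    """Instantiate a preset, optionally overriding realisations/seed/n/grid."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    base = PRESETS[name]
    opts = dict(base["options"])
    opts.update(overrides.pop("options", {}))
    return SweepConfig(
        experiment=name,
        parameter=base["parameter"],
        grid=tuple(overrides.pop("grid", base["grid"])),
        options=opts,
        **overrides,
    )


# ---------------------------------------------------------------------------
# per-realisation measurements

def _ut_network(cfg: SweepConfig, value, rng, lam_norm=None, ff_norm=None):
    opts = cfg.options
    real_kind = opts.get("real_kind", "uniform_with_small_outlier")
    spec = _tri.SpectrumSpec(
        N=cfg.n,
        real_kind=real_kind,
        value=opts.get("real_value", 0.0),
        d_re=opts.get("d_re", 1.0),
        d_im=opts.get("d_im", 20.0) if cfg.parameter != "d_im" else value,
        outlier=opts.get("outlier", 0.0),
    )
    fspec = _tri.FeedforwardSpec(
        kind=opts.get("ff_kind", "uniform"),
        target_norm=ff_norm
        if ff_norm is not None
        else (value if cfg.parameter == "ff_norm" else opts.get("ff_norm", 75.0)),
        template=opts.get("ff_template"),
    )
    return _tri.build_network(spec, fspec, rng, spectrum_norm=lam_norm)


def _amplification_metrics(W: np.ndarray, with_erank_P: bool = False,
                           nonlinear_top: bool = False) -> dict:
    model = NetworkModel(W=W)
    Q = evoked_energy_operator(model)
    basis, energies = optimal_basis(model, Q)
    norms = max_norms_per_condition(model, basis, mode="linear")
    angles = eigvec_angles(W)
    V = np.linalg.eig(W)[1]
    out = {
        "max_norm_top": float(norms[0]),
        "max_norm_best": float(norms.max()),
        "percent_amplified": percent_amplified(norms),
        "pct_angles_lt_45": overlap_fraction(angles, "angle_lt_45"),
        "erank_V": effective_rank(V / np.linalg.norm(V, axis=0)),
    }
    if with_erank_P:
        from .amplification import AmplificationReport
        from .geometry import build_P

        report = AmplificationReport(
            basis=basis, energies=energies, max_norms=norms, mode="linear"
        )
        P = build_P(model, report, mode="linear")
        out["n_amplified"] = report.n_amplified
        out["erank_P"] = effective_rank(P) if P.shape[1] else np.nan
    if nonlinear_top:
        traj = simulate(model, basis[:, 0], duration=100.0 * model.tau,
                        mode="nonlinear", stop_norm=1e-3)
        td = transient_duration(traj)
        out["delta_t_ms"] = td.delta_t
        out["censored"] = td.censored
    return out


def _run_point(cfg: SweepConfig, value, rng) -> dict:
    name = cfg.experiment
    opts = cfg.options
    if name in ("fig3A", "fig3B", "fig4A", "fig4B", "fig6"):
        net = _ut_network(cfg, value, rng)
        return _amplification_metrics(net.W, with_erank_P=opts.get("with_erank_P", False))
    if name == "fig5B":
        ff, lam = value
        net = _ut_network(cfg, value, rng, lam_norm=lam, ff_norm=ff)
        m = _amplification_metrics(net.W, nonlinear_top=True)
        m["ff_norm"], m["lam_norm"] = ff, lam
        return m
    if name == "fig5C":
        spec = _tri.SpectrumSpec(N=cfg.n, real_kind="uniform_with_small_outlier")
        spectrum = _tri.sample_spectrum(spec, rng)
        T = _tri.sample_feedforward(
            _tri.FeedforwardSpec(kind="uniform", target_norm=1.0), spectrum, rng
        )
        net = _tri.split_norm(opts.get("total_norm", 700.0), value, spectrum, T)
        return _amplification_metrics(net.W)
    if name in ("fig6D", "fig8"):
        dspec = _dale.DaleSpec(N=cfg.n, ie_ratio=opts.get("build_ie", 40.0))
        soc = _dale.soc_stabilise(_dale.init_random(dspec, rng))
        scaled = _dale.scale_inhibition(soc, value)
        lam = scaled.eigenvalues()
        out = {
            "outlier_empirical": float(lam.real.min()),
            "outlier_predicted": _dale.predicted_outlier(scaled.spec),
            "abscissa": float(lam.real.max()),
        }
        if name == "fig8":
            W = scaled.W
            if float(lam.real.max()) < 1.0:
                out.update(_amplification_metrics(W))
        return out
    if name == "fig7":
        dspec = _dale.DaleSpec(N=cfg.n, ie_ratio=value)
        raw = _dale.init_random(dspec, rng)
        lam_raw = raw.eigenvalues()
        outer_raw, inner_raw = _dale.empirical_radii(lam_raw)
        soc = _dale.soc_stabilise(raw, rng=rng)
        lam_soc = soc.eigenvalues()
        outer_soc, inner_soc = _dale.empirical_radii(lam_soc)
        out = {
            "outlier_raw": float(lam_raw.real.min()),
            "outlier_soc": float(lam_soc.real.min()),
            "outlier_predicted": _dale.predicted_outlier(dspec),
            "outer_diam_raw": 2 * outer_raw,
            "outer_diam_soc": 2 * outer_soc,
            "inner_diam_raw": 2 * inner_raw,
            "inner_diam_soc": 2 * inner_soc,
        }
        norm = opts.get("frobenius_norm")
        if norm:
            fixed = _dale.frobenius_normalise(soc, norm)
            if float(np.max(fixed.eigenvalues().real)) < 1.0:
                out.update(_amplification_metrics(fixed.W))
        return out
    if name == "fig9C":
        dspec = _dale.DaleSpec(N=cfg.n, ie_ratio=opts.get("ie_ratio", 3.0))
        soc = _dale.scale_etoi(dspec, value, rng=rng,
                               reference_norm=opts.get("reference_norm"))
        lam = soc.eigenvalues()
        outer, _ = _dale.empirical_radii(lam)
        from scipy.linalg import schur

        Tform, _u = schur(soc.W, output="real")
        strict = np.triu(Tform, k=1)
        sub = np.diag(Tform, -1)
        for i in np.nonzero(np.abs(sub) > 1e-12)[0]:
            strict[i, i + 1] = 0.0
        out = {
            "imag_diam": 2 * outer,
            "schur_ff_norm": float(np.linalg.norm(strict, "fro")),
            "schur_spectrum_norm": float(
                np.sqrt(np.sum(np.abs(lam) ** 2))
            ),
        }
        return out
    raise ValueError(f"unknown experiment {name!r}")


def run_sweep(cfg: SweepConfig, out_dir: str | Path | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the sweep; returns (rows, summary) tables.

    One row per grid point x realisation; failed realisations are logged
    in the ``error`` column and excluded from the summary (which averages
    numeric metrics per grid point).  With ``out_dir``, writes rows.csv,
    summary.csv and a config snapshot.
    """
    records = []
    for pi, value in enumerate(cfg.grid):
        for ri in range(cfg.realisations):
            ss = np.random.SeedSequence((cfg.seed, pi, ri))
            rng = np.random.default_rng(ss)
            row = {
                "experiment": cfg.experiment,
                cfg.parameter: value if not isinstance(value, tuple) else str(value),
                "realisation": ri,
                "seed": cfg.seed,
                "error": "",
            }
            try:
                row.update(_run_point(cfg, value, rng))
            except Exception as exc:   # noqa: BLE001 - logged, not fatal
                row["error"] = f"{type(exc).__name__}: {exc}"
            records.append(row)
    rows = pd.DataFrame.from_records(records)
    ok = rows[rows["error"] == ""]
    numeric = ok.select_dtypes(include=[np.number]).columns.difference(
        ["realisation", "seed", cfg.parameter]
    )
    summary = ok.groupby(cfg.parameter, sort=False)[list(numeric)].mean().reset_index()
    summary.insert(0, "n_failed", int((rows["error"] != "").sum()))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows.to_csv(out / "rows.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        (out / "config.json").write_text(json.dumps(
            {**cfg.__dict__, "grid": list(map(str, cfg.grid)),
             "options": {k: str(v) for k, v in cfg.options.items()},
             "numpy": np.__version__}, indent=2))
    return rows, summary


def make_fixtures(seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Small deterministic instances of each network family (for tests).

    Returns a dict with an upper-triangular network (N=10), a raw Dalean
    network (N=30) and a stabilised one (N=30, modest radius).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF1)))
    sspec = _tri.SpectrumSpec(N=10, real_kind="uniform_with_small_outlier",
                              d_im=4.0, n_real=2)
    fspec = _tri.FeedforwardSpec(kind="uniform", target_norm=5.0)
    ut = _tri.build_network(sspec, fspec, rng)

    dspec = _dale.DaleSpec(N=30, p=0.3, R_outer=2.0, ie_ratio=3.0)
    raw = _dale.init_random(dspec, rng)
    soc = _dale.soc_stabilise(raw, _dale.SOCConfig(learning_rate=2.0))

    fixtures = {"upper_triangular": ut, "dale_raw": raw, "dale_soc": soc}
    if out_dir is not None:
        from .io import save_matrix

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_matrix(out / "upper_triangular.csv", ut.W,
                    {"seed": seed, "spec": sspec, "feedforward": {"kind": "uniform", "target_norm": 5.0}})
        save_matrix(out / "dale_raw.csv", raw.W, {"seed": seed, "spec": dspec})
        save_matrix(out / "dale_soc.csv", soc.W,
                    {"seed": seed, "spec": dspec, "optimisation": soc.optimisation})
    return fixtures
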