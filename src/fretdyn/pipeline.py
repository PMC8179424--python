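"""End-to-end pipeline orchestration.

Wires the stages together: photon simulation -> burst analysis -> PDA and
FRET-FCS; toy structures -> accessible-volume distance distributions ->
trajectory observables.  A single root seed derives per-stage child seeds
deterministically, so identical config + seed reproduces every output file
byte for byte.  Outputs are plain text (CSV + JSON); a failing stage is
recorded in the report and its dependents are skipped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .av import DyeParams, ensemble_distributions
from .bursts import CorrectionFactors, process_bursts
from .fcs import correlate, global_fit
from .kinetics import KineticScheme, three_state_scheme
from .pda import (BurstSizeDistribution, fit_pda, proximity_histogram,
                  state_ratio)
from .photonsim import SimConfig, load_photon_hdf5, save_photon_hdf5, simulate_photon_stream
from .toystruct import designated_pairs, interpolate_coords, make_toy_dimer, write_pdb
from .traj import Trajectory, distance_series, domain_rmsd, radius_of_gyration, timescale_report

STAGE_ORDER = ("simulate", "bursts", "pda", "fcs", "structures", "av", "traj")
_DEPENDS = {
    "bursts": ("simulate",),
    "pda": ("bursts",),
    "fcs": ("simulate",),
    "av": ("structures",),
    "traj": ("structures",),
}


def demo_config(duration: float = 20.0) -> dict:
    """Bundled demo: three-state exchange with the well-resolved
    nucleotide-analogue-like populations, all stages enabled."""
    return {
        "seed": 1,
        "stages": {
            "simulate": {"enabled": True,
                         "scheme": {"weights": [0.20, 0.31, 0.49],
                                    "mu_R": [75.0, 55.0, 45.0],
                                    "sigma_R": [3.0, 2.0, 2.0]},
                         "config": {"duration": duration, "alpha": 0.05,
                                    "delta": 0.0}},
            "bursts": {"enabled": True, "m": 10, "T": 5e-4, "L_min": 50},
            "pda": {"enabled": True, "K": 3},
            "fcs": {"enabled": True, "n_terms": 2},
            "structures": {"enabled": True, "n_res_per_domain": 8, "n_frames": 12},
            "av": {"enabled": True, "grid_spacing": 2.0, "R0": 65.0},
            "traj": {"enabled": True},
        },
    }


def validate_config(config: dict) -> list[str]:
    """Schema and cross-field checks; violations are returned, not raised."""
    v = []
    if "stages" not in config or not isinstance(config["stages"], dict):
        return ["missing 'stages' mapping"]
    stages = config["stages"]
    if not isinstance(config.get("seed", 0), int):
        v.append("seed must be an integer")
    for name, spec in stages.items():
        if name not in STAGE_ORDER:
            v.append(f"unknown stage '{name}'")
            continue
        if not spec.get("enabled", False):
            continue
        inp = spec.get("input")
        if inp is not None and not Path(inp).exists():
            v.append(f"stage '{name}': input path '{inp}' does not exist")
        for dep in _DEPENDS.get(name, ()):
            dep_on = stages.get(dep, {}).get("enabled", False)
            if not dep_on and spec.get("input") is None:
                v.append(f"stage '{name}' requires stage '{dep}' or an input path")
    sim = stages.get("simulate", {})
    if sim.get("enabled") and "scheme" in sim:
        sch = sim["scheme"]
        if "rate_matrix" in sch and np.any(np.asarray(sch["rate_matrix"]) < 0):
            v.append("simulate.scheme.rate_matrix has negative rates")
        if "weights" in sch and np.any(np.asarray(sch["weights"]) < 0):
            v.append("simulate.scheme.weights has negative entries")
    if stages.get("pda", {}).get("enabled") and stages.get("av", {}).get("enabled"):
        r0_pda = stages.get("pda", {}).get("R0",
                  sim.get("config", {}).get("R0", 65.0))
        r0_av = stages.get("av", {}).get("R0", 65.0)
        if not np.isclose(r0_pda, r0_av):
            v.append("PDA R0 and AV R0 differ while both stages are enabled")
    return v


def _build_scheme(spec: dict) -> KineticScheme:
    if "rate_matrix" in spec:
        return KineticScheme(spec.get("labels", [f"s{i}" for i in
                                                 range(len(spec["mu_R"]))]),
                             np.asarray(spec["mu_R"], float),
                             np.asarray(spec["sigma_R"], float),
                             np.asarray(spec["rate_matrix"], float))
    return three_state_scheme(spec["weights"], tuple(spec.get("mu_R", (75.0, 55.0, 45.0))),
                              tuple(spec.get("sigma_R", (3.0, 2.0, 2.0))))


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages in dependency order; returns (and writes)
    the run report."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    seed = int(config.get("seed", 0))
    children = np.random.SeedSequence(seed).spawn(len(STAGE_ORDER))
    child_seed = {name: int(ss.generate_state(1)[0] % (2 ** 31))
                  for name, ss in zip(STAGE_ORDER, children)}

    report: dict = {"seed": seed, "version": __version__, "stages": {}}
    status: dict[str, str] = {}
    artefacts: dict[str, object] = {}

    def enabled(name):
        return stages.get(name, {}).get("enabled", False)

    def deps_ok(name):
        return all(status.get(d) == "ok" or stages.get(name, {}).get("input")
                   for d in _DEPENDS.get(name, ()))

    for name in STAGE_ORDER:
        if not enabled(name):
            status[name] = "disabled"
            continue
        if not deps_ok(name):
            status[name] = "skipped (failed dependency)"
            report["stages"][name] = {"status": status[name]}
            continue
        spec = stages[name]
        try:
            result = _STAGE_FUNCS[name](spec, child_seed[name], outdir,
                                        artefacts, stages)
            status[name] = "ok"
            report["stages"][name] = {"status": "ok", "seed": child_seed[name],
                                      **result}
        except Exception as err:  # stage isolation
            status[name] = "failed"
            report["stages"][name] = {"status": "failed", "error": str(err)}

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


# --- stage implementations -------------------------------------------------

def _stage_simulate(spec, seed, outdir, art, stages):
    scheme = _build_scheme(spec["scheme"])
    cfg = SimConfig(**{**spec.get("config", {}), "seed": seed})
    stream = simulate_photon_stream(scheme, cfg)
    save_photon_hdf5(outdir / "photons.h5", stream)
    art["stream"], art["scheme"], art["simcfg"] = stream, scheme, cfg
    return {"n_photons": len(stream), "duration_s": cfg.duration,
            "output": str(outdir / "photons.h5")}


def _stage_bursts(spec, seed, outdir, art, stages):
    stream = art.get("stream")
    if stream is None:
        stream = load_photon_hdf5(spec["input"])
        art["stream"] = stream
    cfg = art.get("simcfg")
    cf = CorrectionFactors(
        alpha=spec.get("alpha", cfg.alpha if cfg else 0.0),
        delta=spec.get("delta", cfg.delta if cfg else 0.0),
        gamma_=spec.get("gamma", cfg.gamma_ if cfg else 1.0),
        beta_=spec.get("beta", cfg.beta_ if cfg else 1.0),
        bg_rates=spec.get("bg_rates", cfg.background_rates if cfg
                          else {"DD": 0.0, "DA": 0.0, "AA": 0.0}),
    )
    df = process_bursts(stream, cf, m=spec.get("m", 10), T=spec.get("T", 5e-4),
                        L_min=spec.get("L_min", 50))
    df.to_csv(outdir / "bursts.csv", index=False)
    art["bursts"], art["corrections"] = df, cf
    return {"n_bursts": len(df), "output": str(outdir / "bursts.csv")}


def _stage_pda(spec, seed, outdir, art, stages):
    df = art["bursts"]
    mid = df[df["species"] == "mid"]
    cfg = art.get("simcfg")
    cf = art.get("corrections")
    r0 = spec.get("R0", cfg.R0 if cfg else 65.0)
    hist = proximity_histogram(mid["F_DA"], mid["F_DD"])
    sizes = BurstSizeDistribution.from_counts((mid["F_DA"] + mid["F_DD"]).to_numpy(),
                                              mid["duration"].to_numpy())
    mean_dur = float(mid["duration"].mean())
    bg_d = (cf.bg_rates.get("DD", 0.0) if cf else 0.0) * mean_dur / 2
    bg_a = (cf.bg_rates.get("DA", 0.0) if cf else 0.0) * mean_dur / 2
    fit = fit_pda(hist, spec.get("K", 3), R0=r0, burst_sizes=sizes,
                  bg_D=bg_d, bg_A=bg_a, alpha=cf.alpha if cf else 0.0,
                  fixed_mu=spec.get("fixed_mu"), seed=seed,
                  n_starts=spec.get("n_starts", 16))
    states = [{"mu_R": s.mu_R, "sigma_R": s.sigma_R, "weight": s.weight}
              for s in fit.model.states]
    ratio = None
    if len(states) >= 3:
        ratio = state_ratio(fit, 1, 2, n_boot=spec.get("n_boot", 30), seed=seed)
    out = {"states": states, "chi2_red": fit.chi2_red,
           "closedB_over_closedA": ratio}
    (outdir / "pda_fit.json").write_text(json.dumps(out, indent=2))
    np.savetxt(outdir / "pda_hist.csv",
               np.column_stack([hist.centers, hist.counts]),
               delimiter=",", header="E_center,count", comments="")
    art["pda_fit"] = fit
    return out


def _stage_fcs(spec, seed, outdir, art, stages):
    stream = art["stream"]
    curves = {p: correlate(stream, p, segments=spec.get("segments", 10))
              for p in ("DonxDon", "FRETxFRET", "DonxFRET")}
    rows = []
    for name, c in curves.items():
        for l, g, s in zip(c.lag, c.G, c.sem):
            rows.append(f"{name},{l},{g},{s}")
    (outdir / "fcs_curves.csv").write_text("pair,lag_s,G,sem\n" + "\n".join(rows))
    fit = global_fit(curves, n_terms=spec.get("n_terms", 2))
    out = {
        "tau_fast_us": fit.shared_taus[0] * 1e6,
        "tau_slow_us": fit.shared_taus[-1] * 1e6,
        "chi2_red": fit.chi2_red,
        "resolved": bool(fit.resolved),
        "amplitudes": {n: [a for a, _ in m.kinetic_terms]
                       for n, m in fit.models.items()},
        "kinetic_weights": {n: list(fit.kinetic_weights(n))
                            for n in fit.models},
    }
    (outdir / "fcs_fit.json").write_text(json.dumps(out, indent=2))
    return out


def _stage_structures(spec, seed, outdir, art, stages):
    n = spec.get("n_res_per_domain", 8)
    a = make_toy_dimer(n, "closedA", seed)
    b = make_toy_dimer(n, "closedB", seed)
    coords = interpolate_coords(a, b, spec.get("n_frames", 12))
    write_pdb(outdir / "closedA.pdb", a)
    write_pdb(outdir / "closedB.pdb", b)
    write_pdb(outdir / "trajectory.pdb", a, coords)
    art["struct_A"], art["struct_B"], art["traj_coords"] = a, b, coords
    return {"n_frames": len(coords), "n_atoms": a.n_atoms}


def _stage_av(spec, seed, outdir, art, stages):
    a = art["struct_A"]
    coords = art["traj_coords"]
    dye = DyeParams(**spec.get("dye", {}))
    pairs = {f"pair{i+1}": (a.atom_index(*p[0]), a.atom_index(*p[1]))
             for i, p in enumerate(designated_pairs(a))}
    df = ensemble_distributions(coords, a.vdw_radius, pairs, dye,
                                spec.get("R0", 65.0),
                                spec.get("grid_spacing", 2.0), seed=seed)
    df.to_csv(outdir / "av_distances.csv", index=False)
    n = len(coords)
    summary = {}
    for label in pairs:
        sub = df[df["pair"] == label]
        summary[label] = {
            "start_mean_R_app": float(sub[sub["model"] < n // 4]["R_app"].mean()),
            "end_mean_R_app": float(sub[sub["model"] >= 3 * n // 4]["R_app"].mean()),
        }
    return {"pairs": summary}


def _stage_traj(spec, seed, outdir, art, stages):
    a = art["struct_A"]
    coords = art["traj_coords"]
    traj = Trajectory.from_structure(a, coords)
    rg = radius_of_gyration(traj)
    m_idx = traj.select(res_range=a.domain_map["M"])
    n_idx = traj.select(res_range=a.domain_map["N"])
    rmsd_m = domain_rmsd(traj, n_idx, m_idx, coords[-1])
    pair = designated_pairs(a)[0]
    d = distance_series(traj, np.array([a.atom_index(*pair[0])]),
                        np.array([a.atom_index(*pair[1])]), mode="atom")
    np.savetxt(outdir / "traj_observables.csv",
               np.column_stack([traj.times, rg, rmsd_m, d]), delimiter=",",
               header="time,Rg,rmsd_M_in_N_frame,d_pair1", comments="")
    series = {"rmsd_M": (traj.times, rmsd_m.max() - rmsd_m),
              "contraction": (traj.times, d.max() - d)}
    thresholds = {k: 0.5 * (v[1].max() + v[1].min()) for k, v in series.items()}
    events = timescale_report(series, thresholds)
    return {"Rg_first": float(rg[0]), "Rg_last": float(rg[-1]),
            "events": events.to_dict("records")}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "bursts": _stage_bursts,
    "pda": _stage_pda,
    "fcs": _stage_fcs,
    "structures": _stage_structures,
    "av": _stage_av,
    "traj": _stage_traj,
}
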