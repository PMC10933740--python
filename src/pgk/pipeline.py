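"""Scenario orchestration: end-to-end runs with a single JSON report format.

Four scenarios chain the library stages:

* ``reference-lattices`` — regenerate the five (q4, q6) classification
  references and their pairwise distance table (deterministic).
* ``saxs-roundtrip`` — synthesise a noisy scattering profile from known
  parameters, fit it, report recovered vs true values.
* ``patchy-sediment`` — sediment tetrahedral patchy particles to a target
  packing fraction, then contact statistics + BOO classification.
* ``tomogram-emulation`` — voxelize a ground-truth assembly, degrade it
  (shrinkage/deformation/noise), extract spheres, apply the isotropic
  rescale correction, and compare recovered statistics with the truth.

Reports are plain dictionaries (JSON-serialisable), schema-versioned, and
bit-reproducible for identical config + seed.
"""

from __future__ import annotations

import json
import time
import traceback
import numpy as np

import pgk
from pgk.assembly import RunConfig, SphereAssembly
from pgk.boo import averaged_boo, classify_structure, reference_points
from pgk.contacts import contact_graph, n_touch_distribution, select_bulk
from pgk.lattices import JamSpec, generate_jammed_packing
from pgk.patchy import PatchyModel, SimSettings, equilibrate_to_density
from pgk.saxs import SAXSModelParams, fit_saxs, synthetic_profile
from pgk.tomo import DegradationSpec, degrade, extract_spheres, rescale_assembly, voxelize

__all__ = ["run_pipeline", "SCENARIOS", "DEFAULT_GRAVITY"]

REPORT_SCHEMA = 1

# Gravity (k_BT/sigma) that equilibrates the default patchy sediment near
# phi = 0.46; the starting point for the bisection in equilibrate_to_density.
DEFAULT_GRAVITY = 0.65


def _scenario_reference_lattices(cfg: RunConfig) -> dict:
    params = cfg.stages.get("reference_lattices", {})
    refs = reference_points(include_mrj=params.get("include_mrj", True),
                            mrj_seed=cfg.seed + 12345)
    table = {}
    for r in refs:
        _, dists = classify_structure(r.q4, r.q6, refs)
        table[r.label] = {"q4": r.q4, "q6": r.q6,
                          "provenance": r.provenance,
                          "distances": dists}
    return {"references": table}


def _scenario_saxs_roundtrip(cfg: RunConfig) -> dict:
    p = cfg.stages.get("saxs", {})
    true = SAXSModelParams(
        d_mean=p.get("d_mean", 218.0), d_sd=p.get("d_sd", 26.0),
        phi=p.get("phi", 0.49), scale=p.get("scale", 1.0),
        background=p.get("background", 1e-4))
    model = p.get("model", "py")
    rng = np.random.default_rng(cfg.seed)
    prof = synthetic_profile(true, model=model,
                             noise=p.get("noise", 0.02), rng=rng)
    init = SAXSModelParams(d_mean=true.d_mean * 1.15, d_sd=true.d_mean * 0.05,
                           phi=0.4, scale=true.scale * 0.5,
                           background=true.background,
                           tau=0.5 if model == "sticky" else None)
    fitted, unc, redchi = fit_saxs(prof, model, init)
    return {
        "true": {"d_mean": true.d_mean, "d_sd": true.d_sd, "phi": true.phi},
        "fitted": {"d_mean": fitted.d_mean, "d_sd": fitted.d_sd,
                   "phi": fitted.phi, "tau": fitted.tau,
                   "scale": fitted.scale, "background": fitted.background},
        "uncertainties": unc, "redchi": redchi,
        "rel_err_d_mean": abs(fitted.d_mean - true.d_mean) / true.d_mean,
        "rel_err_phi": abs(fitted.phi - true.phi) / true.phi,
    }


def _sediment(cfg: RunConfig):
    p = cfg.stages.get("patchy", {})
    model = PatchyModel(sigma=p.get("sigma", 210.0),
                        eps_patch=p.get("eps_patch", 8.0),
                        eps_body=p.get("eps_body", 3.0),
                        gravity=p.get("gravity", DEFAULT_GRAVITY))
    settings = SimSettings(dt=p.get("dt", 0.002),
                           steps=p.get("steps", 100_000),
                           seed=cfg.seed,
                           validate_dt=p.get("validate_dt", True))
    final, phi, g = equilibrate_to_density(
        model, p.get("target_phi", 0.46), settings,
        n=p.get("n", 1080), lateral=p.get("lateral", 8.0),
        initial_g=p.get("gravity", DEFAULT_GRAVITY))
    return final, phi, g


def _structure_report(a: SphereAssembly, gap: float,
                      bulk: bool, mrj_seed: int) -> dict:
    subset = select_bulk(a) if bulk else None
    g = contact_graph(a, gap_tol=gap)
    summ = n_touch_distribution(g, subset=subset)
    boo = averaged_boo(a, gap_tol=gap)
    sel = subset if subset is not None else slice(None)
    q4 = float(np.nanmean(boo.q[4][sel]))
    q6 = float(np.nanmean(boo.q[6][sel]))
    q4bar = float(np.nanmean(boo.q_avg[4][sel]))
    q6bar = float(np.nanmean(boo.q_avg[6][sel]))
    refs = reference_points(mrj_seed=mrj_seed)
    label, dists = classify_structure(q4, q6, refs)
    return {"contacts": summ.as_dict(),
            "boo": {"q4_mean": q4, "q6_mean": q6,
                    "q4bar_mean": q4bar, "q6bar_mean": q6bar,
                    "classification": label, "distances": dists}}


def _scenario_patchy_sediment(cfg: RunConfig) -> dict:
    final, phi, g = _sediment(cfg)
    rep = _structure_report(final, cfg.contact_gap, bulk=True,
                            mrj_seed=12345)
    rep["achieved_phi"] = phi
    rep["gravity"] = g
    rep["n"] = final.n
    return rep


def _scenario_tomogram_emulation(cfg: RunConfig) -> dict:
    p = cfg.stages.get("tomo", {})
    src = p.get("source", "jam")
    if src == "patchy":
        truth, phi, _ = _sediment(cfg)
        truth = truth.copy()
        truth.periodic = np.array([False] * 3)
    else:
        truth = generate_jammed_packing(JamSpec(n=p.get("n", 400),
                                                seed=cfg.seed))
        # scale so spheres have the nominal tomogram diameter, then
        # re-frame as a finite walled field of view
        truth = rescale_assembly(truth,
                                 p.get("d_nm", 210.0) / (2 * truth.radii.mean()))
        from pgk.tomo import as_walled_sample
        truth = as_walled_sample(truth)
    gap = cfg.contact_gap
    g_true = contact_graph(truth, gap_tol=gap)
    true_summ = n_touch_distribution(g_true)

    shrink = p.get("shrink_factor", 0.83)
    vol = voxelize(truth, pitch=cfg.voxel_pitch)
    spec = DegradationSpec(shrink_factor=shrink,
                           deform_amplitude=p.get("deform_amplitude", 8.0),
                           noise_rate=p.get("noise_rate", 0.002),
                           seed=cfg.seed)
    degraded = degrade(vol, spec)
    extracted = extract_spheres(degraded,
                                expected_radius=shrink * float(truth.radii.mean()))
    if extracted is None:
        raise RuntimeError("no particles recovered from degraded volume")
    corrected = rescale_assembly(extracted, 1.0 / shrink)
    g_rec = contact_graph(corrected, gap_tol=gap)
    rec_summ = n_touch_distribution(g_rec)
    rep = _structure_report(corrected, gap, bulk=False, mrj_seed=12345)
    rep.update({
        "true_n": truth.n, "recovered_n": extracted.n,
        "true_mean_n_touch": true_summ.n_touch_mean,
        "recovered_mean_n_touch": rec_summ.n_touch_mean,
        "true_mean_diameter_nm": float(2 * truth.radii.mean()),
        "recovered_mean_diameter_nm": float(2 * corrected.radii.mean()),
        "shrink_factor": shrink,
    })
    return rep


SCENARIOS = {
    "reference-lattices": _scenario_reference_lattices,
    "saxs-roundtrip": _scenario_saxs_roundtrip,
    "patchy-sediment": _scenario_patchy_sediment,
    "tomogram-emulation": _scenario_tomogram_emulation,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute a scenario's stage chain; returns the JSON-ready report.

    Identical config + seed reproduces all numerics bit-identically.  A
    stage failure is recorded in the report (status 'failed'); nothing
    downstream runs.
    """
    if config.scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {config.scenario!r}; "
                         f"choose from {sorted(SCENARIOS)}")
    report = {
        "schema": REPORT_SCHEMA,
        "package_version": pgk.__version__,
        "scenario": config.scenario,
        "seed": config.seed,
        "config": {"voxel_pitch": config.voxel_pitch,
                   "contact_gap": config.contact_gap,
                   "stages": config.stages},
    }
    t0 = time.perf_counter()
    try:
        report["result"] = SCENARIOS[config.scenario](config)
        report["status"] = "ok"
    except Exception as exc:  # recorded, not raised: partial report contract
        report["status"] = "failed"
        report["error"] = f"{type(exc).__name__}: {exc}"
        report["traceback"] = traceback.format_exc(limit=5)
    report["wallclock_s"] = round(time.perf_counter() - t0, 3)
    return report


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")
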