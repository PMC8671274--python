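"""End-to-end two-stage workflow orchestration.

``run_all`` executes the complete study on the synthetic geometry: build
the anatomy and its coordinate frame, the fascicle-based HPS, the
Purkinje-based HPS, simulate sinus rhythm and RV apical pacing with both
representations, render and post-process the 12-lead pseudo-ECGs and
compare them.  As in the two-stage personalization idea, the fascicle
timings for the comparison are taken from the Purkinje model's own
simulated root timings, so both representations share earliest-activation
sites and instants; the printed baseline timings remain available on the
returned fascicle config.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .activation import run_scenario
from .config import FASCICLE_ORDER, baseline_config, override, save_config
from .ecg import (
    compare_ecg,
    default_electrodes,
    ms_action_potential,
    postprocess_ecg,
    pseudo_ecg_12lead,
)
from .fascicle import build_fascicle_hps, select_se_layer
from .geometry import GeometryParams, generate_ideal_biv
from .purkinje import build_full_purkinje
from . import io as hio


def run_all(
    seed: int,
    outdir: str | Path | None = None,
    geometry: GeometryParams | None = None,
    configs=None,
    match_timings: bool = True,
    log=print,
):
    """Run the full two-representation study; optionally persist artifacts.

    Returns a dict with the built objects, activation maps, ECGs and the
    per-scenario fascicle-vs-Purkinje comparison metrics.
    """
    timings = {}
    eas, fas, purk, sim = configs or baseline_config()

    t0 = time.perf_counter()
    mesh, frame = generate_ideal_biv(geometry, seed)
    layer = select_se_layer(frame, eas, mesh)
    timings["geometry"] = time.perf_counter() - t0
    log(f"geometry: {len(mesh.nodes)} nodes, {len(mesh.elements)} tets, "
        f"SE layer {len(layer.node_indices)} nodes")

    t0 = time.perf_counter()
    net = build_full_purkinje(mesh, frame, layer, eas, purk, seed)
    timings["purkinje"] = time.perf_counter() - t0
    log(f"purkinje HPS: {len(net)} nodes, {net.n_segments} segments, "
        f"{len(net.pvj_couplings)} PVJs ({net.pvj_dropped} dropped)")

    t0 = time.perf_counter()
    amap_p_sinus, roots_p = run_scenario(mesh, frame, net, sim, "sinus")
    if match_timings:
        fas_run = override(fas, t_his=tuple(roots_p[n] for n in FASCICLE_ORDER))
    else:
        fas_run = fas
    hps = build_fascicle_hps(frame, layer, eas, fas_run)
    amap_f_sinus, roots_f = run_scenario(mesh, frame, hps, sim, "sinus")
    amap_p_pace, _ = run_scenario(mesh, frame, net, sim, "rv_apical")
    amap_f_pace, _ = run_scenario(mesh, frame, hps, sim, "rv_apical")
    timings["activation"] = time.perf_counter() - t0
    log("purkinje sinus EAS timings (ms): "
        + ", ".join(f"{n}={roots_p[n]:.2f}" for n in FASCICLE_ORDER))

    t0 = time.perf_counter()
    tmpl = ms_action_potential()
    electrodes = default_electrodes(mesh)
    ecgs, comparisons = {}, {}
    for scen, amap_p, amap_f in (
        ("sinus", amap_p_sinus, amap_f_sinus),
        ("rv_apical", amap_p_pace, amap_f_pace),
    ):
        raw_p = pseudo_ecg_12lead(amap_p, mesh, tmpl, electrodes, sim)
        raw_f = pseudo_ecg_12lead(amap_f, mesh, tmpl, electrodes, sim)
        ref = postprocess_ecg(raw_p)
        ali = postprocess_ecg(raw_f, reference=ref)
        ecgs[("purkinje", scen)] = ref
        ecgs[("fascicle", scen)] = ali
        comparisons[scen] = compare_ecg(ali, ref)
    timings["ecg"] = time.perf_counter() - t0
    log(f"ECG agreement: sinus mean r={comparisons['sinus']['mean_r']:.3f}, "
        f"rv_apical mean r={comparisons['rv_apical']['mean_r']:.3f}")

    result = {
        "mesh": mesh, "frame": frame, "layer": layer, "net": net, "hps": hps,
        "configs": (eas, fas_run, purk, sim),
        "activation": {
            ("purkinje", "sinus"): amap_p_sinus,
            ("fascicle", "sinus"): amap_f_sinus,
            ("purkinje", "rv_apical"): amap_p_pace,
            ("fascicle", "rv_apical"): amap_f_pace,
        },
        "eas_timings": {"purkinje": roots_p, "fascicle": roots_f},
        "ecgs": ecgs,
        "comparisons": comparisons,
        "timings": timings,
        "seed": seed,
    }
    if outdir is not None:
        write_artifacts(Path(outdir), result)
    return result


def write_artifacts(outdir: Path, result):
    """Persist every stage artifact; the manifest stays byte-deterministic
    (wall times go to a separate informational log)."""
    outdir.mkdir(parents=True, exist_ok=True)
    mesh, frame, net = result["mesh"], result["frame"], result["net"]
    eas, fas, purk, sim = result["configs"]
    paths = {}

    save_config(outdir / "config.yaml", eas, fas, purk, sim)
    paths["config"] = "config.yaml"
    hio.write_vtu(outdir / "biv.vtu", mesh, frame)
    hio.write_carp(outdir / "biv", mesh)
    (outdir / "frame.json").write_text(json.dumps({
        "target_edge_length": frame.target_edge_length,
        "l_ab": {str(k): v for k, v in frame.l_ab.items()},
        "params": asdict(mesh.params) if mesh.params else None,
    }, indent=1))
    paths["geometry"] = ["biv.vtu", "biv.pts", "biv.elem", "biv.lon", "biv.surf", "frame.json"]

    hio.write_vtp(outdir / "hps.vtp", net)
    hio.write_cable(outdir / "hps.cable", net)
    hio.write_pvj_couplings(outdir / "pvj_couplings.txt", net)
    paths["purkinje"] = ["hps.vtp", "hps.cable", "pvj_couplings.txt"]

    hps = result["hps"]
    disc_tag = np.full(len(mesh.nodes), -1.0)
    for k, name in enumerate(FASCICLE_ORDER):
        disc_tag[hps.disc_nodes[name]] = k
    hio.write_dat(outdir / "se_layer.dat", hps.layer._member.astype(float))
    hio.write_dat(outdir / "fascicle_discs.dat", disc_tag)
    paths["fascicle"] = ["se_layer.dat", "fascicle_discs.dat"]

    paths["activation"] = []
    for (model, scen), amap in result["activation"].items():
        name = f"act_{model}_{scen}.dat"
        hio.write_dat(outdir / name, amap.tissue_times)
        paths["activation"].append(name)
    with open(outdir / "eas_timings.csv", "w") as f:
        f.write("model," + ",".join(FASCICLE_ORDER) + "\n")
        for model, rep in result["eas_timings"].items():
            f.write(model + "," + ",".join(repr(rep[n]) for n in FASCICLE_ORDER) + "\n")
    paths["activation"].append("eas_timings.csv")

    paths["ecg"] = []
    for (model, scen), ecg in result["ecgs"].items():
        name = f"ecg_{model}_{scen}.csv"
        hio.write_ecg_csv(outdir / name, ecg)
        paths["ecg"].append(name)
    (outdir / "comparison.json").write_text(json.dumps(result["comparisons"], indent=1))
    paths["compare"] = ["comparison.json"]

    manifest = {
        "seed": result["seed"],
        "version": __version__,
        "paths": paths,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    # stage wall times are informational only and go to the stderr log,
    # never into artifacts, so repeated runs stay byte-identical
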