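"""End-to-end drivers and the ``run-all`` orchestration.

Two entry points mirror the two experimental arms:

* :func:`analyze_compression` — one full stiffness measurement: simulate
  (or accept) a reference + loaded image sequence, track the tips,
  convert deflections to forces, infer the compression from the tracked
  tip separation, and fit the Young's modulus.
* :func:`analyze_tem_strip` — one TEM strip: generate the tessellation,
  cut panels, select center/outer panels, measure space densities, apply
  the complete-cell filter and the inner/outer partition.

:func:`run_all` chains both arms for the configured presets, writes every
artifact under the output directory and returns a manifest mapping each
artifact path to its SHA-256 content hash.  All randomness flows from the
single seed via ``numpy.random.SeedSequence`` spawning; identical seeds
give identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from . import presets as _presets
from .config import PipelineConfig, write_effective_config
from .mechanics import (
    ForceDisplacementCurve,
    ModulusEstimate,
    cantilever_spring_constant,
    compression_series,
    fit_modulus,
    force_from_deflection,
    force_ratio,
)
from .morphometry import (
    complete_cells_in_panels,
    intercellular_space_density,
    partition_regions,
    select_density_panels,
    summarize_groups,
)
from .specs import ActuationProfile, CantileverSpec, SpheroidSpec
from .stats import build_report, welch_t_test
from .synth_mech import FrameSpec, make_tip_template, simulate_compression_experiment
from .synth_tem import render_tem_panels, sample_cell_tessellation
from .tracking import TipTemplate, compute_deflections, track_tips

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompressionResult:
    estimate: ModulusEstimate
    curve: ForceDisplacementCurve
    deflections_um: np.ndarray
    separation_um: np.ndarray
    truth: object  # SyntheticGroundTruth for synthetic runs
    trajectories: tuple  # (loaded, reference)


def analyze_compression(
    spheroid: SpheroidSpec,
    seed: int = 0,
    profile: ActuationProfile | None = None,
    cantilever: CantileverSpec | None = None,
    noise_sd: float = 0.02,
    frame: FrameSpec | None = None,
    initial_separation_um: float = 500.0,
    search_radius: int = 10,
    score_floor: float = 0.5,
) -> CompressionResult:
    """Simulate and analyze one complete compression experiment."""
    profile = profile or _presets.ACTUATION
    cantilever = cantilever or _presets.CANTILEVER
    frame = frame or FrameSpec()
    ref_frames, load_frames, truth = simulate_compression_experiment(
        profile, cantilever, spheroid, frame=frame, noise_sd=noise_sd, seed=seed,
        initial_separation_um=initial_separation_um)
    template = TipTemplate(make_tip_template())
    init = truth.reference_positions_px[0]
    reference = track_tips(ref_frames, template, init, search_radius, score_floor,
                           run="reference")
    loaded = track_tips(load_frames, template, init, search_radius, score_floor,
                        run="loaded")
    deflections = compute_deflections(loaded, reference, frame.pixel_pitch_um)
    spring_k = cantilever_spring_constant(cantilever)
    forces = force_from_deflection(deflections.deflections_um, spring_k)
    delta, contact_step = compression_series(deflections.separation_um,
                                             spheroid.diameter_um)
    curve = ForceDisplacementCurve(delta, forces, contact_step,
                                   spheroid.radius_um, spheroid.poisson_ratio)
    estimate = fit_modulus(curve)
    return CompressionResult(estimate=estimate, curve=curve,
                             deflections_um=deflections.deflections_um,
                             separation_um=deflections.separation_um,
                             truth=truth, trajectories=(loaded, reference))


@dataclass(frozen=True)
class TemStripResult:
    strip: object
    panels: list
    center_density_pct: float
    outer_density_pct: float
    cell_records: pd.DataFrame  # complete cells: region + areas


def analyze_tem_strip(
    tem_presets: dict,
    diameter_um: float,
    seed: int = 0,
    strip_height_um: float = 100.0,
    panel_width_um: float = 60.0,
    panel_overlap: float = 0.1,
    resolution_px_per_um: float = 2.0,
    group: str = "custom",
    render: bool = False,
) -> TemStripResult:
    """Generate and analyze one TEM strip end to end."""
    strip = sample_cell_tessellation(diameter_um, strip_height_um, tem_presets,
                                     seed=seed)
    panels, _cells_per_panel = render_tem_panels(
        strip, panel_width_um, panel_overlap, resolution_px_per_um, render=render)
    center, outer_pair = select_density_panels(panels)
    center_density = intercellular_space_density(center, strip.cells,
                                                 resolution_px_per_um)
    outer_density = float(np.mean([
        intercellular_space_density(p, strip.cells, resolution_px_per_um)
        for p in outer_pair]))
    complete = complete_cells_in_panels(strip.cells, panels)
    labels = partition_regions(complete, (0.0, strip.length_um))
    records = pd.DataFrame({
        "group": group,
        "region": labels,
        "cell_area_um2": [c.cell_area for c in complete],
        "nucleus_area_um2": [c.nucleus_area for c in complete],
        "cell_id": [c.cell_id for c in complete],
    })
    return TemStripResult(strip=strip, panels=panels,
                          center_density_pct=center_density,
                          outer_density_pct=outer_density, cell_records=records)


def _spheroid_for(config: PipelineConfig, preset: str) -> SpheroidSpec:
    if preset in _presets.SPHEROIDS:
        return _presets.SPHEROIDS[preset]
    if config.diameter_um is None or config.youngs_modulus_pa is None:
        raise ValueError("custom preset needs diameter_um and youngs_modulus_pa")
    return SpheroidSpec(config.diameter_um, config.youngs_modulus_pa,
                        config.poisson_ratio)


def run_all(config: PipelineConfig, presets_to_run=("day5", "day20")) -> dict[str, str]:
    """Run both arms for each preset; write artifacts; return the manifest.

    The manifest maps every written artifact (relative path) to its
    SHA-256 hash; it is itself written as ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_effective_config(config, out)
    root_seq = np.random.SeedSequence(config.seed)
    arm_seeds = {p: s for p, s in zip(presets_to_run, root_seq.spawn(len(presets_to_run)))}

    cantilever = (_presets.CANTILEVER if config.spring_constant is None
                  else CantileverSpec(spring_constant=config.spring_constant))
    frame = FrameSpec(pixel_pitch_um=config.pixel_pitch_um)

    moduli: dict[str, tuple[float, float, int]] = {}
    modulus_samples: dict[str, list[float]] = {}
    all_cells, all_densities = [], []

    for preset in presets_to_run:
        log.info("[%s] mechanics arm: %d runs", preset, config.n_mech_runs)
        spheroid = _spheroid_for(config, preset)
        mech_seeds = arm_seeds[preset].spawn(config.n_mech_runs + config.n_tem_strips)
        pdir = out / preset
        pdir.mkdir(exist_ok=True)
        estimates = []
        for i in range(config.n_mech_runs):
            seed_i = int(mech_seeds[i].generate_state(1)[0] % 2**31)
            result = analyze_compression(
                spheroid, seed=seed_i, cantilever=cantilever,
                noise_sd=config.noise_sd, frame=frame,
                initial_separation_um=config.initial_separation_um,
                search_radius=config.search_radius_px,
                score_floor=config.score_floor)
            estimates.append(result.estimate.youngs_modulus_pa)
            run_dir = pdir / f"mech_run_{i:02d}"
            run_dir.mkdir(exist_ok=True)
            loaded, reference = result.trajectories
            defl = compute_deflections(loaded, reference, config.pixel_pitch_um)
            sio.write_trajectory_csv(run_dir / "trajectories.csv", loaded, reference, defl)
            sio.write_curve_csv(run_dir / "curve.csv", result.curve.compression_um,
                                result.curve.force_n)
            sio.write_estimate_json(run_dir / "estimate.json", result.estimate)
            sio.write_ground_truth_json(run_dir / "ground_truth.json", result.truth)
            if i == 0:
                ref_frames, load_frames, _ = simulate_compression_experiment(
                    _presets.ACTUATION, cantilever, spheroid, frame=frame,
                    noise_sd=config.noise_sd, seed=seed_i,
                    initial_separation_um=config.initial_separation_um)
                sio.write_image_sequence(ref_frames, run_dir / "reference")
                sio.write_image_sequence(load_frames, run_dir / "loaded")
        est = np.asarray(estimates)
        moduli[preset] = (float(est.mean()),
                          float(est.std(ddof=1)) if len(est) >= 2 else 0.0, len(est))
        modulus_samples[preset] = estimates

        log.info("[%s] TEM arm: %d strips", preset, config.n_tem_strips)
        tem = _presets.TEM_PRESETS.get(preset, _presets.TEM_PRESETS["day5"])
        for i in range(config.n_tem_strips):
            seed_i = int(mech_seeds[config.n_mech_runs + i].generate_state(1)[0] % 2**31)
            strip_result = analyze_tem_strip(
                tem, spheroid.diameter_um, seed=seed_i,
                strip_height_um=config.strip_height_um,
                panel_width_um=config.panel_width_um,
                panel_overlap=config.panel_overlap,
                resolution_px_per_um=config.resolution_px_per_um,
                group=preset)
            sio.write_cells_geojson(pdir / f"strip_{i:02d}.geojson",
                                    strip_result.strip.cells)
            sio.write_panels_csv(pdir / f"strip_{i:02d}_panels.csv",
                                 strip_result.panels)
            all_cells.append(strip_result.cell_records)
            all_densities.extend([
                {"group": preset, "spheroid": i, "region": "inner",
                 "density_pct": strip_result.center_density_pct},
                {"group": preset, "spheroid": i, "region": "outer",
                 "density_pct": strip_result.outer_density_pct},
            ])

    cell_records = pd.concat(all_cells, ignore_index=True)
    density_records = pd.DataFrame(all_densities)
    summary = summarize_groups(cell_records, density_records)
    sio.write_summary(out, summary)

    comparisons = []
    if len(modulus_samples) == 2 and all(len(s) >= 2 for s in modulus_samples.values()):
        a, b = presets_to_run
        comparisons.append(welch_t_test(modulus_samples[b], modulus_samples[a],
                                        label_a=b, label_b=a))
    for preset in presets_to_run:
        sub = cell_records[cell_records["group"] == preset]
        inner = sub[sub["region"] == "inner"]["cell_area_um2"]
        outer = sub[sub["region"] == "outer"]["cell_area_um2"]
        if len(inner) >= 2 and len(outer) >= 2:
            comparisons.append(welch_t_test(inner, outer,
                                            label_a=f"{preset}:inner",
                                            label_b=f"{preset}:outer"))
    report = build_report(summary, comparisons, moduli,
                          expected_groups=list(presets_to_run))
    (out / "report.md").write_text(report.to_markdown() + "\n")
    report.table.to_csv(out / "report_table.csv", index=False)
    (out / "comparisons.json").write_text(json.dumps([{
        "a": c.label_a, "b": c.label_b, "t": c.t_statistic, "df": c.df,
        "p": c.p_value, "mark": c.significance_mark} for c in comparisons],
        sort_keys=True, indent=2) + "\n")
    if len(moduli) == 2:
        ratio = force_ratio(max(m[0] for m in moduli.values()),
                            min(m[0] for m in moduli.values()))
        (out / "force_ratio.json").write_text(
            json.dumps({"force_ratio": ratio}, sort_keys=True) + "\n")

    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest[str(path.relative_to(out))] = digest
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2)
                                       + "\n")
    if config.strict and not report.complete:
        raise RuntimeError("report incomplete in strict mode")
    return manifest
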