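"""Pipeline orchestration: simulate -> segment -> quantify -> report.

Each stage is runnable standalone from the previous stage's on-disk outputs
and every parameter and seed is logged and echoed into the output directory,
so a rerun with the same config and seed reproduces the report byte for
byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as asio
from .errors import AmyloidscopeError, ConfigurationError
from .quantify import (QuantParams, SizeHistogram, compare_group_fractions,
                       correct_shrinkage, place_sample_cubes, quantify_animal,
                       segment_cortex, size_histogram)
from .segmentation import (RECORD_COLUMNS, SegmentationParams,
                           midpoint_threshold, segment_volume)
from .stats import kruskal_wallis, mann_whitney_u, welch_t
from .synthetic import (CohortConfig, GroupConfig, NoiseConfig,
                        SimulationConfig, SizeDistributionSpec,
                        YOUNG_SIZE_DISTRIBUTION, ADULT_SIZE_DISTRIBUTION,
                        generate_cohort)

log = logging.getLogger("amyloidscope")

__all__ = ["demo_config", "build_cohort_config", "run_pipeline",
           "validate_report", "STAGES"]

STAGES = ("simulate", "segment", "quantify", "report")


def demo_config() -> dict:
    """A small two-group, two-animal exact-totals configuration that runs
    end to end in a few seconds: 150 plaques planted in the young group's
    sample cubes, 600 in the adult group's, sizes drawn from the default
    group distributions, imaged with mild noise and a wide-waist sheet."""
    return {
        "cohort": {
            "groups": [
                {"name": "young", "n_animals": 2, "exact_total": 150,
                 "size_distribution": {
                     "mode": "empirical_bins",
                     "bin_edges_um": list(YOUNG_SIZE_DISTRIBUTION.bin_edges_um),
                     "probabilities": [float(p) for p in
                                       YOUNG_SIZE_DISTRIBUTION.probabilities]}},
                {"name": "adult", "n_animals": 2, "exact_total": 600,
                 "size_distribution": {
                     "mode": "empirical_bins",
                     "bin_edges_um": list(ADULT_SIZE_DISTRIBUTION.bin_edges_um),
                     "probabilities": [float(p) for p in
                                       ADULT_SIZE_DISTRIBUTION.probabilities]}},
            ],
            "min_separation_um": 6.0,
            "supersample": 2,
            "apply_blur": True,
        },
        "simulation": {
            "voxel_size_um": [2.0, 2.0, 2.0],
            "background_level": 100.0,
            "plaque_amplitude": 3000.0,
            "sheet_waist_halfwidth_w0_um": 200.0,
            "noise": {"gaussian_sigma": 20.0, "poisson": False},
        },
        "segmentation": {"threshold_mode": "fixed", "fixed_threshold": 1550.0,
                         "connectivity": 26, "min_diameter_um": 8.0},
        "quantification": {"cubes_per_hemisphere": 6,
                           "cube_volume_fraction": 0.001,
                           "apply_shrinkage": False},
    }


def _pick(cls, d: dict):
    fields = cls.__dataclass_fields__
    return cls(**{k: v for k, v in d.items() if k in fields})


def _size_dist(d: dict) -> SizeDistributionSpec:
    if d.get("mode", "empirical_bins") == "empirical_bins":
        return SizeDistributionSpec.empirical(d["bin_edges_um"], d["probabilities"])
    return SizeDistributionSpec.truncated_lognormal(
        d["log_mean"], d["log_sd"], d["d_min_um"], d["d_max_um"])


def build_simulation_config(cfg: dict) -> SimulationConfig:
    sim = dict(cfg.get("simulation", {}))
    if "noise" in sim:
        sim["noise"] = _pick(NoiseConfig, sim["noise"])
    if "grid_shape" in sim:
        sim["grid_shape"] = tuple(sim["grid_shape"])
    if "voxel_size_um" in sim:
        sim["voxel_size_um"] = tuple(sim["voxel_size_um"])
    return _pick(SimulationConfig, sim)


def build_cohort_config(cfg: dict) -> CohortConfig:
    cdict = dict(cfg.get("cohort", {}))
    groups = []
    for g in cdict.pop("groups", []):
        g = dict(g)
        if "size_distribution" in g:
            g["size_distribution"] = _size_dist(g["size_distribution"])
        groups.append(_pick(GroupConfig, g))
    if not groups:
        raise ConfigurationError("config.cohort.groups must not be empty")
    cdict["groups"] = tuple(groups)
    cdict["sim"] = build_simulation_config(cfg)
    return _pick(CohortConfig, cdict)


def build_segmentation_params(cfg: dict) -> SegmentationParams:
    seg = dict(cfg.get("segmentation", {}))
    if seg.get("threshold_mode", "fixed") == "fixed" and \
            seg.get("fixed_threshold") is None:
        sim = cfg.get("simulation", {})
        seg["fixed_threshold"] = midpoint_threshold(
            sim.get("background_level", 100.0), sim.get("plaque_amplitude", 3000.0))
    return _pick(SegmentationParams, seg)


def build_quant_params(cfg: dict) -> QuantParams:
    return _pick(QuantParams, dict(cfg.get("quantification", {})))


def _animal_ids(cfg: dict):
    for g in cfg["cohort"]["groups"]:
        for a in range(int(g["n_animals"])):
            yield g["name"], f"{g['name']}_{a + 1:02d}"


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise AmyloidscopeError(
            f"stage '{stage}' needs {path.name}, which is produced by the "
            f"'{produced_by}' stage; run that stage first")
    return path


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: dict, seed: int, outdir: Path) -> None:
    cohort = build_cohort_config(cfg)
    scenes = generate_cohort(cohort, seed)
    asio.write_cohort(scenes, outdir, config_echo={"config": cfg, "seed": seed})
    log.info("simulate: wrote %d animal volumes to %s", len(scenes), outdir)


def stage_segment(cfg: dict, seed: int, outdir: Path) -> None:
    params = build_segmentation_params(cfg)
    for _group, animal in _animal_ids(cfg):
        vol_path = _require(outdir / f"{animal}.tif", "segment", "simulate")
        grid, meta = asio.read_volume(vol_path)
        labels, records = segment_volume(grid, params, meta.voxel_size_um)
        asio.write_table(records[RECORD_COLUMNS], outdir / f"plaques_{animal}.csv")
        asio.write_volume(labels.astype(np.int32), meta,
                          outdir / f"labels_{animal}.tif")
        log.info("segment: %s -> %d components, %d retained", animal,
                 len(records), int(records["retained"].sum()))


def stage_quantify(cfg: dict, seed: int, outdir: Path) -> None:
    qp = build_quant_params(cfg)
    cubes_path = outdir / "cubes.csv"
    cube_df = pd.read_csv(cubes_path) if cubes_path.exists() else None
    from .quantify import SampleCube

    all_rows = []
    histogram_rows = []
    per_animal = {}
    for idx, (group, animal) in enumerate(_animal_ids(cfg)):
        rec_path = _require(outdir / f"plaques_{animal}.csv", "quantify", "segment")
        records = asio.read_table(rec_path, RECORD_COLUMNS)
        labels, meta = asio.read_volume(outdir / f"labels_{animal}.tif")
        if cube_df is not None:
            rows = cube_df[cube_df["animal"] == animal]
            cubes = [SampleCube(id=int(r.cube_id),
                                origin_um=(r.origin_z_um, r.origin_y_um, r.origin_x_um),
                                edge_um=float(r.edge_um), hemisphere=r.hemisphere)
                     for r in rows.itertuples()]
        else:
            cortex, _ = asio.read_volume(outdir / f"cortex_{animal}.tif")
            mask, _vol = segment_cortex(cortex, meta.voxel_size_um, mode="mask")
            rng = np.random.default_rng(np.random.SeedSequence([seed, idx, 7]))
            cubes = place_sample_cubes(mask, qp, rng, meta.voxel_size_um)
        table = quantify_animal(records, labels, cubes, meta.voxel_size_um)
        table.insert(0, "animal", animal)
        table.insert(0, "group", group)
        all_rows.append(table)

        retained = records[records["retained"].astype(bool)]
        diam = retained["equivalent_diameter_um"].to_numpy()
        if cfg.get("quantification", {}).get("apply_shrinkage", False):
            diam = correct_shrinkage(diam, qp.shrinkage_fraction)
        hist = size_histogram(diam, qp.histogram_edges_um)
        for i in range(hist.counts.size):
            histogram_rows.append({
                "group": group, "animal": animal,
                "bin_lo_um": hist.edges_um[i], "bin_hi_um": hist.edges_um[i + 1],
                "count": int(hist.counts[i]),
                "relative_percent": float(hist.relative_percent[i])})
        per_animal[animal] = {
            "group": group,
            "total_retained": int(len(retained)),
            "mean_density_per_mm3": float(table["density_per_mm3"].mean()),
            "pooled_density_per_mm3": float(
                table["count"].sum() / table["volume_mm3"].sum()),
            "mean_load_percent": float(table["load_percent"].mean()),
            "cubes": table.drop(columns=["group", "animal"]).to_dict("records"),
        }

    cube_table = pd.concat(all_rows, ignore_index=True)
    asio.write_table(cube_table, outdir / "cube_table.csv")
    asio.write_table(pd.DataFrame(histogram_rows), outdir / "histograms.csv")
    payload = {"seed": seed, "per_animal": per_animal,
               "histogram_edges_um": [float(e) for e in qp.histogram_edges_um]}
    (outdir / "quantify.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str))
    log.info("quantify: wrote cube_table.csv, histograms.csv, quantify.json")


def _hist_from_rows(rows: pd.DataFrame) -> SizeHistogram:
    edges = np.append(rows["bin_lo_um"].to_numpy(),
                      rows["bin_hi_um"].to_numpy()[-1])
    counts = rows["count"].to_numpy()
    rel = rows["relative_percent"].to_numpy()
    return SizeHistogram(edges, counts, rel, n_input=int(counts.sum()),
                         empty=counts.sum() == 0)


def _result_dict(res) -> dict:
    return {"statistic": float(res.statistic), "p_value": float(res.p_value),
            "n_per_group": list(res.n_per_group), "method": res.method,
            "stars": res.stars}


def stage_report(cfg: dict, seed: int, outdir: Path) -> dict:
    cube_table = pd.read_csv(
        _require(outdir / "cube_table.csv", "report", "quantify"))
    histograms = pd.read_csv(outdir / "histograms.csv")
    quant = json.loads((outdir / "quantify.json").read_text())
    groups = [g["name"] for g in cfg["cohort"]["groups"]]

    report = {"seed": seed, "groups": groups, "within_group": {},
              "per_animal": quant["per_animal"]}

    per_animal = quant["per_animal"]
    by_group = {g: [a for a, d in per_animal.items() if d["group"] == g]
                for g in groups}

    # within-group variability: per-cube counts, animals as groups
    for g, animals in by_group.items():
        samples = [cube_table[cube_table["animal"] == a]["count"].to_numpy()
                   for a in animals]
        if len(samples) >= 2:
            report["within_group"][g] = _result_dict(kruskal_wallis(samples))

    # outlier flags only (no exclusion rule): animals far below their group
    for g, animals in by_group.items():
        totals = np.array([per_animal[a]["total_retained"] for a in animals])
        if totals.size >= 3:
            q1, q3 = np.percentile(totals, [25, 75])
            low = q1 - 1.5 * (q3 - q1)
            report.setdefault("outlier_flags", {}).update(
                {a: True for a, t in zip(animals, totals) if t < low})

    if len(groups) == 2:
        ga, gb = groups
        dens = {g: [per_animal[a]["mean_density_per_mm3"] for a in by_group[g]]
                for g in groups}
        load = {g: [per_animal[a]["mean_load_percent"] for a in by_group[g]]
                for g in groups}
        between = {
            "density_per_mm3": _result_dict(mann_whitney_u(dens[ga], dens[gb])),
            "load_percent": _result_dict(mann_whitney_u(load[ga], load[gb])),
        }
        if min(len(load[ga]), len(load[gb])) >= 2:
            between["load_percent_welch_t_supplementary"] = _result_dict(
                welch_t(load[ga], load[gb]))
        # exploratory per-cube comparison (pseudo-replicated; flagged)
        cubes_a = cube_table[cube_table["group"] == ga]["density_per_mm3"]
        cubes_b = cube_table[cube_table["group"] == gb]["density_per_mm3"]
        between["density_per_cube_exploratory"] = _result_dict(
            mann_whitney_u(cubes_a, cubes_b))
        report["between_groups"] = between

        hists = {g: [_hist_from_rows(histograms[histograms["animal"] == a])
                     for a in by_group[g]] for g in groups}
        frac = compare_group_fractions(hists[ga], hists[gb], labels=(ga, gb))
        asio.write_table(frac, outdir / "bin_fractions.csv")
        report["bin_fractions"] = frac.to_dict("records")

    report["totals"] = {
        g: int(cube_table[cube_table["group"] == g]["count"].sum())
        for g in groups}
    validate_report(report)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str))
    log.info("report: wrote report.json")
    return report


def validate_report(report: dict) -> None:
    """Structural check of the report bundle."""
    for key in ("seed", "groups", "per_animal", "totals"):
        if key not in report:
            raise AmyloidscopeError(f"report missing required key {key!r}")
    for animal, d in report["per_animal"].items():
        for key in ("group", "total_retained", "mean_density_per_mm3", "cubes"):
            if key not in d:
                raise AmyloidscopeError(
                    f"report.per_animal[{animal!r}] missing {key!r}")


_STAGE_FUNCS = {"simulate": stage_simulate, "segment": stage_segment,
                "quantify": stage_quantify, "report": stage_report}


def run_pipeline(cfg: dict, seed: int, outdir, stages=STAGES) -> Optional[dict]:
    """Run the requested stages in order into ``outdir``; returns the report
    dict when the report stage is included."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = None
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ConfigurationError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        out = _STAGE_FUNCS[stage](cfg, seed, outdir)
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
        if stage == "report":
            result = out
    return result
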