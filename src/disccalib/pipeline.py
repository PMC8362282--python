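"""End-to-end measurement -> reliability -> calibration -> validation runs.

``run_pipeline`` orchestrates the full study workflow on either a synthetic
cohort or user-supplied measurement CSVs:

1. cohort: generate subjects (or ingest measurement/rating tables);
2. reliability: pairwise kappa on the pre-exclusion gradings, Cronbach's
   alpha per indicator on the included (all-observers-normal) subjects;
3. ratios: pooled P1/P2 from the included measurement records;
4. calibration: P1 sweep against the in-vitro RoM targets, driven either by
   the embedded published sweep table or by the live mechanical surrogate;
5. validation: surrogate indicators (RoM, DC, IDP proxy) with the intact
   nucleus at the calibrated P1, scored against a reference table;
6. report: JSON summary plus CSV tables and a run log in the output
   directory.  All randomness is seeded; a fixed config yields a
   byte-identical bundle.
"""

from __future__ import annotations

import json
import tomllib
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .calibration import (
    DEFAULT_THRESHOLD,
    CalibrationTargets,
    calibrate_p1,
    default_grid,
    sweep_report,
)
from .cohort import (
    CohortParams,
    generate_cohort,
    included_subjects,
    simulate_observers,
    published_sweep_fixture,
    write_cohort_csvs,
)
from .exceptions import DiscCalibError
from .geometry import Contour, compute_ratios, place_nucleus, read_measurement_csv
from .mechanics import (
    CANONICAL_LOAD_CASES,
    DEFAULT_MATERIALS,
    MaterialSet,
    SectionModel,
    SurrogateRomEvaluator,
    bending_rom,
    compression_response,
)
from .validation import (
    DEFAULT_ACCURACY_FLOOR,
    ComputedValue,
    load_references,
    validate,
)

__all__ = ["run_pipeline", "load_config", "default_references_path"]


def default_references_path() -> Path:
    """Packaged *synthetic* reference table (placeholder scatter around the
    surrogate's operating point; replace with real in-vitro values)."""
    return Path(resources.files("disccalib") / "data" / "references_synthetic.json")


def load_config(path: str | Path) -> dict:
    """Read a pipeline config from TOML or JSON (by extension)."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return json.load(fh)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DiscCalibError as err:
                raise type(err)(f"[stage:{name}] {err}") from err

        return wrapped

    return deco


def _cohort_stage(cfg: Mapping[str, Any], log: list[str]):
    ccfg = dict(cfg.get("cohort", {}))
    if "measurements_csv" in ccfg:
        records = read_measurement_csv(ccfg["measurements_csv"])
        ratings = pd.read_csv(ccfg["ratings_csv"], index_col="subject_id")
        params = None
        log.append(f"cohort: loaded {records['subject_id'].nunique()} subjects from CSV")
    else:
        params = CohortParams(**ccfg)
        cohort = generate_cohort(params)
        records, ratings = simulate_observers(cohort, params)
        log.append(f"cohort: generated {len(cohort)} subjects (seed={params.seed})")
    return params, records, ratings


def _materials(cfg: Mapping[str, Any]) -> MaterialSet:
    mcfg = cfg.get("materials")
    return MaterialSet.from_dict(mcfg) if mcfg else DEFAULT_MATERIALS


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write the report bundle to ``out_dir``.

    ``config`` is a nested mapping (or a path to a TOML/JSON file) with
    optional sections ``cohort``, ``calibration``, ``materials`` and
    ``validation``; every key has a default.  Returns the report dict, which
    is also written as ``report.json``.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"disccalib {__version__}"]

    params, records, ratings = _stage("cohort")(_cohort_stage)(config, log)
    write_cohort_csvs(records, ratings, out)

    # reliability: kappa on the full pre-exclusion ratings, alpha on the
    # included subjects' measurements
    from .reliability import alpha_by_indicator, pairwise_kappa

    kappas = _stage("reliability")(pairwise_kappa)(ratings)
    included = included_subjects(ratings)
    if len(included) < 2:
        raise DiscCalibError("[stage:reliability] fewer than 2 included subjects")
    inc_records = records[records["subject_id"].isin(included)]
    alphas = _stage("reliability")(alpha_by_indicator)(inc_records)
    log.append(
        f"reliability: {len(included)}/{ratings.shape[0]} subjects included; "
        f"alpha range [{min(alphas.values()):.3f}, {max(alphas.values()):.3f}]"
    )

    ratios = _stage("ratios")(compute_ratios)(inc_records)
    log.append(f"ratios: P1={ratios.p1_report:.2f}, P2={ratios.p2_percent}%")

    ccfg = dict(config.get("calibration", {}))
    mode = ccfg.get("mode", "table")
    targets = CalibrationTargets(**ccfg.get("targets", {}))
    materials = _materials(config)
    mean_disc = _mean_disc(params)
    calib_section: dict[str, Any] | None = None
    calibrated_p1 = ratios.p1
    if mode != "none":
        fixture = published_sweep_fixture()
        if mode == "table":
            evaluator = fixture.evaluator()
        elif mode == "surrogate":
            evaluator = SurrogateRomEvaluator(
                mean_disc, ratios.p2, materials=materials,
                load=CANONICAL_LOAD_CASES["rom_10Nm_100N"], nucleus_suppressed=True,
            )
        else:
            raise ValueError(f"unknown calibration mode {mode!r}")
        # table mode can only be evaluated on the tabulated sweep; the live
        # surrogate sweeps outward from the measured P1 as the study did
        grid = ccfg.get("grid") or (
            list(fixture.p1) if mode == "table" else default_grid(ratios.p1_report)
        )
        threshold = float(ccfg.get("threshold", DEFAULT_THRESHOLD))
        result = _stage("calibration")(calibrate_p1)(evaluator, targets, grid, threshold)
        sweep = sweep_report(evaluator, targets, grid)
        sweep.to_csv(out / "calibration_trace.csv", index=False, float_format="%.6f")
        calibrated_p1 = result.calibrated_p1
        calib_section = {
            "mode": mode,
            "threshold": result.threshold,
            "converged": bool(result.converged),
            "calibrated_p1": result.calibrated_p1,
            "grid": [float(p) for p in grid],
            "trace": result.trace.round(6).to_dict(orient="records"),
        }
        log.append(
            f"calibration[{mode}]: P1={result.calibrated_p1:.2f} "
            f"(converged={result.converged}, threshold={result.threshold}%)"
        )
    else:
        log.append("calibration: skipped (measured-only mode)")

    vcfg = dict(config.get("validation", {}))
    val_section: dict[str, Any] | None = None
    if vcfg.get("enabled", True):
        ref_path = vcfg.get("references", default_references_path())
        references = load_references(ref_path)
        computed = _surrogate_indicators(mean_disc, calibrated_p1, ratios.p2, materials)
        floor = float(vcfg.get("accuracy_floor", DEFAULT_ACCURACY_FLOOR))
        report = _stage("validation")(validate)(computed, references, floor)
        val_section = report.to_dict()
        log.append(
            f"validation: overall_pass={report.overall_pass} "
            f"({len(report.entries)} indicators, floor={floor}%)"
        )
    else:
        log.append("validation: skipped")

    nucleus = place_nucleus(mean_disc, calibrated_p1, ratios.p2)
    _write_geojson(out / "calibrated_geometry.json", mean_disc, nucleus)

    report_dict = {
        "package": {"name": "disccalib", "version": __version__},
        "cohort": {
            "n_subjects": int(ratings.shape[0]),
            "n_observers": int(ratings.shape[1]),
            "n_included": len(included),
        },
        "reliability": {
            "pairwise_kappa": {f"{a}&{b}": v for (a, b), v in kappas.items()},
            "cronbach_alpha": alphas,
        },
        "ratios": {
            "p1": ratios.p1,
            "p2": ratios.p2,
            "p1_report": ratios.p1_report,
            "p2_percent": ratios.p2_percent,
        },
        "calibration": calib_section,
        "validation": val_section,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return report_dict


def _mean_disc(params: CohortParams | None) -> Contour:
    p = params or CohortParams()
    return Contour.ellipse(p.semi_axis_ap_mean, p.semi_axis_lat_mean, n_vertices=256)


def _surrogate_indicators(
    disc: Contour, p1: float, p2: float, materials: MaterialSet
) -> list[ComputedValue]:
    """Indicators the sagittal-plane surrogate can compute with the intact
    nucleus; lateral bending, axial rotation and FCF need external values."""
    nucleus = place_nucleus(disc, p1, p2)
    section = SectionModel(disc, nucleus, nucleus_suppressed=False)
    rom_load = CANONICAL_LOAD_CASES["rom_10Nm_100N"]
    from dataclasses import replace

    flex = bending_rom(section, materials, replace(rom_load, moment_nm=abs(rom_load.moment_nm)))
    ext = bending_rom(section, materials, replace(rom_load, moment_nm=-abs(rom_load.moment_nm)))
    dc, idp = compression_response(section, materials, CANONICAL_LOAD_CASES["dc_1200N"])
    return [
        ComputedValue("RoM", "flexion", "rom_10Nm_100N", flex),
        ComputedValue("RoM", "extension", "rom_10Nm_100N", ext),
        ComputedValue("DC", "n/a", "dc_1200N", dc),
        ComputedValue("IDP", "n/a", "dc_1200N", idp),
    ]


def _write_geojson(path: Path, disc: Contour, nucleus: Contour) -> None:
    def poly(c: Contour) -> dict:
        ring = [[round(float(x), 6), round(float(y), 6)] for x, y in c.points]
        ring.append(ring[0])
        return {"type": "Polygon", "coordinates": [ring]}

    payload = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"role": "disc"}, "geometry": poly(disc)},
            {"type": "Feature", "properties": {"role": "nucleus"}, "geometry": poly(nucleus)},
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")
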