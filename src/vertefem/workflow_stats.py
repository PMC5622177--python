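"""Agreement statistics and end-to-end pipeline orchestration.

Agreement between simulated and experimental stiffness is summarised by
Lin's concordance correlation coefficient (CCC) and a Bland-Altman
analysis; between-species comparisons use Shapiro-Wilk normality checks, a
Kruskal-Wallis omnibus test and pairwise rank tests (all delegated to
scipy.stats — supporting routines, not this package's contribution).

``run_pipeline`` drives the whole chain on a YAML config:
normalize -> down-sample -> segment -> mesh -> solve, experimental curve ->
stiffness, then per-species calibration / validation of alpha and the
agreement statistics, emitting a deterministic JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from vertefem import io as vio
from vertefem.calibration import (
    SpecimenRecord,
    calibrate_alpha,
    split_records,
    validate_alpha,
)
from vertefem.fe_solver import LoadCase
from vertefem.image_ops import (
    convert_scanner_grayscale,
    downsample_partial_volume,
    normalize_grayscale,
    segment_continuum,
)
from vertefem.meshing import build_voxel_mesh
from vertefem.mech_curves import extract_stiffness

logger = logging.getLogger("vertefem")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and specimen id."""

    def __init__(self, stage: str, specimen: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed for specimen '{specimen}': {cause}")
        self.stage = stage
        self.specimen = specimen


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n)
    moments:

        ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2)

    Equals 1 only for perfect identity agreement; bounded by the Pearson
    correlation in absolute value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D with n >= 2")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    dmean = float(np.mean(x) - np.mean(y))
    if sx2 == 0 and sy2 == 0:
        if dmean == 0:
            return 1.0
        raise ValueError("both sequences constant and unequal: CCC undefined")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return 2.0 * sxy / (sx2 + sy2 + dmean**2)


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray
    n: int


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman agreement of y against x: per-pair differences
    ``y - x``, their mean (bias) and the 95% limits of agreement
    ``bias +/- 1.96 * sample sd``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    diffs = y - x
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(x + y) / 2.0,
        diffs=diffs,
        n=x.size,
    )


@dataclass
class GroupComparisonReport:
    shapiro: dict[str, dict]  # group -> {statistic, p} or {applicable: False}
    kruskal_statistic: float
    kruskal_p: float
    pairwise: dict[str, dict]  # "a_vs_b" -> {statistic, p}


def compare_groups(values_by_group: dict[str, list]) -> GroupComparisonReport:
    """Shapiro-Wilk per group, Kruskal-Wallis omnibus, pairwise rank tests.

    Between-species groups are independent samples of unequal size, so the
    post hoc pairwise test is the Mann-Whitney rank-sum test; p-values are
    reported raw (no multiplicity correction).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) < 3 for v in groups.values()):
        raise ValueError("need >= 2 groups with n >= 3 each")
    shapiro = {}
    for name, v in groups.items():
        if np.ptp(v) == 0:
            shapiro[name] = {"applicable": False}
        else:
            s = sps.shapiro(v)
            shapiro[name] = {"statistic": float(s.statistic), "p": float(s.pvalue), "applicable": True}
    try:
        kw = sps.kruskal(*groups.values())
        kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)
    except ValueError:  # all values identical across groups
        kw_stat, kw_p = 0.0, 1.0
    names = sorted(groups)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            try:
                mw = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
                pairwise[f"{a}_vs_{b}"] = {"statistic": float(mw.statistic), "p": float(mw.pvalue)}
            except ValueError:
                pairwise[f"{a}_vs_{b}"] = {"statistic": 0.0, "p": 1.0}
    return GroupComparisonReport(
        shapiro=shapiro, kruskal_statistic=kw_stat, kruskal_p=kw_p, pairwise=pairwise
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_GLOBAL_DEFAULTS = {
    "target_spacing": 1.0,
    "window_mm": 0.6,
    "reference_max": 255.0,
    "alpha_bracket": [1e-5, 0.1],
    "e_cement": 2.45,
    "nu": 0.3,
    "e_floor": 0.001,
    "closing_radius": 2,
    "gray_gain": None,
    "gray_offset": 0.0,
    "displacement": 1.0,
}


def _process_specimen(spec_cfg: dict, gcfg: dict, base: Path):
    """Image chain for one specimen: read raw -> normalize -> (convert) ->
    down-sample -> segment -> mesh.  Returns (mesh, down-sampled gray)."""
    sid = spec_cfg["id"]
    try:
        vol = vio.read_volume(base / spec_cfg["image"], spacing=spec_cfg.get("spacing"))
    except Exception as exc:
        raise PipelineError("read_image", sid, exc) from exc
    try:
        gray = normalize_grayscale(vol, reference_max=gcfg["reference_max"])
        if gcfg["gray_gain"] is not None:
            gray = convert_scanner_grayscale(gray, gcfg["gray_gain"], gcfg["gray_offset"])
    except Exception as exc:
        raise PipelineError("normalize", sid, exc) from exc
    try:
        gray_ds = downsample_partial_volume(gray, gcfg["target_spacing"])
    except Exception as exc:
        raise PipelineError("downsample", sid, exc) from exc
    try:
        planes = spec_cfg["cement_planes"]
        mask = segment_continuum(
            gray_ds,
            cement_planes=(float(planes[0]), float(planes[1])),
            closing_radius_voxels=int(gcfg["closing_radius"]),
        )
        mesh = build_voxel_mesh(mask)
    except Exception as exc:
        raise PipelineError("segment_mesh", sid, exc) from exc
    return mesh, gray_ds


def run_pipeline(config, out_dir=None) -> dict:
    """Run the full calibration/validation pipeline from a config.

    ``config`` is a YAML path or an equivalent dict with ``global`` options
    and per-species specimen lists (image file, curve file, group,
    cement planes).  Returns the report dict; when ``out_dir`` is given the
    report is written as ``report.json``, per-specimen stiffness pairs as
    ``pairs.csv``, and a parameter log as ``pipeline.log``.  Reruns with the
    same config are byte-identical.
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        with open(config_path) as fh:
            config = yaml.safe_load(fh)
        base = config_path.parent
    else:
        base = Path(config.get("base_dir", "."))
    gcfg = {**_GLOBAL_DEFAULTS, **(config.get("global") or {})}

    report: dict = {"species": {}, "parameters": {k: gcfg[k] for k in sorted(gcfg)}}
    all_pairs_rows = []
    for species, scfg in sorted((config.get("species") or {}).items()):
        records: list[SpecimenRecord] = []
        loadcase = LoadCase(prescribed_axial_displacement=gcfg["displacement"])
        for spec_cfg in scfg["specimens"]:
            sid = spec_cfg["id"]
            mesh, gray_ds = _process_specimen(spec_cfg, gcfg, base)
            try:
                curve = vio.read_curve_csv(base / spec_cfg["curve"], specimen_id=sid)
                k_exp = extract_stiffness(curve, window_width=gcfg["window_mm"]).stiffness
            except Exception as exc:
                raise PipelineError("read_curve", sid, exc) from exc
            records.append(
                SpecimenRecord(
                    id=sid,
                    k_exp=k_exp,
                    group=spec_cfg.get("group", "calibration"),
                    mesh=mesh,
                    gray=gray_ds,
                    loadcase=loadcase,
                    E_cement=gcfg["e_cement"],
                    nu=gcfg["nu"],
                    E_floor=gcfg["e_floor"],
                )
            )
        cal, val = split_records(records)
        cache: dict = {}
        try:
            calres = calibrate_alpha(
                cal, bracket=tuple(gcfg["alpha_bracket"]), cache=cache
            )
        except Exception as exc:
            raise PipelineError("calibrate", species, exc) from exc
        entry = {
            "alpha": calres.alpha,
            "calibration_rmse": calres.rmse,
            "n_calibration": len(cal),
            "n_validation": len(val),
            "termination": calres.termination,
            "fe_evaluations": calres.iterations,
        }
        pairs = dict(calres.pairs)
        if val:
            valres = validate_alpha(calres.alpha, val, cache=cache)
            entry["validation_rmse"] = valres.rmse
            entry["validation_relative_errors"] = valres.relative_errors
            entry["max_validation_relative_error"] = valres.max_abs_relative_error
            pairs.update(valres.pairs)
        k_exp_all = [pairs[s][0] for s in sorted(pairs)]
        k_sim_all = [pairs[s][1] for s in sorted(pairs)]
        if len(pairs) >= 2:
            try:
                entry["ccc"] = lin_ccc(k_exp_all, k_sim_all)
            except ValueError:
                entry["ccc"] = None
            ba = bland_altman(k_exp_all, k_sim_all)
            entry["bland_altman"] = {
                "bias": ba.bias,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
            }
        entry["pairs"] = {s: list(pairs[s]) for s in sorted(pairs)}
        report["species"][species] = entry
        for s in sorted(pairs):
            grp = next(r.group for r in records if r.id == s)
            all_pairs_rows.append(
                {"species": species, "specimen": s, "group": grp,
                 "k_exp_kN_mm": pairs[s][0], "k_sim_kN_mm": pairs[s][1]}
            )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        pd.DataFrame(all_pairs_rows).to_csv(out_dir / "pairs.csv", index=False)
        with open(out_dir / "pipeline.log", "w") as fh:
            for k in sorted(gcfg):
                fh.write(f"parameter {k} = {gcfg[k]}\n")
            for sp, entry in report["species"].items():
                fh.write(
                    f"species {sp}: alpha={entry['alpha']:.6g} "
                    f"cal_rmse={entry['calibration_rmse']:.6g} "
                    f"val_rmse={entry.get('validation_rmse', float('nan')):.6g}\n"
                )
    return report


# ---------------------------------------------------------------------------
# packaged synthetic demo
# ---------------------------------------------------------------------------


def make_demo_config(
    workdir,
    n_specimens: int = 6,
    alpha_true: float = 0.008,
    seed: int = 0,
    curve_noise_sd: float = 0.0,
) -> Path:
    """Materialize a self-contained synthetic study into ``workdir``.

    Generates ``n_specimens`` small phantoms of varying bone volume
    fraction, simulates each specimen's "experimental" stiffness by running
    the model at ``alpha_true``, writes matching load-displacement curves
    (ground-truth slope = simulated stiffness), splits specimens
    alternately into calibration and validation groups, and writes the
    pipeline config.  Returns the config path.
    """
    from vertefem.phantom import CurveSpec, PhantomSpec, generate_curve, generate_phantom
    from vertefem.calibration import SpecimenRecord  # noqa: F401  (docs cross-ref)

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    gcfg = dict(_GLOBAL_DEFAULTS)
    specimens = []
    for i in range(n_specimens):
        sid = f"syn{i:02d}"
        pspec = PhantomSpec(
            body_radius=6.0,
            body_height=8.0,
            endcap_height=2.0,
            shell_thickness=1.0,
            voxel_spacing=0.5,
            trabecular_bvtv_target=float(0.30 + 0.05 * (i % 4)),
            anisotropy_stretch=2.0,
            noise_sd=2.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, truth = generate_phantom(pspec)
        vio.write_volume(workdir / f"{sid}.mhd", vol)

        gray = normalize_grayscale(vol, reference_max=gcfg["reference_max"])
        gray_ds = downsample_partial_volume(gray, gcfg["target_spacing"])
        mask = segment_continuum(
            gray_ds,
            cement_planes=truth.cement_planes,
            closing_radius_voxels=int(gcfg["closing_radius"]),
        )
        mesh = build_voxel_mesh(mask)
        from vertefem.meshing import assign_materials
        from vertefem.fe_solver import assemble, solve_compression

        mats = assign_materials(
            mesh, gray_ds, alpha=alpha_true,
            E_cement=gcfg["e_cement"], nu=gcfg["nu"], E_floor=gcfg["e_floor"],
        )
        k_true = solve_compression(
            assemble(mesh, mats), LoadCase(prescribed_axial_displacement=gcfg["displacement"])
        ).apparent_stiffness
        curve = generate_curve(
            CurveSpec(
                true_stiffness=k_true,
                toe_length=0.15,
                total_displacement=1.5,
                sample_step=0.005,
                noise_sd=curve_noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        vio.write_curve_csv(workdir / f"{sid}.csv", curve)
        specimens.append(
            {
                "id": sid,
                "image": f"{sid}.mhd",
                "curve": f"{sid}.csv",
                "group": "calibration" if i % 2 == 0 else "validation",
                "cement_planes": [float(truth.cement_planes[0]), float(truth.cement_planes[1])],
            }
        )
    config = {
        "global": {k: v for k, v in gcfg.items() if v is not None},
        "species": {"synthetic": {"specimens": specimens}},
    }
    cfg_path = workdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path
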