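"""Pipeline orchestration: YAML config in, deterministic report bundle out.

A config selects stages (traction, rheology, coloc, qpcr); every stage is
seeded from the single top-level seed, runs on synthetic inputs from
:mod:`cytomech.synthgen`, and contributes a block to one report JSON plus
per-stage CSVs. Re-running the same config reproduces the bundle
bit-for-bit (the report carries its own content hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import fttm, histoquant, microburden, sntm, synthgen

logger = logging.getLogger("cytomech")

REPORT_SCHEMA_VERSION = 1

_STAGE_KEYS = {
    "traction": {
        "grid_shape", "grid_spacing", "youngs_modulus", "poisson_ratio",
        "dipoles", "mode", "effective_height_um", "pad_factor", "mask_sigma_factor",
    },
    "rheology": {
        "alpha_true", "dstar_true", "n_beads", "frame_interval", "duration",
        "fit_window", "averaging",
    },
    "coloc": {
        "image_shape", "n_spots_a", "overlap_fraction", "n_extra_b",
        "spot_sigma", "noise_sd", "method",
    },
    "qpcr": {
        "efficiency", "intercept_ct", "noise_sd", "tissues", "n_per_group",
        "control_equivalents", "fold", "pairing",
    },
}
_TOP_KEYS = {"seed", "out_dir", "stages"}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    stages = cfg.get("stages", {})
    if not isinstance(stages, dict) or not stages:
        raise ConfigError("config needs a non-empty 'stages' mapping")
    for name, block in stages.items():
        if name not in _STAGE_KEYS:
            raise ConfigError(f"unknown stage '{name}' (known: {sorted(_STAGE_KEYS)})")
        unknown = set(block or {}) - _STAGE_KEYS[name]
        if unknown:
            raise ConfigError(f"unknown key(s) in stage '{name}': {sorted(unknown)}")


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), allow_nan=False)


def report_hash(report: dict) -> str:
    body = {k: v for k, v in report.items() if k != "report_sha256"}
    return hashlib.sha256(_canonical_json(body).encode()).hexdigest()


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _run_traction(block: dict, seed: int, out_dir: Path) -> dict:
    shape = tuple(block.get("grid_shape", (48, 48)))
    substrate = fttm.GelSubstrate(
        youngs_modulus=block.get("youngs_modulus", 1300.0),
        poisson_ratio=block.get("poisson_ratio", 0.48),
        grid_spacing=block.get("grid_spacing", 2.0),
        grid_shape=shape,
    )
    dip_blocks = block.get("dipoles") or [{}]
    extent = (
        (shape[1] - 1) * substrate.grid_spacing / 2.0,
        (shape[0] - 1) * substrate.grid_spacing / 2.0,
    )
    dipoles = [
        synthgen.DipoleSpec(
            center=tuple(d.get("center", extent)),
            axis=tuple(d.get("axis", (1.0, 0.0))),
            force_magnitude=d.get("force_magnitude", 1e5),
            separation=d.get("separation", 20.0),
            patch_sigma=d.get("patch_sigma", 3.0),
            sense=d.get("sense", "contractile"),
        )
        for d in dip_blocks
    ]
    truth = synthgen.make_traction_scene(substrate, dipoles)
    disp = fttm.forward_displacement(truth, substrate, pad_factor=block.get("pad_factor", 2))
    sigma_factor = block.get("mask_sigma_factor", 4.0)
    gx, gy = truth.coords()
    mask = np.zeros(shape, dtype=bool)
    for dip in dipoles:
        ax = np.asarray(dip.axis)
        for sign in (-1.0, 1.0):
            pc = np.asarray(dip.center) + sign * 0.5 * dip.separation * ax
            mask |= np.hypot(gx - pc[0], gy - pc[1]) <= sigma_factor * dip.patch_sigma
    # also cover the span between patch centers
    for dip in dipoles:
        mask |= (
            np.abs((gx - dip.center[0]) * dip.axis[1] - (gy - dip.center[1]) * dip.axis[0])
            <= sigma_factor * dip.patch_sigma
        ) & (
            np.abs((gx - dip.center[0]) * dip.axis[0] + (gy - dip.center[1]) * dip.axis[1])
            <= dip.separation / 2.0 + sigma_factor * dip.patch_sigma
        )
    cell_mask = fttm.CellMask(mask=mask, pixel_area=substrate.grid_spacing**2)

    mode = block.get("mode", "constrained")
    if mode == "constrained":
        recovered = fttm.invert_constrained(disp, substrate, cell_mask)
    elif mode == "unconstrained":
        recovered = fttm.invert_unconstrained(disp, substrate)
    else:
        raise ConfigError("traction mode must be 'constrained' or 'unconstrained'")
    metrics = fttm.mechanics_metrics(
        recovered, disp, cell_mask, effective_height_um=block.get("effective_height_um", 5.0)
    )
    truth_metrics = fttm.mechanics_metrics(
        truth, disp, cell_mask, effective_height_um=block.get("effective_height_um", 5.0)
    )
    disp.to_csv(out_dir / "displacement.csv")
    recovered.to_csv(out_dir / "traction.csv")
    return {
        "mode": mode,
        "metrics": {k: round(v, 10) for k, v in metrics.to_dict().items()},
        "truth_metrics": {k: round(v, 10) for k, v in truth_metrics.to_dict().items()},
        "inversion_meta": {
            k: (round(v, 12) if isinstance(v, float) else v) for k, v in recovered.meta.items()
        },
    }


def _run_rheology(block: dict, seed: int, out_dir: Path) -> dict:
    model = synthgen.ActiveTrajectoryModel(
        alpha_true=block.get("alpha_true", 1.5),
        dstar_true=block.get("dstar_true", 2.0),
        n_beads=block.get("n_beads", 75),
        frame_interval=block.get("frame_interval", 1.0),
        duration=block.get("duration", 300.0),
        seed=seed,
    )
    traj = synthgen.simulate_trajectories(model)
    traj.to_csv(out_dir / "trajectories.csv")
    msd = sntm.compute_msd(traj, averaging=block.get("averaging", "ensemble_time"))
    window = tuple(block.get("fit_window", (10.0, 300.0)))
    fit = sntm.fit_power_law(msd, window_s=window)
    np.savetxt(
        out_dir / "msd.csv",
        np.column_stack([msd.lag_s, msd.msd_nm2, msd.n_pairs]),
        delimiter=",", header="lag_s,msd_nm2,n_pairs", comments="",
    )
    return {
        "alpha_true": model.alpha_true,
        "fit": {k: (round(v, 10) if isinstance(v, float) else v) for k, v in fit.to_dict().items()},
        "regime": sntm.classify_motion(fit),
    }


def _run_coloc(block: dict, seed: int, out_dir: Path) -> dict:
    scene = synthgen.ColocScene(
        image_shape=tuple(block.get("image_shape", (256, 256))),
        n_spots_a=block.get("n_spots_a", 60),
        overlap_fraction=block.get("overlap_fraction", 0.5),
        n_extra_b=block.get("n_extra_b", 30),
        spot_sigma=block.get("spot_sigma", 2.0),
        noise_sd=block.get("noise_sd", 0.1),
        seed=seed,
    )
    pair, truth = synthgen.make_coloc_scene(scene)
    res = histoquant.coloc_coefficient(
        pair,
        method=block.get("method", "manders_m1"),
        smooth_sigma_px=scene.spot_sigma,
        partner_dilation_px=1,
    )
    return {
        "overlap_fraction_true": truth["overlap_fraction_true"],
        "coefficient": round(res.coefficient, 10),
        "method": res.method,
    }


def _run_qpcr(block: dict, seed: int, out_dir: Path) -> dict:
    rng = np.random.default_rng(seed)
    tissues = block.get("tissues", ["liver", "lung", "spleen"])
    n = block.get("n_per_group", 5)
    ctrl_mean = block.get("control_equivalents", 50.0)
    fold = block.get("fold", 100.0)
    true_eq, labels = [], []
    for tissue in tissues:
        for grp, mean in (("control", ctrl_mean), ("knockdown", ctrl_mean * fold)):
            vals = mean * rng.lognormal(0.0, 0.5, n)
            for i, v in enumerate(vals):
                true_eq.append(float(v))
                labels.append((f"{tissue}_{grp}_{i}", tissue, grp))
    spec = synthgen.QpcrSimSpec(
        efficiency=block.get("efficiency", 1.0),
        intercept_ct=block.get("intercept_ct", 38.0),
        noise_sd=block.get("noise_sd", 0.2),
        true_equivalents=tuple(true_eq),
        sample_labels=tuple(labels),
        seed=seed + 1,
    )
    table = synthgen.simulate_ct_table(spec)
    table.to_csv(out_dir / "ct_table.csv", index=False)
    curve, unknowns = microburden.burden_from_table(table)
    result = microburden.fold_change_summary(
        unknowns, control_group="control", case_group="knockdown",
        pairing=block.get("pairing", "per_tissue_median"),
    )
    result.per_sample.to_csv(out_dir / "burden.csv", index=False)
    return {
        "curve": {
            "slope": round(curve.slope, 10),
            "intercept": round(curve.intercept, 10),
            "efficiency": round(curve.efficiency, 10),
            "r2": round(curve.r_squared, 10),
        },
        "median_fold": round(result.median_fold, 10),
        "fold_range": [round(v, 10) for v in result.fold_range],
        "fold_true": fold,
        "comparison": {
            "test": result.comparison["test"],
            "U": result.comparison["U"],
            "p_value": round(result.comparison["p_value"], 12),
        },
    }


_RUNNERS = {
    "traction": _run_traction,
    "rheology": _run_rheology,
    "coloc": _run_coloc,
    "qpcr": _run_qpcr,
}
_STAGE_SEED_OFFSET = {"traction": 11, "rheology": 23, "coloc": 37, "qpcr": 53}


def run_pipeline(config: dict | str | Path, out_dir=None, seed: int | None = None) -> dict:
    """Execute the configured stages and write the report bundle.

    ``config`` may be a path to a YAML file or a config mapping. Returns
    the report dict (also written to ``<out_dir>/report.json``).
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        validate_config(config)
        cfg = config
    if seed is None:
        seed = int(cfg.get("seed", 0))
    out_dir = Path(out_dir if out_dir is not None else cfg.get("out_dir", "cytomech_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed,
        "stages": {},
    }
    for name, block in cfg["stages"].items():
        stage_seed = (seed * 1000 + _STAGE_SEED_OFFSET[name]) % (2**31 - 1)
        logger.info("running stage %s (seed %d)", name, stage_seed)
        report["stages"][name] = _RUNNERS[name](block or {}, stage_seed, out_dir)
    report["report_sha256"] = report_hash(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
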