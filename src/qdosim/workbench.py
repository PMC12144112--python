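"""Run orchestration: configuration loading/validation, deterministic seed
fan-out, structured run manifests, and the library-level entry points behind
the CLI verbs (simulate, train, evaluate, makedata, hybrid, sensitivity).

Every command echoes all effective parameters (defaults included) into a
``manifest.json`` in the output directory, sufficient to replay the run;
identical config + seed reproduce byte-identical primary outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from . import metrics as dm
from . import phantoms as ph
from . import transport as tr
from .quantum import HHLConfig, hhl_cost_model, hhl_solve
from .sensitivity import ParameterSpace, posterior_summary, sobol_indices
from .surrogate import (
    LossConfig,
    TrainedModel,
    TrainingConfig,
    build_network,
    predict_dose,
    reference_architecture,
    train,
)
from .hybrid import HybridConfig, SurrogateAdapter, run_hybrid_loop

logger = logging.getLogger("qdosim")

__all__ = [
    "derive_seed",
    "load_config",
    "cmd_simulate",
    "cmd_train",
    "cmd_evaluate",
    "cmd_makedata",
    "cmd_hybrid",
    "cmd_sensitivity",
]


def derive_seed(global_seed: int, stream: str) -> int:
    """Deterministic named-stream seed fan-out (always < 2**31)."""
    return (int(global_seed) ^ zlib.crc32(stream.encode())) % (2**31 - 1)


def load_config(path_or_mapping) -> dict:
    if isinstance(path_or_mapping, Mapping):
        return dict(path_or_mapping)
    with open(path_or_mapping) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path_or_mapping} must be a YAML mapping")
    return cfg


def _write_manifest(outdir: Path, name: str, effective: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"command": name, "effective_config": effective}, fh, indent=2, sort_keys=True, default=str)


def _phantom_from_config(cfg: dict, seed: int) -> ph.Phantom:
    spec = ph.PhantomSpec(
        shape=tuple(cfg.get("shape", (16, 16, 16))),
        pattern=cfg.get("pattern", "uniform"),
        tissue_densities=[tuple(p) for p in cfg.get("tissue_densities", [(0, 1.0)])],
        spacing=tuple(cfg.get("spacing", (2.0, 2.0, 2.0))),
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        seed=seed,
    )
    return ph.generate_phantom(spec)


def _materials_from_config(cfg: dict) -> dict:
    if "material_table_path" in cfg:
        path = Path(cfg["material_table_path"])
        if not path.exists():
            raise FileNotFoundError(f"material table not found: {path}")
        raw = yaml.safe_load(path.read_text())
        return {int(k): tuple(v) for k, v in raw.items()}
    if "materials" in cfg:
        return {int(k): tuple(v) for k, v in cfg["materials"].items()}
    return dict(tr.DEFAULT_MATERIALS)


# ---------------------------------------------------------------------------
# Commands
# ---------------------------------------------------------------------------

def cmd_simulate(config, outdir) -> dict:
    """Run MC and/or deterministic transport; write dose NIfTI + report JSON."""
    cfg = load_config(config)
    outdir = Path(outdir)
    seed = int(cfg.get("seed", 0))
    phantom = _phantom_from_config(cfg.get("phantom", {}), derive_seed(seed, "phantom"))
    materials = _materials_from_config(cfg)
    media = tr.build_media(phantom, materials)
    source = ph.make_source(cfg.get("source", {"modality": "external_beam"}))

    report: dict = {"phantom_shape": list(phantom.shape)}
    transport_cfg = cfg.get("transport", {})
    outdir.mkdir(parents=True, exist_ok=True)

    if transport_cfg.get("monte_carlo", True):
        n_particles = int(transport_cfg.get("n_particles", 20000))
        mc_dose = tr.run_monte_carlo(
            phantom, media, source, n_particles=n_particles,
            seed=derive_seed(seed, "monte_carlo"),
        )
        mc_dose.write_nifti(outdir / "dose_mc.nii.gz")
        report["monte_carlo"] = {
            "n_particles": n_particles,
            "energy_emitted": mc_dose.energy_emitted,
            "energy_absorbed": mc_dose.energy_absorbed,
            "energy_escaped": mc_dose.energy_escaped,
            "conservation_residual": abs(
                mc_dose.energy_emitted - mc_dose.energy_absorbed - mc_dose.energy_escaped
            ) / mc_dose.energy_emitted,
        }

    if transport_cfg.get("deterministic", True):
        n_ord = int(transport_cfg.get("n_ordinates", 6))
        system = tr.build_transport_system(phantom, media, source, n_ordinates=n_ord)
        flux = tr.solve_classical(system)
        det_dose = tr.flux_to_dose(
            flux, media, normalization=source.prescription_dose,
            density=phantom.density, spacing=phantom.spacing,
        )
        det_dose.write_nifti(outdir / "dose_deterministic.nii.gz")
        report["deterministic"] = {
            "n_ordinates": n_ord,
            "dimension": system.dimension,
            "sparsity_s": system.s,
            "kappa": system.kappa,
            "residual": flux.residual,
        }
        if transport_cfg.get("quantum", False):
            # HHL demonstration on a reduced toy system (dimension-capped)
            toy = np.asarray(transport_cfg.get("quantum_matrix", [[2.0, 0.0], [0.0, 1.0]]))
            toy_b = np.asarray(transport_cfg.get("quantum_rhs", [1.0, 1.0]))
            hhl = hhl_solve(toy, toy_b, HHLConfig(seed=derive_seed(seed, "hhl")))
            cost = hhl_cost_model(system.dimension, system.s, max(system.kappa, 1.0), 0.01)
            report["quantum"] = {
                "fidelity": hhl.fidelity,
                "success_probability": hhl.success_probability,
                "resources": hhl.resources,
                "predicted_cost": cost.predicted_cost,
                "classical_cost": cost.classical_cost,
            }

    with open(outdir / "simulate_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_manifest(outdir, "simulate", {"config": cfg, "seed": seed})
    return report


def cmd_makedata(spec, outdir, force: bool = False) -> dict:
    """Generate a seeded (phantom features, dose) training corpus."""
    cfg = load_config(spec)
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is non-empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    count = int(cfg.get("count", 20))
    seed = int(cfg.get("seed", 0))
    shape = tuple(cfg.get("shape", (16, 16, 16)))
    n_particles = int(cfg.get("n_particles", 4000))
    manifest_items = []
    for i in range(count):
        item_seed = derive_seed(seed, f"item-{i}")
        rng = np.random.default_rng(item_seed)
        pattern = ["slab", "concentric"][i % 2]
        densities = [(0, 1.0), (1, float(rng.uniform(1.05, 1.3))), (2, float(rng.uniform(0.2, 0.5)))]
        pspec = ph.PhantomSpec(
            shape=shape, pattern=pattern, tissue_densities=densities,
            spacing=tuple(cfg.get("spacing", (2.0, 2.0, 2.0))), seed=item_seed,
        )
        phantom = ph.generate_phantom(pspec)
        media = tr.build_media(phantom)
        source = ph.make_source(
            {"modality": "external_beam", "field_size_mm": float(cfg.get("field_size_mm", 20.0))}
        )
        dose = tr.run_monte_carlo(
            phantom, media, source, n_particles=n_particles, seed=derive_seed(item_seed, "mc")
        )
        path = outdir / f"pair_{i:04d}.npz"
        np.savez_compressed(
            path,
            features=phantom.density.astype(np.float32),
            dose=dose.dose.astype(np.float32),
            spacing=np.asarray(phantom.spacing),
        )
        item = {
            "file": path.name,
            "seed": item_seed,
            "pattern": pattern,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            "energy_emitted": dose.energy_emitted,
            "energy_absorbed": dose.energy_absorbed,
            "energy_escaped": dose.energy_escaped,
        }
        manifest_items.append(item)
    manifest = {"count": count, "seed": seed, "items": manifest_items}
    with open(outdir / "dataset_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _write_manifest(outdir, "makedata", {"config": cfg})
    return manifest


def load_dataset(datadir) -> list[tuple[np.ndarray, np.ndarray]]:
    """Load (features, dose) pairs; corrupt pairs are skipped with a warning."""
    datadir = Path(datadir)
    pairs = []
    skipped = 0
    for path in sorted(datadir.glob("pair_*.npz")):
        try:
            with np.load(path) as z:
                pairs.append((z["features"].astype(float), z["dose"].astype(float)))
        except Exception as exc:
            skipped += 1
            logger.warning("skipping corrupt pair %s: %s", path.name, exc)
    if skipped:
        logger.warning("skipped %d corrupt pairs", skipped)
    return pairs


def cmd_train(config, datadir, outdir) -> dict:
    """Train the surrogate on a makedata corpus; write checkpoint + history CSV."""
    cfg = load_config(config)
    outdir = Path(outdir)
    dataset = load_dataset(datadir)
    if not dataset:
        raise FileNotFoundError(f"no training pairs found in {datadir}")
    seed = int(cfg.get("seed", 0))
    tcfg = TrainingConfig(
        learning_rate=float(cfg.get("learning_rate", 0.001)),
        batch_size=int(cfg.get("batch_size", 32)),
        epochs=int(cfg.get("epochs", 100)),
        validation_split=float(cfg.get("validation_split", 0.2)),
        optimizer=str(cfg.get("optimizer", "adam")),
        dropout_rate=float(cfg.get("dropout_rate", 0.3)),
        seed=derive_seed(seed, "train"),
    )
    lcfg = LossConfig(lam=float(cfg.get("lambda", 1e-4)))
    shape = dataset[0][0].shape
    model, _counts = build_network(
        reference_architecture(input_shape=(*shape, 1)),
        seed=derive_seed(seed, "init"),
        dropout_rate=tcfg.dropout_rate,
    )
    model = train(model, dataset, tcfg, lcfg)
    outdir.mkdir(parents=True, exist_ok=True)
    model.save(outdir / "checkpoint.npz")
    with open(outdir / "history.csv", "w") as fh:
        fh.write("epoch,train_loss,val_loss\n")
        for rec in model.history:
            fh.write(f"{rec['epoch']},{rec['train_loss']:.10g},{rec['val_loss']:.10g}\n")
    _write_manifest(outdir, "train", {"config": cfg, "n_pairs": len(dataset)})
    return {"final_train_loss": model.history[-1]["train_loss"], "epochs": len(model.history)}


def cmd_evaluate(pred_path, ref_path, outdir, criteria: Optional[dict] = None) -> dict:
    """Compare two dose volumes; write metrics JSON, DVH CSV and gamma NIfTI."""
    criteria = criteria or {}
    outdir = Path(outdir)
    pred = ph.read_volume(str(pred_path))
    ref = ph.read_volume(str(ref_path))
    if pred.shape != ref.shape or not np.allclose(pred.spacing, ref.spacing):
        raise ValueError("prediction and reference volumes must share one grid")
    dp = tr.DoseGrid(dose=pred.density, spacing=pred.spacing)
    dr = tr.DoseGrid(dose=ref.density, spacing=ref.spacing)
    gc = dm.GammaCriteria(
        dose_tolerance_percent=float(criteria.get("dose_tolerance_percent", 3.0)),
        distance_tolerance_mm=float(criteria.get("distance_tolerance_mm", 3.0)),
        normalization=str(criteria.get("normalization", "global")),
        dose_cutoff_percent=float(criteria.get("dose_cutoff_percent", 10.0)),
    )
    mae, mse = dm.error_metrics(dp, dr)
    gamma = dm.gamma_index(dp, dr, gc)
    threshold = float(criteria.get("isodose_threshold", 0.5 * dr.dose.max()))
    dice = dm.dice_isodose(dp, dr, threshold)
    try:
        hausdorff = dm.hausdorff_isodose(dp, dr, threshold)
    except ValueError:
        hausdorff = float("nan")
    dvh = dm.compute_dvh(dr, bin_width_gy=float(criteria.get("dvh_bin_width_gy", 0.1)))
    outdir.mkdir(parents=True, exist_ok=True)
    dvh.to_csv(outdir / "dvh_reference.csv")
    tr.DoseGrid(dose=gamma.gamma_map, spacing=dr.spacing).write_nifti(outdir / "gamma_map.nii.gz")
    result = {
        "mae_gy": mae,
        "mse_gy2": mse,
        "gamma_pass_rate_percent": gamma.pass_rate,
        "dice": dice,
        "hausdorff_mm": hausdorff,
        "isodose_threshold_gy": threshold,
    }
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    _write_manifest(outdir, "evaluate", {"criteria": criteria})
    return result


def cmd_hybrid(config, datadir, outdir) -> dict:
    """Hybrid refinement of a surrogate against a simulated reference."""
    cfg = load_config(config)
    outdir = Path(outdir)
    seed = int(cfg.get("seed", 0))
    dataset = load_dataset(datadir)
    if not dataset:
        raise FileNotFoundError(f"no pairs found in {datadir}")
    features, ref_dose = dataset[0]
    spacing = tuple(cfg.get("spacing", (2.0, 2.0, 2.0)))
    model, _ = build_network(
        reference_architecture(input_shape=(*features.shape, 1)),
        seed=derive_seed(seed, "init"), dropout_rate=0.0,
    )
    reference = tr.DoseGrid(dose=ref_dose, spacing=spacing)
    hcfg = HybridConfig(
        tolerance=float(cfg.get("tolerance", 0.05)),
        max_iterations=int(cfg.get("max_iterations", 10)),
        discrepancy_metric=str(cfg.get("discrepancy_metric", "mae")),
        learning_rate=float(cfg.get("learning_rate", 0.01)),
        seed=derive_seed(seed, "hybrid"),
    )
    adapter = SurrogateAdapter(model, spacing=spacing)
    _, trace = run_hybrid_loop(adapter, lambda _pred: reference, features, reference, hcfg)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "hybrid_trace.json", "w") as fh:
        json.dump(trace.to_json_dict(), fh, indent=2, sort_keys=True)
    with open(outdir / "hybrid_trace.csv", "w") as fh:
        fh.write("iteration,discrepancy,learning_rate\n")
        for r in trace.records:
            fh.write(f"{r['iteration']},{r['discrepancy']:.10g},{r['learning_rate']:.10g}\n")
    _write_manifest(outdir, "hybrid", {"config": cfg})
    return trace.to_json_dict()


def cmd_sensitivity(config, outdir) -> dict:
    """Sobol/FAST screening of a dose summary over treatment parameters."""
    cfg = load_config(config)
    outdir = Path(outdir)
    seed = int(cfg.get("seed", 0))
    space = (
        ParameterSpace({k: tuple(v) for k, v in cfg["parameters"].items()})
        if "parameters" in cfg
        else ParameterSpace.treatment_planning_default()
    )
    shape = tuple(cfg.get("shape", (8, 8, 8)))
    spec = ph.PhantomSpec(shape=shape, pattern="uniform", spacing=(2.0, 2.0, 2.0),
                          seed=derive_seed(seed, "phantom"))
    base_phantom = ph.generate_phantom(spec)

    def dose_summary(params: np.ndarray) -> float:
        vals = dict(zip(space.names, params))
        density = base_phantom.density * vals.get("patient_anatomy", 1.0)
        phantom = ph.Phantom(density=density, labels=base_phantom.labels,
                             spacing=base_phantom.spacing)
        media = tr.build_media(phantom)
        # beam energy scales attenuation down (harder beam penetrates deeper);
        # beam tilt enters as the smooth slant-path correction 1/cos(angle)
        energy = vals.get("beam_energy", 6.0)
        angle = min(abs(vals.get("beam_direction", 0.0)), 1.2)
        slant = 1.0 / np.cos(angle)
        media = tr.MediumProperties(
            mu_t=media.mu_t * 6.0 / energy * slant,
            mu_s=media.mu_s * 6.0 / energy * slant,
            g=media.g,
        )
        source = ph.make_source(
            {"modality": "external_beam", "direction": (1.0, 0.0, 0.0), "field_size_mm": 10.0}
        )
        system = tr.build_transport_system(phantom, media, source, n_ordinates=6,
                                           estimate_kappa=False)
        flux = tr.solve_classical(system)
        dose = tr.flux_to_dose(flux, media, normalization=2.0, density=phantom.density,
                               spacing=phantom.spacing)
        return float(dose.dose.mean())

    report = sobol_indices(
        dose_summary, space,
        n_base_samples=int(cfg.get("n_base_samples", 256)),
        seed=derive_seed(seed, "sobol"),
        compute_interactions=bool(cfg.get("interactions", False)),
    )
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "sensitivity.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    with open(outdir / "sensitivity.csv", "w") as fh:
        fh.write("parameter,first_order,total_order,fast_importance\n")
        for name in space.names:
            fh.write(
                f"{name},{report.first_order[name]:.6g},"
                f"{report.total_order[name]:.6g},{report.fast_importance[name]:.6g}\n"
            )
    _write_manifest(outdir, "sensitivity", {"config": cfg})
    return report.to_json_dict()
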