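"""End-to-end orchestration: superpose -> PCA -> separation search -> FMA ->
WHAM -> basins, behind one configuration file.

The configuration is a YAML mapping; :func:`validate_config` normalizes it
(defaults filled, units checked, paths verified) before any computation.
:func:`run_pipeline` executes the stages in order, writes every intermediate
artifact under the output directory, and returns a machine-readable summary.
Stages whose artifacts already exist can be skipped with ``resume=True``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import fma as _fma
from . import free_energy as fe
from . import pca as _pca
from . import rc_search as rc
from .ensemble_io import read_flat
from .exceptions import ConfigurationError, InputError
from .synthetic import read_window_manifest
from .units import DEFAULT_TEMPERATURE, spring_kt_to_kj

logger = logging.getLogger("dimerbend.pipeline")

#: Defaults for every recognized configuration key (nested by section).
CONFIG_DEFAULTS = {
    "seed": 0,
    "out_dir": "pipeline_out",
    "temperature": DEFAULT_TEMPERATURE,
    "ensembles": {"a": None, "b": None},
    "separation": {
        "d": 10, "n_scans": 500, "n_vectors": 2000,
        "density_model": "gaussian",
    },
    "fma": {"k_max": 10, "split": "half", "reference": "first"},
    "wham": {
        "manifest": None, "bins": 100, "n_boot": 20, "tol": 1e-7,
        "spring_k_unit": "kJ/mol/nm^2",
    },
    "basins": {"split": "auto"},
}


@dataclasses.dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    temperature: float
    ensembles: dict
    separation: dict
    fma: dict
    wham: dict
    basins: dict


def _merge_defaults(user: dict, defaults: dict, path="") -> dict:
    out = {}
    unknown = [f"{path}{k}" for k in user if k not in defaults]
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {', '.join(unknown)}")
    for key, default in defaults.items():
        if isinstance(default, dict):
            out[key] = _merge_defaults(user.get(key, {}) or {}, default, f"{path}{key}.")
        else:
            out[key] = user.get(key, default)
    return out


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse, default-fill and sanity-check a pipeline configuration."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    cfg = _merge_defaults(raw, CONFIG_DEFAULTS)

    problems = []
    sep = cfg["separation"]
    if sep["n_scans"] < 1 or sep["n_vectors"] < 1:
        problems.append("separation.n_scans and n_vectors must be >= 1")
    if sep["d"] < 2:
        problems.append("separation.d must be >= 2")
    if cfg["temperature"] <= 0:
        problems.append("temperature must be positive (K)")
    if cfg["fma"]["k_max"] < 1:
        problems.append("fma.k_max must be >= 1")
    for side in ("a", "b"):
        p = cfg["ensembles"][side]
        if p is not None and not Path(p).exists():
            problems.append(f"ensembles.{side}: file not found: {p}")
    if cfg["wham"]["manifest"] is not None and not Path(cfg["wham"]["manifest"]).exists():
        problems.append(f"wham.manifest: file not found: {cfg['wham']['manifest']}")
    unit = cfg["wham"]["spring_k_unit"]
    if unit not in ("kJ/mol/nm^2", "kT/nm^2"):
        problems.append(f"wham.spring_k_unit must be kJ/mol/nm^2 or kT/nm^2, got {unit}")
    if problems:
        raise ConfigurationError("invalid configuration:\n  " + "\n  ".join(problems))

    return PipelineConfig(
        seed=int(cfg["seed"]),
        out_dir=Path(cfg["out_dir"]),
        temperature=float(cfg["temperature"]),
        ensembles=cfg["ensembles"],
        separation=sep,
        fma=cfg["fma"],
        wham=cfg["wham"],
        basins=cfg["basins"],
    )


def _stage(summary, name, out_dir, resume, artifact, fn):
    """Run one stage unless its artifact exists and resume is requested."""
    path = out_dir / artifact
    if resume and path.exists():
        logger.info("stage %s: artifact %s exists, skipping", name, artifact)
        summary.setdefault("skipped", []).append(name)
        return None
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception:
        logger.error("stage %s failed; inputs preserved under %s", name, out_dir)
        raise
    summary.setdefault("stage_seconds", {})[name] = round(time.perf_counter() - t0, 3)
    return result


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the analysis chain described by *config*.

    Writes intermediate artifacts (PCA spectrum, projections, separation
    vector, FMA tables, WHAM profile, basin report) under ``config.out_dir``
    and returns the summary dict, which is also written as
    ``summary.json``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)
    sub_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                 for name, s in zip(("separation", "fma", "bootstrap"),
                                    seed_seq.spawn(3))}
    summary = {"seed": config.seed, "sub_seeds": sub_seeds}

    flat_a = flat_b = None
    if config.ensembles["a"] and config.ensembles["b"]:
        flat_a = read_flat(config.ensembles["a"])
        flat_b = read_flat(config.ensembles["b"])

        def do_pca():
            combined = np.vstack([flat_a.X, flat_b.X])
            from .ensemble_io import FlatEnsemble
            basis = _pca.compute_pca(FlatEnsemble(X=combined, mean=combined.mean(axis=0)))
            frac = _pca.variance_fractions(basis)
            np.savetxt(out / "pca_eigenvalues.tsv",
                       np.column_stack([basis.eigenvalues, frac]),
                       delimiter="\t", header="eigenvalue_nm2\tvariance_fraction")
            summary["pca_top_fraction"] = float(frac[0])
            return basis

        basis = _stage(summary, "pca", out, resume, "pca_eigenvalues.tsv", do_pca)

        def do_separation():
            cfg = rc.SeparationSearchConfig(
                d=config.separation["d"],
                n_scans=config.separation["n_scans"],
                n_vectors=config.separation["n_vectors"],
                density_model=config.separation["density_model"],
                seed=sub_seeds["separation"],
            )
            res = rc.search_separation_rc(flat_a, flat_b, cfg)
            np.savetxt(out / "separation_vector.tsv", res.n_hat, delimiter="\t")
            np.savetxt(out / "separation_variance_trace.tsv", res.variance_trace,
                       delimiter="\t")
            ortho = _pca.max_variance_orthogonal(
                _combined_flat(flat_a, flat_b), res.n_hat)
            table = np.column_stack([
                np.concatenate([flat_a.X @ res.n_hat, flat_b.X @ res.n_hat]),
                np.concatenate([flat_a.X @ ortho, flat_b.X @ ortho]),
                np.concatenate([np.zeros(flat_a.n_frames), np.ones(flat_b.n_frames)]),
            ])
            np.savetxt(out / "separation_projection_2d.tsv", table, delimiter="\t",
                       header="separation_rc\tmax_var_orthogonal\tensemble")
            summary["overlap"] = res.overlap_value
            summary["separation_variance_final"] = float(res.variance_trace[-1].max())
            return res

        _stage(summary, "separation", out, resume, "separation_vector.tsv",
               do_separation)

        def do_fma():
            ref = (flat_a.X[0] if config.fma["reference"] == "first"
                   else np.loadtxt(config.fma["reference"]))
            f = _fma.rmsd_series(flat_a, ref)
            rv, k_chosen, model = _fma.cross_validate(
                flat_a.X, f, config.fma["k_max"], split=config.fma["split"],
                seed=sub_seeds["fma"])
            np.savetxt(out / "fma_rv_by_k.tsv",
                       np.column_stack([np.arange(1, rv.size + 1), rv]),
                       delimiter="\t", header="k\trv")
            np.savetxt(out / "fma_mode.tsv", model.mode, delimiter="\t")
            pred = model.predict(flat_a.X)
            np.savetxt(out / "fma_f_vs_fhat.tsv", np.column_stack([f, pred]),
                       delimiter="\t", header="f\tf_hat")
            summary["fma_k_chosen"] = int(k_chosen)
            summary["fma_rm"] = float(model.rm)
            summary["fma_rv"] = float(rv[k_chosen - 1])
            return model

        _stage(summary, "fma", out, resume, "fma_mode.tsv", do_fma)

    profile = None
    if config.wham["manifest"]:
        def do_wham():
            windows = read_window_manifest(config.wham["manifest"])
            if config.wham["spring_k_unit"] == "kT/nm^2":
                for w in windows:
                    w.spring_k = spring_kt_to_kj(w.spring_k, config.temperature)
            prof = fe.wham(windows, bins=config.wham["bins"],
                           temperature=config.temperature, tol=config.wham["tol"])
            err = fe.bootstrap_profile_error(
                windows, bins=config.wham["bins"], temperature=config.temperature,
                n_boot=config.wham["n_boot"], seed=sub_seeds["bootstrap"])
            prof.err = err
            force_err = fe.mean_force_error(windows, temperature=config.temperature)
            force_err.to_csv(out / "wham_force_errors.tsv", sep="\t", index=False)
            prof.to_frame().to_csv(out / "wham_profile.tsv", sep="\t", index=False)
            return prof

        profile = _stage(summary, "wham", out, resume, "wham_profile.tsv", do_wham)
        if profile is None and (out / "wham_profile.tsv").exists():
            import pandas as pd
            df = pd.read_csv(out / "wham_profile.tsv", sep="\t")
            profile = fe.FreeEnergyProfile(
                axis=df["rc"].to_numpy(), G=df["G_kT"].to_numpy(),
                err=df["err_kT"].to_numpy(), occupied=df["occupied"].to_numpy(bool))

        def do_basins():
            basins = fe.basin_analysis(profile, split=config.basins["split"])
            report = {
                "dg_basin_1": basins.dg_basin_1,
                "dg_basin_2": basins.dg_basin_2,
                "ddg": basins.ddg,
                "p_deeper": basins.p_deeper,
                "barrier_position": basins.barrier_position,
            }
            (out / "basin_report.json").write_text(json.dumps(report, indent=2))
            summary.update({"ddg": basins.ddg, "p_deeper": basins.p_deeper})
            return basins

        _stage(summary, "basins", out, resume, "basin_report.json", do_basins)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def _combined_flat(flat_a, flat_b):
    from .ensemble_io import FlatEnsemble
    X = np.vstack([flat_a.X, flat_b.X])
    return FlatEnsemble(X=X, mean=X.mean(axis=0))
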