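"""End-to-end orchestration: data -> GPA -> symmetry ANOVA -> D/G/P ->
rank selection -> matrix comparisons -> alignment tests.

A run is driven by a single RunConfig (YAML-serializable, all seeds explicit)
and produces a directory of JSON/CSV artifacts plus a manifest with input
hashes, seeds, stage timings and output checksums. Identical config and seeds
give identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import align as align_mod
from . import compare as compare_mod
from . import io as io_mod
from . import procrustes as procrustes_mod
from . import simulate as simulate_mod
from . import varcomp as varcomp_mod

__all__ = ["RunConfig", "RunManifest", "run", "PipelineError"]

logger = logging.getLogger("shapevar")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    ``source`` selects simulated input (preset 'paper' or 'calibration') or a
    CSV/TPS file; every stochastic stage has an explicit seed derived from
    ``seed``. Defaults mirror the published analysis (q = 6 reference axes,
    10 000 MVN resamples and skewers); ``RunConfig.demo()`` gives a
    reduced-cost preset for smoke tests.
    """

    source: str = "simulate"  # 'simulate' | 'csv' | 'tps'
    path: str | None = None
    preset: str = "paper"
    sim_seed: int = 1
    seed: int = 0
    q: int = 6
    n_resamples: int = 10000
    n_skewers: int = 10000
    n_permutations: int = 999
    m_max: int = 8
    method: str = "moment"  # 'moment' | 'reml'
    rank_selection: bool = True
    use_factor_models: bool = False
    alignment_null: str = "permute"
    n_alignment_resamples: int = 10000
    jackknife: bool = True
    output_dir: str = "shapevar_out"

    @classmethod
    def demo(cls, output_dir: str = "shapevar_demo") -> "RunConfig":
        return cls(
            n_resamples=1000,
            n_skewers=1000,
            n_permutations=199,
            n_alignment_resamples=999,
            rank_selection=False,
            jackknife=False,
            output_dir=output_dir,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text: str | Path) -> "RunConfig":
        p = Path(path_or_text)
        text = p.read_text() if p.exists() else str(path_or_text)
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    stages: list[dict] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    input_hash: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")


def run(config: RunConfig) -> RunManifest:
    """Execute all stages; artifacts land in ``config.output_dir``.

    Any stage error halts the run with a PipelineError naming the stage;
    artifacts of completed stages are preserved.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["anova", "rank", "subspace", "skewers", "eigvec", "aligntest"],
            rng.spawn(6),
        )
    }
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seeds={"root": config.seed, "simulation": config.sim_seed, **stage_seeds},
        versions={"numpy": np.__version__},
    )

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                manifest.stages.append(
                    {"name": name, "seconds": round(dt, 3), "ok": exc is None}
                )
                if exc is not None:
                    _write_json(outdir / "manifest.json", json.loads(manifest.to_json()))
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Ctx()

    # --- input --------------------------------------------------------------
    with stage("input"):
        truth = None
        if config.source == "simulate":
            if config.preset == "paper":
                params = simulate_mod.default_paper_design(seed=config.sim_seed)
            elif config.preset == "calibration":
                params = simulate_mod.calibration_design(seed=config.sim_seed)
            else:
                raise ValueError(f"unknown preset {config.preset!r}")
            configs, design, truth = simulate_mod.simulate_dataset(params)
            manifest.input_hash = hashlib.sha256(
                config.preset.encode() + str(config.sim_seed).encode()
            ).hexdigest()
        elif config.source == "csv":
            configs, design = io_mod.read_table(config.path)
            manifest.input_hash = _sha256(Path(config.path))
        elif config.source == "tps":
            configs = io_mod.read_tps(config.path)
            design = None
            manifest.input_hash = _sha256(Path(config.path))
        else:
            raise ValueError(f"unknown source {config.source!r}")
        report = io_mod.validate_design(configs, design)
        _write_json(outdir / "design_report.json", json.loads(report.to_json()))

    # --- alignment ----------------------------------------------------------
    with stage("gpa"):
        aligned = procrustes_mod.gpa(configs)
        aligned.to_frame().to_csv(outdir / "aligned.csv", index=False)
        logger.info(
            "GPA converged in %d iterations (change %.2e)",
            aligned.n_iterations,
            aligned.final_change,
        )

    # --- symmetry ANOVA -----------------------------------------------------
    with stage("anova"):
        anova = procrustes_mod.symmetry_anova(
            aligned, n_permutations=config.n_permutations, seed=stage_seeds["anova"]
        )
        anova.table.to_csv(outdir / "symmetry_anova.csv")
        _write_json(outdir / "symmetry_anova.json", json.loads(anova.to_json()))

    # --- variance components --------------------------------------------------
    with stage("estimate"):
        mats = varcomp_mod.estimate_dgp(aligned, design, method=config.method)
        for label, cm in mats.items():
            _write_json(outdir / f"{label}_matrix.json", cm.to_dict())

    rank_tables = {}
    if config.rank_selection:
        with stage("rank"):
            for structure, label in (("individual_by_side", "D"), ("family", "G")):
                try:
                    m_star, table, models = varcomp_mod.select_rank(
                        aligned,
                        design,
                        m_max=config.m_max,
                        random_structure=structure,
                        seed=stage_seeds["rank"],
                    )
                except varcomp_mod.EstimationError as err:
                    logger.warning("rank selection for %s failed: %s", label, err)
                    continue
                rank_tables[label] = {"m_star": m_star, "table": table.to_dict("records")}
                non_conv = table[~table["converged"]]["m"].tolist()
                if non_conv:
                    logger.warning("non-converged FA ranks for %s: %s", label, non_conv)
                if config.use_factor_models:
                    mats[label] = varcomp_mod.reconstruct_cov(models[m_star])
                    # MVN resampling needs the sampling covariance of the fit
                    refit = varcomp_mod.fit_factor_model(
                        aligned,
                        design,
                        m_star,
                        random_structure=structure,
                        seed=stage_seeds["rank"],
                        compute_sampling_cov=True,
                    )
                    mats[label] = varcomp_mod.reconstruct_cov(refit)
            _write_json(outdir / "rank_selection.json", rank_tables)

    # --- matrix comparisons ---------------------------------------------------
    with stage("compare"):
        jk_r = jk_b = jk_vec = None
        if config.jackknife and design is not None:
            k_obs = compare_mod.reference_basis(mats["P"], config.q)

            def stat_r(dgp):
                return compare_mod.krzanowski_compare(dgp["D"], dgp["G"], k_obs).r

            def stat_b(dgp):
                return compare_mod.krzanowski_compare(dgp["D"], dgp["G"], k_obs).b

            def stat_vec(dgp):
                return compare_mod.vector_correlation(
                    dgp["D"].leading_eigenvector, dgp["G"].leading_eigenvector
                )

            jk_r = varcomp_mod.jackknife_dgp(aligned, design, stat_r, unit="family")
            jk_b = varcomp_mod.jackknife_dgp(aligned, design, stat_b, unit="family")
            jk_vec = varcomp_mod.jackknife_dgp(aligned, design, stat_vec, unit="family")
        subspace = compare_mod.subspace_comparison_with_ci(
            mats["D"],
            mats["G"],
            mats["P"],
            q=config.q,
            n_samples=config.n_resamples,
            seed=stage_seeds["subspace"],
            jackknife_r=jk_r,
            jackknife_b=jk_b,
        )
        _write_json(outdir / "subspace_comparison.json", subspace.to_dict())
        skewers = compare_mod.random_skewers(
            mats["D"], mats["G"], n_vectors=config.n_skewers, seed=stage_seeds["skewers"]
        )
        _write_json(outdir / "random_skewers.json", skewers.to_dict())
        eig_corr = compare_mod.eigenvector_correlation_with_ci(
            mats["D"],
            mats["G"],
            n_samples=config.n_resamples,
            seed=stage_seeds["eigvec"],
            jackknife_values=jk_vec,
        )
        _write_json(outdir / "eigenvector_correlation.json", eig_corr)

    # --- alignment of shape-change vectors ------------------------------------
    alignment_out = {}
    if design is not None and "latitude" in design.table.columns:
        with stage("aligntest"):
            dmax = mats["D"].leading_eigenvector
            gmax = mats["G"].leading_eigenvector
            for covariate in ("temperature", "latitude"):
                try:
                    vec = align_mod.fit_shape_regression(aligned, design, covariate)
                except ValueError as err:
                    logger.warning("shape regression for %s failed: %s", covariate, err)
                    continue
                e_test = align_mod.e_beta_test(
                    vec,
                    mats["D"],
                    n_resamples=config.n_alignment_resamples,
                    seed=stage_seeds["aligntest"],
                    null=config.alignment_null,
                    reference="D",
                )
                ang_d = align_mod.angle_test(
                    vec,
                    dmax,
                    n_resamples=config.n_alignment_resamples,
                    seed=stage_seeds["aligntest"] + 1,
                    null=config.alignment_null,
                    reference="dmax",
                )
                ang_g = align_mod.angle_test(
                    vec,
                    gmax,
                    n_resamples=config.n_alignment_resamples,
                    seed=stage_seeds["aligntest"] + 2,
                    null=config.alignment_null,
                    reference="gmax",
                )
                e_test_g = align_mod.e_beta_test(
                    vec,
                    mats["G"],
                    n_resamples=config.n_alignment_resamples,
                    seed=stage_seeds["aligntest"] + 3,
                    null=config.alignment_null,
                    reference="G",
                )
                alignment_out[covariate] = {
                    "vector": vec.to_dict(),
                    "e_beta_D": e_test.to_dict(),
                    "e_beta_G": e_test_g.to_dict(),
                    "angle_dmax": ang_d.to_dict(),
                    "angle_gmax": ang_g.to_dict(),
                }
            _write_json(outdir / "alignment_tests.json", alignment_out)

    with stage("manifest"):
        for f in sorted(outdir.glob("*.json")) + sorted(outdir.glob("*.csv")):
            if f.name != "manifest.json":
                manifest.outputs[f.name] = _sha256(f)
        _write_json(outdir / "manifest.json", json.loads(manifest.to_json()))
    return manifest
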