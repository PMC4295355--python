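"""End-to-end pipeline: simulate -> fit -> regress -> score -> summarize.

Each stage reads and writes delimited-text artifacts in one output
directory, so any stage can also be re-run from files produced elsewhere.
A machine-readable manifest (seed, parameters, parameter hash, per-stage
timing, collected warnings) is written alongside; every output CSV begins
with a comment header carrying the run seed and the parameter hash, and a
rerun from the same configuration is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort, specimen_frame
from .exceptions import ConfigError
from .fitting import peel_off_fit
from .regression import fit_quadratic
from .scoring import CancerProbabilityScorer, printed_scorers
from .stats import correlation_frame, correlation_table, summary_table
from .tableio import fit_results_frame, read_curves, write_curves, write_table

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("tissuediff.pipeline")

STAGES = ("simulate", "fit", "regress", "score", "summarize")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``stages`` toggles each step; disabled upstream stages must have their
    outputs already present in ``out_dir`` (the dependency check fails
    otherwise).  All module defaults are surfaced here so a manifest fully
    determines a run.
    """

    out_dir: str | Path = "tissuediff_run"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    # simulate
    mode: str = "group_parameter"
    n_control: int | None = None
    n_cancer: int | None = None
    noise_sigma: float = 0.005
    # fit
    tail_fraction: float = 0.4
    refine: bool = True
    n_initial: int = 3
    # regress
    regression_design: str = "pure_quadratic"
    # score
    score_variants: tuple[str, ...] = ("morphology", "diffusion2", "diffusion3")
    threshold: float = 0.5
    refit_scorers: bool = False
    log_level: str = "INFO"

    def parameter_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self) | {"out_dir": None}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _check_dependencies(cfg: RunConfig, out: Path) -> None:
    enabled = set(cfg.stages)
    unknown = enabled - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")

    def available(artifact: str, producer: str) -> bool:
        return producer in enabled or (out / artifact).exists()

    if "fit" in enabled and not available("curves.csv", "simulate"):
        raise ConfigError("stage 'fit' needs curves.csv: enable 'simulate' or provide it")
    needs_specimens = enabled & {"regress", "score", "summarize"}
    if needs_specimens and not available("specimens.csv", "simulate"):
        raise ConfigError(
            f"stages {sorted(needs_specimens)} need specimens.csv: "
            "enable 'simulate' or provide it"
        )
    diffusion_variants = {"diffusion2", "diffusion3"} & set(cfg.score_variants)
    if "score" in enabled and diffusion_variants and not available(
        "specimens_fitted.csv", "fit"
    ):
        raise ConfigError(
            "scoring on diffusion variants needs fitted parameters: enable the "
            "'fit' stage or provide specimens_fitted.csv"
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    On a stage failure the partially written outputs of that stage are
    renamed with a ``.partial`` suffix and the exception is re-raised with
    the stage named.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _check_dependencies(config, out)

    meta = {
        "seed": config.seed,
        "config_sha": config.parameter_hash(),
        "tissuediff_version": __version__,
    }
    manifest: dict = {
        "config": dataclasses.asdict(config) | {"out_dir": str(out)},
        "parameter_hash": config.parameter_hash(),
        "version": __version__,
        "stages": {},
        "warnings": [],
    }

    runners = {
        "simulate": _stage_simulate,
        "fit": _stage_fit,
        "regress": _stage_regress,
        "score": _stage_score,
        "summarize": _stage_summarize,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        written: list[Path] = []
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                runners[stage](config, out, meta, written)
            for w in caught:
                manifest["warnings"].append({"stage": stage, "message": str(w.message)})
        except Exception as exc:
            for p in written:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"seconds": round(dt, 3), "outputs": [p.name for p in written]}
        log.info("stage %s finished in %.2f s", stage, dt)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_simulate(cfg: RunConfig, out: Path, meta: dict, written: list[Path]):
    cohort_cfg = CohortConfig(
        mode=cfg.mode, noise_sigma=cfg.noise_sigma, seed=cfg.seed
    ).resize(n_control=cfg.n_control, n_cancer=cfg.n_cancer)
    specimens = generate_cohort(cohort_cfg)
    written.append(out / "specimens.csv")
    write_table(specimen_frame(specimens), written[-1], meta=meta)
    written.append(out / "curves.csv")
    write_curves([s.curve for s in specimens], written[-1], meta=meta)


def _stage_fit(cfg: RunConfig, out: Path, meta: dict, written: list[Path]):
    curves = read_curves(out / "curves.csv")
    results = {}
    for cid, curve in curves.items():
        results[cid] = peel_off_fit(
            curve,
            tail_fraction=cfg.tail_fraction,
            refine=cfg.refine,
            n_initial=cfg.n_initial,
        )
    fits = fit_results_frame(results)
    written.append(out / "fit_results.csv")
    write_table(fits, written[-1], meta=meta)
    # merge fitted parameters back onto the specimen table
    spec = pd.read_csv(out / "specimens.csv", comment="#")
    merged = spec.drop(columns=["d_fast_1e9", "d_slow_1e11", "p1", "adc_1e9"]).merge(
        fits.rename(columns={"curve_id": "specimen_id"}).drop(columns=["method", "residual_rms"]),
        on="specimen_id",
        how="inner",
    )
    written.append(out / "specimens_fitted.csv")
    write_table(merged, written[-1], meta=meta)


def _stage_regress(cfg: RunConfig, out: Path, meta: dict, written: list[Path]):
    src = out / "specimens_fitted.csv"
    if not src.exists():
        src = out / "specimens.csv"
    df = pd.read_csv(src, comment="#")
    X = df[["p", "st", "at", "pce", "v"]].to_numpy()
    rows = []
    for resp, units in [("d_fast_1e9", "1e-9 m^2/s"), ("d_slow_1e11", "1e-11 m^2/s"), ("p1", "")]:
        model = fit_quadratic(
            X,
            df[resp].to_numpy(),
            design_kind=cfg.regression_design,
            feature_names=["P", "St", "AT", "PCE", "V"],
            response_name=resp,
            response_units=units,
        )
        for term, coef, p in zip(model.term_names, model.coefficients, model.p_values):
            rows.append(
                dict(response=resp, term=term, coefficient=coef, p_value=p,
                     r_squared=model.r_squared)
            )
    written.append(out / "regression_coefficients.csv")
    write_table(pd.DataFrame(rows), written[-1], meta=meta)


def _stage_score(cfg: RunConfig, out: Path, meta: dict, written: list[Path]):
    fitted = out / "specimens_fitted.csv"
    df_m = pd.read_csv(out / "specimens.csv", comment="#")
    df_d = pd.read_csv(fitted, comment="#") if fitted.exists() else None
    frames = []
    for variant in cfg.score_variants:
        if variant == "morphology":
            df, cols = df_m, ["p", "st", "at", "pce", "v"]
        else:
            if df_d is None:
                raise ConfigError(f"variant {variant!r} needs fitted diffusion parameters")
            df = df_d
            cols = ["d_fast_1e9", "d_slow_1e11"] + (["p1"] if variant == "diffusion3" else [])
        X = df[cols].to_numpy()
        y = (df["group"] == "cancer").to_numpy(int)
        if cfg.refit_scorers:
            scorer = CancerProbabilityScorer(variant=variant, threshold=cfg.threshold).fit(X, y)
        else:
            scorer = printed_scorers(threshold=cfg.threshold)[variant]
        raw = scorer.decision_function(X)
        prob = scorer.predict_probability(X)
        frames.append(
            pd.DataFrame(
                dict(
                    specimen_id=df["specimen_id"],
                    variant=variant,
                    raw_score=raw,
                    probability=prob,
                    label=["malignant" if p else "nonmalignant" for p in scorer.predict(X)],
                    true_group=df["group"],
                )
            )
        )
    written.append(out / "scores.csv")
    write_table(pd.concat(frames, ignore_index=True), written[-1], meta=meta)


def _stage_summarize(cfg: RunConfig, out: Path, meta: dict, written: list[Path]):
    src = out / "specimens_fitted.csv"
    if not src.exists():
        src = out / "specimens.csv"
    df = pd.read_csv(src, comment="#")
    cols = ["p", "st", "at", "pce", "pve", "v", "d_fast_1e9", "d_slow_1e11", "p1", "adc_1e9"]
    written.append(out / "group_summaries.csv")
    write_table(summary_table(df, cols), written[-1], meta=meta)
    entries = correlation_table(df)
    written.append(out / "correlations.csv")
    write_table(correlation_frame(entries), written[-1], meta=meta)
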