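"""End-to-end orchestration: model file(s) in, fit tables and reports out.

A run is a pure function of (inputs, config, seed).  Every run writes a
fixed set of file names into a fresh run directory:

* ``features.csv`` — the per-pair feature table
* ``pca_scores.csv``, ``pca_summary.csv`` — PC scores and variable diagnostics
* ``fit_full.csv`` — coefficient table of the full model (REML)
* ``fit_report.json`` — variances, logLik, AIC, R², scaling, convergence
* ``comparisons.json`` — LRTs with/without the GC term and the interaction
* ``fit_steps1.csv`` .. ``fit_steps3.csv`` — per-step-class subset fits
* ``group_tests.json`` — Welch ANOVA of pyr_diff across step classes and
  Welch t-tests of PC1/PC2 differences for one- vs two-step pairs
* ``run.log``, ``config.yaml`` — narrative log and the resolved config

The config hash is embedded in the directory name, so a changed config can
never overwrite a previous run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import build_feature_table
from .matrix_io import (
    matrix_similarity,
    read_nonreversible_model,
    read_reversible_model,
    to_rate_table,
)
from .modeling import (
    ModelSpec,
    compare_models,
    fit_by_steps,
    fit_lmm,
    welch_anova,
    welch_t_test,
)
from .pca import run_pca
from .properties import (
    builtin_properties,
    pairwise_differences,
    parse_aaindex,
    read_property_csv,
)
from .synth import SynthScenario, generate_exchange_model

__all__ = ["RunConfig", "run_full_analysis", "compare_taxa", "load_model"]

log = logging.getLogger("aasub")


@dataclass
class RunConfig:
    """Everything that determines a run; round-trips through YAML."""

    model_path: str | None = None
    model_kind: str = "reversible"          # reversible | nonreversible
    synthetic: bool = False                  # use a SynthScenario instead of a file
    mode: str = "directed"                   # directed | undirected
    property_source: str = "builtin"         # builtin | <aaindex file> | <csv file>
    log_base: float = float(np.e)
    normalize_rates: bool = False
    zscore: bool = True
    fixed: tuple[str, ...] = ("PC1", "PC2", "min_steps", "pyr_diff", "PC1:PC2")
    outdir: str = "runs"
    seed: int = 0
    name: str = ""
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.synthetic == (self.model_path is not None):
            raise ValueError(
                "exactly one model source: either a model_path or synthetic=True"
            )
        self.fixed = tuple(self.fixed)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["fixed"] = list(d["fixed"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        d["fixed"] = tuple(d.get("fixed", ()))
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the analysis-determining fields (not where output goes)."""
        d = asdict(self)
        d["fixed"] = list(d["fixed"])
        for key in ("outdir", "verbosity"):
            d.pop(key)
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def load_model(config: RunConfig):
    if config.synthetic:
        # Generate log rates on the PC scores of the *configured* property
        # source, so a synthetic run carries the same property signal the
        # downstream fit will look for.
        from .features import feature_skeleton

        scenario = SynthScenario(seed=config.seed, mode=config.mode)
        pca = run_pca(pairwise_differences(_load_properties(config.property_source)))
        skeleton = feature_skeleton(pca, mode=config.mode)
        return generate_exchange_model(scenario, features=skeleton)
    if config.model_kind == "reversible":
        return read_reversible_model(config.model_path)
    if config.model_kind == "nonreversible":
        return read_nonreversible_model(config.model_path)
    raise ValueError(f"unknown model_kind {config.model_kind!r}")


def _load_properties(source: str) -> pd.DataFrame:
    if source == "builtin":
        return builtin_properties()
    path = Path(source)
    if path.suffix.lower() == ".csv":
        return read_property_csv(path)
    return parse_aaindex(path)


def _fit_to_json(fit) -> dict:
    return {
        "terms": fit.terms,
        "beta": fit.beta.to_dict(),
        "se": fit.se.to_dict(),
        "df": fit.df.to_dict(),
        "p": fit.p.to_dict(),
        "var_u": fit.var_u,
        "sigma2": fit.sigma2,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "r2_marginal": fit.r2_marginal,
        "r2_conditional": fit.r2_conditional,
        "converged": fit.converged,
        "boundary": fit.boundary,
        "n": fit.n,
        "reml": fit.reml,
        "scaling": {k: list(v) for k, v in fit.scaling.items()},
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the output bundle; returns results in memory."""
    run_name = config.name or "run"
    run_dir = Path(config.outdir) / f"{run_name}-{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(run_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.verbosity)
    results: dict = {"run_dir": run_dir}
    stage = "setup"
    try:
        log.info("aasub %s, config hash %s", __version__, config.config_hash())
        (run_dir / "config.yaml").write_text(config.to_yaml())

        stage = "model"
        model = load_model(config)
        log.info("model %r loaded (reversible=%s)", model.name, model.reversible)

        stage = "rates"
        rates = to_rate_table(
            model,
            mode=config.mode,
            normalize=config.normalize_rates,
            log_base=config.log_base,
        )
        log.info("rate table: %d %s rows", len(rates), config.mode)

        stage = "properties"
        props = _load_properties(config.property_source)
        diffs = pairwise_differences(props)
        log.info("properties: %d scales from %s", props.shape[1],
                 config.property_source)

        stage = "pca"
        pca = run_pca(diffs, standardize=True)
        log.info(
            "PCA: PC1 %.1f%%, PC2 %.1f%% of variance (190 unordered pairs)",
            100 * pca.explained_fraction.iloc[0],
            100 * pca.explained_fraction.iloc[1],
        )

        stage = "features"
        feats = build_feature_table(rates, pca)
        feats.to_csv(run_dir / "features.csv", index=False)
        pca.scores.reset_index().to_csv(run_dir / "pca_scores.csv", index=False)
        summary = pd.concat(
            {
                "loading": pca.loadings,
                "contribution": pca.contributions,
                "cos2": pca.cos2,
            },
            axis=1,
        )
        summary.to_csv(run_dir / "pca_summary.csv")
        (run_dir / "pca_explained.json").write_text(
            json.dumps(
                {
                    "config_hash": config.config_hash(),
                    "explained_fraction": pca.explained_fraction.to_dict(),
                    "eigenvalues": pca.eigenvalues.to_dict(),
                    "n_pairs": int(pca.scores.shape[0]),
                },
                indent=2,
            )
        )

        stage = "fit_full"
        spec = ModelSpec(
            fixed=config.fixed,
            zscore_response=config.zscore,
            zscore_predictors=config.zscore,
        )
        fit_full = fit_lmm(feats, spec)
        fit_full.summary_table().to_csv(run_dir / "fit_full.csv", index=False)
        (run_dir / "fit_report.json").write_text(
            json.dumps(
                {"config_hash": config.config_hash(), **_fit_to_json(fit_full)},
                indent=2,
            )
        )
        log.info(
            "full model: R2m=%.3f R2c=%.3f AIC=%.2f",
            fit_full.r2_marginal, fit_full.r2_conditional, fit_full.aic,
        )

        stage = "comparisons"
        ml = spec.with_ml()
        fit_ml = fit_lmm(feats, ml)
        comparisons = {}
        if "gc_diff" not in config.fixed:
            with_gc = fit_lmm(feats, replace(ml, fixed=ml.fixed + ("gc_diff",)))
            comparisons["gc_term"] = compare_models(with_gc, fit_ml)
        else:
            without_gc = fit_lmm(feats, ml.without("gc_diff"))
            comparisons["gc_term"] = compare_models(fit_ml, without_gc)
        if "PC1:PC2" in config.fixed:
            no_int = fit_lmm(feats, ml.without("PC1:PC2"))
            comparisons["interaction"] = compare_models(fit_ml, no_int)
        (run_dir / "comparisons.json").write_text(
            json.dumps(
                {"config_hash": config.config_hash(), **comparisons}, indent=2
            )
        )
        log.info("comparisons: %s", {k: round(v["p"], 4) for k, v in
                                     comparisons.items()})

        stage = "steps"
        step_spec = spec.without("min_steps")
        step_fits = {}
        for k in (1, 2, 3):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                f = fit_by_steps(feats, step_spec, k)
            f.summary_table().to_csv(run_dir / f"fit_steps{k}.csv", index=False)
            step_fits[k] = f
        results["step_fits"] = step_fits

        stage = "group_tests"
        pairs = feats
        if config.mode == "directed":
            pairs = feats[feats["aa_from"] < feats["aa_to"]]
        anova = welch_anova(pairs["pyr_diff"], pairs["min_steps"])
        one = pairs[pairs["min_steps"] == 1]
        two = pairs[pairs["min_steps"] == 2]
        ttests = {}
        for pc in ("PC1", "PC2"):
            res = welch_t_test(one[pc], two[pc])
            res["mean_one_step"] = float(one[pc].mean())
            res["mean_two_step"] = float(two[pc].mean())
            ttests[pc] = res
        group_tests = {"pyr_diff_by_steps_welch_anova": anova,
                       "pc_by_steps_t_tests": ttests}
        (run_dir / "group_tests.json").write_text(
            json.dumps(
                {"config_hash": config.config_hash(), **group_tests}, indent=2
            )
        )

        results.update(
            model=model, rates=rates, properties=props, diffs=diffs, pca=pca,
            features=feats, fit_full=fit_full, comparisons=comparisons,
            group_tests=group_tests,
        )
        log.info("run complete: %s", run_dir)
        return results
    except Exception:
        log.exception("stage %r failed; partial outputs kept in %s", stage, run_dir)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from None
    finally:
        log.removeHandler(handler)
        handler.close()


def compare_taxa(configs: list[RunConfig]) -> dict:
    """Fit each taxon's model and correlate their log-rate tables.

    Returns per-taxon coefficient tables plus the Pearson similarity matrix
    of log rates across matched pairs.
    """
    if len(configs) < 2:
        raise ValueError("need at least two model sources to compare")
    modes = {c.mode for c in configs}
    if len(modes) != 1:
        raise ValueError(f"all configs must share a mode, got {modes}")
    names, tables, fits = [], [], []
    for cfg in configs:
        model = load_model(cfg)
        rates = to_rate_table(model, mode=cfg.mode,
                              normalize=cfg.normalize_rates,
                              log_base=cfg.log_base)
        props = _load_properties(cfg.property_source)
        pca = run_pca(pairwise_differences(props), standardize=True)
        feats = build_feature_table(rates, pca)
        spec = ModelSpec(fixed=cfg.fixed, zscore_response=cfg.zscore,
                         zscore_predictors=cfg.zscore)
        fit = fit_lmm(feats, spec)
        label = cfg.name or model.name
        names.append(label)
        tables.append(rates)
        fits.append(fit)
    k = len(names)
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            sim[i, j] = sim[j, i] = matrix_similarity(tables[i], tables[j])
    rows = []
    for label, fit in zip(names, fits):
        tab = fit.summary_table()
        tab.insert(0, "taxon", label)
        rows.append(tab)
    return {
        "similarity": pd.DataFrame(sim, index=names, columns=names),
        "fits": dict(zip(names, fits)),
        "fit_table": pd.concat(rows, ignore_index=True),
    }
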