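"""End-to-end orchestration: stratify -> match -> weight -> tree -> validate.

Driven by a YAML/JSON run config.  The observational and RCT branches are
explicit in the config (never auto-detected): the RCT branch skips the
confounding-weight machinery entirely and instead repairs sparse high-risk
strata by seeded oversampling when the balance diagnostics flag them.

Every data-dependent decision (merged buckets, dropped buckets, the selected
weight, the fitted tree) lands in the run log, and re-running with the same
config and seed reproduces all artifacts byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import baseline as bl
from . import evaluation as ev
from . import matching as mt
from . import rewards as rw
from . import synthetic as syn
from . import tree as tr
from .cohort import Cohort, ColumnMap, derive_horizon_label, read_cohort, validate_cohort
from .exceptions import PipelineError

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    mode: str                               # observational | rct
    seed: int
    out_dir: str
    train: dict = field(default_factory=dict)        # {path, columns} or {preset, n, overrides}
    validation: dict = field(default_factory=dict)
    horizon: float | None = None
    buckets: dict = field(default_factory=lambda: {"strategy": "quantile",
                                                   "m": 6, "min_per_arm": 5})
    distance_covariates: list | None = None
    weight: dict = field(default_factory=lambda: {"grid": None,
                                                  "rule": "max_youden",
                                                  "sens_floor": 0.85})
    tree: dict = field(default_factory=lambda: {"minbucket": 15, "max_depth": 4})
    model: dict | None = None
    ratio_threshold: float = 2.0

    def __post_init__(self):
        if self.mode not in ("observational", "rct"):
            raise ValueError(f"mode must be observational or rct, got {self.mode!r}")
        if self.mode == "rct" and self.weight.get("grid"):
            raise ValueError("rct mode takes no weight grid; "
                             "the confounding correction is not engaged")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        payload = yaml.safe_load(open(path).read())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _load_side(spec: dict, seed: int) -> tuple[Cohort, syn.GroundTruth | None]:
    """A cohort side is either a file + column map or a synthetic preset."""
    if "path" in spec:
        cols = spec["columns"]
        cmap = ColumnMap(**cols) if isinstance(cols, dict) else ColumnMap.from_file(cols)
        return read_cohort(spec["path"], cmap), None
    if "preset" in spec:
        cfg = syn.PRESETS[spec["preset"]](**spec.get("overrides", {}))
        if "n" in spec:
            cfg = dataclasses.replace(cfg, n=spec["n"])
        cohort, gt = syn.simulate(cfg, seed=spec.get("seed", seed))
        return cohort, gt
    raise ValueError("cohort spec needs either 'path' or 'preset'")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the artifact bundle.

    Returns a summary dict (also persisted as ``run_log.json``).  A stage
    failure raises :class:`PipelineError` naming the stage; artifacts written
    before the failure are left in place for diagnosis.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"mode": config.mode, "seed": config.seed, "stages": []}

    def stage(name):
        log["stages"].append(name)

    def fail(name, exc):
        _write_json(out / "run_log.json", log)
        raise PipelineError(name, str(exc)) from exc

    # -- load -------------------------------------------------------------
    try:
        stage("load")
        train, _ = _load_side(config.train, config.seed)
        validation, _ = _load_side(config.validation, config.seed + 1)
        if config.horizon is not None and train.follow_up is not None:
            train = derive_horizon_label(train, config.horizon)
            validation = derive_horizon_label(validation, config.horizon)
        log["train_report"] = validate_cohort(train).to_dict()
        log["validation_report"] = validate_cohort(validation).to_dict()
        train_core = train.subset(train.training_mask)
        log["excluded_from_training"] = int((~train.training_mask).sum())
    except PipelineError:
        raise
    except Exception as exc:
        fail("load", exc)

    # -- baseline risk + strata -------------------------------------------
    try:
        stage("stratify")
        model = bl.fit_baseline_model(train_core, config=config.model,
                                      seed=config.seed)
        w = bl.predict_baseline_risk(model, train_core)
        b = config.buckets
        sc = bl.stratify(train_core, w, strategy=b.get("strategy", "quantile"),
                         m=b.get("m", bl.default_bucket_count(train_core.n,
                                                              config.mode)),
                         min_per_arm=b.get("min_per_arm", 5))
        sc.to_frame().to_csv(out / "stratification.csv", index=False,
                             float_format=_FLOAT_FMT)
        diag = bl.diagnose_balance(sc, ratio_threshold=config.ratio_threshold)
        log["buckets"] = {"m": sc.m, "merges": sc.merge_log,
                          "flagged": diag.flagged_buckets}
    except Exception as exc:
        fail("stratify", exc)

    # -- arm equalization --------------------------------------------------
    validation_untreated = validation.subset(validation.treatment == 0)
    try:
        if config.mode == "observational":
            stage("match")
            mc = mt.match_cohort(sc, distance_covariates=config.distance_covariates)
            mc.pairs.to_csv(out / "match_pairs.csv", index=False,
                            float_format=_FLOAT_FMT)
            log["match"] = {"n_s": mc.n_s,
                            "dropped_buckets": mc.dropped_buckets}
            reward_source = mc
        else:
            stage("oversample")
            if diag.any_flagged:
                sc2 = mt.oversample_strata(sc, seed=config.seed,
                                           ratio_threshold=config.ratio_threshold)
                log["oversample"] = {
                    "remedy": "applied",
                    "added": sc2.cohort.n - sc.cohort.n,
                    "buckets": diag.flagged_buckets,
                }
                sc = sc2
            else:
                log["oversample"] = {"remedy": "no imbalance; no remedy applied"}
            reward_source = sc
    except PipelineError:
        raise
    except Exception as exc:
        fail("match", exc)

    # -- weight / rewards --------------------------------------------------
    try:
        tree_cfg = config.tree
        if config.mode == "observational":
            stage("weight")
            grid = config.weight.get("grid") or rw.default_weight_grid(step=0.25)
            tuning = ev.tune_weight(
                reward_source, validation_untreated, grid,
                rule=config.weight.get("rule", "max_youden"),
                sens_floor=config.weight.get("sens_floor", 0.85),
                config=config.model, seed=config.seed,
                minbucket=tree_cfg.get("minbucket", 15),
                max_depth=tree_cfg.get("max_depth", 4),
            )
            tuning.table[["rho", "sensitivity", "specificity"]].to_csv(
                out / "tuning_table.csv", index=False, float_format=_FLOAT_FMT)
            tuning.table[["rho", "w_hat_t1", "w_hat_t0", "gap"]].to_csv(
                out / "weight_trace.csv", index=False, float_format=_FLOAT_FMT)
            closing = tuning.table.loc[tuning.table["gap"] <= 0, "rho"]
            log["weight"] = {
                "selected_rho": tuning.selected_rho,
                "rule": tuning.rule,
                "rho_min_gap_closed": (float(closing.iloc[0])
                                       if not closing.empty else None),
            }
            rho = tuning.selected_rho
        else:
            rho = 1.0
            log["weight"] = {"selected_rho": 1.0,
                            "note": "rct mode: weight correction not engaged"}
        pair = rw.fit_reward_models(reward_source, rho=rho, config=config.model,
                                    seed=config.seed)
        rm = rw.predict_rewards(pair, reward_source)
        rm.to_frame().assign(rho=rho).to_csv(out / "rewards.csv",
                                             index=False, float_format=_FLOAT_FMT)
        if config.mode == "rct":
            _write_json(out / "weight_trace.json",
                        {"rho": 1.0, "w_hat_t1": rm.w_hat_t1,
                         "w_hat_t0": rm.w_hat_t0,
                         "gap": rm.w_hat_t1 - rm.w_hat_t0})
    except PipelineError:
        raise
    except Exception as exc:
        fail("weight", exc)

    # -- policy tree -------------------------------------------------------
    try:
        stage("tree")
        tree = tr.fit_policy_tree(rm, minbucket=tree_cfg.get("minbucket", 15),
                                  max_depth=tree_cfg.get("max_depth", 4),
                                  seed=config.seed)
        (out / "tree.json").write_text(tree.to_json(indent=2) + "\n")
        (out / "tree.txt").write_text(tree.render() + "\n")
        log["tree"] = {"depth": tree.depth(), "leaves": len(tree.leaves()),
                       "treated_leaves": sum(l.treatment for l in tree.leaves())}
    except Exception as exc:
        fail("tree", exc)

    # -- validation --------------------------------------------------------
    try:
        stage("validate")
        report = ev.evaluate_policy(tree, validation_untreated)
        _write_json(out / "metrics.json", report.to_dict())
        log["metrics"] = {"sensitivity": report.sensitivity,
                          "specificity": report.specificity,
                          "npv": report.npv}
    except Exception as exc:
        fail("validate", exc)

    _write_json(out / "run_log.json", log)
    return log


def _write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
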