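"""Config-driven orchestration: simulate -> score -> QC -> derive ->
validate -> survive, with CSV artifacts shaped like the study's summary
tables and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._containers import ConfigurationError
from . import __version__, lifestyle, qc, signature, survival as surv, validation
from .synthetic import (
    SimConfig, draw_case_cohort, generate_cohort, generate_metabolome,
    generate_outcomes, _STAGE_METABOLOME,
)

log = logging.getLogger("hlmetsig")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run depends on; the seed is mandatory."""

    seed: int
    sim: SimConfig = field(default_factory=lambda: SimConfig())
    families: tuple[str, ...] = ("linear",)
    alpha_linear: float = 0.1
    alpha_logistic: float = 0.6
    R: int = 10
    K: int = 10
    train_alpha: bool = False
    qc_n_trees: int = 50
    qc_max_iter: int = 5
    outcomes: tuple[str, ...] = ("t2d", "cvd")
    extra_covariates: tuple[str, ...] = tuple(surv.MODEL2_EXTRA)
    hl_rules_path: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        for fam in self.families:
            if fam not in ("linear", "logistic"):
                raise ConfigurationError(f"unknown family {fam!r}")
        self.sim = self.sim if isinstance(self.sim, SimConfig) else SimConfig(**self.sim)

    @classmethod
    def from_yaml(cls, path: str, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        if seed is not None:
            raw["seed"] = seed
            sim = sim.replace(seed=seed)
        return cls(sim=sim, **raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _timed(name):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.time()
            out = fn(*a, **kw)
            log.info("stage %-10s %6.1fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage on a synthetic study and write CSV artifacts.

    Artifacts: cohort/HL scores, exclusion log, QC report, signature model
    (per family), a validation table (correlation and AUC at baseline and
    the 1-year re-measurement) and a survival table (three nested Cox
    models x signature form x visit per outcome), plus ``manifest.json``.
    Identical config + seed reproduce identical artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    sim = cfg.sim if cfg.sim.seed == cfg.seed else cfg.sim.replace(seed=cfg.seed)

    try:
        rules = lifestyle.load_component_rules(cfg.hl_rules_path)

        # -- simulate -----------------------------------------------------
        cohort, truth = generate_cohort(sim)
        for cov in cfg.extra_covariates:
            if cov not in cohort.columns:
                raise ConfigurationError(f"undefined covariate {cov!r} in survival config")
        met_base = generate_metabolome(cohort, truth, sim)
        met_year1 = generate_metabolome(cohort, truth, sim, stage=_STAGE_METABOLOME + 50)
        cohort.to_csv(outdir / "cohort.csv")
        met_base.values.to_csv(outdir / "metabolome_baseline.csv")

        # -- lifestyle score and exclusions -------------------------------
        scores = lifestyle.compute_hl_score(cohort, rules)
        kept, excl_log = lifestyle.apply_exclusions(cohort, met_base)
        scores.to_csv(outdir / "hl_scores.csv")
        pd.DataFrame([excl_log]).to_csv(outdir / "exclusion_log.csv", index=False)
        cohort = cohort.loc[kept]
        scores = scores.loc[kept]

        # -- metabolomics QC ----------------------------------------------
        qcd, qc_log = {}, {}
        for label, m in [("baseline", met_base), ("year1", met_year1)]:
            mm, lg = qc.qc_pipeline(
                m, n_trees=cfg.qc_n_trees, max_iter=cfg.qc_max_iter,
                seed=cfg.seed,
            )
            keep = mm.values.index.intersection(kept)
            mm.values = mm.values.loc[keep]
            mm.run_order = mm.run_order[: len(keep)]
            mm.is_reference = np.zeros(len(keep), dtype=bool)
            qcd[label] = mm
            qc_log[label] = lg
        pd.DataFrame(qc_log).to_csv(outdir / "qc_report.csv")
        X_base = qcd["baseline"].participant_values().loc[cohort.index]
        X_year1 = qcd["year1"].participant_values().loc[cohort.index]
        X_year1 = X_year1[X_base.columns]

        # -- derive + validate --------------------------------------------
        y_cont = scores["hl_total"]
        y_cat = (scores["hl_category"] == "high").astype(float)
        models: dict[str, signature.SignatureModel] = {}
        val_rows = []
        for fam in cfg.families:
            y = y_cont if fam == "linear" else y_cat
            alpha = cfg.alpha_linear if fam == "linear" else cfg.alpha_logistic
            if cfg.train_alpha:
                alpha = signature.select_alpha(
                    X_base.to_numpy(), y.to_numpy(), family=fam, seed=cfg.seed,
                )
            model = signature.derive_signature(
                X_base, y.to_numpy(), family=fam, alpha=alpha,
                R=cfg.R, K=cfg.K, seed=cfg.seed,
            )
            models[fam] = model
            model.to_csv(outdir / f"signature_{fam}.csv",
                         outdir / f"signature_{fam}_header.json")
            for label, Xv in [("baseline", X_base), ("year1", X_year1)]:
                pred = signature.score_signature(model, Xv)
                if fam == "linear":
                    rep = validation.pearson_with_ci(pred, y_cont, sample_label=label)
                else:
                    rep = validation.roc_auc_with_ci(pred, y_cat, seed=cfg.seed,
                                                     sample_label=label)
                pos = int((model.coef_avg > 0).sum())
                neg = int((model.coef_avg < 0).sum())
                val_rows.append({
                    "assessment": "HL score" if fam == "linear" else "HL categories",
                    "visit": label, "metric": rep.metric,
                    "estimate": round(rep.estimate, 4),
                    "ci_low": round(rep.ci_low, 4), "ci_high": round(rep.ci_high, 4),
                    "n": rep.n, "total_metabolites": model.signature_size,
                    "positive_coefficients": pos, "negative_coefficients": neg,
                })
        pd.DataFrame(val_rows).to_csv(outdir / "validation_report.csv", index=False)

        # -- survival ------------------------------------------------------
        fam0 = cfg.families[0]
        model0 = models[fam0]
        sig_cont = pd.Series(signature.score_signature(model0, X_base),
                             index=cohort.index)
        if fam0 == "linear":
            sig_cat = pd.Series(lifestyle.classify_hl(sig_cont), index=cohort.index)
        else:
            sig_cat = pd.Series(np.where(sig_cont > 0, "high", "low"), index=cohort.index)
        surv_rows, inter_rows = [], []
        for i, outcome in enumerate(cfg.outcomes):
            outcomes_tab = generate_outcomes(cohort, _subset_truth(truth, cohort, sim), sim,
                                             stage=100 + 10 * i)
            design = draw_case_cohort(outcomes_tab, sim.subcohort_fraction,
                                      seed=cfg.seed + i)
            for visit in ("baseline", "year1"):
                tab, _ = surv.run_models(
                    design, cohort, sig_cont, sig_cat,
                    scores["hl_total"], scores["hl_category"],
                    outcome=outcome, visit=visit,
                )
                surv_rows.append(tab)
            it = surv.interaction_test(design, cohort, sig_cat)
            it.insert(0, "outcome", outcome)
            inter_rows.append(it)
        pd.concat(surv_rows, ignore_index=True).to_csv(
            outdir / "survival_report.csv", index=False)
        pd.concat(inter_rows, ignore_index=True).to_csv(
            outdir / "interaction_report.csv", index=False)

        # -- manifest ------------------------------------------------------
        import sklearn, lifelines, scipy
        manifest = {
            "config": asdict(cfg), "config_hash": cfg.digest(), "seed": cfg.seed,
            "versions": {
                "hlmetsig": __version__, "numpy": np.__version__,
                "pandas": pd.__version__, "scikit-learn": sklearn.__version__,
                "lifelines": lifelines.__version__, "scipy": scipy.__version__,
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    return outdir


def _subset_truth(truth, cohort, sim):
    from .synthetic import GroundTruth
    sig = (cohort["hl_true"].to_numpy() - sim.hl_mean()) / sim.hl_sd()
    return GroundTruth(
        true_loadings=truth.true_loadings,
        true_signature_values=sig,
        true_logHR=truth.true_logHR,
        signal_metabolites=truth.signal_metabolites,
    )


def make_report(artifact_dir: str | Path) -> str:
    """Render a human-readable summary of a completed run."""
    d = Path(artifact_dir)
    for required in ("validation_report.csv", "survival_report.csv", "manifest.json"):
        if not (d / required).exists():
            raise FileNotFoundError(f"missing artifact: {required}")
    lines = ["= Healthy-lifestyle metabolite signature: run report ="]
    manifest = json.loads((d / "manifest.json").read_text())
    lines.append(f"seed {manifest['seed']}  config {manifest['config_hash']}")

    lines.append("\n-- Signature performance (predicted vs self-reported HL) --")
    val = pd.read_csv(d / "validation_report.csv")
    lines.append(val.to_string(index=False))

    for fam in ("linear", "logistic"):
        path = d / f"signature_{fam}.csv"
        if not path.exists():
            continue
        sig = pd.read_csv(path)
        header = json.loads((d / f"signature_{fam}_header.json").read_text())
        R = header["R"]
        sel = sig[sig["selection_count"] == R].copy()
        sel = sel.reindex(sel["coef_avg"].abs().sort_values(ascending=False).index)
        lines.append(f"\n-- Selected metabolites ({fam} family, "
                     f"selected {R}/{R} times) --")
        if sel.empty:
            lines.append("no metabolites selected")
        else:
            neg = sel[sel["coef_avg"] < 0]
            pos = sel[sel["coef_avg"] > 0]
            lines.append(f"negative coefficients (n={len(neg)}):")
            lines.append(neg.to_string(index=False) if len(neg) else "  none")
            lines.append(f"positive coefficients (n={len(pos)}):")
            lines.append(pos.to_string(index=False) if len(pos) else "  none")

    lines.append("\n-- Case-cohort hazard ratios (Barlow-weighted Cox) --")
    tab3 = pd.read_csv(d / "survival_report.csv")
    lines.append(tab3.to_string(index=False))
    if (d / "interaction_report.csv").exists():
        lines.append("\n-- Arm x signature interaction (pseudo-LRT) --")
        lines.append(pd.read_csv(d / "interaction_report.csv").to_string(index=False))
    report = "\n".join(lines) + "\n"
    (d / "report.txt").write_text(report)
    return report
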