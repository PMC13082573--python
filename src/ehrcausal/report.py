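"""Run orchestration, attrition accounting and report rendering."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

import ehrcausal
from ehrcausal.balance import standardized_mean_differences
from ehrcausal.cohort import build_cohort, write_cohort_csv
from ehrcausal.covariates import CovariateSpec, build_covariate_matrix
from ehrcausal.estimation import AnalysisConfig, estimate_effects
from ehrcausal.events import DrugClassMap, read_events_csv
from ehrcausal.nuisance import AdaptiveLassoSpec, fit_propensity


def arm_share_percent(arm_count: int, total: int, ndigits: int = 1) -> float:
    """Share of the cohort in one arm, as a percentage rounded to ndigits."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= arm_count <= total:
        raise ValueError("arm count out of range")
    return round(100.0 * arm_count / total, ndigits)


@dataclass
class RunManifest:
    """Provenance record: every run is reproducible from this alone."""

    config: dict
    seed: int
    software_version: str = ehrcausal.__version__
    input_digests: dict = field(default_factory=dict)
    n_patients_in: int = 0
    n_eligible: int = 0
    exclusion_counts: dict = field(default_factory=dict)
    arm_sizes: dict = field(default_factory=dict)
    n_switchers: int = 0

    def validate_attrition(self) -> None:
        total = self.n_eligible + sum(self.exclusion_counts.values())
        if total != self.n_patients_in:
            raise ValueError(
                f"attrition mismatch: {self.n_patients_in} in, "
                f"{self.n_eligible} eligible + {sum(self.exclusion_counts.values())} excluded"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_analysis_yaml(path) -> tuple[AnalysisConfig, AdaptiveLassoSpec, list[str]]:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    styles = d.pop("styles", ["intent-to-treat", "per-protocol"])
    lasso = d.pop("lasso", {})
    if "comparison" in d:
        d["comparison"] = tuple(d["comparison"])
    cfg = AnalysisConfig(**d)
    spec = AdaptiveLassoSpec(**lasso)
    return cfg, spec, styles


def render_markdown(results: dict, manifest: RunManifest) -> str:
    lines = ["# Comparative-effectiveness analysis report", ""]
    lines.append(f"Software version {manifest.software_version}, seed {manifest.seed}.")
    lines.append("")
    lines.append("## Attrition")
    lines.append("")
    lines.append(f"- patients in event stream: {manifest.n_patients_in}")
    for reason, cnt in manifest.exclusion_counts.items():
        lines.append(f"- excluded ({reason}): {cnt}")
    lines.append(f"- eligible cohort: {manifest.n_eligible}")
    for arm, cnt in manifest.arm_sizes.items():
        share = arm_share_percent(cnt, manifest.n_eligible)
        lines.append(f"- arm {arm}: {cnt} ({share}%)")
    lines.append(f"- post-index switchers: {manifest.n_switchers}")
    lines.append("")
    lines.append("## Effect estimates")
    lines.append("")
    lines.append("| style | estimand | point | 95% CI | p | n | B |")
    lines.append("|---|---|---|---|---|---|---|")
    for style, ests in results.items():
        if style == "nuisances":
            continue
        for name, e in ests.items():
            lines.append(
                f"| {style} | {name} | {e['point']:.4f} | "
                f"({e['ci_low']:.4f}, {e['ci_high']:.4f}) | {e['p_value']:.3f} "
                f"| {e['n']} | {e['n_bootstrap']} |"
            )
    lines.append("")
    return "\n".join(lines)


def run_analysis(
    events_path,
    classes_path,
    out_dir,
    covariates_path=None,
    analysis_path=None,
    comparison: tuple[str, str] | None = None,
    seed: int | None = None,
    tau_days: int | None = None,
    feature_dictionary: list[dict] | None = None,
) -> RunManifest:
    """Execute the full pipeline: cohort, covariates, estimation, report.

    Writes ``cohort.csv``, ``balance.csv``, ``results.json``,
    ``manifest.json`` and ``report.md`` under ``out_dir``.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    events = read_events_csv(events_path)
    classes = DrugClassMap.from_yaml(classes_path)
    if analysis_path is not None:
        config, spec, styles = _load_analysis_yaml(analysis_path)
    else:
        config, spec, styles = AnalysisConfig(), AdaptiveLassoSpec(), ["intent-to-treat", "per-protocol"]
    if comparison is not None:
        config.comparison = comparison
    if seed is not None:
        config.seed = seed
        spec.seed = seed
    if tau_days is not None:
        config.tau_days = tau_days

    cohort, exclusions = build_cohort(events, classes, config.comparison, config.tau_days)
    write_cohort_csv(cohort, exclusions, os.path.join(out_dir, "cohort.csv"))
    if cohort.empty:
        raise RuntimeError("cohort stage produced no eligible patients")

    if covariates_path is not None:
        cov_spec = CovariateSpec.from_yaml(covariates_path)
    else:
        cov_spec = CovariateSpec(feature_dictionary=feature_dictionary or [])
    matrix = build_covariate_matrix(events, cohort, cov_spec, classes=classes)
    matrix.to_csv(os.path.join(out_dir, "covariates.csv"),
                  os.path.join(out_dir, "covariates_meta.json"))

    X = matrix.X
    A = cohort["arm"].to_numpy()
    T = cohort["follow_days"].to_numpy()
    delta = cohort["event"].to_numpy()
    switched = cohort["switched"].to_numpy()

    from ehrcausal.nuisance import fit_nuisances

    results: dict[str, dict] = {}
    for style in styles:
        cfg = AnalysisConfig(**{**asdict(config), "style": style,
                                "comparison": config.comparison})
        ests = estimate_effects(X, A, T, delta, switched, cfg, spec)
        results[style] = {k: v.to_dict() for k, v in ests.items()}

    # audit record of the full-data nuisance fits (deterministic refit)
    bundle = fit_nuisances(X, A, T, delta, config.tau_days, spec)
    bundle.to_json(os.path.join(out_dir, "nuisances.json"))
    results["nuisances"] = {
        "n_covariates": int(X.shape[1]),
        "propensity_selected": int(np.sum(bundle.propensity.fit.coef != 0)),
        "outcome_selected": int(np.sum(bundle.outcome_logistic.fit.coef != 0)),
        "hazards_selected": int(np.sum(bundle.additive_hazards.beta != 0)),
        "lambdas": bundle.lambdas,
    }
    with open(os.path.join(out_dir, "results.json"), "w") as fh:
        json.dump(results, fh, indent=2)

    prop = fit_propensity(X, A, spec)
    balance = standardized_mean_differences(X, A, prop.predict(X), columns=matrix.columns)
    balance.to_csv(os.path.join(out_dir, "balance.csv"), index=False)

    manifest = RunManifest(
        config={"analysis": asdict(config), "lasso": asdict(spec), "styles": styles,
                "covariates": {"prevalence_threshold": cov_spec.prevalence_threshold,
                               "n_features": len(cov_spec.feature_dictionary)}},
        seed=config.seed,
        input_digests={"events": _digest(events_path), "classes": _digest(classes_path)},
        n_patients_in=int(events["patient_id"].nunique()),
        n_eligible=int(len(cohort)),
        exclusion_counts={k: int(v) for k, v in
                          exclusions["exclusion_reason"].value_counts().items()},
        arm_sizes={str(k): int(v) for k, v in cohort["arm"].value_counts().sort_index().items()},
        n_switchers=int(cohort["switched"].sum()),
    )
    manifest.validate_attrition()
    manifest.to_json(os.path.join(out_dir, "manifest.json"))
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write(render_markdown(results, manifest))
    return manifest
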