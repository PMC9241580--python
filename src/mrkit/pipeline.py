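"""Config-driven orchestration: one exposure, many outcomes, full battery.

For each outcome the pipeline runs selection -> harmonization -> estimation
(IVW with multiplicative random effects as the primary model; weighted
median and MR-Egger as complementary estimators when instrument count
permits) -> diagnostics (Cochran's Q, Egger intercept, MR-PRESSO,
leave-one-out), then pools designated outcome groups by fixed-effect
meta-analysis and classifies primary p-values against the Bonferroni
threshold.  Everything is written as TSV plus a JSON manifest echoing the
config and seeds, so a run is reproducible byte for byte.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .diagnostics import leave_one_out, pleiotropy_report, write_diagnostics_table
from .estimators import MREstimate, egger, ivw, weighted_median
from .harmonize import harmonize, write_harmonization_report
from .instruments import (
    SelectionConfig,
    select_instruments,
    strength_report,
    write_audit_trail,
)
from .meta import classify_pvalue, fixed_effect_meta, write_meta_table
from .sumstats import (
    read_exclusion_list,
    read_ld_table,
    read_proxy_map,
    read_sumstats,
    write_results_table,
)

log = logging.getLogger(__name__)


@dataclass
class DatasetSpec:
    name: str
    path: str
    column_map: dict[str, str] | None = None
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass
class RunConfig:
    exposure: DatasetSpec
    outcomes: list[DatasetSpec]
    out_dir: str
    seed: int
    ld_path: str | None = None
    exclusions_path: str | None = None
    proxies_path: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    meta_groups: dict[str, list[str]] = field(default_factory=dict)
    n_boot: int = 1000
    n_sim: int = 1000
    alpha: float = 0.05
    n_tests: int | None = None
    palindrome_eaf_limit: float = 0.42
    proxy_r2_min: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        sel = raw.get("selection", {})
        return cls(
            exposure=DatasetSpec(**raw["exposure"]),
            outcomes=[DatasetSpec(**o) for o in raw["outcomes"]],
            out_dir=raw["out_dir"],
            seed=int(raw["seed"]),
            ld_path=raw.get("ld_path"),
            exclusions_path=raw.get("exclusions_path"),
            proxies_path=raw.get("proxies_path"),
            selection=SelectionConfig(**sel) if not isinstance(sel, SelectionConfig) else sel,
            meta_groups={k: list(v) for k, v in raw.get("meta_groups", {}).items()},
            n_boot=int(raw.get("n_boot", 1000)),
            n_sim=int(raw.get("n_sim", 1000)),
            alpha=float(raw.get("alpha", 0.05)),
            n_tests=raw.get("n_tests"),
            palindrome_eaf_limit=float(raw.get("palindrome_eaf_limit", 0.42)),
            proxy_r2_min=float(raw.get("proxy_r2_min", 0.8)),
        )


def validate_config(path: str | Path) -> list[str]:
    """Static checks on a config file: missing files, duplicates, bad keys.

    Returns a list of human-readable issues; empty means valid.
    """
    issues: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except Exception as exc:  # unparseable is fatal-by-report
        return [f"cannot parse config: {exc}"]
    if not isinstance(raw, dict):
        return ["config root must be a mapping"]

    known = {
        "exposure", "outcomes", "out_dir", "seed", "ld_path", "exclusions_path",
        "proxies_path", "selection", "meta_groups", "n_boot", "n_sim", "alpha",
        "n_tests", "palindrome_eaf_limit", "proxy_r2_min",
    }
    for key in raw:
        if key not in known:
            issues.append(f"unused key: {key}")
    for key in ("exposure", "outcomes", "out_dir", "seed"):
        if key not in raw:
            issues.append(f"missing required key: {key}")
    if issues and ("exposure" not in raw or "outcomes" not in raw):
        return issues

    paths = [("exposure", raw["exposure"].get("path"))]
    names = []
    for o in raw["outcomes"]:
        names.append(o.get("name"))
        paths.append((o.get("name", "?"), o.get("path")))
    for key in ("ld_path", "exclusions_path", "proxies_path"):
        if raw.get(key):
            paths.append((key, raw[key]))
    for label, p in paths:
        if p is None:
            issues.append(f"{label}: no path given")
        elif not Path(p).exists():
            issues.append(f"{label}: file not found: {p}")
    if len(names) != len(set(names)):
        issues.append("duplicate outcome names")
    for group, members in raw.get("meta_groups", {}).items():
        for m in members:
            if m not in names:
                issues.append(f"meta_group {group!r} refers to unknown outcome {m!r}")
    try:
        sel = raw.get("selection", {})
        if sel:
            SelectionConfig(**sel)
    except (TypeError, ValueError) as exc:
        issues.append(f"selection config invalid: {exc}")
    return issues


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; writes TSVs + manifest, returns the bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exposure = read_sumstats(
        config.exposure.path,
        column_map=config.exposure.column_map,
        trait_name=config.exposure.name,
        n_cases=config.exposure.n_cases,
        n_controls=config.exposure.n_controls,
    )
    ld = read_ld_table(config.ld_path) if config.ld_path else None
    selection = config.selection
    if config.exclusions_path:
        exclusions = read_exclusion_list(config.exclusions_path)
        selection = SelectionConfig(
            p_threshold=selection.p_threshold,
            ld_r2_max=selection.ld_r2_max,
            ld_window_kb=selection.ld_window_kb,
            maf_min=selection.maf_min,
            exclusion_ids=exclusions,
        )
    proxies = read_proxy_map(config.proxies_path) if config.proxies_path else None

    sel_result = select_instruments(exposure, ld, selection)
    write_audit_trail(sel_result.audit, out_dir / "audit.tsv")
    log.info("selected %d instruments", len(sel_result.selected))

    n_exp = exposure.n_total or next(iter(exposure)).n
    strength = None
    if n_exp is not None:
        strength = strength_report(exposure, sel_result.selected, n_exp)
        log.info("total R2 %.4f, F %.1f", strength.total_r2, strength.f_stat)

    estimates: list[tuple[str, MREstimate]] = []
    diagnostics: list[tuple[str, Any]] = []
    primary: dict[str, MREstimate] = {}
    for spec in config.outcomes:
        outcome = read_sumstats(
            spec.path,
            column_map=spec.column_map,
            trait_name=spec.name,
            n_cases=spec.n_cases,
            n_controls=spec.n_controls,
        )
        instrs = harmonize(
            exposure,
            outcome,
            sel_result.selected,
            proxies=proxies,
            palindrome_eaf_limit=config.palindrome_eaf_limit,
            proxy_r2_min=config.proxy_r2_min,
        )
        write_harmonization_report(instrs, out_dir / f"harmonization_{spec.name}.tsv")
        usable = [i for i in instrs if i.usable]
        k = len(usable)
        log.info("%s: %d of %d instruments usable", spec.name, k, len(instrs))
        if k == 0:
            raise RuntimeError(f"outcome {spec.name}: no usable instruments after harmonization")

        primary_est = ivw(usable, model="mre")  # falls back to Wald at k = 1
        primary[spec.name] = primary_est
        estimates.append((spec.name, primary_est))
        if k >= 3:
            estimates.append((spec.name, weighted_median(usable, config.n_boot, seed=config.seed)))
            e_int, e_slope = egger(usable)
            estimates.append((spec.name, e_slope))
            estimates.append((spec.name, e_int))
            diagnostics.append(
                (spec.name, pleiotropy_report(usable, n_sim=config.n_sim, seed=config.seed))
            )
            loo = leave_one_out(usable)
            _write_loo(loo, out_dir / f"leave_one_out_{spec.name}.tsv")
        else:
            log.warning("%s: k=%d, complementary estimators and diagnostics unavailable", spec.name, k)
        _write_scatter(usable, out_dir / f"scatter_{spec.name}.tsv")

    write_results_table(estimates, out_dir / "estimates.tsv")
    if diagnostics:
        write_diagnostics_table(diagnostics, out_dir / "diagnostics.tsv")

    meta_results = {}
    for group, members in config.meta_groups.items():
        studies = [(m, primary[m].beta, primary[m].se) for m in members]
        meta_results[group] = fixed_effect_meta(studies)
        write_meta_table(meta_results[group], out_dir / f"meta_{group}.tsv")

    n_tests = config.n_tests or len(config.outcomes)
    classification = {
        name: classify_pvalue(est.pval, config.alpha, n_tests)
        for name, est in primary.items()
    }
    _write_classification(primary, classification, out_dir / "classification.tsv")

    manifest = {
        "mrkit_version": __version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "n_sim": config.n_sim,
        "n_instruments": len(sel_result.selected),
        "instruments": sel_result.selected,
        "total_r2": strength.total_r2 if strength else None,
        "f_stat": strength.f_stat if strength else None,
        "n_tests": n_tests,
        "alpha": config.alpha,
        "classification": classification,
        "config": _config_echo(config),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "selection": sel_result,
        "strength": strength,
        "estimates": estimates,
        "diagnostics": diagnostics,
        "meta": meta_results,
        "classification": classification,
        "manifest": manifest,
    }


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    echo["selection"]["exclusion_ids"] = dict(echo["selection"]["exclusion_ids"])
    return echo


def _write_scatter(instrs: Sequence, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "variant_id": i.variant_id,
                "beta_exp": i.beta_exp,
                "se_exp": i.se_exp,
                "beta_out": i.beta_out,
                "se_out": i.se_out,
            }
            for i in instrs
        ]
    ).to_csv(path, sep="\t", index=False)


def _write_loo(entries: Sequence, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "excluded_id": e.excluded_id,
                "beta": e.estimate.beta,
                "se": e.estimate.se,
                "ci_low": e.estimate.ci_low,
                "ci_high": e.estimate.ci_high,
                "pval": e.estimate.pval,
            }
            for e in entries
        ]
    ).to_csv(path, sep="\t", index=False)


def _write_classification(
    primary: Mapping[str, MREstimate], classification: Mapping[str, str], path: Path
) -> None:
    import math

    import pandas as pd

    pd.DataFrame(
        [
            {
                "outcome": name,
                "or": math.exp(est.beta),
                "pval": est.pval,
                "class": classification[name],
            }
            for name, est in primary.items()
        ]
    ).to_csv(path, sep="\t", index=False)
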