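"""Study orchestration: instruments x biomarkers x sources x outcomes.

One YAML configuration describes the full design: drug targets (loci and
selection thresholds), exposure biomarkers with primary and replication
summary-statistics sources, outcome traits, LD matrices, and the reporting
parameters (Bonferroni family size, colocalization gate). ``run_study``
builds instruments per target and source, harmonizes them against every
outcome, applies the primary estimator (Wald ratio for one SNP, IVW
otherwise) plus the sensitivity suite for 3+ SNP instruments,
heterogeneity and Steiger diagnostics, gated colocalization, and
multiple-testing / replication-consistency flags, emitting a tidy report.

Effect direction: instruments are oriented so effect alleles raise the
biomarker; agonism *lowers* it, so when ``direction`` is "lowering"
(default) reported estimates are sign-flipped to read per 1 SD biomarker
decrease, and case-control outcomes additionally carry odds-ratio columns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import mr as mr_mod
from .exceptions import ConfigurationError, DomainError, TargetMRError
from .instruments import (InstrumentSet, TargetSpec, orient_to_agonism,
                          select_cis_instruments)
from .sumstats import (CANONICAL_COLUMNS, LDMatrix, LocusDefinition,
                       SummaryTable, TraitMeta, harmonize, read_sumstats,
                       slice_locus)

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "target", "biomarker", "source", "outcome", "method", "n_snp",
    "beta", "se", "ci_low", "ci_high", "pval",
    "or", "or_low", "or_high",
    "q_stat", "q_pval", "steiger_correct", "steiger_pval",
    "coloc_pp_h4", "coloc_cond_h4",
    "cascade_level", "min_f", "set_r2",
    "bonferroni_pass", "replication_consistent", "error",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected significance threshold alpha/n_tests."""
    if n_tests < 1:
        raise DomainError("n_tests must be >= 1")
    return alpha / n_tests


def or_percent_change(or_value: float) -> float:
    """Signed percent change in odds for an odds ratio: (OR - 1) * 100."""
    if or_value <= 0:
        raise DomainError("odds ratio must be positive")
    return (or_value - 1.0) * 100.0


def format_or_percent(or_value: float) -> str:
    """Human-readable odds interpretation, e.g. OR 0.62 -> '38% lower odds'."""
    pct = or_percent_change(or_value)
    if pct == 0:
        return "0% change in odds"
    word = "lower" if pct < 0 else "higher"
    return f"{abs(pct):g}% {word} odds"


@dataclass
class OutcomeSpec:
    label: str
    path: str
    trait_type: str = "quantitative"
    s: float | None = None


@dataclass
class BiomarkerSource:
    name: str
    sources: dict[str, str]          # source label -> sumstats path
    trait_type: str = "quantitative"
    sd: float | None = 1.0


@dataclass
class StudyConfig:
    """Full study design, loadable from one YAML file."""

    targets: list[TargetSpec]
    biomarkers: list[BiomarkerSource]
    outcomes: list[OutcomeSpec]
    ld: dict[str, str]               # gene -> LD TSV path
    alpha: float = 0.05
    n_tests: int = 1
    coloc_gate_p: float = 0.05
    direction: str = "lowering"
    seed: int = 0
    base_dir: Path = field(default_factory=Path)
    coloc_force: bool = False
    boot_reps: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        targets = [
            TargetSpec(t["name"],
                       [LocusDefinition(**loc) for loc in t["loci"]],
                       p_cascade=tuple(t.get("p_cascade", (5e-8, 5e-6))),
                       ld_r2_max=t.get("ld_r2_max", 0.1))
            for t in raw["targets"]]
        biomarkers = [BiomarkerSource(b["name"], dict(b["sources"]),
                                      b.get("trait_type", "quantitative"),
                                      b.get("sd", 1.0))
                      for b in raw["biomarkers"]]
        outcomes = [OutcomeSpec(o["label"], o["path"],
                                o.get("trait_type", "quantitative"), o.get("s"))
                    for o in raw["outcomes"]]
        return cls(targets, biomarkers, outcomes, dict(raw.get("ld", {})),
                   alpha=raw.get("alpha", 0.05), n_tests=raw.get("n_tests", 1),
                   coloc_gate_p=raw.get("coloc_gate_p", 0.05),
                   direction=raw.get("direction", "lowering"),
                   seed=raw.get("seed", 0), base_dir=path.parent,
                   coloc_force=raw.get("coloc_force", False),
                   boot_reps=raw.get("boot_reps", 1000))

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


@dataclass
class StudyReport:
    """Tidy per-method results plus per-locus colocalization and run metadata."""

    report: pd.DataFrame
    coloc: pd.DataFrame
    metadata: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(outdir / "report.tsv", sep="\t", index=False,
                           float_format="%.8g")
        self.coloc.to_csv(outdir / "coloc.tsv", sep="\t", index=False,
                          float_format="%.8g")
        (outdir / "run_metadata.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True))


def _sign(direction: str) -> float:
    return -1.0 if direction == "lowering" else 1.0


def _result_row(base: dict, res: mr_mod.MRResult, sign: float,
                binary: bool) -> dict:
    beta = sign * res.beta
    lo, hi = sorted((sign * res.ci_low, sign * res.ci_high))
    row = dict(base, method=res.method, n_snp=res.n_snp, beta=beta, se=res.se,
               ci_low=lo, ci_high=hi, pval=res.pval)
    if binary and res.method != "egger_intercept":
        row.update({"or": np.exp(beta), "or_low": np.exp(lo),
                    "or_high": np.exp(hi)})
    return row


def _instrument_table(iset: InstrumentSet, name: str) -> SummaryTable:
    return SummaryTable(iset.df[CANONICAL_COLUMNS].reset_index(drop=True),
                        TraitMeta(name, "quantitative", sd=1.0))


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the configured study end to end.

    Stage failures for one target/biomarker/source/outcome combination are
    recorded in the report row (``error`` column), never fatal to the run.
    Determinism: all stochastic steps (bootstrap SEs) are seeded from
    ``config.seed``, so re-running an identical configuration reproduces the
    report byte-for-byte.
    """
    sign = _sign(config.direction)
    ld_by_gene = {g: LDMatrix.from_tsv(config.resolve(p))
                  for g, p in config.ld.items()}
    exposure_tables = {
        (b.name, src): read_sumstats(config.resolve(path),
                                     trait=TraitMeta(b.name, b.trait_type, sd=b.sd))
        for b in config.biomarkers for src, path in b.sources.items()}
    outcome_tables = {
        o.label: read_sumstats(config.resolve(o.path),
                               trait=TraitMeta(o.label, o.trait_type, s=o.s))
        for o in config.outcomes}

    rows: list[dict] = []
    coloc_rows: list[dict] = []
    meta: dict = {"seed": config.seed, "direction": config.direction,
                  "bonferroni_threshold": bonferroni_threshold(config.alpha,
                                                               config.n_tests),
                  "instruments": {}, "errors": []}

    for target in config.targets:
        for biomarker in config.biomarkers:
            for source in sorted(biomarker.sources):
                key = f"{target.name}|{biomarker.name}|{source}"
                exposure = exposure_tables[(biomarker.name, source)]
                try:
                    spec = dataclasses.replace(target, exposure=biomarker.name)
                    iset = orient_to_agonism(
                        select_cis_instruments(exposure, spec, ld_by_gene),
                        config.direction)
                except TargetMRError as exc:
                    meta["errors"].append({"stage": "instruments", "key": key,
                                           "error": str(exc)})
                    for outcome in config.outcomes:
                        rows.append({"target": target.name,
                                     "biomarker": biomarker.name,
                                     "source": source, "outcome": outcome.label,
                                     "method": "primary", "error": str(exc),
                                     "is_primary": True})
                    continue
                meta["instruments"][key] = {
                    "n_snp": len(iset),
                    "cascade_level": {g: float(v)
                                      for g, v in iset.cascade_used.items()},
                    "min_f": iset.min_f, "set_r2": iset.set_r2,
                    "snp_ids": iset.snp_ids,
                }
                inst_table = _instrument_table(iset, biomarker.name)
                for outcome in config.outcomes:
                    base = {"target": target.name, "biomarker": biomarker.name,
                            "source": source, "outcome": outcome.label,
                            "cascade_level": "|".join(
                                f"{g}:{v:g}" for g, v in
                                sorted(iset.cascade_used.items())),
                            "min_f": iset.min_f, "set_r2": iset.set_r2}
                    binary = outcome.trait_type == "case-control"
                    try:
                        ht = harmonize(inst_table, outcome_tables[outcome.label])
                        primary = mr_mod.primary_estimate(ht)
                        prow = _result_row(base, primary, sign, binary)
                        prow["is_primary"] = True
                        if len(ht) >= 2:
                            q = mr_mod.cochran_q(ht)
                            prow.update(q_stat=q.Q, q_pval=q.pval)
                        if not binary:
                            st = mr_mod.steiger(ht)
                            prow.update(steiger_correct=st.direction_correct,
                                        steiger_pval=st.pval)
                        else:
                            # liability-scale variance explained not computed
                            prow.update(steiger_correct="not_computed")
                        rows.append(prow)
                        if len(ht) >= 3:
                            for res in mr_mod.sensitivity_suite(
                                    ht, seed=config.seed,
                                    boot_reps=config.boot_reps):
                                rows.append(_result_row(base, res, sign, binary))
                        if primary.pval < config.coloc_gate_p or config.coloc_force:
                            cres = _run_coloc(target, biomarker, source, outcome,
                                              exposure,
                                              outcome_tables[outcome.label])
                            coloc_rows.extend(cres)
                            if cres:
                                prow["coloc_pp_h4"] = max(c["pp_h4"] for c in cres)
                                prow["coloc_cond_h4"] = max(
                                    c["conditional_h4"] for c in cres)
                    except TargetMRError as exc:
                        meta["errors"].append({"stage": "mr", "key": key,
                                               "outcome": outcome.label,
                                               "error": str(exc)})
                        rows.append(dict(base, method="primary",
                                         error=str(exc), is_primary=True))

    report = pd.DataFrame(rows)
    for col in REPORT_COLUMNS + ["is_primary"]:
        if col not in report.columns:
            report[col] = np.nan
    bonf = bonferroni_threshold(config.alpha, config.n_tests)
    report["bonferroni_pass"] = report["pval"] < bonf
    _flag_replication(report, config)
    report = report[REPORT_COLUMNS + ["is_primary"]]
    coloc_df = pd.DataFrame(
        coloc_rows, columns=["target", "biomarker", "source", "outcome",
                             "locus", "n_snp", "pp_h0", "pp_h1", "pp_h2",
                             "pp_h3", "pp_h4", "conditional_h4"])
    return StudyReport(report, coloc_df, meta)


def _run_coloc(target, biomarker, source, outcome, exposure_table,
               outcome_table) -> list[dict]:
    """Per-locus colocalization between the full exposure window and the
    outcome, on their shared SNPs (ABFs use z², so orientation is moot)."""
    spec_x = coloc_mod.TraitSpec("quantitative", sdY=1.0)
    if outcome.trait_type == "case-control":
        spec_y = coloc_mod.TraitSpec("case-control", s=outcome.s)
    else:
        spec_y = coloc_mod.TraitSpec("quantitative", sdY=1.0)
    out = []
    for locus in target.loci:
        window_x = slice_locus(exposure_table, locus)
        window_y = slice_locus(outcome_table, locus)
        if not len(window_x) or not len(window_y):
            continue
        res = coloc_mod.colocalize(window_x, window_y, spec_x, spec_y)
        out.append({"target": target.name, "biomarker": biomarker.name,
                    "source": source, "outcome": outcome.label,
                    "locus": locus.gene, "n_snp": res.n_snp,
                    "pp_h0": res.pp_h0, "pp_h1": res.pp_h1,
                    "pp_h2": res.pp_h2, "pp_h3": res.pp_h3,
                    "pp_h4": res.pp_h4, "conditional_h4": res.conditional_h4})
    return out


def _flag_replication(report: pd.DataFrame, config: StudyConfig) -> None:
    """Both sources P < alpha with sign-concordant estimates, per
    (target, biomarker, outcome, method); sources are never pooled."""
    report["replication_consistent"] = False
    if report.empty:
        return
    grp = report.groupby(["target", "biomarker", "outcome", "method"],
                         dropna=False)
    for _, idx in grp.groups.items():
        sub = report.loc[idx]
        if sub["source"].nunique() < 2:
            continue
        ok = ((sub["pval"] < config.alpha).all()
              and (np.sign(sub["beta"]).nunique() == 1))
        report.loc[idx, "replication_consistent"] = bool(ok)
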