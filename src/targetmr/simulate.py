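"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the inputs of a drug-target MR study: per-SNP
marginal association estimates for an exposure biomarker and an outcome,
measured in two non-overlapping cohorts, at a cis locus with block (or
AR(1)) LD structure. For a unit-variance trait and allele frequency f the
sampling standard error of a marginal per-allele estimate at sample size n
is 1/sqrt(2 n f (1-f)); binary outcomes are simulated on the log-odds scale
with SE 1/sqrt(2 n s (1-s) f (1-f)) (s the case proportion) — an
approximation adequate for method testing. Marginal true effects are
R @ beta_causal (R the LD correlation matrix); outcome true effects are
theta * marginal exposure effects plus per-SNP pleiotropy alpha_j on a
configurable fraction of invalid instruments (balanced or directional).
Estimates for the two traits are drawn independently (two-sample design)
from multivariate normals with correlation R.

Everything is driven by one seeded generator per call, so identical
configurations reproduce bit-identical tables. Setting a noise scale to 0
yields the noise-free diagnostic mode in which estimators must recover the
true causal effect exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .sumstats import CANONICAL_COLUMNS, LDMatrix, LocusDefinition, SummaryTable, TraitMeta

log = logging.getLogger(__name__)

#: non-palindromic allele pairs the generator draws from
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                 ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T")]


@dataclass
class SimConfig:
    """Conditions of one simulated locus.

    Defaults emulate a well-powered European-ancestry biomarker GWAS
    (exposure n = 350k, roughly a UK Biobank biomarker) against an outcome
    GWAS of 150k, with 60 SNPs in 5-SNP LD blocks (within-block correlation
    0.5), 5 causal SNPs whose per-allele effects (0.01-0.05 SD) put
    instrument F-statistics in the tens-to-hundreds range, and no invalid
    instruments unless requested.
    """

    n_snp: int = 60
    eaf_range: tuple[float, float] = (0.05, 0.95)
    ld_model: str = "block"            # "block" | "ar1"
    ld_block_size: int = 5
    ld_rho: float = 0.5
    n_exposure: int = 350_000
    n_outcome: int = 150_000
    theta: float = 0.3
    n_causal: int = 5
    causal_beta_range: tuple[float, float] = (0.01, 0.05)
    invalid_fraction: float = 0.0
    pleiotropy_model: str = "balanced"  # "balanced" | "directional"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.02
    outcome_type: str = "quantitative"  # "quantitative" | "case-control"
    case_proportion: float = 0.3
    noise_scale_exposure: float = 1.0
    noise_scale_outcome: float = 1.0
    chrom: str = "6"
    pos_start: int = 38_600_000
    pos_spacing: int = 1_000
    id_prefix: str = "rs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp <= 0 or self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ConfigurationError("sizes must be positive")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ConfigurationError("invalid_fraction must lie in [0, 1]")
        if self.n_causal > self.n_snp:
            raise ConfigurationError("n_causal cannot exceed n_snp")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        if self.ld_model not in ("block", "ar1"):
            raise ConfigurationError(f"unknown LD model {self.ld_model!r}")


@dataclass
class SimTruth:
    """Ground truth of one simulation, for recovery tests."""

    theta: float
    snp_ids: list[str]
    beta_marg_x: list[float]
    alpha: list[float]
    causal_ids: list[str]
    invalid_ids: list[str]
    scenario: str | None
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


def build_ld_corr(config: SimConfig) -> np.ndarray:
    """LD correlation matrix R: block-constant (positive definite for
    rho < 1 by construction) or AR(1) with lag-1 correlation rho."""
    k, rho = config.n_snp, config.ld_rho
    if config.ld_model == "ar1":
        idx = np.arange(k)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    R = np.eye(k)
    for start in range(0, k, config.ld_block_size):
        stop = min(start + config.ld_block_size, k)
        R[start:stop, start:stop] = rho
    np.fill_diagonal(R, 1.0)
    return R


def _cholesky(R: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        log.warning("LD matrix not positive definite; ridge regularization applied")
        w, V = np.linalg.eigh(R)
        R = (V * np.maximum(w, 1e-8)) @ V.T
        d = np.sqrt(np.diag(R))
        return np.linalg.cholesky(R / np.outer(d, d))


def _draw_panel(config: SimConfig, rng: np.random.Generator):
    """Allele frequencies, alleles, ids and positions for one SNP panel."""
    k = config.n_snp
    f = rng.uniform(*config.eaf_range, size=k)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=k)]
    pos = config.pos_start + config.pos_spacing * np.arange(k)
    ids = [f"{config.id_prefix}{p}" for p in pos]
    return f, pairs, pos, ids


def _se_quantitative(n: float, f: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * f * (1.0 - f))


def _se_case_control(n: float, s: float, f: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * s * (1.0 - s) * f * (1.0 - f))


def _assemble(ids, chrom, pos, pairs, f, beta_hat, se, n) -> pd.DataFrame:
    pvals = 2.0 * stats.norm.sf(np.abs(beta_hat) / se)
    return pd.DataFrame({
        "snp_id": ids, "chrom": str(chrom), "pos": pos,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "eaf": f, "beta": beta_hat, "se": se,
        "pval": np.clip(pvals, np.finfo(float).tiny, 1.0),
        "n": float(n),
    })[CANONICAL_COLUMNS]


def _draw_estimates(beta_true, se, L, noise_scale, rng):
    eps = rng.standard_normal(len(beta_true))
    return beta_true + noise_scale * se * (L @ eps)


def simulate_two_sample(config: SimConfig,
                        exposure_name: str = "exposure",
                        outcome_name: str = "outcome"):
    """Simulate one exposure-outcome pair at one locus.

    Returns (exposure SummaryTable, outcome SummaryTable, LDMatrix of r²,
    SimTruth). The outcome tables share the exposure's panel (ids, alleles,
    frequencies) as if both GWAS were run on one imputation panel.
    """
    rng = np.random.default_rng(config.seed)
    f, pairs, pos, ids = _draw_panel(config, rng)
    R = build_ld_corr(config)
    L = _cholesky(R)

    beta_causal = np.zeros(config.n_snp)
    causal_idx = np.sort(rng.choice(config.n_snp, size=config.n_causal,
                                    replace=False))
    mags = rng.uniform(*config.causal_beta_range, size=config.n_causal)
    signs = rng.choice([-1.0, 1.0], size=config.n_causal)
    beta_causal[causal_idx] = mags * signs
    beta_marg_x = R @ beta_causal

    n_invalid = int(round(config.invalid_fraction * config.n_snp))
    invalid_idx = np.sort(rng.choice(config.n_snp, size=n_invalid,
                                     replace=False)) if n_invalid else np.array([], int)
    alpha = np.zeros(config.n_snp)
    if n_invalid:
        mean = config.pleiotropy_mean if config.pleiotropy_model == "directional" else 0.0
        alpha[invalid_idx] = rng.normal(mean, config.pleiotropy_sd, size=n_invalid)

    se_x = _se_quantitative(config.n_exposure, f)
    if config.outcome_type == "case-control":
        se_y = _se_case_control(config.n_outcome, config.case_proportion, f)
    else:
        se_y = _se_quantitative(config.n_outcome, f)
    beta_marg_y = config.theta * beta_marg_x + alpha

    bx = _draw_estimates(beta_marg_x, se_x, L, config.noise_scale_exposure, rng)
    by = _draw_estimates(beta_marg_y, se_y, L, config.noise_scale_outcome, rng)

    exposure = SummaryTable(
        _assemble(ids, config.chrom, pos, pairs, f, bx, se_x, config.n_exposure),
        TraitMeta(exposure_name, "quantitative", sd=1.0))
    outcome = SummaryTable(
        _assemble(ids, config.chrom, pos, pairs, f, by, se_y, config.n_outcome),
        TraitMeta(outcome_name, config.outcome_type,
                  s=config.case_proportion if config.outcome_type == "case-control" else None,
                  sd=1.0 if config.outcome_type == "quantitative" else None))
    truth = SimTruth(config.theta, ids, beta_marg_x.tolist(), alpha.tolist(),
                     [ids[i] for i in causal_idx], [ids[i] for i in invalid_idx],
                     None, config.seed)
    return exposure, outcome, LDMatrix(ids, R ** 2), truth


# ---------------------------------------------------------------------------
# colocalization scenarios

COLOC_SCENARIOS = ("H0", "H1", "H2", "H3", "H4")


def simulate_coloc_scenario(config: SimConfig, scenario: str,
                            beta1: float = 0.03, beta2: float | None = None,
                            h3_r2_max: float = 0.04):
    """Simulate one of the five colocalization configurations at a locus.

    H0: no causal variant for either trait; H1/H2: one trait only;
    H3: distinct causal variants whose LD r² does not exceed ``h3_r2_max``;
    H4: one shared causal variant. ``beta1``/``beta2`` are the causal
    per-allele effects for trait 1 (sample size ``n_exposure``) and trait 2
    (``n_outcome``). Returns (trait1, trait2, LDMatrix, SimTruth) with the
    scenario recorded in the truth.
    """
    if scenario not in COLOC_SCENARIOS:
        raise ConfigurationError(f"scenario must be one of {COLOC_SCENARIOS}")
    beta2 = beta1 if beta2 is None else beta2
    rng = np.random.default_rng(config.seed)
    f, pairs, pos, ids = _draw_panel(config, rng)
    R = build_ld_corr(config)
    L = _cholesky(R)

    idx1 = int(rng.integers(config.n_snp))
    b1 = np.zeros(config.n_snp)
    b2 = np.zeros(config.n_snp)
    causal: list[str] = []
    if scenario in ("H1", "H3", "H4"):
        b1[idx1] = beta1
        causal.append(ids[idx1])
    if scenario in ("H2", "H4"):
        idx2 = idx1
        b2[idx2] = beta2
        if scenario == "H2":
            causal.append(ids[idx2])
    if scenario == "H3":
        candidates = np.flatnonzero(R[idx1] ** 2 <= h3_r2_max)
        candidates = candidates[candidates != idx1]
        if candidates.size == 0:
            raise ConfigurationError("no SNP in low enough LD for an H3 scenario")
        idx2 = int(rng.choice(candidates))
        b2[idx2] = beta2
        causal.append(ids[idx2])

    marg1, marg2 = R @ b1, R @ b2
    se1 = _se_quantitative(config.n_exposure, f)
    se2 = _se_quantitative(config.n_outcome, f)
    est1 = _draw_estimates(marg1, se1, L, config.noise_scale_exposure, rng)
    est2 = _draw_estimates(marg2, se2, L, config.noise_scale_outcome, rng)

    t1 = SummaryTable(_assemble(ids, config.chrom, pos, pairs, f, est1, se1,
                                config.n_exposure),
                      TraitMeta("trait1", "quantitative", sd=1.0))
    t2 = SummaryTable(_assemble(ids, config.chrom, pos, pairs, f, est2, se2,
                                config.n_outcome),
                      TraitMeta("trait2", "quantitative", sd=1.0))
    truth = SimTruth(0.0, ids, marg1.tolist(), [0.0] * config.n_snp, causal,
                     [], scenario, config.seed)
    return t1, t2, LDMatrix(ids, R ** 2), truth


# ---------------------------------------------------------------------------
# mediation

@dataclass
class MediationSim:
    """Three linked two-sample pairs exercising two-step MR mediation."""

    pairs: dict          # "total"|"step1"|"step2" -> (SummaryTable, SummaryTable)
    ld: dict             # "exposure"|"mediator" -> LDMatrix
    beta1: float
    beta2: float
    direct: float
    seed: int

    @property
    def theta_total(self) -> float:
        return self.direct + self.beta1 * self.beta2


def simulate_mediation(config: SimConfig, beta1: float, beta2: float,
                       direct: float, n_mediator: int = 150_000) -> MediationSim:
    """Simulate an exposure whose effect on the outcome decomposes as
    direct + beta1*beta2 through a mediator.

    Emits three harmonizable table pairs: exposure SNPs vs outcome (total
    effect), exposure SNPs vs mediator (step 1, beta1), and an independent
    panel of mediator instruments vs outcome (step 2, beta2).
    """
    rng = np.random.default_rng(config.seed)
    theta_total = direct + beta1 * beta2
    R = build_ld_corr(config)
    L = _cholesky(R)

    def locus(prefix: str, pos_start: int):
        sub = dataclasses.replace(config, id_prefix=prefix, pos_start=pos_start)
        f, pairs, pos, ids = _draw_panel(sub, rng)
        beta_causal = np.zeros(config.n_snp)
        causal_idx = np.sort(rng.choice(config.n_snp, size=config.n_causal,
                                        replace=False))
        beta_causal[causal_idx] = (rng.uniform(*config.causal_beta_range,
                                               size=config.n_causal)
                                   * rng.choice([-1.0, 1.0], size=config.n_causal))
        return f, pairs, pos, ids, R @ beta_causal

    fx, px, posx, idsx, marg_x = locus("rse", config.pos_start)
    fm, pm, posm, idsm, marg_m = locus("rsm", config.pos_start + 10_000_000)

    def table(ids, pos, pairs, f, beta_true, n, name, noise):
        se = _se_quantitative(n, f)
        est = _draw_estimates(beta_true, se, L, noise, rng)
        return SummaryTable(_assemble(ids, config.chrom, pos, pairs, f, est, se, n),
                            TraitMeta(name, "quantitative", sd=1.0))

    nsx, nso = config.noise_scale_exposure, config.noise_scale_outcome
    exposure = table(idsx, posx, px, fx, marg_x, config.n_exposure, "exposure", nsx)
    outcome_at_x = table(idsx, posx, px, fx, theta_total * marg_x,
                         config.n_outcome, "outcome", nso)
    mediator_at_x = table(idsx, posx, px, fx, beta1 * marg_x, n_mediator,
                          "mediator", nso)
    mediator_exp = table(idsm, posm, pm, fm, marg_m, n_mediator, "mediator", nsx)
    outcome_at_m = table(idsm, posm, pm, fm, beta2 * marg_m, config.n_outcome,
                         "outcome", nso)

    ld = {"exposure": LDMatrix(idsx, R ** 2), "mediator": LDMatrix(idsm, R ** 2)}
    return MediationSim({"total": (exposure, outcome_at_x),
                         "step1": (exposure, mediator_at_x),
                         "step2": (mediator_exp, outcome_at_m)},
                        ld, beta1, beta2, direct, config.seed)


# ---------------------------------------------------------------------------
# study fixture corpus

GLP1R_LOCUS = LocusDefinition("GLP1R", "6", 39_016_574, 39_055_519, 500)
GIPR_LOCUS = LocusDefinition("GIPR", "19", 46_171_502, 46_186_980, 500)

#: true causal effects of each biomarker on each outcome, per 1 SD biomarker
#: increase (positive: lowering the biomarker, as an agonist would, is
#: protective); one outcome is null for BMI
CORPUS_OUTCOMES = {
    "alcohol_freq": {"trait_type": "quantitative", "s": None,
                     "theta": {"BMI": 0.30, "HbA1c": 0.20}},
    "liver_fat": {"trait_type": "quantitative", "s": None,
                  "theta": {"BMI": 0.0, "HbA1c": 0.25}},
    "heavy_drinking": {"trait_type": "case-control", "s": 0.3,
                       "theta": {"BMI": 0.15, "HbA1c": 0.30}},
}

#: GWAS sample sizes per biomarker and source
CORPUS_SOURCES = {
    "BMI": {"primary": 700_000, "replication": 650_000},
    "HbA1c": {"primary": 350_000, "replication": 320_000},
}

CORPUS_N_OUTCOME = 150_000

#: peak true |z| at the primary sample size; GLP1R-BMI is deliberately
#: sub-genome-wide so the selection cascade falls back to the relaxed
#: threshold, as happens at under-powered loci
CORPUS_PEAK_Z = {
    ("GLP1R", "BMI"): 5.2,
    ("GLP1R", "HbA1c"): 12.0,
    ("GIPR", "BMI"): 10.0,
    ("GIPR", "HbA1c"): 14.0,
}


def make_study_corpus(outdir: str | Path, seed: int = 0,
                      n_snp_per_locus: int = 40) -> Path:
    """Materialize a small synthetic study (2 targets x 2 biomarkers x
    primary+replication sources x 3 outcomes) as TSV files plus a YAML study
    configuration, and return the config path.

    Exposure sources are independent draws around one set of true marginal
    effects per biomarker and locus; each outcome's true effects are the
    theta-weighted sum of both biomarkers' marginal effects, so MR on either
    biomarker approximately recovers its own theta.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    loci = {"GLP1R": GLP1R_LOCUS, "GIPR": GIPR_LOCUS}
    n_causal = 3
    base = SimConfig(n_snp=n_snp_per_locus, n_causal=n_causal, seed=seed)
    R = build_ld_corr(dataclasses.replace(base))
    L = _cholesky(R)

    panels, truths = {}, {}
    for gene, locus in loci.items():
        cfg = dataclasses.replace(
            base, chrom=locus.chrom,
            pos_start=locus.window_start + 50_000, pos_spacing=19_000,
            id_prefix=f"rs{gene}_")
        f, pairs, pos, ids = _draw_panel(cfg, rng)
        panels[gene] = (f, pairs, pos, ids, locus)
        for biomarker, peak_z in ((b, CORPUS_PEAK_Z[(gene, b)])
                                  for b in CORPUS_SOURCES):
            se_primary = _se_quantitative(CORPUS_SOURCES[biomarker]["primary"], f)
            beta_causal = np.zeros(n_snp_per_locus)
            cidx = np.sort(rng.choice(n_snp_per_locus, size=n_causal, replace=False))
            # scale magnitudes so the largest true |z| hits the target peak;
            # magnitudes kept within a 0.7-1.0 band so an under-powered locus
            # retains several comparably strong SNPs
            raw = rng.uniform(0.7, 1.0, size=n_causal) * rng.choice([-1., 1.], n_causal)
            beta_causal[cidx] = raw
            marg = R @ beta_causal
            scale = peak_z / np.max(np.abs(marg) / se_primary)
            truths[(gene, biomarker)] = marg * scale

    # exposure tables: one per biomarker and source, spanning both loci
    paths: dict[str, str] = {}
    for biomarker, sources in CORPUS_SOURCES.items():
        for source, n in sources.items():
            frames = []
            for gene, (f, pairs, pos, ids, locus) in panels.items():
                se = _se_quantitative(n, f)
                est = _draw_estimates(truths[(gene, biomarker)], se, L, 1.0, rng)
                frames.append(_assemble(ids, locus.chrom, pos, pairs, f, est, se, n))
            tab = SummaryTable(pd.concat(frames, ignore_index=True),
                               TraitMeta(biomarker, "quantitative", sd=1.0))
            name = f"{biomarker.lower()}_{source}.tsv"
            tab.to_tsv(outdir / name)
            paths[f"{biomarker}:{source}"] = name

    # outcome tables spanning both loci
    outcome_entries = []
    for label, spec in CORPUS_OUTCOMES.items():
        frames = []
        for gene, (f, pairs, pos, ids, locus) in panels.items():
            beta_true = sum(spec["theta"][b] * truths[(gene, b)]
                            for b in CORPUS_SOURCES)
            if spec["trait_type"] == "case-control":
                se = _se_case_control(CORPUS_N_OUTCOME, spec["s"], f)
            else:
                se = _se_quantitative(CORPUS_N_OUTCOME, f)
            est = _draw_estimates(beta_true, se, L, 1.0, rng)
            frames.append(_assemble(ids, locus.chrom, pos, pairs, f, est, se,
                                    CORPUS_N_OUTCOME))
        tab = SummaryTable(pd.concat(frames, ignore_index=True),
                           TraitMeta(label, spec["trait_type"], s=spec["s"]))
        name = f"outcome_{label}.tsv"
        tab.to_tsv(outdir / name)
        outcome_entries.append({"label": label, "path": name,
                                "trait_type": spec["trait_type"],
                                **({"s": spec["s"]} if spec["s"] else {})})

    ld_paths = {}
    for gene, (f, pairs, pos, ids, locus) in panels.items():
        name = f"ld_{gene}.tsv"
        LDMatrix(ids, R ** 2).to_tsv(outdir / name)
        ld_paths[gene] = name

    config = {
        "seed": int(seed), "alpha": 0.05, "n_tests": 20,
        "coloc_gate_p": 0.05, "direction": "lowering",
        "targets": [
            {"name": gene,
             "p_cascade": [5e-8, 5e-6], "ld_r2_max": 0.1,
             "loci": [{"gene": gene, "chrom": locus.chrom,
                       "start": locus.start, "end": locus.end,
                       "window_kb": locus.window_kb}]}
            for gene, locus in loci.items()],
        "biomarkers": [
            {"name": b, "trait_type": "quantitative",
             "sources": {s: paths[f"{b}:{s}"] for s in CORPUS_SOURCES[b]}}
            for b in CORPUS_SOURCES],
        "outcomes": outcome_entries,
        "ld": ld_paths,
    }
    config_path = outdir / "study.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
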