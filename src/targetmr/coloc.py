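"""Bayesian colocalization of two association signals at one locus.

Under the single-causal-variant assumption, each SNP's evidence of
association with a trait is an approximate Bayes factor computed from its
z-statistic and standard error with a normal prior N(0, W) on the true
effect. Enumerating the five configurations —

- H0: no causal variant for either trait,
- H1/H2: a causal variant for one trait only,
- H3: distinct causal variants for the two traits,
- H4: one shared causal variant —

with per-SNP priors p1, p2 (trait-specific causal) and p12 (shared causal)
yields posterior probabilities PP.H0-PP.H4. All sums are done in log space.
A conditional H4 ratio PP.H4/(PP.H3+PP.H4) is reported for loci where the
outcome signal is weak (H1 absorbs most mass, leaving H3+H4 small).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .exceptions import ConfigurationError, InputError

log = logging.getLogger(__name__)

#: prior SD of the causal effect, per trait type (quantitative scaled by sdY)
W_SCALE_QUANTITATIVE = 0.15
W_SCALE_CASE_CONTROL = 0.2

#: decision label threshold for a shared causal variant
H4_THRESHOLD = 0.60


@dataclass
class ColocPriors:
    """Per-SNP prior probabilities of causal configurations."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name, v in (("p1", self.p1), ("p2", self.p2), ("p12", self.p12)):
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ConfigurationError("p12 must not exceed min(p1, p2)")


@dataclass
class TraitSpec:
    """What is needed to set the prior effect variance for one trait."""

    trait_type: str = "quantitative"
    sdY: float = 1.0
    s: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case-control"):
            raise ConfigurationError(f"unknown trait type {self.trait_type!r}")
        if self.sdY <= 0:
            raise ConfigurationError("sdY must be positive")
        if self.s is not None and not 0.0 < self.s < 1.0:
            raise ConfigurationError("case proportion s must lie in (0, 1)")

    @property
    def w_scale(self) -> float:
        if self.trait_type == "quantitative":
            return W_SCALE_QUANTITATIVE * self.sdY
        return W_SCALE_CASE_CONTROL


@dataclass
class ColocResult:
    """Posterior probabilities over the five configurations."""

    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_snp: int
    priors: ColocPriors = field(default_factory=ColocPriors)

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2,
                         self.pp_h3, self.pp_h4])

    @property
    def conditional_h4(self) -> float:
        return conditional_h4(self)

    @property
    def shared_variant_flag(self) -> bool:
        return self.pp_h4 > H4_THRESHOLD


def labf_per_snp(table, spec: TraitSpec | None = None,
                 w_scale: float | None = None) -> np.ndarray:
    """Per-SNP log approximate Bayes factors for association with one trait.

    With z = beta/se, V = se² and prior effect variance W: the shrinkage
    factor is r = W/(W+V) and log-ABF = 0.5*(log(1-r) + r*z²). ``w_scale``
    (the prior SD, sqrt(W)) overrides the trait-type default of 0.15*sdY
    (quantitative) or 0.2 (case-control, log-odds scale).

    ``table`` may be a SummaryTable, a DataFrame with beta/se columns, or a
    (beta, se) pair of arrays.
    """
    if hasattr(table, "df"):
        beta = table.df["beta"].to_numpy(dtype=float)
        se = table.df["se"].to_numpy(dtype=float)
    elif hasattr(table, "columns"):
        beta = table["beta"].to_numpy(dtype=float)
        se = table["se"].to_numpy(dtype=float)
    else:
        beta, se = (np.asarray(v, dtype=float) for v in table)
    if np.any(se <= 0):
        raise InputError("standard errors must be positive")
    sd_prior = w_scale if w_scale is not None else (spec or TraitSpec()).w_scale
    W = sd_prior ** 2
    V = se ** 2
    r = W / (W + V)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z * z)


def estimate_sdy(eaf: np.ndarray, se: np.ndarray, n: np.ndarray) -> float:
    """Estimate the trait SD from summary data: for a standardized genotype,
    var(beta_j) ~ sdY²/(2 f_j (1-f_j) n_j), so regressing 2f(1-f)n on 1/se²
    through the origin has slope sdY²."""
    eaf, se, n = (np.asarray(v, dtype=float) for v in (eaf, se, n))
    oneover = se ** -2.0
    nvx = 2.0 * n * eaf * (1.0 - eaf)
    slope = float(np.sum(nvx * oneover) / np.sum(oneover ** 2))
    if slope <= 0:
        raise InputError("sdY estimate non-positive; supply sdY explicitly")
    return math.sqrt(slope)


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)); -inf when the difference underflows to <= 0."""
    if b >= a - 1e-12:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(labf_x, labf_y,
                     priors: ColocPriors | None = None) -> ColocResult:
    """Combine two traits' per-SNP log-ABFs into posteriors over H0-H4.

    Both lists must be in identical SNP order (a harmonized locus). With
    l1 = logsum(labf_x), l2 = logsum(labf_y) and l12 = logsum(labf_x+labf_y):
    H0 ~ 1; H1 ~ p1*exp(l1); H2 ~ p2*exp(l2);
    H3 ~ p1*p2*(exp(l1+l2) - exp(l12)) (the off-diagonal sum — empty, hence
    PP.H3 = 0, for a single-SNP locus); H4 ~ p12*exp(l12).
    """
    priors = priors or ColocPriors()
    lx = np.asarray(labf_x, dtype=float)
    ly = np.asarray(labf_y, dtype=float)
    if lx.shape != ly.shape:
        raise InputError("trait ABF lists differ in length")
    if lx.size == 0:
        raise InputError("empty locus")
    l1 = float(logsumexp(lx))
    l2 = float(logsumexp(ly))
    l12 = float(logsumexp(lx + ly))
    lh = np.array([
        0.0,
        math.log(priors.p1) + l1,
        math.log(priors.p2) + l2,
        math.log(priors.p1) + math.log(priors.p2) + _logdiffexp(l1 + l2, l12),
        math.log(priors.p12) + l12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocResult(*map(float, pp), n_snp=int(lx.size), priors=priors)


def conditional_h4(result: ColocResult) -> float:
    """PP.H4/(PP.H3+PP.H4); NaN (with a warning) when both are zero."""
    denom = result.pp_h3 + result.pp_h4
    if denom == 0:
        log.warning("conditional H4 undefined: PP.H3 + PP.H4 = 0")
        return float("nan")
    return result.pp_h4 / denom


def colocalize(table_x, table_y, spec_x: TraitSpec | None = None,
               spec_y: TraitSpec | None = None,
               priors: ColocPriors | None = None) -> ColocResult:
    """End-to-end colocalization of two summary tables restricted to their
    shared SNPs (matched on snp_id, position order)."""
    dfx = table_x.df if hasattr(table_x, "df") else table_x
    dfy = table_y.df if hasattr(table_y, "df") else table_y
    shared = dfx.merge(dfy, on="snp_id", suffixes=("_x", "_y"))
    if shared.empty:
        raise InputError("no shared SNPs at the locus")
    labf_x = labf_per_snp((shared["beta_x"], shared["se_x"]), spec_x)
    labf_y = labf_per_snp((shared["beta_y"], shared["se_y"]), spec_y)
    return coloc_posteriors(labf_x, labf_y, priors)
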