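"""Cis-instrument construction for drug-target Mendelian randomization.

Instruments are independent SNPs (pairwise LD r² below a threshold, default
0.1) in a window around the target gene (default ±500 kb) that are
associated with the exposure biomarker. Selection applies a p-value
threshold cascade — genome-wide significance (5e-8) first, falling back to
a relaxed threshold (5e-6) when a locus yields nothing, as is common in
cis-instrument studies of under-powered loci — followed by greedy LD
clumping. Dual-target instruments (e.g. modelling a dual GIPR/GLP1R
agonist) concatenate per-locus instruments built on the same biomarker.

Instrument strength is summarized per SNP by the F-statistic
F = (beta/se)^2 and variance explained r² = F/(F + n - 2); F > 10 is the
conventional bar for minimal weak-instrument bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InstrumentationError
from .sumstats import LDMatrix, LocusDefinition, SummaryTable

log = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0


@dataclass
class TargetSpec:
    """One drug target: its locus (or two loci for a dual target) and
    the selection parameters used to instrument it."""

    name: str
    loci: list[LocusDefinition]
    exposure: str | None = None
    p_cascade: tuple[float, ...] = (5e-8, 5e-6)
    ld_r2_max: float = 0.1

    def __post_init__(self) -> None:
        if not self.loci:
            raise ConfigurationError(f"{self.name}: at least one locus required")
        if len(self.loci) > 2:
            raise ConfigurationError(f"{self.name}: at most two loci supported")
        cascade = tuple(float(p) for p in self.p_cascade)
        if any(b <= a for a, b in zip(cascade, cascade[1:])):
            raise ConfigurationError("p_cascade must be strictly increasing")
        self.p_cascade = cascade
        if not 0.0 < self.ld_r2_max < 1.0:
            raise ConfigurationError("ld_r2_max must lie in (0, 1)")


@dataclass
class InstrumentSet:
    """Selected instrument SNPs with exposure effects and diagnostics.

    ``df`` has the summary-statistics columns plus ``locus`` (source gene),
    ``flipped`` (allele orientation applied), and — after
    :func:`strength_diagnostics` — ``F`` and ``r2_j``.
    """

    df: pd.DataFrame
    exposure: str = "exposure"
    cascade_used: dict[str, float] = field(default_factory=dict)
    direction: str | None = None
    ld: dict[str, LDMatrix] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    @property
    def set_r2(self) -> float:
        """Variance explained, summing per-SNP r² (independence after clumping)."""
        return float(self.df["r2_j"].sum())

    @property
    def min_f(self) -> float:
        return float(self.df["F"].min())

    @property
    def weak_snps(self) -> list[str]:
        return self.df.loc[self.df["F"] < WEAK_F_THRESHOLD, "snp_id"].tolist()

    def max_pairwise_r2(self) -> float:
        """Largest within-locus pairwise r² among selected SNPs (0 if unknown)."""
        worst = 0.0
        for gene, ld in self.ld.items():
            ids = self.df.loc[self.df["locus"] == gene, "snp_id"].tolist()
            ids = [s for s in ids if s in ld]
            if len(ids) > 1:
                sub = ld.submatrix(ids).r2
                worst = max(worst, float(np.max(sub - np.eye(len(ids)))))
        return worst

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def clump(table: SummaryTable, ld: LDMatrix, r2_max: float = 0.1) -> SummaryTable:
    """Greedy LD clumping of a summary table.

    SNPs are ranked by p ascending (ties: larger \\|z\\| first, then
    lexicographic id); the best remaining SNP is kept and every remaining
    SNP with r² >= ``r2_max`` against it discarded, until exhaustion. SNPs
    absent from the LD matrix are dropped first (reason ``no_ld``). Kept
    SNPs are returned in selection order.
    """
    df = table.df
    in_ld = df["snp_id"].isin(ld.ids)
    if (~in_ld).any():
        log.info("clump: %d SNP(s) dropped, no_ld", int((~in_ld).sum()))
    df = df.loc[in_ld].copy()
    df["_absz"] = (df["beta"] / df["se"]).abs()
    ranked = df.sort_values(["pval", "_absz", "snp_id"],
                            ascending=[True, False, True], kind="mergesort")
    remaining = ranked["snp_id"].tolist()
    kept: list[str] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [s for s in remaining if ld.value(best, s) < r2_max]
    out = ranked.set_index("snp_id").loc[kept].reset_index()
    return SummaryTable(out.drop(columns="_absz"), table.trait, 0)


def select_cis_instruments(table: SummaryTable, spec: TargetSpec,
                           ld: LDMatrix | dict[str, LDMatrix]) -> InstrumentSet:
    """Build the instrument set for a target: slice each locus window,
    filter at the first cascade threshold that yields any SNP, clump, attach
    strength diagnostics, and (for dual targets) concatenate loci.

    Raises :class:`InstrumentationError`, naming the locus, when every
    cascade level leaves the window empty.
    """
    from .sumstats import slice_locus  # local import keeps module load light

    ld_by_gene = ld if isinstance(ld, dict) else {loc.gene: ld for loc in spec.loci}
    parts: list[InstrumentSet] = []
    for locus in spec.loci:
        window = slice_locus(table, locus)
        if locus.gene not in ld_by_gene:
            raise ConfigurationError(f"no LD matrix supplied for {locus.gene}")
        selected, level = None, None
        for p_thr in spec.p_cascade:
            hits = window.df.loc[window.df["pval"] < p_thr]
            if hits.empty:
                log.info("%s: no SNPs at P < %.3g, advancing cascade", locus.gene, p_thr)
                continue
            clumped = clump(SummaryTable(hits.reset_index(drop=True), table.trait),
                            ld_by_gene[locus.gene], spec.ld_r2_max)
            if len(clumped):
                selected, level = clumped, p_thr
                break
        if selected is None:
            raise InstrumentationError(
                f"no instrument for {locus.gene} at any cascade threshold "
                f"{spec.p_cascade}")
        df = selected.df.copy()
        df["locus"] = locus.gene
        df["flipped"] = False
        part = InstrumentSet(df, exposure=spec.exposure or table.trait.name,
                             cascade_used={locus.gene: level},
                             ld={locus.gene: ld_by_gene[locus.gene]})
        parts.append(strength_diagnostics(part))
    out = parts[0]
    for other in parts[1:]:
        out = combine_targets(out, other)
    return out


def combine_targets(a: InstrumentSet, b: InstrumentSet) -> InstrumentSet:
    """Concatenate two disjoint per-locus instrument sets into a dual-target set.

    Loci must be disjoint (a duplicated snp_id is an error); per-locus
    provenance is preserved and set-level diagnostics recomputed on the union.
    """
    if a.exposure != b.exposure:
        raise ConfigurationError(
            f"cannot combine instruments for different exposures "
            f"({a.exposure!r} vs {b.exposure!r})")
    dupes = set(a.snp_ids) & set(b.snp_ids)
    if dupes:
        raise InstrumentationError(f"duplicated SNPs across loci: {sorted(dupes)}")
    df = pd.concat([a.df, b.df], ignore_index=True)
    return InstrumentSet(df, a.exposure,
                         {**a.cascade_used, **b.cascade_used},
                         a.direction if a.direction == b.direction else None,
                         {**a.ld, **b.ld})


def orient_to_agonism(iset: InstrumentSet, direction: str = "lowering") -> InstrumentSet:
    """Orient every SNP's effect allele so the stored exposure beta is a
    positive magnitude: SNPs with beta < 0 have allele labels swapped,
    eaf replaced by 1 - eaf, and beta negated, with the flip recorded.

    ``direction`` records the pharmacological reading of the set (a
    "lowering" set models an agonist that reduces the biomarker; reporting
    per 1 SD *decrease* is then a sign convention applied downstream).
    Idempotent. A beta of exactly 0 is left unflipped with a warning.
    """
    if direction not in ("lowering", "raising"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    df = iset.df.copy()
    zero = df["beta"] == 0
    if zero.any():
        log.warning("orient_to_agonism: %d SNP(s) with beta exactly 0 left "
                    "unflipped", int(zero.sum()))
    flip = df["beta"] < 0
    ea = df["effect_allele"].copy()
    df.loc[flip, "effect_allele"] = df.loc[flip, "other_allele"]
    df.loc[flip, "other_allele"] = ea[flip]
    df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
    df.loc[flip, "beta"] = -df.loc[flip, "beta"]
    df["flipped"] = df["flipped"] ^ flip
    return InstrumentSet(df, iset.exposure, dict(iset.cascade_used),
                         direction, dict(iset.ld))


def strength_diagnostics(iset: InstrumentSet, n: float | None = None) -> InstrumentSet:
    """Attach per-SNP F-statistics and variance explained.

    F_j = (beta_j/se_j)²; r²_j = F_j/(F_j + n - 2) with the per-SNP sample
    size unless ``n`` overrides it. Set-level R² sums r²_j (SNPs treated as
    independent after clumping). SNPs with F < 10 are flagged in the log.
    """
    df = iset.df.copy()
    n_eff = df["n"].to_numpy(dtype=float) if n is None else float(n)
    if np.any(np.asarray(n_eff) <= 2):
        raise ConfigurationError("sample size must exceed 2 for diagnostics")
    F = (df["beta"] / df["se"]) ** 2
    df["F"] = F
    df["r2_j"] = F / (F + n_eff - 2)
    weak = df.loc[df["F"] < WEAK_F_THRESHOLD, "snp_id"].tolist()
    if weak:
        log.warning("weak instrument(s) F < %g: %s", WEAK_F_THRESHOLD, weak)
    return InstrumentSet(df, iset.exposure, dict(iset.cascade_used),
                         iset.direction, dict(iset.ld))


def restrict_to_instruments(harmonized_df: pd.DataFrame,
                            iset: InstrumentSet) -> pd.DataFrame:
    """Restrict a harmonized table to the instrument SNPs, in set order."""
    keep = harmonized_df.set_index("snp_id", drop=False)
    ids = [s for s in iset.snp_ids if s in keep.index]
    return keep.loc[ids].reset_index(drop=True)
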