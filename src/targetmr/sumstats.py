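"""GWAS summary-statistics I/O, validation, locus slicing and allele harmonization.

A summary-statistics table holds one row per SNP: identifier, genomic
coordinates (1-based, GRCh37), effect and other allele, effect-allele
frequency ``f``, marginal effect ``beta`` with standard error ``se``,
p-value and sample size. Every downstream formula (Wald ratios, IVW
weights, approximate Bayes factors, carrier probabilities) consumes these
columns, so validation happens once, on read.

Two-sample Mendelian randomization requires the exposure and outcome
effects to be expressed on the *same* effect allele. :func:`harmonize`
aligns the outcome table to the exposure's alleles, resolving swapped
alleles, strand flips (complementary alleles), and strand-ambiguous
palindromic SNPs (A/T, C/G), which cannot be resolved from allele labels
alone and are aligned by allele frequency or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InputError

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical internal column names, in storage order
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: default header names in summary-statistics files
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "POS",
    "effect_allele": "EA", "other_allele": "OA",
    "eaf": "EAF", "beta": "BETA", "se": "SE", "pval": "P", "n": "N",
}


@dataclass
class TraitMeta:
    """Metadata for one trait's summary statistics.

    ``trait_type`` is ``"quantitative"`` or ``"case-control"``; ``s`` is the
    case proportion for case-control traits; ``sd`` is the trait standard
    deviation when known (1 for standardized quantitative traits).
    """

    name: str = "trait"
    trait_type: str = "quantitative"
    s: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case-control"):
            raise ConfigurationError(
                f"trait_type must be quantitative or case-control, got {self.trait_type!r}"
            )
        if self.s is not None and not 0.0 < self.s < 1.0:
            raise ConfigurationError("case proportion s must lie in (0, 1)")


def is_palindromic(a1: str, a2: str) -> bool:
    """True when the allele pair is its own reverse complement (A/T or C/G)."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _validate_frame(df: pd.DataFrame, *, allow_missing_eaf: bool = True):
    """Coerce types, enforce per-row invariants, return (clean, n_dropped).

    Rows violating any invariant are dropped, never repaired (except allele
    case, which is normalized). Indels and non-ACGT codes are rejected: the
    instruments are SNPs.
    """
    df = df.copy()
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["chrom"] = df["chrom"].astype(str).str.replace("^chr", "", regex=True)
    df["snp_id"] = df["snp_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & df["beta"].notna()
        & (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["n"] > 0)
        & df["pos"].notna() & (df["pos"] > 0)
    )
    if allow_missing_eaf:
        ok &= df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    else:
        ok &= (df["eaf"] > 0) & (df["eaf"] < 1)
    # duplicated identifiers: keep the first occurrence
    ok &= ~df["snp_id"].duplicated(keep="first") | ~ok

    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d row(s) failing validation", n_dropped)
    clean = df.loc[ok].reset_index(drop=True)
    clean["pos"] = clean["pos"].astype(np.int64)
    clean["n"] = clean["n"].astype(float)

    _warn_p_z_inconsistency(clean)
    return clean[CANONICAL_COLUMNS], n_dropped


def _warn_p_z_inconsistency(df: pd.DataFrame, rel_tol: float = 1e-3) -> None:
    """Warn (never fail) when p disagrees with |beta/se| on the -log10 scale.

    Published tables round both columns, so this is a sanity check only.
    Rows with p at the float floor are skipped.
    """
    if df.empty:
        return
    with np.errstate(divide="ignore"):
        z = np.abs(df["beta"].to_numpy() / df["se"].to_numpy())
        implied = 2.0 * stats.norm.sf(z)
        mask = (df["pval"].to_numpy() > 1e-300) & (implied > 1e-300)
        lp = -np.log10(df["pval"].to_numpy()[mask])
        li = -np.log10(implied[mask])
    bad = np.abs(lp - li) > rel_tol * np.maximum(np.abs(lp), 1.0)
    if bad.any():
        log.warning(
            "%d row(s) have p-values inconsistent with beta/se beyond rel. tol %.0e",
            int(bad.sum()), rel_tol,
        )


@dataclass
class SummaryTable:
    """Validated per-SNP summary statistics for one trait."""

    df: pd.DataFrame
    trait: TraitMeta = field(default_factory=TraitMeta)
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, trait: TraitMeta | None = None,
                   *, allow_missing_eaf: bool = True) -> "SummaryTable":
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing mandatory column(s): {missing}")
        clean, n_dropped = _validate_frame(df, allow_missing_eaf=allow_missing_eaf)
        if clean.empty:
            raise InputError("no valid summary-statistics rows after filtering")
        return cls(clean, trait or TraitMeta(), n_dropped)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.rename(columns=DEFAULT_COLUMN_MAP)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats(path: str | Path, column_map: dict[str, str] | None = None,
                  trait: TraitMeta | None = None, sep: str = "\t",
                  *, allow_missing_eaf: bool = True) -> SummaryTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names to the file's header names; defaults
    cover the common SNP/CHR/POS/EA/OA/EAF/BETA/SE/P/N dialect. Rows failing
    type or range checks are dropped and counted in ``n_dropped``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep)
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(f"column(s) {missing} not found in {path}")
    df = raw.rename(columns={v: k for k, v in cmap.items()})
    return SummaryTable.from_frame(df, trait, allow_missing_eaf=allow_missing_eaf)


@dataclass
class LocusDefinition:
    """A gene locus plus a flanking cis window (1-based inclusive, GRCh37)."""

    gene: str
    chrom: str
    start: int
    end: int
    window_kb: int = 500

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        if self.start > self.end:
            raise ConfigurationError(f"{self.gene}: start > end")
        if self.window_kb < 0:
            raise ConfigurationError("window_kb must be >= 0")

    @property
    def window_start(self) -> int:
        return self.start - self.window_kb * 1000

    @property
    def window_end(self) -> int:
        return self.end + self.window_kb * 1000

    def overlaps(self, other: "LocusDefinition") -> bool:
        return (self.chrom == other.chrom
                and self.window_start <= other.window_end
                and other.window_start <= self.window_end)


def slice_locus(table: SummaryTable, locus: LocusDefinition) -> SummaryTable:
    """Restrict a table to the cis window, closed on both ends.

    Output is sorted by position so the result does not depend on input row
    order. An empty window is returned empty (and logged), not raised.
    """
    df = table.df
    keep = (df["chrom"] == locus.chrom) & \
           (df["pos"] >= locus.window_start) & (df["pos"] <= locus.window_end)
    out = df.loc[keep].sort_values(["pos", "snp_id"], kind="mergesort").reset_index(drop=True)
    if out.empty:
        log.info("no SNPs in window %s:%d-%d (%s)", locus.chrom,
                 locus.window_start, locus.window_end, locus.gene)
    return SummaryTable(out, table.trait, 0)


@dataclass
class LDMatrix:
    """Pairwise LD (r-squared) among an ordered set of SNPs."""

    ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError("LD matrix shape does not match id count")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ConfigurationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-6):
            raise ConfigurationError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-8 or self.r2.max() > 1 + 1e-8:
            raise ConfigurationError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def value(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def submatrix(self, ids: list[str]) -> "LDMatrix":
        idx = [self._index[s] for s in ids]
        return LDMatrix(ids, self.r2[np.ix_(idx, idx)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# harmonization

#: default frequency below which min(f, 1-f) lets a palindromic SNP be aligned
PALINDROME_FREQ_THRESHOLD = 0.42

HARMONIZED_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf_x", "beta_x", "se_x", "p_x", "n_x",
    "eaf_y", "beta_y", "se_y", "p_y", "n_y",
    "palindromic", "action",
]


@dataclass
class HarmonizedTable:
    """Exposure (x) and outcome (y) effects on one shared effect allele per SNP."""

    df: pd.DataFrame
    dropped: pd.DataFrame
    exposure: TraitMeta = field(default_factory=TraitMeta)
    outcome: TraitMeta = field(default_factory=TraitMeta)

    def __len__(self) -> int:
        return len(self.df)

    def to_tables(self) -> tuple[SummaryTable, SummaryTable]:
        """Split back into two aligned summary tables (used to test idempotence)."""
        base = ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]
        x = self.df[base].assign(
            eaf=self.df["eaf_x"], beta=self.df["beta_x"], se=self.df["se_x"],
            pval=self.df["p_x"], n=self.df["n_x"])
        y = self.df[base].assign(
            eaf=self.df["eaf_y"], beta=self.df["beta_y"], se=self.df["se_y"],
            pval=self.df["p_y"], n=self.df["n_y"])
        return (SummaryTable(x[CANONICAL_COLUMNS].copy(), self.exposure),
                SummaryTable(y[CANONICAL_COLUMNS].copy(), self.outcome))


def _align_one(ea_x, oa_x, ea_y, oa_y, eaf_x, eaf_y, freq_threshold, policy):
    """Classify one SNP. Returns (action, flip_sign) with action in
    kept|flipped|strand_kept|strand_flipped or a drop reason."""
    pal = is_palindromic(ea_x, oa_x)
    if pal:
        # labels cannot distinguish strands; {ea_y, oa_y} must match exactly
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return "allele_mismatch", False
        if policy == "drop":
            return "palindromic_dropped", False
        if policy == "keep":
            # trust reported orientation, align labels directly
            return ("kept", False) if ea_y == ea_x else ("flipped", True)
        # policy == "freq": frequencies must be informative for both traits
        if eaf_y is None or np.isnan(eaf_y) or np.isnan(eaf_x):
            return "palindromic_no_eaf", False
        if min(eaf_x, 1 - eaf_x) >= freq_threshold or \
           min(eaf_y, 1 - eaf_y) >= freq_threshold:
            return "palindromic_ambiguous", False
        same_orientation = (eaf_x < 0.5) == (eaf_y < 0.5)
        return ("kept", False) if same_orientation else ("flipped", True)

    if (ea_y, oa_y) == (ea_x, oa_x):
        return "kept", False
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "flipped", True
    cea, coa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return "strand_kept", False
    if (cea, coa) == (oa_x, ea_x):
        return "strand_flipped", True
    return "allele_mismatch", False


def harmonize(exposure: SummaryTable, outcome: SummaryTable,
              palindrome_policy: str = "freq",
              freq_threshold: float = PALINDROME_FREQ_THRESHOLD) -> HarmonizedTable:
    """Align outcome effects to the exposure's effect alleles, SNP by SNP.

    Where the outcome's alleles are swapped relative to the exposure the
    outcome beta is negated and its eaf replaced by 1-eaf; complementary
    (strand-flipped) alleles are mapped to the exposure strand first.
    Palindromic SNPs follow ``palindrome_policy``:

    - ``"freq"`` (default): align by allele frequency when min(f, 1-f) <
      ``freq_threshold`` for *both* traits, drop otherwise;
    - ``"drop"``: always drop;
    - ``"keep"``: trust the reported allele orientation.

    Irreconcilable allele sets are dropped with reason ``allele_mismatch``.
    """
    if palindrome_policy not in ("freq", "drop", "keep"):
        raise ConfigurationError(f"unknown palindrome policy {palindrome_policy!r}")
    xdf = exposure.df.set_index("snp_id", drop=False)
    ydf = outcome.df.set_index("snp_id", drop=False)
    shared = [s for s in exposure.df["snp_id"] if s in ydf.index]
    if not shared:
        raise InputError("exposure and outcome share no SNP identifiers")

    rows, dropped = [], []
    for snp in shared:
        rx, ry = xdf.loc[snp], ydf.loc[snp]
        action, flip = _align_one(
            rx.effect_allele, rx.other_allele, ry.effect_allele, ry.other_allele,
            rx.eaf, ry.eaf, freq_threshold, palindrome_policy)
        pal = is_palindromic(rx.effect_allele, rx.other_allele)
        if action in ("allele_mismatch", "palindromic_dropped",
                      "palindromic_no_eaf", "palindromic_ambiguous"):
            dropped.append({"snp_id": snp, "reason": action})
            continue
        beta_y = -ry.beta if flip else ry.beta
        eaf_y = ry.eaf if np.isnan(ry.eaf) else (1 - ry.eaf if flip else ry.eaf)
        rows.append({
            "snp_id": snp, "chrom": rx.chrom, "pos": rx.pos,
            "effect_allele": rx.effect_allele, "other_allele": rx.other_allele,
            "eaf_x": rx.eaf, "beta_x": rx.beta, "se_x": rx.se,
            "p_x": rx.pval, "n_x": rx.n,
            "eaf_y": eaf_y, "beta_y": beta_y, "se_y": ry.se,
            "p_y": ry.pval, "n_y": ry.n,
            "palindromic": pal, "action": action,
        })
    df = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    drop_df = pd.DataFrame(dropped, columns=["snp_id", "reason"])
    if drop_df.shape[0]:
        log.info("harmonization dropped %d SNP(s): %s", len(drop_df),
                 drop_df["reason"].value_counts().to_dict())
    return HarmonizedTable(df, drop_df, exposure.trait, outcome.trait)
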