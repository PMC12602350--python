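"""Carrier prevalence of activation alleles under Hardy-Weinberg equilibrium.

For a biallelic SNP with activation-allele frequency f, the probability an
individual carries at least one copy is P_carrier = 1 - (1-f)^2. Across the
independent SNPs of a clumped instrument the locus-level probability of
carrying at least one activation allele anywhere in the set is
P_locus = 1 - prod_i (1-f_i)^2, and an ancestry-level summary averages
P_locus across instrument sets. Frequencies are inputs (per-ancestry EAFs of
the biomarker-lowering alleles); residual LD below the clumping threshold is
ignored, with a warning when the supplied set exceeds it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError

log = logging.getLogger(__name__)


def snp_carrier_prob(f: float) -> float:
    """P(at least one copy) = 1 - (1-f)^2 under Hardy-Weinberg."""
    if not 0.0 <= f <= 1.0:
        raise DomainError(f"allele frequency {f} outside [0, 1]")
    return 1.0 - (1.0 - f) ** 2


def locus_carrier_prob(fs, ld=None, r2_warn: float = 0.1) -> float:
    """P(at least one activation allele across independent SNPs):
    1 - prod_i (1-f_i)^2. Warns when a supplied LD matrix shows residual
    pairwise r² above ``r2_warn`` (the independence assumption is then
    optimistic)."""
    fs = np.asarray(list(fs), dtype=float)
    if fs.size == 0:
        raise DomainError("empty frequency list")
    if np.any((fs < 0) | (fs > 1)):
        raise DomainError("allele frequencies must lie in [0, 1]")
    if ld is not None:
        r2 = np.asarray(ld.r2 if hasattr(ld, "r2") else ld, dtype=float)
        off = r2 - np.eye(r2.shape[0])
        if off.max() >= r2_warn:
            log.warning("max pairwise r2 %.3f exceeds %.2f; independence "
                        "assumption optimistic", float(off.max()), r2_warn)
    return float(1.0 - np.prod((1.0 - fs) ** 2))


@dataclass
class PrevalenceResult:
    """Per-SNP, per-locus and overall carrier-probability summary."""

    per_snp: pd.DataFrame       # set label, frequency, P_carrier
    per_locus: pd.DataFrame     # set label, mean EAF, P_locus
    overall: float              # mean of P_locus across sets


def ancestry_summary(sets) -> PrevalenceResult:
    """Summarize carrier prevalence across instrument sets for one ancestry.

    ``sets`` is an iterable of (label, frequencies) pairs; the overall
    ancestry-level prevalence is the arithmetic mean of per-set P_locus.
    Full precision is stored; round to 2 dp for presentation.
    """
    sets = list(sets)
    if not sets:
        raise DomainError("at least one instrument set required")
    snp_rows, locus_rows = [], []
    for label, fs in sets:
        fs = np.asarray(list(fs), dtype=float)
        for f in fs:
            snp_rows.append({"set": label, "eaf": float(f),
                             "p_carrier": snp_carrier_prob(float(f))})
        locus_rows.append({"set": label, "mean_eaf": float(fs.mean()),
                           "n_snp": int(fs.size),
                           "p_locus": locus_carrier_prob(fs)})
    per_locus = pd.DataFrame(locus_rows)
    return PrevalenceResult(pd.DataFrame(snp_rows), per_locus,
                            float(per_locus["p_locus"].mean()))
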