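"""Two-step MR mediation by the product-of-coefficients method.

A total genetically proxied effect of an exposure on an outcome is
decomposed using two auxiliary MR estimates: step 1 (exposure -> mediator,
beta1) and step 2 (mediator -> outcome, beta2, instrumented by genome-wide
SNPs for the mediator). The indirect effect transmitted through the
mediator is beta1*beta2, with a Sobel-type standard error under the
two-sample independence assumption; the proportion mediated is
indirect/total.

Ratio instability: the proportion is reported as missing when the indirect
and total effects disagree in sign, or when the total effect is too close
to zero relative to its standard error — both configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import ConfigurationError
from .mr import MRResult


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition of a total effect."""

    total: float
    step1: float
    step2: float
    indirect: float
    proportion_mediated: float  # NaN when suppressed
    se_indirect: float
    se_proportion: float
    pval: float
    suppressed_reason: str | None = None


def mediate(total: MRResult, step1: MRResult, step2: MRResult,
            *, min_total_z: float = 10.0, sign_check: bool = True) -> MediationResult:
    """Decompose ``total`` into the component passing through the mediator.

    indirect = beta1*beta2 with Sobel SE sqrt(beta1²*se2² + beta2²*se1²)
    (the two steps come from non-overlapping samples and are treated as
    independent); p from the normal z of the indirect effect. The proportion
    mediated indirect/total carries a first-order SE treating total as
    independent of the product. It is suppressed (NaN, with a reason) when
    the signs of indirect and total conflict, or when
    \\|total\\| < ``min_total_z`` * se_total (a near-zero denominator).

    All three inputs must be on one scale (log-odds for binary outcomes);
    a binary-outcome step mixed with beta-scale steps is a configuration
    error the caller must prevent by converting first.
    """
    for res in (total, step1, step2):
        if not isinstance(res, MRResult):
            raise ConfigurationError("mediate expects three MRResult inputs")
    b1, se1 = step1.beta, step1.se
    b2, se2 = step2.beta, step2.se
    t, se_t = total.beta, total.se

    indirect = b1 * b2
    var_ind = b1 * b1 * se2 * se2 + b2 * b2 * se1 * se1
    se_ind = math.sqrt(var_ind)
    if se_ind > 0:
        pval = float(2 * stats.norm.sf(abs(indirect) / se_ind))
    else:
        pval = 0.0 if indirect != 0 else 1.0

    reason = None
    if t == 0:
        reason = "total_effect_zero"
    elif se_t > 0 and abs(t) < min_total_z * se_t:
        reason = "total_effect_near_zero"
    elif sign_check and indirect != 0 and (indirect > 0) != (t > 0):
        reason = "sign_conflict"

    if reason is not None:
        prop, se_prop = float("nan"), float("nan")
    else:
        prop = indirect / t
        # first-order propagation: var(a/b) ~ var(a)/b^2 + a^2 var(b)/b^4
        se_prop = math.sqrt(var_ind / t ** 2
                            + indirect ** 2 * se_t ** 2 / t ** 4)
    return MediationResult(t, b1, b2, indirect, prop, se_ind, se_prop, pval,
                           reason)
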