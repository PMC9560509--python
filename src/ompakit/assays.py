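"""Phenotype assay metrics: MATH hydrophobicity, biofilm index, NE survival.

These are the study's three sequence-independent readouts:

* cell surface hydrophobicity from the microbial-adhesion-to-hydrocarbons
  (MATH) assay, quantified from OD546 before and after dodecane contact;
* the crystal-violet biofilm formation index OD570/OD620;
* survival of neutrophil-elastase treatment as a CFU ratio against a sham
  control, with a two-tailed t-test at a severe fixed cutoff deciding whether
  killing occurred.

Uncertainties on ratio quantities propagate to first order (quadrature of
relative errors).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.005


def math_hydrophobicity(
    od_initial: float, od_aqueous: float, conventional_denominator: bool = False
) -> float:
    """Cell hydrophobicity (%) from MATH assay OD546 readings.

    As printed in the source study the denominator is the *aqueous-phase* OD:
    ``100 * (od_initial - od_aqueous) / od_aqueous``. The conventional MATH
    formula divides by the initial OD instead; set
    ``conventional_denominator=True`` for that variant. An aqueous OD above
    the initial OD is physically anomalous and yields a negative value with a
    warning rather than an error.
    """
    if od_aqueous <= 0:
        raise ValueError(f"aqueous OD must be positive, got {od_aqueous}")
    if od_initial < 0:
        raise ValueError(f"initial OD must be non-negative, got {od_initial}")
    denom = od_initial if conventional_denominator else od_aqueous
    if denom <= 0:
        raise ValueError("denominator OD must be positive")
    value = 100.0 * (od_initial - od_aqueous) / denom
    if od_aqueous > od_initial:
        warnings.warn(
            f"aqueous OD {od_aqueous} exceeds initial OD {od_initial}; "
            "negative hydrophobicity returned",
            stacklevel=2,
        )
    return value


def biofilm_index(
    od570: float,
    od620: float,
    sd570: float | None = None,
    sd620: float | None = None,
) -> tuple[float, float | None]:
    """Biofilm formation index OD570/OD620 (crystal violet over culture
    density), with first-order propagated SD when replicate SDs are given:
    ``sd = index * sqrt((sd570/od570)^2 + (sd620/od620)^2)``."""
    if od620 <= 0:
        raise ValueError(f"OD620 must be positive, got {od620}")
    if od570 < 0:
        raise ValueError(f"OD570 must be non-negative, got {od570}")
    index = od570 / od620
    sd = None
    if sd570 is not None and sd620 is not None:
        if od570 == 0:
            sd = 0.0  # zero index: relative error undefined, SD pinned to 0
        else:
            sd = index * math.sqrt((sd570 / od570) ** 2 + (sd620 / od620) ** 2)
    return index, sd


@dataclass(frozen=True)
class NESurvivalResult:
    survival: float          # mean(treated CFU) / mean(control CFU)
    p_value: float
    significant_kill: bool   # p < alpha AND mean decrease
    n_treated: int
    n_control: int


def ne_survival(
    cfu_treated,
    cfu_control,
    alpha: float = DEFAULT_ALPHA,
    pooled: bool = True,
) -> NESurvivalResult:
    """Neutrophil-elastase survival fraction with a significant-kill flag.

    Survival is the ratio of mean treated to mean control CFU; killing is
    declared only when a two-tailed Student's t-test (pooled variance by
    default) gives p < `alpha` *and* the treated mean is lower.
    """
    treated = np.asarray(cfu_treated, dtype=float)
    control = np.asarray(cfu_control, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise ValueError("need at least 2 replicates per arm")
    if (treated < 0).any() or (control < 0).any():
        raise ValueError("CFU counts must be non-negative")
    if control.mean() == 0:
        raise ValueError("control mean CFU is zero; survival undefined")
    survival = treated.mean() / control.mean()
    if np.ptp(treated) == 0 and np.ptp(control) == 0:
        p = 1.0 if treated.mean() == control.mean() else 0.0
    else:
        p = float(stats.ttest_ind(treated, control, equal_var=pooled).pvalue)
    return NESurvivalResult(
        survival=float(survival),
        p_value=p,
        significant_kill=bool(p < alpha and treated.mean() < control.mean()),
        n_treated=int(treated.size),
        n_control=int(control.size),
    )


def propagate_ratio_sd(value: float, num: float, num_sd: float, den: float, den_sd: float) -> float:
    """First-order SD of a ratio from the component means and SDs."""
    if num == 0 or den == 0:
        raise ValueError("component means must be non-zero for relative-error propagation")
    return abs(value) * math.sqrt((num_sd / num) ** 2 + (den_sd / den) ** 2)


def summarize_replicates(df, value_column: str = "value", by=("strain", "assay")):
    """Mean, SD (ddof=1) and n per group of a long-format replicate table."""
    grouped = df.groupby(list(by))[value_column]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out
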