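"""Mendelian expectation, lethality estimation and combined incidence accounting.

The accounting mirrors how a knockout colony is censused: homozygous-null
(KO) offspring of a heterozygote intercross are expected at 25%, a deficit
at weaning implies embryonic/perinatal lethality
(expected − observed) / expected, and the overall phenotype incidence among
all KO conceptuses combines a prenatal rate (phenotypes that die before
birth) with the weaning-survivor rate discounted by lethality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "mendelian_expectation",
    "lethality",
    "account",
    "CrossAccount",
    "chi2_prop",
    "observed_ko_fraction",
]

# genotype fractions (wt, het, ko) by cross type
_CROSSES = {
    "hetxhet": {"wt": 0.25, "het": 0.50, "ko": 0.25},
    "hetxwt": {"wt": 0.50, "het": 0.50, "ko": 0.0},
    "wtxwt": {"wt": 1.0, "het": 0.0, "ko": 0.0},
    "koxko": {"wt": 0.0, "het": 0.0, "ko": 1.0},
    "hetxko": {"wt": 0.0, "het": 0.50, "ko": 0.50},
}


def mendelian_expectation(cross: str) -> dict[str, float]:
    """Exact Mendelian genotype fractions for a recognized cross.

    Cross names use 'x' between parental genotypes, e.g. ``hetxhet``.
    """
    key = cross.lower().replace(" ", "").replace("×", "x")
    if key not in _CROSSES:
        raise ValueError(f"unrecognized cross {cross!r}")
    return dict(_CROSSES[key])


def lethality(expected: float, observed: float) -> float:
    """Fraction of the expected genotype lost: (expected − observed)/expected.

    With 25% expected and 10% observed at weaning this is 15/25 = 60%.
    An observed fraction above expected warns (sampling noise) and returns
    the resulting negative value unclamped.
    """
    if not (0 < expected <= 1):
        raise ValueError("expected fraction must lie in (0, 1]")
    if not (0 <= observed <= 1):
        raise ValueError("observed fraction must lie in [0, 1]")
    if observed > expected:
        warnings.warn("observed fraction exceeds expected; negative lethality")
    return (expected - observed) / expected


@dataclass
class CrossAccount:
    """Combined incidence accounting, unrounded and as printed.

    ``survivor_fraction_of_all`` is the weaning-survivor phenotype rate
    re-expressed among all KO conceptuses; ``combined`` adds the prenatal
    rate.  Rounded fields follow the reporting convention: components to
    one decimal percent, the combined figure to a whole percent.
    """

    prenatal_rate: float
    survivor_rate: float
    lethality: float
    survivor_fraction_of_all: float
    combined: float
    survivor_fraction_pct: float
    prenatal_pct: float
    combined_pct: float


def account(
    prenatal_rate: float,
    survivor_rate: float,
    lethality_fraction: float,
    component_decimals: int = 1,
    combined_decimals: int = 0,
) -> CrossAccount:
    """Combine prenatal and survivor phenotype rates into one incidence.

    survivor-of-all = survivor_rate × (1 − lethality); combined =
    prenatal_rate + survivor-of-all.  Percent rounding: components to
    ``component_decimals`` (default one decimal), combined to
    ``combined_decimals`` (default whole percent); the combined percent is
    the sum of the *rounded* component percents, matching how such
    accountings are typically printed.
    """
    for name, v in (
        ("prenatal_rate", prenatal_rate),
        ("survivor_rate", survivor_rate),
        ("lethality", lethality_fraction),
    ):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    surv_all = survivor_rate * (1.0 - lethality_fraction)
    combined = prenatal_rate + surv_all
    surv_pct = round(100 * surv_all, component_decimals)
    pren_pct = round(100 * prenatal_rate, component_decimals)
    comb_pct = round(surv_pct + pren_pct, combined_decimals)
    return CrossAccount(
        prenatal_rate=prenatal_rate,
        survivor_rate=survivor_rate,
        lethality=lethality_fraction,
        survivor_fraction_of_all=surv_all,
        combined=combined,
        survivor_fraction_pct=surv_pct,
        prenatal_pct=pren_pct,
        combined_pct=comb_pct,
    )


def observed_ko_fraction(
    litters: pd.DataFrame, denominator: str = "conceived", expected_ko: float = 0.25
) -> float:
    """Observed KO fraction at census from a litter survivor-count table.

    ``denominator="survivors"`` divides KO survivors by all survivors — the
    fraction literally seen at weaning, which is *renormalized* by the
    missing KO pups and therefore understates the loss.
    ``denominator="conceived"`` (default) divides KO survivors by the total
    conceptus count inferred from the unaffected genotypes,
    (wt + het) / (1 − expected_ko); feeding this into :func:`lethality`
    against the Mendelian expectation recovers the true KO loss, and is the
    arithmetic behind a "10% observed vs 25% expected → 60% lethality"
    accounting.  Expects columns ``wt``, ``het``, ``ko``.
    """
    totals = litters[["wt", "het", "ko"]].sum()
    if denominator == "survivors":
        n = totals.sum()
    elif denominator == "conceived":
        n = (totals["wt"] + totals["het"]) / (1.0 - expected_ko)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if n == 0:
        raise ValueError("no surviving offspring")
    return float(totals["ko"] / n)


def chi2_prop(
    table, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test on a 2×k table of (affected, unaffected) counts.

    No continuity correction by default; Yates available via ``yates``.
    Returns (statistic, df, p).  A zero column margin is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, df, _ = sps.chi2_contingency(t, correction=yates)
    return float(stat), int(df), float(p)
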