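"""Rare-variant prioritization and case–control association.

The cascade: site-level quality filtering (VQSR PASS plus a mapping-quality
or inbreeding-coefficient clause), per-genotype quality filtering (alt
allele fraction, depth, genotype quality — all strict inequalities), cohort
allele-statistic recalculation per population, novelty/rarity
classification against a control allele-count table with a coverage gate,
CADD-style percentile ("C-score") arithmetic, deleteriousness selection,
and Fisher exact association with odds ratios.

The C-score is the phred transform of a deleteriousness percentile rank:
score = −10·log10(r) for rank fraction r in (0, 1], so 13.01 marks the top
5% and 20 the top 1%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GenotypeCall",
    "VariantSite",
    "CohortStats",
    "ControlRecord",
    "AssociationResult",
    "site_filter",
    "genotype_filter",
    "recalc_stats",
    "classify",
    "cscore_from_rank",
    "rank_from_cscore",
    "select_deleterious",
    "associate",
    "read_vcf",
    "prioritize",
]


@dataclass(frozen=True)
class GenotypeCall:
    """One subject's call at one site: diploid GT plus AD/DP/GQ."""

    gt: tuple[int, int]  # allele indices, 0 = ref, 1 = alt; (-1,-1) = missing
    ad_ref: int
    ad_alt: int
    dp: int
    gq: int

    @property
    def n_alt(self) -> int:
        return sum(1 for a in self.gt if a == 1)

    @property
    def missing(self) -> bool:
        return self.gt[0] < 0 or self.gt[1] < 0


@dataclass
class VariantSite:
    """One site: identity, site-level annotations and per-subject calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vqsr_pass: bool | None
    mq: float | None
    inbreeding: float | None
    calls: dict[str, GenotypeCall]  # subject -> call

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class CohortStats:
    ac: int
    an: int

    def __post_init__(self):
        if not (0 <= self.ac <= self.an):
            raise ValueError("need 0 <= AC <= AN")

    @property
    def af(self) -> float:
        return self.ac / self.an if self.an else float("nan")


@dataclass(frozen=True)
class ControlRecord:
    population: str
    ac: int
    an: int
    coverage: float

    @property
    def af(self) -> float:
        return self.ac / self.an if self.an else float("nan")


def site_filter(site: VariantSite) -> tuple[bool, str]:
    """Site retained iff VQSR PASS and (MQ > 20 or inbreeding < −0.3).

    A missing annotation fails the clause it belongs to.  The disjunction is
    applied exactly as stated.
    """
    if not site.vqsr_pass:
        return False, "not VQSR PASS"
    mq_ok = site.mq is not None and site.mq > 20
    inb_ok = site.inbreeding is not None and site.inbreeding < -0.3
    if mq_ok or inb_ok:
        return True, "pass"
    return False, "MQ <= 20 and inbreeding >= -0.3"


def genotype_filter(call: GenotypeCall) -> tuple[bool, str]:
    """Genotype retained iff alt fraction > 25%, DP > 10 and GQ > 20 (strict).

    Homozygous-reference calls carry no alternate allele; the alt-fraction
    clause only applies to carrier genotypes.
    """
    if call.missing:
        return False, "missing genotype"
    if call.dp <= 10:
        if call.dp == 0:
            return False, "zero depth"
        return False, "DP <= 10"
    if call.gq <= 20:
        return False, "GQ <= 20"
    if call.n_alt > 0 and call.ad_alt / call.dp <= 0.25:
        return False, "alt fraction <= 25%"
    return True, "pass"


def recalc_stats(
    site: VariantSite, populations: Mapping[str, str], population: str
) -> CohortStats | None:
    """Recalculate AC/AN/AF for one population from passing genotypes only.

    AN counts two alleles per subject with a passing call; AC counts the
    alternate alleles among them.  Returns None (undefined) when every
    genotype in the population fails.
    """
    ac = an = 0
    for subject, call in site.calls.items():
        if populations.get(subject) != population:
            continue
        ok, _ = genotype_filter(call)
        if not ok:
            continue
        an += 2
        ac += call.n_alt
    if an == 0:
        return None
    return CohortStats(ac=ac, an=an)


def classify(
    case: CohortStats,
    control: ControlRecord | None,
    rare_af: float = 0.01,
    min_coverage: float = 30.0,
) -> str:
    """Classify a variant as novel / rare / common / discard.

    A control locus below the coverage gate (30X) is poor quality and the
    variant is discarded.  Otherwise: absent from controls or control
    AF = 0 → novel; control AF < 0.01 → rare; else common.
    """
    if control is not None and control.coverage < min_coverage:
        return "discard"
    if control is None or control.ac == 0:
        if control is None:
            # no control record at all: coverage unknowable, be conservative
            return "discard"
        return "novel"
    return "rare" if control.af < rare_af else "common"


def cscore_from_rank(rank_fraction: float) -> float:
    """Phred-style deleteriousness score: −10·log10(rank fraction)."""
    r = float(rank_fraction)
    if not (0 < r <= 1):
        raise ValueError("rank fraction must lie in (0, 1]")
    return -10.0 * np.log10(r)


def rank_from_cscore(phred: float) -> float:
    """Inverse of :func:`cscore_from_rank`: r = 10^(−score/10)."""
    if phred < 0:
        raise ValueError("C-score must be non-negative")
    return float(10.0 ** (-float(phred) / 10.0))


def select_deleterious(
    scores: pd.DataFrame, threshold: float, score_col: str = "cscore",
    population_col: str = "population",
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep variants with C-score strictly above threshold.

    Returns the retained subset and per-population counts (with an
    ``overall`` entry).
    """
    kept = scores[scores[score_col] > threshold]
    counts = kept[population_col].value_counts() if population_col in kept else pd.Series(dtype=int)
    counts.loc["overall"] = len(kept)
    return kept, counts


@dataclass
class AssociationResult:
    table: np.ndarray  # 2x2 [case, control] x [alt/carrier, other]
    odds_ratio: float  # inf when a control cell is zero
    odds_ratio_haldane: float
    p: float
    mode: str
    sided: str

    @property
    def or_infinite(self) -> bool:
        return np.isinf(self.odds_ratio)


def associate(
    case: CohortStats,
    control: ControlRecord,
    mode: str = "carrier",
    sided: str = "one",
    case_carriers: int | None = None,
    case_subjects: int | None = None,
) -> AssociationResult:
    """Fisher exact case–control association with odds ratio.

    ``allele`` mode contrasts allele counts: [AC, AN−AC] vs
    [AC_ctrl, AN_ctrl−AC_ctrl].  ``carrier`` mode contrasts subjects
    carrying ≥1 alternate allele; case carriers default to AC (every
    carrier heterozygous, the rare-variant situation) and control carriers
    are approximated by the control AC against AN/2 subjects, since control
    tables carry allele counts only.  One-sided tests case enrichment.
    """
    if mode == "allele":
        a, b = case.ac, case.an - case.ac
        c, d = control.ac, control.an - control.ac
    elif mode == "carrier":
        carriers = case.ac if case_carriers is None else case_carriers
        subjects = case.an // 2 if case_subjects is None else case_subjects
        ctrl_subjects = control.an // 2
        a, b = carriers, subjects - carriers
        c, d = control.ac, ctrl_subjects - control.ac
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if min(a, b, c, d) < 0 or (a + b) == 0 or (c + d) == 0:
        raise ValueError("degenerate 2x2 table")
    table = np.array([[a, b], [c, d]], dtype=int)
    alternative = "greater" if sided == "one" else "two-sided"
    p = float(sps.fisher_exact(table, alternative=alternative)[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.inf if (b == 0 or c == 0) else (a * d) / (b * c)
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return AssociationResult(table, float(odds), float(haldane), p, mode, sided)


# ---------------------------------------------------------------------------
# VCF input and the assembled cascade
# ---------------------------------------------------------------------------

def read_vcf(path) -> list[VariantSite]:
    """Read a VCF 4.2 with FORMAT AD:DP:GQ and INFO MQ / InbreedingCoeff.

    Only the first ALT allele of each record is used (the cascade treats
    sites biallelically, matching how the cohort data are consumed).
    """
    import pysam

    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            calls = {}
            for sample, sd in rec.samples.items():
                gt = sd.get("GT", (None, None))
                gt = tuple(-1 if a is None else int(a) for a in gt)
                if len(gt) == 1:
                    gt = (gt[0], -1)
                ad = sd.get("AD", (0, 0)) or (0, 0)
                ad_ref = int(ad[0] or 0)
                ad_alt = int(ad[1] or 0) if len(ad) > 1 else 0
                calls[sample] = GenotypeCall(
                    gt=gt,
                    ad_ref=ad_ref,
                    ad_alt=ad_alt,
                    dp=int(sd.get("DP") or 0),
                    gq=int(sd.get("GQ") or 0),
                )
            flt = list(rec.filter)
            vqsr = (flt == ["PASS"]) if flt else None
            mq = rec.info.get("MQ")
            inb = rec.info.get("InbreedingCoeff")
            sites.append(
                VariantSite(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(rec.alts[0]) if rec.alts else ".",
                    vqsr_pass=vqsr,
                    mq=None if mq is None else float(mq),
                    inbreeding=None if inb is None else float(inb),
                    calls=calls,
                )
            )
    return sites


def read_controls(path) -> dict[tuple[str, str], ControlRecord]:
    """Control allele-count table: variant, population, AC, AN, coverage."""
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.variant), str(r.population)): ControlRecord(
            population=str(r.population), ac=int(r.AC), an=int(r.AN),
            coverage=float(r.coverage),
        )
        for r in df.itertuples(index=False)
    }


def prioritize(
    sites: Sequence[VariantSite],
    populations: Mapping[str, str],
    controls: Mapping[tuple[str, str], ControlRecord],
    cscores: Mapping[str, float],
    cscore_threshold: float = 13.01,
    mode: str = "carrier",
    sided: str = "one",
) -> pd.DataFrame:
    """Run the full cascade and emit a per-(variant, population) table.

    Columns: variant key, population, AC/AN/AF after quality filtering,
    control AC/AN/AF, class (novel/rare/common/discard), C-score, whether
    it clears the deleteriousness threshold, odds ratio (inf flagged via
    ``or_infinite``), Haldane odds ratio and Fisher p.
    """
    pops = sorted(set(populations.values()))
    rows = []
    for site in sites:
        ok, reason = site_filter(site)
        if not ok:
            continue
        for pop in pops:
            stats = recalc_stats(site, populations, pop)
            if stats is None or stats.ac == 0:
                continue
            control = controls.get((site.key, pop))
            cls = classify(stats, control)
            score = cscores.get(site.key, float("nan"))
            row = {
                "variant": site.key,
                "population": pop,
                "AC": stats.ac,
                "AN": stats.an,
                "AF": stats.af,
                "control_AC": control.ac if control else np.nan,
                "control_AN": control.an if control else np.nan,
                "control_AF": control.af if control else np.nan,
                "class": cls,
                "cscore": score,
                "deleterious": bool(score > cscore_threshold)
                if np.isfinite(score)
                else False,
                "odds_ratio": np.nan,
                "odds_ratio_haldane": np.nan,
                "or_infinite": False,
                "p": np.nan,
            }
            if control is not None and cls != "discard":
                assoc = associate(stats, control, mode=mode, sided=sided)
                row.update(
                    odds_ratio=assoc.odds_ratio,
                    odds_ratio_haldane=assoc.odds_ratio_haldane,
                    or_infinite=assoc.or_infinite,
                    p=assoc.p,
                )
            rows.append(row)
    return pd.DataFrame(rows)
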