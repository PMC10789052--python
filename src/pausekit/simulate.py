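"""Seeded generators for every input the analysis tracks consume.

Each generator is a pure function of a :class:`SimConfig`: one root seed is
expanded into independent per-generator streams (keyed by a stable stream
id), so adding or re-running one generator never perturbs another and an
identical config reproduces bit-identical outputs.

What the generators emulate
---------------------------
* ``make_annotation`` — non-overlapping genes on both strands with 10-kb
  clear flanks, long enough (≥ 2.5 kb) that every derived window is
  non-degenerate.
* ``simulate_chip`` — fixed-length (200 bp) ChIP fragments from a mixture
  of a TSS-proximal promoter component (density ∝ pausing level) and a
  uniform component over the extended gene span, plus uniform intergenic
  background; a planted gene subset gets its expected coverage multiplied
  by ``occupancy_fold`` in the knockout group.  Fragment counts per sample
  sum exactly to the library size.
* ``simulate_counts`` — negative-binomial transcript counts
  (Var = mu + phi mu^2) with an anchor transcript whose mean is identical
  in both groups, and a planted differentially expressed subset.
* ``simulate_cohort`` — diploid genotypes with AD/DP/GQ and site-level
  VQSR/MQ/InbreedingCoeff, planted case-enriched alleles absent from the
  control allele-count table, and a stated fraction of degraded genotypes.
* ``simulate_litters`` — heterozygote-intercross litters with
  genotype-dependent lethality acting before the census and incompletely
  penetrant phenotypes among survivors.
* ``simulate_spectral`` — bait-anchored AP-MS spectral counts with dropout
  zeros and planted true interactors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pausekit.regions import DEFAULT_SCHEME, GeneModel, derive_regions

__all__ = [
    "SimConfig",
    "PlacementError",
    "make_annotation",
    "simulate_chip",
    "simulate_counts",
    "simulate_cohort",
    "simulate_litters",
    "simulate_spectral",
    "write_vcf",
]

# stable stream ids so each generator has an independent substream
_STREAMS = {
    "annotation": 11,
    "chip_genes": 21,
    "chip_sample": 22,
    "rnaseq_genes": 31,
    "rnaseq_sample": 32,
    "cohort": 41,
    "litters": 51,
    "spectral": 61,
}


class PlacementError(ValueError):
    """Raised when genes cannot be placed inside the requested genome."""


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters shared by all generators.

    Defaults are the conditions of the study design the package targets:
    three biological replicate pairs, a 60% embryonic/perinatal lethality,
    a 27.7% survivor phenotype rate, planted two-fold occupancy and
    four-fold (log2 = 2) expression effects.
    """

    seed: int = 0
    # annotation / ChIP
    n_genes: int = 200
    genome_length: int | None = None
    n_samples_per_group: int = 3
    library_size: int = 1_000_000
    pausing_level: float = 2.0
    occupancy_fold: float = 2.0
    occupancy_fraction: float = 0.05
    background_fraction: float = 0.10
    fragment_length: int = 200
    # RNA-seq
    n_transcripts: int = 2000
    de_fraction: float = 0.05
    log2fc_effect: float = 2.0
    nb_dispersion: float = 0.1
    anchor_count_mean: float = 5000.0
    # cohort
    cohort_n_cases: int = 100
    cohort_n_controls: int = 10_000
    n_sites: int = 40
    n_causal: int = 3
    causal_af: float = 0.02
    genotype_fail_rate: float = 0.05
    # litters
    litter_n: int = 2000
    litter_size: int = 8
    lethality: float = 0.6
    penetrance: float = 0.277
    wt_penetrance: float = 0.037
    # AP-MS
    n_preys: int = 200
    n_runs: int = 4
    dropout_rate: float = 0.15

    def __post_init__(self):
        fractions = {
            "occupancy_fraction": self.occupancy_fraction,
            "background_fraction": self.background_fraction,
            "de_fraction": self.de_fraction,
            "causal_af": self.causal_af,
            "genotype_fail_rate": self.genotype_fail_rate,
            "lethality": self.lethality,
            "penetrance": self.penetrance,
            "wt_penetrance": self.wt_penetrance,
            "dropout_rate": self.dropout_rate,
        }
        for name, v in fractions.items():
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "library_size": self.library_size,
            "n_transcripts": self.n_transcripts,
            "cohort_n_cases": self.cohort_n_cases,
            "cohort_n_controls": self.cohort_n_controls,
            "litter_n": self.litter_n,
        }
        for name, v in counts.items():
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.pausing_level < 0 or self.nb_dispersion < 0:
            raise ValueError("pausing_level and nb_dispersion must be >= 0")
        if self.occupancy_fold <= 0:
            raise ValueError("occupancy_fold must be positive")

    def rng(self, stream: str, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream], *extra])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_FLANK = 10_000  # clear flank per gene side, bp
_MIN_GENE = 2_500  # bp; keeps every derived window non-degenerate


def make_annotation(config: SimConfig) -> list[GeneModel]:
    """Place non-overlapping genes (with clear 10-kb flanks) on one chromosome.

    Gene lengths are uniform in [2.5, 8] kb, strands random, and each gene
    carries a simple 3-exon structure with an interior CDS.  Raises
    :class:`PlacementError` when ``genome_length`` cannot hold all genes.
    """
    rng = config.rng("annotation")
    n = config.n_genes
    if n == 0:
        return []
    lengths = rng.integers(_MIN_GENE, 8001, size=n)
    gaps = rng.integers(2 * _FLANK + 500, 2 * _FLANK + 4001, size=n)
    needed = int(lengths.sum() + gaps.sum() + _FLANK)
    if config.genome_length is not None and config.genome_length < needed:
        raise PlacementError(
            f"genome_length {config.genome_length} cannot hold {n} genes "
            f"with 10-kb flanks (needs >= {needed})"
        )
    strands = rng.choice(["+", "-"], size=n)
    if n >= 2:  # both strands always represented
        strands[0], strands[1] = "+", "-"
    genes = []
    pos = _FLANK + int(gaps[0] // 2)
    for i in range(n):
        start = pos
        end = start + int(lengths[i])
        l = end - start
        # 3 exons: two terminal blocks plus one interior block
        e1 = (start, start + int(rng.integers(200, 500)))
        mid = start + l // 2
        e2 = (mid, mid + int(rng.integers(200, 500)))
        e3 = (end - int(rng.integers(200, 500)), end)
        cds = (e1[1] - 100, e3[0] + 100)
        genes.append(
            GeneModel(
                gene_id=f"G{i:05d}",
                chrom="chrS",
                start=start,
                end=end,
                strand=str(strands[i]),
                exons=(e1, e2, e3),
                cds=cds,
            )
        )
        pos = end + int(gaps[i])
    return genes


# ---------------------------------------------------------------------------
# ChIP fragments
# ---------------------------------------------------------------------------

def chip_truth(config: SimConfig, genes: list[GeneModel]) -> pd.DataFrame:
    """Per-gene ground truth shared by all ChIP samples.

    ``expr`` is the gene's relative coverage level; ``planted`` marks the
    subset whose expected fragment count is multiplied by
    ``occupancy_fold`` in the KO group.  Expected promoter and body
    densities are in relative units (per bp, before library scaling).
    """
    rng = config.rng("chip_genes")
    n = len(genes)
    expr = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    n_planted = int(round(config.occupancy_fraction * n))
    planted = np.zeros(n, dtype=bool)
    if n_planted:
        planted[rng.choice(n, size=n_planted, replace=False)] = True
    span = np.array([g.length + 2400 for g in genes], dtype=float)  # TSS−400 … TES+2000
    prom_extra = config.pausing_level * 500.0
    weight = expr * (span + prom_extra)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "expr": expr,
            "planted": planted,
            "span": span,
            "weight": weight,
            "promoter_density": expr * (1.0 + config.pausing_level),
            "body_density": expr,
        }
    ).set_index("gene_id")


def simulate_chip(
    genes: list[GeneModel],
    config: SimConfig,
    group: str = "wt",
    sample_index: int = 0,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one sample's fragment set; returns (fragments BED frame, truth).

    Exactly ``library_size`` fragments are drawn: a multinomial split over
    genes and intergenic background, then within each gene a mixture of a
    uniform component over [TSS − 400, TES + 2000) and an extra
    promoter-window component whose share is pausing_level·500 / (span +
    pausing_level·500).  In the KO group planted genes' weights are
    multiplied by ``occupancy_fold``.  Fragments are ``fragment_length`` bp
    centered on the drawn midpoint.
    """
    if group not in ("wt", "ko"):
        raise ValueError("group must be 'wt' or 'ko'")
    if truth is None:
        truth = chip_truth(config, genes)
    rng = config.rng("chip_sample", 0 if group == "wt" else 1, sample_index)
    fold = np.where(
        (group == "ko") & truth["planted"].to_numpy(), config.occupancy_fold, 1.0
    )
    genome_length = config.genome_length or (
        max(g.end for g in genes) + _FLANK if genes else 1_000_000
    )
    # WT gene shares fill (1 - background_fraction) of the library; the KO
    # fold change scales planted shares directly and the intergenic
    # background absorbs the difference, so at fixed sequencing depth the
    # planted genes' expected counts are exactly fold x their WT counts
    weight = truth["weight"].to_numpy()
    if genes:
        share = weight / weight.sum() * (1.0 - config.background_fraction) * fold
        bg_share = 1.0 - share.sum()
        if bg_share < -1e-9:
            raise ValueError(
                "occupancy inflation exceeds the background reservoir; "
                "raise background_fraction or lower occupancy_fold/fraction"
            )
        bg_share = max(bg_share, 0.0)
    else:
        share, bg_share = np.array([]), 1.0
    w = np.append(share, bg_share)
    counts = rng.multinomial(config.library_size, w)
    half = config.fragment_length // 2
    mids_all = []
    prom_share = (config.pausing_level * 500.0) / (
        truth["span"].to_numpy() + config.pausing_level * 500.0
    )
    for i, g in enumerate(genes):
        c = int(counts[i])
        if c == 0:
            continue
        n_prom = rng.binomial(c, prom_share[i])
        regs = derive_regions(g, DEFAULT_SCHEME).intervals
        ps, pe = regs["promoter"]
        # uniform component over the extended span in genome coordinates
        if g.strand == "+":
            us, ue = g.tss - 400, g.tes + 2000
        else:
            us, ue = g.tes - 2000, g.tss + 400
        mids = np.concatenate(
            [
                rng.integers(ps, pe, size=n_prom),
                rng.integers(us, ue, size=c - n_prom),
            ]
        )
        mids_all.append(mids)
    n_bg = int(counts[-1])
    if n_bg:
        mids_all.append(rng.integers(half, genome_length - half, size=n_bg))
    mids = np.concatenate(mids_all) if mids_all else np.array([], dtype=int)
    frags = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": np.maximum(mids - half, 0),
            "end": mids + half,
        }
    )
    out_truth = truth.copy()
    out_truth["fold"] = fold
    out_truth["expected_count"] = config.library_size * share if genes else 0.0
    return frags, out_truth


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    df = fragments.copy()
    df["name"] = "."
    df["score"] = 0
    df["strand"] = "."
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, Var = mu + phi mu^2) via the gamma–Poisson mixture."""
    if phi < 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


ANCHOR_ID = "anchor_rn7sk"


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial transcript counts for two groups of replicates.

    Returns (counts, truth, groups).  The anchor transcript (the *Rn7sk*
    role) has identical mean in both groups; a ``de_fraction`` subset of
    the others has its group-2 (ko) mean scaled by 2^±log2fc_effect with a
    random sign.  Most transcripts map to their own gene; every 20th shares
    its gene with the previous transcript so gene-level rollups are
    exercised.
    """
    if config.n_samples_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = config.rng("rnaseq_genes")
    n = config.n_transcripts
    tx = [f"T{i:05d}" for i in range(n)] + [ANCHOR_ID]
    base = rng.lognormal(mean=np.log(50.0), sigma=1.2, size=n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(n)
    lfc[de_idx] = sign * config.log2fc_effect
    mu_wt = np.append(base, config.anchor_count_mean)
    mu_ko = np.append(base * 2.0 ** lfc, config.anchor_count_mean)
    counts = {}
    groups = {}
    for g, mu in (("wt", mu_wt), ("ko", mu_ko)):
        for r in range(config.n_samples_per_group):
            srng = config.rng("rnaseq_sample", 0 if g == "wt" else 1, r)
            name = f"{g}{r + 1}"
            counts[name] = _nb_draw(srng, mu, config.nb_dispersion)
            groups[name] = g
    gene_ids = []
    for i in range(n):
        gene_ids.append(f"GE{i - 1:05d}" if i % 20 == 19 else f"GE{i:05d}")
    gene_ids.append("GE_anchor")
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mu_wt": mu_wt,
            "mu_ko": mu_ko,
            "log2fc": np.append(lfc, 0.0),
            "is_de": np.append(lfc != 0, False),
        },
        index=pd.Index(tx, name="transcript"),
    )
    return (
        pd.DataFrame(counts, index=truth.index),
        truth,
        pd.Series(groups, name="group"),
    )


# ---------------------------------------------------------------------------
# cohort genotypes
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig):
    """Diploid case cohort plus a control allele-count table.

    Returns ``(sites, populations, controls, truth)`` where ``sites`` is a
    list of :class:`pausekit.variants.VariantSite`, ``populations`` maps
    subject → population (cases split between 'EUR' and 'MEX'),
    ``controls`` maps (variant key, population) → ControlRecord, and
    ``truth`` flags the planted case-enriched sites (case AF =
    ``causal_af``, control AF = 0, control coverage 45X).  A
    ``genotype_fail_rate`` fraction of calls is degraded so it fails one
    genotype-quality clause; one site is non-PASS and one control locus is
    below the 30X coverage gate.
    """
    from pausekit.variants import ControlRecord, GenotypeCall, VariantSite

    if config.cohort_n_cases < 1 or config.cohort_n_controls < 1:
        raise ValueError("cohort sizes must be >= 1")
    rng = config.rng("cohort")
    n_cases = config.cohort_n_cases
    subjects = [f"S{i:04d}" for i in range(n_cases)]
    populations = {s: ("EUR" if i < n_cases // 2 else "MEX") for i, s in enumerate(subjects)}
    n_sites = config.n_sites
    n_causal = min(config.n_causal, n_sites) if config.causal_af > 0 else 0
    causal = np.zeros(n_sites, dtype=bool)
    causal[:n_causal] = True
    shared_af = rng.uniform(0.005, 0.2, size=n_sites)
    sites = []
    controls: dict[tuple[str, str], ControlRecord] = {}
    truth_rows = []
    an_ctrl = 2 * config.cohort_n_controls
    for j in range(n_sites):
        pos = 1000 + 10 * j
        af = config.causal_af if causal[j] else shared_af[j]
        alt_alleles = rng.binomial(2, af, size=n_cases)
        calls = {}
        for i, s in enumerate(subjects):
            na = int(alt_alleles[i])
            dp = int(rng.poisson(60)) + 12
            if na == 0:
                ad_alt = 0
            elif na == 1:
                ad_alt = int(rng.binomial(dp, 0.5))
            else:
                ad_alt = int(rng.binomial(dp, 0.98))
            gq = int(rng.integers(40, 100))
            if rng.random() < config.genotype_fail_rate:
                which = rng.integers(3)
                if which == 0:
                    dp = int(rng.integers(1, 11))  # DP <= 10
                    ad_alt = min(ad_alt, dp)
                elif which == 1:
                    gq = int(rng.integers(0, 21))  # GQ <= 20
                elif na > 0:
                    ad_alt = max(0, int(dp * 0.2))  # alt fraction <= 25%
            calls[s] = GenotypeCall(
                gt=(0, 0) if na == 0 else ((0, 1) if na == 1 else (1, 1)),
                ad_ref=dp - ad_alt,
                ad_alt=ad_alt,
                dp=dp,
                gq=gq,
            )
        vqsr = j != n_sites - 1 or n_sites < 3  # last site non-PASS (when enough sites)
        site = VariantSite(
            chrom="chr16",
            pos=pos,
            ref="C",
            alt="T",
            vqsr_pass=bool(vqsr),
            mq=float(rng.uniform(40, 60)),
            inbreeding=float(rng.uniform(-0.05, 0.05)),
            calls=calls,
        )
        sites.append(site)
        low_cov = (not causal[j]) and j == n_sites - 2 and n_sites >= 3
        coverage = 12.0 if low_cov else 45.0
        for pop in ("EUR", "MEX"):
            ctrl_ac = 0 if causal[j] else int(rng.binomial(an_ctrl, shared_af[j]))
            controls[(site.key, pop)] = ControlRecord(
                population=pop, ac=ctrl_ac, an=an_ctrl, coverage=coverage
            )
        truth_rows.append(
            {
                "variant": site.key,
                "causal": bool(causal[j]),
                "case_af": af,
                "vqsr_pass": bool(vqsr),
                "control_coverage": coverage,
            }
        )
    return sites, populations, controls, pd.DataFrame(truth_rows).set_index("variant")


def write_vcf(sites, subjects, path) -> None:
    """Write sites as a minimal VCF 4.2 with FORMAT GT:AD:DP:GQ."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr16,length=100000000>",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##INFO=<ID=InbreedingCoeff,Number=1,Type=Float,Description="Inbreeding coefficient">',
        '##FILTER=<ID=VQSRTrancheSNP,Description="Failed VQSR">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects),
    ]
    for site in sites:
        filt = "PASS" if site.vqsr_pass else "VQSRTrancheSNP"
        info = f"MQ={site.mq:.2f};InbreedingCoeff={site.inbreeding:.3f}"
        fields = []
        for s in subjects:
            c = site.calls[s]
            gt = "./." if c.missing else f"{c.gt[0]}/{c.gt[1]}"
            fields.append(f"{gt}:{c.ad_ref},{c.ad_alt}:{c.dp}:{c.gq}")
        lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t100\t{filt}\t"
            f"{info}\tGT:AD:DP:GQ\t" + "\t".join(fields)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_controls(controls, path) -> None:
    rows = [
        {"variant": key[0], "population": key[1], "AC": rec.ac, "AN": rec.an,
         "coverage": rec.coverage}
        for key, rec in controls.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# litters
# ---------------------------------------------------------------------------

def simulate_litters(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Heterozygote-intercross litters with KO lethality and phenotypes.

    Offspring genotypes are drawn 1:2:1; homozygous-null pups are removed
    with probability ``lethality`` before the census; survivors develop the
    phenotype with probability ``penetrance`` (KO) or ``wt_penetrance``
    (WT/het background).  Returns a per-litter survivor/phenotype count
    table and the planted truth.
    """
    if config.litter_n < 1:
        raise ValueError("litter_n must be >= 1")
    rng = config.rng("litters")
    n_litters = int(np.ceil(config.litter_n / config.litter_size))
    sizes = np.full(n_litters, config.litter_size)
    sizes[-1] = config.litter_n - config.litter_size * (n_litters - 1)
    rows = []
    for li, size in enumerate(sizes):
        n_wt, n_het, n_ko = rng.multinomial(size, [0.25, 0.5, 0.25])
        ko_surv = int(rng.binomial(n_ko, 1.0 - config.lethality))
        rows.append(
            {
                "litter": li,
                "wt": int(n_wt),
                "het": int(n_het),
                "ko": ko_surv,
                "ko_conceived": int(n_ko),
                "wt_pheno": int(rng.binomial(n_wt, config.wt_penetrance)),
                "het_pheno": int(rng.binomial(n_het, config.wt_penetrance)),
                "ko_pheno": int(rng.binomial(ko_surv, config.penetrance)),
            }
        )
    truth = {
        "lethality": config.lethality,
        "penetrance": config.penetrance,
        "expected_ko_fraction": 0.25 * (1 - config.lethality)
        / (0.75 + 0.25 * (1 - config.lethality)),
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# AP-MS spectral counts
# ---------------------------------------------------------------------------

BAIT_ID = "BAIT"


def simulate_spectral(
    config: SimConfig, conditions: tuple[str, ...] = ("wt", "mutant", "control")
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Bait-anchored spectral-count matrix with dropout zeros.

    20% of preys are planted true interactors: enriched 4× over control in
    bait runs, and halved in the mutant-bait runs for half of them (lost
    interactions).  Counts are Poisson around the per-condition mean with a
    ``dropout_rate`` chance of recording 0.  Returns (matrix, run →
    condition labels, truth).
    """
    rng = config.rng("spectral")
    n = config.n_preys
    preys = [f"P{i:04d}" for i in range(n)]
    base = rng.lognormal(np.log(8.0), 0.6, size=n)
    interactor = np.zeros(n, dtype=bool)
    interactor[: n // 5] = True
    lost = np.zeros(n, dtype=bool)
    lost[: n // 10] = True  # half of the interactors lose the mutant interaction
    cols = {}
    labels = {}
    for cond in conditions:
        mult = np.ones(n)
        if cond in ("wt", "mutant"):
            mult = np.where(interactor, 4.0, 1.0)
            if cond == "mutant":
                mult = np.where(lost, mult / 4.0, mult)
        for r in range(config.n_runs):
            name = f"{cond}{r + 1}"
            counts = rng.poisson(base * mult).astype(float)
            drop = rng.random(n) < config.dropout_rate
            counts[drop] = 0.0
            cols[name] = counts
            labels[name] = cond
    matrix = pd.DataFrame(cols, index=preys)
    # one bait-level scale per purification; comparable across conditions so
    # that dividing by it puts every run on a common per-bait scale
    bait_counts = {
        name: float(rng.poisson(150) + 50) for name in matrix.columns
    }
    matrix.loc[BAIT_ID] = pd.Series(bait_counts)
    truth = pd.DataFrame(
        {"interactor": interactor, "lost_in_mutant": lost}, index=preys
    )
    return matrix, pd.Series(labels, name="condition"), truth
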