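"""Transcript-level differential expression with anchor-gene normalization.

Instead of composition-based scaling (TMM), samples are normalized on a
single anchor transcript assumed invariant between groups — the role played
by *Rn7sk*, which is transcribed by Pol III and therefore independent of
the Pol II pool the experiment perturbs.  The per-sample factor is the
ratio of the sample's anchor log2 CPM to the across-sample mean anchor
log2 CPM, applied through the effective library size.

Testing is a per-transcript negative-binomial likelihood-ratio test
(Var = mu + phi * mu^2).  The dispersion phi is a method-of-moments
estimate shrunk 50/50 toward the across-transcript median, then held fixed
while group means are fitted by Newton iteration on the log scale with a
log-effective-library offset; the deviance difference is referred to
chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from pausekit.stats import bh_fdr

__all__ = [
    "CountMatrix",
    "cpm_filter",
    "anchor_normalize",
    "fit_nb_lrt",
    "summarize_genes",
    "GeneSummary",
]


@dataclass
class CountMatrix:
    """Raw transcript × sample counts plus design metadata.

    ``groups`` maps sample name → group label; ``ref_group`` names the
    baseline (WT) label.  Library sizes default to column sums.
    """

    counts: pd.DataFrame
    groups: pd.Series
    anchor: str
    tx2gene: pd.Series | None = None
    ref_group: str | None = None
    lib_sizes: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.anchor not in self.counts.index:
            raise ValueError(f"anchor {self.anchor!r} missing from count matrix")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        if self.ref_group is None:
            self.ref_group = sorted(self.groups.unique())[0]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def cpm(self) -> pd.DataFrame:
        return self.counts.div(self.lib_sizes, axis=1) * 1e6


def cpm_filter(cm: CountMatrix, threshold: float = 1.0) -> CountMatrix:
    """Drop transcripts whose mean CPM across all samples is below threshold.

    The strict reading is kept: a transcript at exactly the threshold is
    retained ("less than" removed).  The anchor is exempt but must itself
    pass, otherwise it cannot support normalization and an error is raised.
    """
    mean_cpm = cm.cpm().mean(axis=1)
    if mean_cpm[cm.anchor] < threshold:
        raise ValueError(
            f"anchor {cm.anchor!r} mean CPM {mean_cpm[cm.anchor]:.3g} below "
            f"filter threshold {threshold}; anchor unusable"
        )
    keep = mean_cpm >= threshold
    keep[cm.anchor] = True
    return replace(cm, counts=cm.counts.loc[keep])


def anchor_normalize(cm: CountMatrix) -> pd.Series:
    """Per-sample factors from the anchor transcript's log2 CPM.

    f_s = log2CPM_s(anchor) / mean_s(log2CPM(anchor)); all factors are 1
    when the anchor's relative abundance is identical across samples.  The
    printed form is a ratio of log2 CPMs (not a log-ratio), which is only
    well defined for anchor CPM > 1 (positive log2); lower anchor abundance
    raises.  Factors act through the effective library size
    ``lib_sizes * f``: raising a sample's anchor count raises its factor and
    so deflates that sample's normalized expression.
    """
    anchor_counts = cm.counts.loc[cm.anchor]
    if (anchor_counts <= 0).any():
        raise ValueError("anchor count must be positive in every sample")
    cpm = anchor_counts / cm.lib_sizes * 1e6
    if (cpm <= 1).any():
        bad = list(cpm.index[cpm <= 1])
        raise ValueError(
            f"anchor CPM <= 1 in samples {bad}; the log2-CPM ratio is ill-defined"
        )
    l2 = np.log2(cpm.astype(float))
    return l2 / l2.mean()


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; y, mu are (n, k), phi is (n,)."""
    r = 1.0 / phi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + y * np.log(mu / (mu + r))
            + r * np.log(r / (mu + r))
        )
        ll = np.where((y == 0) & (mu == 0), 0.0, ll)
    return ll.sum(axis=1)


def _fit_nb_intercept(
    y: np.ndarray, log_lib: np.ndarray, phi: np.ndarray, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """MLE of a single log-scale intercept per row with library offsets.

    Solves sum_j (y_ij - mu_ij) / (1 + phi_i mu_ij) = 0 for
    mu_ij = exp(beta_i + log_lib_j) by Newton iteration with Fisher scoring.
    Rows with all-zero counts get beta = -inf and log-likelihood 0 (the
    boundary supremum).  Returns (beta, loglik).
    """
    n, k = y.shape
    total = y.sum(axis=1)
    pos = total > 0
    beta = np.full(n, -np.inf)
    ll = np.zeros(n)
    if pos.any():
        yp = y[pos]
        ph = phi[pos]
        b = np.log(yp.sum(axis=1) / np.exp(log_lib).sum())
        for _ in range(100):
            mu = np.exp(b[:, None] + log_lib[None, :])
            denom = 1.0 + ph[:, None] * mu
            score = ((yp - mu) / denom).sum(axis=1)
            info = (mu / denom).sum(axis=1)
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -5, 5)
            b = b + step
            if np.max(np.abs(step)) < tol:
                break
        beta[pos] = b
        mu = np.exp(b[:, None] + log_lib[None, :])
        ll[pos] = _nb_loglik(yp, mu, ph)
    return beta, ll


def estimate_dispersion(
    y: np.ndarray, eff_lib: np.ndarray, group_idx: Sequence[np.ndarray]
) -> np.ndarray:
    """Moment dispersion per transcript, shrunk 50/50 to the overall median.

    Counts are scaled to a common (geometric-mean) library before the
    within-group moment estimate phi = (s^2 - m) / m^2; negative estimates
    floor at 0 before shrinkage.
    """
    ref = np.exp(np.mean(np.log(eff_lib)))
    z = y * (ref / eff_lib)[None, :]
    num = np.zeros(y.shape[0])
    den = 0.0
    for idx in group_idx:
        if len(idx) < 2:
            continue
        m = z[:, idx].mean(axis=1)
        v = z[:, idx].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (v - m) / np.square(m)
        phi_g = np.where(np.isfinite(phi_g), phi_g, 0.0)
        num += np.maximum(phi_g, 0.0) * (len(idx) - 1)
        den += len(idx) - 1
    if den == 0:
        raise ValueError("need at least 2 samples in some group for dispersion")
    phi = num / den
    med = np.median(phi)
    return 0.5 * phi + 0.5 * med


def fit_nb_lrt(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-transcript NB likelihood-ratio test between the two groups.

    Returns a DataFrame indexed by transcript with log2 fold change
    (non-reference vs reference group), raw p, BH q, direction
    ('up'/'down'/'ns' at the given FDR) and the dispersion used.
    """
    labels = sorted(cm.groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    ref = cm.ref_group
    alt = [l for l in labels if l != ref][0]
    cols = np.array(cm.samples)
    idx_ref = np.where(cm.groups[cols].to_numpy() == ref)[0]
    idx_alt = np.where(cm.groups[cols].to_numpy() == alt)[0]
    if len(idx_ref) < 2 or len(idx_alt) < 2:
        raise ValueError("each group needs at least 2 samples")
    if factors is None:
        factors = pd.Series(1.0, index=cols)
    eff_lib = (cm.lib_sizes * factors)[cols].to_numpy(dtype=float)
    y = cm.counts[cols].to_numpy(dtype=float)
    phi = np.maximum(estimate_dispersion(y, eff_lib, [idx_ref, idx_alt]), 1e-8)
    log_lib = np.log(eff_lib)
    b_ref, ll_ref = _fit_nb_intercept(y[:, idx_ref], log_lib[idx_ref], phi)
    b_alt, ll_alt = _fit_nb_intercept(y[:, idx_alt], log_lib[idx_alt], phi)
    _, ll_null = _fit_nb_intercept(y, log_lib, phi)
    lr = np.maximum(2.0 * (ll_ref + ll_alt - ll_null), 0.0)
    p = sps.chi2.sf(lr, df=1)
    p = np.where(lr == 0, 1.0, p)
    q = bh_fdr(p)
    with np.errstate(invalid="ignore"):
        log2fc = (b_alt - b_ref) / np.log(2)
    direction = np.where(
        q < fdr, np.where(log2fc > 0, "up", "down"), "ns"
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q, "direction": direction, "phi": phi},
        index=cm.counts.index,
    )


@dataclass
class GeneSummary:
    """Gene-level rollup of significant transcripts."""

    up_genes: set[str]
    down_genes: set[str]
    both_genes: set[str] = field(init=False)
    union_genes: set[str] = field(init=False)
    n_sig_transcripts: int = 0
    percent_up: float = 0.0
    percent_down: float = 0.0

    def __post_init__(self):
        self.both_genes = self.up_genes & self.down_genes
        self.union_genes = self.up_genes | self.down_genes

    @property
    def union_size(self) -> int:
        return len(self.union_genes)


def summarize_genes(
    de: pd.DataFrame, tx2gene: Mapping[str, str], fdr: float = 0.05
) -> GeneSummary:
    """Build unique up/down/both gene sets from significant transcripts.

    Percentages of up/down transcripts among all significant transcripts are
    reported to one decimal.  A significant transcript without a gene
    mapping is an error.
    """
    sig = de[de["q"] < fdr]
    missing = [t for t in sig.index if t not in tx2gene]
    if missing:
        raise KeyError(f"significant transcripts without gene mapping: {missing}")
    up_tx = sig.index[sig["log2fc"] > 0]
    down_tx = sig.index[sig["log2fc"] < 0]
    summary = GeneSummary(
        up_genes={tx2gene[t] for t in up_tx},
        down_genes={tx2gene[t] for t in down_tx},
        n_sig_transcripts=len(sig),
    )
    if len(sig):
        summary.percent_up = round(100.0 * len(up_tx) / len(sig), 1)
        summary.percent_down = round(100.0 * len(down_tx) / len(sig), 1)
    return summary
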