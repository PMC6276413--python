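"""Pre-analysis genetic quality checks.

Two checks run before any association work:

* Hardy-Weinberg equilibrium per SNP, via both the 1-df chi-square
  goodness-of-fit test and the conditional exact test (probability of the
  heterozygote count given the allele counts; the p-value sums the
  probabilities of all outcomes no more likely than the observed one).
* An AMOVA-style homogeneity test over the whole panel: total squared
  genotype distance is partitioned within/among groups, a Phi statistic
  (among-group share of the variance components) is formed, and its
  significance comes from permuting group labels.

The grouping factor for AMOVA is a required input; for a plain
"is this sample homogeneous" check, :func:`homogeneity_check` repeatedly
splits the cohort into random halves.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd
from scipy import stats

from .synthcohort import GenotypeMatrix


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

@dataclass
class HweResult:
    snp: str
    n0: int
    n1: int
    n2: int
    chi2: float
    chi2_p: float
    exact_p: float
    in_hwe: bool
    monomorphic: bool = False


def _hwe_chi2(n0: int, n1: int, n2: int) -> tuple[float, float]:
    n = n0 + n1 + n2
    p_hat = (2 * n0 + n1) / (2 * n)
    q_hat = 1 - p_hat
    expected = np.array([p_hat ** 2, 2 * p_hat * q_hat, q_hat ** 2]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _log_het_prob(n_het: int, n_rare: int, n: int) -> float:
    """log P(heterozygote count | allele counts) under HWE.

    ``n_rare`` is the minor allele count, ``n`` the number of diploid
    subjects.  Standard conditional distribution:
    P(nAB) = nA! nB! n! 2^nAB / ( (2n)! nAA! nAB! nBB! ) with
    nAA=(nA-nAB)/2, nBB=(nB-nAB)/2.
    """
    n_common = 2 * n - n_rare
    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = (n_common - n_het) // 2
    return (
        lgamma(n_rare + 1) + lgamma(n_common + 1) + lgamma(n + 1)
        + n_het * log(2.0)
        - lgamma(2 * n + 1) - lgamma(n_hom_rare + 1) - lgamma(n_het + 1)
        - lgamma(n_hom_common + 1)
    )


def hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Conditional exact HWE p-value: sum of the probabilities of all
    heterozygote counts (given the allele counts) whose probability does not
    exceed that of the observed count."""
    n = n0 + n1 + n2
    n_rare = min(2 * n0 + n1, 2 * n2 + n1)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.array([_log_het_prob(int(h), n_rare, n) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n1][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_test(counts: tuple[int, int, int], snp: str = "", alpha: float = 0.05,
             ) -> HweResult:
    """HWE test from genotype counts (n0, n1, n2 alternate-allele dosage).

    A monomorphic SNP (one allele absent) trivially satisfies HWE: both
    p-values are 1 and the result is flagged.
    """
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0 or n0 + n1 + n2 < 1:
        raise ValueError(f"invalid genotype counts {counts}")
    n_rare = min(2 * n0 + n1, 2 * n2 + n1)
    if n_rare == 0:
        return HweResult(snp, n0, n1, n2, 0.0, 1.0, 1.0, True, monomorphic=True)
    chi2, chi2_p = _hwe_chi2(n0, n1, n2)
    exact_p = hwe_exact_p(n0, n1, n2)
    return HweResult(snp, n0, n1, n2, chi2, chi2_p, exact_p,
                     in_hwe=exact_p >= alpha)


def hwe_table(gm: GenotypeMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP HWE results over a genotype matrix."""
    rows = []
    for rsid in gm.genotypes.columns:
        g = gm.genotypes[rsid].dropna().to_numpy(dtype=int)
        counts = (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        rows.append(vars(hwe_test(counts, snp=rsid, alpha=alpha)))
    return pd.DataFrame(rows).set_index("snp")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    phi: float
    p_value: float
    n_permutations: int
    ss_among: float
    ss_within: float
    ss_total: float


def _group_ss(geno: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    """Within-group sum of squares: sum over groups and SNPs of squared
    deviations from the group mean (equals the pairwise squared-distance
    form sum_{i<j in g} d_ij^2 / n_g)."""
    ssw = 0.0
    for u in uniq:
        sub = geno[labels == u]
        ssw += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return ssw


def amova(gm: GenotypeMatrix, grouping, n_permutations: int = 1000,
          seed: int | None = None) -> AmovaResult:
    """AMOVA homogeneity test of a grouping factor over the SNP panel.

    Distance between two subjects is the squared difference of alternate-
    allele counts summed over SNPs.  Variance components follow the standard
    one-level AMOVA expected mean squares; Phi is the among-group share.
    The p-value is the proportion of label permutations with
    Phi_perm >= Phi_obs, with an add-one correction so p is never 0.

    Missing genotypes are mean-imputed per SNP before distance computation.
    """
    labels = pd.Series(grouping)
    labels = labels.reindex(gm.genotypes.index) if labels.index.size else labels
    if labels.isna().any():
        raise ValueError("every subject needs a group label")
    lab = labels.to_numpy()
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 subjects")

    geno = gm.genotypes.to_numpy(dtype=float)
    col_mean = np.nanmean(geno, axis=0)
    nan_mask = np.isnan(geno)
    if nan_mask.any():
        geno = np.where(nan_mask, col_mean[None, :], geno)

    n = geno.shape[0]
    g = len(uniq)
    sst = float(((geno - geno.mean(axis=0)) ** 2).sum())

    def components(labels_arr: np.ndarray) -> tuple[float, float, float]:
        ssw = _group_ss(geno, labels_arr, uniq)
        ssa = sst - ssw
        msw = ssw / (n - g)
        msa = ssa / (g - 1)
        n0 = (n - (counts ** 2).sum() / n) / (g - 1)
        sigma_w = msw
        sigma_a = (msa - msw) / n0
        denom = sigma_a + sigma_w
        phi = sigma_a / denom if denom > 0 else 0.0
        return phi, sigma_a, sigma_w

    if sst == 0.0:
        return AmovaResult(0.0, 0.0, 0.0, 1.0, n_permutations, 0.0, 0.0, 0.0)

    phi_obs, sigma_a, sigma_w = components(lab)
    ssw_obs = _group_ss(geno, lab, uniq)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab)
        phi_perm, _, _ = components(perm)
        if phi_perm >= phi_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return AmovaResult(sigma_a, sigma_w, phi_obs, p, n_permutations,
                       ss_among=sst - ssw_obs, ss_within=ssw_obs, ss_total=sst)


def homogeneity_check(gm: GenotypeMatrix, n_splits: int = 10,
                      n_permutations: int = 200, seed: int | None = None,
                      ) -> pd.DataFrame:
    """Repeated random-halves AMOVA: the default way to 'corroborate the
    homogeneity of the sample' when no natural grouping factor exists."""
    rng = np.random.default_rng(seed)
    n = gm.genotypes.shape[0]
    rows = []
    for i in range(n_splits):
        half = rng.permutation(n) < n // 2
        labels = pd.Series(np.where(half, "A", "B"), index=gm.genotypes.index)
        res = amova(gm, labels, n_permutations=n_permutations,
                    seed=int(rng.integers(2 ** 31)))
        rows.append({"split": i, "phi": res.phi, "p_value": res.p_value})
    return pd.DataFrame(rows).set_index("split")
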