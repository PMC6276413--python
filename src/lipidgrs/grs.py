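"""Phenotype-driven genetic risk scores.

For each lipid (TC, LDL-c, HDL-c, TG) the panel of SNPs is funnelled
through four stages:

1. **ANOVA prescreen** -- one-way ANOVA of the lipid across the three
   genotype groups; SNPs clearly unassociated (p > 0.25) are discarded.
2. **Risk coding** -- the remaining SNPs' genotypes are collapsed to a
   binary risk/nonrisk coding from the observed group means, using pairwise
   post hoc tests (Bonferroni-adjusted pooled t when Levene's test finds the
   variances homogeneous, Dunnett's T3-style Welch comparisons otherwise).
   The *risk* direction is a higher mean for TC/LDL-c/TG and a lower mean
   for HDL-c.  The most adverse genotype anchors the risk category, and any
   genotype not significantly different from the anchor joins it ("genotypes
   with similar effects are grouped").  This accommodates non-additive
   patterns such as heterozygote advantage (both homozygotes at risk).
3. **Binary t selection** -- a pooled two-sample t-test of the lipid between
   the risk and nonrisk categories; SNPs with at least a marginal trend
   (p < 0.10) in the adverse direction are retained.
4. **Prevalence filter** -- SNPs in which either category holds < 10% of
   subjects are dropped to avoid model instability.

Each lipid's genetic risk score is the per-subject count of risk genotypes
over its retained SNPs.  Every drop is recorded in an audit log with the
stage and a machine-readable reason.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthcohort import GenotypeMatrix

#: +1 = higher mean is adverse (TC, LDL-c, TG); -1 = lower mean is adverse.
RISK_DIRECTION = {"tc": 1, "ldl": 1, "hdl": -1, "tg": 1}

LIPIDS = ("tc", "ldl", "hdl", "tg")


@dataclass
class GrsConfig:
    """Thresholds of the four stages (defaults are the procedure's
    canonical values) and handling knobs for the gaps the procedure leaves
    open."""

    alpha_keep: float = 0.25          # prescreen keeps p <= alpha_keep
    alpha_posthoc: float = 0.05       # "similar effects" = p >= this vs anchor
    alpha_levene: float = 0.05        # variance homogeneity gate
    alpha_trend: float = 0.10         # t-selection keeps p < alpha_trend
    min_prevalence: float = 0.10      # both categories need >= this share
    anchor: str = "adverse"           # or "favorable": grouping reference
    min_group: int = 2                # genotype groups smaller than this merge
    missing: str = "complete-case"    # or "observed": GRS over observed SNPs


@dataclass
class RiskCoding:
    """Binary risk/nonrisk coding of one SNP for one lipid, with the audit
    statistics of every stage that produced it."""

    snp: str
    lipid: str
    genotype_map: Dict[int, int]              # genotype -> 1 (risk) / 0 (nonrisk)
    anova_f: float = np.nan
    anova_p: float = np.nan
    levene_p: float = np.nan
    posthoc_method: str = ""
    posthoc_p: Dict[tuple, float] = field(default_factory=dict)
    t_stat: float = np.nan
    t_p: float = np.nan
    risk_prevalence: float = np.nan

    @property
    def risk_genotypes(self) -> List[int]:
        return sorted(g for g, r in self.genotype_map.items() if r == 1)

    @property
    def nonrisk_genotypes(self) -> List[int]:
        return sorted(g for g, r in self.genotype_map.items() if r == 0)


@dataclass
class GrsResult:
    """Output bundle of the four-lipid pipeline."""

    grs: pd.DataFrame                          # subject x grs_<lipid>
    codings: Dict[str, List[RiskCoding]]       # lipid -> retained codings
    audit: pd.DataFrame                        # snp x lipid stage log
    venn: dict                                 # set algebra over lipid SNP sets
    stage_counts: pd.DataFrame                 # per-lipid and union funnel


# ---------------------------------------------------------------------------
# stage 1: ANOVA prescreen
# ---------------------------------------------------------------------------

def anova_prescreen(values: np.ndarray, genotypes: np.ndarray,
                    alpha_keep: float = 0.25):
    """One-way fixed-effects ANOVA of the lipid across genotype groups.

    Returns ``(keep, F, p, reason)``.  SNPs with fewer than two genotype
    groups of >= 2 subjects cannot be tested and are auto-discarded.
    """
    groups = [values[genotypes == g] for g in np.unique(genotypes)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        return False, np.nan, np.nan, "too_few_genotype_groups"
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
        return False, 0.0, 1.0, "prescreen_p_above_threshold"
    f_stat, p = stats.f_oneway(*groups)
    keep = bool(p <= alpha_keep)
    return keep, float(f_stat), float(p), "" if keep else "prescreen_p_above_threshold"


# ---------------------------------------------------------------------------
# stage 2: risk coding via post hoc grouping
# ---------------------------------------------------------------------------

def _pairwise_pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(p) if np.isfinite(p) else 1.0


def _pairwise_welch_t(a: np.ndarray, b: np.ndarray) -> float:
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p) if np.isfinite(p) else 1.0


def code_genotype_risk(values: np.ndarray, genotypes: np.ndarray, lipid: str,
                       config: GrsConfig | None = None) -> RiskCoding | None:
    """Collapse the three genotype groups of one SNP to risk/nonrisk.

    Procedure: Levene's test chooses the post hoc family (Bonferroni-
    adjusted pooled t under homogeneous variances, Dunnett's T3-style Welch
    comparisons with a Sidak-type multiplicity adjustment otherwise); the
    genotype with the most adverse mean anchors the risk category; any
    genotype whose comparison against the anchor is non-significant joins
    it; the rest are nonrisk.  Returns ``None`` when no genotype separates
    from the anchor (all genotypes "similar": the SNP cannot be coded).

    Genotype groups smaller than ``config.min_group`` are merged into the
    group with the nearest mean before testing and inherit its risk label.
    """
    config = config or GrsConfig()
    direction = RISK_DIRECTION[lipid]
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes, dtype=float)
    ok = ~np.isnan(values) & ~np.isnan(genotypes)
    values, genotypes = values[ok], genotypes[ok].astype(int)

    counts = {g: int((genotypes == g).sum()) for g in np.unique(genotypes)}
    big = [g for g, c in counts.items() if c >= config.min_group]
    small = [g for g, c in counts.items() if c < config.min_group]
    if len(big) < 2:
        return None
    # merge tiny genotype groups into the nearest-mean tested group
    merged_into: Dict[int, int] = {}
    means = {g: float(values[genotypes == g].mean()) for g in big}
    work = genotypes.copy()
    for g in small:
        m = float(values[genotypes == g].mean()) if counts[g] else np.nan
        host = min(big, key=lambda h: abs(means[h] - m)) if np.isfinite(m) else big[0]
        merged_into[g] = host
        work[work == g] = host

    groups = {g: values[work == g] for g in big}
    lev_stat, lev_p = stats.levene(*groups.values(), center="median")
    homogeneous = lev_p >= config.alpha_levene
    pair_test = _pairwise_pooled_t if homogeneous else _pairwise_welch_t
    m = len(big) * (len(big) - 1) // 2
    posthoc: Dict[tuple, float] = {}
    for g1, g2 in itertools.combinations(sorted(big), 2):
        raw = pair_test(groups[g1], groups[g2])
        if homogeneous:
            adj = min(1.0, raw * m)                      # Bonferroni
        else:
            adj = 1.0 - (1.0 - min(raw, 1.0)) ** m       # Sidak-type (T3 family)
        posthoc[(g1, g2)] = adj

    sign = direction if config.anchor == "adverse" else -direction
    anchor = max(big, key=lambda g: sign * means[g])

    def p_vs_anchor(g: int) -> float:
        key = (min(g, anchor), max(g, anchor))
        return posthoc[key]

    risk = {anchor} | {g for g in big if g != anchor
                       and p_vs_anchor(g) >= config.alpha_posthoc}
    nonrisk = set(big) - risk
    if config.anchor == "favorable":
        risk, nonrisk = nonrisk, risk
        if not risk:
            return None
    if not nonrisk:
        return None          # nothing separates: SNP cannot be coded

    genotype_map = {g: (1 if g in risk else 0) for g in big}
    for g, host in merged_into.items():
        genotype_map[g] = genotype_map[host]
    risk_mask = np.isin(genotypes, [g for g, r in genotype_map.items() if r == 1])
    return RiskCoding(
        snp="", lipid=lipid, genotype_map=genotype_map,
        levene_p=float(lev_p),
        posthoc_method="Bonferroni" if homogeneous else "DunnettT3",
        posthoc_p=posthoc,
        risk_prevalence=float(risk_mask.mean()),
    )


# ---------------------------------------------------------------------------
# stage 3: binarized t selection
# ---------------------------------------------------------------------------

def binarized_t_select(values: np.ndarray, risk_mask: np.ndarray, lipid: str,
                       alpha_trend: float = 0.10):
    """Pooled-variance two-sample t-test of the lipid by risk category.

    Returns ``(keep, t, p)``.  A SNP is kept when p < ``alpha_trend`` *and*
    the mean difference runs in the lipid's adverse direction (risk mean
    higher for TC/LDL-c/TG, lower for HDL-c).
    """
    values = np.asarray(values, dtype=float)
    risk_mask = np.asarray(risk_mask, dtype=bool)
    a, b = values[risk_mask], values[~risk_mask]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both risk categories must be nonempty")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return False, 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(p):
        return False, 0.0, 1.0
    direction_ok = RISK_DIRECTION[lipid] * (a.mean() - b.mean()) > 0
    return bool(p < alpha_trend and direction_ok), float(t), float(p)


# ---------------------------------------------------------------------------
# stage 4: prevalence filter
# ---------------------------------------------------------------------------

def prevalence_filter(risk_mask: np.ndarray, min_prop: float = 0.10) -> bool:
    """Keep a coded SNP only when both categories hold >= ``min_prop`` of
    subjects (strictly-below share is excluded)."""
    risk_mask = np.asarray(risk_mask, dtype=bool)
    prev = risk_mask.mean()
    return bool(prev >= min_prop and (1 - prev) >= min_prop)


# ---------------------------------------------------------------------------
# summation and pipeline
# ---------------------------------------------------------------------------

def build_grs(codings: Mapping[str, Sequence[RiskCoding]], gm: GenotypeMatrix,
              missing: str = "complete-case") -> pd.DataFrame:
    """Per-subject integer GRS per lipid: the sum of risk indicators.

    ``missing="complete-case"`` leaves the score NaN for subjects missing
    any contributing genotype (they drop from that lipid's models);
    ``"observed"`` sums over the observed SNPs instead.
    """
    out = pd.DataFrame(index=gm.genotypes.index)
    for lipid in LIPIDS:
        cods = codings.get(lipid, [])
        score = np.zeros(len(out))
        any_missing = np.zeros(len(out), dtype=bool)
        for cod in cods:
            if cod.snp not in gm.genotypes.columns:
                raise KeyError(f"coding references SNP {cod.snp!r} absent "
                               "from the genotype matrix")
            g = gm.genotypes[cod.snp].to_numpy(dtype=float)
            miss = np.isnan(g)
            any_missing |= miss
            risk_genos = cod.risk_genotypes
            score += np.where(miss, 0.0, np.isin(g, risk_genos).astype(float))
        col = score.copy()
        if missing == "complete-case":
            col[any_missing] = np.nan
        out[f"grs_{lipid}"] = col
    return out


def venn_summary(snp_sets: Mapping[str, set]) -> dict:
    """Set algebra over the per-lipid associated-SNP sets: per-lipid counts,
    exclusives, pairwise intersections, the 4-way core and the union."""
    lipids = list(snp_sets)
    union = set().union(*snp_sets.values()) if snp_sets else set()
    common_all = set.intersection(*snp_sets.values()) if snp_sets else set()
    exclusives = {
        l: sorted(snp_sets[l] - set().union(*(snp_sets[o] for o in lipids if o != l)))
        for l in lipids
    }
    pairwise = {
        f"{a}&{b}": len(snp_sets[a] & snp_sets[b])
        for a, b in itertools.combinations(lipids, 2)
    }
    return {
        "per_lipid": {l: sorted(snp_sets[l]) for l in lipids},
        "per_lipid_count": {l: len(snp_sets[l]) for l in lipids},
        "exclusive": exclusives,
        "exclusive_count": {l: len(v) for l, v in exclusives.items()},
        "n_exclusive_total": sum(len(v) for v in exclusives.values()),
        "pairwise_count": pairwise,
        "common_all": sorted(common_all),
        "n_union": len(union),
    }


def run_grs_pipeline(cohort: pd.DataFrame, gm: GenotypeMatrix,
                     config: GrsConfig | None = None,
                     lipids: Sequence[str] = LIPIDS) -> GrsResult:
    """Run prescreen -> code -> t-select -> prevalence-filter -> sum for each
    lipid and assemble scores, audit log, funnel counts and Venn summary."""
    config = config or GrsConfig()
    if not cohort.index.equals(gm.genotypes.index):
        raise ValueError("cohort and genotype tables must share the same "
                         "subjects in the same order (see align_cohort_genotypes)")
    audit_rows = []
    codings: Dict[str, List[RiskCoding]] = {l: [] for l in lipids}

    for lipid in lipids:
        y_all = cohort[lipid].to_numpy(dtype=float)
        for rsid in gm.genotypes.columns:
            g_all = gm.genotypes[rsid].to_numpy(dtype=float)
            ok = ~np.isnan(y_all) & ~np.isnan(g_all)
            y, g = y_all[ok], g_all[ok].astype(int)
            row = {"snp": rsid, "lipid": lipid, "stage": "", "kept": False,
                   "reason": "", "anova_p": np.nan, "t_p": np.nan,
                   "risk_prevalence": np.nan, "risk_genotypes": "",
                   "posthoc": ""}

            keep, f_stat, p, reason = anova_prescreen(y, g, config.alpha_keep)
            row["anova_p"] = p
            if not keep:
                row.update(stage="prescreen", reason=reason)
                audit_rows.append(row)
                continue

            cod = code_genotype_risk(y, g, lipid, config)
            if cod is None:
                row.update(stage="coding", reason="no_separable_categories")
                audit_rows.append(row)
                continue
            cod.snp = rsid
            cod.anova_f, cod.anova_p = f_stat, p
            risk_mask = np.isin(g, cod.risk_genotypes)

            keep_t, t, t_p = binarized_t_select(y, risk_mask, lipid,
                                                config.alpha_trend)
            cod.t_stat, cod.t_p = t, t_p
            row["t_p"] = t_p
            row["risk_prevalence"] = cod.risk_prevalence
            row["risk_genotypes"] = ",".join(map(str, cod.risk_genotypes))
            row["posthoc"] = cod.posthoc_method
            if not keep_t:
                row.update(stage="t_select", reason="no_marginal_trend")
                audit_rows.append(row)
                continue

            if not prevalence_filter(risk_mask, config.min_prevalence):
                row.update(stage="prevalence", reason="category_below_min_prevalence")
                audit_rows.append(row)
                continue

            row.update(stage="final", kept=True)
            audit_rows.append(row)
            codings[lipid].append(cod)

    audit = pd.DataFrame(audit_rows)
    grs = build_grs(codings, gm, missing=config.missing)

    snp_sets = {l: {c.snp for c in codings[l]} for l in lipids}
    venn = venn_summary(snp_sets)
    stage_counts = _stage_counts(audit, lipids)
    return GrsResult(grs=grs, codings=codings, audit=audit, venn=venn,
                     stage_counts=stage_counts)


def _stage_counts(audit: pd.DataFrame, lipids: Sequence[str]) -> pd.DataFrame:
    """Funnel counts per lipid plus the union over lipids: SNPs surviving
    the prescreen, the coding step, t-selection, and the prevalence filter."""
    rows = []
    stage_order = ["screened", "coded", "t_selected", "final"]
    union: Dict[str, set] = {s: set() for s in stage_order}
    for lipid in lipids:
        sub = audit[audit["lipid"] == lipid]
        passed_pre = sub[sub["stage"] != "prescreen"]["snp"]
        coded = sub[~sub["stage"].isin(["prescreen", "coding"])]["snp"]
        t_sel = sub[sub["stage"].isin(["prevalence", "final"])]["snp"]
        final = sub[sub["stage"] == "final"]["snp"]
        for s, ids in zip(stage_order, [passed_pre, coded, t_sel, final]):
            union[s] |= set(ids)
        rows.append({"lipid": lipid, "screened": len(passed_pre),
                     "coded": len(coded), "t_selected": len(t_sel),
                     "final": len(final)})
    rows.append({"lipid": "union", **{s: len(union[s]) for s in stage_order}})
    return pd.DataFrame(rows).set_index("lipid")
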