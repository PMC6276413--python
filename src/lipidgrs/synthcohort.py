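"""Synthetic genotype + phenotype cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: a panel of biallelic SNPs drawn under Hardy-Weinberg equilibrium
(optionally with inbreeding), lifestyle/adiposity covariates drawn from
marginal distributions typical of an overweight/obese adult cohort, and
lipid phenotypes generated by a linear model

    lipid_i = intercept + sum_s effect_s[g_is] + sum_c beta_c * x_ic + eps_i

where ``effect_s`` is an arbitrary per-genotype triplet (effect of carrying
0, 1 or 2 alternate alleles, in mg/dl) -- deliberately *not* forced to be
additive in allele dose, so dominance and heterozygote-advantage patterns
can be produced.  TC, HDL-c and TG are simulated; LDL-c is always derived
from them with the Friedewald formula so the four lipids stay internally
consistent.

The default configuration (:func:`default_spec`) emulates a cohort of 304
overweight/obese adults genotyped at 95 obesity-related SNPs, with lipid
marginals of roughly TC 216+/-38, HDL-c 55+/-13, TG 104+/-56 mg/dl.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .phenotypes import friedewald_ldl

SIMULATED_LIPIDS = ("tc", "hdl", "tg")


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSpec:
    """One biallelic SNP: label, minor-allele frequency and inbreeding
    coefficient F (F=0 is Hardy-Weinberg equilibrium; F>0 depletes
    heterozygotes)."""

    rsid: str
    maf: float
    f: float = 0.0
    gene: str = ""
    ref: str = "A"
    alt: str = "G"

    def genotype_frequencies(self) -> Tuple[float, float, float]:
        return genotype_frequencies(self.maf, self.f)


def genotype_frequencies(maf: float, f: float = 0.0) -> Tuple[float, float, float]:
    """Genotype probabilities P(0), P(1), P(2) for alternate-allele count
    under inbreeding coefficient ``f``::

        P(0) = (1-q)^2 + F q (1-q),  P(1) = 2 q (1-q)(1-F),  P(2) = q^2 + F q (1-q)
    """
    q = float(maf)
    if not 0.0 < q <= 0.5:
        raise ValueError(f"MAF must be in (0, 0.5], got {q}")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"inbreeding coefficient must be in [0, 1], got {f}")
    p0 = (1 - q) ** 2 + f * q * (1 - q)
    p1 = 2 * q * (1 - q) * (1 - f)
    p2 = q ** 2 + f * q * (1 - q)
    return p0, p1, p2


@dataclass
class LipidModel:
    """Generating model for one simulated lipid (mg/dl scale).

    ``snp_effects`` maps rsID -> (e0, e1, e2): the phenotype shift for
    genotypes 0/1/2.  ``covariate_betas`` maps covariate name -> slope
    (per unit of the covariate as simulated).
    """

    intercept: float
    snp_effects: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)
    covariate_betas: Dict[str, float] = field(default_factory=dict)
    residual_sd: float = 1.0


@dataclass
class CovariateModel:
    """Marginal distributions of the covariates.

    ``continuous`` maps name -> (mean, sd); draws are normal, truncated at
    the listed floor where physical positivity demands it.  ``binary`` maps
    name -> prevalence.  Covariates are drawn independently by default; an
    optional correlation can be imposed among the adiposity trio
    (bmi, tfat, vfat) via ``adiposity_corr``.
    """

    continuous: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    binary: Dict[str, float] = field(default_factory=dict)
    adiposity_corr: float = 0.0
    #: Covariates whose floor sits well inside the normal range (VFAT, METs)
    #: are drawn from a moment-matched lognormal instead of a truncated
    #: normal, so the (mean, SD) spec -- and hence the analytic variance
    #: bookkeeping -- holds exactly while staying positive.
    lognormal: Tuple[str, ...] = ("vfat", "mets")

    _FLOORS = {
        "age": 18.0, "weight": 40.0, "bmi": 18.0, "tfat": 5.0, "vfat": 0.05,
        "glucose": 50.0, "energy": 800.0, "carb_pct": 10.0, "prot_pct": 5.0,
        "fat_pct": 10.0, "chol_intake": 20.0, "mets": 0.0,
    }


@dataclass
class SimulationSpec:
    """Full configuration for one synthetic cohort."""

    n_subjects: int
    snps: List[SnpSpec]
    lipid_models: Dict[str, LipidModel]
    covariates: CovariateModel
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsIDs in SNP panel")
        panel = set(rsids)
        for s in self.snps:
            genotype_frequencies(s.maf, s.f)  # raises on invalid
        for lipid, model in self.lipid_models.items():
            if lipid not in SIMULATED_LIPIDS:
                raise ValueError(
                    f"lipid_models key {lipid!r}: only {SIMULATED_LIPIDS} are "
                    "simulated (LDL-c is derived via Friedewald)")
            if model.residual_sd < 0:
                raise ValueError(f"{lipid}: residual SD must be >= 0")
            missing = set(model.snp_effects) - panel
            if missing:
                raise ValueError(
                    f"{lipid}: effect triplets for SNPs absent from the panel: "
                    f"{sorted(missing)}")
        for name, (_, sd) in self.covariates.continuous.items():
            if sd < 0:
                raise ValueError(f"covariate {name}: SD must be >= 0")
        for name, prev in self.covariates.binary.items():
            if not 0.0 <= prev <= 1.0:
                raise ValueError(f"covariate {name}: prevalence must be in [0,1]")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs genotype table (alternate-allele counts 0/1/2,
    NaN = missing) plus per-SNP annotation."""

    genotypes: pd.DataFrame          # index subject_id, columns rsid, float w/ NaN
    snps: pd.DataFrame               # index rsid: gene, ref, alt, chrom, pos

    def validate(self) -> None:
        vals = self.genotypes.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if not np.isin(observed, [0.0, 1.0, 2.0]).all():
            raise ValueError("genotypes must be in {0,1,2} or missing")
        if np.isnan(vals).all(axis=0).any():
            raise ValueError("every SNP needs at least one observed genotype")
        if self.genotypes.columns.duplicated().any():
            raise ValueError("rsIDs must be unique")

    @property
    def subject_ids(self) -> pd.Index:
        return self.genotypes.index

    @property
    def rsids(self) -> pd.Index:
        return self.genotypes.columns


@dataclass
class CohortTruth:
    """Generating-model record stored next to a simulated cohort."""

    seed: int
    causal_snps: Dict[str, Dict[str, Tuple[float, float, float]]]
    covariate_betas: Dict[str, Dict[str, float]]
    residual_sd: Dict[str, float]
    explained_variance: Dict[str, float]
    total_variance: Dict[str, float]
    population_r2: Dict[str, float]


# ---------------------------------------------------------------------------
# analytic variance bookkeeping
# ---------------------------------------------------------------------------

def _triplet_variance(freqs: Sequence[float], effects: Sequence[float]) -> float:
    p = np.asarray(freqs, dtype=float)
    e = np.asarray(effects, dtype=float)
    mean = float(p @ e)
    return float(p @ (e - mean) ** 2)


def _covariate_variance(cov: CovariateModel, name: str) -> float:
    if name in cov.continuous:
        return float(cov.continuous[name][1]) ** 2
    if name in cov.binary:
        prev = cov.binary[name]
        return prev * (1 - prev)
    raise KeyError(f"unknown covariate {name!r}")


def lipid_variance_components(spec: SimulationSpec, lipid: str) -> Tuple[float, float]:
    """(explained variance, residual variance) of a lipid under the
    generating model, computed in closed form from genotype frequencies and
    covariate marginals (covariates independent).

    ``lipid`` may be a simulated lipid or ``"ldl"``: the Friedewald-derived
    LDL-c is the linear combination TC - HDL - TG/5 of the three simulated
    channels, so its effective coefficients and residual variance combine
    accordingly.
    """
    panel = {s.rsid: s for s in spec.snps}
    if lipid in spec.lipid_models:
        model = spec.lipid_models[lipid]
        snp_eff = {r: np.asarray(e, float) for r, e in model.snp_effects.items()}
        cov_beta = dict(model.covariate_betas)
        resid_var = model.residual_sd ** 2
    elif lipid == "ldl":
        weights = {"tc": 1.0, "hdl": -1.0, "tg": -0.2}
        snp_eff: Dict[str, np.ndarray] = {}
        cov_beta: Dict[str, float] = {}
        resid_var = 0.0
        for chan, w in weights.items():
            model = spec.lipid_models[chan]
            resid_var += (w * model.residual_sd) ** 2
            for r, e in model.snp_effects.items():
                snp_eff[r] = snp_eff.get(r, np.zeros(3)) + w * np.asarray(e, float)
            for c, b in model.covariate_betas.items():
                cov_beta[c] = cov_beta.get(c, 0.0) + w * b
    else:
        raise KeyError(f"unknown lipid {lipid!r}")

    explained = 0.0
    for rsid, eff in snp_eff.items():
        explained += _triplet_variance(panel[rsid].genotype_frequencies(), eff)
    for name, beta in cov_beta.items():
        explained += beta ** 2 * _covariate_variance(spec.covariates, name)
    return explained, resid_var


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _subject_ids(n: int) -> pd.Index:
    width = max(4, len(str(n)))
    return pd.Index([f"S{i + 1:0{width}d}" for i in range(n)], name="subject_id")


def simulate_genotypes(spec: SimulationSpec, rng: np.random.Generator | None = None,
                       ) -> GenotypeMatrix:
    """Draw the genotype matrix for a spec.

    Per SNP, genotypes are iid draws from the (MAF, F) genotype frequencies;
    reproducible given the spec seed.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cols = {}
    ann = []
    for i, s in enumerate(spec.snps):
        probs = s.genotype_frequencies()
        cols[s.rsid] = rng.choice(3, size=n, p=probs).astype(float)
        ann.append({"rsid": s.rsid, "gene": s.gene, "ref": s.ref, "alt": s.alt,
                    "chrom": "1", "pos": i + 1, "maf": s.maf, "f": s.f})
    geno = pd.DataFrame(cols, index=_subject_ids(n))
    snps = pd.DataFrame(ann).set_index("rsid")
    gm = GenotypeMatrix(geno, snps)
    gm.validate()
    return gm


def _simulate_covariates(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    cov = spec.covariates
    n = spec.n_subjects
    data: Dict[str, np.ndarray] = {}

    adip = [c for c in ("bmi", "tfat", "vfat") if c in cov.continuous]
    shared = rng.standard_normal(n) if cov.adiposity_corr > 0 else None
    for name, (mean, sd) in cov.continuous.items():
        z = rng.standard_normal(n)
        if shared is not None and name in adip:
            rho = cov.adiposity_corr
            z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z
        if name in cov.lognormal and mean > 0 and sd > 0:
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2
            x = np.exp(mu + np.sqrt(sigma2) * z)
        else:
            x = mean + sd * z
            floor = CovariateModel._FLOORS.get(name)
            if floor is not None:
                x = np.maximum(x, floor)
        data[name] = x
    for name, prev in cov.binary.items():
        data[name] = (rng.random(n) < prev).astype(float)
    return pd.DataFrame(data, index=_subject_ids(n))


def simulate_cohort(spec: SimulationSpec,
                    ) -> Tuple[pd.DataFrame, GenotypeMatrix, CohortTruth]:
    """Simulate a full cohort: covariates, genotypes and lipid phenotypes.

    Returns the cohort table (one row per subject, lipids in mg/dl, LDL-c
    Friedewald-derived), the genotype matrix, and a truth record with the
    causal structure and the generating-model population R-squared per lipid
    (including the derived LDL-c channel).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gm = simulate_genotypes(spec, rng)
    covariates = _simulate_covariates(spec, rng)

    cohort = covariates.copy()
    # binary "male" indicator is surfaced as the conventional sex column
    if "male" in cohort.columns:
        cohort["sex"] = np.where(cohort.pop("male") > 0, "M", "F")

    geno = gm.genotypes
    for lipid in SIMULATED_LIPIDS:
        model = spec.lipid_models[lipid]
        y = np.full(spec.n_subjects, model.intercept, dtype=float)
        for rsid, eff in model.snp_effects.items():
            e = np.asarray(eff, dtype=float)
            y += e[geno[rsid].to_numpy(dtype=int)]
        for name, beta in model.covariate_betas.items():
            x = covariates[name].to_numpy()
            y += beta * x
        y += rng.normal(0.0, model.residual_sd, size=spec.n_subjects)
        cohort[lipid] = y

    # keep lipids physical; floors are far (>3 SD) from the default means
    cohort["tc"] = np.maximum(cohort["tc"], 60.0)
    cohort["hdl"] = np.maximum(cohort["hdl"], 15.0)
    cohort["tg"] = np.maximum(cohort["tg"], 20.0)
    cohort["ldl"] = friedewald_ldl(cohort["tc"], cohort["hdl"], cohort["tg"])

    truth = _make_truth(spec)
    return cohort, gm, truth


def _make_truth(spec: SimulationSpec) -> CohortTruth:
    causal, betas, resid, expl, total, r2 = {}, {}, {}, {}, {}, {}
    for lipid in list(SIMULATED_LIPIDS) + ["ldl"]:
        e, rv = lipid_variance_components(spec, lipid)
        expl[lipid], total[lipid] = e, e + rv
        r2[lipid] = e / (e + rv) if e + rv > 0 else 0.0
        resid[lipid] = float(np.sqrt(rv))
        if lipid in spec.lipid_models:
            m = spec.lipid_models[lipid]
            causal[lipid] = {r: tuple(v) for r, v in m.snp_effects.items()}
            betas[lipid] = dict(m.covariate_betas)
    # the derived channel inherits the union of simulated causal SNPs
    causal["ldl"] = {}
    for chan, w in (("tc", 1.0), ("hdl", -1.0), ("tg", -0.2)):
        for rsid, eff in spec.lipid_models[chan].snp_effects.items():
            prev = np.asarray(causal["ldl"].get(rsid, (0.0, 0.0, 0.0)))
            causal["ldl"][rsid] = tuple(prev + w * np.asarray(eff))
    return CohortTruth(
        seed=spec.seed, causal_snps=causal, covariate_betas=betas,
        residual_sd=resid, explained_variance=expl, total_variance=total,
        population_r2=r2,
    )


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------

#: Target marginal (mean, SD) of the simulated lipids, mg/dl.
DEFAULT_LIPID_MARGINALS = {"tc": (216.0, 38.0), "hdl": (55.3, 12.9), "tg": (104.0, 56.0)}

DEFAULT_COVARIATES = CovariateModel(
    continuous={
        "age": (45.8, 10.5),
        "weight": (87.7, 13.0),
        "bmi": (31.6, 3.5),
        "tfat": (36.9, 7.6),
        "vfat": (1.48, 0.90),
        "glucose": (96.6, 14.1),
        "energy": (2970.0, 934.0),
        "carb_pct": (40.7, 6.8),
        "prot_pct": (17.0, 2.9),
        "fat_pct": (40.4, 5.8),
        "chol_intake": (400.0, 150.0),
        "mets": (23.8, 20.0),
    },
    binary={"male": 92 / 304, "smoker": 0.219, "drinker": 0.135},
)

#: Per-risk-genotype effect sizes (mg/dl) of the default causal SNPs; the
#: magnitudes mirror the per-score slopes a cohort of this kind exhibits.
DEFAULT_EFFECT_SIZE = {"tc": 6.55, "hdl": -1.12, "tg": 4.20}

DEFAULT_COVARIATE_BETAS = {
    "tc": {"age": 0.80, "energy": 0.0038},            # energy slope per kcal
    "hdl": {"age": 0.22, "male": -4.51, "energy": 0.0018, "prot_pct": 0.93,
            "chol_intake": -0.01, "drinker": 5.83, "vfat": -5.22},
    "tg": {"drinker": -19.21, "tfat": -1.14, "vfat": 30.95},
}

#: Genotype->effect patterns cycled over causal SNPs: risk carried by the
#: alt homozygote (recessive), by any alt carrier (dominant), or by both
#: homozygotes (heterozygote advantage on the favorable side).
_EFFECT_PATTERNS = ((0.0, 0.0, 1.0), (0.0, 1.0, 1.0), (1.0, 0.0, 1.0))


def default_snp_panel(n_snps: int = 95) -> List[SnpSpec]:
    """Synthetic panel of obesity-related SNPs, all in HWE (F=0).

    MAFs cover [0.05, 0.5] evenly but are interleaved along the panel (fixed
    stride permutation) so any contiguous block of SNPs -- e.g. the default
    causal blocks -- spans the whole frequency range.
    """
    grid = np.linspace(0.05, 0.5, n_snps)
    stride = 37 if n_snps % 37 else 1   # coprime with the default 95
    order = [(i * stride) % n_snps for i in range(n_snps)]
    return [
        SnpSpec(rsid=f"rs9{i:05d}", maf=round(float(grid[order[i]]), 4),
                gene=f"GENE{i:03d}")
        for i in range(n_snps)
    ]


def default_causal_assignment(n_snps: int, causal_per_lipid: int = 10,
                              ) -> Dict[str, List[int]]:
    """Indices of causal SNPs per simulated lipid: consecutive blocks with a
    2-SNP overlap between adjacent lipids, so some SNPs affect several
    phenotypes (as real pleiotropic loci do) while most of the panel is null.
    """
    k = causal_per_lipid
    blocks = {"tc": list(range(0, k)),
              "hdl": list(range(max(k - 2, 0), 2 * k - 2)),
              "tg": list(range(max(2 * k - 4, 0), 3 * k - 4))}
    for lipid, idx in blocks.items():
        if idx and max(idx) >= n_snps:
            raise ValueError("causal_per_lipid too large for the panel")
    return blocks


def default_spec(n_subjects: int = 304, seed: int = 0, n_snps: int = 95,
                 causal_per_lipid: int = 10,
                 effect_size: Mapping[str, float] | None = None) -> SimulationSpec:
    """Default cohort configuration.

    Residual SDs are calibrated analytically so each simulated lipid's
    marginal SD matches :data:`DEFAULT_LIPID_MARGINALS`; intercepts are set
    so the marginal means match.
    """
    snps = default_snp_panel(n_snps)
    causal = default_causal_assignment(n_snps, causal_per_lipid)
    eff = dict(DEFAULT_EFFECT_SIZE)
    if effect_size:
        eff.update(effect_size)

    lipid_models: Dict[str, LipidModel] = {}
    for lipid in SIMULATED_LIPIDS:
        snp_effects = {}
        for j, idx in enumerate(causal[lipid]):
            pattern = np.asarray(_EFFECT_PATTERNS[j % len(_EFFECT_PATTERNS)])
            snp_effects[snps[idx].rsid] = tuple(eff[lipid] * pattern)
        lipid_models[lipid] = LipidModel(
            intercept=0.0, snp_effects=snp_effects,
            covariate_betas=dict(DEFAULT_COVARIATE_BETAS[lipid]),
            residual_sd=1.0)

    spec = SimulationSpec(n_subjects=n_subjects, snps=snps,
                          lipid_models=lipid_models,
                          covariates=DEFAULT_COVARIATES, seed=seed)

    # calibrate residual SD to the target marginal SD, intercept to the mean
    panel = {s.rsid: s for s in snps}
    for lipid, (target_mean, target_sd) in DEFAULT_LIPID_MARGINALS.items():
        model = spec.lipid_models[lipid]
        explained, _ = lipid_variance_components(spec, lipid)
        resid_var = target_sd ** 2 - explained
        if resid_var <= 0:
            raise ValueError(
                f"{lipid}: systematic variance {explained:.1f} exceeds the "
                f"target marginal variance {target_sd ** 2:.1f}")
        model.residual_sd = float(np.sqrt(resid_var))
        mean_sys = 0.0
        for rsid, e in model.snp_effects.items():
            p = np.asarray(panel[rsid].genotype_frequencies())
            mean_sys += float(p @ np.asarray(e))
        for name, beta in model.covariate_betas.items():
            if name in DEFAULT_COVARIATES.continuous:
                mean_sys += beta * DEFAULT_COVARIATES.continuous[name][0]
            else:
                mean_sys += beta * DEFAULT_COVARIATES.binary[name]
        model.intercept = target_mean - mean_sys
    return spec


def spec_to_dict(spec: SimulationSpec) -> dict:
    """Plain-dict (YAML/JSON-ready) form of a spec; numpy scalars are
    converted to native Python numbers."""
    f = float
    return {
        "n_subjects": int(spec.n_subjects),
        "seed": int(spec.seed),
        "snps": [{"rsid": s.rsid, "maf": f(s.maf), "f": f(s.f),
                  "gene": s.gene, "ref": s.ref, "alt": s.alt}
                 for s in spec.snps],
        "lipid_models": {
            lipid: {
                "intercept": f(m.intercept),
                "residual_sd": f(m.residual_sd),
                "snp_effects": {r: [f(x) for x in e]
                                for r, e in m.snp_effects.items()},
                "covariate_betas": {k: f(v)
                                    for k, v in m.covariate_betas.items()},
            }
            for lipid, m in spec.lipid_models.items()
        },
        "covariates": {
            "continuous": {k: [f(v[0]), f(v[1])]
                           for k, v in spec.covariates.continuous.items()},
            "binary": {k: f(v) for k, v in spec.covariates.binary.items()},
            "adiposity_corr": f(spec.covariates.adiposity_corr),
            "lognormal": list(spec.covariates.lognormal),
        },
    }


def spec_from_dict(d: Mapping) -> SimulationSpec:
    snps = [SnpSpec(**s) for s in d["snps"]]
    lipid_models = {
        lipid: LipidModel(
            intercept=m["intercept"],
            residual_sd=m["residual_sd"],
            snp_effects={r: tuple(e) for r, e in m.get("snp_effects", {}).items()},
            covariate_betas=dict(m.get("covariate_betas", {})),
        )
        for lipid, m in d["lipid_models"].items()
    }
    cov = d.get("covariates", {})
    covariates = CovariateModel(
        continuous={k: tuple(v) for k, v in cov.get("continuous", {}).items()},
        binary=dict(cov.get("binary", {})),
        adiposity_corr=cov.get("adiposity_corr", 0.0),
        lognormal=tuple(cov.get("lognormal", ("vfat", "mets"))),
    )
    spec = SimulationSpec(n_subjects=int(d["n_subjects"]), snps=snps,
                          lipid_models=lipid_models, covariates=covariates,
                          seed=int(d.get("seed", 0)))
    spec.validate()
    return spec
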