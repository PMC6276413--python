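import numpy as np
import pandas as pd
import pytest

from lipidgrs import synthcohort


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort (304 subjects x 95 SNPs), shared
    read-only across tests."""
    spec = synthcohort.default_spec(seed=7)
    return synthcohort.simulate_cohort(spec)


def strong_effect_spec(seed: int = 0, n_subjects: int = 304, n_snps: int = 30,
                       causal_per_lipid: int = 6) -> synthcohort.SimulationSpec:
    """Cohort spec with strong causal SNPs on a compact panel, for
    power/recovery checks.

    The coding step's power bottleneck is the pairwise comparison against
    the anchor genotype, whose group can be as small as n*q^2 subjects; at
    n~300 a Bonferroni-adjusted pairwise test needs a noncentrality around
    4 (effect ~0.75 residual SD with MAF >= 0.35) for ~95% per-SNP power.
    Causal variants here are therefore common (MAF 0.35-0.5) with effects
    of 0.75 residual SD, alternating dominant and heterozygote-advantage
    patterns."""
    mafs = np.linspace(0.35, 0.5, n_snps)
    snps = [synthcohort.SnpSpec(rsid=f"rs{i:04d}", maf=float(round(mafs[i], 3)))
            for i in range(n_snps)]
    residual = {"tc": 36.0, "hdl": 10.8, "tg": 47.0}
    patterns = {0: (0.75, (0.0, 1.0, 1.0)),     # dominant
                1: (0.75, (1.0, 0.0, 1.0))}     # heterozygote advantage
    sign = {"tc": 1.0, "hdl": -1.0, "tg": 1.0}
    blocks = {"tc": range(0, causal_per_lipid),
              "hdl": range(causal_per_lipid, 2 * causal_per_lipid),
              "tg": range(2 * causal_per_lipid, 3 * causal_per_lipid)}
    models = {}
    for lipid in synthcohort.SIMULATED_LIPIDS:
        eff = {}
        for j, i in enumerate(blocks[lipid]):
            mult, pattern = patterns[j % 2]
            d = sign[lipid] * mult * residual[lipid]
            eff[snps[i].rsid] = tuple(d * np.asarray(pattern))
        models[lipid] = synthcohort.LipidModel(
            intercept={"tc": 170.0, "hdl": 60.0, "tg": 90.0}[lipid],
            snp_effects=eff,
            covariate_betas=dict(synthcohort.DEFAULT_COVARIATE_BETAS[lipid]),
            residual_sd=residual[lipid])
    spec = synthcohort.SimulationSpec(
        n_subjects=n_subjects, snps=snps, lipid_models=models,
        covariates=synthcohort.DEFAULT_COVARIATES, seed=seed)
    spec.validate()
    return spec


@pytest.fixture(scope="session")
def strong_sim():
    return synthcohort.simulate_cohort(strong_effect_spec(seed=11))


def r2_recovery_spec(seed: int = 0, n_snps: int = 20,
                     n_causal: int = 4) -> synthcohort.SimulationSpec:
    """TC-focused recovery spec with the generating model's population
    R^2 calibrated to 0.25.

    Four common causal SNPs (MAF 0.35-0.5, dominant / heterozygote-
    advantage patterns, 27 mg/dl per risk genotype) plus the age and energy
    slopes; the residual SD is set analytically so explained/total variance
    is exactly 0.25, which keeps the per-genotype effect at ~0.55 residual
    SD."""
    mafs = np.linspace(0.35, 0.5, n_snps)
    snps = [synthcohort.SnpSpec(rsid=f"rs{i:04d}", maf=float(round(mafs[i], 3)))
            for i in range(n_snps)]
    patterns = ((0.0, 1.0, 1.0), (1.0, 0.0, 1.0))
    eff = {snps[i].rsid: tuple(27.0 * np.asarray(patterns[i % 2]))
           for i in range(n_causal)}
    models = {
        "tc": synthcohort.LipidModel(
            intercept=170.0, snp_effects=eff,
            covariate_betas=dict(synthcohort.DEFAULT_COVARIATE_BETAS["tc"]),
            residual_sd=1.0),
        "hdl": synthcohort.LipidModel(
            intercept=55.3,
            covariate_betas=dict(synthcohort.DEFAULT_COVARIATE_BETAS["hdl"]),
            residual_sd=10.8),
        "tg": synthcohort.LipidModel(
            intercept=104.0,
            covariate_betas=dict(synthcohort.DEFAULT_COVARIATE_BETAS["tg"]),
            residual_sd=47.0),
    }
    spec = synthcohort.SimulationSpec(
        n_subjects=304, snps=snps, lipid_models=models,
        covariates=synthcohort.DEFAULT_COVARIATES, seed=seed)
    explained, _ = synthcohort.lipid_variance_components(spec, "tc")
    models["tc"].residual_sd = float(np.sqrt(3.0 * explained))  # R2 = 0.25
    spec.validate()
    return spec


def make_genotype_matrix(values: np.ndarray, subject_ids=None, rsids=None):
    """GenotypeMatrix from a plain array (subjects x SNPs; NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(n)]
    if rsids is None:
        rsids = [f"rs{j}" for j in range(s)]
    geno = pd.DataFrame(values, index=pd.Index(subject_ids, name="subject_id"),
                        columns=rsids)
    snps = pd.DataFrame({"gene": "", "ref": "A", "alt": "G", "chrom": "1",
                         "pos": np.arange(1, s + 1)},
                        index=pd.Index(rsids, name="rsid"))
    return synthcohort.GenotypeMatrix(geno, snps)
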