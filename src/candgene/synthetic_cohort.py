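"""Synthetic case-control cohorts and toy VCF fixtures.

The study this package replicates genotyped ~218 ultrasound-defined NAFLD
cases and ~227 healthy controls at four index SNPs (PNPLA3 rs738409,
TM6SF2 rs58542926, GCKR rs1260326, MBOAT7 rs641738) and resequenced five
candidate genes.  The raw data are not public, so this module generates
cohorts with the statistical structure the downstream analysis assumes:

* genotypes drawn under Hardy-Weinberg equilibrium in the source population,
  independent across SNPs by default (optional pairwise LD via a Gaussian
  copula on haplotypes);
* disease assigned by an additive-on-the-log-odds logistic model,
  ``logit P(D) = logit(K) + sum(dosage * ln OR) + covariate terms``;
* cases and controls accumulated by retrospective (rejection) sampling from
  the population model;
* metabolic covariates with the location/scale/skew of the study's
  baseline table (age and BMI normal; triglycerides, glucose and insulin
  log-normal; HOMA-IR derived as glucose*insulin/405).

It also emits small labelled VCF fixtures that exercise every post-caller
quality-filter rule.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.special import expit, logit

__all__ = [
    "SnpSpec",
    "CovariateParams",
    "CohortSpec",
    "SubjectRecord",
    "DEFAULT_SNPS",
    "DEFAULT_COVARIATES",
    "DEFAULT_COVARIATE_BETAS",
    "CASE_GRADE_PROBS",
    "compute_homa_ir",
    "simulate_cohort",
    "cohort_to_frame",
    "write_subject_table",
    "sample_genotype_counts",
    "simulate_vcf",
]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSpec:
    """One biallelic SNP: population risk-allele frequency and per-allele OR."""

    id: str
    risk_allele_freq: float
    per_allele_or: float
    risk_allele: str = "A"

    def __post_init__(self) -> None:
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError(f"{self.id}: risk_allele_freq must be in (0, 1)")
        if self.per_allele_or <= 0.0:
            raise ValueError(f"{self.id}: per_allele_or must be positive")


@dataclass(frozen=True)
class CovariateParams:
    """Location/scale for one covariate; ``log_scale`` marks a log-normal."""

    mean: float
    sd: float
    log_scale: bool = False

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.normal(self.mean, self.sd, size=n)
        return np.exp(x) if self.log_scale else x


#: Index SNPs with control-population risk-allele frequencies and per-allele
#: odds ratios in the moderate band reported for these loci (TM6SF2 is the
#: low-frequency, larger-effect variant; GCKR/MBOAT7 common, weaker).
DEFAULT_SNPS: tuple[SnpSpec, ...] = (
    SnpSpec("rs738409", 0.30, 2.0, "G"),
    SnpSpec("rs58542926", 0.07, 2.5, "T"),
    SnpSpec("rs1260326", 0.42, 1.5, "T"),
    SnpSpec("rs641738", 0.41, 1.4, "T"),
)

#: Population covariate distributions (age years, BMI kg/m2, sex as male
#: fraction, glucose mg/dL, insulin U/L, TG mg/dL).  Skewed variables are
#: log-normal with parameters matched to control medians / interquartile
#: ranges; case-control shifts emerge from the disease model, not from
#: separate case distributions.
DEFAULT_COVARIATES: dict[str, CovariateParams] = {
    "age": CovariateParams(50.0, 11.0),
    "bmi": CovariateParams(26.0, 3.5),
    "glucose": CovariateParams(np.log(88.0), 0.15, log_scale=True),
    "insulin": CovariateParams(np.log(7.5), 0.50, log_scale=True),
    "tg": CovariateParams(np.log(100.0), 0.40, log_scale=True),
}

DEFAULT_MALE_FRACTION = 0.66

#: Log-odds per unit of each covariate (log-transformed where skewed),
#: centred at the population mean inside the linear predictor so that
#: ``baseline_prevalence`` stays the prevalence of an average subject.
DEFAULT_COVARIATE_BETAS: dict[str, float] = {
    "age": 0.02,       # per year
    "sex_m": 0.20,     # male vs female
    "bmi": 0.19,       # per kg/m2
    "log_homa": 0.80,  # per log-unit HOMA-IR
    "log_tg": 0.60,    # per log-unit TG
}

#: Steatosis grade distribution among cases (semi-quantitative ultrasound
#: scale 0-6): ~23.7% mild (1-2), ~43.7% moderate (3-4), ~32.6% severe (5-6),
#: i.e. ~76.3% moderate-to-severe.  Grade 0 does not occur in cases.
CASE_GRADE_PROBS: np.ndarray = np.array(
    [0.0, 0.1185, 0.1185, 0.2185, 0.2185, 0.163, 0.163]
)


@dataclass(frozen=True)
class CohortSpec:
    n_cases: int = 218
    n_controls: int = 227
    snps: tuple[SnpSpec, ...] = DEFAULT_SNPS
    covariate_params: dict[str, CovariateParams] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    covariate_betas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_BETAS)
    )
    male_fraction: float = DEFAULT_MALE_FRACTION
    baseline_prevalence: float = 0.30
    ld_r: float = 0.0  # pairwise haplotype correlation between adjacent SNPs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if not -1.0 < self.ld_r < 1.0:
            raise ValueError("ld_r must be in (-1, 1)")


@dataclass
class SubjectRecord:
    subject_id: str
    status: str  # "case" | "control"
    dosages: dict[str, int]
    age: float
    sex: str  # "M" | "F"
    bmi: float
    glucose: float
    insulin: float
    homa_ir: float
    tg: float
    steatosis_grade: int


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------

def compute_homa_ir(glucose: float, insulin: float):
    """Insulin-resistance index: fasting glucose (mg/dL) x insulin (U/L) / 405."""
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(glucose <= 0) or np.any(insulin <= 0):
        raise ValueError("glucose and insulin must be positive")
    out = glucose * insulin / 405.0
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def _draw_genotypes(
    rng: np.random.Generator, snps: tuple[SnpSpec, ...], n: int, ld_r: float
) -> np.ndarray:
    """HWE genotypes (risk-allele dosage 0/1/2), shape (n, n_snps).

    With ``ld_r`` nonzero, adjacent SNPs' alleles on the same haplotype are
    correlated through a Gaussian copula (AR(1) structure across the panel).
    """
    k = len(snps)
    freqs = np.array([s.risk_allele_freq for s in snps])
    if ld_r == 0.0 or k == 1:
        return rng.binomial(2, freqs, size=(n, k))
    thresh = np.array([np.clip(f, 1e-12, 1 - 1e-12) for f in freqs])
    from scipy.stats import norm

    z_cut = norm.ppf(thresh)
    dosage = np.zeros((n, k), dtype=np.int64)
    for _hap in range(2):
        z = rng.normal(size=(n, k))
        for j in range(1, k):
            z[:, j] = ld_r * z[:, j - 1] + np.sqrt(1 - ld_r**2) * z[:, j]
        dosage += (z < z_cut).astype(np.int64)
    return dosage


def _linear_predictor(
    spec: CohortSpec,
    dosage: np.ndarray,
    covs: dict[str, np.ndarray],
) -> np.ndarray:
    eta = np.full(dosage.shape[0], logit(spec.baseline_prevalence))
    for j, snp in enumerate(spec.snps):
        eta += dosage[:, j] * np.log(snp.per_allele_or)
    betas = spec.covariate_betas
    cp = spec.covariate_params
    # centring constants: generative population means of each predictor term
    centres = {
        "age": cp["age"].mean,
        "bmi": cp["bmi"].mean,
        "log_homa": cp["glucose"].mean + cp["insulin"].mean - np.log(405.0),
        "log_tg": cp["tg"].mean,
        "sex_m": spec.male_fraction,
    }
    terms = {
        "age": covs["age"],
        "bmi": covs["bmi"],
        "log_homa": np.log(covs["homa_ir"]),
        "log_tg": np.log(covs["tg"]),
        "sex_m": (covs["sex_m"]).astype(float),
    }
    for name, beta in betas.items():
        eta += beta * (terms[name] - centres[name])
    return eta


def simulate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Retrospectively sample a case-control cohort from the population model.

    Draws population subjects in vectorised batches, assigns disease from the
    logistic model, and keeps them until both the case and control quota are
    filled.  Raises ``RuntimeError`` if the quota cannot be met within
    ``1000 * (n_cases + n_controls)`` population draws (prevalence too
    extreme for the requested sizes).
    """
    rng = np.random.default_rng(spec.seed)
    need = {"case": spec.n_cases, "control": spec.n_controls}
    kept: dict[str, list[dict]] = {"case": [], "control": []}
    total = spec.n_cases + spec.n_controls
    max_draws = 1000 * total
    drawn = 0
    while (len(kept["case"]) < need["case"]
           or len(kept["control"]) < need["control"]):
        if drawn >= max_draws:
            raise RuntimeError(
                "retrospective sampling did not fill the requested cohort "
                f"within {max_draws} population draws"
            )
        batch = min(max(2 * total, 1024), max_draws - drawn)
        drawn += batch
        dosage = _draw_genotypes(rng, spec.snps, batch, spec.ld_r)
        covs = {
            name: par.draw(rng, batch)
            for name, par in spec.covariate_params.items()
        }
        covs["sex_m"] = rng.random(batch) < spec.male_fraction
        covs["homa_ir"] = covs["glucose"] * covs["insulin"] / 405.0
        eta = _linear_predictor(spec, dosage, covs)
        is_case = rng.random(batch) < expit(eta)
        grades = rng.choice(7, size=batch, p=CASE_GRADE_PROBS)
        take = np.concatenate([
            np.flatnonzero(is_case)[: need["case"] - len(kept["case"])],
            np.flatnonzero(~is_case)[: need["control"]
                                     - len(kept["control"])],
        ])
        take.sort()  # preserve draw order
        for i in take:
            group = "case" if is_case[i] else "control"
            kept[group].append(
                dict(
                    dosages={
                        s.id: int(dosage[i, j])
                        for j, s in enumerate(spec.snps)
                    },
                    age=float(covs["age"][i]),
                    sex="M" if covs["sex_m"][i] else "F",
                    bmi=float(covs["bmi"][i]),
                    glucose=float(covs["glucose"][i]),
                    insulin=float(covs["insulin"][i]),
                    homa_ir=float(covs["homa_ir"][i]),
                    tg=float(covs["tg"][i]),
                    steatosis_grade=int(grades[i]) if group == "case" else 0,
                )
            )

    records: list[SubjectRecord] = []
    idx = 0
    for group in ("case", "control"):
        for payload in kept[group]:
            idx += 1
            records.append(
                SubjectRecord(subject_id=f"S{idx:05d}", status=group, **payload)
            )
    return records


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten SubjectRecords to a tidy table (one dosage column per SNP)."""
    rows = []
    for r in records:
        row = dataclasses.asdict(r)
        dosages = row.pop("dosages")
        for snp_id, d in dosages.items():
            row[snp_id] = d
        rows.append(row)
    return pd.DataFrame(rows)


def write_subject_table(records: list[SubjectRecord], path) -> None:
    """Write the cohort as a TSV; columns: subject_id, status, covariates,
    steatosis_grade, then one risk-allele-dosage column per SNP."""
    cohort_to_frame(records).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# genotype-count sampler for power validation
# --------------------------------------------------------------------------

def sample_genotype_counts(
    rng: np.random.Generator,
    case_probs,
    control_probs,
    n_cases: int,
    n_controls: int,
    reps: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw case/control genotype counts from their retrospective
    (disease-conditional) genotype distributions.

    Sampling each subject's genotype from P(g | status) is exactly equivalent
    to rejection-sampling population subjects under the penetrance model
    until the quotas fill, so this is the fast path used by Monte-Carlo
    power validation.  Returns two (reps, 3) count arrays.
    """
    case_counts = rng.multinomial(n_cases, np.asarray(case_probs), size=reps)
    control_counts = rng.multinomial(
        n_controls, np.asarray(control_probs), size=reps
    )
    return case_counts, control_counts


# --------------------------------------------------------------------------
# VCF fixture generator
# --------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=candgene-synthetic
##contig=<ID=2>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele fraction in percent">
##INFO=<ID=SAF,Number=1,Type=Integer,Description="Alt observations, forward strand">
##INFO=<ID=SAR,Number=1,Type=Integer,Description="Alt observations, reverse strand">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=ANN,Number=1,Type=String,Description="Annotation class">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Population minor allele fraction">
##INFO=<ID=XFAIL,Number=.,Type=String,Description="Ground-truth filter rules this synthetic record violates">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE1
"""

_GENES = ("GCKR", "LYPLAL1", "NCAN", "PPP1R3B", "TM6SF2")
_BASES = ("A", "C", "G", "T")
_RULES = ("DP", "GQ", "AF", "STRAND")

#: Gene labels for functional variants in the resequenced panel's observed
#: proportions (n=47: 23% GCKR, 15% LYPLAL1, 34% NCAN, 8.5% PPP1R3B,
#: 19% TM6SF2).
FUNCTIONAL_GENE_COUNTS = {
    "GCKR": 11, "LYPLAL1": 7, "NCAN": 16, "PPP1R3B": 4, "TM6SF2": 9,
}

#: Annotation composition of the resequencing screen: 168 variants, 100
#: intronic and 68 exonic (43 missense, 2 nonsense, 2 frameshift,
#: 21 synonymous).
RESEQUENCING_ANNOTATION_COUNTS = {
    "intronic": 100,
    "missense": 43,
    "nonsense": 2,
    "frameshift": 2,
    "synonymous": 21,
}


def _passing_metrics(rng: np.random.Generator) -> dict:
    dp = int(rng.integers(30, 400))
    gq = int(rng.integers(30, 100))
    af = float(rng.choice([rng.uniform(33, 50), rng.uniform(70, 100)]))
    n_alt = max(2, int(round(dp * af / 100.0)))
    saf = int(rng.integers(int(np.ceil(0.3 * n_alt)), int(0.7 * n_alt) + 1))
    return dict(dp=dp, gq=gq, af=round(af, 1), saf=saf, sar=n_alt - saf)


def _failing_metrics(rng: np.random.Generator, rule: str) -> dict:
    m = _passing_metrics(rng)
    # rebalanced strand splits below stay >= the default balance threshold
    # so each record violates exactly the targeted rule
    if rule == "DP":
        m["dp"] = int(rng.integers(5, 30))
        n_alt = min(m["dp"], max(2, int(round(m["dp"] * m["af"] / 100.0))))
        m["saf"] = n_alt // 2
        m["sar"] = n_alt - n_alt // 2
    elif rule == "GQ":
        m["gq"] = int(rng.integers(0, 30))
    elif rule == "AF":
        m["af"] = round(float(rng.choice([rng.uniform(5, 32.9),
                                          rng.uniform(50.1, 69.9)])), 1)
        n_alt = min(m["dp"], max(2, int(round(m["dp"] * m["af"] / 100.0))))
        m["saf"] = n_alt // 2
        m["sar"] = n_alt - n_alt // 2
    elif rule == "STRAND":
        n_alt = m["saf"] + m["sar"]
        m["saf"], m["sar"] = n_alt, 0
    else:  # pragma: no cover
        raise ValueError(f"unknown rule {rule}")
    return m


def simulate_vcf(
    n_variants: int = 50,
    qc_fail_fraction: float = 0.0,
    seed: int = 0,
    annotation_counts: dict[str, int] | None = None,
    functional_gene_counts: dict[str, int] | None = None,
) -> str:
    """Emit a small, labelled VCF v4.2 fixture as text.

    A ``qc_fail_fraction`` of records violate the post-caller quality filter;
    failing records cycle through the four rules (DP, GQ, AF, STRAND) so
    each rule is violated at least once whenever any record fails, and the
    violated rules are recorded in the INFO ``XFAIL`` tag as ground truth.

    ``annotation_counts`` optionally fixes the exact annotation-class
    composition (overriding ``n_variants``); ``functional_gene_counts``
    optionally fixes gene labels for the functional records.
    """
    if not 0.0 <= qc_fail_fraction <= 1.0:
        raise ValueError("qc_fail_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    if annotation_counts is not None:
        annotations: list[str] = []
        for ann, k in annotation_counts.items():
            annotations.extend([ann] * int(k))
        n_variants = len(annotations)
    else:
        annotations = list(
            rng.choice(
                ["missense", "synonymous", "intronic", "nonsense",
                 "frameshift", "splice-region", "other"],
                size=n_variants,
                p=[0.25, 0.15, 0.40, 0.04, 0.04, 0.06, 0.06],
            )
        )

    functional_set = {"nonsense", "frameshift", "splice-region", "missense"}
    gene_pool: list[str] = []
    if functional_gene_counts is not None:
        for g, k in functional_gene_counts.items():
            gene_pool.extend([g] * int(k))
        if len(gene_pool) != sum(a in functional_set for a in annotations):
            raise ValueError(
                "functional_gene_counts must cover exactly the functional "
                "records"
            )

    n_fail = int(round(qc_fail_fraction * n_variants))
    fail_idx = set(rng.choice(n_variants, size=n_fail, replace=False)) \
        if n_fail else set()

    out = io.StringIO()
    out.write(_VCF_HEADER)
    pos = 1000
    fail_counter = 0
    func_counter = 0
    for i in range(n_variants):
        pos += int(rng.integers(50, 500))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        ann = annotations[i]
        if ann in functional_set and gene_pool:
            gene = gene_pool[func_counter]
            func_counter += 1
        else:
            gene = str(rng.choice(_GENES))
        maf = float(np.round(rng.uniform(0.0005, 0.45), 4))
        if i in fail_idx:
            rule = _RULES[fail_counter % len(_RULES)]
            fail_counter += 1
            m = _failing_metrics(rng, rule)
            xfail = f";XFAIL={rule}"
        else:
            m = _passing_metrics(rng)
            xfail = ""
        gt = "0/1" if m["af"] <= 50 else "1/1"
        info = (
            f"DP={m['dp']};GQ={m['gq']};AF={m['af']};SAF={m['saf']};"
            f"SAR={m['sar']};GENE={gene};ANN={ann};MAF={maf}{xfail}"
        )
        out.write(
            f"2\t{pos}\tv{i + 1}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gt}\n"
        )
    return out.getvalue()
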