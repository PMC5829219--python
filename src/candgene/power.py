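"""Analytic power for one-stage case-control genetic association.

Follows the genetic-association power-calculator recipe: given disease
prevalence K, risk-allele frequency p, per-allele relative risk r and a
genetic model, solve the baseline penetrance f0 from
``K = Σ_g P(g | HWE) · f_g`` with genotype relative risks (1, r, 2r−1)
(additive, on the risk scale) or (1, r, r²) (multiplicative); derive the
case/control genotype distributions by Bayes ascertainment,
``P(g|case) = P(g) f_g / K``; and compute the normal-approximation power of
the 1-df allelic (2N-allele) two-proportion comparison — pooled variance
under the null, unpooled under the alternative — at a two-sided alpha.
A Cochran-Armitage trend variant and a Monte-Carlo validation path are
also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .association import GenotypeCounts, allelic_table, pearson_chi2
from .synthetic_cohort import sample_genotype_counts

__all__ = [
    "PowerDesign",
    "genotype_penetrances",
    "case_control_genotype_freqs",
    "analytic_power",
    "empirical_power",
    "solve_min_rr",
]


@dataclass(frozen=True)
class PowerDesign:
    n_cases: int = 218
    n_controls: int = 227
    prevalence: float = 0.30
    risk_allele_freq: float = 0.03
    per_allele_rr: float = 2.0
    alpha: float = 0.05
    model: str = "additive"

    def __post_init__(self) -> None:
        for name in ("prevalence", "risk_allele_freq", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.per_allele_rr <= 0:
            raise ValueError("per_allele_rr must be positive")
        if self.model not in ("additive", "multiplicative"):
            raise ValueError("model must be 'additive' or 'multiplicative'")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")


def _hwe_probs(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def _genotype_rr(design: PowerDesign) -> np.ndarray:
    r = design.per_allele_rr
    if design.model == "additive":
        return np.array([1.0, r, 2 * r - 1.0])
    return np.array([1.0, r, r * r])


def genotype_penetrances(design: PowerDesign
                         ) -> tuple[float, float, float]:
    """Penetrances (f0, f1, f2) consistent with the prevalence and the
    genotype relative risks under HWE; an implied penetrance outside (0, 1)
    is an inconsistent design."""
    probs = _hwe_probs(design.risk_allele_freq)
    rr = _genotype_rr(design)
    f0 = design.prevalence / float(probs @ rr)
    f = f0 * rr
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError(
            "design implies a penetrance outside (0, 1); reduce the "
            "relative risk or prevalence"
        )
    return tuple(float(x) for x in f)


def case_control_genotype_freqs(
    design: PowerDesign,
) -> tuple[np.ndarray, np.ndarray]:
    """Retrospective genotype distributions:
    P(g|case) = P(g)·f_g/K and P(g|control) = P(g)·(1−f_g)/(1−K)."""
    probs = _hwe_probs(design.risk_allele_freq)
    f = np.array(genotype_penetrances(design))
    K = design.prevalence
    case = probs * f / K
    control = probs * (1 - f) / (1 - K)
    return case, control


def _allele_freqs(design: PowerDesign) -> tuple[float, float]:
    case, control = case_control_genotype_freqs(design)
    dose = np.array([0.0, 1.0, 2.0])
    return float(case @ dose / 2.0), float(control @ dose / 2.0)


def analytic_power(design: PowerDesign, statistic: str = "allelic") -> float:
    """Normal-approximation power of the two-sided 1-df association test.

    ``statistic="allelic"`` compares risk-allele frequencies over 2N alleles
    (pooled variance under H0, unpooled under H1); ``"trend"`` uses the
    Cochran-Armitage comparison of mean genotype dosage.
    """
    z_a = stats.norm.isf(design.alpha / 2.0)
    if statistic == "allelic":
        p1, p2 = _allele_freqs(design)
        m1, m2 = 2.0 * design.n_cases, 2.0 * design.n_controls
        delta = p1 - p2
        pbar = (p1 * m1 + p2 * m2) / (m1 + m2)
        se0 = np.sqrt(pbar * (1 - pbar) * (1 / m1 + 1 / m2))
        se1 = np.sqrt(p1 * (1 - p1) / m1 + p2 * (1 - p2) / m2)
    elif statistic == "trend":
        case, control = case_control_genotype_freqs(design)
        dose = np.array([0.0, 1.0, 2.0])
        mu1, mu2 = float(case @ dose), float(control @ dose)
        v1 = float(case @ dose**2) - mu1**2
        v2 = float(control @ dose**2) - mu2**2
        n1, n2 = design.n_cases, design.n_controls
        delta = mu1 - mu2
        w = n1 / (n1 + n2)
        pooled = w * case + (1 - w) * control
        mu0 = float(pooled @ dose)
        v0 = float(pooled @ dose**2) - mu0**2
        se0 = np.sqrt(v0 * (1 / n1 + 1 / n2))
        se1 = np.sqrt(v1 / n1 + v2 / n2)
    else:
        raise ValueError("statistic must be 'allelic' or 'trend'")
    if se1 == 0.0:
        return 1.0 if abs(delta) > 0 else design.alpha
    upper = stats.norm.sf((z_a * se0 - delta) / se1)
    lower = stats.norm.cdf((-z_a * se0 - delta) / se1)
    return float(upper + lower)


def empirical_power(
    design: PowerDesign, reps: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo rejection rate of the allelic Pearson χ² on cohorts
    drawn from the design's retrospective genotype distributions; returns
    (power, binomial Monte-Carlo SE).  ``reps`` must be >= 200."""
    if reps < 200:
        raise ValueError("reps must be >= 200 for a stable estimate")
    rng = np.random.default_rng(seed)
    case_p, control_p = case_control_genotype_freqs(design)
    case_counts, control_counts = sample_genotype_counts(
        rng, case_p, control_p, design.n_cases, design.n_controls, reps
    )
    hits = 0
    for cc, nc in zip(case_counts, control_counts):
        counts = GenotypeCounts(tuple(int(x) for x in cc),
                                tuple(int(x) for x in nc))
        t = allelic_table(counts)
        arr = t.as_array()
        if np.any(arr.sum(axis=0) == 0):
            continue  # monomorphic replicate: no test, no rejection
        _, _, p = pearson_chi2(t)
        if p < design.alpha:
            hits += 1
    power = hits / reps
    se = float(np.sqrt(power * (1 - power) / reps))
    return float(power), se


def solve_min_rr(
    design: PowerDesign, target_power: float = 0.80,
    bracket: tuple[float, float] = (1.0 + 1e-6, 10.0),
) -> float:
    """Smallest per-allele relative risk reaching ``target_power`` under
    the design (all other parameters held fixed)."""
    def gap(r: float) -> float:
        return analytic_power(replace(design, per_allele_rr=r)) - target_power

    def feasible(r: float) -> bool:
        try:
            genotype_penetrances(replace(design, per_allele_rr=r))
        except ValueError:
            return False
        return True

    lo, hi = bracket
    while hi > lo and not feasible(hi):
        hi = lo + 0.9 * (hi - lo)  # shrink to the feasible penetrance range
    if gap(hi) < 0:
        raise ValueError("target power unreachable within the bracket")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-6))
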