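"""Case-control association statistics for candidate-gene variants.

Implements the statistical layer of the study replica:

* Hardy-Weinberg χ² per group;
* 2×3 genotypic and collapsed dominant/recessive (2×2) Pearson χ² tests —
  uncorrected (no Yates continuity correction), which is what reproduces
  the published contingency statistics;
* odds ratios with Woolf (log-scale normal) 95% intervals, Haldane-Anscombe
  0.5 correction for sparse tables;
* gene-level carrier-burden enrichment (subjects carrying >=1 functional
  variant), with a configurable multiple-comparison correction;
* covariate-adjusted logistic modelling (maximum likelihood via
  statsmodels), forward stepwise selection with score-test entry and
  Wald-test removal, Hosmer-Lemeshow calibration, Nagelkerke pseudo-R²,
  nonparametric bootstrap p-value adjustment, and SNP × covariate
  interaction tests;
* the semi-quantitative ultrasound steatosis severity classes
  (0 absent, 1-2 mild, 3-4 moderate, 5-6 severe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "Table2x2",
    "AssociationResult",
    "OddsRatioCI",
    "LogisticModel",
    "StepwiseResult",
    "hwe_chi2",
    "collapse",
    "pearson_chi2",
    "odds_ratio_woolf",
    "genotypic_row_or",
    "allelic_table",
    "snp_association",
    "carrier_burden",
    "burden_table",
    "logistic_fit",
    "score_test",
    "stepwise_forward_wald",
    "hosmer_lemeshow",
    "nagelkerke_r2",
    "bootstrap_adjust",
    "interaction_test",
    "severity_classes",
]

Z_95 = 1.96  # normal quantile used for the Woolf interval


# --------------------------------------------------------------------------
# contingency structures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCounts:
    """2×3 case/control genotype counts, ordered (aa, aA, AA) with A the
    minor/risk allele."""

    cases: tuple[int, int, int]
    controls: tuple[int, int, int]

    def __post_init__(self) -> None:
        for grp in (self.cases, self.controls):
            if len(grp) != 3 or any(c < 0 for c in grp):
                raise ValueError("genotype counts must be 3 non-negatives")
            if sum(grp) == 0:
                raise ValueError("group totals must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.cases, self.controls], dtype=float)

    @classmethod
    def from_subjects(cls, dosages, status) -> "GenotypeCounts":
        """Tabulate risk-allele dosages (0/1/2) by case/control status;
        missing dosages (NaN) are dropped (complete-case per SNP)."""
        d = pd.Series(dosages).astype(float)
        s = pd.Series(status).astype(str)
        ok = d.notna()
        d, s = d[ok].astype(int), s[ok]
        counts = {
            g: [int(((d == k) & (s == g)).sum()) for k in (0, 1, 2)]
            for g in ("case", "control")
        }
        return cls(tuple(counts["case"]), tuple(counts["control"]))


@dataclass(frozen=True)
class Table2x2:
    """a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both group margins must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class OddsRatioCI:
    or_point: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied
    estimable: bool = True


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    df: int
    p: float
    or_point: float | None
    ci_low: float | None
    ci_high: float | None
    model: str
    adjusted: bool = False
    covariates: tuple[str, ...] = ()
    estimable: bool = True


# --------------------------------------------------------------------------
# HWE and contingency tests
# --------------------------------------------------------------------------

def hwe_chi2(counts) -> tuple[float, float]:
    """1-df χ² of observed genotype counts (aa, aA, AA) against the
    Hardy-Weinberg expectation from the sample allele frequency.
    Monomorphic samples return (0, 1)."""
    aa, het, AA = (int(c) for c in counts)
    n = aa + het + AA
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    q = (2 * AA + het) / (2 * n)
    if q == 0.0 or q == 1.0:
        return 0.0, 1.0
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    observed = np.array([aa, het, AA], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def collapse(counts: GenotypeCounts, model: str) -> Table2x2:
    """Collapse a 2×3 genotype table under a penetrance model: dominant
    treats >=1 risk allele as exposed, recessive only homozygotes."""
    ca, cb, cc = counts.cases
    na, nb, nc = counts.controls
    if model == "dominant":
        return Table2x2(a=cb + cc, b=ca, c=nb + nc, d=na)
    if model == "recessive":
        return Table2x2(a=cc, b=ca + cb, c=nc, d=na + nb)
    raise ValueError("model must be 'dominant' or 'recessive'")


def pearson_chi2(table) -> tuple[float, int, float]:
    """Uncorrected Pearson χ² for a 2×2 or 2×3 table.  No continuity
    correction is applied anywhere.  Zero margins are an error."""
    arr = table.as_array() if isinstance(table, Table2x2) \
        else np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


def odds_ratio_woolf(table: Table2x2, zero_policy: str = "haldane"
                     ) -> OddsRatioCI:
    """OR = ad/bc with the Woolf log-interval
    exp(ln OR ± 1.96·sqrt(1/a+1/b+1/c+1/d)).

    Zero cells: with ``zero_policy="haldane"`` 0.5 is added to every cell
    and the result flagged ``corrected``; with ``zero_policy="na"`` the
    result is flagged non-estimable (the convention used when a genotype
    row has no case carriers at all).
    """
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    if np.any(cells == 0):
        if zero_policy == "na":
            return OddsRatioCI(np.nan, np.nan, np.nan, estimable=False)
        if zero_policy != "haldane":
            raise ValueError("zero_policy must be 'haldane' or 'na'")
        cells = cells + 0.5
        corrected = True
    else:
        corrected = False
    a, b, c, d = cells
    or_point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_point) + np.array([-1, 1]) * Z_95 * se)
    return OddsRatioCI(float(or_point), float(lo), float(hi),
                       corrected=corrected)


def genotypic_row_or(counts: GenotypeCounts, genotype: int) -> OddsRatioCI:
    """OR of one non-reference genotype row (1 = heterozygote,
    2 = risk homozygote) versus the reference homozygote row.  A row with
    zero case carriers is reported non-estimable."""
    if genotype not in (1, 2):
        raise ValueError("genotype must be 1 (het) or 2 (risk homozygote)")
    a = counts.cases[genotype]
    c = counts.controls[genotype]
    b = counts.cases[0]
    d = counts.controls[0]
    policy = "na" if a == 0 or c == 0 else "haldane"
    return odds_ratio_woolf(Table2x2(a=a, b=b, c=c, d=d), zero_policy=policy)


def allelic_table(counts: GenotypeCounts) -> Table2x2:
    """Collapse genotypes to the 2N-allele table (risk vs other allele)."""
    ca, cb, cc = counts.cases
    na, nb, nc = counts.controls
    return Table2x2(
        a=2 * cc + cb, b=2 * ca + cb, c=2 * nc + nb, d=2 * na + nb
    )


def snp_association(counts: GenotypeCounts, model: str) -> AssociationResult:
    """One SNP under one penetrance model.

    ``model="genotypic"`` runs the 2-df χ² on the full 2×3 table (no single
    OR is attached; use :func:`genotypic_row_or` for per-row ORs);
    ``"dominant"``/``"recessive"`` collapse first; ``"allelic"`` compares
    allele counts.
    """
    if model == "genotypic":
        chi2, df, p = pearson_chi2(counts.as_array())
        return AssociationResult(chi2, df, p, None, None, None, model)
    if model in ("dominant", "recessive"):
        t = collapse(counts, model)
    elif model == "allelic":
        t = allelic_table(counts)
    else:
        raise ValueError(f"unknown model {model!r}")
    chi2, df, p = pearson_chi2(t)
    orci = odds_ratio_woolf(t)
    return AssociationResult(chi2, df, p, orci.or_point, orci.ci_low,
                             orci.ci_high, model, estimable=orci.estimable)


# --------------------------------------------------------------------------
# carrier burden
# --------------------------------------------------------------------------

def carrier_burden(carrier_flags, status
                   ) -> tuple[Table2x2, AssociationResult]:
    """Gene-level enrichment of functional-variant carriers in cases.

    ``carrier_flags`` marks subjects carrying >=1 qualifying variant in the
    gene; builds the carrier × status 2×2 and reports uncorrected Pearson χ²
    with the Woolf OR.  With no carriers at all the result is flagged
    non-estimable.
    """
    f = np.asarray(carrier_flags, dtype=bool)
    s = np.asarray([str(x) for x in status])
    if f.shape != s.shape:
        raise ValueError("flags and status must align")
    case = s == "case"
    table = Table2x2(
        a=int((f & case).sum()), b=int((~f & case).sum()),
        c=int((f & ~case).sum()), d=int((~f & ~case).sum()),
    )
    if table.a + table.c == 0:
        return table, AssociationResult(
            np.nan, 1, np.nan, np.nan, np.nan, np.nan, "carrier_burden",
            estimable=False,
        )
    chi2, df, p = pearson_chi2(table)
    orci = odds_ratio_woolf(table)
    return table, AssociationResult(
        chi2, df, p, orci.or_point, orci.ci_low, orci.ci_high,
        "carrier_burden",
    )


def burden_table(
    flags_by_gene: pd.DataFrame, status, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Carrier-burden tests for several genes with a family-wise
    multiple-comparison correction (Bonferroni by default; ``correction=None``
    reports raw p only)."""
    rows = []
    m = flags_by_gene.shape[1]
    for gene in flags_by_gene.columns:
        table, res = carrier_burden(flags_by_gene[gene].to_numpy(), status)
        rows.append({
            "gene": gene,
            "case_carriers": table.a, "case_total": table.a + table.b,
            "control_carriers": table.c, "control_total": table.c + table.d,
            "chi2": res.statistic, "p": res.p,
            "or": res.or_point, "ci_low": res.ci_low, "ci_high": res.ci_high,
        })
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_corrected"] = np.minimum(out["p"] * m, 1.0)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return out


# --------------------------------------------------------------------------
# logistic modelling
# --------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit with the pieces the downstream
    diagnostics need."""

    params: pd.Series
    bse: pd.Series
    wald_chi2: pd.Series
    pvalues: pd.Series
    ll_null: float
    ll_fitted: float
    n: int
    converged: bool
    fitted_probs: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    exog: pd.DataFrame = field(repr=False)

    def odds_ratios(self) -> pd.DataFrame:
        """exp(β) with Woolf-style Wald 95% intervals, per term."""
        lo = np.exp(self.params - Z_95 * self.bse)
        hi = np.exp(self.params + Z_95 * self.bse)
        return pd.DataFrame({
            "beta": self.params, "or": np.exp(self.params),
            "ci_low": lo, "ci_high": hi, "p": self.pvalues,
        })


def _design(X: pd.DataFrame, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if add_intercept and "const" not in X.columns:
        X = sm.add_constant(X, has_constant="add")
    return X


def logistic_fit(
    X: pd.DataFrame, y, add_intercept: bool = True,
    tol: float = 1e-8, maxiter: int = 100,
) -> LogisticModel:
    """Fit a binary logistic model by maximum likelihood (Newton/IRLS).

    ``y`` is 0/1 (or case/control strings).  Separation or non-convergence
    is flagged on the result (``converged=False``) rather than silently
    returned; coefficients diverging past |β| > 30 count as separation.
    """
    ya = np.asarray(y)
    if ya.dtype.kind in "biuf":
        yv = (ya.astype(float) > 0.5).astype(int)
    else:
        yv = np.asarray(
            [1 if str(v).lower() in ("1", "case", "true") else 0 for v in ya]
        )
    Xd = _design(X, add_intercept)
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise ValueError("design matrix is rank-deficient (aliased columns)")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yv, Xd).fit(
                disp=0, method="newton", maxiter=maxiter, tol=tol
            )
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:  # separation can raise inside the optimizer
            fit = sm.Logit(yv, Xd).fit(
                disp=0, method="bfgs", maxiter=maxiter
            )
            converged = False
    params = pd.Series(fit.params, index=Xd.columns)
    if np.max(np.abs(params.to_numpy())) > 30:
        converged = False
    bse = pd.Series(fit.bse, index=Xd.columns)
    wald = (params / bse) ** 2
    pvals = pd.Series(stats.chi2.sf(wald, df=1), index=Xd.columns)
    return LogisticModel(
        params=params, bse=bse, wald_chi2=wald, pvalues=pvals,
        ll_null=float(fit.llnull), ll_fitted=float(fit.llf),
        n=len(yv), converged=converged,
        fitted_probs=np.asarray(fit.predict(Xd)), y=yv, exog=Xd,
    )


def score_test(model: LogisticModel, candidate) -> tuple[float, float]:
    """Rao score (Lagrange multiplier) test for adding one column to a
    fitted logistic model; returns (χ², p) on 1 df."""
    x = np.asarray(candidate, dtype=float)
    X0 = model.exog.to_numpy()
    p_hat = model.fitted_probs
    w = p_hat * (1 - p_hat)
    u = float(x @ (model.y - p_hat))
    xtwx0 = (x * w) @ X0
    info0 = (X0 * w[:, None]).T @ X0
    v = float((x * w) @ x - xtwx0 @ np.linalg.solve(info0, xtwx0))
    if v <= 0:
        return 0.0, 1.0
    chi2 = u * u / v
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class StepwiseResult:
    model: LogisticModel
    selected: list[str]
    trace: list[dict]


def stepwise_forward_wald(
    candidates: pd.DataFrame, y,
    entry_p: float = 0.05, removal_p: float = 0.10,
    forced: tuple[str, ...] = (),
) -> StepwiseResult:
    """Forward stepwise logistic selection.

    At each step the candidate with the smallest score-test p-value enters
    if it beats ``entry_p``; after every entry, included terms (other than
    ``forced`` ones) whose Wald p exceeds ``removal_p`` are removed, worst
    first.  Stops when no entry or removal changes the model.  The full
    trace of entries/removals with their p-values is returned.
    """
    candidates = pd.DataFrame(candidates).astype(float)
    selected: list[str] = list(forced)
    remaining = [c for c in candidates.columns if c not in selected]
    trace: list[dict] = []
    model = logistic_fit(candidates[selected] if selected
                         else pd.DataFrame(index=candidates.index), y)
    step = 0
    while True:
        step += 1
        entered = None
        scores = {
            c: score_test(model, candidates[c].to_numpy()) for c in remaining
        }
        if scores:
            best = min(scores, key=lambda c: scores[c][1])
            if scores[best][1] < entry_p:
                entered = best
                selected.append(best)
                remaining.remove(best)
                model = logistic_fit(candidates[selected], y)
                trace.append({"step": step, "action": "enter", "term": best,
                              "p": scores[best][1]})
        removed_any = False
        while True:
            removable = [t for t in selected if t not in forced]
            if not removable:
                break
            pv = model.pvalues.drop("const", errors="ignore")
            pv = pv[pv.index.isin(removable)]
            if pv.empty or pv.max() <= removal_p:
                break
            worst = pv.idxmax()
            selected.remove(worst)
            remaining.append(worst)
            trace.append({"step": step, "action": "remove", "term": worst,
                          "p": float(pv.max())})
            model = logistic_fit(
                candidates[selected] if selected
                else pd.DataFrame(index=candidates.index), y)
            removed_any = True
        if entered is None and not removed_any:
            break
    return StepwiseResult(model=model, selected=selected, trace=trace)


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HosmerLemeshowResult:
    chi2: float
    df: int
    p: float
    groups_used: int
    merged: bool
    informative: bool = True


def hosmer_lemeshow(model: LogisticModel, groups: int = 10
                    ) -> HosmerLemeshowResult:
    """Deciles-of-risk goodness-of-fit χ² with df = groups_used − 2.

    Ties in the fitted probabilities can leave fewer than the requested
    groups (adjacent groups merged); with fewer than 3 surviving groups the
    statistic is flagged non-informative (df 0).
    """
    if groups < 2:
        raise ValueError("groups must be >= 2")
    df_data = pd.DataFrame({"p": model.fitted_probs, "y": model.y})
    binned = pd.qcut(df_data["p"], q=groups, duplicates="drop")
    used = binned.cat.categories.size
    merged = used < groups
    g = df_data.groupby(binned, observed=True)
    obs1 = g["y"].sum().to_numpy(dtype=float)
    n_g = g.size().to_numpy(dtype=float)
    exp1 = g["p"].sum().to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (obs1 - exp1) ** 2 / (exp1 * (1 - exp1 / n_g))
    chi2 = float(np.nansum(contrib))
    dof = used - 2
    if dof <= 0:
        return HosmerLemeshowResult(chi2, 0, np.nan, used, merged,
                                    informative=False)
    return HosmerLemeshowResult(
        chi2, dof, float(stats.chi2.sf(chi2, dof)), used, merged
    )


def nagelkerke_r2(model: LogisticModel) -> float:
    """Cox-Snell pseudo-R² rescaled to a maximum of 1."""
    n = model.n
    r2_cs = 1.0 - np.exp(2.0 * (model.ll_null - model.ll_fitted) / n)
    max_r2 = 1.0 - np.exp(2.0 * model.ll_null / n)
    return float(r2_cs / max_r2)


# --------------------------------------------------------------------------
# bootstrap adjustment
# --------------------------------------------------------------------------

def bootstrap_adjust(
    X: pd.DataFrame, y, B: int = 1000, seed: int = 0,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Nonparametric bootstrap adjustment of logistic Wald inference.

    Subjects are resampled with replacement ``B`` times and the model refit;
    each term's adjusted two-sided p-value is the (add-one) fraction of
    replicates whose coefficient deviates from the observed fit by at least
    the observed magnitude (shift/percentile method), and 95% intervals are
    the 2.5/97.5 bootstrap percentiles of the OR.  Aborts if more than 10%
    of replicates fail to converge.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    X = _design(X, add_intercept)
    base = logistic_fit(X, y, add_intercept=False)
    yv = base.y
    n = base.n
    boot = np.empty((B, X.shape[1]))
    bad = 0
    Xv = X.to_numpy()
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            m = logistic_fit(
                pd.DataFrame(Xv[idx], columns=X.columns), yv[idx],
                add_intercept=False,
            )
            if not m.converged:
                raise RuntimeError
            boot[b] = m.params.to_numpy()
        except Exception:
            bad += 1
            boot[b] = np.nan
    if bad > 0.10 * B:
        raise RuntimeError(
            f"bootstrap unstable: {bad}/{B} replicates failed to converge"
        )
    ok = ~np.isnan(boot).any(axis=1)
    boot = boot[ok]
    beta = base.params.to_numpy()
    shift = np.abs(boot - beta)  # centred null distribution
    p_adj = (1.0 + (shift >= np.abs(beta)).sum(axis=0)) / (len(boot) + 1.0)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "beta": beta, "or": np.exp(beta),
            "p_raw": base.pvalues.to_numpy(), "p_adj": p_adj,
            "or_ci_low": np.exp(lo), "or_ci_high": np.exp(hi),
            "n_bootstrap": len(boot),
        },
        index=X.columns,
    )


# --------------------------------------------------------------------------
# interactions and severity
# --------------------------------------------------------------------------

def interaction_test(
    X: pd.DataFrame, y, term_a: str, term_b: str
) -> tuple[AssociationResult, LogisticModel]:
    """Wald test of a SNP × covariate product term, with both main effects
    kept in the model.  An aliased product (e.g. a term with itself, or a
    product collinear with the mains) is a rank error."""
    X = pd.DataFrame(X).astype(float)
    for t in (term_a, term_b):
        if t not in X.columns:
            raise KeyError(f"main effect {t!r} missing from design")
    name = f"{term_a}:{term_b}"
    X2 = X.copy()
    X2[name] = X[term_a] * X[term_b]
    full = _design(X2, True).to_numpy()
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(f"interaction {name} is aliased with the design")
    model = logistic_fit(X2, y)
    beta = model.params[name]
    se = model.bse[name]
    res = AssociationResult(
        statistic=float(model.wald_chi2[name]), df=1,
        p=float(model.pvalues[name]),
        or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        model="interaction", adjusted=True,
        covariates=tuple(c for c in X.columns if c not in (term_a, term_b)),
    )
    return res, model


_SEVERITY_LABELS = {0: "absent", 1: "mild", 2: "mild", 3: "moderate",
                    4: "moderate", 5: "severe", 6: "severe"}


def severity_classes(grade: int) -> tuple[str, bool]:
    """Map an ultrasound steatosis grade 0-6 to its 4-level label and the
    binary severe flag (grades 5-6 vs 0-4)."""
    g = int(grade)
    if g != grade or not 0 <= g <= 6:
        raise ValueError("steatosis grade must be an integer in 0..6")
    label = _SEVERITY_LABELS[g]
    return label, label == "severe"
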