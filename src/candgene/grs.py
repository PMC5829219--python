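"""Unweighted and weighted 4-SNP genetic risk scores (GRS).

The unweighted score is the plain count of risk alleles across the four
index SNPs (theoretical range 0-8).  The weighted score multiplies each
risk-allele dosage by a fixed per-allele β-coefficient taken from an
external reference cohort (Dallas Heart Study estimates) and sums the
products; the cohort is then split at fixed weighted-score tertile
boundaries and the tertile-disease trend tested by Pearson χ² with
per-tertile odds ratios against the bottom tertile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (
    AssociationResult,
    Table2x2,
    odds_ratio_woolf,
    pearson_chi2,
)

__all__ = [
    "GRSWeights",
    "GRSProfile",
    "DALLAS_HEART_WEIGHTS",
    "DEFAULT_TERTILE_BOUNDARIES",
    "unweighted_grs",
    "weighted_grs",
    "assign_tertile",
    "recompute_tertile_boundaries",
    "grs_profiles",
    "grs_trend_test",
]


@dataclass(frozen=True)
class GRSWeights:
    """Ordered per-SNP risk alleles and per-allele β-coefficients."""

    entries: tuple[tuple[str, str, float], ...]  # (snp_id, risk_allele, beta)

    def __post_init__(self) -> None:
        for snp_id, _allele, beta in self.entries:
            if not np.isfinite(beta):
                raise ValueError(f"{snp_id}: beta must be finite")

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    @property
    def betas(self) -> dict[str, float]:
        return {e[0]: e[2] for e in self.entries}

    @classmethod
    def from_table(cls, path) -> "GRSWeights":
        """Read a weights TSV with columns snp_id, risk_allele, beta."""
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(
            (str(r.snp_id), str(r.risk_allele), float(r.beta))
            for r in df.itertuples()
        ))


#: Per-allele log-odds weights for the 4-SNP score (external reference
#: estimates): PNPLA3 rs738409-G, TM6SF2 rs58542926-T, GCKR rs1260326-T,
#: MBOAT7 rs641738-T.
DALLAS_HEART_WEIGHTS = GRSWeights((
    ("rs738409", "G", 0.2653),
    ("rs58542926", "T", 0.2711),
    ("rs1260326", "T", 0.0649),
    ("rs641738", "T", 0.0575),
))

#: Fixed weighted-score tertile cuts: T1 <= 0.1775 < T2 <= 0.3877 < T3.
DEFAULT_TERTILE_BOUNDARIES = (0.1775, 0.3877)


@dataclass(frozen=True)
class GRSProfile:
    subject_id: str
    unweighted: int
    weighted: float
    tertile: str


def _check_dosages(dosages: dict[str, float]) -> dict[str, int]:
    clean: dict[str, int] = {}
    for snp, d in dosages.items():
        if d is None or (isinstance(d, float) and np.isnan(d)):
            raise ValueError(f"missing dosage for {snp}; no imputation")
        di = int(d)
        if di != d or di not in (0, 1, 2):
            raise ValueError(f"{snp}: dosage must be 0, 1 or 2")
        clean[snp] = di
    return clean


def unweighted_grs(dosages: dict[str, float]) -> int:
    """Count of risk alleles across the panel (0-2 per SNP)."""
    return sum(_check_dosages(dosages).values())


def weighted_grs(dosages: dict[str, float], weights: GRSWeights) -> float:
    """Σ β_i × dosage_i over the weight panel; every dosage SNP must have
    a weight."""
    clean = _check_dosages(dosages)
    betas = weights.betas
    unmatched = set(clean) - set(betas)
    if unmatched:
        raise ValueError(f"no weights for SNPs: {sorted(unmatched)}")
    return float(sum(betas[s] * d for s, d in clean.items()))


def assign_tertile(
    weighted: float, boundaries: tuple[float, float] = DEFAULT_TERTILE_BOUNDARIES
) -> str:
    """T1 if score <= b1; T2 if b1 < score <= b2; T3 if score > b2."""
    b1, b2 = boundaries
    if not b1 < b2:
        raise ValueError("tertile boundaries must be ascending")
    if weighted <= b1:
        return "T1"
    if weighted <= b2:
        return "T2"
    return "T3"


def recompute_tertile_boundaries(scores) -> tuple[float, float]:
    """Empirical 33.3/66.7 percentiles of a score distribution."""
    s = np.asarray(scores, dtype=float)
    if np.unique(s).size < 3:
        raise ValueError("need >= 3 distinct scores to form tertiles")
    b1, b2 = np.percentile(s, [100 / 3, 200 / 3])
    return float(b1), float(b2)


def grs_profiles(
    subjects: pd.DataFrame,
    weights: GRSWeights = DALLAS_HEART_WEIGHTS,
    boundaries: tuple[float, float] | None = DEFAULT_TERTILE_BOUNDARIES,
) -> pd.DataFrame:
    """Per-subject GRS table from a subject frame with one dosage column
    per panel SNP.

    Subjects missing any panel genotype are excluded (no imputation) and
    counted in the ``n_excluded`` attribute of the returned frame.  With
    ``boundaries=None`` the tertile cuts are recomputed empirically from
    the analysed subjects.
    """
    snps = list(weights.snp_ids)
    missing_cols = [s for s in snps if s not in subjects.columns]
    if missing_cols:
        raise ValueError(f"subject table lacks dosage columns: {missing_cols}")
    complete = subjects.dropna(subset=snps)
    rows = []
    for _, r in complete.iterrows():
        dosages = {s: r[s] for s in snps}
        rows.append({
            "subject_id": r.get("subject_id", str(r.name)),
            "status": r.get("status"),
            "unweighted": unweighted_grs(dosages),
            "weighted": weighted_grs(dosages, weights),
        })
    out = pd.DataFrame(rows)
    if boundaries is None:
        boundaries = recompute_tertile_boundaries(out["weighted"])
    out["tertile"] = [assign_tertile(w, boundaries) for w in out["weighted"]]
    out.attrs["n_excluded"] = len(subjects) - len(complete)
    out.attrs["boundaries"] = boundaries
    return out


def grs_trend_test(tertiles, status) -> tuple[AssociationResult, pd.DataFrame]:
    """Pearson χ² across the tertile × status 2×3 table, plus per-tertile
    ORs versus T1.  An empty tertile is an error (flagged upstream)."""
    t = pd.Series([str(x) for x in tertiles])
    s = pd.Series([str(x) for x in status])
    table = pd.crosstab(s, t).reindex(
        index=["case", "control"], columns=["T1", "T2", "T3"], fill_value=0
    )
    if (table.sum(axis=0) == 0).any():
        raise ValueError("empty tertile: trend test not defined")
    chi2, df, p = pearson_chi2(table.to_numpy())
    res = AssociationResult(chi2, df, p, None, None, None, "grs_trend")
    ors = []
    for tert in ("T2", "T3"):
        orci = odds_ratio_woolf(Table2x2(
            a=int(table.loc["case", tert]), b=int(table.loc["case", "T1"]),
            c=int(table.loc["control", tert]),
            d=int(table.loc["control", "T1"]),
        ))
        ors.append({"tertile": tert, "or": orci.or_point,
                    "ci_low": orci.ci_low, "ci_high": orci.ci_high})
    return res, pd.DataFrame(ors)
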