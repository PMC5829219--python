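"""Consensus deleteriousness scoring from five in-silico predictors.

Missense variants are run (upstream, outside this package) through SIFT,
PolyPhen-2, PROVEAN, SNPs&GO and MutationTaster.  This module aggregates
their categorical verdicts into

* a collective score 0-10: each tool contributes 0 (neutral / benign /
  polymorphism), 1 (possibly damaging — a PolyPhen-2-specific grade) or 2
  (deleterious / probably damaging / disease causing);
* a binary "damaging" call: deleterious in at least 3 of the 5 tools
  (the intermediate possibly-damaging grade does not count).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TOOLS",
    "VERDICTS",
    "DEFAULT_VOCABULARY",
    "PredictionSet",
    "normalize_verdict",
    "collective_score",
    "is_damaging",
    "read_predictions",
    "score_table",
]

TOOLS = ("sift", "polyphen2", "provean", "snp_go", "mutation_taster")
VERDICTS = ("neutral", "possibly_damaging", "damaging")

_VERDICT_POINTS = {"neutral": 0, "possibly_damaging": 1, "damaging": 2}

#: normalization of tool-specific output labels to the three-level verdict
#: vocabulary; keys are lower-cased with internal whitespace collapsed.
DEFAULT_VOCABULARY: dict[str, str] = {
    "neutral": "neutral",
    "tolerated": "neutral",
    "benign": "neutral",
    "polymorphism": "neutral",
    "possibly damaging": "possibly_damaging",
    "possibly_damaging": "possibly_damaging",
    "probably damaging": "damaging",
    "probably_damaging": "damaging",
    "damaging": "damaging",
    "deleterious": "damaging",
    "disease causing": "damaging",
    "disease_causing": "damaging",
}


def normalize_verdict(
    label: str, vocabulary: dict[str, str] | None = None
) -> str:
    """Map a raw tool label onto {neutral, possibly_damaging, damaging}."""
    vocab = DEFAULT_VOCABULARY if vocabulary is None else vocabulary
    key = " ".join(str(label).strip().lower().split())
    try:
        return vocab[key]
    except KeyError:
        raise ValueError(f"unrecognized predictor label: {label!r}") from None


@dataclass(frozen=True)
class PredictionSet:
    """Verdicts from exactly the five predictor roles.

    The intermediate grade is PolyPhen-2's "possibly damaging" and is only
    accepted for that role.
    """

    sift: str
    polyphen2: str
    provean: str
    snp_go: str
    mutation_taster: str

    def __post_init__(self) -> None:
        for tool in TOOLS:
            v = getattr(self, tool)
            if v not in VERDICTS:
                raise ValueError(
                    f"{tool}: verdict must be one of {VERDICTS}, got {v!r}"
                )
            if v == "possibly_damaging" and tool != "polyphen2":
                raise ValueError(
                    f"{tool}: possibly_damaging is a PolyPhen-2 grade"
                )

    def verdicts(self) -> tuple[str, ...]:
        return tuple(getattr(self, t) for t in TOOLS)


def collective_score(preds: PredictionSet) -> int:
    """Sum of per-tool points (neutral 0, possibly damaging 1,
    damaging 2); range 0-10."""
    return sum(_VERDICT_POINTS[v] for v in preds.verdicts())


def is_damaging(preds: PredictionSet) -> bool:
    """Consensus damaging call: >= 3 of 5 tools report a full deleterious
    verdict."""
    return sum(v == "damaging" for v in preds.verdicts()) >= 3


# --------------------------------------------------------------------------
# tabular interface
# --------------------------------------------------------------------------

def read_predictions(
    path, vocabulary: dict[str, str] | None = None
) -> dict[str, PredictionSet]:
    """Read a variant x tool verdict TSV (columns: variant, then the five
    tool columns) into PredictionSets keyed by variant id.  Raw labels are
    normalized through the vocabulary; missing verdicts are an error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [t for t in TOOLS if t not in df.columns]
    if missing:
        raise ValueError(f"prediction table lacks tool columns: {missing}")
    out: dict[str, PredictionSet] = {}
    for _, row in df.iterrows():
        if row[list(TOOLS)].isna().any():
            raise ValueError(
                f"variant {row['variant']}: missing predictor verdict"
            )
        out[row["variant"]] = PredictionSet(
            **{t: normalize_verdict(row[t], vocabulary) for t in TOOLS}
        )
    return out


def score_table(preds_by_variant: dict[str, PredictionSet]) -> pd.DataFrame:
    """Per-variant collective score and consensus damaging flag."""
    rows = [
        {
            "variant": vid,
            "collective_score": collective_score(p),
            "damaging": is_damaging(p),
        }
        for vid, p in preds_by_variant.items()
    ]
    return pd.DataFrame(rows, columns=["variant", "collective_score",
                                       "damaging"])
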