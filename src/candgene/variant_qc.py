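"""Post-caller variant quality filtering and annotation classing.

Implements the custom filtering applied to amplicon-resequencing calls after
the variant caller: a call is high-confidence iff

* read depth DP >= 30,
* genotype quality GQ >= 30,
* alternate-allele fraction AF (percent scale) in [33, 50] (heterozygous
  window) or [70, 100] (homozygous window), and
* alternate observations are balanced across strands: each strand carries at
  least ``strand_balance_min`` (default 20%) of the alternate reads.

All thresholds are inclusive.  Also provides the population-MAF frequency
classes (rare < 0.01 <= low-frequency < 0.05 <= common) and the functional
annotation rule (nonsense, frameshift, splice-region, missense).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

__all__ = [
    "ANNOTATION_CLASSES",
    "FUNCTIONAL_ANNOTATIONS",
    "VariantCall",
    "FilterVerdict",
    "filter_high_confidence",
    "classify_maf",
    "classify_function",
    "summarize_variant_classes",
    "read_vcf_calls",
    "filter_vcf",
]

ANNOTATION_CLASSES = frozenset(
    {"nonsense", "frameshift", "splice-region", "missense", "synonymous",
     "intronic", "other"}
)
FUNCTIONAL_ANNOTATIONS = frozenset(
    {"nonsense", "frameshift", "splice-region", "missense"}
)

#: order in which failed rules are reported
_RULE_ORDER = ("DP", "GQ", "AF", "STRAND")


@dataclass(frozen=True)
class VariantCall:
    """One called variant with the QC metrics the filter inspects.

    ``af`` is the alternate-allele fraction on the percent scale (0-100);
    ``maf`` is the population minor-allele fraction in [0, 0.5] or None when
    unknown.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    dp: int
    gq: float
    af: float
    saf: int
    sar: int
    gene: str | None = None
    annotation: str | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.dp < 0:
            raise ValueError("dp must be non-negative")
        if not 0.0 <= self.af <= 100.0:
            raise ValueError("af is a percentage in [0, 100]")
        if self.saf < 0 or self.sar < 0 or self.saf + self.sar > self.dp:
            raise ValueError("strand counts must be >= 0 and sum to <= dp")


@dataclass(frozen=True)
class FilterVerdict:
    kept: bool
    reasons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must hold exactly when no reasons")


def filter_high_confidence(
    call: VariantCall, strand_balance_min: float = 0.2
) -> FilterVerdict:
    """Apply the high-confidence rules; reasons list every failed rule in
    the fixed order DP, GQ, AF, STRAND."""
    reasons: list[str] = []
    if call.dp < 30:
        reasons.append("DP")
    if call.gq < 30:
        reasons.append("GQ")
    if not (33.0 <= call.af <= 50.0 or 70.0 <= call.af <= 100.0):
        reasons.append("AF")
    n_alt = call.saf + call.sar
    if n_alt == 0:
        if call.af > 0:
            # alt fraction claimed but no strand-resolved alt support
            reasons.append("STRAND")
    elif min(call.saf, call.sar) / n_alt < strand_balance_min:
        reasons.append("STRAND")
    return FilterVerdict(kept=not reasons, reasons=tuple(reasons))


def classify_maf(maf: float) -> str:
    """Frequency class of a minor-allele fraction: rare (<0.01),
    low_frequency ([0.01, 0.05)) or common (>=0.05)."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError("minor allele fraction must lie in [0, 0.5]")
    if maf < 0.01:
        return "rare"
    if maf < 0.05:
        return "low_frequency"
    return "common"


def classify_function(annotation: str) -> str:
    """Functional iff nonsense, frameshift, splice-region or missense."""
    if annotation not in ANNOTATION_CLASSES:
        raise ValueError(f"unknown annotation class: {annotation!r}")
    return "functional" if annotation in FUNCTIONAL_ANNOTATIONS \
        else "non_functional"


def summarize_variant_classes(calls: list[VariantCall]) -> pd.DataFrame:
    """Cross-tabulate annotation class against MAF class.

    Returns a DataFrame indexed by annotation with MAF-class columns (an
    ``unknown`` column collects calls without a population MAF); the grand
    total equals ``len(calls)``.
    """
    ann_order = ["nonsense", "frameshift", "splice-region", "missense",
                 "synonymous", "intronic", "other"]
    maf_order = ["rare", "low_frequency", "common", "unknown"]
    table = pd.DataFrame(0, index=ann_order, columns=maf_order, dtype=int)
    for c in calls:
        ann = c.annotation if c.annotation in ANNOTATION_CLASSES else "other"
        mcls = "unknown" if c.maf is None else classify_maf(c.maf)
        table.loc[ann, mcls] += 1
    return table


# --------------------------------------------------------------------------
# VCF I/O
# --------------------------------------------------------------------------

#: default VCF field names for the QC metrics; remap for other caller
#: dialects, e.g. ``{"saf": "FAO_FWD"}``.
DEFAULT_FIELD_MAP = {
    "dp": "DP", "gq": "GQ", "af": "AF", "saf": "SAF", "sar": "SAR",
    "gene": "GENE", "annotation": "ANN", "maf": "MAF",
}


def _lookup(record, sample, key):
    """FORMAT (first sample) takes precedence over INFO."""
    if sample is not None and key in record.samples[sample]:
        v = record.samples[sample][key]
        if v is not None:
            return v
    return record.info.get(key)


def _scalar(value):
    if isinstance(value, tuple):
        value = value[0]
    return value


def read_vcf_calls(
    path, field_map: dict[str, str] | None = None
) -> list[VariantCall]:
    """Read an uncompressed or bgzipped VCF into VariantCall objects.

    QC metrics are sought first in the first sample's FORMAT fields, then
    in INFO, under the (configurable) field names in ``field_map``.
    AF values on the fraction scale (<= 1 with depth support) are assumed to
    already be percentages per the caller dialect written by this package;
    callers emitting fractions should pre-scale via the field map dialects.
    """
    fm = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fm.update(field_map)
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        sample = next(iter(vf.header.samples), None)
        for rec in vf:
            def get(slot, cast=None, default=None):
                v = _scalar(_lookup(rec, sample, fm[slot]))
                if v is None:
                    return default
                return cast(v) if cast else v

            alt = rec.alts[0] if rec.alts else "."
            maf = get("maf", float)
            calls.append(
                VariantCall(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(alt),
                    dp=get("dp", int, 0),
                    gq=get("gq", float, 0.0),
                    af=get("af", float, 0.0),
                    saf=get("saf", int, 0),
                    sar=get("sar", int, 0),
                    gene=get("gene", str),
                    annotation=get("annotation", str),
                    maf=maf,
                )
            )
    return calls


def filter_vcf(
    vcf_in,
    kept_out,
    rejects_out,
    strand_balance_min: float = 0.2,
    field_map: dict[str, str] | None = None,
) -> tuple[int, int]:
    """Filter a VCF file; write kept records to ``kept_out`` (VCF) and
    rejected records with their failed rules to ``rejects_out`` (TSV).
    Returns (n_kept, n_rejected)."""
    fm = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fm.update(field_map)
    n_kept = n_rej = 0
    with pysam.VariantFile(str(vcf_in)) as vf, \
            open(kept_out, "w") as kept_fh, \
            open(rejects_out, "w", newline="") as rej_fh:
        kept_fh.write(str(vf.header))
        writer = csv.writer(rej_fh, delimiter="\t")
        writer.writerow(["chrom", "pos", "ref", "alt", "reasons"])
        sample = next(iter(vf.header.samples), None)
        for rec in vf:
            def get(slot, cast, default):
                v = _scalar(_lookup(rec, sample, fm[slot]))
                return default if v is None else cast(v)

            call = VariantCall(
                chrom=str(rec.chrom), pos=int(rec.pos), ref=str(rec.ref),
                alt=str(rec.alts[0]) if rec.alts else ".",
                dp=get("dp", int, 0), gq=get("gq", float, 0.0),
                af=get("af", float, 0.0),
                saf=get("saf", int, 0), sar=get("sar", int, 0),
            )
            verdict = filter_high_confidence(call, strand_balance_min)
            if verdict.kept:
                kept_fh.write(str(rec))
                n_kept += 1
            else:
                writer.writerow(
                    [call.chrom, call.pos, call.ref, call.alt,
                     ",".join(verdict.reasons)]
                )
                n_rej += 1
    return n_kept, n_rej
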