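"""End-to-end study orchestration: QC → classes → burden → association →
GRS → power, under one flat key-value configuration with reproducible
seeding.

Every output table carries the run seed and a SHA-256 hash of the
normalized configuration in a leading ``#`` comment line, so a report
bundle is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import grs as grs_mod
from . import power as power_mod
from . import variant_qc

log = logging.getLogger("candgene")

__all__ = ["RunConfig", "run_study"]

#: index SNP → gene and the penetrance coding used for adjusted models
SNP_GENES = {
    "rs738409": "PNPLA3",
    "rs58542926": "TM6SF2",
    "rs1260326": "GCKR",
    "rs641738": "MBOAT7",
}
SNP_CODING = {
    "rs738409": "dominant",
    "rs58542926": "dominant",
    "rs1260326": "recessive",
    "rs641738": "recessive",
}

_KNOWN_KEYS = {
    "vcf", "subjects", "weights", "predictions", "out", "seed", "bootstrap",
    "models", "covariates", "strand_balance_min", "entry_p", "removal_p",
    "boundaries",
}


@dataclass
class RunConfig:
    subjects: Path
    out: Path
    vcf: Path | None = None
    weights: Path | None = None
    predictions: Path | None = None
    seed: int = 0
    bootstrap: int = 0
    models: tuple[str, ...] = ("genotypic", "dominant", "recessive")
    covariates: tuple[str, ...] = ("age", "sex_m", "bmi", "log_homa",
                                   "log_tg")
    strand_balance_min: float = 0.2
    entry_p: float = 0.05
    removal_p: float = 0.10
    boundaries: tuple[float, float] = grs_mod.DEFAULT_TERTILE_BOUNDARIES
    raw_text: str = field(default="", repr=False)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` config; unknown keys are rejected."""
        text = Path(path).read_text()
        kv: dict[str, str] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in _KNOWN_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kv[key] = value
        if "subjects" not in kv or "out" not in kv:
            raise ValueError("config must set 'subjects' and 'out'")
        cfg = cls(subjects=Path(kv["subjects"]), out=Path(kv["out"]),
                  raw_text=text)
        for name in ("vcf", "weights", "predictions"):
            if name in kv:
                setattr(cfg, name, Path(kv[name]))
        if "seed" in kv:
            cfg.seed = int(kv["seed"])
        if "bootstrap" in kv:
            cfg.bootstrap = int(kv["bootstrap"])
        if "models" in kv:
            cfg.models = tuple(m.strip() for m in kv["models"].split(","))
        if "covariates" in kv:
            cfg.covariates = tuple(c.strip()
                                   for c in kv["covariates"].split(","))
        for name in ("strand_balance_min", "entry_p", "removal_p"):
            if name in kv:
                setattr(cfg, name, float(kv[name]))
        if "boundaries" in kv:
            b = tuple(float(x) for x in kv["boundaries"].split(","))
            if len(b) != 2:
                raise ValueError("boundaries must be two comma-separated cuts")
            cfg.boundaries = b
        for name in ("subjects", "vcf", "weights", "predictions"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        return cfg

    def hash(self) -> str:
        payload = self.raw_text or json.dumps(
            {k: str(getattr(self, k)) for k in sorted(_KNOWN_KEYS)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp_and_write(df: pd.DataFrame, path: Path, seed: int,
                     cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config_sha256={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _prepare_regression_frame(subjects: pd.DataFrame) -> pd.DataFrame:
    """Derive the analysis covariates: sex indicator and log-transformed
    skewed variables (TG, HOMA-IR)."""
    df = subjects.copy()
    df["sex_m"] = (df["sex"].astype(str) == "M").astype(float)
    df["log_homa"] = np.log(df["homa_ir"].astype(float))
    df["log_tg"] = np.log(df["tg"].astype(float))
    df["y"] = (df["status"].astype(str) == "case").astype(int)
    return df


def run_study(config: RunConfig) -> dict[str, Path]:
    """Run the full replica; returns the paths of the report bundle.

    Stage order: QC (if a VCF is supplied) → variant classes → carrier
    burden → per-SNP association → adjusted/stepwise regression → GRS →
    power.  A stage failure aborts with the stage name and removes any
    partial outputs.
    """
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    written: list[Path] = []
    bundle: dict[str, Path] = {}
    stage = "init"

    def emit(name: str, df: pd.DataFrame, fname: str) -> None:
        path = out_dir / fname
        _stamp_and_write(df, path, config.seed, cfg_hash)
        written.append(path)
        bundle[name] = path

    try:
        # ------------------------------------------------ QC + classes
        if config.vcf is not None:
            stage = "qc"
            kept_path = out_dir / "kept.vcf"
            rejects_path = out_dir / "rejects.tsv"
            n_kept, n_rej = variant_qc.filter_vcf(
                config.vcf, kept_path, rejects_path,
                strand_balance_min=config.strand_balance_min,
            )
            written += [kept_path, rejects_path]
            bundle["kept_vcf"] = kept_path
            bundle["rejects"] = rejects_path
            log.info("qc: %d kept, %d rejected", n_kept, n_rej)
            emit("qc_summary", pd.DataFrame(
                [{"n_input": n_kept + n_rej, "n_kept": n_kept,
                  "n_rejected": n_rej}]), "qc_summary.tsv")

            stage = "variant_classes"
            calls = variant_qc.read_vcf_calls(config.vcf)
            classes = variant_qc.summarize_variant_classes(calls)
            emit("variant_classes",
                 classes.reset_index(names="annotation"),
                 "variant_classes.tsv")
            log.info("variant_classes: %d calls tabulated", len(calls))

        # ------------------------------------------------ subjects
        stage = "subjects"
        subjects = pd.read_csv(config.subjects, sep="\t", comment="#")
        df = _prepare_regression_frame(subjects)
        snps = [s for s in SNP_GENES if s in df.columns]
        if not snps:
            raise ValueError("subject table has no index-SNP dosage columns")
        log.info("subjects: %d cases / %d controls, %d SNPs",
                 int(df["y"].sum()), int((1 - df["y"]).sum()), len(snps))

        # ------------------------------------------------ carrier burden
        stage = "burden"
        flags = pd.DataFrame({
            SNP_GENES[s]: (df[s].astype(float) >= 1) for s in snps
        })
        extra = [c for c in df.columns if c.startswith("carrier_")]
        for c in extra:
            flags[c.removeprefix("carrier_")] = df[c].astype(bool)
        burden = assoc.burden_table(flags, df["status"])
        emit("burden", burden, "burden.tsv")

        # ------------------------------------------------ per-SNP tests
        stage = "association"
        rows = []
        for snp in snps:
            counts = assoc.GenotypeCounts.from_subjects(df[snp], df["status"])
            hwe_chi2, hwe_p = assoc.hwe_chi2(counts.controls)
            for model in config.models:
                r = assoc.snp_association(counts, model)
                rows.append({
                    "snp": snp, "gene": SNP_GENES[snp], "model": model,
                    "chi2": r.statistic, "df": r.df, "p": r.p,
                    "or": r.or_point, "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "hwe_chi2_controls": hwe_chi2, "hwe_p_controls": hwe_p,
                })
        emit("association", pd.DataFrame(rows), "association.tsv")

        # ------------------------------------------------ regression layer
        stage = "regression"
        terms = pd.DataFrame(index=df.index)
        for snp in snps:
            coding = SNP_CODING[snp]
            d = df[snp].astype(float)
            terms[f"{snp}_{coding[:3]}"] = (
                (d >= 1) if coding == "dominant" else (d == 2)
            ).astype(float)
        for cov in config.covariates:
            terms[cov] = df[cov].astype(float)
        sel = assoc.stepwise_forward_wald(
            terms, df["y"], entry_p=config.entry_p,
            removal_p=config.removal_p,
        )
        trace = pd.DataFrame(sel.trace) if sel.trace else pd.DataFrame(
            columns=["step", "action", "term", "p"])
        emit("selection_trace", trace, "selection_trace.tsv")
        if sel.selected:
            ors = sel.model.odds_ratios().reset_index(names="term")
            hl = assoc.hosmer_lemeshow(sel.model)
            diag = pd.DataFrame([{
                "nagelkerke_r2": assoc.nagelkerke_r2(sel.model),
                "hl_chi2": hl.chi2, "hl_df": hl.df, "hl_p": hl.p,
                "converged": sel.model.converged,
            }])
        else:
            ors = pd.DataFrame(columns=["term", "beta", "or", "ci_low",
                                        "ci_high", "p"])
            diag = pd.DataFrame([{"nagelkerke_r2": 0.0, "hl_chi2": np.nan,
                                  "hl_df": 0, "hl_p": np.nan,
                                  "converged": True}])
        emit("adjusted_model", ors, "adjusted_model.tsv")
        emit("model_diagnostics", diag, "model_diagnostics.tsv")

        if config.bootstrap > 0 and sel.selected:
            stage = "bootstrap"
            boot = assoc.bootstrap_adjust(
                terms[sel.selected], df["y"], B=config.bootstrap,
                seed=config.seed,
            )
            emit("bootstrap", boot.reset_index(names="term"),
                 "bootstrap.tsv")

        # ------------------------------------------------ GRS
        stage = "grs"
        weights = (grs_mod.GRSWeights.from_table(config.weights)
                   if config.weights is not None
                   else grs_mod.DALLAS_HEART_WEIGHTS)
        panel = [s for s in weights.snp_ids if s in df.columns]
        if len(panel) == len(weights.snp_ids):
            profiles = grs_mod.grs_profiles(df, weights, config.boundaries)
            emit("grs_profiles", profiles, "grs_profiles.tsv")
            trend, tert_ors = grs_mod.grs_trend_test(
                profiles["tertile"], profiles["status"]
            )
            summary = pd.DataFrame([{
                "chi2": trend.statistic, "df": trend.df, "p": trend.p,
            }])
            emit("grs_trend", summary, "grs_trend.tsv")
            emit("grs_tertile_ors", tert_ors, "grs_tertile_ors.tsv")
        else:
            log.info("grs: skipped (panel SNPs missing from subject table)")

        # ------------------------------------------------ power
        stage = "power"
        n1 = int(df["y"].sum())
        n0 = int((1 - df["y"]).sum())
        designs = {
            "low_frequency": power_mod.PowerDesign(
                n_cases=n1, n_controls=n0, risk_allele_freq=0.03),
            "common": power_mod.PowerDesign(
                n_cases=n1, n_controls=n0, risk_allele_freq=0.30),
        }
        power_rows = [
            {"design": name, "freq": d.risk_allele_freq,
             "rr": d.per_allele_rr, "prevalence": d.prevalence,
             "power": power_mod.analytic_power(d)}
            for name, d in designs.items()
        ]
        emit("power", pd.DataFrame(power_rows), "power.tsv")

        # ------------------------------------------------ manifest
        stage = "manifest"
        manifest = {
            "seed": config.seed, "config_sha256": cfg_hash,
            "outputs": {k: str(v) for k, v in bundle.items()},
        }
        mpath = out_dir / "run_manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        bundle["manifest"] = mpath
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    return bundle
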