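"""End-to-end pipeline stages and the printed-tally reproduction pathway.

Stages (each idempotent given the seed, each recorded in a run manifest):

1. ``cmd_simulate``    — generate a cohort and write it as TSV.
2. ``cmd_profile_bsp`` — pooled BS-PCR sequencing of every sample on both
   strands, conversion QC, three-level calls, block summaries, and the
   HCC-vs-controls pooled-variance t tests.
3. ``cmd_run_msp``     — both MSP assays in duplicate on every sample.
4. ``cmd_evaluate``    — sensitivity/specificity/AUROC per assay and control
   set, the Fisher specificity contrast, ROC points, AFP quadrants, and the
   two-marker combination.
5. ``reproduce_printed`` — recompute the published summary statistics from
   bundled count fixtures through the same diagnostics code paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bsp, diagnostics, msp
from .cohort import (
    Cohort,
    CohortSpec,
    MethylationModel,
    TissueClass,
    default_model,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .reference import (
    CpGCensus,
    Region,
    ReferenceRegion,
    Strand,
    read_region,
    synthetic_promoter,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "load_reference",
    "cmd_simulate",
    "cmd_profile_bsp",
    "cmd_run_msp",
    "cmd_evaluate",
    "run_pipeline",
    "reproduce_printed",
    "PRINTED_FIXTURE_IDS",
]

logger = logging.getLogger("methylmarker")

CONTROL_SETS = {
    "hepatitis+cirrhosis": (TissueClass.HEPATITIS, TissueClass.CIRRHOSIS),
    "hepatitis+cirrhosis+adjacent": (
        TissueClass.HEPATITIS,
        TissueClass.CIRRHOSIS,
        TissueClass.ADJACENT_NON_HCC,
    ),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration for all pipeline stages (YAML-serialisable)."""

    reference: str = "synthetic"  # "synthetic" or a FASTA path
    start_offset: int = 999
    tss_position: int = 1354
    include_extension: bool = True
    boundary_nt: int = -48
    class_counts: dict[str, int] = field(
        default_factory=lambda: {"hcc": 120, "hepatitis": 35, "cirrhosis": 35}
    )
    n_molecules: int = 300
    model: MethylationModel = field(default_factory=default_model)
    bisulfite_efficiency: float = 0.99
    noise_sd: float = 0.02
    detect_limit: float = 0.10
    high_threshold: float = 0.50
    qc_bound: float = 0.95
    msp_input_copies: int = 300
    msp_duplicates: int = 2
    msp_cutoff: float = 10.0
    afp_threshold: float = 20.0
    seed: int = 0
    assays: list[dict] | None = None  # custom assay defs; None = bundled pair

    def __post_init__(self) -> None:
        for name in ("detect_limit", "high_threshold", "qc_bound"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.msp_cutoff < 0 or self.afp_threshold <= 0:
            raise ValueError("cutoffs must be positive")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "model"}
        d["model"] = self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d:
            d["model"] = MethylationModel.from_dict(d["model"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        try:
            return cls.from_dict(d or {})
        except (TypeError, ValueError, KeyError) as e:
            raise PipelineError(f"malformed config {path}: {e}") from e

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_reference(cfg: RunConfig) -> tuple[ReferenceRegion, CpGCensus]:
    if cfg.reference == "synthetic":
        region = synthetic_promoter(include_extension=cfg.include_extension)
    else:
        region = read_region(cfg.reference, cfg.start_offset, cfg.tss_position)
    return region, CpGCensus.from_region(region, cfg.boundary_nt)


def _record_manifest(
    outdir: Path, command: str, cfg: RunConfig, outputs: dict[str, Path]
) -> None:
    manifest_path = outdir / "manifest.json"
    entries = []
    if manifest_path.exists():
        entries = json.loads(manifest_path.read_text())
    for label, path in outputs.items():
        entries.append(
            {
                "output": str(Path(path).relative_to(outdir)),
                "label": label,
                "command": command,
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
            }
        )
    manifest_path.write_text(json.dumps(entries, indent=2))


def _stage_rng(cfg: RunConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


# ---------------------------------------------------------------------------
# stage 1: simulate
# ---------------------------------------------------------------------------


def cmd_simulate(cfg: RunConfig, outdir: str | Path) -> Cohort:
    """Generate the configured cohort and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _, census = load_reference(cfg)
    spec = CohortSpec(
        class_counts={TissueClass(k): v for k, v in cfg.class_counts.items()},
        n_molecules=cfg.n_molecules,
        seed=cfg.seed,
    )
    cohort = generate_cohort(spec, model=cfg.model, census=census)
    outputs = write_cohort(cohort, outdir)
    logger.info("simulated %d samples into %s", len(cohort), outdir)
    _record_manifest(outdir, "simulate", cfg, outputs)
    return cohort


# ---------------------------------------------------------------------------
# stage 2: BSP profiling
# ---------------------------------------------------------------------------


def cmd_profile_bsp(
    cfg: RunConfig, cohort_dir: str | Path, cohort: Cohort | None = None
) -> dict[str, pd.DataFrame]:
    """Profile every sample on both strands, apply conversion QC, call sites,
    and build block summaries plus the HCC-vs-controls t tests."""
    outdir = Path(cohort_dir)
    if cohort is None:
        cohort = read_cohort(outdir)
    region, _ = load_reference(cfg)
    rng = _stage_rng(cfg, 2)

    call_rows: list[dict] = []
    dropped: list[str] = []
    calls_by_class: dict[TissueClass, dict[str, dict[int, bsp.SenseCall]]] = {}
    for sample in cohort.samples:
        sense = bsp.pooled_site_fractions(
            sample,
            Strand.SENSE,
            noise_sd=cfg.noise_sd,
            rng=rng,
            efficiency=cfg.bisulfite_efficiency,
            region=region,
        )
        anti = bsp.pooled_site_fractions(
            sample,
            Strand.ANTISENSE,
            noise_sd=cfg.noise_sd,
            rng=rng,
            efficiency=cfg.bisulfite_efficiency,
            region=region,
        )
        if not (
            bsp.qc_conversion(sense, cfg.qc_bound)
            and bsp.qc_conversion(anti, cfg.qc_bound)
        ):
            dropped.append(sample.sample_id)
            logger.info(
                "QC drop %s: conversion rate %.4f (sense) / %.4f (antisense)",
                sample.sample_id,
                sense.conversion_rate,
                anti.conversion_rate,
            )
            continue
        s_calls = bsp.call_profile_sense(sense, cfg.detect_limit, cfg.high_threshold)
        a_calls = bsp.call_profile_antisense(anti, cfg.detect_limit)
        calls_by_class.setdefault(sample.tissue_class, {})[sample.sample_id] = s_calls
        for n in cohort.census.site_numbers:
            call_rows.append(
                {
                    "sample_id": sample.sample_id,
                    "tissue_class": sample.tissue_class.value,
                    "site_number": n,
                    "sense_call": s_calls[n].value,
                    "antisense_call": a_calls[n].value,
                }
            )
    if dropped:
        logger.info("%d samples dropped by conversion QC", len(dropped))

    calls_df = pd.DataFrame(call_rows)
    summary_rows: list[dict] = []
    detected: dict[tuple[TissueClass, Region], tuple[float, ...]] = {}
    for tissue_class, by_sample in calls_by_class.items():
        for reg in Region:
            sites = cohort.census.region_site_numbers(reg)
            if not sites:
                continue
            summ = bsp.summarize_region(
                by_sample, sites, reg, tissue_class=tissue_class.value
            )
            detected[(tissue_class, reg)] = summ.per_sample_detected
            summary_rows.append(
                {
                    "tissue_class": tissue_class.value,
                    "region": reg.value,
                    "n_samples": summ.n_samples,
                    "n_sites": summ.n_sites,
                    "pct_none": round(summ.pct_none, 1),
                    "pct_low": round(summ.pct_low, 1),
                    "pct_high": round(summ.pct_high, 1),
                    "mean_detected": round(summ.mean_detected, 1),
                    "sd_detected": round(summ.sd_detected, 1),
                }
            )
    summary_df = pd.DataFrame(summary_rows)

    test_rows: list[dict] = []
    non_hcc = (TissueClass.NORMAL_LIVER, TissueClass.HEPATITIS, TissueClass.CIRRHOSIS)
    for reg in Region:
        if (TissueClass.HCC, reg) not in detected:
            continue
        hcc_vals = detected[(TissueClass.HCC, reg)]
        for label, classes in (
            ("hcc_vs_non_hcc", non_hcc),
            ("hcc_vs_non_hcc_plus_adjacent", non_hcc + (TissueClass.ADJACENT_NON_HCC,)),
        ):
            pool = [
                v for c in classes if (c, reg) in detected for v in detected[(c, reg)]
            ]
            if len(pool) < 2:
                continue
            t, p = bsp.compare_groups_ttest(hcc_vals, pool)
            test_rows.append(
                {"region": reg.value, "comparison": label, "t": t, "p": p}
            )
    tests_df = pd.DataFrame(test_rows)

    outputs: dict[str, Path] = {}
    calls_path = outdir / "bsp_calls.tsv"
    calls_df.to_csv(calls_path, sep="\t", index=False)
    outputs["bsp_calls"] = calls_path
    summary_path = outdir / "bsp_summary.tsv"
    summary_df.to_csv(summary_path, sep="\t", index=False)
    outputs["bsp_summary"] = summary_path
    tests_path = outdir / "bsp_tests.tsv"
    tests_df.to_csv(tests_path, sep="\t", index=False)
    outputs["bsp_tests"] = tests_path
    _record_manifest(outdir, "profile-bsp", cfg, outputs)
    return {"calls": calls_df, "summary": summary_df, "tests": tests_df}


# ---------------------------------------------------------------------------
# stage 3: MSP
# ---------------------------------------------------------------------------


def cmd_run_msp(
    cfg: RunConfig, cohort_dir: str | Path, cohort: Cohort | None = None
) -> pd.DataFrame:
    """Run both bundled MSP assays in duplicate on every sample."""
    outdir = Path(cohort_dir)
    if cohort is None:
        cohort = read_cohort(outdir)
    rng = _stage_rng(cfg, 3)
    if cfg.assays:
        defs = [msp.MspAssayDef.from_dict(d) for d in cfg.assays]
        assays = {a.name: a for a in defs}
    else:
        assays = msp.default_assays()
    mispriming = cfg.model.mispriming_rate if cfg.model else 0.0
    rows: list[dict] = []
    for sample in cohort.samples:
        for assay in assays.values():
            res = msp.quantify_msp(
                sample,
                assay,
                input_copies=cfg.msp_input_copies,
                duplicates=cfg.msp_duplicates,
                rng=rng,
                mispriming_rate=mispriming,
                cutoff=cfg.msp_cutoff,
            )
            row = {
                "sample_id": sample.sample_id,
                "tissue_class": sample.tissue_class.value,
                "afp_ng_ml": "" if sample.afp_ng_ml is None else f"{sample.afp_ng_ml:.4f}",
                "assay": assay.name,
                "mean_copies": res.mean_copies,
                "call": int(res.positive),
            }
            for i, c in enumerate(res.duplicate_copies, start=1):
                row[f"duplicate_{i}"] = c
            rows.append(row)
    results = pd.DataFrame(rows)
    path = outdir / "msp_results.tsv"
    results.to_csv(path, sep="\t", index=False)
    _record_manifest(outdir, "run-msp", cfg, {"msp_results": path})
    return results


# ---------------------------------------------------------------------------
# stage 4: evaluation
# ---------------------------------------------------------------------------


def cmd_evaluate(
    cfg: RunConfig,
    results: str | Path | pd.DataFrame,
    outdir: str | Path,
) -> dict[str, pd.DataFrame]:
    """Diagnostic summaries, Fisher specificity contrast, ROC points, AFP
    quadrants, and the two-marker combination, from an MSP results table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not isinstance(results, pd.DataFrame):
        results_path = Path(results)
        if not results_path.exists():
            raise PipelineError(f"missing MSP results file: {results_path}")
        results = pd.read_csv(results_path, sep="\t")
    if len(results) == 0:
        raise PipelineError("empty MSP results: nothing to evaluate")

    outputs: dict[str, Path] = {}
    summary_rows: list[dict] = []
    spec_counts: dict[tuple[str, str], tuple[int, int]] = {}
    for assay_name, sub in results.groupby("assay"):
        for control_label, control_classes in CONTROL_SETS.items():
            control_values = [c.value for c in control_classes]
            mask = sub["tissue_class"].isin(
                control_values + [TissueClass.HCC.value]
            )
            part = sub[mask]
            labels = (part["tissue_class"] == TissueClass.HCC.value).to_numpy()
            if labels.all() or not labels.any():
                continue
            values = part["mean_copies"].to_numpy(dtype=float)
            summ = diagnostics.sensitivity_specificity(
                values, labels, cutoff=cfg.msp_cutoff
            )
            n_ctrl = int((~labels).sum())
            tn = int(round(summ.specificity / 100.0 * n_ctrl))
            spec_counts[(assay_name, control_label)] = (tn, n_ctrl)
            summary_rows.append(
                {
                    "assay": assay_name,
                    "control_set": control_label,
                    "n_case": summ.n_case,
                    "n_control": summ.n_control,
                    "cutoff": summ.cutoff,
                    "sensitivity_pct": round(summ.sensitivity, 1),
                    "specificity_pct": round(summ.specificity, 1),
                    "sensitivity_ci_low": round(summ.sensitivity_ci[0], 1),
                    "sensitivity_ci_high": round(summ.sensitivity_ci[1], 1),
                    "specificity_ci_low": round(summ.specificity_ci[0], 1),
                    "specificity_ci_high": round(summ.specificity_ci[1], 1),
                    "auroc": round(summ.auroc, 3),
                }
            )
            curve, _ = diagnostics.roc_auc(values, labels)
            roc_df = pd.DataFrame(
                {"fpr": curve.fpr, "tpr": curve.tpr, "threshold": curve.thresholds}
            )
            roc_path = outdir / f"roc_{assay_name}_{control_label.replace('+', '_')}.tsv"
            roc_df.to_csv(roc_path, sep="\t", index=False)
            outputs[f"roc:{assay_name}:{control_label}"] = roc_path
    summary_df = pd.DataFrame(summary_rows)
    summary_path = outdir / "diagnostic_summary.tsv"
    summary_df.to_csv(summary_path, sep="\t", index=False)
    outputs["diagnostic_summary"] = summary_path

    # Fisher contrast of assay specificities on each shared control set.
    contrast_rows: list[dict] = []
    for control_label in CONTROL_SETS:
        key5 = ("five_prime_msp", control_label)
        key3 = ("three_prime_msp", control_label)
        if key5 in spec_counts and key3 in spec_counts:
            tn5, n5 = spec_counts[key5]
            tn3, n3 = spec_counts[key3]
            p = diagnostics.fisher_exact_2x2(
                [[tn5, n5 - tn5], [tn3, n3 - tn3]]
            )
            contrast_rows.append(
                {
                    "control_set": control_label,
                    "five_prime_neg": tn5,
                    "five_prime_pos": n5 - tn5,
                    "three_prime_neg": tn3,
                    "three_prime_pos": n3 - tn3,
                    "fisher_p": p,
                }
            )
    contrast_df = pd.DataFrame(contrast_rows)
    contrast_path = outdir / "specificity_contrast.tsv"
    contrast_df.to_csv(contrast_path, sep="\t", index=False)
    outputs["specificity_contrast"] = contrast_path

    # AFP quadrants and two-marker combination on HCC cases (5' assay).
    quad_df = pd.DataFrame()
    hcc = results[
        (results["tissue_class"] == TissueClass.HCC.value)
        & (results["assay"] == "five_prime_msp")
    ].copy()
    if len(hcc) > 0:
        afp = pd.to_numeric(hcc["afp_ng_ml"], errors="coerce")
        known = afp.notna()
        n_excluded = int((~known).sum())
        if n_excluded:
            logger.info("%d HCC cases lack AFP and are excluded", n_excluded)
        hcc = hcc[known]
        afp_v = afp[known].to_numpy(dtype=float)
        copies = hcc["mean_copies"].to_numpy(dtype=float)
        if len(hcc) > 0:
            q = diagnostics.quadrant_counts(
                afp_v, copies, cfg.afp_threshold, cfg.msp_cutoff
            )
            pct = q.percentages()
            combined = [
                diagnostics.combine_with_afp(
                    c >= cfg.msp_cutoff, a, cfg.afp_threshold
                )
                for a, c in zip(afp_v, copies)
            ]
            quad_df = pd.DataFrame(
                [
                    {
                        "quadrant": k,
                        "count": getattr(q, k),
                        "pct": round(pct[k], 1),
                    }
                    for k in pct
                ]
                + [
                    {
                        "quadrant": "combined_sensitivity_pct",
                        "count": int(np.sum(combined)),
                        "pct": round(100.0 * float(np.mean(combined)), 1),
                    },
                    {
                        "quadrant": "afp_alone_sensitivity_pct",
                        "count": int((afp_v > cfg.afp_threshold).sum()),
                        "pct": round(
                            100.0 * float((afp_v > cfg.afp_threshold).mean()), 1
                        ),
                    },
                ]
            )
    quad_path = outdir / "afp_quadrants.tsv"
    quad_df.to_csv(quad_path, sep="\t", index=False)
    outputs["afp_quadrants"] = quad_path

    _record_manifest(outdir, "evaluate", cfg, outputs)
    return {"summary": summary_df, "contrast": contrast_df, "quadrants": quad_df}


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Simulate -> BSP profile -> MSP -> evaluate, all under one directory."""
    outdir = Path(outdir)
    cohort = cmd_simulate(cfg, outdir)
    bsp_out = cmd_profile_bsp(cfg, outdir, cohort=cohort)
    results = cmd_run_msp(cfg, outdir, cohort=cohort)
    eval_out = cmd_evaluate(cfg, results, outdir)
    return {"bsp": bsp_out["summary"], "msp": results, **eval_out}


# ---------------------------------------------------------------------------
# printed-tally reproduction
# ---------------------------------------------------------------------------

PRINTED_FIXTURE_IDS = ("afp-combination", "msp-positivity", "specificity-contrast")

# Representative per-case values expanded from count fixtures; synthetic
# placeholders chosen safely away from every threshold.
_REP_AFP_NEG, _REP_AFP_POS = 5.0, 100.0
_REP_MSP_NEG, _REP_MSP_POS = 0.0, 50.0


def _load_printed_counts() -> dict:
    ref = resources.files("methylmarker.data").joinpath("printed_counts.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def reproduce_printed(fixture_id: str) -> dict[str, float]:
    """Recompute published summary statistics from a bundled count fixture.

    The fixture stores only counts; every reported number is recomputed at
    run time by expanding the counts to per-case indicator values and pushing
    them through the same diagnostics code the simulated pipeline uses.
    """
    fixtures = _load_printed_counts()
    if fixture_id not in fixtures:
        raise KeyError(
            f"unknown fixture {fixture_id!r}; available: {sorted(fixtures)}"
        )
    fx = fixtures[fixture_id]

    if fixture_id == "afp-combination":
        quads = fx["quadrants"]
        afp_vals: list[float] = []
        msp_vals: list[float] = []
        for key, n in quads.items():
            afp_rep = _REP_AFP_NEG if key.startswith("afp_neg") else _REP_AFP_POS
            msp_rep = _REP_MSP_POS if key.endswith("msp_pos") else _REP_MSP_NEG
            afp_vals.extend([afp_rep] * n)
            msp_vals.extend([msp_rep] * n)
        thr = fx["afp_threshold"]
        cut = fx["msp_cutoff"]
        q = diagnostics.quadrant_counts(afp_vals, msp_vals, thr, cut)
        afp_arr = np.asarray(afp_vals)
        msp_arr = np.asarray(msp_vals)
        afp_pos = afp_arr > thr
        msp_pos = msp_arr >= cut
        combined = [
            diagnostics.combine_with_afp(bool(m), a, thr)
            for a, m in zip(afp_arr, msp_arr >= cut)
        ]
        n = q.total
        n_afp_neg = int((~afp_pos).sum())
        return {
            "n": float(n),
            "afp_alone_sensitivity_pct": round(100.0 * afp_pos.mean(), 1),
            "combined_sensitivity_pct": round(100.0 * float(np.mean(combined)), 1),
            "afp_negative_share_pct": round(100.0 * n_afp_neg / n, 1),
            "msp_positive_in_afp_negative_pct": round(
                100.0 * int((~afp_pos & msp_pos).sum()) / n_afp_neg, 1
            ),
        }

    if fixture_id == "msp-positivity":
        cut = fx["msp_cutoff"]
        counts = fx["counts"]
        values: list[float] = []
        labels: list[bool] = []
        for cls_name, c in counts.items():
            is_case = cls_name == "hcc"
            values.extend([_REP_MSP_POS] * c["positive"])
            values.extend([_REP_MSP_NEG] * (c["total"] - c["positive"]))
            labels.extend([is_case] * c["total"])
        summ = diagnostics.sensitivity_specificity(values, labels, cutoff=cut)
        return {
            "n": float(len(values)),
            "hcc_sensitivity_pct": round(summ.sensitivity, 1),
            "adjacent_positivity_pct": round(100.0 - summ.specificity, 1),
        }

    # specificity-contrast
    n_ctrl = fx["controls"]
    tn5 = int(round(fx["five_prime_specificity_pct"] / 100.0 * n_ctrl))
    tn3 = int(round(fx["three_prime_specificity_pct"] / 100.0 * n_ctrl))
    table = diagnostics.ContingencyTable2x2(tn5, n_ctrl - tn5, tn3, n_ctrl - tn3)
    p = diagnostics.fisher_exact_2x2(table)
    return {
        "n": float(2 * n_ctrl),
        "five_prime_controls_negative": float(tn5),
        "three_prime_controls_negative": float(tn3),
        "fisher_p": p,
    }
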