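"""End-to-end study orchestration.

One config drives the whole design: obtain summary statistics (simulated
directly, via per-trait cohort GWAS, or read from files) -> select
instruments -> univariable MR of the exposure on every outcome and every
mediator -> multivariable MR of the mediators (plus, by default, the
exposure) on every outcome -> network-MR mediation -> report tables, an
exclusion log and a run manifest.

Every stage writes only the documented TSV dialects, so stages can be
re-run against external data. Re-running with an identical config and seed
reproduces byte-identical outputs; the manifest records the config hash,
seed, row counts and a SHA-256 per written file to make that checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .instruments import (
    EmptyInstrumentSet,
    InstrumentConfig,
    harmonize,
    mvmr_instrument_union,
    select_instruments,
)
from .io import read_ld_matrix, read_sumstats, write_report_table, write_sumstats, write_ld_matrix
from .mediation import MediationResult, SignificanceRubric, classify_association
from .simulate import EXPOSURE, DagConfig, ld_matrix, simulate_sumstats

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Full study configuration.

    ``families`` maps analysis family -> number of independent tests for
    Bonferroni correction; the three families are explicit configuration,
    not inferred, but default to the registry counts (outcomes; mediators;
    (mediators + exposure) x outcomes when the exposure joins the MVMR).
    """

    dag: DagConfig = field(default_factory=DagConfig)
    sumstats_mode: str = "direct"  # direct | cohort | files
    sumstats_dir: str | None = None
    ld_path: str | None = None
    ld_positions_path: str | None = None
    instruments: InstrumentConfig = field(default_factory=InstrumentConfig)
    p_threshold_by_trait: dict[str, float] = field(
        default_factory=lambda: {"fruit": 1e-5, "vegetables": 1e-5}
    )
    n_boot: int = 1000
    n_sim: int = 1000
    include_exposure_in_mvmr: bool = True
    mediation_b_source: str = "mvmr"  # mvmr | univariable
    families: dict[str, int] | None = None
    outdir: str = "netmr_output"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.families is None:
            n_med = self.dag.n_mediators
            n_out = self.dag.n_outcomes
            k = n_med + (1 if self.include_exposure_in_mvmr else 0)
            self.families = {
                "exposure_outcomes": n_out,
                "exposure_mediators": max(1, n_med),
                "mvmr": max(1, k * n_out),
            }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        dag = DagConfig(**raw.pop("dag", {}))
        inst = InstrumentConfig(**raw.pop("instruments", {}))
        return cls(dag=dag, instruments=inst, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("theta_exp_to_med", "theta_med_to_outcome", "theta_direct", "prevalence"):
            d["dag"][key] = np.asarray(d["dag"][key]).tolist()
        d["dag"]["maf_range"] = list(d["dag"]["maf_range"])
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _derived_seed(base: int, *salt: int) -> int:
    ss = np.random.SeedSequence([int(base), *[int(s) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _obtain_sumstats(config: PipelineConfig):
    dag = DagConfig(**{**_dag_kwargs(config.dag), "seed": config.seed})
    if config.sumstats_mode == "direct":
        return simulate_sumstats(dag, two_sample=False), ld_matrix(dag), dag
    if config.sumstats_mode == "cohort":
        return simulate_sumstats(dag, two_sample=True), ld_matrix(dag), dag
    if config.sumstats_mode == "files":
        if not (config.sumstats_dir and config.ld_path and config.ld_positions_path):
            raise PipelineError("stage=ingest: files mode needs sumstats_dir, ld_path, ld_positions_path")
        tables = {}
        for trait in dag.trait_names:
            tables[trait] = read_sumstats(Path(config.sumstats_dir) / f"{trait}.tsv")
        ld = read_ld_matrix(config.ld_path, config.ld_positions_path)
        return tables, ld, dag
    raise PipelineError(f"stage=ingest: unknown sumstats_mode {config.sumstats_mode!r}")


def _dag_kwargs(dag: DagConfig) -> dict:
    from .simulate import _config_kwargs

    return _config_kwargs(dag)


def _univariable_suite(h, name_x, name_y, scale, config: PipelineConfig, salt: int):
    """IVW + sensitivity battery for one exposure-outcome pair."""
    results = [est.ivw(h, exposure=name_x, outcome=name_y, scale=scale)]
    if h.n_snp >= 3:
        results.append(est.egger(h, exposure=name_x, outcome=name_y, scale=scale))
        results.append(
            est.weighted_median(
                h, n_boot=config.n_boot, seed=_derived_seed(config.seed, 1, salt),
                exposure=name_x, outcome=name_y, scale=scale,
            )
        )
    if h.n_snp >= 4:
        results.append(
            est.mr_presso(
                h, n_sim=config.n_sim, seed=_derived_seed(config.seed, 2, salt),
                exposure=name_x, outcome=name_y, scale=scale,
            )
        )
    return results


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full study; returns the run manifest (also written as
    ``manifest.json``). Any stage that empties its instrument set aborts
    with the stage name and the last exclusion reasons."""
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, ld, dag = _obtain_sumstats(config)

    written: dict[str, Path] = {}

    def save(df: pd.DataFrame, rel: str) -> None:
        path = outdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
        written[rel] = path

    if config.sumstats_mode != "files":
        for trait, table in tables.items():
            path = outdir / "sumstats" / f"{trait}.tsv"
            write_sumstats(table, path)
            written[f"sumstats/{trait}.tsv"] = path
        write_ld_matrix(ld, outdir / "sumstats" / "ld.tsv", outdir / "sumstats" / "ld_positions.tsv")
        written["sumstats/ld.tsv"] = outdir / "sumstats" / "ld.tsv"
        written["sumstats/ld_positions.tsv"] = outdir / "sumstats" / "ld_positions.tsv"

    mediators = dag.mediator_names
    outcomes = dag.outcome_names
    rubric = SignificanceRubric.from_counts(config.families)

    # --- exposure instruments ------------------------------------------------
    try:
        instr_exp = select_instruments(
            tables[EXPOSURE], config.instruments, ld,
            p_threshold=config.p_threshold_by_trait.get(EXPOSURE),
        )
    except EmptyInstrumentSet as e:
        raise PipelineError(f"stage=instruments({EXPOSURE}): {e}") from e
    exclusion_rows = [
        {"trait": EXPOSURE, "variant_id": v, "stage": s, "reason": r}
        for v, s, r in instr_exp.attrs["exclusions"]
    ]
    save(instr_exp, f"instruments/{EXPOSURE}.tsv")

    # --- univariable MR: exposure -> outcomes and exposure -> mediators ------
    mr_outcome_results: dict[str, dict[str, est.MRResult]] = {}
    rows_out: list[est.MRResult] = []
    for i, out in enumerate(outcomes):
        try:
            h = harmonize(
                instr_exp, tables[out],
                palindrome_maf_max=config.instruments.palindrome_maf_max,
                exposure_names=[EXPOSURE], outcome_name=out,
            )
        except ValueError as e:
            raise PipelineError(f"stage=harmonize({EXPOSURE}->{out}): {e}") from e
        suite = _univariable_suite(h, EXPOSURE, out, "log_odds", config, salt=i)
        mr_outcome_results[out] = {r.method: r for r in suite}
        rows_out.extend(suite)
    write_report_table(rows_out, outdir / "mr_exposure_outcomes.tsv")
    written["mr_exposure_outcomes.tsv"] = outdir / "mr_exposure_outcomes.tsv"

    mr_mediator_results: dict[str, dict[str, est.MRResult]] = {}
    rows_med: list[est.MRResult] = []
    for i, med in enumerate(mediators):
        try:
            h = harmonize(
                instr_exp, tables[med],
                palindrome_maf_max=config.instruments.palindrome_maf_max,
                exposure_names=[EXPOSURE], outcome_name=med,
            )
        except ValueError as e:
            raise PipelineError(f"stage=harmonize({EXPOSURE}->{med}): {e}") from e
        suite = _univariable_suite(h, EXPOSURE, med, "sd", config, salt=100 + i)
        mr_mediator_results[med] = {r.method: r for r in suite}
        rows_med.extend(suite)
    write_report_table(rows_med, outdir / "mr_exposure_mediators.tsv")
    written["mr_exposure_mediators.tsv"] = outdir / "mr_exposure_mediators.tsv"

    # --- MVMR ----------------------------------------------------------------
    mvmr_results: dict[str, est.MVMRResult] = {}
    mvmr_exposures = list(mediators) + ([EXPOSURE] if config.include_exposure_in_mvmr else [])
    if len(mvmr_exposures) >= 2:
        thresholds = [
            config.p_threshold_by_trait.get(t, config.instruments.p_threshold)
            for t in mvmr_exposures
        ]
        try:
            union = mvmr_instrument_union(
                [tables[t] for t in mvmr_exposures], config.instruments, ld,
                p_thresholds=thresholds,
            )
        except EmptyInstrumentSet as e:
            raise PipelineError(f"stage=mvmr_union: {e}") from e
        save(union, "instruments/mvmr_union.tsv")
        union_ids = set(union["variant_id"])
        exp_tabs = [
            tables[t][tables[t]["variant_id"].isin(union_ids)].reset_index(drop=True)
            for t in mvmr_exposures
        ]
        mvmr_rows: list[est.MRResult] = []
        for out in outcomes:
            try:
                h = harmonize(
                    exp_tabs, tables[out],
                    palindrome_maf_max=config.instruments.palindrome_maf_max,
                    exposure_names=mvmr_exposures, outcome_name=out,
                )
                res = est.mvmr_ivw(h, outcome=out)
            except ValueError as e:
                raise PipelineError(f"stage=mvmr({out}): {e}") from e
            mvmr_results[out] = res
            mvmr_rows.extend(res.to_mr_results())
        write_report_table(mvmr_rows, outdir / "mvmr.tsv")
        written["mvmr.tsv"] = outdir / "mvmr.tsv"
    else:
        write_report_table([], outdir / "mvmr.tsv")
        written["mvmr.tsv"] = outdir / "mvmr.tsv"

    # --- mediation -----------------------------------------------------------
    mediation_rows: list[MediationResult] = []
    total_flags: list[bool] = []
    for med in mediators:
        a_res = mr_mediator_results[med]["IVW" if "IVW" in mr_mediator_results[med] else "WaldRatio"]
        for out in outcomes:
            c_res = mr_outcome_results[out]["IVW" if "IVW" in mr_outcome_results[out] else "WaldRatio"]
            if config.mediation_b_source == "mvmr" and out in mvmr_results:
                res = mvmr_results[out]
                j = res.exposure_names.index(med)
                b = (float(res.estimates[j]), float(res.ses[j]))
            else:
                # univariable fallback: mediator's own instruments -> outcome
                try:
                    instr_med = select_instruments(
                        tables[med], config.instruments, ld,
                        p_threshold=config.p_threshold_by_trait.get(med),
                    )
                    h = harmonize(instr_med, tables[out],
                                  palindrome_maf_max=config.instruments.palindrome_maf_max)
                    r = est.ivw(h, exposure=med, outcome=out)
                    b = (r.estimate, r.se)
                except (EmptyInstrumentSet, ValueError) as e:
                    raise PipelineError(f"stage=mediation_b({med}->{out}): {e}") from e
            if c_res.estimate == 0:
                raise PipelineError(f"stage=mediation({med}->{out}): zero total effect")
            m = MediationResult(
                exposure=EXPOSURE, mediator=med, outcome=out,
                total_effect=c_res.estimate, se_total=c_res.se,
                beta_exp_to_med=a_res.estimate, se_exp_to_med=a_res.se,
                beta_med_to_outcome_direct=b[0], se_med_to_outcome_direct=b[1],
            )
            mediation_rows.append(m)
            decision = _classify_total(mr_outcome_results[out], rubric)
            total_flags.append(decision)
    med_df = write_report_table(mediation_rows, outdir / "mediation.tsv")
    if len(med_df):
        med_df["total_significant"] = total_flags
    else:
        med_df["total_significant"] = pd.Series(dtype=bool)
    med_df.to_csv(outdir / "mediation.tsv", sep="\t", index=False, na_rep="NA",
                  float_format="%.10g")
    written["mediation.tsv"] = outdir / "mediation.tsv"

    # --- classification ------------------------------------------------------
    class_rows = []
    thr_out = rubric.alpha_family["exposure_outcomes"]
    for out in outcomes:
        d = _classification_row(mr_outcome_results[out], thr_out, rubric)
        if d is not None:
            class_rows.append({"exposure": EXPOSURE, "outcome": out, "family": "exposure_outcomes", **d})
    thr_med = rubric.alpha_family["exposure_mediators"]
    for med in mediators:
        d = _classification_row(mr_mediator_results[med], thr_med, rubric)
        if d is not None:
            class_rows.append({"exposure": EXPOSURE, "outcome": med, "family": "exposure_mediators", **d})
    class_df = pd.DataFrame(
        class_rows,
        columns=["exposure", "outcome", "family", "significant", "ivw_pass",
                 "presso_pass", "direction_concordant", "intercept_ok", "threshold"],
    )
    save(class_df, "classification.tsv")

    excl_df = pd.DataFrame(exclusion_rows, columns=["trait", "variant_id", "stage", "reason"])
    save(excl_df, "exclusions.tsv")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_snps_total": int(sum(len(t) for t in tables.values())),
        "tables": {
            rel: {"sha256": _sha256(p), "n_rows": max(0, sum(1 for _ in open(p)) - 1)}
            for rel, p in sorted(written.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d tables under %s", len(written), outdir)
    return manifest


def _classify_total(results: dict[str, est.MRResult], rubric: SignificanceRubric):
    needed = {"IVW", "Egger", "WeightedMedian"}
    presso = results.get("PRESSO_raw") or results.get("PRESSO_outlier_corrected")
    if not needed.issubset(results) or presso is None:
        return False
    d = classify_association(
        results["IVW"], results["Egger"], results["WeightedMedian"], presso,
        threshold=rubric.alpha_family["exposure_outcomes"],
        egger_intercept_alpha=rubric.egger_intercept_alpha,
    )
    return d.significant


def _classification_row(results: dict[str, est.MRResult], threshold: float,
                        rubric: SignificanceRubric):
    presso = results.get("PRESSO_raw") or results.get("PRESSO_outlier_corrected")
    if not {"IVW", "Egger", "WeightedMedian"}.issubset(results) or presso is None:
        return None
    d = classify_association(
        results["IVW"], results["Egger"], results["WeightedMedian"], presso,
        threshold=threshold, egger_intercept_alpha=rubric.egger_intercept_alpha,
    )
    return {
        "significant": d.significant,
        "ivw_pass": d.ivw_pass,
        "presso_pass": d.presso_pass,
        "direction_concordant": d.direction_concordant,
        "intercept_ok": d.intercept_ok,
        "threshold": d.threshold,
    }
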