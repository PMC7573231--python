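"""End-to-end pipeline driver.

Stages are gated on what the configuration provides: a traces directory
drives the respirometry stage, a cohort file the energetics stage, and a
DE table + GMT file the enrichment stage.  Outputs are diffable TSVs
plus a machine-readable JSON QC report and a manifest; reruns with the
same configuration are byte-identical.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from . import bioenergetics as be
from . import respirometry as resp
from .enrichment import enrich, filter_de
from .errors import NoVarianceError, SealMitoError
from .io import (
    RunConfig,
    read_cohort,
    read_de_table,
    read_gmt,
    read_trace,
    write_tsv,
)
from .protocols import REPEATED_STATES, SINGLE_STATES, load_protocols

try:
    __version__ = version("sealmito")
except PackageNotFoundError:  # pragma: no cover - not installed
    __version__ = "unknown"

STATE_COLUMNS = ["Ln", "OXPHOS", "ETS", "LOmy", "CI", "CII"]
RATIO_COLUMNS = ["SCR_CI", "SCR_CII", "CCR_Ln", "FCR"]


@dataclass
class PipelineResult:
    """In-memory bundle of everything run_pipeline wrote."""

    states: pd.DataFrame | None = None
    ratios: pd.DataFrame | None = None
    prepost: pd.DataFrame | None = None
    budget: pd.DataFrame | None = None
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    outputs: list[Path] = field(default_factory=list)


def _analyze_run(trace, protocol, config, qc_runs) -> resp.RunStates | None:
    entry = {
        "run_id": trace.run_id,
        "animal_id": trace.animal_id,
        "timepoint": trace.timepoint,
        "protocol_id": trace.protocol_id,
        "excluded": False,
        "reasons": [],
        "warnings": [],
    }
    try:
        o2_excursions = resp.check_oxygen_window(trace)
        if o2_excursions:
            entry["warnings"].append(
                f"oxygen outside operating window for {len(o2_excursions)} "
                "interval(s)"
            )
        flux = resp.compute_flux(trace, smoothing_window=config.smoothing_window)
        states = resp.detect_steady_states(
            flux,
            trace.events,
            protocol,
            stability_tol=config.stability_tol,
            window=config.steady_window,
        )
        missing = [s.state_label for s in states if s.missing]
        if missing:
            entry["warnings"].append(f"no steady state for {missing}")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            states = resp.baseline_correct(states, run_id=trace.run_id)
        entry["warnings"].extend(str(w.message) for w in caught)
        run = resp.run_states(protocol, states, run_id=trace.run_id)
        if not run.cytc_pass:
            entry["excluded"] = True
            entry["reasons"].append("cytochrome-c test failed (>10% flux increase)")
        qc_runs.append(entry)
        return run
    except SealMitoError as exc:
        entry["excluded"] = True
        entry["reasons"].append(f"{type(exc).__name__}: {exc}")
        qc_runs.append(entry)
        return None


def _respirometry_stage(config: RunConfig, result: PipelineResult) -> None:
    protocols = load_protocols(config.protocols_file)
    trace_files = sorted(
        p for p in Path(config.traces_dir).glob("*.csv")
        if not p.name.endswith(".events.csv")
    )
    qc_runs: list[dict] = []
    by_sample: dict[tuple[str, str], list[resp.RunStates]] = {}
    provenance: dict[tuple[str, str], list[str]] = {}
    per_run_oxphos: dict[tuple[str, str], dict[str, float]] = {}
    for tf in trace_files:
        trace = read_trace(tf)
        protocol = protocols[trace.protocol_id]
        run = _analyze_run(trace, protocol, config, qc_runs)
        if run is None or run.excluded:
            continue
        key = (trace.animal_id, trace.timepoint)
        by_sample.setdefault(key, []).append(run)
        provenance.setdefault(key, []).append(tf.name)
        if "OXPHOS" in run.states:
            per_run_oxphos.setdefault(key, {})[trace.protocol_id] = run.states["OXPHOS"]

    state_rows, ratio_rows = [], []
    samples: dict[tuple[str, str], resp.SampleStateSet] = {}
    for key in sorted(by_sample):
        animal, timepoint = key
        sample = resp.aggregate_sample(by_sample[key], animal, timepoint)
        samples[key] = sample
        row = {
            "animal_id": animal,
            "timepoint": timepoint,
            "Ln": sample.mean_Ln,
            "OXPHOS": sample.mean_OXPHOS,
            "ETS": sample.mean_ETS,
            "LOmy": sample.std_LOmy,
            "CI": sample.std_CI,
            "CII": sample.std_CII,
            "n_runs": sample.n_runs,
            "excluded": sample.excluded,
            "inputs": ";".join(provenance[key]),
            "version": __version__,
        }
        state_rows.append(row)
        if not sample.excluded:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ratios = resp.respiratory_ratios(sample)
                ratio_rows.append(
                    {
                        "animal_id": animal,
                        "timepoint": timepoint,
                        "SCR_CI": ratios.SCR_CI,
                        "SCR_CII": ratios.SCR_CII,
                        "CCR_Ln": ratios.CCR_Ln,
                        "FCR": ratios.FCR,
                        "inputs": ";".join(provenance[key]),
                        "version": __version__,
                    }
                )
            except SealMitoError as exc:
                qc_runs.append(
                    {
                        "run_id": f"{animal}/{timepoint}",
                        "animal_id": animal,
                        "timepoint": timepoint,
                        "protocol_id": "",
                        "excluded": False,
                        "reasons": [f"ratios unavailable: {exc}"],
                        "warnings": [],
                    }
                )

    result.states = pd.DataFrame(state_rows)
    result.ratios = pd.DataFrame(ratio_rows)

    # paired pre/post comparison across animals, per state and ratio
    prepost_rows = []
    if not result.states.empty:
        merged = {"states": (result.states, STATE_COLUMNS)}
        if not result.ratios.empty:
            merged["ratios"] = (result.ratios, RATIO_COLUMNS)
        for _, (df, cols) in merged.items():
            pre = df[df.timepoint == "pre"].set_index("animal_id")
            post = df[df.timepoint == "post"].set_index("animal_id")
            common = sorted(set(pre.index) & set(post.index))
            for col in cols:
                row = {"measure": col, "n": 0, "mean_pre": math.nan,
                       "mean_post": math.nan, "mean_diff": math.nan,
                       "t": math.nan, "p": math.nan, "significant": False,
                       "note": "", "version": __version__}
                if common:
                    pre_v = pre.loc[common, col].astype(float)
                    post_v = post.loc[common, col].astype(float)
                    row["mean_pre"] = float(pre_v.mean())
                    row["mean_post"] = float(post_v.mean())
                    try:
                        cmpres = resp.paired_compare(
                            pre_v.to_numpy(), post_v.to_numpy(), alpha=config.alpha
                        )
                        row.update(
                            n=cmpres.n, mean_diff=cmpres.mean_diff, t=cmpres.t,
                            p=cmpres.p, significant=cmpres.significant,
                        )
                    except SealMitoError as exc:
                        row["note"] = f"{type(exc).__name__}: {exc}"
                prepost_rows.append(row)
    result.prepost = pd.DataFrame(prepost_rows)

    # pooling justification: OXPHOS with vs without octanoylcarnitine
    # (protocols A/B vs CI/CII); pooling itself does not branch on this.
    with_oc, without_oc = [], []
    for key, oxmap in sorted(per_run_oxphos.items()):
        ab = [oxmap[p] for p in ("A", "B") if p in oxmap]
        cc = [oxmap[p] for p in ("CI", "CII") if p in oxmap]
        if ab and cc:
            with_oc.append(sum(ab) / len(ab))
            without_oc.append(sum(cc) / len(cc))
    pooling: dict = {"n_samples": len(with_oc)}
    if len(with_oc) >= 2:
        try:
            cmpres = resp.paired_compare(with_oc, without_oc)
            pooling.update(t=cmpres.t, p=cmpres.p, mean_diff=cmpres.mean_diff)
        except NoVarianceError:
            pooling["note"] = "no variance in paired differences"
    result.qc["oxphos_pooling_check"] = pooling
    result.qc["runs"] = qc_runs
    result.qc["n_excluded_runs"] = sum(r["excluded"] for r in qc_runs)

    # lowest measured leak flux, available to the energetics stage
    leaks = [
        v
        for s in samples.values()
        for v in (s.mean_Ln, s.std_LOmy)
        if not s.excluded and math.isfinite(v)
    ]
    if leaks:
        result.qc["min_leak_flux"] = min(leaks)


def _energetics_stage(config: RunConfig, result: PipelineResult) -> None:
    records = read_cohort(config.cohort_file)
    comp, eq = config.composition, config.equivalents
    leak_flux = config.leak_flux
    if leak_flux is None:
        leak_flux = result.qc.get("min_leak_flux")

    rows = []
    for rec in records:
        budget = be.seal_budget(rec, comp, eq)
        row = _budget_row(rec.animal_id, budget, rec.mean_mass, leak_flux, eq)
        rows.append(row)
    if records:
        mean_mass = sum(r.mean_mass for r in records) / len(records)
        loss = sum(be.daily_mass_loss(r)[0] for r in records) / len(records)
        pct = sum(be.daily_mass_loss(r)[1] for r in records) / len(records)
        pelage, water, ffm, fat = be.apportion(loss, comp)
        e = be.energy_expenditure(fat, ffm, eq)
        budget = be.EnergyBudget(
            daily_loss=loss, pelage=pelage, water=water, ffm=ffm, fat=fat,
            dee_kcal=e["dee_kcal"], dee_mj=e["dee_mj"],
            dee_mj_kcal_path=e["dee_mj_kcal_path"], fat_mj=e["fat_mj"],
            fat_fraction=e["fat_fraction"], animal_id="cohort_mean",
            extras={"percent_loss": pct, "mean_mass": mean_mass},
        )
        rows.append(_budget_row("cohort_mean", budget, mean_mass, leak_flux, eq))
    result.budget = pd.DataFrame(rows)
    result.qc["energetics"] = {
        "n_animals": len(records),
        "leak_flux_pmol_s_mg": leak_flux,
        "input": Path(config.cohort_file).name,
    }


def _budget_row(animal_id, budget, mean_mass, leak_flux, eq) -> dict:
    muscle = be.muscle_mass(mean_mass, eq)
    row = {
        "animal_id": animal_id,
        "mean_mass_kg": mean_mass,
        "daily_loss_kg": budget.daily_loss,
        "percent_loss": budget.extras.get("percent_loss", math.nan),
        "pelage_kg": budget.pelage,
        "water_kg": budget.water,
        "ffm_kg": budget.ffm,
        "fat_kg": budget.fat,
        "dee_kcal": budget.dee_kcal,
        "dee_mj": budget.dee_mj,
        "dee_mj_kcal_path": budget.dee_mj_kcal_path,
        "fat_mj": budget.fat_mj,
        "fat_fraction": budget.fat_fraction,
        "muscle_kg": muscle,
        "fmr_mj": be.field_metabolic_rate(mean_mass, eq),
        "leak_capacity_mj": (
            be.leak_capacity(muscle, leak_flux, eq)
            if leak_flux and leak_flux > 0
            else math.nan
        ),
        "version": __version__,
    }
    return row


def _enrichment_stage(config: RunConfig, result: PipelineResult) -> None:
    table = read_de_table(config.de_file)
    collection = read_gmt(config.gmt_file)
    up, down = filter_de(table, padj_cut=config.padj_cut, lfc_cut=config.lfc_cut)
    background = set(table["gene_id"])
    result.qc["enrichment"] = {
        "n_genes": len(background),
        "n_up": len(up),
        "n_down": len(down),
        "inputs": [Path(config.de_file).name, Path(config.gmt_file).name],
    }
    for direction, genes in (("up", up), ("down", down)):
        res = enrich(
            set(genes),
            collection,
            background,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        result.enrichment[direction] = pd.DataFrame(
            [
                {
                    "set_name": r.set_name,
                    "direction": direction,
                    "overlap": r.overlap_count,
                    "set_size": r.set_size,
                    "query_size": r.query_size,
                    "background_size": r.background_size,
                    "odds_ratio": r.odds_ratio,
                    "p": r.p,
                    "padj": r.padj,
                    "z": r.z,
                    "combined_score": r.combined_score,
                    "version": __version__,
                }
                for r in res
            ]
        )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all configured stages and write the result bundle.

    Deterministic for a fixed configuration and seed.  Stage failures do
    not abort the other stages: partial outputs are still written, with
    errors collected under ``qc["stage_errors"]``.
    """
    result = PipelineResult()
    result.qc["stage_errors"] = {}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stages = []
    if config.traces_dir is not None:
        stages.append(("respirometry", _respirometry_stage))
    if config.cohort_file is not None:
        stages.append(("energetics", _energetics_stage))
    if config.de_file is not None and config.gmt_file is not None:
        stages.append(("enrichment", _enrichment_stage))

    for name, stage in stages:
        try:
            stage(config, result)
        except SealMitoError as exc:
            result.qc["stage_errors"][name] = f"{type(exc).__name__}: {exc}"

    for attr, fname in (
        ("states", "states.tsv"),
        ("ratios", "ratios.tsv"),
        ("prepost", "prepost.tsv"),
        ("budget", "budget.tsv"),
    ):
        df = getattr(result, attr)
        if df is not None and not df.empty:
            result.outputs.append(write_tsv(df, out / fname))
    for direction, df in result.enrichment.items():
        if not df.empty:
            result.outputs.append(write_tsv(df, out / f"enrichment_{direction}.tsv"))

    qc_path = out / "qc.json"
    qc_path.write_text(json.dumps(result.qc, indent=2, sort_keys=True, default=str))
    result.outputs.append(qc_path)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "outputs": sorted(p.name for p in result.outputs),
        "stages": [name for name, _ in stages],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result.outputs.append(manifest_path)
    return result
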