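"""File dialects: trace CSV + events sidecar, cohort CSV, DE TSV, GMT,
result TSVs, and the run configuration.

Trace files are plain CSV with header ``time_s,o2_nmol_per_ml``; run
metadata lives either in a leading ``# key: value`` comment block or in
a YAML/JSON sidecar, and titration events in
``<stem>.events.csv`` (``time_s,agent,target_conc,unit``).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .bioenergetics import CompositionModel, EnergyEquivalents, SealRecord
from .enrichment import GeneSetCollection
from .errors import ConfigError, ValidationError
from .respirometry import OxygenTrace, TitrationEvent

__all__ = [
    "read_trace",
    "write_trace",
    "read_cohort",
    "write_cohort",
    "read_de_table",
    "write_de_table",
    "read_gmt",
    "write_gmt",
    "write_tsv",
    "RunConfig",
    "load_run_config",
]

_META_KEYS = {
    "chamber_volume_ml": float,
    "tissue_mass_mg": float,
    "animal_id": str,
    "timepoint": str,
    "protocol_id": str,
}


def _read_comment_meta(path: Path) -> dict[str, Any]:
    meta: dict[str, Any] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = yaml.safe_load(val.strip())
    return meta


def _load_meta_file(path: Path) -> dict[str, Any]:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_events(path: str | Path) -> list[TitrationEvent]:
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            conc = row.get("target_conc")
            events.append(
                TitrationEvent(
                    t=float(row["time_s"]),
                    agent=row["agent"].strip(),
                    target_conc=float(conc) if conc not in (None, "") else None,
                    unit=(row.get("unit") or None),
                )
            )
    return events


def read_trace(
    path: str | Path,
    events_path: str | Path | None = None,
    meta_path: str | Path | None = None,
) -> OxygenTrace:
    """Read an oxygen trace with its events sidecar and metadata.

    Metadata is taken from ``meta_path`` (YAML or JSON) when given,
    otherwise from a sidecar ``<stem>.meta.yaml``/``.meta.json`` if one
    exists, otherwise from the leading ``# key: value`` comment block.
    """
    path = Path(path)
    meta: dict[str, Any] = _read_comment_meta(path)
    if meta_path is not None:
        meta.update(_load_meta_file(Path(meta_path)))
    else:
        for suffix in (".meta.yaml", ".meta.yml", ".meta.json"):
            cand = path.with_name(path.stem + suffix)
            if cand.exists():
                meta.update(_load_meta_file(cand))
                break
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ValidationError(f"{path.name}: missing trace metadata {missing}")

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("time_s", "o2_nmol_per_ml"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing column {col!r}")

    if events_path is None:
        cand = path.with_name(path.stem + ".events.csv")
        events_path = cand if cand.exists() else None
    events = read_events(events_path) if events_path else []

    return OxygenTrace(
        run_id=str(meta.get("run_id", path.stem)),
        animal_id=str(meta["animal_id"]),
        timepoint=str(meta["timepoint"]),
        protocol_id=str(meta["protocol_id"]),
        t=df["time_s"].to_numpy(float),
        conc=df["o2_nmol_per_ml"].to_numpy(float),
        chamber_volume=float(meta["chamber_volume_ml"]),
        tissue_mass=float(meta["tissue_mass_mg"]),
        events=events,
    )


def write_trace(trace: OxygenTrace, path: str | Path) -> tuple[Path, Path]:
    """Write a trace CSV (comment-block metadata) plus events sidecar."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# run_id: {trace.run_id}\n")
        fh.write(f"# animal_id: {trace.animal_id}\n")
        fh.write(f"# timepoint: {trace.timepoint}\n")
        fh.write(f"# protocol_id: {trace.protocol_id}\n")
        fh.write(f"# chamber_volume_ml: {float(trace.chamber_volume)!r}\n")
        fh.write(f"# tissue_mass_mg: {float(trace.tissue_mass)!r}\n")
        fh.write("time_s,o2_nmol_per_ml\n")
        for t, c in zip(trace.t, trace.conc):
            fh.write(f"{float(t)!r},{float(c)!r}\n")
    ev_path = path.with_name(path.stem + ".events.csv")
    with open(ev_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "agent", "target_conc", "unit"])
        for e in trace.events:
            writer.writerow(
                [repr(float(e.t)), e.agent, "" if e.target_conc is None else e.target_conc,
                 e.unit or ""]
            )
    return path, ev_path


def read_cohort(path: str | Path) -> list[SealRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = ["animal_id", "mass_pre_kg", "mass_post_kg", "days_ashore"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file missing columns {missing}")
    return [
        SealRecord(
            animal_id=str(r.animal_id),
            mass_pre=float(r.mass_pre_kg),
            mass_post=float(r.mass_post_kg),
            days_ashore=float(r.days_ashore),
        )
        for r in df.itertuples()
    ]


def write_cohort(records: list[SealRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["animal_id", "mass_pre_kg", "mass_post_kg", "days_ashore"])
        for r in records:
            writer.writerow([r.animal_id, repr(float(r.mass_pre)),
                             repr(float(r.mass_post)), repr(float(r.days_ashore))])
    return path


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["gene_id", "log2fc", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"DE table missing columns {missing}")
    return df


def write_de_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name<TAB>description<TAB>gene1<TAB>gene2..."""
    names, descriptions, members = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{Path(path).name}:{ln}: GMT rows need name, description "
                    "and at least one gene"
                )
            names.append(parts[0])
            descriptions.append(parts[1])
            members.append(frozenset(g for g in parts[2:] if g))
    return GeneSetCollection(tuple(names), tuple(descriptions), tuple(members))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, desc, members in zip(
            collection.names, collection.descriptions, collection.members
        ):
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
    return path


def _fmt(v: Any) -> str:
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return f"{v:.6g}"
    return str(v)


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Diffable TSV: fixed column order, 6-significant-digit floats, NA."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    traces_dir: Path | None = None
    protocols_file: Path | None = None
    cohort_file: Path | None = None
    de_file: Path | None = None
    gmt_file: Path | None = None
    out_dir: Path = Path("results")
    composition: CompositionModel = field(default_factory=CompositionModel)
    equivalents: EnergyEquivalents = field(default_factory=EnergyEquivalents)
    stability_tol: float = 0.02
    steady_window: float = 60.0
    smoothing_window: float = 20.0
    leak_flux: float | None = None
    alpha: float = 0.05
    padj_cut: float = 0.05
    lfc_cut: float = 1.0
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("traces_dir", "protocols_file", "cohort_file", "de_file",
                     "gmt_file"):
            value = getattr(self, name)
            if value is not None:
                value = Path(value)
                setattr(self, name, value)
                if not value.exists():
                    raise ConfigError(f"{name}: path {value} does not exist")
        self.out_dir = Path(self.out_dir)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; relative paths resolve to the file."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    def respath(key: str) -> Path | None:
        v = doc.get(key)
        return (base / v) if v is not None else None

    comp = CompositionModel(**doc.get("composition", {}))
    eq = EnergyEquivalents(**doc.get("equivalents", {}))
    detector = doc.get("detector", {})
    enr = doc.get("enrichment", {})
    return RunConfig(
        traces_dir=respath("traces_dir"),
        protocols_file=respath("protocols_file"),
        cohort_file=respath("cohort_file"),
        de_file=respath("de_file"),
        gmt_file=respath("gmt_file"),
        out_dir=base / doc.get("out_dir", "results"),
        composition=comp,
        equivalents=eq,
        stability_tol=float(detector.get("stability_tol", 0.02)),
        steady_window=float(detector.get("steady_window", 60.0)),
        smoothing_window=float(detector.get("smoothing_window", 20.0)),
        leak_flux=(float(doc["leak_flux"]) if "leak_flux" in doc else None),
        alpha=float(doc.get("alpha", 0.05)),
        padj_cut=float(enr.get("padj_cut", 0.05)),
        lfc_cut=float(enr.get("lfc_cut", 1.0)),
        n_permutations=int(enr.get("n_permutations", 1000)),
        seed=int(doc.get("seed", 0)),
    )
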