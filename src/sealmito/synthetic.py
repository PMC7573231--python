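"""Seeded synthetic inputs: respirometry traces, seal cohorts, DE tables.

Traces are piecewise-steady oxygen declines: the chamber concentration
integrates -flux x mass / volume for the current protocol state, steps
change at generated titration times, reoxygenation restores the starting
concentration whenever the lower operating bound is reached, and i.i.d.
Gaussian noise is added to the concentration (where instrument noise
actually arises).  Ground-truth state fluxes are returned alongside so
analysis output can be checked against the generator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioenergetics import SealRecord
from .enrichment import bh_adjust
from .errors import ConfigError, ValidationError
from .protocols import SuitProtocol, default_protocols
from .respirometry import OxygenTrace, SteadyState, TitrationEvent

__all__ = ["TraceSpec", "CohortSpec", "simulate_trace", "simulate_cohort",
           "simulate_de_table"]


@dataclass(frozen=True)
class TraceSpec:
    """Parameters for one simulated SUIT run."""

    protocol_id: str = "B"
    true_state_fluxes: dict = field(
        default_factory=lambda: {"Ln": 5.0, "OXPHOS": 40.0, "LOmy": 8.0,
                                 "ETS": 55.0, "CI": 30.0, "CII": 25.0}
    )
    baseline_flux: float = 2.0
    noise_sd: float = 0.0  # nmol ml^-1 on concentration
    chamber_volume: float = 2.0  # ml
    tissue_mass: float = 3.0  # mg (study range 2-5)
    o2_start: float = 400.0  # nmol ml^-1
    reoxygenate_at: float = 250.0  # nmol ml^-1
    cytc_bump_frac: float = 0.02
    dwell: float = 300.0  # seconds per titration segment
    dwell_jitter: float = 0.0  # sd of dwell jitter, seconds
    dt: float = 1.0  # sampling interval, seconds
    seed: int | None = None
    animal_id: str = "sim"
    timepoint: str = "pre"
    run_id: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.true_state_fluxes.values()):
            raise ConfigError("state fluxes must be >= 0")
        if not (0 < self.reoxygenate_at < self.o2_start):
            raise ConfigError("need 0 < reoxygenate_at < o2_start")
        if self.dwell <= 0 or self.dt <= 0:
            raise ConfigError("dwell and dt must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters for a simulated molt cohort (Table-2-like structure)."""

    n_animals: int = 6
    mass_pre_mean: float = 388.0
    mass_pre_sd: float = 50.0
    daily_loss_mean: float = 3.0
    daily_loss_sd: float = 0.5
    days_mean: float = 34.0
    days_sd: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigError("n_animals must be >= 1")
        if min(self.mass_pre_mean, self.daily_loss_mean, self.days_mean) <= 0:
            raise ConfigError("cohort means must be > 0")


def _segment_fluxes(protocol: SuitProtocol, spec: TraceSpec) -> list[tuple[str, float]]:
    """Total chamber flux (baseline + state) per protocol step, in order.

    Transitional 'none' steps borrow the next labeled state's flux (a
    titration en route to that state); the cytochrome-c check bumps the
    preceding state's flux by ``cytc_bump_frac`` for its segment only.
    """
    steps = protocol.steps
    labeled_flux: list[float | None] = []
    for s in steps:
        if s.state == "baseline":
            labeled_flux.append(0.0)
        elif s.state in spec.true_state_fluxes:
            labeled_flux.append(float(spec.true_state_fluxes[s.state]))
        elif s.state in ("none", "cytc_check"):
            labeled_flux.append(None)
        else:
            raise ConfigError(
                f"protocol {protocol.protocol_id} measures {s.state!r} but "
                "true_state_fluxes does not define it"
            )

    out: list[tuple[str, float]] = []
    for i, s in enumerate(steps):
        flux = labeled_flux[i]
        if flux is None:
            if s.state == "cytc_check":
                prev = next(
                    (labeled_flux[j] for j in range(i - 1, -1, -1)
                     if labeled_flux[j] is not None),
                    0.0,
                )
                flux = prev * (1.0 + spec.cytc_bump_frac)
            else:
                nxt = next(
                    (labeled_flux[j] for j in range(i + 1, len(steps))
                     if labeled_flux[j] is not None),
                    None,
                )
                if nxt is None:
                    nxt = next(
                        (labeled_flux[j] for j in range(i - 1, -1, -1)
                         if labeled_flux[j] is not None),
                        0.0,
                    )
                flux = nxt
        out.append((s.state, spec.baseline_flux + flux))
    return out


def simulate_trace(
    spec: TraceSpec, protocols: dict[str, SuitProtocol] | None = None
) -> tuple[OxygenTrace, list[SteadyState]]:
    """Simulate one SUIT run; returns (trace, ground-truth steady states).

    Ground truth carries the baseline-corrected state fluxes (the values
    the analysis pipeline should recover after its own correction).
    """
    protocols = protocols or default_protocols()
    try:
        protocol = protocols[spec.protocol_id]
    except KeyError:
        raise ConfigError(f"unknown protocol {spec.protocol_id!r}")
    rng = np.random.default_rng(spec.seed)

    seg_fluxes = _segment_fluxes(protocol, spec)
    dwells = [
        max(spec.dwell + (rng.normal(0, spec.dwell_jitter) if spec.dwell_jitter else 0.0),
            spec.dt * 10)
        for _ in seg_fluxes
    ]

    # guard: every segment must be able to hold a steady plateau between
    # reoxygenations (time to drain the O2 window must exceed ~90 s)
    drainable = spec.o2_start - spec.reoxygenate_at
    for (state, total_flux), _d in zip(seg_fluxes, dwells):
        if total_flux <= 0:
            continue
        rate = total_flux * spec.tissue_mass / spec.chamber_volume / 1000.0
        if drainable / rate < 90.0:
            raise ConfigError(
                f"state {state}: flux {total_flux} drains the oxygen window in "
                f"{drainable / rate:.0f}s; no steady plateau possible"
            )

    t_samples: list[float] = []
    conc_samples: list[float] = []
    events: list[TitrationEvent] = []
    truth: list[SteadyState] = []

    conc = spec.o2_start
    t = 0.0
    for i, ((state, total_flux), d) in enumerate(zip(seg_fluxes, dwells)):
        seg_start = t
        if i > 0:
            step = protocol.steps[i]
            for agent in sorted(step.agents):
                events.append(TitrationEvent(t=t, agent=agent))
        rate = total_flux * spec.tissue_mass / spec.chamber_volume / 1000.0
        n_pts = int(round(d / spec.dt))
        for _ in range(n_pts):
            t_samples.append(t)
            conc_samples.append(conc)
            t += spec.dt
            conc -= rate * spec.dt
            if conc <= spec.reoxygenate_at:
                events.append(TitrationEvent(t=t, agent="REOX"))
                conc = spec.o2_start
        if state not in ("none", "cytc_check"):
            flux = 0.0 if state == "baseline" else float(spec.true_state_fluxes[state])
            truth.append(
                SteadyState(
                    state_label=state,
                    flux=(spec.baseline_flux if state == "baseline" else flux),
                    window=(seg_start, t),
                    slope_residual=0.0,
                    baseline_corrected=(state != "baseline"),
                )
            )
    t_samples.append(t)
    conc_samples.append(conc)

    # latent oxygen stays in (0, o2_start] by construction; measurement
    # noise rides on top unclipped (clipping at the ceiling would bias
    # slope estimates wherever the signal sits near o2_start)
    conc_arr = np.clip(np.asarray(conc_samples), np.finfo(float).tiny,
                       spec.o2_start)
    if spec.noise_sd > 0:
        conc_arr = conc_arr + rng.normal(0.0, spec.noise_sd, size=conc_arr.size)
        conc_arr = np.clip(conc_arr, np.finfo(float).tiny, None)

    trace = OxygenTrace(
        run_id=spec.run_id or f"{spec.animal_id}-{spec.timepoint}-{spec.protocol_id}",
        animal_id=spec.animal_id,
        timepoint=spec.timepoint,
        protocol_id=spec.protocol_id,
        t=np.asarray(t_samples),
        conc=conc_arr,
        chamber_volume=spec.chamber_volume,
        tissue_mass=spec.tissue_mass,
        events=events,
    )
    return trace, truth


def simulate_cohort(spec: CohortSpec) -> list[SealRecord]:
    """Draw a seeded cohort of molt records.

    mass_post = mass_pre - daily_loss x days, floored at half the
    pre-molt mass (with a warning) so records stay physical.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_animals):
        mass_pre = max(rng.normal(spec.mass_pre_mean, spec.mass_pre_sd), 1.0)
        loss = max(rng.normal(spec.daily_loss_mean, spec.daily_loss_sd), 0.0)
        days = max(rng.normal(spec.days_mean, spec.days_sd), 1.0)
        mass_post = mass_pre - loss * days
        floor = 0.5 * mass_pre
        if mass_post < floor:
            warnings.warn(
                f"animal {i}: simulated post-molt mass floored at half the "
                "pre-molt mass",
                UserWarning,
                stacklevel=2,
            )
            mass_post = floor
        records.append(
            SealRecord(
                animal_id=f"seal{i + 1:02d}",
                mass_pre=float(mass_pre),
                mass_post=float(mass_post),
                days_ashore=float(days),
            )
        )
    return records


def simulate_de_table(
    n_genes: int = 1000,
    frac_up: float = 0.0,
    frac_down: float = 0.0,
    effect_lfc: float = 2.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Simulate a DE table with a spiked fraction of true up/down genes.

    Null genes: log2fc ~ N(0, 0.3), p ~ U(0, 1).  Spiked genes:
    |log2fc| = effect_lfc + |N(0, 0.5)| and p ~ U(0, 1e-6).  padj is BH
    over all p.  Returns (table, truth) where truth lists the spiked
    up/down gene ids.
    """
    if frac_up + frac_down > 1:
        raise ValidationError("frac_up + frac_down must be <= 1")
    rng = np.random.default_rng(seed)
    n_up = int(round(n_genes * frac_up))
    n_down = int(round(n_genes * frac_down))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    lfc = rng.normal(0.0, 0.3, size=n_genes)
    pvals = rng.uniform(0.0, 1.0, size=n_genes)

    spiked = rng.choice(n_genes, size=n_up + n_down, replace=False)
    up_idx, down_idx = spiked[:n_up], spiked[n_up:]
    lfc[up_idx] = effect_lfc + np.abs(rng.normal(0.0, 0.5, size=n_up))
    lfc[down_idx] = -(effect_lfc + np.abs(rng.normal(0.0, 0.5, size=n_down)))
    pvals[spiked] = rng.uniform(0.0, 1e-6, size=spiked.size)

    table = pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc": lfc,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
        }
    )
    truth = {
        "up": [genes[i] for i in sorted(up_idx)],
        "down": [genes[i] for i in sorted(down_idx)],
    }
    return table, truth
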