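"""Ground-truth-labelled generators for every input the pipeline consumes.

Three generators mirror the statistical structure the analysis assumes:

* spectral-count tables with a Poisson background present in both
  conditions, a spiked subpopulation whose trap-condition counts are
  ``fold`` times higher (with optional reference dropout), and bead binders
  that appear in the negative control with >= 3 unique peptides;
* saturating one-site recovery traces with Gaussian noise, emitted
  un-normalized via an affine intensity transform;
* multiplicative dose-response surfaces with an optional supra-additive
  interaction bonus.

Everything is a pure function of its config: the top-level seed plus a fixed
per-generator stream offset determines every draw, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables_io import FrapTrace, IdentificationTable, ProteinRecord
from .interactome_core import aggregate_replicates

# fixed stream offsets so the three generators are independent
_STREAM_INTERACTOME = 1
_STREAM_FRAP = 2
_STREAM_VIABILITY = 3


@dataclass(frozen=True)
class FrapSimConfig:
    n_traces: int = 10
    t_half: float = 5.0
    ymax: float = 1.0
    ymax_jitter: float = 0.0
    noise_sd: float = 0.05
    t_max: float = 60.0
    dt: float = 2.0
    prebleach: float = 1000.0
    postbleach: float = 200.0

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValidationError("t_half must be > 0")
        if not (0 < self.ymax <= 1.5):
            raise ValidationError("ymax must be in (0, 1.5]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.dt <= 0 or self.t_max <= 0:
            raise ValidationError("dt and t_max must be > 0")


@dataclass(frozen=True)
class ViabilitySimConfig:
    doses_a: tuple[float, ...] = (0.0, 10.0, 100.0)
    doses_b: tuple[float, ...] = (0.0, 1.0, 10.0)
    effects_a: tuple[float, ...] = (0.0, 0.2, 0.5)
    effects_b: tuple[float, ...] = (0.0, 0.3, 0.6)
    bonus: float = 0.0
    bonus_cells: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.02
    n_replicates: int = 3
    vehicle_signal: float = 1000.0

    def __post_init__(self) -> None:
        if len(self.doses_a) != len(self.effects_a):
            raise ValidationError("doses_a and effects_a differ in length")
        if len(self.doses_b) != len(self.effects_b):
            raise ValidationError("doses_b and effects_b differ in length")
        for effects, doses in ((self.effects_a, self.doses_a),
                               (self.effects_b, self.doses_b)):
            if 0.0 not in doses:
                raise ValidationError("dose vectors must include 0")
            for dose, effect in zip(doses, effects):
                if not (0.0 <= effect <= 1.0):
                    raise ValidationError("effects must be in [0, 1]")
                if dose == 0 and effect != 0:
                    raise ValidationError("vehicle effect must be 0")
        if not (0.0 <= self.bonus <= 1.0):
            raise ValidationError("bonus must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_background: int = 300
    n_spiked: int = 20
    n_bead_binders: int = 30
    lambda_bg: float = 10.0
    fold: float = 4.0
    dropout_ref: float = 0.1
    n_replicates: int = 3
    overdispersion: float = 0.0
    frap: FrapSimConfig = field(default_factory=FrapSimConfig)
    viability: ViabilitySimConfig = field(default_factory=ViabilitySimConfig)

    def __post_init__(self) -> None:
        for name in ("n_background", "n_spiked", "n_bead_binders", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.lambda_bg < 0 or self.fold < 0 or self.overdispersion < 0:
            raise ValidationError("rates must be >= 0")
        if not (0.0 <= self.dropout_ref <= 1.0):
            raise ValidationError("dropout_ref must be a probability")


@dataclass(frozen=True)
class SimTruth:
    spiked: tuple[str, ...]
    bead_binders: tuple[str, ...]
    background: tuple[str, ...]
    config: SimConfig

    def __post_init__(self) -> None:
        if set(self.spiked) & set(self.bead_binders):
            raise ValidationError("truth sets must be disjoint")


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------


def _unique_peptides(psms: int, floor: int = 1) -> int:
    """Deterministic peptide count: about half the PSMs, at least ``floor``."""
    if psms == 0:
        return 0
    return max(floor, math.ceil(psms / 2))


def _counts(rng: np.random.Generator, lam: float, size: int,
            overdispersion: float) -> np.ndarray:
    """Poisson counts, or negative binomial when overdispersion > 0."""
    if overdispersion <= 0:
        return rng.poisson(lam, size=size)
    # NB parameterized by mean lam and variance lam * (1 + overdispersion)
    p = 1.0 / (1.0 + overdispersion)
    n = lam / overdispersion
    return rng.negative_binomial(n, p, size=size)


def _ms_score(rng: np.random.Generator, psms: int) -> float:
    if psms == 0:
        return 0.0
    return float(psms * 30.0 * math.exp(rng.normal(0.0, 0.2)))


def simulate_interactome_replicates(
    cfg: SimConfig,
) -> tuple[list[IdentificationTable], list[IdentificationTable],
           IdentificationTable, SimTruth]:
    """Per-replicate trap and reference tables plus one negative control.

    Proteins with zero PSMs in a replicate are absent from that table;
    spiked proteins dropped from the reference (probability ``dropout_ref``)
    are absent from every reference replicate.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_INTERACTOME])

    background = tuple(f"BG{i:05d}" for i in range(cfg.n_background))
    spiked = tuple(f"SP{i:05d}" for i in range(cfg.n_spiked))
    beads = tuple(f"NS{i:05d}" for i in range(cfg.n_bead_binders))
    symbol = lambda acc: f"G{acc}"

    lam_trap = {**{a: cfg.lambda_bg for a in background},
                **{a: cfg.fold * cfg.lambda_bg for a in spiked},
                **{a: 2.0 * cfg.lambda_bg for a in beads}}
    lam_ref = {**{a: cfg.lambda_bg for a in background},
               **{a: cfg.lambda_bg for a in spiked},
               **{a: 2.0 * cfg.lambda_bg for a in beads}}
    dropped = {a for a in spiked if rng.random() < cfg.dropout_ref}

    def build(sample_id: str, condition: str, replicate: int,
              lam: Mapping[str, float], skip: set[str]) -> IdentificationTable:
        records = []
        for accession, rate in lam.items():
            if accession in skip:
                continue
            psms = int(_counts(rng, rate, 1, cfg.overdispersion)[0])
            if psms == 0:
                continue
            records.append(
                ProteinRecord(
                    accession=accession,
                    gene_symbol=symbol(accession),
                    unique_peptides=_unique_peptides(psms),
                    psms=psms,
                    ms_score=_ms_score(rng, psms),
                )
            )
        return IdentificationTable.from_records(
            records, sample_id=sample_id, bait="sim_bait",
            condition=condition, replicate=replicate,
        )

    trap_tables = [
        build(f"trap_rep{r}", "trap", r, lam_trap, set())
        for r in range(1, cfg.n_replicates + 1)
    ]
    ref_tables = [
        build(f"ref_rep{r}", "reference", r, lam_ref, dropped)
        for r in range(1, cfg.n_replicates + 1)
    ]

    # bead binders dominate the negative control with >= 3 unique peptides
    control_records = []
    for accession in beads:
        psms = 6 + int(_counts(rng, 2.0 * cfg.lambda_bg, 1, cfg.overdispersion)[0])
        control_records.append(
            ProteinRecord(
                accession=accession,
                gene_symbol=symbol(accession),
                unique_peptides=_unique_peptides(psms, floor=3),
                psms=psms,
                ms_score=_ms_score(rng, psms),
            )
        )
    control = IdentificationTable.from_records(
        control_records, sample_id="bead_control", bait="control",
        condition="trap", replicate=1,
    )
    truth = SimTruth(spiked=spiked, bead_binders=beads,
                     background=background, config=cfg)
    return trap_tables, ref_tables, control, truth


def simulate_interactome(
    cfg: SimConfig,
) -> tuple[IdentificationTable, IdentificationTable, IdentificationTable, SimTruth]:
    """Replicate-pooled (summed) trap and reference tables, the negative
    control and the generating truth."""
    trap_tables, ref_tables, control, truth = simulate_interactome_replicates(cfg)
    trap = aggregate_replicates(trap_tables, method="sum")
    ref = aggregate_replicates(ref_tables, method="sum")
    return trap, ref, control, truth


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


def simulate_frap(cfg: SimConfig) -> tuple[list[FrapTrace], dict]:
    """Noisy one-site recovery traces, affine-transformed to raw intensities.

    The pre- and post-bleach reference values are the (noise-free) affine
    anchors, so normalization recovers the generating curve plus iid noise on
    every post-bleach frame.
    """
    frap = cfg.frap
    rng = np.random.default_rng([cfg.seed, _STREAM_FRAP])
    times = np.arange(0.0, frap.t_max + frap.dt / 2, frap.dt)
    traces = []
    ymaxes = []
    for index in range(frap.n_traces):
        ymax = frap.ymax
        if frap.ymax_jitter > 0:
            ymax = float(np.clip(
                ymax + rng.uniform(-frap.ymax_jitter, frap.ymax_jitter),
                0.05, 1.5,
            ))
        ymaxes.append(ymax)
        y = ymax * times / (frap.t_half + times)
        if frap.noise_sd > 0:
            y = y + rng.normal(0.0, frap.noise_sd, size=times.size)
        span = frap.prebleach - frap.postbleach
        raw = frap.postbleach + span * y
        traces.append(
            FrapTrace(
                trace_id=f"trace{index:03d}",
                times=tuple(times),
                intensities=tuple(float(v) for v in raw),
                prebleach_value=frap.prebleach,
                postbleach_value=frap.postbleach,
            )
        )
    truth = {
        "t_half": frap.t_half,
        "ymax": ymaxes,
        "noise_sd": frap.noise_sd,
        "n_traces": frap.n_traces,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------


def simulate_viability(cfg: SimConfig):
    """Long-format raw signals for a dose-pair grid plus the generating truth.

    Combination viability is (1 - E_A)(1 - E_B)(1 - bonus) before noise, so a
    zero bonus yields exact Bliss independence in expectation.  Returns a
    (frame, truth) pair; the frame feeds ``ViabilityGrid.from_long``.
    """
    via = cfg.viability
    rng = np.random.default_rng([cfg.seed, _STREAM_VIABILITY])
    bonus_by_cell = {(da, db): b for da, db, b in via.bonus_cells}
    rows = []
    expected_viability = {}
    for da, ea in zip(via.doses_a, via.effects_a):
        for db, eb in zip(via.doses_b, via.effects_b):
            bonus = 0.0
            if da > 0 and db > 0:
                bonus = bonus_by_cell.get((da, db), via.bonus)
            viability = (1.0 - ea) * (1.0 - eb) * (1.0 - bonus)
            expected_viability[(da, db)] = viability
            for rep in range(1, via.n_replicates + 1):
                noisy = viability + (
                    rng.normal(0.0, via.noise_sd) if via.noise_sd > 0 else 0.0
                )
                rows.append((da, db, rep, max(noisy, 0.0) * via.vehicle_signal))
    frame = pd.DataFrame(rows, columns=["dose_a", "dose_b", "replicate", "signal"])
    truth = {
        "expected_viability": expected_viability,
        "bonus": via.bonus,
        "bonus_cells": dict(bonus_by_cell),
        "noise_sd": via.noise_sd,
    }
    return frame, truth


def config_from_dict(data: Mapping) -> SimConfig:
    """Build a SimConfig from a nested plain mapping (e.g. parsed YAML)."""
    data = dict(data)
    frap = FrapSimConfig(**data.pop("frap", {}))
    via = dict(data.pop("viability", {}))
    for key in ("doses_a", "doses_b", "effects_a", "effects_b"):
        if key in via:
            via[key] = tuple(via[key])
    if "bonus_cells" in via:
        via["bonus_cells"] = tuple(tuple(c) for c in via["bonus_cells"])
    return SimConfig(frap=frap, viability=ViabilitySimConfig(**via), **data)
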