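"""Stochastic serial-dilution simulator over repeated growth cycles.

Each transfer cycle: every genotype's propagules grow for one period
according to the deterministic life-history model, total hyphal biomass
is capped at the culture's carrying capacity (proportional rescaling
across genotypes when the cap binds), and a 1/D volumetric aliquot of
the propagule pool seeds the next culture.  Transfer sampling is Poisson
with mean ``census_total / D`` — propagules dilute independently in a
well-mixed aliquot — or, in deterministic mode, the rounded expectation
(round-half-even).

The evolutionary mode adds per-transfer mutation of the heritable
life-history traits (onset time t_c, fragmentation fraction f) on
transferred propagules, so selection on propagule yield emerges from the
dilution bottleneck itself.

Generation accounting follows the regrowth argument: restoring a D-fold
diluted population to its pre-dilution size takes log2(D) doublings per
bout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import yaml

from .life_history import LifeHistory, PropaguleCensus, census

__all__ = [
    "TransferRegime",
    "Genotype",
    "PopulationState",
    "MutationModel",
    "Trajectory",
    "grow_cycle",
    "sample_transfer",
    "run_serial",
    "mutate",
    "run_evolution",
    "generations_per_bout",
    "total_generations",
    "load_scenario",
]


@dataclass(frozen=True)
class TransferRegime:
    """Serial-passage regime: volumes, period, capacity, number of bouts.

    The dilution factor D = culture_volume / transfer_volume; defaults
    reproduce the daily 0.1 mL from 10 mL regime (D = 100, 24 h period).
    """

    culture_volume: float = 10.0
    transfer_volume: float = 0.1
    period: float = 24.0
    carrying_capacity: float = 1e9
    n_transfers: int = 10

    def __post_init__(self) -> None:
        if self.culture_volume <= 0 or self.transfer_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.transfer_volume > self.culture_volume:
            raise ValueError("transfer_volume must be <= culture_volume")
        if self.dilution <= 1:
            raise ValueError("dilution factor must exceed 1")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")
        if self.n_transfers < 0:
            raise ValueError("n_transfers must be >= 0")

    @property
    def dilution(self) -> float:
        return self.culture_volume / self.transfer_volume


@dataclass(frozen=True)
class Genotype:
    """Carrier of heritable life-history traits in the simulator."""

    id: int
    traits: LifeHistory
    parent_id: Optional[int] = None
    birth_transfer: int = 0


@dataclass
class PopulationState:
    """Integer propagule counts per genotype at the start of a cycle."""

    genotypes: Dict[int, Genotype]
    counts: Dict[int, int]
    transfer_index: int = 0

    def __post_init__(self) -> None:
        for gid, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for genotype {gid}")
            if gid not in self.genotypes:
                raise ValueError(f"count for unknown genotype {gid}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def extinct(self) -> bool:
        return self.total == 0


@dataclass(frozen=True)
class MutationModel:
    """Per-transferred-propagule mutation of t_c and/or f.

    ``t_c`` steps are Gaussian with reflection into [0, T]; ``f`` steps
    are Gaussian on the log-odds scale (f is clamped away from the
    boundary before the logit so the scale is defined).
    """

    prob_per_propagule: float = 0.0
    t_c_step_sd: float = 1.0
    f_step_sd: float = 0.0
    mutate_t_c: bool = True
    mutate_f: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_per_propagule <= 1.0:
            raise ValueError("prob_per_propagule must be in [0, 1]")
        if self.t_c_step_sd < 0 or self.f_step_sd < 0:
            raise ValueError("step sds must be >= 0")


@dataclass
class Trajectory:
    """Per-transfer records of a serial-transfer run."""

    records: List[dict] = field(default_factory=list)
    extinction_transfer: Optional[int] = None
    final_state: Optional[PopulationState] = None

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "transfer",
            "total_transferred",
            "mean_t_c",
            "mean_f",
            "conidia_fraction",
            "extinct",
        ]
        return pd.DataFrame(self.records, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        out = {"extinction_transfer": self.extinction_transfer}
        if self.records:
            last = self.records[-1]
            out["final_mean_t_c"] = last["mean_t_c"]
            out["final_mean_f"] = last["mean_f"]
            out["final_total_transferred"] = last["total_transferred"]
        return out

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def grow_cycle(
    state: PopulationState, regime: TransferRegime
) -> Dict[int, PropaguleCensus]:
    """One deterministic growth cycle for every genotype.

    Each genotype's census uses its own traits with P0 = its count and
    T = the regime period.  If summed hyphal biomass exceeds the
    carrying capacity, all hyphal totals are rescaled proportionally to
    sum exactly to the cap, and fragments/conidia are recomputed from
    the capped biomass.
    """
    raw: Dict[int, PropaguleCensus] = {}
    for gid, n in state.counts.items():
        traits = replace(
            state.genotypes[gid].traits, P0=float(n), T=regime.period
        )
        raw[gid] = census(traits)
    total_h = sum(c.hyphal_total for c in raw.values())
    if total_h <= regime.carrying_capacity or total_h == 0.0:
        return raw
    scale = regime.carrying_capacity / total_h
    capped: Dict[int, PropaguleCensus] = {}
    for gid, c in raw.items():
        h = c.hyphal_total * scale
        traits = state.genotypes[gid].traits
        capped[gid] = PropaguleCensus(
            hyphal_total=h,
            suspended_fragments=traits.f * h,
            conidia=traits.r_c * h * (regime.period - traits.t_c),
        )
    return capped


def sample_transfer(
    census_totals: Dict[int, float],
    regime: TransferRegime,
    rng: Optional[np.random.Generator] = None,
    deterministic: bool = False,
) -> Dict[int, int]:
    """Draw the transferred aliquot: Poisson(total / D) per genotype.

    In deterministic mode the expectation is rounded half-to-even
    instead of sampled.
    """
    d = regime.dilution
    out: Dict[int, int] = {}
    for gid, tot in census_totals.items():
        if tot < 0:
            raise ValueError(f"negative census total for genotype {gid}")
        mean = tot / d
        if deterministic:
            out[gid] = int(np.rint(mean))
        else:
            if rng is None:
                raise ValueError("rng required unless deterministic=True")
            out[gid] = int(rng.poisson(mean))
    return out


def _record(
    transfer: int,
    transferred: Dict[int, int],
    censuses: Dict[int, PropaguleCensus],
    state: PopulationState,
) -> dict:
    total = sum(transferred.values())
    conidia = sum(c.conidia for c in censuses.values())
    frags = sum(c.suspended_fragments for c in censuses.values())
    pool = conidia + frags
    if total > 0:
        mean_t_c = (
            sum(
                state.genotypes[g].traits.t_c * n
                for g, n in transferred.items()
            )
            / total
        )
        mean_f = (
            sum(
                state.genotypes[g].traits.f * n
                for g, n in transferred.items()
            )
            / total
        )
    else:
        mean_t_c = math.nan
        mean_f = math.nan
    return {
        "transfer": transfer,
        "total_transferred": total,
        "mean_t_c": mean_t_c,
        "mean_f": mean_f,
        "conidia_fraction": conidia / pool if pool > 0 else math.nan,
        "extinct": total == 0,
    }


def run_serial(
    initial: PopulationState,
    regime: TransferRegime,
    rng: Optional[np.random.Generator] = None,
    deterministic: bool = False,
) -> Trajectory:
    """Iterate grow + sample for n_transfers or until extinction.

    ``extinction_transfer`` is the 1-based index of the first transfer
    at which zero propagules were carried over.
    """
    traj = Trajectory()
    state = initial
    for k in range(1, regime.n_transfers + 1):
        if state.extinct:
            break
        censuses = grow_cycle(state, regime)
        totals = {g: c.total for g, c in censuses.items()}
        transferred = sample_transfer(totals, regime, rng, deterministic)
        transferred = {g: n for g, n in transferred.items() if n > 0}
        state = PopulationState(
            genotypes={
                g: state.genotypes[g] for g in transferred
            } or dict(state.genotypes),
            counts=transferred,
            transfer_index=k,
        )
        traj.records.append(_record(k, transferred, censuses, state))
        if state.extinct and traj.extinction_transfer is None:
            traj.extinction_transfer = k
            break
    traj.final_state = state
    return traj


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    y = (x - lo) % (2 * span)
    return lo + (y if y <= span else 2 * span - y)


def mutate(
    genotype: Genotype,
    model: MutationModel,
    rng: np.random.Generator,
    new_id: int,
    birth_transfer: int = 0,
) -> Genotype:
    """Produce a mutant genotype: perturbed traits, fresh id, parent kept."""
    t = genotype.traits
    t_c, f = t.t_c, t.f
    if model.mutate_t_c and model.t_c_step_sd > 0:
        t_c = _reflect(t_c + rng.normal(0.0, model.t_c_step_sd), 0.0, t.T)
    if model.mutate_f and model.f_step_sd > 0:
        eps = 1e-6
        logit = math.log((min(max(f, eps), 1 - eps)) / (1 - min(max(f, eps), 1 - eps)))
        f = 1.0 / (1.0 + math.exp(-(logit + rng.normal(0.0, model.f_step_sd))))
    return Genotype(
        id=new_id,
        traits=replace(t, t_c=t_c, f=f),
        parent_id=genotype.id,
        birth_transfer=birth_transfer,
    )


def run_evolution(
    initial: PopulationState,
    regime: TransferRegime,
    mutation_model: MutationModel,
    rng: np.random.Generator,
) -> Trajectory:
    """Serial transfers with heritable trait mutation among transferred
    propagules; selection on propagule yield emerges from the bottleneck."""
    traj = Trajectory()
    genotypes = dict(initial.genotypes)
    counts = dict(initial.counts)
    next_id = max(genotypes) + 1 if genotypes else 0
    state = PopulationState(genotypes, counts, initial.transfer_index)
    for k in range(1, regime.n_transfers + 1):
        if state.extinct:
            break
        censuses = grow_cycle(state, regime)
        totals = {g: c.total for g, c in censuses.items()}
        transferred = sample_transfer(totals, regime, rng)
        transferred = {g: n for g, n in transferred.items() if n > 0}
        # mutation among the propagules that made it through the aliquot
        if mutation_model.prob_per_propagule > 0:
            new_counts: Dict[int, int] = {}
            for gid, n in transferred.items():
                n_mut = int(rng.binomial(n, mutation_model.prob_per_propagule))
                n_mut = min(n_mut, n)
                if n - n_mut > 0:
                    new_counts[gid] = n - n_mut
                for _ in range(n_mut):
                    mut = mutate(
                        state.genotypes[gid], mutation_model, rng, next_id, k
                    )
                    genotypes[mut.id] = mut
                    new_counts[mut.id] = new_counts.get(mut.id, 0) + 1
                    next_id += 1
            transferred = new_counts
        surviving = {g: genotypes[g] for g in transferred}
        state = PopulationState(
            genotypes=surviving or dict(genotypes),
            counts=transferred,
            transfer_index=k,
        )
        genotypes = dict(state.genotypes)
        traj.records.append(_record(k, transferred, censuses, state))
        if state.extinct and traj.extinction_transfer is None:
            traj.extinction_transfer = k
            break
    traj.final_state = state
    return traj


def generations_per_bout(dilution: float) -> float:
    """Doublings needed to regrow a D-fold diluted culture: log2(D)."""
    if dilution < 1:
        raise ValueError(f"dilution must be >= 1, got {dilution}")
    return math.log2(dilution)


def total_generations(
    n_transfers: int, dilution: float, rounding_rule: str = "exact"
) -> float:
    """Cumulative generations over a run, under an explicit rounding rule.

    Rules:

    * ``"exact"``: n_transfers * log2(D).
    * ``"one-decimal-floor"``: per-bout generations floored to one
      decimal before multiplying (85 bouts at D = 100 gives 85 * 6.6 = 561).
    * ``"nearest-ten"``: exact product rounded to the nearest ten
      (45 -> 300, 85 -> 560 at D = 100).
    """
    if n_transfers < 0:
        raise ValueError("n_transfers must be >= 0")
    g = generations_per_bout(dilution)
    if rounding_rule == "exact":
        return n_transfers * g
    if rounding_rule == "one-decimal-floor":
        return n_transfers * (math.floor(g * 10.0) / 10.0)
    if rounding_rule == "nearest-ten":
        return float(round(n_transfers * g / 10.0) * 10)
    raise ValueError(f"unknown rounding rule {rounding_rule!r}")


def load_scenario(path):
    """Read a scenario config (regime, genotypes, optional mutation block).

    Returns ``(PopulationState, TransferRegime, MutationModel or None)``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "regime" not in raw or "genotypes" not in raw:
        raise ValueError(f"{path}: scenario needs 'regime' and 'genotypes' blocks")
    regime_kwargs = {
        k: (int(v) if k == "n_transfers" else float(v))
        for k, v in raw["regime"].items()
    }
    regime = TransferRegime(**regime_kwargs)
    genotypes: Dict[int, Genotype] = {}
    counts: Dict[int, int] = {}
    for i, block in enumerate(raw["genotypes"]):
        block = dict(block)
        count = int(block.pop("count"))
        traits = LifeHistory(**{k: float(v) for k, v in block.items()})
        genotypes[i] = Genotype(id=i, traits=traits)
        counts[i] = count
    mut = None
    if "mutation" in raw and raw["mutation"] is not None:
        mut = MutationModel(**raw["mutation"])
    return PopulationState(genotypes, counts), regime, mut
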