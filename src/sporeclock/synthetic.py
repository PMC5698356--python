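"""Synthetic inputs with known planted structure.

The expression generator emulates the shape of a duplicate bulk RNA-seq
experiment contrasting an ancestral and a derived fungal genotype at
18, 22 and 24 hours post transfer: a locus x sample FPKM matrix over
~10^4 loci of which ~700 are grouped into ~28 GO-slim process terms,
with planted genotype-direction effects, genotype x time divergence
slopes, fold-change loci, and per-replicate multiplicative noise.

Effects are planted on the *share* scale — the unit in which the
downstream statistics operate — and mapped back to FPKM through the
exact inverse of the pipeline's normalization: for a locus with
baseline value v0 = log(x0 + 1) and target share q_ct in cell (c, t),
the cell's value is v = 6 * v0 * q_ct and its FPKM is exp(v) - 1.
At zero noise the pipeline therefore recovers the planted shares
exactly.  Per-replicate noise is additive on the share scale, which is
log-normal multiplicative on FPKM + 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .expression import GENOTYPES, TIMEPOINTS, ExpressionMatrix, GOMap
from .life_history import LifeHistory
from .serial_transfer import (
    Genotype,
    MutationModel,
    PopulationState,
    TransferRegime,
)

__all__ = [
    "PlantedTruth",
    "make_go_universe",
    "simulate_expression",
    "make_scenario_fixture",
    "SCENARIO_NAMES",
]

_TIME_MEAN = sum(TIMEPOINTS) / len(TIMEPOINTS)


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic expression matrix.

    ``directional_effects`` maps GO term -> signed derived-minus-ancestor
    mean share difference; ``temporal_slopes`` maps GO term -> per-hour
    slope of the genotype share difference; ``fold_change_multipliers``
    maps locus -> multiplier applied to derived FPKM at every timepoint.
    ``noise_sd`` is the per-replicate share-scale noise standard
    deviation.
    """

    directional_effects: Dict[str, float] = field(default_factory=dict)
    temporal_slopes: Dict[str, float] = field(default_factory=dict)
    fold_change_multipliers: Dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.005
    baseline_meanlog: float = 2.0
    baseline_sdlog: float = 1.5
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_go_universe(
    n_terms: int = 28,
    loci_per_term: int = 25,
    multi_membership_prob: float = 0.1,
    seed: int = 0,
) -> GOMap:
    """Reproducible GO universe: ``n_terms`` terms with ``loci_per_term``
    distinct primary loci each; every locus additionally joins one other
    uniformly chosen term with probability ``multi_membership_prob``.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 GO terms")
    if loci_per_term < 1:
        raise ValueError("loci_per_term must be >= 1")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:04d}" for i in range(n_terms)]
    memberships: Dict[str, set] = {}
    locus_idx = 0
    for term in terms:
        for _ in range(loci_per_term):
            locus = f"locus_{locus_idx:05d}"
            memberships[locus] = {term}
            locus_idx += 1
    if multi_membership_prob > 0:
        for locus, ts in memberships.items():
            if rng.random() < multi_membership_prob:
                others = [t for t in terms if t not in ts]
                ts.add(others[int(rng.integers(len(others)))])
    return GOMap({l: frozenset(ts) for l, ts in memberships.items()})


def _target_shares(
    terms: frozenset,
    truth: PlantedTruth,
) -> np.ndarray:
    """Planted share matrix (2 genotypes x 3 times) for one locus.

    A directional effect D moves each derived cell up by D/2 and each
    ancestor cell down by D/2 (so the mean genotype difference is D and
    the six shares still sum to 1).  A temporal slope s tilts the
    genotype difference by s * (t - mean(t)) per cell, antisymmetric in
    genotype.  Loci in several planted terms accumulate contributions.
    """
    times = np.asarray(TIMEPOINTS, dtype=float)
    q = np.full((2, 3), 1.0 / 6.0)
    for term in terms:
        d = truth.directional_effects.get(term, 0.0)
        if d:
            q[1, :] += d / 2.0
            q[0, :] -= d / 2.0
        s = truth.temporal_slopes.get(term, 0.0)
        if s:
            tilt = s * (times - _TIME_MEAN) / 2.0
            q[1, :] += tilt
            q[0, :] -= tilt
    if (q <= 0).any():
        raise ValueError(
            "planted effects push a share non-positive; reduce effect sizes"
        )
    return q


def simulate_expression(
    gomap: GOMap,
    truth: PlantedTruth,
    n_reps: int = 2,
    n_background_loci: int = 9037,
) -> ExpressionMatrix:
    """Generate an FPKM matrix over the GO universe plus unmapped
    background loci, with the planted structure of ``truth``.

    Baseline FPKM is log-normal (meanlog 2, sdlog 1.5 by default) per
    locus, identical across cells before effects and noise.  Fold-change
    multipliers scale derived-genotype FPKM after share construction.
    """
    rng = np.random.default_rng(truth.seed)
    mapped = sorted(gomap.memberships)
    background = [
        f"bg_{i:05d}" for i in range(n_background_loci)
    ]
    loci = mapped + background
    n = len(loci)
    x0 = rng.lognormal(truth.baseline_meanlog, truth.baseline_sdlog, size=n)
    v0 = np.log1p(x0)

    # planted per-locus share matrices, accumulated over term memberships
    q = np.empty((n, 2, 3))
    for i, locus in enumerate(loci):
        terms = gomap.memberships.get(locus, frozenset())
        q[i] = _target_shares(terms, truth)

    cols = [
        (g, t, r)
        for g in GENOTYPES
        for t in TIMEPOINTS
        for r in range(1, n_reps + 1)
    ]
    gi = np.array([GENOTYPES.index(g) for g, _, _ in cols])
    ti = np.array([TIMEPOINTS.index(t) for _, t, _ in cols])
    shares = q[:, gi, ti]  # (n, 12)
    if truth.noise_sd > 0:
        shares = shares + rng.normal(0.0, truth.noise_sd, size=shares.shape)
        shares = np.maximum(shares, 1e-9)
    data = np.expm1(6.0 * v0[:, None] * shares)
    df = pd.DataFrame(
        data, index=pd.Index(loci, name="locus_id"),
        columns=pd.MultiIndex.from_tuples(cols),
    )
    for locus, mult in truth.fold_change_multipliers.items():
        if locus in df.index:
            df.loc[locus, "derived"] = df.loc[locus, "derived"].to_numpy() * mult
    return ExpressionMatrix(df)


SCENARIO_NAMES = ("ancestor-like", "derived-like", "near-extinction")


def make_scenario_fixture(
    name: str,
) -> Tuple[PopulationState, TransferRegime, Optional[MutationModel], Dict]:
    """Named simulator fixtures reproducing qualitative contrasts.

    * ``ancestor-like``: submerged mycelial growth with conidiation
      deferred to the full 24 h period — zero fresh conidia in a cycle.
    * ``derived-like``: early onset and fast conidiation — a conidia
      pool >= 1e7 per 10 mL culture (1e6 per mL scale) within one cycle,
      >= 100x the ancestor-like propagule pool.
    * ``near-extinction``: per-capita transferable yield below 1, so a
      ~100-propagule founding population goes extinct within about five
      daily transfers.

    Returns (initial state, regime, mutation model or None, expected
    qualitative outcome record).
    """
    if name == "ancestor-like":
        traits = LifeHistory(r_h=0.25, r_c=0.5, f=0.01, T=24.0, t_c=24.0)
        state = PopulationState(
            {0: Genotype(0, traits)}, {0: 5_000_000}
        )
        regime = TransferRegime(carrying_capacity=1e9, n_transfers=5)
        expected = {"conidia_at_24h": 0.0}
    elif name == "derived-like":
        traits = LifeHistory(r_h=0.45, r_c=0.5, f=0.05, T=24.0, t_c=18.0)
        state = PopulationState({0: Genotype(0, traits)}, {0: 10_000})
        regime = TransferRegime(carrying_capacity=1e9, n_transfers=5)
        expected = {"min_conidia_at_24h": 1e7}
    elif name == "near-extinction":
        traits = LifeHistory(r_h=0.10, r_c=0.0, f=0.5, T=24.0, t_c=24.0)
        state = PopulationState({0: Genotype(0, traits)}, {0: 100})
        regime = TransferRegime(carrying_capacity=1e9, n_transfers=10)
        expected = {"max_extinction_transfer": 5}
    else:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}"
        )
    return state, regime, None, expected
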