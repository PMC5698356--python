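"""GO-grouped statistics on bulk FPKM expression tables.

The pipeline consumes a locus x sample FPKM matrix over a
2-genotype (ancestor, derived) x 3-timepoint (18, 22, 24 h) x
replicate design and a locus -> GO-slim term map, and performs:

1. fold-change filtering on replicate-mean FPKM (|log2 FC| > 1 at one
   or more timepoints, with a pseudocount for zero FPKM);
2. normalization: replicate-average each genotype x time cell, take
   log(x + 1) (natural log), and divide each locus's six values by
   their sum, giving per-locus relative expression shares that sum
   to 1;
3. a global fixed-effects ANOVA on the GO-term x genotype x time
   cell-mean table with terms GO + genotype + time + GO:genotype +
   GO:time (model df 4G-1, residual df 2G for G terms — the residual
   pools genotype:time and the three-way cell variation);
4. per-GO locus-level two-way ANOVAs (genotype, time, interaction on
   member-locus shares), with Benjamini-Hochberg correction across
   terms for the directional (genotype main effect) and temporal
   (genotype x time interaction) calls;
5. per-GO deviation profiles: genotype x time cell means centered on
   the term's grand mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GENOTYPES: Tuple[str, str] = ("ancestor", "derived")
TIMEPOINTS: Tuple[int, int, int] = (18, 22, 24)

__all__ = [
    "GENOTYPES",
    "TIMEPOINTS",
    "ExpressionMatrix",
    "GOMap",
    "NormalizedMatrix",
    "GOGroupStats",
    "GlobalAnovaFit",
    "ExpressionValidationError",
    "load_expression",
    "load_go_map",
    "fold_change_loci",
    "normalize_expression",
    "global_fit",
    "directional_tests",
    "temporal_tests",
    "deviation_profile",
    "write_group_stats",
    "write_deviation_profile",
]


class ExpressionValidationError(ValueError):
    """Malformed expression or GO-map input."""


def _parse_sample(col: str) -> Tuple[str, int, int]:
    """Parse '<genotype>_<time>h_r<rep>' sample column names."""
    try:
        geno, time_s, rep_s = col.split("_")
        if not time_s.endswith("h") or not rep_s.startswith("r"):
            raise ValueError
        time = int(time_s[:-1])
        rep = int(rep_s[1:])
    except ValueError:
        raise ExpressionValidationError(
            f"malformed sample column {col!r}; expected <genotype>_<time>h_r<rep>"
        ) from None
    if geno not in GENOTYPES:
        raise ExpressionValidationError(
            f"unknown genotype {geno!r} in column {col!r}"
        )
    if time not in TIMEPOINTS:
        raise ExpressionValidationError(
            f"unknown timepoint {time} in column {col!r}"
        )
    return geno, time, rep


@dataclass
class ExpressionMatrix:
    """Locus x sample FPKM values with (genotype, time, replicate) columns."""

    values: pd.DataFrame  # index: locus_id; columns: MultiIndex (genotype, time, rep)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ExpressionValidationError(f"duplicate locus ids: {dups[:5]}")
        if (v.to_numpy() < 0).any():
            bad = v.index[(v < 0).any(axis=1)][0]
            raise ExpressionValidationError(
                f"negative FPKM value at locus {bad!r}"
            )
        reps = sorted({c[2] for c in v.columns})
        expected = {
            (g, t, r) for g in GENOTYPES for t in TIMEPOINTS for r in reps
        }
        if set(v.columns) != expected:
            raise ExpressionValidationError(
                "incomplete genotype x time x replicate crossing"
            )

    @property
    def loci(self) -> pd.Index:
        return self.values.index

    @property
    def n_loci(self) -> int:
        return len(self.values)

    @property
    def replicates(self) -> List[int]:
        return sorted({c[2] for c in self.values.columns})

    def cell_means(self) -> pd.DataFrame:
        """Replicate-average FPKM per genotype x time cell (6 columns)."""
        means = self.values.T.groupby(level=[0, 1]).mean().T
        cols = [(g, t) for g in GENOTYPES for t in TIMEPOINTS]
        return means.loc[:, cols]

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.columns = [f"{g}_{t}h_r{r}" for g, t, r in df.columns]
        df.index.name = "locus_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a wide frame with '<genotype>_<time>h_r<rep>' columns."""
        parsed = [_parse_sample(c) for c in df.columns]
        out = df.copy()
        out.columns = pd.MultiIndex.from_tuples(parsed)
        return cls(out)


@dataclass
class GOMap:
    """Locus -> set of GO-slim process terms; unmapped loci permitted."""

    memberships: Dict[str, FrozenSet[str]]

    @property
    def terms(self) -> List[str]:
        out: Set[str] = set()
        for ts in self.memberships.values():
            out |= ts
        return sorted(out)

    def loci_of(self, term: str) -> List[str]:
        return sorted(
            l for l, ts in self.memberships.items() if term in ts
        )

    @property
    def n_memberships(self) -> int:
        return sum(len(ts) for ts in self.memberships.values())

    def to_tsv(self, path) -> None:
        rows = [
            (l, t)
            for l in sorted(self.memberships)
            for t in sorted(self.memberships[l])
        ]
        pd.DataFrame(rows, columns=["locus_id", "go_term"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class NormalizedMatrix:
    """Per-locus relative expression shares over the six genotype x time
    cells; shares of a locus sum to 1 unless the locus is all-zero."""

    shares: pd.DataFrame  # index locus_id, columns MultiIndex (genotype, time)
    zero_loci: FrozenSet[str] = field(default_factory=frozenset)

    def locus_array(self, loci: Sequence[str]) -> np.ndarray:
        """Shares as array (n_loci, 2, 3) in (genotype, time) canonical order."""
        arr = self.shares.loc[list(loci)].to_numpy()
        return arr.reshape(len(loci), len(GENOTYPES), len(TIMEPOINTS))


@dataclass(frozen=True)
class GlobalAnovaFit:
    """Summary of the GO-grouped cell-mean fixed-effects ANOVA."""

    df_model: int
    df_resid: int
    f_statistic: float
    adj_r_squared: float
    n_terms: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "df_model": self.df_model,
                    "df_resid": self.df_resid,
                    "F": self.f_statistic,
                    "adj_r2": self.adj_r_squared,
                    "n_terms": self.n_terms,
                },
                fh,
                indent=2,
            )


@dataclass
class GOGroupStats:
    """Per-GO-term test results from the locus-level two-way ANOVA."""

    term: str
    n_loci: int
    effect: float  # derived-minus-ancestor mean share
    p_genotype: float
    q_genotype: float
    p_interaction: float
    q_interaction: float
    directional: bool
    temporal: bool
    direction: int  # sign of effect
    slope_sign: int  # sign of d(derived - ancestor share)/d(time)
    tested: bool = True


def load_expression(path) -> ExpressionMatrix:
    """Read an expression TSV: locus_id column + sample columns."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "locus_id":
        raise ExpressionValidationError(
            f"first column must be 'locus_id', got {df.columns[0]!r}"
        )
    dup = df["locus_id"][df["locus_id"].duplicated()]
    if len(dup):
        raise ExpressionValidationError(
            f"duplicate locus rows: {dup.unique().tolist()[:5]}"
        )
    df = df.set_index("locus_id")
    for col in df.columns:
        bad = df.index[~pd.to_numeric(df[col], errors="coerce").notna()]
        if len(bad):
            raise ExpressionValidationError(
                f"non-numeric FPKM in column {col!r}, locus {bad[0]!r}"
            )
        neg = df.index[df[col].astype(float) < 0]
        if len(neg):
            raise ExpressionValidationError(
                f"negative FPKM in column {col!r}, locus {neg[0]!r}"
            )
    return ExpressionMatrix.from_frame(df.astype(float))


def load_go_map(path) -> GOMap:
    """Read a two-column locus_id / go_term TSV (one row per membership)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["locus_id", "go_term"]:
        raise ExpressionValidationError(
            f"GO map must have columns locus_id, go_term; got {list(df.columns)}"
        )
    memberships: Dict[str, Set[str]] = {}
    for locus, term in df.itertuples(index=False):
        memberships.setdefault(locus, set()).add(term)
    return GOMap({l: frozenset(ts) for l, ts in memberships.items()})


def fold_change_loci(
    m: ExpressionMatrix,
    threshold_log2: float = 1.0,
    pseudocount: float = 0.1,
) -> Set[str]:
    """Loci whose genotypes differ more than ``2**threshold_log2``-fold in
    replicate-mean FPKM at one or more timepoints.

    The pseudocount guards the ratio against zero FPKM on either side.
    """
    cm = m.cell_means()
    anc = cm["ancestor"].to_numpy()
    der = cm["derived"].to_numpy()
    lfc = np.log2((der + pseudocount) / (anc + pseudocount))
    hit = (np.abs(lfc) > threshold_log2).any(axis=1)
    return set(m.loci[hit])


def normalize_expression(m: ExpressionMatrix) -> NormalizedMatrix:
    """Replicate-average, log(x+1)-transform, and rescale each locus so
    its six genotype x time values sum to one.

    All-zero loci get zero shares and are flagged in ``zero_loci``.
    """
    cm = m.cell_means()
    v = np.log1p(cm.to_numpy())
    totals = v.sum(axis=1)
    zero = totals == 0.0
    safe = np.where(zero, 1.0, totals)
    shares = v / safe[:, None]
    shares[zero] = 0.0
    out = pd.DataFrame(shares, index=cm.index, columns=cm.columns)
    return NormalizedMatrix(
        shares=out, zero_loci=frozenset(m.loci[zero])
    )


def _term_cell_table(
    norm: NormalizedMatrix, gomap: GOMap
) -> Tuple[pd.DataFrame, List[str]]:
    """Long cell-mean table (term, genotype, time, share); drops empty terms."""
    present = set(norm.shares.index)
    rows = []
    kept = []
    for term in gomap.terms:
        loci = [l for l in gomap.loci_of(term) if l in present]
        if not loci:
            logger.warning("GO term %r has no loci in the matrix; dropped", term)
            continue
        kept.append(term)
        cell = norm.shares.loc[loci].mean(axis=0)
        for (g, t), v in cell.items():
            rows.append({"term": term, "genotype": g, "time": t, "share": v})
    return pd.DataFrame(rows), kept


def global_fit(norm: NormalizedMatrix, gomap: GOMap) -> GlobalAnovaFit:
    """Fit the GO-grouped fixed-effects ANOVA on the cell-mean table.

    Response: mean share over the term's member loci in each of the
    G x 2 x 3 cells (loci in multiple terms contribute to each).  Model:
    GO + genotype + time + GO:genotype + GO:time, so the residual pools
    the genotype:time and GO:genotype:time strata — model df 4G-1,
    residual df 2G.
    """
    table, kept = _term_cell_table(norm, gomap)
    if len(kept) < 2:
        raise ValueError("global fit needs at least 2 GO terms with loci")
    fit = smf.ols(
        "share ~ C(term) + C(genotype) + C(time) "
        "+ C(term):C(genotype) + C(term):C(time)",
        data=table,
    ).fit()
    # a (near-)constant response makes the F ratio 0/0; report it as no
    # explainable variation rather than statsmodels' roundoff artifact
    if float(np.var(table["share"].to_numpy())) < 1e-24:
        f_stat, adj_r2 = 0.0, 0.0
    else:
        f_stat, adj_r2 = float(fit.fvalue), float(fit.rsquared_adj)
    return GlobalAnovaFit(
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        f_statistic=f_stat,
        adj_r_squared=adj_r2,
        n_terms=len(kept),
    )


def _twoway_anova(y: np.ndarray) -> Tuple[float, float, float, float]:
    """Balanced two-way fixed-effects ANOVA with loci as replicates.

    ``y`` has shape (n_loci, 2 genotypes, 3 times).  Returns
    (p_genotype, p_interaction, effect, slope) where effect is the
    derived-minus-ancestor mean share and slope is the least-squares
    slope of the per-time genotype difference against time in hours.
    Closed-form sums of squares for the balanced design (cross-checked
    against a formula-interface OLS in the test suite).
    """
    n, a, b = y.shape  # n loci, 2 genotypes, 3 timepoints
    grand = y.mean()
    m_g = y.mean(axis=(0, 2))  # per genotype
    m_t = y.mean(axis=(0, 1))  # per time
    m_gt = y.mean(axis=0)  # cell means (2, 3)
    ss_a = n * b * np.sum((m_g - grand) ** 2)
    ss_b = n * a * np.sum((m_t - grand) ** 2)
    ss_ab = n * np.sum(
        (m_gt - m_g[:, None] - m_t[None, :] + grand) ** 2
    )
    ss_e = np.sum((y - m_gt[None, :, :]) ** 2)
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (n - 1)
    if df_e <= 0 or ss_e <= 0:
        p_g = 0.0 if ss_a > 0 else 1.0
        p_i = 0.0 if ss_ab > 0 else 1.0
    else:
        mse = ss_e / df_e
        p_g = float(scipy.stats.f.sf(ss_a / df_a / mse, df_a, df_e))
        p_i = float(scipy.stats.f.sf(ss_ab / df_ab / mse, df_ab, df_e))
    effect = float(m_g[1] - m_g[0])  # derived minus ancestor
    diff = m_gt[1] - m_gt[0]  # per-time genotype difference
    times = np.asarray(TIMEPOINTS, dtype=float)
    slope = float(np.polyfit(times, diff, 1)[0])
    return p_g, p_i, effect, slope


def _group_anovas(
    norm: NormalizedMatrix, gomap: GOMap
) -> List[GOGroupStats]:
    present = set(norm.shares.index)
    out: List[GOGroupStats] = []
    for term in gomap.terms:
        loci = [l for l in gomap.loci_of(term) if l in present]
        if len(loci) < 2:
            out.append(
                GOGroupStats(
                    term=term,
                    n_loci=len(loci),
                    effect=np.nan,
                    p_genotype=np.nan,
                    q_genotype=np.nan,
                    p_interaction=np.nan,
                    q_interaction=np.nan,
                    directional=False,
                    temporal=False,
                    direction=0,
                    slope_sign=0,
                    tested=False,
                )
            )
            continue
        y = norm.locus_array(loci)
        p_g, p_i, effect, slope = _twoway_anova(y)
        out.append(
            GOGroupStats(
                term=term,
                n_loci=len(loci),
                effect=effect,
                p_genotype=p_g,
                q_genotype=np.nan,
                p_interaction=p_i,
                q_interaction=np.nan,
                directional=False,
                temporal=False,
                direction=int(np.sign(effect)),
                slope_sign=int(np.sign(slope)) if slope != 0 else 0,
                tested=True,
            )
        )
    return out


def _adjust(
    stats: List[GOGroupStats], which: str, alpha: float, correction: str
) -> None:
    tested = [s for s in stats if s.tested]
    if not tested:
        return
    ps = [getattr(s, f"p_{which}") for s in tested]
    reject, qs, _, _ = multipletests(ps, alpha=alpha, method=correction)
    flag_attr = "directional" if which == "genotype" else "temporal"
    for s, q, rej in zip(tested, qs, reject):
        setattr(s, f"q_{which}", float(q))
        setattr(s, flag_attr, bool(rej))


def directional_tests(
    norm: NormalizedMatrix,
    gomap: GOMap,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> List[GOGroupStats]:
    """Per-GO genotype main-effect tests (directional expression change).

    Each term's member-locus shares enter a locus-level two-way ANOVA
    (genotype, time, genotype x time); the genotype main-effect p-values
    are corrected across terms (Benjamini-Hochberg by default).  The
    direction is the sign of the derived-minus-ancestor mean share.
    Terms with fewer than 2 loci are reported untested.
    """
    stats = _group_anovas(norm, gomap)
    _adjust(stats, "genotype", alpha, correction)
    _adjust(stats, "interaction", alpha, correction)
    return stats


def temporal_tests(
    norm: NormalizedMatrix,
    gomap: GOMap,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> List[GOGroupStats]:
    """Per-GO genotype x time interaction tests (temporal divergence).

    Same locus-level ANOVA as :func:`directional_tests`; the interaction
    p-values are corrected across terms.  The slope sign tracks whether
    the derived-minus-ancestor share difference grows or shrinks from
    18 to 24 hours.
    """
    return directional_tests(norm, gomap, alpha, correction)


def deviation_profile(
    norm: NormalizedMatrix, gomap: GOMap
) -> pd.DataFrame:
    """Per-term genotype x time deviations from the term's grand mean share.

    For each GO term the six cell means (mean share over member loci)
    are centered on their grand mean, so deviations sum to zero within
    a term.  Long format: term, genotype, time, deviation.
    """
    present = set(norm.shares.index)
    rows = []
    for term in gomap.terms:
        loci = [l for l in gomap.loci_of(term) if l in present]
        if not loci:
            continue
        cell = norm.shares.loc[loci].mean(axis=0)
        grand = cell.mean()
        for (g, t), v in cell.items():
            rows.append(
                {
                    "term": term,
                    "genotype": g,
                    "time": t,
                    "deviation": v - grand,
                }
            )
    return pd.DataFrame(rows, columns=["term", "genotype", "time", "deviation"])


def write_group_stats(stats: List[GOGroupStats], path) -> None:
    """Per-term results CSV in the documented column order."""
    rows = [
        {
            "term": s.term,
            "n_loci": s.n_loci,
            "effect": s.effect,
            "p": s.p_genotype,
            "q": s.q_genotype,
            "direction": s.direction,
            "interaction_p": s.p_interaction,
            "interaction_q": s.q_interaction,
            "temporal_flag": s.temporal,
            "slope_sign": s.slope_sign,
        }
        for s in stats
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_deviation_profile(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, index=False)
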