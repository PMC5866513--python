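"""Empirical, expression-conditioned test for differential splicing.

The test treats between-replicate PSI variability as the null model for
between-condition changes. For every event and every unordered pair of
replicates within a condition, one background point is recorded:

* ``E_rep`` — the mean over that condition's replicates of
  log10(summed TPM of the event's transcripts), and
* ``|dPSI|`` — the absolute PSI difference between the two replicates.

For an observed between-condition change, the covariate ``E_cond`` (the
average of the two per-condition mean log10 total TPM values) locates, by
binary search in the E_rep-sorted background, a fixed-size window (1000
points by default) of expression-matched null |dPSI| values. These define
an empirical cumulative distribution function and the p-value

    p = (1 - ECDF(|dPSI|)) / 2,

the division by two reflecting the symmetry of the signed null. A floor of
1/(2n) keeps p positive at the ECDF's granularity. An optional
Benjamini-Hochberg correction is applied per gene, since events of one
gene share transcripts and are not independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation import SpliceEvent
from .psi import (
    DEFAULT_PSEUDOCOUNT,
    ExpressionMatrix,
    PsiMatrix,
    event_total_tpm,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 1000

DPSI_COLUMNS = ("gene_id", "dpsi", "e_cond", "pvalue", "adj_pvalue", "significant", "n_background")


@dataclass(frozen=True)
class BackgroundDistribution:
    """Pooled (E_rep, |dPSI|) between-replicate points, sorted by E_rep."""

    e_rep: np.ndarray
    abs_dpsi: np.ndarray
    window_size: int = DEFAULT_WINDOW_SIZE

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if len(self.e_rep) != len(self.abs_dpsi):
            raise ValueError("e_rep and abs_dpsi length mismatch")
        if np.any(np.diff(self.e_rep) < 0):
            raise ValueError("background must be sorted by E_rep")
        if len(self.abs_dpsi) and (
            np.nanmin(self.abs_dpsi) < 0 or np.nanmax(self.abs_dpsi) > 1
        ):
            raise ValueError("|dPSI| background values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.e_rep)


@dataclass(frozen=True)
class ComparisonPlan:
    """Ordered condition labels and the condition pairs to compare."""

    conditions: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        known = set(self.conditions)
        for c1, c2 in self.pairs:
            if c1 not in known or c2 not in known:
                raise ValueError(f"comparison ({c1}, {c2}) names unknown condition")

    @classmethod
    def consecutive(cls, conditions: Sequence[str]) -> "ComparisonPlan":
        conditions = tuple(conditions)
        if len(conditions) < 2:
            raise ValueError("need at least two conditions")
        pairs = tuple(zip(conditions[:-1], conditions[1:]))
        return cls(conditions=conditions, pairs=pairs)


def log_event_expression(
    events: Sequence[SpliceEvent],
    expr: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """log10(pseudocount + total event TPM), per event and sample."""
    tot = event_total_tpm(events, expr)
    return np.log10(pseudocount + tot)


def build_background(
    psi: PsiMatrix,
    expr: ExpressionMatrix,
    events: Sequence[SpliceEvent],
    conditions: Sequence[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> BackgroundDistribution:
    """Pool within-condition replicate-pair |dPSI| values over all events.

    Replicate pairs are formed within conditions only; cross-condition
    pairs would carry true signal. Events with an undefined PSI in either
    replicate of a pair contribute no point for that pair.
    """
    if conditions is None:
        conditions = expr.conditions
    logexpr = log_event_expression(events, expr, pseudocount)
    common = psi.values.index.intersection(logexpr.index)
    es, ds = [], []
    usable = False
    for cond in conditions:
        samples = expr.samples_of(cond)
        if len(samples) < 2:
            continue
        usable = True
        erep = logexpr.loc[common, samples].mean(axis=1).to_numpy()
        mat = psi.values.loc[common, samples].to_numpy()
        for i, j in combinations(range(len(samples)), 2):
            d = np.abs(mat[:, i] - mat[:, j])
            ok = ~np.isnan(d)
            es.append(erep[ok])
            ds.append(d[ok])
    if not usable:
        raise ValueError(
            "cannot estimate replicate variability: no condition has >= 2 replicates"
        )
    e = np.concatenate(es) if es else np.empty(0)
    d = np.concatenate(ds) if ds else np.empty(0)
    order = np.argsort(e, kind="stable")
    return BackgroundDistribution(
        e_rep=e[order], abs_dpsi=d[order], window_size=window_size
    )


def nearest_window(bg: BackgroundDistribution, e_cond: float) -> np.ndarray:
    """Expression-matched null |dPSI| values around ``e_cond``.

    Binary search locates the background point closest in E_rep (ties to
    the lower index); the window of ``window_size`` values centered there is
    shifted inward at the edges so its size stays constant, and clamps to
    the whole background when fewer points exist.
    """
    n = len(bg)
    if n == 0:
        raise ValueError("empty background distribution")
    w = min(bg.window_size, n)
    i = int(np.searchsorted(bg.e_rep, e_cond))
    if i == 0:
        center = 0
    elif i == n:
        center = n - 1
    else:
        center = i - 1 if e_cond - bg.e_rep[i - 1] <= bg.e_rep[i] - e_cond else i
    start = min(max(center - (w - 1) // 2, 0), n - w)
    return bg.abs_dpsi[start : start + w]


def empirical_pvalue(observed_dpsi: float, window: np.ndarray) -> float:
    """p = (1 - ECDF(|observed|)) / 2, floored at half an ECDF step.

    The ECDF is right-continuous (counts values <= the observation). The
    floor 1/(2n) prevents exact zeros, which the background's granularity
    cannot support.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty background window")
    obs = abs(float(observed_dpsi))
    if obs > 1:
        raise ValueError(f"|dPSI| cannot exceed 1, got {observed_dpsi}")
    n = window.size
    ecdf = np.count_nonzero(window <= obs) / n
    return max((1.0 - ecdf) / 2.0, 1.0 / (2 * n))


def correct_per_gene(records: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg correction applied independently within each gene.

    Returns a copy with ``adj_pvalue`` and ``significant`` (adj p < fdr)
    filled in; rows with undefined p-values keep NaN and are never flagged.
    """
    if not (0 < fdr <= 1):
        raise ValueError(f"fdr must be in (0, 1], got {fdr}")
    out = records.copy()
    out["adj_pvalue"] = np.nan
    for _, idx in out.groupby("gene_id").groups.items():
        p = out.loc[idx, "pvalue"]
        defined = p.notna()
        if defined.any():
            adj = multipletests(p[defined].to_numpy(), method="fdr_bh")[1]
            out.loc[p.index[defined], "adj_pvalue"] = adj
    out["significant"] = out["adj_pvalue"] < fdr
    return out


def diffsplice_pair(
    psi: PsiMatrix,
    expr: ExpressionMatrix,
    events: Sequence[SpliceEvent],
    condition1: str,
    condition2: str,
    window_size: int = DEFAULT_WINDOW_SIZE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fdr: float = 0.05,
    correct: bool = True,
) -> pd.DataFrame:
    """Differential splicing between two conditions.

    Per event: ``dpsi`` is mean PSI(condition2) - mean PSI(condition1) over
    the defined replicates; ``e_cond`` averages the two per-condition mean
    log10 total TPM values; the p-value comes from the expression-matched
    empirical null. Events with no defined PSI in one of the conditions are
    reported with NaN statistics and counted in the log.
    """
    for cond in (condition1, condition2):
        if len(expr.samples_of(cond)) < 1:
            raise ValueError(f"condition {cond!r} has no samples")
    bg = build_background(
        psi,
        expr,
        events,
        conditions=[condition1, condition2],
        pseudocount=pseudocount,
        window_size=window_size,
    )
    logexpr = log_event_expression(events, expr, pseudocount)
    gene_of = {ev.event_id: ev.gene_id for ev in events}
    index = psi.values.index.intersection(logexpr.index)
    s1 = expr.samples_of(condition1)
    s2 = expr.samples_of(condition2)
    m1 = psi.values.loc[index, s1].mean(axis=1)
    m2 = psi.values.loc[index, s2].mean(axis=1)
    dpsi = (m2 - m1).to_numpy()
    e_cond = (
        0.5
        * (
            logexpr.loc[index, s1].mean(axis=1) + logexpr.loc[index, s2].mean(axis=1)
        ).to_numpy()
    )
    pvals = np.full(len(index), np.nan)
    for k in range(len(index)):
        if np.isnan(dpsi[k]):
            continue
        window = nearest_window(bg, e_cond[k])
        pvals[k] = empirical_pvalue(dpsi[k], window)
    n_na = int(np.isnan(dpsi).sum())
    if n_na:
        logger.info(
            "%s vs %s: %d events excluded from testing (PSI undefined in all "
            "replicates of one condition)",
            condition1,
            condition2,
            n_na,
        )
    records = pd.DataFrame(
        {
            "gene_id": [gene_of[e] for e in index],
            "dpsi": dpsi,
            "e_cond": e_cond,
            "pvalue": pvals,
            "adj_pvalue": np.nan,
            "significant": False,
            "n_background": min(window_size, len(bg)),
        },
        index=pd.Index(index, name="event_id"),
    )
    if correct:
        records = correct_per_gene(records, fdr=fdr)
    else:
        records["adj_pvalue"] = records["pvalue"]
        records["significant"] = records["pvalue"] < fdr
    logger.info(
        "%s vs %s: %d events tested against %d background points, %d significant",
        condition1,
        condition2,
        int(records["pvalue"].notna().sum()),
        len(bg),
        int(records["significant"].sum()),
    )
    return records


def diffsplice_multi(
    psi: PsiMatrix,
    expr: ExpressionMatrix,
    events: Sequence[SpliceEvent],
    plan: ComparisonPlan | None = None,
    **kwargs,
) -> dict[tuple[str, str], pd.DataFrame]:
    """One pairwise comparison per planned condition pair.

    The default plan chains consecutive conditions in design order, the
    natural choice for time courses.
    """
    if plan is None:
        plan = ComparisonPlan.consecutive(expr.conditions)
    known = set(expr.conditions)
    for c1, c2 in plan.pairs:
        if c1 not in known or c2 not in known:
            raise ValueError(f"comparison ({c1}, {c2}) names unknown condition")
    return {
        (c1, c2): diffsplice_pair(psi, expr, events, c1, c2, **kwargs)
        for c1, c2 in plan.pairs
    }


def merge_dpsi(results: Mapping[tuple[str, str], pd.DataFrame]) -> pd.DataFrame:
    """Wide event x comparison table (dpsi/pvalue/adj_pvalue per pair)."""
    pieces = []
    for (c1, c2), df in results.items():
        tag = f"{c1}-{c2}"
        pieces.append(
            df[["dpsi", "pvalue", "adj_pvalue"]].rename(
                columns={
                    "dpsi": f"{tag}_dpsi",
                    "pvalue": f"{tag}_pvalue",
                    "adj_pvalue": f"{tag}_adj_pvalue",
                }
            )
        )
    return pd.concat(pieces, axis=1)


def write_dpsi(records: pd.DataFrame, path) -> None:
    """Per-comparison TSV: event_id, dpsi, pvalue, adj_pvalue."""
    records[["dpsi", "pvalue", "adj_pvalue"]].to_csv(
        path, sep="\t", na_rep="nan", float_format="%.10g", index_label="event_id"
    )
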