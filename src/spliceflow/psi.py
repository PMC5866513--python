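"""PSI (proportion spliced-in) quantification from transcript TPM tables.

PSI of an event in a sample is the TPM mass of its inclusion transcripts
divided by the TPM mass of all event-informative transcripts. It is
undefined (NaN) when the denominator does not exceed ``min_total_tpm``.
The event *expression* covariate used by the differential test is the mean
over samples of log10(pseudocount + total event TPM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import SpliceEvent

logger = logging.getLogger(__name__)

#: matches the conventional log10(TPM + 0.01) expression scale
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass
class ExpressionMatrix:
    """Transcript x sample TPM matrix with a condition/replicate design.

    ``design`` maps each sample id to a ``(condition, replicate)`` pair;
    condition order follows first appearance in the mapping.
    """

    values: pd.DataFrame
    design: Mapping[str, tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("negative TPM values in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate transcript ids in expression matrix")
        if self.design is not None:
            missing = set(self.values.columns) - set(self.design)
            if missing:
                raise ValueError(f"samples missing from design: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        if self.design is None:
            raise ValueError("expression matrix has no condition design")
        seen: dict[str, None] = {}
        for sample in self.values.columns:
            seen.setdefault(self.design[sample][0], None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        if self.design is None:
            raise ValueError("expression matrix has no condition design")
        return [s for s in self.values.columns if self.design[s][0] == condition]

    @classmethod
    def read_tsv(cls, path, design=None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.astype(float), design=design)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g", index_label="transcript_id")


@dataclass
class PsiMatrix:
    """Event x sample PSI matrix; NaN marks undefined values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float, copy=False)
        defined = arr[~np.isnan(arr)]
        if defined.size and ((defined < 0).any() or (defined > 1).any()):
            raise ValueError("PSI values outside [0, 1]")
        self.values.index.name = "event_id"

    @property
    def event_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def event_total_tpm(
    events: Sequence[SpliceEvent], expr: ExpressionMatrix
) -> pd.DataFrame:
    """Sum of total-transcript TPM per event and sample.

    Events with transcripts absent from the matrix are dropped with a
    warning (their rows are omitted).
    """
    known = set(expr.values.index)
    rows, index, skipped = [], [], []
    for ev in events:
        total = sorted(ev.total_transcripts)
        if not set(total) <= known:
            skipped.append(ev.event_id)
            continue
        rows.append(expr.values.loc[total].sum(axis=0))
        index.append(ev.event_id)
    if skipped:
        logger.warning(
            "%d events dropped: transcripts missing from expression matrix (e.g. %s)",
            len(skipped),
            skipped[0],
        )
    return pd.DataFrame(rows, index=index, columns=expr.values.columns)


def compute_psi(
    events: SpliceEvent | Sequence[SpliceEvent],
    expr: ExpressionMatrix,
    min_total_tpm: float = 0.0,
) -> PsiMatrix:
    """Per-sample PSI for each event: inclusion TPM / total TPM.

    PSI is NaN wherever the total event TPM is <= ``min_total_tpm``; with
    the default 0 the ratio is defined whenever the denominator is positive.
    """
    if min_total_tpm < 0:
        raise ValueError("min_total_tpm must be >= 0")
    if isinstance(events, SpliceEvent):
        events = [events]
    known = set(expr.values.index)
    rows, index = [], []
    skipped = []
    for ev in events:
        if not ev.total_transcripts <= known:
            skipped.append(ev.event_id)
            continue
        inc = expr.values.loc[sorted(ev.inclusion_transcripts)].sum(axis=0)
        tot = expr.values.loc[sorted(ev.total_transcripts)].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = inc.to_numpy() / tot.to_numpy()
        psi[tot.to_numpy() <= min_total_tpm] = np.nan
        rows.append(psi)
        index.append(ev.event_id)
    if skipped:
        logger.warning(
            "%d events skipped in PSI computation: transcripts missing (e.g. %s)",
            len(skipped),
            skipped[0],
        )
    values = pd.DataFrame(
        np.array(rows) if rows else np.empty((0, expr.values.shape[1])),
        index=index,
        columns=expr.values.columns,
    )
    return PsiMatrix(values=values)


def event_expression(
    event: SpliceEvent,
    expr: ExpressionMatrix,
    samples: Sequence[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Mean over samples of log10(pseudocount + summed total-transcript TPM)."""
    if samples is None:
        samples = expr.sample_ids
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    tot = expr.values.loc[sorted(event.total_transcripts), list(samples)].sum(axis=0)
    return float(np.mean(np.log10(pseudocount + tot.to_numpy())))


def write_psi(psi: PsiMatrix, path) -> None:
    """Serialize to TSV with the NA token ``nan``.

    Values are written with the shortest exact decimal repr, so a
    write/read cycle reproduces the matrix bit for bit.
    """
    psi.values.to_csv(path, sep="\t", na_rep="nan", index_label="event_id")


def read_psi(path) -> PsiMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            if raw == "nan" or raw == "":
                out[i, j] = math.nan
                continue
            try:
                out[i, j] = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric PSI value {raw!r} at event "
                    f"{df.index[i]!r}, sample {col!r}"
                ) from None
    return PsiMatrix(values=pd.DataFrame(out, index=df.index, columns=df.columns))
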