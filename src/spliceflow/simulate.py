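"""Synthetic two-isoform splicing datasets with known ground truth.

Each simulated gene carries exactly two transcripts that differ by a single
binary splicing event (cassette exon or alternative 5'/3' splice site), the
simplest gene class in which PSI is analytic: PSI = inclusion TPM / (sum of
both isoform TPMs). Differential splicing is planted by *exchanging* the
two isoforms' theoretical abundances between conditions; only genes whose
isoform abundances differ enough in relative terms,

    |TPM1 - TPM2| / (TPM1 + TPM2) > min_relative_change  (default 0.2),

are eligible to be positives, so every planted change is sizable. Negative
genes keep their abundances in all conditions and have, by construction,
the same total-expression distribution as the positives. Replicate-level
measurement noise is multiplicative log-normal on each transcript TPM;
sigma maps qualitatively to sequencing depth (larger sigma, shallower
library). All draws derive from one integer seed and are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .psi import ExpressionMatrix

DEFAULT_EVENT_MIX: Mapping[str, float] = {"SE": 0.5, "A5": 0.25, "A3": 0.25}


@dataclass
class SimulationConfig:
    """Study design of the synthetic dataset."""

    n_genes: int = 1000
    event_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_MIX)
    )
    n_conditions: int = 2
    replicates_per_condition: int = 3
    noise_sd: float = 0.1
    positive_fraction: float = 0.5
    min_relative_change: float = 0.2
    base_tpm_range: tuple[float, float] = (1.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if set(self.event_mix) - {"SE", "A5", "A3"}:
            raise ValueError("event_mix supports SE, A5 and A3 only")
        if not np.isclose(sum(self.event_mix.values()), 1.0):
            raise ValueError("event_mix proportions must sum to 1")
        if self.base_tpm_range[0] > self.base_tpm_range[1]:
            raise ValueError("base_tpm_range low must be <= high")
        if self.base_tpm_range[0] <= 0:
            raise ValueError("base TPM must be positive")
        if not (0 <= self.positive_fraction <= 1):
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_conditions < 2 or self.replicates_per_condition < 1:
            raise ValueError("need >= 2 conditions and >= 1 replicate each")


def relative_change(tpm1: float, tpm2: float) -> float:
    """|TPM1 - TPM2| / (TPM1 + TPM2); the planted-change size criterion."""
    total = tpm1 + tpm2
    if total <= 0:
        raise ValueError("relative change undefined: TPM1 + TPM2 must be > 0")
    return abs(tpm1 - tpm2) / total


def _type_counts(n_genes: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so counts are deterministic."""
    order = [t for t in ("SE", "A5", "A3") if t in mix]
    raw = {t: n_genes * mix[t] for t in order}
    counts = {t: int(np.floor(raw[t])) for t in order}
    short = n_genes - sum(counts.values())
    for t in sorted(order, key=lambda t: raw[t] - counts[t], reverse=True)[:short]:
        counts[t] += 1
    return counts


def make_annotation(config: SimulationConfig) -> tuple[str, pd.DataFrame]:
    """GTF text plus a per-gene ground-truth table.

    Every gene has two transcripts (``<gene>.t1`` = inclusion form,
    ``<gene>.t2`` = exclusion form) realizing exactly one event of the
    assigned type on non-overlapping loci of one chromosome. The table
    declares the event the geometry encodes (type, expected event id,
    transcript roles), which downstream enumeration must reproduce.
    """
    rng = np.random.default_rng([config.seed, 0])
    counts = _type_counts(config.n_genes, config.event_mix)
    types = [t for t in ("SE", "A5", "A3") for _ in range(counts.get(t, 0))]
    rng.shuffle(types)

    chrom = "chr1"
    cursor = 1000
    gtf_lines: list[str] = []
    rows = []
    for g, etype in enumerate(types, start=1):
        gene = f"G{g:05d}"
        strand = rng.choice(["+", "-"])
        cursor += int(rng.integers(500, 2000))
        exlen = lambda: int(rng.integers(50, 300))
        intron = lambda: int(rng.integers(200, 2000))
        s1 = cursor
        if etype == "SE":
            e1 = s1 + exlen()
            ms = e1 + intron()
            me = ms + int(rng.integers(10, 200))  # some cassettes are microexons
            s3 = me + intron()
            e3 = s3 + exlen()
            t1_exons = [(s1, e1), (ms, me), (s3, e3)]
            t2_exons = [(s1, e1), (s3, e3)]
            event_id = f"{gene};SE:{chrom}:{e1}-{ms}:{me}-{s3}:{strand}"
            cursor = e3
        else:
            # A5 on + / A3 on -: variable upstream-exon end (intron start);
            # A3 on + / A5 on -: variable downstream-exon start (intron end).
            vary_start = (etype == "A5") == (strand == "+")
            shift = int(rng.integers(30, 150))
            if vary_start:
                d1 = s1 + exlen()
                d2 = d1 + shift
                a = d2 + intron()
                e2 = a + exlen()
                t1_exons = [(s1, d2), (a, e2)]  # longer exon = inclusion form
                t2_exons = [(s1, d1), (a, e2)]
                event_id = f"{gene};{etype}:{chrom}:{d2}-{a}:{d1}-{a}:{strand}"
            else:
                d = s1 + exlen()
                a1 = d + intron()
                a2 = a1 + shift
                e2 = a2 + exlen()
                t1_exons = [(s1, d), (a1, e2)]
                t2_exons = [(s1, d), (a2, e2)]
                event_id = f"{gene};{etype}:{chrom}:{d}-{a1}:{d}-{a2}:{strand}"
            cursor = e2
        for tname, exons in ((f"{gene}.t1", t1_exons), (f"{gene}.t2", t2_exons)):
            attrs = f'gene_id "{gene}"; transcript_id "{tname}";'
            gtf_lines.append(
                f"{chrom}\tsim\ttranscript\t{exons[0][0]}\t{exons[-1][1]}\t.\t{strand}\t.\t{attrs}"
            )
            for s, e in exons:
                gtf_lines.append(
                    f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}"
                )
        rows.append(
            {
                "gene_id": gene,
                "event_type": etype,
                "event_id": event_id,
                "chrom": chrom,
                "strand": strand,
                "inclusion_transcript": f"{gene}.t1",
                "exclusion_transcript": f"{gene}.t2",
            }
        )
    genes = pd.DataFrame(rows).set_index("gene_id")
    return "\n".join(gtf_lines) + "\n", genes


def simulate_expression(
    genes: pd.DataFrame, config: SimulationConfig
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Replicate-level TPM matrix plus per-gene ground truth.

    Positives (a random ``positive_fraction`` of genes, drawn among those
    passing the relative-change filter) have their two isoform abundances
    exchanged in every condition after the first; ``planted_dpsi`` is the
    analytic PSI difference (condition 2 minus condition 1, zero for
    negatives). Each replicate observes theoretical TPM times
    LogNormal(0, noise_sd) noise, independently per transcript and sample.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = len(genes)
    lo, hi = config.base_tpm_range
    tpm = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=(n, 2))
    tpm1, tpm2 = tpm[:, 0], tpm[:, 1]
    rel = np.abs(tpm1 - tpm2) / (tpm1 + tpm2)
    eligible = np.flatnonzero(rel > config.min_relative_change)
    n_pos = int(round(config.positive_fraction * n))
    if n_pos > len(eligible):
        raise ValueError(
            f"cannot plant {n_pos} positives: only {len(eligible)} of {n} genes "
            f"exceed the relative-change threshold {config.min_relative_change} "
            f"(short by {n_pos - len(eligible)})"
        )
    is_positive = np.zeros(n, dtype=bool)
    is_positive[rng.choice(eligible, size=n_pos, replace=False)] = True

    conditions = [f"c{i}" for i in range(1, config.n_conditions + 1)]
    samples, design = [], {}
    for cond in conditions:
        for r in range(1, config.replicates_per_condition + 1):
            name = f"{cond}_r{r}"
            samples.append(name)
            design[name] = (cond, r)

    transcript_ids = []
    for gene in genes.index:
        transcript_ids.append(genes.loc[gene, "inclusion_transcript"])
        transcript_ids.append(genes.loc[gene, "exclusion_transcript"])

    values = np.empty((2 * n, len(samples)))
    for j, sample in enumerate(samples):
        swapped = (design[sample][0] != conditions[0]) & is_positive
        inc = np.where(swapped, tpm2, tpm1)
        exc = np.where(swapped, tpm1, tpm2)
        theo = np.empty(2 * n)
        theo[0::2] = inc
        theo[1::2] = exc
        noise = np.exp(rng.normal(0.0, config.noise_sd, size=2 * n))
        values[:, j] = theo * noise

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=transcript_ids, columns=samples),
        design=design,
    )
    truth = genes.copy()
    truth["tpm_inclusion"] = tpm1
    truth["tpm_exclusion"] = tpm2
    truth["relative_change"] = rel
    truth["is_positive"] = is_positive
    psi_base = tpm1 / (tpm1 + tpm2)
    truth["psi_baseline"] = psi_base
    truth["planted_dpsi"] = np.where(is_positive, (tpm2 - tpm1) / (tpm1 + tpm2), 0.0)
    return expr, truth


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: (gtf_text, genes, expression, truth)."""
    gtf_text, genes = make_annotation(config)
    expr, truth = simulate_expression(genes, config)
    return gtf_text, genes, expr, truth
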