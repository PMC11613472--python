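"""Rule-based somatic CNV calling from per-locus WES copy-number tables.

The cohort meta-analysis works on per-tumor copy-number profiles: average
ploidy is estimated per tumor after excluding highly amplified "hailstorm"
loci, each locus is expressed as a fold change (copy number / ploidy), and
fold-change thresholds partition loci into loss (<= 0.5), neutral,
amplification (>= 1.5) and high amplification (>= 4.0).  Cohort summaries
report the percentage of tumors carrying each call class per gene, and
expression prevalence counts samples expressing a gene above the RNA-seq
limit of quantitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LOSS_FC",
    "AMP_FC",
    "HIGH_AMP_FC",
    "PloidyEstimate",
    "estimate_ploidy",
    "call_cnv",
    "call_sample",
    "cohort_frequency",
    "expression_prevalence",
]

LOSS_FC = 0.5
AMP_FC = 1.5
HIGH_AMP_FC = 4.0


@dataclass(frozen=True)
class PloidyEstimate:
    sample: str
    ploidy: float
    n_loci_used: int
    n_excluded_hailstorm: int


def estimate_ploidy(
    segments: pd.DataFrame,
    sample: str,
    hailstorm_fc: float = HIGH_AMP_FC,
    weight_by_length: bool = False,
) -> PloidyEstimate:
    """Average ploidy of one tumor with hailstorm loci excluded.

    Two passes: a provisional ploidy is the mean copy number over all of
    the sample's loci; loci whose copy number is >= ``hailstorm_fc`` times
    the provisional value (default: the 4.0 high-amplification bound) are
    treated as hailstorm events and excluded; the final ploidy is the mean
    over the remainder.  With ``weight_by_length`` and ``start``/``end``
    columns present, means are segment-length weighted instead of
    per-locus.

    Raises ``ValueError`` if the sample has no loci or the exclusion
    removes every locus (degenerate profile).
    """
    sub = segments.loc[segments["sample"] == sample]
    if sub.empty:
        raise ValueError(f"sample {sample!r} has no loci")
    cn = sub["copy_number"].to_numpy(dtype=float)
    if (cn < 0).any():
        raise ValueError("copy numbers must be >= 0")
    if weight_by_length:
        if not {"start", "end"}.issubset(sub.columns):
            raise ValueError("weight_by_length requires start/end columns")
        w = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        if (w <= 0).any():
            raise ValueError("segment lengths must be positive")
    else:
        w = np.ones_like(cn)
    provisional = np.average(cn, weights=w)
    if provisional <= 0:
        raise ValueError(f"sample {sample!r} has zero provisional ploidy")
    keep = cn / provisional < hailstorm_fc
    if not keep.any():
        raise ValueError(
            f"sample {sample!r}: all loci excluded as hailstorm; "
            "degenerate profile"
        )
    ploidy = float(np.average(cn[keep], weights=w[keep]))
    return PloidyEstimate(
        sample=sample,
        ploidy=ploidy,
        n_loci_used=int(keep.sum()),
        n_excluded_hailstorm=int((~keep).sum()),
    )


def call_cnv(copy_number: float, ploidy: float):
    """Classify one locus by fold change against the sample ploidy.

    Returns ``(fold_change, call)`` with call in
    ``{loss, neutral, amplification, high_amplification}``:
    loss when fold change <= 0.5, high_amplification when >= 4.0,
    amplification when >= 1.5 (< 4.0), neutral otherwise.  Boundary
    values are inclusive exactly as stated.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be > 0")
    if copy_number < 0:
        raise ValueError("copy_number must be >= 0")
    fc = copy_number / ploidy
    if fc <= LOSS_FC:
        call = "loss"
    elif fc >= HIGH_AMP_FC:
        call = "high_amplification"
    elif fc >= AMP_FC:
        call = "amplification"
    else:
        call = "neutral"
    return fc, call


def call_sample(
    segments: pd.DataFrame, sample: str, hailstorm_fc: float = HIGH_AMP_FC
) -> pd.DataFrame:
    """Ploidy-normalize and call every locus of one sample.

    Returns a table with columns ``sample, locus, fold_change, call``.
    """
    est = estimate_ploidy(segments, sample, hailstorm_fc=hailstorm_fc)
    sub = segments.loc[segments["sample"] == sample]
    fc = sub["copy_number"].to_numpy(dtype=float) / est.ploidy
    call = np.select(
        [fc <= LOSS_FC, fc >= HIGH_AMP_FC, fc >= AMP_FC],
        ["loss", "high_amplification", "amplification"],
        default="neutral",
    )
    return pd.DataFrame(
        {
            "sample": sample,
            "locus": sub["locus"].to_numpy(),
            "fold_change": fc,
            "call": call,
        }
    )


def cohort_frequency(calls: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Percentage of tumors bearing each call class, per gene.

    ``calls`` is a concatenation of :func:`call_sample` outputs.  For each
    gene the denominator is the number of samples assayed at that gene.
    A high amplification (fold change >= 4.0) also counts toward
    amplification, since >= 1.5 subsumes >= 4.0.  Genes absent from every
    sample are omitted with a warning.
    """
    if calls.empty:
        raise ValueError("empty call set")
    if genes is None:
        genes = sorted(calls["locus"].unique())
    rows = []
    for gene in genes:
        sub = calls.loc[calls["locus"] == gene]
        n = sub["sample"].nunique()
        if n == 0:
            warnings.warn(f"gene {gene!r} absent from all samples; omitted")
            continue
        n_loss = sub.loc[sub["call"] == "loss", "sample"].nunique()
        n_high = sub.loc[sub["call"] == "high_amplification", "sample"].nunique()
        n_amp = sub.loc[
            sub["call"].isin(["amplification", "high_amplification"]), "sample"
        ].nunique()
        rows.append(
            (gene, n, 100.0 * n_loss / n, 100.0 * n_amp / n, 100.0 * n_high / n)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_samples",
            "pct_loss",
            "pct_amplification",
            "pct_high_amplification",
        ],
    )


def expression_prevalence(
    expr: pd.DataFrame, genes, loq: float, cohorts: pd.Series | None = None
):
    """Fraction of samples expressing each gene above the limit of
    quantitation, plus the union over a gene list.

    ``expr`` is a genes x samples matrix; a sample "expresses" a gene iff
    its value is strictly above ``loq``.  ``cohorts`` optionally maps
    sample -> cohort label (e.g. AM/CM); counts are then reported per
    cohort.  Returns ``(per_gene, union)`` where ``per_gene`` has columns
    ``cohort, gene, n_expressing, n_samples, pct`` (genes missing from the
    matrix get ``n_expressing = NaN``, flagged not-evaluable) and
    ``union`` has per-cohort rows with the union count of samples
    expressing >= 1 listed gene and an overlap breakdown
    (``n_multi`` = samples expressing more than one).
    """
    if loq < 0:
        raise ValueError("loq must be >= 0")
    if cohorts is None:
        cohorts = pd.Series("all", index=expr.columns)
    cohorts = cohorts.reindex(expr.columns)
    per_gene_rows = []
    union_rows = []
    for cohort in pd.unique(cohorts.dropna()):
        samples = cohorts.index[cohorts == cohort]
        n = len(samples)
        expressed = {}
        for gene in genes:
            if gene not in expr.index:
                per_gene_rows.append((cohort, gene, np.nan, n, np.nan))
                continue
            mask = expr.loc[gene, samples] > loq
            expressed[gene] = set(samples[mask.to_numpy(dtype=bool)])
            per_gene_rows.append(
                (cohort, gene, len(expressed[gene]), n,
                 100.0 * len(expressed[gene]) / n if n else np.nan)
            )
        union = set().union(*expressed.values()) if expressed else set()
        counts = pd.Series(
            [sum(s in v for v in expressed.values()) for s in union],
            dtype=int,
        )
        n_multi = int((counts > 1).sum()) if len(union) else 0
        union_rows.append(
            (cohort, len(union), n, 100.0 * len(union) / n if n else np.nan,
             n_multi)
        )
    per_gene = pd.DataFrame(
        per_gene_rows, columns=["cohort", "gene", "n_expressing", "n_samples", "pct"]
    )
    union_df = pd.DataFrame(
        union_rows, columns=["cohort", "n_union", "n_samples", "pct_union", "n_multi"]
    )
    return per_gene, union_df
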