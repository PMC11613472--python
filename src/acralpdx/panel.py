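"""Targeted amplicon-panel analysis: variant filtering, zygosity, and
primer-level gene CNV calling.

The panel reports per-primer depth tracks and candidate SNVs per gene.
Variants pass a five-gate filter (caller allele frequency > 0.027,
alternative observations >= 5, unique alternative observations >= 3,
depth >= 250, VAF >= 10%); zygosity is read off the VAF (>= 75%
homozygous, 33-75% heterozygous, < 33% low-VAF).  Gene-level copy number
is called from the ordered linear fold-change track: per-primer classes
are deletion (< 0.1), loss (0.1-0.6, closed interval) and amplification
(> 1.75); a full-gene call needs a strict majority of primers in one
class with every remaining primer approximating that class's boundary,
a focal call needs a stretch of >= 6 consecutive primers, and an
amplification is flagged highly amplified when it exceeds 8 copies
(fold change x assumed ploidy) on at least 3 primers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FILTER_GATES",
    "PanelThresholds",
    "GeneCNVCall",
    "NotEvaluable",
    "filter_variants",
    "classify_zygosity",
    "primer_classes",
    "call_gene_cnv",
    "normalize_to_controls",
]


class NotEvaluable(ValueError):
    """Input fails a precondition (too few primers, missing fields)."""


# gate name -> (column, predicate). Gates are conjunctive, hence
# order-independent for the passing set; order fixes only which gate is
# named first in the rejection log.
FILTER_GATES = (
    ("allele_frequency", lambda v: v > 0.027),
    ("alt_obs", lambda v: v >= 5),
    ("unique_alt_obs", lambda v: v >= 3),
    ("depth", lambda v: v >= 250),
    ("vaf", lambda v: v >= 0.10),
)


def filter_variants(records: pd.DataFrame):
    """Apply the five-gate SNV filter.

    ``records`` needs columns ``allele_frequency, alt_obs,
    unique_alt_obs, depth, vaf`` (extra columns pass through).  Returns
    ``(passing, log)`` where ``log`` has one row per non-passing record
    with the first failing gate, or ``not_evaluable`` with the missing
    field named.
    """
    required = [g[0] for g in FILTER_GATES]
    passing_idx, log_rows = [], []
    for idx, row in records.iterrows():
        missing = [c for c in required if c not in row or pd.isna(row[c])]
        if missing:
            log_rows.append((idx, "not_evaluable", f"missing field {missing[0]}"))
            continue
        failed = next(
            (name for name, pred in FILTER_GATES if not pred(row[name])), None
        )
        if failed is None:
            passing_idx.append(idx)
        else:
            log_rows.append((idx, "rejected", failed))
    log = pd.DataFrame(log_rows, columns=["index", "status", "gate"])
    return records.loc[passing_idx], log


def classify_zygosity(vaf: float) -> str:
    """Zygosity class from VAF: >= 0.75 homozygous, 0.33-0.75
    heterozygous, < 0.33 low_vaf."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    if vaf >= 0.75:
        return "homozygous"
    if vaf >= 0.33:
        return "heterozygous"
    return "low_vaf"


@dataclass(frozen=True)
class PanelThresholds:
    """Primer-level CNV calling thresholds (linear fold change).

    ``approx_band`` widens each class boundary multiplicatively for the
    full-gene rule: a remaining primer "approximates" the boundary when it
    lies within a factor of (1 + approx_band) of it.  ``min_stretch`` is
    the consecutive-primer requirement for focal calls; ``high_amp_copies``
    and ``high_amp_primers`` define the highly-amplified flag.
    """

    deletion_fc: float = 0.1
    loss_lo: float = 0.1
    loss_hi: float = 0.6
    amp_fc: float = 1.75
    min_stretch: int = 6
    approx_band: float = 0.25
    high_amp_copies: float = 8.0
    high_amp_primers: int = 3
    min_primers: int = 6


@dataclass(frozen=True)
class GeneCNVCall:
    sample: str
    gene: str
    call: str  # deletion | loss | amplification | none
    extent: str | None = None  # full | focal; None iff call == none
    high_amplification: bool = False
    supporting_primers: tuple = ()

    def __post_init__(self):
        if self.high_amplification and self.call != "amplification":
            raise ValueError("high_amplification requires an amplification call")
        if (self.extent is None) != (self.call == "none"):
            raise ValueError("extent defined exactly when call != none")


def primer_classes(fc: np.ndarray, thr: PanelThresholds) -> np.ndarray:
    """Per-primer class from linear fold change."""
    fc = np.asarray(fc, dtype=float)
    return np.select(
        [fc < thr.deletion_fc, (fc >= thr.loss_lo) & (fc <= thr.loss_hi),
         fc > thr.amp_fc],
        ["deletion", "loss", "amplification"],
        default="neutral",
    )


def _approximates(fc: float, cls: str, thr: PanelThresholds) -> bool:
    """Is fc within the relaxation band of the class boundary?"""
    band = 1.0 + thr.approx_band
    if cls == "deletion":
        return fc <= thr.deletion_fc * band
    if cls == "loss":
        return thr.loss_lo / band <= fc <= thr.loss_hi * band
    if cls == "amplification":
        return fc >= thr.amp_fc / band
    raise ValueError(cls)


def _longest_run(mask: np.ndarray):
    """(start, length) of the longest run of True; (0, 0) if none."""
    best_start = best_len = 0
    start = None
    for i, m in enumerate(np.append(mask, False)):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    return best_start, best_len


def call_gene_cnv(
    track: pd.DataFrame,
    assumed_ploidy: float = 2.0,
    thresholds: PanelThresholds | None = None,
) -> GeneCNVCall:
    """Call gene-level CNV from one gene's ordered primer track.

    ``track`` has columns ``sample, gene, position, fold_change`` with
    strictly increasing positions (linear fold change; convert log2
    inputs with ``2**x`` on read).  Decision order:

    1. full-gene call if a strict majority (> 50%) of primers share one
       non-neutral class and every remaining primer approximates that
       class's boundary;
    2. else focal call if >= ``min_stretch`` consecutive primers share a
       non-neutral class (the longest qualifying stretch wins; ties break
       toward deletion < loss < amplification severity order);
    3. else no call.

    Amplification calls are flagged ``high_amplification`` when
    ``fold_change * assumed_ploidy > high_amp_copies`` on at least
    ``high_amp_primers`` primers inside the supporting set.
    """
    thr = thresholds or PanelThresholds()
    pos = track["position"].to_numpy()
    if np.any(np.diff(pos) <= 0):
        raise ValueError("primer positions must be strictly increasing")
    n = len(track)
    if n < thr.min_primers:
        raise NotEvaluable(
            f"{n} primers < {thr.min_primers}; gene not evaluable"
        )
    fc = track["fold_change"].to_numpy(dtype=float)
    if (fc < 0).any():
        raise ValueError("fold changes must be >= 0")
    sample = track["sample"].iloc[0]
    gene = track["gene"].iloc[0]
    classes = primer_classes(fc, thr)

    def _high_amp(support: np.ndarray) -> bool:
        copies = fc[support] * assumed_ploidy
        return int((copies > thr.high_amp_copies).sum()) >= thr.high_amp_primers

    # full-gene rule
    for cls in ("deletion", "loss", "amplification"):
        member = classes == cls
        if member.sum() * 2 > n and all(
            _approximates(f, cls, thr) for f in fc[~member]
        ):
            support = np.arange(n)
            return GeneCNVCall(
                sample, gene, cls, "full",
                high_amplification=(cls == "amplification" and _high_amp(member)),
                supporting_primers=tuple(support),
            )
    # focal rule: longest stretch >= min_stretch of one class
    best = None
    for cls in ("deletion", "loss", "amplification"):
        start, length = _longest_run(classes == cls)
        if length >= thr.min_stretch and (best is None or length > best[2]):
            best = (cls, start, length)
    if best is not None:
        cls, start, length = best
        support = np.arange(start, start + length)
        return GeneCNVCall(
            sample, gene, cls, "focal",
            high_amplification=(cls == "amplification" and _high_amp(support)),
            supporting_primers=tuple(support),
        )
    return GeneCNVCall(sample, gene, "none")


def normalize_to_controls(
    sample_depth: pd.DataFrame, control_depths: pd.DataFrame
) -> pd.DataFrame:
    """Per-primer linear fold change of a sample against a control panel.

    ``sample_depth`` has columns ``sample, gene, position, depth``;
    ``control_depths`` has one column per control sample indexed by
    ``(gene, position)``.  Each sample's depths are first normalized by
    that sample's median depth, then divided by the median of the
    controls' own median-normalized depths at the same primer.  Primers
    missing from the controls, or with zero control median, are dropped
    with a warning.  Requires >= 2 controls.
    """
    import warnings

    if control_depths.shape[1] < 2:
        raise ValueError("need >= 2 control samples")
    idx = pd.MultiIndex.from_frame(sample_depth[["gene", "position"]])
    missing = ~np.asarray(idx.isin(control_depths.index))
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} primers absent from controls; dropped"
        )
    kept = sample_depth.loc[~missing].copy()
    kidx = pd.MultiIndex.from_frame(kept[["gene", "position"]])
    ctrl = control_depths.loc[kidx]
    ctrl_norm = ctrl / ctrl.median(axis=0)
    ref = ctrl_norm.median(axis=1).to_numpy()
    zero = ref <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} primers with zero control depth; dropped")
        kept = kept.loc[~zero]
        ref = ref[~zero]
    depth = kept["depth"].to_numpy(dtype=float)
    fold = (depth / np.median(depth)) / ref
    out = kept[["sample", "gene", "position"]].copy()
    out["fold_change"] = fold
    return out.reset_index(drop=True)
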