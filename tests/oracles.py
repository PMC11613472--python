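"""Independent brute-force oracles used to check the fast implementations.

These evaluate the published rules literally — enumerating every window,
re-deriving every mean — and deliberately share no code with the package
paths they validate.
"""

import numpy as np


def brute_primer_class(fc, thr):
    """Literal per-primer class from the printed linear thresholds."""
    if fc < thr.deletion_fc:
        return "deletion"
    if thr.loss_lo <= fc <= thr.loss_hi:
        return "loss"
    if fc > thr.amp_fc:
        return "amplification"
    return "neutral"


def brute_approximates(fc, cls, thr):
    band = 1.0 + thr.approx_band
    if cls == "deletion":
        return fc <= thr.deletion_fc * band
    if cls == "loss":
        return thr.loss_lo / band <= fc <= thr.loss_hi * band
    return fc >= thr.amp_fc / band


def brute_call_gene_cnv(fold_changes, thr, assumed_ploidy=2.0):
    """Exhaustive rule evaluation: returns (call, extent, high_amp).

    Full-gene: a class held by a strict majority of primers while every
    other primer approximates that class's boundary.  Focal: enumerate
    ALL windows, keep those where every primer in the window shares one
    non-neutral class and the window length is >= min_stretch; the
    longest window wins, ties broken in class order deletion, loss,
    amplification.  High amplification: > high_amp_copies observed
    copies on >= high_amp_primers primers of the supporting set.
    """
    fc = list(map(float, fold_changes))
    n = len(fc)
    classes = [brute_primer_class(f, thr) for f in fc]

    def high_amp(idx):
        return sum(
            fc[i] * assumed_ploidy > thr.high_amp_copies for i in idx
        ) >= thr.high_amp_primers

    for cls in ("deletion", "loss", "amplification"):
        members = [i for i in range(n) if classes[i] == cls]
        rest = [i for i in range(n) if classes[i] != cls]
        if len(members) * 2 > n and all(
            brute_approximates(fc[i], cls, thr) for i in rest
        ):
            ha = cls == "amplification" and high_amp(members)
            return cls, "full", ha
    best = None  # (length, class_rank, start)
    for rank, cls in enumerate(("deletion", "loss", "amplification")):
        for start in range(n):
            for stop in range(start + thr.min_stretch, n + 1):
                window = range(start, stop)
                if all(classes[i] == cls for i in window):
                    length = stop - start
                    if best is None or length > best[0]:
                        best = (length, rank, start, cls)
    if best is not None:
        length, _, start, cls = best
        idx = range(start, start + length)
        ha = cls == "amplification" and high_amp(idx)
        return cls, "focal", ha
    return "none", None, False


def brute_ploidy(copy_numbers, hailstorm_fc=4.0):
    """Two-pass mean with literal hailstorm exclusion."""
    cn = list(map(float, copy_numbers))
    provisional = sum(cn) / len(cn)
    kept = [c for c in cn if c / provisional < hailstorm_fc]
    return sum(kept) / len(kept), len(cn) - len(kept)


def brute_ols_slope(x, y):
    """Closed-form OLS slope, no library calls."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    return float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
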