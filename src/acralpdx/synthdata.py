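"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one of the study's measurement modalities:

* per-locus copy-number profiles with optional "hailstorm" loci (complex
  amplification events reaching 10-100x the background ploidy),
* ordered per-primer fold-change tracks from a targeted amplicon panel,
* caliper-measured exponential tumor-growth cohorts with treatment arms,
* single-cell dry-mass trajectories under a dose-dependent growth rate,
* synthetic quantitative-phase images of cells with known integrated
  optical path length (hence known dry mass).

Noise models: Gaussian on copy number, Gaussian on log2 primer fold change,
multiplicative log-normal on volumes and masses.  Every generator takes an
explicit seed and returns machine-readable ground truth (``truth_``-prefixed
columns) next to the data; with the noise parameter at zero the outputs
reproduce their closed forms exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimCNProfileSpec",
    "SimGrowthCohortSpec",
    "SimQPISpec",
    "gen_cn_profile",
    "gen_primer_track",
    "gen_tumor_cohort",
    "gen_cell_mass_tracks",
    "gen_phase_image",
]

CN_EVENT_LABELS = ("loss", "amp", "high_amp", "hailstorm")

# Pinned caliper decomposition: a = CALIPER_ASPECT * b so that V = 0.5*a*b^2
# has a unique (a, b) for every volume.
CALIPER_ASPECT = 1.5


@dataclass(frozen=True)
class SimCNProfileSpec:
    """Per-locus copy-number profile: flat background ploidy plus events.

    ``events`` is a list of ``(start, stop, copy_number, label)`` with
    half-open locus ranges ``[start, stop)``; labels are one of
    ``loss``, ``amp``, ``high_amp``, ``hailstorm``.  Hailstorm events must
    be at least 10x the base ploidy, matching the magnitude of the complex
    amplification events they emulate.
    """

    n_loci: int
    base_ploidy: float = 2.0
    events: tuple = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.base_ploidy <= 0:
            raise ValueError("base_ploidy must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        occupied = np.zeros(self.n_loci, dtype=bool)
        for start, stop, cn, label in self.events:
            if label not in CN_EVENT_LABELS:
                raise ValueError(f"unknown event label {label!r}")
            if not (0 <= start < stop <= self.n_loci):
                raise ValueError(
                    f"event range [{start}, {stop}) outside [0, {self.n_loci})"
                )
            if occupied[start:stop].any():
                raise ValueError(f"event ranges overlap at [{start}, {stop})")
            occupied[start:stop] = True
            if label == "hailstorm" and cn < 10 * self.base_ploidy:
                raise ValueError(
                    "hailstorm events must have copy number >= 10x base ploidy"
                )


def gen_cn_profile(spec: SimCNProfileSpec, sample: str = "S1"):
    """Simulate one sample's per-locus copy numbers.

    Returns ``(segments, truth)``: a copy-number table with columns
    ``sample, locus, copy_number`` and a truth table with
    ``locus, truth_copy_number, truth_label`` (label ``neutral`` outside
    events).  Observed copy number is truth plus Gaussian noise, clipped
    at zero.
    """
    rng = np.random.default_rng(spec.seed)
    truth_cn = np.full(spec.n_loci, float(spec.base_ploidy))
    truth_label = np.full(spec.n_loci, "neutral", dtype=object)
    for start, stop, cn, label in spec.events:
        truth_cn[start:stop] = cn
        truth_label[start:stop] = label
    observed = truth_cn + rng.normal(0.0, spec.noise_sd, size=spec.n_loci)
    observed = np.clip(observed, 0.0, None)
    loci = [f"locus_{i:04d}" for i in range(spec.n_loci)]
    segments = pd.DataFrame(
        {"sample": sample, "locus": loci, "copy_number": observed}
    )
    truth = pd.DataFrame(
        {"locus": loci, "truth_copy_number": truth_cn, "truth_label": truth_label}
    )
    return segments, truth


# Whole-gene event fold changes used by gen_primer_track; deletion/loss/amp
# values sit safely inside the panel caller's thresholds (0.1 / 0.1-0.6 / >1.75).
_PRIMER_EVENT_FC = {"deletion": 0.05, "loss": 0.3, "amp": 3.0}


def gen_primer_track(
    gene: str,
    n_primers: int,
    event: str = "none",
    focal: tuple | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample: str = "S1",
):
    """Simulate an ordered per-primer linear fold-change track for one gene.

    ``event`` is one of ``none``, ``deletion``, ``loss``, ``amp``, or
    ``focal``; for ``focal`` pass ``focal=(start, length, fold_change)``.
    Noise is Gaussian in log2 fold-change space (``noise_sd`` log2 units).

    Returns ``(track, truth)`` where ``track`` has columns
    ``sample, gene, position, fold_change`` and ``truth`` records the event
    label, range, and fold change.
    """
    if n_primers < 1:
        raise ValueError("n_primers must be >= 1")
    if event not in ("none", "deletion", "loss", "amp", "focal"):
        raise ValueError(f"unknown event {event!r}")
    fc = np.ones(n_primers)
    truth = {"truth_gene": gene, "truth_event": event, "truth_fc": 1.0,
             "truth_start": 0, "truth_len": n_primers}
    if event == "focal":
        if focal is None:
            raise ValueError("focal event requires focal=(start, length, fc)")
        start, length, event_fc = focal
        if length > n_primers or start < 0 or start + length > n_primers:
            raise ValueError("focal range must lie within the primer set")
        fc[start:start + length] = event_fc
        truth.update(truth_fc=float(event_fc), truth_start=int(start),
                     truth_len=int(length))
    elif event != "none":
        event_fc = _PRIMER_EVENT_FC[event]
        fc[:] = event_fc
        truth.update(truth_fc=event_fc)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        fc = 2.0 ** (np.log2(fc) + rng.normal(0.0, noise_sd, size=n_primers))
    positions = 1000 + 100 * np.arange(n_primers)
    track = pd.DataFrame(
        {"sample": sample, "gene": gene, "position": positions, "fold_change": fc}
    )
    return track, pd.Series(truth)


@dataclass(frozen=True)
class SimGrowthCohortSpec:
    """Caliper-measured PDX cohort: exponential growth per arm.

    Volumes follow ``V(t) = 10^(log10 v0_mean + slope * t)`` times
    multiplicative log-normal noise with coefficient of variation
    ``measurement_cv``; slopes are per-arm in log10(mm^3)/day.
    """

    n_animals_per_arm: int
    v0_mean: float  # mm^3
    slopes: dict = field(default_factory=dict)  # arm -> log10(mm^3)/day
    measurement_cv: float = 0.0
    days: tuple = (0, 3, 7, 10, 14, 17, 21)
    seed: int = 0

    def __post_init__(self):
        if self.n_animals_per_arm < 1:
            raise ValueError("n_animals_per_arm must be >= 1")
        if self.v0_mean <= 0:
            raise ValueError("v0_mean must be positive")
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be >= 0")
        if not self.slopes:
            raise ValueError("at least one arm with a true slope is required")
        d = list(self.days)
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("days must be strictly increasing")


def caliper_decompose(volume):
    """Split a volume into caliper diameters (a, b) with a = 1.5 b.

    Any (a, b) with ``V = 0.5 a b^2`` would do; the 1.5 aspect ratio is
    pinned so the decomposition is unique and reproducible.
    """
    volume = np.asarray(volume, dtype=float)
    b = (volume / (0.5 * CALIPER_ASPECT)) ** (1.0 / 3.0)
    return CALIPER_ASPECT * b, b


def gen_tumor_cohort(spec: SimGrowthCohortSpec):
    """Simulate caliper logs for a multi-arm PDX cohort.

    Returns ``(measurements, truth)``: a long table with columns
    ``model, animal, arm, day, a_mm, b_mm`` and a per-arm truth table with
    ``arm, truth_log10_slope``.  Always ``a_mm >= b_mm``.
    """
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.days, dtype=float)
    # cv of a log-normal: sigma in ln-space from cv
    sigma = np.sqrt(np.log1p(spec.measurement_cv**2))
    rows = []
    for arm, slope in spec.slopes.items():
        for i in range(spec.n_animals_per_arm):
            ideal = 10.0 ** (np.log10(spec.v0_mean) + slope * days)
            if sigma > 0:
                noise = rng.lognormal(-0.5 * sigma**2, sigma, size=days.size)
            else:
                noise = 1.0
            a, b = caliper_decompose(ideal * noise)
            for d, ai, bi in zip(days, a, b):
                rows.append(("SIM", f"{arm}_{i:02d}", arm, d, ai, bi))
    measurements = pd.DataFrame(
        rows, columns=["model", "animal", "arm", "day", "a_mm", "b_mm"]
    )
    truth = pd.DataFrame(
        {"arm": list(spec.slopes), "truth_log10_slope": list(spec.slopes.values())}
    )
    return measurements, truth


@dataclass(frozen=True)
class SimQPISpec:
    """Single-cell dry-mass trajectories under a dose-dependent growth rate.

    Per-cell specific growth rates at dose ``c`` are drawn around a mean
    ``k(c) = sgr_mean * log2(1 + GR_truth(c))`` where the truth GR curve is
    the three-parameter logistic
    ``GR_truth(c) = gr_inf + (1 - gr_inf) / (1 + (c / true_gr50)^hill)``.
    Under the growth-rate-inhibition metric ``GR = 2^(k/k_ctrl) - 1`` the
    population mean therefore traces the logistic exactly.  ``gr_inf`` is
    the high-dose GR plateau (negative = cytotoxic).
    """

    n_cells: int
    sgr_mean: float = 0.02  # h^-1, untreated
    sgr_sd: float = 0.005  # h^-1 between-cell spread
    doses: tuple = (0.0, 0.0064, 0.064, 0.32, 1.6, 8.0, 40.0)  # uM
    true_gr50: float = 1.0  # uM
    hill: float = 1.0
    gr_inf: float = -0.5
    frame_interval: float = 0.5  # h
    n_frames: int = 20
    mass_noise_cv: float = 0.0
    m0_pg: float = 250.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if any(c < 0 for c in self.doses):
            raise ValueError("doses must be >= 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if not -1.0 <= self.gr_inf <= 1.0:
            raise ValueError("gr_inf must lie in [-1, 1]")
        if self.mass_noise_cv < 0:
            raise ValueError("mass_noise_cv must be >= 0")


def truth_gr_curve(spec: SimQPISpec, doses=None):
    """Ground-truth GR value at each dose under the spec's logistic."""
    c = np.asarray(spec.doses if doses is None else doses, dtype=float)
    return spec.gr_inf + (1.0 - spec.gr_inf) / (
        1.0 + (c / spec.true_gr50) ** spec.hill
    )


def gen_cell_mass_tracks(spec: SimQPISpec, culture: str = "C1", drug: str = "drug"):
    """Simulate per-cell mass tracks for every dose in the spec.

    Returns ``(tracks, truth)``: a long table with columns
    ``culture, drug, dose_uM, cell, time_h, mass_pg`` and a truth table with
    ``dose_uM, truth_mean_sgr, truth_gr``.  Masses are
    ``m0 * exp(k_i t)`` with per-frame multiplicative log-normal noise.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.frame_interval * np.arange(spec.n_frames)
    gr = truth_gr_curve(spec)
    k_mean = spec.sgr_mean * np.log2(1.0 + gr)
    sigma = np.sqrt(np.log1p(spec.mass_noise_cv**2))
    frames = []
    for dose, k_c in zip(spec.doses, k_mean):
        k = rng.normal(k_c, spec.sgr_sd, size=spec.n_cells)
        mass = spec.m0_pg * np.exp(np.outer(k, t))  # cells x frames
        if sigma > 0:
            mass = mass * rng.lognormal(
                -0.5 * sigma**2, sigma, size=mass.shape
            )
        n_c, n_t = mass.shape
        frames.append(
            pd.DataFrame(
                {
                    "culture": culture,
                    "drug": drug,
                    "dose_uM": dose,
                    "cell": np.repeat(
                        [f"{dose:g}_{i:04d}" for i in range(n_c)], n_t
                    ),
                    "time_h": np.tile(t, n_c),
                    "mass_pg": mass.ravel(),
                }
            )
        )
    tracks = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {"dose_uM": spec.doses, "truth_mean_sgr": k_mean, "truth_gr": gr}
    )
    return tracks, truth


def gen_phase_image(cells, shape=(256, 256), allow_overlap=False):
    """Render a synthetic phase map of smooth cell-shaped blobs.

    ``cells`` is a list of ``((row, col), radius_px, total_opl)`` where
    ``total_opl`` is the blob's integrated optical path length in
    OPL-units x pixel (the per-pixel sum of the image over the blob equals
    it exactly).  Blobs use a raised-cosine profile; background is zero.

    Overlapping blobs are rejected unless ``allow_overlap=True`` (used to
    exercise watershed splitting of touching cells).  Returns
    ``(image, truth)`` with truth columns
    ``cell, row, col, radius_px, truth_opl``.
    """
    image = np.zeros(shape, dtype=np.float64)
    occupancy = np.zeros(shape, dtype=np.int32)
    rows = []
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, ((r0, c0), radius, opl) in enumerate(cells):
        if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
            raise ValueError(f"cell {i} center {(r0, c0)} outside image")
        dist = np.hypot(yy - r0, xx - c0)
        profile = np.where(
            dist < radius, np.cos(0.5 * np.pi * dist / radius) ** 2, 0.0
        )
        total = profile.sum()
        if total == 0:
            raise ValueError(f"cell {i} has empty footprint (radius {radius})")
        image += opl * profile / total
        occupancy += profile > 0
        rows.append((f"cell_{i:03d}", r0, c0, radius, opl))
    if not allow_overlap and (occupancy > 1).any():
        raise ValueError("blobs overlap; pass allow_overlap=True if intended")
    truth = pd.DataFrame(
        rows, columns=["cell", "row", "col", "radius_px", "truth_opl"]
    )
    return image.astype(np.float32), truth


def spec_to_dict(spec) -> dict:
    """Serializable view of any generator spec (for run manifests)."""
    return dataclasses.asdict(spec)
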