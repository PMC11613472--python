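"""Quantitative-phase-imaging growth kinetics and GR dose response.

A phase image maps optical path length (OPL), which is proportional to
cellular dry mass through the refractive increment alpha (default
1.8e-4 m^3/kg): ``mass = (1/alpha) * sum(OPL * pixel_area)``.  Cells are
segmented with a Sobel edge map, morphological cleanup and a
distance-transform-seeded watershed.  Per-cell specific growth rate
(SGR, h^-1) is the OLS slope of ln(mass) vs time; whole-image growth
velocity is the linear-regression slope of frame-total mass normalized
to frame 0.  Drug response uses the growth-rate-inhibition convention

    GR(c) = 2^(k(c) / k_ctrl) - 1

so GR = 1 means unaffected growth, 0 cytostasis, negative cytotoxicity.
GR50 (the concentration where GR = 0.5) comes from a bounded
three-parameter logistic fit and is reported as non-estimable when the
fitted curve never reaches 0.5 inside the tested dose range — the
situation for drugs that leave the cells growing, and for cultures whose
control arm is not growing at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage import filters, measure, morphology, segmentation

__all__ = [
    "ALPHA_M3_PER_KG",
    "QPIConfig",
    "DoseResponseFit",
    "segment_cells",
    "mass_from_phase",
    "image_masses",
    "specific_growth_rate",
    "sgr_population",
    "normalized_mass_velocity",
    "gr_metric",
    "fit_gr50",
    "response_descriptors",
]

ALPHA_M3_PER_KG = 1.8e-4
# 1 m^3/kg = 1e18 um^3 / 1e15 pg = 1e3 um^3/pg
_ALPHA_UM3_PER_PG = ALPHA_M3_PER_KG * 1e3  # 0.18 um^3/pg


@dataclass(frozen=True)
class QPIConfig:
    """Acquisition geometry and analysis parameters.

    ``alpha`` is the refractive increment in m^3/kg; ``pixel_area`` in
    um^2; ``phase_units`` either ``opl_um`` (OPL in micrometers) or
    ``radians`` (requires ``wavelength_um``).  Segmentation defaults:
    Li threshold on the Sobel gradient magnitude, minimum object area
    50 px, watershed seeds from distance-transform maxima.
    """

    alpha: float = ALPHA_M3_PER_KG
    pixel_area: float = 1.0
    phase_units: str = "opl_um"
    wavelength_um: float | None = None
    min_track_frames: int = 5
    min_area: int = 50
    peak_min_distance: int = 5
    edge_threshold: str = "li"  # li | otsu; Li keeps dim cells when bright
    # cells dominate the gradient histogram

    def __post_init__(self):
        if self.alpha <= 0 or self.pixel_area <= 0:
            raise ValueError("alpha and pixel_area must be positive")
        if self.phase_units not in ("opl_um", "radians"):
            raise ValueError("phase_units must be 'opl_um' or 'radians'")
        if self.phase_units == "radians" and not self.wavelength_um:
            raise ValueError("radians phase units require wavelength_um")


def _to_opl_um(phase: np.ndarray, config: QPIConfig) -> np.ndarray:
    if config.phase_units == "radians":
        return phase * config.wavelength_um / (2.0 * np.pi)
    return phase


def segment_cells(phase_image: np.ndarray, config: QPIConfig | None = None):
    """Label single cells in a phase image.

    Sobel gradient magnitude -> intensity threshold (Li by default) -> morphological closing,
    hole filling and small-object removal -> binary mask -> watershed
    seeded at distance-transform maxima to split touching cells.
    Returns ``(labels, n_cells)``; a blank image yields zero labels.
    """
    config = config or QPIConfig()
    img = np.asarray(phase_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("phase image must be single-channel 2-D")
    edges = filters.sobel(img)
    if edges.max() <= 0:
        return np.zeros(img.shape, dtype=np.int32), 0
    threshold_fn = {
        "li": filters.threshold_li,
        "otsu": filters.threshold_otsu,
    }[config.edge_threshold]
    mask = edges > threshold_fn(edges)
    mask = morphology.closing(mask, morphology.disk(3))
    mask = ndimage.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=config.min_area - 1)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32), 0
    distance = ndimage.distance_transform_edt(mask)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        distance,
        min_distance=config.peak_min_distance,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(mask)
    labels = np.asarray(
        segmentation.watershed(-distance, markers, mask=mask), dtype=np.int32
    )
    # drop fragments below min_area produced by the split
    for region in measure.regionprops(labels):
        if region.area < config.min_area:
            labels[labels == region.label] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return labels, int(labels.max())


def mass_from_phase(phase_values, config: QPIConfig | None = None) -> float:
    """Dry mass (pg) of a set of phase pixels.

    OPL per pixel (radians converted via ``OPL = phi * lambda / 2 pi``),
    then ``mass = (1/alpha) * sum(OPL * pixel_area)`` with alpha expressed
    in um^3/pg.
    """
    config = config or QPIConfig()
    opl = _to_opl_um(np.asarray(phase_values, dtype=float), config)
    alpha_um3_pg = config.alpha * 1e3
    return float(opl.sum() * config.pixel_area / alpha_um3_pg)


def image_masses(phase_image: np.ndarray, labels: np.ndarray,
                 config: QPIConfig | None = None,
                 capture_halo: bool = True) -> pd.DataFrame:
    """Per-cell dry mass from a labelled phase image.

    Returns ``label, mass_pg`` rows; label 0 (background/unsegmented
    residual) is excluded.  With ``capture_halo`` (default), faint
    above-background pixels outside the edge-based mask — the dim rim of
    each cell the gradient threshold misses — are assigned to the
    nearest label before integration, so per-cell masses account for the
    whole cell signal.
    """
    config = config or QPIConfig()
    img = np.asarray(phase_image, dtype=float)
    labels = np.asarray(labels)
    if capture_halo and labels.max() > 0:
        background_signal = (labels == 0) & (img > 0.005 * img.max())
        if background_signal.any():
            _, (ir, ic) = ndimage.distance_transform_edt(
                labels == 0, return_indices=True
            )
            nearest = labels[ir, ic]
            labels = labels.copy()
            labels[background_signal] = nearest[background_signal]
    rows = [
        (lab, mass_from_phase(img[labels == lab], config))
        for lab in range(1, int(labels.max()) + 1)
    ]
    return pd.DataFrame(rows, columns=["label", "mass_pg"])


def specific_growth_rate(times_h, masses_pg,
                         min_frames: int = 2) -> float:
    """SGR (h^-1): OLS slope of ln(mass) vs time for one cell track."""
    t = np.asarray(times_h, dtype=float)
    m = np.asarray(masses_pg, dtype=float)
    if t.size < min_frames or t.size < 2:
        raise ValueError("track too short for SGR")
    if (m <= 0).any():
        raise ValueError("masses must be positive")
    return float(stats.linregress(t, np.log(m)).slope)


def sgr_population(tracks: pd.DataFrame,
                   min_track_frames: int = 5) -> pd.DataFrame:
    """Per-cell SGR for a long table of mass tracks.

    ``tracks`` has columns ``dose_uM, cell, time_h, mass_pg`` (extra
    grouping columns such as culture/drug pass through).  Tracks shorter
    than ``min_track_frames`` are excluded and counted in the function's
    warning.  Vectorized closed-form OLS per cell.
    """
    g = tracks.groupby(["dose_uM", "cell"], sort=False)
    n = g["time_h"].transform("size")
    short = n < min_track_frames
    if short.any():
        n_short = tracks.loc[short, ["dose_uM", "cell"]].drop_duplicates().shape[0]
        warnings.warn(f"{n_short} track(s) shorter than {min_track_frames} "
                      "frames excluded")
    ok = tracks.loc[~short].copy()
    ok["logm"] = np.log(ok["mass_pg"].to_numpy(dtype=float))
    g = ok.groupby(["dose_uM", "cell"], sort=False)
    t = ok["time_h"].to_numpy(dtype=float)
    tm = g["time_h"].transform("mean").to_numpy()
    ym = g["logm"].transform("mean").to_numpy()
    ok["_num"] = (t - tm) * (ok["logm"].to_numpy() - ym)
    ok["_den"] = (t - tm) ** 2
    agg = g[["_num", "_den"]].sum()
    out = (agg["_num"] / agg["_den"]).rename("sgr").reset_index()
    return out


def normalized_mass_velocity(times_h, total_masses) -> float:
    """Whole-image growth velocity: regression slope of normalized mass.

    Total segmented mass per frame is divided by the frame-0 value; the
    returned velocity is the OLS slope of that normalized mass vs time
    (h^-1 in normalized-mass units).
    """
    t = np.asarray(times_h, dtype=float)
    m = np.asarray(total_masses, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 frames")
    if m[0] <= 0:
        raise ValueError("frame-0 total mass must be positive")
    return float(stats.linregress(t, m / m[0]).slope)


def gr_metric(k_treated: float, k_control: float) -> float:
    """Growth-rate-inhibition metric GR = 2^(k/k_ctrl) - 1.

    Returns NaN (not evaluable) when the control is not growing
    (k_control <= 0) — GR is undefined for a non-growing reference
    culture.
    """
    if k_control <= 0:
        return float("nan")
    return float(2.0 ** (k_treated / k_control) - 1.0)


@dataclass(frozen=True)
class DoseResponseFit:
    culture: str
    drug: str
    doses: tuple
    gr_values: tuple
    gr_inf: float
    gr50: float | None
    hill: float
    gr50_estimable: bool
    residual: float
    low_quality: bool = False


def _gr_logistic(c, gr_inf, gr50, hill):
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, c / gr50, 0.0)
    return gr_inf + (1.0 - gr_inf) / (1.0 + ratio**hill)


def fit_gr50(
    doses,
    gr_values,
    culture: str = "",
    drug: str = "",
    residual_threshold: float = 0.15,
) -> DoseResponseFit:
    """Bounded three-parameter logistic fit of GR vs dose.

    ``GR(c) = gr_inf + (1 - gr_inf) / (1 + (c/gr50)^hill)`` fitted by
    least squares with gr_inf in [-1, 1], hill in (0, 5], gr50 within
    [min positive dose / 10, max dose * 10].  ``gr50_estimable`` is False
    when the fitted curve never crosses GR = 0.5 inside the tested dose
    range or the bounded fit pins gr50 at a boundary — the explicit
    non-estimable outcome for drugs that leave the culture growing.
    RMS residual above ``residual_threshold`` flags the fit low-quality
    (still reported).
    """
    c = np.asarray(doses, dtype=float)
    g = np.asarray(gr_values, dtype=float)
    keep = np.isfinite(g)
    c, g = c[keep], g[keep]
    if np.unique(c).size < 4:
        raise ValueError("need >= 4 dose levels (including control)")
    pos = c[c > 0]
    lo, hi = pos.min() / 10.0, c.max() * 10.0
    bounds = ([-1.0, lo, 1e-6], [1.0, hi, 5.0])
    # multi-start over gr50 decades; keep best SSE
    best = None
    for g50_init in np.geomspace(max(lo * 1.01, 1e-9), hi * 0.99, 5):
        p0 = [float(np.clip(g.min(), -1, 1)), g50_init, 1.0]
        try:
            popt, _ = optimize.curve_fit(
                _gr_logistic, c, g, p0=p0, bounds=bounds, maxfev=5000
            )
        except RuntimeError:
            continue
        sse = float(np.sum((_gr_logistic(c, *popt) - g) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise RuntimeError("logistic fit failed to converge from all starts")
    (gr_inf, gr50, hill), sse = best
    rms = float(np.sqrt(sse / c.size))
    fitted = _gr_logistic(c, gr_inf, gr50, hill)
    crosses = fitted.min() <= 0.5 <= fitted.max()
    at_boundary = gr50 <= lo * 1.05 or gr50 >= hi * 0.95
    estimable = bool(crosses and not at_boundary)
    return DoseResponseFit(
        culture=culture,
        drug=drug,
        doses=tuple(c),
        gr_values=tuple(g),
        gr_inf=float(gr_inf),
        gr50=float(gr50) if estimable else None,
        hill=float(hill),
        gr50_estimable=estimable,
        residual=rms,
        low_quality=rms > residual_threshold,
    )


def response_descriptors(
    sgr_windows: pd.DataFrame, control_dose: float = 0.0
) -> pd.DataFrame:
    """Depth, time and heterogeneity of response per dose.

    ``sgr_windows`` has columns ``dose_uM, window_time_h, cell, sgr``:
    time-resolved single-cell SGR in sliding windows.  For each treated
    dose: depth of response is the minimum over time of the mean-SGR
    ratio to the control at the same window (clipped at 0); time of
    response is the first window time at which the mean treated SGR
    drops below 50% of control (NaN = not reached); heterogeneity is the
    standard deviation of single-cell SGR in the final window.
    """
    ctrl = (
        sgr_windows.loc[sgr_windows["dose_uM"] == control_dose]
        .groupby("window_time_h")["sgr"].mean()
    )
    if ctrl.empty:
        raise ValueError("control dose absent from SGR windows")
    rows = []
    for dose, g in sgr_windows.groupby("dose_uM"):
        mean_by_t = g.groupby("window_time_h")["sgr"].mean()
        common = mean_by_t.index.intersection(ctrl.index)
        ratio = (mean_by_t[common] / ctrl[common]).clip(lower=0.0)
        below = ratio[ratio < 0.5]
        t_resp = float(below.index.min()) if not below.empty else float("nan")
        final_t = g["window_time_h"].max()
        het = float(g.loc[g["window_time_h"] == final_t, "sgr"].std(ddof=1))
        rows.append((dose, float(ratio.min()), t_resp, het))
    return pd.DataFrame(
        rows,
        columns=["dose_uM", "depth_of_response", "time_of_response_h",
                 "heterogeneity"],
    )
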