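"""Synthetic fluorescence images and concentration-response tables.

The raw screens this package analyses — HepG2 p53-pathway GFP reporter cells
(p53, p21, BTG2) imaged in 2D monolayers and 3D spheroids — are not publicly
deposited, so every downstream stage is exercised against generated data with
known ground truth:

* monolayer fields: elliptical Gaussian nuclei (Hoechst), a GFP channel with a
  controllable per-cell level, and a propidium-iodide (PI) channel painted
  over a chosen subset (and, optionally, a chosen fraction) of nuclei;
* spheroid z-stacks: spherical Hoechst clusters sampled at the 30 µm plane
  spacing of the original confocal protocol, with aligned GFP/PI stacks;
* well-level response tables: Hill-shaped GFP induction or viability decline
  over 8-point geometric concentration series with solvent-control wells,
  replicates and Gaussian noise, together with the analytically true
  point of departure (PoD) and absolute IC50 per condition.

Everything is driven by a single integer seed per generator call; identical
seeds give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidRangeError, InvalidStackError, PackingError
from .images import INTENSITY_MAX, ChannelImage, LabelMap, ZStack

__all__ = [
    "ImagingGroundTruth",
    "ResponseModel",
    "PlateDesign",
    "geometric_series",
    "generate_monolayer_images",
    "generate_spheroid_stack",
    "generate_response_table",
    "default_plate_design",
    "TABLE1_RANGES",
]

#: Compound concentration ranges tested in the original screen (µM, 8 points).
TABLE1_RANGES: Dict[str, Tuple[float, float]] = {
    "aflatoxin B1": (0.10, 21.54),
    "brequinar": (0.22, 100.0),
    "cisplatin": (0.10, 21.54),
    "gemcitabine": (0.0037, 0.80),
    "mitomycin C": (0.10, 21.54),
}


# ---------------------------------------------------------------------------
# concentration series


def geometric_series(lowest: float, highest: float, n: int = 8) -> np.ndarray:
    """``n`` concentrations equally spaced in log10 between the endpoints.

    Endpoints are included exactly; the common ratio is
    ``(highest/lowest)**(1/(n-1))``.

    Raises
    ------
    InvalidRangeError
        If the endpoints are nonpositive or not strictly increasing, or n < 2.
    """
    if n < 2:
        raise InvalidRangeError(f"need at least 2 concentrations, got {n}")
    if not (0 < lowest < highest):
        raise InvalidRangeError(
            f"endpoints must satisfy 0 < lowest < highest, got ({lowest}, {highest})"
        )
    series = np.logspace(math.log10(lowest), math.log10(highest), n)
    series[0], series[-1] = lowest, highest  # exact endpoints
    return series


# ---------------------------------------------------------------------------
# imaging ground truth


@dataclass
class ImagingGroundTruth:
    """What the generator actually drew, for oracle-style comparisons."""

    nucleus_centers: List[Tuple[float, float]] = field(default_factory=list)
    nucleus_masks: Optional[LabelMap] = None
    pi_positive_ids: set = field(default_factory=set)
    spheroid_masks: Optional[LabelMap] = None
    per_object_gfp_mean: Dict[int, float] = field(default_factory=dict)
    #: per-object painted PI fraction (of nuclear or projected spheroid area)
    pi_fraction_by_id: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = self.nucleus_masks if self.nucleus_masks is not None else self.spheroid_masks
        if ref is not None:
            present = ref.label_set()
            missing = set(self.pi_positive_ids) - present
            if missing:
                raise ValueError(f"pi_positive_ids not present in masks: {sorted(missing)}")


def _render_blob(
    canvas: np.ndarray, cy: float, cx: float, sy: float, sx: float, amplitude: float
) -> np.ndarray:
    """Add an axis-aligned 2D Gaussian blob; returns its half-maximum mask."""
    h, w = canvas.shape
    ry, rx = int(math.ceil(4 * sy)), int(math.ceil(4 * sx))
    y0, y1 = max(0, int(cy) - ry), min(h, int(cy) + ry + 1)
    x0, x1 = max(0, int(cx) - rx), min(w, int(cx) + rx + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    g = np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
    canvas[y0:y1, x0:x1] += amplitude * g
    mask = np.zeros(canvas.shape, dtype=bool)
    mask[y0:y1, x0:x1] = g >= 0.5
    return mask


def _place_centers(
    rng: np.random.Generator,
    n: int,
    size: int,
    min_distance: float,
    margin: float,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Rejection-sample ``n`` centers with pairwise distance >= min_distance."""
    centers: List[Tuple[float, float]] = []
    for _ in range(n):
        for attempt in range(max_attempts):
            c = rng.uniform(margin, size - margin, size=2)
            if all((c[0] - y) ** 2 + (c[1] - x) ** 2 >= min_distance**2 for y, x in centers):
                centers.append((float(c[0]), float(c[1])))
                break
        else:
            raise PackingError(
                f"could not place nucleus {len(centers) + 1}/{n} after {max_attempts} "
                f"attempts (size={size}, min_distance={min_distance})"
            )
    return np.asarray(centers).reshape(n, 2)


def generate_monolayer_images(
    n_nuclei: int,
    image_size: int = 512,
    gfp_level: float = 8000.0,
    pi_fraction: float = 0.0,
    seed: int = 0,
    *,
    min_distance: float = 16.0,
    radius_range: Tuple[float, float] = (5.0, 9.0),
    hoechst_level: float = 20000.0,
    pi_level: float = 40000.0,
    noise_sd: float = 100.0,
    pi_partial_fraction: Optional[float] = None,
) -> Tuple[Dict[str, ChannelImage], ImagingGroundTruth]:
    """Render a 2D monolayer field as three aligned channels plus ground truth.

    Nuclei are anisotropic Gaussian blobs whose half-maximum contours (ellipses
    with radii drawn from ``radius_range``) define the ground-truth masks.
    ``round(pi_fraction * n_nuclei)`` randomly chosen nuclei are PI-positive;
    their PI signal covers the whole nuclear mask, or — when
    ``pi_partial_fraction`` is given — the first ``round(f * area)`` pixels of
    the mask in row-major order, which pins the PI overlap fraction exactly for
    boundary tests of the 10 % classification rule.

    Returns a dict with keys ``hoechst``, ``gfp``, ``pi`` and the ground truth.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be nonnegative")
    if not (0.0 <= pi_fraction <= 1.0):
        raise ValueError("pi_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = (image_size, image_size)
    hoechst = np.zeros(shape, dtype=np.float64)
    gfp = np.zeros(shape, dtype=np.float64)
    pi = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)

    margin = radius_range[1] + 2
    centers = (
        _place_centers(rng, n_nuclei, image_size, min_distance, margin)
        if n_nuclei
        else np.empty((0, 2))
    )
    half_max_to_sigma = 1.0 / math.sqrt(2.0 * math.log(2.0))
    gfp_means: Dict[int, float] = {}
    for lab, (cy, cx) in enumerate(centers, start=1):
        r_a, r_b = sorted(rng.uniform(*radius_range, size=2), reverse=True)
        sy, sx = (r_a, r_b) if rng.random() < 0.5 else (r_b, r_a)
        sy *= half_max_to_sigma
        sx *= half_max_to_sigma
        amp = hoechst_level * rng.uniform(0.85, 1.15)
        mask = _render_blob(hoechst, cy, cx, sy, sx, amp)
        mask &= labels == 0  # a pixel belongs to exactly one nucleus
        labels[mask] = lab
        gfp_means[lab] = float(gfp_level)

    # GFP: constant level over each cell footprint (nucleus + ~6 px halo)
    if n_nuclei:
        from scipy import ndimage as ndi

        footprint = ndi.binary_dilation(labels > 0, iterations=6)
        gfp[footprint] = gfp_level

    n_pos = int(round(pi_fraction * n_nuclei))
    pos_ids = set(int(i) for i in rng.choice(np.arange(1, n_nuclei + 1), size=n_pos, replace=False)) if n_pos else set()
    pi_frac_by_id: Dict[int, float] = {}
    for lab in sorted(pos_ids):
        ys, xs = np.nonzero(labels == lab)
        order = np.lexsort((xs, ys))  # row-major
        area = len(ys)
        k = area if pi_partial_fraction is None else int(round(pi_partial_fraction * area))
        sel = order[:k]
        pi[ys[sel], xs[sel]] = pi_level
        pi_frac_by_id[lab] = k / area if area else 0.0

    if noise_sd > 0:
        for chan in (hoechst, gfp, pi):
            chan += rng.normal(0.0, noise_sd, size=shape)
    channels = {
        name: ChannelImage(np.clip(arr, 0, INTENSITY_MAX), name)
        for name, arr in (("hoechst", hoechst), ("gfp", gfp), ("pi", pi))
    }
    truth = ImagingGroundTruth(
        nucleus_centers=[(float(y), float(x)) for y, x in centers],
        nucleus_masks=LabelMap(labels, kind="nuclei"),
        pi_positive_ids=pos_ids,
        per_object_gfp_mean=gfp_means,
        pi_fraction_by_id=pi_frac_by_id,
    )
    return channels, truth


def generate_spheroid_stack(
    n_spheroids: int,
    n_planes: int = 9,
    plane_step: float = 30.0,
    seed: int = 0,
    *,
    image_size: int = 512,
    pixel_size: float = 2.0,
    radius_um_range: Tuple[float, float] = (80.0, 120.0),
    gfp_level: float = 8000.0,
    hoechst_level: float = 20000.0,
    pi_level: float = 40000.0,
    pi_area_fraction: float = 0.0,
    noise_sd: float = 100.0,
) -> Tuple[Dict[str, ZStack], ImagingGroundTruth]:
    """Render spheroids as spheres sampled by a z-stack of ``n_planes`` planes.

    Sphere centers sit on the middle plane, so the maximum-intensity projection
    of the Hoechst stack is exactly each sphere's equatorial disk; the
    ground-truth ``spheroid_masks`` store those projected disks.  A concentric
    core covering ``pi_area_fraction`` of each projected disk is painted PI-hot
    on every plane; the realised per-object pixel fraction is recorded in
    ``pi_fraction_by_id``.
    """
    if n_planes < 1:
        raise InvalidStackError(f"n_planes must be >= 1, got {n_planes}")
    if n_spheroids < 0:
        raise ValueError("n_spheroids must be nonnegative")
    rng = np.random.default_rng(seed)
    shape = (image_size, image_size)
    hoechst = np.zeros((n_planes, *shape), dtype=np.float64)
    gfp = np.zeros_like(hoechst)
    pi = np.zeros_like(hoechst)
    proj_labels = np.zeros(shape, dtype=np.int32)

    radii_px = []
    max_r_px = radius_um_range[1] / pixel_size
    centers = (
        _place_centers(rng, n_spheroids, image_size, 2.2 * max_r_px, max_r_px + 2)
        if n_spheroids
        else np.empty((0, 2))
    )
    z_um = (np.arange(n_planes) - (n_planes - 1) / 2.0) * plane_step
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    gfp_means: Dict[int, float] = {}
    pi_frac_by_id: Dict[int, float] = {}
    for lab, (cy, cx) in enumerate(centers, start=1):
        r_um = rng.uniform(*radius_um_range)
        r_px = r_um / pixel_size
        radii_px.append(r_px)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        eq_disk = d2 <= r_px**2
        proj_labels[eq_disk & (proj_labels == 0)] = lab
        core = d2 <= pi_area_fraction * r_px**2  # concentric core: area fraction f
        for iz, dz in enumerate(z_um):
            if abs(dz) >= r_um:
                continue
            rz_px = math.sqrt(r_um**2 - dz**2) / pixel_size
            disk = d2 <= rz_px**2
            hoechst[iz][disk] = hoechst_level
            gfp[iz][disk] = gfp_level
            if pi_area_fraction > 0:
                pi[iz][disk & core] = pi_level
        gfp_means[lab] = float(gfp_level)
        n_disk = int(eq_disk.sum())
        pi_frac_by_id[lab] = float((eq_disk & core).sum() / n_disk) if n_disk else 0.0

    if noise_sd > 0:
        for chan in (hoechst, gfp, pi):
            chan += rng.normal(0.0, noise_sd, size=chan.shape)
    stacks = {
        name: ZStack(
            [ChannelImage(np.clip(p, 0, INTENSITY_MAX), name, pixel_size) for p in arr],
            step=plane_step,
        )
        for name, arr in (("hoechst", hoechst), ("gfp", gfp), ("pi", pi))
    }
    truth = ImagingGroundTruth(
        nucleus_centers=[(float(y), float(x)) for y, x in centers],
        spheroid_masks=LabelMap(proj_labels, kind="spheroid"),
        pi_positive_ids=set(lab for lab, f in pi_frac_by_id.items() if f > 0),
        per_object_gfp_mean=gfp_means,
        pi_fraction_by_id=pi_frac_by_id,
    )
    return stacks, truth


# ---------------------------------------------------------------------------
# concentration-response tables


def _hill(c: np.ndarray, ec50: float, slope: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return c**slope / (c**slope + ec50**slope)


@dataclass
class ResponseModel:
    """Parametric truth behind one condition's concentration-response curve.

    The mean response at concentration ``c`` is Hill-shaped::

        increase:  baseline * (1 + (max_fold_change - 1) * hill(c; ec50, slope))
        decrease:  baseline * (1 - (max_fold_change - 1) * hill(c; ec50, slope))

    clipped at zero for decreasing curves, plus Gaussian noise with SD
    ``noise_sd``.  ``onset_concentration`` is the analytically true point of
    departure: the concentration at which the noiseless mean curve crosses
    ``baseline ± 2 * noise_sd`` (the same ±2·SD solvent band the estimator
    uses).  Use :meth:`from_onset` to build a model whose onset is exact by
    construction, or :meth:`from_ec50` to derive the onset from an EC50.
    """

    baseline: float
    max_fold_change: float
    onset_concentration: Optional[float]
    hill_slope: float
    ec50: float
    noise_sd: float
    direction: str = "increase"

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")
        if self.max_fold_change < 1:
            raise ValueError("max_fold_change must be >= 1")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if (
            self.direction == "increase"
            and self.onset_concentration is not None
            and self.ec50 < self.onset_concentration
        ):
            raise ValueError("ec50 must be >= onset_concentration for increasing curves")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_onset(
        cls,
        baseline: float,
        max_fold_change: float,
        onset_concentration: float,
        hill_slope: float,
        noise_sd: float,
        direction: str = "increase",
    ) -> "ResponseModel":
        """Build a model whose mean curve exits the ±2·noise_sd control band
        exactly at ``onset_concentration``."""
        if onset_concentration <= 0:
            raise ValueError("onset_concentration must be positive")
        if noise_sd <= 0:
            raise ValueError("from_onset needs noise_sd > 0 (the band has zero width otherwise)")
        q = 2.0 * noise_sd / (baseline * (max_fold_change - 1.0))
        if not (0 < q < 1):
            raise ValueError(
                "effect too small: 2*noise_sd must be below baseline*(max_fold_change-1)"
            )
        ec50 = onset_concentration * ((1.0 - q) / q) ** (1.0 / hill_slope)
        return cls(baseline, max_fold_change, onset_concentration, hill_slope, ec50, noise_sd, direction)

    @classmethod
    def from_ec50(
        cls,
        baseline: float,
        max_fold_change: float,
        ec50: float,
        hill_slope: float,
        noise_sd: float,
        direction: str = "increase",
    ) -> "ResponseModel":
        """Derive the true onset from the EC50 (None for flat/no-band curves)."""
        onset: Optional[float] = None
        if max_fold_change > 1 and noise_sd > 0:
            q = 2.0 * noise_sd / (baseline * (max_fold_change - 1.0))
            if 0 < q < 1:
                onset = ec50 * (q / (1.0 - q)) ** (1.0 / hill_slope)
        return cls(baseline, max_fold_change, onset, hill_slope, ec50, noise_sd, direction)

    # -- evaluation ---------------------------------------------------------

    def mean_response(self, concentrations: np.ndarray) -> np.ndarray:
        """Noiseless mean response at the given concentrations (µM)."""
        effect = (self.max_fold_change - 1.0) * _hill(concentrations, self.ec50, self.hill_slope)
        if self.direction == "increase":
            return self.baseline * (1.0 + effect)
        return np.clip(self.baseline * (1.0 - effect), 0.0, None)

    def true_ic50(self, half_level: Optional[float] = None) -> Optional[float]:
        """Concentration where the decreasing mean curve crosses half baseline.

        None for increasing curves or when the curve never reaches 50 %.
        """
        if self.direction != "decrease" or self.max_fold_change <= 1.5:
            return None
        q = 0.5 / (self.max_fold_change - 1.0)
        return self.ec50 * (q / (1.0 - q)) ** (1.0 / self.hill_slope)


@dataclass
class PlateDesign:
    """Factorial layout of one simulated screen."""

    models: List[str]
    reporters: List[str]
    compounds: Dict[str, np.ndarray]  # compound -> 8-point series (µM)
    durations: List[str]
    n_replicates: int = 3
    solvent_control_wells: int = 6

    def __post_init__(self) -> None:
        for name, series in self.compounds.items():
            series = np.asarray(series, dtype=float)
            if len(series) != 8 or not np.all(np.diff(series) > 0):
                raise ValueError(
                    f"compound {name!r}: expected 8 strictly increasing concentrations"
                )
            self.compounds[name] = series
        if self.n_replicates < 3:
            raise ValueError("at least 3 biological replicates are required")

    def conditions(self) -> Iterable[Tuple[str, str, str, str]]:
        for m in self.models:
            for r in self.reporters:
                for c in self.compounds:
                    for d in self.durations:
                        yield (m, r, c, d)


def default_plate_design(
    n_replicates: int = 3, solvent_control_wells: int = 6
) -> PlateDesign:
    """The screen layout of the original study: 4 culture models × 3 reporters
    × 5 compounds (8-point geometric series from Table-style ranges) × 3
    exposure durations."""
    compounds = {
        name: geometric_series(lo, hi, 8) for name, (lo, hi) in TABLE1_RANGES.items()
    }
    return PlateDesign(
        models=["2D-DMEM", "2D-AAGLY", "3D-DMEM", "3D-AAGLY"],
        reporters=["p53", "p21", "BTG2"],
        compounds=compounds,
        durations=["24h", "48h", "72h"],
        n_replicates=n_replicates,
        solvent_control_wells=solvent_control_wells,
    )


ConditionKey = Tuple[str, str, str, str]  # (model, reporter, compound, duration)


def generate_response_table(
    design: PlateDesign,
    models: Mapping[ConditionKey, "ResponseModel | Mapping[str, ResponseModel]"],
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a tidy well-level measurement table for a whole plate design.

    ``models`` maps each (model, reporter, compound, duration) condition to a
    :class:`ResponseModel` (taken as the ``gfp`` readout) or to a mapping
    ``readout -> ResponseModel`` (e.g. ``{"gfp": ..., "atp": ...}``).

    Returns
    -------
    (measurements, truth)
        ``measurements`` has columns model, reporter, compound,
        concentration_uM, duration, replicate, well_type, readout, value;
        solvent-control wells carry concentration 0.  ``truth`` has one row
        per condition and readout with the analytic ``true_pod`` and
        ``true_ic50`` (NaN when undefined).
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for key in design.conditions():
        model_id, reporter, compound, duration = key
        if key not in models:
            raise ConfigurationError(f"no ResponseModel for condition {key}")
        spec = models[key]
        readout_models: Mapping[str, ResponseModel]
        if isinstance(spec, ResponseModel):
            readout_models = {"gfp": spec}
        else:
            readout_models = spec
        series = design.compounds[compound]
        for readout, rm in readout_models.items():
            mean = rm.mean_response(series)
            for rep in range(1, design.n_replicates + 1):
                vals = mean + rng.normal(0.0, rm.noise_sd, size=len(series))
                for c, v in zip(series, vals):
                    rows.append(
                        (model_id, reporter, compound, float(c), duration, rep, "treated", readout, float(v))
                    )
            ctrl = rm.baseline + rng.normal(0.0, rm.noise_sd, size=design.solvent_control_wells)
            for i, v in enumerate(ctrl, start=1):
                rows.append(
                    (model_id, reporter, compound, 0.0, duration, i, "solvent", readout, float(v))
                )
            truth_rows.append(
                (
                    model_id, reporter, compound, duration, readout,
                    rm.onset_concentration if rm.onset_concentration is not None else np.nan,
                    rm.true_ic50() if rm.true_ic50() is not None else np.nan,
                )
            )
    measurements = pd.DataFrame(
        rows,
        columns=[
            "model", "reporter", "compound", "concentration_uM", "duration",
            "replicate", "well_type", "readout", "value",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["model", "reporter", "compound", "duration", "readout", "true_pod", "true_ic50"],
    )
    return measurements, truth
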