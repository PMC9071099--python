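"""End-to-end validation studies on synthetic data.

Each function simulates data with the generators in :mod:`ddrquant.synthetic`,
runs the corresponding analysis stage, and returns summary metrics against the
known ground truth.  They back both the acceptance test suite and
``scripts/acceptance.py``; problem sizes default to the study conditions the
statistics assume (8-point series, 3 biological replicates, 10 % measurement
noise, 512x512 monolayer fields).
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np

from . import quant2d, quant3d
from .doseresponse import (
    LoessConfig,
    ResponseCurve,
    compute_ic50,
    compute_pod,
)
from .synthetic import (
    ResponseModel,
    generate_monolayer_images,
    generate_spheroid_stack,
    geometric_series,
)

__all__ = [
    "pod_recovery_study",
    "pod_null_study",
    "ic50_recovery_study",
    "segmentation_study",
    "spheroid_projection_study",
    "pi_rule_study",
    "cytoplasm_ring_study",
    "clustering_study",
    "ddct_example_study",
    "adjusted_rand_index",
]

#: default 8-point series (aflatoxin B1 / cisplatin / mitomycin C range)
DEFAULT_SERIES = (0.10, 21.54)


def _simulate_curve(
    rm: ResponseModel,
    concentrations: np.ndarray,
    n_replicates: int,
    n_controls: int,
    rng: np.random.Generator,
) -> ResponseCurve:
    mean = rm.mean_response(concentrations)
    reps = [
        mean + rng.normal(0.0, rm.noise_sd, size=len(concentrations))
        for _ in range(n_replicates)
    ]
    responses = [np.array([r[i] for r in reps]) for i in range(len(concentrations))]
    controls = rm.baseline + rng.normal(0.0, rm.noise_sd, size=n_controls)
    return ResponseCurve(concentrations, responses, controls)


def pod_recovery_study(
    n_curves: int = 200,
    seed: int = 0,
    *,
    n_replicates: int = 3,
    n_controls: int = 6,
    noise_fraction: float = 0.10,
    baseline: float = 1000.0,
    span: float = 0.5,
) -> Dict[str, float]:
    """PoD recovery across curves with onsets spanning the tested range.

    Each curve is an 8-point geometric series (3 biological replicates,
    noise SD = ``noise_fraction`` x baseline) whose true onset — the
    concentration where the noiseless curve exits the +/-2 SD control band —
    is drawn log-uniformly over the tested range; fold changes up to 5 and
    Hill slopes 1-3 cover the induction shapes seen in reporter screens.
    Undefined estimates count as infinite error so they penalise the median.

    Returns median/90th-percentile |log10(PoD) - log10(true onset)| and the
    fraction of curves where the PoD was defined.
    """
    rng = np.random.default_rng(seed)
    concentrations = geometric_series(*DEFAULT_SERIES, 8)
    noise_sd = noise_fraction * baseline
    config = LoessConfig(span=span)
    errors = []
    n_defined = 0
    for _ in range(n_curves):
        onset = float(
            10 ** rng.uniform(np.log10(concentrations[0]), np.log10(concentrations[-1]))
        )
        rm = ResponseModel.from_onset(
            baseline=baseline,
            max_fold_change=float(rng.uniform(2.0, 5.0)),
            onset_concentration=onset,
            hill_slope=float(rng.uniform(1.0, 3.0)),
            noise_sd=noise_sd,
        )
        curve = _simulate_curve(rm, concentrations, n_replicates, n_controls, rng)
        result = compute_pod(curve, config)
        if result.defined:
            n_defined += 1
            errors.append(abs(math.log10(result.pod) - math.log10(onset)))
        else:
            errors.append(math.inf)
    errors = np.asarray(errors)
    return {
        "median_abs_log10_error": float(np.median(errors)),
        "p90_abs_log10_error": float(np.quantile(errors, 0.9)),
        "fraction_defined": n_defined / n_curves,
        "n": n_curves,
    }


def pod_null_study(
    n_curves: int = 200,
    seed: int = 0,
    *,
    n_replicates: int = 3,
    n_controls: int = 6,
    noise_fraction: float = 0.10,
    baseline: float = 1000.0,
    span: float = 0.5,
) -> Dict[str, float]:
    """False-positive behaviour on flat curves (max fold change = 1).

    A PoD on a flat curve is a false positive of the 2-SD band rule; the
    fraction of curves returning *undefined* is reported.
    """
    rng = np.random.default_rng(seed)
    concentrations = geometric_series(*DEFAULT_SERIES, 8)
    rm = ResponseModel(
        baseline=baseline,
        max_fold_change=1.0,
        onset_concentration=None,
        hill_slope=1.0,
        ec50=1.0,
        noise_sd=noise_fraction * baseline,
    )
    config = LoessConfig(span=span)
    n_undefined = 0
    for _ in range(n_curves):
        curve = _simulate_curve(rm, concentrations, n_replicates, n_controls, rng)
        if not compute_pod(curve, config).defined:
            n_undefined += 1
    return {"fraction_undefined": n_undefined / n_curves, "n": n_curves}


def ic50_recovery_study(
    seed: int = 0,
    *,
    noise_percent: float = 0.0,
    n_replicates: int = 3,
    hill_slope: float = 1.5,
) -> Dict[str, float]:
    """Absolute-IC50 recovery with the true IC50 placed at each of the 8
    design concentrations.

    Viability runs from 100 % down to 0 % (log-logistic, slope 1.5); optional
    Gaussian noise in percent-of-control units.  Returns the maximum relative
    recovery error over the 8 placements, as a percentage.
    """
    rng = np.random.default_rng(seed)
    concentrations = geometric_series(*DEFAULT_SERIES, 8)
    max_rel_err = 0.0
    n_defined = n_interior_defined = 0
    interior = concentrations[1:-1]
    for true_ic50 in concentrations:
        mean = 100.0 / (1.0 + (concentrations / true_ic50) ** hill_slope)
        responses = [
            np.array(
                [m + rng.normal(0.0, noise_percent) if noise_percent else m for _ in range(n_replicates)]
            )
            for m in mean
        ]
        controls = 100.0 + (
            rng.normal(0.0, noise_percent, size=6) if noise_percent else np.zeros(6)
        )
        curve = ResponseCurve(concentrations, responses, controls)
        result = compute_ic50(curve)
        if result.defined:
            n_defined += 1
            n_interior_defined += true_ic50 in interior
            max_rel_err = max(max_rel_err, abs(result.ic50 - true_ic50) / true_ic50)
    return {
        "max_relative_error_percent": 100.0 * max_rel_err,
        "n_defined": n_defined,
        "n_interior_defined": n_interior_defined,
        "n_interior": len(interior),
        "n": len(concentrations),
    }


def segmentation_study(
    n_images: int = 20,
    seed: int = 0,
    *,
    image_size: int = 512,
    n_nuclei_range: tuple = (100, 300),
    noise_sd: float = 0.0,
) -> Dict[str, float]:
    """Nuclei-segmentation accuracy on synthetic monolayers.

    Fields of 100-300 nuclei at >= 1.5x-radius spacing are segmented and
    matched one-to-one to the ground-truth centers (match radius = the
    maximum nucleus radius).  Returns the pooled recall and spurious-object
    fraction over all images.
    """
    rng = np.random.default_rng(seed)
    radius_range = (5.0, 9.0)
    match_radius = radius_range[1]
    n_true_total = n_found_total = n_matched_total = 0
    for _ in range(n_images):
        n_nuclei = int(rng.integers(n_nuclei_range[0], n_nuclei_range[1] + 1))
        channels, truth = generate_monolayer_images(
            n_nuclei,
            image_size=image_size,
            seed=int(rng.integers(2**31)),
            min_distance=1.5 * radius_range[1],  # center spacing >= 1.5x radius
            radius_range=radius_range,
            noise_sd=noise_sd,
        )
        found = quant2d.segment_nuclei(channels["hoechst"])
        m = quant2d.match_objects(found, np.asarray(truth.nucleus_centers), match_radius)
        n_true_total += m["n_true"]
        n_found_total += m["n_found"]
        n_matched_total += m["n_matched"]
    return {
        "recall": n_matched_total / n_true_total if n_true_total else 1.0,
        "spurious_fraction": (
            (n_found_total - n_matched_total) / n_found_total if n_found_total else 0.0
        ),
        "n_images": n_images,
        "n_true": n_true_total,
        "n_found": n_found_total,
    }


def spheroid_projection_study(
    seed: int = 0,
    *,
    pi_area_fraction: float = 0.5,
    n_planes: int = 9,
    radius_um: float = 100.0,
    pixel_size: float = 2.0,
) -> Dict[str, float]:
    """Single-spheroid stack: projected-area error vs the analytic equatorial
    disk (pi r^2 for a sphere of known radius) and recovery of the painted PI
    area fraction."""
    stacks, truth = generate_spheroid_stack(
        1,
        n_planes=n_planes,
        seed=seed,
        pi_area_fraction=pi_area_fraction,
        noise_sd=0.0,
        radius_um_range=(radius_um, radius_um),
        pixel_size=pixel_size,
    )
    analytic_area = math.pi * (radius_um / pixel_size) ** 2
    hoechst_proj = quant3d.max_project(stacks["hoechst"])
    gfp_proj = quant3d.max_project(stacks["gfp"])
    pi_proj = quant3d.max_project(stacks["pi"])
    labels = quant3d.segment_spheroids(hoechst_proj)
    records = quant3d.measure_spheroids(labels, gfp_proj, pi_proj)
    rec = records[0] if records else None
    true_pi = truth.pi_fraction_by_id.get(1, 0.0)
    return {
        "n_spheroids_found": len(records),
        "area_px": rec.area if rec else 0,
        "analytic_area_px": analytic_area,
        "area_relative_error_percent": (
            100.0 * abs(rec.area - analytic_area) / analytic_area if rec else math.inf
        ),
        "pi_fraction_measured": rec.pi_area_fraction if rec else math.nan,
        "pi_fraction_true": true_pi,
        "pi_fraction_abs_error": abs(rec.pi_area_fraction - true_pi) if rec else math.inf,
    }


def pi_rule_study(fractions=(0.05, 0.09, 0.10, 0.50, 1.0)) -> Dict[str, object]:
    """Exactness of the 10 % PI-overlap rule on constructed fixtures.

    One 10x10-pixel (100 px) square nucleus per fraction, with exactly
    ``fraction * 100`` PI-hot pixels painted inside it, so the overlap
    fraction is exact by construction.  Returns the measured fractions and
    classifications alongside the expected ones (positive iff >= 0.10).
    """
    from .images import ChannelImage, LabelMap
    from .quant2d import measure_cells, segment_cytoplasm

    size = 40
    measured, classified = [], []
    for frac in fractions:
        labels = np.zeros((size, size), dtype=np.int32)
        labels[10:20, 10:20] = 1
        pi_mask = np.zeros((size, size), dtype=bool)
        k = int(round(frac * 100))
        ys, xs = np.nonzero(labels == 1)
        pi_mask[ys[:k], xs[:k]] = True
        nuclei = LabelMap(labels, kind="nuclei")
        cyto = segment_cytoplasm(nuclei)
        gfp = ChannelImage(np.full((size, size), 500.0), "gfp")
        rec = measure_cells(nuclei, cyto, gfp, pi_mask)[0]
        measured.append(rec.pi_overlap_fraction)
        classified.append(rec.pi_positive)
    expected = [f >= 0.10 for f in fractions]
    return {
        "fractions": list(fractions),
        "measured_fractions": measured,
        "classified_positive": classified,
        "expected_positive": expected,
        "all_correct": classified == expected,
        "n_correct": sum(c == e for c, e in zip(classified, expected)),
    }


def cytoplasm_ring_study(radius: int = 10, expansion: int = 6) -> Dict[str, float]:
    """Ring geometry on a single-disk fixture.

    A disk nucleus of the given radius is expanded by ``expansion`` px; the
    ring's inner and outer radii (min/max distance of ring pixels from the
    center) are compared with the expected radius and radius+expansion.
    """
    from .images import LabelMap
    from .quant2d import segment_cytoplasm

    size = 4 * (radius + expansion)
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    labels = (d <= radius).astype(np.int32)
    nuclei = LabelMap(labels, kind="nuclei")
    ring = segment_cytoplasm(nuclei, expansion=expansion)
    ring_d = d[ring.labels == 1]
    return {
        "inner_radius": float(ring_d.min()),
        "outer_radius": float(ring_d.max()),
        "expected_inner": float(radius),
        "expected_outer": float(radius + expansion),
        "ring_width": float(ring_d.max() - ring_d.min()),
        "labels_conserved": ring.label_set() == nuclei.label_set(),
        "overlaps_nucleus": bool(np.any((ring.labels > 0) & (labels > 0))),
    }


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two flat partitions (chance-corrected)."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    cats_a, cats_b = np.unique(a), np.unique(b)
    table = np.array([[np.sum((a == i) & (b == j)) for j in cats_b] for i in cats_a])
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(axis=1)).sum()
    sum_b = comb(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def clustering_study(
    seed: int = 0, *, n_per_group: int = 4, n_features: int = 16, separation: float = 10.0
) -> Dict[str, float]:
    """Planted two-group profile recovery under both supported linkages.

    Two groups of condition profiles whose between-group distance is
    ``separation`` times the within-group spread; the tree is cut at 2
    clusters and compared with the planting by adjusted Rand index (1.0 =
    exact recovery).
    """
    import pandas as pd

    from .comparison import euclidean_distances, hierarchical_cluster

    rng = np.random.default_rng(seed)
    base_a = rng.uniform(0, 1, n_features)
    base_b = base_a + separation
    rows = [base_a + rng.normal(0, 0.05, n_features) for _ in range(n_per_group)]
    rows += [base_b + rng.normal(0, 0.05, n_features) for _ in range(n_per_group)]
    planted = [0] * n_per_group + [1] * n_per_group
    matrix = pd.DataFrame(rows, index=[f"cond{i}" for i in range(2 * n_per_group)])
    dist = euclidean_distances(matrix)
    out: Dict[str, float] = {}
    for linkage in ("complete", "ward"):
        tree = hierarchical_cluster(dist, linkage=linkage)
        out[f"ari_{linkage}"] = adjusted_rand_index(planted, tree.cut(2))
    out["n_profiles"] = 2 * n_per_group
    return out


def ddct_example_study() -> Dict[str, float]:
    """Hand-checkable comparative-Ct example: dCt 3 vs reference dCt 5 gives
    ddCt = -2, fold = 4."""
    import pandas as pd

    from .expression import delta_delta_ct

    table = pd.DataFrame(
        {
            "sample": ["ref", "ref", "treated", "treated"],
            "gene": ["GAPDH", "CDKN1A", "GAPDH", "CDKN1A"],
            "ct": [20.0, 25.0, 21.0, 24.0],  # dCt: ref 5, treated 3
        }
    )
    folds = delta_delta_ct(table, reference_sample="ref")
    treated = folds[folds["sample"] == "treated"].iloc[0]
    ref = folds[folds["sample"] == "ref"].iloc[0]
    return {
        "treated_fold": float(treated["fold_change"]),
        "treated_ddct": float(treated["delta_delta_ct"]),
        "reference_fold": float(ref["fold_change"]),
    }
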