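"""Nucleocytoplasmic partitioning and immunofluorescence quantification.

Per cell, the nucleus is segmented inside the soma ROI from a nuclear
channel (tagged protein or DNA dye), mean intensities are measured in the
nuclear and cytoplasmic (soma minus nucleus) compartments, and their ratio
summarizes localization. Immunoreactivity is quantified as the
background-subtracted mean antibody-channel intensity over the soma ROI;
fold-changes compare condition means. Group comparisons use the two-tailed
t-test or one-way ANOVA with Tukey's post-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "NucCytoMeasurement",
    "ImmunoMeasurement",
    "nuclear_mask",
    "nuc_cyto_ratio",
    "quantify_immunoreactivity",
    "compare_groups",
]


@dataclass
class NucCytoMeasurement:
    cell_id: str | int
    nuclear_mean: float
    cytoplasmic_mean: float
    ratio: float | None  # None when flagged unbounded
    unbounded: bool
    nuclear_integrated: float = 0.0
    cytoplasmic_integrated: float = 0.0


@dataclass
class ImmunoMeasurement:
    cell_id: str | int
    condition: str
    intensity: float  # background-subtracted soma mean, clamped at 0


def nuclear_mask(
    cell_roi_mask: np.ndarray,
    nuclear_channel_image: np.ndarray,
    threshold: float | None = None,
) -> np.ndarray:
    """Largest above-threshold connected region of the nuclear channel
    inside the soma ROI.

    Default threshold: Otsu over the in-ROI nuclear-channel intensities.
    """
    soma = np.asarray(cell_roi_mask, dtype=bool)
    img = np.asarray(nuclear_channel_image, dtype=float)
    if not soma.any():
        raise ValueError("cell ROI is empty")
    vals = img[soma]
    if np.ptp(vals) == 0:
        raise ValueError("nucleus not found: no nuclear signal inside soma")
    thr = float(threshold_otsu(vals)) if threshold is None else float(threshold)
    candidate = soma & (img > thr)
    if not candidate.any():
        raise ValueError("nucleus not found: no nuclear signal inside soma")
    labels = measure.label(candidate, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(np.argmax(sizes))


def nuc_cyto_ratio(
    cell_roi_mask: np.ndarray,
    nuclear_mask_arr: np.ndarray,
    reporter_image: np.ndarray,
    cell_id: str | int = 0,
    noise_floor: float | None = None,
    background_pixels: np.ndarray | None = None,
    use_integrated: bool = False,
) -> NucCytoMeasurement:
    """Nuclear over cytoplasmic mean (or integrated) reporter intensity.

    The cytoplasmic compartment is the soma ROI minus the nucleus. A
    cytoplasmic mean at or below the noise floor (default: median + 2 MAD of
    ``background_pixels``, else 0) flags the ratio as unbounded rather than
    reporting an arbitrarily large number; unbounded cells are excluded from
    group means downstream.
    """
    soma = np.asarray(cell_roi_mask, dtype=bool)
    nuc = np.asarray(nuclear_mask_arr, dtype=bool)
    img = np.asarray(reporter_image, dtype=float)
    if (nuc & ~soma).any():
        raise ValueError("nuclear mask must lie inside the soma ROI")
    cyto = soma & ~nuc
    if not cyto.any():
        raise ValueError("empty cytoplasmic region")
    if not nuc.any():
        raise ValueError("empty nuclear mask")
    nuc_vals, cyto_vals = img[nuc], img[cyto]
    if noise_floor is None:
        if background_pixels is not None:
            bg = np.asarray(background_pixels, dtype=float).ravel()
            mad = np.median(np.abs(bg - np.median(bg)))
            noise_floor = float(np.median(bg) + 2.0 * mad)
        else:
            noise_floor = 0.0
    nuc_mean = float(nuc_vals.mean())
    cyto_mean = float(cyto_vals.mean())
    unbounded = cyto_mean <= noise_floor
    if use_integrated:
        num, den = float(nuc_vals.sum()), float(cyto_vals.sum())
    else:
        num, den = nuc_mean, cyto_mean
    return NucCytoMeasurement(
        cell_id=cell_id,
        nuclear_mean=nuc_mean,
        cytoplasmic_mean=cyto_mean,
        ratio=None if unbounded else num / den,
        unbounded=unbounded,
        nuclear_integrated=float(nuc_vals.sum()),
        cytoplasmic_integrated=float(cyto_vals.sum()),
    )


def quantify_immunoreactivity(
    images: Sequence[np.ndarray],
    soma_rois: Sequence[np.ndarray],
    condition_labels: Sequence[str],
    reference_condition: str,
    background_policy: str = "per_image_median",
) -> tuple[list[ImmunoMeasurement], dict[str, float]]:
    """Background-subtracted per-cell antibody intensities and fold-changes.

    ``background_policy`` ``"per_image_median"`` estimates each image's
    background as the median of its non-ROI pixels; ``"none"`` skips
    subtraction. Fold-change per condition is
    ``mean(condition) / mean(reference_condition)``; knockdown percent is
    ``100 * (1 - fold_change)``.
    """
    if len({len(images), len(soma_rois), len(condition_labels)}) != 1:
        raise ValueError("images, ROIs and labels must align")
    measurements = []
    for i, (img, roi, cond) in enumerate(
        zip(images, soma_rois, condition_labels)
    ):
        img = np.asarray(img, dtype=float)
        roi = np.asarray(roi, dtype=bool)
        if background_policy == "per_image_median":
            bg = float(np.median(img[~roi])) if (~roi).any() else 0.0
        elif background_policy == "none":
            bg = 0.0
        else:
            raise ValueError(f"unknown background policy {background_policy!r}")
        val = max(float(img[roi].mean()) - bg, 0.0)
        measurements.append(
            ImmunoMeasurement(cell_id=i, condition=cond, intensity=val)
        )
    df = pd.DataFrame(
        {"condition": [m.condition for m in measurements],
         "intensity": [m.intensity for m in measurements]}
    )
    means = df.groupby("condition")["intensity"].mean()
    if reference_condition not in means.index:
        raise ValueError(f"no cells in reference {reference_condition!r}")
    ref = means[reference_condition]
    if ref <= 0:
        raise ValueError("reference condition mean is not positive")
    fold = {c: float(m / ref) for c, m in means.items()}
    return measurements, fold


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    method: str = "anova_tukey",
    welch: bool = False,
) -> pd.DataFrame:
    """Two-tailed t-test (two groups) or one-way ANOVA with Tukey HSD.

    Returns a tidy table of pairwise comparisons with the test statistic
    and (adjusted, for Tukey) p-value. Zero-variance degenerate inputs
    resolve exactly: equal means give p = 1, unequal means p = 0.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each group needs n >= 2")
    names = list(groups)
    all_vals = np.concatenate(list(groups.values()))
    if np.ptp(all_vals) == 0:
        pairs = [
            (a, b, 0.0, 1.0)
            for i, a in enumerate(names)
            for b in names[i + 1:]
        ]
        return pd.DataFrame(
            pairs, columns=["group1", "group2", "statistic", "p"]
        )
    if all(np.ptp(v) == 0 for v in groups.values()):
        # zero within-group variance: degenerate exact comparison
        pairs = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                equal = groups[a][0] == groups[b][0]
                pairs.append((a, b, 0.0 if equal else np.inf,
                              1.0 if equal else 0.0))
        return pd.DataFrame(
            pairs, columns=["group1", "group2", "statistic", "p"]
        )
    if method == "t_test":
        if len(groups) != 2:
            raise ValueError("t-test requires exactly two groups")
        a, b = names
        res = stats.ttest_ind(groups[a], groups[b], equal_var=not welch)
        return pd.DataFrame(
            [(a, b, float(res.statistic), float(res.pvalue))],
            columns=["group1", "group2", "statistic", "p"],
        )
    if method == "anova_tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        f_stat, f_p = stats.f_oneway(*groups.values())
        values = np.concatenate([groups[g] for g in names])
        labels = np.concatenate([[g] * len(groups[g]) for g in names])
        tuk = pairwise_tukeyhsd(values, labels)
        rows = []
        for row, p in zip(tuk._results_table.data[1:], tuk.pvalues):
            rows.append((row[0], row[1], float(row[2]), float(p)))
        df = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p"])
        df.attrs["anova_F"] = float(f_stat)
        df.attrs["anova_p"] = float(f_p)
        return df
    raise ValueError(f"unknown method {method!r}")
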