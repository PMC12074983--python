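"""Nuclear morphometrics from voxelized nuclei.

Two per-cell features: the coefficient of variation (COV) of in-mask DAPI
voxel intensities — a chromatin "texture" / unevenness readout — and the
3D sphericity Psi = pi^(1/3) (6V)^(2/3) / A, which is 1 for a perfect
sphere and drops for multi-lobed nuclei. Surface area comes from a
marching-cubes mesh after resampling the (typically anisotropic:
200-nm z steps vs 108-nm pixels) voxel grid to isotropic spacing;
voxel-face counting would systematically overestimate A and is not used.

Arrays are ordered (z, y, x) and voxel sizes are given in the same order,
in nm. Segmentation is upstream: this module consumes masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .screen import fdr_correct, z_score

MIN_CELLS = 10


@dataclass
class NucleusImage:
    """One nucleus: intensity stack, binary mask and voxel size (z, y, x) nm."""

    intensity: np.ndarray
    mask: np.ndarray
    voxel_size_nm: tuple

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensity.shape != self.mask.shape:
            raise ValueError("intensity and mask shapes differ")
        if self.intensity.ndim != 3 or len(self.voxel_size_nm) != 3:
            raise ValueError("expect 3-D stacks with a 3-tuple voxel size")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")


def intensity_cov(img: NucleusImage) -> float:
    """SD / mean of in-mask voxel intensities (invariant to positive
    intensity rescaling)."""
    vals = img.intensity[img.mask]
    if vals.size == 0:
        raise ValueError("empty nuclear mask")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("COV undefined: zero mean in-mask intensity")
    return float(vals.std() / mean)


def _resample_mask_isotropic(mask: np.ndarray, voxel_size_nm) -> tuple:
    """Nearest-neighbor resample to the finest lateral spacing."""
    vz, vy, vx = (float(v) for v in voxel_size_nm)
    target = min(vy, vx)
    factors = (vz / target, vy / target, vx / target)
    if np.allclose(factors, 1.0):
        return mask.copy(), target
    res = ndimage.zoom(mask.astype(np.uint8), factors, order=0, grid_mode=True, mode="grid-constant")
    return res.astype(bool), target


#: Gaussian pre-smoothing (voxels) applied before meshing: suppresses the
#: staircase overestimate of marching-cubes areas on binary masks (a raw
#: binary sphere reads ~8% too much area; smoothed, under 1%).
MESH_SMOOTHING_SIGMA = 0.8


def _mesh_area(mask_iso: np.ndarray, spacing: float) -> float:
    padded = np.pad(mask_iso, 2).astype(float)
    smoothed = ndimage.gaussian_filter(padded, MESH_SMOOTHING_SIGMA)
    if smoothed.max() <= 0.5:  # mask too thin to survive smoothing
        smoothed = padded
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=(spacing,) * 3)
    return float(mesh_surface_area(verts, faces))


def mask_sphericity(mask: np.ndarray, voxel_size_nm=(1.0, 1.0, 1.0)) -> float:
    """Sphericity Psi of a binary mask.

    V is the voxel volume of the mask; A the surface area of a
    marching-cubes isosurface meshed on the isotropically resampled,
    lightly smoothed grid. Discretization keeps Psi within a small mesh
    tolerance of the continuous value (a digitized sphere of radius >= 30
    voxels reads well above 0.97; convex polyhedra land within ~0.03 of
    their closed forms).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_comp = ndimage.label(mask)[1]
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} connected components; split nuclei first")
    iso, spacing = _resample_mask_isotropic(mask, voxel_size_nm)
    volume = iso.sum() * spacing ** 3
    area = _mesh_area(iso, spacing)
    return float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)


def sphericity(img: NucleusImage) -> float:
    return mask_sphericity(img.mask, img.voxel_size_nm)


def nuclear_features(img: NucleusImage) -> dict:
    """Per-nucleus feature vector: COV, sphericity, volume (um^3) and
    marching-cubes surface area (um^2)."""
    iso, spacing = _resample_mask_isotropic(img.mask, img.voxel_size_nm)
    volume_nm3 = iso.sum() * spacing ** 3
    area_nm2 = _mesh_area(iso, spacing)
    psi = float(np.pi ** (1 / 3) * (6.0 * volume_nm3) ** (2 / 3) / area_nm2)
    return {
        "cov": intensity_cov(img),
        "sphericity": psi,
        "volume_um3": float(volume_nm3 / 1e9),
        "surface_area_um2": float(area_nm2 / 1e6),
    }


def nuclear_tests(features_by_sgrna: dict, control_sgrnas,
                  feature_names=("sphericity", "cov"),
                  min_cells: int = MIN_CELLS):
    """Per-perturbation nuclear statistics against pooled controls.

    ``features_by_sgrna`` maps sgRNA id -> DataFrame-like mapping of
    feature name -> per-cell value array. Two-sided Wilcoxon rank-sum on
    per-cell values, log2fc of group means, BH FDR across perturbations
    per feature. Returns a tidy DataFrame.
    """
    import pandas as pd
    from scipy import stats

    control_sgrnas = [sg for sg in control_sgrnas if sg in features_by_sgrna]
    if not control_sgrnas:
        raise ValueError("no control sgRNAs with nuclear features")
    pooled = {
        f: np.concatenate([np.asarray(features_by_sgrna[sg][f], float) for sg in control_sgrnas])
        for f in feature_names
    }
    rows = []
    for sg in sorted(features_by_sgrna):
        is_ctrl = sg in control_sgrnas
        for f in feature_names:
            vals = np.asarray(features_by_sgrna[sg][f], float)
            vals = vals[~np.isnan(vals)]
            ctrl = pooled[f][~np.isnan(pooled[f])]
            if len(vals) < min_cells or len(ctrl) < min_cells:
                rows.append((sg, f, len(vals), np.nan, np.nan, np.nan, is_ctrl))
                continue
            log2fc = float(np.log2(vals.mean() / ctrl.mean()))
            p = float(stats.mannwhitneyu(vals, ctrl, alternative="two-sided").pvalue)
            rows.append((sg, f, len(vals), log2fc, p, z_score(vals, ctrl), is_ctrl))
    table = pd.DataFrame(
        rows, columns=["sgrna", "phenotype", "n_cells", "log2fc", "p", "z", "is_control"]
    )
    table["phenotype"] = table["phenotype"].map({"cov": "intensity_cov"}).fillna(table["phenotype"])
    table["fdr"] = np.nan
    for ph, idx in table.groupby("phenotype").groups.items():
        table.loc[idx, "fdr"] = fdr_correct(table.loc[idx, "p"].to_numpy())
    return table
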