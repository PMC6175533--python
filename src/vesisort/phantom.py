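"""Synthetic tomogram phantoms of a synaptic bouton with known ground truth.

The generator plants non-overlapping spherical vesicles of two kinds into a
uniform background:

* clear-core vesicles (CCV): a dark spherical membrane shell around a lumen
  close to the background gray level;
* dense-core vesicles (DCV): larger spheres with the same dark membrane
  shell but a dark, electron-dense interior.

DCV centers are biased towards larger distances from a marked active-zone
(AZ) point, reproducing the spatial segregation seen at neuromuscular
junctions: CCVs cluster near the release site while DCVs sit at the rim of
the vesicle pool.  Stored intensity follows the usual EM display convention,
low = electron dense (dark).

A second, image-free generator draws per-vesicle feature tables directly
from class-conditional Gaussians, for exercising the classifier and the
training/evaluation machinery at scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .tomo_io import TomogramStack

__all__ = [
    "PhantomSpec",
    "ClassFeatureParams",
    "DEFAULT_CLASS_PARAMS",
    "CapacityError",
    "generate_phantom_stack",
    "sample_feature_table",
]


class CapacityError(RuntimeError):
    """Raised when the requested vesicles cannot be placed without overlap."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic bouton tomogram.

    Radii and distances in nm; gray levels in stored (dark = low) intensity
    on a 0-255 scale.  Defaults emulate the conditions reported for
    C. elegans NMJ tomograms: CCV inner radii around 9-10 nm, DCV inner
    radii around 15-17 nm, a membrane ~4.5 nm thick, roughly one vesicle in
    eight a DCV, and DCVs displaced away from the active zone.
    """

    shape: tuple[int, int, int] = (48, 220, 220)       # (z, y, x) voxels
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.2)  # (x, y, z) nm
    n_vesicles: int = 40
    dcv_fraction: float = 0.12
    ccv_radius_mean_nm: float = 9.8
    ccv_radius_sd_nm: float = 1.5
    dcv_radius_mean_nm: float = 15.5
    dcv_radius_sd_nm: float = 2.0
    membrane_nm: float = 4.5
    background_gray: float = 128.0
    lumen_gray: float = 134.0
    membrane_gray: float = 60.0
    dense_core_gray: float = 72.0
    az_point_nm: tuple[float, float, float] | None = None  # (x, y, z); default: mid-bottom
    dcv_distance_bias: float = 2.0   # exponent of the distance-weighted DCV placement
    noise_sd: float = 0.0
    z_blur_sigma: float = 0.0        # mild tomographic elongation along z
    min_gap_nm: float = 3.0          # clearance between outer surfaces
    seed: int = 0
    max_tries: int = 20000

    def __post_init__(self) -> None:
        if not 0.0 <= self.dcv_fraction <= 1.0:
            raise ValueError("dcv_fraction must be in [0, 1]")
        for name in ("ccv_radius_mean_nm", "dcv_radius_mean_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.az_point_nm is None:
            nz, ny, nx = self.shape
            sx, sy, sz = self.spacing
            # AZ at the center of the bottom (y = 0) face, mid-depth
            self.az_point_nm = (nx * sx / 2.0, 0.0, nz * sz / 2.0)


def _place_centers(spec: PhantomSpec, radii_nm: np.ndarray,
                   is_dcv: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping centers (nm, (x, y, z) per row)."""
    nz, ny, nx = spec.shape
    sx, sy, sz = spec.spacing
    extent = np.array([nx * sx, ny * sy, nz * sz])
    az = np.array(spec.az_point_nm, dtype=float)
    d_max = float(np.linalg.norm(extent))
    outer = radii_nm + spec.membrane_nm
    # place the big DCVs first so packing failures surface early
    order = np.argsort(~is_dcv, kind="stable")
    centers = np.empty((len(radii_nm), 3))
    placed_centers: list[np.ndarray] = []
    placed_outer: list[float] = []
    for idx in order:
        r_out = outer[idx]
        if np.any(extent - 2 * r_out <= 0):
            raise CapacityError(
                f"vesicle with outer radius {r_out:.1f} nm does not fit the "
                f"volume extent {tuple(np.round(extent, 1))} nm")
        tries = 0
        while True:
            tries += 1
            if tries > spec.max_tries:
                raise CapacityError(
                    f"could not place vesicle {idx} (r_out={r_out:.1f} nm) "
                    f"within {spec.max_tries} tries")
            c = rng.uniform(r_out, extent - r_out)
            if is_dcv[idx] and spec.dcv_distance_bias > 0:
                d = np.linalg.norm(c - az)
                if rng.random() > (d / d_max) ** spec.dcv_distance_bias:
                    continue
            if all(np.linalg.norm(c - pc) > r_out + po + spec.min_gap_nm
                   for pc, po in zip(placed_centers, placed_outer)):
                break
        placed_centers.append(c)
        placed_outer.append(float(r_out))
        centers[idx] = c
    return centers


def generate_phantom_stack(spec: PhantomSpec) -> tuple[TomogramStack, pd.DataFrame]:
    """Render a phantom tomogram and return it with its ground truth.

    Returns
    -------
    stack:
        float32 :class:`TomogramStack` with ``spec.spacing``.
    truth:
        DataFrame with one row per planted vesicle: ``x, y, z`` (center, nm),
        ``class`` (CCV/DCV), ``r_inner`` (nm) and ``distAZ`` (nm).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_vesicles
    is_dcv = rng.random(n) < spec.dcv_fraction
    radii = np.where(
        is_dcv,
        rng.normal(spec.dcv_radius_mean_nm, spec.dcv_radius_sd_nm, n),
        rng.normal(spec.ccv_radius_mean_nm, spec.ccv_radius_sd_nm, n),
    )
    radii = np.clip(radii, 3.0, None)

    centers = _place_centers(spec, radii, is_dcv, rng)

    nz, ny, nx = spec.shape
    sx, sy, sz = spec.spacing
    vol = np.full(spec.shape, spec.background_gray, dtype=np.float32)
    # voxel i sits at i * spacing, matching the feature module's convention
    zc = np.arange(nz) * sz
    yc = np.arange(ny) * sy
    xc = np.arange(nx) * sx
    for i in range(n):
        cxn, cyn, czn = centers[i]
        r_in = radii[i]
        r_out = r_in + spec.membrane_nm
        # local bounding box in voxel indices
        zi = np.flatnonzero(np.abs(zc - czn) <= r_out + sz)
        yi = np.flatnonzero(np.abs(yc - cyn) <= r_out + sy)
        xi = np.flatnonzero(np.abs(xc - cxn) <= r_out + sx)
        if len(zi) == 0 or len(yi) == 0 or len(xi) == 0:
            continue
        dz = (zc[zi] - czn)[:, None, None]
        dy = (yc[yi] - cyn)[None, :, None]
        dx = (xc[xi] - cxn)[None, None, :]
        dist = np.sqrt(dx**2 + dy**2 + dz**2)
        sub = vol[np.ix_(zi, yi, xi)]
        # both vesicle kinds carry a dark membrane shell; the interior is a
        # clear lumen for CCVs and a dense dark core for DCVs
        sub[dist <= r_out] = spec.membrane_gray
        sub[dist <= r_in] = (spec.dense_core_gray if is_dcv[i]
                             else spec.lumen_gray)
        vol[np.ix_(zi, yi, xi)] = sub

    if spec.z_blur_sigma > 0:
        vol = ndimage.gaussian_filter1d(vol, spec.z_blur_sigma, axis=0)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape).astype(np.float32)

    az = np.asarray(spec.az_point_nm, dtype=float)
    truth = pd.DataFrame({
        "x": centers[:, 0], "y": centers[:, 1], "z": centers[:, 2],
        "class": np.where(is_dcv, "DCV", "CCV"),
        "r_inner": radii,
        "distAZ": np.linalg.norm(centers - az, axis=1),
    })
    stack = TomogramStack(voxels=vol.astype(np.float32), spacing=spec.spacing,
                          id=f"phantom-seed{spec.seed}")
    return stack, truth


# ---------------------------------------------------------------------------
# image-free feature-table sampling
# ---------------------------------------------------------------------------

@dataclass
class ClassFeatureParams:
    """Per-class Gaussian (location, scale) for each of the four features.

    Units: r and distAZ in nm, gv and GVSD in density-oriented intensity
    (electron-dense = numerically larger).  Negative draws of the
    intrinsically positive features are clipped at a small positive floor.
    """

    r: tuple[float, float]
    gv: tuple[float, float]
    GVSD: tuple[float, float]
    distAZ: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("r", "gv", "GVSD", "distAZ"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"scale of {name} must be positive")


#: class-conditional defaults reflecting the reported group contrasts:
#: DCVs larger (median inner radius ~15 vs ~9-10 nm), denser (higher gv),
#: lower central-slice contrast (GVSD) and further from the active zone.
DEFAULT_CLASS_PARAMS: dict[str, ClassFeatureParams] = {
    "C": ClassFeatureParams(r=(9.8, 1.8), gv=(128.2, 3.6),
                            GVSD=(6.3, 1.4), distAZ=(235.0, 105.0)),
    "D": ClassFeatureParams(r=(15.5, 2.4), gv=(135.5, 3.2),
                            GVSD=(4.2, 1.2), distAZ=(345.0, 125.0)),
}


def sample_feature_table(class_params: dict[str, ClassFeatureParams] | None = None,
                         n: int = 100, dcv_fraction: float = 0.12,
                         seed: int = 0, source: str = "synthetic") -> pd.DataFrame:
    """Draw a labeled feature table from a two-class Gaussian mixture.

    Returns a DataFrame in the standard layout (``r, gv, GVSD, distAZ,
    label``) with labels C/D, suitable as training or validation input.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = class_params or DEFAULT_CLASS_PARAMS
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(n) < dcv_fraction, "D", "C")
    cols: dict[str, np.ndarray] = {}
    for feat in ("r", "gv", "GVSD", "distAZ"):
        vals = np.empty(n)
        for code in ("C", "D"):
            mask = labels == code
            loc, scale = getattr(params[code], feat)
            vals[mask] = rng.normal(loc, scale, mask.sum())
        if feat in ("r", "GVSD", "distAZ"):
            vals = np.clip(vals, 1e-3, None)
        cols[feat] = vals
    table = pd.DataFrame(cols)
    table["label"] = labels
    table.attrs["source"] = source
    return table
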