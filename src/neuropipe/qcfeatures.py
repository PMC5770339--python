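"""The 190-feature T1 quality-control vector.

Features are computed from the subject's T1 volume together with the
segmentation products the pipeline already produced (brain mask, tissue
partial-volume maps, subcortical labels, lobe atlas, WMH mask, warp
magnitude, template alignment).  They cover 16 categories: discrepancy
from the template, SNR, tissue volumes, subcortical volumes (raw and
head-size normalised), subcortical and global asymmetry, normalised
subcortical intensities, grey matter outside the mask, tissue on the
mask border, tissue edge volumes (Canny), comparison with alternative
brain extractions, mask-border intensities, holes in grey/white matter,
warp-field magnitude, white-matter hyperintensities, and per-lobe
distance between the brain-mask border and the template border.

The extractor is manifest-driven: the shipped reference manifest fixes
an exact decomposition of the categories into 190 named features; other
decompositions can be loaded.  Missing features (empty structures,
absent inputs) are flagged as NaN, never silently zeroed.  All intensity
features are median-normalised or ratios, hence invariant to global
intensity scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature

from .phantom import BILATERAL_PAIRS, SUBCORTICAL_NAMES, PhantomBundle

__all__ = [
    "FeatureManifest",
    "QCFeatureVector",
    "default_manifest",
    "template_and_warp_features",
    "intensity_and_snr_features",
    "segmentation_volume_features",
    "mask_quality_features",
    "extract_all",
]

SNR_CAP = 1e6
TISSUES = ("csf", "gm", "wm")

CATEGORY_NAMES = {
    1: "template_discrepancy",
    2: "snr",
    3: "global_volumes",
    4: "subcortical_volumes",
    5: "subcortical_asymmetry",
    6: "global_asymmetry",
    7: "subcortical_intensity",
    8: "gm_outside_mask",
    9: "border_tissue",
    10: "canny_edges",
    11: "mask_comparison",
    12: "border_intensity",
    13: "holes",
    14: "warp_field",
    15: "wmh",
    16: "border_distance",
}


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    category: int
    units: str


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered list of 190 feature descriptors."""

    features: tuple[FeatureDescriptor, ...]

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        if len(names) != 190:
            raise ValueError(f"manifest must hold exactly 190 features, "
                             f"got {len(names)}")
        cats = {f.category for f in self.features}
        if cats != set(CATEGORY_NAMES):
            raise ValueError("every category 1-16 must be represented")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def to_json(self, path: str | Path) -> None:
        payload = [{"name": f.name, "category": f.category, "units": f.units}
                   for f in self.features]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureManifest":
        payload = json.loads(Path(path).read_text())
        return cls(tuple(FeatureDescriptor(d["name"], d["category"],
                                           d["units"]) for d in payload))


@dataclass
class QCFeatureVector:
    """190 values aligned to a manifest; NaN marks a flagged-missing value."""

    subject_id: str
    manifest: FeatureManifest
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.manifest),):
            raise ValueError("values must align with the manifest")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.manifest.names, self.values.tolist()))


def _structure_names() -> list[str]:
    return [SUBCORTICAL_NAMES[k] for k in sorted(SUBCORTICAL_NAMES)]


def default_manifest() -> FeatureManifest:
    """The reference 190-feature decomposition shipped with the toolkit."""
    feats: list[FeatureDescriptor] = []

    def add(name, cat, units=""):
        feats.append(FeatureDescriptor(name, cat, units))

    # 1. template discrepancy (12)
    add("template_ncc", 1)
    add("template_absdiff_global", 1)
    for r in range(1, 11):
        add(f"template_absdiff_lobe_{r}", 1)
    # 2. SNR (5)
    add("snr_background", 2)
    add("foreground_mean", 2, "intensity")
    add("foreground_std", 2, "intensity")
    add("cnr_gm_wm", 2)
    add("cnr_gm_csf", 2)
    # 3. global volumes (8)
    for n in ("brain_volume", "gm_volume", "wm_volume", "csf_volume",
              "ventricular_csf_volume", "peripheral_gm_volume",
              "head_size_proxy"):
        add(n, 3, "mm^3")
    add("gm_brain_ratio", 3)
    # 4. subcortical volumes, raw then normalised (15 + 15)
    for s in _structure_names():
        add(f"vol_{s}", 4, "mm^3")
    for s in _structure_names():
        add(f"vol_{s}_norm", 4)
    # 5. subcortical asymmetry (7)
    for pair, _, _ in BILATERAL_PAIRS:
        add(f"asym_{pair}", 5)
    # 6. global asymmetry (4)
    add("mirror_intensity_corr", 6)
    for t in TISSUES:
        add(f"lr_volume_ratio_{t}", 6)
    # 7. normalised subcortical intensity (45)
    for s in _structure_names():
        for stat in ("mean", "median", "iqr"):
            add(f"intensity_{stat}_{s}", 7)
    # 8. GM outside mask (2)
    add("gm_outside_volume", 8, "mm^3")
    add("gm_outside_fraction", 8)
    # 9. tissue on mask border (6)
    for t in TISSUES:
        add(f"border_pve_{t}_volume", 9, "mm^3")
        add(f"border_pve_{t}_fraction", 9)
    # 10. Canny tissue edges (6)
    for t in TISSUES:
        add(f"canny_{t}_count", 10, "voxels")
        add(f"canny_{t}_fraction", 10)
    # 11. comparison with alternative brain extractions (6)
    for slot in (1, 2):
        add(f"altmask{slot}_dice", 11)
        add(f"altmask{slot}_volume_ratio", 11)
        add(f"altmask{slot}_symdiff_volume", 11, "mm^3")
    # 12. mask border intensity (5)
    add("border_internal_mean", 12)
    add("border_internal_std", 12)
    add("border_external_mean", 12)
    add("border_external_std", 12)
    add("border_internal_external_ratio", 12)
    # 13. holes in GM/WM (4)
    add("gm_hole_volume", 13, "mm^3")
    add("gm_hole_count", 13)
    add("wm_hole_volume", 13, "mm^3")
    add("wm_hole_count", 13)
    # 14. warp magnitude (7)
    add("warp_mean", 14, "mm")
    add("warp_std", 14, "mm")
    add("warp_max", 14, "mm")
    add("warp_p95", 14, "mm")
    add("jacobian_proxy_min", 14)
    add("jacobian_proxy_max", 14)
    add("jacobian_proxy_negative_count", 14, "voxels")
    # 15. WMH (4)
    add("wmh_volume", 15, "mm^3")
    add("wmh_count", 15)
    add("wmh_periventricular_volume", 15, "mm^3")
    add("wmh_deep_volume", 15, "mm^3")
    # 16. border distance per atlas region (39)
    for r in range(1, 14):
        for stat in ("mean", "max", "std"):
            add(f"border_dist_{stat}_region_{r}", 16, "mm")

    return FeatureManifest(tuple(feats))


# ---------------------------------------------------------------------------
# helpers


def _median_normalised(t1: np.ndarray, mask: np.ndarray) -> np.ndarray:
    med = np.median(t1[mask])
    return t1 / med if med != 0 else t1.copy()


def _iqr(vals: np.ndarray) -> float:
    q1, q3 = np.percentile(vals, [25.0, 75.0])
    return float(q3 - q1)


def _border_shells(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-voxel internal and external border shells of a mask."""
    m = mask.astype(bool)
    internal = m & ~ndimage.binary_erosion(m)
    external = ndimage.binary_dilation(m) & ~m
    return internal, external


def _ventricular_csf_mask(bundle: PhantomBundle) -> np.ndarray:
    """Deep (ventricular) CSF: CSF partial volume well inside the mask."""
    deep = ndimage.binary_erosion(bundle.brain_mask, iterations=3)
    return (bundle.tissue_pves[0] > 0.5) & deep


# ---------------------------------------------------------------------------
# partial extractors


def template_and_warp_features(bundle: PhantomBundle) -> dict[str, float]:
    """Template discrepancy (12), warp magnitude (7) and per-region
    brain-border-to-template-border distances (39)."""
    out: dict[str, float] = {}
    t1, template = bundle.t1, bundle.template
    tmask = template > 0

    t1n = _median_normalised(t1, tmask)
    tpn = _median_normalised(template, tmask)
    a, b = t1n[tmask], tpn[tmask]
    if a.std() > 0 and b.std() > 0:
        out["template_ncc"] = float(np.corrcoef(a, b)[0, 1])
    else:
        out["template_ncc"] = np.nan
    diff = np.abs(t1n - tpn)
    out["template_absdiff_global"] = float(diff[tmask].mean())
    for r in range(1, 11):
        region = bundle.lobe_atlas == r
        out[f"template_absdiff_lobe_{r}"] = \
            float(diff[region].mean()) if region.any() else np.nan

    w = bundle.warp_magnitude
    brain = bundle.brain_mask
    wv = w[brain] if brain.any() else w.ravel()
    out["warp_mean"] = float(wv.mean())
    out["warp_std"] = float(wv.std())
    out["warp_max"] = float(wv.max())
    out["warp_p95"] = float(np.percentile(wv, 95.0))
    grads = np.gradient(w, *bundle.params.voxel_size)
    jac = 1.0 + sum(grads)
    out["jacobian_proxy_min"] = float(jac[brain].min()) if brain.any() else np.nan
    out["jacobian_proxy_max"] = float(jac[brain].max()) if brain.any() else np.nan
    out["jacobian_proxy_negative_count"] = float(np.count_nonzero(jac[brain] <= 0))

    # Distance from each subject mask-border voxel to the template border,
    # summarised per atlas region of the border voxel.
    t_border, _ = _border_shells(tmask)
    s_border, _ = _border_shells(brain)
    dist_to_template = ndimage.distance_transform_edt(
        ~t_border, sampling=bundle.params.voxel_size)
    for r in range(1, 14):
        sel = s_border & (bundle.lobe_atlas == r)
        if sel.any():
            d = dist_to_template[sel]
            out[f"border_dist_mean_region_{r}"] = float(d.mean())
            out[f"border_dist_max_region_{r}"] = float(d.max())
            out[f"border_dist_std_region_{r}"] = float(d.std())
        else:
            for stat in ("mean", "max", "std"):
                out[f"border_dist_{stat}_region_{r}"] = np.nan
    return out


def intensity_and_snr_features(bundle: PhantomBundle) -> dict[str, float]:
    """SNR (5), normalised subcortical intensities (45) and mask-border
    intensities (5)."""
    out: dict[str, float] = {}
    t1, brain = bundle.t1, bundle.brain_mask
    head = bundle.template > 0
    background = ~ndimage.binary_dilation(head, iterations=2)

    # All intensity-derived features are ratios (or median-normalised), so
    # they are invariant to a global intensity rescaling.
    norm = _median_normalised(t1, brain)
    fg = norm[brain]
    bg_std = float(norm[background].std()) if background.any() else 0.0
    out["foreground_mean"] = float(fg.mean())
    out["foreground_std"] = float(fg.std())
    pves = bundle.tissue_pves
    means = [float(norm[(pves[i] > 0.5) & brain].mean())
             if ((pves[i] > 0.5) & brain).any() else np.nan for i in range(3)]
    if bg_std > 0:
        out["snr_background"] = min(float(fg.mean()) / bg_std, SNR_CAP)
        out["cnr_gm_wm"] = min(abs(means[2] - means[1]) / bg_std, SNR_CAP)
        out["cnr_gm_csf"] = min(abs(means[1] - means[0]) / bg_std, SNR_CAP)
    else:  # zero background noise: SNR degenerate, capped at the maximum
        out["snr_background"] = SNR_CAP
        out["cnr_gm_wm"] = SNR_CAP
        out["cnr_gm_csf"] = SNR_CAP

    labels = bundle.subcortical_labels
    for lab, name in sorted(SUBCORTICAL_NAMES.items()):
        vals = norm[labels == lab]
        if vals.size:
            out[f"intensity_mean_{name}"] = float(vals.mean())
            out[f"intensity_median_{name}"] = float(np.median(vals))
            out[f"intensity_iqr_{name}"] = _iqr(vals)
        else:
            for stat in ("mean", "median", "iqr"):
                out[f"intensity_{stat}_{name}"] = np.nan

    internal, external = _border_shells(brain)
    int_vals = norm[internal] if internal.any() else np.array([np.nan])
    ext_vals = norm[external] if external.any() else np.array([np.nan])
    out["border_internal_mean"] = float(np.mean(int_vals))
    out["border_internal_std"] = float(np.std(int_vals))
    out["border_external_mean"] = float(np.mean(ext_vals))
    out["border_external_std"] = float(np.std(ext_vals))
    ext_mean = out["border_external_mean"]
    out["border_internal_external_ratio"] = \
        out["border_internal_mean"] / ext_mean if ext_mean else np.nan
    return out


def segmentation_volume_features(bundle: PhantomBundle) -> dict[str, float]:
    """Global and subcortical volumes (8 + 30), asymmetries (7 + 4) and
    WMH summaries (4)."""
    out: dict[str, float] = {}
    vv = bundle.voxel_volume
    pves, brain = bundle.tissue_pves, bundle.brain_mask
    labels = bundle.subcortical_labels

    csf_v, gm_v, wm_v = (float(pves[i].sum()) * vv for i in range(3))
    brain_v = float(np.count_nonzero(brain)) * vv
    out["brain_volume"] = brain_v
    out["gm_volume"] = gm_v
    out["wm_volume"] = wm_v
    out["csf_volume"] = csf_v
    vent = _ventricular_csf_mask(bundle)
    out["ventricular_csf_volume"] = float(pves[0][vent].sum()) * vv
    out["peripheral_gm_volume"] = float(pves[1][labels == 0].sum()) * vv
    if brain.any():
        idx = np.argwhere(brain)
        extent = (idx.max(axis=0) - idx.min(axis=0) + 1)
        out["head_size_proxy"] = float(np.prod(extent)) * vv
    else:
        out["head_size_proxy"] = np.nan
    out["gm_brain_ratio"] = gm_v / brain_v if brain_v else np.nan

    counts = {lab: int(np.count_nonzero(labels == lab))
              for lab in sorted(SUBCORTICAL_NAMES)}
    for lab, name in sorted(SUBCORTICAL_NAMES.items()):
        v = counts[lab] * vv
        out[f"vol_{name}"] = v if counts[lab] else np.nan
        out[f"vol_{name}_norm"] = v / brain_v if brain_v and counts[lab] else np.nan

    for pair, left, right in BILATERAL_PAIRS:
        vl, vr = counts[left], counts[right]
        out[f"asym_{pair}"] = abs(np.log(vl / vr)) if vl and vr else np.nan

    flipped_t1 = bundle.t1[::-1]
    both = brain & brain[::-1]
    if both.any() and bundle.t1[both].std() > 0:
        out["mirror_intensity_corr"] = float(
            np.corrcoef(bundle.t1[both], flipped_t1[both])[0, 1])
    else:
        out["mirror_intensity_corr"] = np.nan
    nx = bundle.t1.shape[0]
    left_half = np.zeros_like(brain)
    left_half[: nx // 2] = True
    for i, t in enumerate(TISSUES):
        lv = float(pves[i][left_half].sum())
        rv = float(pves[i][~left_half].sum())
        out[f"lr_volume_ratio_{t}"] = lv / rv if rv else np.nan

    wmh = bundle.wmh_mask.astype(bool)
    out["wmh_volume"] = float(np.count_nonzero(wmh)) * vv
    _, n_comp = ndimage.label(wmh)
    out["wmh_count"] = float(n_comp)
    if wmh.any() and vent.any():
        dist_to_vent = ndimage.distance_transform_edt(
            ~vent, sampling=bundle.params.voxel_size)
        peri = wmh & (dist_to_vent <= 10.0)
        out["wmh_periventricular_volume"] = float(np.count_nonzero(peri)) * vv
        out["wmh_deep_volume"] = float(np.count_nonzero(wmh & ~peri)) * vv
    else:
        out["wmh_periventricular_volume"] = 0.0
        out["wmh_deep_volume"] = 0.0
    return out


def mask_quality_features(bundle: PhantomBundle,
                          alt_masks: list[np.ndarray] | None = None
                          ) -> dict[str, float]:
    """GM outside the mask (2), tissue on the border (6), Canny tissue
    edges (6), alternative-extraction comparison (6), GM/WM holes (4)."""
    out: dict[str, float] = {}
    if alt_masks is None:
        alt_masks = bundle.alt_masks
    pves, brain, vv = bundle.tissue_pves, bundle.brain_mask, bundle.voxel_volume

    gm_total = float(pves[1].sum())
    gm_out = float(pves[1][~brain].sum())
    out["gm_outside_volume"] = gm_out * vv
    out["gm_outside_fraction"] = gm_out / gm_total if gm_total else np.nan

    internal, external = _border_shells(brain)
    for i, t in enumerate(TISSUES):
        s = float(pves[i][internal].sum())
        total = float(pves[i].sum())
        out[f"border_pve_{t}_volume"] = s * vv
        out[f"border_pve_{t}_fraction"] = s / total if total else np.nan

    # Canny edges of the T1, assigned per tissue, excluding the brain-mask
    # border shell.  2D detector applied slice-wise (axial planes).
    t1 = _median_normalised(bundle.t1, brain) if brain.any() else bundle.t1
    edges = np.zeros(t1.shape, dtype=bool)
    for k in range(t1.shape[2]):
        sl = t1[:, :, k]
        if sl.std() > 0:
            edges[:, :, k] = skfeature.canny(sl, sigma=1.0,
                                             low_threshold=0.1,
                                             high_threshold=0.2,
                                             use_quantiles=False)
    excluded = internal | external
    for i, t in enumerate(TISSUES):
        tissue = (pves[i] > 0.5) & ~excluded
        cnt = float(np.count_nonzero(edges & tissue))
        n_tissue = float(np.count_nonzero(tissue))
        out[f"canny_{t}_count"] = cnt
        out[f"canny_{t}_fraction"] = cnt / n_tissue if n_tissue else np.nan

    n_brain = float(np.count_nonzero(brain))
    for slot in (1, 2):
        if len(alt_masks) >= slot:
            alt = alt_masks[slot - 1].astype(bool)
            inter = float(np.count_nonzero(alt & brain))
            n_alt = float(np.count_nonzero(alt))
            denom = n_alt + n_brain
            out[f"altmask{slot}_dice"] = 2 * inter / denom if denom else np.nan
            out[f"altmask{slot}_volume_ratio"] = \
                n_alt / n_brain if n_brain else np.nan
            out[f"altmask{slot}_symdiff_volume"] = \
                float(np.count_nonzero(alt ^ brain)) * vv
        else:
            out[f"altmask{slot}_dice"] = np.nan
            out[f"altmask{slot}_volume_ratio"] = np.nan
            out[f"altmask{slot}_symdiff_volume"] = np.nan

    # Holes: non-tissue voxels strictly inside the brain, attributed to the
    # tissue that surrounds them.
    non_tissue = brain & (pves.sum(axis=0) < 0.5)
    comp, n_comp = ndimage.label(non_tissue)
    stats = {"gm": [0.0, 0], "wm": [0.0, 0]}
    for c in range(1, n_comp + 1):
        hole = comp == c
        ring = ndimage.binary_dilation(hole) & ~hole
        gm_n = int(np.count_nonzero(pves[1][ring] > 0.5))
        wm_n = int(np.count_nonzero(pves[2][ring] > 0.5))
        if gm_n == 0 and wm_n == 0:
            continue
        key = "wm" if wm_n >= gm_n else "gm"
        stats[key][0] += float(np.count_nonzero(hole)) * vv
        stats[key][1] += 1
    out["gm_hole_volume"], out["gm_hole_count"] = \
        stats["gm"][0], float(stats["gm"][1])
    out["wm_hole_volume"], out["wm_hole_count"] = \
        stats["wm"][0], float(stats["wm"][1])
    return out


def extract_all(bundle: PhantomBundle,
                manifest: FeatureManifest | None = None,
                subject_id: str = "phantom") -> QCFeatureVector:
    """Compute the full 190-value feature vector in manifest order.

    Raises if any manifest name is not produced by the extractors;
    features whose inputs are degenerate come back NaN (flagged missing).
    """
    if manifest is None:
        manifest = default_manifest()
    computed: dict[str, float] = {}
    computed.update(template_and_warp_features(bundle))
    computed.update(intensity_and_snr_features(bundle))
    computed.update(segmentation_volume_features(bundle))
    computed.update(mask_quality_features(bundle))

    missing = [n for n in manifest.names if n not in computed]
    if missing:
        raise KeyError(f"extractors produced no value for: {missing}")
    values = np.array([computed[n] for n in manifest.names], dtype=float)
    return QCFeatureVector(subject_id=subject_id, manifest=manifest,
                           values=values)
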