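"""Synthetic brain-MRI phantom generation.

Every downstream stage of the toolkit (conformance checking, defacing,
bias-field transfer, susceptibility-weighted processing, fieldmap b=0
selection, network-matrix estimation and the T1 quality-control system)
is exercised on phantoms produced here, with known ground truth.

The anatomy is parametric: nested ellipsoids for CSF / grey matter /
white matter, two ventricular CSF ellipsoids, and 15 subcortical grey
structures (brainstem plus 7 left/right pairs).  The phantom is built
bilaterally symmetric about the mid-sagittal plane so that asymmetry
features have an exact null.  "Standard space" is the clean phantom's
own grid; the affine to standard defaults to identity.

Artifact injection follows a coded taxonomy of problems (0-10) and
imperfections (1-7) seen in large-cohort structural imaging: bad FOV,
motion ringing, bias/contrast problems, atypical anatomy (lesions,
enlarged ventricles) and brain-mask failures.  Severity in [0, 1] maps
linearly onto the corruption magnitude of each code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomParams",
    "PhantomBundle",
    "ArtifactSpec",
    "SwmriAcquisition",
    "B0Series",
    "GroupFmriDataset",
    "PROBLEM_CODES",
    "IMPERFECTION_CODES",
    "SUBCORTICAL_NAMES",
    "BILATERAL_PAIRS",
    "generate_t1_bundle",
    "inject_artifact",
    "generate_swmri",
    "generate_b0_series",
    "generate_fmri_group",
    "smooth_random_field",
    "default_t2star_truth",
]

# Tissue reference intensities for the T1 contrast (CSF < GM < WM).
CSF_INTENSITY = 30.0
GM_INTENSITY = 60.0
WM_INTENSITY = 90.0

# Problem / imperfection enumerations for T1 QC.
PROBLEM_CODES = {
    0: "No problem",
    1: "Multiple/Unknown problems",
    2: "Missing or incomplete modality",
    3: "Bad FOV",
    4: "Bad registration: Bad head motion/Noise",
    5: "Bad registration: Structurally atypical: Important lesions",
    6: "Bad registration: Structurally atypical: Big Ventricles",
    7: "Bad registration: General Registration failure",
    8: "Bad registration: Bad brain mask on the top",
    9: "Bad registration: Bad brain mask on the temporal lobe",
    10: "Bad registration: Brain mask out of the brain",
}

IMPERFECTION_CODES = {
    1: "Multiple/Unknown imperfections",
    2: "Bad head movement",
    3: "Movement-related ringing/blurring",
    4: "Bias field/contrast problem",
    5: "Structurally atypical",
    6: "Problem on top (brain mask)",
    7: "Problem on temp. lobe (brain mask)",
}

# Label 0 is background.  15 structures: brainstem + 7 bilateral pairs.
SUBCORTICAL_NAMES = {
    1: "brainstem",
    2: "thalamus_left",
    3: "thalamus_right",
    4: "caudate_left",
    5: "caudate_right",
    6: "putamen_left",
    7: "putamen_right",
    8: "pallidum_left",
    9: "pallidum_right",
    10: "hippocampus_left",
    11: "hippocampus_right",
    12: "amygdala_left",
    13: "amygdala_right",
    14: "accumbens_left",
    15: "accumbens_right",
}

# (name, left label, right label) for asymmetry features.
BILATERAL_PAIRS = [
    ("thalamus", 2, 3),
    ("caudate", 4, 5),
    ("putamen", 6, 7),
    ("pallidum", 8, 9),
    ("hippocampus", 10, 11),
    ("amygdala", 12, 13),
    ("accumbens", 14, 15),
]


class PhantomConfigError(ValueError):
    """Raised for invalid phantom parameters."""


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the structural phantom.

    ``shape`` is the voxel grid, ``voxel_size`` the voxel edge lengths in
    mm.  ``brain_radii`` are the outer ellipsoid semi-axes in mm; the grey
    and white matter compartments are concentric shells at fixed fractions
    of the outer radius.  ``bias_amplitude`` is the peak deviation of the
    multiplicative bias field from 1, ``noise_sigma`` the additive Gaussian
    noise standard deviation in intensity units.
    """

    shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    brain_radii: tuple[float, float, float] = (58.0, 72.0, 56.0)
    gm_fraction: float = 0.92     # r/R below which tissue stops being CSF
    wm_fraction: float = 0.75     # r/R below which tissue is white matter
    ventricle_scale: float = 1.0  # multiplies ventricle ellipsoid radii
    bias_amplitude: float = 0.05
    noise_sigma: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 32 for n in self.shape):
            raise PhantomConfigError(
                f"grid shape must be 3 axes of >= 32 voxels, got {self.shape}"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise PhantomConfigError("voxel size must be positive")
        if self.noise_sigma < 0:
            raise PhantomConfigError("noise sigma must be >= 0")
        if self.bias_amplitude < 0:
            raise PhantomConfigError("bias amplitude must be >= 0")
        if not (0 < self.wm_fraction < self.gm_fraction <= 1.0):
            raise PhantomConfigError("need 0 < wm_fraction < gm_fraction <= 1")

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world (RAS+ mm) affine, world origin at grid centre."""
        aff = np.eye(4)
        for a in range(3):
            aff[a, a] = self.voxel_size[a]
            aff[a, 3] = -(self.shape[a] - 1) / 2.0 * self.voxel_size[a]
        return aff


@dataclass
class ArtifactSpec:
    """One coded corruption: kind 'problem' or 'imperfection', Table code,
    severity in [0, 1] mapping linearly to corruption magnitude."""

    kind: str
    code: int
    severity: float = 1.0

    def validate(self) -> None:
        if self.kind == "problem":
            table = PROBLEM_CODES
        elif self.kind == "imperfection":
            table = IMPERFECTION_CODES
        else:
            raise ValueError(
                f"artifact kind must be 'problem' or 'imperfection', got {self.kind!r}"
            )
        if self.code not in table:
            raise ValueError(
                f"unknown {self.kind} code {self.code}; valid codes: "
                + ", ".join(f"{k} = {v}" for k, v in table.items())
            )
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError("severity must be in [0, 1]")


@dataclass
class PhantomBundle:
    """A synthetic subject with every volume the downstream stages consume."""

    params: PhantomParams
    t1: np.ndarray                 # 3D intensity volume
    template: np.ndarray           # clean intensity volume in "standard" space
    affine_to_standard: np.ndarray  # 4x4, native -> standard (world mm)
    warp_magnitude: np.ndarray     # 3D |warp| field, mm
    brain_mask: np.ndarray         # bool
    tissue_pves: np.ndarray        # (3, *shape): CSF, GM, WM in [0, 1]
    subcortical_labels: np.ndarray  # int, 0..15
    lobe_atlas: np.ndarray         # int, 0..13
    wmh_mask: np.ndarray           # bool
    bias_field: np.ndarray         # multiplicative field applied to t1
    alt_masks: list[np.ndarray] = field(default_factory=list)
    truth_record: list[dict] = field(default_factory=list)

    @property
    def affine(self) -> np.ndarray:
        return self.params.affine

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.params.voxel_size))

    def copy(self) -> "PhantomBundle":
        return PhantomBundle(
            params=self.params,
            t1=self.t1.copy(),
            template=self.template.copy(),
            affine_to_standard=self.affine_to_standard.copy(),
            warp_magnitude=self.warp_magnitude.copy(),
            brain_mask=self.brain_mask.copy(),
            tissue_pves=self.tissue_pves.copy(),
            subcortical_labels=self.subcortical_labels.copy(),
            lobe_atlas=self.lobe_atlas.copy(),
            wmh_mask=self.wmh_mask.copy(),
            bias_field=self.bias_field.copy(),
            alt_masks=[m.copy() for m in self.alt_masks],
            truth_record=[dict(r) for r in self.truth_record],
        )


def _world_grid(params: PhantomParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World-mm coordinate arrays (broadcastable) for each voxel centre."""
    coords = []
    for a in range(3):
        n, v = params.shape[a], params.voxel_size[a]
        c = (np.arange(n) - (n - 1) / 2.0) * v
        shape = [1, 1, 1]
        shape[a] = n
        coords.append(c.reshape(shape))
    return tuple(coords)


def _ellipsoid(params: PhantomParams, center: Sequence[float],
               radii: Sequence[float]) -> np.ndarray:
    x, y, z = _world_grid(params)
    d = ((x - center[0]) / radii[0]) ** 2 \
        + ((y - center[1]) / radii[1]) ** 2 \
        + ((z - center[2]) / radii[2]) ** 2
    return d <= 1.0


def smooth_random_field(shape: Sequence[int], rng: np.random.Generator,
                        smooth_vox: float = 8.0) -> np.ndarray:
    """Smooth zero-mean random field normalised to max |value| = 1."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_vox)
    f -= f.mean()
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return f


# Subcortical geometry: (label, centre-x [mirrored for pairs], y, z, radii mm)
_SUBCORTICAL_GEOM = [
    (1, 0.0, -10.0, -34.0, (9.0, 9.0, 16.0)),   # brainstem (midline)
    (2, -10.0, -12.0, 2.0, (6.0, 8.0, 6.0)),    # thalamus
    (4, -12.0, 6.0, 10.0, (4.0, 9.0, 4.0)),     # caudate
    (6, -24.0, 2.0, 0.0, (5.0, 9.0, 5.0)),      # putamen
    (8, -16.5, 0.0, -6.0, (3.0, 5.0, 3.5)),     # pallidum
    (10, -27.0, -20.0, -12.0, (5.0, 10.0, 5.0)),  # hippocampus
    (12, -24.0, -4.0, -16.0, (4.0, 5.0, 4.0)),  # amygdala
    (14, -8.0, 12.0, -7.0, (3.0, 4.0, 3.2)),    # accumbens
]

_VENTRICLE_GEOM = [(-7.0, 0.0, 11.0, (4.5, 18.0, 6.0)),
                   (7.0, 0.0, 11.0, (4.5, 18.0, 6.0))]


def _build_anatomy(params: PhantomParams) -> dict:
    """Deterministic noiseless anatomy: masks, labels, pves, atlas."""
    x, y, z = _world_grid(params)
    rx, ry, rz = params.brain_radii
    rnorm = np.sqrt((x / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2)
    brain = rnorm <= 1.0

    tissue = np.zeros(params.shape, dtype=np.int8)  # 0 bg, 1 CSF, 2 GM, 3 WM
    tissue[brain] = 1
    tissue[rnorm <= params.gm_fraction] = 2
    tissue[rnorm <= params.wm_fraction] = 3

    # Ventricles: CSF islands inside the white matter.
    ventricles = np.zeros(params.shape, dtype=bool)
    for cx, cy, cz, radii in _VENTRICLE_GEOM:
        r = tuple(np.asarray(radii) * params.ventricle_scale)
        ventricles |= _ellipsoid(params, (cx, cy, cz), r)
    ventricles &= brain
    tissue[ventricles] = 1

    # Subcortical grey structures; painted last so they are GM islands.
    labels = np.zeros(params.shape, dtype=np.int16)
    for lab, cx, cy, cz, radii in _SUBCORTICAL_GEOM:
        if cx == 0.0:
            spots = [(lab, (cx, cy, cz))]
        else:
            spots = [(lab, (cx, cy, cz)), (lab + 1, (-cx, cy, cz))]
        for this_lab, centre in spots:
            m = _ellipsoid(params, centre, radii) & brain & (labels == 0) \
                & ~ventricles
            labels[m] = this_lab
    tissue[labels > 0] = 2

    pves = np.zeros((3,) + params.shape, dtype=np.float64)
    for i in range(3):
        pves[i] = (tissue == i + 1).astype(np.float64)

    # Lobe atlas: 13 regions.  Regions 1-12: hemisphere x 3 y-bands x 2
    # z-bands of the cortex; region 13: the deep central zone (|x| < 12 mm).
    atlas = np.zeros(params.shape, dtype=np.int16)
    central = (np.abs(x) < 12.0) & brain
    yb = np.digitize(np.broadcast_to(y, params.shape),
                     [-ry / 3.0, ry / 3.0])          # 0, 1, 2
    zb = (np.broadcast_to(z, params.shape) >= 0).astype(int)
    hemi = (np.broadcast_to(x, params.shape) >= 0).astype(int)
    region = 1 + hemi * 6 + yb * 2 + zb
    atlas[brain] = region[brain]
    atlas[central] = 13

    intensity = np.zeros(params.shape)
    intensity[tissue == 1] = CSF_INTENSITY
    intensity[tissue == 2] = GM_INTENSITY
    intensity[tissue == 3] = WM_INTENSITY

    return {
        "brain": brain,
        "ventricles": ventricles,
        "labels": labels,
        "pves": pves,
        "atlas": atlas,
        "intensity": intensity,
    }


def generate_t1_bundle(params: PhantomParams | None = None) -> PhantomBundle:
    """Generate a clean structural phantom bundle.

    The returned bundle is deterministic for a fixed seed, bilaterally
    symmetric up to noise, and has tissue intensity means ordered
    CSF < GM < WM.  The template is the noiseless, bias-free intensity
    volume; the affine to standard is the identity.
    """
    if params is None:
        params = PhantomParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    anat = _build_anatomy(params)
    template = anat["intensity"]

    bias = 1.0 + params.bias_amplitude * smooth_random_field(params.shape, rng)
    t1 = template * bias
    if params.noise_sigma > 0:
        t1 = t1 + params.noise_sigma * rng.standard_normal(params.shape)

    # Residual-registration warp-magnitude stand-in: small, smooth, >= 0.
    warp = 0.5 * np.abs(smooth_random_field(params.shape, rng)) \
        * anat["brain"].astype(float)

    brain = anat["brain"]
    alt_masks = [
        ndimage.binary_dilation(brain, iterations=1),
        ndimage.binary_erosion(brain, iterations=1),
    ]

    return PhantomBundle(
        params=params,
        t1=t1,
        template=template,
        affine_to_standard=np.eye(4),
        warp_magnitude=warp,
        brain_mask=brain,
        tissue_pves=anat["pves"],
        subcortical_labels=anat["labels"],
        lobe_atlas=anat["atlas"],
        wmh_mask=np.zeros(params.shape, dtype=bool),
        bias_field=bias,
        alt_masks=alt_masks,
        truth_record=[],
    )


# ---------------------------------------------------------------------------
# Artifact injection


def _inject_ringing(b: PhantomBundle, amount: float,
                    rng: np.random.Generator) -> None:
    """Motion ghosting: perturb the phase of k-space lines along y."""
    if amount <= 0:
        return
    k = np.fft.fft(b.t1, axis=1)
    ny = b.t1.shape[1]
    n_lines = max(1, int(round(amount * 0.3 * ny)))
    lines = rng.choice(ny, size=n_lines, replace=False)
    phases = rng.uniform(-np.pi, np.pi, size=n_lines) * amount
    k[:, lines, :] *= np.exp(1j * phases)[None, :, None]
    b.t1 = np.fft.ifft(k, axis=1).real


def _inject_bias(b: PhantomBundle, amount: float,
                 rng: np.random.Generator) -> None:
    extra = 1.0 + 0.6 * amount * smooth_random_field(b.t1.shape, rng)
    b.t1 = b.t1 * extra
    b.bias_field = b.bias_field * extra


def _inject_fov_cut(b: PhantomBundle, amount: float) -> None:
    """Truncate the superior end of the FOV across all acquired volumes."""
    nz = b.t1.shape[2]
    cut = max(1, int(round(amount * 0.3 * nz)))
    sl = (slice(None), slice(None), slice(nz - cut, nz))
    b.t1[sl] = 0.0
    b.brain_mask[sl] = False
    b.tissue_pves[(slice(None),) + sl] = 0.0
    b.subcortical_labels[sl] = 0
    b.lobe_atlas[sl] = 0
    for m in b.alt_masks:
        m[sl] = False


def _inject_big_ventricles(b: PhantomBundle, amount: float) -> None:
    """Enlarge ventricles; CSF volume strictly grows for amount > 0."""
    scale = 1.0 + 1.2 * amount
    grown = np.zeros(b.t1.shape, dtype=bool)
    for cx, cy, cz, radii in _VENTRICLE_GEOM:
        r = tuple(np.asarray(radii) * b.params.ventricle_scale * scale)
        grown |= _ellipsoid(b.params, (cx, cy, cz), r)
    grown &= b.brain_mask
    new_csf = grown & (b.tissue_pves[0] < 1.0)
    b.tissue_pves[0][grown] = 1.0
    b.tissue_pves[1][grown] = 0.0
    b.tissue_pves[2][grown] = 0.0
    b.subcortical_labels[grown] = 0
    b.t1[new_csf] = CSF_INTENSITY * b.bias_field[new_csf]


def _inject_lesions(b: PhantomBundle, amount: float,
                    rng: np.random.Generator) -> None:
    """Insert WM lesions (FLAIR-bright / T1-dark blobs) into white matter."""
    n = 1 + int(round(amount * 4))
    wm = b.tissue_pves[2] > 0.5
    idx = np.argwhere(wm)
    if len(idx) == 0:
        return
    for _ in range(n):
        c = idx[rng.integers(len(idx))]
        r_vox = 1 + amount * 2.0
        gx, gy, gz = np.ogrid[:b.t1.shape[0], :b.t1.shape[1], :b.t1.shape[2]]
        blob = ((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) \
            <= r_vox ** 2
        blob &= wm
        b.wmh_mask |= blob
        b.t1[blob] = (WM_INTENSITY - amount * 40.0) * b.bias_field[blob]


def _inject_mask_top(b: PhantomBundle, amount: float) -> None:
    """Spurious brain-mask protrusion above the vertex."""
    it = 1 + int(round(amount * 3))
    nz = b.t1.shape[2]
    top = np.zeros_like(b.brain_mask)
    top[:, :, int(0.6 * nz):] = True
    grown = ndimage.binary_dilation(b.brain_mask, iterations=it) & top
    b.brain_mask |= grown


def _inject_mask_temporal(b: PhantomBundle, amount: float) -> None:
    """Erode the mask in the inferior-lateral (temporal) zones."""
    it = 1 + int(round(amount * 2))
    x, _, z = _world_grid(b.params)
    zone = np.broadcast_to((np.abs(x) > 0.5 * b.params.brain_radii[0])
                           & (z < 0), b.t1.shape)
    eroded = ndimage.binary_erosion(b.brain_mask, iterations=it)
    b.brain_mask = np.where(zone, eroded, b.brain_mask)


def _inject_mask_shift(b: PhantomBundle, amount: float) -> None:
    """Translate the brain mask off the brain (registration failure)."""
    shift = max(1, int(round(amount * 6)))
    b.brain_mask = np.roll(b.brain_mask, shift, axis=1)
    b.brain_mask[:, :shift, :] = False


# code -> (function name, severity multiplier)
_PROBLEM_ACTIONS = {
    0: [],
    1: [("ringing", 1.0), ("bias", 1.0)],
    2: [("fov", 1.0)],
    3: [("fov", 1.0)],
    4: [("ringing", 1.0)],
    5: [("lesions", 1.0)],
    6: [("ventricles", 1.0)],
    7: [("mask_shift", 1.0)],
    8: [("mask_top", 1.0)],
    9: [("mask_temporal", 1.0)],
    10: [("mask_shift", 1.5)],
}

_IMPERFECTION_ACTIONS = {
    1: [("ringing", 0.5), ("bias", 0.5)],
    2: [("ringing", 0.5)],
    3: [("ringing", 0.7)],
    4: [("bias", 1.0)],
    5: [("lesions", 0.5)],
    6: [("mask_top", 0.5)],
    7: [("mask_temporal", 0.5)],
}


def inject_artifact(bundle: PhantomBundle, spec: ArtifactSpec,
                    seed: int = 0) -> PhantomBundle:
    """Return a corrupted copy of ``bundle``; the truth record is appended.

    Severity 0 (and problem code 0) leave the data untouched apart from
    the record.  The mapping from code to corruption is linear in
    severity and documented per injector.
    """
    spec.validate()
    out = bundle.copy()
    out.truth_record.append(
        {"kind": spec.kind, "code": spec.code, "severity": spec.severity}
    )
    if spec.severity == 0.0:
        return out

    actions = (_PROBLEM_ACTIONS if spec.kind == "problem"
               else _IMPERFECTION_ACTIONS)[spec.code]
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, spec.code, hash(spec.kind) & 0xFFFF]))
    for name, mult in actions:
        amt = min(1.0, spec.severity * mult)
        if name == "ringing":
            _inject_ringing(out, amt, rng)
        elif name == "bias":
            _inject_bias(out, amt, rng)
        elif name == "fov":
            _inject_fov_cut(out, amt)
        elif name == "ventricles":
            _inject_big_ventricles(out, amt)
        elif name == "lesions":
            _inject_lesions(out, amt, rng)
        elif name == "mask_top":
            _inject_mask_top(out, amt)
        elif name == "mask_temporal":
            _inject_mask_temporal(out, amt)
        elif name == "mask_shift":
            _inject_mask_shift(out, amt)
    return out


# ---------------------------------------------------------------------------
# swMRI acquisition simulation


@dataclass
class SwmriAcquisition:
    """Per-coil complex two-echo gradient-echo data.

    ``data[coil][echo]`` is a complex 3D image; echo times in ms.
    """

    data: list[list[np.ndarray]]
    te1: float = 9.4
    te2: float = 20.0

    @property
    def n_coils(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        if not (0 < self.te1 < self.te2):
            raise ValueError("need te2 > te1 > 0")
        shapes = {d.shape for coil in self.data for d in coil}
        if len(shapes) != 1:
            raise ValueError("all coil images must share one grid")


def default_t2star_truth(shape: Sequence[int],
                         vein_t2star: float = 10.6) -> tuple[np.ndarray, np.ndarray]:
    """A simple T2* ground-truth map (ms) plus a vein mask.

    Tissue T2* 50 ms inside a central ellipsoid, deep nucleus at 25 ms,
    a few vein line segments at ``vein_t2star``; 0 outside (no signal).
    """
    shape = tuple(shape)
    gx, gy, gz = np.ogrid[:shape[0], :shape[1], :shape[2]]
    c = [(n - 1) / 2.0 for n in shape]
    r = [0.4 * n for n in shape]
    tissue = ((gx - c[0]) / r[0]) ** 2 + ((gy - c[1]) / r[1]) ** 2 \
        + ((gz - c[2]) / r[2]) ** 2 <= 1.0
    t2 = np.where(tissue, 50.0, 0.0)
    nucleus = ((gx - c[0]) / (0.12 * shape[0])) ** 2 \
        + ((gy - c[1]) / (0.12 * shape[1])) ** 2 \
        + ((gz - c[2]) / (0.12 * shape[2])) ** 2 <= 1.0
    t2[nucleus & tissue] = 25.0

    veins = np.zeros(shape, dtype=bool)
    zc = int(c[2])
    for frac in (0.35, 0.5, 0.65):
        xi = int(frac * shape[0])
        veins[xi, int(0.3 * shape[1]):int(0.7 * shape[1]), zc] = True
    veins &= tissue
    t2[veins] = vein_t2star
    return t2, veins


def generate_swmri(t2star_truth: np.ndarray, vein_mask: np.ndarray,
                   n_coils: int = 4, seed: int = 0,
                   te1: float = 9.4, te2: float = 20.0,
                   vein_phase: float = 1.0, s0: float = 100.0,
                   noise_sigma: float = 0.0) -> SwmriAcquisition:
    """Simulate per-coil two-echo complex swMRI data.

    Magnitude decays as ``s0 * exp(-TE / T2*)``; each coil carries a smooth
    low-frequency phase offset (its receive phase profile), and voxels in
    ``vein_mask`` carry an additional TE-proportional paramagnetic phase
    (positive sign convention) of ``vein_phase`` radians at the second echo.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    t2 = np.asarray(t2star_truth, dtype=float)
    signal = t2 > 0
    if np.any(t2[signal] <= 0):
        raise ValueError("t2star truth must be positive where signal exists")
    rng = np.random.default_rng(seed)

    data: list[list[np.ndarray]] = []
    for _ in range(n_coils):
        coil_phase = np.pi * smooth_random_field(t2.shape, rng, smooth_vox=10.0)
        sens = 1.0 + 0.3 * smooth_random_field(t2.shape, rng, smooth_vox=10.0)
        echoes = []
        for te in (te1, te2):
            mag = np.zeros_like(t2)
            mag[signal] = s0 * sens[signal] * np.exp(-te / t2[signal])
            tissue_phase = np.where(vein_mask, vein_phase * te / te2, 0.0)
            img = mag * np.exp(1j * (coil_phase + tissue_phase))
            if noise_sigma > 0:
                img = img + noise_sigma * (
                    rng.standard_normal(t2.shape)
                    + 1j * rng.standard_normal(t2.shape))
            echoes.append(img)
        data.append(echoes)
    acq = SwmriAcquisition(data=data, te1=te1, te2=te2)
    acq.validate()
    return acq


# ---------------------------------------------------------------------------
# b=0 series simulation


@dataclass
class B0Series:
    """AP/PA b=0 volumes sharing one anatomy, with planted best indices."""

    ap: list[np.ndarray]
    pa: list[np.ndarray]
    truth_ap: int
    truth_pa: int


def _b0_base(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    base = ndimage.gaussian_filter(rng.standard_normal(shape), 3.0)
    base -= base.min()
    return base / base.max() * 100.0


def generate_b0_series(n_ap: int = 5, n_pa: int = 3,
                       motion_scale: float = 1.0, noise_sigma: float = 1.0,
                       planted_best_ap: int = 0, planted_best_pa: int = 0,
                       seed: int = 0,
                       shape: tuple[int, int, int] = (32, 32, 32)) -> B0Series:
    """Simulate interspersed b=0 volumes with one least-perturbed volume.

    All volumes share the same anatomy; every volume except the planted
    best index receives a random sub-voxel shift scaled by
    ``motion_scale`` plus additive noise.  The planted index receives no
    shift and one-fifth of the noise, so it has the smallest perturbation.
    """
    if n_ap < 2:
        raise ValueError("need n_ap >= 2")
    rng = np.random.default_rng(seed)
    base = _b0_base(shape, rng)

    def series(n: int, planted: int) -> list[np.ndarray]:
        vols = []
        for i in range(n):
            if i == planted:
                v = base + 0.2 * noise_sigma * rng.standard_normal(shape)
            else:
                shift = motion_scale * rng.uniform(-1.5, 1.5, size=3)
                v = ndimage.shift(base, shift, order=1, mode="nearest")
                v = v + noise_sigma * rng.standard_normal(shape)
            vols.append(v)
        return vols

    return B0Series(ap=series(n_ap, planted_best_ap),
                    pa=series(n_pa, planted_best_pa),
                    truth_ap=planted_best_ap, truth_pa=planted_best_pa)


# ---------------------------------------------------------------------------
# Group fMRI simulation


@dataclass
class GroupFmriDataset:
    """Group resting-fMRI data with known network ground truth.

    ``maps`` is (n_maps, V); ``subject_data`` a list of (T, V) arrays;
    ``subject_ts`` the true node timeseries used to build each dataset;
    ``truth_correlation`` the node correlation implied by the generating
    precision matrix; ``artifact_node_ids`` the 0-based structured-noise
    nodes.
    """

    maps: np.ndarray
    subject_data: list[np.ndarray]
    subject_ts: list[np.ndarray]
    truth_precision: np.ndarray
    truth_correlation: np.ndarray
    artifact_node_ids: list[int]
    tr: float = 0.735


def generate_fmri_group(n_subjects: int, n_maps: int, n_timepoints: int,
                        truth_precision: np.ndarray,
                        artifact_node_ids: Sequence[int] = (),
                        seed: int = 0, n_voxels: int = 600,
                        noise_sigma: float = 0.0,
                        orthonormal_maps: bool = False,
                        tr: float = 0.735) -> GroupFmriDataset:
    """Simulate a group of 4D-equivalent (T x V) fMRI datasets.

    Node timeseries are drawn from the zero-mean multivariate Gaussian
    with covariance ``inv(truth_precision)``; artifact nodes are replaced
    with structured noise (a drifting sinusoid plus AR(1) noise) that is
    independent of the network.  Data = timeseries @ maps + white noise.
    """
    P = np.asarray(truth_precision, dtype=float)
    if P.shape != (n_maps, n_maps) or not np.allclose(P, P.T):
        raise ValueError("truth precision must be symmetric n_maps x n_maps")
    w = np.linalg.eigvalsh(P)
    if w.min() <= 0:
        raise ValueError("truth precision must be positive definite")
    cov = np.linalg.inv(P)
    d = np.sqrt(np.diag(cov))
    truth_corr = cov / np.outer(d, d)
    L = np.linalg.cholesky(cov)

    rng = np.random.default_rng(seed)
    maps = ndimage.gaussian_filter1d(
        rng.standard_normal((n_maps, n_voxels)), 3.0, axis=1)
    if orthonormal_maps:
        # Orthonormal rows via QR on the transpose.
        q, _ = np.linalg.qr(maps.T)
        maps = q[:, :n_maps].T
    else:
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)

    artifact_node_ids = sorted(int(i) for i in artifact_node_ids)
    if any(i < 0 or i >= n_maps for i in artifact_node_ids):
        raise ValueError("artifact node ids out of range")

    subject_data, subject_ts = [], []
    t = np.arange(n_timepoints)
    for _ in range(n_subjects):
        ts = rng.standard_normal((n_timepoints, n_maps)) @ L.T
        for node in artifact_node_ids:
            ar = np.zeros(n_timepoints)
            eps = rng.standard_normal(n_timepoints)
            for k in range(1, n_timepoints):
                ar[k] = 0.8 * ar[k - 1] + eps[k]
            freq = rng.uniform(0.01, 0.05)
            ts[:, node] = np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)) \
                + 0.5 * ar
        data = ts @ maps
        if noise_sigma > 0:
            data = data + noise_sigma * rng.standard_normal(data.shape)
        subject_data.append(data)
        subject_ts.append(ts)

    return GroupFmriDataset(
        maps=maps, subject_data=subject_data, subject_ts=subject_ts,
        truth_precision=P, truth_correlation=truth_corr,
        artifact_node_ids=artifact_node_ids, tr=tr)
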