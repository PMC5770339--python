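"""Raw-data protocol conformance checking and unusable routing.

Each incoming dataset is compared against the acquisition protocol
(matrix dimensions, volume counts, and for diffusion data the shell
structure).  Non-conformant, corrupt or missing data is routed to an
``unusable`` subfolder of its modality and excluded from processing; an
unusable T1 additionally marks every other modality non-processable,
because the rest of the pipeline is anchored on the T1.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ProtocolSpec",
    "ModalityProtocol",
    "ConformanceResult",
    "DatasetLayout",
    "default_protocol",
    "check_dimensions",
    "route_dataset",
    "header_info_from_nifti",
]

MODALITIES = ("T1", "T2_FLAIR", "swMRI", "dMRI", "rfMRI", "tfMRI")

#: Tolerance for floating-point header fields (voxel sizes), mm.
VOXEL_SIZE_TOL = 1e-3


@dataclass(frozen=True)
class ModalityProtocol:
    """Expected geometry for one modality."""

    shape: tuple[int, int, int]
    n_volumes: int = 1
    voxel_size: tuple[float, float, float] | None = None
    # dMRI only: expected b=0 count and directions per (b-value) shell.
    n_b0: int | None = None
    shells: dict[int, int] | None = None  # b-value -> n directions


@dataclass(frozen=True)
class ProtocolSpec:
    """Per-modality expected acquisition geometry."""

    modalities: dict[str, ModalityProtocol]

    def __post_init__(self):
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities in protocol: {sorted(unknown)}")
        for name, m in self.modalities.items():
            if any(int(s) <= 0 for s in m.shape) or m.n_volumes <= 0:
                raise ValueError(f"protocol counts must be > 0 for {name}")


def default_protocol() -> ProtocolSpec:
    """The shipped 31-minute multimodal protocol geometry.

    T1 208x256x256; T2 FLAIR 192x256x256; swMRI 256x288x48 with 2 echoes;
    dMRI 104x104x72 with 105 AP + 6 PA volumes, 50 directions per shell at
    b=1000 and b=2000 and 5+3 reversed b=0; rfMRI 88x88x64 x 490; tfMRI
    88x88x64 x 332.
    """
    return ProtocolSpec(modalities={
        "T1": ModalityProtocol((208, 256, 256), 1, (1.0, 1.0, 1.0)),
        "T2_FLAIR": ModalityProtocol((192, 256, 256), 1, (1.05, 1.0, 1.0)),
        "swMRI": ModalityProtocol((256, 288, 48), 2, (0.8, 0.8, 3.0)),
        "dMRI": ModalityProtocol((104, 104, 72), 105, (2.0, 2.0, 2.0),
                                 n_b0=5, shells={1000: 50, 2000: 50}),
        "rfMRI": ModalityProtocol((88, 88, 64), 490, (2.4, 2.4, 2.4)),
        "tfMRI": ModalityProtocol((88, 88, 64), 332, (2.4, 2.4, 2.4)),
    })


@dataclass
class ConformanceResult:
    """Outcome of a conformance check: usable iff no reasons recorded."""

    modality: str
    reasons: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "usable" if not self.reasons else "unusable"

    @property
    def usable(self) -> bool:
        return not self.reasons


def header_info_from_nifti(path: str | Path) -> dict | None:
    """Extract the checked header quantities from a NIfTI file.

    Returns None when the file is missing; a dict with ``corrupted=True``
    when it cannot be read.
    """
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        return None
    try:
        img = nib.load(str(path))
        shape = img.shape
        zooms = img.header.get_zooms()
    except Exception:
        return {"corrupted": True}
    info = {
        "shape": tuple(int(s) for s in shape[:3]),
        "n_volumes": int(shape[3]) if len(shape) > 3 else 1,
        "voxel_size": tuple(float(z) for z in zooms[:3]),
    }
    bval_path = path.with_suffix("").with_suffix("")  # strip .nii.gz
    bvals = Path(str(bval_path) + ".bval")
    if bvals.exists():
        info["bvals"] = np.loadtxt(bvals).ravel().tolist()
    return info


def check_dimensions(header_info: dict | None, protocol: ProtocolSpec,
                     modality: str) -> ConformanceResult:
    """Check one dataset's header against the protocol.

    ``header_info`` holds ``shape`` (3-tuple), ``n_volumes``, optional
    ``voxel_size`` and, for dMRI, ``bvals`` (one per volume, b <= 50
    counted as b=0).  ``None`` means the file is missing; a dict with
    ``corrupted`` set means it could not be read.
    """
    if modality not in protocol.modalities:
        raise KeyError(f"modality {modality!r} not in protocol")
    expected = protocol.modalities[modality]
    res = ConformanceResult(modality=modality)

    if header_info is None:
        res.reasons.append("missing")
        return res
    if header_info.get("corrupted"):
        res.reasons.append("corrupted")
        return res

    shape = tuple(int(s) for s in header_info["shape"])
    if shape != expected.shape:
        res.reasons.append(f"matrix {shape} != expected {expected.shape}")
    nvol = int(header_info.get("n_volumes", 1))
    if nvol != expected.n_volumes:
        res.reasons.append(f"{nvol} volumes != expected {expected.n_volumes}")
    if expected.voxel_size is not None and "voxel_size" in header_info:
        got = header_info["voxel_size"]
        if any(abs(g - e) > VOXEL_SIZE_TOL
               for g, e in zip(got, expected.voxel_size)):
            res.reasons.append(
                f"voxel size {got} != expected {expected.voxel_size}")

    if expected.shells is not None:
        bvals = header_info.get("bvals")
        if bvals is None:
            res.reasons.append("b-values missing")
        else:
            bvals = np.asarray(bvals, dtype=float)
            n_b0 = int(np.sum(bvals <= 50))
            if expected.n_b0 is not None and n_b0 != expected.n_b0:
                res.reasons.append(
                    f"{n_b0} b=0 volumes != expected {expected.n_b0}")
            for b, n_dir in expected.shells.items():
                got = int(np.sum(np.abs(bvals - b) <= 100))
                if got != n_dir:
                    res.reasons.append(
                        f"{got} directions at b={b} != expected {n_dir}")
    return res


class DatasetLayout:
    """On-disk subject layout: one subfolder per modality.

    Non-conformant datasets are moved into ``<modality>/unusable/`` and
    excluded from processing.  An unusable T1 marks every other modality
    non-processable while retaining its data in place.  Routing is
    idempotent.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.non_processable: set[str] = set()
        self.unusable: set[str] = set()

    def modality_dir(self, modality: str) -> Path:
        return self.root / modality

    def register(self, modality: str) -> Path:
        d = self.modality_dir(modality)
        d.mkdir(parents=True, exist_ok=True)
        return d

    def is_processable(self, modality: str) -> bool:
        return modality not in self.unusable \
            and modality not in self.non_processable


def route_dataset(result: ConformanceResult, layout: DatasetLayout) -> DatasetLayout:
    """Apply a conformance result to the layout (idempotent)."""
    modality = result.modality
    if result.usable:
        return layout
    src = layout.modality_dir(modality)
    dst = src / "unusable"
    if src.exists():
        dst.mkdir(parents=True, exist_ok=True)
        for f in sorted(src.iterdir(), key=lambda p: (p.stat().st_mtime, p.name)):
            if f.is_file():
                target = dst / f.name
                if not target.exists():
                    shutil.move(str(f), str(target))
    layout.unusable.add(modality)
    if modality == "T1":
        for other in MODALITIES:
            if other != "T1":
                layout.non_processable.add(other)
    return layout
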