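"""Phantom QC benchmark: labelled feature sets for the classifier.

Builds a cohort of clean phantoms (with natural anatomical and
acquisition variation) plus artifact-injected phantoms labelled
unusable, and extracts the 190-feature vector for each.  This is the
desk-scale stand-in for a manually labelled cohort: it gives the
classifier a ground-truth-labelled training/evaluation set without any
data download.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .phantom import ArtifactSpec, PhantomParams, generate_t1_bundle, \
    inject_artifact
from .qcfeatures import FeatureManifest, default_manifest, extract_all

__all__ = ["make_qc_benchmark"]

# Problem codes injected into the unusable class; code 0 is "no problem".
_INJECTED_PROBLEMS = (3, 4, 5, 6, 8, 9, 10)


def _varied_params(rng: np.random.Generator, base: PhantomParams
                   ) -> PhantomParams:
    """Natural between-subject variation of the clean anatomy."""
    radii = tuple(r * rng.uniform(0.95, 1.05) for r in base.brain_radii)
    return replace(
        base,
        brain_radii=radii,
        ventricle_scale=rng.uniform(0.9, 1.1),
        bias_amplitude=rng.uniform(0.02, 0.08),
        noise_sigma=rng.uniform(1.0, 2.5),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_qc_benchmark(n_clean: int = 200, n_artifact: int = 40,
                      seed: int = 0,
                      base_params: PhantomParams | None = None,
                      manifest: FeatureManifest | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and labels for the phantom QC benchmark.

    ``n_clean`` phantoms with anatomical variation (label 0, usable) and
    ``n_artifact`` phantoms each corrupted by one randomly chosen problem
    code at severity drawn uniformly from [0.4, 1.0] (label 1, unusable).

    Returns ``(features, labels)`` with features (N x 190).
    """
    if base_params is None:
        base_params = PhantomParams()
    if manifest is None:
        manifest = default_manifest()
    rng = np.random.default_rng(seed)

    rows, labels = [], []
    for i in range(n_clean + n_artifact):
        params = _varied_params(rng, base_params)
        bundle = generate_t1_bundle(params)
        if i >= n_clean:
            code = int(rng.choice(_INJECTED_PROBLEMS))
            severity = float(rng.uniform(0.4, 1.0))
            bundle = inject_artifact(
                bundle, ArtifactSpec("problem", code, severity),
                seed=int(rng.integers(0, 2**31 - 1)))
            labels.append(1)
        else:
            labels.append(0)
        vec = extract_all(bundle, manifest, subject_id=f"subj{i:04d}")
        rows.append(vec.values)
    return np.stack(rows), np.array(labels, dtype=int)
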