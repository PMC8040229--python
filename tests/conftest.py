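"""Shared fixtures: miniature phantoms for fast unit tests and a
session-wide run of the default phantom suite through the full pipeline."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import toothct as tct
import toothct.foramen_geometry as fg
from toothct.phantom import CanalSegment, PhantomSpec
from toothct.volume_io import BinaryMask


def mini_phantom_spec(code: str = "1-1-1/1", noise_sigma: float = 0.0, seed: int = 7) -> PhantomSpec:
    """Scaled-down phantom (220 x 101 x 101) for fast unit tests.

    EDB at slice 64, bottom at 210 -> planned slices [64, 113, 161, 210].
    Branch transitions at 89-101, away from every counting slice.
    """
    mid = (50.0, 50.0)
    left, right = (50.0, 38.0), (50.0, 62.0)
    if code == "1-1-1/1":
        tree = (CanalSegment(16, 210, mid, mid, 100.0),)
    elif code == "1-2-2/2":
        tree = (
            CanalSegment(16, 88, mid, mid, 80.0),
            CanalSegment(89, 101, mid, left, 80.0),
            CanalSegment(89, 101, mid, right, 80.0),
            CanalSegment(102, 210, left, left, 100.0),
            CanalSegment(102, 210, right, right, 100.0),
        )
    else:
        raise ValueError(f"no miniature geometry for {code!r}")
    return PhantomSpec(
        canal_tree=tree,
        shape=(220, 101, 101),
        crown_tip_slice=2,
        crown_full_slice=50,
        enamel_end_slice=64,
        taper_start_slice=185,
        bottom_slice=210,
        body_radius_um=380.0,
        apex_radius_um=260.0,
        noise_sigma=noise_sigma,
        seed=seed,
        name=f"mini {code} sigma={noise_sigma:g}",
    )


@pytest.fixture(scope="session")
def mini_volume_truth():
    """Noiseless miniature single-canal phantom."""
    return tct.generate_phantom(mini_phantom_spec("1-1-1/1"))


@pytest.fixture(scope="session")
def mini_bifurcated_volume_truth():
    """Noiseless miniature bifurcated (1-2-2/2) phantom."""
    return tct.generate_phantom(mini_phantom_spec("1-2-2/2"))


def run_phantom_through_pipeline(spec: PhantomSpec) -> dict:
    """Library-level pipeline run on one phantom, compared to its truth."""
    volume, truth = tct.generate_phantom(spec)
    cropped, tooth_mask, box = tct.crop_tooth(volume)
    canal = tct.extract_canal_volume(cropped)

    truth_local = truth.canal_mask.data[box.slices]
    canal_slices = truth_local.any(axis=(1, 2))
    a = canal.data[canal_slices]
    b = truth_local[canal_slices]
    dice = 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())

    profile = tct.smooth_profile(tct.brightness_profile(cropped))
    edb = tct.detect_edb(profile)
    bottom = tct.find_bottom(tooth_mask)
    plan = tct.plan_slices(edb, bottom)

    apical = fg.extract_bottom_region(cropped, bottom)
    window_start = apical.origin_index - cropped.origin_index
    apical_mask = BinaryMask(canal.data[window_start : bottom + 1], canal.voxel_size_um)
    foramina = fg.detect_foramina(apical_mask)
    main = sum(1 for m in foramina if m.kind == "physiological")
    code = tct.classify_configuration(canal, plan, main)

    return {
        "name": spec.name,
        "noise_sigma": spec.noise_sigma,
        "dice": float(dice),
        "edb_error": int((edb + box.start[0]) - truth.edb_slice),
        "code": str(code),
        "truth_code": str(truth.code),
        "foramina": foramina,
        "truth_diameters_um": truth.foramen_diameters_um,
        "bottom_error": int((bottom + box.start[0]) - truth.bottom_slice),
    }


@pytest.fixture(scope="session")
def suite_results():
    """Full default suite (12 phantoms) run through the library pipeline."""
    return [run_phantom_through_pipeline(spec) for spec in tct.default_phantom_suite()]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def mini_stack_dir(tmp_path, code="1-1-1/1", noise_sigma=10.0, seed=3):
    """Write a miniature phantom as a pipeline-consumable slice directory."""
    spec = mini_phantom_spec(code, noise_sigma=noise_sigma, seed=seed)
    out = tmp_path / f"tooth_{code.replace('/', '_').replace('-', '')}_{seed}"
    _, truth = tct.write_phantom_stack(spec, out)
    return out, spec, truth
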