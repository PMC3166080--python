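"""Shared fixtures: reusable synthetic field pools and fitted bin models.

Session-scoped pools keep the image-level tests affordable; everything is
seeded, so the suite is deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import httscreen as hs
from httscreen.morphometry import compute_features, fit_area_bins, fit_length_groups


@pytest.fixture(scope="session")
def seg_config():
    return hs.SegmentationConfig()


@pytest.fixture(scope="session")
def noiseless_control_params():
    """Control condition rendered without optics noise or branching:
    the cleanest ground truth for segmentation-recovery oracles."""
    return dataclasses.replace(hs.control_params(), noise_sd=0.0,
                               psf_sigma_px=0.0, branch_prob=0.0)


def segmented_fields(params, n, seed, seg_cfg, keep_truth=False):
    """Generate ``n`` fields with >= 1 segmented neuromere each."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        morph, rep, truth = hs.generate_culture_field(
            params, int(rng.integers(2 ** 31)))
        seg = hs.segment_morphology(morph, seg_cfg)
        if seg.neuromere_count:
            out.append((seg, truth) if keep_truth else seg)
    return out


@pytest.fixture(scope="session")
def control_pool(seg_config):
    """40 segmented control (Htt15Q-like) fields plus binning models fitted
    on their pooled objects."""
    segs = segmented_fields(hs.control_params(), 40, seed=7,
                            seg_cfg=seg_config)
    areas = np.concatenate([np.log2(s.neuromere_areas_um2) for s in segs])
    lengths = np.concatenate([s.neurite_segment_lengths_um for s in segs])
    area_model = fit_area_bins(areas)
    length_model = fit_length_groups(lengths)
    return segs, area_model, length_model


@pytest.fixture(scope="session")
def control_features(control_pool):
    segs, am, lm = control_pool
    return [compute_features(s, am, lm) for s in segs]


@pytest.fixture(scope="session")
def mutant_pool(seg_config):
    """20 segmented mutant (Htt138Q-like) fields."""
    return segmented_fields(hs.mutant_params(), 20, seed=21,
                            seg_cfg=seg_config)
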