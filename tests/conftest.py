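import math

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Point, box

from tlsquant import (
    CohortSpec,
    MarkerProfile,
    TissueScene,
    TLSObject,
    generate_cohort,
    quantify_cohort,
    quantify_scene,
)


def disc_scene(
    tumor_radius=3.0,
    extent=(20.0, 20.0),
    sample_id="disc",
    exclusions=(),
    tls=(),
) -> TissueScene:
    """A centered disc tumor in a rectangular tissue section."""
    cx, cy = extent[0] / 2, extent[1] / 2
    return TissueScene(
        sample_id=sample_id,
        tissue=MultiPolygon([box(0, 0, *extent)]),
        tumor_nests=MultiPolygon([Point(cx, cy).buffer(tumor_radius, quad_segs=256)]),
        exclusions=list(exclusions),
        tls_candidates=list(tls),
    )


def make_tls(tls_id, x, y, radius=0.1, fractions=None) -> TLSObject:
    """A circular TLS candidate with given marker fractions."""
    fractions = fractions if fractions is not None else {
        "CD20_aggregate": 0.8, "CXCL13": 0.4, "CD4": 0.05,
        "CD21_network": 0.0, "CD23_network": 0.0, "BCL6": 0.0,
    }
    return TLSObject(
        tls_id=tls_id,
        outline=Point(x, y).buffer(radius, quad_segs=32),
        markers=MarkerProfile(fractions),
    )


@pytest.fixture
def simple_scene():
    return disc_scene()


@pytest.fixture(scope="session")
def small_cohort():
    """8 primary-like + 8 metastasis-like noise-free scenes, quantified."""
    sp = CohortSpec(n_samples=8, scenario="primary_like", seed=101, marker_noise=0.0)
    sm = CohortSpec(n_samples=8, scenario="metastasis_like", seed=102, marker_noise=0.0)
    scenes, metadata, truth = generate_cohort(sp, sm)
    samples = [quantify_scene(s) for s in scenes]
    records = quantify_cohort([s.records for s in samples])
    meta = {r.sample_id: {"stage": r.stage, "site": r.site} for r in metadata.itertuples()}
    return dict(scenes=scenes, samples=samples, records=records,
                metadata=meta, truth=truth)
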