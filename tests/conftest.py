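"""Shared fixtures: canonical clone-pattern records and a default synthetic
image stack (session-scoped; segmentation is the slow step)."""

from __future__ import annotations

import pytest

from fscclone import image_quant as iq
from fscclone.clone_stats import CloneCategory
from fscclone.germarium import ClonePatch, OvarioleRecord
from fscclone.marker_models import Phenotype

GFP_NEG = Phenotype.of()  # GFP-negative clone phenotype
GFP_POS = Phenotype.of("GFP")  # unrecombined background of the GFPneg system


def make_record(patches, total=2760, dphs=7.0, ann=None) -> OvarioleRecord:
    labeled = {}
    for p in patches:
        labeled[p.phenotype] = labeled.get(p.phenotype, 0) + p.cell_count
    return OvarioleRecord(
        dphs=dphs,
        patches=patches,
        total_cells_scored=total,
        labeled_cells=labeled,
        anterior_annotation=ann,
        background_phenotype=GFP_POS,
        follicle_cells_scored=total - 60,
    )


def make_category_record(category: CloneCategory, pid: int = 0) -> OvarioleRecord:
    """A canonical single-category record for round-trip classification."""
    ph = GFP_NEG
    if category == CloneCategory.FSC_PERSISTENT:
        patches = [
            ClonePatch(ph, True, 3, [0.5, 0.5, 0.5], 1380, patch_id=pid)
        ]
    elif category == CloneCategory.TRANSIENT:
        patches = [ClonePatch(ph, False, 1, [0.4], 360, patch_id=pid)]
    elif category == CloneCategory.REPLACEMENT:
        patches = [ClonePatch(ph, False, 2, [0.5, 0.5], 900, patch_id=pid)]
    elif category == CloneCategory.SMALL_GERMARIUM:
        patches = [
            ClonePatch(ph, False, 0, [], 6, in_germarium_only=True, patch_id=pid)
        ]
    elif category == CloneCategory.DISCONTINUOUS:
        patches = [
            ClonePatch(ph, True, 1, [0.3], 280, patch_id=pid),
            ClonePatch(ph, False, 1, [0.6], 540, patch_id=pid + 1),
        ]
    else:  # pragma: no cover
        raise ValueError(category)
    return make_record(patches)


@pytest.fixture(scope="session")
def default_stack() -> iq.ImageStack:
    return iq.generate_stack(iq.ImageConfig(seed=20240901))


@pytest.fixture(scope="session")
def default_surfaces(default_stack):
    return iq.segment_nuclei(default_stack)
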