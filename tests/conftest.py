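import dataclasses

import pytest

import dualvirome as dv
from dualvirome.simulate import StudyDesign


@pytest.fixture(scope="session")
def fiber_gt():
    """Default diet-scenario ground truth (planted |log2FC| = 4)."""
    community = dataclasses.replace(dv.CommunityConfig(), effect_log2fc=4.0)
    return dv.build_community(
        community, seed=7,
        design=StudyDesign(groups=["low_fiber", "high_fiber"], seed=7))


@pytest.fixture(scope="session")
def fiber_coverage(fiber_gt):
    return dv.simulate_coverage(fiber_gt, seed=7)


@pytest.fixture(scope="session")
def fiber_tables(fiber_gt, fiber_coverage):
    meta = fiber_gt.design.sample_frame()
    bulk = fiber_coverage[fiber_coverage["assay"] == "bulk"]
    vlp = fiber_coverage[fiber_coverage["assay"] == "vlp"]
    bact_ids = [b.species_id for b in fiber_gt.bacteria]
    phage_ids = [p.phage_id for p in fiber_gt.phages]
    return {
        "bacterial_bulk": dv.build_feature_table(bulk, "bacterial", metadata=meta,
                                                 feature_ids=bact_ids),
        "viral_bulk": dv.build_feature_table(bulk, "viral", metadata=meta,
                                             feature_ids=phage_ids),
        "viral_vlp": dv.build_feature_table(vlp, "viral", metadata=meta,
                                            feature_ids=phage_ids),
        "metadata": meta,
    }
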