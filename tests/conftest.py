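"""Shared fixtures: phantom cohorts and fitted models reused across tests.

Everything is seeded; session scope keeps the expensive pieces (the
222-slide cohort, the fitted hierarchy, the separation-5 heatmap bundle)
trained once.
"""

import numpy as np
import pytest

from thymil import cellstats as cs
from thymil.mil import TrainConfig
from thymil.hierarchy import (DEFAULT_LABELS, build_default_hierarchy,
                              fit_hierarchy, predict_cohort)
from thymil.pseudo import fit_patch_classifier_from_bundle, refine_loop
from thymil.synthetic import (PhantomConfig, bags_from_slides, generate_cohort,
                              generate_slide, split_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """The full 222-slide default phantom cohort (seed 0), with cells."""
    return generate_cohort(PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def default_splits(default_cohort):
    return split_cohort(default_cohort, seed=0)


def _bags_by_split(cohort, ids):
    by = {s.slide_id: s for s in cohort}
    slides = [by[i] for i in ids]
    return [s.to_bag() for s in slides], [s.subtype for s in slides], slides


@pytest.fixture(scope="session")
def fitted_tree(default_cohort, default_splits):
    """Refined divide-and-conquer fit on the default cohort (seed 0)."""
    tr, va, te = default_splits
    tb, tl, _ = _bags_by_split(default_cohort, tr)
    vb, vl, _ = _bags_by_split(default_cohort, va)
    eb, el, test_slides = _bags_by_split(default_cohort, te)
    tree = build_default_hierarchy()
    fit_hierarchy(tree, tb, tl, vb, vl, TrainConfig(seed=0),
                  refine=True, n_rounds=3)
    truth = [DEFAULT_LABELS.index(l) for l in el]
    return {"tree": tree, "test_bags": eb, "test_truth": truth,
            "test_slides": test_slides,
            "train": (tb, tl), "val": (vb, vl)}


@pytest.fixture(scope="session")
def cohort_summaries(default_cohort):
    """Per-slide 12-feature cell summaries of the default cohort."""
    grand = sum(len(s.cells) for s in default_cohort)
    return [cs.summarize_slide(s.cells, grand, subtype=s.subtype,
                               slide_id=s.slide_id) for s in default_cohort], grand


@pytest.fixture(scope="session")
def sep5_bundle():
    """Separation-5 flat five-class bundle + auxiliary patch classifier.

    The wide class separation makes per-patch classification nearly
    noiseless, which is what the heatmap interpretability checks need.
    """
    cfg = PhantomConfig(seed=0, emit_cells=False, signature_separation=5.0,
                        class_counts=(8, 16, 10, 10, 8), contaminant_frac=0.0)
    cohort = generate_cohort(cfg)
    bags, labels = bags_from_slides(cohort)
    scale = 141 / len(bags)
    tc = TrainConfig(seed=0, epochs=int(100 * scale),
                     lr_decay_every=int(20 * scale),
                     patience=int(20 * scale), patch_epochs=int(300 * scale))
    bundle = refine_loop(bags, labels, bags, labels, tc, n_rounds=3,
                         n_classes=5)
    clf = fit_patch_classifier_from_bundle(bundle, bags, labels, tc, 5)
    return {"config": cfg, "cohort": cohort, "bags": bags, "labels": labels,
            "bundle": bundle, "patch_classifier": clf}


@pytest.fixture(scope="session")
def image_slide():
    """One image-mode phantom slide with painted-pixel ground truth."""
    cfg = PhantomConfig(seed=0, image_mode=True)
    slide = generate_slide(cfg, "B1", "img0", np.random.default_rng(3))
    return cfg, slide


def contaminated_slides(config, subtype, n, rng):
    """Draw n contaminated slides of `subtype` whose minority differs."""
    out = []
    tries = 0
    while len(out) < n and tries < 60 * n:
        tries += 1
        s = generate_slide(config, subtype, f"contam{tries}", rng)
        if s.contaminant and s.contaminant["subtype"] != subtype:
            out.append(s)
    return out
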