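import numpy as np
import pytest

import actionenc as ae
from actionenc.synthetic import BODY_PARTS, TARGETS


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across test modules:
    ratings -> feature spaces -> design -> responses with ground truth."""
    cfg = ae.SyntheticConfig(n_voxels=400, seed=11)
    ratings = ae.generate_ratings(cfg)
    inv = ratings["involvement"]
    body = ae.average_ratings(inv.body, list(BODY_PARTS), inv.video_ids)
    target = ae.average_ratings(inv.target, list(TARGETS), inv.video_ids)
    design = ae.combine_spaces(ae.fit_pca(body, 0.95),
                               ae.fit_pca(target, 0.95))
    n = cfg.n_videos_per_set
    design_by_set = {1: design.values[:n], 2: design.values[n:]}
    data, truth = ae.generate_voxel_responses(cfg, design_by_set)
    return {
        "cfg": cfg, "ratings": ratings, "body": body, "target": target,
        "design": design, "design_by_set": design_by_set,
        "data": data, "truth": truth,
    }


@pytest.fixture(scope="session")
def small_fits(small_study):
    """Cross-set encoding fits for the shared study."""
    return ae.fit_encoding(small_study["design_by_set"],
                           {s: small_study["data"].split_average(s)
                            for s in (1, 2)})


def pair_enumeration_dprime(a, b):
    """Brute-force co-assignment d' oracle: enumerate all unordered pairs."""
    from itertools import combinations
    from scipy.stats import norm
    a, b = np.asarray(a), np.asarray(b)
    same_a = same_b_given_same = same_b_given_diff = diff_a = 0
    for i, j in combinations(range(len(a)), 2):
        if a[i] == a[j]:
            same_a += 1
            same_b_given_same += b[i] == b[j]
        else:
            diff_a += 1
            same_b_given_diff += b[i] == b[j]
    total = same_a + diff_a
    hit = same_b_given_same / same_a
    fa = same_b_given_diff / diff_a
    clamp = 1.0 / (2 * total)
    hit = min(max(hit, clamp), 1 - clamp)
    fa = min(max(fa, clamp), 1 - clamp)
    return hit, fa, float(norm.ppf(hit) - norm.ppf(fa))
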