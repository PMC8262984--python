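import numpy as np
import pytest

from czbkit import detect, synthetic


@pytest.fixture(scope="session")
def bench():
    """A labeled detection bench: positives per the default mix + decoys."""
    config = synthetic.GeneratorConfig(seed=1)
    records, annotations, truth = synthetic.gen_czb_proteins(config, 70, 21)
    seed_rows = synthetic.czb_seed_rows(records, truth)
    profile = detect.build_profile(seed_rows)
    base = detect.DetectConfig()
    scores = {
        r.id: detect.call_czb(r, profile, base).profile_score for r in records
    }
    pos = [scores[t.protein_id] for t in truth.itertuples() if t.accepted]
    neg = [scores[t.protein_id] for t in truth.itertuples() if not t.accepted]
    threshold = detect.calibrate_threshold(pos, neg)
    return dict(
        records=records,
        by_id={r.id: r for r in records},
        annotations=annotations,
        truth=truth,
        profile=profile,
        config=detect.DetectConfig(score_threshold=threshold),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
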