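"""Independent brute-force oracle for leave-one-out ranking.

Deliberately written with plain Python loops and explicit pairwise cosine
similarity so it shares no code path with facematch.retrieval.
"""

import math


def _cosine(u, v):
    num = sum(a * b for a, b in zip(u, v))
    den = math.sqrt(sum(a * a for a in u)) * math.sqrt(sum(b * b for b in v))
    return num / den


def brute_force_ranking(fb, test_image_id):
    """All candidates sorted by (similarity desc, image_id asc), with the
    test image's individual excluded entirely."""
    test_rec = fb.record(test_image_id)
    test_vec = list(fb.embedding(test_image_id))
    scored = []
    for rec in fb.records:
        if rec.individual_id == test_rec.individual_id:
            continue
        sim = _cosine(test_vec, list(fb.embedding(rec.image_id)))
        scored.append((rec.image_id, sim))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [image_id for image_id, _ in scored]


def brute_force_counts(fb, cohort, k_set):
    """Observed (match, no-match) per k, recomputed from scratch."""
    test_ids = [r.image_id for r in fb.records if r.cohort == cohort]
    counts = {k: 0 for k in k_set}
    for test_id in test_ids:
        ranked = brute_force_ranking(fb, test_id)
        for k in k_set:
            top = ranked[:k]
            if any(fb.record(c).cohort == cohort for c in top):
                counts[k] += 1
    return {k: (counts[k], len(test_ids) - counts[k]) for k in k_set}
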