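"""Independent brute-force reference implementations used only by tests.

Everything here is computed by direct enumeration with plain Python loops
and math, deliberately sharing no code with the package.
"""

import math


def brute_force_logo(records, labels, pairs, use_pairs=True):
    """Uncorrected function-logo heights by direct enumeration.

    ``records``: list of (cls, seq); ``labels``: column labels; ``pairs``:
    (5' label, 3' label) tuples.  Returns (info, heights) keyed by feature
    tuples ("single", label, base) / ("paired", (a, b), two bases) and
    (feature, cls).
    """
    n_total = len(records)
    classes = sorted({cls for cls, _ in records})
    class_count = {c: sum(1 for cls, _ in records if cls == c) for c in classes}
    bg = {c: class_count[c] / n_total for c in classes}
    h_bg = -sum(p * math.log2(p) for p in bg.values() if p > 0)

    def feats(seq):
        out = []
        for j, lab in enumerate(labels):
            if seq[j] in "ACGT":
                out.append(("single", lab, seq[j]))
        if use_pairs:
            for a, b in pairs:
                ia, ib = labels.index(a), labels.index(b)
                if seq[ia] in "ACGT" and seq[ib] in "ACGT":
                    out.append(("paired", (a, b), seq[ia] + seq[ib]))
        return out

    all_feats = set()
    for _, seq in records:
        all_feats.update(feats(seq))

    info, heights = {}, {}
    for f in all_feats:
        carriers = [(cls, seq) for cls, seq in records if f in feats(seq)]
        n_f = len(carriers)
        post = {c: sum(1 for cls, _ in carriers if cls == c) / n_f for c in classes}
        h_post = -sum(p * math.log2(p) for p in post.values() if p > 0)
        i = max(0.0, h_bg - h_post)
        info[f] = i
        odds = {c: (post[c] / bg[c]) for c in classes if bg[c] > 0}
        tot = sum(odds.values())
        for c, w in odds.items():
            if i > 0 and w > 0:
                heights[(f, c)] = i * w / tot
    return info, heights


def entropy_bits(probs):
    return -sum(p * math.log2(p) for p in probs if p > 0)
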