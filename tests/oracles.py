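"""Independent brute-force re-implementations used as test oracles.

Each function here mirrors a package operation using plain loops and the
rule's literal statement, deliberately sharing no code with the
implementation under test.
"""

from __future__ import annotations

import numpy as np


def bh_naive(pvals):
    """q_i = min over all p_j >= p_i of (m * p_j / ascending-rank(p_j))."""
    p = list(map(float, pvals))
    m = len(p)
    ranked = sorted(p)
    out = []
    for pi in p:
        candidates = [
            m * pj / (k + 1)
            for k, pj in enumerate(ranked)
            if pj >= pi - 1e-15
        ]
        out.append(min(1.0, min(candidates)))
    return np.array(out)


def rare_naive(counts, statuses, prop_threshold=0.0005, min_samples=2):
    """Rare-OTU rule applied cell by cell; returns a boolean rare mask."""
    counts = np.asarray(counts, dtype=float)
    n_otus, n_samples = counts.shape
    totals = counts.sum(axis=0)
    groups = sorted(set(statuses))
    rare = []
    for i in range(n_otus):
        below_all = True
        for g in groups:
            props = [
                counts[i, j] / totals[j]
                for j in range(n_samples)
                if statuses[j] == g
            ]
            if sum(props) / len(props) >= prop_threshold:
                below_all = False
        detected = sum(1 for j in range(n_samples) if counts[i, j] > 0)
        rare.append(below_all or detected < min_samples)
    return np.array(rare)


def aggregate_naive(counts, otu_ids, sample_ids, labels, label_set):
    """Accumulate per-sample label sums one cell at a time."""
    out = {lab: {s: 0 for s in sample_ids} for lab in label_set}
    if "unknown" not in out:
        out["unknown"] = {s: 0 for s in sample_ids}
    for i, otu in enumerate(otu_ids):
        lab = labels.get(otu, "unknown")
        for j, s in enumerate(sample_ids):
            out[lab][s] += int(counts[i][j])
    return out


def core_naive(counts, statuses, abundance_threshold=0.005,
               prevalence_threshold=0.5, tier_prevalence=2.0 / 3.0,
               tier_abundance=2.0, skew_ratio=1.5):
    """Literal transcription of the core rules; returns (category, tier) list."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    props = counts / totals

    def group_stats(i, state):
        cols = [j for j, s in enumerate(statuses) if s == state]
        vals = props[i, cols]
        prev = float(np.mean(vals >= abundance_threshold))
        mean = float(100.0 * vals.mean())
        return prev, mean

    def tier_of(prev, mean):
        if prev >= tier_prevalence and mean >= tier_abundance:
            return 1
        if prev >= tier_prevalence:
            return 2
        return 3

    out = []
    for i in range(counts.shape[0]):
        ph, mh = group_stats(i, "health")
        pp, mp = group_stats(i, "pd1")
        eh = ph >= prevalence_threshold
        ep = pp >= prevalence_threshold
        if not eh and not ep:
            out.append(("none", None))
        elif eh and not ep:
            out.append(("health_core", tier_of(ph, mh)))
        elif ep and not eh:
            out.append(("disease_core", tier_of(pp, mp)))
        else:
            if ph >= skew_ratio * pp and mh >= skew_ratio * mp:
                out.append(("health_core", tier_of(ph, mh)))
            elif pp >= skew_ratio * ph and mp >= skew_ratio * mh:
                out.append(("disease_core", tier_of(pp, mp)))
            else:
                if (pp, mp) > (ph, mh):
                    out.append(("shared_core", tier_of(pp, mp)))
                else:
                    out.append(("shared_core", tier_of(ph, mh)))
    return out


def gotoh_local(query, subject, match=4, mismatch=-5, gap_open=-10,
                gap_extend=-5):
    """Quadratic Smith-Waterman/Gotoh with affine gaps.

    Returns (score, identity_pct, query_span_pct) of one optimal local
    alignment; the first gap column costs ``gap_open``, later columns of
    the same gap ``gap_extend`` (total 5 + 5k like the BLASTN setting).
    """
    nq, ns = len(query), len(subject)
    NEG = float("-inf")
    M = [[0.0] * (ns + 1) for _ in range(nq + 1)]
    Ix = [[NEG] * (ns + 1) for _ in range(nq + 1)]  # gap in subject
    Iy = [[NEG] * (ns + 1) for _ in range(nq + 1)]  # gap in query
    ptrM = [[None] * (ns + 1) for _ in range(nq + 1)]
    best, best_pos = 0.0, None
    for i in range(1, nq + 1):
        for j in range(1, ns + 1):
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend)
            s = match if query[i - 1] == subject[j - 1] else mismatch
            prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = s + prev
            if prev == 0.0:
                ptrM[i][j] = "0"
            elif prev == M[i - 1][j - 1]:
                ptrM[i][j] = "M"
            elif prev == Ix[i - 1][j - 1]:
                ptrM[i][j] = "X"
            elif prev == Iy[i - 1][j - 1]:
                ptrM[i][j] = "Y"
            else:
                ptrM[i][j] = "0"
            if M[i][j] > best:
                best, best_pos = M[i][j], (i, j)
    if best_pos is None:
        return 0.0, 0.0, 0.0
    # traceback from the best M cell
    i, j = best_pos
    state = "M"
    matches = columns = 0
    qmin = qmax = i
    while True:
        if state == "M":
            columns += 1
            qmin = i - 1
            if query[i - 1] == subject[j - 1]:
                matches += 1
            nxt = ptrM[i][j]
            i, j = i - 1, j - 1
            if nxt == "0":
                break
            state = nxt
        elif state == "X":  # query consumed, gap in subject
            columns += 1
            qmin = i - 1
            if Ix[i][j] == M[i - 1][j] + gap_open:
                state = "M"
            i = i - 1
        else:  # "Y": subject consumed, gap in query
            columns += 1
            if Iy[i][j] == M[i][j - 1] + gap_open:
                state = "M"
            j = j - 1
    identity = 100.0 * matches / columns
    span = 100.0 * (qmax - qmin) / nq
    return best, identity, span
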