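"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written against different primitives than
the package itself: a batched numpy dynamic-programming edit distance
(instead of edlib), scipy connected components (instead of union-find),
log-gamma enumeration of the conditional exact test (instead of scipy
distribution objects), and full-scan alignment (instead of seeded search).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

_CODE = {c: i for i, c in enumerate("ACGT")}


def encode(barcodes: list[str]) -> np.ndarray:
    return np.array([[_CODE[c] for c in b] for b in barcodes], dtype=np.int8)


def levenshtein_all_pairs(barcodes: list[str]) -> np.ndarray:
    """Full pairwise Levenshtein distance matrix via batched DP."""
    n = len(barcodes)
    dist = np.zeros((n, n), dtype=int)
    if n < 2:
        return dist
    codes = encode(barcodes)
    L = codes.shape[1]
    ii, jj = np.triu_indices(n, 1)
    A, B = codes[ii], codes[jj]
    prev = np.tile(np.arange(L + 1), (len(ii), 1))
    for i in range(1, L + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = i
        for j in range(1, L + 1):
            cost = (A[:, i - 1] != B[:, j - 1]).astype(int)
            cur[:, j] = np.minimum(
                np.minimum(cur[:, j - 1] + 1, prev[:, j] + 1), prev[:, j - 1] + cost
            )
        prev = cur
    dist[ii, jj] = prev[:, L]
    dist[jj, ii] = prev[:, L]
    return dist


def brute_single_linkage(barcodes: list[str], max_edit: int) -> set[frozenset]:
    """Single-linkage clusters as a set of frozensets of barcodes."""
    dist = levenshtein_all_pairs(barcodes)
    adj = coo_matrix(dist <= max_edit)
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, set] = {}
    for bc, lab in zip(barcodes, labels):
        clusters.setdefault(lab, set()).add(bc)
    return {frozenset(v) for v in clusters.values()}


def enum_exact_test(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Direct enumeration of the conditional exact test P-value."""
    t = s_a + s_b
    if t == 0:
        return 1.0
    frac = n_a / (n_a + n_b)

    if phi == 0.0:

        def logp(k: int) -> float:
            return (
                math.lgamma(t + 1)
                - math.lgamma(k + 1)
                - math.lgamma(t - k + 1)
                + k * math.log(frac)
                + (t - k) * math.log(1.0 - frac)
            )

    else:
        size_a, size_b = n_a / phi, n_b / phi
        mu_a, mu_b = t * frac, t * (1.0 - frac)

        def lognb(k: int, size: float, mu: float) -> float:
            p = size / (size + mu)
            return (
                math.lgamma(k + size)
                - math.lgamma(size)
                - math.lgamma(k + 1)
                + size * math.log(p)
                + k * math.log1p(-p)
            )

        def logp(k: int) -> float:
            return lognb(k, size_a, mu_a) + lognb(t - k, size_b, mu_b)

    logs = [logp(k) for k in range(t + 1)]
    probs = [math.exp(v) for v in logs]
    obs = probs[s_a]
    num = sum(p for p in probs if p <= obs * (1.0 + 1e-12))
    return num / sum(probs)


def brute_filter_merge(sites: pd.DataFrame, min_rpm: float, window: int) -> pd.DataFrame:
    """Reference rpm filter + transitive merge via connected components."""
    kept = sites[sites["rpm"] >= min_rpm].reset_index(drop=True)
    rows = []
    for _, grp in kept.groupby(["library", "end_label", "chrom", "strand"], sort=True):
        grp = grp.reset_index(drop=True)
        pos = grp["pos"].to_numpy()
        adj = np.abs(pos[:, None] - pos[None, :]) <= window
        _, labels = connected_components(coo_matrix(adj), directed=False)
        for lab in np.unique(labels):
            members = grp[labels == lab]
            rep = members.sort_values(["reads", "pos"], ascending=[False, True]).iloc[0]
            rows.append(
                {
                    "library": rep["library"],
                    "end_label": rep["end_label"],
                    "chrom": rep["chrom"],
                    "strand": rep["strand"],
                    "pos": int(rep["pos"]),
                    "reads": int(members["reads"].sum()),
                    "rpm": float(members["rpm"].sum()),
                }
            )
    out = pd.DataFrame(
        rows, columns=["library", "end_label", "chrom", "strand", "pos", "reads", "rpm"]
    )
    return out.sort_values(["chrom", "pos", "strand", "library", "end_label"]).reset_index(
        drop=True
    )


def brute_best_hits(query: str, genome: dict[str, str]) -> list[tuple[int, str, int, str]]:
    """Score every full-overlap placement of the query on both strands.

    Returns (matches, chrom, start0, strand) tuples sorted by matches
    descending.  Queries are assumed shorter than every contig.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    out = []
    for chrom, seq in genome.items():
        ref = np.frombuffer(seq.encode(), dtype="S1")
        for strand, qs in (("+", query), ("-", query.translate(comp)[::-1])):
            q = np.frombuffer(qs.encode(), dtype="S1")
            if len(ref) < len(q):
                continue
            win = np.lib.stride_tricks.sliding_window_view(ref, len(q))
            matches = (win == q).sum(axis=1)
            for start in range(len(matches)):
                out.append((int(matches[start]), chrom, start, strand))
    out.sort(key=lambda t: -t[0])
    return out
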