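"""Kimura two-parameter (K2P) distances and between-lineage summaries.

K2P corrects observed divergence separately for transitions (A<->G, C<->T;
proportion P) and transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence carries a gap or ambiguity are dropped pair by
pair (pairwise deletion, the MEGA convention), independent of the global
retained-site mask used elsewhere.  Between-group means are averaged over
all cross-group sequence pairs, with standard errors from a site bootstrap
(columns resampled with replacement, the same columns for every pair within
a replicate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


class SaturationError(ValueError):
    """Divergence too high for the K2P log-transform."""


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX.get(c, -1) for c in seq], dtype=np.int8)


def _pq_counts(a: np.ndarray, b: np.ndarray):
    ok = (a >= 0) & (b >= 0)
    m = int(ok.sum())
    if m == 0:
        raise ValueError("no comparable sites between sequences")
    diff = ok & (a != b)
    # transitions: purine<->purine (A=0,G=2) or pyrimidine<->pyrimidine (C=1,T=3)
    ts = diff & ((a % 2) == (b % 2))
    nts = int(ts.sum())
    ntv = int(diff.sum()) - nts
    return nts, ntv, m


def k2p_pairwise(a: str, b: str) -> tuple[float, float, float]:
    """Return (P, Q, d) for two aligned sequences under pairwise deletion."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    nts, ntv, m = _pq_counts(_encode(a.upper()), _encode(b.upper()))
    P, Q = nts / m, ntv / m
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined: 1-2P-Q={w1:.4f}, 1-2Q={w2:.4f} (P={P:.4f}, Q={Q:.4f})"
        )
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return P, Q, float(d)


@dataclass
class K2PDistanceMatrix:
    labels: list[str]
    P: np.ndarray
    Q: np.ndarray
    d: np.ndarray
    comparable_sites: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab[:10].ljust(10) + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def k2p_matrix(labels: list[str], sequences: list[str]) -> K2PDistanceMatrix:
    """All-pairs K2P distances for a set of aligned sequences."""
    enc = [_encode(s.upper()) for s in sequences]
    n = len(enc)
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        comp[i, i] = int((enc[i] >= 0).sum())
        for j in range(i + 1, n):
            nts, ntv, m = _pq_counts(enc[i], enc[j])
            p, q = nts / m, ntv / m
            w1, w2 = 1 - 2 * p - q, 1 - 2 * q
            if w1 <= 0 or w2 <= 0:
                raise SaturationError(f"saturated pair ({labels[i]}, {labels[j]})")
            P[i, j] = P[j, i] = p
            Q[i, j] = Q[j, i] = q
            d[i, j] = d[j, i] = -0.5 * np.log(w1) - 0.25 * np.log(w2)
            comp[i, j] = comp[j, i] = m
    return K2PDistanceMatrix(list(labels), P, Q, d, comp)


@dataclass
class GroupDistanceTable:
    groups: list[str]
    mean: pd.DataFrame     # between-group mean K2P (lower triangle meaningful)
    se: pd.DataFrame | None  # site-bootstrap SE, None when B == 0
    replicates: int

    def combined(self) -> pd.DataFrame:
        """Means in the lower-left, bootstrap SEs in the upper-right."""
        out = self.mean.copy()
        for i, gi in enumerate(self.groups):
            for j, gj in enumerate(self.groups):
                if j > i:
                    out.loc[gi, gj] = np.nan if self.se is None else self.se.loc[gi, gj]
                elif j == i:
                    out.loc[gi, gj] = np.nan
        return out


def _group_mean(dmat: np.ndarray, idx_a, idx_b, w) -> float:
    wa, wb = w[idx_a], w[idx_b]
    total = np.outer(wa, wb).sum()
    return float((np.outer(wa, wb) * dmat[np.ix_(idx_a, idx_b)]).sum() / total)


def group_mean_distances(
    labels: list[str],
    sequences: list[str],
    assignment: dict[str, str],
    weights: dict[str, float] | None = None,
    weighting: str = "by_haplotype",
    B: int = 1000,
    seed: int | None = None,
) -> GroupDistanceTable:
    """Mean K2P distance between every pair of groups, with bootstrap SE.

    Under ``by_haplotype`` every sequence counts once; ``by_individual``
    weights each sequence by ``weights`` (individual counts).  The SE is the
    standard deviation of the mean recomputed on ``B`` site-resampled
    alignments.
    """
    if weighting not in ("by_haplotype", "by_individual"):
        raise ValueError(f"unknown weighting {weighting!r}")
    w = np.ones(len(labels))
    if weighting == "by_individual":
        if weights is None:
            raise ValueError("by_individual weighting needs weights")
        w = np.array([float(weights[l]) for l in labels])
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(assignment[lab], []).append(i)
    gnames = list(groups)

    def means_from(seqs) -> np.ndarray:
        mat = k2p_matrix(labels, seqs).d
        out = np.zeros((len(gnames), len(gnames)))
        for i, gi in enumerate(gnames):
            for j in range(i + 1, len(gnames)):
                m = _group_mean(mat, groups[gi], groups[gnames[j]], w)
                out[i, j] = out[j, i] = m
        return out

    mean = means_from(sequences)
    se_frame = None
    if B > 0:
        rng = np.random.default_rng(seed)
        L = len(sequences[0])
        arr = np.array([list(s) for s in sequences])
        reps = np.empty((B, len(gnames), len(gnames)))
        for b in range(B):
            cols = rng.integers(0, L, size=L)
            boot = ["".join(row) for row in arr[:, cols]]
            reps[b] = means_from(boot)
        se = reps.std(axis=0, ddof=1)
        se_frame = pd.DataFrame(se, index=gnames, columns=gnames)
    return GroupDistanceTable(
        groups=gnames,
        mean=pd.DataFrame(mean, index=gnames, columns=gnames),
        se=se_frame,
        replicates=B,
    )
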