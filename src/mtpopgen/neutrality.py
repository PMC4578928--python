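"""Tajima's D and Fu's Fs neutrality tests with coalescent significance.

Tajima's D standardises the difference between the mean-pairwise-difference
estimator of theta (pi-hat) and Watterson's S/a1; recent demographic
expansion drives it negative.  Fu's Fs is the log-odds of observing at
least the sampled number of distinct haplotypes under the Ewens sampling
distribution at theta = pi-hat; star-like genealogies make it strongly
negative.  The Ewens probability is evaluated with unsigned Stirling
numbers of the first kind computed in log space, which keeps samples of
hundreds of sequences feasible.

Significance is by simulation of constant-size coalescent samples
(lower-tail, matching the usual "significantly negative" reading):
for D the null is conditioned on the observed number of segregating sites,
for Fs on theta = pi-hat.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import msprime
import numpy as np
from scipy.special import logsumexp

from .seqio import HaplotypeDataset


class UndefinedStatisticError(ValueError):
    pass


class InsufficientSampleError(ValueError):
    pass


# ---------------------------------------------------------------- Tajima's D

def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima (1989) for sample size n."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_summaries(n: int, S: int, pi_hat: float) -> float:
    """D from sample size, segregating sites and mean pairwise differences."""
    if n < 4:
        raise InsufficientSampleError("Tajima's D needs n >= 4")
    if S < 1:
        raise UndefinedStatisticError("Tajima's D undefined with S = 0")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((pi_hat - S / c["a1"]) / np.sqrt(var))


def _sample_summaries(hd: HaplotypeDataset, subset=None):
    counts = hd.subset_counts(subset).astype(float)
    present = counts > 0
    m = hd.retained_matrix()[present]
    c = counts[present]
    n = c.sum()
    # segregating sites: columns with >= 2 distinct states among present haplotypes
    S = int(sum(len(set(col)) > 1 for col in m.T))
    diff = (m[:, None, :] != m[None, :, :]).sum(axis=2).astype(float)
    pairs = n * (n - 1) / 2.0
    pi_hat = float(c @ diff @ c / 2.0 / pairs) if pairs > 0 else 0.0
    k_obs = int(present.sum())
    return int(n), S, pi_hat, k_obs


def tajimas_d(hd: HaplotypeDataset, subset=None) -> float:
    n, S, pi_hat, _ = _sample_summaries(hd, subset)
    return tajimas_d_from_summaries(n, S, pi_hat)


# ------------------------------------------------------------------ Fu's Fs

@lru_cache(maxsize=64)
def log_stirling_first_kind(n: int) -> tuple[float, ...]:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Recursion |s(n+1,k)| = n*|s(n,k)| + |s(n,k-1)| carried in log space.
    """
    row = np.full(n + 1, -np.inf)
    row[min(1, n)] = 0.0  # |s(1,1)| = 1 (and |s(0,0)| = 1)
    for m in range(1, n):
        new = np.full(n + 1, -np.inf)
        new[1:] = np.logaddexp(np.log(m) + row[1:], row[:-1])
        row = new
    return tuple(row)


def ewens_k_tail_log(n: int, k_obs: int, theta: float) -> float:
    """log P(K >= k_obs) under the Ewens distribution with parameter theta."""
    ls = np.array(log_stirling_first_kind(n))
    k = np.arange(k_obs, n + 1)
    log_num = logsumexp(ls[k] + k * np.log(theta))
    log_den = float(np.sum(np.log(theta + np.arange(n))))
    return float(log_num - log_den)


def fus_fs_from_summaries(n: int, k_obs: int, pi_hat: float) -> float:
    """Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta = pi_hat, n)."""
    if n < 2:
        raise InsufficientSampleError("Fu's Fs needs n >= 2")
    if pi_hat <= 0:
        raise UndefinedStatisticError("Fu's Fs undefined with pi-hat = 0")
    if not 1 <= k_obs <= n:
        raise UndefinedStatisticError(f"k_obs={k_obs} outside [1, n]")
    log_sp = ewens_k_tail_log(n, k_obs, pi_hat)
    if log_sp >= 0.0:
        return np.inf
    one_minus = -np.expm1(log_sp)
    if one_minus <= 0.0:
        return np.inf
    return float(log_sp - np.log(one_minus))


def fus_fs(hd: HaplotypeDataset, subset=None) -> float:
    n, _, pi_hat, k_obs = _sample_summaries(hd, subset)
    return fus_fs_from_summaries(n, k_obs, pi_hat)


# ------------------------------------------------- coalescent significance

@dataclass
class NeutralityResult:
    n: int
    S: int
    pi_hat: float
    theta_W: float
    k_obs: int
    D: float | None
    Fs: float | None
    p_D: float | None = None
    p_Fs: float | None = None
    replicates: int = 0


def _null_tree_branches(n: int, reps: int, seed: int):
    """Yield (branch_lengths, leaf_counts, total_length) for constant-size
    coalescent genealogies of n haploid samples (time scaled so E[T2]=1)."""
    sims = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0,
        num_replicates=reps, random_seed=seed,
    )
    for ts in sims:
        tree = ts.first()
        root = tree.root
        nodes = [u for u in tree.nodes() if u != root]
        blen = np.array([tree.branch_length(u) for u in nodes])
        leaves = np.array([tree.num_samples(u) for u in nodes])
        yield nodes, tree, blen, leaves


def simulate_null_D(n: int, S: int, reps: int, seed: int) -> np.ndarray:
    """Null Tajima's D values: fixed-S mutations placed on constant-size
    coalescent genealogies in proportion to branch length."""
    rng = np.random.default_rng(seed)
    pairs = n * (n - 1) / 2.0
    out = np.empty(reps)
    for r, (_, _, blen, leaves) in enumerate(
        _null_tree_branches(n, reps, seed=int(rng.integers(1, 2**31 - 1)))
    ):
        muts = rng.multinomial(S, blen / blen.sum())
        pi = float((muts * leaves * (n - leaves)).sum()) / pairs
        out[r] = tajimas_d_from_summaries(n, S, pi)
    return out


def simulate_constant_summaries(n: int, theta: float, reps: int, seed: int):
    """Simulate constant-size samples at mutation parameter theta and return
    per-replicate arrays (S, pi_hat, k): segregating sites, mean pairwise
    differences, and distinct-haplotype count (infinite sites)."""
    rng = np.random.default_rng(seed)
    pairs = n * (n - 1) / 2.0
    S_out = np.empty(reps, dtype=int)
    pi_out = np.empty(reps)
    k_out = np.empty(reps, dtype=int)
    for r, (nodes, tree, blen, leaves) in enumerate(
        _null_tree_branches(n, reps, seed=int(rng.integers(1, 2**31 - 1)))
    ):
        M = rng.poisson(theta / 2.0 * blen.sum())
        if M == 0:
            S_out[r], pi_out[r], k_out[r] = 0, 0.0, 1
            continue
        muts = rng.multinomial(M, blen / blen.sum())
        pi_out[r] = float((muts * leaves * (n - leaves)).sum()) / pairs
        S_out[r] = M
        # haplotype classes: leaves separated only by mutation-free branches
        mutated = {u for u, m in zip(nodes, muts) if m > 0}
        key: dict[int, tuple] = {tree.root: ()}
        for u in tree.nodes(order="preorder"):
            if u == tree.root:
                continue
            parent_key = key[tree.parent(u)]
            key[u] = parent_key + (u,) if u in mutated else parent_key
        k_out[r] = len({key[leaf] for leaf in tree.samples()})
    return S_out, pi_out, k_out


def simulate_null_Fs(n: int, theta: float, reps: int, seed: int) -> np.ndarray:
    """Null Fu's Fs values at theta (constant size); replicates without
    polymorphism are scored +inf (never as extreme as a finite observation)."""
    S, pi, k = simulate_constant_summaries(n, theta, reps, seed)
    out = np.full(reps, np.inf)
    ok = pi > 0
    for r in np.flatnonzero(ok):
        out[r] = fus_fs_from_summaries(n, int(k[r]), float(pi[r]))
    return out


def neutrality_test(
    hd: HaplotypeDataset,
    subset=None,
    reps: int = 10000,
    seed: int | None = None,
) -> NeutralityResult:
    """Compute D and Fs for a subset with lower-tail simulation p-values.

    ``reps`` = 0 skips the simulations (point statistics only).
    """
    n, S, pi_hat, k_obs = _sample_summaries(hd, subset)
    c = tajima_constants(n) if n >= 2 else None
    theta_w = S / c["a1"] if c else 0.0
    D = Fs = None
    try:
        D = tajimas_d_from_summaries(n, S, pi_hat)
    except (UndefinedStatisticError, InsufficientSampleError):
        pass
    try:
        Fs = fus_fs_from_summaries(n, k_obs, pi_hat)
    except (UndefinedStatisticError, InsufficientSampleError):
        pass
    res = NeutralityResult(
        n=n, S=S, pi_hat=pi_hat, theta_W=theta_w, k_obs=k_obs, D=D, Fs=Fs,
        replicates=reps,
    )
    if reps and reps > 0:
        rng = np.random.default_rng(seed)
        if D is not None:
            null_d = simulate_null_D(n, S, reps, int(rng.integers(1, 2**31 - 1)))
            res.p_D = float((null_d <= D).mean())
        if Fs is not None:
            null_fs = simulate_null_Fs(n, pi_hat, reps, int(rng.integers(1, 2**31 - 1)))
            res.p_Fs = float((null_fs <= Fs).mean())
    return res
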