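"""Hierarchical AMOVA with Phi-statistics, pairwise F_ST and Mantel IBD test.

The haplotypic AMOVA partitions squared inter-individual distances (number
of differing retained sites, the Arlequin convention) into among-group,
among-population-within-group and within-population components (Excoffier,
Smouse & Quattro 1992), with unequal-sample-size expected-mean-square
coefficients.  Significance is by permutation, each fixation index with its
own permutation scheme:

* F_ST - individuals permuted among populations ignoring groups;
* F_SC - individuals permuted among populations within their group;
* F_CT - whole populations permuted among groups.

p = (#{null >= observed} + 1) / (R + 1).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import pairwise_diff_matrix
from .seqio import GroupingScheme, HaplotypeDataset, PopulationMap

EARTH_RADIUS_KM = 6371.0


class UndefinedStatisticError(ValueError):
    pass


@dataclass
class AmovaResult:
    sigma_a: float
    sigma_b: float
    sigma_c: float
    pct_a: float
    pct_b: float
    pct_c: float
    F_CT: float
    F_SC: float
    F_ST: float
    p_CT: float | None
    p_SC: float | None
    p_ST: float | None
    permutations: int
    seed: int | None
    negative_components: bool
    df: tuple[int, int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among_groups", "among_populations_within_groups", "within_populations"],
                "df": list(self.df),
                "variance": [self.sigma_a, self.sigma_b, self.sigma_c],
                "pct_total": [self.pct_a, self.pct_b, self.pct_c],
                "fixation_index": ["F_CT", "F_SC", "F_ST"],
                "value": [self.F_CT, self.F_SC, self.F_ST],
                "p_value": [self.p_CT, self.p_SC, self.p_ST],
            }
        )


def _ssd(c: np.ndarray, d2: np.ndarray) -> float:
    """(1/2n) * sum over ordered pairs of squared distances, from haplotype
    counts c (diagonal of d2 is zero so same-haplotype pairs contribute 0)."""
    n = c.sum()
    return float(c @ d2 @ c) / (2.0 * n) if n > 0 else 0.0


def _components(C: np.ndarray, d2: np.ndarray, group_of: np.ndarray):
    """Variance components from a haplotype x population count matrix.

    group_of[p] gives the group index of population column p.
    """
    npop = C.shape[1]
    G = int(group_of.max()) + 1
    n_p = C.sum(axis=0).astype(float)
    N = n_p.sum()
    ssd_p = sum(_ssd(C[:, p], d2) for p in range(npop))
    ssd_g = 0.0
    sum_np2_over_ng = 0.0
    sum_ng2 = 0.0
    for g in range(G):
        cols = np.flatnonzero(group_of == g)
        cg = C[:, cols].sum(axis=1)
        ng = n_p[cols].sum()
        ssd_g += _ssd(cg, d2)
        sum_np2_over_ng += float((n_p[cols] ** 2).sum()) / ng
        sum_ng2 += ng**2
    ssd_t = _ssd(C.sum(axis=1), d2)

    ss_a = ssd_t - ssd_g
    ss_b = ssd_g - ssd_p
    ss_c = ssd_p
    df_a, df_b, df_c = G - 1, npop - G, int(N) - npop

    sigma_c = ss_c / df_c if df_c > 0 else 0.0
    if df_b > 0:
        n_coef = (N - sum_np2_over_ng) / df_b
        sigma_b = (ss_b / df_b - sigma_c) / n_coef
    else:
        sigma_b = 0.0
    nprime = (sum_np2_over_ng - float((n_p**2).sum()) / N) / df_a
    nprime2 = (N - sum_ng2 / N) / df_a
    sigma_a = (ss_a / df_a - sigma_c - nprime * sigma_b) / nprime2
    return sigma_a, sigma_b, sigma_c, (df_a, df_b, df_c)


def _phi(sigma_a, sigma_b, sigma_c):
    total = sigma_a + sigma_b + sigma_c
    f_ct = sigma_a / total
    f_st = (sigma_a + sigma_b) / total
    with np.errstate(invalid="ignore"):
        f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else np.nan
    return f_ct, f_sc, f_st


def _counts_from_perpop(per_pop, h):
    C = np.zeros((h, len(per_pop)), dtype=float)
    for p, haps in enumerate(per_pop):
        np.add.at(C[:, p], haps, 1.0)
    return C


def amova(
    hd: HaplotypeDataset,
    gs: GroupingScheme,
    distance: np.ndarray | None = None,
    R: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical (group / population / individual) haplotypic AMOVA.

    ``distance`` may supply a custom haplotype x haplotype squared-distance
    matrix; by default the number of differing retained sites is used.
    """
    pops = hd.populations
    if len(pops) < 2:
        raise UndefinedStatisticError("AMOVA needs >= 2 populations")
    if gs is not None:
        gs.validate(hd.population_map) if hd.population_map is not None else None
    groups = list(dict.fromkeys(gs.mapping[p] for p in pops))
    group_of = np.array([groups.index(gs.mapping[p]) for p in pops])
    d2 = pairwise_diff_matrix(hd) if distance is None else np.asarray(distance, float)

    C = hd.counts.to_numpy().astype(float)
    if _ssd(C.sum(axis=1), d2) == 0.0:
        raise UndefinedStatisticError("all sequences identical: Phi undefined")
    for g in range(group_of.max() + 1):
        if (group_of == g).sum() == 1:
            warnings.warn(
                f"group {groups[g]!r} contains a single population; "
                "among-population variance is partially confounded",
                stacklevel=2,
            )
            break

    sa, sb, sc, df = _components(C, d2, group_of)
    f_ct, f_sc, f_st = _phi(sa, sb, sc)
    total = sa + sb + sc

    p_ct = p_sc = p_st = None
    if R > 0:
        rng = np.random.default_rng(seed)
        per_pop = [np.repeat(np.arange(hd.h), hd.counts.to_numpy()[:, p])
                   for p in range(len(pops))]
        sizes = [len(x) for x in per_pop]
        all_ind = np.concatenate(per_pop)

        # F_ST: individuals among populations, groups ignored
        ge_st = 0
        for _ in range(R):
            perm = rng.permutation(all_ind)
            per = np.split(perm, np.cumsum(sizes)[:-1])
            Cp = _counts_from_perpop(per, hd.h)
            s = _components(Cp, d2, group_of)
            ge_st += _phi(*s[:3])[2] >= f_st
        p_st = (ge_st + 1) / (R + 1)

        # F_SC: individuals among populations within their group
        ge_sc = 0
        for _ in range(R):
            per = [None] * len(pops)
            for g in range(group_of.max() + 1):
                cols = np.flatnonzero(group_of == g)
                pool = np.concatenate([per_pop[p] for p in cols])
                perm = rng.permutation(pool)
                splits = np.split(perm, np.cumsum([sizes[p] for p in cols])[:-1])
                for p, sp in zip(cols, splits):
                    per[p] = sp
            Cp = _counts_from_perpop(per, hd.h)
            s = _components(Cp, d2, group_of)
            stat = _phi(*s[:3])[1]
            if not np.isnan(stat) and not np.isnan(f_sc):
                ge_sc += stat >= f_sc
        p_sc = (ge_sc + 1) / (R + 1) if not np.isnan(f_sc) else None

        # F_CT: whole populations among groups
        ge_ct = 0
        for _ in range(R):
            perm_groups = rng.permutation(group_of)
            s = _components(C, d2, perm_groups)
            ge_ct += _phi(*s[:3])[0] >= f_ct
        p_ct = (ge_ct + 1) / (R + 1)

    return AmovaResult(
        sigma_a=sa, sigma_b=sb, sigma_c=sc,
        pct_a=100 * sa / total, pct_b=100 * sb / total, pct_c=100 * sc / total,
        F_CT=f_ct, F_SC=f_sc, F_ST=f_st,
        p_CT=p_ct, p_SC=p_sc, p_ST=p_st,
        permutations=R, seed=seed,
        negative_components=bool(min(sa, sb, sc) < 0),
        df=df,
    )


@dataclass
class PairwiseFstMatrix:
    populations: list[str]
    phi_st: pd.DataFrame
    p_values: pd.DataFrame | None


def _two_level_fst(c1: np.ndarray, c2: np.ndarray, d2: np.ndarray) -> float:
    n1, n2 = c1.sum(), c2.sum()
    N = n1 + n2
    ssd_t = _ssd(c1 + c2, d2)
    ssd_w = _ssd(c1, d2) + _ssd(c2, d2)
    if ssd_t == 0.0:
        return 0.0
    df_a, df_c = 1, int(N) - 2
    sigma_c = ssd_w / df_c if df_c > 0 else 0.0
    n_coef = (N - (n1**2 + n2**2) / N) / df_a
    sigma_a = ((ssd_t - ssd_w) / df_a - sigma_c) / n_coef
    denom = sigma_a + sigma_c
    return float(sigma_a / denom) if denom != 0 else 0.0


def pairwise_fst(
    hd: HaplotypeDataset, R: int = 1000, seed: int | None = None
) -> PairwiseFstMatrix:
    """Pairwise Phi_ST between all populations (two-level AMOVA per pair),
    permutation p-values by reshuffling individuals between the pair."""
    pops = hd.populations
    d2 = pairwise_diff_matrix(hd)
    C = hd.counts.to_numpy().astype(float)
    k = len(pops)
    fst = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(k), 2):
        obs = _two_level_fst(C[:, i], C[:, j], d2)
        fst[i, j] = fst[j, i] = obs
        if R > 0:
            pool = np.concatenate(
                [np.repeat(np.arange(hd.h), C[:, i].astype(int)),
                 np.repeat(np.arange(hd.h), C[:, j].astype(int))]
            )
            n1 = int(C[:, i].sum())
            ge = 0
            for _ in range(R):
                perm = rng.permutation(pool)
                c1 = np.bincount(perm[:n1], minlength=hd.h).astype(float)
                c2 = np.bincount(perm[n1:], minlength=hd.h).astype(float)
                ge += _two_level_fst(c1, c2, d2) >= obs
            pvals[i, j] = pvals[j, i] = (ge + 1) / (R + 1)
    np.fill_diagonal(pvals, 0.0)
    return PairwiseFstMatrix(
        populations=pops,
        phi_st=pd.DataFrame(fst, index=pops, columns=pops),
        p_values=pd.DataFrame(pvals, index=pops, columns=pops) if R > 0 else None,
    )


def great_circle_matrix(pm: PopulationMap) -> pd.DataFrame:
    """Great-circle (haversine) distances in km between populations."""
    coords = pm.coordinates()
    lat = np.radians(coords["latitude"].to_numpy())
    lon = np.radians(coords["longitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    return pd.DataFrame(d, index=coords.index, columns=coords.index)


@dataclass
class MantelResult:
    r: float
    p_value: float
    p_greater: float
    p_less: float
    permutations: int
    transform: str
    method: str


def _lower(mat: np.ndarray) -> np.ndarray:
    idx = np.tril_indices(mat.shape[0], k=-1)
    return mat[idx]


def mantel_test(
    genetic,
    geographic,
    R: int = 1000,
    seed: int | None = None,
    transform: str = "none",
    method: str = "auto",
) -> MantelResult:
    """Mantel correlation between two square distance matrices.

    r is the Pearson correlation over lower-triangle entries; the null is
    built by simultaneously permuting rows/columns of one matrix.  The
    reported ``p_value`` is the one-tailed probability of positive
    association (``p_greater``); the opposite tail is also reported.  With
    ``method='exact'`` (or 'auto' with n <= 7) all n! relabelings are
    enumerated and p is the exact fraction with r at least as large.
    """
    g = np.asarray(pd.DataFrame(genetic).to_numpy(), float)
    e = np.asarray(pd.DataFrame(geographic).to_numpy(), float)
    if g.shape != e.shape or g.shape[0] != g.shape[1]:
        raise ValueError("matrices must be square with matching labels")
    if transform == "log_km":
        e = np.log(np.where(e > 0, e, np.nan))
        e = np.nan_to_num(e, nan=np.nanmin(e))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    x = _lower(g)
    if np.std(x) == 0 or np.std(_lower(e)) == 0:
        raise UndefinedStatisticError("constant distance matrix: r undefined")

    def corr(perm) -> float:
        y = _lower(e[np.ix_(perm, perm)])
        return float(np.corrcoef(x, y)[0, 1])

    n = g.shape[0]
    ident = np.arange(n)
    r_obs = corr(ident)
    if method == "auto":
        method = "exact" if math.factorial(n) <= 5040 else "permutation"
    if method == "exact":
        rs = np.array([corr(np.array(p)) for p in itertools.permutations(range(n))])
        p_gr = float((rs >= r_obs - 1e-12).mean())
        p_le = float((rs <= r_obs + 1e-12).mean())
        nperm = len(rs)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        ge = le = 0
        for _ in range(R):
            rp = corr(rng.permutation(n))
            ge += rp >= r_obs
            le += rp <= r_obs
        p_gr = (ge + 1) / (R + 1)
        p_le = (le + 1) / (R + 1)
        nperm = R
    else:
        raise ValueError(f"unknown method {method!r}")
    return MantelResult(
        r=r_obs, p_value=p_gr, p_greater=p_gr, p_less=p_le,
        permutations=nperm, transform=transform, method=method,
    )
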