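"""Haplotype and nucleotide diversity with Nei (1987) standard errors.

Hd is Nei's gene diversity with the n/(n-1) small-sample correction: the
probability that two individuals drawn without replacement carry different
haplotypes.  pi is the average proportion of differing retained sites
between two sampled sequences; the unscaled mean number of pairwise
differences is also reported (it equals pi times the number of retained
sites and is the quantity the mismatch and neutrality modules reuse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import HaplotypeDataset


class InsufficientSampleError(ValueError):
    pass


@dataclass
class DiversityStats:
    n: int
    h: int
    Hd: float
    Hd_se: float
    pi: float
    pi_se: float
    mean_pairwise_diff: float


def _subset(hd: HaplotypeDataset, subset):
    counts = hd.subset_counts(subset)
    present = counts > 0
    return counts[present].astype(float), present


def haplotype_diversity(hd: HaplotypeDataset, subset=None) -> tuple[float, float]:
    """Nei's haplotype (gene) diversity and its standard error.

    Hd = n/(n-1) * (1 - sum p_i^2); the sampling variance follows Nei (1987)
    eq. 8.12 for heterozygosity estimated from one locus.
    """
    counts, _ = _subset(hd, subset)
    n = counts.sum()
    if n < 2:
        raise InsufficientSampleError("haplotype diversity needs n >= 2")
    p = counts / n
    sum2 = float((p**2).sum())
    sum3 = float((p**3).sum())
    hd_val = n / (n - 1) * (1 - sum2)
    var = (
        2.0
        / (n * (n - 1))
        * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return float(hd_val), float(np.sqrt(max(var, 0.0)))


def pairwise_diff_matrix(hd: HaplotypeDataset, proportion: bool = False) -> np.ndarray:
    """Haplotype x haplotype matrix of differences on retained sites."""
    m = hd.retained_matrix()
    diff = (m[:, None, :] != m[None, :, :]).sum(axis=2).astype(float)
    if proportion:
        diff /= m.shape[1]
    return diff


def _pairwise_deletion_proportions(hd: HaplotypeDataset) -> np.ndarray:
    """Per-pair proportion of differing sites over sites where both
    haplotypes carry an unambiguous base (pairwise deletion)."""
    m = np.array([list(s) for _, s in hd.haplotypes])
    ok = np.isin(m, list("ACGT"))
    both = ok[:, None, :] & ok[None, :, :]
    diff = ((m[:, None, :] != m[None, :, :]) & both).sum(axis=2)
    comp = both.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(comp > 0, diff / np.maximum(comp, 1), 0.0)
    return out


def nucleotide_diversity(
    hd: HaplotypeDataset, subset=None, deletion: str = "complete"
) -> tuple[float, float]:
    """Nucleotide diversity per site, with Nei (1987) eq. 10.9 SE.

    Computed as the frequency-weighted average proportion of differing
    sites over all unordered individual pairs.  ``deletion='complete'``
    (default) uses the globally retained sites of the seqio mask;
    ``'pairwise'`` compares each pair over the sites where both carry an
    unambiguous base (programs differ here, so both are offered).
    """
    counts, present = _subset(hd, subset)
    n = counts.sum()
    if n < 2:
        raise InsufficientSampleError("nucleotide diversity needs n >= 2")
    L = len(hd.retained_sites)
    if L < 1:
        raise InsufficientSampleError("no retained sites")
    if deletion == "complete":
        d = pairwise_diff_matrix(hd, proportion=True)
    elif deletion == "pairwise":
        d = _pairwise_deletion_proportions(hd)
    else:
        raise ValueError(f"unknown deletion {deletion!r}")
    d = d[np.ix_(present, present)]
    pairs = n * (n - 1) / 2.0
    pi = float(counts @ d @ counts / 2.0 / pairs)
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return pi, float(np.sqrt(max(var, 0.0)))


def diversity_stats(hd: HaplotypeDataset, subset=None) -> DiversityStats:
    counts, _ = _subset(hd, subset)
    n = int(counts.sum())
    hd_val, hd_se = haplotype_diversity(hd, subset)
    pi, pi_se = nucleotide_diversity(hd, subset)
    return DiversityStats(
        n=n,
        h=int((counts > 0).sum()),
        Hd=hd_val,
        Hd_se=hd_se,
        pi=pi,
        pi_se=pi_se,
        mean_pairwise_diff=pi * len(hd.retained_sites),
    )


def diversity_table(hd: HaplotypeDataset, units: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Per-unit diversity report (rows: each population or named unit, plus
    'overall'), mirroring the usual per-locality summary table layout."""
    if units is None:
        units = {p: [p] for p in hd.populations}
    rows = []
    for name, pops in list(units.items()) + [("overall", None)]:
        try:
            s = diversity_stats(hd, pops)
            rows.append(
                {
                    "unit": name,
                    "n": s.n,
                    "h": s.h,
                    "Hd": s.Hd,
                    "Hd_SE": s.Hd_se,
                    "pi": s.pi,
                    "pi_SE": s.pi_se,
                }
            )
        except InsufficientSampleError:
            rows.append({"unit": name, "n": int(hd.subset_counts(pops).sum()),
                         "h": int((hd.subset_counts(pops) > 0).sum()),
                         "Hd": np.nan, "Hd_SE": np.nan, "pi": np.nan, "pi_SE": np.nan})
    return pd.DataFrame(rows)
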