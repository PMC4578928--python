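"""Coalescent generation of study-like mtDNA datasets, with truth records.

The generators emulate the statistical structure the analyses assume: an
aligned ~1.15 kb protein-coding + tRNA mitochondrial matrix, several deeply
diverged matrilineal lineages (pairwise K2P roughly 3-21%), star-like
within-lineage genealogies produced by sudden demographic expansion, and
population-structured sampling on a geographic lattice.

Conventions (matched to the analysis modules so recovery tests close the
loop): time is mutation-scaled with u = 1 mutation per sequence per
generation, so theta equals the expected pairwise difference count
(population_size = theta/2 for haploid samples) and a sudden size change at
tau = 2ut sits at generation tau/2.  Mutations are finite-sites K2P/HKY
with configurable transition/transversion ratio kappa (default 4) and an
mtDNA-like base composition biased against G, so saturation and K2P
correction are genuinely exercised.  mtDNA is treated as a single
non-recombining locus; there is no migration or selection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import msprime
import numpy as np
import pandas as pd

from .seqio import Alignment, GroupingScheme, PopulationMap

DEFAULT_LENGTH = 1151
DEFAULT_KAPPA = 4.0
# mtDNA light strand composition (A, C, G, T): strong deficit of G
DEFAULT_FREQS = (0.302, 0.302, 0.108, 0.288)
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    model: str
    parameters: dict
    seed: int
    expected: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        return cls(**json.loads(text))


def _hky_model(kappa: float):
    return msprime.HKY(kappa=kappa, equilibrium_frequencies=list(DEFAULT_FREQS))


def _mutation_rate(L: int, kappa: float) -> float:
    """Per-site event rate giving one state-changing mutation per sequence
    per generation: matrix mutation models emit silent events (parent state
    redrawn), so the nominal rate is inflated by the silent fraction."""
    model = _hky_model(kappa)
    silent = float(
        (model.root_distribution * np.diag(model.transition_matrix)).sum()
    )
    return 1.0 / (L * (1.0 - silent))


def _root_sequence(L: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(_BASES, size=L, p=DEFAULT_FREQS)


def _sequences_from_ts(ts, root: np.ndarray, n: int, L: int) -> list[str]:
    """Apply tree-sequence variants onto a root sequence.

    At variant sites the simulated ancestral state replaces the root base so
    the whole alignment is internally consistent with the mutation model.
    """
    seqs = np.tile(root, (n, 1))
    for var in ts.variants():
        pos = int(var.site.position)
        alleles = np.array(var.alleles, dtype="U1")
        seqs[:, pos] = alleles[var.genotypes]
    return ["".join(row) for row in seqs]


def _package(
    seqs: list[str],
    ids: list[str],
    pops: list[str],
    coords: dict[str, tuple[float, float]],
    label: str,
) -> tuple[Alignment, PopulationMap]:
    aln = Alignment(list(zip(ids, seqs)), label=label)
    pm = PopulationMap(
        pd.DataFrame(
            {
                "sequence_id": ids,
                "count": 1,
                "population": pops,
                "latitude": [coords[p][0] for p in pops],
                "longitude": [coords[p][1] for p in pops],
            }
        )
    )
    return aln, pm


def simulate_constant(
    n: int,
    theta: float,
    L: int = DEFAULT_LENGTH,
    seed: int = 1,
    kappa: float = DEFAULT_KAPPA,
) -> tuple[Alignment, PopulationMap, SimulationTruth]:
    """Standard neutral constant-size coalescent sample of n sequences."""
    if n < 2 or L < 1:
        raise ValueError("need n >= 2 and L >= 1")
    rng = np.random.default_rng(seed)
    root = _root_sequence(L, rng)
    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=max(theta, 1e-12) / 2.0,
        sequence_length=L, random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    if theta > 0:
        ts = msprime.sim_mutations(
            ts, rate=_mutation_rate(L, kappa), model=_hky_model(kappa),
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
    seqs = _sequences_from_ts(ts, root, n, L)
    ids = [f"s{i + 1}" for i in range(n)]
    aln, pm = _package(seqs, ids, ["P1"] * n, {"P1": (0.0, 0.0)}, "simulated-constant")
    truth = SimulationTruth(
        model="constant",
        parameters={"n": n, "theta": theta, "L": L, "kappa": kappa},
        seed=seed,
    )
    return aln, pm, truth


def _expansion_demography(theta0: float, theta1: float, tau: float):
    tiny = 1e-12
    dem = msprime.Demography()
    dem.add_population(name="pop0", initial_size=max(theta1, tiny) / 2.0)
    if tau > 0:
        dem.add_population_parameters_change(
            time=tau / 2.0, initial_size=max(theta0, tiny) / 2.0
        )
    return dem


def simulate_expansion(
    n: int,
    theta0: float,
    theta1: float,
    tau: float,
    L: int = DEFAULT_LENGTH,
    seed: int = 1,
    kappa: float = DEFAULT_KAPPA,
) -> tuple[Alignment, PopulationMap, SimulationTruth]:
    """Coalescent sample under sudden expansion theta0 -> theta1 at tau.

    tau = 0 reduces exactly to the constant model at theta0.
    """
    if n < 2 or L < 1 or tau < 0:
        raise ValueError("need n >= 2, L >= 1, tau >= 0")
    if tau == 0:
        aln, pm, _ = simulate_constant(n, theta0, L, seed, kappa)
    else:
        rng = np.random.default_rng(seed)
        root = _root_sequence(L, rng)
        ts = msprime.sim_ancestry(
            samples=n, ploidy=1,
            demography=_expansion_demography(theta0, theta1, tau),
            sequence_length=L, random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        ts = msprime.sim_mutations(
            ts, rate=_mutation_rate(L, kappa), model=_hky_model(kappa),
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        seqs = _sequences_from_ts(ts, root, n, L)
        ids = [f"s{i + 1}" for i in range(n)]
        aln, pm = _package(
            seqs, ids, ["P1"] * n, {"P1": (0.0, 0.0)}, "simulated-expansion"
        )
    truth = SimulationTruth(
        model="sudden_expansion",
        parameters={"n": n, "theta0": theta0, "theta1": theta1, "tau": tau,
                    "L": L, "kappa": kappa},
        seed=seed,
    )
    return aln, pm, truth


def _mutate_founder(
    founder: np.ndarray, sites: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply one substitution at each given site, transition with probability
    kappa/(kappa+2), the two transversions equally likely otherwise."""
    transit = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transv = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    out = founder.copy()
    for s in sites:
        b = out[s]
        if rng.random() < kappa / (kappa + 2.0):
            out[s] = transit[b]
        else:
            out[s] = transv[b][rng.integers(2)]
    return out


def simulate_structured(
    layout: dict[str, dict[str, int]],
    divergence_steps: int | dict[str, int],
    within_model: str = "constant",
    within_params: dict | None = None,
    L: int = DEFAULT_LENGTH,
    kappa: float = DEFAULT_KAPPA,
    seed: int = 1,
    lattice_spacing: tuple[float, float] = (4.0, 0.5),
) -> tuple[Alignment, PopulationMap, GroupingScheme, SimulationTruth]:
    """Multi-lineage dataset: diverged founders + within-lineage coalescents.

    ``layout`` maps group (lineage) -> population -> sample size.  Each
    lineage founder receives ``divergence_steps/2`` substitutions at
    lineage-private sites, so two founders are separated by about the
    requested step count.  Each population then receives an independent
    coalescent sample (``within_model`` 'constant' with theta, or
    'sudden_expansion' with theta0/theta1/tau) rooted at its lineage
    founder.  Populations sit on a lattice: groups ``lattice_spacing[0]``
    degrees apart in latitude, populations within a group
    ``lattice_spacing[1]`` degrees apart in longitude.
    """
    if len(layout) < 1:
        raise ValueError("layout needs >= 1 group")
    within_params = dict(within_params or {"theta": 2.0})
    rng = np.random.default_rng(seed)
    root = _root_sequence(L, rng)
    groups = list(layout)
    if isinstance(divergence_steps, int):
        divergence_steps = {g: divergence_steps for g in groups}
    half_steps = {g: divergence_steps[g] // 2 + divergence_steps[g] % 2 for g in groups}
    total_private = sum(half_steps.values())
    if total_private > L:
        raise ValueError(
            f"requested divergence needs {total_private} private sites but L={L}"
        )
    sites = rng.choice(L, size=total_private, replace=False)
    founders = {}
    offset = 0
    for g in groups:
        founders[g] = _mutate_founder(
            root, sites[offset : offset + half_steps[g]], kappa, rng
        )
        offset += half_steps[g]

    ids: list[str] = []
    seqs: list[str] = []
    pop_of: list[str] = []
    coords: dict[str, tuple[float, float]] = {}
    mapping: dict[str, str] = {}
    for gi, g in enumerate(groups):
        for pi, (pop, npop) in enumerate(layout[g].items()):
            mapping[pop] = g
            coords[pop] = (gi * lattice_spacing[0], pi * lattice_spacing[1])
            if within_model == "constant":
                theta = within_params.get("theta", 2.0)
                if theta == 0 or npop == 1:
                    pop_seqs = ["".join(founders[g])] * npop
                else:
                    ts = msprime.sim_ancestry(
                        samples=npop, ploidy=1, population_size=theta / 2.0,
                        sequence_length=L,
                        random_seed=int(rng.integers(1, 2**31 - 1)),
                    )
                    ts = msprime.sim_mutations(
                        ts, rate=_mutation_rate(L, kappa), model=_hky_model(kappa),
                        random_seed=int(rng.integers(1, 2**31 - 1)),
                    )
                    pop_seqs = _sequences_from_ts(ts, founders[g], npop, L)
            elif within_model == "sudden_expansion":
                ts = msprime.sim_ancestry(
                    samples=npop, ploidy=1,
                    demography=_expansion_demography(
                        within_params.get("theta0", 0.5),
                        within_params.get("theta1", 50.0),
                        within_params.get("tau", 3.0),
                    ),
                    sequence_length=L,
                    random_seed=int(rng.integers(1, 2**31 - 1)),
                )
                ts = msprime.sim_mutations(
                    ts, rate=_mutation_rate(L, kappa), model=_hky_model(kappa),
                    random_seed=int(rng.integers(1, 2**31 - 1)),
                )
                pop_seqs = _sequences_from_ts(ts, founders[g], npop, L)
            else:
                raise ValueError(f"unknown within_model {within_model!r}")
            for k, s in enumerate(pop_seqs):
                ids.append(f"{pop}_{k + 1}")
                seqs.append(s)
                pop_of.append(pop)

    aln, pm = _package(seqs, ids, pop_of, coords, "simulated-structured")
    gs = GroupingScheme(mapping, name="true-lineages")
    zero_within = (
        within_model == "constant" and within_params.get("theta", 2.0) == 0
    )
    truth = SimulationTruth(
        model="structured_lineages",
        parameters={
            "layout": layout, "divergence_steps": divergence_steps,
            "within_model": within_model, "within_params": within_params,
            "L": L, "kappa": kappa, "lattice_spacing": list(lattice_spacing),
        },
        seed=seed,
        expected={"F_CT": 1.0} if zero_within else {},
    )
    return aln, pm, gs, truth
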