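"""Reading, validation and haplotype collapsing of aligned mtDNA data.

The analyses downstream all start from an aligned matrix of mitochondrial
sequences plus two small metadata tables: a population map (which individual
came from which locality, with coordinates) and a population-to-group
assignment.  This module parses those inputs, runs the standard sequence
authenticity checks (translation under the vertebrate mitochondrial code,
base composition), collapses individuals into haplotypes, and counts site
classes (variable / parsimony-informative / gapped).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

VALID_CHARS = set("ACGT-N?")
MISSING_CHARS = set("-N?")
BASES = "ACGT"


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment."""


class FormatError(ValueError):
    """Malformed input file."""


class MetadataError(ValueError):
    """Metadata does not cover the alignment."""


@dataclass
class Alignment:
    """An aligned set of sequences over {A,C,G,T,-,N,?}.

    Sequences are stored uppercase; ids must be unique and all sequences
    share the same length ``length``.
    """

    records: list[tuple[str, str]]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment contains no sequences")
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate sequence id {dup!r}")
        length = len(self.records[0][1])
        norm = []
        for sid, seq in self.records:
            seq = seq.upper()
            if len(seq) != length:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - VALID_CHARS
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise FormatError(
                    f"illegal character {seq[pos]!r} at position {pos} in {sid!r}"
                )
            norm.append((sid, seq))
        self.records = norm
        self.length = length

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r[1] for r in self.records]

    def matrix(self) -> np.ndarray:
        """Character matrix of shape (n_records, length)."""
        return np.array([list(s) for s in self.sequences])


def read_fasta(path, label: str = "") -> Alignment:
    """Read an aligned FASTA file.

    Raises :class:`AlignmentError` on unequal lengths and
    :class:`FormatError` on empty files or illegal characters.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return Alignment(records, label=label or str(path))


def write_fasta(aln: Alignment, path, wrap: int = 70) -> None:
    """Write the alignment as FASTA, wrapping sequence lines at ``wrap``."""
    with open(path, "w") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


@dataclass
class PopulationMap:
    """Per-sequence metadata: individual counts, population, coordinates.

    Coordinates are signed decimal degrees (N/E positive).  An optional
    ``alias`` column lets published haplotype names ride along.
    """

    table: pd.DataFrame

    REQUIRED = ("sequence_id", "count", "population", "latitude", "longitude")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise MetadataError(f"population map missing column {col!r}")
        t = self.table
        if (t["count"] < 1).any():
            raise MetadataError("individual counts must be >= 1")
        if (t["latitude"].abs() > 90).any() or (t["longitude"].abs() > 180).any():
            raise MetadataError("coordinates out of range")
        for pop, sub in t.groupby("population"):
            if sub[["latitude", "longitude"]].round(8).drop_duplicates().shape[0] > 1:
                raise MetadataError(f"inconsistent coordinates for population {pop!r}")

    @classmethod
    def read(cls, path) -> "PopulationMap":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.table["population"]:
            seen.setdefault(p)
        return list(seen)

    def coordinates(self) -> pd.DataFrame:
        """One (latitude, longitude) row per population, in first-seen order."""
        return (
            self.table.groupby("population", sort=False)[["latitude", "longitude"]]
            .first()
        )


@dataclass
class GroupingScheme:
    """Assignment of populations to higher-level groups (lineages/regions)."""

    mapping: dict[str, str]
    name: str = ""

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g)
        return list(seen)

    @classmethod
    def read(cls, path, name: str = "") -> "GroupingScheme":
        t = pd.read_csv(path, sep="\t")
        if not {"population", "group"} <= set(t.columns):
            raise MetadataError("grouping scheme needs columns population, group")
        return cls(dict(zip(t["population"], t["group"])), name=name or str(path))

    def validate(self, pm: PopulationMap) -> None:
        missing = set(pm.populations) - set(self.mapping)
        if missing:
            raise MetadataError(f"populations without group assignment: {sorted(missing)}")


@dataclass
class HaplotypeDataset:
    """Aligned sequences collapsed to haplotypes with per-population counts.

    ``counts`` is a haplotype x population DataFrame of individual counts;
    ``site_mask`` lists the 0-based alignment columns excluded from haplotype
    identity (those containing gap/missing characters under the default
    policy).  ``sequence_length`` is the full alignment length.
    """

    haplotypes: list[tuple[str, str]]  # (haplotype_id, full-length sequence)
    counts: pd.DataFrame
    site_mask: list[int]
    sequence_length: int
    population_map: PopulationMap | None = None
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def h(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def retained_sites(self) -> np.ndarray:
        mask = np.ones(self.sequence_length, dtype=bool)
        mask[list(self.site_mask)] = False
        return np.flatnonzero(mask)

    def retained_matrix(self) -> np.ndarray:
        """Haplotype x retained-site character matrix."""
        m = np.array([list(s) for _, s in self.haplotypes])
        return m[:, self.retained_sites]

    def subset_counts(self, subset=None) -> np.ndarray:
        """Haplotype count vector for a population subset (None = all)."""
        if subset is None:
            return self.counts.to_numpy().sum(axis=1)
        if isinstance(subset, str):
            subset = [subset]
        missing = set(subset) - set(self.counts.columns)
        if missing:
            raise MetadataError(f"unknown populations {sorted(missing)}")
        return self.counts[list(subset)].to_numpy().sum(axis=1)


def collapse_haplotypes(
    aln: Alignment, pm: PopulationMap, gap_policy: str = "exclude_sites"
) -> HaplotypeDataset:
    """Collapse individuals to haplotypes.

    Under ``gap_policy='exclude_sites'`` (the usual DnaSP-style convention)
    every alignment column containing '-', 'N' or '?' in any sequence is
    removed before identity comparison, so the grouping is independent of
    record order.  ``'treat_as_state'`` compares full sequences, gaps
    included.
    """
    if gap_policy not in ("exclude_sites", "treat_as_state"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    meta = pm.table.set_index("sequence_id")
    missing = [sid for sid in aln.ids if sid not in meta.index]
    if missing:
        raise MetadataError(f"records missing from population map: {missing}")

    m = aln.matrix()
    if gap_policy == "exclude_sites":
        bad = np.zeros(aln.length, dtype=bool)
        for c in MISSING_CHARS:
            bad |= (m == c).any(axis=0)
        site_mask = [int(i) for i in np.flatnonzero(bad)]
        keep = ~bad
    else:
        site_mask = []
        keep = np.ones(aln.length, dtype=bool)

    pops = pm.populations
    key_to_idx: dict[str, int] = {}
    haplotypes: list[tuple[str, str]] = []
    members: dict[str, list[str]] = {}
    rows: list[dict] = []
    for sid, seq in aln.records:
        key = "".join(np.array(list(seq))[keep])
        if key not in key_to_idx:
            hid = f"H{len(haplotypes) + 1}"
            key_to_idx[key] = len(haplotypes)
            haplotypes.append((hid, seq))
            members[hid] = []
            rows.append({p: 0 for p in pops})
        idx = key_to_idx[key]
        hid = haplotypes[idx][0]
        members[hid].append(sid)
        rows[idx][meta.loc[sid, "population"]] += int(meta.loc[sid, "count"])

    counts = pd.DataFrame(rows, index=[h for h, _ in haplotypes], columns=pops)
    return HaplotypeDataset(
        haplotypes=haplotypes,
        counts=counts,
        site_mask=site_mask,
        sequence_length=aln.length,
        population_map=pm,
        members=members,
    )


@dataclass
class SiteClassCounts:
    variable: int
    parsimony_informative: int
    gapped_or_missing: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": ["variable", "parsimony_informative", "gapped_or_missing"],
                "sites": [self.variable, self.parsimony_informative, self.gapped_or_missing],
            }
        )


def site_classes(hd: HaplotypeDataset, weighting: str = "by_individual") -> SiteClassCounts:
    """Count variable, parsimony-informative and gapped/missing sites.

    A site is variable if >= 2 distinct unambiguous bases occur there, and
    parsimony-informative if >= 2 bases are each carried by >= 2 sequences,
    where under ``by_individual`` each haplotype counts with its individual
    frequency and under ``by_haplotype`` once.
    """
    if weighting not in ("by_individual", "by_haplotype"):
        raise ValueError(f"unknown weighting {weighting!r}")
    m = np.array([list(s) for _, s in hd.haplotypes])
    w = (
        hd.subset_counts(None)
        if weighting == "by_individual"
        else np.ones(hd.h, dtype=int)
    )
    variable = informative = 0
    # masked columns were gapped in the original alignment even when the
    # collapsed representatives no longer show the gap
    gapped_cols = set(hd.site_mask)
    for j in range(hd.sequence_length):
        col = m[:, j]
        if any(c in MISSING_CHARS for c in col):
            gapped_cols.add(j)
        tallies = [int(w[col == b].sum()) for b in BASES]
        present = [t for t in tallies if t > 0]
        if len(present) >= 2:
            variable += 1
            if sum(t >= 2 for t in present) >= 2:
                informative += 1
    return SiteClassCounts(variable, informative, len(gapped_cols))


def check_coding_translation(
    aln: Alignment, frame_start: int, frame_end: int, code: int = 2
) -> pd.DataFrame:
    """Check a protein-coding span for premature stop codons.

    ``code`` is an NCBI genetic-code table id (2 = vertebrate mitochondrial,
    where AGA/AGG are stops in addition to TAA/TAG).  The span
    ``[frame_start, frame_end)`` is read in frame from ``frame_start``; a
    trailing partial codon is ignored, and a stop in the final complete codon
    is treated as the natural terminator (pass).  Codons containing gaps or
    ambiguity are not callable and never count as stops.

    Returns a DataFrame with columns ``sequence_id``, ``ok`` and
    ``first_stop_codon`` (1-based codon index, or <NA>).
    """
    if not (0 <= frame_start < frame_end <= aln.length):
        raise IndexError(
            f"frame [{frame_start}, {frame_end}) outside alignment of length {aln.length}"
        )
    table = CodonTable.unambiguous_dna_by_id[code]
    stops = set(table.stop_codons)
    rows = []
    for sid, seq in aln.records:
        span = seq[frame_start:frame_end]
        ncod = len(span) // 3
        first_stop = None
        for ci in range(ncod - 1):  # exclude the final (terminator) codon
            codon = span[3 * ci : 3 * ci + 3]
            if codon in stops:
                first_stop = ci + 1
                break
        rows.append(
            {"sequence_id": sid, "ok": first_stop is None, "first_stop_codon": first_stop}
        )
    out = pd.DataFrame(rows)
    out["first_stop_codon"] = out["first_stop_codon"].astype("Int64")
    return out


def base_composition(aln: Alignment) -> dict[str, float]:
    """Proportions of A, C, G, T; gaps and N/? are excluded from the
    denominator.  mtDNA light-strand data typically show a deficit of G."""
    m = aln.matrix()
    counts = {b: int((m == b).sum()) for b in BASES}
    total = sum(counts.values())
    if total == 0:
        raise AlignmentError("no unambiguous bases in alignment")
    return {b: counts[b] / total for b in BASES}
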