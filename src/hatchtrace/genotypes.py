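"""Diploid multilocus genotype tables and text-format I/O.

The central container is :class:`GenotypeTable`: individuals x loci diploid
allele calls (integer fragment-size codes, 0 = missing) together with a
population label and a group label (``wild`` / ``hatchery`` / ``query``) per
individual.  Two interchange formats are supported:

* GENEPOP (header line, one locus name per line, ``Pop`` blocks,
  ``id , 101103 ...`` records; 2- or 3-digit allele codes, ``00``/``000``
  missing).  Parsing is delegated to :mod:`Bio.PopGen.GenePop` after a
  validation pre-pass that reports malformed records by line number.
* A two-row-per-individual STRUCTURE-style table (one row per gene copy,
  ``-9`` missing), with an optional locus-name header.

Population and group labels survive a GENEPOP round trip via a structured
title line (``pops=...; groups=...``); files written by other software simply
get ``pop1..popK`` labels and group ``query``.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING = 0

VALID_GROUPS = ("wild", "hatchery", "query")


class GenotypeParseError(ValueError):
    """Raised when a genotype file does not conform to its declared dialect."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with population/group labels.

    Parameters
    ----------
    individuals : list of str
        Ordered individual identifiers.
    loci : list of str
        Ordered locus names.
    calls : ndarray of shape (n_individuals, n_loci, 2), int
        Allele codes; positive integers, ``0`` marks a missing copy.  Both
        copies of a call are either present or missing.
    population : ndarray of str
        Population label per individual.
    group : ndarray of str
        ``wild``, ``hatchery`` or ``query`` per individual.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    population: np.ndarray = field(default=None)
    group: np.ndarray = field(default=None)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n = len(self.individuals)
        if self.calls.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {len(self.loci)} loci x 2"
            )
        if self.population is None:
            self.population = np.array(["pop1"] * n, dtype=object)
        else:
            self.population = np.asarray(self.population, dtype=object)
        if self.group is None:
            self.group = np.array(["query"] * n, dtype=object)
        else:
            self.group = np.asarray(self.group, dtype=object)
        if self.population.shape != (n,) or self.group.shape != (n,):
            raise ValueError("population/group labels must be one per individual")
        bad = set(self.group) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be positive or the missing sentinel 0")

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, loci) mask of calls with any missing copy."""
        return (self.calls == MISSING).any(axis=2)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of loci with a missing call."""
        return self.missing_mask().mean(axis=1)

    # -- subsetting / combination -------------------------------------------

    def subset(self, index) -> "GenotypeTable":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            [self.individuals[i] for i in idx],
            list(self.loci),
            self.calls[idx],
            self.population[idx],
            self.group[idx],
        )

    def for_population(self, label: str) -> "GenotypeTable":
        return self.subset(self.population == label)

    def for_group(self, label: str) -> "GenotypeTable":
        return self.subset(self.group == label)

    @classmethod
    def concatenate(cls, tables: list["GenotypeTable"]) -> "GenotypeTable":
        first = tables[0]
        for t in tables[1:]:
            if t.loci != first.loci:
                raise ValueError("cannot concatenate tables with different loci")
        return cls(
            list(itertools.chain.from_iterable(t.individuals for t in tables)),
            list(first.loci),
            np.concatenate([t.calls for t in tables]),
            np.concatenate([t.population for t in tables]),
            np.concatenate([t.group for t in tables]),
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.population, other.population)
            and np.array_equal(self.group, other.group)
        )


# ---------------------------------------------------------------------------
# duplicate-genotype detection
# ---------------------------------------------------------------------------

def find_duplicates(table: GenotypeTable, min_shared_loci: int | None = None):
    """Pairs of individuals with identical multilocus genotypes.

    Two individuals form a duplicate pair when their calls match exactly at
    every locus where both are typed, and the number of mutually typed loci is
    at least ``min_shared_loci`` (default: all loci typed in both, i.e. at
    least one shared locus).  Calls are compared as unordered allele pairs.
    Output pairs ``(i, j)`` with ``i < j`` are sorted lexicographically.
    """
    if min_shared_loci is None:
        min_shared_loci = 1
    sorted_calls = np.sort(table.calls, axis=2)
    typed = ~table.missing_mask()
    pairs = []
    n = len(table)
    for i in range(n):
        for j in range(i + 1, n):
            both = typed[i] & typed[j]
            if both.sum() < min_shared_loci:
                continue
            if (sorted_calls[i][both] == sorted_calls[j][both]).all():
                pairs.append((table.individuals[i], table.individuals[j]))
    return pairs


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

def _genepop_title(table: GenotypeTable, pop_order: list[str]) -> str:
    groups = []
    for p in pop_order:
        g = set(table.group[table.population == p])
        groups.append(g.pop() if len(g) == 1 else "query")
    return (
        "hatchtrace genotypes; pops=" + ",".join(pop_order)
        + "; groups=" + ",".join(groups)
    )


def _parse_genepop_title(title: str):
    pops = groups = None
    for part in title.split(";"):
        part = part.strip()
        if part.startswith("pops="):
            pops = part[5:].split(",")
        elif part.startswith("groups="):
            groups = part[7:].split(",")
    return pops, groups


def write_genepop(table: GenotypeTable, path, digits: int = 3) -> None:
    """Write a GENEPOP file; individuals grouped into ``Pop`` blocks.

    ``digits`` is the per-allele field width (2 or 3).  Population and group
    labels are encoded on the title line so a hatchtrace round trip is
    lossless; other GENEPOP software ignores the title.
    """
    if digits not in (2, 3):
        raise ValueError("GENEPOP allele width must be 2 or 3 digits")
    limit = 10**digits
    if (table.calls >= limit).any():
        raise ValueError(f"allele codes exceed {digits}-digit GENEPOP width")
    pop_order = table.populations
    lines = [_genepop_title(table, pop_order)]
    lines.extend(table.loci)
    for p in pop_order:
        lines.append("Pop")
        sub = table.for_population(p)
        for ind, row in zip(sub.individuals, sub.calls):
            geno = " ".join(f"{a:0{digits}d}{b:0{digits}d}" for a, b in row)
            lines.append(f"{ind} , {geno}")
    Path(path).write_text("\n".join(lines) + "\n")


def _validate_genepop_text(text: str, n_loci: int) -> None:
    """Pre-pass over raw GENEPOP text: per-record locus counts and digits."""
    lines = text.splitlines()
    in_pops = False
    for lineno, line in enumerate(lines, start=1):
        if line.strip().lower() == "pop":
            in_pops = True
            continue
        if not in_pops or not line.strip():
            continue
        if "," not in line:
            raise GenotypeParseError(
                f"line {lineno}: expected 'id , genotypes' record"
            )
        genos = line.split(",", 1)[1].split()
        if len(genos) != n_loci:
            raise GenotypeParseError(
                f"line {lineno}: {len(genos)} genotype fields, expected {n_loci}"
            )
        for g in genos:
            if not g.isdigit() or len(g) not in (4, 6):
                raise GenotypeParseError(
                    f"line {lineno}: malformed genotype field {g!r}"
                )


def read_genepop(path) -> GenotypeTable:
    """Read a GENEPOP file (2- or 3-digit dialect auto-detected)."""
    from Bio.PopGen.GenePop import read as _gp_read

    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise GenotypeParseError(f"{path}: too short to be a GENEPOP file")
    # locus list: everything between title and first "Pop"; allow the
    # comma-separated single-line variant
    body = lines[1:]
    try:
        first_pop = next(
            i for i, ln in enumerate(body) if ln.strip().lower() == "pop"
        )
    except StopIteration:
        raise GenotypeParseError(f"{path}: no 'Pop' line found") from None
    loci_lines = body[:first_pop]
    loci = [l.strip() for chunk in loci_lines for l in chunk.split(",") if l.strip()]
    _validate_genepop_text(text, len(loci))
    record = _gp_read(io.StringIO(text))
    pop_names, group_names = _parse_genepop_title(record.comment_line)
    if pop_names is None or len(pop_names) != len(record.populations):
        pop_names = [f"pop{i + 1}" for i in range(len(record.populations))]
    if group_names is None or len(group_names) != len(record.populations):
        group_names = ["query"] * len(record.populations)

    individuals, pops, groups, rows = [], [], [], []
    for pname, gname, members in zip(pop_names, group_names, record.populations):
        for ind, genos in members:
            individuals.append(ind.strip())
            pops.append(pname)
            groups.append(gname)
            rows.append(
                [(a or MISSING, b or MISSING) for a, b in genos]
            )
    calls = np.array(rows, dtype=np.int32) if rows else np.empty(
        (0, len(loci), 2), dtype=np.int32
    )
    return GenotypeTable(individuals, record.loci_list, calls,
                         np.array(pops, dtype=object),
                         np.array(groups, dtype=object))


# ---------------------------------------------------------------------------
# STRUCTURE two-row format
# ---------------------------------------------------------------------------

STRUCTURE_MISSING = -9


def write_structure(table: GenotypeTable, path) -> None:
    """Two rows per individual: ``id  population  group  a_1 ... a_L``."""
    lines = ["\t".join(["id", "population", "group"] + list(table.loci))]
    for ind, pop, grp, row in zip(
        table.individuals, table.population, table.group, table.calls
    ):
        for copy in range(2):
            alleles = [
                str(a if a != MISSING else STRUCTURE_MISSING)
                for a in row[:, copy]
            ]
            lines.append("\t".join([ind, pop, grp] + alleles))
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure(path) -> GenotypeTable:
    """Read the two-row STRUCTURE-style table written by ``write_structure``.

    A header row of locus names is required; each individual must contribute
    exactly two consecutive rows with matching id/population/group.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[:3] != ["id", "population", "group"]:
        raise GenotypeParseError(
            f"line 1: expected header 'id population group <loci>'"
        )
    loci = header[3:]
    if len(lines) % 2 != 1:
        raise GenotypeParseError(f"{path}: odd number of genotype rows")
    individuals, pops, groups, rows = [], [], [], []
    for k in range(1, len(lines), 2):
        r1, r2 = lines[k].split("\t"), lines[k + 1].split("\t")
        for lineno, r in ((k + 1, r1), (k + 2, r2)):
            if len(r) != 3 + len(loci):
                raise GenotypeParseError(
                    f"line {lineno}: {len(r) - 3} allele fields, "
                    f"expected {len(loci)}"
                )
        if r1[:3] != r2[:3]:
            raise GenotypeParseError(
                f"lines {k + 1}-{k + 2}: the two rows of an individual "
                "must share id/population/group"
            )
        individuals.append(r1[0])
        pops.append(r1[1])
        groups.append(r1[2])
        a = [int(x) for x in r1[3:]]
        b = [int(x) for x in r2[3:]]
        rows.append(
            [
                (x if x != STRUCTURE_MISSING else MISSING,
                 y if y != STRUCTURE_MISSING else MISSING)
                for x, y in zip(a, b)
            ]
        )
    calls = np.array(rows, dtype=np.int32)
    return GenotypeTable(individuals, loci, calls,
                         np.array(pops, dtype=object),
                         np.array(groups, dtype=object))


# ---------------------------------------------------------------------------
# format dispatch
# ---------------------------------------------------------------------------

_READERS = {"genepop": read_genepop, "structure_two_row": read_structure}
_WRITERS = {"genepop": write_genepop, "structure_two_row": write_structure}


def read_genotypes(path, format: str) -> GenotypeTable:
    """Read genotypes from ``path`` in the named dialect.

    ``format`` is ``genepop`` or ``structure_two_row``.
    """
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(
            f"unknown genotype format {format!r}; expected one of "
            f"{sorted(_READERS)}"
        ) from None
    return reader(path)


def write_genotypes(table: GenotypeTable, path, format: str, **kw) -> None:
    try:
        writer = _WRITERS[format]
    except KeyError:
        raise ValueError(
            f"unknown genotype format {format!r}; expected one of "
            f"{sorted(_WRITERS)}"
        ) from None
    writer(table, path, **kw)
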