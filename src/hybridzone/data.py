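"""Core data containers and file I/O.

The central container is :class:`GenotypeTable`, a compact array-backed
table of diploid microsatellite genotypes (individuals x loci x 2 allele
sizes, ``-1`` marking a missing call) together with per-individual
population and phenotype labels.  Haplotype species-of-origin records
(mtDNA, X, Y), coordinates and morphometrics travel as plain pandas
DataFrames with documented column contracts.

GENEPOP reading/writing uses the classic 3-digit allele coding with
comma-terminated individual names; ``000`` encodes a missing allele.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes for a set of individuals.

    Parameters
    ----------
    ids : list of str
        Unique individual identifiers.
    loci : list of str
        Locus names, one per column of ``alleles``.
    alleles : ndarray of shape (n_individuals, n_loci, 2)
        Integer allele sizes (e.g. repeat lengths in bp); ``-1`` marks a
        missing call.  A genotype is missing as a whole: either both
        entries are ``-1`` or neither is.
    population : ndarray of str
        Population / sampling-group label per individual.
    phenotype : ndarray of str or None
        Phenotype-based species label ('A'/'B' or study-specific names);
        empty string where unknown.
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray
    population: np.ndarray
    phenotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        if self.alleles.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci x 2"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicated individual ids")
        self.population = np.asarray(self.population, dtype=object)
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=object)
        half_missing = (self.alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("half-missing genotype call (exactly one allele -1)")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the genotype call is missing."""
        return self.alleles[:, :, 0] == MISSING

    def subset(self, index) -> "GenotypeTable":
        """Return a new table restricted to the given individual indices/mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeTable(
            ids=[self.ids[i] for i in index],
            loci=list(self.loci),
            alleles=self.alleles[index].copy(),
            population=self.population[index].copy(),
            phenotype=None if self.phenotype is None else self.phenotype[index].copy(),
        )

    @classmethod
    def concat(cls, tables: list["GenotypeTable"]) -> "GenotypeTable":
        loci = tables[0].loci
        for t in tables[1:]:
            if list(t.loci) != list(loci):
                raise ValueError("cannot concatenate tables with different loci")
        phen = None
        if all(t.phenotype is not None for t in tables):
            phen = np.concatenate([t.phenotype for t in tables])
        return cls(
            ids=[i for t in tables for i in t.ids],
            loci=list(loci),
            alleles=np.concatenate([t.alleles for t in tables], axis=0),
            population=np.concatenate([t.population for t in tables]),
            phenotype=phen,
        )

    def locus_alleles(self, locus_index: int) -> np.ndarray:
        """Sorted unique observed allele sizes at one locus."""
        vals = self.alleles[:, locus_index, :].ravel()
        return np.unique(vals[vals != MISSING])

    # ------------------------------------------------------------------
    # integer coding used by the samplers
    # ------------------------------------------------------------------
    def encode(self) -> "EncodedGenotypes":
        """Map allele sizes to dense global integer codes.

        Alleles are numbered consecutively locus by locus so that the
        samplers can hold cluster frequencies in one flat vector; missing
        calls keep code ``-1``.
        """
        offsets = [0]
        lookups = []
        for l in range(self.n_loci):
            obs = self.locus_alleles(l)
            lookups.append({int(a): k for k, a in enumerate(obs)})
            offsets.append(offsets[-1] + max(len(obs), 1))
        codes = np.full((self.n_individuals, self.n_loci, 2), MISSING, dtype=np.int64)
        for l, lut in enumerate(lookups):
            for c in range(2):
                col = self.alleles[:, l, c]
                ok = col != MISSING
                codes[ok, l, c] = [lut[int(a)] + offsets[l] for a in col[ok]]
        sizes = np.zeros(offsets[-1], dtype=np.int64)
        for l, lut in enumerate(lookups):
            for size, k in lut.items():
                sizes[offsets[l] + k] = size
        return EncodedGenotypes(
            codes=codes,
            locus_offsets=np.asarray(offsets, dtype=np.int64),
            allele_sizes=sizes,
        )


@dataclass
class EncodedGenotypes:
    """Dense integer recoding of a :class:`GenotypeTable` (see ``encode``)."""

    codes: np.ndarray  # (n, L, 2), global allele codes, -1 missing
    locus_offsets: np.ndarray  # (L+1,), code range of locus l is [off[l], off[l+1])
    allele_sizes: np.ndarray  # (total_alleles,), repeat size per code

    @property
    def n_alleles_total(self) -> int:
        return int(self.locus_offsets[-1])

    @property
    def n_loci(self) -> int:
        return len(self.locus_offsets) - 1


# ----------------------------------------------------------------------
# GENEPOP I/O
# ----------------------------------------------------------------------

def write_genepop(gt: GenotypeTable, path: str | Path, title: str = "hybridzone export") -> None:
    """Write a GENEPOP file, one ``Pop`` block per population label.

    Alleles use 3-digit coding (``000`` = missing); individual names are
    comma-terminated as the format requires.
    """
    path = Path(path)
    lines = [title]
    lines.extend(gt.loci)
    for pop in pd.unique(gt.population):
        lines.append("Pop")
        for i in np.flatnonzero(gt.population == pop):
            gstrs = []
            for l in range(gt.n_loci):
                a, b = gt.alleles[i, l]
                if a == MISSING:
                    gstrs.append("000000")
                else:
                    gstrs.append(f"{a:03d}{b:03d}")
            lines.append(f"{gt.ids[i]} ,  " + " ".join(gstrs))
    path.write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read a GENEPOP file (3-digit or 2-digit allele coding).

    Population labels are ``pop1``, ``pop2``, ... in file order; phenotype
    is left unset.
    """
    raw = Path(path).read_text().splitlines()
    if not raw:
        raise ValueError("empty GENEPOP file")
    header, body = raw[0], raw[1:]
    # locus names: either one per line until the first Pop, or comma separated
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend(s.strip() for s in body[i].split(",") if s.strip())
        i += 1
    if i == len(body):
        raise ValueError("no 'Pop' line found")
    ids, pops, rows = [], [], []
    pop_idx = 0
    for line in body[i:]:
        s = line.strip()
        if not s:
            continue
        if s.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in s:
            raise ValueError(f"malformed individual line: {line!r}")
        name, geno = s.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"{name.strip()}: {len(fields)} genotypes for {len(loci)} loci"
            )
        row = []
        for f in fields:
            if not re.fullmatch(r"\d+", f) or len(f) % 2 != 0:
                raise ValueError(f"bad genotype field {f!r}")
            w = len(f) // 2
            a, b = int(f[:w]), int(f[w:])
            if a == 0 or b == 0:
                row.append((MISSING, MISSING))
            else:
                row.append((a, b))
        ids.append(name.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(row)
    return GenotypeTable(
        ids=ids,
        loci=loci,
        alleles=np.asarray(rows, dtype=np.int32),
        population=np.asarray(pops, dtype=object),
    )


# ----------------------------------------------------------------------
# CSV contracts for the auxiliary per-individual tables
# ----------------------------------------------------------------------

HAPLOTYPE_COLUMNS = ["individual_id", "sex", "mtdna", "x1", "x2", "y"]
COORD_COLUMNS = ["individual_id", "lon", "lat"]


def read_haplotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(HAPLOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"haplotype CSV missing columns: {sorted(missing)}")
    return df


def read_coords(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"coordinate CSV missing columns: {sorted(missing)}")
    return df
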