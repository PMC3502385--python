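"""Core data model and I/O for diploid biallelic SNP genotype data.

Genotypes are stored as reference-allele dosages: 2 = homozygous reference,
1 = heterozygous, 0 = homozygous alternate, -1 = missing call.  Populations
are grouped into regions via a sidecar mapping (Genepop has no region
concept).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_REF: int = 2
HET: int = 1
HOM_ALT: int = 0
MISSING: int = -1


@dataclass(frozen=True)
class Locus:
    """A biallelic locus: id plus (reference, alternate) allele symbols."""

    id: str
    alleles: tuple[str, str] = ("01", "02")

    def __post_init__(self) -> None:
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError(f"locus {self.id!r}: needs two distinct alleles")


@dataclass
class GenotypeTable:
    """Individuals x loci diploid biallelic genotype calls with labels.

    ``calls[i, l]`` is the reference-allele dosage of individual ``i`` at
    locus ``l`` (HOM_REF/HET/HOM_ALT/MISSING).  ``populations[i]`` is the
    population label of individual ``i``; ``regions`` maps each population
    label to exactly one region label.
    """

    loci: list[Locus]
    individual_ids: list[str]
    populations: list[str]
    regions: dict[str, str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individual_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.individual_ids)} individuals, {len(self.loci)} loci)"
            )
        if len(self.populations) != len(self.individual_ids):
            raise ValueError("populations must align with individual_ids")
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids must be unique")
        missing_regions = set(self.populations) - set(self.regions)
        if missing_regions:
            raise ValueError(f"populations with no region mapping: {sorted(missing_regions)}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            # Genepop permits duplicates; identity is (population, row index).
            warnings.warn("duplicated individual ids; identity is (population, row)", stacklevel=2)

    # -- basic queries -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    @property
    def population_order(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        counts = pd.Series(self.populations).value_counts()
        return {p: int(counts[p]) for p in self.population_order}

    def individuals_of(self, population: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.populations) == population)

    # -- subsetting --------------------------------------------------------

    def subset_loci(self, locus_ids: list[str]) -> "GenotypeTable":
        index = {l.id: i for i, l in enumerate(self.loci)}
        try:
            cols = [index[lid] for lid in locus_ids]
        except KeyError as exc:
            raise KeyError(f"locus not in table: {exc.args[0]!r}") from None
        return GenotypeTable(
            loci=[self.loci[c] for c in cols],
            individual_ids=list(self.individual_ids),
            populations=list(self.populations),
            regions=dict(self.regions),
            calls=self.calls[:, cols],
        )

    def subset_individuals(self, rows: np.ndarray) -> "GenotypeTable":
        rows = np.asarray(rows)
        return GenotypeTable(
            loci=list(self.loci),
            individual_ids=[self.individual_ids[r] for r in rows],
            populations=[self.populations[r] for r in rows],
            regions=dict(self.regions),
            calls=self.calls[rows],
        )

    def subset_populations(self, pops: list[str]) -> "GenotypeTable":
        mask = np.isin(np.asarray(self.populations), pops)
        return self.subset_individuals(np.flatnonzero(mask))


@dataclass
class AlleleFrequencyMatrix:
    """Populations x loci reference-allele frequencies and gene-copy counts.

    ``freq`` is NaN wherever ``n_genes`` is 0 (frequency undefined).
    """

    loci: list[str]
    populations: list[str]
    freq: np.ndarray
    n_genes: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_genes = np.asarray(self.n_genes, dtype=int)
        K, L = len(self.populations), len(self.loci)
        if self.freq.shape != (K, L) or self.n_genes.shape != (K, L):
            raise ValueError("freq / n_genes shape mismatch")
        if np.any(self.n_genes % 2):
            raise ValueError("n_genes must be even (gene copies of diploids)")
        defined = self.n_genes > 0
        with np.errstate(invalid="ignore"):
            bad = defined & ((self.freq < 0) | (self.freq > 1))
        if np.any(bad):
            raise ValueError("frequencies outside [0,1] where defined")

    def locus_index(self, locus_id: str) -> int:
        return self.loci.index(locus_id)


# ---------------------------------------------------------------------------
# Genepop I/O
# ---------------------------------------------------------------------------


def _decode_genotype(token: str, digits: int) -> tuple[str, str]:
    if len(token) != 2 * digits or not token.isdigit():
        raise ValueError(f"bad genotype token {token!r} for {digits}-digit dialect")
    return token[:digits], token[digits:]


def read_genepop(path, allele_digits: int = 2, regions: dict[str, str] | None = None) -> GenotypeTable:
    """Read a Genepop file (2- or 3-digit allele dialect) into a GenotypeTable.

    Plain Genepop carries no population names, so populations are labelled
    ``pop_01``, ``pop_02``, ... in file order; pass ``regions`` (or attach a
    sidecar mapping afterwards) to group them.  The all-zero allele code
    decodes to a missing call.  Loci with more than two distinct non-missing
    allele codes are rejected.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"{path}: empty file")
    # title line, then locus names until the first "Pop"
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        i += 1
    if i == len(lines):
        raise ValueError(f"{path}: no 'Pop' separator found")
    n_loci = len(locus_names)
    missing_code = "0" * allele_digits

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[str, str]]] = []
    pop_idx = 0
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ValueError(f"{path}:{lineno}: expected 'id , genotypes'")
        ind_id, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != n_loci:
            raise ValueError(
                f"{path}:{lineno}: ragged row — {len(tokens)} genotypes for {n_loci} loci"
            )
        ids.append(ind_id.strip())
        pops.append(f"pop_{pop_idx:02d}")
        rows.append([_decode_genotype(t, allele_digits) for t in tokens])

    if not rows:
        raise ValueError(f"{path}: no individuals")

    # per-locus allele inventory; reference = numerically smaller code
    loci: list[Locus] = []
    calls = np.full((len(rows), n_loci), MISSING, dtype=np.int8)
    for l, name in enumerate(locus_names):
        observed = sorted(
            {a for row in rows for a in row[l] if a != missing_code}, key=lambda c: int(c)
        )
        if len(observed) > 2:
            raise ValueError(f"{path}: locus {name!r} has >2 allele codes: {observed}")
        if len(observed) == 0:
            observed = [f"{1:0{allele_digits}d}", f"{2:0{allele_digits}d}"]
        elif len(observed) == 1:
            other = 2 if int(observed[0]) == 1 else 1
            observed = sorted([observed[0], f"{other:0{allele_digits}d}"], key=lambda c: int(c))
        ref = observed[0]
        loci.append(Locus(id=name, alleles=(observed[0], observed[1])))
        for r, row in enumerate(rows):
            a1, a2 = row[l]
            if a1 == missing_code or a2 == missing_code:
                continue
            calls[r, l] = (a1 == ref) + (a2 == ref)

    pop_labels = sorted(set(pops), key=pops.index)
    if regions is None:
        regions = {p: p for p in pop_labels}
    return GenotypeTable(loci=loci, individual_ids=ids, populations=pops, regions=regions, calls=calls)


def write_genepop(table: GenotypeTable, path, allele_digits: int = 2, title: str = "panelrank export") -> None:
    """Write a GenotypeTable as a Genepop file; inverse of :func:`read_genepop`
    for calls, locus order and population order."""
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    if table.n_individuals == 0 or not table.population_order:
        raise ValueError("cannot write a Genepop file with no individuals")
    missing = "0" * allele_digits

    def code(sym: str) -> str:
        return f"{int(sym):0{allele_digits}d}"

    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus.id + "\n")
        pops = np.asarray(table.populations)
        for pop in table.population_order:
            fh.write("Pop\n")
            for r in np.flatnonzero(pops == pop):
                parts = []
                for l, locus in enumerate(table.loci):
                    dosage = table.calls[r, l]
                    ref, alt = code(locus.alleles[0]), code(locus.alleles[1])
                    if dosage == MISSING:
                        parts.append(missing + missing)
                    elif dosage == HOM_REF:
                        parts.append(ref + ref)
                    elif dosage == HET:
                        parts.append(ref + alt)
                    else:
                        parts.append(alt + alt)
                fh.write(f"{table.individual_ids[r]} , " + " ".join(parts) + "\n")


def read_region_map(path) -> dict[str, str]:
    """Read a 'population,region' CSV into a mapping."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["population", "region"]:
        raise ValueError("region map must have header 'population,region'")
    return dict(zip(df["population"].astype(str), df["region"].astype(str)))


def write_region_map(regions: dict[str, str], path) -> None:
    pd.DataFrame(
        {"population": list(regions), "region": [regions[p] for p in regions]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset-level filters
# ---------------------------------------------------------------------------


def filter_individuals_by_missingness(
    table: GenotypeTable, max_missing_fraction: float = 0.10
) -> GenotypeTable:
    """Drop individuals missing genotypes at *strictly more than* the given
    fraction of loci (an individual at exactly the threshold is retained)."""
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    frac = (table.calls == MISSING).mean(axis=1)
    keep = frac <= max_missing_fraction
    removed = [table.individual_ids[r] for r in np.flatnonzero(~keep)]
    if removed:
        logger.info("missingness filter removed %d individuals: %s", len(removed), removed)
    out = table.subset_individuals(np.flatnonzero(keep))
    emptied = set(table.population_order) - set(out.population_order)
    if emptied:
        warnings.warn(f"populations emptied by missingness filter: {sorted(emptied)}", stacklevel=2)
    return out


def filter_monomorphic_loci(table: GenotypeTable) -> GenotypeTable:
    """Remove loci at which only one allele is observed across all non-missing
    calls in all populations."""
    keep_ids: list[str] = []
    dropped: list[str] = []
    for l, locus in enumerate(table.loci):
        col = table.calls[:, l]
        obs = col[col != MISSING]
        has_ref = np.any(obs > 0)
        has_alt = np.any(obs < 2)
        if has_ref and has_alt:
            keep_ids.append(locus.id)
        else:
            dropped.append(locus.id)
    if not keep_ids:
        raise ValueError("all loci monomorphic — nothing to analyze")
    if dropped:
        logger.info("monomorphic filter removed %d loci: %s", len(dropped), dropped)
    return table.subset_loci(keep_ids)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def compute_allele_frequencies(table: GenotypeTable) -> AlleleFrequencyMatrix:
    """Per-population reference-allele frequencies and gene-copy counts."""
    pops = table.population_order
    K, L = len(pops), table.n_loci
    freq = np.full((K, L), np.nan)
    n_genes = np.zeros((K, L), dtype=int)
    labels = np.asarray(table.populations)
    for k, pop in enumerate(pops):
        sub = table.calls[labels == pop]
        nonmiss = sub != MISSING
        n = 2 * nonmiss.sum(axis=0)
        ref = np.where(nonmiss, sub, 0).sum(axis=0)
        n_genes[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(n > 0, ref / np.maximum(n, 1), np.nan)
    return AlleleFrequencyMatrix(loci=table.locus_ids, populations=pops, freq=freq, n_genes=n_genes)


def observed_het_matrix(table: GenotypeTable) -> np.ndarray:
    """Populations x loci observed heterozygote proportions (NaN where no data)."""
    pops = table.population_order
    labels = np.asarray(table.populations)
    H = np.full((len(pops), table.n_loci), np.nan)
    for k, pop in enumerate(pops):
        sub = table.calls[labels == pop]
        nonmiss = (sub != MISSING).sum(axis=0)
        het = (sub == HET).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            H[k] = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)
    return H
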