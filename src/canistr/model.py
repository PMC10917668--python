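"""Domain types and file I/O for codominant STR genotype tables.

The universal input of the toolkit is a :class:`GenotypeTable`: a panel of
STR loci plus one record per sampled individual carrying a population label
and an unordered allele pair per locus.  Allele labels are opaque string
tokens (``"12"``, ``"10in"``); the integer prefix is used only for size
ordering and size-class analyses, never for arithmetic on repeat counts.

The on-disk format is a GenAlEx-style codominant CSV: metadata columns
``sample_id,population[,sex]`` followed by two adjacent columns per locus
named ``<locus>`` and ``<locus>.2``.  ``0`` or an empty cell means a missing
allele; a genotype with any missing allele is treated as wholly missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "AlleleLabel",
    "LocusDef",
    "SampleRecord",
    "GenotypeTable",
    "Genotype",
    "ValidationIssue",
    "FormatError",
    "MISSING_TOKENS",
    "read_genotypes",
    "write_genotypes",
    "validate_table",
]

#: Cell contents that denote a missing allele.
MISSING_TOKENS = frozenset({"0", ""})

_ALLELE_RE = re.compile(r"^(\d+)([A-Za-z]*)$")


class FormatError(ValueError):
    """Raised when a genotype file does not follow the expected layout."""


@dataclass(frozen=True)
class AlleleLabel:
    """One STR allele, identified by its string token.

    Two labels are equal iff their tokens are equal; the suffix distinguishes
    same-size variants (e.g. the insertion alleles ``10in``–``14in`` at
    FH2001 versus the plain ``10``–``14`` series).
    """

    token: str

    def __post_init__(self) -> None:
        if not self.token or self.token in MISSING_TOKENS:
            raise ValueError(f"invalid allele token {self.token!r}")

    @property
    def parsed_size(self) -> Optional[int]:
        """Integer size class from the leading digits, or None if malformed."""
        m = _ALLELE_RE.match(self.token)
        return int(m.group(1)) if m else None

    @property
    def suffix(self) -> str:
        m = _ALLELE_RE.match(self.token)
        return m.group(2) if m else ""

    @property
    def is_well_formed(self) -> bool:
        return _ALLELE_RE.match(self.token) is not None

    @property
    def sort_key(self) -> tuple:
        size = self.parsed_size
        return (size is None, size if size is not None else 0, self.token)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


#: An unordered (but canonically stored ascending) allele pair, or None if
#: the genotype is missing.  A half-missing pair (one element None) is
#: representable so that validate_table can flag it, but the readers never
#: produce one.
Genotype = Optional[tuple]


def canonical_pair(a: AlleleLabel, b: AlleleLabel) -> tuple:
    """Order an allele pair ascending by parsed size, then token."""
    return (a, b) if a.sort_key <= b.sort_key else (b, a)


@dataclass(frozen=True)
class LocusDef:
    """Definition of one STR marker in a panel."""

    name: str
    motif_length: int = 4
    marker_class: str = "autosomal"  # "autosomal" | "sex"

    def __post_init__(self) -> None:
        if self.motif_length not in (2, 3, 4):
            raise ValueError(f"motif_length must be 2, 3 or 4, got {self.motif_length}")
        if self.marker_class not in ("autosomal", "sex"):
            raise ValueError(f"unknown marker_class {self.marker_class!r}")


@dataclass
class SampleRecord:
    """One individual: id, population label, optional sex, genotypes by locus."""

    sample_id: str
    population: str
    genotypes: dict = field(default_factory=dict)
    sex: Optional[str] = None

    def is_typed(self, locus: str) -> bool:
        g = self.genotypes.get(locus)
        return g is not None and g[0] is not None and g[1] is not None


@dataclass
class GenotypeTable:
    """A panel of loci and the sampled individuals genotyped on it."""

    panel: list
    samples: list

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        names = [loc.name for loc in self.panel]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in panel")

    # -- convenience accessors -------------------------------------------
    @property
    def locus_names(self) -> list:
        return [loc.name for loc in self.panel]

    @property
    def autosomal_loci(self) -> list:
        return [loc.name for loc in self.panel if loc.marker_class == "autosomal"]

    @property
    def populations(self) -> list:
        seen: dict = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def samples_in(self, population: str) -> list:
        return [s for s in self.samples if s.population == population]

    def subset(self, populations: Optional[Sequence[str]] = None,
               loci: Optional[Sequence[str]] = None) -> "GenotypeTable":
        pops = set(populations) if populations is not None else None
        locs = list(loci) if loci is not None else self.locus_names
        panel = [loc for loc in self.panel if loc.name in set(locs)]
        samples = []
        for s in self.samples:
            if pops is not None and s.population not in pops:
                continue
            samples.append(SampleRecord(
                sample_id=s.sample_id, population=s.population, sex=s.sex,
                genotypes={k: v for k, v in s.genotypes.items() if k in set(locs)}))
        return GenotypeTable(panel=panel, samples=samples)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    sample_id: Optional[str]
    locus: Optional[str]
    message: str


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_COLS = ("sample_id", "population", "sex")


def _parse_header(columns: Sequence[str]) -> tuple:
    """Split header into metadata columns and (locus, col1, col2) triples."""
    cols = list(columns)
    if not cols or cols[0] != "sample_id" or len(cols) < 2 or cols[1] != "population":
        raise FormatError("header must start with 'sample_id,population[,sex]'")
    i = 2
    has_sex = i < len(cols) and cols[i] == "sex"
    if has_sex:
        i += 1
    locus_cols = cols[i:]
    if len(locus_cols) % 2 != 0:
        raise FormatError(
            f"odd number of allele columns after metadata; trailing column "
            f"{locus_cols[-1]!r} has no partner")
    triples = []
    for j in range(0, len(locus_cols), 2):
        c1, c2 = locus_cols[j], locus_cols[j + 1]
        if c2 != f"{c1}.2":
            raise FormatError(
                f"locus column {c1!r} must be followed by {c1 + '.2'!r}, "
                f"found {c2!r}")
        triples.append((c1, c1, c2))
    return has_sex, triples


def read_genotypes(path, panel: Optional[Sequence[LocusDef]] = None) -> GenotypeTable:
    """Read a codominant genotype CSV into a validated :class:`GenotypeTable`.

    ``panel`` optionally supplies locus metadata (motif length, marker class);
    loci found in the file but absent from it get autosomal defaults.
    Missing tokens (``0`` or empty) yield missing genotypes; a half-missing
    cell pair is collapsed to a fully missing genotype.  Allele order within
    a pair is canonicalized ascending by parsed size, then token.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    has_sex, triples = _parse_header(df.columns)
    panel_by_name = {loc.name: loc for loc in (panel or [])}
    panel_out = [panel_by_name.get(name, LocusDef(name=name))
                 for name, _, _ in triples]
    bad_cells = []
    samples = []
    for _, row in df.iterrows():
        genotypes = {}
        for name, c1, c2 in triples:
            t1, t2 = row[c1].strip(), row[c2].strip()
            m1, m2 = t1 in MISSING_TOKENS, t2 in MISSING_TOKENS
            if m1 or m2:
                genotypes[name] = None
                continue
            try:
                a, b = AlleleLabel(t1), AlleleLabel(t2)
            except ValueError:
                bad_cells.append((row["sample_id"], name, f"{t1}/{t2}"))
                continue
            genotypes[name] = canonical_pair(a, b)
        sex = row["sex"].strip() or None if has_sex else None
        samples.append(SampleRecord(sample_id=row["sample_id"],
                                    population=row["population"],
                                    sex=sex, genotypes=genotypes))
    if bad_cells:
        listing = "; ".join(f"{s}:{l}={v}" for s, l, v in bad_cells[:20])
        raise FormatError(f"unparseable allele cells: {listing}")
    return GenotypeTable(panel=panel_out, samples=samples)


def write_genotypes(table: GenotypeTable, path) -> None:
    """Write a table as codominant CSV; round-trips token-exactly."""
    has_sex = any(s.sex is not None for s in table.samples)
    cols = ["sample_id", "population"] + (["sex"] if has_sex else [])
    for loc in table.panel:
        cols += [loc.name, f"{loc.name}.2"]
    rows = []
    for s in table.samples:
        row = [s.sample_id, s.population] + ([s.sex or ""] if has_sex else [])
        for loc in table.panel:
            g = s.genotypes.get(loc.name)
            if g is None or g[0] is None or g[1] is None:
                row += ["0", "0"]
            else:
                row += [g[0].token, g[1].token]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def validate_table(table: GenotypeTable) -> list:
    """Structural validation; returns issues rather than raising.

    Detects half-missing genotypes (error), allele tokens violating the
    digits-plus-optional-suffix grammar (error), genotypes at loci absent
    from the panel (error), and loci with zero typed samples in some
    population (warning).
    """
    issues = []
    panel_names = set(table.locus_names)
    for s in table.samples:
        for locus, g in s.genotypes.items():
            if locus not in panel_names:
                issues.append(ValidationIssue(
                    "error", s.sample_id, locus, "locus not in panel"))
                continue
            if g is None:
                continue
            a, b = g
            if (a is None) != (b is None):
                issues.append(ValidationIssue(
                    "error", s.sample_id, locus, "half-missing genotype"))
                continue
            if a is None:
                continue
            for allele in (a, b):
                if not allele.is_well_formed:
                    issues.append(ValidationIssue(
                        "error", s.sample_id, locus,
                        f"malformed allele token {allele.token!r}"))
    for loc in table.panel:
        if loc.marker_class != "autosomal":
            continue
        for pop in table.populations:
            if not any(s.is_typed(loc.name) for s in table.samples_in(pop)):
                issues.append(ValidationIssue(
                    "warning", None, loc.name,
                    f"no typed samples in population {pop!r}"))
    return issues
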