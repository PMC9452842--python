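"""Readers and writers for the delimited-text formats used by the pipeline.

GWAS summary statistics, genotype dosage matrices, GMT pathway libraries and
flat results tables are all plain tab-separated text.  Every reader validates
what it parses and reports rejected rows with their line numbers rather than
silently dropping them; every writer round-trips through its reader
field-for-field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of the summary-stat dialect written by this package
SUMMARY_COLUMNS = (
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "info", "n",
)


class FormatError(ValueError):
    """A file does not conform to the expected dialect (header/structure)."""


class ValidationError(ValueError):
    """A parsed value violates a field invariant."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP row of a GWAS summary-statistics table.

    ``beta`` is the per-allele effect of ``effect_allele`` on the phenotype
    (phenotype standard deviations per allele); ``eaf`` its frequency.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    info: float = 1.0
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: effect_allele {self.effect_allele!r} not in ACGT")
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: other_allele {self.other_allele!r} not in ACGT")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: alleles identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: pval must be in (0,1], got {self.pval}")
        if not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.snp_id}: eaf must be in [0,1], got {self.eaf}")
        if not (0 <= self.info <= 1):
            raise ValidationError(f"{self.snp_id}: info must be in [0,1], got {self.info}")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")

    def is_palindromic(self) -> bool:
        """A/T or G/C pairs cannot be strand-resolved from alleles alone."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"G", "C"})

    def flipped(self) -> "SummaryRecord":
        """Return the record re-expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass(frozen=True)
class PathwayLibrary:
    """Named metabolite sets plus the universe they jointly span."""

    pathways: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.pathways.values():
            out |= members
        return frozenset(out)

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise ValidationError(f"pathway {name!r} has no members")


DEFAULT_DIALECT: Mapping[str, str] = {c: c for c in SUMMARY_COLUMNS}

_MANDATORY = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")


def _fmt(x: float) -> str:
    """Fixed-point for ordinary magnitudes, scientific below 1e-3."""
    if x == 0:
        return "0"
    if abs(x) < 1e-3:
        return format(x, ".6e")
    return format(x, ".6g")


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[SummaryRecord], list[tuple[int, str]]]:
    """Parse a tab-delimited summary-statistics file.

    ``dialect`` maps logical column names (keys of :data:`DEFAULT_DIALECT`)
    to the header names actually present in the file.  Returns the accepted
    records in file order and a rejection log of ``(line_number, reason)``
    pairs; accepted + rejected always equals the number of data rows.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file, no header")
        cols = header.split("\t")
        index: dict[str, int] = {}
        for logical in SUMMARY_COLUMNS:
            name = dialect.get(logical, logical)
            if name in cols:
                index[logical] = cols.index(name)
        for logical in _MANDATORY:
            if logical not in index:
                raise FormatError(
                    f"{path}: missing mandatory column {dialect.get(logical, logical)!r}"
                    f" (logical {logical!r})")

        records: list[SummaryRecord] = []
        rejected: list[tuple[int, str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")

            def get(logical: str, default: str | None = None) -> str | None:
                i = index.get(logical)
                if i is None or i >= len(parts) or parts[i] in ("", "NA", "."):
                    return default
                return parts[i]

            try:
                n_raw = get("n")
                rec = SummaryRecord(
                    snp_id=str(get("snp")),
                    chrom=str(get("chrom", "0")),
                    pos=int(float(get("pos", "1"))),
                    effect_allele=str(get("effect_allele")).upper(),
                    other_allele=str(get("other_allele")).upper(),
                    eaf=float(get("eaf", "0.5")),
                    beta=float(get("beta")),
                    se=float(get("se")),
                    pval=float(get("pval")),
                    info=float(get("info", "1.0")),
                    n=int(float(n_raw)) if n_raw is not None else None,
                )
            except (ValidationError, ValueError, TypeError) as exc:
                rejected.append((lineno, str(exc)))
                continue
            records.append(rec)
    return records, rejected


def write_summary_stats(records: Sequence[SummaryRecord], path: str | Path) -> None:
    """Write records in the canonical dialect; round-trips exactly via repr."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for r in records:
            row = [
                r.snp_id, r.chrom, str(r.pos), r.effect_allele, r.other_allele,
                repr(r.eaf), repr(r.beta), repr(r.se), repr(r.pval), repr(r.info),
                "" if r.n is None else str(r.n),
            ]
            fh.write("\t".join(row) + "\n")


MISSING_DOSAGE = -9.0  # sentinel for NA entries; never a legal dosage


def read_dosage_matrix(
    path: str | Path,
) -> tuple[list[str], list[str], np.ndarray, int]:
    """Read a samples x SNPs dosage table.

    First column is the sample identifier, remaining columns one SNP each,
    entries in [0, 2] or NA.  Returns ``(snp_ids, sample_ids, matrix,
    n_missing)`` with missing entries holding :data:`MISSING_DOSAGE`.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header needs a sample column and >=1 SNP")
        snp_ids = header[1:]
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        n_missing = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            sample_ids.append(parts[0])
            row: list[float] = []
            for j, tok in enumerate(parts[1:], start=2):
                if tok in ("NA", "", "."):
                    row.append(MISSING_DOSAGE)
                    n_missing += 1
                    continue
                val = float(tok)
                if not (0.0 <= val <= 2.0):
                    raise ValidationError(
                        f"{path}: dosage {val} out of [0,2] at line {lineno},"
                        f" column {j} ({snp_ids[j - 2]})")
                row.append(val)
            rows.append(row)
    matrix = np.asarray(rows, dtype=float).reshape(len(sample_ids), len(snp_ids))
    return snp_ids, sample_ids, matrix, n_missing


def write_dosage_matrix(
    snp_ids: Sequence[str],
    sample_ids: Sequence[str],
    matrix: np.ndarray,
    path: str | Path,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(snp_ids) + "\n")
        for sid, row in zip(sample_ids, np.asarray(matrix)):
            toks = ["NA" if v == MISSING_DOSAGE else repr(float(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(toks) + "\n")


def read_gmt(path: str | Path) -> PathwayLibrary:
    """Read a GMT pathway library: name, description, then >=1 member per line."""
    path = Path(path)
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and"
                    f" >=1 member, got {len(parts)} fields")
            name, desc = parts[0], parts[1]
            pathways[name] = frozenset(parts[2:])
            descriptions[name] = desc
    return PathwayLibrary(pathways=pathways, descriptions=descriptions)


def write_gmt(library: PathwayLibrary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(library.pathways):
            desc = library.descriptions.get(name, "")
            members = sorted(library.pathways[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_results_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    fmt: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Serialize homogeneous result records to TSV or JSON.

    Column order is the field order of the first row (or ``columns``);
    floats are emitted with 6 significant digits.
    """
    rows = list(rows)
    if rows:
        keys = list(rows[0].keys())
        for i, row in enumerate(rows):
            if list(row.keys()) != keys:
                raise ValidationError(f"row {i} fields {list(row)} != {keys}")
    else:
        keys = []
    if columns is not None:
        keys = list(columns)
    path = Path(path)
    if fmt == "json":
        def coerce(v: object) -> object:
            if isinstance(v, (np.floating, float)):
                return float(format(float(v), ".6g"))
            if isinstance(v, (np.integer,)):
                return int(v)
            return v
        payload = [{k: coerce(r[k]) for k in keys} for r in rows]
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    with path.open("w") as fh:
        fh.write("\t".join(keys) + "\n")
        for r in rows:
            toks = []
            for k in keys:
                v = r[k]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    toks.append("NA")
                elif isinstance(v, (float, np.floating)):
                    toks.append(_fmt(float(v)))
                else:
                    toks.append(str(v))
            fh.write("\t".join(toks) + "\n")


def records_to_frame(records: Sequence[SummaryRecord]):
    """Convenience: view a record list as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame([{f.name: getattr(r, f.name) for f in fields(r)}
                         for r in records])
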