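"""Genome function profiles from protein annotation evidence.

A *function profile* is the per-genome tally of genes assigned to each
function in a reference ontology: Enzyme Commission (EC) numbers for
metabolic enzymes, KEGG Orthology (KO) ids for transmembrane transporters.
Profiles are built from tabular protein-vs-reference alignment hit tables
(the standard 12-column BLAST outfmt-6 layout) by assigning each query
protein to the function of its single best hit below an e-value cutoff.

The enzyme and transporter profiles are built independently: a protein
present in both reference sets legitimately contributes to both, and the
two function namespaces are never mixed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import NichecastError

log = logging.getLogger(__name__)

#: Column names of the standard 12-column tabular alignment format.
HIT_COLUMNS = (
    "query_id", "subject_id", "pident", "length", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

PROFILE_KINDS = ("enzyme", "transporter")


@dataclass(frozen=True)
class AnnotationHit:
    """One alignment hit of a query protein against an annotated reference."""

    query_id: str
    subject_id: str
    function_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise NichecastError(f"negative e-value for {self.query_id}: {self.evalue}")
        if not self.function_id:
            raise NichecastError(f"empty function id on hit {self.query_id} -> {self.subject_id}")


@dataclass
class FunctionProfile:
    """Counts of genes per annotated function for one genome."""

    genome_id: str
    kind: str  # 'enzyme' or 'transporter'
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise NichecastError(f"unknown profile kind {self.kind!r}; expected one of {PROFILE_KINDS}")
        bad = {f: c for f, c in self.counts.items() if c < 0}
        if bad:
            raise NichecastError(f"negative counts in profile {self.genome_id}: {bad}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def parse_function_id(subject_id: str, *, delimiter: str = "|", field_index: int = -1) -> str:
    """Extract the annotation label from a reference sequence identifier.

    Reference FASTA headers commonly carry the function as a delimited field,
    e.g. ``prot123|1.1.1.1`` or ``gi|456|K02014``. Which field holds the
    function is configurable because header conventions vary between
    reference sets.
    """
    parts = subject_id.split(delimiter)
    try:
        out = parts[field_index]
    except IndexError:
        raise NichecastError(
            f"cannot take field {field_index} of subject id {subject_id!r} (delimiter {delimiter!r})"
        ) from None
    if not out:
        raise NichecastError(f"empty function field in subject id {subject_id!r}")
    return out


def read_function_map(path: str | Path) -> dict[str, str]:
    """Read a two-column subject-id -> function-id TSV sidecar table."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise NichecastError(f"function map {path} needs two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_hits(
    path: str | Path,
    *,
    function_map: Mapping[str, str] | None = None,
    delimiter: str = "|",
    field_index: int = -1,
) -> list[AnnotationHit]:
    """Parse a 12-column alignment hit table into :class:`AnnotationHit` rows.

    Function ids come from ``function_map`` (subject -> function) when given,
    otherwise they are parsed out of the subject id itself. Malformed rows are
    logged with their line number and skipped; they are never fatal, so one
    truncated line cannot sink a whole-genome annotation run.
    """
    hits: list[AnnotationHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(HIT_COLUMNS):
                log.warning("%s line %d: expected 12 columns, got %d; row skipped",
                            path, lineno, len(fields))
                continue
            try:
                query, subject = fields[0], fields[1]
                evalue = float(fields[10])
                bitscore = float(fields[11])
                if function_map is not None:
                    if subject not in function_map:
                        log.warning("%s line %d: subject %r absent from function map; row skipped",
                                    path, lineno, subject)
                        continue
                    function = function_map[subject]
                else:
                    function = parse_function_id(subject, delimiter=delimiter, field_index=field_index)
                hits.append(AnnotationHit(query, subject, function, evalue, bitscore))
            except (ValueError, NichecastError) as exc:
                log.warning("%s line %d: %s; row skipped", path, lineno, exc)
    return hits


def assign_annotations(hits: Iterable[AnnotationHit], evalue_cutoff: float = 1e-10) -> dict[str, str]:
    """Assign each query protein the function of its single best hit.

    Only hits with e-value strictly below ``evalue_cutoff`` are considered.
    The best hit is the one with minimal e-value; ties are broken by higher
    bitscore, then lexicographically smaller subject id, which makes the
    assignment deterministic and independent of input row order. Queries with
    no passing hit are absent from the result.
    """
    if evalue_cutoff <= 0:
        raise NichecastError(f"evalue_cutoff must be positive, got {evalue_cutoff}")
    best: dict[str, AnnotationHit] = {}
    for hit in hits:
        if hit.evalue >= evalue_cutoff:
            continue
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.query_id] = hit
    return {q: h.function_id for q, h in best.items()}


def _hit_rank(hit: AnnotationHit) -> tuple[float, float, str]:
    # total order: min e-value, then max bitscore, then min subject_id
    return (hit.evalue, -hit.bitscore, hit.subject_id)


def build_profile(assignments: Mapping[str, str], genome_id: str, kind: str) -> FunctionProfile:
    """Tally query -> function assignments into a per-genome count profile."""
    return FunctionProfile(genome_id, kind, dict(Counter(assignments.values())))


def merge_profiles(profiles: list[FunctionProfile]) -> pd.DataFrame:
    """Merge single-genome profiles into a genomes x functions count matrix.

    Function columns are the sorted union of every function observed in any
    profile; a genome lacking a function gets an explicit 0 rather than a
    missing value.
    """
    if not profiles:
        raise NichecastError("no profiles to merge")
    kinds = {p.kind for p in profiles}
    if len(kinds) > 1:
        raise NichecastError(f"cannot merge profiles of mixed kinds: {sorted(kinds)}")
    seen: set[str] = set()
    for p in profiles:
        if p.genome_id in seen:
            raise NichecastError(f"duplicate genome id: {p.genome_id}")
        seen.add(p.genome_id)
    functions = sorted(set().union(*(p.counts.keys() for p in profiles)))
    matrix = pd.DataFrame(
        [[p.counts.get(f, 0) for f in functions] for p in profiles],
        index=pd.Index([p.genome_id for p in profiles], name="genome"),
        columns=functions,
        dtype=int,
    )
    return matrix


def split_matrix(matrix: pd.DataFrame, kind: str) -> list[FunctionProfile]:
    """Inverse of :func:`merge_profiles`; zero cells are dropped from counts."""
    return [
        FunctionProfile(str(g), kind, {f: int(c) for f, c in row.items() if c != 0})
        for g, row in matrix.iterrows()
    ]


def write_profile_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genomes x functions matrix as wide TSV (header row of function ids)."""
    out = matrix.copy()
    out.index.name = out.index.name or "genome"
    out.to_csv(path, sep="\t")


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    """Read a wide genomes x functions count TSV written by :func:`write_profile_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise NichecastError(f"duplicate genome ids in {path}: {dups}")
    if (df.values < 0).any():
        raise NichecastError(f"negative counts in {path}")
    return df


def read_long_profiles(path: str | Path) -> pd.DataFrame:
    """Read the long three-column dialect (genome<TAB>function<TAB>count) to a wide matrix."""
    df = pd.read_csv(path, sep="\t", header=None, names=["genome", "function", "count"],
                     dtype={"genome": str, "function": str}, comment="#")
    if df.duplicated(["genome", "function"]).any():
        dup = df[df.duplicated(["genome", "function"])].iloc[0]
        raise NichecastError(f"duplicate (genome, function) pair in {path}: "
                             f"({dup['genome']}, {dup['function']})")
    wide = df.pivot(index="genome", columns="function", values="count").fillna(0).astype(int)
    wide.columns.name = None
    wide = wide.sort_index(axis=1)
    return wide
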