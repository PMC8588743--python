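"""Sequence ingestion, primer-flanked amplicon extraction, and locus concatenation.

The pipeline consumes per-locus FASTA files (aligned or unaligned), an isolate
metadata table, and a primer table. Amplicon extraction recovers the region a
primer pair would have amplified — the interior *between* the primer sites,
primers excluded, so that downstream similarity scores do not count the
invariant primer-binding sites themselves.

Coordinates are 1-based closed intervals throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentError,
    AmbiguousPrimerMatchError,
    DuplicateRecordError,
    FastaParseError,
    PrimerOrientationError,
)

#: IUPAC nucleotide codes expanded to the unambiguous bases they stand for.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

UNAMBIGUOUS = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes and gaps."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One isolate x locus nucleotide sequence with optional taxon labels.

    ``residues`` is uppercase DNA over {A,C,G,T, IUPAC ambiguity codes, '-', 'N'}
    after ingestion ('U' is normalized to 'T'). ``untrimmed`` marks records
    returned unchanged by :func:`extract_amplicon` because a primer was absent.
    """

    isolate_id: str
    locus: str
    residues: str
    species_label: str | None = None
    population_label: str | None = None
    untrimmed: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty residues for {self.isolate_id}/{self.locus}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse PCR primers for one locus, both written 5'->3' on their own strand."""

    locus: str
    forward: str
    reverse: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.forward) < 10 or len(self.reverse) < 10:
            raise ValueError("primers must be at least 10 nt long")
        if self.max_mismatches < 0 or self.max_mismatches >= min(len(self.forward), len(self.reverse)) / 2:
            raise ValueError("max_mismatches must satisfy 0 <= m < min(primer length)/2")


@dataclass
class Alignment:
    """Equal-length rows over one locus (or a concatenation of loci).

    ``partition_map`` is only present on concatenations: a list of
    ``(locus, start, end)`` with 1-based closed column intervals that are
    disjoint, ordered, and cover exactly ``1..column_count``.
    """

    locus: str
    rows: list[SequenceRecord]
    partition_map: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"rows of unequal length in alignment {self.locus!r}: {sorted(lengths)}")
        if self.partition_map is not None:
            expected = 1
            for loc, start, end in self.partition_map:
                if start != expected or end < start:
                    raise AlignmentError(f"partition interval ({loc},{start},{end}) breaks coverage")
                expected = end + 1
            if expected != self.column_count + 1:
                raise AlignmentError("partition map does not cover all columns")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def isolate_ids(self) -> list[str]:
        return [r.isolate_id for r in self.rows]

    def row(self, isolate_id: str) -> SequenceRecord:
        for r in self.rows:
            if r.isolate_id == isolate_id:
                return r
        raise KeyError(isolate_id)

    def take_columns(self, indices: Sequence[int]) -> "Alignment":
        """New alignment from 0-based column ``indices`` (used by the bootstrap)."""
        rows = [replace(r, residues="".join(r.residues[i] for i in indices)) for r in self.rows]
        return Alignment(locus=self.locus, rows=rows)

    def slice_partition(self, locus: str) -> "Alignment":
        """Recover one locus block of a concatenation (inverse of concatenate_loci)."""
        if self.partition_map is None:
            raise AlignmentError("alignment has no partition map")
        for loc, start, end in self.partition_map:
            if loc == locus:
                rows = [replace(r, residues=r.residues[start - 1:end]) for r in self.rows]
                return Alignment(locus=locus, rows=rows)
        raise KeyError(locus)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the isolate metadata TSV (isolate_id, species, population, locality[, accession])."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "isolate_id" not in meta.columns:
        raise ValueError(f"metadata {path} lacks an isolate_id column")
    return meta


def read_primer_table(path: str | Path) -> dict[str, PrimerPair]:
    """Read the primer TSV (locus, forward, reverse, max_mismatches) into PrimerPairs."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    pairs = {}
    for row in table.itertuples(index=False):
        pairs[row.locus] = PrimerPair(
            locus=row.locus,
            forward=row.forward.upper(),
            reverse=row.reverse.upper(),
            max_mismatches=int(getattr(row, "max_mismatches", 0) or 0),
        )
    return pairs


def _normalize(residues: str) -> str:
    return residues.upper().replace("U", "T")


def read_fasta(
    path: str | Path,
    locus: str,
    metadata: pd.DataFrame | None = None,
) -> list[SequenceRecord]:
    """Read one locus from FASTA; join species/population labels from metadata.

    The first whitespace-delimited header token is the isolate id, or an
    accession that the metadata table maps to one (via an ``accession`` column).
    Residues are uppercased and 'U' is normalized to 'T'.
    """
    path = Path(path)
    first = ""
    with open(path) as handle:
        for line in handle:
            if line.strip():
                first = line
                break
    if not first.startswith(">"):
        raise FastaParseError(f"{path}: first non-blank line is not a FASTA header: {first.strip()!r}")

    by_accession: Mapping[str, str] = {}
    labels: Mapping[str, tuple[str | None, str | None]] = {}
    if metadata is not None:
        if "accession" in metadata.columns:
            by_accession = dict(zip(metadata["accession"], metadata["isolate_id"]))
        labels = {
            row.isolate_id: (getattr(row, "species", None), getattr(row, "population", None))
            for row in metadata.itertuples(index=False)
        }

    records: list[SequenceRecord] = []
    seen: set[tuple[str, str]] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        token = entry.id
        isolate = by_accession.get(token, token)
        key = (isolate, locus)
        if key in seen:
            raise DuplicateRecordError(f"duplicate record {isolate}/{locus} in {path}")
        seen.add(key)
        species, population = labels.get(isolate, (None, None))
        records.append(
            SequenceRecord(
                isolate_id=isolate,
                locus=locus,
                residues=_normalize(str(entry.seq)),
                species_label=None if pd.isna(species) else species,
                population_label=None if pd.isna(population) else population,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as minimal two-line-per-entry FASTA (round-trips read_fasta)."""
    with open(path, "w") as handle:
        for record in records:
            handle.write(f">{record.isolate_id}\n{record.residues}\n")


def _best_match(seq: str, primer: str, max_mismatches: int) -> tuple[int | None, list[int]]:
    """Best primer placement by mismatch count under IUPAC-compatible matching.

    Returns (best 0-based offset or None, all offsets achieving the best count).
    A primer position matches a target position when their IUPAC expansions
    intersect; fewer residual mismatches wins.
    """
    plen, best, hits = len(primer), None, []
    for offset in range(len(seq) - plen + 1):
        mismatches = 0
        for p, t in zip(primer, seq[offset:offset + plen]):
            if IUPAC.get(p, frozenset()).isdisjoint(IUPAC.get(t, frozenset())):
                mismatches += 1
                if best is not None and mismatches > best:
                    break
        else:
            if best is None or mismatches < best:
                best, hits = mismatches, [offset]
            elif mismatches == best:
                hits.append(offset)
    if best is None or best > max_mismatches:
        return None, []
    return hits[0], hits


def extract_amplicon(record: SequenceRecord, primers: PrimerPair) -> SequenceRecord:
    """Trim a record to the region strictly between the primer binding sites.

    The forward primer is matched on the given strand and the reverse primer as
    its reverse complement downstream; both primer sites are excluded from the
    result. If either primer is not found within ``max_mismatches``, the record
    is passed through unchanged but flagged ``untrimmed`` — deposited sequences
    may already lack primer sites.
    """
    if record.locus != primers.locus:
        raise ValueError(f"record locus {record.locus!r} != primer locus {primers.locus!r}")
    if "-" in record.residues:
        raise ValueError("extract_amplicon expects unaligned residues (no '-')")

    seq = record.residues
    fwd, fwd_hits = _best_match(seq, primers.forward, primers.max_mismatches)
    rev_primer = reverse_complement(primers.reverse)
    rev, rev_hits = _best_match(seq, rev_primer, primers.max_mismatches)

    if fwd is None or rev is None:
        return replace(record, untrimmed=True)
    if len(fwd_hits) > 1:
        raise AmbiguousPrimerMatchError(
            f"{record.isolate_id}/{record.locus}: forward primer matches equally well at "
            f"1-based positions {[h + 1 for h in fwd_hits]}"
        )
    start = fwd + len(primers.forward)
    if rev < start:
        raise PrimerOrientationError(
            f"{record.isolate_id}/{record.locus}: reverse-primer site (pos {rev + 1}) "
            f"upstream of forward-primer end (pos {start})"
        )
    return replace(record, residues=seq[start:rev])


def concatenate_loci(
    alignments: Sequence[Alignment],
    isolates: Sequence[str],
    mode: str = "strict",
) -> Alignment:
    """Concatenate per-locus alignments into a partitioned super-alignment.

    In ``strict`` mode (default) every isolate must be present in every locus;
    ``lenient`` mode gap-fills missing rows with '-'. The partition map records
    each locus's 1-based closed column interval.
    """
    if mode not in {"strict", "lenient"}:
        raise ValueError(f"unknown mode {mode!r}")
    partition_map: list[tuple[str, int, int]] = []
    pieces: dict[str, list[str]] = {iso: [] for iso in isolates}
    labels: dict[str, tuple[str | None, str | None]] = {}
    next_col = 1
    for aln in alignments:
        width = aln.column_count
        partition_map.append((aln.locus, next_col, next_col + width - 1))
        next_col += width
        present = {r.isolate_id: r for r in aln.rows}
        for iso in isolates:
            if iso in present:
                pieces[iso].append(present[iso].residues)
                rec = present[iso]
                labels.setdefault(iso, (rec.species_label, rec.population_label))
            elif mode == "strict":
                raise AlignmentError(f"isolate {iso!r} missing from locus {aln.locus!r}")
            else:
                pieces[iso].append("-" * width)
    loci = "+".join(a.locus for a in alignments)
    rows = [
        SequenceRecord(
            isolate_id=iso,
            locus=loci,
            residues="".join(pieces[iso]),
            species_label=labels.get(iso, (None, None))[0],
            population_label=labels.get(iso, (None, None))[1],
        )
        for iso in isolates
    ]
    return Alignment(locus=loci, rows=rows, partition_map=partition_map)
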