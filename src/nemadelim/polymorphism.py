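"""Species- and population-diagnostic fixed-site detection and variant naming.

A diagnostic site is an alignment column at which every member of one group
carries one unambiguous base and every member of another group carries a
different unambiguous base — the "signature" polymorphisms that separate
species, or populations within a species. Variants are named in the
``g.<pos><ref>><alt>`` style against a designated reference sequence's
ungapped coordinates (e.g. ``g.1212A>G``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

from .errors import GroupingError, ReferenceMappingError
from .seq_io import UNAMBIGUOUS, Alignment

TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' for A<->G and C<->T, 'transversion' otherwise."""
    if ref not in UNAMBIGUOUS or alt not in UNAMBIGUOUS:
        raise ValueError(f"bases must be unambiguous A/C/G/T, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("identical bases are not a substitution")
    return "transition" if frozenset((ref, alt)) in TRANSITION_PAIRS else "transversion"


@dataclass(frozen=True)
class DiagnosticSite:
    """An alignment column fixed-different between two groups."""

    alignment_column: int  # 1-based
    group_a: str
    state_a: str
    group_b: str
    state_b: str
    change_class: str
    level: str  # "species" | "population"
    reference_position: int | None = None
    insertion_relative_to_reference: bool = False

    def __post_init__(self) -> None:
        if self.state_a == self.state_b:
            raise ValueError("diagnostic site states must differ")


@dataclass(frozen=True)
class VariantName:
    """g.POSREF>ALT name plus the fields it was built from."""

    text: str
    position: int
    ref: str
    alt: str
    site: DiagnosticSite


def find_diagnostic_sites(
    alignment: Alignment,
    grouping: Mapping[str, str],
    level: str = "species",
    reference_id: str | None = None,
) -> list[DiagnosticSite]:
    """All fixed-different columns for every unordered group pair.

    Columns containing any gap or ambiguity code in any member of either group
    of a pair are skipped for that pair. Output is sorted by (group pair,
    column). ``group_a`` (the ref-state side) is the group containing
    ``reference_id`` when given, else the alphabetically first of the pair.
    """
    members: dict[str, list[str]] = {}
    for iso in alignment.isolate_ids:
        if iso not in grouping:
            raise GroupingError(f"isolate {iso!r} has no {level} group")
        members.setdefault(grouping[iso], []).append(iso)
    if len(members) < 2:
        raise GroupingError(f"need at least 2 {level} groups, got {len(members)}")
    for group, isolates in members.items():
        if not isolates:
            raise GroupingError(f"group {group!r} has no members")

    columns = {g: [alignment.row(i).residues for i in isolates] for g, isolates in members.items()}
    ref_group = grouping.get(reference_id) if reference_id else None

    sites: list[DiagnosticSite] = []
    groups = sorted(members)
    for idx_a in range(len(groups)):
        for idx_b in range(idx_a + 1, len(groups)):
            g1, g2 = groups[idx_a], groups[idx_b]
            # orient ref-state side first
            if ref_group == g2:
                ga, gb = g2, g1
            else:
                ga, gb = g1, g2
            for col in range(alignment.column_count):
                states_a = {seq[col] for seq in columns[ga]}
                states_b = {seq[col] for seq in columns[gb]}
                if not states_a <= UNAMBIGUOUS or not states_b <= UNAMBIGUOUS:
                    continue
                if len(states_a) == 1 and len(states_b) == 1 and states_a != states_b:
                    (a,), (b,) = states_a, states_b
                    sites.append(
                        DiagnosticSite(
                            alignment_column=col + 1,
                            group_a=ga, state_a=a,
                            group_b=gb, state_b=b,
                            change_class=classify_substitution(a, b),
                            level=level,
                        )
                    )
    return sites


def map_to_reference(alignment: Alignment, reference_id: str, column: int) -> tuple[int, bool]:
    """Map a 1-based alignment column to the reference's ungapped coordinates.

    Returns ``(position, is_insertion)``: the number of non-gap reference
    characters in columns 1..column. Columns where the reference itself has a
    gap map to the preceding reference position with ``is_insertion=True``.
    """
    ref = alignment.row(reference_id).residues
    if not 1 <= column <= alignment.column_count:
        raise ValueError(f"column {column} outside 1..{alignment.column_count}")
    prefix = ref[:column]
    position = len(prefix) - prefix.count("-")
    if position == 0:
        raise ReferenceMappingError(
            f"reference {reference_id!r} is all gaps up to column {column}"
        )
    return position, ref[column - 1] == "-"


def with_reference_positions(
    sites: list[DiagnosticSite], alignment: Alignment, reference_id: str
) -> list[DiagnosticSite]:
    """Annotate each site with reference coordinates (convenience wrapper)."""
    out = []
    for site in sites:
        pos, ins = map_to_reference(alignment, reference_id, site.alignment_column)
        out.append(replace(site, reference_position=pos, insertion_relative_to_reference=ins))
    return out


def name_variant(site: DiagnosticSite) -> VariantName:
    """Build the g.POSREF>ALT name, ref state taken from the reference-bearing group."""
    if site.reference_position is None:
        raise ValueError(
            "site has no reference_position; run map_to_reference / with_reference_positions first"
        )
    text = f"g.{site.reference_position}{site.state_a}>{site.state_b}"
    return VariantName(
        text=text, position=site.reference_position,
        ref=site.state_a, alt=site.state_b, site=site,
    )


def write_site_report(sites: list[DiagnosticSite], path: str | Path) -> None:
    """TSV report: group pair, level, column, reference position, name, change class."""
    with open(path, "w") as fh:
        fh.write("group_a\tgroup_b\tlevel\talignment_column\treference_position\tvariant_name\tchange_class\n")
        for s in sites:
            name = name_variant(s).text if s.reference_position is not None else ""
            fh.write(
                f"{s.group_a}\t{s.group_b}\t{s.level}\t{s.alignment_column}\t"
                f"{s.reference_position if s.reference_position is not None else ''}\t"
                f"{name}\t{s.change_class}\n"
            )
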