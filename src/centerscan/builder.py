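"""Consensus motif construction from alignments of functional centers.

Given an alignment of annotated centers (catalytic sites, gas-sensing or
hormone-binding regions) from distantly related organisms, keep only the
highly conserved "anchor" columns as fixed residues or residue classes
and collapse each run of non-conserved columns into a single ranged
wildcard whose bounds are the fewest and most non-gap residues any row
places in that run.  The result is a PROSITE-dialect search motif such
as ``Hx(12)Px(14,16)YxSxR``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import AlignIO

from .pattern import (
    STANDARD_AA,
    MotifPattern,
    PatternElement,
    length_range,
    render_pattern,
)

__all__ = [
    "RESIDUE_GROUPS",
    "CenterAlignment",
    "BuildParams",
    "ColumnProfile",
    "read_alignment",
    "column_profile",
    "profile_frame",
    "build_motif",
    "validate_motif",
]

logger = logging.getLogger(__name__)

#: Default physicochemical residue groups used both to detect conserved
#: columns and (opt-in) to complete classes with unobserved group members.
RESIDUE_GROUPS: dict[str, frozenset[str]] = {
    "basic": frozenset("KR"),
    "acidic": frozenset("DE"),
    "aliphatic": frozenset("ILVM"),
    "aromatic": frozenset("FYW"),
    "hydroxyl": frozenset("ST"),
}

GAP = "-"


@dataclass(frozen=True)
class CenterAlignment:
    """Aligned functional-center sequences with row labels."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(widths)}")
        for rid, seq in self.rows:
            bad = set(seq.upper()) - STANDARD_AA - {GAP}
            if bad:
                raise ValueError(f"row {rid}: invalid characters {sorted(bad)}")

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, index: int) -> list[str]:
        """Residues (and gaps) at a 0-based column."""
        return [seq[index].upper() for _, seq in self.rows]


@dataclass(frozen=True)
class BuildParams:
    """Stringency controls for consensus construction.

    ``conservation_threshold`` — minimum fraction of non-gap rows that the
    dominant residue (or residue group) must reach for a column to become
    an anchor.  ``max_gap_fraction`` — columns gappier than this are never
    anchors.  ``force_positions`` — 1-based column numbers always kept as
    anchors regardless of conservation.  ``complete_groups`` — when True,
    anchor classes are completed with unobserved members of each observed
    residue's group (e.g. an observed ``K`` contributes ``[KR]``).
    ``length_bounds`` — advisory motif-length window; violations warn but
    never block.
    """

    conservation_threshold: float = 0.9
    max_gap_fraction: float = 0.2
    grouping_scheme: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(RESIDUE_GROUPS)
    )
    force_positions: frozenset[int] = frozenset()
    complete_groups: bool = False
    length_bounds: tuple[int, int] = (12, 50)

    def __post_init__(self) -> None:
        if not 0 < self.conservation_threshold <= 1:
            raise ValueError("conservation_threshold must lie in (0, 1]")
        lo, hi = self.length_bounds
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length bounds ({lo},{hi})")


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column residue statistics."""

    position: int  # 1-based
    counts: tuple[tuple[str, int], ...]  # residue -> count, descending
    gap_count: int
    n_nongap: int
    top_residue: str
    residue_conservation: float
    top_group: str
    group_conservation: float

    @property
    def conservation(self) -> float:
        """Best conservation over single residues and residue groups."""
        return max(self.residue_conservation, self.group_conservation)

    @property
    def gap_fraction(self) -> float:
        return self.gap_count / (self.gap_count + self.n_nongap)


def read_alignment(path: str | Path) -> CenterAlignment:
    """Read an aligned FASTA (``-`` gaps); CLUSTAL is accepted and converted."""
    path = Path(path)
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError:
        aln = AlignIO.read(str(path), "clustal")
    return CenterAlignment(
        rows=tuple((rec.id, str(rec.seq).upper()) for rec in aln)
    )


def column_profile(
    a: CenterAlignment,
    grouping_scheme: dict[str, frozenset[str]] | None = None,
) -> list[ColumnProfile]:
    """Residue frequencies and conservation for every alignment column.

    Conservation is computed among non-gap rows only, both for the single
    most frequent residue and for the best residue group under the
    grouping scheme (ungrouped residues count as singleton groups).
    """
    scheme = RESIDUE_GROUPS if grouping_scheme is None else grouping_scheme
    group_of: dict[str, tuple[str, frozenset[str]]] = {}
    for name, members in scheme.items():
        for r in members:
            group_of[r] = (name, members)

    profiles: list[ColumnProfile] = []
    for ci in range(a.column_count):
        col = a.column(ci)
        residues = [c for c in col if c != GAP]
        gap_count = len(col) - len(residues)
        counts: dict[str, int] = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        group_counts: dict[str, int] = {}
        for r, n in counts.items():
            gname = group_of.get(r, (r, None))[0]
            group_counts[gname] = group_counts.get(gname, 0) + n
        n_nongap = len(residues)
        if n_nongap:
            top_r = max(counts, key=lambda r: (counts[r], r))
            top_g = max(group_counts, key=lambda g: (group_counts[g], g))
            res_cons = counts[top_r] / n_nongap
            grp_cons = group_counts[top_g] / n_nongap
        else:
            top_r, top_g, res_cons, grp_cons = "", "", 0.0, 0.0
        ordered = tuple(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        profiles.append(
            ColumnProfile(
                position=ci + 1,
                counts=ordered,
                gap_count=gap_count,
                n_nongap=n_nongap,
                top_residue=top_r,
                residue_conservation=res_cons,
                top_group=top_g,
                group_conservation=grp_cons,
            )
        )
    return profiles


def profile_frame(
    a: CenterAlignment,
    params: BuildParams | None = None,
) -> pd.DataFrame:
    """Tabular build report: per-column conservation and anchor decisions."""
    params = params or BuildParams()
    profs = column_profile(a, params.grouping_scheme)
    anchors = _anchor_columns(profs, params)
    return pd.DataFrame(
        {
            "position": [p.position for p in profs],
            "n_nongap": [p.n_nongap for p in profs],
            "gap_fraction": [round(p.gap_fraction, 4) for p in profs],
            "top_residue": [p.top_residue for p in profs],
            "residue_conservation": [
                round(p.residue_conservation, 4) for p in profs
            ],
            "top_group": [p.top_group for p in profs],
            "group_conservation": [
                round(p.group_conservation, 4) for p in profs
            ],
            "anchor": [p.position - 1 in anchors for p in profs],
            "residues": ["".join(r for r, _ in p.counts) for p in profs],
        }
    )


def _anchor_columns(
    profiles: list[ColumnProfile], params: BuildParams
) -> set[int]:
    """0-based indices of columns kept as anchors (threshold inclusive)."""
    anchors: set[int] = set()
    forced = {p - 1 for p in params.force_positions}
    for prof in profiles:
        ci = prof.position - 1
        if ci in forced:
            anchors.add(ci)
            continue
        if prof.n_nongap == 0:
            continue
        if prof.gap_fraction > params.max_gap_fraction:
            continue
        if prof.conservation >= params.conservation_threshold:
            anchors.add(ci)
    return anchors


def _anchor_element(
    a: CenterAlignment, ci: int, params: BuildParams
) -> PatternElement:
    observed = {c for c in a.column(ci) if c != GAP}
    if not observed:
        raise ValueError(f"forced anchor column {ci + 1} is all gaps")
    if params.complete_groups:
        completed = set(observed)
        for r in observed:
            for members in params.grouping_scheme.values():
                if r in members:
                    completed |= members
        observed = completed
    if len(observed) == 1:
        return PatternElement("fixed", frozenset(observed), 1, 1)
    return PatternElement("class", frozenset(observed), 1, 1)


def build_motif(
    a: CenterAlignment,
    params: BuildParams | None = None,
    motif_id: str = "built",
) -> MotifPattern:
    """Derive a consensus search motif from a center alignment.

    Anchor columns (conserved or forced) become fixed/class elements of
    the residues observed there; each maximal run of non-anchor columns
    becomes one wildcard whose range is the minimum and maximum number of
    non-gap residues any row spans across that run.  Leading and trailing
    non-anchor runs are trimmed.  A motif whose length range leaves the
    advisory bounds triggers a warning, not an error.
    """
    params = params or BuildParams()
    if a.n_rows < 2:
        if a.n_rows == 1 and all(c != GAP for c in a.rows[0][1]):
            # single-row pass-through: the sequence is its own motif
            els = tuple(
                PatternElement("fixed", frozenset(c), 1, 1)
                for c in a.rows[0][1].upper()
            )
            return MotifPattern(motif_id, els, source_text=a.rows[0][1])
        raise ValueError("motif building needs at least 2 aligned rows")

    profiles = column_profile(a, params.grouping_scheme)
    anchors = _anchor_columns(profiles, params)
    if not anchors:
        raise ValueError(
            "no column reaches the conservation threshold "
            f"{params.conservation_threshold}; lower it or force anchors"
        )

    first, last = min(anchors), max(anchors)
    elements: list[PatternElement] = []
    ci = first
    while ci <= last:
        if ci in anchors:
            elements.append(_anchor_element(a, ci, params))
            ci += 1
            continue
        run_start = ci
        while ci <= last and ci not in anchors:
            ci += 1
        run = range(run_start, ci)
        spans = [
            sum(1 for k in run if seq[k].upper() != GAP) for _, seq in a.rows
        ]
        lo, hi = min(spans), max(spans)
        if hi > 0:
            elements.append(PatternElement("wildcard", frozenset(), lo, hi))

    pattern = MotifPattern(
        motif_id,
        tuple(elements),
        source_text="",
    )
    pattern = MotifPattern(
        motif_id, tuple(elements), source_text=render_pattern(pattern)
    )
    for w in validate_motif(pattern, params.length_bounds):
        logger.warning("%s", w)
    return pattern


def validate_motif(
    p: MotifPattern, bounds: tuple[int, int] = (12, 50)
) -> list[str]:
    """Advisory length checks for a built or parsed motif.

    Functional centers typically span 12–50 residues: a motif shorter than
    the lower bound risks false positives, one longer than the upper bound
    risks missing candidates.  Also flags motifs made only of wildcards.
    Returns human-readable warnings; never raises.
    """
    lo, hi = length_range(p)
    lower, upper = bounds
    warnings: list[str] = []
    if lo < lower:
        warnings.append(
            f"motif {p.motif_id!r} minimum length {lo} < {lower}: "
            "too short; false-positive risk"
        )
    if hi > upper:
        warnings.append(
            f"motif {p.motif_id!r} maximum length {hi} > {upper}: "
            "too long; may miss divergent candidates"
        )
    if all(el.kind == "wildcard" for el in p.elements):
        warnings.append(
            f"motif {p.motif_id!r} contains no specific residues; "
            "it will match almost everywhere"
        )
    return warnings
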