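"""Proteome scanning with curated or user-supplied center motifs.

Bundles the five curated functional-center motifs — guanylate cyclase
(GC) and adenylate cyclase (AC) catalytic centers, the cyclic-nucleotide
phosphodiesterase (PDE) center, the heme-nitric-oxide/oxygen (H-NOX)
gas-sensing center and the abscisic-acid (ABA) interaction center — and
runs them (or any custom pattern) over a FASTA proteome.  GC/AC hits are
additionally annotated for the "cation-binding" variant: an acidic
residue (D or E) one to three positions downstream of the center, which
experimentally correlates with higher catalytic activity.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .pattern import (
    MatchSpan,
    MotifPattern,
    find_matches,
    length_range,
    parse_pattern,
    sanitize_sequence,
)
from .ranking import FEATURE_NAMES, ScoreCard

__all__ = [
    "MotifRecord",
    "HitReport",
    "BUILTIN_MOTIF_DEFS",
    "builtin_motifs",
    "load_proteome",
    "scan",
    "annotate_downstream_acidic",
    "export_hits",
    "read_hits_tsv",
    "export_candidates",
]

logger = logging.getLogger(__name__)

ACIDIC = frozenset("DE")
FLANK = 5  # residues of context kept on each side of a hit


@dataclass(frozen=True)
class MotifRecord:
    """A registered search motif with its expected span and provenance."""

    motif_id: str
    center_class: str  # GC | AC | PDE | HNOX | ABA | custom
    pattern: MotifPattern
    expected_length_range: tuple[int, int]
    provenance_note: str = ""


@dataclass(frozen=True)
class HitReport:
    """A motif occurrence enriched with context and optional scores."""

    seq_id: str
    motif_id: str
    center_class: str
    start: int  # 1-based
    end: int  # inclusive
    matched_text: str
    downstream_acidic_offset: int | None = None
    flank_before: str = ""
    flank_after: str = ""
    scores: ScoreCard | None = None

    @classmethod
    def from_span(
        cls, span: MatchSpan, center_class: str, seq: str
    ) -> "HitReport":
        s0, e0 = span.start - 1, span.end  # 0-based half-open
        return cls(
            seq_id=span.seq_id,
            motif_id=span.motif_id,
            center_class=center_class,
            start=span.start,
            end=span.end,
            matched_text=span.matched_text,
            flank_before=seq[max(0, s0 - FLANK) : s0],
            flank_after=seq[e0 : e0 + FLANK],
        )


# motif_id, center_class, pattern text (verbatim), expected length, note
BUILTIN_MOTIF_DEFS: tuple[tuple[str, str, str, tuple[int, int], str], ...] = (
    (
        "GC",
        "GC",
        "[KS]x[CGS]x(10)[KR]",
        (14, 14),
        "guanylate cyclase catalytic-center consensus, 14 aa",
    ),
    (
        "AC",
        "AC",
        "[RKS]x[DE]x(10)[KR]",
        (14, 14),
        "adenylate cyclase catalytic-center consensus, 14 aa",
    ),
    (
        "PDE",
        "PDE",
        "[YFW]Hx[YFW]Rx(20,40)[HRK][DE]",
        (27, 47),
        "cyclic-nucleotide phosphodiesterase center, 27-47 aa",
    ),
    (
        "HNOX",
        "HNOX",
        "Hx(12)Px(14,16)YxSxR",
        (33, 35),
        "heme-nitric-oxide/oxygen (H-NOX) gas-sensing center, 33-35 aa; "
        "H is the distal NO ligand, YxSxR stabilizes the porphyrin ring",
    ),
    (
        "ABA",
        "ABA",
        "[DE]x(7,8)Rx(3,4)[DE]x(5)Yx(6)H",
        (26, 28),
        "abscisic-acid interaction center from PYR/PYL receptor "
        "binding residues, 26-28 aa",
    ),
)


def builtin_motifs() -> list[MotifRecord]:
    """The five curated functional-center motifs (GC, AC, PDE, HNOX, ABA)."""
    records = []
    for motif_id, cls, text, expected, note in BUILTIN_MOTIF_DEFS:
        pattern = parse_pattern(text, motif_id)
        assert length_range(pattern) == expected, motif_id
        records.append(
            MotifRecord(
                motif_id=motif_id,
                center_class=cls,
                pattern=pattern,
                expected_length_range=expected,
                provenance_note=note,
            )
        )
    return records


def registry_hash(motifs: list[MotifRecord]) -> str:
    """Short digest of the motif set, recorded in export headers."""
    blob = "|".join(
        f"{m.motif_id}:{m.pattern.source_text}" for m in motifs
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_proteome(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA into ordered (seq_id, sequence) pairs.

    Sequences are upper-cased, trailing stop characters stripped and gap
    characters removed (each with a logged warning).  Duplicate IDs and
    empty files are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: record with empty header")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, sanitize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    logger.info("loaded %d sequences from %s", len(records), path)
    return records


def scan(
    proteome: list[tuple[str, str]],
    motifs: list[MotifRecord],
    mode: str = "all_spans",
    acidic_window: tuple[int, int] = (1, 3),
    annotate_acidic: bool = True,
) -> list[HitReport]:
    """Run every motif over every sequence.

    Hits are ordered by proteome position, then start, then end, then
    motif; they are never de-duplicated across motifs (a 14-mer matching
    both the GC and AC patterns yields two rows, since the classes carry
    distinct biology).  Sequences are visited one at a time, so memory
    stays proportional to a single sequence.
    """
    if not motifs:
        raise ValueError("motif list is empty")
    hits: list[HitReport] = []
    counts: dict[str, int] = {m.motif_id: 0 for m in motifs}
    for seq_id, seq in proteome:
        per_seq: list[tuple[int, int, str, HitReport]] = []
        for m in motifs:
            for span in find_matches(m.pattern, seq, seq_id=seq_id, mode=mode):
                hit = HitReport.from_span(span, m.center_class, seq)
                if annotate_acidic:
                    hit = annotate_downstream_acidic(hit, seq, acidic_window)
                per_seq.append((span.start, span.end, m.motif_id, hit))
                counts[m.motif_id] += 1
        per_seq.sort(key=lambda t: (t[0], t[1], t[2]))
        hits.extend(h for _, _, _, h in per_seq)
    for motif_id, n in counts.items():
        logger.info("motif %s: %d hit(s)", motif_id, n)
    return hits


def annotate_downstream_acidic(
    hit: HitReport,
    seq: str,
    window: tuple[int, int] = (1, 3),
) -> HitReport:
    """Flag the cation-binding variant of GC/AC centers.

    Records the smallest offset within ``window`` (positions downstream
    of the hit end) at which an acidic residue D or E occurs; hits of
    other center classes and hits flush with the sequence end pass
    through unchanged.
    """
    if hit.center_class not in {"GC", "AC"}:
        return hit
    w_lo, w_hi = window
    seq = seq.upper()
    for offset in range(w_lo, w_hi + 1):
        pos = hit.end - 1 + offset  # 0-based index of end + offset
        if pos >= len(seq):
            break
        if seq[pos] in ACIDIC:
            return replace(hit, downstream_acidic_offset=offset)
    return hit


# ---------------------------------------------------------------------------
# export

_TSV_COLUMNS = [
    "seq_id",
    "motif_id",
    "center_class",
    "start",
    "end",
    "length",
    "matched_seq",
    "downstream_acidic_offset",
    "flank_before",
    "flank_after",
    "overall_score",
    *[f"score_{n}" for n in FEATURE_NAMES],
    "classification",
    "selected",
]


def _header_lines(motifs: list[MotifRecord] | None, options: dict) -> list[str]:
    lines = [
        f"# centerscan v{__version__}",
        "# coordinates: 1-based, ends inclusive",
    ]
    if motifs:
        lines.append(f"# motif registry hash: {registry_hash(motifs)}")
    for k in sorted(options):
        lines.append(f"# option {k} = {options[k]}")
    return lines


def export_hits(
    hits: list[HitReport],
    path: str | Path,
    fmt: str = "TSV",
    motifs: list[MotifRecord] | None = None,
    options: dict | None = None,
) -> Path:
    """Write hits as TSV or GFF3 with a commented provenance header."""
    path = Path(path)
    options = options or {}
    fmt = fmt.upper()
    if fmt == "TSV":
        rows = []
        for h in hits:
            sc = h.scores
            rows.append(
                {
                    "seq_id": h.seq_id,
                    "motif_id": h.motif_id,
                    "center_class": h.center_class,
                    "start": h.start,
                    "end": h.end,
                    "length": h.end - h.start + 1,
                    "matched_seq": h.matched_text,
                    "downstream_acidic_offset": (
                        "" if h.downstream_acidic_offset is None
                        else h.downstream_acidic_offset
                    ),
                    "flank_before": h.flank_before,
                    "flank_after": h.flank_after,
                    "overall_score": "" if sc is None else f"{sc.overall:.6f}",
                    **{
                        f"score_{n}": (
                            "" if sc is None else f"{sc.feature_scores[n]:.6f}"
                        )
                        for n in FEATURE_NAMES
                    },
                    "classification": "" if sc is None else sc.overall_class,
                    "selected": "" if sc is None else str(sc.selected).lower(),
                }
            )
        frame = pd.DataFrame(rows, columns=_TSV_COLUMNS)
        with open(path, "w") as fh:
            for line in _header_lines(motifs, options):
                fh.write(line + "\n")
            frame.to_csv(fh, sep="\t", index=False)
    elif fmt == "GFF3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for line in _header_lines(motifs, options):
                fh.write(line + "\n")
            for h in sorted(hits, key=lambda h: (h.seq_id, h.start, h.end)):
                score = "." if h.scores is None else f"{h.scores.overall:.4f}"
                attrs = [
                    f"motif_id={h.motif_id}",
                    f"center_class={h.center_class}",
                ]
                if h.downstream_acidic_offset is not None:
                    attrs.append(
                        f"downstream_acidic_offset={h.downstream_acidic_offset}"
                    )
                if h.scores is not None:
                    attrs.append(f"selected={str(h.scores.selected).lower()}")
                fh.write(
                    "\t".join(
                        [
                            h.seq_id,
                            "centerscan",
                            "protein_match",
                            str(h.start),
                            str(h.end),
                            score,
                            ".",
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    logger.info("wrote %d hit(s) to %s (%s)", len(hits), path, fmt)
    return path


def read_hits_tsv(path: str | Path) -> pd.DataFrame:
    """Re-read an exported TSV (comments skipped); coordinates round-trip."""
    return pd.read_csv(path, sep="\t", comment="#")


def export_candidates(
    hits: list[HitReport],
    proteome: list[tuple[str, str]],
    path: str | Path,
    top_n: int = 10,
    pad: int = 20,
) -> Path:
    """FASTA of top candidate regions for downstream structural work.

    Takes the first ``top_n`` hits (rank beforehand with
    :func:`centerscan.ranking.rank_hits`), pads each by ``pad`` residues
    on both sides (clipped to the sequence bounds) and writes records
    whose headers embed the coordinates, motif and score — the handoff
    point to external homology modelling and docking.
    """
    if top_n < 0 or pad < 0:
        raise ValueError("top_n and pad must be non-negative")
    seqs = dict(proteome)
    path = Path(path)
    with open(path, "w") as fh:
        chosen = hits[:top_n]
        if not chosen:
            fh.write("; centerscan candidates: none selected\n")
        for h in chosen:
            seq = seqs[h.seq_id]
            lo = max(1, h.start - pad)
            hi = min(len(seq), h.end + pad)
            score = "NA" if h.scores is None else f"{h.scores.overall:.4f}"
            fh.write(
                f">{h.seq_id}|{lo}-{hi}|motif={h.motif_id}|"
                f"center={h.start}-{h.end}|score={score}\n"
            )
            region = seq[lo - 1 : hi]
            for i in range(0, len(region), 60):
                fh.write(region[i : i + 60] + "\n")
    logger.info("wrote %d candidate region(s) to %s", min(top_n, len(hits)), path)
    return path
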