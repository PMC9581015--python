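"""Deterministic synthetic data: random proteomes, planted motifs, toy alignments.

Everything here is seeded and reproducible, so the full
generate → scan → rank → export pipeline is testable without any
sequence download.  Planted motif instances are sampled uniformly from a
motif's language and verified against the pattern at generation time;
their exact coordinates form the ground truth for recall/precision
evaluation of a scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .builder import GAP, RESIDUE_GROUPS, BuildParams, CenterAlignment
from .pattern import MotifPattern, PatternElement, find_matches
from .scanner import HitReport, MotifRecord

__all__ = [
    "AA_ORDER",
    "EMPIRICAL_FREQS",
    "PlantedTruth",
    "ScanEvaluation",
    "random_proteome",
    "plant_instances",
    "sample_from_pattern",
    "toy_center_alignment",
    "toy_alignment_from_pattern",
    "evaluate_scan",
    "write_fasta",
    "write_truth_tsv",
]

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Approximate amino-acid frequencies in well-curated protein databases,
#: for users who want a more realistic background than the uniform null.
EMPIRICAL_FREQS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "E": 0.0672, "Q": 0.0393, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0581, "M": 0.0241, "F": 0.0386, "P": 0.0473,
    "S": 0.0664, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

# residue groups plus singletons, used to keep random alignment columns
# from drifting into spurious group-level conservation
_ALL_GROUPS: list[frozenset[str]] = list(RESIDUE_GROUPS.values()) + [
    frozenset(r) for r in "ACGHNPQ"
]

_MAX_PLACEMENT_TRIES = 1000


@dataclass(frozen=True)
class PlantedInstance:
    seq_id: str
    start: int  # 1-based
    end: int  # inclusive
    motif_id: str
    planted_text: str


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth table of planted motif instances."""

    instances: tuple[PlantedInstance, ...]
    seed: int
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ScanEvaluation:
    recall: float
    precision: float
    coordinate_exact: float


def _composition_probs(composition) -> np.ndarray:
    if composition == "uniform" or composition is None:
        return np.full(20, 1.0 / 20)
    if composition == "empirical":
        composition = EMPIRICAL_FREQS
    probs = np.array([composition.get(a, 0.0) for a in AA_ORDER], dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError("composition must be non-negative and sum to 1")
    return probs / probs.sum()


def random_proteome(
    n_seqs: int,
    length_law: int | tuple[float, float] = 300,
    composition="uniform",
    seed: int = 0,
) -> list[tuple[str, str]]:
    """I.i.d. random protein sequences.

    ``length_law`` is either a fixed length or a (mean, sd) pair for a
    normal law truncated at 1.  Identical seeds give byte-identical
    output.
    """
    if n_seqs < 0:
        raise ValueError("n_seqs must be non-negative")
    rng = np.random.default_rng(seed)
    probs = _composition_probs(composition)
    letters = np.frombuffer(AA_ORDER.encode(), dtype="S1")
    width = max(3, len(str(max(n_seqs - 1, 0))))
    records = []
    for i in range(n_seqs):
        if isinstance(length_law, tuple):
            mean, sd = length_law
            length = max(1, int(round(rng.normal(mean, sd))))
        else:
            length = int(length_law)
        seq = rng.choice(letters, size=length, p=probs).tobytes().decode()
        records.append((f"SYN{i:0{width}d}", seq))
    return records


def sample_from_pattern(p: MotifPattern, rng: np.random.Generator) -> str:
    """One string drawn uniformly from a motif's language."""
    out: list[str] = []
    for el in p.elements:
        count = int(rng.integers(el.repeat_min, el.repeat_max + 1))
        if el.kind == "wildcard":
            pool = AA_ORDER
        elif el.kind == "excluded_class":
            pool = "".join(sorted(set(AA_ORDER) - el.residues))
        else:
            pool = "".join(sorted(el.residues))
        out.extend(pool[int(rng.integers(len(pool)))] for _ in range(count))
    return "".join(out)


def plant_instances(
    proteome: list[tuple[str, str]],
    motif: MotifRecord,
    k: int,
    seed: int = 0,
    with_downstream_de: bool = False,
) -> tuple[list[tuple[str, str]], PlantedTruth]:
    """Overwrite ``k`` random non-overlapping regions with motif instances.

    Each planted string is sampled uniformly from the motif's language
    (random class members, random gap lengths and fillers) and asserted
    to match the pattern before placement.  With ``with_downstream_de``,
    a D or E is written at a random offset 1–3 past each instance —
    the cation-binding variant.  Placement uses rejection sampling with a
    retry cap; an over-full proteome is an error.
    """
    rng = np.random.default_rng(seed)
    seqs = {sid: list(s) for sid, s in proteome}
    order = [sid for sid, _ in proteome]
    occupied: dict[str, list[tuple[int, int]]] = {sid: [] for sid in order}
    instances: list[PlantedInstance] = []

    for _ in range(k):
        placed = False
        for _attempt in range(_MAX_PLACEMENT_TRIES):
            text = sample_from_pattern(motif.pattern, rng)
            spans = find_matches(motif.pattern, text)
            assert any(
                s.start == 1 and s.end == len(text) for s in spans
            ), "sampled instance fails to match its own motif"
            tail = 3 if with_downstream_de else 0
            sid = order[int(rng.integers(len(order)))]
            seq = seqs[sid]
            room = len(seq) - len(text) - tail
            if room < 0:
                continue
            pos = int(rng.integers(room + 1))  # 0-based
            span = (pos, pos + len(text) + tail)
            if any(
                span[0] < e and s < span[1] for s, e in occupied[sid]
            ):
                continue
            seq[pos : pos + len(text)] = list(text)
            de_offset = None
            if with_downstream_de:
                de_offset = int(rng.integers(1, 4))
                # scrub the window so the planted offset is the smallest hit
                for off in range(1, 4):
                    if seq[pos + len(text) + off - 1] in "DE":
                        seq[pos + len(text) + off - 1] = "G"
                seq[pos + len(text) + de_offset - 1] = "DE"[
                    int(rng.integers(2))
                ]
            occupied[sid].append(span)
            instances.append(
                PlantedInstance(
                    seq_id=sid,
                    start=pos + 1,
                    end=pos + len(text),
                    motif_id=motif.motif_id,
                    planted_text=text,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place instance {len(instances) + 1}/{k} "
                f"after {_MAX_PLACEMENT_TRIES} tries; proteome too full"
            )

    modified = [(sid, "".join(seqs[sid])) for sid in order]
    truth = PlantedTruth(
        instances=tuple(instances),
        seed=seed,
        params={
            "motif_id": motif.motif_id,
            "k": k,
            "with_downstream_de": with_downstream_de,
        },
    )
    return modified, truth


# ---------------------------------------------------------------------------
# toy alignments


def _diverse_fill(
    n_rows: int, rng: np.random.Generator
) -> list[str]:
    """One alignment column of residues from pairwise-distinct groups.

    Guarantees no column can reach group-level conservation above
    ``ceil(n/len(groups))/n``, so random filler never masquerades as an
    anchor.
    """
    perm = rng.permutation(len(_ALL_GROUPS))
    col = []
    for r in range(n_rows):
        members = sorted(_ALL_GROUPS[perm[r % len(_ALL_GROUPS)]])
        col.append(members[int(rng.integers(len(members)))])
    return col


def toy_center_alignment(
    anchors: list[str],
    gaps: list[tuple[int, int]],
    n_rows: int = 11,
    seed: int = 0,
) -> CenterAlignment:
    """Synthetic center alignment with known anchor/gap structure.

    ``anchors[i]`` is the residue (or multi-residue class, e.g. ``"KR"``)
    at the i-th anchor column; ``gaps[i]`` is the (min, max) number of
    non-gap residues each row places between anchors i and i+1 (so
    ``len(gaps) == len(anchors) - 1``).  Every class member and both gap
    extremes are guaranteed to be observed, so consensus building
    recovers the intended pattern exactly.
    """
    if len(gaps) != max(len(anchors) - 1, 0):
        raise ValueError("need exactly one gap spec between consecutive anchors")
    if not anchors:
        raise ValueError("at least one anchor required")
    if n_rows < 1:
        raise ValueError("n_rows must be positive")
    for lo, hi in gaps:
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid gap range ({lo},{hi})")
        if lo != hi and n_rows < 2:
            raise ValueError("ranged gaps need at least 2 rows")
    for a in anchors:
        if n_rows < len(set(a)):
            raise ValueError(
                f"anchor class {a!r} has more members than rows; "
                "not all residues can be observed"
            )

    rng = np.random.default_rng(seed)
    rows: list[list[str]] = [[] for _ in range(n_rows)]

    def add_anchor(members: str) -> None:
        ms = sorted(set(members))
        assign = [ms[i % len(ms)] for i in range(n_rows)]
        perm = rng.permutation(n_rows)
        for r in range(n_rows):
            rows[r].append(assign[perm[r]])

    def add_gap_run(lo: int, hi: int) -> None:
        if hi == 0:
            return
        # per-row non-gap counts; force both extremes to be observed
        ks = [int(rng.integers(lo, hi + 1)) for _ in range(n_rows)]
        if lo != hi:
            ks[0], ks[1] = lo, hi
        perm = rng.permutation(n_rows)
        ks = [ks[perm[r]] for r in range(n_rows)]
        cols = [_diverse_fill(n_rows, rng) for _ in range(hi)]
        for c in range(hi):
            for r in range(n_rows):
                rows[r].append(cols[c][r] if c < ks[r] else GAP)

    add_anchor(anchors[0])
    for (lo, hi), anchor in zip(gaps, anchors[1:]):
        add_gap_run(lo, hi)
        add_anchor(anchor)

    return CenterAlignment(
        rows=tuple(
            (f"row{r + 1:02d}", "".join(rows[r])) for r in range(n_rows)
        )
    )


def toy_alignment_from_pattern(
    p: MotifPattern, n_rows: int = 11, seed: int = 0
) -> tuple[CenterAlignment, BuildParams]:
    """Alignment whose consensus regenerates a given motif pattern.

    Non-wildcard elements become anchor columns, wildcards become gap
    runs.  Anchor classes whose residues span several physicochemical
    groups (e.g. ``[KS]``) cannot clear a group-conservation threshold
    by construction, so those columns are returned in
    ``BuildParams.force_positions``; group-pure anchors are left to
    natural conservation detection.
    """
    anchors: list[str] = []
    gaps: list[tuple[int, int]] = []
    forced: set[int] = set()
    col = 0  # running 1-based column number in the generated alignment
    pending_gap: tuple[int, int] | None = None
    for el in p.elements:
        if el.kind == "wildcard":
            if not anchors:
                raise ValueError("pattern must start with a specific element")
            if pending_gap is not None:
                raise ValueError("adjacent wildcards; merge them first")
            pending_gap = (el.repeat_min, el.repeat_max)
            col += el.repeat_max
            continue
        if el.kind == "excluded_class":
            raise ValueError("excluded classes have no alignment analogue")
        residues = "".join(sorted(el.residues))
        for _ in range(el.repeat_min):  # fixed repeats expand to columns
            if anchors:
                gaps.append(pending_gap if pending_gap is not None else (0, 0))
            pending_gap = None
            anchors.append(residues)
            col += 1
            if len(el.residues) > 1 and not any(
                el.residues <= g for g in RESIDUE_GROUPS.values()
            ):
                forced.add(col)
    if pending_gap is not None:
        raise ValueError("pattern must end with a specific element")
    # drop zero-width pseudo-gaps between consecutive anchor columns
    merged_gaps = [g if g != (0, 0) else (0, 0) for g in gaps]
    aln = toy_center_alignment(anchors, merged_gaps, n_rows=n_rows, seed=seed)
    return aln, BuildParams(force_positions=frozenset(forced))


def evaluate_scan(
    hits: list[HitReport], truth: PlantedTruth
) -> ScanEvaluation:
    """Recall / precision of a scan against planted ground truth.

    A truth instance is recovered only by a hit with identical
    (seq_id, start, end, motif_id); recall uses exact-coordinate
    matching, precision is the fraction of hits that correspond to a
    planted instance.
    """
    truth_keys = {
        (t.seq_id, t.start, t.end, t.motif_id) for t in truth.instances
    }
    hit_keys = [(h.seq_id, h.start, h.end, h.motif_id) for h in hits]
    matched = truth_keys & set(hit_keys)
    recall = len(matched) / len(truth_keys) if truth_keys else 1.0
    precision = (
        sum(1 for k in hit_keys if k in truth_keys) / len(hit_keys)
        if hit_keys
        else 0.0
    )
    return ScanEvaluation(
        recall=recall, precision=precision, coordinate_exact=recall
    )


# ---------------------------------------------------------------------------
# plain-text output helpers


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


def write_truth_tsv(truth: PlantedTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# seed = {truth.seed}; params = {truth.params}\n")
        fh.write("seq_id\tstart\tend\tmotif_id\tplanted_text\n")
        for t in truth.instances:
            fh.write(
                f"{t.seq_id}\t{t.start}\t{t.end}\t{t.motif_id}\t{t.planted_text}\n"
            )
    return path
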