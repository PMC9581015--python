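"""Physicochemical confidence scoring of motif hits.

Candidate functional centers are screened by comparing simple
physicochemical descriptors of the matched fragment — molecular weight,
isoelectric point and mean hydrophobicity (GRAVY) — against the mean
values of a pool of experimentally validated centers.  Each descriptor
receives a score in [0, 1] where 1 means "exactly at the validated
mean", scores are colour-classified (green / amber / red), and a hit is
*selected* when the overall mean score is green, at least two individual
descriptors are green, and none is red.

The score is a linear decay in the standardised distance from the
reference mean::

    score = max(0, 1 - |x - mu| / (c * sigma))      (default c = 3)

chosen for monotonicity, a bounded 0–1 range and an exact anchor of 1 at
the mean.  The spread multiplier ``c`` and the green/red cut-offs
(defaults 0.6 / 0.3) are configurable and recorded in output headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from scipy.optimize import brentq

from .pattern import STANDARD_AA

__all__ = [
    "WATER_MASS",
    "FEATURE_NAMES",
    "FeatureVector",
    "ReferenceStats",
    "ScoreCard",
    "compute_features",
    "reference_stats",
    "score_hit",
    "classify_score",
    "rank_hits",
    "residue_masses",
    "hydropathy_scale",
    "pka_table",
]

logger = logging.getLogger(__name__)

WATER_MASS = 18.01528

#: Descriptors that enter the score; net charge at pH 7 is auxiliary only.
FEATURE_NAMES = ("molecular_weight", "isoelectric_point", "gravy")


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("centerscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def residue_masses() -> dict[str, float]:
    """Average free-amino-acid masses (Da), from the shipped table."""
    df = _load_table("residue_masses.tsv")
    return dict(zip(df["residue"], df["mass"]))


def hydropathy_scale() -> dict[str, float]:
    """Kyte–Doolittle per-residue hydropathy values."""
    df = _load_table("kyte_doolittle.tsv")
    return dict(zip(df["residue"], df["hydropathy"]))


def pka_table() -> list[tuple[str, float, int]]:
    """Ionizable groups: (group, pKa, charge sign of the protonated form)."""
    df = _load_table("pka.tsv")
    return list(zip(df["group"], df["pka"], df["sign"]))


_MASSES = residue_masses()
_KD = hydropathy_scale()
_PKA = pka_table()


@dataclass(frozen=True)
class FeatureVector:
    """Physicochemical descriptors of one protein fragment."""

    molecular_weight: float  # Da
    isoelectric_point: float  # pH units
    gravy: float  # mean Kyte-Doolittle hydropathy, dimensionless
    net_charge_ph7: float  # elementary charges, auxiliary

    def get(self, name: str) -> float:
        return getattr(self, name if name != "mean_hydrophobicity" else "gravy")


@dataclass(frozen=True)
class ReferenceStats:
    """Per-feature mean and dispersion over validated-center fragments."""

    means: dict[str, float]
    sds: dict[str, float]
    n_reference: int
    provenance: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScoreCard:
    """Scores, colour classes and the selection verdict for one hit."""

    feature_scores: dict[str, float]
    feature_classes: dict[str, str]
    overall: float
    overall_class: str
    selected: bool
    downstream_acidic: bool = False  # cation-binding bonus flag, not scored


def _net_charge(seq: str, ph: float) -> float:
    """Net charge of a fragment at a given pH (Henderson–Hasselbalch)."""
    counts = {"Nterm": 1, "Cterm": 1}
    for ch in seq:
        counts[ch] = counts.get(ch, 0) + 1
    charge = 0.0
    for group, pka, sign in _PKA:
        n = counts.get(group, 0)
        if not n:
            continue
        if sign > 0:
            charge += n / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def compute_features(subseq: str) -> FeatureVector:
    """Descriptors of a fragment, deterministic to 1e-6.

    Ambiguity codes (X, B, Z, J, U, O) are excluded from every average
    with a logged warning; a fragment with no standard residue at all is
    an error.  MW uses free-residue masses minus one water per peptide
    bond; pI is the bisection root of the net-charge curve on (0, 14).
    """
    seq = subseq.upper()
    if not seq:
        raise ValueError("empty fragment")
    std = [c for c in seq if c in STANDARD_AA]
    dropped = len(seq) - len(std)
    if dropped:
        logger.warning(
            "fragment %r: %d ambiguous residue(s) excluded from averages",
            seq[:20],
            dropped,
        )
    if not std:
        raise ValueError("fragment contains no standard residues")
    bad = set(seq) - STANDARD_AA - set("XBZJUO")
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in fragment")
    n = len(std)
    mw = sum(_MASSES[c] for c in std) - (n - 1) * WATER_MASS
    gravy = sum(_KD[c] for c in std) / n
    frag = "".join(std)
    pi = brentq(lambda ph: _net_charge(frag, ph), 1e-4, 14 - 1e-4, xtol=1e-9)
    return FeatureVector(
        molecular_weight=round(mw, 6),
        isoelectric_point=round(pi, 6),
        gravy=round(gravy, 6),
        net_charge_ph7=round(_net_charge(frag, 7.0), 6),
    )


def reference_stats(
    ref_seqs: list[str] | list[tuple[str, str]],
) -> ReferenceStats:
    """Feature means and standard deviations over a validated pool.

    Accepts bare fragments or (label, fragment) pairs.  Standard
    deviations are floored at ``1e-6 * |mean| + 1e-9`` so a single-member
    or degenerate pool still yields usable (if razor-thin) spreads.
    """
    if not ref_seqs:
        raise ValueError("reference pool is empty")
    labelled = [
        s if isinstance(s, tuple) else (f"ref{i + 1}", s)
        for i, s in enumerate(ref_seqs)
    ]
    feats = pd.DataFrame(
        [
            {name: compute_features(seq).get(name) for name in FEATURE_NAMES}
            for _, seq in labelled
        ]
    )
    means = feats.mean().to_dict()
    sds = feats.std(ddof=0).fillna(0.0).to_dict()
    floored = {
        k: max(sds[k], 1e-6 * abs(means[k]) + 1e-9) for k in FEATURE_NAMES
    }
    return ReferenceStats(
        means={k: float(means[k]) for k in FEATURE_NAMES},
        sds={k: float(floored[k]) for k in FEATURE_NAMES},
        n_reference=len(labelled),
        provenance=tuple(lbl for lbl, _ in labelled),
    )


def classify_score(
    score: float, green: float = 0.6, red: float = 0.3
) -> str:
    """Colour class of a 0–1 confidence score."""
    if score >= green:
        return "green"
    if score < red:
        return "red"
    return "amber"


def score_hit(
    f: FeatureVector,
    ref: ReferenceStats,
    c: float = 3.0,
    green: float = 0.6,
    red: float = 0.3,
    downstream_acidic: bool = False,
) -> ScoreCard:
    """Score one fragment against the validated-center reference.

    Selection requires a green overall mean score, at least two green
    individual descriptors, and no red descriptor.
    """
    if c <= 0:
        raise ValueError("spread multiplier c must be positive")
    scores: dict[str, float] = {}
    classes: dict[str, str] = {}
    for name in FEATURE_NAMES:
        mu, sd = ref.means[name], ref.sds[name]
        score = max(0.0, 1.0 - abs(f.get(name) - mu) / (c * sd))
        scores[name] = score
        classes[name] = classify_score(score, green, red)
    overall = sum(scores.values()) / len(scores)
    overall_class = classify_score(overall, green, red)
    n_green = sum(1 for v in classes.values() if v == "green")
    n_red = sum(1 for v in classes.values() if v == "red")
    selected = overall_class == "green" and n_green >= 2 and n_red == 0
    return ScoreCard(
        feature_scores=scores,
        feature_classes=classes,
        overall=overall,
        overall_class=overall_class,
        selected=selected,
        downstream_acidic=downstream_acidic,
    )


def rank_hits(hits: list) -> list:
    """Order scored hits from high to low confidence.

    Sort key: selected first, then overall score, then number of green
    descriptors, then (seq_id, start) for a stable total order.  Hits
    must carry a ``scores`` ScoreCard; unscored hits sort last.
    """

    def key(h):
        sc: ScoreCard | None = h.scores
        if sc is None:
            return (1, 0.0, 0, h.seq_id, h.start)
        greens = sum(1 for v in sc.feature_classes.values() if v == "green")
        return (0 if sc.selected else 1, -sc.overall, -greens, h.seq_id, h.start)

    return sorted(hits, key=key)
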