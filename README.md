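# centerscan

Motif-based discovery of hidden functional centers in complex
multi-domain proteins.

Many proteins moonlight: besides their annotated primary domain they
carry a short *functional center* — typically 12–50 residues in which
only the few amino acids that actually perform a molecular function are
conserved. Classic examples are guanylate/adenylate cyclase (GC/AC)
catalytic centers, cyclic-nucleotide phosphodiesterase (PDE) centers,
heme-nitric-oxide/oxygen (H-NOX) gas-sensing centers and abscisic-acid
(ABA) binding centers tucked inside kinases, channels and transporters.
Because almost everything between the key residues is free to drift,
such centers sit below the detection limit of BLAST-style similarity
search. `centerscan` implements the alternative: align annotated
centers from distantly related organisms, keep only the conserved
anchors, collapse everything else into ranged gaps, and search proteomes
with the resulting PROSITE-dialect pattern, e.g.

```
[KS]-x-[CGS]-x(10)-[KR]        GC catalytic center, 14 aa
Hx(12)Px(14,16)YxSxR           H-NOX center, 33–35 aa
```

It is aimed at protein biochemists and bioinformaticians shortlisting
candidates for experimental validation (activity assays, heme/ligand
binding, structure).

## What it does

* **`pattern_engine`** (`centerscan.pattern`) — parse/render compact or
  hyphenated PROSITE-dialect patterns (classes `[KR]`, exclusions `{P}`,
  ranged wildcards `x(N,M)`, terminal anchors `<`/`>`); enumerate *all*
  overlapping match spans with a memoized polynomial matcher, backed by
  an independent brute-force oracle; relax motifs by class expansion
  (`[IL]` → `[VIL]`) or gap widening, both provably match-preserving.
* **`motif_builder`** (`centerscan.builder`) — derive a consensus motif
  from an aligned FASTA of centers: columns whose dominant residue or
  physicochemical group reaches a conservation threshold (default 0.9,
  gap fraction ≤ 0.2) become anchors; non-conserved runs become
  `x(min,max)` gaps counted per row.
* **`scanner`** (`centerscan.scanner`) — scan proteome FASTA files with
  the five curated motifs (GC, AC, PDE, HNOX, ABA) or custom patterns;
  flag the GC/AC *cation-binding variant* (D/E at 1–3 residues
  downstream of the center, associated with higher catalytic activity);
  export TSV/GFF3 and padded candidate FASTA for structural follow-up.
* **`ranking`** (`centerscan.ranking`) — score each hit 0–1 per
  physicochemical descriptor (molecular weight, isoelectric point,
  Kyte–Doolittle GRAVY) against reference statistics from validated
  centers: `score = max(0, 1 − |x − μ|/(3σ))`; classify green/amber/red
  and select candidates with a green overall score, ≥ 2 green
  descriptors and no red.
* **`simulate`** (`centerscan.simulate`) — seeded synthetic proteomes
  with planted motif instances and ground-truth coordinates, plus toy
  center alignments whose consensus provably regenerates a given motif.

## Worked example

```bash
# a 50 x 300-aa synthetic proteome with 5 planted GC centers,
# each followed by D/E 1-3 residues downstream
centerscan simulate --n 50 --len 300 --plant GC:5 --with-de --seed 42 \
    --out sim.fasta --truth truth.tsv

# scan with the curated GC motif and score against a validated pool
centerscan scan --fasta sim.fasta --motif GC --reference ref.fasta \
    --out hits.tsv --gff3 hits.gff3 --candidates cand.fasta --top-n 5
```

prints `24 hit(s) written to hits.tsv`, whose top rows are

```
seq_id  motif_id center_class start end length matched_seq    downstream_acidic_offset ... overall_score classification selected
SYN021  GC       GC           88    101 14     SLCYIVEGSGVKLK 2                            0.741181      green          true
SYN002  GC       GC           179   192 14     SVGWLPYITHSPFK                              0.741160      green          true
```

Each row is one 14-residue GC-motif occurrence (1-based inclusive
coordinates). `downstream_acidic_offset 2` means an acidic residue sits
two positions past the center — the cation-binding variant. The
`overall_score` is the mean of the three 0–1 physicochemical scores
against the reference pool; `selected true` marks candidates passing
the green/red rule. `cand.fasta` holds the top hits padded by 20
residues for downstream homology modelling and docking:

```
>SYN021|68-121|motif=GC|center=88-101|score=0.7412
FNRVCYRGFGVGLRVQSEVGSLCYIVEGSGVKLKFEMERYFPFASKWMEKFVQH
```

The same operations are available as library calls
(`parse_pattern`, `find_matches`, `build_motif`, `scan`, `score_hit`,
`rank_hits`, …) — see the module docstrings.

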