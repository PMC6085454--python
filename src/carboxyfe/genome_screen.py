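"""Genome screening for carboxydotrophy and iron-reduction determinants.

The screens collected here mirror how genomic evidence is assembled for a
CO-oxidizing Fe(III) reducer:

* degenerate-consensus scanning for CooA transcription-factor binding sites
  (the CO/redox-sensing regulator binds TGTCRNNNNNNYGACR-type palindromes
  upstream of the operons it controls);
* operon inference from intergenic distances on annotated CDS tables, and
  assignment of regulator sites to the operons they sit upstream of;
* a CXXCH heme-binding-motif census identifying multiheme c-type
  cytochromes, the workhorses of extracellular electron transfer;
* global pairwise protein alignment, active-site ligand checks and a
  reciprocal-best-hit strain comparison that isolates strain-exclusive
  proteins (e.g. a 17-heme cytochrome present only in an Fe(III)-reducing
  strain);
* fragment-based average nucleotide identity (ANI) between genomes, with
  the conventional 95% species threshold in mind.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

# --- IUPAC degenerate motif scanning ---------------------------------------

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """A consensus match, in plus-strand coordinates of its window start."""

    contig: str
    start: int       # 1-based plus-strand coordinate of the window start
    strand: str      # "+" | "-"
    matched: str     # as read on the hit's strand

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def _pattern_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern to an overlapping-match regex.

    An ``N`` in the subject matches only a pattern ``N``: an ambiguous base
    is never allowed to satisfy a constrained position.
    """
    classes = []
    for i, code in enumerate(pattern.upper()):
        if code not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i + 1}")
        allowed = IUPAC_CODES[code] + ("N" if code == "N" else "")
        classes.append(f"[{allowed}]")
    return re.compile(f"(?=({''.join(classes)}))")


def scan_iupac(seq: str, pattern: str, strands: str = "both",
               contig: str = "") -> list[MotifHit]:
    """All (overlapping) windows of *seq* matching an IUPAC consensus.

    Minus-strand hits are reported at the plus-strand coordinate of the
    window start, with ``matched`` giving the site as read on the minus
    strand (the reverse complement of the window).
    """
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    hits: list[MotifHit] = []
    if strands in ("both", "+"):
        rx = _pattern_regex(pattern)
        for m in rx.finditer(seq):
            hits.append(MotifHit(contig, m.start() + 1, "+", m.group(1)))
    if strands in ("both", "-"):
        rx = _pattern_regex(reverse_complement(pattern.upper()))
        for m in rx.finditer(seq):
            hits.append(MotifHit(contig, m.start() + 1, "-",
                                 reverse_complement(m.group(1))))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def expected_hit_density(pattern: str) -> float:
    """Probability that a uniform random window matches, per strand-position."""
    p = 1.0
    for code in pattern.upper():
        if code not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {code!r}")
        p *= len(IUPAC_CODES[code]) / 4.0
    return p


# --- gene features and operons ---------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature in 1-based inclusive coordinates."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    type: str = "CDS"
    product: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.id}: invalid coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class Operon:
    """A maximal run of same-strand genes with small intergenic gaps."""

    gene_ids: tuple[str, ...]
    contig: str
    strand: str
    span: tuple[int, int]

    @property
    def name(self) -> str:
        return self.gene_ids[0] if len(self.gene_ids) == 1 else \
            f"{self.gene_ids[0]}..{self.gene_ids[-1]}"

    def __len__(self) -> int:
        return len(self.gene_ids)


def infer_operons(features: Sequence[GeneFeature], max_gap: int = 60) -> list[Operon]:
    """Group genes into operons by intergenic distance.

    Consecutive genes on the same contig and strand whose intergenic gap is
    at most ``max_gap`` bp share an operon; a strand flip always splits.
    The default threshold sits below the 70-100 bp spacing that marks a gene
    as transcriptionally alone.  Every gene lands in exactly one operon
    (singletons are one-gene operons).
    """
    ids = [f.id for f in features]
    dup = [i for i, c in Counter(ids).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate feature ids: {dup}")
    ordered = sorted(features, key=lambda f: (f.contig, f.start, f.end))
    operons: list[Operon] = []
    run: list[GeneFeature] = []

    def flush() -> None:
        if run:
            operons.append(Operon(tuple(g.id for g in run), run[0].contig,
                                  run[0].strand,
                                  (run[0].start, max(g.end for g in run))))

    for f in ordered:
        if run:
            prev = run[-1]
            gap = f.start - prev.end - 1
            if f.contig != prev.contig or f.strand != prev.strand or gap > max_gap:
                flush()
                run = []
        run.append(f)
    flush()
    return operons


def assign_sites_to_operons(hits: Sequence[MotifHit], operons: Sequence[Operon],
                            upstream_window: int = 300) -> dict[Operon, list[MotifHit]]:
    """Map regulator sites to the operons they plausibly control.

    A hit maps to an operon if its start lies within ``upstream_window`` bp
    upstream of the operon's 5' gene start on the operon's strand; a hit
    inside any operon's span (i.e. a coding region) stays unmapped.  A hit
    maps to at most one operon: strand-matching candidates win, ties break
    by smaller upstream distance, then lower operon coordinate.
    """
    mapping: dict[Operon, list[MotifHit]] = {}
    for hit in hits:
        inside = any(op.contig == hit.contig and op.span[0] <= hit.start <= op.span[1]
                     for op in operons)
        if inside:
            continue
        candidates = []
        for op in operons:
            if op.contig != hit.contig:
                continue
            if op.strand == "+":
                distance = op.span[0] - hit.start
            else:
                distance = hit.start - op.span[1]
            if 1 <= distance <= upstream_window:
                strand_mismatch = 0 if hit.strand == op.strand else 1
                candidates.append((strand_mismatch, distance, op.span[0], op))
        if candidates:
            _, _, _, best = min(candidates, key=lambda c: c[:3])
            mapping.setdefault(best, []).append(hit)
    return mapping


# --- heme-motif census ------------------------------------------------------

# c-type heme attachment motif CXXCH; the extended policy also admits the
# rarer CX(3)CH and CX(4)CH variants.  X (unknown residue) never matches.
_SPACER = "[A-WY-Z]"
_HEME_STRICT = re.compile(f"C{_SPACER}{{2}}CH")
_HEME_EXTENDED = re.compile(f"C(?:{_SPACER}{{2}}|{_SPACER}{{3}}|{_SPACER}{{4}})CH")


@dataclass(frozen=True)
class HemeCensusEntry:
    protein_id: str
    count: int
    positions: tuple[int, ...]  # 1-based motif start positions
    length: int

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("motif positions must be strictly increasing")


def count_heme_motifs(protein: str, spacer_policy: str = "strict",
                      protein_id: str = "") -> HemeCensusEntry:
    """Non-overlapping left-to-right census of heme-binding motifs.

    ``strict`` counts only the canonical C-x(2)-C-H; ``extended`` also
    admits C-x(3)-C-H and C-x(4)-C-H, preferring the shortest variant at
    each position.
    """
    if spacer_policy not in ("strict", "extended"):
        raise ValueError("spacer_policy must be 'strict' or 'extended'")
    rx = _HEME_STRICT if spacer_policy == "strict" else _HEME_EXTENDED
    seq = protein.upper()
    positions = tuple(m.start() + 1 for m in rx.finditer(seq))
    return HemeCensusEntry(protein_id, len(positions), positions, len(seq))


def find_multihemes(proteome: Mapping[str, str], min_hemes: int = 3,
                    spacer_policy: str = "strict") -> list[HemeCensusEntry]:
    """Proteins with at least ``min_hemes`` heme-binding motifs.

    Sorted by motif count descending, then id.  The default threshold of 3
    targets multiheme cytochromes while ignoring mono/diheme proteins.
    """
    entries = [count_heme_motifs(seq, spacer_policy, protein_id=pid)
               for pid, seq in proteome.items()]
    hits = [e for e in entries if e.count >= min_hemes]
    hits.sort(key=lambda e: (-e.count, e.protein_id))
    return hits


# --- pairwise protein alignment --------------------------------------------


@dataclass(frozen=True)
class AlignmentResult:
    identity: float      # % of aligned columns (end gaps excluded) that match
    coverage_a: float    # % of sequence A inside the aligned core
    coverage_b: float
    score: float
    columns: int
    aligned_a: str = field(repr=False, default="")
    aligned_b: str = field(repr=False, default="")


def _default_aligner(scoring: Optional[dict] = None) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    scoring = scoring or {}
    matrix = scoring.get("matrix", "BLOSUM62")
    if matrix == "unit":
        aligner.match_score = 1
        aligner.mismatch_score = -1
    else:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = scoring.get("open_gap", -11)
    aligner.extend_gap_score = scoring.get("extend_gap", -1)
    # do not penalize terminal overhangs
    aligner.open_end_gap_score = 0
    aligner.extend_end_gap_score = 0
    return aligner


def pairwise_align(a: str, b: str, scoring: Optional[dict] = None) -> AlignmentResult:
    """Global affine-gap alignment with end-gap-free identity and coverage.

    Identity is matches over alignment columns between the first and last
    column where both sequences have started/not yet ended (end gaps
    excluded); coverage is the share of each sequence inside that core.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _default_aligner(scoring)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    def core(row: str) -> tuple[int, int]:
        first = len(row) - len(row.lstrip("-"))
        last = len(row.rstrip("-")) - 1
        return first, last

    fa, la = core(row_a)
    fb, lb = core(row_b)
    first, last = max(fa, fb), min(la, lb)
    columns = max(last - first + 1, 0)
    matches = sum(1 for i in range(first, last + 1)
                  if row_a[i] == row_b[i] and row_a[i] != "-")
    identity = 100.0 * matches / columns if columns else 0.0
    cov_a = 100.0 * sum(1 for i in range(first, last + 1) if row_a[i] != "-") / len(a)
    cov_b = 100.0 * sum(1 for i in range(first, last + 1) if row_b[i] != "-") / len(b)
    return AlignmentResult(identity, cov_a, cov_b, float(aln.score), columns,
                           row_a, row_b)


@dataclass(frozen=True)
class SiteRecord:
    reference_position: int
    expected: str
    aligned_residue: str  # "-" marks a deletion in the query
    conserved: bool


@dataclass(frozen=True)
class ActiveSiteReport:
    sites: tuple[SiteRecord, ...]
    identity: float
    reliable: bool

    @property
    def all_conserved(self) -> bool:
        return all(s.conserved for s in self.sites)


def check_active_site(query: str, reference: str,
                      reference_positions: Sequence[int],
                      expected_residues: Sequence[str],
                      min_identity: float = 30.0,
                      scoring: Optional[dict] = None) -> ActiveSiteReport:
    """Check conservation of reference active-site residues in a query.

    Each 1-based reference position (e.g. the Ni-coordinating Cys of a
    [Ni,Fe]-CO dehydrogenase C-cluster) is mapped through the global
    alignment; the aligned query residue ("-" for a deletion) is conserved
    iff it equals the expected residue.  Pairs aligning below
    ``min_identity`` are flagged unreliable.
    """
    if len(reference_positions) != len(expected_residues):
        raise ValueError("positions and expected residues differ in length")
    for p in reference_positions:
        if not (1 <= p <= len(reference)):
            raise ValueError(f"position {p} outside reference (length {len(reference)})")
    res = pairwise_align(query, reference, scoring)
    row_q, row_r = res.aligned_a, res.aligned_b
    # column index of each reference residue
    ref_cols = [i for i, c in enumerate(row_r) if c != "-"]
    sites = []
    for pos, expected in zip(reference_positions, expected_residues):
        col = ref_cols[pos - 1]
        aligned = row_q[col]
        sites.append(SiteRecord(pos, expected, aligned, aligned == expected))
    return ActiveSiteReport(tuple(sites), res.identity,
                            reliable=res.identity >= min_identity)


# --- strain comparison ------------------------------------------------------


@dataclass
class StrainComparison:
    shared: list[tuple[str, str, float, float]]  # (idA, idB, %identity, %coverage)
    unique_to_a: list[str]
    unique_to_b: list[str]


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _best_hits(qs: Mapping[str, str], ts: Mapping[str, str]) -> dict[str, str]:
    """Best hit per query by edit distance, with a length prescreen."""
    best: dict[str, str] = {}
    for qid, q in qs.items():
        cand, cand_d = None, None
        for tid, t in ts.items():
            if min(len(q), len(t)) < 0.4 * max(len(q), len(t)):
                continue
            d = _edit_distance(q, t)
            if cand_d is None or d < cand_d or (d == cand_d and tid < cand):
                cand, cand_d = tid, d
        if cand is not None:
            best[qid] = cand
    return best


def reciprocal_unique(proteome_a: Mapping[str, str], proteome_b: Mapping[str, str],
                      min_identity: float = 40.0,
                      min_coverage: float = 70.0) -> StrainComparison:
    """Reciprocal-best-hit orthology and strain-exclusive proteins.

    A pair is shared when each protein is the other's best match and the
    global alignment clears the identity and coverage floors; everything
    else is unique to its strain.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    ab = _best_hits(proteome_a, proteome_b)
    ba = _best_hits(proteome_b, proteome_a)
    shared, unique_a = [], []
    paired_b: set[str] = set()
    for ida, seq_a in proteome_a.items():
        idb = ab.get(ida)
        if idb is not None and ba.get(idb) == ida:
            res = pairwise_align(seq_a, proteome_b[idb])
            coverage = min(res.coverage_a, res.coverage_b)
            if res.identity >= min_identity and coverage >= min_coverage:
                shared.append((ida, idb, res.identity, coverage))
                paired_b.add(idb)
                continue
        unique_a.append(ida)
    unique_b = [idb for idb in proteome_b if idb not in paired_b]
    return StrainComparison(shared, sorted(unique_a), sorted(unique_b))


# --- average nucleotide identity -------------------------------------------


class ANIError(ValueError):
    pass


def _identity_from_cigar(cigar: str, edit_distance: int) -> float:
    """Identity over alignment columns from an edlib CIGAR."""
    columns = sum(int(n) for n in re.findall(r"(\d+)[=XMIDN]", cigar))
    if columns == 0:
        return 0.0
    return 100.0 * (columns - edit_distance) / columns


def _kmer_index(genome: str, k: int, step: int) -> dict[str, int]:
    return {genome[i:i + k]: i for i in range(0, len(genome) - k + 1, step)}


def _best_fragment_identity(fragment: str, genome: str, index: dict[str, int],
                            k: int, max_offsets: int = 3) -> Optional[float]:
    """Place one fragment in the target genome by seed-and-extend.

    Seeds are shared k-mers against a sampled index of the target; each
    candidate offset gets a banded (edlib infix) alignment of the fragment
    against a window around it, and the best identity is kept.
    """
    offsets: Counter = Counter()
    for i in range(0, len(fragment) - k + 1):
        pos = index.get(fragment[i:i + k])
        if pos is not None:
            offsets[pos - i] += 1
    if not offsets:
        return None
    best = None
    pad = 64
    for off, _ in offsets.most_common(max_offsets):
        lo = max(off - pad, 0)
        hi = min(off + len(fragment) + pad, len(genome))
        res = edlib.align(fragment, genome[lo:hi], mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        ident = _identity_from_cigar(res["cigar"], res["editDistance"])
        if best is None or ident > best:
            best = ident
    return best


def _ani_one_direction(a: str, b: str, fragment_length: int, min_identity: float,
                       k: int = 16, index_step: int = 4) -> list[float]:
    index = _kmer_index(b.upper(), k, index_step)
    b_up = b.upper()
    identities = []
    a_up = a.upper()
    for start in range(0, len(a_up) - fragment_length + 1, fragment_length):
        frag = a_up[start:start + fragment_length]
        ident = _best_fragment_identity(frag, b_up, index, k)
        if ident is None:
            ident = _best_fragment_identity(reverse_complement(frag), b_up, index, k)
        if ident is not None and ident >= min_identity:
            identities.append(ident)
    return identities


def ani(genome_a: str, genome_b: str, fragment_length: int = 1020,
        min_identity: float = 30.0) -> float:
    """Fragment-based average nucleotide identity, in percent.

    Genome A is chopped into consecutive ``fragment_length`` bp fragments,
    each aligned to its best location in genome B (seed-and-extend, then a
    windowed edlib alignment spanning the whole fragment, so the canonical
    70%-of-length coverage condition holds by construction).  Fragments
    under ``min_identity`` % identity are discarded; the directional ANI is
    the mean identity of the kept fragments, and the reported value averages
    both directions.  Values of 95% and above indicate a single species.
    """
    if len(genome_a) < 2 * fragment_length or len(genome_b) < 2 * fragment_length:
        raise ANIError("genomes must be at least two fragments long")
    fwd = _ani_one_direction(genome_a, genome_b, fragment_length, min_identity)
    rev = _ani_one_direction(genome_b, genome_a, fragment_length, min_identity)
    if not fwd or not rev:
        raise ANIError("genomes too divergent: no fragment passed the filters")
    return float((np.mean(fwd) + np.mean(rev)) / 2.0)


# --- I/O --------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_TABLE_COLUMNS = ("id", "contig", "start", "end", "strand", "type", "product")


def read_feature_table(path) -> list[GeneFeature]:
    """Minimal tab-separated feature table (id, contig, start, end, strand,
    type, product)."""
    features = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TABLE_COLUMNS:
            raise ValueError(f"expected columns {_TABLE_COLUMNS}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            fid, contig, start, end, strand, ftype, product = \
                line.rstrip("\n").split("\t")
            features.append(GeneFeature(fid, contig, int(start), int(end),
                                        strand, ftype, product))
    return features


def write_feature_table(features: Iterable[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for f in features:
            fh.write(f"{f.id}\t{f.contig}\t{f.start}\t{f.end}\t{f.strand}\t"
                     f"{f.type}\t{f.product}\n")


def read_gff3(path) -> list[GeneFeature]:
    """Minimal GFF3 reader for CDS/RNA features (ID and product attributes)."""
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in ("CDS", "RNA", "gene", "tRNA", "rRNA"):
                continue
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            fid = fields.get("ID", f"{contig}:{start}-{end}")
            features.append(GeneFeature(fid, contig, int(start), int(end), strand,
                                        "RNA" if ftype.endswith("RNA") else "CDS",
                                        fields.get("product", "")))
    return features


def write_gff3(features: Iterable[GeneFeature], path,
               contig_lengths: Optional[Mapping[str, int]] = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for contig, length in contig_lengths.items():
                fh.write(f"##sequence-region {contig} 1 {length}\n")
        for f in features:
            attrs = f"ID={f.id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(f"{f.contig}\tcarboxyfe\t{f.type}\t{f.start}\t{f.end}\t.\t"
                     f"{f.strand}\t0\t{attrs}\n")


def write_bed(hits: Iterable[MotifHit], path) -> None:
    """Motif hits as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for h in hits:
            end = h.start - 1 + len(h.matched)
            fh.write(f"{h.contig}\t{h.start - 1}\t{end}\tmotif\t0\t{h.strand}\n")


def census_tsv(entries: Iterable[HemeCensusEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\theme_count\tlength_aa\tpositions\n")
        for e in entries:
            pos = ",".join(map(str, e.positions))
            fh.write(f"{e.protein_id}\t{e.count}\t{e.length}\t{pos}\n")
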