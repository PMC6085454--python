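"""Motif scanning, operon inference, heme census, alignment and ANI."""

import numpy as np
import pytest

from carboxyfe import genome_screen as gs
from carboxyfe.synthetic_data import (COOA_CONSENSUS, mutate_sequence,
                                      random_genome)

# --- IUPAC scanning --------------------------------------------------------


def brute_force_scan(seq, pattern, strands="both"):
    """Window-by-window reference matcher (independent of the regex path)."""
    seq = seq.upper()
    hits = []

    def match_at(s, pat, i):
        for j, code in enumerate(pat):
            allowed = gs.IUPAC_CODES[code] + ("N" if code == "N" else "")
            if s[i + j] not in allowed:
                return False
        return True

    n, m = len(seq), len(pattern)
    if strands in ("both", "+"):
        for i in range(n - m + 1):
            if match_at(seq, pattern, i):
                hits.append(("+", i + 1, seq[i:i + m]))
    if strands in ("both", "-"):
        rc_pat = gs.reverse_complement(pattern)
        for i in range(n - m + 1):
            if match_at(seq, rc_pat, i):
                hits.append(("-", i + 1, gs.reverse_complement(seq[i:i + m])))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def test_scan_single_consensus_instance():
    hits = gs.scan_iupac("TGTCAAAAAAATGACA", COOA_CONSENSUS, strands="+")
    assert len(hits) == 1
    assert hits[0].start == 1 and hits[0].strand == "+"
    assert hits[0].matched == "TGTCAAAAAAATGACA"


def test_scan_homopolymer_has_no_hits():
    assert gs.scan_iupac("A" * 100, COOA_CONSENSUS) == []


def test_scan_strand_symmetry():
    seq = random_genome(5000, 0.5, seed=42)
    fwd = gs.scan_iupac(seq, COOA_CONSENSUS)
    rev = gs.scan_iupac(gs.reverse_complement(seq), COOA_CONSENSUS)
    assert len(fwd) == len(rev)
    # a + hit at position p mirrors a - hit at L - p - len + 2
    L, m = len(seq), len(COOA_CONSENSUS)
    fwd_keys = sorted((h.start, h.strand, h.matched) for h in fwd)
    mirrored = sorted((L - h.start - m + 2, {"+": "-", "-": "+"}[h.strand],
                       h.matched) for h in rev)
    assert fwd_keys == mirrored


def test_scan_agrees_with_brute_force_on_random_sequences():
    for seed in range(5):
        seq = random_genome(10_000, 0.49, seed=seed)
        got = sorted((h.strand, h.start, h.matched)
                     for h in gs.scan_iupac(seq, COOA_CONSENSUS))
        want = sorted(brute_force_scan(seq, COOA_CONSENSUS))
        assert got == want


def test_scan_overlapping_hits_reported():
    # TGTCA twice overlapping with pattern TGTC
    hits = gs.scan_iupac("TGTCGTCG", "TGTC", strands="+")
    assert [h.start for h in hits] == [1]
    hits = gs.scan_iupac("TGTGTC", "TGTC", strands="+")
    assert [h.start for h in hits] == [3]
    hits = gs.scan_iupac("AAAA", "AA", strands="+")
    assert [h.start for h in hits] == [1, 2, 3]


def test_scan_subject_n_never_matches_fixed_letters():
    assert gs.scan_iupac("TGTCNAAAAAATGACA", COOA_CONSENSUS, strands="+") == []
    # ...but N in the subject does match a pattern N
    hits = gs.scan_iupac("TGTCANNNNNATGACA", COOA_CONSENSUS, strands="+")
    assert len(hits) == 1


def test_scan_invalid_code_named():
    with pytest.raises(ValueError, match="position 3"):
        gs.scan_iupac("ACGT", "AC!T")
    with pytest.raises(ValueError, match="non-ACGTN"):
        gs.scan_iupac("ACXT", "ACGT")


def test_expected_hit_density():
    # 7 fixed letters and 3 two-fold degenerate positions
    assert gs.expected_hit_density(COOA_CONSENSUS) == pytest.approx(
        (1 / 4) ** 7 * (1 / 2) ** 3)


# --- operons ---------------------------------------------------------------


def _genes(spans, strand="+", contig="c"):
    return [gs.GeneFeature(f"g{i}", contig, a, b, s if isinstance(s, str) else strand)
            for i, (a, b, *rest) in enumerate(spans)
            for s in [rest[0] if rest else strand]]


def test_operon_small_gaps_merge():
    feats = _genes([(1, 100), (111, 200), (221, 300)])  # gaps 10 and 20
    ops = gs.infer_operons(feats, max_gap=60)
    assert len(ops) == 1 and len(ops[0]) == 3


def test_operon_large_gap_splits():
    feats = _genes([(1, 100), (111, 200), (281, 400)])  # gaps 10 and 80
    ops = gs.infer_operons(feats, max_gap=60)
    assert sorted(len(o) for o in ops) == [1, 2]


def test_operon_strand_flip_always_splits():
    feats = _genes([(1, 100, "+"), (105, 200, "-"), (205, 300, "-")])
    ops = gs.infer_operons(feats, max_gap=1000)
    assert sorted(len(o) for o in ops) == [1, 2]


def test_operon_duplicate_ids_rejected():
    feats = [gs.GeneFeature("g1", "c", 1, 100, "+"),
             gs.GeneFeature("g1", "c", 200, 300, "+")]
    with pytest.raises(ValueError, match="duplicate"):
        gs.infer_operons(feats)


def test_operons_partition_gene_set():
    rng = np.random.default_rng(0)
    pos, feats = 1, []
    for i in range(60):
        length = int(rng.integers(90, 900))
        feats.append(gs.GeneFeature(
            f"g{i}", f"ctg{i % 3}", pos, pos + length,
            "+" if rng.random() < 0.5 else "-"))
        pos += length + int(rng.integers(1, 200))
    ops = gs.infer_operons(feats, max_gap=60)
    seen = [g for op in ops for g in op.gene_ids]
    assert sorted(seen) == sorted(f.id for f in feats)
    assert len(seen) == len(set(seen))


def test_site_assignment_coding_region_unmapped():
    ops = gs.infer_operons(_genes([(1000, 2000)]))
    hit = gs.MotifHit("c", 1500, "+", "TGTCAAAAAAATGACA")
    assert gs.assign_sites_to_operons([hit], ops) == {}


def test_site_assignment_divergent_tie_prefers_strand_match():
    left = gs.GeneFeature("gl", "c", 100, 900, "-")
    right = gs.GeneFeature("gr", "c", 1200, 2000, "+")
    ops = gs.infer_operons([left, right])
    # equidistant upstream of both divergent operons (50 bp each side)
    hit = gs.MotifHit("c", 1000 + 50, "+", "TGTCAAAAAAATGACA")
    mapping = gs.assign_sites_to_operons([hit], ops, upstream_window=300)
    [(op, hits)] = mapping.items()
    assert op.gene_ids == ("gr",)


def test_site_assignment_planted_pair(strain_pair):
    b = strain_pair.strain_b
    hits = gs.scan_iupac(b.genome, COOA_CONSENSUS, contig=b.name)
    planted = set(strain_pair.truth["strain_b"]["cooA_sites"])
    assert planted <= {h.start for h in hits}
    ops = gs.infer_operons(b.features)
    mapping = gs.assign_sites_to_operons(hits, ops)
    flagged = {op.gene_ids: {h.start for h in hs} for op, hs in mapping.items()}
    coo = strain_pair.truth["strain_b"]["coo_operons"]
    # the cooS-cooC and ECH operons carry the two planted sites upstream
    assert tuple(coo[1]) in flagged and planted & flagged[tuple(coo[1])]
    assert tuple(coo[2]) in flagged and planted & flagged[tuple(coo[2])]


# --- heme census -----------------------------------------------------------


def brute_force_heme_count(seq, policy):
    """Reference non-overlapping left-to-right scanner."""
    spans = {"strict": (2, 2), "extended": (2, 4)}[policy]
    i, count = 0, 0
    n = len(seq)
    while i < n:
        matched = False
        for spacer in range(spans[0], spans[1] + 1):
            j = i + spacer + 3
            if j <= n and seq[i] == "C" and seq[i + spacer + 1] == "C" \
                    and seq[i + spacer + 2] == "H" \
                    and "X" not in seq[i + 1:i + spacer + 1]:
                count += 1
                i = j
                matched = True
                break
        if not matched:
            i += 1
    return count


@pytest.mark.parametrize("seq,strict,extended", [
    ("CAACH", 1, 1),
    ("CAACHGGCAACH", 2, 2),
    ("CAACAACH", 1, 1),   # CxxCH sits at offset 4; confirmed by the oracle
    ("CAAACH", 0, 1),     # C-x(3)-C-H only counts in extended mode
    ("CAAAACH", 0, 1),    # C-x(4)-C-H likewise
    ("", 0, 0),
])
def test_heme_motif_examples(seq, strict, extended):
    assert brute_force_heme_count(seq, "strict") == strict
    assert brute_force_heme_count(seq, "extended") == extended
    assert gs.count_heme_motifs(seq, "strict").count == strict
    assert gs.count_heme_motifs(seq, "extended").count == extended


def test_heme_motif_oracle_equivalence_over_small_alphabet():
    """Exhaustive agreement with the brute-force scanner on all <=8-mers
    over {C, A, H} (covers every spacer/overlap interaction)."""
    from itertools import product
    for n in range(1, 9):
        for letters in product("CAH", repeat=n):
            seq = "".join(letters)
            for policy in ("strict", "extended"):
                assert (gs.count_heme_motifs(seq, policy).count
                        == brute_force_heme_count(seq, policy)), (seq, policy)


def test_heme_motif_x_never_matches():
    assert gs.count_heme_motifs("CAXCH").count == 0
    assert gs.count_heme_motifs("XAACH").count == 0


def test_heme_positions_strictly_increasing():
    entry = gs.count_heme_motifs("CAACHGGCAACHGGCAACH")
    assert entry.count == 3
    assert list(entry.positions) == sorted(entry.positions)


def test_find_multihemes_on_planted_proteomes(strain_pair):
    census_a = gs.find_multihemes(strain_pair.strain_a.proteome)
    census_b = gs.find_multihemes(strain_pair.strain_b.proteome)
    assert len(census_a) == 30
    assert len(census_b) == 31
    counts = {e.protein_id: e.count for e in census_b}
    for locus, planted in strain_pair.truth["strain_b"]["multiheme_counts"].items():
        assert counts[locus] == planted
    # counts sorted descending
    values = [e.count for e in census_b]
    assert values == sorted(values, reverse=True)


def test_find_multihemes_monotone_in_threshold(strain_pair):
    proteome = strain_pair.strain_a.proteome
    lengths = [len(gs.find_multihemes(proteome, min_hemes=k))
               for k in (1, 3, 5, 10, 18)]
    assert lengths == sorted(lengths, reverse=True)
    heme_free = {"p1": "AAAAGGGG", "p2": "MKLV"}
    assert gs.find_multihemes(heme_free, min_hemes=1) == []


# --- pairwise alignment ----------------------------------------------------


def brute_force_best_alignment(a, b):
    """Exhaustive alignment enumeration under unit match/mismatch/gap costs,
    maximizing matches - mismatches - gaps; returns the best score."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = -10**9
        if i < len(a) and j < len(b):
            best = max(best, (1 if a[i] == b[j] else -1) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, -1 + rec(i + 1, j))
        if j < len(b):
            best = max(best, -1 + rec(i, j + 1))
        return best

    return rec(0, 0)


def test_identical_sequences_align_perfectly():
    res = gs.pairwise_align("MKTAYIAKQR", "MKTAYIAKQR")
    assert res.identity == 100.0
    assert res.coverage_a == res.coverage_b == 100.0


def test_internal_gap_identity_matches_dp_oracle():
    scoring = {"matrix": "unit", "open_gap": -1, "extend_gap": -1}
    res = gs.pairwise_align("ACD", "AD", scoring)
    assert res.identity == pytest.approx(100 * 2 / 3)
    assert res.columns == 3
    # oracle: best unit-cost alignment has 2 matches and one gap (score 1)
    assert brute_force_best_alignment("ACD", "AD") == 1


def test_alignment_symmetric_under_swap():
    a, b = "MKTACYWIAK", "MKTCYWMAK"
    r1 = gs.pairwise_align(a, b)
    r2 = gs.pairwise_align(b, a)
    assert r1.identity == pytest.approx(r2.identity)
    assert r1.coverage_a == pytest.approx(r2.coverage_b)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        gs.pairwise_align("", "ACD")


# --- active-site conservation ----------------------------------------------


def test_active_site_identity_case():
    ref = "MKTAYICKQRHG"
    report = gs.check_active_site(ref, ref, [7], ["C"])
    assert report.all_conserved and report.reliable


def test_active_site_substitution_detected():
    report = gs.check_active_site("AAGAA", "AACAA", [3], ["C"],
                                  scoring={"matrix": "unit"})
    assert not report.sites[0].conserved
    assert report.sites[0].aligned_residue == "G"


def test_active_site_deletion_reported_as_gap():
    ref = "MKTAYICKQRHG"
    query = "MKTAYIKQRHG"  # the catalytic C deleted
    report = gs.check_active_site(query, ref, [7], ["C"],
                                  scoring={"matrix": "unit", "open_gap": -2,
                                           "extend_gap": -2})
    assert report.sites[0].aligned_residue == "-"
    assert not report.sites[0].conserved


def test_active_site_position_bounds():
    with pytest.raises(ValueError, match="outside reference"):
        gs.check_active_site("AAA", "AAA", [4], ["A"])


# --- strain comparison ------------------------------------------------------


def test_reciprocal_unique_on_strain_pair(strain_pair):
    comp = gs.reciprocal_unique(strain_pair.strain_a.proteome,
                                strain_pair.strain_b.proteome)
    assert comp.unique_to_a == []
    assert comp.unique_to_b == [strain_pair.truth["unique_locus_b"]]
    unique_entry = gs.count_heme_motifs(
        strain_pair.strain_b.proteome[comp.unique_to_b[0]])
    assert unique_entry.count == strain_pair.truth["unique_hemes"] == 17


def test_reciprocal_unique_identical_proteomes():
    proteome = {"p1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
                "p2": "MSLNRRQFLQLLGGLTAAGLAGCAAQSDDA"}
    comp = gs.reciprocal_unique(proteome, dict(proteome))
    assert comp.unique_to_a == [] and comp.unique_to_b == []
    assert len(comp.shared) == 2


def test_reciprocal_unique_disjoint_proteomes():
    rng = np.random.default_rng(3)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    make = lambda n: {f"q{i}": "".join(rng.choice(aas, 60)) for i in range(n)}
    comp = gs.reciprocal_unique(make(4), make(4), min_identity=40)
    assert len(comp.unique_to_a) == 4 and len(comp.unique_to_b) == 4


# --- ANI --------------------------------------------------------------------


def test_ani_self_is_perfect():
    g = random_genome(60_000, 0.49, seed=5)
    assert gs.ani(g, g) == 100.0


def test_ani_tracks_substitution_rate_and_is_symmetric():
    g = random_genome(120_000, 0.49, seed=6)
    values = []
    for rate, seed in ((0.003, 1), (0.03, 2), (0.10, 3)):
        m = mutate_sequence(g, rate, seed)
        fwd, rev = gs.ani(g, m), gs.ani(m, g)
        assert abs(fwd - rev) < 0.2
        values.append(fwd)
        assert fwd == pytest.approx(100 * (1 - rate), abs=0.5)
    assert values == sorted(values, reverse=True)


def test_ani_too_short_rejected():
    with pytest.raises(gs.ANIError, match="two fragments"):
        gs.ani("ACGT" * 100, "ACGT" * 100)


# --- I/O --------------------------------------------------------------------


def test_feature_table_roundtrip(tmp_path, strain_pair):
    feats = strain_pair.strain_a.features[:10]
    path = tmp_path / "features.tsv"
    gs.write_feature_table(feats, path)
    assert gs.read_feature_table(path) == feats


def test_gff3_roundtrip(tmp_path, strain_pair):
    feats = strain_pair.strain_a.features[:10]
    path = tmp_path / "features.gff3"
    gs.write_gff3(feats, path, {"strain_A": 120_000})
    back = gs.read_gff3(path)
    assert [(f.id, f.contig, f.start, f.end, f.strand) for f in back] == \
           [(f.id, f.contig, f.start, f.end, f.strand) for f in feats]


def test_fasta_roundtrip(tmp_path):
    records = {"a": "ACGTACGT", "b": "TTTTCCCC"}
    path = tmp_path / "seqs.fna"
    gs.write_fasta(records, path)
    assert gs.read_fasta(path) == records


def test_bed_output(tmp_path):
    hits = [gs.MotifHit("ctg", 101, "+", "TGTCAAAAAAATGACA")]
    path = tmp_path / "hits.bed"
    gs.write_bed(hits, path)
    fields = path.read_text().strip().split("\t")
    assert fields[:3] == ["ctg", "100", "116"] and fields[5] == "+"
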