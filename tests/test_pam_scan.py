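"""PAM scanning and editable-coverage, checked against naive oracles."""

import numpy as np
import pytest

from yeastedit.pam_scan import (
    ALL_SYSTEMS,
    ASCAS12A,
    SACAS9,
    SPCAS9,
    coverage_fraction,
    editable_positions,
    find_pam_sites,
    get_system,
    read_coverage_tsv,
    write_coverage_tsv,
    write_sites_bed,
)
from yeastedit.seq_core import NucSequence, matches_iupac, revcomp
from yeastedit.synth import SyntheticGenomeSpec, synth_genome


# ---------------------------------------------------------------- oracles


def naive_site_set(seq: NucSequence, system) -> set[tuple[int, str]]:
    """Every PAM occurrence as (plus-strand pam_start, strand), found by
    testing each window on the plus strand and on the explicit reverse
    complement with coordinates re-projected."""
    n, L = len(seq), system.pam_len
    out = set()
    for i in range(n - L + 1):
        if matches_iupac(system.pam, seq.seq[i : i + L]):
            out.add((i, "+"))
    rc = revcomp(seq.seq)
    for j in range(n - L + 1):
        if matches_iupac(system.pam, rc[j : j + L]):
            out.add((n - L - j, "-"))
    return out


def naive_editable_mask(seq: NucSequence, system) -> np.ndarray:
    """Per-nucleotide marking computed strand-locally on the oriented
    sequence, then projected — independent of the implementation's
    plus-strand interval arithmetic."""
    n, L, W = len(seq), system.pam_len, system.editable_window_len
    mask = np.zeros(n, dtype=bool)

    def mark_local(s: str, project):
        for j in range(n - L + 1):
            if not matches_iupac(system.pam, s[j : j + L]):
                continue
            if system.pam_side == "three_prime":
                window = range(j - W, j)
            else:
                window = range(j + L, j + L + W)
            for q in window:
                if 0 <= q < n:
                    mask[project(q)] = True
            for k in range(L):
                if k not in system.pam.degenerate_positions:
                    mask[project(j + k)] = True

    mark_local(seq.seq, lambda q: q)
    mark_local(revcomp(seq.seq), lambda q: n - 1 - q)
    return mask


# ---------------------------------------------------------- find_pam_sites


def test_edge_site_is_truncated():
    sites = find_pam_sites(NucSequence("chrI", "AAAACGGAAA"), SPCAS9)
    assert len(sites) == 1
    (s,) = sites
    assert s.strand == "+"
    assert s.pam_interval == (4, 7)
    assert s.protospacer_interval == (0, 4)
    assert s.truncated


def test_no_match_returns_empty():
    for system in ALL_SYSTEMS:
        assert find_pam_sites(NucSequence("x", "A" * 40), system) == []


def test_five_prime_pam_places_protospacer_downstream():
    seq = NucSequence("x", "TTTC" + "A" * 30)
    sites = [
        s for s in find_pam_sites(seq, ASCAS12A) if s.strand == "+"
    ]
    assert sites[0].pam_interval == (0, 4)
    assert sites[0].protospacer_interval == (4, 27)
    assert not sites[0].truncated


def test_overlapping_occurrences_all_reported():
    # NGG matches at consecutive offsets inside a G run
    seq = NucSequence("x", "AAAGGGGAAA")
    starts = [
        s.pam_interval[0]
        for s in find_pam_sites(seq, SPCAS9)
        if s.strand == "+"
    ]
    assert starts == [2, 3, 4]


def test_scanner_matches_naive_oracle_random_sequences():
    genome = synth_genome(
        SyntheticGenomeSpec(n_contigs=20, contig_len=2000, gc=0.45, seed=3)
    )
    for contig in genome:
        for system in ALL_SYSTEMS:
            found = {
                (s.pam_interval[0], s.strand)
                for s in find_pam_sites(contig, system)
            }
            assert found == naive_site_set(contig, system)


def test_scanner_agrees_with_biopython_motif_search(yeastlike_genome):
    """Independent cross-check: plus-strand PAM starts match Biopython's
    IUPAC-aware nt_search on the forward and reverse-complemented text."""
    from Bio.SeqUtils import nt_search

    contig = yeastlike_genome[0]
    n = len(contig)
    for system in ALL_SYSTEMS:
        pat, L = system.pam.pattern, system.pam_len
        plus = set(nt_search(contig.seq, pat)[1:])
        minus = {n - L - j for j in nt_search(revcomp(contig.seq), pat)[1:]}
        found_plus = {
            s.pam_interval[0]
            for s in find_pam_sites(contig, system)
            if s.strand == "+"
        }
        found_minus = {
            s.pam_interval[0]
            for s in find_pam_sites(contig, system)
            if s.strand == "-"
        }
        assert found_plus == plus
        assert found_minus == minus


def test_sites_sorted_and_within_bounds(yeastlike_genome):
    for contig in yeastlike_genome:
        for system in ALL_SYSTEMS:
            sites = find_pam_sites(contig, system)
            keys = [(s.pam_interval[0], s.strand) for s in sites]
            assert keys == sorted(keys)
            for s in sites:
                a, b = s.footprint
                assert 0 <= a < b <= len(contig)


# ------------------------------------------------------ editable_positions


def test_per_site_editable_counts(planted_genome):
    """Full-length sites contribute exactly 13 (Sp: 11+GG), 13 (Sa: 11+G,T)
    and 20 (As12a: 17+TTT) positions."""
    contig, plants = planted_genome
    expected = {"SpCas9": 13, "SaCas9": 13, "AsCas12a": 20}
    for plant in plants:
        system = get_system(plant.system)
        sites = [
            s
            for s in find_pam_sites(contig, system)
            if s.strand == plant.strand
            and s.footprint[0] == plant.position
        ]
        assert sites, f"planted {plant} not found"
        for site in sites:
            assert not site.truncated
            assert len(editable_positions(site, system)) == expected[plant.system]


def test_editable_positions_match_oracle(yeastlike_genome):
    contig = yeastlike_genome[0]
    for system in ALL_SYSTEMS:
        mask = np.zeros(len(contig), dtype=bool)
        for site in find_pam_sites(contig, system):
            pos = editable_positions(site, system)
            assert all(0 <= p < len(contig) for p in pos)
            mask[list(pos)] = True
        assert np.array_equal(mask, naive_editable_mask(contig, system))


def test_editable_positions_rejects_system_mismatch(planted_genome):
    contig, _ = planted_genome
    site = find_pam_sites(contig, SPCAS9)[0]
    with pytest.raises(ValueError):
        editable_positions(site, SACAS9)


# -------------------------------------------------------- coverage_fraction


def test_all_a_genome_has_zero_coverage():
    report = coverage_fraction([NucSequence("x", "A" * 100)], ALL_SYSTEMS)
    assert all(f == 0.0 for _, f in report.per_system.values())
    assert all(f == 0.0 for _, f in report.per_combination.values())


def test_single_site_contig_fraction_is_13_over_100():
    """A 100-nt contig holding exactly one full SpCas9 site and no other
    PAM of any system (footprint flush with the contig end so the PAM-free
    poly-A background stays PAM-free)."""
    seq = "A" * 77 + "ACACACACACACACACACAC" + "AGG"
    assert len(seq) == 100
    contig = NucSequence("mini", seq)
    # precondition: single site, no other PAM for any system
    assert naive_site_set(contig, SPCAS9) == {(97, "+")}
    assert naive_site_set(contig, SACAS9) == set()
    assert naive_site_set(contig, ASCAS12A) == set()
    report = coverage_fraction([contig], ALL_SYSTEMS)
    assert report.per_system["SpCas9"] == (13, 0.13)
    assert report.per_system["SaCas9"][0] == 0
    assert report.per_combination[("SpCas9",)][1] == 0.13
    assert report.per_combination[("AsCas12a", "SaCas9", "SpCas9")][1] == 0.13


def test_coverage_matches_brute_force_union(yeastlike_genome):
    report = coverage_fraction(yeastlike_genome, ALL_SYSTEMS)
    total = sum(len(c) for c in yeastlike_genome)
    assert report.genome_length == total
    masks = {
        s.name: np.concatenate(
            [naive_editable_mask(c, s) for c in yeastlike_genome]
        )
        for s in ALL_SYSTEMS
    }
    for combo, (count, frac) in report.per_combination.items():
        union = np.zeros(total, dtype=bool)
        for name in combo:
            union |= masks[name]
        assert count == int(union.sum())
        assert frac == pytest.approx(count / total)


def test_strand_symmetry_of_coverage(yeastlike_genome):
    fwd = coverage_fraction(yeastlike_genome, ALL_SYSTEMS)
    rev = coverage_fraction(
        [c.reverse_complement() for c in yeastlike_genome], ALL_SYSTEMS
    )
    assert {k: v for k, v in fwd.per_combination.items()} == {
        k: v for k, v in rev.per_combination.items()
    }


def test_union_monotonicity(yeastlike_genome):
    report = coverage_fraction(yeastlike_genome, ALL_SYSTEMS)
    combos = report.per_combination
    for combo, (count, frac) in combos.items():
        for member in combo:
            assert frac >= combos[(member,)][1]
    singles = sum(combos[(s.name,)][0] for s in ALL_SYSTEMS)
    assert combos[tuple(sorted(s.name for s in ALL_SYSTEMS))][0] <= singles


# ------------------------------------------------------------------ output


def test_bed_output_footprint(tmp_path):
    sites = find_pam_sites(NucSequence("chrI", "AAAACGGAAA"), SPCAS9)
    path = tmp_path / "sites.bed"
    write_sites_bed(sites, path)
    assert path.read_text() == "chrI\t0\t7\tSpCas9\t0\t+\n"


def test_bed_empty_for_no_sites(tmp_path):
    path = tmp_path / "empty.bed"
    write_sites_bed([], path)
    assert path.read_text() == ""


def test_coverage_tsv_round_trip(tmp_path, yeastlike_genome):
    report = coverage_fraction(yeastlike_genome, ALL_SYSTEMS)
    path = tmp_path / "cov.tsv"
    write_coverage_tsv(report, path)
    back = read_coverage_tsv(path)
    for combo, (_, frac) in report.per_combination.items():
        assert back[combo] == pytest.approx(frac, abs=5e-7)


def test_outputs_deterministic(tmp_path, yeastlike_genome):
    report = coverage_fraction(yeastlike_genome, ALL_SYSTEMS)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_coverage_tsv(report, p1)
    write_coverage_tsv(coverage_fraction(yeastlike_genome, ALL_SYSTEMS), p2)
    assert p1.read_bytes() == p2.read_bytes()
    b1, b2 = tmp_path / "a.bed", tmp_path / "b.bed"
    sites = find_pam_sites(yeastlike_genome[0], SPCAS9)
    write_sites_bed(sites, b1)
    write_sites_bed(find_pam_sites(yeastlike_genome[0], SPCAS9), b2)
    assert b1.read_bytes() == b2.read_bytes()
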