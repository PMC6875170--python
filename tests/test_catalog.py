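import numpy as np
import pytest

from tescope.catalog import (
    count_identical_paralogs,
    delimit_families,
    find_tsd,
    find_tsd_detailed,
    pair_insertions,
    scan_terminal_repeats,
    summarize_family,
)
from tescope.errors import ParameterError
from tescope.genetics import revcomp
from tescope.simulate import FamilySpec, evolve_copy, generate_family


def smith_waterman(target: str, query: str):
    """Independent full Smith-Waterman oracle (match +1, mismatch -1, gap -2).

    Returns (score, target interval, matches, aligned columns) of the best
    local alignment, recovered by traceback.
    """
    t, q = target.upper(), query.upper()
    n, m = len(t), len(q)
    H = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    tarr = np.frombuffer(t.encode(), dtype="S1")
    qarr = np.frombuffer(q.encode(), dtype="S1")
    for i in range(1, n + 1):
        sub = np.where(qarr == tarr[i - 1], 1.0, -1.0)
        for j in range(1, m + 1):
            best = H[i - 1, j - 1] + sub[j - 1]
            p = 1
            if H[i - 1, j] - 2 > best:
                best, p = H[i - 1, j] - 2, 2
            if H[i, j - 1] - 2 > best:
                best, p = H[i, j - 1] - 2, 3
            if best <= 0:
                best, p = 0.0, 0
            H[i, j] = best
            ptr[i, j] = p
    i, j = np.unravel_index(np.argmax(H), H.shape)
    score = H[i, j]
    end_t = i
    matches = columns = 0
    while ptr[i, j] != 0:
        if ptr[i, j] == 1:
            matches += t[i - 1] == q[j - 1]
            i, j = i - 1, j - 1
        elif ptr[i, j] == 2:
            i -= 1
        else:
            j -= 1
        columns += 1
    return score, (i, end_t), matches, columns


class TestScanner:
    def test_verbatim_probe_found_at_exact_coordinates(self, rng):
        probe = "".join(rng.choice(list("ACGT"), size=250))
        genome = "".join(rng.choice(list("ACGT"), size=3000)) + probe + "".join(
            rng.choice(list("ACGT"), size=3000)
        )
        hits = scan_terminal_repeats(genome, probe, "f:ltr")
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (3000, 3250, "+")
        assert h.identity == 1.0

    def test_diverged_probe_identity_tracks_divergence(self, rng):
        probe = "".join(rng.choice(list("ACGT"), size=400))
        copy = evolve_copy(probe, 0.05, rng)
        genome = "".join(rng.choice(list("ACGT"), size=2000)) + copy + "".join(
            rng.choice(list("ACGT"), size=2000)
        )
        hits = scan_terminal_repeats(genome, probe, "f:ltr")
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(0.95, abs=0.02)

    def test_reverse_complement_planting_reported_on_minus_strand(self, rng):
        probe = "".join(rng.choice(list("ACGT"), size=250))
        genome = "".join(rng.choice(list("ACGT"), size=2000)) + revcomp(probe) + "".join(
            rng.choice(list("ACGT"), size=2000)
        )
        hits = scan_terminal_repeats(genome, probe, "f:ltr")
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (2000, 2250)

    def test_probe_shorter_than_seed_rejected(self):
        with pytest.raises(ParameterError):
            scan_terminal_repeats("ACGT" * 100, "ACGTACGT", seed_k=12)

    def test_two_nearby_copies_both_reported(self, rng):
        # copies closer than a probe length must not shadow each other
        probe = "".join(rng.choice(list("ACGT"), size=300))
        spacer = "".join(rng.choice(list("ACGT"), size=500))
        genome = spacer + probe + spacer[:400] + evolve_copy(probe, 0.03, rng) + spacer
        hits = scan_terminal_repeats(genome, probe, "f:ltr")
        assert len(hits) == 2

    def test_agrees_with_full_smith_waterman_oracle(self, rng):
        # the scanner's aligned interval and identity match an independent
        # full SW traceback on short sequences
        for _ in range(5):
            probe = "".join(rng.choice(list("ACGT"), size=120))
            copy = evolve_copy(probe, 0.06, rng, indel_rate=0.05)
            genome = (
                "".join(rng.choice(list("ACGT"), size=700))
                + copy
                + "".join(rng.choice(list("ACGT"), size=700))
            )
            hits = scan_terminal_repeats(genome, probe, "f:ltr", min_identity=0.8)
            assert len(hits) == 1
            h = hits[0]
            _, (o_start, o_end), o_matches, o_columns = smith_waterman(genome, probe)
            assert abs(h.start - o_start) <= 1 and abs(h.end - o_end) <= 1
            assert h.identity == pytest.approx(o_matches / o_columns, abs=1 / o_columns)


class TestFindTsd:
    def test_planted_duplication_recovered(self):
        genome = "A" * 50 + "GCGCA" + "T" * 100 + "GCGCA" + "A" * 50
        assert find_tsd(genome, 55, 155, (2, 9)) == "GCGCA"

    def test_absent_duplication_gives_none(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=60))
        # force mismatching flanks
        genome = "AAAA" + genome + "CCCC"
        assert find_tsd("AACCGGTTAACC" + "T" * 40 + "GGAATTCCGGAA", 12, 52, (5, 9)) is None

    def test_longest_duplication_wins_over_prefix(self):
        tsd = "GATTACA"  # 7-mer whose 5-mer prefix also matches
        genome = "C" * 50 + tsd + "G" * 80 + tsd + "C" * 50
        assert find_tsd(genome, 57, 137, (2, 9)) == tsd

    def test_bounds_at_contig_edge_flagged(self):
        res = find_tsd_detailed("ACGTACGT", 1, 7, (2, 4))
        assert res.seq is None and res.at_edge


class TestPairing:
    def test_default_simulation_counts_recovered(self, small_sim):
        from tescope.catalog import catalog_genome

        records, partials = catalog_genome(small_sim["contigs"], small_sim["families"])
        truth = small_sim["truth"].insertions
        matched = sum(
            any(
                r.family == t.family
                and r.kind == t.kind
                and not (r.end <= t.start or t.end <= r.start)
                for r in records
            )
            for t in truth
        )
        assert matched == len(truth)
        # copy-number display format: total (FLE/solo/truncated)
        summary = summarize_family("simcv1", [r for r in records if r.family == "simcv1"])
        assert summary.copy_number_display == "16 (8/5/3)"

    def test_single_solo_ltr_genome(self, codon_model, rng):
        spec = FamilySpec(name="f", te_class="LTR_copia", terminal_repeat_len=150,
                          tsd_len=5, orf_len_codons=150)
        fam = generate_family(spec, codon_model, rng)
        genome = (
            "".join(rng.choice(list("ACGT"), size=3000))
            + "TACGG" + fam.terminal_repeat + "TACGG"
            + "".join(rng.choice(list("ACGT"), size=3000))
        )
        hits = scan_terminal_repeats(genome, fam.terminal_repeat, "f:ltr")
        hits += scan_terminal_repeats(genome, fam.internal_seq, "f:internal",
                                      min_coverage=0.25)
        records, _ = pair_insertions(hits, fam, genome)
        assert len(records) == 1
        rec = records[0]
        assert rec.kind == "solo_LTR"
        assert rec.tsd_seq == "TACGG"

    def test_fle_at_contig_edge_excluded_from_counts(self, codon_model, rng):
        spec = FamilySpec(name="f", te_class="LTR_copia", terminal_repeat_len=150,
                          tsd_len=5, orf_len_codons=150, utr5_len=60, utr3_len=60)
        fam = generate_family(spec, codon_model, rng)
        # 3' LTR truncated by the contig end
        genome = "".join(rng.choice(list("ACGT"), size=3000)) + fam.consensus[:-20]
        hits = scan_terminal_repeats(genome, fam.terminal_repeat, "f:ltr")
        hits += scan_terminal_repeats(genome, fam.internal_seq, "f:internal",
                                      min_coverage=0.25)
        records, partials = pair_insertions(hits, fam, genome)
        assert records == []
        assert len(partials) >= 1

    def test_strand_symmetry_of_cataloguing(self, small_sim):
        from tescope.catalog import catalog_genome

        contigs = small_sim["contigs"]
        flipped = {k: revcomp(v) for k, v in contigs.items()}
        fwd, _ = catalog_genome(contigs, small_sim["families"])
        rev, _ = catalog_genome(flipped, small_sim["families"])
        assert len(fwd) == len(rev)
        L = len(contigs["chr1"])
        fwd_keys = sorted((r.family, r.kind, r.start, r.end, r.strand) for r in fwd)
        rev_keys = sorted(
            (r.family, r.kind, L - r.end, L - r.start,
             {"+": "-", "-": "+"}[r.strand])
            for r in rev
        )
        for (f1, k1, s1, e1, st1), (f2, k2, s2, e2, st2) in zip(fwd_keys, rev_keys):
            assert (f1, k1) == (f2, k2)
            assert abs(s1 - s2) <= 3 and abs(e1 - e2) <= 3
            # rev_keys strands are pre-flipped, so they must now agree
            assert st1 == st2


class TestDelimitFamilies:
    def test_identical_sequences_same_family(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        part = delimit_families({"a": seq, "b": seq})
        assert part.groups == [["a", "b"]]
        assert not part.subfamily_pairs

    def test_seventy_percent_identity_splits_families(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=400))
        b = evolve_copy(a, 0.45, rng)  # ~34% observed difference, <80% identity
        part = delimit_families({"a": a, "b": b})
        assert part.groups == [["a"], ["b"]]

    def test_divergent_pair_with_conserved_terminus_is_subfamily_split(self, rng):
        # emulates two subfamilies sharing >98% identity over the terminal
        # 160 bp of their 3' ends while diverging over the rest
        tail = "".join(rng.choice(list("ACGT"), size=160))
        a = "".join(rng.choice(list("ACGT"), size=440)) + tail
        b = "".join(rng.choice(list("ACGT"), size=440)) + tail
        part = delimit_families({"a": a, "b": b})
        assert part.groups == [["a", "b"]]
        assert ("a", "b") in part.subfamily_pairs

    def test_short_alignment_is_undecidable_not_a_split(self):
        part = delimit_families({"a": "ACGTACGTAC" * 4, "b": "ACGTACGTAC" * 4 + ""})
        # identical 40 bp: aligned length below 80 bp floor
        assert ("a", "b") in part.undecidable_pairs
        assert part.groups == [["a"], ["b"]]


class TestParalogs:
    def test_unique_sequences_count_zero(self):
        assert count_identical_paralogs(["AAA", "CCC", "GGG"]) == 0

    def test_pair_of_identical_counts_both(self):
        assert count_identical_paralogs(["ACGT", "ACGT", "TTTT"]) == 2

    def test_age_zero_copies_all_counted(self, codon_model, rng):
        spec = FamilySpec(name="f", te_class="LTR_copia", terminal_repeat_len=100,
                          orf_len_codons=150)
        fam = generate_family(spec, codon_model, rng)
        seqs = [fam.consensus] * 4 + [evolve_copy(fam.consensus, 0.05, rng)]
        assert count_identical_paralogs(seqs) == 4


class TestSummaries:
    def test_empty_family_zero_row(self):
        s = summarize_family("f", [])
        assert s.copy_number_total == 0
        assert s.copy_number_display == "0 (0/0/0)"

    def test_total_equals_sum_of_kinds(self, small_sim):
        from tescope.catalog import catalog_genome

        records, _ = catalog_genome(small_sim["contigs"], small_sim["families"])
        for fam in small_sim["families"]:
            s = summarize_family(fam, records)
            assert s.copy_number_total == s.n_fle + s.n_solo + s.n_truncated
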