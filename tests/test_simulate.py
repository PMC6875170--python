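import numpy as np
import pytest

from tescope.errors import (
    FeasibilityError,
    ParameterError,
    PlacementError,
    ValidationError,
)
from tescope.genetics import revcomp, standard_genetic_code
from tescope.simulate import (
    SYNTHETIC_OPTIMAL_CODONS,
    FamilySpec,
    InsertionPlan,
    build_codon_model,
    evolve_copy,
    generate_family,
    plant_insertions,
    simulate_expression,
    simulate_genome,
    slippage_mutate,
)


def _measured_fop(codons, optimal):
    return sum(1 for c in codons if c in optimal) / len(codons)


class TestCodonModel:
    def test_fop_one_emits_only_optimal_for_degenerate_aas(self, rng):
        # an optimal codon for every amino acid makes Fop = 1 attainable
        full = frozenset(SYNTHETIC_OPTIMAL_CODONS | {"ATG", "TGG"})
        model = build_codon_model(full, 1.0, 1.0)
        for aa, (codons, probs) in model.per_aa_codon_probs.items():
            top = {c for c, p in zip(codons, probs) if p > 0}
            assert top == {codons[0]} and codons[0] in full

    def test_fop_zero_gives_optimal_probability_zero(self):
        model = build_codon_model(SYNTHETIC_OPTIMAL_CODONS, 0.0, 0.30)
        for codons, probs in model.per_aa_codon_probs.values():
            for c, p in zip(codons, probs):
                if c in SYNTHETIC_OPTIMAL_CODONS:
                    assert p == 0.0

    def test_monte_carlo_fop_within_binomial_error(self, rng):
        model = build_codon_model(SYNTHETIC_OPTIMAL_CODONS, 0.75, 0.85)
        codons = model.sample_codons(10_000, rng)
        # binomial se ~ sqrt(.75*.25/1e4) ~ 0.004; +-0.02 is ~5 se
        assert _measured_fop(codons, SYNTHETIC_OPTIMAL_CODONS) == pytest.approx(0.75, abs=0.02)

    def test_monte_carlo_gc3s_within_tolerance(self, rng):
        code = standard_genetic_code()
        model = build_codon_model(SYNTHETIC_OPTIMAL_CODONS, 0.60, 0.70)
        codons = model.sample_codons(20_000, rng)
        deg = [c for c in codons if code.degeneracy_class[code.codon_to_aa[c]] >= 2]
        gc3 = sum(1 for c in deg if c[2] in "GC") / len(deg)
        assert gc3 == pytest.approx(0.70, abs=0.02)

    def test_infeasible_target_pair_reports_attainable_range(self):
        with pytest.raises(FeasibilityError, match="attainable range"):
            build_codon_model(SYNTHETIC_OPTIMAL_CODONS, 0.9, 0.10)

    def test_fop_above_feasible_maximum_rejected(self):
        with pytest.raises(FeasibilityError):
            build_codon_model(SYNTHETIC_OPTIMAL_CODONS, 0.99, 0.9)


class TestGenerateFamily:
    def test_ltr_family_terminal_repeats_identical(self, codon_model, rng):
        spec = FamilySpec(name="f", te_class="LTR_copia", terminal_repeat_len=300,
                          orf_len_codons=200)
        fam = generate_family(spec, codon_model, rng)
        assert fam.consensus[:300] == fam.consensus[-300:]

    def test_itr_family_terminal_repeats_reverse_complementary(self, codon_model, rng):
        spec = FamilySpec(name="f", te_class="DNA_transposon", terminal_repeat_len=25,
                          tsd_len=8, orf_len_codons=200)
        fam = generate_family(spec, codon_model, rng)
        assert revcomp(fam.consensus[:25]) == fam.consensus[-25:]

    def test_orf_translates_without_internal_stop(self, codon_model, rng, code):
        spec = FamilySpec(name="f", te_class="LTR_chromovirus", orf_len_codons=300)
        fam = generate_family(spec, codon_model, rng)
        coding = "".join(fam.consensus[s:e] for s, e, _ in fam.orf_intervals)
        aa = code.translate(coding)
        assert aa.startswith("M")
        assert aa.endswith("*") and "*" not in aa[:-1]

    def test_intron_boundaries_are_gt_ag(self, codon_model, rng):
        spec = FamilySpec(name="f", te_class="DNA_transposon", terminal_repeat_len=25,
                          orf_len_codons=200, intron_positions=((70, 80), (140, 66)))
        fam = generate_family(spec, codon_model, rng)
        assert len(fam.intron_intervals) == 2
        for s, e in fam.intron_intervals:
            assert fam.consensus[s : s + 2] == "GT"
            assert fam.consensus[e - 2 : e] == "AG"

    def test_domain_intervals_fall_inside_orf(self, codon_model, rng):
        spec = FamilySpec(name="f", te_class="LTR_copia", orf_len_codons=300,
                          domain_codon_intervals=((50, 120),))
        fam = generate_family(spec, codon_model, rng)
        orf_span = (min(s for s, _, _ in fam.orf_intervals),
                    max(e for _, e, _ in fam.orf_intervals))
        for s, e in fam.domain_intervals:
            assert orf_span[0] <= s < e <= orf_span[1]


class TestEvolveCopy:
    def test_age_zero_is_identity(self, rng):
        seq = "ACGT" * 100
        assert evolve_copy(seq, 0.0, rng) == seq

    def test_negative_age_rejected(self, rng):
        with pytest.raises(ParameterError):
            evolve_copy("ACGT", -0.1, rng)

    def test_divergence_density_matches_age(self, rng):
        # 200 replicates of 10 kb at age 0.05: mean per-site difference
        # (correction-free counting) concentrates tightly around 0.05
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        diffs = []
        for _ in range(200):
            mutated = evolve_copy(seq, 0.05, rng)
            diffs.append(sum(a != b for a, b in zip(seq, mutated)) / len(seq))
        assert 0.045 <= float(np.mean(diffs)) <= 0.055

    def test_fle_ltr_identity_near_99_percent_at_age_005(self, rng):
        # two LTRs mutating independently at age 0.005 diverge by ~1%
        ltr = "".join(rng.choice(list("ACGT"), size=2000))
        idents = []
        for _ in range(100):
            element = ltr + ltr
            evolved = evolve_copy(element, 0.005, rng)
            a, b = evolved[:2000], evolved[2000:]
            idents.append(sum(x == y for x, y in zip(a, b)) / 2000)
        assert float(np.mean(idents)) == pytest.approx(0.99, abs=0.003)

    def test_slippage_changes_dinucleotide_run_length(self, rng):
        seq = "GGGG" + "CA" * 30 + "TTTT"
        out = slippage_mutate(seq, rng, rate=1.0)
        assert out.startswith("GGGG") and out.endswith("TTTT")
        assert out.count("CACA") != seq.count("CACA") or len(out) != len(seq)


class TestPlantInsertions:
    @pytest.fixture
    def family(self, codon_model, rng):
        spec = FamilySpec(name="famA", te_class="LTR_copia", terminal_repeat_len=100,
                          tsd_len=5, orf_len_codons=150, utr5_len=50, utr3_len=50)
        return generate_family(spec, codon_model, rng)

    def test_single_fle_grows_genome_by_element_plus_tsd(self, family, rng):
        background = "".join(rng.choice(list("ACGT"), size=5000))
        plan = InsertionPlan(family="famA", kind="FLE", age=0.0, position=2500)
        genome, truth = plant_insertions(background, {"famA": family}, [plan], rng)
        assert len(genome) == 5000 + len(family.consensus) + 5
        (ins,) = truth.insertions
        assert genome[ins.start : ins.end] == family.consensus
        # identical TSD copies immediately flank the element
        assert genome[ins.start - 5 : ins.start] == genome[ins.end : ins.end + 5] == ins.tsd_seq

    def test_solo_ltr_contains_no_internal_sequence(self, family, rng):
        background = "".join(rng.choice(list("ACGT"), size=5000))
        plan = InsertionPlan(family="famA", kind="solo_LTR", age=0.0, position=2500)
        genome, truth = plant_insertions(background, {"famA": family}, [plan], rng)
        (ins,) = truth.insertions
        assert genome[ins.start : ins.end] == family.terminal_repeat
        assert family.internal_seq[:50] not in genome

    def test_family_without_tsd_creates_no_duplication(self, codon_model, rng):
        spec = FamilySpec(name="noTsd", te_class="LTR_copia", terminal_repeat_len=100,
                          tsd_len=None, orf_len_codons=150)
        fam = generate_family(spec, codon_model, rng)
        background = "".join(rng.choice(list("ACGT"), size=5000))
        plan = InsertionPlan(family="noTsd", kind="FLE", age=0.0, position=2500)
        genome, truth = plant_insertions(background, {"noTsd": fam}, [plan], rng)
        assert len(genome) == 5000 + len(fam.consensus)
        assert truth.insertions[0].tsd_seq is None

    def test_minus_strand_plants_reverse_complement(self, family, rng):
        background = "".join(rng.choice(list("ACGT"), size=5000))
        plan = InsertionPlan(family="famA", kind="FLE", age=0.0, position=2500, strand="-")
        genome, truth = plant_insertions(background, {"famA": family}, [plan], rng)
        (ins,) = truth.insertions
        assert genome[ins.start : ins.end] == revcomp(family.consensus)

    def test_overlapping_plans_rejected(self, family, rng):
        background = "A" * 5000
        plans = [
            InsertionPlan(family="famA", kind="FLE", age=0.0, position=2500),
            InsertionPlan(family="famA", kind="FLE", age=0.0, position=2600),
        ]
        with pytest.raises(PlacementError):
            plant_insertions(background, {"famA": family}, plans, rng)

    def test_solo_plan_for_non_ltr_family_rejected(self, codon_model, rng):
        spec = FamilySpec(name="tnp", te_class="DNA_transposon", terminal_repeat_len=25,
                          orf_len_codons=150)
        fam = generate_family(spec, codon_model, rng)
        plan = InsertionPlan(family="tnp", kind="solo_LTR", age=0.0, position=2500)
        with pytest.raises(ValidationError):
            plant_insertions("A" * 5000, {"tnp": fam}, [plan], rng)


class TestExpression:
    def test_poisson_limit_variance_matches_mean(self, rng):
        names = [f"f{i}" for i in range(10_000)]
        counts = simulate_expression(names, [50.0] * len(names), None, rng)
        values = np.array(list(counts.values()))
        assert values.mean() == pytest.approx(50, rel=0.05)
        assert values.var() == pytest.approx(values.mean(), rel=0.1)

    def test_zero_mean_gives_all_zeros(self, rng):
        counts = simulate_expression(["a", "b"], [0.0, 0.0], 1.0, rng)
        assert set(counts.values()) == {0}

    def test_counts_span_four_orders_of_magnitude(self, rng):
        counts = simulate_expression(["lo", "hi"], [1.0, 10_000.0], None, rng)
        assert counts["hi"] > 100 * max(counts["lo"], 1)

    def test_negative_dispersion_rejected(self, rng):
        with pytest.raises(ParameterError):
            simulate_expression(["a"], [10.0], -1.0, rng)


class TestDeterminism:
    def test_same_seed_same_genome_and_truth(self):
        a = simulate_genome(seed=99)
        b = simulate_genome(seed=99)
        assert a[0] == b[0]
        assert [vars(x) for x in a[2].insertions] == [vars(y) for y in b[2].insertions]
        assert a[3] == b[3]

    def test_fle_truth_carries_ltr_intervals_and_identical_tsds(self, small_sim):
        genome = small_sim["contigs"]["chr1"]
        for ins in small_sim["truth"].insertions:
            assert 0 <= ins.start < ins.end <= len(genome)
            if ins.kind == "FLE":
                assert len(ins.ltr_intervals) == 2
                if ins.tsd_seq:
                    k = len(ins.tsd_seq)
                    assert genome[ins.start - k : ins.start] == ins.tsd_seq
                    assert genome[ins.end : ins.end + k] == ins.tsd_seq
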