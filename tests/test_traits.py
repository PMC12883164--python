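"""Per-transcript trait calculations against brute-force oracles."""

import math
import random

import numpy as np
import pytest

from genetraits.genetic_code import SiteClass, default_code
from genetraits.io import CodingSequence
from genetraits.reference import CodonCountTable, build_reference
from genetraits.traits import (
    AminoAcidTables,
    amino_acid_traits,
    at_skew,
    cai,
    enc_prime,
    fop,
    gc_content,
    gc_skew,
    length_filter,
    milc,
    profile,
    translate_cds,
)

CODE = default_code()


def random_reference(seed):
    rng = np.random.default_rng(seed)
    counts = {c: float(rng.integers(1, 1000)) for c in CODE.sense_codons}
    return build_reference(CodonCountTable(f"r{seed}", counts), pseudocount=0.5)


def random_cds(rng, n_codons):
    sense = CODE.sense_codons
    return "".join(sense[i] for i in rng.integers(0, len(sense), n_codons))


# --- independent oracles ---------------------------------------------------

def cai_oracle(seq, ref):
    """Geometric mean of weights via an explicit per-codon list in log space."""
    logs = [math.log(ref.w_c[seq[i:i + 3]]) for i in range(0, len(seq), 3)]
    return math.exp(sum(logs) / len(logs))


def milc_oracle(seq, ref):
    """Termwise evaluation: M_a = Σ O_c ln(f_obs/g); MILC = ΣM_a/L − C."""
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    L = len(codons)
    aas = sorted({CODE.codon_to_aa[c] for c in codons})
    m_total, corr = 0.0, 0.0
    for aa in aas:
        fam = sorted(CODE.synonymous_family(aa).codons)
        obs = {c: codons.count(c) for c in fam if codons.count(c) > 0}
        L_a = sum(obs.values())
        m_total += sum(n * math.log((n / L_a) / ref.g_c[c]) for c, n in obs.items())
        corr += len(fam) - 1
    return m_total / L - (corr / L - 0.5)


def enc_prime_oracle(seq, ref):
    """Second implementation of background-corrected ENC, written term by term."""
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    f_by_class = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in CODE.families().items():
        r = fam.r_a
        if r == 1:
            continue
        n_a = sum(1 for c in codons if CODE.codon_to_aa[c] == aa)
        if n_a < 2:
            continue
        chi2 = 0.0
        for c in sorted(fam.codons):
            expected = n_a * ref.g_c[c]
            observed = codons.count(c)
            chi2 += (observed - expected) ** 2 / expected
        f_by_class[r].append((chi2 + n_a - r) / (r * (n_a - 1)))
    fbar = {r: sum(v) / len(v) for r, v in f_by_class.items() if v}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    if set(fbar) != {2, 3, 4, 6}:
        return float("nan")
    enc = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(max(enc, 1.0), 61.0)


def site_pool_oracle(seq, site_class):
    pool = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        for pos in (1, 2, 3):
            if site_class is None or CODE.classify_site(codon, pos) is site_class:
                pool.append(codon[pos - 1])
    return pool


# --- profile ----------------------------------------------------------------

class TestProfile:
    def test_glutamate_example(self):
        prof = profile("GAAGAAGAG")
        assert prof.O_c == {"GAA": 2, "GAG": 1} and prof.L == 3

    def test_single_codon(self):
        prof = profile("ATG")
        assert prof.O_c == {"ATG": 1} and prof.L == 1

    def test_ambiguous_codon_skipped_and_tallied(self):
        prof = profile("GAANNNGAG")
        assert prof.L == 2 and prof.n_ambiguous == 1

    def test_stop_excluded_from_length(self):
        prof = profile("GAATAA")
        assert prof.L == 1 and prof.n_stop == 1

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            profile("")


# --- indices ----------------------------------------------------------------

class TestCai:
    def test_printed_worked_example_rounds_to_040(self):
        ref = build_reference(CodonCountTable("x", {"GAA": 20.0, "GAG": 80.0}),
                              pseudocount=0.0)
        value = cai(profile("GAAGAAGAG"), ref)
        assert value == pytest.approx((0.25 * 0.25 * 1.0) ** (1 / 3))
        assert round(value, 2) == 0.40

    def test_all_optimal_codons_give_cai_one(self):
        ref = random_reference(1)
        seq = "".join(sorted(ref.optimal)[:50])
        assert cai(profile(seq), ref) == pytest.approx(1.0)

    def test_matches_log_domain_oracle_on_random_genes(self):
        rng = np.random.default_rng(2)
        ref = random_reference(2)
        for _ in range(20):
            seq = random_cds(rng, 300)
            assert cai(profile(seq), ref) == pytest.approx(
                cai_oracle(seq, ref), abs=1e-12)

    def test_zero_weight_directs_to_pseudocount(self):
        ref = build_reference(CodonCountTable("x", {"GAA": 10.0}), pseudocount=0.0)
        with pytest.raises(ValueError, match="pseudocount"):
            cai(profile("TGG"), ref)


class TestFop:
    def test_example_transcript_one_third_optimal(self):
        ref = build_reference(CodonCountTable("x", {"GAA": 20.0, "GAG": 80.0}),
                              pseudocount=0.0)
        assert fop(profile("GAAGAAGAG"), ref) == pytest.approx(1 / 3)

    def test_all_optimal_is_one(self):
        ref = random_reference(3)
        seq = "".join(sorted(ref.optimal)[:30])
        assert fop(profile(seq), ref) == 1.0

    def test_uniform_reference_ties_make_everything_optimal(self, code):
        counts = {c: 1.0 for c in code.sense_codons}
        ref = build_reference(CodonCountTable("u", counts), pseudocount=0.0)
        rng = np.random.default_rng(4)
        assert fop(profile(random_cds(rng, 100)), ref) == 1.0


class TestMilc:
    def test_hand_evaluated_glutamate_construction(self):
        # 100 codons, Glu only, 50/50 usage against g = {0.5, 0.5}:
        # ΣM_a = 0 and C = (2−1)/100 − 0.5 = −0.49, so MILC = 0.49
        ref = build_reference(CodonCountTable("y", {"GAA": 50.0, "GAG": 50.0}),
                              pseudocount=0.0)
        seq = "GAA" * 50 + "GAG" * 50
        assert milc(profile(seq), ref) == pytest.approx(0.49)

    def test_equals_minus_c_when_usage_matches_expected_exactly(self):
        ref = build_reference(
            CodonCountTable("y", {"GAA": 25.0, "GAG": 75.0, "TTT": 40.0,
                                  "TTC": 60.0}), pseudocount=0.0)
        seq = "GAA" * 25 + "GAG" * 75 + "TTT" * 40 + "TTC" * 60
        L = 200
        c = ((2 - 1) + (2 - 1)) / L - 0.5
        assert milc(profile(seq), ref) == pytest.approx(-c, abs=1e-12)

    def test_matches_termwise_oracle_on_random_genes(self):
        rng = np.random.default_rng(5)
        ref = random_reference(5)
        for _ in range(20):
            seq = random_cds(rng, 250)
            assert milc(profile(seq), ref) == pytest.approx(
                milc_oracle(seq, ref), abs=1e-12)

    def test_increases_as_usage_diverges_from_expected(self):
        ref = build_reference(CodonCountTable("y", {"GAA": 50.0, "GAG": 50.0}),
                              pseudocount=0.0)
        values = [milc(profile("GAA" * n + "GAG" * (100 - n)), ref)
                  for n in (50, 70, 90, 100)]
        assert values == sorted(values)


class TestEncPrime:
    def test_usage_at_background_long_limit_near_61(self):
        rng = np.random.default_rng(6)
        counts = {c: 100.0 for c in CODE.sense_codons}
        ref = build_reference(CodonCountTable("u", counts), pseudocount=0.0)
        fams = CODE.families()
        aas = sorted(fams)
        seq = "".join(rng.choice(sorted(fams[aa].codons))
                      for aa in rng.choice(aas, 20000))
        assert enc_prime(profile(seq), ref) > 58.0

    def test_one_codon_per_family_uniform_background_is_20(self):
        counts = {c: 100.0 for c in CODE.sense_codons}
        ref = build_reference(CodonCountTable("u", counts), pseudocount=0.0)
        seq = "".join(sorted(f.codons)[0] * 50 for f in CODE.families().values())
        assert enc_prime(profile(seq), ref) == pytest.approx(20.0, abs=1e-9)

    def test_matches_independent_reimplementation_on_random_genes(self):
        rng = np.random.default_rng(7)
        ref = random_reference(7)
        diffs = []
        for _ in range(50):
            seq = random_cds(rng, 300)
            a = enc_prime(profile(seq), ref)
            b = enc_prime_oracle(seq, ref)
            diffs.append(abs(a - b))
        assert max(diffs) < 1e-9

    def test_insufficient_data_flagged_nan(self):
        ref = random_reference(8)
        assert math.isnan(enc_prime(profile("ATG"), ref))


# --- nucleotide composition --------------------------------------------------

class TestComposition:
    def test_gc_all_sites(self):
        assert gc_content("GGCCCC") == 1.0

    def test_gc_fourfold_alanine_thirds(self):
        # GCT GCG: third positions T and G -> GC fraction 0.5
        assert gc_content("GCTGCG", SiteClass.FOURFOLD_SYNONYMOUS) == 0.5

    def test_empty_pool_is_nan(self):
        # ATG TGG: no fourfold-degenerate position exists
        assert math.isnan(gc_content("ATGTGG", SiteClass.FOURFOLD_SYNONYMOUS))

    @pytest.mark.parametrize("site_class", [
        None, SiteClass.FOURFOLD_SYNONYMOUS, SiteClass.NONSYNONYMOUS])
    def test_matches_per_site_oracle_on_random_genes(self, site_class):
        rng = np.random.default_rng(9)
        for _ in range(10):
            seq = random_cds(rng, 120)
            pool = site_pool_oracle(seq, site_class)
            expect = sum(1 for nt in pool if nt in "GC") / len(pool)
            assert gc_content(seq, site_class) == pytest.approx(expect, abs=1e-12)

    def test_skew_zero_at_balanced_composition(self):
        assert gc_skew("GGGCCC") == pytest.approx(0.0)
        assert at_skew("AATTTA") == pytest.approx(0.0)

    def test_skew_extremes(self):
        assert gc_skew("GGAGGA") == 1.0   # all-G pool among G/C
        assert gc_skew("CCACCA") == -1.0
        assert at_skew("AAGAAG") == 1.0
        assert at_skew("TTGTTG") == -1.0

    def test_skew_undefined_when_denominator_zero(self):
        assert math.isnan(gc_skew("AATTTA"))
        assert math.isnan(at_skew("GGGCCC"))


# --- amino acid traits -------------------------------------------------------

class TestAminoAcids:
    def test_homopolymer_mean_cost_is_residue_cost(self):
        tables = AminoAcidTables.default()
        for r in "AGWK":
            cost, _ = amino_acid_traits(r * 10, tables)
            assert cost == pytest.approx(tables.cost[r])

    def test_poly_glycine_cn_is_two(self):
        # glycine C2H5NO2: 2 C per 1 N
        assert amino_acid_traits("GGGG")[1] == pytest.approx(2.0)

    def test_poly_arginine_cn_is_1_5(self):
        # arginine C6H14N4O2: 6 C per 4 N
        assert amino_acid_traits("RRRR")[1] == pytest.approx(1.5)

    def test_unknown_residue_skipped_or_strict_error(self):
        cost_loose, _ = amino_acid_traits("GGXG")
        assert cost_loose == pytest.approx(amino_acid_traits("GGG")[0])
        with pytest.raises(ValueError):
            amino_acid_traits("GGXG", strict=True)

    def test_synonymous_recoding_leaves_aa_traits_unchanged(self):
        rng = np.random.default_rng(10)
        seq = random_cds(rng, 150)
        residues = translate_cds(seq)
        recoded = "".join(
            sorted(CODE.synonymous_family(aa).codons)[0] for aa in residues)
        assert amino_acid_traits(residues) == pytest.approx(
            amino_acid_traits(translate_cds(recoded)))


# --- filters and invariants --------------------------------------------------

class TestLengthFilter:
    def _gene(self, n):
        return CodingSequence(gene_id=f"g{n}", sequence="GAA" * n)

    def test_79_discarded_80_retained(self):
        kept = length_filter([self._gene(79), self._gene(80)])
        assert [g.length_codons for g in kept] == [80]

    def test_zero_threshold_is_identity(self):
        genes = [self._gene(5), self._gene(200)]
        assert length_filter(genes, min_codons=0) == genes


class TestTraitInvariants:
    def test_ranges_on_random_genes(self):
        rng = np.random.default_rng(11)
        ref = random_reference(11)
        for _ in range(10):
            seq = random_cds(rng, 150)
            prof = profile(seq)
            assert 0 < cai(prof, ref) <= 1
            assert 0 <= fop(prof, ref) <= 1
            assert 0 <= gc_content(seq) <= 1
            for f in (gc_skew, at_skew):
                v = f(seq)
                assert math.isnan(v) or -1 <= v <= 1

    def test_codon_permutation_leaves_all_traits_unchanged(self):
        rng = np.random.default_rng(12)
        ref = random_reference(12)
        seq = random_cds(rng, 200)
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        random.Random(0).shuffle(codons)
        shuffled = "".join(codons)
        for f in (cai, fop, milc, enc_prime):
            assert f(profile(seq), ref) == pytest.approx(
                f(profile(shuffled), ref), abs=1e-12)
        assert gc_content(seq, SiteClass.FOURFOLD_SYNONYMOUS) == pytest.approx(
            gc_content(shuffled, SiteClass.FOURFOLD_SYNONYMOUS))

    def test_swapping_in_the_optimal_codon_never_decreases_cai_or_fop(self):
        rng = np.random.default_rng(13)
        ref = random_reference(13)
        seq = random_cds(rng, 120)
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        prof0 = profile(seq)
        base_cai, base_fop = cai(prof0, ref), fop(prof0, ref)
        for idx in rng.integers(0, len(codons), 25):
            aa = CODE.codon_to_aa[codons[idx]]
            swapped = list(codons)
            swapped[idx] = ref.optimal_of_family(aa)
            prof1 = profile("".join(swapped))
            assert cai(prof1, ref) >= base_cai - 1e-12
            assert fop(prof1, ref) >= base_fop - 1e-12
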