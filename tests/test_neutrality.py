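import itertools
import math

import numpy as np
import pytest

from panselect.neutrality import (
    compute_all,
    faywu_h_normalized,
    fu_li_outgroup,
    fu_li_star,
    ng86_dnds,
    nucleotide_diversity,
    tajimas_d,
    watterson_theta,
)
from panselect.sites import UnfoldedSFS

from conftest import alignment_from_derived_counts, make_alignment, random_alignment


class TestPi:
    def test_four_haplotype_example(self, toy_pi_alignment):
        # all 6 pairs differ by 8/6 on average over L=2 -> 0.6667 per site
        assert nucleotide_diversity(toy_pi_alignment) == pytest.approx(8 / 6 / 2, abs=1e-12)

    def test_identical_haplotypes(self):
        aln = make_alignment(["ACGT", "ACGT", "ACGT"], "ACGT")
        assert nucleotide_diversity(aln) == 0.0

    def test_mask_restricts_columns(self, toy_pi_alignment):
        pi = nucleotide_diversity(toy_pi_alignment, mask=np.array([True, False]))
        # column 0 alone: minor 2 of 4 -> pairwise 4/6 over L=1
        assert pi == pytest.approx(4 / 6, abs=1e-12)


class TestWatterson:
    def test_hand_value(self):
        assert watterson_theta(2, 4, 1) == pytest.approx(2 / (1 + 0.5 + 1 / 3), abs=1e-9)

    def test_no_variation(self):
        assert watterson_theta(0, 10, 100) == 0.0

    def test_n2_harmonic_is_one(self):
        assert watterson_theta(3, 2, 1) == 3.0


class TestTajima:
    def test_zero_numerator(self):
        a1 = 1 + 0.5 + 1 / 3
        assert tajimas_d(2, 2 / a1, 4) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        assert tajimas_d(2, 4 / 3, 4) == pytest.approx(1.8930564, abs=1e-6)

    def test_undefined_without_segregation(self):
        assert math.isnan(tajimas_d(0, 0.0, 10))


class TestFuLi:
    """Hand-evaluated on n=4, derived counts {1,1,2,3}: S=4, eta_s=3,
    eta_e=2, pi_locus=13/6 (values worked through the corrected variance
    constants by hand)."""

    def test_starred_hand_values(self):
        dstar, fstar = fu_li_star(4, 3, 13 / 6, 4)
        assert dstar == pytest.approx(-0.0650102, abs=1e-6)
        assert fstar == pytest.approx(-0.0600437, abs=1e-6)

    def test_outgroup_hand_values(self):
        d, f = fu_li_outgroup(4, 2, 13 / 6, 4)
        assert d == pytest.approx(0.1506751, abs=1e-6)
        assert f == pytest.approx(0.1330928, abs=1e-6)

    def test_all_derived_singletons_negative(self):
        # every variant a derived singleton: rare-variant excess
        aln = alignment_from_derived_counts([1] * 6, n=10)
        st = compute_all(aln)
        assert st.fuli_d < 0 and st.fuli_d_star < 0


class TestFayWuH:
    def test_n2_numerator_forced_zero(self):
        sfs = UnfoldedSFS(n=2, counts=np.array([5]))
        assert faywu_h_normalized(sfs) == 0.0

    def test_high_frequency_derived_negative(self):
        counts = np.zeros(9, dtype=int)
        counts[-1] = 6  # all variants at derived count n-1
        assert faywu_h_normalized(UnfoldedSFS(n=10, counts=counts)) < 0

    def test_hand_value_n4(self):
        # derived counts {1,1,2,3}: theta_pi=13/6, theta_L=7/3, hand variance
        sfs = UnfoldedSFS(n=4, counts=np.array([2, 1, 1]))
        assert faywu_h_normalized(sfs) == pytest.approx(-0.2942347, abs=1e-6)


class TestComputeAll:
    def test_low_s_gene_not_tested(self):
        aln = alignment_from_derived_counts([1, 2, 3, 1], n=6)
        st = compute_all(aln)
        assert st.S == 4 and not st.tested
        assert not math.isnan(st.pi_site)
        assert math.isnan(st.tajima_d)

    def test_boundary_s5_all_tests_present(self):
        aln = alignment_from_derived_counts([1, 2, 3, 1, 4], n=6)
        st = compute_all(aln)
        assert st.tested
        for value in (st.tajima_d, st.fuli_d_star, st.fuli_f_star,
                      st.fuli_d, st.fuli_f, st.faywu_h_norm):
            assert not math.isnan(value)

    def test_unpolarized_gene_keeps_starred_tests(self):
        aln = alignment_from_derived_counts([1, 2, 3, 1, 4], n=6)
        aln.outgroup[:] = b"N"
        st = compute_all(aln)
        assert not math.isnan(st.fuli_d_star)
        assert math.isnan(st.fuli_d) and math.isnan(st.faywu_h_norm)
        assert st.polarized_fraction == 0.0

    def test_row_and_column_permutation_invariance(self, rng):
        aln = random_alignment(rng, n=8, L=60, p_gap=0.02, p_missing=0.02)
        st = compute_all(aln, min_segregating=1)
        perm = rng.permutation(aln.n)
        shuffled = make_shuffled(aln, perm)
        st2 = compute_all(shuffled, min_segregating=1)
        for field in ("S", "eta_s", "eta_e", "pi_site", "theta_w_site", "tajima_d",
                      "fuli_d_star", "fuli_f_star", "fuli_d", "fuli_f", "faywu_h_norm"):
            a, b = getattr(st, field), getattr(st2, field)
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, abs=1e-12)

    def test_monotone_contracts(self):
        """Intermediate-frequency variants push D up; derived singletons
        push Fu & Li's D down."""
        base = [1, 2, 3, 1, 4]
        aln = alignment_from_derived_counts(base, n=10)
        more_mid = alignment_from_derived_counts(base + [5, 5], n=10)
        more_singletons = alignment_from_derived_counts(base + [1, 1], n=10)
        d0 = compute_all(aln).tajima_d
        assert compute_all(more_mid).tajima_d > d0
        fd0 = compute_all(aln).fuli_d
        assert compute_all(more_singletons).fuli_d < fd0


def make_shuffled(aln, perm):
    from panselect.alignment import GeneAlignment

    return GeneAlignment(
        gene_id=aln.gene_id,
        population=aln.population,
        haplotypes=aln.haplotypes[perm],
        outgroup=aln.outgroup,
        positions=aln.positions,
    )


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------

def brute_force_ng86(seq_a, seq_b):
    """Independent NG86 reimplementation by naive enumeration."""
    from panselect.neutrality import _CODON_TABLE

    def syn_sites(codon):
        s = 0.0
        for pos in range(3):
            for alt in "TCAG":
                if alt == codon[pos]:
                    continue
                m = codon[:pos] + alt + codon[pos + 1:]
                if _CODON_TABLE[m] == _CODON_TABLE[codon]:
                    s += 1 / 3
        return s

    def diffs(c1, c2):
        pos = [i for i in range(3) if c1[i] != c2[i]]
        if not pos:
            return 0.0, 0.0
        paths = []
        for order in itertools.permutations(pos):
            cur, sd, nd, stop = c1, 0.0, 0.0, False
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1:]
                if _CODON_TABLE[nxt] == "*" and nxt != c2:
                    stop = True
                sd, nd = (sd + 1, nd) if _CODON_TABLE[cur] == _CODON_TABLE[nxt] else (sd, nd + 1)
                cur = nxt
            paths.append((sd, nd, stop))
        ok = [p for p in paths if not p[2]] or paths
        return sum(p[0] for p in ok) / len(ok), sum(p[1] for p in ok) / len(ok)

    S = N = sd = nd = 0.0
    for k in range(len(seq_a) // 3):
        ca, cb = seq_a[3 * k: 3 * k + 3], seq_b[3 * k: 3 * k + 3]
        S += (syn_sites(ca) + syn_sites(cb)) / 2
        d = diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    N = len(seq_a) - S
    ps, pn = (sd / S if S else 0.0), (nd / N if N else 0.0)
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3) if p < 0.75 else math.nan
    return jc(pn), jc(ps)


class TestNG86:
    def test_identical_sequences(self):
        rec = ng86_dnds("ATGGCT", "ATGGCT")
        assert rec.dn == 0.0 and rec.ds == 0.0 and math.isnan(rec.dnds)

    def test_single_codon_phe_leu(self):
        # TTT vs TTA: 1 nonsynonymous difference, 0 synonymous;
        # TTT has 1/3 synonymous site (only TTT->TTC at position 3)
        rec = ng86_dnds("TTT", "TTA")
        assert rec.dn > 0 and rec.ds == 0.0 and math.isnan(rec.dnds)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            ng86_dnds("ATGG", "ATGG")
        with pytest.raises(ValueError):
            ng86_dnds("TAA", "TAA")  # stop codon

    def test_matches_brute_force_on_random_pairs(self, rng):
        bases = "TCAG"
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(15):
            codons_a, codons_b = [], []
            while len(codons_a) < 30:
                ca = "".join(rng.choice(list(bases), size=3))
                cb = "".join(
                    ca[i] if rng.random() < 0.8 else str(rng.choice(list(bases)))
                    for i in range(3)
                )
                if ca in stops or cb in stops:
                    continue
                codons_a.append(ca)
                codons_b.append(cb)
            sa, sb = "".join(codons_a), "".join(codons_b)
            rec = ng86_dnds(sa, sb)
            dn, ds = brute_force_ng86(sa, sb)
            assert rec.dn == pytest.approx(dn, abs=1e-9, nan_ok=True)
            assert rec.ds == pytest.approx(ds, abs=1e-9, nan_ok=True)
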