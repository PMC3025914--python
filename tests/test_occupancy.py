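"""PWM energies, binding-isotherm occupancy, allele-aware scanning."""

import numpy as np
import pytest

from admixlpa import (
    PWM,
    OccupancyHit,
    SNPContext,
    filter_by_tf_allowlist,
    occupancy_probability,
    read_pwm_file,
    read_snp_contexts_fasta,
    scan_snp,
    site_score,
)

BASES = "ACGT"


def _pwm(rows, **kw):
    return PWM(kw.pop("motif_id", "M"), kw.pop("tf_name", "TF"), np.array(rows), **kw)


def _context(ref_base, alt_base, left=None, right=None, snp_id="rs1"):
    rng = np.random.default_rng(0)
    left = left or "".join(rng.choice(list(BASES), 20))
    right = right or "".join(rng.choice(list(BASES), 20))
    return SNPContext(snp_id, ref_base, alt_base,
                      left + ref_base + right, left + alt_base + right)


class TestSiteScore:
    def test_uniform_pwm_scores_zero(self):
        pwm = _pwm([[0.25] * 4] * 5)
        assert site_score(pwm, "ACGTA") == pytest.approx(0.0)
        assert site_score(pwm, "TTTTT") == pytest.approx(0.0)

    def test_consensus_attains_maximum(self):
        pwm = _pwm([[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]])
        assert site_score(pwm, pwm.consensus) == pytest.approx(pwm.max_score)
        for w in ("AC", "CA", "GG", "CT"):
            assert site_score(pwm, w) <= pwm.max_score + 1e-12

    def test_hand_computed_two_position_scores(self):
        # rows (0.7,0.1,0.1,0.1); pseudocount 0.01, uniform background
        pwm = _pwm([[0.7, 0.1, 0.1, 0.1]] * 2, pseudocount=0.01)
        fA = (0.7 + 0.01 * 0.25) / 1.01
        fC = (0.1 + 0.01 * 0.25) / 1.01
        s_aa = 2 * np.log(fA / 0.25)
        s_ac = np.log(fA / 0.25) + np.log(fC / 0.25)
        assert site_score(pwm, "AA") == pytest.approx(s_aa, abs=1e-12)
        assert site_score(pwm, "AC") == pytest.approx(s_ac, abs=1e-12)

    def test_n_base_neutral(self):
        pwm = _pwm([[0.7, 0.1, 0.1, 0.1]] * 2)
        assert site_score(pwm, "AN") == pytest.approx(site_score(pwm, "AA") / 2)

    def test_invalid_base_named(self):
        pwm = _pwm([[0.25] * 4] * 3)
        with pytest.raises(ValueError, match="position 1"):
            site_score(pwm, "AXG")

    def test_zero_count_column_finite_with_pseudocount(self):
        pwm = _pwm([[1.0, 0.0, 0.0, 0.0]])
        assert np.isfinite(site_score(pwm, "T"))


class TestOccupancy:
    def test_half_at_consensus(self):
        pwm = _pwm([[0.8, 0.1, 0.05, 0.05]] * 6)
        assert occupancy_probability(pwm, pwm.consensus) == pytest.approx(0.5)

    def test_uniform_pwm_all_sites_optimal(self):
        pwm = _pwm([[0.25] * 4] * 4)
        for w in ("ACGT", "TTTT", "GGCC"):
            assert occupancy_probability(pwm, w) == pytest.approx(0.5)

    def test_closed_form_drop(self):
        # a window ln(3) below the optimum has occupancy exactly 1/4
        pwm = _pwm([[3 / 8, 1 / 8, 0.25, 0.25]], pseudocount=0.0)
        # score(A) - score(C) = ln(3); consensus is A
        assert occupancy_probability(pwm, "C") == pytest.approx(0.25)

    def test_bounded_by_half_and_positive(self):
        rng = np.random.default_rng(1)
        pwm = _pwm(rng.dirichlet(np.ones(4), size=8))
        for _ in range(50):
            w = "".join(rng.choice(list(BASES), 8))
            p = occupancy_probability(pwm, w)
            assert 0.0 < p <= 0.5

    def test_monotone_in_base_quality(self):
        pwm = _pwm([[0.6, 0.2, 0.15, 0.05]] * 3)
        # replacing a base by one with lower regularized frequency never raises p
        assert occupancy_probability(pwm, "AAA") >= occupancy_probability(pwm, "AAC")
        assert occupancy_probability(pwm, "AAC") >= occupancy_probability(pwm, "ACC")
        assert occupancy_probability(pwm, "ACC") >= occupancy_probability(pwm, "CCT")


class TestScanSnp:
    def test_equivalent_alleles_no_hit(self):
        # both flanks contain the consensus away from the SNP: delta 0
        pwm = _pwm([[0.9, 0.04, 0.03, 0.03]] * 4)  # consensus AAAA
        left = "C" * 16 + "AAAA"
        right = "C" * 20
        ctx = _context("G", "T", left=left, right=right)
        assert scan_snp(pwm, ctx) is None

    def test_allele_disrupting_consensus_is_hit(self):
        # consensus TATTA centred on the SNP; alt C breaks it
        pwm = _pwm(
            [
                [0.05, 0.05, 0.05, 0.85],
                [0.85, 0.05, 0.05, 0.05],
                [0.05, 0.05, 0.05, 0.85],
                [0.05, 0.05, 0.05, 0.85],
                [0.85, 0.05, 0.05, 0.05],
            ]
        )
        left = "G" * 18 + "TA"
        right = "TA" + "G" * 18
        ctx = _context("T", "C", left=left, right=right)
        hit = scan_snp(pwm, ctx)
        assert hit is not None
        assert hit.p_occ_ref == pytest.approx(0.5)
        assert hit.p_occ_ref > hit.p_occ_alt
        assert hit.delta > 0.2

    def test_delta_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(2)
        pwm = _pwm(rng.dirichlet(np.full(4, 0.5), size=6))
        ctx = _context("A", "G")

        def brute_max(seq, center_only):
            best = 0.0
            for start in range(0, 41 - 6 + 1):
                if center_only and not (start <= 20 < start + 6):
                    continue
                w = seq[start : start + 6]
                rc = w.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                best = max(
                    best,
                    occupancy_probability(pwm, w),
                    occupancy_probability(pwm, rc),
                )
            return best

        p_ref = brute_max(ctx.flank_ref, center_only=True)
        p_alt = brute_max(ctx.flank_alt, center_only=True)
        hit = scan_snp(pwm, ctx, p_min=0.0, delta_min=-1.0)
        assert hit.p_occ_ref == pytest.approx(p_ref, abs=1e-12)
        assert hit.p_occ_alt == pytest.approx(p_alt, abs=1e-12)
        assert hit.delta == pytest.approx(abs(p_ref - p_alt), abs=1e-12)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        pwm = _pwm(rng.dirichlet(np.ones(4), size=5))
        ctx = _context("A", "C")
        comp = str.maketrans("ACGT", "TGCA")
        rc = lambda s: s.translate(comp)[::-1]
        ctx_rc = SNPContext(
            "rs1rc",
            rc(ctx.ref_allele),
            rc(ctx.alt_allele),
            rc(ctx.flank_ref),
            rc(ctx.flank_alt),
        )
        h1 = scan_snp(pwm, ctx, p_min=0.0, delta_min=-1.0)
        h2 = scan_snp(pwm, ctx_rc, p_min=0.0, delta_min=-1.0)
        assert h1.p_occ_ref == pytest.approx(h2.p_occ_ref, abs=1e-12)
        assert h1.p_occ_alt == pytest.approx(h2.p_occ_alt, abs=1e-12)

    def test_hit_set_stable_across_threshold_range(self):
        """The reported hit does not flicker over thresholds 0.10-0.30."""
        pwm = _pwm(
            [
                [0.05, 0.05, 0.05, 0.85],
                [0.85, 0.05, 0.05, 0.05],
                [0.05, 0.05, 0.05, 0.85],
                [0.05, 0.05, 0.05, 0.85],
                [0.85, 0.05, 0.05, 0.05],
            ]
        )
        left = "G" * 18 + "TA"
        right = "TA" + "G" * 18
        strong = _context("T", "C", left=left, right=right)
        weak = _context("G", "T")  # no motif anywhere near the SNP
        for thr in np.arange(0.10, 0.31, 0.05):
            assert scan_snp(pwm, strong, p_min=thr, delta_min=thr) is not None
            assert scan_snp(pwm, weak, p_min=thr, delta_min=thr) is None

    def test_motif_longer_than_flank_rejected(self):
        pwm = _pwm([[0.25] * 4] * 42)
        with pytest.raises(ValueError):
            scan_snp(pwm, _context("A", "C"))


class TestAllowlist:
    def _hits(self):
        mk = lambda tf: OccupancyHit("rs1", "M", tf, "+", 0, 0.5, 0.1, 0.4)
        return [mk("GATA1"), mk("YY1"), mk("FOXA2")]

    def test_full_list_identity(self):
        hits = self._hits()
        assert filter_by_tf_allowlist(hits, {"GATA1", "YY1", "FOXA2"}) == hits

    def test_empty_list_passthrough_with_warning(self):
        hits = self._hits()
        with pytest.warns(UserWarning):
            assert filter_by_tf_allowlist(hits, set()) == hits

    def test_subset(self):
        out = filter_by_tf_allowlist(self._hits(), {"GATA1"})
        assert [h.tf_name for h in out] == ["GATA1"]


class TestParsers:
    def test_jaspar_roundtrip(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0001.1 GATA1\n"
            "A [ 10  2  0 20 ]\n"
            "C [  2  1  0  0 ]\n"
            "G [  5 15  0  0 ]\n"
            "T [  3  2 20  0 ]\n"
        )
        pwms = read_pwm_file(path, "jaspar")
        assert len(pwms) == 1
        assert pwms[0].tf_name == "GATA1"
        assert pwms[0].length == 4
        assert pwms[0].consensus == "AGTA"

    def test_transfac_parse(self, tmp_path):
        path = tmp_path / "m.transfac"
        path.write_text(
            "ID  YY1_motif\n"
            "BF  T00001 YY1\n"
            "P0      A      C      G      T\n"
            "01      4      1      1      1      A\n"
            "02      1      1      1      4      T\n"
            "03      1      4      1      1      C\n"
            "XX\n"
            "//\n"
        )
        pwms = read_pwm_file(path, "transfac")
        assert len(pwms) == 1
        assert pwms[0].length == 3
        assert pwms[0].consensus == "ATC"

    def test_context_fasta_pairs(self, tmp_path):
        left = "A" * 20
        right = "C" * 20
        path = tmp_path / "ctx.fa"
        path.write_text(
            f">rs9|ref|G\n{left}G{right}\n>rs9|alt|T\n{left}T{right}\n"
        )
        ctxs = read_snp_contexts_fasta(path)
        assert len(ctxs) == 1
        assert ctxs[0].ref_allele == "G" and ctxs[0].alt_allele == "T"

    def test_context_fasta_missing_pair_rejected(self, tmp_path):
        path = tmp_path / "ctx.fa"
        path.write_text(">rs9|ref|G\n" + "A" * 20 + "G" + "C" * 20 + "\n")
        with pytest.raises(ValueError, match="both ref and alt"):
            read_snp_contexts_fasta(path)

    def test_mismatched_center_rejected(self):
        with pytest.raises(ValueError):
            SNPContext("rs1", "A", "C", "G" * 41, "G" * 20 + "C" + "G" * 20)
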